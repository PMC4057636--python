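"""Power to detect a small-effect QTL: short inventory vs linked inventories.

A biallelic SNP (allele frequency 0.5) explains 0.9% of latent-trait
variance.  Each replicate simulates genotypes and item responses,
re-calibrates the measurement model, EAP-scores everyone, and tests the
score-genotype association at alpha = 1e-8.  Linking inventories helps
twice over: more persons can be phenotyped (larger n) and each person is
measured more reliably (higher score-trait correlation rho), and the 1-df
test's non-centrality is approximately n * q2 * rho.
"""

import numpy as np

import traitlink as tl
from traitlink.power_study import (
    PowerScenario,
    analytic_power,
    compare_schemes,
    run_power_scenario,
)

rng = np.random.default_rng(7)
bank = {
    f"q{j}": tl.ItemParameters(
        float(np.exp(0.3 * rng.standard_normal())),
        np.linspace(-2.0, 2.0, 4) + rng.uniform(-0.5, 0.5),
    )
    for j in range(24)
}
items = list(bank)
q2, alpha, reps = 0.009, 1e-8, 30

short = PowerScenario(
    "12 items, n=1200", {i: bank[i] for i in items[:12]}, [(1.0, items[:12])],
    tl.SnpDesign(maf=0.5, q2=q2, n=1200), alpha=alpha, n_reps=reps, seed=1,
)
linked = PowerScenario(
    "24 linked items, n=4000", bank, [(1.0, items)],
    tl.SnpDesign(maf=0.5, q2=q2, n=4000), alpha=alpha, n_reps=reps, seed=2,
)

estimates = [run_power_scenario(short), run_power_scenario(linked)]
for row in compare_schemes(estimates):
    pred = analytic_power(row["n"], q2, row["reliability"], alpha)
    print(f"{row['scheme']:24s} power {row['power']:.2f} (SE {row['se']:.2f}), "
          f"score reliability {row['reliability']:.2f}, analytic approx {pred:.2f}")
print("\nThe linked design wins through larger n and higher measurement reliability.")
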