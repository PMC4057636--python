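# Methods

This note records the models implemented in `traitlink`, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical choices that affect results.

## Measurement model

All items follow the logistic graded response model (GRM). For item *k*
with discrimination *a_k* > 0 and strictly increasing thresholds
*b_{k1} < … < b_{k,K−1}*:

    P(Y_k ≥ c | θ) = logistic(a_k (θ − b_{kc})),   c = 1 … K−1,

with category probabilities as successive differences. Dichotomous items
are the K = 2 special case (a 2PL model); one family covers Likert and
yes/no inventories so they can be linked on one metric. 1PL/3PL,
multidimensional and nonparametric models are out of scope.

**Calibration** is marginal maximum likelihood: Bock–Aitkin EM over a
standard-normal latent prior (the single-sample identification), with the
marginal likelihood integrated on 61 equally spaced nodes on [−6, 6]
carrying normal weights. The M-step maximizes each item's expected
complete-data log-likelihood with L-BFGS-B on (log a, b₁, log-increments),
started at the current parameters, so the marginal log-likelihood is
monotone non-decreasing across cycles (asserted in the tests). EM stops
when the largest parameter change falls below 1e-4 (500-cycle cap; a
non-converged fit is returned flagged, with a warning). Starting values:
a = 1 and thresholds at inverse-normal cumulative category proportions.

Categories observed fewer than 5 times are collapsed into the adjacent
category (with a logged warning) to avoid degenerate thresholds; the code
map is stored in the calibration and applied again at scoring time. An
item with a single observed category raises an error naming the item.
Reverse-keyed items are recoded at read time from the item key, so the
engine always sees positively keyed codes.

**Scoring** is EAP on the same quadrature: posterior mean and SD of θ
given the person's observed items only, i.e. missing items are skipped
under a missing-at-random assumption. A person with no observed items is
returned at the prior (mean 0, SD 1) and flagged via `n_items = 0`. The
61-node grid reproduces a 10⁴-point trapezoid integration within 1e-4 on
the cases tested.

## Linking

Inventories are linked by one *concurrent* calibration per cohort: the GRM
is fitted jointly to the union of items, with each person contributing only
their observed items. This requires every pair of inventories to be
connected (directly or transitively) through bridge persons; a
disconnected design is an error listing the components. The alternative —
separate calibration plus a mean/sigma or Stocking–Lord transformation —
was deliberately not implemented: with bridge subsamples and
missing-at-random handling, the concurrent fit is the natural estimator
and avoids a second layer of transformation error. This is the single
largest interpretive choice in the package. Scores for a cohort always
come from the richest available calibration (all linked inventories).

Diagnostics: (i) local independence — EAP scores for one item set under
the combined vs a single-inventory calibration should correlate near 1;
(ii) TIC additivity — under one latent dimension the test information of
the pooled instrument should be close to the sum of the separately
calibrated parts (reported as max relative deviation where the combined
curve exceeds 10% of its peak); (iii) cross-calibration correlations —
scoring one sample under another cohort's item parameters. Item screening
for related scales ranks candidates by pairwise-complete Pearson
correlation with the target scale's sum score; raw ordinal codes are used
rather than polychoric correlations for determinism and simplicity, and
ties break by item id.

## Measurement invariance across cohorts

The hierarchical model is a probit-link graded model (probit chosen for
the MCMC module; the ±1.7 discrimination scale difference vs the logistic
engine is a known cross-module caveat, and the synthetic generator can
produce either family). Cohort-specific thresholds and log-discriminations
are level-1 parameters, normally distributed around level-2 means with one
deviation variance per parameter type. Cohorts have their own trait means
and variances.

Identification, enforced by recentering/rescaling after every sweep along
likelihood-invariant directions: the product of each cohort's
discriminations is 1 (fixes the scale, making cohort trait variances
estimable); each cohort's mean threshold equals the level-2 mean threshold
(cohorts may differ in trait mean, and single items may drift, but the
average difficulty is common); and the level-2 mean threshold is 0 (pins
the overall location — without it the trait origin is held only by the
priors and wanders).

Priors (weakly informative defaults): level-2 thresholds N(0, 2²),
level-2 log-discriminations N(0, 1), deviation variances IG(1, 0.1),
cohort means N(0, 2²), cohort variances IG(1, 1). Sampling is
Metropolis-within-Gibbs: vectorized random-walk MH for person traits and
for each cohort-item parameter block, conjugate updates for level-2 means,
deviation variances and cohort moments; proposal steps adapt toward
standard acceptance rates during burn-in. Defaults: 6000 sweeps, 1000
burn-in, thinning 1, fixed seed — all overridable; the tests and the demo
pipeline use short chains (≈1200–1500 sweeps) which mix adequately at
their problem sizes (split-R̂ of cohort means is computed every run and a
value above 1.1 flags the fit with a warning).

**DIF Bayes factors.** For each item, every cohort-level deviation (each
threshold and the log-discrimination) gets a Savage–Dickey density ratio —
Gaussian-kernel posterior density at zero over the marginal prior density
at zero (analytic under the inverse-gamma variance prior) — and the ratios
multiply over the item's parameters and cohorts. At least 500 retained
draws are required. Classification: BF < 0.3 ⇒ DIF, BF > 3 ⇒ invariant,
between ⇒ inconclusive. This construction is an approximation chosen for
transparency; the product over cohorts assumes approximate posterior
independence, which makes the evidence scale multiplicative in cohort
count — classifications are robust to this, the raw magnitudes should not
be over-interpreted.

Cohort moments report posterior means/SDs of μ_j and σ²_j and the
between-cohort variance (posterior mean of the per-draw population
variance of the cohort means).

## Twin ADE meta-analysis

Per cohort, a saturated model per sex-by-zygosity group (MZM, DZM, MZF,
DZF, DOS): one mean, one variance and one covariance per group, one age
slope shared across groups — 16 parameters with a DOS group, 13 without.
The likelihood is full-information bivariate normal; pairs with one
missing member contribute their univariate marginal. Correlations are
standardized covariances with Fisher-z 95% confidence intervals on the
complete-pair count.

The pooled stage fits, to a table of correlations r_g with pair counts
N_g, the ADE expectations

    MZ: h² + d²,   same-sex DZ: ½h² + ¼d²,
    DOS: ½ h_m h_f + ¼ d_m d_f   (or a free parameter),

parameterized in path coefficients (h, d ≥ 0; proportions are squares, so
nonnegativity is built in). Model labels implement the test sequence:
`base` (sex-specific paths, free DOS), `no-qualitative` (DOS at its
expectation), `no-quantitative` (sex-equal paths; `free_dos=True` keeps
the qualitative effect), `no-dominance` (d = 0). The sequence tests
qualitative sex effects (Δdf = 1), quantitative sex effects (Δdf = 2,
carrying the previous decision forward), then dominance; sex-difference
steps use α = 0.01, the dominance step α = 0.05.

**Discrepancy function.** The default is the normal-theory ML fit function
for each group's 2×2 correlation matrix, Σ_g N_g [ln((1−ρ_g²)/(1−r_g²)) +
2(1−r_g ρ_g)/(1−ρ_g²) − 2]. A Fisher-z weighted least squares alternative,
Σ_g (N_g−3)(z(r_g) − z(ρ_g))², is available via `discrepancy="fisher-z"`.
Both are minimized by multi-start bounded quasi-Newton (5 fixed starts)
with a high-precision simplex polish, give χ² statistics linear in the
weights, and respect nesting exactly. They produce essentially identical
parameter estimates; the ML form is the default because it is the fit
function an SEM package evaluates on correlation matrices, so its χ² values
are comparable to published SEM discrepancies, whereas Fisher-z WLS χ²
values run noticeably lower on the same tables. Simulation (in the test
suite) shows both give dominance-test type-I rates near nominal at
consortium-scale pair counts. Pair counts as printed (including
single-twin pairs) are used as weights.

## Synthetic data

The generator realizes the study design the pipeline targets: several
cohorts with their own trait means/variances (standard normal in the
reference cohort), one or more inventories of graded items, a bridge
subsample — an exact per-cohort fraction, chosen independently of the
trait, so the induced missingness is missing-at-random by construction —
and cohort-level item-parameter deviations: independent normal noise with
SD `dif_sd` on thresholds and log-discriminations (thresholds re-sorted),
plus, for designated DIF items, a ±`dif_shift` threshold shift alternating
in sign across cohorts (so the shift averages out and is not absorbed by
the identification constraints — a same-sign shift in *all* cohorts is
indistinguishable from a harder item). Twin pairs are bivariate normal per
group with the ADE-implied correlation (cross-sex sharing scaled by a
single genetic-correlation multiplier ≤ 1 to induce qualitative sex
effects); an age effect and single-twin missingness are optional. SNP
genotypes are Hardy–Weinberg draws whose allelic effect is set to explain
exactly q² of unit latent variance in expectation.

Not emulated: real inventory content, selection/ascertainment into
cohorts, repeated measures, multi-SNP architecture or LD, family structure
in the power study (association is OLS on unrelateds), and any
non-ignorable missingness. Passing tests therefore certify the statistical
machinery under the stated generating model, not robustness to those
real-data features.

All generators are deterministic given a seed; the whole-study and
pipeline entry points spawn per-stage substreams from one seed
(`numpy` `SeedSequence`).

## Power study

Each replicate redraws genotypes, traits and item responses, re-calibrates
(matching a real analysis chain, where item parameters come from the same
sample), EAP-scores, and tests the score–genotype slope by OLS/Wald at
α = 10⁻⁸. Power is compared with the non-centrality approximation
P(χ²₁(n·q²·ρ) > crit), with ρ the realized squared score–trait
correlation. Because published empirical item parameters are not
available, scenarios use the synthetic bank (log-normal(0, 0.3²)
discriminations, thresholds spread over [−2, 2]); the package asserts the
*ordering and calibration* of power — linked, larger-n phenotyping beats a
short inventory at small n; a null SNP yields no hits — not any particular
published percentage.

## Problem sizes used in the checks

Chosen as the package's own verification budget: meta-analysis checks run
on the packaged 27-correlation tables (deterministic, seconds); IRT
recovery at n = 2000, 12 five-category items, 20 replicates; linking
quality at n = 3000 with two 12-item inventories and a 30% bridge; DIF
calibration over 10 hierarchical fits of 4 cohorts × 1000 persons × 12
three-category items with ~1200-sweep chains; twin-component recovery over
20 replicates at the packaged table's pair counts; power at n = 4000 (24
linked items) vs n = 1200 (12 items), q² = 0.009, 40 replicates.

## Known limitations

* The concurrent-calibration linking strategy is asserted by diagnostics,
  not compared against transformation-based equating.
* The DIF Bayes factor is a Savage–Dickey approximation with a
  posterior-independence aggregation; only the 0.3/3 classifications are
  validated, not the BF magnitudes.
* Probit (MCMC) and logistic (MML) modules sit on scales differing by
  ≈1.7 in discrimination; cross-module parameter comparisons must apply
  that factor.
* The correlation-level meta-analysis treats printed pair counts as
  precision weights; with many incomplete pairs this mildly overstates
  precision.
* Cohort trait variances from the hierarchical model are posterior means;
  with strong skew they can differ from posterior modes.
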