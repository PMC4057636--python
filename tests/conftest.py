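"""Shared fixtures: small simulated studies generated at test time."""

import numpy as np
import pytest

import traitlink as tl


@pytest.fixture(scope="session")
def item_bank_12():
    """12 well-behaved 5-category items with unit-scale discriminations."""
    rng = np.random.default_rng(42)
    bank = {}
    for j in range(12):
        a = float(np.exp(0.3 * rng.standard_normal()))
        th = np.linspace(-1.5, 1.5, 4) + rng.uniform(-0.3, 0.3)
        bank[f"i{j + 1}"] = tl.ItemParameters(a, th)
    return bank


@pytest.fixture(scope="session")
def calibrated_sample(item_bank_12):
    """One simulated sample (n=2000) with its MML calibration."""
    traits = tl.gen_latent_traits(2000, 0.0, 1.0, seed=7)
    resp = tl.gen_item_responses(traits, item_bank_12, seed=8)
    calib = tl.calibrate_mml(resp)
    return {"traits": traits, "responses": resp, "calibration": calib}


@pytest.fixture(scope="session")
def bridge_study():
    """Two-inventory bridge design used by the linking tests."""
    config = tl.SimulationConfig(
        n_cohorts=1,
        persons_per_cohort=1500,
        cohort_trait_means=[0.0],
        cohort_trait_variances=[1.0],
        inventories=[tl.InventorySpec("A", 8, 4), tl.InventorySpec("B", 8, 4)],
        bridge_fraction=0.3,
        seed=11,
    )
    return tl.simulate_study(config)
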