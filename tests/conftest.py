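"""Shared synthetic-cohort fixtures.

The heavy end-to-end runs (the dlbcl-like preset and its variants) are
session-scoped so the signature-recovery, stratification, and expression
tests all reuse one simulation per condition.
"""

import pytest

from ashmscan.pipeline import simulate_and_scan
from ashmscan.simulate import SyntheticCohortConfig

TEST_SEED = 0


@pytest.fixture(scope="session")
def dlbcl_run():
    """The dlbcl-like preset: 40 samples, 500 genes, 10% aSHM genes, coupling on."""
    config = SyntheticCohortConfig(seed=TEST_SEED)
    return config, *simulate_and_scan(config)


@pytest.fixture(scope="session")
def coupling_off_run():
    """Same preset with the expression-mutation coupling switched off."""
    config = SyntheticCohortConfig(seed=TEST_SEED, expression_coupling=0.0)
    return config, *simulate_and_scan(config)


@pytest.fixture(scope="session")
def null_run():
    """No-signature cohort: uniform placement, neutral motif/C:G factors,
    transitions at the random 1-in-3 rate, ~10 SNVs per region over 200 regions."""
    config = SyntheticCohortConfig(
        seed=TEST_SEED,
        n_samples=20,
        n_genes=200,
        frac_ashm_genes=1.0,
        ashm_rate_multiplier=125.0,
        positional_decay_mean=None,
        motif_multiplier=1.0,
        cg_bias=1.0,
        transition_bias=1.0 / 3.0,
        expression_coupling=0.0,
        rearrangement_rate=0.0,
    )
    return config, *simulate_and_scan(config, use_expression=False, use_rearrangements=False,
                                      cap_at_half=False)
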