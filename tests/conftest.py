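import numpy as np
import pandas as pd
import pytest

from adipomr import SimConfig, make_study


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """A scaled-down study: same structure, tractable for per-test reuse."""
    return SimConfig(
        n_gwas=4000,
        n_subcohort=400,
        n_variants=80,
        n_variants_rare=10,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    return make_study(small_config)


@pytest.fixture(scope="session")
def small_cohort(small_study):
    return small_study[0]


@pytest.fixture(scope="session")
def small_truth(small_study):
    return small_study[1]


def make_summary_stats(
    n_variants: int,
    true_effect: float,
    seed: int,
    se_exposure: float = 0.002,
    se_outcome: float = 0.01,
    pleiotropy=None,
):
    """Simulated two-sample summary statistics for MR estimator tests.

    True per-variant exposure effects are positive (effect-allele coding);
    outcome betas are ``true_effect * beta_exp + pleiotropy`` plus noise.
    """
    from adipomr import SummaryAssoc

    rng = np.random.default_rng(seed)
    bx_true = rng.uniform(0.05, 0.15, n_variants)
    delta = np.zeros(n_variants) if pleiotropy is None else np.asarray(pleiotropy, dtype=float)
    bx = bx_true + rng.normal(0, se_exposure, n_variants)
    by = true_effect * bx_true + delta + rng.normal(0, se_outcome, n_variants)
    return [
        SummaryAssoc(
            id=f"v{j}",
            beta_exposure=float(bx[j]),
            se_exposure=se_exposure,
            beta_outcome=float(by[j]),
            se_outcome=se_outcome,
        )
        for j in range(n_variants)
    ]
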