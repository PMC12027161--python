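import numpy as np
import pandas as pd
import pytest

from loadrisk.synthetic import SimParams, simulate_cohort, simulate_summary_stats


@pytest.fixture(scope="session")
def small_cohort():
    """A 300-individual cohort with default (signal-bearing) weights."""
    params = SimParams(n_cases=69, n_controls=231, n_snps=40, seed=11)
    return simulate_cohort(params)


@pytest.fixture(scope="session")
def tiny_stats():
    return simulate_summary_stats(n_snps=8, beta_sd=0.1, seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def toy_genotypes():
    """5 individuals x 4 SNPs, no missingness, hand-checkable."""
    return pd.DataFrame(
        {
            "snpA": [0.0, 1.0, 2.0, 1.0, 0.0],
            "snpB": [2.0, 2.0, 2.0, 2.0, 1.0],
            "snpC": [0.0, 0.0, 1.0, 0.0, 0.0],
            "snpD": [1.0, 0.0, 2.0, 1.0, 1.0],
        },
        index=pd.Index([f"i{k}" for k in range(1, 6)], name="individual_id"),
    )
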