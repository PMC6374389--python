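import numpy as np
import pandas as pd
import pytest

import sleepmet as sm
from sleepmet.simulate import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def manifest():
    return sm.default_manifest()


@pytest.fixture(scope="session")
def small_cohort(manifest):
    """Study-sized cohort: 11 per group, default effects and correlations."""
    cfg = SimConfig(manifest=manifest, n_per_group=11, seed=42)
    table, design, covs = simulate_cohort(cfg)
    return table, design, covs


@pytest.fixture(scope="session")
def large_cohort(manifest):
    """n = 1000 per group, for checking convergence of ratios/correlations."""
    cfg = SimConfig(manifest=manifest, n_per_group=1000, seed=7)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def sr_contrast(small_cohort):
    """Pooled SR vs CT labels + concentrations from the small cohort."""
    table, design, _ = small_cohort
    conc = table.study_concentrations()
    sr = [s for s in conc.index if design.table.at[s, "procedure"] == "SR"]
    ct = [s for s in conc.index if design.table.at[s, "procedure"] == "CT"]
    ids = ct + sr
    labels = pd.Series([1 if s in sr else 0 for s in ids], index=ids)
    return conc.loc[ids], labels


def rng_matrix(seed, n, p):
    return np.random.default_rng(seed).standard_normal((n, p))
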