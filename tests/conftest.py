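import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import finelocus as fl
from finelocus.simulate import CohortSpec

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def rin3_variants():
    """The packaged published RIN3 variant count table (18 rows)."""
    return fl.rin3_variant_table()


@pytest.fixture(scope="session")
def rin3_by_protein(rin3_variants):
    return {v.protein_change: v for v in rin3_variants if v.protein_change}


@pytest.fixture()
def rng():
    return np.random.default_rng(20150220)


@pytest.fixture(scope="session")
def null_cohort():
    """A null-model cohort (all ORs = 1): 1000 cases + 1000 controls."""
    spec = CohortSpec(
        n_cases=1000,
        n_controls=1000,
        seed=42,
        common_variant_or=1.0,
        rare_variants=[],
    )
    gm, truth = fl.simulate_cohort(spec)
    return spec, gm, truth


@pytest.fixture(scope="session")
def default_cohort():
    """A cohort under the default study conditions (risk haplotype + rares)."""
    spec = CohortSpec(n_cases=1000, n_controls=1000, seed=7)
    gm, truth = fl.simulate_cohort(spec)
    return spec, gm, truth
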