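import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from htrx import HaplotypePanel, PhenotypeTable

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def tiny_diploid_panel():
    """Two diploid samples over two SNPs."""
    return HaplotypePanel.from_strings(
        [("10", "11"), ("00", "01")], sample_ids=["a", "b"]
    )


@pytest.fixture
def exhaustive_panel():
    """All 2**u haploid haplotypes, one sample each (u=3)."""
    haps = [format(i, "03b") for i in range(8)]
    return HaplotypePanel.from_strings(haps)


def make_linear_pheno(rng, n, beta, F, noise=1.0, covariates=None):
    y = F @ np.asarray(beta) + noise * rng.standard_normal(n)
    if covariates is not None:
        y = y + covariates.sum(axis=1)
    return PhenotypeTable(y, covariates, "linear")
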