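import numpy as np
import pytest

from ginkgopop.genotypes import GenotypeMatrix
from ginkgopop.models import DemographicModel, SampleConfig


def make_matrix(
    geno,
    popmap=None,
    positions=None,
    chrom="chr1",
    chrom_length=None,
    samples=None,
) -> GenotypeMatrix:
    """Build a GenotypeMatrix from a plain (samples x sites) array."""
    geno = np.asarray(geno, dtype=np.int8)
    n, m = geno.shape
    samples = samples or [f"s{i}" for i in range(n)]
    positions = (
        np.asarray(positions, dtype=np.int64)
        if positions is not None
        else np.arange(1, m + 1, dtype=np.int64)
    )
    length = chrom_length or (int(positions.max()) if m else 1)
    return GenotypeMatrix(
        geno,
        positions,
        np.array([chrom] * m, dtype=object),
        samples,
        dict(popmap or {}),
        {chrom: length},
    )


@pytest.fixture
def single_deme_model() -> DemographicModel:
    return DemographicModel(demes=("A",), sizes={"A": 50_514.0})


@pytest.fixture
def two_deme_split_model() -> DemographicModel:
    """Two demes diverged long ago (deep differentiation)."""
    from ginkgopop.models import Split

    m = DemographicModel(
        demes=("P1", "P2"),
        sizes={"P1": 28_456.0, "P2": 28_456.0},
        splits=[Split(515_780.0, "P2", "P1")],
    )
    m.validate()
    return m


@pytest.fixture
def small_samples() -> SampleConfig:
    return SampleConfig({"A": 2})
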