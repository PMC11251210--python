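import numpy as np
import pytest

from svedne import GenotypeMatrix, SimConfig, VariantRecord, simulate


def make_matrix(columns, positions=None, chrom="chr1", samples=None):
    """Build a GenotypeMatrix from dosage columns (one sequence per variant)."""
    cols = [np.asarray(c, dtype=np.int8) for c in columns]
    n = len(cols[0])
    if positions is None:
        positions = [100 * (j + 1) for j in range(len(cols))]
    variants = [
        VariantRecord(chrom=chrom, pos=int(p), ref="A", alt="T") for p in positions
    ]
    if samples is None:
        samples = [f"s{i}" for i in range(n)]
    return GenotypeMatrix(variants=variants, samples=samples, dosage=np.stack(cols, axis=1))


@pytest.fixture
def matrix_factory():
    return make_matrix


@pytest.fixture(scope="session")
def sim_panel():
    """Equilibrated random-mating panel on a frozen seed (used as the committed
    simulation fixture for LD-structure checks)."""
    return simulate(SimConfig(seed=7))
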