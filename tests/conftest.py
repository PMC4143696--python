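import numpy as np
import pytest

from roblogit.glm import DesignMatrix
from roblogit.ingest import MISSING, GenotypeMatrix, PhenotypeRecord, VariantRecord


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def toy_design(rng):
    """A well-conditioned 50 x 2 logistic problem with known coefficients."""
    n = 50
    x = rng.normal(size=n)
    X = DesignMatrix(np.column_stack([np.ones(n), x]), ["intercept", "x"])
    eta = -0.3 + 0.9 * x
    y = (rng.uniform(size=n) < 1.0 / (1.0 + np.exp(-eta))).astype(float)
    return X, y


def make_genotypes(dosages, ids=None, variant_ids=None):
    dosages = np.asarray(dosages, dtype=np.int8)
    n, m = dosages.shape
    ids = ids or [f"I{i}" for i in range(n)]
    variant_ids = variant_ids or [f"V{j}" for j in range(m)]
    variants = [
        VariantRecord(variant_id=v, chromosome="3", position=100 * (j + 1))
        for j, v in enumerate(variant_ids)
    ]
    return GenotypeMatrix(dosages, ids, variants)


@pytest.fixture
def filter_fixture():
    """Hand-traced cohort: each filter criterion removes exactly one item.

    6 individuals x 5 variants, run at missing_rate_threshold=0.25 (with only
    4 post-(b) variants a single missing call is already 25%, so a 5% cutoff
    could never leave a missing call for criterion (d) on a matrix this
    small).  P6 has no complete measurement -> (a) drops P6.  V2 is
    monomorphic among P1..P5 -> (b) drops V2.  P5 misses 2 of the 4
    remaining genotypes (50% > 25%) -> (c) drops P5.  P2's single missing
    call (25%, not strictly above the threshold) survives to (d), which
    drops V4.  Final: P1-P4 x {V1, V3, V5}.
    """
    phenotypes = [
        PhenotypeRecord("P1", 1, 40.0, "F", "no", 1),
        PhenotypeRecord("P2", 0, 55.0, "M", "no", 1),
        PhenotypeRecord("P3", 1, 62.0, "F", "yes", 1),
        PhenotypeRecord("P4", 0, 48.0, "M", "no", 1),
        PhenotypeRecord("P5", 0, 70.0, "F", "no", 1),
        PhenotypeRecord("P6", None, 33.0, "M", "no", 1),  # no complete record
    ]
    M = MISSING
    #       V1 V2 V3 V4 V5
    dosages = [
        [0, 1, 2, 1, 0],  # P1
        [1, 1, 0, M, 1],  # P2  (V4 missing survives to (d))
        [2, 1, 1, 0, 0],  # P3
        [0, 1, 0, 1, 2],  # P4
        [1, 1, M, 0, M],  # P5  (2 of 4 post-(b) genotypes missing -> (c))
        [0, 1, 1, 1, 1],  # P6
    ]
    genotypes = make_genotypes(
        dosages, ids=[f"P{i}" for i in range(1, 7)], variant_ids=[f"V{j}" for j in range(1, 6)]
    )
    return phenotypes, genotypes
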