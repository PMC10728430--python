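import numpy as np
import pandas as pd
import pytest

from bwtpred.imprinting import H19_ICR1, KCNQ1OT1_ICR2
from bwtpred.io import ProbeBetaMatrix


def make_matrix(records, samples):
    """Build a ProbeBetaMatrix from (probe_id, chrom, pos, *betas) tuples."""
    probes = pd.DataFrame(
        [(r[0], r[1], r[2]) for r in records],
        columns=["probe_id", "chrom", "pos"],
    ).set_index("probe_id")
    beta = pd.DataFrame(
        [r[3:] for r in records],
        index=probes.index, columns=samples, dtype=float,
    )
    return ProbeBetaMatrix(probes, beta)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def tiny_matrix():
    """Two H19 probes, one ICR2 probe, one background probe; two samples."""
    return make_matrix(
        [
            ("p1", "chr11", 2_020_000, 0.4, 0.8),
            ("p2", "chr11", 2_024_000, 0.6, 0.9),
            ("p3", "chr11", 2_721_500, 0.5, 0.2),
            ("p4", "chr2", 1_000_000, 0.1, 0.9),
        ],
        ["s1", "s2"],
    )


@pytest.fixture
def random_matrix(rng):
    """50 random probes across several chromosomes, 8 samples."""
    chroms = rng.choice(["chr1", "chr2", "chr11", "chrX"], size=50)
    pos = rng.choice(np.arange(1, 10_000_000), size=50, replace=False)
    records = [
        (f"cg{i:03d}", chroms[i], int(pos[i]), *rng.uniform(0, 1, 8))
        for i in range(50)
    ]
    return make_matrix(records, [f"s{j}" for j in range(8)])


@pytest.fixture
def h19_region():
    return H19_ICR1


@pytest.fixture
def icr2_region():
    return KCNQ1OT1_ICR2
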