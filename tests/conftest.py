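import numpy as np
import pytest

from poolassoc.data import PoolDesign, PooledCounts


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def design4():
    """Two control + two case pools, 10 chromosomes each."""
    return PoolDesign(
        pool_ids=("c1", "c2", "t1", "t2"),
        group=("control", "control", "case", "case"),
        s=10,
    )


def make_counts(major, depth, pool_ids, snp_ids=None, ref=None, alt=None):
    major = np.atleast_2d(np.asarray(major, dtype=float))
    depth = np.atleast_2d(np.asarray(depth, dtype=float))
    n = major.shape[0]
    if snp_ids is None:
        snp_ids = [f"snp{i+1}" for i in range(n)]
    return PooledCounts(
        snp_id=np.array(snp_ids, dtype=object),
        chrom=np.array(["chr1"] * n, dtype=object),
        pos=np.arange(1, n + 1) * 10,
        ref_allele=np.array(ref if ref is not None else ["A"] * n, dtype=object),
        alt_allele=np.array(alt if alt is not None else ["G"] * n, dtype=object),
        major_reads=major,
        depth=depth,
        pool_ids=tuple(pool_ids),
    )


@pytest.fixture
def counts4(design4):
    """Two SNPs on the 4-pool design."""
    return make_counts(
        major=[[45, 80, 30, 60], [48, 88, 39, 68]],
        depth=[[50, 90, 40, 70], [50, 90, 40, 70]],
        pool_ids=design4.pool_ids,
    )
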