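"""SNP and pool filtering applied before association testing.

Four screens are applied to the raw count table:

1. a minimum total read depth per group (default >= 8);
2. a minor-allele-frequency partition into common and rare variants;
3. for rare variants only, a random-error screen -- sequencing errors
   should scatter minor reads across pools in proportion to depth,
   whereas a genuine rare variant concentrates them in the few pools
   containing carriers;
4. for the binomial/Fisher test only, a chromosome-coverage filter that
   keeps a pool only when its read depth gives a high probability of
   sampling at least ``k`` of the ``s`` chromosomes in the pool.

The coverage probability is the classical occupancy problem: ``R`` reads
land independently and uniformly on ``s`` chromosomes and we ask for the
distribution of the number of distinct chromosomes hit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .data import PooledCounts, PoolDesign

__all__ = [
    "FilterReport",
    "min_depth_filter",
    "maf_partition",
    "random_error_screen",
    "occupancy_pmf",
    "coverage_probability",
    "min_depth_for_coverage",
    "chromosome_coverage_filter",
    "apply_filters",
]

COMMON = "common"
RARE = "rare"
DEGENERATE = "degenerate"


@dataclass
class FilterReport:
    """Per-SNP record of every filtering decision."""

    snp_id: str
    passed_depth: bool = True
    maf_class: str = ""
    error_screen_p: float = float("nan")
    called_true_snp: bool = False
    valid_pools: np.ndarray | None = None
    reason: str = ""


def min_depth_filter(
    counts: PooledCounts,
    design: PoolDesign,
    min_depth: int = 8,
    per_pool: bool = False,
) -> np.ndarray:
    """Boolean pass mask for the minimum-depth filter.

    By default the summed depth within each group (case, control) must
    reach ``min_depth``, mirroring a site-level caller filter; with
    ``per_pool=True`` every individual pool must reach it.
    """
    if min_depth < 0:
        raise ValueError("min_depth must be >= 0")
    if per_pool:
        return np.all(counts.depth >= min_depth, axis=1)
    ok = np.ones(counts.n_snps, dtype=bool)
    for mask in (design.case_mask, design.control_mask):
        ok &= counts.depth[:, mask].sum(axis=1) >= min_depth
    return ok


def maf_partition(counts: PooledCounts, maf_threshold: float = 0.05) -> np.ndarray:
    """Classify each SNP as 'common' or 'rare' by its overall MAF.

    The MAF is the pooled minor-read fraction over all pools; the
    boundary is inclusive on the common side.  SNPs with zero total depth
    are 'degenerate'.
    """
    if not 0 < maf_threshold < 0.5:
        raise ValueError("maf_threshold must be in (0, 0.5)")
    total = counts.depth.sum(axis=1)
    minor = counts.minor_reads.sum(axis=1)
    out = np.full(counts.n_snps, RARE, dtype=object)
    with np.errstate(invalid="ignore", divide="ignore"):
        maf = np.where(total > 0, minor / np.maximum(total, 1), np.nan)
    out[maf >= maf_threshold] = COMMON
    out[total == 0] = DEGENERATE
    return out


def random_error_screen(
    minor_reads: np.ndarray,
    depth: np.ndarray,
    n_tests: int,
    alpha: float = 0.05,
    n_mc: int = 10_000,
    rng: np.random.Generator | None = None,
) -> tuple[float, bool]:
    """Test one rare SNP's minor reads against a random-error null.

    Under the null, the SNP's minor reads are sequencing errors and land
    on pools in proportion to pool depth.  The statistic is the Pearson
    chi-square of minor-read counts against that depth-proportional
    expectation; its null distribution is obtained by Monte-Carlo
    multinomial resampling (add-one p-value, so never exactly 0).  When
    the observed statistic exceeds every resampled one the p-value is
    refined by the chi-square(m-1) upper tail, capped at the Monte-Carlo
    floor, so Bonferroni thresholds below the floor remain decidable.

    Returns ``(p_value, called_true_snp)`` where a call additionally
    requires at least one pool with more than two minor reads.
    """
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    rng = np.random.default_rng(rng)
    minor = np.asarray(np.rint(minor_reads), dtype=int)
    depth = np.asarray(depth, dtype=float)
    use = depth > 0
    m = int(minor[use].sum())
    if m == 0:
        return 1.0, False
    probs = depth[use] / depth[use].sum()
    expected = m * probs
    stat = float(((minor[use] - expected) ** 2 / expected).sum())

    # batched sampling with early stopping: once the tail clearly holds
    # plenty of mass the p-value is far from any Bonferroni threshold
    # and further draws cannot change the decision
    n_ge, n_drawn = 0, 0
    for batch in (min(500, n_mc), n_mc - min(500, n_mc)):
        if batch <= 0:
            continue
        draws = rng.multinomial(m, probs, size=batch)
        null_stats = ((draws - expected) ** 2 / expected).sum(axis=1)
        n_ge += int((null_stats >= stat - 1e-12).sum())
        n_drawn += batch
        if n_ge >= 10:
            break
    p = (1 + n_ge) / (1 + n_drawn)
    if n_ge == 0:
        # tail refinement beyond Monte-Carlo resolution
        p = min(p, float(stats.chi2.sf(stat, df=use.sum() - 1)))
    called = (p < alpha / n_tests) and (minor.max() > 2)
    return p, called


def occupancy_pmf(R: int, s: int) -> np.ndarray:
    """Distribution of the number of distinct chromosomes hit by R reads.

    Exact dynamic programme over reads: after each uniform, independent
    read the count of distinct chromosomes hit either stays (prob t/s) or
    grows by one (prob (s-t)/s).  Returns probabilities for t = 0..s.
    """
    if R < 0 or s < 1:
        raise ValueError("need R >= 0 and s >= 1")
    f = np.zeros(s + 1)
    f[0] = 1.0
    stay = np.arange(s + 1) / s
    grow = 1.0 - stay
    for _ in range(int(R)):
        nf = f * stay
        nf[1:] += f[:-1] * grow[:-1]
        f = nf
    return f


def coverage_probability(R: int, s: int, k: int) -> float:
    """P(at least k of s chromosomes receive >= 1 of R uniform reads)."""
    if not 1 <= k <= s:
        raise ValueError("need 1 <= k <= s")
    if R < 0:
        raise ValueError("R must be >= 0")
    if R < k:
        return 0.0
    pmf = occupancy_pmf(R, s)
    return float(pmf[k:].sum())


def min_depth_for_coverage(s: int, k: int, prob: float) -> int:
    """Smallest read depth R with coverage_probability(R, s, k) > prob.

    coverage_probability is non-decreasing in R, so a bracketed binary
    search is exact; used to apply the coverage filter to whole count
    matrices without one dynamic programme per cell.
    """
    lo, hi = k, max(2 * k, 2 * s)
    while coverage_probability(hi, s, k) <= prob:
        lo, hi = hi, hi * 2
        if hi > 10_000_000:
            raise RuntimeError("coverage target unattainable")
    while lo < hi:
        mid = (lo + hi) // 2
        if coverage_probability(mid, s, k) > prob:
            hi = mid
        else:
            lo = mid + 1
    return lo


def chromosome_coverage_filter(
    counts: PooledCounts,
    design: PoolDesign,
    k: int = 80,
    prob: float = 0.8,
) -> tuple[np.ndarray, np.ndarray]:
    """Pool validity mask and SNP drop decision for the binomial test.

    A pool is valid at a SNP iff its depth gives strictly more than
    ``prob`` probability of covering at least ``k`` of the ``s``
    chromosomes; a SNP is dropped iff one group retains no valid pool.
    Returns ``(valid_pools, dropped)``.
    """
    if design.s < k:
        raise ValueError("k cannot exceed the number of chromosomes per pool")
    r_min = min_depth_for_coverage(design.s, k, prob)
    valid = counts.depth >= r_min
    dropped = np.zeros(counts.n_snps, dtype=bool)
    for mask in (design.case_mask, design.control_mask):
        dropped |= ~valid[:, mask].any(axis=1)
    return valid, dropped


def apply_filters(
    counts: PooledCounts,
    design: PoolDesign,
    min_depth: int = 8,
    maf_threshold: float = 0.05,
    alpha: float = 0.05,
    n_mc: int = 10_000,
    rng: np.random.Generator | None = None,
    per_pool_depth: bool = False,
) -> list[FilterReport]:
    """Run depth filter, MAF partition and the rare-variant error screen.

    The Bonferroni denominator for the error screen is the number of
    rare candidates actually screened in this run.  A SNP is retained
    (``called_true_snp``) if it is common, or if it is rare and passes
    the error screen.  The surviving set is order-independent.
    """
    import zlib

    rng = np.random.default_rng(rng)
    passed = min_depth_filter(counts, design, min_depth, per_pool=per_pool_depth)
    classes = maf_partition(counts, maf_threshold)
    reports = [FilterReport(snp_id=str(sid)) for sid in counts.snp_id]
    rare_idx = [
        i for i in range(counts.n_snps)
        if passed[i] and classes[i] == RARE
    ]
    n_tests = max(1, len(rare_idx))
    # per-SNP Monte-Carlo streams keyed on the SNP id (not its position)
    # so the surviving set does not depend on input ordering
    base = int(rng.integers(0, 2**31 - 1))
    seeds = {
        i: np.random.SeedSequence(
            entropy=base, spawn_key=(zlib.crc32(str(counts.snp_id[i]).encode()),)
        )
        for i in rare_idx
    }
    for i, rep in enumerate(reports):
        rep.passed_depth = bool(passed[i])
        rep.maf_class = str(classes[i])
        if not rep.passed_depth:
            rep.reason = "below minimum depth"
            continue
        if rep.maf_class == DEGENERATE:
            rep.reason = "zero total depth"
            continue
        if rep.maf_class == COMMON:
            rep.called_true_snp = True
            continue
        p, called = random_error_screen(
            counts.minor_reads[i], counts.depth[i],
            n_tests=n_tests, alpha=alpha, n_mc=n_mc,
            rng=np.random.default_rng(seeds[i]),
        )
        rep.error_screen_p = p
        rep.called_true_snp = called
        if not called:
            rep.reason = "consistent with random errors"
    return reports
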