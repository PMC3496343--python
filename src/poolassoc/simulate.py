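"""Synthetic pooled case-control sequencing data with truth labels.

The generator mimics a targeted pooled-resequencing experiment: 500
cases and 500 controls split into 20 pools of 50 people, sequenced at an
average per-person coverage of 40x.  Each allele copy (chromosome)
contributes a gamma-distributed number of reads (shape 1/6, scale
3 x coverage), so a person's depth is Gamma(1/3, 3 x coverage) with
mean = coverage -- amplification and library effects make per-template
yields extremely uneven, which both spreads pool depths widely and
makes the within-pool allele split gamma-proportion (Beta) rather than
binomial.  That is the over-dispersion the extra-binomial tests target.
Each read is miscalled as the other allele with a symmetric base error
probability.

Three SNP classes are simulated: 'null' (MAF = 0, only error reads),
'neutral' (equal MAF in cases and controls, spanning 0.005-0.5) and
'disease' (case MAF raised according to a multiplicative per-allele
relative risk, default 1.5).  Null SNPs let a blinded analysis estimate
error rates; neutral and disease SNPs calibrate Type-1 error and power.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .data import CASE, CONTROL, PoolDesign, PooledCounts

__all__ = [
    "SimConfig",
    "SimTruth",
    "case_maf",
    "simulate_pool_depths",
    "simulate_dataset",
    "run_simulation_study",
]

DEFAULT_MAF_GRID = (0.005, 0.01, 0.02, 0.05, 0.1, 0.2, 0.5)

_BASES = "ACGT"
_PAIRS = [(a, b) for a, b in itertools.product(_BASES, _BASES) if a != b]


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated dataset."""

    n_cases: int = 500
    n_controls: int = 500
    pools_per_group: int = 10
    avg_coverage_per_person: float = 40.0
    gamma_shape: float = 1.0 / 3.0
    gamma_scale_factor: float = 3.0  # scale = factor x avg coverage
    n_null: int = 700
    n_neutral: int = 700
    n_disease: int = 700
    maf_grid: tuple[float, ...] = DEFAULT_MAF_GRID
    rr: float = 1.5
    error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_cases", "n_controls", "pools_per_group"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_cases % self.pools_per_group or self.n_controls % self.pools_per_group:
            raise ValueError("cases/controls must divide evenly into pools")
        if self.rr <= 0:
            raise ValueError("rr must be positive")
        if not 0.0 <= self.error_rate <= 1.0:
            raise ValueError("error_rate must be in [0, 1]")
        if min(self.n_null, self.n_neutral, self.n_disease) < 0:
            raise ValueError("SNP counts must be non-negative")
        if any(not 0.0 < m <= 0.5 for m in self.maf_grid):
            raise ValueError("maf_grid values must be in (0, 0.5]")
        if self.avg_coverage_per_person <= 0 or self.gamma_shape <= 0:
            raise ValueError("coverage and gamma_shape must be positive")

    @property
    def persons_per_pool(self) -> int:
        return self.n_cases // self.pools_per_group

    @property
    def s(self) -> int:
        """Distinct chromosomes per pool (2 per diploid person)."""
        return 2 * self.persons_per_pool

    @property
    def gamma_scale(self) -> float:
        return self.gamma_scale_factor * self.avg_coverage_per_person


@dataclass(frozen=True)
class SimTruth:
    snp_id: str
    clazz: str  # null | neutral | disease
    maf_control: float
    maf_case: float

    def __post_init__(self) -> None:
        if self.clazz == "null" and (self.maf_control or self.maf_case):
            raise ValueError("null SNPs must have MAF 0 in both groups")
        if self.clazz == "neutral" and self.maf_case != self.maf_control:
            raise ValueError("neutral SNPs must have equal group MAFs")


def case_maf(maf_control: float, rr: float) -> float:
    """Case minor-allele frequency under a multiplicative per-allele risk.

    q_case = q rr / (q rr + 1 - q), so the allele odds ratio of case
    versus control equals rr exactly (rare-disease approximation of the
    relative risk).
    """
    if not 0.0 < maf_control < 1.0:
        raise ValueError("maf_control must be in (0, 1)")
    if rr <= 0:
        raise ValueError("rr must be positive")
    return maf_control * rr / (maf_control * rr + 1.0 - maf_control)


def simulate_pool_depths(
    config: SimConfig,
    n_pools: int,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Draw total read depths for ``n_pools`` independent pool-SNP cells.

    Uses the same per-chromosome gamma draws (rounded per allele class)
    as the full dataset generator.
    """
    rng = np.random.default_rng(rng)
    k = config.gamma_shape / 2.0
    shape = (n_pools, config.persons_per_pool)
    per_person = (np.round(rng.gamma(k, config.gamma_scale, size=shape))
                  + np.round(rng.gamma(k, config.gamma_scale, size=shape)))
    return per_person.sum(axis=1)


def _truth_tables(config: SimConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-SNP class labels and group MAFs (control, case)."""
    classes = (["null"] * config.n_null
               + ["neutral"] * config.n_neutral
               + ["disease"] * config.n_disease)
    grid = config.maf_grid
    maf_c = np.zeros(len(classes))
    maf_d = np.zeros(len(classes))
    for k in range(config.n_neutral):
        q = grid[k % len(grid)]
        maf_c[config.n_null + k] = q
        maf_d[config.n_null + k] = q
    for k in range(config.n_disease):
        q = grid[k % len(grid)]
        i = config.n_null + config.n_neutral + k
        maf_c[i] = q
        maf_d[i] = case_maf(q, config.rr)
    return np.array(classes, dtype=object), maf_c, maf_d


def _simulate_group_counts(maf, config, n_pools, rng):
    """(minor reads, depth) per (snp, pool) for one group.

    Per person: minor-allele dose g ~ Bin(2, maf); each allele class
    contributes gamma-distributed reads with shape proportional to its
    copy number (shape g k for the minor allele, (2 - g) k for the
    major, k = gamma_shape / 2 per chromosome) and common scale, rounded
    to integers; each read is then miscalled as the other allele with
    probability error_rate; pool counts are person sums.

    The gamma's infinite divisibility makes a person's total depth
    Gamma(gamma_shape, scale) with mean = average coverage, while the
    allele split given the genotype is gamma-proportion (Beta) rather
    than binomial -- amplification noise attaches to chromosomes, not
    to individual reads, which is what makes pooled frequency estimates
    much noisier than read counting alone suggests.
    """
    n_snps = len(maf)
    P = config.persons_per_pool
    k = config.gamma_shape / 2.0  # per chromosome
    dose = rng.binomial(2, maf[:, None, None], size=(n_snps, n_pools, P))
    minor = np.round(rng.gamma(dose * k, config.gamma_scale)).astype(np.int64)
    major = np.round(rng.gamma((2 - dose) * k, config.gamma_scale)).astype(np.int64)
    e = config.error_rate
    if e > 0:
        flips_out = rng.binomial(minor, e)
        flips_in = rng.binomial(major, e)
        minor = minor - flips_out + flips_in
        major = major - flips_in + flips_out
    depth = minor + major
    return minor.sum(axis=2, dtype=np.int64), depth.sum(axis=2, dtype=np.int64)


def simulate_dataset(
    config: SimConfig,
    rng: np.random.Generator | int | None = None,
) -> tuple[PooledCounts, PoolDesign, list[SimTruth]]:
    """Generate one dataset: counts, design and per-SNP truth labels.

    Deterministic for a fixed ``config.seed`` (or explicit generator).
    Counts are oriented so the true major allele is the reference; the
    true minor allele is the alternative base.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    elif not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    classes, maf_c, maf_d = _truth_tables(config)
    n_snps = len(classes)
    npg = config.pools_per_group
    minor_ctrl, depth_ctrl = _simulate_group_counts(maf_c, config, npg, rng)
    minor_case, depth_case = _simulate_group_counts(maf_d, config, npg, rng)
    minor = np.hstack([minor_ctrl, minor_case])
    depth = np.hstack([depth_ctrl, depth_case])
    pool_ids = tuple(
        [f"ctrl{j+1:02d}" for j in range(npg)] + [f"case{j+1:02d}" for j in range(npg)]
    )
    design = PoolDesign(
        pool_ids=pool_ids,
        group=tuple([CONTROL] * npg + [CASE] * npg),
        s=config.s,
    )
    pair_idx = rng.integers(0, len(_PAIRS), size=n_snps)
    ref = np.array([_PAIRS[i][0] for i in pair_idx], dtype=object)
    alt = np.array([_PAIRS[i][1] for i in pair_idx], dtype=object)
    snp_id = np.array([f"s{i+1:06d}" for i in range(n_snps)], dtype=object)
    counts = PooledCounts(
        snp_id=snp_id,
        chrom=np.array(["sim1"] * n_snps, dtype=object),
        pos=np.arange(1, n_snps + 1) * 100,
        ref_allele=ref,
        alt_allele=alt,
        major_reads=depth - minor,
        depth=depth,
        pool_ids=pool_ids,
        major_is_ref=np.ones(n_snps, dtype=bool),
    )
    truth = [
        SimTruth(snp_id=str(snp_id[i]), clazz=str(classes[i]),
                 maf_control=float(maf_c[i]), maf_case=float(maf_d[i]))
        for i in range(n_snps)
    ]
    return counts, design, truth


def run_simulation_study(
    config: SimConfig,
    error_rates: tuple[float, ...] = (0.0, 0.01, 0.05),
    methods: tuple[str, ...] = ("fisher", "eb2"),
    alpha: float = 0.05,
    n_reps: int = 10,
    seed: int = 0,
    screen_mc: int = 10_000,
) -> pd.DataFrame:
    """Estimate Type-1 error and power over a grid of error rates.

    For every replicate a fresh dataset is generated and pushed through
    the blinded pipeline (depth filter, MAF partition, rare-variant
    error screen, error-rate estimation from screen failures, count
    correction, tests).  Rejections at level ``alpha`` are tallied per
    method x truth class x generating MAF x error rate; neutral SNPs
    give Type-1 error, disease SNPs give power.  Excluded or filtered
    SNPs count in ``n_removed``, never as rejections, and the rate
    denominator is the number actually tested.

    The global ``seed`` spawns one independent substream per replicate,
    so any single replicate can be reproduced in isolation.
    """
    from .pipeline import analyze  # local import to avoid a cycle

    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    bad = set(methods) - {"fisher", "eb1", "eb2"}
    if bad:
        raise ValueError(f"unknown methods: {sorted(bad)}")
    tally: dict[tuple, list[int]] = {}

    def cell(key):
        return tally.setdefault(key, [0, 0, 0])  # reject, tested, removed

    for e_idx, e in enumerate(error_rates):
        cfg = replace(config, error_rate=float(e))
        for rep in range(n_reps):
            ss = np.random.SeedSequence(entropy=seed, spawn_key=(e_idx, rep))
            rng = np.random.default_rng(ss)
            counts, design, truth = simulate_dataset(cfg, rng=rng)
            out = analyze(
                counts, design, methods=methods,
                rng=np.random.default_rng(ss.spawn(1)[0]),
                screen_mc=screen_mc,
            )
            for method in methods:
                res_map = {r.snp_id: r for r in out.results[method]}
                for t in truth:
                    if t.clazz == "null":
                        continue
                    key = (method, t.clazz, t.maf_control, e)
                    c = cell(key)
                    r = res_map.get(t.snp_id)
                    if r is None or r.status != "tested":
                        c[2] += 1
                        continue
                    c[1] += 1
                    if r.p_value < alpha:
                        c[0] += 1
    rows = []
    for (method, clazz, maf, e), (rej, tested, removed) in sorted(tally.items()):
        rate = rej / tested if tested else float("nan")
        se = (np.sqrt(rate * (1 - rate) / tested) if tested else float("nan"))
        rows.append({
            "method": method,
            "class": clazz,
            "maf": maf,
            "error_rate": e,
            "alpha": alpha,
            "n_tested": tested,
            "n_removed": removed,
            "n_rejected": rej,
            "rate": rate,
            "se": se,
        })
    return pd.DataFrame(rows)
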