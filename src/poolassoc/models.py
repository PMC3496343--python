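"""Association tests for pooled case-control allele counts.

Three tests of the null hypothesis that the major-allele frequency is
equal in case and control chromosomes:

``fisher``
    The naive binomial model: per-pool frequencies are averaged with
    equal weight, converted to chromosome counts (frequency x s x number
    of valid pools, rounded) and compared in a 2x2 table by Fisher's
    exact test.  Ignores between-pool variation entirely.

``eb1``
    Williams' quasi-likelihood extra-binomial model: the variance of the
    major-read count in pool j is inflated to
    R_j pi (1 - pi) [1 + phi_i (R_j - 1)] with a per-SNP heterogeneity
    parameter phi_i.  phi_i is estimated by equating the weighted Pearson
    goodness-of-fit statistic of the full (case/control) model to its
    degrees of freedom; the test statistic is the increase in that
    statistic when the case-control factor is deleted (chi-square, 1 df).

``eb2``
    The globally calibrated extra-binomial model: the per-pool frequency
    estimate p_hat_ij = y_ij / R_ij is assigned variance

        Var(p_hat_ij) = p_i (1 - p_i) (a / R_ij + b / s),

    with two universal parameters shared by every SNP.  In the ideal
    two-stage sampling limit (s chromosomes into the pool, R_ij reads
    from them, no other noise) a -> 1 and b -> 1.  Matching against a
    plain binomial variance p(1-p)/R* defines the adjusted depth

        R*_ij = s R_ij / (a s + b R_ij),

    the effective number of independent reads a pool contributes.
    Adjusted allele counts p_hat_ij R*_ij are summed over case and
    control pools into a 2x2 table tested by Pearson chi-square (1 df,
    no continuity correction, fractional entries allowed).

(a, b) are estimated once, across all usable SNPs: the per-SNP
normalised dispersion statistic

    T_i = sum_j (y_ij - R_ij p_ig)^2 / (R_ij p_ig (1 - p_ig)) / (n - 2)

(p_ig: pooled frequency of pool j's group, so the fit stays blind to any
true case-control difference; n - 2 degrees of freedom are left after
the two group means) has expectation a + b (mean depth / s), so ordinary
least-squares regression of T_i on mean depth / s yields the intercept
a-hat and slope b-hat.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats
from scipy.special import gammaln

from .data import AssocResult, PoolDesign, PooledCounts

__all__ = [
    "DispersionFit",
    "EB1Fit",
    "fisher_exact_2x2",
    "fisher_test",
    "eb1_test",
    "fit_dispersion",
    "eb2_test",
    "pearson_chi2_2x2",
    "odds_ratio",
]


# ---------------------------------------------------------------------------
# Fisher / binomial model
# ---------------------------------------------------------------------------

def fisher_exact_2x2(table: np.ndarray) -> float:
    """Two-sided Fisher exact p-value for an integer 2x2 table.

    Sums hypergeometric probabilities of all tables (with the observed
    margins) no more probable than the observed one, the same definition
    scipy uses; computed with log-space binomial coefficients so large
    margins stay cheap and stable.
    """
    a, b = int(round(table[0, 0])), int(round(table[0, 1]))
    c, d = int(round(table[1, 0])), int(round(table[1, 1]))
    if min(a, b, c, d) < 0:
        raise ValueError("negative cell in 2x2 table")
    M = a + b + c + d
    if M == 0:
        return 1.0
    n1 = a + b          # first row margin
    K = a + c           # first column margin
    lo, hi = max(0, n1 + K - M), min(n1, K)
    x = np.arange(lo, hi + 1)

    def logC(n, k):
        return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)

    logpmf = logC(K, x) + logC(M - K, n1 - x) - logC(M, n1)
    pmf = np.exp(logpmf)
    p_obs = pmf[a - lo]
    p = float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())
    return min(p, 1.0)


def fisher_test(
    counts: PooledCounts,
    design: PoolDesign,
    coverage_mask: np.ndarray | None = None,
) -> list[AssocResult]:
    """Fisher's exact test on estimated chromosome counts, per SNP.

    Each group's major-allele frequency is the unweighted mean of the
    per-pool frequencies over that group's valid pools; chromosome
    counts are frequency x (s x number of valid pools), rounded to the
    nearest integer (ties to even).  A SNP with no valid pool in one
    group is excluded, mirroring the coverage-filter drop rule.
    """
    valid = counts.depth > 0
    if coverage_mask is not None:
        valid = valid & coverage_mask
    results = []
    masks = {"control": design.control_mask, "case": design.case_mask}
    for i in range(counts.n_snps):
        sid = str(counts.snp_id[i])
        freqs, chrom_major, chrom_total = {}, {}, {}
        ok = True
        for g, gmask in masks.items():
            use = valid[i] & gmask
            if not use.any():
                ok = False
                break
            p_hat = counts.major_reads[i, use] / counts.depth[i, use]
            freqs[g] = float(p_hat.mean())
            total = design.s * int(use.sum())
            major = int(np.rint(freqs[g] * total))
            chrom_major[g] = major
            chrom_total[g] = total
        if not ok:
            results.append(AssocResult(
                snp_id=sid, method="fisher", status="excluded",
                reason="no valid pool in one group",
            ))
            continue
        table = np.array([
            [chrom_major["control"], chrom_major["case"]],
            [chrom_total["control"] - chrom_major["control"],
             chrom_total["case"] - chrom_major["case"]],
        ], dtype=float)
        p = fisher_exact_2x2(table)
        # sample odds ratio of the table, as a descriptive statistic
        num = table[0, 0] * table[1, 1]
        den = table[0, 1] * table[1, 0]
        stat = num / den if den > 0 else math.inf if num > 0 else math.nan
        results.append(AssocResult(
            snp_id=sid, method="fisher", statistic=stat, df=1, p_value=p,
            p_hat_control=freqs["control"], p_hat_case=freqs["case"],
            table=table,
        ))
    return results


# ---------------------------------------------------------------------------
# Williams extra-binomial model (EB1)
# ---------------------------------------------------------------------------

@dataclass
class EB1Fit:
    """Diagnostics from one SNP's Williams quasi-likelihood fit."""

    phi: float
    beta: float
    X2_full: float
    X2_null: float
    iterations: int
    converged: bool


def _eb1_x2(y, R, group_idx, phi, null):
    """Weighted Pearson statistic at dispersion phi.

    group_idx: 0 = control, 1 = case; ``null`` collapses both groups.
    Returns (X2, per-group fitted frequencies).
    """
    w = 1.0 / (1.0 + phi * (R - 1.0))
    if null:
        pi = np.full(2, (w * y).sum() / (w * R).sum())
    else:
        pi = np.empty(2)
        for g in (0, 1):
            m = group_idx == g
            pi[g] = (w[m] * y[m]).sum() / (w[m] * R[m]).sum()
    pi = np.clip(pi, 1e-12, 1 - 1e-12)
    mu = R * pi[group_idx]
    X2 = float((w * (y - mu) ** 2 / (mu * (1 - pi[group_idx]))).sum())
    return X2, pi


def eb1_test(
    counts: PooledCounts,
    design: PoolDesign,
    max_iter: int = 50,
    tol: float = 1e-8,
) -> tuple[list[AssocResult], list[EB1Fit | None]]:
    """Williams' extra-binomial quasi-likelihood test, per SNP.

    phi is the non-negative root of X2_full(phi) = n - 2 (the weighted
    Pearson statistic of the two-group model equated to its residual
    degrees of freedom); with phi fixed, the statistic is
    X2_null - X2_full, referred to chi-square with one degree of
    freedom.  SNPs with zero total minor reads in either group are
    excluded (no variance information to estimate phi from).
    """
    group_idx_full = np.where(design.case_mask, 1, 0)
    results: list[AssocResult] = []
    fits: list[EB1Fit | None] = []
    for i in range(counts.n_snps):
        sid = str(counts.snp_id[i])
        use = counts.depth[i] > 0
        y = counts.major_reads[i, use]
        R = counts.depth[i, use]
        gidx = group_idx_full[use]
        minor = R - y
        excluded = None
        for g, name in ((0, "control"), (1, "case")):
            if not np.any(gidx == g):
                excluded = f"no covered pool in {name} group"
            elif minor[gidx == g].sum() <= 0:
                excluded = f"zero minor reads in {name} group"
        n_used = int(use.sum())
        if excluded is None and n_used < 3:
            excluded = "fewer than 3 covered pools"
        if excluded is None and np.all(minor == R):
            excluded = "zero major reads everywhere"
        if excluded is not None:
            results.append(AssocResult(
                snp_id=sid, method="eb1", status="excluded", reason=excluded,
            ))
            fits.append(None)
            continue

        dfree = n_used - 2
        evals = 0

        def g_of(phi):
            nonlocal evals
            evals += 1
            return _eb1_x2(y, R, gidx, phi, null=False)[0] - dfree

        converged = True
        if g_of(0.0) <= 0:
            phi = 0.0
        else:
            hi = 1e-4
            while g_of(hi) > 0 and hi < 1e6:
                hi *= 10
            if g_of(hi) > 0:
                phi, converged = hi, False
            else:
                phi = float(optimize.brentq(g_of, 0.0, hi, xtol=tol,
                                            maxiter=max_iter * 4))
        X2_full, pi_full = _eb1_x2(y, R, gidx, phi, null=False)
        X2_null, _ = _eb1_x2(y, R, gidx, phi, null=True)
        delta = max(0.0, X2_null - X2_full)
        p = float(stats.chi2.sf(delta, df=1))
        beta = float(np.log(pi_full[1] / (1 - pi_full[1]))
                     - np.log(pi_full[0] / (1 - pi_full[0])))
        w = 1.0 / (1.0 + phi * (R - 1.0))
        table = np.array([
            [(w * y)[gidx == 0].sum(), (w * y)[gidx == 1].sum()],
            [(w * (R - y))[gidx == 0].sum(), (w * (R - y))[gidx == 1].sum()],
        ])
        status = "tested" if converged else "degenerate"
        results.append(AssocResult(
            snp_id=sid, method="eb1", statistic=delta, df=1, p_value=p,
            p_hat_control=float(pi_full[0]), p_hat_case=float(pi_full[1]),
            table=table, status=status,
            reason="" if converged else "phi search hit upper bound",
        ))
        fits.append(EB1Fit(phi=phi, beta=beta, X2_full=X2_full,
                           X2_null=X2_null, iterations=evals,
                           converged=converged))
    return results, fits


# ---------------------------------------------------------------------------
# EB2: global dispersion fit and adjusted-depth chi-square test
# ---------------------------------------------------------------------------

@dataclass
class DispersionFit:
    """Global over-dispersion parameters and their provenance."""

    a: float
    b: float
    s: int
    per_snp_stat: np.ndarray
    per_snp_mean_depth: np.ndarray
    n_snps_used: int
    se_a: float = math.nan
    se_b: float = math.nan

    @classmethod
    def from_params(cls, a: float, b: float, s: int) -> "DispersionFit":
        """Build a fit object from externally supplied (a, b)."""
        return cls(a=a, b=b, s=s, per_snp_stat=np.empty(0),
                   per_snp_mean_depth=np.empty(0), n_snps_used=0)

    def adjusted_depth(self, R: np.ndarray) -> np.ndarray:
        """R* = s R / (a s + b R); the information content of each pool."""
        R = np.asarray(R, dtype=float)
        denom = self.a * self.s + self.b * R
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.where(denom > 0, self.s * R / denom, np.nan)
        return out


def fit_dispersion(
    counts: PooledCounts,
    design: PoolDesign,
    min_maf: float = 0.0,
    min_snps: int = 20,
) -> DispersionFit:
    """Estimate the universal dispersion parameters (a, b).

    Uses every SNP whose pooled major-allele frequency is strictly
    inside (0, 1) in both groups and which retains at least three pools
    with positive depth.  The per-SNP statistic T_i is regressed on
    mean depth / s by ordinary least squares; a-hat is the intercept and
    b-hat the slope.

    ``min_maf`` restricts the fit to SNPs with pooled minor-allele
    frequency at or above it (when at least ``min_snps`` such SNPs
    exist): at very low minor counts the normalised dispersion
    statistic is attenuated by the noise of the estimated group
    frequencies in its denominator, which would bias (a, b) downwards
    for every SNP.  Rare SNPs are still tested with the fitted
    parameters -- their own attenuation then makes the test
    conservative rather than anti-conservative.
    """
    if min_maf > 0:
        total = counts.depth.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            maf = np.where(total > 0,
                           counts.minor_reads.sum(axis=1) / np.maximum(total, 1),
                           0.0)
        eligible = maf >= min_maf
        if eligible.sum() >= min_snps:
            sub = fit_dispersion(counts.subset(eligible), design, min_maf=0.0)
            return sub
    gidx = np.where(design.case_mask, 1, 0)
    stats_list, regs = [], []
    pool_y, pool_x, pool_snp = [], [], []
    for i in range(counts.n_snps):
        use = counts.depth[i] > 0
        n_used = int(use.sum())
        if n_used < 3:
            continue
        y = counts.major_reads[i, use]
        R = counts.depth[i, use]
        g = gidx[use]
        ok = True
        resid_sq = []
        for gg in (0, 1):
            m = g == gg
            if not m.any():
                ok = False
                break
            pig = y[m].sum() / R[m].sum()
            if not 0.0 < pig < 1.0:
                ok = False
                break
            resid_sq.extend(
                (y[m] - R[m] * pig) ** 2 / (R[m] * pig * (1 - pig))
            )
        if not ok:
            continue
        # n/(n-2) undoes the two estimated group means on average
        corr = n_used / (n_used - 2)
        stats_list.append(float(np.sum(resid_sq)) / (n_used - 2))
        regs.append(R.mean() / design.s)
        pool_y.extend(r * corr for r in resid_sq)
        pool_x.extend(R / design.s)
        pool_snp.extend([len(stats_list) - 1] * n_used)
    if len(stats_list) < 2:
        raise ValueError(
            f"dispersion regression needs >= 2 usable SNPs, got {len(stats_list)}"
        )
    # regression at per-pool resolution: every pool contributes its own
    # squared Pearson residual against its own depth, which is what
    # identifies the a/R and b/s components separately when mean depths
    # barely differ between SNPs
    x = np.asarray(pool_x)
    T = np.asarray(pool_y)
    if np.ptp(x) == 0:
        raise ValueError("dispersion regression is degenerate: constant depths")
    X = np.column_stack([np.ones_like(x), x])
    coef, *_ = np.linalg.lstsq(X, T, rcond=None)
    a, b = float(coef[0]), float(coef[1])
    # cluster-robust (by SNP) standard errors: residuals within a SNP
    # share the estimated group frequencies
    resid = T - X @ coef
    bread = np.linalg.inv(X.T @ X)
    snp_idx = np.asarray(pool_snp)
    meat = np.zeros((2, 2))
    for i in np.unique(snp_idx):
        m = snp_idx == i
        xe = X[m].T @ resid[m]
        meat += np.outer(xe, xe)
    cov = bread @ meat @ bread
    se_a, se_b = math.sqrt(cov[0, 0]), math.sqrt(cov[1, 1])
    return DispersionFit(
        a=a, b=b, s=design.s,
        per_snp_stat=np.asarray(stats_list),
        per_snp_mean_depth=np.asarray(regs) * design.s,
        n_snps_used=len(stats_list), se_a=se_a, se_b=se_b,
    )


def pearson_chi2_2x2(table: np.ndarray) -> float:
    """Pearson chi-square for a (possibly fractional) 2x2 table, 1 df,
    no continuity correction.  Zero when any margin is empty."""
    table = np.asarray(table, dtype=float)
    N = table.sum()
    rows = table.sum(axis=1)
    cols = table.sum(axis=0)
    if N <= 0 or np.any(rows <= 0) or np.any(cols <= 0):
        return 0.0
    det = table[0, 0] * table[1, 1] - table[0, 1] * table[1, 0]
    return float(N * det * det / (rows[0] * rows[1] * cols[0] * cols[1]))


def eb2_test(
    counts: PooledCounts,
    design: PoolDesign,
    fit: DispersionFit,
) -> list[AssocResult]:
    """Chi-square test on adjusted allele counts, per SNP.

    Each pool contributes p_hat_ij R*_ij major and (1 - p_hat_ij) R*_ij
    minor adjusted counts; pools whose adjusted depth is non-positive
    (possible when b-hat < 0 at low depth) are dropped, and a SNP whose
    case or control group loses every pool is excluded.
    """
    gidx = np.where(design.case_mask, 1, 0)
    results = []
    Rstar_all = fit.adjusted_depth(counts.depth)
    for i in range(counts.n_snps):
        sid = str(counts.snp_id[i])
        use = counts.depth[i] > 0
        if not (use[gidx == 0].any() and use[gidx == 1].any()):
            results.append(AssocResult(
                snp_id=sid, method="eb2", status="excluded",
                reason="zero depth in one group",
            ))
            continue
        rstar = Rstar_all[i]
        good = use & np.isfinite(rstar) & (rstar > 0)
        if not (good[gidx == 0].any() and good[gidx == 1].any()):
            results.append(AssocResult(
                snp_id=sid, method="eb2", status="excluded",
                reason="non-positive adjusted depth in one group",
            ))
            continue
        p_hat = np.zeros(counts.n_pools)
        p_hat[good] = counts.major_reads[i, good] / counts.depth[i, good]
        adj_major = p_hat * rstar
        adj_minor = (1 - p_hat) * rstar
        table = np.zeros((2, 2))
        for col, gg in enumerate((0, 1)):  # control, case
            m = good & (gidx == gg)
            table[0, col] = adj_major[m].sum()
            table[1, col] = adj_minor[m].sum()
        stat = pearson_chi2_2x2(table)
        p = float(stats.chi2.sf(stat, df=1))
        totals = table.sum(axis=0)
        results.append(AssocResult(
            snp_id=sid, method="eb2", statistic=stat, df=1, p_value=p,
            p_hat_control=float(table[0, 0] / totals[0]),
            p_hat_case=float(table[0, 1] / totals[1]),
            table=table,
        ))
    return results


def odds_ratio(maf_control: float, maf_case: float) -> float:
    """Odds ratio of the minor allele in cases relative to controls."""
    for v in (maf_control, maf_case):
        if not 0.0 < v < 1.0:
            raise ValueError(f"MAF must be strictly inside (0, 1), got {v}")
    return (maf_case / (1 - maf_case)) / (maf_control / (1 - maf_control))
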