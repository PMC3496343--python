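"""Q-Q diagnostics and Type-1-error / power summaries.

A set of p-values from a well-calibrated test, converted to chi-square
(1 df) scale through the inverse survival function, should follow the
chi-square(1) distribution.  Plotting sorted observed values against
expected quantiles at plotting positions k/(m+1) and fitting a
through-the-origin slope gives the genomic-inflation style diagnostic:
slope 1 for calibrated tests, slope c when statistics are inflated
c-fold.  The pointwise 95% concentration band comes from the
Beta(k, m+1-k) distribution of uniform order statistics mapped to the
chi-square scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["QQSummary", "pvalues_to_chisq", "qq_summary", "type1_power_table"]

#: smallest p-value admitted before chi-square inversion (underflow cap)
MIN_P = np.nextafter(0.0, 1.0)


@dataclass
class QQSummary:
    observed_quantiles: np.ndarray
    expected_quantiles: np.ndarray
    slope: float
    max_observed: float
    band_lo: np.ndarray
    band_hi: np.ndarray
    n_capped: int = 0
    degenerate: bool = False


def pvalues_to_chisq(p: np.ndarray) -> np.ndarray:
    """Upper-tail chi-square(1 df) quantiles of p-values.

    p = 1 maps to 0.  p = 0 (underflow) is capped at the smallest
    positive double before inversion, which keeps the result finite;
    callers that need to know how many values were capped should check
    beforehand (qq_summary reports the count).
    """
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must be in [0, 1]")
    return stats.chi2.isf(np.maximum(p, MIN_P), df=1)


def qq_summary(p_values: np.ndarray, band_level: float = 0.95) -> QQSummary:
    """Observed-vs-expected chi-square quantiles, slope and 95% band.

    Expected quantiles are chi-square(1) quantiles at plotting positions
    k/(m+1); the slope is the least-squares regression of observed on
    expected through the origin.  All-identical p-values give a flagged
    degenerate slope.
    """
    p = np.asarray(p_values, dtype=float)
    p = p[np.isfinite(p)]
    if len(p) < 10:
        raise ValueError("need at least 10 finite p-values")
    n_capped = int((p <= MIN_P).sum())
    obs = np.sort(pvalues_to_chisq(p))
    m = len(obs)
    k = np.arange(1, m + 1)
    expected = stats.chi2.ppf(k / (m + 1.0), df=1)
    lo = (1 - band_level) / 2
    # k-th smallest of m uniforms ~ Beta(k, m+1-k); map to chi-square scale
    band_lo = stats.chi2.ppf(stats.beta.ppf(lo, k, m + 1 - k), df=1)
    band_hi = stats.chi2.ppf(stats.beta.ppf(1 - lo, k, m + 1 - k), df=1)
    degenerate = bool(np.all(obs == obs[0]))
    denom = float((expected ** 2).sum())
    slope = float((obs * expected).sum() / denom) if denom > 0 else float("nan")
    return QQSummary(
        observed_quantiles=obs,
        expected_quantiles=expected,
        slope=slope,
        max_observed=float(obs[-1]),
        band_lo=band_lo,
        band_hi=band_hi,
        n_capped=n_capped,
        degenerate=degenerate,
    )


def qq_frame(summary: QQSummary) -> pd.DataFrame:
    return pd.DataFrame({
        "expected": summary.expected_quantiles,
        "observed": summary.observed_quantiles,
        "band_lo": summary.band_lo,
        "band_hi": summary.band_hi,
    })


def plot_qq(summary: QQSummary, path) -> None:
    """Write a Q-Q plot PNG (requires matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    ax.fill_between(summary.expected_quantiles, summary.band_lo,
                    summary.band_hi, alpha=0.3, color="grey",
                    label="95% concentration band")
    ax.plot(summary.expected_quantiles, summary.observed_quantiles,
            ".", ms=4, label="observed")
    lim = max(summary.expected_quantiles.max(), 1.0)
    ax.plot([0, lim], [0, lim], "k--", lw=1)
    ax.plot([0, lim], [0, summary.slope * lim], "r-", lw=1,
            label=f"slope = {summary.slope:.3g}")
    ax.set_xlabel("expected $\\chi^2_1$ quantile")
    ax.set_ylabel("observed $\\chi^2_1$ quantile")
    ax.legend(loc="upper left", frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def type1_power_table(
    results,
    truth,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Rejection rates by truth class and MAF with exact binomial CIs.

    ``results`` is a list of AssocResult, ``truth`` a list of SimTruth;
    they are joined on snp_id.  Excluded or degenerate SNPs are counted
    in ``n_removed`` and never as rejections.  Empty cells give NA rows.
    """
    if not 0.0 < alpha <= 1.0:
        raise ValueError("alpha must be in (0, 1]")
    tmap = {t.snp_id: t for t in truth}
    tally: dict[tuple, list[int]] = {}
    for r in results:
        t = tmap.get(r.snp_id)
        if t is None:
            continue
        key = (r.method, t.clazz, t.maf_control)
        c = tally.setdefault(key, [0, 0, 0])
        if r.status != "tested":
            c[2] += 1
            continue
        c[1] += 1
        if r.p_value < alpha:
            c[0] += 1
    rows = []
    for (method, clazz, maf), (rej, tested, removed) in sorted(tally.items()):
        if tested:
            rate = rej / tested
            lo, hi = stats.binomtest(rej, tested).proportion_ci(0.95, "exact")
        else:
            rate, lo, hi = float("nan"), float("nan"), float("nan")
        rows.append({
            "method": method, "class": clazz, "maf": maf, "alpha": alpha,
            "n_tested": tested, "n_removed": removed, "n_rejected": rej,
            "rate": rate, "ci_lo": lo, "ci_hi": hi,
        })
    return pd.DataFrame(rows)
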