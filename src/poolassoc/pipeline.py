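"""The blinded analysis pipeline: filters, error correction, tests.

Mirrors how a pooled-resequencing dataset is analysed end to end without
knowledge of which candidate sites are real variants:

1. orient counts to the major allele;
2. minimum-depth filter and MAF partition;
3. rare candidates are screened against the random-error null; failures
   are treated as error sites, not SNPs;
4. base-specific error rates are estimated from those error sites and
   all surviving counts are de-biased;
5. the requested association tests run on the corrected counts (the
   Fisher path additionally applies the chromosome-coverage filter; the
   EB2 path first fits the global dispersion parameters on all
   surviving SNPs).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import filters as flt
from .data import AssocResult, PoolDesign, PooledCounts, orient_major_allele
from .error_model import ErrorRates, correct_counts, estimate_error_rates
from .models import DispersionFit, eb1_test, eb2_test, fisher_test, fit_dispersion

__all__ = ["PipelineResult", "analyze"]


@dataclass
class PipelineResult:
    """Everything the pipeline produced, keyed by method."""

    results: dict[str, list[AssocResult]]
    filter_reports: list[flt.FilterReport]
    error_rates: ErrorRates
    dispersion: DispersionFit | None
    kept_mask: np.ndarray
    counts_corrected: PooledCounts


def _site_frame(counts: PooledCounts, mask: np.ndarray) -> pd.DataFrame:
    """Summed ref/alt read totals for the masked positions."""
    sub = counts.subset(mask)
    ref_reads = np.where(sub.major_is_ref, sub.major_reads.sum(axis=1),
                         sub.minor_reads.sum(axis=1))
    alt_reads = sub.depth.sum(axis=1) - ref_reads
    return pd.DataFrame({
        "chrom": sub.chrom,
        "pos": sub.pos,
        "ref": sub.ref_allele,
        "alt": sub.alt_allele,
        "ref_reads": ref_reads,
        "alt_reads": alt_reads,
    })


def analyze(
    counts: PooledCounts,
    design: PoolDesign,
    methods: tuple[str, ...] = ("fisher", "eb1", "eb2"),
    min_depth: int = 8,
    maf_threshold: float = 0.05,
    screen_alpha: float = 0.05,
    screen_mc: int = 10_000,
    coverage_k: int | None = 80,
    coverage_prob: float = 0.8,
    error_correction: bool = True,
    dispersion: DispersionFit | None = None,
    rng: np.random.Generator | None = None,
) -> PipelineResult:
    """Run the blinded pipeline and the requested tests.

    SNPs removed by filtering appear in the per-method result lists with
    status ``excluded`` so downstream summaries can account for them.
    ``dispersion`` overrides the internally fitted EB2 parameters (for
    applying a fit exported from another dataset).
    """
    rng = np.random.default_rng(rng)
    counts = orient_major_allele(counts)
    reports = flt.apply_filters(
        counts, design, min_depth=min_depth, maf_threshold=maf_threshold,
        alpha=screen_alpha, n_mc=screen_mc, rng=rng,
    )
    kept = np.array([r.called_true_snp for r in reports], dtype=bool)
    # positions screened out as random errors inform the error model
    error_sites = np.array(
        [r.passed_depth and not r.called_true_snp and r.maf_class == flt.RARE
         for r in reports], dtype=bool,
    )
    if error_correction and error_sites.any():
        rates = estimate_error_rates(_site_frame(counts, error_sites))
    else:
        rates = ErrorRates.zero()
    kept_counts = counts.subset(kept)
    if error_correction:
        kept_counts = correct_counts(kept_counts, rates)

    removed = [
        AssocResult(snp_id=str(counts.snp_id[i]), method="", status="excluded",
                    reason=reports[i].reason or "filtered")
        for i in np.flatnonzero(~kept)
    ]
    results: dict[str, list[AssocResult]] = {}
    disp = dispersion
    for method in methods:
        if method == "fisher":
            if kept_counts.n_snps:
                # k = 80 assumes s ~ 96-100; scale the 5/6 ratio down for
                # small designs so toy fixtures remain analysable
                k = coverage_k
                if k is None or k > design.s:
                    k = max(1, int(np.ceil(design.s * 5 / 6)))
                valid, _ = flt.chromosome_coverage_filter(
                    kept_counts, design, k=k, prob=coverage_prob)
                res = fisher_test(kept_counts, design, coverage_mask=valid)
            else:
                res = []
        elif method == "eb1":
            res, _ = eb1_test(kept_counts, design)
        elif method == "eb2":
            if disp is None:
                try:
                    disp = fit_dispersion(kept_counts, design,
                                          min_maf=maf_threshold)
                except ValueError:
                    res = [
                        AssocResult(snp_id=str(s), method="eb2",
                                    status="degenerate",
                                    reason="dispersion fit failed")
                        for s in kept_counts.snp_id
                    ]
                    results[method] = res + _tag(removed, method)
                    continue
            res = eb2_test(kept_counts, design, disp)
        else:
            raise ValueError(f"unknown method {method!r}")
        results[method] = res + _tag(removed, method)
    return PipelineResult(
        results=results,
        filter_reports=reports,
        error_rates=rates,
        dispersion=disp,
        kept_mask=kept,
        counts_corrected=kept_counts,
    )


def _tag(removed: list[AssocResult], method: str) -> list[AssocResult]:
    return [
        AssocResult(snp_id=r.snp_id, method=method, status=r.status,
                    reason=r.reason)
        for r in removed
    ]
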