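"""High-level modelling interface over the pipeline.

``PooledAssociation`` is constructed from a count table and a pool
design; ``fit`` runs the blinded pipeline (filters, error model,
dispersion estimation, tests) and returns a results object carrying the
per-SNP test results, the fitted global dispersion parameters with
their standard errors, the estimated error rates and Q-Q diagnostics.
"""

from __future__ import annotations

import io

import numpy as np
import pandas as pd

from .data import PoolDesign, PooledCounts, read_count_table, results_to_frame
from .evaluate import QQSummary, qq_summary
from .pipeline import PipelineResult, analyze

__all__ = ["PooledAssociation", "PooledAssociationResults"]


class PooledAssociation:
    """Case-control association model for pooled allele counts.

    Parameters mirror the pipeline stages; see :func:`poolassoc.pipeline.analyze`.
    """

    def __init__(
        self,
        counts: PooledCounts,
        design: PoolDesign,
        methods: tuple[str, ...] = ("fisher", "eb1", "eb2"),
        min_depth: int = 8,
        maf_threshold: float = 0.05,
        screen_alpha: float = 0.05,
        screen_mc: int = 10_000,
        coverage_k: int = 80,
        coverage_prob: float = 0.8,
        error_correction: bool = True,
    ) -> None:
        self.counts = counts
        self.design = design
        self.methods = tuple(methods)
        self.params = dict(
            min_depth=min_depth, maf_threshold=maf_threshold,
            screen_alpha=screen_alpha, screen_mc=screen_mc,
            coverage_k=coverage_k, coverage_prob=coverage_prob,
            error_correction=error_correction,
        )

    @classmethod
    def from_files(
        cls,
        count_path,
        design_path,
        format: str = "generic_tsv",
        **kwargs,
    ) -> "PooledAssociation":
        counts, design = read_count_table(count_path, format=format,
                                          design=design_path)
        return cls(counts, design, **kwargs)

    def fit(self, seed: int | None = 0, dispersion=None) -> "PooledAssociationResults":
        out = analyze(
            self.counts, self.design, methods=self.methods,
            rng=np.random.default_rng(seed), dispersion=dispersion,
            **self.params,
        )
        return PooledAssociationResults(self, out)


class PooledAssociationResults:
    """Fitted pipeline: per-SNP results plus global estimates."""

    def __init__(self, model: PooledAssociation, raw: PipelineResult) -> None:
        self.model = model
        self._raw = raw
        self.results = raw.results
        self.dispersion_ = raw.dispersion
        self.error_rates_ = raw.error_rates
        self.filter_reports_ = raw.filter_reports

    def frame(self, method: str) -> pd.DataFrame:
        """Per-SNP result table for one method."""
        return results_to_frame(self.results[method])

    def qq(self, method: str) -> QQSummary:
        """Q-Q diagnostic over the method's tested p-values."""
        p = np.array([r.p_value for r in self.results[method]
                      if r.status == "tested"])
        return qq_summary(p)

    def summary(self) -> str:
        buf = io.StringIO()
        n = self.model.counts.n_snps
        kept = int(self._raw.kept_mask.sum())
        print("Pooled case-control association results", file=buf)
        print("=" * 54, file=buf)
        print(f"SNPs supplied: {n:6d}   pools: {self.model.design.n}"
              f"   chromosomes/pool (s): {self.model.design.s}", file=buf)
        print(f"SNPs surviving filters: {kept}", file=buf)
        if self.dispersion_ is not None and self.dispersion_.n_snps_used:
            d = self.dispersion_
            print(
                f"dispersion fit: a = {d.a:.4g} (se {d.se_a:.3g}), "
                f"b = {d.b:.4g} (se {d.se_b:.3g}), "
                f"on {d.n_snps_used} SNPs", file=buf,
            )
        nonzero = {k: v for k, v in self.error_rates_.rate.items() if v > 0}
        if nonzero:
            mean_rate = np.mean(list(nonzero.values()))
            print(f"error rates: {len(nonzero)} substitution classes, "
                  f"mean {mean_rate:.3g}", file=buf)
        print("-" * 54, file=buf)
        for method in self.model.methods:
            res = self.results[method]
            tested = [r for r in res if r.status == "tested"]
            if tested:
                pmin = min(r.p_value for r in tested)
                qq = self.qq(method) if len(tested) >= 10 else None
                slope = f"{qq.slope:.3f}" if qq else "   na"
                print(f"{method:>7}: {len(tested):5d} tested, "
                      f"{len(res) - len(tested):4d} excluded, "
                      f"min p = {pmin:.3g}, QQ slope = {slope}", file=buf)
            else:
                print(f"{method:>7}: nothing tested", file=buf)
        return buf.getvalue()
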