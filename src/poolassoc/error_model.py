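"""Base-specific sequencing error-rate estimation and count correction.

Positions that carry no real variant still show a trickle of non-reference
reads from base-calling errors.  Pooling those positions by ordered base
substitution (A->C, A->G, ... 12 classes) gives one error rate per class:
rate = alternative reads / total reads over all contributing positions.
The rates are then inverted to de-bias SNP read counts: if a fraction
eps_Mm of true major-allele bases is miscalled as the minor allele and
eps_mM vice versa, the observed major count has expectation

    E[y_obs] = y_true (1 - eps_Mm) + (R - y_true) eps_mM,

so y_corr = (y_obs - R eps_mM) / (1 - eps_Mm - eps_mM) is unbiased for
y_true.  Corrected counts are real-valued and clamped to [0, depth].
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import PooledCounts

__all__ = ["ErrorRates", "estimate_error_rates", "correct_counts",
           "read_rates", "write_rates", "SUBSTITUTIONS"]

log = logging.getLogger(__name__)

_BASES = "ACGT"
SUBSTITUTIONS: tuple[tuple[str, str], ...] = tuple(
    (a, b) for a, b in itertools.product(_BASES, _BASES) if a != b
)

#: rates smaller than this are numerically meaningless and treated as zero
RATE_FLOOR = 1e-8


@dataclass
class ErrorRates:
    """One error rate per ordered base substitution a -> a-bar."""

    rate: dict[tuple[str, str], float] = field(default_factory=dict)
    denominator_bases: dict[tuple[str, str], int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for key in SUBSTITUTIONS:
            self.rate.setdefault(key, 0.0)
            self.denominator_bases.setdefault(key, 0)
        for key, r in self.rate.items():
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"rate for {key} outside [0, 1]: {r}")

    def get(self, a: str, abar: str) -> float:
        r = self.rate[(a, abar)]
        return r if r >= RATE_FLOOR else 0.0

    @classmethod
    def zero(cls) -> "ErrorRates":
        return cls()


def estimate_error_rates(
    site_counts: pd.DataFrame,
    snp_positions: set | None = None,
) -> ErrorRates:
    """Estimate per-substitution error rates from non-SNP positions.

    ``site_counts`` has one row per position with columns ``chrom``,
    ``pos``, ``ref``, ``alt``, ``ref_reads``, ``alt_reads`` (reads summed
    over pools).  Rows whose ``(chrom, pos)`` is in ``snp_positions``
    (called-and-passed SNPs) are excluded; everything else contributes to
    the substitution class (ref -> alt) observed at that position.
    Classes with zero denominator get rate 0 with a logged warning.
    """
    required = {"chrom", "pos", "ref", "alt", "ref_reads", "alt_reads"}
    missing = required - set(site_counts.columns)
    if missing:
        raise ValueError(f"site_counts missing columns {sorted(missing)}")
    snp_positions = snp_positions or set()
    num = {key: 0.0 for key in SUBSTITUTIONS}
    den = {key: 0.0 for key in SUBSTITUTIONS}
    for row in site_counts.itertuples(index=False):
        if (row.chrom, row.pos) in snp_positions:
            continue
        key = (str(row.ref).upper(), str(row.alt).upper())
        if key not in num:
            continue  # non-SNV or ref==alt row
        num[key] += float(row.alt_reads)
        den[key] += float(row.ref_reads) + float(row.alt_reads)
    rates, denominators = {}, {}
    for key in SUBSTITUTIONS:
        if den[key] > 0:
            rates[key] = num[key] / den[key]
        else:
            rates[key] = 0.0
            log.warning("no data for substitution %s->%s; rate set to 0", *key)
        denominators[key] = int(round(den[key]))
    return ErrorRates(rate=rates, denominator_bases=denominators)


def correct_counts(
    counts: PooledCounts,
    rates: ErrorRates,
    scale: float = 1.0,
) -> PooledCounts:
    """De-bias major-allele read counts for base-calling error.

    Only the SNP's own allele pair matters: the applicable rates are
    rate[major_base -> minor_base] and rate[minor_base -> major_base].
    ``scale`` multiplies every rate before use (sensitivity analysis for
    misspecified error rates).  Depths are unchanged; corrected counts
    are real-valued and clamped to [0, depth].
    """
    out = counts.copy()
    ref = np.asarray(out.ref_allele, dtype=object)
    alt = np.asarray(out.alt_allele, dtype=object)
    major_base = np.where(out.major_is_ref, ref, alt)
    minor_base = np.where(out.major_is_ref, alt, ref)
    eps_Mm = np.array([
        rates.get(str(M), str(m)) for M, m in zip(major_base, minor_base)
    ]) * scale
    eps_mM = np.array([
        rates.get(str(m), str(M)) for M, m in zip(major_base, minor_base)
    ]) * scale
    denom = 1.0 - eps_Mm - eps_mM
    if np.any(denom <= 0):
        raise ValueError("error rates too large: eps_Mm + eps_mM >= 1")
    y = (out.major_reads - out.depth * eps_mM[:, None]) / denom[:, None]
    clipped = (y < 0) | (y > out.depth)
    if np.any(clipped):
        log.debug("error correction clamped %d pool counts", int(clipped.sum()))
    out.major_reads = np.clip(y, 0.0, out.depth)
    return out


def write_rates(rates: ErrorRates, path) -> None:
    pd.DataFrame({
        "ref": [a for a, _ in SUBSTITUTIONS],
        "alt": [b for _, b in SUBSTITUTIONS],
        "rate": [rates.rate[k] for k in SUBSTITUTIONS],
        "denominator_bases": [rates.denominator_bases[k] for k in SUBSTITUTIONS],
    }).to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_rates(path) -> ErrorRates:
    df = pd.read_csv(path, sep="\t", dtype={"ref": str, "alt": str})
    rate = {(r.ref, r.alt): float(r.rate) for r in df.itertuples(index=False)}
    den = {(r.ref, r.alt): int(r.denominator_bases) for r in df.itertuples(index=False)}
    return ErrorRates(rate=rate, denominator_bases=den)
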