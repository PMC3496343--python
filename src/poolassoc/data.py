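"""Domain types and I/O for pooled allele-count data.

Pooled case-control sequencing yields, for every SNP, one pair of allele
read counts per DNA pool rather than per person.  The containers here hold
the per-SNP x per-pool major-allele read counts ``y_ij`` and depths
``R_ij`` together with the pool design (number of pools ``n``, distinct
chromosomes per pool ``s``, case/control assignment), which is everything
the downstream tests consume.

All on-disk formats are plain tab-separated UTF-8 text:

* generic count table -- columns ``snp_id, chrom, pos, ref, alt`` followed
  by ``<pool>_ref`` / ``<pool>_alt`` pairs, one row per SNP;
* design sidecar -- columns ``pool_id, group, s``;
* VarScan-style per-pool SNP call files -- columns
  ``chrom, position, ref, var, reads1, reads2`` (one file per pool);
* results table -- one row per SNP per test.
"""

from __future__ import annotations

import dataclasses
import math
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PoolDesign",
    "PooledCounts",
    "AssocResult",
    "read_count_table",
    "read_design",
    "write_count_table",
    "write_design",
    "orient_major_allele",
    "write_results",
    "read_results",
    "results_to_frame",
]

CASE = "case"
CONTROL = "control"
_GROUPS = (CASE, CONTROL)


class CountTableError(ValueError):
    """Malformed or inconsistent count/design input."""


@dataclass(frozen=True)
class PoolDesign:
    """Pool layout: ids, case/control labels and chromosomes per pool.

    ``s`` is the number of distinct chromosomes sampled in one pool
    (2 x persons per pool for diploids); it bounds the allele-frequency
    resolution a single pool can provide.
    """

    pool_ids: tuple[str, ...]
    group: tuple[str, ...]
    s: int

    def __post_init__(self) -> None:
        if len(self.pool_ids) != len(self.group):
            raise CountTableError("pool_ids and group must have equal length")
        if self.n < 2:
            raise CountTableError("need at least two pools")
        unknown = set(self.group) - set(_GROUPS)
        if unknown:
            raise CountTableError(f"unknown group label(s): {sorted(unknown)}")
        if CASE not in self.group or CONTROL not in self.group:
            raise CountTableError("need at least one case and one control pool")
        if self.s < 2 or self.s % 2:
            raise CountTableError("s must be an even integer >= 2 (diploid pools)")
        if len(set(self.pool_ids)) != self.n:
            raise CountTableError("duplicate pool ids")

    @property
    def n(self) -> int:
        return len(self.pool_ids)

    @property
    def case_mask(self) -> np.ndarray:
        return np.array([g == CASE for g in self.group])

    @property
    def control_mask(self) -> np.ndarray:
        return np.array([g == CONTROL for g in self.group])


@dataclass
class PooledCounts:
    """Per-SNP, per-pool major-allele read counts and depths.

    Arrays are (n_snps, n_pools).  ``major_reads`` is y_ij, ``depth`` is
    R_ij = major + minor reads.  ``major_is_ref`` records the current
    orientation so the base-substitution error rates applicable to each
    SNP remain identifiable after re-orientation.  Counts may be
    real-valued (after error correction); a missing pool at a SNP is
    encoded as depth 0, never dropped.
    """

    snp_id: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    ref_allele: np.ndarray
    alt_allele: np.ndarray
    major_reads: np.ndarray
    depth: np.ndarray
    pool_ids: tuple[str, ...]
    major_is_ref: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.snp_id = np.asarray(self.snp_id, dtype=object)
        self.major_reads = np.atleast_2d(np.asarray(self.major_reads, dtype=float))
        self.depth = np.atleast_2d(np.asarray(self.depth, dtype=float))
        if self.major_is_ref is None:
            self.major_is_ref = np.ones(len(self.snp_id), dtype=bool)
        self.major_is_ref = np.asarray(self.major_is_ref, dtype=bool)
        if self.major_reads.shape != self.depth.shape:
            raise CountTableError("major_reads and depth shapes differ")
        if self.major_reads.shape != (len(self.snp_id), len(self.pool_ids)):
            raise CountTableError(
                f"count arrays must be (n_snps={len(self.snp_id)}, "
                f"n_pools={len(self.pool_ids)}), got {self.major_reads.shape}"
            )
        if np.any(self.depth < 0):
            raise CountTableError("negative depth")
        bad = (self.major_reads < 0) | (self.major_reads > self.depth)
        if np.any(bad):
            i, j = np.argwhere(bad)[0]
            raise CountTableError(
                f"major_reads outside [0, depth] for SNP {self.snp_id[i]!r}, "
                f"pool {self.pool_ids[j]!r}"
            )

    @property
    def n_snps(self) -> int:
        return len(self.snp_id)

    @property
    def n_pools(self) -> int:
        return len(self.pool_ids)

    @property
    def minor_reads(self) -> np.ndarray:
        return self.depth - self.major_reads

    def copy(self) -> "PooledCounts":
        return PooledCounts(
            snp_id=self.snp_id.copy(),
            chrom=np.asarray(self.chrom).copy(),
            pos=np.asarray(self.pos).copy(),
            ref_allele=np.asarray(self.ref_allele).copy(),
            alt_allele=np.asarray(self.alt_allele).copy(),
            major_reads=self.major_reads.copy(),
            depth=self.depth.copy(),
            pool_ids=self.pool_ids,
            major_is_ref=self.major_is_ref.copy(),
        )

    def subset(self, mask: np.ndarray) -> "PooledCounts":
        """Row-subset of SNPs (boolean mask or index array)."""
        return PooledCounts(
            snp_id=self.snp_id[mask],
            chrom=np.asarray(self.chrom)[mask],
            pos=np.asarray(self.pos)[mask],
            ref_allele=np.asarray(self.ref_allele)[mask],
            alt_allele=np.asarray(self.alt_allele)[mask],
            major_reads=self.major_reads[mask],
            depth=self.depth[mask],
            pool_ids=self.pool_ids,
            major_is_ref=self.major_is_ref[mask],
        )


@dataclass
class AssocResult:
    """Per-SNP association test output.

    ``table`` is the 2x2 (allele x group) table the test was computed on;
    entries may be real-valued for the model-adjusted tests.  ``p_hat_control``
    and ``p_hat_case`` are the estimated group major-allele frequencies.
    """

    snp_id: str
    method: str
    statistic: float = math.nan
    df: int = 1
    p_value: float = math.nan
    p_hat_control: float = math.nan
    p_hat_case: float = math.nan
    table: np.ndarray | None = None
    status: str = "tested"
    reason: str = ""


def orient_major_allele(counts: PooledCounts) -> PooledCounts:
    """Re-express counts so successes correspond to the major allele.

    The major allele at a SNP is the allele with the larger total read
    count summed over all pools; an exact tie resolves to the reference
    allele.  Idempotent.
    """
    out = counts.copy()
    ref_total = np.where(
        out.major_is_ref,
        out.major_reads.sum(axis=1),
        out.minor_reads.sum(axis=1),
    )
    alt_total = out.depth.sum(axis=1) - ref_total
    want_ref_major = ref_total >= alt_total  # tie -> reference
    flip = want_ref_major != out.major_is_ref
    out.major_reads[flip] = out.depth[flip] - out.major_reads[flip]
    out.major_is_ref = want_ref_major
    return out


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_design(path: str | os.PathLike) -> PoolDesign:
    """Read a design sidecar TSV with columns pool_id, group, s."""
    df = pd.read_csv(path, sep="\t", dtype={"pool_id": str, "group": str})
    for col in ("pool_id", "group", "s"):
        if col not in df.columns:
            raise CountTableError(f"design file {path}: missing column {col!r}")
    s_vals = df["s"].unique()
    if len(s_vals) != 1:
        raise CountTableError(f"design file {path}: s must be constant, got {s_vals}")
    return PoolDesign(
        pool_ids=tuple(df["pool_id"]),
        group=tuple(df["group"]),
        s=int(s_vals[0]),
    )


def write_design(design: PoolDesign, path: str | os.PathLike) -> None:
    pd.DataFrame(
        {"pool_id": design.pool_ids, "group": design.group, "s": design.s}
    ).to_csv(path, sep="\t", index=False)


_FIXED_COLS = ["snp_id", "chrom", "pos", "ref", "alt"]


def _read_generic(path: str | os.PathLike, design: PoolDesign | None):
    df = pd.read_csv(path, sep="\t", dtype={"snp_id": str, "chrom": str})
    for col in _FIXED_COLS:
        if col not in df.columns:
            raise CountTableError(f"{path}: missing column {col!r}")
    pool_cols = [c for c in df.columns if c not in _FIXED_COLS]
    pool_ids = []
    for c in pool_cols:
        if c.endswith("_ref"):
            pid = c[: -len("_ref")]
            if f"{pid}_alt" not in pool_cols:
                raise CountTableError(f"{path}: pool {pid!r} missing _alt column")
            pool_ids.append(pid)
        elif not c.endswith("_alt"):
            raise CountTableError(f"{path}: unrecognised column {c!r}")
    if not pool_ids:
        raise CountTableError(f"{path}: no per-pool count columns found")
    if design is not None:
        if set(pool_ids) != set(design.pool_ids):
            raise CountTableError(
                f"{path}: pools in header do not match the design sidecar"
            )
        pool_ids = list(design.pool_ids)  # order pools per the design
    ref = df[[f"{p}_ref" for p in pool_ids]].to_numpy(dtype=float)
    alt = df[[f"{p}_alt" for p in pool_ids]].to_numpy(dtype=float)
    if np.any(ref < 0) or np.any(alt < 0):
        raise CountTableError(f"{path}: negative read count")
    counts = PooledCounts(
        snp_id=df["snp_id"].to_numpy(dtype=object),
        chrom=df["chrom"].to_numpy(dtype=object),
        pos=df["pos"].to_numpy(dtype=int),
        ref_allele=df["ref"].to_numpy(dtype=object),
        alt_allele=df["alt"].to_numpy(dtype=object),
        major_reads=ref,
        depth=ref + alt,
        pool_ids=tuple(pool_ids),
        major_is_ref=np.ones(len(df), dtype=bool),
    )
    return counts


def _read_varscan(path: str | os.PathLike, design: PoolDesign):
    """Read a set of per-pool VarScan-style SNP call files.

    ``path`` is a directory containing one ``<pool_id>.tsv`` per pool with
    columns chrom, position, ref, var, reads1 (reference-supporting reads)
    and reads2 (variant-supporting reads).  Positions absent from a pool's
    file get depth 0 for that pool.
    """
    if design is None:
        raise CountTableError("varscan format requires a design sidecar")
    frames = {}
    keys: list[tuple] = []
    seen = set()
    for pid in design.pool_ids:
        f = os.path.join(os.fspath(path), f"{pid}.tsv")
        if not os.path.exists(f):
            raise CountTableError(f"missing VarScan file for pool {pid!r}: {f}")
        df = pd.read_csv(f, sep="\t", dtype={"chrom": str, "ref": str, "var": str})
        for col in ("chrom", "position", "ref", "var", "reads1", "reads2"):
            if col not in df.columns:
                raise CountTableError(f"{f}: missing column {col!r}")
        df = df.set_index(["chrom", "position", "ref", "var"])
        if df.index.has_duplicates:
            raise CountTableError(f"{f}: duplicate site rows")
        frames[pid] = df
        for key in df.index:
            if key not in seen:
                seen.add(key)
                keys.append(key)
    n = len(keys)
    npools = design.n
    ref = np.zeros((n, npools))
    alt = np.zeros((n, npools))
    for j, pid in enumerate(design.pool_ids):
        df = frames[pid]
        for i, key in enumerate(keys):
            if key in df.index:
                row = df.loc[key]
                ref[i, j] = float(row["reads1"])
                alt[i, j] = float(row["reads2"])
    chrom = np.array([k[0] for k in keys], dtype=object)
    pos = np.array([k[1] for k in keys], dtype=int)
    refb = np.array([k[2] for k in keys], dtype=object)
    altb = np.array([k[3] for k in keys], dtype=object)
    snp_id = np.array([f"{c}:{p}" for c, p in zip(chrom, pos)], dtype=object)
    return PooledCounts(
        snp_id=snp_id,
        chrom=chrom,
        pos=pos,
        ref_allele=refb,
        alt_allele=altb,
        major_reads=ref,
        depth=ref + alt,
        pool_ids=tuple(design.pool_ids),
        major_is_ref=np.ones(n, dtype=bool),
    )


def read_count_table(
    path: str | os.PathLike,
    format: str = "generic_tsv",
    design: str | os.PathLike | PoolDesign | None = None,
) -> tuple[PooledCounts, PoolDesign]:
    """Read a count table plus its pool design.

    ``design`` may be a :class:`PoolDesign` or a path to a design sidecar
    TSV.  For the generic format the sidecar is optional only if it is
    supplied separately later; the varscan format requires it.
    """
    if isinstance(design, (str, os.PathLike)):
        design = read_design(design)
    if format == "generic_tsv":
        if design is None:
            raise CountTableError("generic_tsv requires a design sidecar")
        counts = _read_generic(path, design)
    elif format == "varscan":
        counts = _read_varscan(path, design)
    else:
        raise CountTableError(f"unknown format {format!r}")
    return counts, design


def write_count_table(counts: PooledCounts, path: str | os.PathLike) -> None:
    """Write the generic TSV dialect (ref/alt counts per pool)."""
    ref = np.where(counts.major_is_ref[:, None], counts.major_reads, counts.minor_reads)
    alt = counts.depth - ref

    def _fmt(a):
        if np.allclose(a, np.round(a)):
            return a.astype(int)
        return a

    data = {
        "snp_id": counts.snp_id,
        "chrom": counts.chrom,
        "pos": counts.pos,
        "ref": counts.ref_allele,
        "alt": counts.alt_allele,
    }
    for j, pid in enumerate(counts.pool_ids):
        data[f"{pid}_ref"] = _fmt(ref[:, j])
        data[f"{pid}_alt"] = _fmt(alt[:, j])
    pd.DataFrame(data).to_csv(path, sep="\t", index=False)


_RESULT_COLS = [
    "snp_id", "method", "statistic", "df", "p_value",
    "p_hat_control", "p_hat_case",
    "table_major_control", "table_minor_control",
    "table_major_case", "table_minor_case",
    "status", "reason",
]


def results_to_frame(results: list[AssocResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        t = r.table if r.table is not None else np.full((2, 2), np.nan)
        rows.append({
            "snp_id": r.snp_id,
            "method": r.method,
            "statistic": r.statistic,
            "df": r.df,
            "p_value": r.p_value,
            "p_hat_control": r.p_hat_control,
            "p_hat_case": r.p_hat_case,
            "table_major_control": t[0, 0],
            "table_minor_control": t[1, 0],
            "table_major_case": t[0, 1],
            "table_minor_case": t[1, 1],
            "status": r.status,
            "reason": r.reason,
        })
    return pd.DataFrame(rows, columns=_RESULT_COLS)


def write_results(results: list[AssocResult], path: str | os.PathLike) -> None:
    """Write one row per SNP: statistic, df, p, group frequencies, status.

    Excluded or degenerate SNPs carry empty statistic/p fields.  Values
    are written with enough digits to round-trip within 1e-12.
    """
    if not results:
        raise ValueError("no results to write")
    df = results_to_frame(results)
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_results(path: str | os.PathLike) -> list[AssocResult]:
    df = pd.read_csv(path, sep="\t", dtype={"snp_id": str, "method": str})
    out = []
    for _, row in df.iterrows():
        table = np.array([
            [row["table_major_control"], row["table_major_case"]],
            [row["table_minor_control"], row["table_minor_case"]],
        ])
        out.append(AssocResult(
            snp_id=row["snp_id"],
            method=row["method"],
            statistic=float(row["statistic"]),
            df=int(row["df"]) if not math.isnan(row["df"]) else 1,
            p_value=float(row["p_value"]),
            p_hat_control=float(row["p_hat_control"]),
            p_hat_case=float(row["p_hat_case"]),
            table=table if not np.all(np.isnan(table)) else None,
            status=str(row["status"]),
            reason="" if pd.isna(row["reason"]) else str(row["reason"]),
        ))
    return out
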