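"""Readers/writers for NOMe-seq on-disk formats and trinucleotide context rules.

All in-memory coordinates are 0-based, half-open. BED matches this natively;
any 1-based conversion would live here and nowhere else. Cytosine calls are
held as pandas DataFrames with the columns in :data:`CALL_COLUMNS`.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

CALL_COLUMNS = ["chrom", "pos", "strand", "context", "n_meth", "n_total"]
ANALYSIS_CONTEXTS = ("GCH", "HCG")
#: GCG sites are ambiguous between enzyme and endogenous methylation and are
#: excluded from every analysis.
EXCLUDED_CONTEXTS = ("GCG",)

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_H = set("ACT")


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval with optional BED6 attributes."""

    chrom: str
    start: int
    end: int
    name: str = "."
    score: float = 0.0
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"empty or inverted interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


def classify_context(trinucleotide: str, strand: str = "+") -> str:
    """Classify the trinucleotide around a cytosine into GCH/HCG/GCG/other.

    ``trinucleotide`` is written 5'->3' on the reference (+) strand; for a
    cytosine on the minus strand it is reverse-complemented before applying
    the rules, so the center base must read C on ``strand``.
    """
    tri = trinucleotide.upper()
    if len(tri) != 3 or any(b not in "ACGT" for b in tri):
        raise ValueError(f"invalid trinucleotide {trinucleotide!r}")
    if strand not in ("+", "-"):
        raise ValueError(f"invalid strand {strand!r}")
    if strand == "-":
        tri = tri.translate(_COMPLEMENT)[::-1]
    if tri[1] != "C":
        raise ValueError(f"center base of {trinucleotide!r} is not C on {strand}")
    if tri[0] == "G":
        return "GCG" if tri[2] == "G" else "GCH"
    if tri[2] == "G":
        return "HCG"
    return "other"


def validate_calls(calls: pd.DataFrame) -> pd.DataFrame:
    """Validate and normalize a cytosine-call table (sorted by chrom, pos)."""
    missing = [c for c in CALL_COLUMNS if c not in calls.columns]
    if missing:
        raise ValueError(f"call table missing columns {missing}")
    out = calls[CALL_COLUMNS].copy()
    out["pos"] = out["pos"].astype(np.int64)
    out["n_meth"] = out["n_meth"].astype(np.int64)
    out["n_total"] = out["n_total"].astype(np.int64)
    if (out["n_meth"] < 0).any() or (out["n_total"] < 0).any():
        raise ValueError("negative counts in call table")
    if (out["n_meth"] > out["n_total"]).any():
        bad = out.index[(out["n_meth"] > out["n_total"])][0]
        raise ValueError(f"n_meth > n_total at row {bad}")
    bad_strand = ~out["strand"].isin(["+", "-"])
    if bad_strand.any():
        raise ValueError("invalid strand in call table")
    out = out.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    return out


def read_cytosine_report(
    path: Union[str, Path],
    context_filter: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Read a cytosine-report TSV (chrom, pos, strand, context, n_meth, n_total).

    Records are validated (counts sane, line numbers reported on failure) and
    returned sorted by (chrom, pos). When ``context_filter`` is given, only
    those contexts are kept; GCG is never part of the analysis contexts.
    Gzip input is handled transparently by extension.
    """
    path = Path(path)
    try:
        df = pd.read_csv(
            path, sep="\t", header=None, names=CALL_COLUMNS, comment="#",
            dtype={"chrom": str, "strand": str, "context": str},
        )
    except (ValueError, pd.errors.ParserError) as exc:
        raise ValueError(f"malformed cytosine report {path}: {exc}") from exc
    for col in ("pos", "n_meth", "n_total"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        if coerced.isna().any():
            lineno = int(coerced.index[coerced.isna()][0]) + 1
            raise ValueError(f"{path}: non-numeric {col} at line {lineno}")
        df[col] = coerced
    over = df["n_meth"] > df["n_total"]
    if over.any():
        lineno = int(df.index[over][0]) + 1
        raise ValueError(f"{path}: n_meth > n_total at line {lineno}")
    if context_filter is not None:
        df = df[df["context"].isin(list(context_filter))]
    return validate_calls(df)


def write_cytosine_report(calls: pd.DataFrame, path: Union[str, Path]) -> None:
    calls = validate_calls(calls)
    calls.to_csv(path, sep="\t", header=False, index=False)


def read_bed(path: Union[str, Path]) -> list[GenomicInterval]:
    """Read BED3/BED6 into GenomicIntervals (strand preserved when present)."""
    out: list[GenomicInterval] = []
    path = Path(path)
    import gzip

    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: fewer than 3 BED fields at line {lineno}")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            name = fields[3] if len(fields) > 3 else "."
            score = float(fields[4]) if len(fields) > 4 and fields[4] != "." else 0.0
            strand = fields[5] if len(fields) > 5 else "."
            try:
                out.append(GenomicInterval(chrom, start, end, name, score, strand))
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from exc
    return out


def write_bed(intervals: Iterable[GenomicInterval], path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t{iv.score:g}\t{iv.strand}\n"
            )


def read_bedgraph(path: Union[str, Path]) -> pd.DataFrame:
    """Read a bedGraph file into a (chrom, start, end, value) DataFrame."""
    df = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "value"],
        comment="#", dtype={"chrom": str},
    )
    if (df["start"] >= df["end"]).any():
        raise ValueError(f"{path}: empty interval in bedGraph")
    return df


def write_bedgraph(df: pd.DataFrame, path: Union[str, Path]) -> None:
    df[["chrom", "start", "end", "value"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def pooled_level(n_meth: np.ndarray, n_total: np.ndarray) -> float:
    """Aggregate methylation level as a pooled-count ratio sum(meth)/sum(total).

    Pooled ratios (not means of per-site ratios) are the aggregation used
    throughout because the MAR significance test operates on pooled counts.
    Returns NaN when no reads.
    """
    total = int(np.sum(n_total))
    if total == 0:
        return float("nan")
    return float(np.sum(n_meth)) / total


def per_site_levels(calls: pd.DataFrame, min_total: int = 1) -> pd.DataFrame:
    """Per-site methylation ratios, dropping sites below ``min_total`` reads."""
    kept = calls[calls["n_total"] >= min_total].copy()
    kept["level"] = kept["n_meth"] / kept["n_total"]
    return kept
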