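"""Nucleosome-depleted region calling from MAR/MPR segmentation.

Each methyltransferase-accessible region (MAR) is scored against its local
protected background: all MPRs within +/-100 kb are pooled and an exact
one-tailed binomial test asks whether the MAR's methylated-count fraction
exceeds that background rate. P-values are Benjamini-Hochberg corrected
genome-wide per replicate; significant MARs (q < 0.01) longer than 100 bp
are NDRs, and only NDRs overlapping between the two biological replicates
are kept, reported as the union of the overlapping pair.
"""

from __future__ import annotations

import warnings
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as sps

FDR_CUTOFF = 0.01
NDR_MIN_LEN = 101  # strict '> 100 bp'
DEFAULT_FLANK = 100_000

NDR_COLUMNS = [
    "chrom", "start", "end", "n_sites", "n_meth", "n_total",
    "background_rate", "background_fallback", "p_value", "q_value",
    "is_significant", "is_ndr",
]


class MPRIndex:
    """Per-chromosome sorted MPR arrays with prefix-summed counts.

    Supports pooled-count queries over a window in O(log n); a brute-force
    linear scan over the same arrays is the test oracle.
    """

    def __init__(self, mprs: pd.DataFrame):
        self._by_chrom: dict[str, dict[str, np.ndarray]] = {}
        self._chrom_totals: dict[str, tuple[int, int]] = {}
        for chrom, grp in mprs[mprs["state"] == "MPR"].groupby("chrom"):
            grp = grp.sort_values("start")
            self._by_chrom[str(chrom)] = {
                "start": grp["start"].to_numpy(np.int64),
                "end": grp["end"].to_numpy(np.int64),
                "cmeth": np.concatenate([[0], np.cumsum(grp["n_meth"].to_numpy(np.int64))]),
                "ctotal": np.concatenate([[0], np.cumsum(grp["n_total"].to_numpy(np.int64))]),
            }
            self._chrom_totals[str(chrom)] = (
                int(grp["n_meth"].sum()), int(grp["n_total"].sum()),
            )

    def pooled_counts(self, chrom: str, lo: int, hi: int) -> tuple[int, int]:
        """Summed (n_meth, n_total) of MPRs overlapping [lo, hi) by >= 1 bp."""
        d = self._by_chrom.get(chrom)
        if d is None:
            return 0, 0
        # overlap requires start < hi and end > lo; MPRs are disjoint & sorted
        i = int(np.searchsorted(d["end"], lo, side="right"))
        j = int(np.searchsorted(d["start"], hi, side="left"))
        if j <= i:
            return 0, 0
        return (
            int(d["cmeth"][j] - d["cmeth"][i]),
            int(d["ctotal"][j] - d["ctotal"][i]),
        )

    def chrom_counts(self, chrom: str) -> tuple[int, int]:
        return self._chrom_totals.get(chrom, (0, 0))


def local_background(
    mar: pd.Series,
    mpr_index: MPRIndex,
    flank: int = DEFAULT_FLANK,
) -> tuple[int, int, float, bool]:
    """Pooled MPR counts in the MAR's +/-flank window and the pooled rate.

    The window [start - flank, end + flank) is half-open: an MPR starting
    exactly at end + flank is excluded. When no MPR falls in the window the
    chromosome-wide MPR rate is used and the result flagged as a fallback.
    Returns (n_meth, n_total, rate, fallback).
    """
    lo = int(mar["start"]) - flank
    hi = int(mar["end"]) + flank
    meth, total = mpr_index.pooled_counts(str(mar["chrom"]), lo, hi)
    fallback = False
    if total == 0:
        meth, total = mpr_index.chrom_counts(str(mar["chrom"]))
        fallback = True
        if total == 0:
            return 0, 0, float("nan"), True
    return meth, total, meth / total, fallback


def mar_binomial_test(k: int, n: int, p0: float) -> float:
    """Exact one-tailed upper binomial tail P[X >= k], X ~ Binomial(n, p0)."""
    if not (0 <= k <= n):
        raise ValueError("require 0 <= k <= n")
    if not (0 <= p0 <= 1):
        raise ValueError("require 0 <= p0 <= 1")
    if n == 0:
        return 1.0
    return float(sps.binom.sf(k - 1, n, p0))


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return sps.false_discovery_control(p, method="bh")


def score_mars(
    segments: pd.DataFrame,
    flank: int = DEFAULT_FLANK,
    fdr_cutoff: float = FDR_CUTOFF,
    min_len: int = NDR_MIN_LEN,
) -> pd.DataFrame:
    """Score every MAR of one replicate's segmentation and call NDRs.

    is_significant = (q < fdr_cutoff); is_ndr additionally requires
    end - start > 100 bp (strictly).
    """
    mars = segments[segments["state"] == "MAR"].reset_index(drop=True)
    index = MPRIndex(segments)
    rows = []
    for _, mar in mars.iterrows():
        meth, total, rate, fb = local_background(mar, index, flank=flank)
        if np.isnan(rate):
            warnings.warn(f"no MPR background on {mar['chrom']}; p set to 1")
            p = 1.0
            rate = float("nan")
        else:
            p = mar_binomial_test(int(mar["n_meth"]), int(mar["n_total"]), rate)
        rows.append({
            "chrom": mar["chrom"], "start": int(mar["start"]), "end": int(mar["end"]),
            "n_sites": int(mar["n_sites"]), "n_meth": int(mar["n_meth"]),
            "n_total": int(mar["n_total"]), "background_rate": rate,
            "background_fallback": fb, "p_value": p,
        })
    calls = pd.DataFrame(rows, columns=[c for c in NDR_COLUMNS if c not in
                                        ("q_value", "is_significant", "is_ndr")])
    if len(calls) == 0:
        calls["q_value"] = np.empty(0)
        calls["is_significant"] = np.empty(0, bool)
        calls["is_ndr"] = np.empty(0, bool)
        return calls
    calls["q_value"] = bh_fdr(calls["p_value"].to_numpy())
    calls["is_significant"] = calls["q_value"] < fdr_cutoff
    calls["is_ndr"] = calls["is_significant"] & (
        (calls["end"] - calls["start"]) >= min_len
    )
    return calls


def call_ndrs(scored: pd.DataFrame) -> pd.DataFrame:
    """Subset scored MARs to NDR calls (significant and > 100 bp)."""
    return scored[scored["is_ndr"]].reset_index(drop=True)


def _merge_intervals(iv: np.ndarray) -> np.ndarray:
    """Merge overlapping/touching-by-overlap [start, end) rows (sorted input)."""
    if len(iv) == 0:
        return iv
    out = [list(iv[0])]
    for s, e in iv[1:]:
        if s < out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return np.asarray(out)


def intersect_replicates(ndrs_rep1: pd.DataFrame, ndrs_rep2: pd.DataFrame) -> pd.DataFrame:
    """Replicate-supported NDRs: unions of >= 1 bp overlapping cross-replicate pairs.

    Each overlapping (rep1, rep2) pair contributes the union of the two
    intervals; transitively overlapping unions are merged into one interval.
    NDRs without a partner in the other replicate are dropped.
    """
    out_rows = []
    chroms = sorted(set(ndrs_rep1["chrom"]).intersection(set(ndrs_rep2["chrom"])))
    for chrom in chroms:
        a = ndrs_rep1.loc[ndrs_rep1["chrom"] == chrom, ["start", "end"]].to_numpy(np.int64)
        b = ndrs_rep2.loc[ndrs_rep2["chrom"] == chrom, ["start", "end"]].to_numpy(np.int64)
        a = a[np.argsort(a[:, 0])]
        b = b[np.argsort(b[:, 0])]
        unions = []
        j0 = 0
        for s, e in a:
            for s2, e2 in b[j0:]:
                if e2 <= s:
                    j0 += 1
                    continue
                if s2 >= e:
                    break
                unions.append((min(s, s2), max(e, e2)))
        if not unions:
            continue
        unions = np.asarray(sorted(unions))
        for s, e in _merge_intervals(unions):
            out_rows.append({"chrom": chrom, "start": int(s), "end": int(e)})
    return pd.DataFrame(out_rows, columns=["chrom", "start", "end"])
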