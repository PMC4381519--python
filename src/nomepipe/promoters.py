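"""Promoter methylation classes, nucleosome phasing, and NP/NDR subclustering.

Promoters are classified from endogenous (HCG) methylation in a -300/+500 bp
transcription-oriented window around the TSS, in two samples: a parental
methylated line (A, HCT116-like) and a demethylated derivative (B,
DKO1-like). Classes: UU (unmethylated in both, < 5%), MU (methylated in A
>= 60%, unmethylated in B < 5%), MM (methylated in both, >= 60% / >= 25%).
Promoters failing the coverage filters (>= 3 HCG sites and >= 10 reads per
sample) or falling between the cutoffs are unclassified.

Nucleosome phasing is quantified as a positional autocorrelation: Pearson
correlation of per-site GpC accessibility levels between pairs of GCH sites
0-700 bp downstream of the TSS, pooled across all promoters of a class and
binned by pair distance. MU promoters are subclustered into NP (gained
phased nucleosomes only) vs NDR (also gained central depletion) by k=2
hierarchical clustering of their accessibility profiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .io import pooled_level

WINDOW_UP = 300
WINDOW_DOWN = 500


@dataclass(frozen=True)
class ClassCutoffs:
    """Classification thresholds (fractions) and coverage filters."""

    unmeth: float = 0.05
    meth_a: float = 0.60
    meth_b: float = 0.25
    min_sites: int = 3
    min_reads: int = 10


@dataclass(frozen=True)
class WindowSummary:
    """Per-sample HCG summary over one promoter window."""

    n_hcg_sites: int
    n_reads: int
    level: float  # pooled sum(meth)/sum(total); NaN when no reads


def promoter_window(
    tss: int, strand: str, up: int = WINDOW_UP, down: int = WINDOW_DOWN,
    chrom_length: Optional[int] = None,
) -> tuple[int, int]:
    """Transcription-oriented [-up, +down) window around a stranded TSS.

    On the minus strand the window is mirrored so that -300/+500 remain
    upstream/downstream in the transcription sense. Windows are clipped at
    chromosome bounds when ``chrom_length`` is given.
    """
    if strand == "+":
        lo, hi = tss - up, tss + down
    elif strand == "-":
        lo, hi = tss - down + 1, tss + up + 1
    else:
        raise ValueError(f"invalid strand {strand!r}")
    if chrom_length is not None:
        clipped = (lo < 0) or (hi > chrom_length)
        lo, hi = max(lo, 0), min(hi, chrom_length)
        if clipped:
            warnings.warn(f"promoter window at {tss} clipped to [{lo}, {hi})")
    return lo, hi


def summarize_window(
    hcg_calls: pd.DataFrame, chrom: str, lo: int, hi: int
) -> WindowSummary:
    """Pooled HCG methylation summary over [lo, hi) on one chromosome."""
    sel = hcg_calls[
        (hcg_calls["chrom"] == chrom)
        & (hcg_calls["pos"] >= lo)
        & (hcg_calls["pos"] < hi)
        & (hcg_calls["n_total"] > 0)
    ]
    return WindowSummary(
        n_hcg_sites=len(sel),
        n_reads=int(sel["n_total"].sum()),
        level=pooled_level(sel["n_meth"].to_numpy(), sel["n_total"].to_numpy()),
    )


def classify_promoter(
    summary_a: WindowSummary,
    summary_b: WindowSummary,
    cutoffs: ClassCutoffs = ClassCutoffs(),
) -> str:
    """Assign UU/MU/MM/unclassified from the two per-sample window summaries.

    Levels between the unmethylated and methylated cutoffs fall into a gap
    zone and are unclassified, as are promoters failing the coverage filters
    and UM promoters (unmethylated in A, methylated in B), which are not a
    class in this design.
    """
    for s in (summary_a, summary_b):
        if s.n_hcg_sites < cutoffs.min_sites or s.n_reads < cutoffs.min_reads:
            return "unclassified"
    a, b = summary_a.level, summary_b.level
    if np.isnan(a) or np.isnan(b):
        return "unclassified"
    if a < cutoffs.unmeth and b < cutoffs.unmeth:
        return "UU"
    if a >= cutoffs.meth_a:
        if b < cutoffs.unmeth:
            return "MU"
        if b >= cutoffs.meth_b:
            return "MM"
    return "unclassified"


PROMOTER_TABLE_COLUMNS = [
    "name", "chrom", "tss", "strand", "is_cgi",
    "n_sites_a", "n_reads_a", "level_a",
    "n_sites_b", "n_reads_b", "level_b",
    "class_label", "mu_subclass",
]


def classify_promoters(
    hcg_calls_a: pd.DataFrame,
    hcg_calls_b: pd.DataFrame,
    tss: pd.DataFrame,
    cgi: Optional[pd.DataFrame] = None,
    cutoffs: ClassCutoffs = ClassCutoffs(),
    chrom_lengths: Optional[dict[str, int]] = None,
) -> pd.DataFrame:
    """Build the promoter table: window summaries and class per stranded TSS.

    ``tss`` is a BED6-like frame (chrom, start, end, name, score, strand)
    with start = TSS position; ``cgi`` intervals set the is_cgi flag.
    Replicates should be pooled into each sample's call table beforehand.
    """
    cgi_by_chrom: dict[str, np.ndarray] = {}
    if cgi is not None and len(cgi):
        for chrom, grp in cgi.groupby("chrom"):
            iv = grp[["start", "end"]].to_numpy(np.int64)
            cgi_by_chrom[str(chrom)] = iv[np.argsort(iv[:, 0])]
    rows = []
    n_um = 0
    for _, t in tss.iterrows():
        chrom, pos, strand = str(t["chrom"]), int(t["start"]), str(t["strand"])
        clen = chrom_lengths.get(chrom) if chrom_lengths else None
        lo, hi = promoter_window(pos, strand, chrom_length=clen)
        sa = summarize_window(hcg_calls_a, chrom, lo, hi)
        sb = summarize_window(hcg_calls_b, chrom, lo, hi)
        label = classify_promoter(sa, sb, cutoffs)
        if (
            label == "unclassified"
            and not np.isnan(sa.level) and not np.isnan(sb.level)
            and sa.level < cutoffs.unmeth and sb.level >= cutoffs.meth_b
        ):
            n_um += 1
        is_cgi = False
        iv = cgi_by_chrom.get(chrom)
        if iv is not None:
            is_cgi = bool(np.any((iv[:, 0] < hi) & (iv[:, 1] > lo)))
        rows.append({
            "name": t.get("name", "."), "chrom": chrom, "tss": pos,
            "strand": strand, "is_cgi": is_cgi,
            "n_sites_a": sa.n_hcg_sites, "n_reads_a": sa.n_reads, "level_a": sa.level,
            "n_sites_b": sb.n_hcg_sites, "n_reads_b": sb.n_reads, "level_b": sb.level,
            "class_label": label, "mu_subclass": "none",
        })
    if n_um:
        warnings.warn(f"{n_um} UM promoters (unmethylated A, methylated B) left unclassified")
    return pd.DataFrame(rows, columns=PROMOTER_TABLE_COLUMNS)


# ---------------------------------------------------------------------------
# Phasing autocorrelation
# ---------------------------------------------------------------------------

def phasing_autocorrelation(
    gch_calls: pd.DataFrame,
    promoters: pd.DataFrame,
    max_dist: int = 700,
    bin_width: int = 10,
    min_pairs: int = 30,
    min_total: int = 3,
) -> pd.DataFrame:
    """Positional Pearson autocorrelation of GpC accessibility downstream of TSSs.

    For every promoter, per-site methylation ratios of GCH sites 0..max_dist
    bp downstream (transcription-oriented) are paired within the promoter;
    pairs are pooled across all promoters and binned by distance rounded to
    the nearest multiple of ``bin_width``. Lag 0 holds the self-pairs (r = 1
    by identity); distinct-site pairs rounding to lag 0 are discarded. Bins
    with fewer than ``min_pairs`` pairs, or with zero variance on either
    side, report r = NaN.

    ``promoters`` needs columns chrom, tss, strand (e.g. a slice of the
    promoter table restricted to one class). Returns (lag, r, n_pairs).
    """
    if len(promoters) < 2:
        raise ValueError("need at least two promoters")
    lag_chunks: list[np.ndarray] = []
    a_chunks: list[np.ndarray] = []
    b_chunks: list[np.ndarray] = []
    n_self = 0
    calls = gch_calls[gch_calls["n_total"] >= min_total]
    by_chrom = {str(c): g for c, g in calls.groupby("chrom")}
    for _, pr in promoters.iterrows():
        grp = by_chrom.get(str(pr["chrom"]))
        if grp is None:
            continue
        tss, strand = int(pr["tss"]), str(pr["strand"])
        pos = grp["pos"].to_numpy()
        if strand == "+":
            mask = (pos >= tss) & (pos <= tss + max_dist)
            dist = pos[mask] - tss
        else:
            mask = (pos <= tss) & (pos >= tss - max_dist)
            dist = tss - pos[mask]
        n_self += int(mask.sum())
        if mask.sum() < 2:
            continue
        lev = (grp["n_meth"].to_numpy()[mask] / grp["n_total"].to_numpy()[mask])
        iu = np.triu_indices(lev.size, k=1)
        dd = np.abs(dist[iu[0]] - dist[iu[1]])
        lag = (np.round(dd / bin_width) * bin_width).astype(int)
        keep = lag > 0
        lag_chunks.append(lag[keep])
        a_chunks.append(lev[iu[0]][keep])
        b_chunks.append(lev[iu[1]][keep])
    rows = [{"lag": 0, "r": 1.0 if n_self else float("nan"), "n_pairs": n_self}]
    if lag_chunks:
        lag = np.concatenate(lag_chunks)
        a = np.concatenate(a_chunks)
        b = np.concatenate(b_chunks)
        for lg in np.unique(lag):
            sel = lag == lg
            x, y = a[sel], b[sel]
            if x.size < min_pairs or np.std(x) == 0 or np.std(y) == 0:
                r = float("nan")
            else:
                # pairs are unordered: symmetrize so r is orientation-free
                xx = np.concatenate([x, y])
                yy = np.concatenate([y, x])
                r = float(np.corrcoef(xx, yy)[0, 1])
            rows.append({"lag": int(lg), "r": r, "n_pairs": int(x.size)})
    return pd.DataFrame(rows, columns=["lag", "r", "n_pairs"])


# ---------------------------------------------------------------------------
# NP vs NDR subclustering
# ---------------------------------------------------------------------------

def subcluster_mu(
    matrix: np.ndarray,
    has_ndr: Sequence[bool],
) -> tuple[np.ndarray, np.ndarray]:
    """Split MU promoters into NP vs NDR chromatin configurations.

    ``matrix`` is an anchor-aligned accessibility ProfileMatrix (rows =
    promoters, transcription-oriented bins, typically +/-1 kb of the TSS in
    the demethylated sample). Rows are centered and scaled, clustered by
    average-linkage Euclidean hierarchical clustering, and the k=2 cut whose
    cluster members more frequently contain a called NDR overlapping the
    promoter window is labeled "NDR"; the other is "NP".

    Returns (labels array of "NP"/"NDR", dendrogram leaf order).
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 4:
        raise ValueError("need a 2-D matrix with at least 4 promoters")
    has_ndr = np.asarray(list(has_ndr), dtype=bool)
    if has_ndr.shape[0] != X.shape[0]:
        raise ValueError("has_ndr must align with matrix rows")
    # fill missing bins with the row mean; all-missing rows with 0
    row_mean = np.nanmean(np.where(np.isfinite(X), X, np.nan), axis=1)
    row_mean = np.where(np.isfinite(row_mean), row_mean, 0.0)
    X = np.where(np.isfinite(X), X, row_mean[:, None])
    # row normalization: center and unit-scale (constant rows stay centered)
    X = X - X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1)
    X = X / np.where(sd > 0, sd, 1.0)[:, None]
    d = pdist(X, metric="euclidean")
    Z = hierarchy.linkage(d, method="average")
    leaf_order = np.asarray(hierarchy.leaves_list(Z))
    k2 = hierarchy.fcluster(Z, t=2, criterion="maxclust")
    if len(np.unique(k2)) < 2:
        warnings.warn("degenerate profiles: single effective cluster")
        label = "NDR" if has_ndr.mean() > 0.5 else "NP"
        return np.full(X.shape[0], label, dtype=object), leaf_order
    freq = {c: has_ndr[k2 == c].mean() for c in np.unique(k2)}
    ndr_cluster = max(freq, key=lambda c: freq[c])
    labels = np.where(k2 == ndr_cluster, "NDR", "NP").astype(object)
    return labels, leaf_order


def ndr_overlap_flags(
    promoters: pd.DataFrame,
    ndrs: pd.DataFrame,
    up: int = WINDOW_UP,
    down: int = WINDOW_DOWN,
) -> np.ndarray:
    """True where a called NDR overlaps the promoter's [-up, +down) window."""
    by_chrom: dict[str, np.ndarray] = {}
    for chrom, grp in ndrs.groupby("chrom"):
        iv = grp[["start", "end"]].to_numpy(np.int64)
        by_chrom[str(chrom)] = iv[np.argsort(iv[:, 0])]
    flags = np.zeros(len(promoters), dtype=bool)
    for i, (_, pr) in enumerate(promoters.iterrows()):
        iv = by_chrom.get(str(pr["chrom"]))
        if iv is None:
            continue
        lo, hi = promoter_window(int(pr["tss"]), str(pr["strand"]), up, down)
        flags[i] = bool(np.any((iv[:, 0] < hi) & (iv[:, 1] > lo)))
    return flags
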