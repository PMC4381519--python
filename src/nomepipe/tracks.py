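"""Binned-signal utilities: Z-scoring, anchor-aligned profiles, clustering,
and megabase-scale domain summaries.

ChIP-seq style enrichment is consumed as a fixed-width binned track
(bedGraph in, 10-bp bins by default) and normalized to a genome-wide
Z-score (subtract the genome mean, divide by the genome SD). Accessibility
and methylation enter as cytosine-call tables whose aggregate level per bin
is the pooled-count ratio. ProfileMatrix rows are transcription-oriented:
minus-strand anchors are reversed so that left-to-right is 5'->3'.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
import pandas as pd


@dataclass
class BinnedTrack:
    """Fixed-width binned genome signal; NaN marks missing bins."""

    bin_width: int
    values: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ValueError("bin width must be positive")
        for chrom, v in self.values.items():
            self.values[chrom] = np.asarray(v, dtype=float)

    @classmethod
    def from_bedgraph(
        cls, df: pd.DataFrame, bin_width: int = 10,
        chrom_lengths: Optional[dict[str, int]] = None,
    ) -> "BinnedTrack":
        """Average bedGraph intervals into fixed bins (interval-length weighted)."""
        values: dict[str, np.ndarray] = {}
        for chrom, grp in df.groupby("chrom"):
            chrom = str(chrom)
            end = chrom_lengths[chrom] if chrom_lengths else int(grp["end"].max())
            nbins = -(-end // bin_width)
            tot = np.zeros(nbins)
            cov = np.zeros(nbins)
            for s, e, v in grp[["start", "end", "value"]].itertuples(index=False):
                b0, b1 = s // bin_width, -(-e // bin_width)
                for b in range(b0, min(b1, nbins)):
                    lo = max(s, b * bin_width)
                    hi = min(e, (b + 1) * bin_width)
                    tot[b] += v * (hi - lo)
                    cov[b] += hi - lo
            vals = np.full(nbins, np.nan)
            vals[cov > 0] = tot[cov > 0] / cov[cov > 0]
            values[chrom] = vals
        return cls(bin_width=bin_width, values=values)

    def to_bedgraph(self) -> pd.DataFrame:
        rows = []
        for chrom, vals in self.values.items():
            for b, v in enumerate(vals):
                if np.isfinite(v):
                    rows.append((chrom, b * self.bin_width, (b + 1) * self.bin_width, v))
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])

    def flat(self) -> np.ndarray:
        return np.concatenate([v for v in self.values.values()]) if self.values else np.empty(0)


def zscore_track(track: BinnedTrack) -> BinnedTrack:
    """Genome-wide Z-score: subtract the genome mean, divide by the genome SD.

    Missing bins stay missing and are excluded from the moments. Raises on
    zero variance or fewer than two covered bins.
    """
    flat = track.flat()
    covered = flat[np.isfinite(flat)]
    if covered.size < 2:
        raise ValueError("need at least two covered bins to Z-score")
    mean = covered.mean()
    sd = covered.std()
    if sd == 0:
        raise ValueError("zero genome-wide variance; Z-score undefined")
    return BinnedTrack(
        bin_width=track.bin_width,
        values={c: (v - mean) / sd for c, v in track.values.items()},
    )


@dataclass
class ProfileMatrix:
    """Anchors x positional-bin matrix for metaplots, heatmaps and clustering.

    Columns span [-flank, +flank) in transcription-oriented ``bin_width``
    steps; ``anchors`` records (chrom, pos, strand) row order.
    """

    matrix: np.ndarray
    anchors: pd.DataFrame
    flank: int
    bin_width: int

    def __post_init__(self) -> None:
        expect = 2 * self.flank // self.bin_width
        if self.matrix.shape[1] != expect:
            raise ValueError(f"expected {expect} columns, got {self.matrix.shape[1]}")

    @property
    def bin_centers(self) -> np.ndarray:
        return np.arange(-self.flank, self.flank, self.bin_width) + self.bin_width / 2

    def metaplot(self) -> np.ndarray:
        """Column means ignoring missing bins."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(self.matrix, axis=0)

    def column_slice(self, lo: int, hi: int) -> np.ndarray:
        """Column index range covering oriented positions [lo, hi)."""
        i0 = max((lo + self.flank) // self.bin_width, 0)
        i1 = min(-(-(hi + self.flank) // self.bin_width), self.matrix.shape[1])
        return np.arange(i0, i1)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.matrix, columns=[f"{int(c)}" for c in self.bin_centers])
        return pd.concat([self.anchors.reset_index(drop=True), df], axis=1)


def aggregate_profile(
    source: Union[pd.DataFrame, BinnedTrack],
    anchors: pd.DataFrame,
    flank: int = 1000,
    bin_width: int = 10,
    min_coverage: float = 0.1,
) -> ProfileMatrix:
    """Anchor-aligned aggregation of calls or a binned track.

    ``source`` is either a cytosine-call DataFrame (per-bin value = pooled
    sum(meth)/sum(total) over member sites) or a BinnedTrack (per-bin value =
    mean of overlapping track bins). ``anchors`` has chrom, pos, strand;
    minus-strand rows are reversed. Rows covering fewer than ``min_coverage``
    of their bins are reported missing (all-NaN) and counted in a warning;
    anchors on absent chromosomes are likewise all-NaN.
    """
    nbins = 2 * flank // bin_width
    mat = np.full((len(anchors), nbins), np.nan)
    is_calls = isinstance(source, pd.DataFrame)
    if is_calls:
        by_chrom = {
            str(c): (g["pos"].to_numpy(), g["n_meth"].to_numpy(), g["n_total"].to_numpy())
            for c, g in source.groupby("chrom")
        }
    low_cov = 0
    dropped = 0
    for i, (_, an) in enumerate(anchors.iterrows()):
        chrom, pos, strand = str(an["chrom"]), int(an["pos"]), str(an["strand"])
        lo = pos - flank
        if is_calls:
            entry = by_chrom.get(chrom)
            if entry is None:
                dropped += 1
                continue
            p, m, t = entry
            sel = (p >= lo) & (p < pos + flank) & (t > 0)
            if not sel.any():
                low_cov += 1
                continue
            idx = (p[sel] - lo) // bin_width
            meth = np.bincount(idx, weights=m[sel], minlength=nbins)
            tot = np.bincount(idx, weights=t[sel], minlength=nbins)
            row = np.full(nbins, np.nan)
            row[tot > 0] = meth[tot > 0] / tot[tot > 0]
        else:
            vals = source.values.get(chrom)
            if vals is None:
                dropped += 1
                continue
            row = np.full(nbins, np.nan)
            for b in range(nbins):
                s = lo + b * bin_width
                e = s + bin_width
                b0 = max(s // source.bin_width, 0)
                b1 = min(-(-e // source.bin_width), vals.size)
                if b1 > b0:
                    chunk = vals[b0:b1]
                    if np.isfinite(chunk).any():
                        row[b] = np.nanmean(chunk)
        if strand == "-":
            row = row[::-1]
        if np.isfinite(row).sum() < min_coverage * nbins:
            low_cov += 1
            continue
        mat[i] = row
    if dropped:
        warnings.warn(f"{dropped} anchors on chromosomes absent from the source")
    if low_cov:
        warnings.warn(f"{low_cov} anchor rows below {min_coverage:.0%} bin coverage")
    return ProfileMatrix(matrix=mat, anchors=anchors.reset_index(drop=True),
                         flank=flank, bin_width=bin_width)


def hcluster_rows(
    profile: Union[ProfileMatrix, np.ndarray],
    k: int,
    window: Optional[tuple[int, int]] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Average-linkage Euclidean clustering of profile rows.

    ``window`` restricts the distance computation to oriented positions
    [lo, hi) (e.g. (-250, 250) to cluster on the central accessibility only).
    Missing bins are filled with the row mean for the distance computation.
    Returns (cluster labels 1..k, dendrogram leaf order).
    """
    from scipy.cluster import hierarchy
    from scipy.spatial.distance import pdist

    if isinstance(profile, ProfileMatrix):
        X = profile.matrix
        if window is not None:
            X = X[:, profile.column_slice(*window)]
    else:
        X = np.asarray(profile, dtype=float)
        if window is not None:
            raise ValueError("window restriction requires a ProfileMatrix")
    if X.shape[0] < k:
        raise ValueError(f"cannot cut {X.shape[0]} rows into {k} clusters")
    row_mean = np.nanmean(np.where(np.isfinite(X), X, np.nan), axis=1)
    row_mean = np.where(np.isfinite(row_mean), row_mean, 0.0)
    X = np.where(np.isfinite(X), X, row_mean[:, None])
    Z = hierarchy.linkage(pdist(X), method="average")
    labels = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    return labels, np.asarray(hierarchy.leaves_list(Z))


WINDOW_SUMMARY_COLUMNS = ["chrom", "start", "end", "gch_level", "hcg_level"]


def window_summarize(
    gch_calls: Optional[pd.DataFrame],
    hcg_calls: Optional[pd.DataFrame],
    tracks: Optional[dict[str, BinnedTrack]],
    chrom_lengths: dict[str, int],
    window: int = 1_000_000,
    cgi: Optional[pd.DataFrame] = None,
    rank_by: str = "gch_level",
) -> pd.DataFrame:
    """Tile the genome into fixed windows and summarize each.

    Per window: pooled GCH (accessibility) and HCG (methylation) levels and
    the mean of each Z-scored track; track bins inside CGI intervals are
    excluded from the track means. Windows with no covered data report NaN.
    Output sorted by ``rank_by`` descending (NaN last) with a ``rank`` column.
    """
    rows = []
    for chrom, length in chrom_lengths.items():
        for w0 in range(0, length, window):
            rows.append({"chrom": chrom, "start": w0, "end": min(w0 + window, length)})
    out = pd.DataFrame(rows)

    def pooled(calls: pd.DataFrame) -> np.ndarray:
        res = np.full(len(out), np.nan)
        for i, r in out.iterrows():
            sel = calls[
                (calls["chrom"] == r["chrom"])
                & (calls["pos"] >= r["start"]) & (calls["pos"] < r["end"])
            ]
            tot = sel["n_total"].sum()
            if tot > 0:
                res[i] = sel["n_meth"].sum() / tot
        return res

    out["gch_level"] = pooled(gch_calls) if gch_calls is not None else np.nan
    out["hcg_level"] = pooled(hcg_calls) if hcg_calls is not None else np.nan
    cgi_by_chrom: dict[str, np.ndarray] = {}
    if cgi is not None and len(cgi):
        for chrom, grp in cgi.groupby("chrom"):
            cgi_by_chrom[str(chrom)] = grp[["start", "end"]].to_numpy(np.int64)
    for name, track in (tracks or {}).items():
        col = np.full(len(out), np.nan)
        for i, r in out.iterrows():
            vals = track.values.get(str(r["chrom"]))
            if vals is None:
                continue
            b0 = r["start"] // track.bin_width
            b1 = min(-(-r["end"] // track.bin_width), vals.size)
            if b1 <= b0:
                continue
            chunk = vals[b0:b1].copy()
            iv = cgi_by_chrom.get(str(r["chrom"]))
            if iv is not None:
                centers = (np.arange(b0, b1) + 0.5) * track.bin_width
                inside = np.zeros(centers.size, dtype=bool)
                for s, e in iv:
                    inside |= (centers >= s) & (centers < e)
                chunk[inside] = np.nan
            if np.isfinite(chunk).any():
                col[i] = np.nanmean(chunk)
        out[name] = col
    out = out.sort_values(rank_by, ascending=False, na_position="last").reset_index(drop=True)
    out.insert(0, "rank", np.arange(1, len(out) + 1))
    return out
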