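"""Synthetic NOMe-seq data generator.

Emulates the latent structure a GpC methyltransferase footprinting assay
observes: nucleosome-depleted regions (NDRs) flanked by phased nucleosome
arrays whose positioning decays with distance, an unphased occupied
background, and megabase-scale low-accessibility domains. From an occupancy
landscape the generator samples per-site GpC (GCH) methylation calls with a
configurable enzyme labeling efficiency, background leak and overdispersed
read depth, and samples endogenous CpG (HCG) methylation for two-sample
promoter-class studies (a parental methylated line and a demethylated
derivative, HCT116-like vs DKO1-like).

Positions are simulated directly as irregular site lists (no reference
sequence); coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

#: Canonical human nucleosome repeat length (bp); configurable everywhere,
#: hard-coded nowhere outside this module.
DEFAULT_REPEAT_LENGTH = 190
#: Nucleosome core footprint (bp).
NUCLEOSOME_FOOTPRINT = 147


@dataclass(frozen=True)
class NDRFeature:
    """Nucleosome-depleted interval: occupancy forced to 0 inside."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("NDR interval must be non-empty")


@dataclass(frozen=True)
class PhasedArrayFeature:
    """Phased nucleosome array around an anchor.

    Rectangular nucleosome footprints are placed at anchor ± k·repeat_length
    (k = 1..n_nucleosomes; k = 0 too when ``include_anchor``), with occupancy
    amplitude decaying geometrically per nucleosome. Linker DNA between
    footprints takes ``linker_occupancy``. Geometric decay keeps the
    occupancy at lag repeat_length an affine function of the occupancy one
    repeat closer to the anchor, which is what makes the phasing
    autocorrelation peak exactly at the repeat length.
    """

    anchor: int
    repeat_length: int = DEFAULT_REPEAT_LENGTH
    n_nucleosomes: int = 4
    decay: float = 0.9
    amplitude: float = 0.95
    linker_occupancy: float = 0.1
    include_anchor: bool = False

    def __post_init__(self) -> None:
        if self.repeat_length <= NUCLEOSOME_FOOTPRINT:
            raise ValueError("repeat length must exceed the 147-bp footprint")
        if not (0 < self.decay <= 1):
            raise ValueError("decay must be in (0, 1]")
        if not (0 <= self.linker_occupancy < self.amplitude <= 1):
            raise ValueError("need 0 <= linker occupancy < amplitude <= 1")
        if self.n_nucleosomes < 1:
            raise ValueError("n_nucleosomes must be >= 1")

    @property
    def span(self) -> tuple[int, int]:
        half = (self.n_nucleosomes + 0.5) * self.repeat_length
        return int(self.anchor - half), int(self.anchor + half)


@dataclass(frozen=True)
class DomainFeature:
    """Low-accessibility domain: labeling ceiling multiplied by ``scale``."""

    start: int
    end: int
    scale: float

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("domain interval must be non-empty")
        if not (0 < self.scale <= 1):
            raise ValueError("domain accessibility scale must be in (0, 1]")


Feature = Union[NDRFeature, PhasedArrayFeature, DomainFeature]


@dataclass
class OccupancyLandscape:
    """Ground-truth nucleosome occupancy over one synthetic chromosome."""

    chrom: str
    length: int
    background: float = 0.85
    ndrs: list[NDRFeature] = field(default_factory=list)
    arrays: list[PhasedArrayFeature] = field(default_factory=list)
    domains: list[DomainFeature] = field(default_factory=list)

    @property
    def truth_ndrs(self) -> list[tuple[int, int]]:
        return [(f.start, f.end) for f in self.ndrs]

    @property
    def truth_phased(self) -> list[tuple[int, int, int, float]]:
        return [
            (f.anchor, f.repeat_length, f.n_nucleosomes, f.decay)
            for f in self.arrays
        ]

    @property
    def truth_domains(self) -> list[tuple[tuple[int, int], float]]:
        return [((f.start, f.end), f.scale) for f in self.domains]

    def occupancy(self, pos: np.ndarray) -> np.ndarray:
        """Nucleosome occupancy probability at each position, in [0, 1]."""
        pos = np.asarray(pos, dtype=np.int64)
        occ = np.full(pos.shape, self.background, dtype=float)
        half = NUCLEOSOME_FOOTPRINT // 2
        for arr in self.arrays:
            lo, hi = arr.span
            in_span = (pos >= lo) & (pos < hi)
            if not in_span.any():
                continue
            occ[in_span] = np.minimum(occ[in_span], arr.linker_occupancy)
            ks = range(0, arr.n_nucleosomes + 1) if arr.include_anchor else range(
                1, arr.n_nucleosomes + 1
            )
            for k in ks:
                amp = arr.amplitude * arr.decay ** max(k - 1, 0)
                for sign in ((1,) if k == 0 else (-1, 1)):
                    c = arr.anchor + sign * k * arr.repeat_length
                    hit = (pos >= c - half) & (pos < c - half + NUCLEOSOME_FOOTPRINT)
                    occ[hit] = np.maximum(occ[hit], amp)
        for ndr in self.ndrs:
            occ[(pos >= ndr.start) & (pos < ndr.end)] = 0.0
        return np.clip(occ, 0.0, 1.0)

    def accessibility_scale(self, pos: np.ndarray) -> np.ndarray:
        """Domain multiplier on the labeling ceiling (1 outside domains)."""
        pos = np.asarray(pos, dtype=np.int64)
        scale = np.ones(pos.shape, dtype=float)
        for dom in self.domains:
            scale[(pos >= dom.start) & (pos < dom.end)] = dom.scale
        return scale


@dataclass(frozen=True)
class SimulationConfig:
    """Assay parameters for sampling NOMe-seq calls from a landscape."""

    mean_gch_spacing: float = 15.0
    mean_hcg_spacing: float = 80.0
    enzyme_efficiency: float = 0.8
    background_leak: float = 0.05
    mean_depth: float = 30.0
    depth_dispersion: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.background_leak < self.enzyme_efficiency <= 1):
            raise ValueError("need 0 <= background_leak < enzyme_efficiency <= 1")
        if self.mean_gch_spacing <= 0 or self.mean_hcg_spacing <= 0:
            raise ValueError("site spacings must be positive")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        if self.depth_dispersion < 0:
            raise ValueError("depth_dispersion must be >= 0")


def simulate_sites(chrom_length: int, mean_spacing: float, seed: int) -> np.ndarray:
    """Sample strictly increasing site positions with geometric inter-site gaps.

    Gap lengths are i.i.d. Geometric with the given mean (support >= 1), so the
    site count over L bp is approximately Poisson(L / mean_spacing).
    """
    if chrom_length < 0 or mean_spacing <= 0:
        raise ValueError("chrom_length must be >= 0 and mean_spacing > 0")
    if chrom_length == 0:
        return np.empty(0, dtype=np.int64)
    rng = np.random.default_rng(seed)
    n_guess = int(chrom_length / mean_spacing * 1.3) + 16
    positions: list[np.ndarray] = []
    last = -1
    while last < chrom_length:
        gaps = rng.geometric(1.0 / mean_spacing, size=n_guess)
        block = last + np.cumsum(gaps)
        positions.append(block)
        last = int(block[-1])
    pos = np.concatenate(positions)
    return pos[pos < chrom_length].astype(np.int64)


def build_landscape(
    length: int,
    features: Sequence[Feature],
    repeat_length: int = DEFAULT_REPEAT_LENGTH,
    background: float = 0.85,
    chrom: str = "chrS",
) -> OccupancyLandscape:
    """Assemble an occupancy landscape from feature specs.

    Features carrying a repeat length of None inherit ``repeat_length``.
    Overlapping NDRs and overlapping domains are contradictory and rejected;
    phased arrays may interleave (occupancy takes the maximum footprint).
    """
    ndrs = [f for f in features if isinstance(f, NDRFeature)]
    arrays = [f for f in features if isinstance(f, PhasedArrayFeature)]
    domains = [f for f in features if isinstance(f, DomainFeature)]
    for group, label in ((ndrs, "NDR"), (domains, "domain")):
        ivs = sorted((f.start, f.end) for f in group)
        for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
            if s2 < e1:
                raise ValueError(f"overlapping {label} features are contradictory")
    for f in ndrs + domains:
        if f.start < 0 or f.end > length:
            raise ValueError("feature interval outside the chromosome")
    return OccupancyLandscape(
        chrom=chrom, length=length, background=background,
        ndrs=ndrs, arrays=arrays, domains=domains,
    )


def _draw_depth(rng: np.random.Generator, n: int, mean: float, disp: float) -> np.ndarray:
    """Overdispersed read depth: NB with Var = m + disp*m^2 (disp=0 -> Poisson)."""
    if disp == 0:
        return rng.poisson(mean, size=n)
    r = 1.0 / disp
    p = r / (r + mean)
    return rng.negative_binomial(r, p, size=n)


def sample_nome_calls(
    landscape: OccupancyLandscape,
    config: SimulationConfig,
    n_replicates: int = 1,
    sites: Optional[np.ndarray] = None,
) -> list[pd.DataFrame]:
    """Sample GCH cytosine-call tables from a landscape.

    Per site the labeling probability is
    ``leak + (efficiency - leak) * (1 - occupancy) * domain_scale``; the read
    total is overdispersed around ``mean_depth`` and the methylated count is
    Binomial(total, p). Replicates share site positions (the genome is fixed)
    but are resampled independently — a biological-replicate model.
    """
    if sites is None:
        sites = simulate_sites(landscape.length, config.mean_gch_spacing, config.seed)
    occ = landscape.occupancy(sites)
    scale = landscape.accessibility_scale(sites)
    p = config.background_leak + (
        config.enzyme_efficiency - config.background_leak
    ) * (1.0 - occ) * scale
    ss = np.random.SeedSequence(entropy=config.seed, spawn_key=(1,))
    out = []
    for child in ss.spawn(n_replicates):
        rng = np.random.default_rng(child)
        total = _draw_depth(rng, sites.size, config.mean_depth, config.depth_dispersion)
        meth = rng.binomial(total, p)
        out.append(
            pd.DataFrame(
                {
                    "chrom": landscape.chrom,
                    "pos": sites,
                    "strand": "+",
                    "context": "GCH",
                    "n_meth": meth,
                    "n_total": total,
                }
            )
        )
    return out


# ---------------------------------------------------------------------------
# Two-sample promoter study
# ---------------------------------------------------------------------------

PROMOTER_CLASSES = ("UU", "MU", "MM")


@dataclass(frozen=True)
class PromoterTruth:
    """Ground truth for one synthetic promoter in the two-sample design.

    ``level_a``/``level_b`` are endogenous HCG methylation fractions in the
    parental (A, HCT116-like) and demethylated (B, DKO1-like) samples;
    they must be consistent with the class cutoffs the classifier applies
    (<5% unmethylated; >=60% / >=25% methylated in A / B).
    """

    tss: int
    strand: str
    is_cgi: bool
    class_truth: str
    level_a: float
    level_b: float
    mu_subclass_truth: str = "none"  # NP | NDR | none
    n_hcg_override: Optional[int] = None
    depth_override: Optional[float] = None
    name: str = ""

    def __post_init__(self) -> None:
        if self.class_truth not in PROMOTER_CLASSES:
            raise ValueError(f"unknown promoter class {self.class_truth!r}")
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be + or -")
        if self.mu_subclass_truth not in ("NP", "NDR", "none"):
            raise ValueError("mu_subclass_truth must be NP, NDR or none")
        if self.mu_subclass_truth != "none" and self.class_truth != "MU":
            raise ValueError("only MU promoters carry an NP/NDR subclass")
        checks = {
            "UU": self.level_a < 0.05 and self.level_b < 0.05,
            "MU": self.level_a >= 0.60 and self.level_b < 0.05,
            "MM": self.level_a >= 0.60 and self.level_b >= 0.25,
        }
        if not checks[self.class_truth]:
            raise ValueError(
                f"truth levels ({self.level_a}, {self.level_b}) inconsistent "
                f"with class {self.class_truth}"
            )


def _promoter_window(tss: int, strand: str, up: int = 300, down: int = 500) -> tuple[int, int]:
    if strand == "+":
        return tss - up, tss + down
    return tss - down + 1, tss + up + 1


def sample_promoters(
    truths: Sequence[PromoterTruth],
    config: SimulationConfig,
    chrom: str = "chrS",
) -> dict:
    """Sample two-sample HCG calls plus TSS/CGI annotations for a promoter set.

    HCG sites inside each promoter's -300/+500 window carry binomial counts at
    the promoter's truth methylation level in each sample. Site counts and
    depth can be forced per promoter (to build filter-failing promoters).
    Returns ``{"hcg_calls": {"A": df, "B": df}, "tss": df, "cgi": df}``.
    """
    rng = np.random.default_rng(np.random.SeedSequence(entropy=config.seed, spawn_key=(2,)))
    rows_a, rows_b, tss_rows, cgi_rows = [], [], [], []
    for i, tr in enumerate(truths):
        lo, hi = _promoter_window(tr.tss, tr.strand)
        width = hi - lo
        if tr.n_hcg_override is not None:
            n_sites = tr.n_hcg_override
        else:
            n_sites = max(3, rng.poisson(width / config.mean_hcg_spacing))
        sites = np.sort(rng.choice(np.arange(lo, hi), size=min(n_sites, width), replace=False))
        depth = tr.depth_override if tr.depth_override is not None else config.mean_depth
        for level, rows in ((tr.level_a, rows_a), (tr.level_b, rows_b)):
            total = _draw_depth(rng, sites.size, depth, config.depth_dispersion)
            meth = rng.binomial(total, level)
            for pos, m, t in zip(sites, meth, total):
                rows.append((chrom, int(pos), "+", "HCG", int(m), int(t)))
        name = tr.name or f"prom{i}"
        tss_rows.append((chrom, tr.tss, tr.tss + 1, name, 0, tr.strand))
        if tr.is_cgi:
            cgi_rows.append((chrom, lo, hi, f"CGI_{name}", 0, "."))
    cols = ["chrom", "pos", "strand", "context", "n_meth", "n_total"]
    bed_cols = ["chrom", "start", "end", "name", "score", "strand"]
    return {
        "hcg_calls": {
            "A": pd.DataFrame(rows_a, columns=cols).sort_values(["chrom", "pos"]).reset_index(drop=True),
            "B": pd.DataFrame(rows_b, columns=cols).sort_values(["chrom", "pos"]).reset_index(drop=True),
        },
        "tss": pd.DataFrame(tss_rows, columns=bed_cols),
        "cgi": pd.DataFrame(cgi_rows, columns=bed_cols),
    }


def promoter_landscape_features(
    truths: Sequence[PromoterTruth],
    sample: str,
    repeat_length: int = DEFAULT_REPEAT_LENGTH,
    ndr_halfwidth: tuple[int, int] = (80, 120),
    n_nucleosomes: int = 4,
    decay: float = 0.9,
) -> list[Feature]:
    """Chromatin features implied by promoter truth classes for one sample.

    Sample A (parental): UU promoters are open (NDR + phased flanks);
    methylated promoters (MU, MM) sit in unphased occupied chromatin — no
    features. Sample B (demethylated): UU unchanged; MU-NP promoters gain a
    phased array with a nucleosome positioned over the TSS and no depletion;
    MU-NDR promoters gain a central NDR flanked by phased arrays; MM stay
    closed.
    """
    if sample not in ("A", "B"):
        raise ValueError("sample must be 'A' or 'B'")
    feats: list[Feature] = []
    up, down = ndr_halfwidth
    for tr in truths:
        sgn = 1 if tr.strand == "+" else -1
        open_here = tr.class_truth == "UU" or (
            sample == "B" and tr.class_truth == "MU" and tr.mu_subclass_truth == "NDR"
        )
        phased_only = (
            sample == "B" and tr.class_truth == "MU" and tr.mu_subclass_truth == "NP"
        )
        if open_here:
            lo = tr.tss - (up if sgn == 1 else down)
            hi = tr.tss + (down if sgn == 1 else up)
            feats.append(NDRFeature(lo, hi))
            for edge in (lo, hi):
                feats.append(
                    PhasedArrayFeature(
                        anchor=edge, repeat_length=repeat_length,
                        n_nucleosomes=n_nucleosomes, decay=decay,
                    )
                )
        elif phased_only:
            feats.append(
                PhasedArrayFeature(
                    anchor=tr.tss, repeat_length=repeat_length,
                    n_nucleosomes=n_nucleosomes, decay=decay, include_anchor=True,
                )
            )
    return feats


def simulate_promoter_study(
    truths: Sequence[PromoterTruth],
    config: SimulationConfig,
    length: int,
    repeat_length: int = DEFAULT_REPEAT_LENGTH,
    n_replicates: int = 2,
    chrom: str = "chrS",
) -> dict:
    """Full two-sample study: GCH calls per sample/replicate, HCG calls, BEDs.

    Returns a dict with keys ``gch_calls`` ({"A": [rep...], "B": [rep...]}),
    ``hcg_calls``, ``tss``, ``cgi``, ``landscapes``.
    """
    landscapes = {}
    gch = {}
    sites = simulate_sites(length, config.mean_gch_spacing, config.seed)
    for k, sample in enumerate(("A", "B")):
        feats = promoter_landscape_features(truths, sample, repeat_length)
        landscapes[sample] = build_landscape(
            length, feats, repeat_length=repeat_length, chrom=chrom
        )
        sub = SimulationConfig(
            **{**config.__dict__, "seed": (config.seed * 2 + k) % (2**31 - 1)}
        )
        gch[sample] = sample_nome_calls(
            landscapes[sample], sub, n_replicates=n_replicates, sites=sites
        )
    prom = sample_promoters(truths, config, chrom=chrom)
    return {
        "gch_calls": gch,
        "hcg_calls": prom["hcg_calls"],
        "tss": prom["tss"],
        "cgi": prom["cgi"],
        "landscapes": landscapes,
    }


def scatter_ndr_landscape(
    length: int,
    n_ndrs: int,
    seed: int = 0,
    ndr_halfwidth: tuple[int, int] = (75, 200),
    min_spacing: int = 25_000,
    repeat_length: int = DEFAULT_REPEAT_LENGTH,
    chrom: str = "chrS",
) -> OccupancyLandscape:
    """Scatter NDRs (each flanked by phased arrays) across a synthetic genome.

    NDR half-widths are drawn uniformly from ``ndr_halfwidth`` (so lengths
    are at least 150 bp by default); centers are spaced at least
    ``min_spacing`` apart. The landscape's ``truth_ndrs`` are the benchmark
    ground truth for end-to-end NDR recovery.
    """
    rng = np.random.default_rng(seed)
    lanes = np.arange(min_spacing, length - min_spacing, min_spacing)
    if n_ndrs > lanes.size:
        raise ValueError("too many NDRs for the requested genome length")
    centers = np.sort(rng.choice(lanes, size=n_ndrs, replace=False))
    centers = centers + rng.integers(-min_spacing // 5, min_spacing // 5, size=n_ndrs)
    feats: list[Feature] = []
    for c in centers:
        half = int(rng.integers(ndr_halfwidth[0], ndr_halfwidth[1] + 1))
        s, e = int(c - half), int(c + half)
        feats.append(NDRFeature(s, e))
        for edge in (s, e):
            feats.append(PhasedArrayFeature(anchor=edge, repeat_length=repeat_length))
    return build_landscape(length, feats, repeat_length=repeat_length, chrom=chrom)


def default_promoter_truths(
    n_uu: int,
    n_mu: int,
    n_mm: int,
    n_fail: int = 0,
    spacing: int = 6000,
    start: int = 5000,
    seed: int = 0,
    mu_ndr_fraction: float = 0.2,
) -> list[PromoterTruth]:
    """A shuffled promoter truth set with class levels clearing the cutoffs.

    Filter-failing promoters (UU levels but only two HCG sites) exercise the
    classifier's unclassified sink. MU promoters split into NP/NDR subclasses
    at ``mu_ndr_fraction``.
    """
    rng = np.random.default_rng(seed)
    specs: list[dict] = []
    specs += [dict(class_truth="UU", level_a=0.01, level_b=0.01) for _ in range(n_uu)]
    n_ndr = int(round(n_mu * mu_ndr_fraction))
    specs += [
        dict(class_truth="MU", level_a=0.8, level_b=0.01,
             mu_subclass_truth="NDR" if i < n_ndr else "NP")
        for i in range(n_mu)
    ]
    specs += [dict(class_truth="MM", level_a=0.8, level_b=0.5) for _ in range(n_mm)]
    specs += [
        dict(class_truth="UU", level_a=0.01, level_b=0.01, n_hcg_override=2)
        for _ in range(n_fail)
    ]
    rng.shuffle(specs)
    truths = []
    for i, sp in enumerate(specs):
        strand = "+" if rng.random() < 0.5 else "-"
        truths.append(
            PromoterTruth(
                tss=start + i * spacing, strand=strand, is_cgi=True,
                name=f"prom{i}", **sp,
            )
        )
    return truths
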