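# Methods

## The observation model

NOMe-seq reports, for every cytosine, a methylated count *k* and a read
total *n*. Trinucleotide context partitions the sites: GCH (H = A, C, T)
carries the exogenous GpC methyltransferase signal — enzyme accessibility —
HCG carries endogenous CpG methylation, and GCG is ambiguous between the
two and excluded from every analysis. All aggregate "levels" are
pooled-count ratios Σk/Σn rather than means of per-site ratios, because the
NDR significance test operates on pooled counts; the one exception is the
phasing autocorrelation, which correlates per-site ratios by construction
(sites under 3 reads dropped there, configurable).

Coordinates are uniformly 0-based half-open in memory and in BED on disk.

## Accessibility segmentation

The ordered GCH series of one sample replicate is modeled by a two-state
hidden Markov chain. State 0 is methyltransferase-protected (MPR-like),
state 1 accessible (MAR-like); identifiability is enforced by requiring the
accessible emission mean α₁/(α₁+β₁) to exceed the protected mean. Emissions
are beta-binomial — binomial labeling with a latent Beta-distributed
per-site rate — which absorbs the overdispersion that depth variation and
residual occupancy heterogeneity create; the pmf is evaluated in log space
via log-gamma.

Transitions are homogeneous between consecutive GCH sites regardless of
their genomic distance, and the series is broken into independent chains
wherever consecutive sites are more than `max_gap` = 500 bp apart (or at a
chromosome change). Distance-independent transitions keep the model
identical to its standard two-state form; the chain break prevents state
information from propagating across site deserts, where a homogeneous
transition would otherwise manufacture phantom segments. The 500 bp default
is an exposed flag, not a fitted quantity.

Fitting is EM: exact forward–backward in log space for the E-step;
transition and initial probabilities updated exactly; emission shapes
updated by method of moments on responsibility-weighted counts (the
weighted variance of per-site fractions decomposes into the latent beta
variance plus binomial noise E[θ(1−θ)]/n, and the moment equations are
solved for the beta variance). The moment update is fast and deterministic
but is not an exact M-step, so each iteration is guarded: if the full
update would lower the total log-likelihood, the iteration falls back to
the exact transition-only update — a generalized EM step that cannot
decrease the likelihood — and fitting stops. The recorded log-likelihood
trace is therefore non-decreasing by construction, and in practice the
guard almost never triggers. Training is per replicate; each replicate is
decoded with its own parameters.

Viterbi decoding is exact joint maximization in log space with ties broken
deterministically toward the protected state (the conservative call).
Maximal same-state runs with fewer than 3 GCH sites are absorbed into the
flanking run whose state carries the higher emission likelihood for the
absorbed sites (ties and chain-terminal runs go to the preceding or only
neighbor), with their counts pooled into the host segment — absorption
rather than deletion so that segments tile every chain. Because runs
alternate, both flanks of an interior short run share a state and the
likelihood comparison reduces to the tie-break; the general rule is kept
for robustness. A chain with fewer than 3 sites in total yields no
segments. Segment end coordinates are the last member GCH position + 2,
covering the dinucleotide. MPR segments of 100–200 bp flanked by MARs on
both sides are flagged as candidate mononucleosomes.

## NDR calling

Each MAR is compared to the pooled counts of every MPR overlapping its
±100 kb window (half-open: an MPR starting exactly at the boundary is
outside). With background rate p₀ = Σk/Σn over those MPRs, the MAR's
pooled counts give an exact one-tailed upper binomial tail
P[X ≥ k], X ~ Bin(n, p₀) — no normal approximation, so small-count
behavior is exact and the test is conservative on discrete counts. When no
MPR falls in the window the chromosome-wide MPR rate is used and the call
flagged. P-values are Benjamini–Hochberg adjusted genome-wide across all
MARs of a replicate (the field-default FDR procedure); q < 0.01 marks
significance, and significant MARs strictly longer than 100 bp are NDRs.
Replicates are segmented and tested independently, then intersected: each
cross-replicate pair overlapping by ≥ 1 bp contributes the union of the two
intervals, and transitively overlapping unions merge. The union (rather
than the intersection or one replicate's interval) is a design choice;
downstream overlap logic is insensitive to it at ≥ 1 bp stringency.

## Promoter methylation classes

Promoter windows are −300/+500 bp around the TSS, mirrored on the minus
strand so the bounds stay transcription-oriented. Replicates are pooled
per sample before summarizing. A promoter enters classification only with
≥ 3 HCG sites and ≥ 10 reads in each sample; then, with A the parental and
B the demethylated sample: A < 5% and B < 5% → UU; A ≥ 60% and B < 5% →
MU; A ≥ 60% and B ≥ 25% → MM. Levels between the unmethylated and
methylated cutoffs fall in a gap zone and are deliberately unclassified —
the cutoffs define the classes, and exclusion is the only reading under
which the classes do not exhaust all promoters. UM promoters
(unmethylated in A, methylated in B) are not a class in this design; they
are counted and reported unclassified with a warning.

## Phasing autocorrelation

For one promoter class, per-site GCH levels of sites 0–700 bp downstream
of each TSS are paired within promoters, pooled across the class, and
binned by pair distance rounded to the nearest multiple of 10 bp (bins
centered on multiples of 10, matching the track binning; per-bp lags are
not estimable with irregular GCH spacing). Lag 0 is the self-pair bin
(r = 1 by the Pearson identity); distinct pairs rounding to lag 0 (< 5 bp
apart) are discarded. Pairs are unordered, so each bin's correlation is
computed on the symmetrized pair set, making r orientation-free. Bins with
fewer than 30 pairs, or with zero variance on either side, report NaN.
Pooling across promoters (rather than averaging per-promoter correlations)
is a design choice: it weights promoters by their informative pairs and is
stable at realistic site densities.

Two statistical caveats are documented rather than hidden. First, pairs
within a promoter share sites, so the null variance of r per bin is
slightly larger than the i.i.d. 1/√n; second, ~70 lag bins are examined
simultaneously. Under a null simulation the max over bins of |r|·√n
typically lands between 2 and 3.4 — occasionally above a naive per-bin 3σ
envelope. Unit tests therefore bound the max statistic at 4; the phased
vs unphased contrast itself is far larger (peak r ≈ 0.85 against a null
envelope of ≈ 0.03 at the peak's lag) and unaffected.

## NP/NDR subclustering

MU promoters are clustered on their anchor-aligned accessibility profiles
in the demethylated sample (±1 kb, 10-bp bins, minus-strand rows reversed).
Rows are centered and unit-scaled, missing bins filled with the row mean,
and average-linkage Euclidean hierarchical clustering is cut at k = 2. The
cluster whose members more often contain a called NDR overlapping the
promoter window is labeled NDR; the other NP. Identical-profile degeneracy
(a single effective cluster) is flagged with a warning rather than an
arbitrary split.

## Tracks and domains

ChIP-style enrichment enters as bedGraph, is averaged into 10-bp bins
(interval-length weighted) and Z-scored against the genome: subtract the
genome-wide mean over covered bins, divide by the genome-wide SD
(population SD, ddof 0). Profile matrices are anchors × oriented 10-bp
bins; per-bin values are pooled-count levels (calls) or track-bin means;
metaplots are column means ignoring missing values. Rows with under 10%
bin coverage are reported missing — the data give no principled coverage
floor, so the floor is explicit and configurable. Window summaries tile
each chromosome with 1-Mb windows, compute pooled GCH/HCG levels and mean
track Z-scores (track bins inside CpG islands excluded from the means, so
that focal CGI signal does not mask domain-scale enrichment), and rank by a
chosen column, accessibility by default.

## The synthetic generator

The generator emulates the latent structure the assay observes, not the
assay chemistry. An occupancy landscape is background occupancy 0.85
(unphased chromatin), zero inside truth NDRs, and rectangular 147-bp
nucleosome footprints at anchor ± k·R for phased arrays (repeat length R
defaulting to 190 bp — the canonical human value; the pipeline itself
never assumes any repeat length), with amplitude 0.95 decaying
geometrically (0.9 per nucleosome) over linker occupancy 0.1. Geometric
decay makes occupancy at x + R an affine function of occupancy at x, so
the phasing autocorrelation genuinely peaks at R — a property of the
generative model, not of the statistic. An `include_anchor` option places
a footprint on the anchor itself, used for NP-type promoters (a nucleosome
positioned over the TSS, no depletion); NDR-type promoters get a central
truth NDR with arrays anchored at its edges.

GCH labeling probability is leak + (efficiency − leak)·(1 − occupancy)·
domain-scale with defaults efficiency 0.8 and leak 0.05 — the assay's true
labeling efficiency is not quantified anywhere, so these are fixed,
documented choices producing realistic dynamic range (background level
≈ 0.16, NDR level ≈ 0.8). Read depth is negative-binomial with mean 30 and
dispersion 0.1 (Var = m + 0.1 m²; dispersion 0 degenerates to Poisson).
GCH/HCG positions are drawn directly as geometric-gap site lists (mean
spacing 15 bp and 80 bp) rather than from a reference sequence; replicates
share positions (the genome is fixed) and resample counts independently —
a biological-replicate model. Promoter truth levels (UU 1%/1%, MU 80%/1%,
MM 80%/50%) clear the classification cutoffs by wide margins, so
classification errors reflect sampling noise, not boundary ambiguity.

What the generator does not emulate — and what passing tests therefore do
not establish about real data: sequence-dependent enzyme preferences,
bisulfite conversion failure, mapping bias, copy-number variation,
cell-to-cell heterogeneity of nucleosome positioning (occupancy is a
deterministic landscape, not a mixture of molecules), and correlated noise
between nearby sites. Recovery rates on synthetic data are upper bounds on
real-data performance.

## Problem sizes

Study-scale checks run at sizes chosen to make the properties sharp while
staying desk-sized: NDR recovery on a 10-Mb genome with 250 truth NDRs and
two replicates at depth 30 (~670k GCH sites each); parameter recovery from
50k sites; significance calibration on a 10k-MAR null; classification on
600 promoters; phasing on 500 promoters per repeat length; subclustering
on 200 promoters with an 80/20 NP/NDR split.

## Known limitations

- The HMM uses homogeneous transitions; distance-scaled transition
  variants used by some footprinting HMMs are out of scope, and segment
  boundaries within long linkers are only as precise as site spacing.
- The exact binomial test treats sites as independent within a segment;
  read-level dependence between neighboring GCHs on the same molecule is
  not modeled (it would make the test anticonservative at very high
  depth on short segments).
- BH assumes positive dependence at worst across MARs; local background
  sharing between nearby MARs mildly violates independence but in the
  conservative direction observed in the null calibration.
- The NP/NDR split is a hard k = 2 cut; genuinely intermediate promoters
  are forced into one side.
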