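# Methods

This note documents the models, conventions and parameter choices behind
`h1contrast`, and what the synthetic-data generators do and do not emulate.

## Coordinates and interval algebra

All coordinates are 0-based half-open (BED convention), including bedGraph
output. Chromosome sort order is the order of the chromosome-size table,
never lexicographic, so toy genomes and real assemblies behave identically.
Overlap means ≥ 1 shared base (bedtools-intersect default); merging joins
bookended intervals (gap 0). Merging with a gap tolerance is deliberately
not offered: region counts downstream depend on it, so it must be an
explicit caller decision.

## Window statistics

Tracks are per-chromosome arrays at a fixed bin size (default 100 bp).
Windowed quantities average bins into non-overlapping tiles; the trailing
partial window averages its available bins. The replicate-consistency
filter is the relative standard deviation, RSD = s/μ with the sample
(n−1) standard deviation; windows with μ = 0 are flagged undefined and
excluded listwise from correlations and dominance calls. RSD is scale-free:
multiplying all replicates by a constant leaves it unchanged, which is why
the synthetic replicate noise is multiplicative lognormal (see below).

Input normalization scales both tracks to the mean of their two totals and
then takes (signal + pseudocount) / (input + pseudocount) per bin.
Pseudocount default 1.0; it bounds the ratio at zero-Input bins.
Correlations (default window 1000 bp) accept either raw or Input-normalized
window means — both modes are exposed because the choice changes the
magnitude, though not the sign structure, of the between-condition
correlations.

## Variant dominance

A 100-bp window is assigned to a variant when (i) both conditions' RSD
< 0.5, (ii) the symmetric relative difference |a−b| / ((a+b)/2) of the two
window means exceeds 0.99, and (iii) that variant's mean is larger. On the
0–2 scale of this statistic, 0.99 corresponds to roughly a 3-fold
disparity. The alternative convention |a−b|/max(a,b) (0–1 scale) is
available via `DominanceParams.rel_diff_mode`. Windows are non-overlapping
tiles: detected regions are then maximal runs of same-label windows, with
no gap bridging, so region counts are non-redundant. Occupancy input is raw
windowed coverage by default ("average occupancy"); Input-normalized mode
is available. Promoters, where needed, are TSS ± 1000 bp — a configurable
definition, since no single convention is universal.

## Shuffle-null enrichment

Fold enrichment = observed / expected count of query regions overlapping
≥ 1 feature region, the expectation estimated by `n_shuffles` (default
1000) independent uniform re-placements of each query interval with its
length preserved. Chromosome assignment is preserved by default
(`same_chrom=True`), the safer choice on genomes with heterogeneous
chromosome sizes; genome-wide placement (probability ∝ chromosome size) is
available. Placements are independent, so shuffled intervals may overlap
each other — matching the null of bedtools shuffle without `-noOverlapping`.
For a single query interval of length q and a single feature of length f on
a chromosome of length L this Monte-Carlo expectation has the closed form
(f + q − 1)/(L − q + 1), which the test suite uses as a calibration oracle.
An empirical two-sided tail fraction accompanies each fold.

## Aggregate profiles

Profiles are ratio-of-averages: the signal track is averaged across anchors
per offset bin, the Input likewise, and the division happens last. This is
the lower-variance convention at low-coverage offsets (versus
average-of-ratios). Anchors whose flank would cross a chromosome end are
dropped, never zero-padded. Strand-aware mode reverses the window of
minus-strand anchors. Dip widths are measured as the full width at half
depth: baseline from the outer 10% of offsets, floor from the central half,
crossings linearly interpolated.

## NRL estimation

The distance spectrum counts **all** same-region ordered dyad pairs within
`max_distance` (default 1000 bp), phasogram style, not only adjacent pairs —
robust to under-called nucleosomes, at the cost of summits at every multiple
of the repeat length (which is exactly what the regression wants).
Frequencies are smoothed with a Savitzky–Golay filter (window 21 bp,
polynomial order 3); summits are local maxima ≥ 100 bp apart with prominence
≥ 5% of the smoothed range **and** height ≥ 5% of the smoothed maximum. The
height floor matters: Savitzky–Golay side lobes are slightly negative, so on
sparse spectra a flat zero plateau between true summits becomes a
technically prominent local maximum without it. The NRL is the OLS slope of
summit position on peak order k = 1..K with a free intercept; the intercept
absorbs systematic offsets (e.g. integer rounding of the first summit), so
including k = 1 is safe. On phased arrays with 10-bp positional jitter and
≥ 5000 dyads the estimator recovers repeat lengths of 184–200 bp to well
within ± 2 bp, comfortably resolving between-condition differences of ~6 bp.

## Methylation profiles

Methylation tables are per-CpG records (chrom, position, methylated
fraction, read coverage), strand-collapsed to the + strand C position.
Profiles are coverage-weighted means of fractions per offset bin — the
variance-optimal estimator when per-read calls are approximately binomial —
with a minimum-coverage filter (default 5 reads). Offset bins with no
covered CpG are NaN, never imputed. Nucleosome dyads are classified into
(inside/outside CpG island) × (H1 signal peak set) classes by point
containment of the dyad center; a dyad may carry several signal labels but
exactly one island label, and dyads in no peak are dropped.

## Chromomere sizing

Both image models are parameterized directly in FWHM so the rejection rule
applies to a fitted parameter without error propagation:

    gaussian:   offset + A · exp(−4 ln2 · ((x−x₀)²/w_x² + (y−y₀)²/w_y²))
    lorentzian: offset + A / (1 + 4 · ((x−x₀)²/w_x² + (y−y₀)²/w_y²))

Fits are nonlinear least squares over a square ROI (default half-width
7 px; 12 px for the wider confocal spots) with a fitted background offset.
The fractional width uncertainty is sd(w)/w from the residual-variance-
scaled inverse normal-equations matrix, computed from a central-difference
Jacobian at the optimum (this yields exactly 0 for noiseless fits and ∞ for
singular ones, where black-box covariance routines return undefined
values); the larger of the X and Y values is compared to the 60% threshold.
A fit is rejected for non-convergence, amplitude ≤ 0, center outside the
ROI, or fractional uncertainty > 0.60.

STED segmentation is brightest-first: a box filter of ROI size scores the
summed local intensity of unclaimed pixels, the maximum seeds the next
Lorentzian fit, and the ROI is claimed regardless of outcome. Segmentation
stops when, among the most recent 20 attempts, at least 50% were rejected —
checked only once 20 attempts exist — or when no unclaimed seed remains.
Because the claim mask covers only the ROI, the tail of a bright domain can
seed a second, slightly narrower fit; on synthetic fixtures this biases the
mean accepted size by under 10%. Reported tables carry one row per attempt;
rejected rows have NA parameters (a divergent fit's parameters are
meaningless, and printing them would couple output bytes to floating-point
noise).

## Synthetic data: what it emulates, and what it does not

All generators are pure functions of (config, seed); one global seed drives
fixed, independent substreams per component, so adding a generator never
perturbs another's output.

**Genome and features.** Three toy chromosomes (3/2/1 Mb). Active TSS,
inactive TSS, enhancers and CpG islands (defaults 120/120/80/80) are placed
uniformly at random, ≥ 5 kb apart, ≥ 20 kb from chromosome ends so profile
flanks never truncate. Half of the enhancers are designated hidden-epitope
loci.

**Tracks.** The condition mean is a positive base (2.0) plus a smooth
protocol-signed shared latent field plus a weaker variant-specific latent;
signing the shared field by protocol makes within-protocol correlations
positive and cross-protocol correlations negative by construction, and
halving the variant-latent weight for xxChIP makes the xxChIP pair more
strongly correlated than the xChIP pair — the qualitative ordering of the
real data. The xChIP-pair correlation target (default 0.6) fixes the weight
ratio; realized correlations are verified empirically, not imposed. Feature
effects are Gaussian in shape: a gain (xChIP) or loss (xxChIP) at
hidden-epitope loci; an occupancy dip of FWHM 300 bp at active TSS in xChIP
and of FWHM 3000 bp at **all** TSS in xxChIP, so measured profile widths
equal the planted FWHM up to neighbor-feature overlap (at the default
feature density, broad dips of nearby TSS overlap within a 6-kb flank and
widen the measured xxChIP dip by ~15%, still within the tested 20% band).
Replicates are the condition mean times per-bin lognormal noise (σ = 0.2 on
the log scale), chosen multiplicative so the replicate RSD is approximately
scale-free, matching the semantics of the RSD filter. The generator does
not model read-level sampling, fragment-size distributions, mappability or
GC bias — passing tests demonstrate correctness of the estimators under the
declared signal structure, not robustness to those real-data artifacts.

**Nucleosome maps.** Dyads at phase + k·L + N(0, σ) within a region,
truncated to it; default repeat lengths per condition are 190.6/184.5 bp
(xChIP H1.2/H1.5) and 191.8/188.8 bp (xxChIP), jitter σ = 10 bp. No
nucleosome eviction, no occupancy variation, no linker-length mixture.

**Methylation.** CpG sites ~1/10 bp inside islands and ~1/100 bp outside;
fractions Beta(2,8) inside (mean 0.2) and Beta(8,2) outside (mean 0.8);
coverage Poisson(30) floored at 1. No intermediate-methylation domains, no
strand asymmetry, no coverage–methylation coupling.

**Images.** Each domain renders as an isotropic Gaussian of apparent FWHM
√(true² + PSF²) — default PSFs 210 nm (confocal) and 50 nm (STED) — scaled
by a photon count and Poisson-sampled; `photon_scale=None` disables noise
for exact-recovery fixtures. Real STED PSFs are not Gaussian and real
chromomeres are not isotropic; the fixtures test the fitting machinery, not
PSF physics. Note the STED pipeline fits a Lorentzian to these
Gaussian-rendered spots, as it would to real data; the recovered mean size
agrees with the apparent size to within ~5–10%.

## Pipeline

`run_pipeline` executes simulate → windows → dominance → enrichment →
profiles → NRL → methylation → chromomere. In files mode, stages whose
inputs are missing are marked `skipped: <reason>` in the manifest rather
than failing. Every stage writes into its own subdirectory (write-once);
the manifest records parameters and SHA-256 checksums per output file, and
reruns with the same config and seed reproduce the checksums exactly. The
built-in peak caller (Input-normalized bins above a quantile, merged) exists
so synthetic mode is self-contained; it is a simple threshold caller and its
outputs are labeled `thresholdpeak` to distinguish them from dedicated
peak-calling tools.

## Problem sizes

Defaults throughout target desk-scale runs: 6-Mb toy genome at 100-bp bins,
1000-bp correlation windows, 1.1-Mb phased arrays (~5800 dyads) per NRL
estimate, 500–1000 shuffles per enrichment, 256×256 px images. The full
pipeline completes in seconds and the whole test suite in well under a
minute on one CPU.

## Known limitations

- The threshold peak caller is not a substitute for dedicated peak callers
  on real data; peaks for real analyses should be supplied as BED.
- Enrichment shuffling offers no GC- or gap-matched null and no assembly
  blacklist (an exclude set can be supplied); for toy genomes none exists.
- The summit-order regression assumes detected summits are consecutive
  multiples of the repeat length; a missed intermediate summit would bias
  the slope (mitigated by all-pairs counting, which strengthens every
  harmonic).
- Image fitting is 2D only: no deconvolution, drift correction or 3D
  modeling, and overlapping domains closer than the ROI are not
  deblended.
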