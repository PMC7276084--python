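# h1contrast

Tools for contrasting **single-fixation (xChIP)** and **double-fixation
(xxChIP)** linker-histone ChIP-seq signals, aimed at epigenomics groups
studying where histone H1 epitopes are exposed or hidden by higher-order
chromatin structure in situ.

In xChIP, chromatin is fixed once and sonicated to nucleosome-size fragments
*before* antibody binding, so every epitope is accessible. In xxChIP, the
antibody binds fixed intact chromatin first and is locked in place by a
second fixation before sonication, so only epitopes exposed in situ are
recovered. Comparing the two signals for H1 variants (H1.2, H1.5) localizes
"hidden" epitopes — loci where intact chromatin occludes antibody access —
and this package implements the full computational side of that comparison:

- **Interval algebra and I/O** — BED/bedGraph/chromosome-size/FASTA readers
  and writers, merging, overlap counting (0-based half-open throughout).
- **Window statistics** — binned coverage, running-mean smoothing,
  signal/Input normalization, replicate mean and relative standard
  deviation (RSD = sd/mean, n−1 denominator), and genome-wide pairwise
  Pearson correlations over tiling windows.
- **Variant dominance** — windows where one H1 variant's occupancy dominates
  the other: both conditions' replicate RSD < 0.5 and symmetric relative
  difference |a−b| / ((a+b)/2) > 0.99 over 100-bp windows; consecutive
  windows merge into dominant regions, summarized against promoters.
- **Shuffle-null enrichment** — fold enrichment of a peak set in a feature
  set as observed / expected overlap counts, with the expectation estimated
  by re-placing query intervals uniformly at random (length-preserving).
- **Aggregate profiles** — anchor-centered mean signal/Input ratios
  (ratio-of-averages) around TSS, binding-site summits, CpG islands, plus
  GC-content profiles from FASTA.
- **NRL estimation** — the phasogram method: histogram all same-region
  dyad–dyad distances, smooth (Savitzky–Golay), locate periodic summits, and
  regress summit position on peak order *k*; the slope is the nucleosome
  repeat length.
- **Methylation profiles** — coverage-weighted mean methylation around
  nucleosome dyads (stratified by CpG-island membership × H1-signal class),
  around CpGs, and around peak centers.
- **Chromomere sizing** — punctate chromatin domains in microscopy images:
  user-seeded 2D Gaussian fits (confocal) and brightest-first automated 2D
  Lorentzian segmentation (STED), both parameterized directly in FWHM, with
  rejection rules (negative amplitude, center outside the ROI, fractional
  width uncertainty > 60%) and a stopping rule (half of the last 20
  attempted fits rejected).
- **Synthetic data** — seeded generators for toy genomes, condition-
  structured replicate tracks, phased nucleosome arrays, CpG-island-
  structured methylation and PSF-convolved image pairs, each with recorded
  ground truth, so every stage is testable without sequencing data.

## Worked example

Estimate the nucleosome repeat length of a phased array with 10-bp
positional jitter:

```python
from h1contrast import (Genome, GenomicInterval, IntervalSet,
                        simulate_nucleosome_map, estimate_nrl)

genome = Genome({"chr1": 1_200_000})
region = IntervalSet([GenomicInterval("chr1", 0, 1_100_000)], genome=genome)
dyads = simulate_nucleosome_map(region, repeat_length=190.6,
                                jitter_sd=10.0, seed=3)
fit = estimate_nrl(dyads, region, max_distance=1000)
print(f"NRL = {fit.slope:.1f} bp  (r^2 = {fit.r_squared:.4f})")
print("summits:", fit.summit_positions)
```

prints

```
NRL = 190.3 bp  (r^2 = 1.0000)
summits: [193. 379. 571. 764. 952.]
```

The distance spectrum has summits near multiples of the true repeat length
(190.6, 381.2, …); the regression slope recovers the repeat length to well
under 1 bp, and the intercept absorbs the small systematic offset of the
first summit.

The same end-to-end flow, from synthesis through every analysis stage, runs
as one command:

```bash
h1contrast run --outdir out --seed 7
```

which writes per-stage outputs (bedGraph tracks, BED region sets, TSV
profiles and fit tables, TIFF images), a `summary.json` with the headline
numbers (4×4 correlation matrix, dominant-region counts, fold-enrichment
table, NRL per condition, chromomere size summaries) and a `manifest.json`
with per-file checksums — rerunning with the same seed reproduces the
checksums byte-for-byte. Single stages are available as subcommands
(`simulate`, `windows`, `dominance`, `enrich`, `profile`, `nrl`,
`methprofile`, `chromomere`).

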