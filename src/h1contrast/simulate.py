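"""Seeded synthetic-data generators with recorded ground truth.

Emulates the study conditions end to end on a toy genome: triplicate
coverage tracks for 4 conditions (xChIP/xxChIP x H1.2/H1.5) whose
within-protocol correlations are positive and cross-protocol correlations
negative; hidden-epitope loci where xChIP gains signal and xxChIP loses
it; a narrow (~300 bp) xChIP occupancy dip at active TSS versus a broad
(~3 kb) xxChIP dip at all TSS; phased nucleosome arrays of configurable
repeat length; CpG-island-structured methylation; and point-like image
domains convolved with confocal/STED point-spread functions.

Every generator is a pure function of (config, seed); a single global seed
drives independent per-component substreams, so adding one generator never
perturbs another's output.
"""
from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .core import Genome, GenomicInterval, IntervalSet
from .methylation import MethylationTable
from .tracks import SignalTrack, TrackMeta, _n_bins
from .imaging import MicroscopyImage

CONDITIONS = (("xChIP", "H1.2"), ("xChIP", "H1.5"),
              ("xxChIP", "H1.2"), ("xxChIP", "H1.5"))

# fixed substream keys: component name -> spawn key
_SUBSTREAMS = {"genome": 0, "tracks": 1, "nucleosomes": 2, "methylation": 3,
               "images": 4, "dominance": 5}


def substream(seed: int, component: str) -> np.random.Generator:
    """Independent, reproducible RNG substream for one generator component."""
    return np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(_SUBSTREAMS[component],)))


def default_genome() -> Genome:
    return Genome({"chr1": 3_000_000, "chr2": 2_000_000, "chr3": 1_000_000})


@dataclass
class SimConfig:
    genome: Genome = field(default_factory=default_genome)
    bin_size: int = 100
    n_active_tss: int = 120
    n_inactive_tss: int = 120
    n_enhancers: int = 80
    n_cpg_islands: int = 80
    #: fraction of enhancers where the epitope is hidden in situ:
    #: xChIP enriched, xxChIP depleted
    hidden_epitope_fraction: float = 0.5
    #: target Pearson r between the two xChIP variants over 1-kb windows;
    #: the xxChIP pair correlates more strongly by construction and the
    #: cross-protocol r is approximately -sqrt(r_x * r_xx)
    within_protocol_r: float = 0.6
    cross_protocol_r: float = -0.6
    xchip_tss_dip_width: int = 300
    xxchip_tss_dip_width: int = 3000
    #: repeat length per condition, the values the estimator should recover
    nrl_by_class: dict = field(default_factory=lambda: {
        ("xChIP", "H1.2"): 190.6, ("xChIP", "H1.5"): 184.5,
        ("xxChIP", "H1.2"): 191.8, ("xxChIP", "H1.5"): 188.8})
    jitter_sd: float = 10.0
    noise_sd: float = 0.05
    replicate_sd: float = 0.2
    min_separation: int = 5000
    edge_margin: int = 20000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.xchip_tss_dip_width <= 0 or self.xxchip_tss_dip_width <= 0:
            raise ValueError("dip widths must be positive")
        if not 0 <= self.hidden_epitope_fraction <= 1:
            raise ValueError("hidden_epitope_fraction must be in [0, 1]")
        if not (0 < self.within_protocol_r <= 1) or not (-1 <= self.cross_protocol_r < 0):
            raise ValueError("within_protocol_r must be in (0,1], "
                             "cross_protocol_r in [-1,0)")


@dataclass
class GroundTruth:
    """Everything needed to score downstream stages without the config."""

    features: dict[str, IntervalSet] = field(default_factory=dict)
    hidden_epitope: Optional[IntervalSet] = None
    dominant_regions: dict[str, IntervalSet] = field(default_factory=dict)
    nrl_by_class: dict = field(default_factory=dict)
    tss_dip_widths: dict[str, int] = field(default_factory=dict)
    image_domains: list[dict] = field(default_factory=list)


# ---------------------------------------------------------------------------
# toy genome and feature placement

_FEATURE_WIDTHS = {"active_tss": 1, "inactive_tss": 1,
                   "enhancer": 500, "cpg_island": 1000}


def make_toy_genome(cfg: SimConfig) -> tuple[Genome, dict[str, IntervalSet], GroundTruth]:
    """Place non-overlapping features uniformly at random, min 5 kb apart.

    TSS are 1-bp stranded anchors; enhancers and CpG islands are wider
    intervals.  Deterministic given ``cfg.seed``; raises when the genome
    cannot hold the requested features at the required separation.
    """
    rng = substream(cfg.seed, "genome")
    genome = cfg.genome
    counts = {"active_tss": cfg.n_active_tss, "inactive_tss": cfg.n_inactive_tss,
              "enhancer": cfg.n_enhancers, "cpg_island": cfg.n_cpg_islands}
    total = sum(counts.values())
    names = genome.chrom_names
    sizes = np.array([genome.chrom_sizes[c] for c in names], dtype=float)
    usable = sizes - 2 * cfg.edge_margin
    if (usable <= 0).any() or total * cfg.min_separation > usable.sum():
        raise ValueError("genome too small for the requested features at "
                         f"{cfg.min_separation} bp separation")
    placed_centers: dict[str, list[int]] = {c: [] for c in names}
    assignments: list[tuple[str, str, int]] = []  # (feature class, chrom, center)
    p = usable / usable.sum()
    for feat, n in counts.items():
        for _ in range(n):
            ok = False
            for _attempt in range(200):
                chrom = names[rng.choice(len(names), p=p)]
                lo = cfg.edge_margin
                hi = genome.chrom_sizes[chrom] - cfg.edge_margin
                center = int(rng.integers(lo, hi))
                cur = placed_centers[chrom]
                i = bisect.bisect_left(cur, center)
                if (i > 0 and center - cur[i - 1] < cfg.min_separation) or \
                        (i < len(cur) and cur[i] - center < cfg.min_separation):
                    continue
                cur.insert(i, center)
                assignments.append((feat, chrom, center))
                ok = True
                break
            if not ok:
                raise ValueError("could not place all features: genome too "
                                 "crowded at the requested separation")
    features: dict[str, list[GenomicInterval]] = {f: [] for f in counts}
    for feat, chrom, center in assignments:
        w = _FEATURE_WIDTHS[feat]
        strand = "."
        if feat.endswith("tss"):
            strand = "+" if rng.random() < 0.5 else "-"
        half = w // 2
        features[feat].append(GenomicInterval(
            chrom, center - half, center - half + w, strand))
    feature_sets = {f: IntervalSet(ivs, genome=genome).sort()
                    for f, ivs in features.items()}
    # hidden-epitope loci: a seeded subset of enhancers
    enh = list(feature_sets["enhancer"])
    n_hidden = int(round(cfg.hidden_epitope_fraction * len(enh)))
    hidden_idx = rng.choice(len(enh), size=n_hidden, replace=False) if enh else []
    hidden = IntervalSet([enh[i] for i in sorted(hidden_idx)],
                         genome=genome).sort()
    truth = GroundTruth(features=feature_sets, hidden_epitope=hidden,
                        nrl_by_class=dict(cfg.nrl_by_class),
                        tss_dip_widths={"xChIP": cfg.xchip_tss_dip_width,
                                        "xxChIP": cfg.xxchip_tss_dip_width})
    return genome, feature_sets, truth


# ---------------------------------------------------------------------------
# condition-structured replicate tracks

def _smooth_latent(rng: np.random.Generator, n_bins: int,
                   sigma_bins: float = 10.0) -> np.ndarray:
    """Unit-variance smooth random field (Gaussian-filtered white noise)."""
    x = gaussian_filter1d(rng.standard_normal(n_bins), sigma_bins, mode="reflect")
    sd = x.std()
    return x / sd if sd > 0 else x


def _add_gaussian_bump(arr: np.ndarray, center_bp: int, fwhm_bp: float,
                       amplitude: float, bin_size: int) -> None:
    """Add amplitude * exp(-4 ln2 (x-c)^2 / fwhm^2) sampled at bin centers."""
    half_support = int(2 * fwhm_bp)
    b0 = max(0, (center_bp - half_support) // bin_size)
    b1 = min(len(arr), (center_bp + half_support) // bin_size + 1)
    if b1 <= b0:
        return
    x = (np.arange(b0, b1) + 0.5) * bin_size
    arr[b0:b1] += amplitude * np.exp(
        -4.0 * np.log(2.0) * (x - center_bp) ** 2 / fwhm_bp ** 2)


BASE_LEVEL = 2.0
SHARED_WEIGHT = 1.0          # weight of the protocol-signed latent
HIDDEN_BUMP_AMP = 1.5        # xChIP gain at hidden-epitope loci
HIDDEN_DIP_AMP = 1.2         # xxChIP loss at hidden-epitope loci
HIDDEN_WIDTH = 600           # bp FWHM of the hidden-epitope effect
XCHIP_DIP_DEPTH = 1.6
XXCHIP_DIP_DEPTH = 1.4
MEAN_FLOOR = 0.05


def simulate_chip_tracks(genome: Genome, features: dict[str, IntervalSet],
                         cfg: SimConfig,
                         hidden_epitope: Optional[IntervalSet] = None,
                         ) -> tuple[dict[tuple[str, str], list[SignalTrack]],
                                    dict[str, SignalTrack]]:
    """12 replicate tracks (4 conditions x 3) plus one Input per protocol.

    The condition mean is a positive base plus a protocol-signed shared
    latent field (inducing the positive-within / negative-cross correlation
    structure) plus variant-specific latents — weaker for xxChIP, so the
    xxChIP pair correlates more strongly than the xChIP pair.  Feature
    effects: Gaussian gain (xChIP) / loss (xxChIP) at hidden-epitope loci;
    a narrow xChIP dip at active TSS; a broad xxChIP dip at all TSS.
    Replicates are the condition mean times lognormal noise.
    """
    rng = substream(cfg.seed, "tracks")
    bs = cfg.bin_size
    nb = {c: _n_bins(s, bs) for c, s in genome.chrom_sizes.items()}
    # variant-latent weight chosen so that r(xChIP pair) ~= within_protocol_r
    b_x = SHARED_WEIGHT * np.sqrt(max(1.0 / cfg.within_protocol_r - 1.0, 1e-9))
    b_xx = b_x / 2.0

    shared = {c: _smooth_latent(rng, n) for c, n in nb.items()}
    variant_latents = {}
    for protocol, variant in CONDITIONS:
        variant_latents[(protocol, variant)] = {
            c: _smooth_latent(rng, n) for c, n in nb.items()}

    means: dict[tuple[str, str], dict[str, np.ndarray]] = {}
    for protocol, variant in CONDITIONS:
        sign = 1.0 if protocol == "xChIP" else -1.0
        bvar = b_x if protocol == "xChIP" else b_xx
        per_chrom = {}
        for chrom, n in nb.items():
            m = (BASE_LEVEL + sign * SHARED_WEIGHT * shared[chrom]
                 + bvar * variant_latents[(protocol, variant)][chrom])
            per_chrom[chrom] = m
        means[(protocol, variant)] = per_chrom

    hidden = hidden_epitope if hidden_epitope is not None else IntervalSet()
    for iv in hidden:
        for protocol, variant in CONDITIONS:
            arr = means[(protocol, variant)][iv.chrom]
            amp = HIDDEN_BUMP_AMP if protocol == "xChIP" else -HIDDEN_DIP_AMP
            _add_gaussian_bump(arr, iv.center, HIDDEN_WIDTH, amp, bs)

    active = features.get("active_tss", IntervalSet())
    inactive = features.get("inactive_tss", IntervalSet())
    for iv in active:
        for variant in ("H1.2", "H1.5"):
            _add_gaussian_bump(means[("xChIP", variant)][iv.chrom], iv.center,
                               cfg.xchip_tss_dip_width, -XCHIP_DIP_DEPTH, bs)
    for tss_set in (active, inactive):
        for iv in tss_set:
            for variant in ("H1.2", "H1.5"):
                _add_gaussian_bump(means[("xxChIP", variant)][iv.chrom],
                                   iv.center, cfg.xxchip_tss_dip_width,
                                   -XXCHIP_DIP_DEPTH, bs)

    tracks: dict[tuple[str, str], list[SignalTrack]] = {}
    for cond in CONDITIONS:
        protocol, variant = cond
        noisy = {}
        for chrom, m in means[cond].items():
            mm = m + cfg.noise_sd * rng.standard_normal(len(m))
            noisy[chrom] = np.clip(mm, MEAN_FLOOR, None)
        reps = []
        for rep in range(1, 4):
            vals = {}
            for chrom, m in noisy.items():
                if cfg.replicate_sd > 0:
                    factor = np.exp(rng.normal(0.0, cfg.replicate_sd, len(m)))
                else:
                    factor = 1.0
                vals[chrom] = m * factor
            reps.append(SignalTrack(genome, bs, vals,
                                    TrackMeta(protocol, variant, rep)))
        tracks[cond] = reps

    inputs = {}
    for protocol in ("xChIP", "xxChIP"):
        vals = {c: np.clip(BASE_LEVEL + 0.2 * _smooth_latent(rng, n),
                           MEAN_FLOOR, None)
                for c, n in nb.items()}
        inputs[protocol] = SignalTrack(genome, bs, vals,
                                       TrackMeta(protocol, "Input"))
    return tracks, inputs


# ---------------------------------------------------------------------------
# nucleosome maps

def simulate_nucleosome_map(regions: IntervalSet, repeat_length: float,
                            jitter_sd: float, seed: int,
                            rng: Optional[np.random.Generator] = None,
                            ) -> IntervalSet:
    """Phased dyad positions: phase + k * repeat_length + N(0, jitter_sd)
    within each region, truncated to the region."""
    if repeat_length < 147:
        raise ValueError("repeat_length must be >= 147 bp (nucleosome core)")
    if rng is None:
        rng = np.random.default_rng(seed)
    dyads = []
    for region in regions:
        phase = rng.uniform(0, repeat_length)
        k = np.arange(int((len(region) - phase) / repeat_length) + 1)
        pos = region.start + phase + k * repeat_length
        if jitter_sd > 0:
            pos = pos + rng.normal(0.0, jitter_sd, len(pos))
        pos = np.rint(pos).astype(int)
        pos = pos[(pos >= region.start) & (pos < region.end)]
        dyads.extend(GenomicInterval(region.chrom, int(x), int(x) + 1)
                     for x in np.sort(pos))
    return IntervalSet(dyads, genome=regions.genome).sort()


def simulate_nucleosome_maps_by_condition(
        genome: Genome, cfg: SimConfig,
        region_length: int = 200_000) -> dict[tuple[str, str], IntervalSet]:
    """One phased array per condition on chr1, repeat length per
    ``cfg.nrl_by_class``, in disjoint regions."""
    rng = substream(cfg.seed, "nucleosomes")
    maps = {}
    offset = 0
    chrom = genome.chrom_names[0]
    for cond in CONDITIONS:
        region = IntervalSet([GenomicInterval(chrom, offset,
                                              offset + region_length)],
                             genome=genome)
        maps[cond] = simulate_nucleosome_map(region, cfg.nrl_by_class[cond],
                                             cfg.jitter_sd, 0, rng=rng)
        offset += region_length
    return maps


# ---------------------------------------------------------------------------
# methylation

def simulate_methylation(genome: Genome, cpg_islands: IntervalSet, seed: int,
                         island_density: float = 0.1,
                         background_density: float = 0.01,
                         island_beta: tuple[float, float] = (2.0, 8.0),
                         background_beta: tuple[float, float] = (8.0, 2.0),
                         coverage_mean: float = 30.0) -> MethylationTable:
    """CpG sites dense and hypomethylated inside islands (~1/10 bp,
    Beta mean 0.2), sparse and hypermethylated outside (~1/100 bp, Beta
    mean 0.8); coverage Poisson with the given mean (floored at 1)."""
    rng = np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(_SUBSTREAMS["methylation"],)))
    islands = cpg_islands.by_chrom()
    rows = []
    for chrom, size in genome.chrom_sizes.items():
        n_bg = rng.poisson(background_density * size)
        pos = rng.choice(size, size=min(n_bg, size), replace=False)
        in_island = np.zeros(len(pos), dtype=bool)
        for iv in islands.get(chrom, []):
            n_is = rng.poisson(island_density * len(iv))
            if n_is == 0:
                continue
            ipos = iv.start + rng.choice(len(iv), size=min(n_is, len(iv)),
                                         replace=False)
            pos = np.concatenate([pos, ipos])
            in_island = np.concatenate([in_island, np.ones(len(ipos), dtype=bool)])
        pos, idx = np.unique(pos, return_index=True)
        in_island = in_island[idx]
        # island membership wins for background sites that landed inside one
        for iv in islands.get(chrom, []):
            in_island |= (pos >= iv.start) & (pos < iv.end)
        frac = np.where(in_island,
                        rng.beta(*island_beta, len(pos)),
                        rng.beta(*background_beta, len(pos)))
        cov = np.maximum(rng.poisson(coverage_mean, len(pos)), 1)
        rows.append(pd.DataFrame({"chrom": chrom, "pos": pos,
                                  "fraction": frac, "coverage": cov}))
    df = pd.concat(rows, ignore_index=True)
    return MethylationTable.from_dataframe(df)


# ---------------------------------------------------------------------------
# microscopy image pairs

def simulate_image_pair(domain_centers_nm: Sequence[tuple[float, float]],
                        fwhm_true_nm: Sequence[float] | float,
                        psf_confocal_fwhm: float = 210.0,
                        psf_sted_fwhm: float = 50.0,
                        pixel_nm: float = 10.0,
                        photon_scale: Optional[float] = 2000.0,
                        background: float = 5.0,
                        image_shape: tuple[int, int] = (256, 256),
                        seed: int = 0,
                        ) -> tuple[MicroscopyImage, MicroscopyImage, GroundTruth]:
    """Render the same domains through confocal and STED point-spread
    functions.

    Each domain becomes an isotropic Gaussian of apparent FWHM
    sqrt(fwhm_true^2 + psf_fwhm^2) with peak amplitude ``photon_scale``;
    ``photon_scale=None`` disables Poisson noise (noiseless, unit peak).
    """
    if pixel_nm <= 0:
        raise ValueError("pixel_nm must be positive")
    ny, nx = image_shape
    centers = [(float(x), float(y)) for x, y in domain_centers_nm]
    if np.isscalar(fwhm_true_nm):
        fwhms = [float(fwhm_true_nm)] * len(centers)
    else:
        fwhms = [float(f) for f in fwhm_true_nm]
    if any(f < 0 for f in fwhms):
        raise ValueError("true FWHMs must be >= 0")
    for (x, y) in centers:
        if not (0 <= x < nx * pixel_nm and 0 <= y < ny * pixel_nm):
            raise ValueError(f"domain at ({x}, {y}) nm outside the field of view")
    rng = np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(_SUBSTREAMS["images"],)))
    yy, xx = np.mgrid[0:ny, 0:nx]
    xnm, ynm = (xx + 0.5) * pixel_nm, (yy + 0.5) * pixel_nm
    truth = GroundTruth()
    images = []
    amp = 1.0 if photon_scale is None else float(photon_scale)
    for modality, psf in (("confocal", psf_confocal_fwhm),
                          ("STED", psf_sted_fwhm)):
        if psf <= 0:
            raise ValueError("PSF FWHMs must be positive")
        img = np.full((ny, nx), 0.0 if photon_scale is None else background)
        for (cx, cy), ft in zip(centers, fwhms):
            w = np.hypot(ft, psf)
            img += amp * np.exp(-4.0 * np.log(2.0)
                                * ((xnm - cx) ** 2 + (ynm - cy) ** 2) / w ** 2)
            truth.image_domains.append(
                {"modality": modality, "center_nm": (cx, cy),
                 "fwhm_true_nm": ft, "fwhm_apparent_nm": float(w)})
        if photon_scale is not None:
            img = rng.poisson(img).astype(float)
        images.append(MicroscopyImage(img, pixel_nm, modality))
    return images[0], images[1], truth


# ---------------------------------------------------------------------------
# planted-dominance scenario

def simulate_dominance_scenario(genome: Genome, cfg: SimConfig,
                                n_regions_per_variant: int = 25,
                                region_windows: int = 5,
                                dominant_level: float = 4.0,
                                recessive_level: float = 0.02,
                                replicate_sd: float = 0.05,
                                ) -> tuple[dict[str, list[SignalTrack]], GroundTruth]:
    """Triplicate xChIP H1.2/H1.5 tracks with planted dominant regions.

    Background: both variants share one positive mean track (relative
    difference ~0 up to replicate noise).  Planted regions (aligned to the
    window grid, ``region_windows`` windows wide) set one variant to
    ``dominant_level`` and the other near zero — relative difference ~2.0 —
    with small multiplicative replicate noise so the RSD filter passes.
    """
    rng = substream(cfg.seed, "dominance")
    bs = cfg.bin_size
    window = 100
    per = window // bs if window >= bs else 1
    nb = {c: _n_bins(s, bs) for c, s in genome.chrom_sizes.items()}
    base = {c: np.clip(BASE_LEVEL + 0.3 * _smooth_latent(rng, n), 0.5, None)
            for c, n in nb.items()}
    means = {"H1.2": {c: v.copy() for c, v in base.items()},
             "H1.5": {c: v.copy() for c, v in base.items()}}
    truth_regions: dict[str, list[GenomicInterval]] = {"H1.2": [], "H1.5": []}
    gap_windows = 4 * region_windows
    stride = (region_windows + gap_windows) * per
    slots = []
    for chrom, n in nb.items():
        for start_bin in range(stride, n - stride, stride):
            slots.append((chrom, start_bin))
    need = 2 * n_regions_per_variant
    if len(slots) < need:
        raise ValueError("genome too small for the requested planted regions")
    chosen = rng.choice(len(slots), size=need, replace=False)
    for idx, slot in enumerate(chosen):
        chrom, b0 = slots[slot]
        variant = "H1.2" if idx < n_regions_per_variant else "H1.5"
        other = "H1.5" if variant == "H1.2" else "H1.2"
        b1 = b0 + region_windows * per
        means[variant][chrom][b0:b1] = dominant_level
        means[other][chrom][b0:b1] = recessive_level
        truth_regions[variant].append(
            GenomicInterval(chrom, b0 * bs, b1 * bs))
    tracks = {}
    for variant in ("H1.2", "H1.5"):
        reps = []
        for rep in range(1, 4):
            vals = {c: m * np.exp(rng.normal(0.0, replicate_sd, len(m)))
                    for c, m in means[variant].items()}
            reps.append(SignalTrack(genome, bs, vals,
                                    TrackMeta("xChIP", variant, rep)))
        tracks[variant] = reps
    truth = GroundTruth(dominant_regions={
        v: IntervalSet(ivs, genome=genome).sort()
        for v, ivs in truth_regions.items()})
    return tracks, truth
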