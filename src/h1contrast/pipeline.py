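"""End-to-end orchestration: synthesize or ingest data, then run windows,
correlations, dominance, enrichment, profiles, NRL, methylation and
imaging stages, writing a manifest with per-file checksums.

The bundled peak caller is a simple threshold caller (Input-normalized
bins above a quantile, merged); it exists so synthetic mode is
self-contained and is NOT equivalent to dedicated peak callers (MUSIC,
MACS2, ...) used on real data — outputs are labeled ``thresholdpeak`` to
make that explicit.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import numpy as np

from . import simulate as sim
from .core import (Genome, GenomicInterval, IntervalSet, merge_intervals,
                   read_bed, write_bed, write_chrom_sizes)
from .dominance import DominanceParams, find_dominant_regions, \
    promoter_overlap_fraction, regions_to_interval_set
from .enrichment import fold_enrichment
from .imaging import FitParams, fit_gaussian2d, segment_domains_sted, \
    size_distribution
from .methylation import classify_nucleosomes, methylation_profile, \
    read_methylation_table, signal_profile_around_points, \
    write_methylation_table
from .nrl import estimate_nrl
from .profiles import aggregate_profile, anchor_points, profile_dip_width
from .tracks import SignalTrack, normalize_by_input, pairwise_correlation, \
    read_bedgraph, replicate_stats, window_means, write_bedgraph

logger = logging.getLogger(__name__)

STAGES = ("simulate", "windows", "dominance", "enrichment", "profiles",
          "nrl", "methylation", "chromomere")


@dataclass
class PipelineConfig:
    mode: str = "synthetic"          # synthetic | files
    outdir: str = "h1contrast_out"
    seed: int = 0
    # module parameter blocks
    sim: dict = field(default_factory=dict)
    correlation_window: int = 1000
    dominance_window: int = 100
    rsd_max: float = 0.5
    rel_diff_min: float = 0.99
    promoter_flank: int = 1000
    n_shuffles: int = 200
    peak_quantile: float = 0.90
    profile_flank: int = 6000
    profile_bin: int = 100
    nrl_max_distance: int = 1000
    meth_flank: int = 2000
    meth_bin: int = 50
    # files-mode inputs (paths); absent roles skip their stages
    paths: dict = field(default_factory=dict)

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = json.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def call_peaks_threshold(signal: SignalTrack, input_: SignalTrack,
                         quantile: float = 0.90,
                         min_width_bins: int = 2) -> IntervalSet:
    """Threshold peak caller for synthetic data (not equivalent to a
    dedicated peak caller such as MUSIC or MACS2).

    Bins whose Input-normalized value exceeds the genome-wide quantile are
    merged into peaks; runs shorter than ``min_width_bins`` are dropped.
    """
    norm = normalize_by_input(signal, input_)
    pooled = np.concatenate(list(norm.values.values()))
    cutoff = float(np.quantile(pooled, quantile))
    bs = norm.bin_size
    ivs = []
    for chrom, v in norm.values.items():
        above = v > cutoff
        i = 0
        while i < len(above):
            if not above[i]:
                i += 1
                continue
            j = i
            while j + 1 < len(above) and above[j + 1]:
                j += 1
            if j - i + 1 >= min_width_bins:
                end = min((j + 1) * bs, signal.genome.chrom_sizes[chrom])
                ivs.append(GenomicInterval(chrom, i * bs, end,
                                           name="thresholdpeak"))
            i = j + 1
    return IntervalSet(ivs, genome=signal.genome, sorted=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _mean_track(reps: list[SignalTrack]) -> SignalTrack:
    vals = {c: np.mean([t.values[c] for t in reps], axis=0)
            for c in reps[0].values}
    meta = dataclasses.replace(reps[0].meta, replicate=None)
    return reps[0].copy_with(vals, meta)


def _cond_key(cond: tuple[str, str]) -> str:
    return f"{cond[0]}_{cond[1]}"


class PipelineRun:
    """Mutable state threaded through the stages of one pipeline run."""

    def __init__(self, cfg: PipelineConfig):
        self.cfg = cfg
        self.outdir = Path(cfg.outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.manifest: dict[str, Any] = {"seed": cfg.seed, "mode": cfg.mode,
                                         "stages": {}}
        self.summary: dict[str, Any] = {}
        # data bundle
        self.genome: Optional[Genome] = None
        self.features: dict[str, IntervalSet] = {}
        self.truth: Optional[sim.GroundTruth] = None
        self.tracks: dict[tuple[str, str], list[SignalTrack]] = {}
        self.inputs: dict[str, SignalTrack] = {}
        self.peaks: dict[tuple[str, str], IntervalSet] = {}
        self.nuc_maps: dict[tuple[str, str], IntervalSet] = {}
        self.meth = None
        self.images = None

    def record(self, stage: str, status: str, outputs: list[Path],
               params: Optional[dict] = None) -> None:
        self.manifest["stages"][stage] = {
            "status": status,
            "parameters": params or {},
            "outputs": {str(p.relative_to(self.outdir)): _sha256(p)
                        for p in outputs},
        }

    def skip(self, stage: str, why: str) -> None:
        self.manifest["stages"][stage] = {"status": f"skipped: {why}",
                                          "parameters": {}, "outputs": {}}


def _stage_simulate(run: PipelineRun) -> None:
    cfg = run.cfg
    sim_kwargs = dict(cfg.sim)
    sim_kwargs["seed"] = cfg.seed
    if isinstance(sim_kwargs.get("genome"), dict):  # JSON-config form
        sim_kwargs["genome"] = Genome(sim_kwargs["genome"])
    scfg = sim.SimConfig(**sim_kwargs)
    genome, features, truth = sim.make_toy_genome(scfg)
    tracks, inputs = sim.simulate_chip_tracks(genome, features, scfg,
                                              truth.hidden_epitope)
    nuc_maps = sim.simulate_nucleosome_maps_by_condition(genome, scfg)
    meth = sim.simulate_methylation(genome, features["cpg_island"], cfg.seed)
    centers = [(400 + 700 * i, 400 + 700 * j)
               for i in range(3) for j in range(3)]
    confocal, sted, img_truth = sim.simulate_image_pair(
        centers, 70.0, pixel_nm=10.0, photon_scale=3000.0,
        image_shape=(256, 256), seed=cfg.seed)
    truth.image_domains = img_truth.image_domains

    run.genome, run.features, run.truth = genome, features, truth
    run.tracks, run.inputs = tracks, inputs
    run.nuc_maps, run.meth = nuc_maps, meth
    run.images = (confocal, sted, centers)

    out = run.outdir / "simulate"
    out.mkdir(exist_ok=True)
    files = []
    write_chrom_sizes(genome, out / "genome.chrom.sizes")
    files.append(out / "genome.chrom.sizes")
    for name, fs in features.items():
        p = out / f"{name}.bed"
        write_bed(fs, p)
        files.append(p)
    for cond, reps in tracks.items():
        for t in reps:
            p = out / f"{_cond_key(cond)}_rep{t.meta.replicate}.bedgraph"
            write_bedgraph(t, p)
            files.append(p)
    for protocol, t in inputs.items():
        p = out / f"{protocol}_Input.bedgraph"
        write_bedgraph(t, p)
        files.append(p)
    for cond, dyads in nuc_maps.items():
        p = out / f"nucleosomes_{_cond_key(cond)}.bed"
        write_bed(dyads, p)
        files.append(p)
    p = out / "methylation.tsv"
    write_methylation_table(meth, p)
    files.append(p)
    import tifffile
    for img, tag in ((confocal, "confocal"), (sted, "sted")):
        p = out / f"{tag}.tiff"
        tifffile.imwrite(p, img.pixels.astype(np.float32))
        files.append(p)
    run.record("simulate", "ok", files, dataclasses.asdict(scfg) | {
        "genome": dict(genome.chrom_sizes),
        "nrl_by_class": {f"{k[0]}_{k[1]}": v
                         for k, v in scfg.nrl_by_class.items()}})


def _stage_windows(run: PipelineRun) -> None:
    cfg = run.cfg
    out = run.outdir / "windows"
    out.mkdir(exist_ok=True)
    conds = sorted(run.tracks, key=_cond_key)
    means = []
    for cond in conds:
        wm = [window_means(t, cfg.correlation_window) for t in run.tracks[cond]]
        means.append({c: np.mean([m[c] for m in wm], axis=0)
                      for c in run.genome.chrom_names})
    corr = pairwise_correlation([], cfg.correlation_window, means=means)
    labels = [_cond_key(c) for c in conds]
    p = out / "correlation_matrix.tsv"
    with open(p, "w") as fh:
        fh.write("\t" + "\t".join(labels) + "\n")
        for lab, row in zip(labels, corr):
            fh.write(lab + "\t" + "\t".join(f"{v:.6f}" for v in row) + "\n")
    files = [p]
    # 1000-bp smoothed chromosome-scale tracks of the condition means
    for cond in conds:
        from .tracks import smooth_running
        sm = smooth_running(_mean_track(run.tracks[cond]), 1000)
        p2 = out / f"{_cond_key(cond)}_smoothed1000.bedgraph"
        write_bedgraph(sm, p2)
        files.append(p2)
    run.summary["correlation_matrix"] = {"labels": labels,
                                         "values": corr.tolist()}
    run.record("windows", "ok", files,
               {"correlation_window": cfg.correlation_window})


def _stage_dominance(run: PipelineRun) -> None:
    cfg = run.cfg
    out = run.outdir / "dominance"
    out.mkdir(exist_ok=True)
    params = DominanceParams(cfg.dominance_window, cfg.rsd_max,
                             cfg.rel_diff_min)
    stats_a = replicate_stats(run.tracks[("xChIP", "H1.2")], params.window)
    stats_b = replicate_stats(run.tracks[("xChIP", "H1.5")], params.window)
    regions = find_dominant_regions(stats_a, stats_b, run.genome, params)
    iset = regions_to_interval_set(regions, run.genome)
    p = out / "dominant_regions.bed"
    write_bed(iset, p)
    counts = {"H1.2": sum(r.dominant_variant == "H1.2" for r in regions),
              "H1.5": sum(r.dominant_variant == "H1.5" for r in regions)}
    promoters = _promoters(run, cfg.promoter_flank)
    frac = {}
    for variant in ("H1.2", "H1.5"):
        sub = [r for r in regions if r.dominant_variant == variant]
        frac[variant] = (promoter_overlap_fraction(sub, promoters)
                         if sub else None)
    run.summary["dominance"] = {"counts": counts,
                                "promoter_overlap_fraction": frac}
    run.record("dominance", "ok", [p], dataclasses.asdict(params))


def _promoters(run: PipelineRun, flank: int) -> IntervalSet:
    tss = list(run.features.get("active_tss", [])) + \
        list(run.features.get("inactive_tss", []))
    ivs = []
    for iv in tss:
        c = iv.center
        size = run.genome.chrom_sizes[iv.chrom]
        ivs.append(GenomicInterval(iv.chrom, max(0, c - flank),
                                   min(size, c + flank)))
    return merge_intervals(IntervalSet(ivs, genome=run.genome).sort())


def _stage_enrichment(run: PipelineRun) -> None:
    cfg = run.cfg
    out = run.outdir / "enrichment"
    out.mkdir(exist_ok=True)
    # peaks per condition via the threshold caller (synthetic mode)
    if not run.peaks:
        for cond, reps in run.tracks.items():
            run.peaks[cond] = call_peaks_threshold(
                _mean_track(reps), run.inputs[cond[0]], cfg.peak_quantile)
    feature_sets = {"hidden_epitope": run.truth.hidden_epitope}
    for name in ("enhancer", "cpg_island"):
        if name in run.features:
            feature_sets[name] = run.features[name]
    rows = []
    rng_seeds = np.random.SeedSequence(cfg.seed).generate_state(
        len(run.peaks) * len(feature_sets)) % (2 ** 31)
    i = 0
    results = {}
    for cond in sorted(run.peaks, key=_cond_key):
        pbed = out / f"peaks_{_cond_key(cond)}.bed"
        write_bed(run.peaks[cond], pbed)
        for fname, fset in feature_sets.items():
            if fset is None or len(fset) == 0 or len(run.peaks[cond]) == 0:
                continue
            res = fold_enrichment(run.peaks[cond], fset, run.genome,
                                  n_shuffles=cfg.n_shuffles,
                                  seed=int(rng_seeds[i]),
                                  query_name=_cond_key(cond),
                                  feature_name=fname)
            i += 1
            rows.append(res)
            results[f"{_cond_key(cond)}:{fname}"] = res.fold
    p = out / "fold_enrichment.tsv"
    with open(p, "w") as fh:
        fh.write("query\tfeature\tobserved\texpected\tfold\tn_shuffles\tp_empirical\n")
        for r in rows:
            fold = f"{r.fold:.4f}" if r.fold is not None else "NA"
            fh.write(f"{r.query_name}\t{r.feature_name}\t{r.observed}\t"
                     f"{r.expected:.3f}\t{fold}\t{r.n_shuffles}\t"
                     f"{r.p_empirical:.4g}\n")
    files = [p] + [out / f"peaks_{_cond_key(c)}.bed" for c in
                   sorted(run.peaks, key=_cond_key)]
    run.summary["fold_enrichment"] = results
    run.record("enrichment", "ok", files,
               {"n_shuffles": cfg.n_shuffles, "peak_quantile": cfg.peak_quantile,
                "peak_caller": "threshold (not a dedicated peak caller)"})


def _stage_profiles(run: PipelineRun) -> None:
    cfg = run.cfg
    out = run.outdir / "profiles"
    out.mkdir(exist_ok=True)
    anchors = anchor_points(run.features["active_tss"], "center")
    files = []
    widths = {}
    for cond in sorted(run.tracks, key=_cond_key):
        prof = aggregate_profile(_mean_track(run.tracks[cond]),
                                 run.inputs[cond[0]], anchors,
                                 cfg.profile_flank, cfg.profile_bin,
                                 strand_aware=True, name=_cond_key(cond))
        p = out / f"active_tss_{_cond_key(cond)}.tsv"
        _write_profile(prof, p)
        files.append(p)
        try:
            widths[_cond_key(cond)] = profile_dip_width(prof)
        except ValueError:
            widths[_cond_key(cond)] = None
    run.summary["tss_dip_widths_bp"] = widths
    run.record("profiles", "ok", files,
               {"flank": cfg.profile_flank, "bin": cfg.profile_bin})


def _write_profile(prof, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# anchors={prof.n_anchors}\noffset\tvalue\n")
        for o, v in zip(prof.offsets, prof.values):
            fh.write(f"{o}\t{v:.6g}\n")


def _stage_nrl(run: PipelineRun) -> None:
    cfg = run.cfg
    out = run.outdir / "nrl"
    out.mkdir(exist_ok=True)
    estimates = {}
    files = []
    for cond, dyads in sorted(run.nuc_maps.items(), key=lambda kv: _cond_key(kv[0])):
        span = IntervalSet([GenomicInterval(iv.chrom, 0,
                                            run.genome.chrom_sizes[iv.chrom])
                            for iv in merge_intervals(dyads)],
                           genome=run.genome)
        regions = merge_intervals(span)
        fit = estimate_nrl(dyads, regions, cfg.nrl_max_distance)
        estimates[_cond_key(cond)] = {"nrl_bp": fit.slope,
                                      "intercept_bp": fit.intercept,
                                      "r_squared": fit.r_squared,
                                      "summits_bp": fit.summit_positions.tolist()}
        p = out / f"nrl_{_cond_key(cond)}.json"
        with open(p, "w") as fh:
            json.dump(estimates[_cond_key(cond)], fh, indent=1)
        files.append(p)
    run.summary["nrl"] = {k: v["nrl_bp"] for k, v in estimates.items()}
    run.record("nrl", "ok", files, {"max_distance": cfg.nrl_max_distance})


def _stage_methylation(run: PipelineRun) -> None:
    cfg = run.cfg
    out = run.outdir / "methylation"
    out.mkdir(exist_ok=True)
    files = []
    if not run.peaks:
        for cond, reps in run.tracks.items():
            run.peaks[cond] = call_peaks_threshold(
                _mean_track(reps), run.inputs[cond[0]], cfg.peak_quantile)
    all_dyads = IntervalSet(
        [iv for dy in run.nuc_maps.values() for iv in dy],
        genome=run.genome).sort()
    peak_sets = {_cond_key(c): s for c, s in run.peaks.items()}
    classes = classify_nucleosomes(all_dyads, run.features["cpg_island"],
                                   peak_sets)
    means = {}
    for cls in classes:
        tag = f"{'inside' if cls.inside_cpg_island else 'outside'}_{cls.h1_signal}"
        if not cls.anchors:
            means[tag] = None
            continue
        try:
            prof = methylation_profile(run.meth, cls.anchors, cfg.meth_flank,
                                       cfg.meth_bin)
        except ValueError:
            means[tag] = None
            continue
        p = out / f"meth_profile_{tag}.tsv"
        _write_profile(prof, p)
        files.append(p)
        means[tag] = float(np.nanmean(prof.values))
    run.summary["methylation_class_means"] = means
    run.record("methylation", "ok", files,
               {"flank": cfg.meth_flank, "bin": cfg.meth_bin})


def _stage_chromomere(run: PipelineRun) -> None:
    out = run.outdir / "chromomere"
    out.mkdir(exist_ok=True)
    confocal, sted, centers = run.images
    params_conf = FitParams(roi_half_width=12)
    conf_fits = []
    for cx, cy in centers:
        seed_px = (int(cx / confocal.pixel_size), int(cy / confocal.pixel_size))
        conf_fits.append(fit_gaussian2d(confocal, seed_px, params_conf))
    sted_fits = segment_domains_sted(sted, FitParams(roi_half_width=7))
    files = []
    summary = {}
    for tag, fits in (("confocal", conf_fits), ("sted", sted_fits)):
        from .imaging import FIT_TABLE_HEADER, fit_table_row
        p = out / f"fits_{tag}.tsv"
        with open(p, "w") as fh:
            fh.write(FIT_TABLE_HEADER + "\n")
            for f in fits:
                fh.write(fit_table_row(f) + "\n")
        files.append(p)
        accepted = [f for f in fits if f.accepted]
        if accepted:
            dist = size_distribution(fits)
            summary[tag] = {"n_accepted": len(accepted),
                            "mean_fwhm_nm": dist.mean,
                            "median_fwhm_nm": dist.median, "sd_nm": dist.sd}
        else:
            summary[tag] = {"n_accepted": 0}
    run.summary["chromomere"] = summary
    run.record("chromomere", "ok", files, {})


def _load_files_mode(run: PipelineRun) -> None:
    """Populate the bundle from user paths; missing roles leave gaps that
    cause their stages to be skipped."""
    from .core import read_chrom_sizes
    cfg = run.cfg
    paths = cfg.paths
    if "chrom_sizes" not in paths:
        raise ValueError("files mode requires paths.chrom_sizes")
    run.genome = read_chrom_sizes(paths["chrom_sizes"])
    bin_size = int(paths.get("bin_size", 100))
    for cond in sim.CONDITIONS:
        key = f"tracks_{_cond_key(cond)}"
        if key in paths:
            run.tracks[cond] = [read_bedgraph(p, run.genome, bin_size)
                                for p in paths[key]]
    for protocol in ("xChIP", "xxChIP"):
        key = f"input_{protocol}"
        if key in paths:
            run.inputs[protocol] = read_bedgraph(paths[key], run.genome,
                                                 bin_size)
    for role in ("active_tss", "inactive_tss", "enhancer", "cpg_island"):
        if role in paths:
            run.features[role] = read_bed(paths[role], run.genome)
    for cond in sim.CONDITIONS:
        key = f"peaks_{_cond_key(cond)}"
        if key in paths:
            run.peaks[cond] = read_bed(paths[key], run.genome)
        key = f"nucleosomes_{_cond_key(cond)}"
        if key in paths:
            run.nuc_maps[cond] = read_bed(paths[key], run.genome)
    if "methylation" in paths:
        run.meth = read_methylation_table(paths["methylation"])
    if "confocal_image" in paths and "sted_image" in paths:
        import tifffile
        px = float(paths.get("pixel_nm", 10.0))
        from .imaging import MicroscopyImage
        conf = MicroscopyImage(tifffile.imread(paths["confocal_image"]),
                               px, "confocal")
        sted = MicroscopyImage(tifffile.imread(paths["sted_image"]), px, "STED")
        seeds = []
        if "confocal_seeds" in paths:
            with open(paths["confocal_seeds"]) as fh:
                for line in fh:
                    if line.strip():
                        x, y = line.split()[:2]
                        seeds.append((float(x) * px, float(y) * px))
        run.images = (conf, sted, seeds)
    run.truth = sim.GroundTruth(hidden_epitope=IntervalSet())


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run all stages; returns the manifest (also written to disk).

    Stage outputs land under ``cfg.outdir/<stage>/``; the manifest lists
    each stage's parameters and output checksums, and ``summary.json``
    holds the headline numbers (correlation matrix, dominant-region
    counts, fold-enrichment table, NRL per condition, chromomere sizes).
    """
    run = PipelineRun(cfg)
    if cfg.mode == "synthetic":
        _stage_simulate(run)
    elif cfg.mode == "files":
        _load_files_mode(run)
        run.skip("simulate", "files mode")
    else:
        raise ValueError(f"unknown mode {cfg.mode!r}")

    def have_tracks() -> bool:
        return len(run.tracks) == 4 and len(run.inputs) == 2

    stage_table = [
        ("windows", _stage_windows, have_tracks, "missing tracks/inputs"),
        ("dominance", _stage_dominance,
         lambda: (("xChIP", "H1.2") in run.tracks and
                  ("xChIP", "H1.5") in run.tracks and bool(run.features)),
         "missing xChIP replicate tracks or TSS features"),
        ("enrichment", _stage_enrichment,
         lambda: (have_tracks() or bool(run.peaks)) and
         (run.truth.hidden_epitope is not None and len(run.truth.hidden_epitope) > 0
          or any(f in run.features for f in ("enhancer", "cpg_island"))),
         "missing peaks/tracks or feature sets"),
        ("profiles", _stage_profiles,
         lambda: have_tracks() and "active_tss" in run.features,
         "missing tracks or TSS features"),
        ("nrl", _stage_nrl, lambda: bool(run.nuc_maps),
         "missing nucleosome maps"),
        ("methylation", _stage_methylation,
         lambda: run.meth is not None and bool(run.nuc_maps)
         and "cpg_island" in run.features and
         (have_tracks() or bool(run.peaks)),
         "missing methylation table, nucleosome maps or peaks"),
        ("chromomere", _stage_chromomere, lambda: run.images is not None,
         "missing images"),
    ]
    for name, fn, ready, why in stage_table:
        if not ready():
            run.skip(name, why)
            continue
        try:
            fn(run)
        except Exception as exc:
            run.manifest["stages"][name] = {
                "status": "failed", "error": {"stage": name,
                                              "type": type(exc).__name__,
                                              "message": str(exc)}}
            _write_manifest(run)
            raise RuntimeError(f"stage {name} failed: {exc}") from exc
    _write_manifest(run)
    return run.manifest


def _write_manifest(run: PipelineRun) -> None:
    with open(run.outdir / "summary.json", "w") as fh:
        json.dump(run.summary, fh, indent=1, default=float)
    with open(run.outdir / "manifest.json", "w") as fh:
        json.dump(run.manifest, fh, indent=1, default=str)
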