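"""Variant-dominance detection: relative difference, window labeling,
region merging and promoter overlap."""
import numpy as np
import pytest

from h1contrast import (
    DominanceParams,
    Genome,
    GenomicInterval,
    IntervalSet,
    SimConfig,
    count_overlaps,
    detect_dominant_windows,
    find_dominant_regions,
    merge_dominant_regions,
    promoter_overlap_fraction,
    relative_difference,
    replicate_stats,
    simulate_dominance_scenario,
)
from h1contrast.dominance import LABEL_A, LABEL_B, LABEL_NONE
from h1contrast.tracks import SignalTrack, WindowStats


def stats_from_values(genome, values, rsd=0.1):
    """WindowStats with given per-window means and a constant RSD."""
    mean = {c: np.asarray(v, dtype=float) for c, v in values.items()}
    return WindowStats(genome, 100, mean,
                       {c: np.full(len(v), rsd) for c, v in mean.items()},
                       {c: np.asarray(v) > 0 for c, v in mean.items()})


class TestRelativeDifference:
    def test_equal_values_zero(self):
        assert relative_difference(5.0, 5.0) == 0.0

    def test_one_sided_limit_is_two(self):
        assert relative_difference(10.0, 0.0) == 2.0

    def test_hand_computed(self):
        assert relative_difference(3.0, 1.0) == pytest.approx(1.0)

    def test_max_convention(self):
        assert relative_difference(3.0, 1.0, mode="max") == pytest.approx(2 / 3)

    def test_undefined_at_double_zero(self):
        with pytest.raises(ValueError):
            relative_difference(0.0, 0.0)


class TestDetectWindows:
    def test_strong_disparity_labels_a(self, toy_genome):
        sa = stats_from_values(toy_genome, {"chrA": [10.0] * 100,
                                            "chrB": [10.0] * 200})
        sb = stats_from_values(toy_genome, {"chrA": [0.01] * 100,
                                            "chrB": [0.01] * 200})
        labels = detect_dominant_windows(sa, sb)
        assert (labels["chrA"] == LABEL_A).all()

    def test_equal_means_unlabeled(self, toy_genome):
        s = stats_from_values(toy_genome, {"chrA": [5.0] * 100,
                                           "chrB": [5.0] * 200})
        labels = detect_dominant_windows(s, s)
        assert (labels["chrA"] == LABEL_NONE).all()

    def test_high_rsd_filters_out_window(self, toy_genome):
        sa = stats_from_values(toy_genome, {"chrA": [10.0] * 100,
                                            "chrB": [10.0] * 200}, rsd=0.6)
        sb = stats_from_values(toy_genome, {"chrA": [0.01] * 100,
                                            "chrB": [0.01] * 200}, rsd=0.1)
        labels = detect_dominant_windows(sa, sb)
        assert (labels["chrA"] == LABEL_NONE).all()

    def test_swapping_inputs_swaps_labels(self, rng, toy_genome):
        va = {"chrA": rng.random(100) * 10, "chrB": rng.random(200) * 10}
        vb = {"chrA": rng.random(100) * 10, "chrB": rng.random(200) * 10}
        sa, sb = stats_from_values(toy_genome, va), stats_from_values(toy_genome, vb)
        l1 = detect_dominant_windows(sa, sb)
        l2 = detect_dominant_windows(sb, sa)
        for c in l1:
            swapped = np.where(l1[c] == LABEL_A, LABEL_B,
                               np.where(l1[c] == LABEL_B, LABEL_A, LABEL_NONE))
            np.testing.assert_array_equal(l2[c], swapped)

    def test_raising_threshold_never_adds_windows(self, rng, toy_genome):
        va = {"chrA": rng.random(100) * 10, "chrB": rng.random(200) * 10}
        vb = {"chrA": rng.random(100) * 10, "chrB": rng.random(200) * 10}
        sa, sb = stats_from_values(toy_genome, va), stats_from_values(toy_genome, vb)
        n_prev = None
        for thr in (0.3, 0.6, 0.99, 1.5):
            labels = detect_dominant_windows(
                sa, sb, DominanceParams(rel_diff_min=thr))
            n = sum(int((v != LABEL_NONE).sum()) for v in labels.values())
            if n_prev is not None:
                assert n <= n_prev
            n_prev = n


class TestMergeRegions:
    def test_single_run(self, toy_genome):
        labels = {"chrA": np.array([LABEL_A] * 3 + [LABEL_NONE] * 97,
                                   dtype=np.int8),
                  "chrB": np.zeros(200, dtype=np.int8)}
        regions = merge_dominant_regions(labels, 100, toy_genome)
        assert len(regions) == 1
        r = regions[0]
        assert (r.interval.start, r.interval.end, r.n_windows) == (0, 300, 3)

    def test_no_gap_bridging(self, toy_genome):
        lab = np.zeros(100, dtype=np.int8)
        lab[0] = lab[2] = LABEL_A
        regions = merge_dominant_regions(
            {"chrA": lab, "chrB": np.zeros(200, dtype=np.int8)}, 100, toy_genome)
        assert len(regions) == 2
        assert all(r.n_windows == 1 for r in regions)

    def test_matches_rle_oracle(self, rng, toy_genome):
        for _ in range(100):
            lab = rng.integers(0, 3, size=100).astype(np.int8)
            labels = {"chrA": lab, "chrB": np.zeros(200, dtype=np.int8)}
            regions = merge_dominant_regions(labels, 100, toy_genome)
            # oracle: explicit run-length encoding
            runs = []
            i = 0
            while i < len(lab):
                j = i
                while j + 1 < len(lab) and lab[j + 1] == lab[i]:
                    j += 1
                if lab[i] != LABEL_NONE:
                    runs.append((i * 100, (j + 1) * 100,
                                 "H1.2" if lab[i] == LABEL_A else "H1.5"))
                i = j + 1
            got = [(r.interval.start, r.interval.end, r.dominant_variant)
                   for r in regions]
            assert got == runs


class TestPromoterOverlap:
    def _regions(self, toy_genome, intervals):
        labels = {"chrA": np.zeros(100, dtype=np.int8),
                  "chrB": np.zeros(200, dtype=np.int8)}
        for chrom, b0, b1 in intervals:
            labels[chrom][b0:b1] = LABEL_A
        return merge_dominant_regions(labels, 100, toy_genome)

    def test_whole_genome_promoters(self, toy_genome):
        regions = self._regions(toy_genome, [("chrA", 0, 2), ("chrB", 5, 9)])
        promoters = IntervalSet([GenomicInterval("chrA", 0, 10_000),
                                 GenomicInterval("chrB", 0, 20_000)])
        assert promoter_overlap_fraction(regions, promoters) == 1.0

    def test_no_promoters(self, toy_genome):
        regions = self._regions(toy_genome, [("chrA", 0, 2)])
        assert promoter_overlap_fraction(regions, IntervalSet()) == 0.0

    def test_constructed_fraction(self, toy_genome):
        # 10 regions, the first 4 inside the promoter zone
        spans = [("chrA", 10 * i, 10 * i + 2) for i in range(10)]
        regions = self._regions(toy_genome, spans)
        promoters = IntervalSet([GenomicInterval("chrA", 0, 3_300)])
        assert promoter_overlap_fraction(regions, promoters) == pytest.approx(0.4)

    def test_empty_regions_undefined(self):
        with pytest.raises(ValueError):
            promoter_overlap_fraction([], IntervalSet())


class TestPlantedRecovery:
    def test_precision_and_recall(self):
        cfg = SimConfig(genome=Genome({"chr1": 1_000_000, "chr2": 600_000}),
                        seed=21)
        tracks, truth = simulate_dominance_scenario(cfg.genome, cfg)
        sa = replicate_stats(tracks["H1.2"], 100)
        sb = replicate_stats(tracks["H1.5"], 100)
        regions = find_dominant_regions(sa, sb, cfg.genome)
        det = IntervalSet([r.interval for r in regions], genome=cfg.genome)
        tr = IntervalSet([iv for s in truth.dominant_regions.values()
                          for iv in s], genome=cfg.genome)
        precision = count_overlaps(det, tr) / len(det)
        recall = count_overlaps(tr, det) / len(tr)
        assert precision >= 0.95 and recall >= 0.95
        # detected variant agrees with the planted one
        for r in regions:
            planted = truth.dominant_regions[r.dominant_variant]
            assert count_overlaps(IntervalSet([r.interval]), planted) == 1
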