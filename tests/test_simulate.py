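"""Synthetic-data generators: determinism, placement, correlation structure
and ground-truth fidelity."""
import numpy as np
import pytest

from h1contrast import (
    CONDITIONS,
    Genome,
    GenomicInterval,
    IntervalSet,
    SimConfig,
    make_toy_genome,
    simulate_chip_tracks,
    simulate_image_pair,
    simulate_methylation,
    simulate_nucleosome_map,
)
from h1contrast.tracks import pairwise_correlation, window_means


@pytest.fixture(scope="module")
def small_cfg():
    return SimConfig(genome=Genome({"chr1": 1_500_000, "chr2": 800_000}),
                     n_active_tss=40, n_inactive_tss=40, n_enhancers=30,
                     n_cpg_islands=30, seed=11)


@pytest.fixture(scope="module")
def small_sim(small_cfg):
    genome, feats, truth = make_toy_genome(small_cfg)
    tracks, inputs = simulate_chip_tracks(genome, feats, small_cfg,
                                          truth.hidden_epitope)
    return genome, feats, truth, tracks, inputs


class TestToyGenome:
    def test_zero_counts_give_empty_sets(self):
        cfg = SimConfig(n_active_tss=0, n_inactive_tss=0, n_enhancers=0,
                        n_cpg_islands=0)
        _, feats, _ = make_toy_genome(cfg)
        assert all(len(s) == 0 for s in feats.values())

    def test_deterministic_given_seed(self, small_cfg):
        _, f1, _ = make_toy_genome(small_cfg)
        _, f2, _ = make_toy_genome(small_cfg)
        for k in f1:
            assert [(iv.chrom, iv.start, iv.end) for iv in f1[k]] == \
                   [(iv.chrom, iv.start, iv.end) for iv in f2[k]]

    def test_min_separation_enforced(self, small_sim):
        _, feats, _, _, _ = small_sim
        centers = {}
        for fs in feats.values():
            for iv in fs:
                centers.setdefault(iv.chrom, []).append(iv.center)
        for chrom, cs in centers.items():
            cs = sorted(cs)
            gaps = np.diff(cs)
            assert (gaps >= 5000).all()

    def test_capacity_error_when_genome_too_small(self):
        cfg = SimConfig(genome=Genome({"chr1": 60_000}), n_active_tss=500)
        with pytest.raises(ValueError):
            make_toy_genome(cfg)


class TestChipTracks:
    def test_noise_free_replicates_identical(self):
        cfg = SimConfig(genome=Genome({"chr1": 500_000}), n_active_tss=10,
                        n_inactive_tss=10, n_enhancers=10, n_cpg_islands=10,
                        noise_sd=0.0, replicate_sd=0.0, seed=3)
        genome, feats, truth = make_toy_genome(cfg)
        tracks, _ = simulate_chip_tracks(genome, feats, cfg,
                                         truth.hidden_epitope)
        for reps in tracks.values():
            for t in reps[1:]:
                np.testing.assert_array_equal(t.values["chr1"],
                                              reps[0].values["chr1"])

    def test_tracks_nonnegative_and_deterministic(self, small_cfg, small_sim):
        genome, feats, truth, tracks, inputs = small_sim
        for reps in tracks.values():
            for t in reps:
                assert all((v >= 0).all() for v in t.values.values())
        tracks2, _ = simulate_chip_tracks(genome, feats, small_cfg,
                                          truth.hidden_epitope)
        for cond in tracks:
            for t1, t2 in zip(tracks[cond], tracks2[cond]):
                for c in t1.values:
                    np.testing.assert_array_equal(t1.values[c], t2.values[c])

    def test_correlation_sign_structure(self, small_sim):
        genome, _, _, tracks, _ = small_sim
        means = []
        for cond in CONDITIONS:
            wm = [window_means(t, 1000) for t in tracks[cond]]
            means.append({c: np.mean([m[c] for m in wm], axis=0)
                          for c in genome.chrom_names})
        r = pairwise_correlation([], 1000, means=means)
        # order: x12, x15, xx12, xx15
        assert r[0, 1] > 0 and r[2, 3] > 0
        assert r[2, 3] > r[0, 1]            # xxChIP pair more alike
        for i in (0, 1):
            for j in (2, 3):
                assert r[i, j] < 0          # cross-protocol negative

    def test_hidden_epitope_contrast(self, small_sim):
        """xChIP mean exceeds xxChIP mean at hidden-epitope loci."""
        genome, _, truth, tracks, _ = small_sim
        assert len(truth.hidden_epitope) > 0
        for iv in truth.hidden_epitope:
            b = iv.center // 100
            x = np.mean([t.values[iv.chrom][b]
                         for t in tracks[("xChIP", "H1.2")]])
            xx = np.mean([t.values[iv.chrom][b]
                          for t in tracks[("xxChIP", "H1.2")]])
            assert x > xx


class TestNucleosomeMap:
    def test_exact_spacing_without_jitter(self):
        g = Genome({"chr1": 10_000})
        region = IntervalSet([GenomicInterval("chr1", 0, 2000)], genome=g)
        dy = simulate_nucleosome_map(region, 200, 0.0, seed=1)
        pos = np.array([iv.start for iv in dy])
        np.testing.assert_array_equal(np.diff(pos), 200)

    def test_deterministic(self):
        g = Genome({"chr1": 100_000})
        region = IntervalSet([GenomicInterval("chr1", 0, 100_000)], genome=g)
        d1 = simulate_nucleosome_map(region, 190, 10.0, seed=5)
        d2 = simulate_nucleosome_map(region, 190, 10.0, seed=5)
        assert [iv.start for iv in d1] == [iv.start for iv in d2]

    def test_mean_adjacent_spacing_near_repeat_length(self):
        g = Genome({"chr1": 1_000_000})
        region = IntervalSet([GenomicInterval("chr1", 0, 1_000_000)], genome=g)
        dy = simulate_nucleosome_map(region, 200, 10.0, seed=2)
        spacing = np.diff([iv.start for iv in dy])
        assert abs(spacing.mean() - 200) < 1.0

    def test_sub_nucleosomal_repeat_rejected(self):
        g = Genome({"chr1": 10_000})
        region = IntervalSet([GenomicInterval("chr1", 0, 2000)], genome=g)
        with pytest.raises(ValueError):
            simulate_nucleosome_map(region, 100, 0.0, seed=1)


class TestMethylation:
    def test_no_islands_all_background(self):
        g = Genome({"chr1": 200_000})
        meth = simulate_methylation(g, IntervalSet(genome=g), seed=1)
        # background regime: high methylation (Beta mean 0.8)
        assert meth.fraction["chr1"].mean() > 0.6

    def test_fractions_in_unit_interval_and_coverage_positive(self):
        g = Genome({"chr1": 300_000})
        islands = IntervalSet([GenomicInterval("chr1", i, i + 1000)
                               for i in range(10_000, 100_000, 10_000)],
                              genome=g)
        meth = simulate_methylation(g, islands, seed=2)
        f = meth.fraction["chr1"]
        assert ((f >= 0) & (f <= 1)).all()
        assert (meth.coverage["chr1"] >= 1).all()

    def test_island_sites_less_methylated(self):
        g = Genome({"chr1": 2_000_000})
        islands = IntervalSet([GenomicInterval("chr1", i, i + 1000)
                               for i in range(10_000, 1_500_000, 10_000)],
                              genome=g)
        meth = simulate_methylation(g, islands, seed=3)
        pos = meth.pos["chr1"]
        inside = np.zeros(len(pos), dtype=bool)
        for iv in islands:
            inside |= (pos >= iv.start) & (pos < iv.end)
        assert inside.sum() >= 1000 and (~inside).sum() >= 1000
        assert meth.fraction["chr1"][inside].mean() < \
            meth.fraction["chr1"][~inside].mean()


class TestImagePair:
    def test_same_seed_bit_identical(self):
        args = dict(domain_centers_nm=[(500, 500)], fwhm_true_nm=70.0,
                    pixel_nm=10.0, photon_scale=500.0,
                    image_shape=(100, 100), seed=9)
        c1, s1, _ = simulate_image_pair(**args)
        c2, s2, _ = simulate_image_pair(**args)
        np.testing.assert_array_equal(c1.pixels, c2.pixels)
        np.testing.assert_array_equal(s1.pixels, s2.pixels)

    def test_noiseless_peak_at_domain_center(self):
        conf, sted, _ = simulate_image_pair([(505, 755)], 0.0, pixel_nm=10.0,
                                            photon_scale=None,
                                            image_shape=(100, 100), seed=0)
        for img in (conf, sted):
            iy, ix = np.unravel_index(np.argmax(img.pixels), img.pixels.shape)
            assert abs(ix - 50) <= 1 and abs(iy - 75) <= 1

    def test_domain_outside_fov_rejected(self):
        with pytest.raises(ValueError):
            simulate_image_pair([(5000, 50)], 70.0, pixel_nm=10.0,
                                image_shape=(100, 100), seed=0)
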