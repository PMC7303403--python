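"""GFP, peak extraction, modified K-means, back-fitting, smoothing, statistics."""

import numpy as np
import pytest

from eegmicrostates.containers import EpochedRecording, MicrostateMaps, Segmentation
from eegmicrostates.microstates import (aggregate_and_cluster,
                                        assign_canonical_labels, backfit,
                                        canonicalize_to_templates,
                                        compute_stats, extract_gfp_peaks, gfp,
                                        modified_kmeans, smooth_segmentation,
                                        spatial_correlation)
from eegmicrostates.montage import MONTAGE_10_20
from eegmicrostates.preprocess import average_reference, epoch
from eegmicrostates.synthetic import SubjectSimConfig, simulate_subject

from conftest import brute_force_kmeans


class TestGfp:
    def test_hand_computed_value(self):
        frame = np.zeros(19)
        frame[0], frame[1] = 1.0, -1.0
        assert gfp(frame) == pytest.approx(np.sqrt(2 / 19))

    def test_constant_frame_is_zero(self):
        assert gfp(np.full(19, 3.7)) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("scale", [-2.5, 0.5, 10.0])
    def test_absolute_homogeneity(self, scale):
        rng = np.random.default_rng(0)
        frame = rng.normal(size=19)
        assert gfp(scale * frame) == pytest.approx(abs(scale) * gfp(frame))


class TestExtractGfpPeaks:
    def test_close_peaks_resolved_to_higher_one(self):
        # two local maxima closer than the minimum distance: lower one dropped
        trace = np.array([0.0, 1.0, 0.9, 1.2, 0.0, 0.0, 0.0, 0.0])
        data = np.zeros((19, len(trace)))
        data[0] = trace * 2  # channel deviation creates the GFP trace shape
        ep = EpochedRecording(data[None], fs=8.0, montage=MONTAGE_10_20,
                              epoch_length_s=1.0)
        peaks = extract_gfp_peaks(ep, min_distance_ms=400.0, max_peaks=10,
                                  sd_threshold=np.inf)
        assert list(peaks.peak_times) == [3]

    def test_peak_density_matches_rectified_carrier(self, templates):
        """|sin| envelope at 10 Hz -> ~ 2 * 10 peaks per second."""
        cfg = SubjectSimConfig(templates=templates, duration_s=60.0, snr=20.0)
        rec, _ = simulate_subject(cfg, 5)
        ep = epoch(rec, 1.0)
        peaks = extract_gfp_peaks(ep, max_peaks=10 ** 6, sd_threshold=np.inf)
        assert peaks.n_peaks == pytest.approx(1200, rel=0.10)

    def test_equal_peaks_none_excluded_by_sd_rule(self):
        t = np.arange(200) / 200.0
        data = np.zeros((19, 200))
        data[0] = np.abs(np.sin(2 * np.pi * 10 * t))
        ep = EpochedRecording(data[None], fs=200.0, montage=MONTAGE_10_20,
                              epoch_length_s=1.0)
        all_peaks = extract_gfp_peaks(ep, sd_threshold=np.inf)
        with_rule = extract_gfp_peaks(ep, sd_threshold=2.0)
        assert with_rule.n_peaks == all_peaks.n_peaks

    def test_first_max_peaks_in_temporal_order(self, sim_epoched):
        peaks = extract_gfp_peaks(sim_epoched, max_peaks=100)
        assert peaks.n_peaks == 100
        assert np.all(np.diff(peaks.peak_times) > 0)


class TestModifiedKmeans:
    def test_single_map_degenerate_case(self):
        rng = np.random.default_rng(1)
        m = rng.normal(size=19)
        m -= m.mean()
        m /= np.linalg.norm(m)
        signs = rng.choice([-1, 1], size=12)
        topos = np.outer(signs, m)
        maps = modified_kmeans(topos, 1, restarts=3, seed=0)
        assert abs(spatial_correlation(maps.maps[0], m)) > 1 - 1e-12
        assert maps.residual_variance == pytest.approx(0, abs=1e-12)

    def test_orthogonal_planted_maps_recovered(self, templates):
        rng = np.random.default_rng(2)
        base, _ = np.linalg.qr(rng.normal(size=(19, 4)))
        base = (base - base.mean(0)).T
        base /= np.linalg.norm(base, axis=1, keepdims=True)
        topos = np.vstack([s * base + rng.normal(0, 1e-4, base.shape)
                           for s in (1, -1, 1)])
        maps = modified_kmeans(topos, 4, restarts=20, seed=3)
        corr = np.abs(base @ maps.maps.T)
        assert corr.max(axis=1).min() > 0.99

    def test_matches_brute_force_optimum(self):
        """Iterative algorithm attains the exhaustive-assignment optimum."""
        rng = np.random.default_rng(4)
        for _ in range(10):
            n = int(rng.integers(5, 9))
            topos = rng.normal(size=(n, 4))
            topos -= topos.mean(axis=1, keepdims=True)
            maps = modified_kmeans(topos, 2, restarts=20, seed=5)
            oracle = brute_force_kmeans(topos, 2)
            assert maps.residual_variance == pytest.approx(oracle, abs=1e-9)

    def test_more_clusters_than_points_rejected(self):
        with pytest.raises(ValueError):
            modified_kmeans(np.zeros((3, 19)), 4)

    def test_aggregate_single_subject_identity(self, sim_epoched):
        peaks = extract_gfp_peaks(sim_epoched, max_peaks=200)
        direct = modified_kmeans(peaks.topographies, 4, restarts=5, seed=9)
        via_agg = aggregate_and_cluster([peaks], 4, 200, restarts=5, seed=9)
        assert np.allclose(direct.maps, via_agg.maps)


class TestCanonicalLabels:
    def test_identity_assignment(self, templates):
        maps = MicrostateMaps(maps=-templates.maps, montage=templates.montage,
                              labels=("0", "1", "2", "3"))
        labeled = assign_canonical_labels(maps, templates)
        assert labeled.labels == ("A", "B", "C", "D")
        assert np.allclose(labeled.template_correlations, 1.0)

    def test_labels_follow_shuffle(self, templates):
        order = [2, 0, 3, 1]
        maps = MicrostateMaps(maps=templates.maps[order],
                              montage=templates.montage,
                              labels=("0", "1", "2", "3"))
        labeled = assign_canonical_labels(maps, templates)
        assert labeled.labels == ("C", "A", "D", "B")

    def test_hybrid_label_for_intermediate_map(self, templates):
        # a map equidistant between templates A and C gets a hybrid label
        # (A+B is not usable here: with mirror-symmetric diagonal templates
        # the x-components cancel and A+B coincides with C itself)
        hybrid = templates.maps[0] + templates.maps[2]
        hybrid /= np.linalg.norm(hybrid)
        rows = np.vstack([hybrid, templates.maps[1:]])
        maps = MicrostateMaps(maps=rows, montage=templates.montage,
                              labels=("0", "1", "2", "3"))
        labeled = assign_canonical_labels(maps, templates)
        assert labeled.labels[0] == "A/C"

    def test_canonicalize_reorders_to_template_order(self, templates):
        order = [3, 1, 0, 2]
        maps = MicrostateMaps(maps=templates.maps[order],
                              montage=templates.montage,
                              labels=("0", "1", "2", "3"))
        fixed, info = canonicalize_to_templates(maps, templates)
        assert fixed.labels == ("A", "B", "C", "D")
        assert np.allclose(np.abs(np.sum(fixed.maps * templates.maps, axis=1)), 1)


class TestBackfit:
    def _envelope_recording(self, templates, map_idx, sign=1.0):
        t = np.arange(400) / 200.0
        env = np.abs(np.sin(2 * np.pi * 10 * t)) + 0.05
        data = sign * np.outer(templates.maps[map_idx], env)
        return EpochedRecording(data.reshape(19, 2, 200).transpose(1, 0, 2),
                                fs=200.0, montage=templates.montage,
                                epoch_length_s=1.0)

    def _maps(self, templates):
        return MicrostateMaps(maps=templates.maps, montage=templates.montage,
                              labels=templates.labels)

    def test_pure_map_c_labeled_c_everywhere(self, templates):
        seg = backfit(self._envelope_recording(templates, 2), self._maps(templates))
        assert np.all(seg.labels == 2)
        assert seg.fit.min() > 0.999

    def test_polarity_invariance(self, templates):
        seg = backfit(self._envelope_recording(templates, 2, sign=-1.0),
                      self._maps(templates))
        assert np.all(seg.labels == 2)

    def test_label_accuracy_at_gfp_peaks(self, templates, sim_subject):
        rec, true_labels = sim_subject
        ep = epoch(average_reference(rec), 1.0)
        seg = backfit(ep, self._maps(templates))
        peaks = extract_gfp_peaks(ep, max_peaks=10 ** 6)
        fitted = seg.labels.reshape(-1)[peaks.peak_times]
        truth = true_labels[:seg.labels.size][peaks.peak_times]
        assert np.mean(fitted == truth) >= 0.95

    def test_montage_mismatch_rejected(self, templates, sim_epoched):
        maps = MicrostateMaps(maps=templates.maps[:, :5],
                              montage=templates.montage[:5],
                              labels=templates.labels)
        with pytest.raises(ValueError, match="montage"):
            backfit(sim_epoched, maps)


class TestSmoothing:
    def _segmentation_from_labels(self, labels, templates, fs=200.0):
        labels = np.asarray(labels)[None]
        k, n = 4, labels.shape[1]
        fit_all = np.full((1, k, n), 0.5)
        fit_all[0, labels[0], np.arange(n)] = 0.9
        maps = MicrostateMaps(maps=templates.maps, montage=templates.montage,
                              labels=templates.labels)
        seg = Segmentation(labels=labels, fit=np.full((1, n), 0.9),
                           gfp=np.ones((1, n)), fs=fs, maps=maps)
        seg.fit_all = fit_all
        return seg

    def test_short_run_absorbed_by_neighbours(self, templates):
        labels = [0] * 20 + [1] * 2 + [0] * 20  # 100 ms, 10 ms, 100 ms
        seg = self._segmentation_from_labels(labels, templates)
        out = smooth_segmentation(seg, 30.0)
        assert np.all(out.labels == 0)

    def test_identity_when_all_runs_long(self, templates):
        labels = [0] * 20 + [1] * 20 + [2] * 20
        seg = self._segmentation_from_labels(labels, templates)
        out = smooth_segmentation(seg, 30.0)
        assert np.array_equal(out.labels, seg.labels)

    def test_sub_sample_threshold_is_noop(self, templates):
        labels = [0, 1, 0, 1]
        seg = self._segmentation_from_labels(labels, templates)
        assert smooth_segmentation(seg, 1.0) is seg

    def test_label_noise_removed(self, templates, sim_epoched):
        maps = MicrostateMaps(maps=templates.maps, montage=templates.montage,
                              labels=templates.labels)
        seg = backfit(sim_epoched, maps)
        clean = smooth_segmentation(seg, 30.0)
        rng = np.random.default_rng(8)
        noisy_labels = clean.labels.copy()
        flip = rng.random(noisy_labels.shape) < 0.05
        noisy_labels[flip] = (noisy_labels[flip] + rng.integers(
            1, 4, size=int(flip.sum()))) % 4
        noisy = Segmentation(labels=noisy_labels, fit=clean.fit, gfp=clean.gfp,
                             fs=clean.fs, maps=maps)
        noisy.fit_all = clean.fit_all
        restored = smooth_segmentation(noisy, 30.0)
        agreement = np.mean(restored.labels == clean.labels)
        assert agreement >= 0.99


class TestComputeStats:
    def test_worked_micro_example(self, templates):
        labels = np.array([0] * 40 + [1] * 60 + [0] * 100)[None]
        maps = MicrostateMaps(maps=templates.maps, montage=templates.montage,
                              labels=templates.labels)
        seg = Segmentation(labels=labels, fit=np.ones_like(labels, float),
                           gfp=np.ones_like(labels, float), fs=200.0, maps=maps)
        stats = compute_stats(seg)
        assert stats.duration_ms[0] == pytest.approx(350.0)
        assert stats.duration_ms[1] == pytest.approx(300.0)
        assert stats.coverage_pct[0] == pytest.approx(70.0)
        assert stats.coverage_pct[1] == pytest.approx(30.0)
        assert stats.occurrence_per_s[0] == pytest.approx(2.0)
        assert stats.occurrence_per_s[1] == pytest.approx(1.0)
        assert np.isnan(stats.duration_ms[2])
        assert stats.occurrence_per_s[2] == 0.0

    def test_gev_is_one_for_self_consistent_signal(self, templates):
        t = np.arange(600) / 200.0
        env = np.abs(np.sin(2 * np.pi * 10 * t)) + 0.05
        states = np.repeat([0, 1, 2], 200)
        data = templates.maps[states].T * env
        ep = EpochedRecording(data.reshape(19, 3, 200).transpose(1, 0, 2),
                              fs=200.0, montage=templates.montage,
                              epoch_length_s=1.0)
        maps = MicrostateMaps(maps=templates.maps, montage=templates.montage,
                              labels=templates.labels)
        stats = compute_stats(backfit(ep, maps))
        assert stats.gev_total == pytest.approx(1.0, abs=1e-10)

    def test_coverage_sums_to_100(self, templates, sim_epoched):
        maps = MicrostateMaps(maps=templates.maps, montage=templates.montage,
                              labels=templates.labels)
        stats = compute_stats(smooth_segmentation(backfit(sim_epoched, maps), 30))
        assert stats.coverage_pct.sum() == pytest.approx(100.0)

    def test_coverage_duration_occurrence_identity(self, templates, sim_epoched):
        maps = MicrostateMaps(maps=templates.maps, montage=templates.montage,
                              labels=templates.labels)
        stats = compute_stats(smooth_segmentation(backfit(sim_epoched, maps), 30))
        product = stats.duration_ms * stats.occurrence_per_s / 10.0
        assert np.allclose(product, stats.coverage_pct, rtol=0.02)

    @pytest.mark.parametrize("factor", [-1.0, 3.5])
    def test_sign_flip_and_rescaling_invariance(self, templates, sim_subject,
                                                factor):
        rec, _ = sim_subject
        maps = MicrostateMaps(maps=templates.maps, montage=templates.montage,
                              labels=templates.labels)
        ep = epoch(average_reference(rec), 1.0)
        scaled = EpochedRecording(ep.epochs * factor, fs=ep.fs,
                                  montage=ep.montage, epoch_length_s=1.0)
        base = compute_stats(smooth_segmentation(backfit(ep, maps), 30))
        other = compute_stats(smooth_segmentation(backfit(scaled, maps), 30))
        assert np.allclose(base.duration_ms, other.duration_ms)
        assert np.allclose(base.coverage_pct, other.coverage_pct)
        assert base.gev_total == pytest.approx(other.gev_total)
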