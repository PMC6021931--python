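"""Detection, cross-sample matching, and feature-matrix assembly."""

import numpy as np
import pandas as pd
import pytest

import chromclass as cc
from chromclass.peaks import DetectedPeak, build_feature_matrix, detect_peaks, match_peaks
from chromclass.preprocess import NoiseStats


def _corrected(y):
    c = cc.Chromatogram(rt=np.arange(len(y)) / 120.0 + 0.5, intensity=np.asarray(y, float))
    c.stage_tag = "baseline_corrected"
    return c


class TestDetectPeaks:
    def test_single_triangular_peak(self):
        y = np.zeros(101)
        y[40:51] = np.linspace(0, 5.0, 11)
        y[50:61] = np.linspace(5.0, 0, 11)
        dets = detect_peaks(_corrected(y), NoiseStats(0.0, 0.5))
        assert len(dets) == 1
        assert dets[0].height == pytest.approx(5.0)

    def test_plateau_takes_leftmost_apex(self):
        y = np.zeros(50)
        y[20:24] = 3.0
        dets = detect_peaks(_corrected(y), NoiseStats(0.0, 0.1))
        assert len(dets) == 1
        assert dets[0].rt_apex == pytest.approx(0.5 + 20 / 120.0)

    def test_noiseless_trace_yields_exactly_22_true_apexes(self, default_specs):
        design = cc.StudyDesign(noise_sd=1e-9, baseline_amplitude=0.0)
        rng = np.random.default_rng(1)
        c = cc.simulate_chromatogram(default_specs, 2, 0.0, 0.0, design, rng)
        corrected, _ = cc.preprocess_chromatogram(c)
        dets = detect_peaks(corrected, NoiseStats(0.0, 0.01))
        assert len(dets) == 22
        step = 1.0 / design.points_per_min
        for s, d in zip(default_specs, dets):
            assert abs(d.rt_apex - s.retention_time) <= step + 1e-12

    def test_false_positive_rate_on_pure_noise(self):
        # Gaussian tail oracle: above-threshold local maxima are rare
        rng = np.random.default_rng(5)
        n, reps, counts = 3301, 20, []
        for _ in range(reps):
            y = rng.normal(0, 1.0, n)
            counts.append(len(detect_peaks(_corrected(y), NoiseStats(0.0, 1.0))))
        assert np.mean(counts) <= 0.01 * n

    def test_threshold_monotone(self):
        rng = np.random.default_rng(8)
        y = rng.normal(0, 1.0, 2000)
        lower = {d.rt_apex for d in detect_peaks(_corrected(y), NoiseStats(0.0, 0.8))}
        higher = {d.rt_apex for d in detect_peaks(_corrected(y), NoiseStats(0.0, 1.2))}
        assert higher <= lower

    def test_requires_corrected_stage(self):
        c = cc.Chromatogram(rt=np.arange(10.0), intensity=np.zeros(10))
        with pytest.raises(ValueError):
            detect_peaks(c, NoiseStats(0.0, 1.0))


def _det(rt, h=1.0):
    return DetectedPeak(rt_apex=rt, height=h)


class TestMatchPeaks:
    def test_identical_detections_full_presence(self):
        dets = [[_det(5.0), _det(9.0), _det(14.0)] for _ in range(10)]
        reg = match_peaks(dets)
        assert len(reg) == 3
        np.testing.assert_allclose(reg.consensus_rts, [5.0, 9.0, 14.0])
        assert (reg.table["presence_fraction"] == 1.0).all()

    def test_presence_threshold_semantics(self):
        dets = [[_det(5.0), _det(9.0)] for _ in range(9)] + [[_det(5.0)]]
        strict = match_peaks(dets, presence_threshold=1.0)
        relaxed = match_peaks(dets, presence_threshold=0.9)
        assert list(strict.consensus_rts) == [5.0]
        assert list(relaxed.consensus_rts) == [5.0, 9.0]

    def test_order_invariance(self):
        rng = np.random.default_rng(2)
        dets = [
            [_det(5.0 + rng.normal(0, 0.01)), _det(9.0 + rng.normal(0, 0.01))]
            for _ in range(20)
        ]
        reg1 = match_peaks(dets)
        reg2 = match_peaks(dets[::-1])
        np.testing.assert_allclose(reg1.consensus_rts, reg2.consensus_rts)

    def test_robust_to_sparse_spurious_apexes(self):
        # a few stray apexes between true peaks must not bridge clusters
        rng = np.random.default_rng(3)
        dets = []
        for _ in range(50):
            d = [_det(5.0 + rng.normal(0, 0.005)), _det(6.0 + rng.normal(0, 0.005))]
            for _ in range(rng.poisson(2)):
                d.append(_det(rng.uniform(4.0, 7.0), h=0.1))
            dets.append(sorted(d, key=lambda x: x.rt_apex))
        reg = match_peaks(dets, rt_tol=0.1, presence_threshold=1.0)
        np.testing.assert_allclose(reg.consensus_rts, [5.0, 6.0], atol=0.01)

    def test_invalid_tolerance_rejected(self):
        with pytest.raises(ValueError):
            match_peaks([[_det(1.0)]], rt_tol=0.0)

    def test_default_small_study_recovers_22_peaks(self, small_study_processed):
        assert len(small_study_processed["registry"]) == 22


class TestBuildFeatureMatrix:
    def test_shape_and_metadata(self, small_study_processed):
        fm = small_study_processed["features"]
        n_traces = len(small_study_processed["manifest"])
        assert fm.values.shape == (n_traces, 22)
        assert list(fm.meta.columns) == ["sample_id", "replicate_id", "class_label"]
        assert not fm.values.isna().any().any()

    def test_identical_traces_give_identical_rows(self):
        dets = [[_det(5.0, 2.0), _det(9.0, 3.0)]] * 4
        manifest = pd.DataFrame(
            {"sample_id": list("abcd"), "replicate_id": 1, "class_label": 1}
        )
        reg = match_peaks(dets)
        fm = build_feature_matrix(dets, [0.1] * 4, manifest, reg)
        assert (fm.values.nunique() == 1).all()

    def test_missing_match_imputed_with_floor_and_flagged(self):
        dets = [[_det(5.0, 2.0), _det(9.0, 3.0)]] * 9 + [[_det(5.0, 2.0)]]
        manifest = pd.DataFrame(
            {"sample_id": [f"s{i}" for i in range(10)], "replicate_id": 1, "class_label": 1}
        )
        reg = match_peaks(dets, presence_threshold=0.9)
        fm = build_feature_matrix(dets, [0.5] * 10, manifest, reg)
        assert fm.values.iloc[9, 1] == pytest.approx(0.5)  # detection floor
        assert fm.imputed.iloc[9, 1]
        assert not fm.imputed.iloc[:9].any().any()

    def test_noiseless_study_matches_generator_heights(self, default_specs):
        design = cc.StudyDesign(
            class_sizes=(1, 1, 1, 1),
            replicates_per_sample=1,
            noise_sd=1e-9,
            baseline_amplitude=0.0,
            eo_log_sd=1e-12,
            replicate_log_sd=1e-12,
        )
        traces, manifest = cc.simulate_study(default_specs, design, seed=2)
        dets, thresholds = [], []
        for c in traces:
            corrected, _ = cc.preprocess_chromatogram(c)
            dets.append(detect_peaks(corrected, NoiseStats(0.0, 0.01)))
            thresholds.append(0.03)
        reg = match_peaks(dets)
        fm = build_feature_matrix(dets, thresholds, manifest, reg)
        for i, cls in enumerate(manifest["class_label"]):
            for j, s in enumerate(default_specs):
                true = cc.synthetic.adjusted_class_log_heights(s, 1.0)[cls - 1]
                assert 10 ** fm.values.iloc[i, j] == pytest.approx(10 ** true, rel=0.02)

    def test_end_to_end_determinism(self, small_study_processed):
        d = small_study_processed
        fm2 = build_feature_matrix(
            d["detections"], d["thresholds"], d["manifest"], d["registry"]
        )
        assert fm2.values.equals(d["features"].values)

    def test_empty_registry_rejected(self):
        reg = match_peaks([[_det(1.0)], []], presence_threshold=1.0)
        manifest = pd.DataFrame(
            {"sample_id": ["a", "b"], "replicate_id": 1, "class_label": 1}
        )
        with pytest.raises(ValueError):
            build_feature_matrix([[_det(1.0)], []], [0.1, 0.1], manifest, reg)
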