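"""Shared fixtures: small simulated studies reused across test modules."""

import pytest

import chromclass as cc


@pytest.fixture(scope="session")
def default_specs():
    return cc.default_peak_specs()


@pytest.fixture(scope="session")
def small_design():
    """A reduced-footprint study: 14 oils in triplicate, default noise."""
    return cc.StudyDesign(class_sizes=(3, 4, 4, 3), seed=11)


@pytest.fixture(scope="session")
def small_study(default_specs, small_design):
    """Simulated traces + manifest for the reduced study."""
    return cc.simulate_study(default_specs, small_design, seed=11)


@pytest.fixture(scope="session")
def small_study_processed(default_specs, small_study):
    """Detections, thresholds, registry and features of the reduced study."""
    traces, manifest = small_study
    detections, thresholds = [], []
    for c in traces:
        corrected, stats = cc.preprocess_chromatogram(c)
        detections.append(cc.detect_peaks(corrected, stats))
        thresholds.append(stats.threshold)
    registry = cc.match_peaks(detections)
    features = cc.build_feature_matrix(detections, thresholds, manifest, registry)
    return {
        "detections": detections,
        "thresholds": thresholds,
        "registry": registry,
        "features": features,
        "manifest": manifest,
    }


@pytest.fixture(scope="session")
def default_heights(default_specs):
    """Directly simulated 303 x 22 log-height features, default design."""
    return cc.simulate_log_heights(default_specs, cc.StudyDesign(seed=3))
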