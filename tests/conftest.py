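import numpy as np
import pytest

import vocalshift as vs


@pytest.fixture(scope="session")
def small_session():
    """A 150+150-call synthetic session with ground truth (shared)."""
    spec = vs.SessionSpec(n_calls_baseline=150, n_calls_post=150, seed=3)
    recording, truth = vs.generate_session(spec)
    return spec, recording, truth


@pytest.fixture(scope="session")
def small_session_calls(small_session):
    """Validated, condition-labelled feature table for the small session."""
    _, recording, truth = small_session
    segments = vs.extract_calls(recording)
    calls = vs.features_table(segments, recording.sample_rate_hz,
                              valid_only=True)
    idx = vs.match_detections(calls, truth)
    keep = idx >= 0
    calls = calls[keep].reset_index(drop=True)
    calls["condition"] = truth["condition"].to_numpy()[idx[keep]]
    calls["context_label"] = truth["context_label"].to_numpy()[idx[keep]]
    calls["true_centroid_khz"] = \
        truth["true_centroid_khz"].to_numpy()[idx[keep]]
    return calls


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
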