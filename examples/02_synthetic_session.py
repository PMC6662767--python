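"""Generate a small ground-truthed recording session and detect its calls.

A session is a continuous 192-kHz waveform containing harmonic social
calls over a noise floor, plus cage-noise transients.  Per-call spectral
centroids drift as an AR(1) process whose mean is raised by 3 kHz in the
post-noise condition.  The detector's precision/recall are scored
against the generator's ground-truth call table.
"""

import vocalshift as vs

spec = vs.SessionSpec(n_calls_baseline=100, n_calls_post=100,
                      centroid_shift_khz=3.0, seed=42)
recording, truth = vs.generate_session(spec)
print(f"session: {recording.duration_s:.1f} s at "
      f"{recording.sample_rate_hz/1000:.0f} kHz, {len(truth)} true calls")

segments = vs.extract_calls(recording)
calls = vs.features_table(segments, recording.sample_rate_hz,
                          valid_only=True)
metrics = vs.detection_precision_recall(calls, truth)
print(f"detected {metrics['n_detected']} calls: "
      f"precision {metrics['precision']:.3f}, recall {metrics['recall']:.3f}")

base = truth[truth.condition == "baseline"].true_centroid_khz.mean()
post = truth[truth.condition == "post"].true_centroid_khz.mean()
print(f"true centroid means: baseline {base:.2f} kHz, post {post:.2f} kHz")
print("\nPrecision/recall near 1 mean the envelope detector recovers the")
print("synthetic calls and rejects the cage-noise transients.")
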