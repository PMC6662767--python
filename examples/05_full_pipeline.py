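"""End-to-end run: synthesis -> detection -> features -> bins -> statistics.

Generates a 400+400-call session with a 3 kHz injected centroid shift,
runs the complete pipeline and prints the recovered shift, its AR(1)
z-test, the per-parameter shift table and the bin classifier's
cross-validated accuracies.
"""

import vocalshift as vs

cfg = vs.RunConfig()
cfg.session = vs.SessionSpec(n_calls_baseline=400, n_calls_post=400,
                             centroid_shift_khz=3.0, seed=99)
cfg.binning = vs.BinningParams(bin_size=35)
result = vs.run_pipeline(cfg)

m = result.detection_metrics
print(f"detection: precision {m['precision']:.3f} recall {m['recall']:.3f}")
ct = result.centroid_test
print(f"centroid shift {ct.mean_diff/1000:+.3f} kHz "
      f"(SE {ct.corrected_se/1000:.3f}), z {ct.z:.2f}, p {ct.p:.2e}; "
      f"alpha {result.alpha_corrected}")
print("\nper-parameter shifts (post - baseline):")
print(result.shift_table[["parameter", "shift", "p", "significant"]]
      .to_string(index=False))
if result.classifier:
    print(f"\nclassifier per-class accuracy: "
          f"{result.classifier.per_class_accuracy}")
print("\nThe recovered shift should lie near the injected 3.0 kHz and be")
print("significant at the Bonferroni-corrected alpha; untouched")
print("parameters stay non-significant.")
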