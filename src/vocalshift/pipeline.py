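"""End-to-end orchestration: synthesis/ingest, detect, features, bins, stats.

``run_pipeline`` composes the full analysis on one session: generate (or
load) audio, detect and validate calls, compute the 11 acoustic
parameters, apply the validity filter, summarize into observation bins
per condition, run the AR(1)-aware statistics on the spectral centroid,
build the per-parameter shift table and trajectories, and classify bins
by condition.  Everything is seeded, and a result bundle carries all
intermediate tables plus the parameters used.

``stratify_by_context`` mirrors the context-specific analysis: calls are
split by behavioral context label, summarized in 35-call bins, and each
context is tested with the AR(1) z-test — falling back to Simulation
Modelling Analysis when either side has fewer than 30 bins.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .audio import AudioRecording, read_wav, write_wav
from .binning import BinningParams, sliding_mean, summarize
from .classify import ClassifierConfig, classify_bins
from .detect import DetectionParams, extract_calls
from .features import FEATURE_COLUMNS, FeatureParams, features_table
from .stats import (AR1TestResult, SMAResult, ar1_ztest, bonferroni_alpha,
                    sma_test)
from .synth import SessionSpec, generate_session

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything one pipeline run needs, with fixed seeds."""

    session: SessionSpec = field(default_factory=SessionSpec)
    detection: DetectionParams = field(default_factory=DetectionParams)
    features: FeatureParams = field(default_factory=FeatureParams)
    binning: BinningParams = field(default_factory=BinningParams)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    alpha: float = 0.05
    n_parameters: int = 11
    seed: int = 0
    input_wav: str | None = None      # analyze an existing recording instead
    truth_csv: str | None = None
    outdir: str | None = None
    run_classifier: bool = True

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        for key, sub_cls in [("session", SessionSpec),
                             ("detection", DetectionParams),
                             ("features", FeatureParams),
                             ("binning", BinningParams),
                             ("classifier", ClassifierConfig)]:
            if key in raw:
                sub = raw.pop(key)
                for k, v in list(sub.items()):
                    if isinstance(v, list):
                        sub[k] = tuple(v)
                kwargs[key] = sub_cls(**sub)
        kwargs.update(raw)
        return cls(**kwargs)


@dataclass
class PipelineResult:
    calls: pd.DataFrame               # valid calls with condition labels
    bins: pd.DataFrame                # observation bins per condition
    centroid_test: AR1TestResult
    shift_table: pd.DataFrame         # per-parameter shift and significance
    trajectory: pd.DataFrame
    classifier: object | None
    detection_metrics: dict | None
    alpha_corrected: float
    config: RunConfig


# ---------------------------------------------------------------------------
# ground-truth matching


def match_detections(detected: pd.DataFrame,
                     truth: pd.DataFrame) -> np.ndarray:
    """Index of the overlapping ground-truth call per detection (-1: none).

    A detection matches the truth interval containing its midpoint
    (padded by 5 ms on each side to absorb envelope-edge jitter).
    """
    idx = np.full(len(detected), -1, dtype=int)
    if len(truth) == 0 or len(detected) == 0:
        return idx
    onsets = truth["onset_s"].to_numpy()
    offsets = truth["offset_s"].to_numpy()
    mids = ((detected["start_s"] + detected["end_s"]) / 2.0).to_numpy()
    lo = np.searchsorted(onsets, mids) - 1
    for i, (mid, j) in enumerate(zip(mids, lo)):
        for cand in (j, j + 1):
            if 0 <= cand < len(truth) and \
                    onsets[cand] - 0.005 <= mid <= offsets[cand] + 0.005:
                idx[i] = cand
                break
    return idx


def detection_precision_recall(detected: pd.DataFrame,
                               truth: pd.DataFrame) -> dict:
    """Precision/recall of a detection table against the ground truth."""
    idx = match_detections(detected, truth)
    matched = idx >= 0
    n_det = len(detected)
    precision = float(matched.sum() / n_det) if n_det else 0.0
    recall = float(len(np.unique(idx[matched])) / len(truth)) if len(truth) \
        else 0.0
    return {"precision": precision, "recall": recall,
            "n_detected": int(n_det), "n_truth": int(len(truth)),
            "n_matched": int(matched.sum())}


# ---------------------------------------------------------------------------
# full pipeline


def analyze_recording(recording: AudioRecording, config: RunConfig
                      ) -> pd.DataFrame:
    """Detect calls and compute validated features for one recording."""
    segments = extract_calls(recording, config.detection)
    calls = features_table(segments, recording.sample_rate_hz,
                           config.features, valid_only=False)
    return calls


def run_pipeline(config: RunConfig | None = None) -> PipelineResult:
    """Execute the full analysis and return the result bundle.

    With the default config a synthetic session is generated from
    ``config.session``; alternatively ``input_wav`` (+ optional
    ``truth_csv``) analyzes an existing recording.  Stage failures
    propagate with a stage-tagged message.
    """
    if config is None:
        config = RunConfig()
    try:
        if config.input_wav is not None:
            recording = read_wav(config.input_wav)
            truth = (pd.read_csv(config.truth_csv)
                     if config.truth_csv else None)
        else:
            recording, truth = generate_session(config.session)
    except Exception as exc:
        raise RuntimeError(f"[synth] session generation failed: {exc}") from exc

    try:
        calls = analyze_recording(recording, config)
    except Exception as exc:
        raise RuntimeError(f"[detect/features] call analysis failed: "
                           f"{exc}") from exc

    detection_metrics = None
    if truth is not None and len(calls):
        valid = calls[calls["is_valid"]].reset_index(drop=True)
        detection_metrics = detection_precision_recall(valid, truth)
        # label conditions and contexts from the matched ground truth
        idx = match_detections(valid, truth)
        keep = idx >= 0
        valid = valid[keep].reset_index(drop=True)
        valid["condition"] = truth["condition"].to_numpy()[idx[keep]]
        valid["context_label"] = truth["context_label"].to_numpy()[idx[keep]]
        valid["true_centroid_khz"] = \
            truth["true_centroid_khz"].to_numpy()[idx[keep]]
        calls = valid
    elif len(calls):
        calls = calls[calls["is_valid"]].reset_index(drop=True)
        calls["condition"] = "all"

    try:
        bins = summarize(calls, config.binning,
                         feature_columns=FEATURE_COLUMNS,
                         group_keys=["condition"])
    except Exception as exc:
        raise RuntimeError(f"[binning] summarization failed: {exc}") from exc

    conditions = [c for c in ("baseline", "post")
                  if c in set(bins.get("condition", []))]
    alpha_corr = bonferroni_alpha(config.alpha, config.n_parameters)
    centroid_test = None
    shift_rows = []
    if len(conditions) == 2:
        base = bins[bins["condition"] == "baseline"]
        post = bins[bins["condition"] == "post"]
        try:
            centroid_test = ar1_ztest(base["centroid_hz"], post["centroid_hz"])
            for feat in FEATURE_COLUMNS:
                r = ar1_ztest(base[feat], post[feat])
                shift_rows.append({
                    "parameter": feat, "shift": r.mean_diff,
                    "corrected_se": r.corrected_se, "r1": r.r1,
                    "z": r.z, "p": r.p,
                    "significant": bool(r.p < alpha_corr)})
        except Exception as exc:
            raise RuntimeError(f"[stats] inference failed: {exc}") from exc
    shift_table = pd.DataFrame(shift_rows)

    trajectory = pd.DataFrame()
    if len(calls) >= 10:
        from .binning import fraction_window
        win, hop = fraction_window(len(calls))
        trajectory = sliding_mean(calls, win, hop,
                                  feature_columns=["centroid_hz"])

    clf_result = None
    if config.run_classifier and len(conditions) == 2:
        counts = bins["condition"].value_counts()
        if counts.min() >= config.classifier.cv_folds:
            try:
                clf_result = classify_bins(bins, "condition",
                                           config.classifier)
            except Exception as exc:
                raise RuntimeError(f"[classify] classifier failed: "
                                   f"{exc}") from exc

    result = PipelineResult(calls=calls, bins=bins,
                            centroid_test=centroid_test,
                            shift_table=shift_table, trajectory=trajectory,
                            classifier=clf_result,
                            detection_metrics=detection_metrics,
                            alpha_corrected=alpha_corr, config=config)
    if config.outdir:
        write_outputs(result, config.outdir, recording=None)
    return result


def write_outputs(result: PipelineResult, outdir,
                  recording: AudioRecording | None = None) -> None:
    """Write bins CSV, results JSON, shift table and trajectory CSVs."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    result.bins.to_csv(out / "bins.csv", index=False)
    result.shift_table.to_csv(out / "shift_table.csv", index=False)
    result.trajectory.to_csv(out / "trajectory.csv", index=False)
    if recording is not None:
        write_wav(out / "session.wav", recording)
    payload = {
        "alpha_corrected": result.alpha_corrected,
        "seed": result.config.seed,
        "session_seed": result.config.session.seed,
        "detection_metrics": result.detection_metrics,
        "n_valid_calls": int(len(result.calls)),
        "n_bins": int(len(result.bins)),
    }
    if result.centroid_test is not None:
        payload["centroid_test"] = asdict(result.centroid_test)
    if result.classifier is not None:
        payload["classifier_per_class_accuracy"] = \
            result.classifier.per_class_accuracy
    with open(out / "results.json", "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)


# ---------------------------------------------------------------------------
# context stratification


def stratify_by_context(calls: pd.DataFrame, bin_size: int = 35,
                        value: str = "centroid_hz",
                        sma_iterations: int = 20000, seed: int = 0,
                        min_bins_for_ztest: int = 30) -> pd.DataFrame:
    """Per-context condition comparison on 35-call bins.

    For every context label with both conditions present and at least
    ``2 * bin_size`` calls per condition, the calls are summarized into
    bins and the conditions compared: with fewer than
    ``min_bins_for_ztest`` bins on either side the Simulation Modelling
    Analysis is used, otherwise the AR(1) z-test.  Sparse or one-sided
    contexts are skipped with a notice.  Returns one row per analyzed
    context with the estimate, test used and p-value.
    """
    rows = []
    params = BinningParams(bin_size=bin_size)
    for context, block in calls.groupby("context_label"):
        conds = sorted(pd.unique(block["condition"]))
        if len(conds) < 2:
            logger.info("context %r present in one condition only: skipped",
                        context)
            continue
        per_cond = {}
        too_sparse = False
        for c in conds[:2]:
            sub = block[block["condition"] == c]
            if len(sub) < 2 * bin_size:
                too_sparse = True
                break
            per_cond[c] = summarize(sub, params,
                                    feature_columns=[value])[value].to_numpy()
        if too_sparse:
            logger.info("context %r too sparse: skipped", context)
            continue
        a, b = per_cond[conds[0]], per_cond[conds[1]]
        use_sma = min(len(a), len(b)) < min_bins_for_ztest
        if use_sma:
            res: SMAResult = sma_test(a, b, iterations=sma_iterations,
                                      seed=seed)
            rows.append({"context_label": context, "test": "sma",
                         "mean_diff": res.mean_diff, "p": res.p_empirical,
                         "r1": res.r1, "R": res.R,
                         "n_bins_a": len(a), "n_bins_b": len(b)})
        else:
            res: AR1TestResult = ar1_ztest(a, b)
            rows.append({"context_label": context, "test": "ar1_ztest",
                         "mean_diff": res.mean_diff, "p": res.p,
                         "r1": res.r1, "R": np.nan,
                         "n_bins_a": len(a), "n_bins_b": len(b)})
    return pd.DataFrame(rows)
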