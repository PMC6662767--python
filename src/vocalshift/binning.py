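"""Observation bins, baseline normalization and sliding-window trajectories.

Per-call features are averaged in consecutive, non-overlapping blocks of
a fixed number of calls (70 in the main analysis; 50 for half data sets;
35 for context-stratified sets); an incomplete trailing block is
dropped, so n calls yield floor(n / bin_size) bins.  Binning never
crosses a condition boundary.  Bin means are the unit of all downstream
inference; the Lilliefors test is available to check their approximate
normality (raw per-call values are typically non-Gaussian, bin means
much closer, by the central limit theorem).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.diagnostic import lilliefors as _lilliefors

logger = logging.getLogger(__name__)


@dataclass
class BinningParams:
    bin_size: int = 70
    drop_incomplete_tail: bool = True

    def __post_init__(self) -> None:
        if self.bin_size < 1:
            raise ValueError("bin_size must be >= 1")


def bin_count(n_calls: int, bin_size: int) -> int:
    """Number of complete observation bins from n calls."""
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    return n_calls // bin_size


def summarize(calls: pd.DataFrame, params: BinningParams | None = None,
              feature_columns: list[str] | None = None,
              group_keys: list[str] | None = None) -> pd.DataFrame:
    """Average every ``bin_size`` consecutive calls into observation bins.

    ``calls`` must be time-ordered.  When ``group_keys`` (e.g.
    ``["group", "condition"]``) are given, binning restarts at each key
    combination so bins are condition-pure.  Returns one row per bin
    with ``bin_index``, ``n_calls`` and the per-feature means; fewer
    calls than one bin yields an empty frame (with a log notice).
    """
    if params is None:
        params = BinningParams()
    if feature_columns is None:
        feature_columns = [c for c in calls.columns
                           if np.issubdtype(calls[c].dtype, np.number)]
    group_keys = group_keys or []

    def _one(block: pd.DataFrame) -> pd.DataFrame:
        n = len(block)
        k = bin_count(n, params.bin_size)
        if k == 0:
            logger.info("only %d calls (< bin_size %d): no bins",
                        n, params.bin_size)
            return pd.DataFrame(columns=["bin_index", "n_calls",
                                         *feature_columns])
        used = block.iloc[: k * params.bin_size]
        idx = np.repeat(np.arange(k), params.bin_size)
        means = used[feature_columns].groupby(idx).mean()
        out = means.reset_index(drop=True)
        out.insert(0, "bin_index", np.arange(k))
        out.insert(1, "n_calls", params.bin_size)
        return out

    if not group_keys:
        return _one(calls)
    pieces = []
    for keys, block in calls.groupby(group_keys, sort=False):
        binned = _one(block)
        if not isinstance(keys, tuple):
            keys = (keys,)
        for name, val in zip(group_keys, keys):
            binned[name] = val
        pieces.append(binned)
    if not pieces:
        return pd.DataFrame(columns=["bin_index", "n_calls", *feature_columns])
    return pd.concat(pieces, ignore_index=True)


def normalize_to_baseline(values: np.ndarray,
                          baseline_bins: np.ndarray) -> np.ndarray:
    """Center by the baseline-bin mean, scale by max |centered baseline|.

    out = (x - mean(b)) / max|b - mean(b)|, so the baseline maps to mean
    zero with maximum absolute value one.  A constant baseline has no
    scale and raises.
    """
    b = np.asarray(baseline_bins, dtype=np.float64)
    if len(b) == 0:
        raise ValueError("baseline_bins must be non-empty")
    center = b.mean()
    scale = np.max(np.abs(b - center))
    if scale == 0:
        raise ZeroDivisionError("constant baseline: normalization undefined")
    return (np.asarray(values, dtype=np.float64) - center) / scale


def sliding_mean(calls: pd.DataFrame, window_calls: int, hop_calls: int,
                 feature_columns: list[str] | None = None) -> pd.DataFrame:
    """Trajectory of feature means over a sliding call window.

    Windows start at call 0, hop, 2*hop, ...; the last *full* window is
    included, giving floor((n - window) / hop) + 1 points.  Fewer calls
    than one window yields an empty trajectory.
    """
    if window_calls < 1 or hop_calls < 1:
        raise ValueError("window_calls and hop_calls must be >= 1")
    if feature_columns is None:
        feature_columns = [c for c in calls.columns
                           if np.issubdtype(calls[c].dtype, np.number)]
    n = len(calls)
    if n < window_calls:
        return pd.DataFrame(columns=["bin_number", *feature_columns])
    starts = np.arange(0, n - window_calls + 1, hop_calls)
    rows = []
    for j, s in enumerate(starts):
        w = calls.iloc[s:s + window_calls]
        rows.append({"bin_number": j,
                     **{c: w[c].mean() for c in feature_columns}})
    return pd.DataFrame(rows)


def fraction_window(n_calls: int, window_frac: float = 0.25,
                    hop_frac: float = 0.10) -> tuple[int, int]:
    """Window/hop sizes expressed as fractions of the call count.

    The per-parameter trajectory view uses windows of 25% of all calls
    advanced by 10% of all calls.
    """
    return (max(1, int(round(window_frac * n_calls))),
            max(1, int(round(hop_frac * n_calls))))


def lilliefors_check(values: np.ndarray) -> tuple[float, float]:
    """Lilliefors normality test (statistic, p) for binned feature values."""
    v = np.asarray(values, dtype=np.float64)
    if len(v) < 5:
        raise ValueError("need at least 5 bins for the Lilliefors test")
    if np.ptp(v) == 0:
        raise ValueError("degenerate (constant) bin values")
    stat, p = _lilliefors(v, dist="norm")
    return float(stat), float(p)
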