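"""Shuffle-null statistics for event-aligned signals.

Two statistics quantify event-locked structure:

* ``maxmin_slope`` — the slope of the line connecting the maximum and the
  minimum of the signal in the 0.5 s window ending at approach completion
  (positive when the maximum follows the minimum);
* ``peak`` — the maximum of the signal within 1 s after the event.

Significance is assessed against a null built by recomputing the same
session-mean statistic at pseudo-event times drawn uniformly from the valid
session range (1000 shuffles); the observed value is called significant when
it falls outside the null's 2.5th-97.5th percentile interval.  Both
statistics are unit-agnostic, so the identical machinery serves dF/F traces
and smoothed firing rates.
"""

from __future__ import annotations

import warnings
from typing import Mapping

import numpy as np

from .containers import (
    ConfigError,
    CorrectedTrace,
    DataIntegrityError,
    ShuffleTestResult,
)

__all__ = [
    "maxmin_slope",
    "peak_statistic",
    "shuffle_test",
    "count_significant",
    "SignificanceTally",
]

#: window placement relative to the event for each statistic
_STAT_SIDE = {"maxmin_slope": "pre", "peak": "post"}


def maxmin_slope(values: np.ndarray, times: np.ndarray) -> float:
    """Slope of the line connecting the segment's maximum and minimum.

    First occurrences break ties; a constant segment has slope 0 by
    definition.  The sign is positive when the maximum occurs after the
    minimum.
    """
    values = np.asarray(values, dtype=float)
    times = np.asarray(times, dtype=float)
    if values.size < 2:
        raise DataIntegrityError("maxmin_slope needs at least 2 samples")
    i_max = int(np.argmax(values))
    i_min = int(np.argmin(values))
    if i_max == i_min:
        return 0.0
    return float((values[i_max] - values[i_min]) / (times[i_max] - times[i_min]))


def peak_statistic(values: np.ndarray) -> float:
    """Maximum of the segment (no rectification: an all-negative segment
    returns its own, negative, maximum)."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise DataIntegrityError("empty segment has no peak")
    return float(values.max())


def _maxmin_slope_rows(M: np.ndarray, dt: float) -> np.ndarray:
    """Vectorized maxmin_slope over the rows of a windows x samples matrix."""
    i_max = np.argmax(M, axis=1)
    i_min = np.argmin(M, axis=1)
    num = M[np.arange(M.shape[0]), i_max] - M[np.arange(M.shape[0]), i_min]
    den = (i_max - i_min) * dt
    out = np.zeros(M.shape[0])
    nz = den != 0
    out[nz] = num[nz] / den[nz]
    return out


def _window_rows(trace: CorrectedTrace, idx: np.ndarray, n_w: int, side: str) -> np.ndarray:
    """Extract fixed-length windows before ('pre') or after ('post') indices."""
    if side == "pre":
        start = idx - n_w
    else:
        start = idx
    return trace.dff[start[:, None] + np.arange(n_w)[None, :]]


def shuffle_test(
    trace: CorrectedTrace,
    event_times: np.ndarray,
    statistic: str = "maxmin_slope",
    window: float = 0.5,
    n_shuffles: int = 1000,
    seed: int = 0,
    per_event_null: bool = False,
) -> ShuffleTestResult:
    """Compare a session-mean event-aligned statistic with a random-time null.

    observed = mean of the statistic over the real events; each of the
    ``n_shuffles`` shuffles draws the same number of pseudo-event times
    uniformly from the session (margins of one window at both ends) and
    recomputes the mean.  ``ci`` is the (2.5th, 97.5th) percentile of the
    null and the call is two-sided: significant iff observed falls outside.

    With ``per_event_null`` each shuffle contributes its individual
    pseudo-event statistics to the null instead of their mean.
    """
    if statistic not in _STAT_SIDE:
        raise ConfigError(f"unknown statistic {statistic!r}")
    if n_shuffles < 100:
        warnings.warn(f"n_shuffles={n_shuffles} gives a coarse 95% interval")
    event_times = np.asarray(event_times, dtype=float)
    if event_times.size == 0:
        raise DataIntegrityError("no events supplied")
    side = _STAT_SIDE[statistic]
    n_w = int(round(window * trace.rate))
    if n_w < 2:
        raise ConfigError("window too short for this trace rate")
    n = trace.dff.size
    if n < 10 * n_w:
        raise DataIntegrityError("session shorter than 10 analysis windows")
    dt = 1.0 / trace.rate
    t0 = trace.times[0]

    idx = np.round((event_times - t0) * trace.rate).astype(int)
    ok = (idx - (n_w if side == "pre" else 0) >= 0) & \
         (idx + (n_w if side == "post" else 0) <= n)
    idx = idx[ok]
    if idx.size == 0:
        raise DataIntegrityError("no event window fits inside the session")
    n_ev = idx.size

    def stat_rows(M: np.ndarray) -> np.ndarray:
        if statistic == "maxmin_slope":
            return _maxmin_slope_rows(M, dt)
        return M.max(axis=1)

    observed = float(stat_rows(_window_rows(trace, idx, n_w, side)).mean())

    rng = np.random.default_rng(seed)
    # pseudo-events anywhere a full window fits, regardless of side
    lo_i, hi_i = n_w, n - n_w
    sh_idx = rng.integers(lo_i, hi_i, size=(n_shuffles, n_ev))
    sh_stats = stat_rows(
        _window_rows(trace, sh_idx.ravel(), n_w, side)
    ).reshape(n_shuffles, n_ev)
    null = sh_stats.ravel() if per_event_null else sh_stats.mean(axis=1)
    ci = (float(np.percentile(null, 2.5)), float(np.percentile(null, 97.5)))
    return ShuffleTestResult(
        statistic_name=statistic,
        observed=observed,
        null_values=null,
        ci=ci,
        significant=bool(observed < ci[0] or observed > ci[1]),
        n_shuffles=int(null.size),
        seed=seed,
        n_events=int(n_ev),
    )


class SignificanceTally:
    """Per-recording significance bookkeeping: k significant of n, with signs."""

    def __init__(self, results: Mapping[str, ShuffleTestResult]):
        if not results:
            raise DataIntegrityError("empty results map")
        self.results = dict(results)
        self.k = sum(1 for r in results.values() if r.significant)
        self.n = len(results)
        self.directions = {rid: r.direction for rid, r in results.items()}

    @property
    def k_up(self) -> int:
        return sum(
            1 for r in self.results.values() if r.significant and r.direction > 0
        )

    @property
    def k_down(self) -> int:
        return sum(
            1 for r in self.results.values() if r.significant and r.direction < 0
        )

    def __iter__(self):
        return iter((self.k, self.n))

    def __repr__(self) -> str:
        return f"SignificanceTally({self.k}/{self.n} significant, {self.k_down} down)"


def count_significant(results: Mapping[str, ShuffleTestResult]) -> SignificanceTally:
    """Tally significant recordings, preserving identity and direction."""
    return SignificanceTally(results)
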