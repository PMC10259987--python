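"""Trial-structured, event-aligned views of traces and spike trains.

Alignment snaps each event to the nearest frame of the trace's own sampling
grid — no resampling — because the frame rate (~33-50 Hz) is coarse relative
to the analysis windows and interpolation would manufacture smoothness that
the downstream shuffle statistics could exploit.  Windows are half-open
``[-pre, +post)``: the event sample is the first post-event sample.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import ndimage as _ndi

from .containers import (
    ConfigError,
    CorrectedTrace,
    DataIntegrityError,
    EventLog,
    LATENCY_COLUMNS,
    PeriEventMatrix,
    SpikeTrain,
)

__all__ = [
    "align_trace",
    "sort_by_latency",
    "smooth_spikes",
    "extract_latencies",
]

#: which later event defines the behavioral latency for each aligning event
LATENCY_PARTNER = {"click": "food_port_in", "light_on": "center_in"}


def _nearest_index(trace_times: np.ndarray, rate: float, t: float) -> int:
    return int(round((t - trace_times[0]) * rate))


def align_trace(
    trace: CorrectedTrace,
    events: EventLog,
    event_type: str,
    window: tuple[float, float],
    latency_to: str | None = None,
) -> PeriEventMatrix:
    """Build a trials x samples matrix of the trace around each event.

    ``window = (pre, post)`` seconds; each row spans ``[t - pre, t + post)``
    on the trace grid.  Events whose window falls outside the session are
    excluded and reported in ``excluded``.  ``trial_meta.latency`` holds the
    time from the aligning event to its partner event within the same trial
    (food-port entry for clicks, center entry for light-on), when present.
    """
    ev = events.of_type(event_type)
    if len(ev) == 0:
        raise DataIntegrityError(f"no events of type {event_type!r} in the log")
    pre, post = window
    n_pre = int(round(pre * trace.rate))
    n_post = int(round(post * trace.rate))
    if n_pre + n_post < 1:
        raise ConfigError("window contains no samples at this trace rate")
    partner = latency_to if latency_to is not None else LATENCY_PARTNER.get(event_type)
    partner_times: dict = {}
    if partner is not None:
        ptab = events.of_type(partner)
        partner_times = dict(zip(ptab["trial_id"], ptab["time_s"]))
    rows, meta, kept_times, excluded = [], [], [], []
    n = trace.dff.size
    for rec in ev.itertuples():
        i = _nearest_index(trace.times, trace.rate, rec.time_s)
        lo, hi = i - n_pre, i + n_post
        if lo < 0 or hi > n:
            excluded.append(float(rec.time_s))
            continue
        rows.append(trace.dff[lo:hi])
        kept_times.append(float(rec.time_s))
        lat = partner_times.get(rec.trial_id, np.nan)
        meta.append(
            {
                "trial_id": rec.trial_id,
                "event_time": float(rec.time_s),
                "latency": float(lat) - float(rec.time_s) if np.isfinite(lat) else np.nan,
                "condition": rec.condition,
            }
        )
    if not rows:
        raise DataIntegrityError(
            f"every {event_type!r} event window falls outside the session"
        )
    return PeriEventMatrix(
        alignment_event=event_type,
        window=(pre, post),
        trial_times=np.asarray(kept_times),
        data=np.vstack(rows),
        sample_rate=trace.rate,
        trial_meta=pd.DataFrame(meta),
        excluded=excluded,
    )


def sort_by_latency(m: PeriEventMatrix) -> PeriEventMatrix:
    """Reorder trials by ascending behavioral latency (stable sort)."""
    lat = m.trial_meta["latency"].to_numpy(dtype=float)
    if np.any(~np.isfinite(lat)):
        bad = m.trial_meta.loc[~np.isfinite(lat), "trial_id"].tolist()
        raise DataIntegrityError(f"trials missing latency: {bad}")
    order = np.argsort(lat, kind="stable")
    return PeriEventMatrix(
        alignment_event=m.alignment_event,
        window=m.window,
        trial_times=m.trial_times[order],
        data=m.data[order],
        sample_rate=m.sample_rate,
        trial_meta=m.trial_meta.iloc[order].reset_index(drop=True),
        excluded=list(m.excluded),
    )


def smooth_spikes(
    spikes: SpikeTrain,
    kernel_sd: float = 0.100,
    rate_grid: float = 100.0,
    t_start: float = 0.0,
    t_end: float | None = None,
) -> CorrectedTrace:
    """Gaussian-kernel firing-rate estimate on a uniform grid.

    The rate integrates to the spike count (reflected boundaries conserve
    mass).  Returns a CorrectedTrace whose ``dff`` field holds rate in Hz so
    the ramp statistics apply unchanged.
    """
    if kernel_sd <= 0:
        raise ConfigError("kernel_sd must be positive")
    if t_end is None:
        t_end = float(spikes.spike_times[-1]) + 4 * kernel_sd if len(spikes) else t_start + 1.0
    dt = 1.0 / rate_grid
    edges = np.arange(t_start, t_end + dt, dt)
    centers = edges[:-1] + dt / 2.0
    if len(spikes) == 0:
        warnings.warn(f"unit {spikes.unit_id}: empty spike train, returning zero rate")
        return CorrectedTrace(times=centers, dff=np.zeros(centers.size),
                              rate=rate_grid, label=spikes.unit_id)
    counts, _ = np.histogram(spikes.spike_times, bins=edges)
    rate = _ndi.gaussian_filter1d(counts.astype(float), sigma=kernel_sd / dt,
                                  mode="reflect") / dt
    return CorrectedTrace(times=centers, dff=rate, rate=rate_grid, label=spikes.unit_id)


def extract_latencies(
    events: EventLog,
    from_type: str = "light_on",
    to_type: str = "center_in",
    min_latency: float | None = 1.0,
    session_id: str = "",
) -> pd.DataFrame:
    """Per-trial latency between two event types, with a long-latency filter.

    Latency = t(to) - t(from) within each trial.  Rows with latency <=
    ``min_latency`` are excluded when the filter is set (default 1 s, the
    long-latency criterion used to dissociate cue-onset responses from
    approach).  Trials with a from-event but no to-event are kept as
    censored rows.
    """
    f = events.of_type(from_type)
    if len(f) == 0:
        raise DataIntegrityError(f"no {from_type!r} events")
    t_to = dict(zip(events.of_type(to_type)["trial_id"], events.of_type(to_type)["time_s"]))
    rows = []
    for rec in f.itertuples():
        to_time = t_to.get(rec.trial_id)
        if to_time is None:
            rows.append((session_id, "", rec.condition, rec.trial_id, np.nan, True))
            continue
        lat = float(to_time) - float(rec.time_s)
        if lat < 0:
            raise DataIntegrityError(
                f"trial {rec.trial_id}: {to_type} precedes {from_type} by {-lat:.3f} s"
            )
        if min_latency is not None and lat <= min_latency:
            continue
        rows.append((session_id, "", rec.condition, rec.trial_id, lat, False))
    return pd.DataFrame(rows, columns=LATENCY_COLUMNS)
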