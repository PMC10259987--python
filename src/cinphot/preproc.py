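"""Raw multiplexed stream -> per-channel, isosbestic-corrected dF/F.

The rig alternates excitation LEDs in 10 ms frames (4 ms on, 6 ms off) on a
single detector sampled at 10 kHz.  Demultiplexing averages the detector
samples within each frame's on-window (after a short settling discard) to one
value per frame; the isosbestic (405 nm) channel is then least-squares
rescaled onto each signal channel over the whole session, and
dF/F = (signal - fitted) / fitted.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as _stats

from .containers import (
    ChannelTrace,
    ConfigError,
    CorrectedTrace,
    DataIntegrityError,
    LedSchedule,
    RawPhotometry,
)

__all__ = [
    "demultiplex",
    "isosbestic_correct",
    "zscore_trace",
    "normalize_to_reference",
]

#: samples discarded at the start of each on-window (LED/detector settling)
DEFAULT_SETTLE_MS = 1.0


def demultiplex(
    raw: RawPhotometry,
    schedule: LedSchedule,
    settle_ms: float = DEFAULT_SETTLE_MS,
) -> list[ChannelTrace]:
    """Split a TDM detector stream into one frame-rate trace per channel.

    Each frame value is the mean of the detector samples within that frame's
    on-window ``[start, start + on_len)`` after discarding the first
    ``settle_ms``; frames are timestamped at the on-window center.  A
    trailing partial cycle is dropped.
    """
    if raw.samples.size == 0:
        raise DataIntegrityError("empty detector stream")
    fs = raw.sample_rate
    spf_f = fs * schedule.frame_len
    spf = int(round(spf_f))
    if abs(spf_f - spf) > 1e-6 or spf < 1:
        raise ConfigError(
            f"sample_rate {fs} Hz is not commensurate with frame_len "
            f"{schedule.frame_len} s"
        )
    on_n = int(round(fs * schedule.on_len))
    settle_n = int(round(fs * settle_ms / 1000.0))
    if settle_n >= on_n:
        raise ConfigError("settle_ms leaves no samples in the on-window")
    n_ch = schedule.n_channels
    cycle = spf * n_ch
    n_cycles = raw.samples.size // cycle
    if n_cycles < 1:
        raise DataIntegrityError("stream shorter than one full channel cycle")
    frames = raw.samples[: n_cycles * cycle].reshape(n_cycles, n_ch, spf)
    vals = frames[:, :, settle_n:on_n].mean(axis=2)
    rate = 1.0 / (schedule.frame_len * n_ch)
    traces = []
    for k, (label, _nm) in enumerate(schedule.channels):
        times = raw.t0 + (np.arange(n_cycles) * n_ch + k) * schedule.frame_len \
            + schedule.on_len / 2.0
        traces.append(ChannelTrace(label=label, times=times, values=vals[:, k], rate=rate))
    return traces


def isosbestic_correct(signal: ChannelTrace, control: ChannelTrace) -> CorrectedTrace:
    """Motion-correct a signal channel against the isosbestic control.

    The control is rescaled onto the signal by ordinary least squares over
    the whole session (``fitted = a * control + b``) and
    ``dff = (signal - fitted) / fitted``.  Because the fit absorbs any affine
    transform of the control, the result is invariant to control rescaling.

    TDM channels are never sampled simultaneously (the control frame sits a
    fixed fraction of a cycle away from the signal frame), so the control is
    linearly interpolated onto the signal's frame times before fitting;
    otherwise a shared artifact leaves a residual proportional to its time
    derivative times the inter-channel skew.
    """
    if signal.values.size != control.values.size:
        raise DataIntegrityError("signal and control traces differ in length")
    if not np.allclose(signal.times, control.times, atol=1.0 / signal.rate):
        raise DataIntegrityError("signal and control are on different time grids")
    if np.array_equal(signal.times, control.times):
        c = control.values
    else:
        c = np.interp(signal.times, control.times, control.values)
    if np.ptp(c) == 0 or np.var(c) == 0:
        raise DataIntegrityError(
            f"degenerate regressor: control channel {control.label!r} is constant"
        )
    fit = _stats.linregress(c, signal.values)
    fitted = fit.slope * c + fit.intercept
    dff = (signal.values - fitted) / fitted
    return CorrectedTrace(
        times=signal.times.copy(),
        dff=dff,
        rate=signal.rate,
        fit_coeffs=(float(fit.slope), float(fit.intercept)),
        label=signal.label,
    )


def zscore_trace(
    trace: CorrectedTrace, baseline_window: tuple[float, float] | None = None
) -> CorrectedTrace:
    """Z-score a trace using the whole session or a baseline window."""
    if baseline_window is None:
        ref = trace.dff
    else:
        lo, hi = baseline_window
        if lo >= hi or lo < trace.times[0] or hi > trace.times[-1] + 1.0 / trace.rate:
            raise ConfigError(f"baseline window {baseline_window} outside the session")
        mask = (trace.times >= lo) & (trace.times < hi)
        ref = trace.dff[mask]
        if ref.size == 0:
            raise ConfigError(f"baseline window {baseline_window} contains no samples")
    sd = ref.std()
    if sd == 0:
        raise DataIntegrityError("zero-variance trace cannot be z-scored")
    return CorrectedTrace(
        times=trace.times.copy(),
        dff=(trace.dff - ref.mean()) / sd,
        rate=trace.rate,
        fit_coeffs=trace.fit_coeffs,
        zscored=True,
        label=trace.label,
    )


def normalize_to_reference(
    responses: dict[str, dict[str, float]], reference: str
) -> dict[str, dict[str, float]]:
    """Within-subject normalization of evoked amplitudes to a reference condition.

    ``responses`` maps condition -> {subject: amplitude}.  Each subject's
    amplitudes are divided by that subject's amplitude at the ``reference``
    condition before any cross-subject averaging.
    """
    if reference not in responses:
        raise ConfigError(f"reference condition {reference!r} missing")
    ref = responses[reference]
    subjects = set().union(*(v.keys() for v in responses.values()))
    for s in subjects:
        if s not in ref:
            raise ConfigError(f"subject {s!r} has no reference amplitude")
        if ref[s] <= 0:
            raise DataIntegrityError(
                f"subject {s!r} has non-positive reference amplitude {ref[s]}"
            )
    return {
        cond: {s: amp / ref[s] for s, amp in per_subj.items()}
        for cond, per_subj in responses.items()
    }
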