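"""Synthetic photometry, spiking, stimulation, and behavior generators.

Every generator is deterministic in ``config.seed`` and returns its latent
ground truth (true dF/F, rate function, hazard) alongside the observable so
recovery tests never have to re-derive truth from noisy output.  A single
master seed is split into named substreams (events, motion, noise, spikes,
latency), so adding one noise component never perturbs the others.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import signal as _sig

from .config import SynthConfig
from .containers import (
    LATENCY_COLUMNS,
    ConfigError,
    CorrectedTrace,
    EventLog,
    LedSchedule,
    RawPhotometry,
    SpikeTrain,
    StimTrain,
)

import pandas as pd

__all__ = [
    "SessionTruth",
    "PavlovianSession",
    "StimSession",
    "SpikeTrainResult",
    "transient_kernel",
    "generate_pavlovian_session",
    "generate_stim_session",
    "generate_spike_train",
    "generate_pharm_latencies",
    "generate_bandit_session",
    "PAVLOVIAN_SCHEDULE",
    "OPTO_SCHEDULE",
]

#: triple-color schedule used for dual-sensor recordings (DA + CIN + isosbestic)
PAVLOVIAN_SCHEDULE = LedSchedule(
    channels=(("rdlight", 565), ("gcamp", 470), ("iso", 405))
)
#: two-color schedule used when the blue line drives the opsin instead
OPTO_SCHEDULE = LedSchedule(channels=(("rdlight", 565), ("iso", 405)))

#: relative brightness of the isosbestic channel (405 nm excitation is dimmer)
ISO_BASELINE_FRAC = 0.7

#: collection latencies are clipped into this range (s); the lognormal tail
#: would otherwise occasionally outlast the inter-click gap
LATENCY_CLIP = (0.1, 8.0)

HAZARD_BIN = 0.250


def _rng(seed: int, name: str) -> np.random.Generator:
    """Named substream of the master seed."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(name.encode())])
    )


def transient_kernel(t: np.ndarray, rise: float, decay: float) -> np.ndarray:
    """Difference-of-exponentials kernel normalized to unit peak; 0 for t<0."""
    t = np.asarray(t, dtype=float)
    k = np.where(t >= 0, np.exp(-np.maximum(t, 0) / decay) - np.exp(-np.maximum(t, 0) / rise), 0.0)
    t_peak = rise * decay / (decay - rise) * np.log(decay / rise)
    peak = np.exp(-t_peak / decay) - np.exp(-t_peak / rise)
    return k / peak


@dataclass
class SessionTruth:
    """Latent components of a synthetic session on the detector sample grid."""

    times: np.ndarray
    dff_true: np.ndarray
    motion: np.ndarray

    def dff_at(self, t: np.ndarray) -> np.ndarray:
        return np.interp(t, self.times, self.dff_true)

    def motion_at(self, t: np.ndarray) -> np.ndarray:
        return np.interp(t, self.times, self.motion)


@dataclass
class PavlovianSession:
    raw: RawPhotometry
    schedule: LedSchedule
    events: EventLog
    truth: SessionTruth


@dataclass
class StimSession:
    raw: RawPhotometry
    schedule: LedSchedule
    events: EventLog
    truth: SessionTruth
    protocol: list[StimTrain]

    def evoked_trace(self) -> CorrectedTrace:
        """Noise-free evoked dF/F on the detector grid (analysis ground truth)."""
        return CorrectedTrace(
            times=self.truth.times,
            dff=self.truth.dff_true,
            rate=1.0 / (self.truth.times[1] - self.truth.times[0]),
            label="evoked_true",
        )


@dataclass
class SpikeTrainResult:
    train: SpikeTrain
    rate_times: np.ndarray
    rate_hz: np.ndarray

    def rate_at(self, t: np.ndarray) -> np.ndarray:
        return np.interp(t, self.rate_times, self.rate_hz)


def _motion_process(rng: np.random.Generator, n: int, fs: float, sd: float) -> np.ndarray:
    """Shared multiplicative artifact: 2 Hz low-passed Gaussian process.

    The process is band-limited well below 100 Hz, so it is synthesized on a
    200 Hz grid and linearly interpolated onto the detector grid.
    """
    if sd == 0 or n == 0:
        return np.zeros(n)
    fs_m = 200.0
    n_m = int(np.ceil(n * fs_m / fs)) + 2
    white = rng.standard_normal(n_m)
    sos = _sig.butter(2, 2.0, btype="low", fs=fs_m, output="sos")
    coarse = _sig.sosfiltfilt(sos, white)
    m = np.interp(np.arange(n) / fs, np.arange(n_m) / fs_m, coarse)
    s = m.std()
    if s == 0:
        return np.zeros(n)
    return m * (sd / s)


def _collection_latency(rng: np.random.Generator, dist: tuple[str, Mapping[str, float]]) -> float:
    name, params = dist
    if name == "lognormal":
        lat = float(np.exp(rng.normal(params["mu"], params["sigma"])))
    elif name == "uniform":
        lat = float(rng.uniform(params["lo"], params["hi"]))
    elif name == "constant":
        lat = float(params["value"])
    else:
        raise ConfigError(f"unknown collection latency distribution {name!r}")
    return float(np.clip(lat, *LATENCY_CLIP))


def _multiplex(
    channel_fluor: Sequence[np.ndarray],
    schedule: LedSchedule,
    fs: float,
    noise: np.ndarray,
) -> np.ndarray:
    """Compose the single-detector TDM stream from per-channel fluorescence.

    During channel k's on-window the detector reads that channel's
    fluorescence; off-windows read dark (noise only).
    """
    spf = int(round(fs * schedule.frame_len))
    if abs(fs * schedule.frame_len - spf) > 1e-9:
        raise ConfigError("sample_rate is not commensurate with frame_len")
    on_n = int(round(fs * schedule.on_len))
    n_ch = schedule.n_channels
    cycle = spf * n_ch
    n_total = (len(noise) // cycle) * cycle
    det = noise[:n_total].copy()
    view = det.reshape(-1, n_ch, spf)
    for k, F in enumerate(channel_fluor):
        Fv = F[:n_total].reshape(-1, n_ch, spf)
        view[:, k, :on_n] += Fv[:, k, :on_n]
    return det


def _dff_events(
    config: SynthConfig,
    n: int,
    clicks: np.ndarray,
    port_ins: np.ndarray,
) -> np.ndarray:
    """True dF/F: a transient at each click plus a linear ramp into each port-in."""
    fs = config.sample_rate
    dff = np.zeros(n)
    if config.transient_amplitude != 0 and clicks.size:
        k_len = int(round((config.transient_rise + 8 * config.transient_decay) * fs))
        tt = np.arange(k_len) / fs
        kern = config.transient_amplitude * transient_kernel(
            tt, config.transient_rise, config.transient_decay
        )
        for tc in clicks:
            i0 = int(round(tc * fs))
            sl = slice(i0, min(i0 + k_len, n))
            dff[sl] += kern[: sl.stop - sl.start]
    if config.ramp_slope != 0 and config.ramp_duration > 0 and port_ins.size:
        d_len = int(round(config.ramp_duration * fs))
        peak = config.ramp_slope * config.ramp_duration
        # linear rise ending exactly at port-in, then relaxation back to
        # baseline with the transient decay constant
        decay_len = int(round(8 * config.transient_decay * fs))
        ramp = np.concatenate(
            [
                config.ramp_slope * (np.arange(d_len + 1) / fs),
                peak * np.exp(-np.arange(1, decay_len) / fs / config.transient_decay),
            ]
        )
        for tp in port_ins:
            i1 = int(round(tp * fs))
            i0 = i1 - d_len
            lo = max(i0, 0)
            hi = min(i0 + ramp.size, n)
            dff[lo:hi] += ramp[lo - i0 : hi - i0]
    return dff


def _compose_session(
    config: SynthConfig,
    schedule: LedSchedule,
    dff_by_label: Mapping[str, np.ndarray],
    n: int,
) -> tuple[RawPhotometry, SessionTruth, np.ndarray]:
    """Assemble the multiplexed detector stream from per-channel dF/F."""
    fs = config.sample_rate
    t = np.arange(n) / fs
    motion = _motion_process(_rng(config.seed, "motion"), n, fs, config.motion_sd)
    # bleaching is slow (tau >> frame); evaluate exp on a coarse grid
    t_c = np.linspace(0.0, t[-1] if n else 0.0, min(n, 100_000))
    bleach = np.interp(t, t_c, np.exp(-t_c / config.bleach_tau))
    noise = config.noise_sd * config.baseline_F * _rng(config.seed, "noise").standard_normal(n) \
        if config.noise_sd > 0 else np.zeros(n)
    fluor = []
    for lbl, _nm in schedule.channels:
        base = config.baseline_F * (ISO_BASELINE_FRAC if lbl == "iso" else 1.0)
        dff = dff_by_label.get(lbl, np.zeros(n) if lbl == "iso" else None)
        if dff is None:
            raise ConfigError(f"no dF/F provided for channel {lbl!r}")
        fluor.append(base * bleach * (1.0 + dff + motion))
    det = _multiplex(fluor, schedule, fs, noise)
    n_total = det.size
    truth = SessionTruth(
        times=t[:n_total],
        dff_true=next(iter(dff_by_label.values()))[:n_total],
        motion=motion[:n_total],
    )
    return RawPhotometry(samples=det, sample_rate=fs), truth, t


def generate_pavlovian_session(
    config: SynthConfig, schedule: LedSchedule = PAVLOVIAN_SCHEDULE
) -> PavlovianSession:
    """Unexpected-reward session: clicks at uniform(15-30) s gaps, each
    followed by a food-port entry at a sampled collection latency.

    The true dF/F (shared by both sensor channels) carries a transient at
    each click and a linear ramp of ``ramp_slope`` ending exactly at each
    food-port entry.  The raw stream is
    ``baseline * exp(-t/bleach_tau) * (1 + dff_true + motion) + noise`` with
    motion (but not dff_true) shared into the isosbestic channel.
    """
    config.validate()
    lo, hi = config.click_interval_range
    if config.session_duration <= hi:
        raise ConfigError("session_duration must exceed the maximum click interval")
    fs = config.sample_rate
    ev_rng = _rng(config.seed, "events")
    margin = LATENCY_CLIP[1] + config.ramp_duration  # room for the slowest collection
    clicks, port_ins, records = [], [], []
    t = float(ev_rng.uniform(lo, hi))
    trial = 0
    while t < config.session_duration - margin:
        lat = _collection_latency(ev_rng, config.collection_latency_dist)
        clicks.append(t)
        port_ins.append(t + lat)
        records.append((t, "click", trial, "", ""))
        records.append((t + lat, "food_port_in", trial, "", ""))
        trial += 1
        t += float(ev_rng.uniform(lo, hi))
    n = int(round(config.session_duration * fs))
    dff = _dff_events(config, n, np.asarray(clicks), np.asarray(port_ins))
    raw, truth, _ = _compose_session(
        config, schedule, {lbl: dff for lbl in schedule.labels if lbl != "iso"} | {"iso": np.zeros(n)}, n
    )
    return PavlovianSession(
        raw=raw, schedule=schedule, events=EventLog.from_records(records), truth=truth
    )


def _stim_dff(config: SynthConfig, protocol: Sequence[StimTrain], n: int) -> np.ndarray:
    """Evoked dF/F with phenomenological short-term depression.

    Each pulse adds the transient kernel scaled by pulse width (relative to a
    4 ms reference) and by a depression state ``s``: the pulse amplitude is
    ``A * s``, then ``s *= (1 - depression_factor)`` and relaxes toward 1
    with time constant ``depression_recovery_tau``.  With
    ``depression_factor == 0`` the response is an exact linear superposition
    of identical single-pulse kernels.
    """
    fs = config.sample_rate
    dff = np.zeros(n)
    k_len = int(round((config.transient_rise + 8 * config.transient_decay) * fs))
    tt = np.arange(k_len) / fs
    kern = transient_kernel(tt, config.transient_rise, config.transient_decay)
    d = config.depression_factor
    tau = config.depression_recovery_tau
    for train in protocol:
        amp0 = config.transient_amplitude * (train.pulse_width_ms / 4.0)
        s = 1.0
        t_prev = None
        for tp in train.pulse_times:
            if t_prev is not None:
                s = 1.0 - (1.0 - s) * np.exp(-(tp - t_prev) / tau)
            amp = amp0 * s
            s *= 1.0 - d
            t_prev = tp
            i0 = int(round(tp * fs))
            sl = slice(i0, min(i0 + k_len, n))
            if sl.start >= n:
                raise ConfigError(f"pulse at {tp} s falls outside the session")
            dff[sl] += amp * kern[: sl.stop - sl.start]
    return dff


def generate_stim_session(
    config: SynthConfig,
    protocol: Sequence[StimTrain],
    schedule: LedSchedule = OPTO_SCHEDULE,
) -> StimSession:
    """Optogenetic stimulation session on the two-color (565/405) schedule."""
    config.validate()
    protocol = sorted(protocol, key=lambda tr: tr.onset)
    for a, b in zip(protocol, protocol[1:]):
        if b.onset <= a.onset + a.duration:
            raise ConfigError(
                f"stim trains overlap: train at {a.onset} s (span {a.duration} s) "
                f"collides with train at {b.onset} s"
            )
    fs = config.sample_rate
    n = int(round(config.session_duration * fs))
    dff = _stim_dff(config, protocol, n)
    raw, truth, _ = _compose_session(
        config, schedule,
        {lbl: dff for lbl in schedule.labels if lbl != "iso"} | {"iso": np.zeros(n)}, n
    )
    records = [
        (tp, "laser_pulse", i, "", f"width_ms={tr.pulse_width_ms};power_mw={tr.power_mw}")
        for i, tr in enumerate(protocol)
        for tp in tr.pulse_times
    ]
    return StimSession(
        raw=raw,
        schedule=schedule,
        events=EventLog.from_records(records),
        truth=truth,
        protocol=list(protocol),
    )


def generate_spike_train(
    config: SynthConfig,
    events: EventLog,
    ramp: bool,
    event_type: str = "food_port_in",
    unit_id: str = "unit0",
) -> SpikeTrainResult:
    """Inhomogeneous-Poisson spike train by thinning.

    If ``ramp``, the rate rises linearly by ``spike_ramp_gain`` Hz/s over
    ``ramp_duration`` before each ``event_type`` event; otherwise the rate is
    homogeneous at ``spike_base_rate``.
    """
    config.validate()
    if config.spike_base_rate <= 0:
        raise ConfigError("spike_base_rate must be positive")
    T = config.session_duration
    base = config.spike_base_rate
    gain = config.spike_ramp_gain if ramp else 0.0
    dur = config.ramp_duration
    anchors = events.times_of(event_type) if ramp else np.array([])

    def rate_at(t: np.ndarray) -> np.ndarray:
        r = np.full(np.shape(t), base, dtype=float)
        for tp in anchors:
            in_ramp = (t >= tp - dur) & (t <= tp)
            r = np.where(in_ramp, base + gain * (t - (tp - dur)), r)
        return r

    r_max = base + gain * dur
    rng = _rng(config.seed, "spikes")
    n_cand = rng.poisson(r_max * T)
    cand = np.sort(rng.uniform(0.0, T, n_cand))
    keep = rng.uniform(0.0, r_max, n_cand) < rate_at(cand)
    spikes = np.unique(cand[keep])
    grid = np.arange(0.0, T, 0.01)
    return SpikeTrainResult(
        train=SpikeTrain(unit_id=unit_id, spike_times=spikes),
        rate_times=grid,
        rate_hz=rate_at(grid),
    )


def _condition_hazard(config: SynthConfig, condition: str, n_bins: int) -> np.ndarray:
    """Per-bin hazard for a condition: baseline x profile multiplier."""
    profile = config.hazard_profile.get(condition, {})
    h = np.full(n_bins, config.hazard_baseline, dtype=float)
    for b, mult in profile.items():
        if 0 <= int(b) < n_bins:
            h[int(b)] *= mult
    if np.any((h < 0) | (h > 1)):
        raise ConfigError(f"hazard for condition {condition!r} falls outside [0, 1]")
    return h


def generate_pharm_latencies(
    config: SynthConfig,
    conditions: Sequence[str],
    n_trials_per: int,
    n_subjects: int = 1,
) -> tuple[pd.DataFrame, dict[str, np.ndarray]]:
    """Trial-initiation latencies by discrete-time hazard sampling (250 ms bins).

    Returns the latency table (columns ``session_id, subject, condition,
    trial_id, latency_s, censored``) and the true per-bin hazard of each
    condition.  Observation is capped at ``latency_cap``; slower trials are
    censored at the cap.
    """
    config.validate()
    n_bins = int(round(config.latency_cap / HAZARD_BIN))
    rng = _rng(config.seed, "latency")
    rows = []
    truth: dict[str, np.ndarray] = {}
    for cond in conditions:
        h = _condition_hazard(config, cond, n_bins)
        truth[cond] = h
        u = rng.random((n_trials_per, n_bins))
        hit = u < h[None, :]
        initiated = hit.any(axis=1)
        first = np.argmax(hit, axis=1)
        jitter = rng.random(n_trials_per)
        lat = np.where(initiated, (first + jitter) * HAZARD_BIN, config.latency_cap)
        for i in range(n_trials_per):
            subj = f"s{i % n_subjects}"
            rows.append(
                {
                    "session_id": f"{cond}_{subj}",
                    "subject": subj,
                    "condition": cond,
                    "trial_id": i,
                    "latency_s": float(lat[i]),
                    "censored": not bool(initiated[i]),
                }
            )
    return pd.DataFrame(rows, columns=LATENCY_COLUMNS), truth


def generate_bandit_session(
    config: SynthConfig,
    n_trials: int = 100,
    timeout_prob: float = 0.1,
    condition: str = "vehicle",
    session_id: str = "sess0",
) -> tuple[EventLog, dict]:
    """Operant trial-and-error session with a known trial plan.

    Each trial: light-on, initiation latency sampled from the condition's
    hazard, a 500-1500 ms hold until the go cue, then a choice poke.  Reward
    probabilities (10/50/90%) change in blocks of 35-45 trials; hold failures
    emit a ``timeout`` event.  Returns the event log and the ground-truth
    plan (per-category trial counts).
    """
    config.validate()
    rng = _rng(config.seed, "events")
    n_bins = int(round(config.latency_cap / HAZARD_BIN))
    h = _condition_hazard(config, condition, n_bins)
    records = []
    plan = {"n_trials": n_trials, "n_completed": 0, "n_timeout": 0, "n_noinit": 0,
            "n_rewarded": 0}
    t = 5.0
    block_left = 0
    p_reward = 0.5
    for trial in range(n_trials):
        if block_left == 0:
            block_left = int(rng.integers(35, 46))
            p_reward = float(rng.choice([0.1, 0.5, 0.9]))
        block_left -= 1
        records.append((t, "light_on", trial, condition, f"p_reward={p_reward}"))
        u = rng.random(n_bins)
        hit = u < h
        if not hit.any():
            plan["n_noinit"] += 1
            t += config.latency_cap + rng.uniform(2.0, 5.0)
            continue
        lat = (int(np.argmax(hit)) + float(rng.random())) * HAZARD_BIN
        t_center = t + lat
        records.append((t_center, "center_in", trial, condition, ""))
        hold = rng.uniform(0.5, 1.5)
        if rng.random() < timeout_prob:
            records.append((t_center + hold * rng.random(), "timeout", trial, condition, ""))
            plan["n_timeout"] += 1
            t = t_center + hold + rng.uniform(2.0, 5.0)
            continue
        t_go = t_center + hold
        records.append((t_go, "go_cue", trial, condition, ""))
        t_choice = t_go + rng.uniform(0.2, 0.8)
        records.append((t_choice, "choice_in", trial, condition, ""))
        plan["n_completed"] += 1
        if rng.random() < p_reward:
            t_click = t_choice + 0.5
            records.append((t_click, "click", trial, condition, ""))
            lat_c = _collection_latency(rng, config.collection_latency_dist)
            records.append((t_click + lat_c, "food_port_in", trial, condition, ""))
            plan["n_rewarded"] += 1
            t = t_click + lat_c + rng.uniform(2.0, 5.0)
        else:
            t = t_choice + rng.uniform(2.0, 5.0)
    return EventLog.from_records(records), plan
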