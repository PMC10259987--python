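"""Configuration of the synthetic-session generators.

The generator emulates a dual/triple-color fiber photometry rig: a single
femtowatt detector sampled at 10 kHz while LEDs are time-division multiplexed
in 10 ms frames (4 ms on).  Fluorescence in each channel is composed as

    F(t) = baseline * exp(-t / bleach_tau) * (1 + dff_true(t) + motion(t))

with detector noise added to the multiplexed stream.  Motion is a shared,
multiplicative low-frequency artifact injected identically into signal and
isosbestic channels; dff_true carries the event-locked biology (click-evoked
transients and approach ramps).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from .containers import ConfigError

__all__ = ["SynthConfig"]


@dataclass
class SynthConfig:
    """All knobs of the synthetic-data generators, with realistic defaults.

    Parameters
    ----------
    session_duration : float
        Session length, seconds.
    seed : int
        Master seed; it fully determines every generated stream.
    bleach_tau : float
        Photobleaching time constant, seconds.  Slow relative to the session
        so bleaching is a gentle trend, as with a healthy sensor prep.
    baseline_F : float
        Pre-bleach fluorescence baseline of the signal channels, detector
        units.  The isosbestic channel runs at ``0.7 * baseline_F``.
    motion_sd : float
        SD of the shared multiplicative motion artifact, as a fraction of
        baseline (low-pass Gaussian process, 2 Hz cutoff).
    noise_sd : float
        SD of per-sample detector noise at 10 kHz, fraction of baseline.
    transient_rise, transient_decay : float
        Time constants (s) of the difference-of-exponentials transient
        kernel, normalized to unit peak.
    transient_amplitude : float
        Peak dF/F of the click-evoked transient.
    ramp_slope : float
        Slope of the approach ramp, dF/F per second.
    ramp_duration : float
        Ramp length, seconds; the ramp ends exactly at approach completion.
    click_interval_range : tuple
        Uniform range (s) of gaps between unexpected reward clicks.
    collection_latency_dist : tuple
        ``(name, params)`` of the click -> food-port-in latency distribution;
        default lognormal(mu=0.7, sigma=0.6) s so both fast (<1 s) and slow
        (>2 s) collections occur.
    depression_factor : float
        Fraction of evoked-response amplitude lost at each laser pulse
        (0 = strictly linear generator).
    depression_recovery_tau : float
        Recovery time constant (s) of the depression state toward 1.
    spike_base_rate : float
        Baseline firing rate (Hz) of synthetic single units.
    spike_ramp_gain : float
        Linear rate increase (Hz per second into the ramp) applied over
        ``ramp_duration`` before each approach completion when ramping.
    hazard_baseline : float
        Baseline per-bin (250 ms) probability of initiating a trial.
    hazard_profile : mapping
        Per-condition map {bin index -> hazard multiplier}; missing bins
        default to 1.  Conditions absent from the map use all-ones.
    latency_cap : float
        Observation cap (s) for initiation latencies; slower trials are
        recorded as censored.
    """

    session_duration: float = 600.0
    seed: int = 0
    bleach_tau: float = 3600.0
    baseline_F: float = 1.0
    motion_sd: float = 0.05
    noise_sd: float = 0.01
    transient_rise: float = 0.050
    transient_decay: float = 0.500
    transient_amplitude: float = 0.02
    ramp_slope: float = 0.2
    ramp_duration: float = 1.0
    click_interval_range: tuple[float, float] = (15.0, 30.0)
    collection_latency_dist: tuple[str, Mapping[str, float]] = (
        "lognormal",
        None,  # filled in __post_init__
    )
    depression_factor: float = 0.0
    depression_recovery_tau: float = 1.0
    spike_base_rate: float = 10.0
    spike_ramp_gain: float = 10.0
    hazard_baseline: float = 0.15
    hazard_profile: Mapping[str, Mapping[int, float]] = field(default_factory=dict)
    latency_cap: float = 10.0
    sample_rate: float = 10_000.0

    def __post_init__(self) -> None:
        if self.collection_latency_dist[1] is None:
            self.collection_latency_dist = ("lognormal", {"mu": 0.7, "sigma": 0.6})
        self.validate()

    def validate(self) -> None:
        if self.session_duration <= 0:
            raise ConfigError("session_duration must be positive")
        if self.bleach_tau <= 0:
            raise ConfigError("bleach_tau must be positive")
        if self.transient_rise <= 0 or self.transient_decay <= 0:
            raise ConfigError("transient time constants must be positive")
        if self.transient_rise >= self.transient_decay:
            raise ConfigError("transient rise tau must be shorter than decay tau")
        if not (0.0 <= self.depression_factor <= 1.0):
            raise ConfigError("depression_factor must lie in [0, 1]")
        if self.depression_recovery_tau <= 0:
            raise ConfigError("depression_recovery_tau must be positive")
        lo, hi = self.click_interval_range
        if not (0 < lo <= hi):
            raise ConfigError("click_interval_range must satisfy 0 < lo <= hi")
        if self.motion_sd < 0 or self.noise_sd < 0:
            raise ConfigError("noise/motion SDs must be non-negative")
        if self.sample_rate <= 0:
            raise ConfigError("sample_rate must be positive")
        if self.ramp_duration < 0:
            raise ConfigError("ramp_duration must be non-negative")
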