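"""Core data containers shared across the pipeline.

These are thin, typed wrappers around numpy arrays and pandas frames.  Every
container that crosses a stage boundary can round-trip through plain CSV so
that pipeline stages can be run (and inspected) independently.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ConfigError",
    "DataIntegrityError",
    "LedSchedule",
    "RawPhotometry",
    "ChannelTrace",
    "CorrectedTrace",
    "EventLog",
    "SpikeTrain",
    "PeriEventMatrix",
    "StimTrain",
    "ShuffleTestResult",
    "HazardCurve",
    "LATENCY_COLUMNS",
]

#: canonical column order for latency tables (one row per trial)
LATENCY_COLUMNS = ["session_id", "subject", "condition", "trial_id", "latency_s", "censored"]

#: behavioral / stimulation event vocabulary
EVENT_TYPES = frozenset(
    {"light_on", "center_in", "go_cue", "choice_in", "click",
     "food_port_in", "laser_pulse", "timeout"}
)


class ConfigError(ValueError):
    """Invalid configuration (non-positive durations, bad rates, ...)."""


class DataIntegrityError(ValueError):
    """Input data violates a structural contract (ordering, pairing, ...)."""


@dataclass(frozen=True)
class LedSchedule:
    """Time-division-multiplexing schedule for alternating LED excitation.

    Each LED is on for ``on_len`` seconds at the start of its ``frame_len``
    frame; channels cycle frame by frame, so one full cycle lasts
    ``frame_len * len(channels)`` seconds.
    """

    frame_len: float = 0.010
    on_len: float = 0.004
    channels: tuple[tuple[str, int], ...] = (
        ("rdlight", 565),
        ("gcamp", 470),
        ("iso", 405),
    )

    def __post_init__(self) -> None:
        if self.frame_len <= 0 or self.on_len <= 0:
            raise ConfigError("frame_len and on_len must be positive")
        if self.on_len >= self.frame_len:
            raise ConfigError("on_len must be shorter than frame_len")
        if not self.channels:
            raise ConfigError("schedule needs at least one channel")

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    @property
    def cycle_len(self) -> float:
        """Duration of one full pass through all channels, seconds."""
        return self.frame_len * self.n_channels

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(lbl for lbl, _ in self.channels)

    def to_file(self, path: str | Path) -> None:
        """Write as a flat key=value file."""
        lines = [f"frame_len={self.frame_len!r}", f"on_len={self.on_len!r}"]
        for lbl, nm in self.channels:
            lines.append(f"channel={lbl}:{nm}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "LedSchedule":
        frame_len, on_len = 0.010, 0.004
        channels: list[tuple[str, int]] = []
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, val = line.partition("=")
            key = key.strip()
            val = val.strip()
            if key == "frame_len":
                frame_len = float(val)
            elif key == "on_len":
                on_len = float(val)
            elif key == "channel":
                lbl, _, nm = val.partition(":")
                channels.append((lbl, int(nm)))
        if not channels:
            raise ConfigError(f"no channels found in schedule file {path}")
        return cls(frame_len=frame_len, on_len=on_len, channels=tuple(channels))


@dataclass
class RawPhotometry:
    """A single multiplexed detector stream (all LEDs share one detector)."""

    samples: np.ndarray
    sample_rate: float = 10_000.0
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sample_rate <= 0:
            raise ConfigError("sample_rate must be positive")

    @property
    def duration(self) -> float:
        return self.samples.size / self.sample_rate

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.samples.size) / self.sample_rate

    def to_npy(self, path: str | Path) -> None:
        np.save(path, self.samples)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"time_s": self.times, "detector_v": self.samples}).to_csv(
            path, index=False
        )


@dataclass
class ChannelTrace:
    """One demultiplexed channel: mean in-frame fluorescence at frame centers."""

    label: str
    times: np.ndarray
    values: np.ndarray
    rate: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise DataIntegrityError("times and values must have equal length")


@dataclass
class CorrectedTrace:
    """Isosbestic-corrected dF/F (or any uniformly sampled analysis trace).

    Also used for smoothed firing-rate traces: the downstream statistics are
    unit-agnostic, so ``dff`` then simply holds rate in Hz.
    """

    times: np.ndarray
    dff: np.ndarray
    rate: float
    fit_coeffs: tuple[float, float] = (float("nan"), float("nan"))
    zscored: bool = False
    label: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.dff = np.asarray(self.dff, dtype=float)
        if self.times.shape != self.dff.shape:
            raise DataIntegrityError("times and dff must have equal length")

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"time_s": self.times, "dff": self.dff}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, label: str = "") -> "CorrectedTrace":
        df = pd.read_csv(path)
        t = df["time_s"].to_numpy()
        if t.size < 2:
            raise DataIntegrityError(f"trace in {path} too short")
        rate = 1.0 / float(np.median(np.diff(t)))
        return cls(times=t, dff=df["dff"].to_numpy(), rate=rate, label=label)


@dataclass
class EventLog:
    """Typed, timestamped behavioral/stimulation events for one session.

    Backed by a DataFrame with columns
    ``time_s, event_type, trial_id, condition, extra``.
    """

    df: pd.DataFrame

    COLUMNS = ("time_s", "event_type", "trial_id", "condition", "extra")

    def __post_init__(self) -> None:
        missing = set(self.COLUMNS) - set(self.df.columns)
        if missing:
            raise DataIntegrityError(f"EventLog missing columns: {sorted(missing)}")
        t = self.df["time_s"].to_numpy(dtype=float)
        if t.size and np.any(np.diff(t) < 0):
            raise DataIntegrityError("EventLog times must be non-decreasing")

    @classmethod
    def from_records(cls, records: Sequence[tuple]) -> "EventLog":
        """records: iterable of (time_s, event_type, trial_id, condition, extra)."""
        df = pd.DataFrame(records, columns=list(cls.COLUMNS))
        df = df.sort_values("time_s", kind="stable").reset_index(drop=True)
        return cls(df)

    def times_of(self, event_type: str) -> np.ndarray:
        sel = self.df[self.df["event_type"] == event_type]
        return sel["time_s"].to_numpy(dtype=float)

    def of_type(self, event_type: str) -> pd.DataFrame:
        return self.df[self.df["event_type"] == event_type]

    def __len__(self) -> int:
        return len(self.df)

    def to_csv(self, path: str | Path) -> None:
        self.df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "EventLog":
        df = pd.read_csv(path, keep_default_na=False, na_values=[])
        df["time_s"] = df["time_s"].astype(float)
        return cls(df)


@dataclass
class SpikeTrain:
    """Spike times for one single unit, seconds from session start."""

    unit_id: str
    spike_times: np.ndarray

    def __post_init__(self) -> None:
        self.spike_times = np.asarray(self.spike_times, dtype=float)
        if self.spike_times.size and np.any(np.diff(self.spike_times) <= 0):
            raise DataIntegrityError("spike times must be strictly increasing")

    def __len__(self) -> int:
        return self.spike_times.size


@dataclass
class PeriEventMatrix:
    """Trial-aligned matrix of a continuous trace: trials x samples.

    Every row spans exactly ``[t_event - pre, t_event + post)`` on the trace's
    own sampling grid.  Events whose window would fall outside the session
    are excluded and listed in ``excluded``.
    """

    alignment_event: str
    window: tuple[float, float]
    trial_times: np.ndarray
    data: np.ndarray
    sample_rate: float
    trial_meta: pd.DataFrame
    excluded: list[float] = field(default_factory=list)

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def rel_times(self) -> np.ndarray:
        """Sample times relative to the aligning event."""
        n_pre = int(round(self.window[0] * self.sample_rate))
        return (np.arange(self.data.shape[1]) - n_pre) / self.sample_rate

    def to_csv(self, path: str | Path, meta_path: str | Path | None = None) -> None:
        df = pd.DataFrame(self.data)
        df.insert(0, "trial_id", self.trial_meta["trial_id"].to_numpy())
        df.to_csv(path, index=False)
        if meta_path is not None:
            self.trial_meta.to_csv(meta_path, index=False)


@dataclass(frozen=True)
class StimTrain:
    """A laser pulse train: regular pulses at ``frequency`` from ``onset``."""

    onset: float
    pulse_width_ms: float
    power_mw: float
    frequency_hz: float
    n_pulses: int

    def __post_init__(self) -> None:
        if self.n_pulses < 1:
            raise ConfigError("n_pulses must be >= 1")
        if self.pulse_width_ms <= 0:
            raise ConfigError("pulse_width_ms must be positive")
        if self.n_pulses > 1 and self.frequency_hz <= 0:
            raise ConfigError("frequency_hz must be positive for multi-pulse trains")

    @property
    def pulse_times(self) -> np.ndarray:
        if self.n_pulses == 1:
            return np.array([self.onset])
        return self.onset + np.arange(self.n_pulses) / self.frequency_hz

    @property
    def duration(self) -> float:
        """Time from first to last pulse onset."""
        return 0.0 if self.n_pulses == 1 else (self.n_pulses - 1) / self.frequency_hz

    @staticmethod
    def protocol_to_csv(trains: Sequence["StimTrain"], path: str | Path) -> None:
        pd.DataFrame(
            [
                {
                    "onset_s": tr.onset,
                    "pulse_width_ms": tr.pulse_width_ms,
                    "power_mw": tr.power_mw,
                    "frequency_hz": tr.frequency_hz,
                    "n_pulses": tr.n_pulses,
                }
                for tr in trains
            ]
        ).to_csv(path, index=False)

    @staticmethod
    def protocol_from_csv(path: str | Path) -> list["StimTrain"]:
        df = pd.read_csv(path)
        return [
            StimTrain(
                onset=float(r.onset_s),
                pulse_width_ms=float(r.pulse_width_ms),
                power_mw=float(r.power_mw),
                frequency_hz=float(r.frequency_hz),
                n_pulses=int(r.n_pulses),
            )
            for r in df.itertuples()
        ]


@dataclass
class ShuffleTestResult:
    """An observed event-aligned statistic with its shuffle null distribution."""

    statistic_name: str
    observed: float
    null_values: np.ndarray
    ci: tuple[float, float]
    significant: bool
    n_shuffles: int
    seed: int
    n_events: int = 0

    def __post_init__(self) -> None:
        self.null_values = np.asarray(self.null_values, dtype=float)
        if self.null_values.size != self.n_shuffles:
            raise DataIntegrityError("null_values length must equal n_shuffles")
        if self.ci[0] > self.ci[1]:
            raise DataIntegrityError("ci must be ordered (lo, hi)")

    @property
    def direction(self) -> int:
        """Sign of the observed statistic (+1 up, -1 down, 0 flat)."""
        return int(np.sign(self.observed))


@dataclass
class HazardCurve:
    """Discrete per-bin hazard of trial-initiation latencies for one condition.

    ``hazard[i] = events[i] / at_risk[i]``; censored trials leave the risk
    set without counting as events.
    """

    bin_edges: np.ndarray
    hazard: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray
    censored: np.ndarray
    condition: str
    truncated: bool = False

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def cdf_from_hazard(self) -> np.ndarray:
        """Cumulative event probability implied by the hazard: 1 - prod(1-h)."""
        return 1.0 - np.cumprod(1.0 - self.hazard)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_lo": self.bin_edges[:-1],
                "bin_hi": self.bin_edges[1:],
                "hazard": self.hazard,
                "at_risk": self.at_risk,
                "events": self.events,
                "censored": self.censored,
                "condition": self.condition,
            }
        )


def dataclass_to_dict(obj) -> dict:
    """JSON-friendly dict of a result dataclass (arrays -> lists)."""
    out = {}
    for f in dataclasses.fields(obj):
        v = getattr(obj, f.name)
        if isinstance(v, np.ndarray):
            v = v.tolist()
        out[f.name] = v
    return out
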