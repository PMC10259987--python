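"""Replicate study designs that validate the pipeline on synthetic sessions.

Each function runs the full pipeline (generate -> demultiplex -> correct ->
test) under a fixed study design and returns summary numbers: shuffle-interval
coverage on null sessions, linear-summation ratios, ramp-slope recovery,
hazard recovery and per-bin test calibration, and motion-artifact
attenuation.  Session lengths are chosen so a full study runs in minutes on
one core; the designs are deterministic in their base seed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .behavior import hazard_rate, per_bin_condition_test
from .config import SynthConfig
from .containers import CorrectedTrace, StimTrain
from .plasticity import summation_ratio
from .preproc import demultiplex, isosbestic_correct
from .rampstats import shuffle_test
from .synth import generate_pavlovian_session, generate_pharm_latencies

__all__ = [
    "corrected_from_session",
    "null_session_coverage",
    "summation_linearity",
    "ramp_slope_recovery",
    "hazard_recovery",
    "per_bin_null_flag_rate",
    "motion_attenuation",
]

#: session length used by the replicate designs (~18 click trials each)
STUDY_SESSION_S = 420.0


def corrected_from_session(sess, channel: str = "rdlight") -> CorrectedTrace:
    """Demultiplex a synthetic session and isosbestic-correct one channel."""
    traces = {tr.label: tr for tr in demultiplex(sess.raw, sess.schedule)}
    return isosbestic_correct(traces[channel], traces["iso"])


def null_session_coverage(
    n_sessions: int = 200,
    base_seed: int = 1,
    n_shuffles: int = 1000,
    window: float = 0.5,
    session_duration: float = STUDY_SESSION_S,
) -> tuple[float, int]:
    """Coverage of the shuffle 95% interval on null sessions.

    Generates sessions with no event-locked signal (ramp slope and transient
    amplitude zero; bleaching, motion and noise at defaults), runs the
    max-min slope shuffle test at the true food-port-entry times, and
    returns (fraction of sessions whose observed statistic falls inside the
    interval, number of sessions).  Calibration predicts ~0.95.
    """
    inside = 0
    for i in range(n_sessions):
        seed = base_seed + i
        cfg = SynthConfig(
            seed=seed, session_duration=session_duration,
            ramp_slope=0.0, transient_amplitude=0.0,
        )
        sess = generate_pavlovian_session(cfg)
        corr = corrected_from_session(sess)
        res = shuffle_test(
            corr, sess.events.times_of("food_port_in"),
            statistic="maxmin_slope", window=window,
            n_shuffles=n_shuffles, seed=seed,
        )
        inside += not res.significant
    return inside / n_sessions, n_sessions


def summation_linearity(
    frequencies: tuple[float, ...] = (4.0, 8.0, 16.0),
    n_pulses: int = 4,
    depression_factor: float = 0.0,
    seed: int = 1,
) -> dict[float, float]:
    """Observed/predicted peak ratio of a pulse train per stimulation frequency.

    Simulates a single pulse and an ``n_pulses`` train with noise and motion
    off, and compares the train's evoked response against the linear
    superposition of time-shifted single-pulse responses on the detector
    grid (where the pulse periods are exact sample counts).
    """
    from .synth import generate_stim_session

    out = {}
    for freq in frequencies:
        cfg = SynthConfig(
            seed=seed, session_duration=120.0, motion_sd=0.0, noise_sd=0.0,
            depression_factor=depression_factor,
        )
        single = StimTrain(onset=10.0, pulse_width_ms=4.0, power_mw=10.0,
                           frequency_hz=0.0, n_pulses=1)
        train = StimTrain(onset=60.0, pulse_width_ms=4.0, power_mw=10.0,
                          frequency_hz=freq, n_pulses=n_pulses)
        sess = generate_stim_session(cfg, [single, train])
        ev = sess.evoked_trace()

        def seg(onset: float, length: float = 20.0) -> CorrectedTrace:
            i0 = int(round(onset * ev.rate))
            i1 = i0 + int(round(length * ev.rate))
            return CorrectedTrace(times=ev.times[i0:i1] - onset,
                                  dff=ev.dff[i0:i1], rate=ev.rate)

        out[freq] = summation_ratio(seg(train.onset), seg(single.onset),
                                    n_pulses, freq)
    return out


def ramp_slope_recovery(
    slopes: tuple[float, ...] = (0.1, 0.25, 0.5, 0.75, 1.0),
    n_sessions_per: int = 3,
    base_seed: int = 1,
    window: float = 0.5,
    session_duration: float = STUDY_SESSION_S,
) -> pd.DataFrame:
    """Recovery of injected approach-ramp slopes at the default noise level.

    For each slope on the grid, runs full-pipeline sessions and measures the
    session-mean max-min slope in the window before food-port entry.
    Returns a frame with columns ``slope, observed, rel_error``.
    """
    rows = []
    for j, slope in enumerate(slopes):
        obs = []
        for i in range(n_sessions_per):
            seed = base_seed + 1000 * (j + 1) + i
            cfg = SynthConfig(
                seed=seed, session_duration=session_duration,
                ramp_slope=slope, transient_amplitude=0.0,
            )
            sess = generate_pavlovian_session(cfg)
            corr = corrected_from_session(sess)
            res = shuffle_test(
                corr, sess.events.times_of("food_port_in"),
                statistic="maxmin_slope", window=window, n_shuffles=100, seed=seed,
            )
            obs.append(res.observed)
        mean_obs = float(np.mean(obs))
        rows.append(
            {"slope": slope, "observed": mean_obs,
             "rel_error": abs(mean_obs - slope) / slope}
        )
    return pd.DataFrame(rows)


def hazard_recovery(
    seed: int = 1,
    n_trials: int = 20_000,
    baseline: float = 0.2,
    multiplier: float = 0.5,
) -> dict:
    """Hazard machinery on generator output with a known 1-2 s suppression.

    Returns the fitted hazard trend (per second) of a constant-hazard
    condition, and the estimated hazard ratio in the suppressed (1-2 s) and
    untouched (0-1 s) bins of a drug condition.
    """
    cfg = SynthConfig(
        seed=seed, hazard_baseline=baseline,
        hazard_profile={"drug": {b: multiplier for b in range(4, 8)}},
    )
    tab, _ = generate_pharm_latencies(cfg, ["vehicle", "drug"], n_trials)
    curves = hazard_rate(tab)
    veh, drug = curves["vehicle"], curves["drug"]
    use = veh.at_risk > 200
    trend = float(np.polyfit(veh.bin_centers[use], veh.hazard[use], 1)[0])
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = drug.hazard / veh.hazard
    return {
        "trend_per_s": trend,
        "ratio_suppressed": float(np.nanmean(ratio[4:8])),
        "ratio_untouched": float(np.nanmean(ratio[:4])),
    }


def per_bin_null_flag_rate(
    n_replicates: int = 25,
    n_trials: int = 800,
    n_perm: int = 1000,
    alpha: float = 0.01,
    base_seed: int = 1,
) -> tuple[float, int]:
    """False-flag rate of the per-bin permutation test under the null.

    Two conditions share an identical hazard; returns (fraction of flagged
    bins across replicates, number of bin tests).  Calibration predicts
    ~``alpha``.
    """
    flagged = total = 0
    for i in range(n_replicates):
        cfg = SynthConfig(seed=base_seed + i, hazard_baseline=0.2)
        tab, _ = generate_pharm_latencies(cfg, ["vehicle", "sham"], n_trials)
        out = per_bin_condition_test(tab, reference="vehicle", alpha=alpha,
                                     n_perm=n_perm, seed=base_seed + i)
        flagged += int(out["flag"].sum())
        total += len(out)
    return flagged / total, total


def motion_attenuation(seed: int = 1, session_duration: float = STUDY_SESSION_S) -> dict:
    """Correlation of the shared motion artifact with raw vs corrected traces."""
    cfg = SynthConfig(seed=seed, session_duration=session_duration)
    sess = generate_pavlovian_session(cfg)
    traces = {tr.label: tr for tr in demultiplex(sess.raw, sess.schedule)}
    corr = isosbestic_correct(traces["rdlight"], traces["iso"])
    m = sess.truth.motion_at(corr.times)
    return {
        "r_raw": float(np.corrcoef(traces["rdlight"].values, m)[0, 1]),
        "r_corrected": float(np.corrcoef(corr.dff, m)[0, 1]),
    }
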