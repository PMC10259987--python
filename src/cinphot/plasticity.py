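"""Stimulation-evoked response quantification and short-term plasticity.

Covers the evoked-amplitude measurement, the paired-pulse ratio (template
subtraction isolates the second-pulse response), the observed-vs-predicted
linear-summation ratio for pulse trains, and the fixed-effects
repeated-measures ANOVAs used to summarize dose-response tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .containers import (
    ConfigError,
    CorrectedTrace,
    DataIntegrityError,
    StimTrain,
)

__all__ = [
    "evoked_amplitude",
    "paired_pulse_amplitudes",
    "summation_ratio",
    "one_way_rm_anova",
    "two_way_rm_anova",
    "AnovaResult",
    "PairedPulseResult",
]

#: peak-measurement window after a single pulse, seconds
SINGLE_PULSE_WINDOW = 2.0
#: pre-train baseline duration, seconds
BASELINE_LEN = 1.0


def _slice(trace: CorrectedTrace, t_lo: float, t_hi: float) -> np.ndarray:
    i0 = int(round((t_lo - trace.times[0]) * trace.rate))
    i1 = int(round((t_hi - trace.times[0]) * trace.rate))
    if i0 < 0 or i1 > trace.dff.size or i1 <= i0:
        raise DataIntegrityError(
            f"window [{t_lo:.3f}, {t_hi:.3f}] s falls outside the trace"
        )
    return trace.dff[i0:i1]


def evoked_amplitude(
    trace: CorrectedTrace,
    train: StimTrain,
    response_window: float | None = None,
    next_train_onset: float | None = None,
) -> float:
    """Peak baseline-subtracted dF/F after the first pulse of a train.

    Baseline is the mean over 1 s preceding the train; the peak is searched
    in ``[onset, onset + response_window]``.  The default window is 2 s for
    single pulses and train duration + 2 s for trains.
    """
    if response_window is None:
        response_window = train.duration + SINGLE_PULSE_WINDOW
    if next_train_onset is not None and train.onset + response_window > next_train_onset:
        raise DataIntegrityError(
            f"response window ({response_window} s) overlaps the next train at "
            f"{next_train_onset} s"
        )
    baseline = _slice(trace, train.onset - BASELINE_LEN, train.onset).mean()
    seg = _slice(trace, train.onset, train.onset + response_window)
    return float(seg.max() - baseline)


@dataclass
class PairedPulseResult:
    a1: float
    a2: float
    ratio: float | None
    flagged: bool = False


def paired_pulse_amplitudes(
    trace: CorrectedTrace,
    pulse_pair: StimTrain,
    single_pulse_template: CorrectedTrace,
    noise_floor: float = 0.0,
    response_window: float = SINGLE_PULSE_WINDOW,
) -> PairedPulseResult:
    """Paired-pulse amplitudes with template subtraction.

    A1 is the evoked amplitude of the first pulse.  The single-pulse template
    (a trace aligned so its t=0 is the pulse onset) is scaled to A1, shifted
    to the first-pulse onset and subtracted, isolating the residual response
    to the second pulse; A2 is its baseline-subtracted peak after the second
    pulse.  Template scaling by A1 (rather than using the template's own
    amplitude) absorbs slow session-level amplitude drift.
    """
    if pulse_pair.n_pulses != 2:
        raise ConfigError("paired_pulse_amplitudes requires a 2-pulse train")
    t1, t2 = pulse_pair.pulse_times
    a1 = evoked_amplitude(
        trace, StimTrain(t1, pulse_pair.pulse_width_ms, pulse_pair.power_mw, 0.0, 1),
        response_window=min(response_window, t2 - t1),
    )
    if a1 <= noise_floor:
        return PairedPulseResult(a1=a1, a2=np.nan, ratio=None, flagged=True)
    tmpl_peak = float(np.nanmax(single_pulse_template.dff))
    if tmpl_peak <= 0:
        raise DataIntegrityError("single-pulse template has non-positive peak")
    scaled = single_pulse_template.dff * (a1 / tmpl_peak)
    # subtract the template, shifted so its t=0 lands on the first pulse
    resid = trace.dff - np.interp(
        trace.times - t1, single_pulse_template.times, scaled, left=0.0, right=0.0
    )
    resid_trace = CorrectedTrace(times=trace.times, dff=resid, rate=trace.rate)
    baseline = _slice(resid_trace, t1 - BASELINE_LEN, t1).mean()
    seg = _slice(resid_trace, t2, t2 + response_window)
    a2 = float(seg.max() - baseline)
    return PairedPulseResult(a1=a1, a2=a2, ratio=a2 / a1)


def summation_ratio(
    observed: CorrectedTrace,
    single_pulse: CorrectedTrace,
    n_pulses: int,
    frequency: float,
) -> float:
    """Observed-over-predicted peak ratio for a pulse train.

    Both traces must be aligned so t=0 is the first pulse onset.  The
    prediction sums ``n_pulses`` copies of the single-pulse response shifted
    by ``k / frequency``; the ratio is observed peak / predicted peak.
    Shifts are applied as exact integer sample offsets when the trace rate is
    commensurate with the pulse frequency, and by linear interpolation
    otherwise.  A linear (non-depressing) release process gives a ratio of 1.
    """
    if n_pulses < 1:
        raise ConfigError("n_pulses must be >= 1")
    if n_pulses > 1 and frequency <= 0:
        raise ConfigError("frequency must be positive")
    pred = np.zeros_like(single_pulse.dff)
    for k in range(n_pulses):
        shift = 0.0 if n_pulses == 1 else k / frequency
        shift_samples = shift * single_pulse.rate
        if abs(shift_samples - round(shift_samples)) < 1e-9:
            s = int(round(shift_samples))
            if s < pred.size:
                pred[s:] += single_pulse.dff[: pred.size - s]
        else:
            pred += np.interp(
                single_pulse.times - shift,
                single_pulse.times,
                single_pulse.dff,
                left=0.0,
                right=0.0,
            )
    pred_peak = float(pred.max())
    if pred_peak <= 0:
        raise DataIntegrityError("predicted peak is non-positive")
    obs_peak = float(np.max(observed.dff))
    return obs_peak / pred_peak


@dataclass
class AnovaResult:
    """One F test from a repeated-measures decomposition."""

    effect: str
    F: float
    df1: int
    df2: int
    p: float

    def __repr__(self) -> str:
        return f"{self.effect}: F({self.df1},{self.df2}) = {self.F:.3g}, p = {self.p:.3g}"


def _f_p(ss_num: float, df1: int, ss_den: float, df2: int, effect: str) -> AnovaResult:
    if ss_num <= 0 or df1 <= 0:
        return AnovaResult(effect, 0.0, df1, df2, 1.0)
    if ss_den <= 0 or df2 <= 0:
        return AnovaResult(effect, float("inf"), df1, df2, 0.0)
    F = (ss_num / df1) / (ss_den / df2)
    return AnovaResult(effect, float(F), df1, df2, float(_stats.f.sf(F, df1, df2)))


def _check_balanced(df: pd.DataFrame, subject: str, factors: list[str]) -> None:
    counts = df.groupby([subject] + factors, observed=True).size()
    if counts.nunique() != 1 or counts.iloc[0] != 1:
        raise DataIntegrityError("unbalanced table: need exactly one value per cell")
    expected = df[subject].nunique()
    for f in factors:
        expected *= df[f].nunique()
    if counts.size != expected:
        raise DataIntegrityError("unbalanced table: missing subject x level cells")


def one_way_rm_anova(
    table: pd.DataFrame,
    value: str = "value",
    subject: str = "subject",
    level: str = "level",
) -> AnovaResult:
    """Fixed-effects one-way repeated-measures ANOVA.

    ``F = MS_condition / MS_(condition x subject)`` with df1 = k-1 and
    df2 = (k-1)(n-1).  A table with zero between-level variance returns
    F = 0, p = 1.
    """
    _check_balanced(table, subject, [level])
    x = table[value].to_numpy(dtype=float)
    gm = x.mean()
    k = table[level].nunique()
    n = table[subject].nunique()
    if k < 2 or n < 2:
        raise DataIntegrityError("need at least 2 levels and 2 subjects")
    lvl_means = table.groupby(level, observed=True)[value].mean().to_numpy()
    sub_means = table.groupby(subject, observed=True)[value].mean().to_numpy()
    ss_cond = n * float(((lvl_means - gm) ** 2).sum())
    ss_subj = k * float(((sub_means - gm) ** 2).sum())
    ss_tot = float(((x - gm) ** 2).sum())
    ss_err = ss_tot - ss_cond - ss_subj
    return _f_p(ss_cond, k - 1, max(ss_err, 0.0), (k - 1) * (n - 1), level)


def two_way_rm_anova(
    table: pd.DataFrame,
    value: str = "value",
    subject: str = "subject",
    factor_a: str = "pulse_order",
    factor_b: str = "interval",
) -> dict[str, AnovaResult]:
    """Two-factor repeated-measures decomposition.

    Returns the two main effects and their interaction, each tested against
    its own factor-by-subject error term (e.g. the interaction of pulse
    order x inter-pulse interval has df ((a-1)(b-1), (a-1)(b-1)(n-1))).
    """
    _check_balanced(table, subject, [factor_a, factor_b])
    a = table[factor_a].nunique()
    b = table[factor_b].nunique()
    n = table[subject].nunique()
    if a < 2 or b < 2 or n < 2:
        raise DataIntegrityError("need >= 2 levels per factor and >= 2 subjects")
    x = table[value].to_numpy(dtype=float)
    gm = x.mean()

    def means(*cols: str) -> pd.Series:
        return table.groupby(list(cols), observed=True)[value].mean()

    m_a, m_b, m_s = means(factor_a), means(factor_b), means(subject)
    m_ab, m_as, m_bs = means(factor_a, factor_b), means(factor_a, subject), means(factor_b, subject)

    ss_a = b * n * float(((m_a - gm) ** 2).sum())
    ss_b = a * n * float(((m_b - gm) ** 2).sum())
    ss_s = a * b * float(((m_s - gm) ** 2).sum())
    dev_ab = m_ab - m_a.reindex(m_ab.index.get_level_values(0)).to_numpy() \
        - m_b.reindex(m_ab.index.get_level_values(1)).to_numpy() + gm
    ss_ab = n * float((dev_ab ** 2).sum())
    dev_as = m_as - m_a.reindex(m_as.index.get_level_values(0)).to_numpy() \
        - m_s.reindex(m_as.index.get_level_values(1)).to_numpy() + gm
    ss_as = b * float((dev_as ** 2).sum())
    dev_bs = m_bs - m_b.reindex(m_bs.index.get_level_values(0)).to_numpy() \
        - m_s.reindex(m_bs.index.get_level_values(1)).to_numpy() + gm
    ss_bs = a * float((dev_bs ** 2).sum())
    ss_tot = float(((x - gm) ** 2).sum())
    ss_abs = max(ss_tot - (ss_a + ss_b + ss_s + ss_ab + ss_as + ss_bs), 0.0)

    return {
        factor_a: _f_p(ss_a, a - 1, ss_as, (a - 1) * (n - 1), factor_a),
        factor_b: _f_p(ss_b, b - 1, ss_bs, (b - 1) * (n - 1), factor_b),
        "interaction": _f_p(
            ss_ab, (a - 1) * (b - 1), ss_abs, (a - 1) * (b - 1) * (n - 1), "interaction"
        ),
    }
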