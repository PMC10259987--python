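"""Pharmacology-session behavioral analyses.

Completed-trial counts, long-latency cumulative distributions at 250 ms bins,
discrete hazard rates of trial initiation, per-bin permutation comparisons
against the vehicle condition, and the within-subject ANOVA over completed
trials.  Latency tables follow the canonical column layout
``session_id, subject, condition, trial_id, latency_s, censored``.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .containers import ConfigError, DataIntegrityError, EventLog, HazardCurve
from .plasticity import AnovaResult, one_way_rm_anova

__all__ = [
    "completed_trials",
    "latency_cdf",
    "hazard_rate",
    "per_bin_condition_test",
    "condition_anova",
    "ConditionAnovaResult",
]

DEFAULT_BIN = 0.250
DEFAULT_MIN_LATENCY = 1.0

#: required order of events within a completed trial
_TRIAL_SEQUENCE = ("light_on", "center_in", "go_cue", "choice_in")


def completed_trials(events: EventLog) -> tuple[int, list]:
    """Count completed trials: light-on -> center-in -> go-cue -> choice-in,
    in order, with no timeout event in the trial.

    Returns ``(count, malformed)`` where ``malformed`` lists trial ids whose
    event sequence is out of order (they are reported, never silently
    dropped, and never counted as completed).
    """
    count = 0
    malformed = []
    for trial_id, grp in events.df.groupby("trial_id", sort=True):
        types = grp["event_type"].tolist()
        times = dict(zip(grp["event_type"], grp["time_s"]))
        if "timeout" in types:
            continue
        if not all(et in types for et in _TRIAL_SEQUENCE):
            continue
        seq_times = [times[et] for et in _TRIAL_SEQUENCE]
        if any(b < a for a, b in zip(seq_times, seq_times[1:])):
            malformed.append(trial_id)
            continue
        count += 1
    return count, malformed


def _filter_long(table: pd.DataFrame, min_latency: float | None) -> pd.DataFrame:
    keep = ~table["censored"].astype(bool)
    if min_latency is not None:
        keep &= table["latency_s"] > min_latency
    return table[keep]


def latency_cdf(
    table: pd.DataFrame,
    bin: float = DEFAULT_BIN,
    min_latency: float | None = DEFAULT_MIN_LATENCY,
) -> pd.DataFrame:
    """Per-condition empirical CDF of long (> ``min_latency``) latencies.

    Binned at ``bin`` seconds and normalized to the retained (uncensored,
    long-latency) trial set of each condition.  Returns a tidy frame with
    columns ``condition, bin_hi, cdf``.
    """
    retained = _filter_long(table, min_latency)
    if retained.empty:
        raise DataIntegrityError("no trials retained after the long-latency filter")
    start = min_latency if min_latency is not None else 0.0
    t_max = float(retained["latency_s"].max())
    n_bins = int(np.ceil((t_max - start) / bin))
    edges = start + bin * np.arange(n_bins + 1)
    rows = []
    for cond, grp in retained.groupby("condition", sort=False):
        counts, _ = np.histogram(grp["latency_s"], bins=edges)
        cdf = np.cumsum(counts) / len(grp)
        for hi, c in zip(edges[1:], cdf):
            rows.append({"condition": cond, "bin_hi": float(hi), "cdf": float(c)})
    return pd.DataFrame(rows)


def _trial_bins(
    table: pd.DataFrame, bin: float, start: float
) -> tuple[np.ndarray, np.ndarray]:
    """Bin index of each trial's event (or censoring) plus an is-event flag."""
    lat = table["latency_s"].to_numpy(dtype=float)
    cens = table["censored"].to_numpy(dtype=bool)
    idx = np.floor((lat - start) / bin).astype(int)
    idx = np.maximum(idx, 0)
    return idx, ~cens


def _hazard_from_bins(
    bin_idx: np.ndarray, is_event: np.ndarray, n_bins: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    events = np.bincount(bin_idx[is_event], minlength=n_bins)[:n_bins]
    leaving = np.bincount(bin_idx, minlength=n_bins)[:n_bins]
    censored = leaving - events
    at_risk = bin_idx.size - np.concatenate(([0], np.cumsum(leaving)[:-1]))
    with np.errstate(invalid="ignore", divide="ignore"):
        hazard = np.where(at_risk > 0, events / np.maximum(at_risk, 1), np.nan)
    return hazard, at_risk, events, censored


def hazard_rate(
    table: pd.DataFrame,
    bin: float = DEFAULT_BIN,
    min_latency: float | None = None,
    condition: str | None = None,
    pool_subjects: bool = True,
) -> HazardCurve | dict[str, HazardCurve]:
    """Discrete per-bin hazard of trial initiation.

    ``hazard[i] = events_in_bin[i] / at_risk[i]``; censored trials leave the
    risk set without counting as events.  With ``min_latency`` set, only
    trials slower than the threshold enter and bins start there (the
    conditional, long-latency hazard).  When the risk set empties the curve
    is truncated and flagged.  By default trials are pooled across subjects;
    ``pool_subjects=False`` averages per-subject curves instead.
    """
    if condition is None:
        return {
            str(cond): hazard_rate(grp, bin=bin, min_latency=min_latency,
                                   condition=str(cond), pool_subjects=pool_subjects)
            for cond, grp in table.groupby("condition", sort=False)
        }
    sub = table[table["condition"] == condition] if "condition" in table else table
    if min_latency is not None:
        sub = sub[sub["censored"].astype(bool) | (sub["latency_s"] > min_latency)]
    if sub.empty:
        raise DataIntegrityError(f"no trials for condition {condition!r}")
    start = min_latency if min_latency is not None else 0.0
    bin_idx_all, is_event_all = _trial_bins(sub, bin, start)
    n_bins = int(bin_idx_all.max()) + 1
    edges = start + bin * np.arange(n_bins + 1)

    if pool_subjects:
        hazard, at_risk, events, censored = _hazard_from_bins(
            bin_idx_all, is_event_all, n_bins
        )
    else:
        per = []
        for _s, grp in sub.groupby("subject", sort=False):
            bi, ie = _trial_bins(grp, bin, start)
            per.append(_hazard_from_bins(bi, ie, n_bins)[0])
        hazard = np.nanmean(np.vstack(per), axis=0)
        _, at_risk, events, censored = _hazard_from_bins(bin_idx_all, is_event_all, n_bins)

    truncated = bool(np.any(at_risk == 0))
    if truncated:
        first_empty = int(np.argmax(at_risk == 0))
        warnings.warn(
            f"condition {condition!r}: risk set empty from bin {first_empty}; "
            "curve truncated"
        )
        n_bins = first_empty
        edges = edges[: n_bins + 1]
        hazard, at_risk = hazard[:n_bins], at_risk[:n_bins]
        events, censored = events[:n_bins], censored[:n_bins]
    return HazardCurve(
        bin_edges=edges,
        hazard=hazard,
        at_risk=at_risk,
        events=events,
        censored=censored,
        condition=condition,
        truncated=truncated,
    )


def _perm_within_subject(
    rng: np.random.Generator, labels: np.ndarray, subjects: np.ndarray
) -> np.ndarray:
    out = labels.copy()
    for s in np.unique(subjects):
        m = subjects == s
        out[m] = rng.permutation(labels[m])
    return out


def per_bin_condition_test(
    table: pd.DataFrame,
    reference: str = "vehicle",
    bin: float = DEFAULT_BIN,
    min_latency: float | None = None,
    alpha: float = 0.01,
    n_perm: int = 10_000,
    seed: int = 0,
    statistic: str = "hazard",
) -> pd.DataFrame:
    """Per-bin permutation comparison of each condition against the reference.

    For every bin, the statistic is the difference (condition - reference) in
    per-bin hazard (or CDF).  The null permutes condition labels across
    trials within subject; bins with two-sided permutation p < ``alpha`` are
    flagged.  Bin-wise tests are uncorrected, matching per-bin significance
    marks on hazard/CDF panels.  Returns a tidy frame with columns
    ``condition, bin_lo, bin_hi, observed_diff, p, flag``.
    """
    conds = [c for c in table["condition"].unique() if c != reference]
    if reference not in set(table["condition"]):
        raise ConfigError(f"reference condition {reference!r} absent from the table")
    if not conds:
        raise ConfigError("need at least 2 conditions")
    start = min_latency if min_latency is not None else 0.0
    rows = []
    for cond in conds:
        sub = table[table["condition"].isin([reference, cond])].reset_index(drop=True)
        if min_latency is not None:
            sub = sub[sub["censored"].astype(bool) | (sub["latency_s"] > min_latency)]
            sub = sub.reset_index(drop=True)
        bin_idx, is_event = _trial_bins(sub, bin, start)
        n_bins = int(bin_idx.max()) + 1
        edges = start + bin * np.arange(n_bins + 1)
        labels = (sub["condition"] == cond).to_numpy()
        subjects = sub["subject"].to_numpy()

        def curve_diff(lab: np.ndarray) -> np.ndarray:
            if statistic == "hazard":
                h1 = _hazard_from_bins(bin_idx[lab], is_event[lab], n_bins)[0]
                h0 = _hazard_from_bins(bin_idx[~lab], is_event[~lab], n_bins)[0]
                return h1 - h0
            c1 = np.cumsum(np.bincount(bin_idx[lab & is_event], minlength=n_bins)[:n_bins])
            c0 = np.cumsum(np.bincount(bin_idx[~lab & is_event], minlength=n_bins)[:n_bins])
            n1 = max((lab & is_event).sum(), 1)
            n0 = max((~lab & is_event).sum(), 1)
            return c1 / n1 - c0 / n0

        obs = curve_diff(labels)
        rng = np.random.default_rng([seed, zlib.crc32(str(cond).encode())])
        exceed = np.zeros(n_bins)
        valid = np.zeros(n_bins)
        for _ in range(n_perm):
            d = curve_diff(_perm_within_subject(rng, labels, subjects))
            with np.errstate(invalid="ignore"):
                ge = np.abs(d) >= np.abs(obs)
            fin = np.isfinite(d) & np.isfinite(obs)
            exceed += np.where(fin & ge, 1.0, 0.0)
            valid += fin
        with np.errstate(invalid="ignore", divide="ignore"):
            p = (1.0 + exceed) / (1.0 + valid)
        p = np.where(np.isfinite(obs) & (valid > 0), p, np.nan)
        for i in range(n_bins):
            rows.append(
                {
                    "condition": cond,
                    "bin_lo": float(edges[i]),
                    "bin_hi": float(edges[i + 1]),
                    "observed_diff": float(obs[i]) if np.isfinite(obs[i]) else np.nan,
                    "p": float(p[i]) if np.isfinite(p[i]) else np.nan,
                    "flag": bool(np.isfinite(p[i]) and p[i] < alpha),
                }
            )
    return pd.DataFrame(rows)


@dataclass
class ConditionAnovaResult:
    anova: AnovaResult
    posthoc: pd.DataFrame  # condition, t, p_raw, p_holm


def condition_anova(
    counts: pd.DataFrame,
    reference: str = "vehicle",
    value: str = "count",
    subject: str = "subject",
    condition: str = "condition",
) -> ConditionAnovaResult:
    """Within-subject one-way ANOVA over per-session completed-trial counts,
    plus paired post-hoc comparisons of each drug condition against the
    reference with Holm correction.
    """
    conds = list(pd.unique(counts[condition]))
    if reference not in conds:
        raise ConfigError(f"reference condition {reference!r} missing")
    pivot = counts.pivot_table(index=subject, columns=condition, values=value)
    if pivot.isna().any().any():
        missing = pivot[pivot.isna().any(axis=1)].index.tolist()
        raise DataIntegrityError(f"subjects with missing conditions: {missing}")
    anova = one_way_rm_anova(
        counts.rename(columns={value: "value", subject: "subject", condition: "level"})
    )
    others = [c for c in conds if c != reference]
    raws = []
    for c in others:
        t, p = _stats.ttest_rel(pivot[c], pivot[reference])
        raws.append((c, float(t), float(p)))
    # Holm step-down over the vehicle-vs-drug contrasts
    order = np.argsort([p for _, _, p in raws])
    m = len(raws)
    p_holm = np.empty(m)
    running = 0.0
    for rank, j in enumerate(order):
        adj = (m - rank) * raws[j][2]
        running = max(running, adj)
        p_holm[j] = min(running, 1.0)
    posthoc = pd.DataFrame(
        [
            {"condition": c, "t": t, "p_raw": p, "p_holm": float(ph)}
            for (c, t, p), ph in zip(raws, p_holm)
        ]
    )
    return ConditionAnovaResult(anova=anova, posthoc=posthoc)
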