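"""Completed trials, latency CDF, hazard curves, per-bin permutation tests."""

import numpy as np
import pandas as pd
import pytest

from cinphot import (
    ConfigError,
    DataIntegrityError,
    EventLog,
    SynthConfig,
    completed_trials,
    condition_anova,
    generate_pharm_latencies,
    hazard_rate,
    latency_cdf,
    per_bin_condition_test,
)
from cinphot.containers import LATENCY_COLUMNS


def _table(latencies, condition="vehicle", censored=None, subject="s0"):
    censored = censored or [False] * len(latencies)
    rows = [
        (f"{condition}_{subject}", subject, condition, i, lat, c)
        for i, (lat, c) in enumerate(zip(latencies, censored))
    ]
    return pd.DataFrame(rows, columns=LATENCY_COLUMNS)


class TestCompletedTrials:
    def _log(self, trials):
        """trials: list of event-type sequences; times auto-increment."""
        recs, t = [], 0.0
        for tid, seq in enumerate(trials):
            for et in seq:
                recs.append((t, et, tid, "veh", ""))
                t += 1.0
        return EventLog.from_records(recs)

    def test_counts_well_formed_trials_only(self):
        good = ["light_on", "center_in", "go_cue", "choice_in"]
        bad = ["light_on", "center_in", "timeout"]
        log = self._log([good, good, good, bad])
        count, malformed = completed_trials(log)
        assert count == 3 and malformed == []

    def test_empty_log_counts_zero(self):
        count, malformed = completed_trials(EventLog.from_records([]))
        assert count == 0 and malformed == []

    def test_timeout_disqualifies_even_full_sequence(self):
        seq = ["light_on", "center_in", "go_cue", "choice_in", "timeout"]
        count, _ = completed_trials(self._log([seq]))
        assert count == 0

    def test_malformed_order_reported_not_counted(self):
        # go cue fires before the center poke: structurally invalid trial
        recs = [
            (0.0, "light_on", 0, "", ""), (1.0, "go_cue", 0, "", ""),
            (2.0, "center_in", 0, "", ""), (3.0, "choice_in", 0, "", ""),
        ]
        count, malformed = completed_trials(EventLog.from_records(recs))
        assert count == 0 and malformed == [0]


class TestLatencyCdf:
    def test_reaches_one_at_last_latency_bin(self):
        out = latency_cdf(_table([1.1, 1.3, 2.0]), bin=0.25, min_latency=1.0)
        assert out["cdf"].iloc[-1] == pytest.approx(1.0)
        assert out.loc[out["bin_hi"] == 2.0, "cdf"].iloc[0] == pytest.approx(1.0)

    def test_short_latencies_do_not_change_cdf(self):
        a = latency_cdf(_table([1.1, 1.3, 2.0]), min_latency=1.0)
        b = latency_cdf(_table([0.5, 1.1, 1.3, 2.0]), min_latency=1.0)
        pd.testing.assert_frame_equal(a, b)

    def test_all_filtered_rejected(self):
        with pytest.raises(DataIntegrityError):
            latency_cdf(_table([0.2, 0.5]), min_latency=1.0)

    def test_geometric_latencies_match_closed_form(self):
        """Constant-hazard generator latencies reproduce 1-(1-h)^k."""
        cfg = SynthConfig(seed=17, hazard_baseline=0.2)
        tab, _ = generate_pharm_latencies(cfg, ["vehicle"], 10_000)
        out = latency_cdf(tab, bin=0.25, min_latency=None)
        k = np.arange(1, len(out) + 1)
        # condition on initiating within the cap, as the empirical CDF does
        p_obs = 1.0 - (1.0 - 0.2) ** 40
        expected = (1.0 - (1.0 - 0.2) ** k) / p_obs
        np.testing.assert_allclose(out["cdf"], expected, atol=0.02)


class TestHazardRate:
    def test_exponential_latencies_flat_hazard(self):
        """Memorylessness: constant-hazard draws give a per-bin hazard with
        no trend across bins (fitted slope ~ 0 at n = 10,000)."""
        cfg = SynthConfig(seed=23, hazard_baseline=0.15)
        tab, _ = generate_pharm_latencies(cfg, ["vehicle"], 10_000)
        hc = hazard_rate(tab, condition="vehicle")
        use = hc.at_risk > 200
        slope = np.polyfit(hc.bin_centers[use], hc.hazard[use], 1)[0]
        assert abs(slope) < 0.01  # per second
        np.testing.assert_allclose(hc.hazard[use], 0.15, atol=0.05)

    def test_all_latencies_in_one_bin_give_hazard_one(self):
        hc = hazard_rate(_table([0.1, 0.12, 0.2]), condition="vehicle")
        assert hc.hazard.tolist() == [1.0]
        assert len(hc.hazard) == 1  # no bins defined past the empty risk set

    def test_risk_set_conservation(self):
        cfg = SynthConfig(seed=29, hazard_baseline=0.1)
        tab, _ = generate_pharm_latencies(cfg, ["vehicle"], 2000)
        hc = hazard_rate(tab, condition="vehicle")
        assert hc.at_risk[0] == 2000
        np.testing.assert_array_equal(
            hc.at_risk[1:], hc.at_risk[:-1] - hc.events[:-1] - hc.censored[:-1]
        )
        assert hc.at_risk[-1] - hc.events[-1] - hc.censored[-1] == 0

    def test_hazard_multiplier_recovered(self):
        """A generator hazard halved in the 1-2 s bins shows a ~0.5 hazard
        ratio against vehicle exactly there."""
        cfg = SynthConfig(
            seed=37, hazard_baseline=0.2,
            hazard_profile={"dhbe30": {b: 0.5 for b in range(4, 8)}},
        )
        tab, _ = generate_pharm_latencies(cfg, ["vehicle", "dhbe30"], 20_000)
        curves = hazard_rate(tab)
        with np.errstate(invalid="ignore", divide="ignore"):
            ratio = curves["dhbe30"].hazard / curves["vehicle"].hazard
        np.testing.assert_allclose(ratio[4:8], 0.5, atol=0.1)
        np.testing.assert_allclose(ratio[:4], 1.0, atol=0.1)

    def test_cdf_hazard_consistency(self):
        """CDF rebuilt from the hazard curve (1 - prod(1-h)) matches the
        directly computed CDF bin for bin (uncensored data)."""
        cfg = SynthConfig(seed=41, hazard_baseline=0.3)
        tab, _ = generate_pharm_latencies(cfg, ["vehicle"], 5000)
        tab = tab[~tab["censored"]].reset_index(drop=True)
        hc = hazard_rate(tab, condition="vehicle")
        direct = latency_cdf(tab, bin=0.25, min_latency=None)
        np.testing.assert_allclose(
            hc.cdf_from_hazard(), direct["cdf"].to_numpy()[: len(hc.hazard)], atol=1e-12
        )


class TestPerBinConditionTest:
    def test_reference_against_itself_no_flags(self):
        cfg = SynthConfig(seed=43, hazard_baseline=0.2)
        tab, _ = generate_pharm_latencies(cfg, ["vehicle", "sham"], 800)
        out = per_bin_condition_test(tab, reference="vehicle", n_perm=500, seed=1)
        assert out["flag"].sum() <= 1  # at alpha=0.01 over ~tens of bins

    def test_seed_reproducible(self):
        cfg = SynthConfig(seed=47, hazard_baseline=0.2,
                          hazard_profile={"drug": {4: 0.5, 5: 0.5}})
        tab, _ = generate_pharm_latencies(cfg, ["vehicle", "drug"], 400)
        a = per_bin_condition_test(tab, n_perm=300, seed=9)
        b = per_bin_condition_test(tab, n_perm=300, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_suppressed_bins_flagged_at_large_n(self):
        cfg = SynthConfig(
            seed=53, hazard_baseline=0.25,
            hazard_profile={"drug": {b: 0.4 for b in range(4, 8)}},
        )
        tab, _ = generate_pharm_latencies(cfg, ["vehicle", "drug"], 4000)
        out = per_bin_condition_test(tab, n_perm=1000, seed=2)
        flagged = set(out.loc[out["flag"], "bin_lo"].round(2))
        assert {1.0, 1.25, 1.5, 1.75} <= flagged
        early = out[out["bin_lo"] < 1.0]
        assert not early["flag"].any()

    def test_fewer_than_two_conditions_rejected(self):
        tab = _table([1.1, 1.5, 2.0])
        with pytest.raises(ConfigError):
            per_bin_condition_test(tab, reference="vehicle")


class TestConditionAnova:
    def _counts(self, effect=0.0, n_subj=13, rng=None):
        rng = rng or np.random.default_rng(0)
        rows = []
        for s in range(n_subj):
            base = 300 + rng.normal(0, 20)
            for cond, shift in [("vehicle", 0.0), ("dhbe15", -effect / 2),
                                ("dhbe30", -effect), ("flu", -1.5 * effect)]:
                rows.append({"subject": f"s{s}", "condition": cond,
                             "count": base + shift + rng.normal(0, 10)})
        return pd.DataFrame(rows)

    def test_identical_counts_give_f_zero(self):
        rows = [{"subject": f"s{s}", "condition": c, "count": 250.0}
                for s in range(5) for c in ["vehicle", "dhbe15", "dhbe30", "flu"]]
        res = condition_anova(pd.DataFrame(rows))
        assert res.anova.F == 0.0

    def test_four_conditions_thirteen_subjects_df(self):
        res = condition_anova(self._counts(effect=30.0))
        assert (res.anova.df1, res.anova.df2) == (3, 36)

    def test_posthoc_detects_lowered_conditions(self):
        res = condition_anova(self._counts(effect=60.0))
        ph = res.posthoc.set_index("condition")
        assert ph.loc["flu", "p_holm"] < 0.01
        assert ph.loc["dhbe30", "p_holm"] < 0.05
        assert res.anova.p < 0.001

    def test_null_effect_rarely_significant(self):
        res = condition_anova(self._counts(effect=0.0,
                                           rng=np.random.default_rng(11)))
        assert res.anova.p > 0.01

    def test_missing_cells_rejected(self):
        df = self._counts().iloc[:-1]
        with pytest.raises(DataIntegrityError):
            condition_anova(df)

    def test_holm_correction_monotone(self):
        res = condition_anova(self._counts(effect=25.0))
        ph = res.posthoc
        assert (ph["p_holm"] >= ph["p_raw"] - 1e-12).all()
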