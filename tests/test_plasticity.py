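"""Evoked amplitudes, paired-pulse ratio, linear summation, RM-ANOVA."""

import itertools

import numpy as np
import pandas as pd
import pytest

from cinphot import (
    ConfigError,
    CorrectedTrace,
    DataIntegrityError,
    StimTrain,
    SynthConfig,
    generate_stim_session,
    one_way_rm_anova,
    paired_pulse_amplitudes,
    summation_ratio,
    two_way_rm_anova,
)


def quiet_config(**kw):
    base = dict(seed=2, session_duration=150.0, motion_sd=0.0, noise_sd=0.0)
    base.update(kw)
    return SynthConfig(**base)


def _segment(trace, onset, length=20.0):
    i0 = int(round(onset * trace.rate))
    i1 = i0 + int(round(length * trace.rate))
    return CorrectedTrace(times=trace.times[i0:i1] - onset,
                          dff=trace.dff[i0:i1], rate=trace.rate)


SINGLE = StimTrain(onset=10.0, pulse_width_ms=4.0, power_mw=10.0,
                   frequency_hz=0.0, n_pulses=1)


class TestEvokedAmplitude:
    def test_flat_trace_gives_zero(self):
        from cinphot import evoked_amplitude

        tr = CorrectedTrace(times=np.arange(3000) / 100.0, dff=np.zeros(3000), rate=100.0)
        assert evoked_amplitude(tr, SINGLE) == 0.0

    def test_generator_amplitude_recovered(self):
        from cinphot import evoked_amplitude

        cfg = quiet_config(transient_amplitude=0.03)
        sess = generate_stim_session(cfg, [SINGLE])
        a = evoked_amplitude(sess.evoked_trace(), SINGLE)
        assert a == pytest.approx(0.03, rel=1e-3)

    def test_window_overlapping_next_train_rejected(self):
        from cinphot import evoked_amplitude

        tr = CorrectedTrace(times=np.arange(3000) / 100.0, dff=np.zeros(3000), rate=100.0)
        with pytest.raises(DataIntegrityError):
            evoked_amplitude(tr, SINGLE, response_window=5.0, next_train_onset=12.0)

    def test_train_outside_trace_rejected(self):
        from cinphot import evoked_amplitude

        tr = CorrectedTrace(times=np.arange(500) / 100.0, dff=np.zeros(500), rate=100.0)
        with pytest.raises(DataIntegrityError):
            evoked_amplitude(tr, StimTrain(100.0, 4.0, 10.0, 0.0, 1))


class TestPairedPulse:
    def _session(self, depression, interval=1.0):
        cfg = quiet_config(depression_factor=depression,
                           depression_recovery_tau=1e12)
        pair = StimTrain(onset=60.0, pulse_width_ms=4.0, power_mw=10.0,
                         frequency_hz=1.0 / interval, n_pulses=2)
        sess = generate_stim_session(cfg, [SINGLE, pair])
        return sess.evoked_trace(), pair

    def test_linear_generator_ratio_one(self):
        tr, pair = self._session(0.0)
        res = paired_pulse_amplitudes(tr, pair, _segment(tr, SINGLE.onset))
        assert res.ratio == pytest.approx(1.0, abs=1e-6)

    def test_depression_half_gives_ratio_half(self):
        tr, pair = self._session(0.5)
        res = paired_pulse_amplitudes(tr, pair, _segment(tr, SINGLE.onset))
        assert res.ratio == pytest.approx(0.5, abs=1e-6)

    def test_long_interval_template_subtraction_negligible(self):
        """With the pulses far apart the kernel tail is gone, so template
        subtraction changes A2 by well under 1%."""
        tr, pair = self._session(0.0, interval=8.0)
        with_tmpl = paired_pulse_amplitudes(tr, pair, _segment(tr, SINGLE.onset))
        t2 = pair.pulse_times[1]
        i0 = int(round(t2 * tr.rate))
        raw_a2 = tr.dff[i0 : i0 + int(2 * tr.rate)].max()
        assert with_tmpl.a2 == pytest.approx(raw_a2, rel=0.01)

    def test_subthreshold_first_pulse_flagged(self):
        tr = CorrectedTrace(times=np.arange(20_000) / 100.0,
                            dff=np.zeros(20_000), rate=100.0)
        pair = StimTrain(60.0, 4.0, 10.0, 1.0, 2)
        res = paired_pulse_amplitudes(tr, pair, _segment(tr, 10.0), noise_floor=0.001)
        assert res.flagged and res.ratio is None


class TestSummationRatio:
    @pytest.mark.parametrize("freq", [4.0, 8.0, 16.0])
    @pytest.mark.parametrize("n_pulses", [2, 4])
    def test_linear_generator_ratio_is_one(self, freq, n_pulses):
        cfg = quiet_config(depression_factor=0.0)
        train = StimTrain(60.0, 4.0, 10.0, freq, n_pulses)
        sess = generate_stim_session(cfg, [SINGLE, train])
        tr = sess.evoked_trace()
        r = summation_ratio(_segment(tr, train.onset), _segment(tr, SINGLE.onset),
                            n_pulses, freq)
        assert abs(r - 1.0) < 1e-6

    def test_depression_drops_ratio_below_one(self):
        cfg = quiet_config(depression_factor=0.5)
        train = StimTrain(60.0, 4.0, 10.0, 8.0, 4)
        sess = generate_stim_session(cfg, [SINGLE, train])
        tr = sess.evoked_trace()
        r = summation_ratio(_segment(tr, train.onset), _segment(tr, SINGLE.onset), 4, 8.0)
        assert r < 1.0

    def test_monotone_degradation_in_depression(self):
        ratios = []
        for d in [0.0, 0.2, 0.4, 0.6, 0.8]:
            cfg = quiet_config(depression_factor=d)
            train = StimTrain(60.0, 4.0, 10.0, 16.0, 4)
            sess = generate_stim_session(cfg, [SINGLE, train])
            tr = sess.evoked_trace()
            ratios.append(
                summation_ratio(_segment(tr, train.onset), _segment(tr, SINGLE.onset),
                                4, 16.0)
            )
        assert ratios == sorted(ratios, reverse=True)

    def test_single_pulse_ratio_identically_one(self):
        cfg = quiet_config()
        sess = generate_stim_session(cfg, [SINGLE])
        tr = sess.evoked_trace()
        seg = _segment(tr, SINGLE.onset)
        assert summation_ratio(seg, seg, 1, 0.0) == pytest.approx(1.0)

    def test_nonpositive_prediction_rejected(self):
        seg = CorrectedTrace(times=np.arange(100) / 100.0, dff=np.full(100, -1.0),
                             rate=100.0)
        with pytest.raises(DataIntegrityError):
            summation_ratio(seg, seg, 4, 8.0)


def brute_force_one_way_rm(table):
    """SS decomposition by explicit loops (independent oracle)."""
    levels = sorted(table["level"].unique())
    subjects = sorted(table["subject"].unique())
    x = {(r.subject, r.level): r.value for r in table.itertuples()}
    gm = np.mean(list(x.values()))
    k, n = len(levels), len(subjects)
    ss_cond = n * sum((np.mean([x[s, l] for s in subjects]) - gm) ** 2 for l in levels)
    ss_subj = k * sum((np.mean([x[s, l] for l in levels]) - gm) ** 2 for s in subjects)
    ss_tot = sum((v - gm) ** 2 for v in x.values())
    ss_err = ss_tot - ss_cond - ss_subj
    df1, df2 = k - 1, (k - 1) * (n - 1)
    F = (ss_cond / df1) / (ss_err / df2)
    return F, df1, df2


def random_rm_table(rng, k, n):
    rows = []
    subj_eff = rng.normal(0, 1, n)
    lvl_eff = rng.normal(0, 1, k)
    for i, j in itertools.product(range(n), range(k)):
        rows.append({"subject": f"s{i}", "level": f"l{j}",
                     "value": subj_eff[i] + lvl_eff[j] + rng.normal()})
    return pd.DataFrame(rows)


class TestOneWayRmAnova:
    def test_all_levels_identical_gives_f_zero(self):
        rows = [{"subject": f"s{i}", "level": f"l{j}", "value": float(i)}
                for i in range(4) for j in range(3)]
        res = one_way_rm_anova(pd.DataFrame(rows))
        assert res.F == 0.0 and res.p == 1.0

    def test_matches_brute_force_oracle(self, rng):
        for k, n in [(3, 4), (4, 5), (5, 6), (2, 3)]:
            table = random_rm_table(rng, k, n)
            res = one_way_rm_anova(table)
            F, df1, df2 = brute_force_one_way_rm(table)
            assert res.F == pytest.approx(F, rel=1e-10)
            assert (res.df1, res.df2) == (df1, df2)

    def test_dose_response_df_structure(self, rng):
        """Four levels x five subjects gives the F(3,12) layout of a
        pulse-width dose-response design."""
        res = one_way_rm_anova(random_rm_table(rng, 4, 5))
        assert (res.df1, res.df2) == (3, 12)

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.anova import AnovaRM

        table = random_rm_table(rng, 4, 6)
        res = one_way_rm_anova(table)
        sm = AnovaRM(table, depvar="value", subject="subject",
                     within=["level"]).fit()
        assert res.F == pytest.approx(float(sm.anova_table["F Value"].iloc[0]), rel=1e-8)
        assert res.p == pytest.approx(float(sm.anova_table["Pr > F"].iloc[0]), abs=1e-10)

    def test_unbalanced_rejected(self, rng):
        table = random_rm_table(rng, 3, 4).iloc[:-1]
        with pytest.raises(DataIntegrityError):
            one_way_rm_anova(table)


def random_two_way_table(rng, a, b, n, interaction=0.0):
    rows = []
    for s, i, j in itertools.product(range(n), range(a), range(b)):
        val = rng.normal() + 0.5 * i - 0.3 * j + interaction * i * j + rng.normal(0, 0.3)
        rows.append({"subject": f"s{s}", "pulse_order": i + 1, "interval": f"i{j}",
                     "value": val})
    return pd.DataFrame(rows)


class TestTwoWayRmAnova:
    def test_all_equal_gives_all_f_zero(self):
        rows = [{"subject": f"s{s}", "pulse_order": o, "interval": f"i{i}", "value": 1.0}
                for s in range(4) for o in (1, 2) for i in range(3)]
        out = two_way_rm_anova(pd.DataFrame(rows))
        assert all(r.F == 0.0 for r in out.values())

    def test_paired_pulse_df_structure(self, rng):
        """Two pulse orders x three intervals x four subjects gives the
        interaction df (2, 6)."""
        out = two_way_rm_anova(random_two_way_table(rng, 2, 3, 4))
        assert (out["interaction"].df1, out["interaction"].df2) == (2, 6)

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.anova import AnovaRM

        table = random_two_way_table(rng, 2, 3, 5, interaction=0.4)
        out = two_way_rm_anova(table)
        sm = AnovaRM(table, depvar="value", subject="subject",
                     within=["pulse_order", "interval"]).fit().anova_table
        assert out["pulse_order"].F == pytest.approx(sm.loc["pulse_order", "F Value"], rel=1e-8)
        assert out["interval"].F == pytest.approx(sm.loc["interval", "F Value"], rel=1e-8)
        assert out["interaction"].F == pytest.approx(
            sm.loc["pulse_order:interval", "F Value"], rel=1e-8
        )

    def test_additive_effects_give_small_interaction_f(self):
        """With purely additive factor effects the interaction F stays near
        its null expectation at large n."""
        rng = np.random.default_rng(77)
        table = random_two_way_table(rng, 2, 3, 40, interaction=0.0)
        out = two_way_rm_anova(table)
        # F ~ F(2, 78) under the null; far from significance
        assert out["interaction"].p > 0.01

    def test_unbalanced_rejected(self, rng):
        table = random_two_way_table(rng, 2, 3, 4).iloc[:-1]
        with pytest.raises(DataIntegrityError):
            two_way_rm_anova(table)
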