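"""Calorimetry processing, marker tension pipeline, paired statistics."""

import numpy as np
import pytest

from exorun import analysis as an
from exorun import synth
from exorun.contact import ExotendonSpec


def make_breaths(power_w, minutes=6.0, rer=0.85, rate=0.75, mass=70.0, label="t"):
    n = int(minutes * 60 * rate)
    t = np.arange(1, n + 1) / rate
    vo2 = np.full(n, power_w * 60.0 / ((16.58 + 4.51 * rer) * 1000.0))
    return an.BreathRecord(t, vo2, vo2 * rer, label=label, body_mass_kg=mass)


class TestCalorimetry:
    def test_constant_breaths_match_closed_form(self):
        """Brockway power for constant gas exchange is hand-computable:
        1 L/min O2 at RER 0.85 -> (16.58 + 4.51*0.85) kJ/min."""
        rer = 0.85
        rec = make_breaths(500.0, rer=rer)
        hand = (16.58 + 4.51 * rer) * 1000.0 / 60.0 * rec.vo2_l_min[0]
        assert an.brockway_power_w(rec.vo2_l_min[0], rec.vco2_l_min[0]) == \
            pytest.approx(hand)
        tm = an.net_metabolic_power(rec, make_breaths(100.0, minutes=5.0))
        assert tm.gross_w_kg == pytest.approx(500.0 / 70.0, rel=1e-9)
        assert tm.net_w_kg == pytest.approx(400.0 / 70.0, rel=1e-9)

    def test_trial_equal_to_standing_nets_zero(self):
        trial = make_breaths(120.0)
        standing = make_breaths(120.0, minutes=5.0)
        tm = an.net_metabolic_power(trial, standing)
        assert tm.net_w_kg == pytest.approx(0.0, abs=1e-12)

    def test_rer_above_one_excluded(self):
        tm = an.net_metabolic_power(make_breaths(500.0, rer=1.02),
                                    make_breaths(100.0, minutes=5.0, rer=0.8))
        assert tm.excluded
        assert tm.mean_rer == pytest.approx(1.02, abs=1e-9)
        tm_ok = an.net_metabolic_power(make_breaths(500.0, rer=0.98),
                                       make_breaths(100.0, minutes=5.0, rer=0.8))
        assert not tm_ok.excluded

    def test_short_record_raises(self):
        with pytest.raises(an.InsufficientDataError):
            an.net_metabolic_power(make_breaths(500.0, minutes=0.5),
                                   make_breaths(100.0, minutes=5.0))

    def test_averaging_invariant_to_resampling(self):
        """Doubling the breath rate (same underlying power) changes the
        final-minute average by < 0.5%."""
        rng = np.random.default_rng(3)
        t1 = np.cumsum(rng.uniform(1.0, 1.6, 300))
        p = 480.0 * (1 + 0.2 * np.sin(t1 / 40.0))
        vo2 = p * 60.0 / ((16.58 + 4.51 * 0.85) * 1000.0)
        r1 = an.BreathRecord(t1, vo2, vo2 * 0.85, label="a", body_mass_kg=70.0)
        t2 = np.arange(0.4, t1[-1], 0.65)
        vo2_2 = np.interp(t2, t1, vo2)
        r2 = an.BreathRecord(t2, vo2_2, vo2_2 * 0.85, label="b", body_mass_kg=70.0)
        s = make_breaths(100.0, minutes=5.0)
        g1 = an.net_metabolic_power(r1, s).gross_w_kg
        g2 = an.net_metabolic_power(r2, s).gross_w_kg
        assert g2 == pytest.approx(g1, rel=5e-3)

    def test_percent_change_values(self):
        nat = an.TrialMetabolics(11.0, 10.0, 0.85, False)
        t1 = an.TrialMetabolics(10.0, 9.0, 0.85, False)
        t2 = an.TrialMetabolics(12.2, 11.2, 0.9, False)
        t3 = an.TrialMetabolics(12.0, 11.0, 1.05, True)
        pc = an.percent_change_by_condition({"a": t1, "b": t2, "c": t3, "d": nat}, nat)
        assert pc["a"] == pytest.approx(-10.0)
        assert pc["b"] == pytest.approx(12.0)
        assert np.isnan(pc["c"])          # excluded propagates as missing
        assert pc["d"] == pytest.approx(0.0)

    def test_natural_excluded_raises(self):
        nat = an.TrialMetabolics(11.0, 10.0, 1.02, True)
        with pytest.raises(ValueError):
            an.percent_change_by_condition({}, nat)


class TestSegmentation:
    def test_known_period_boundaries(self):
        spec = ExotendonSpec.from_percent(120, 25)
        T = 0.70
        trial, _ = synth.generate_marker_trial(spec, duration=8.0, stride_duration=T)
        b = an.segment_gait_cycles(trial)
        periods = np.diff(b) / trial.rate_hz
        assert np.all(np.abs(periods - T) <= 1.5 / trial.rate_hz)

    def test_stationary_markers_rejected(self):
        spec = ExotendonSpec.from_percent(120, 25)
        pos = np.tile([[0.0, 0.05, -0.1], [0.0, 0.05, 0.1]], (2000, 1, 1))
        trial = an.MarkerTrial(["a", "b"], pos, 200.0, spec)
        with pytest.raises(an.InsufficientDataError):
            an.segment_gait_cycles(trial)

    def test_exactly_five_cycles(self):
        spec = ExotendonSpec.from_percent(120, 25)
        # strikes sit at multiples of T; the two boundary strikes are not
        # detectable as interior minima, so 7 strides hold exactly 6
        # interior strikes = 5 full cycles
        trial, _ = synth.generate_marker_trial(spec, duration=7 * 0.70 + 0.05)
        b = an.segment_gait_cycles(trial)
        assert len(b) - 1 == 5
        res = an.tension_from_markers(trial)
        assert res.n_cycles_used == 5


class TestTensionPipeline:
    def test_noiseless_recovery(self):
        """Pipeline equals the scalar law pointwise (generative inverse)."""
        spec = ExotendonSpec.from_percent(240, 12.5)
        trial, truth = synth.generate_marker_trial(spec, duration=10.0, noise_m=0.0)
        b = an.segment_gait_cycles(trial)
        res = an.tension_from_markers(trial)
        grid = np.linspace(0, 1, an.N_CYCLE_POINTS)
        for c, (s, e) in enumerate(zip(b[:-1], b[1:])):
            expected = np.interp(grid, np.linspace(0, 1, e - s + 1), truth[s:e + 1])
            assert np.max(np.abs(res.cycle_profiles[c] - expected)) < 1e-9

    def test_all_slack_profile_zero(self):
        spec = ExotendonSpec(stiffness=120.0, slack_length=5.0)
        trial, _ = synth.generate_marker_trial(spec, duration=8.0)
        res = an.tension_from_markers(trial)
        assert np.all(res.mean_profile == 0.0)
        assert res.peak_n == 0.0

    def test_noise_propagation_bound(self):
        """Marker noise sigma changes the mean-profile peak by at most
        k * E[distance error] scale (Monte-Carlo error-propagation check)."""
        spec = ExotendonSpec.from_percent(240, 12.5)
        sigma = 0.002
        _, truth = synth.generate_marker_trial(spec, duration=12.0, noise_m=0.0)
        peak_true = truth.max()
        peaks = []
        for rep in range(10):
            trial, _ = synth.generate_marker_trial(spec, duration=12.0,
                                                   noise_m=sigma, seed=100 + rep)
            peaks.append(an.tension_from_markers(trial).peak_n)
        # distance error for two markers with isotropic noise ~ sigma*sqrt(2)
        bound = spec.stiffness * sigma * np.sqrt(2) * 5
        assert abs(np.mean(peaks) - peak_true) < bound

    def test_gap_handling(self):
        spec = ExotendonSpec.from_percent(120, 25)
        trial, _ = synth.generate_marker_trial(spec, duration=10.0)
        pos = trial.positions.copy()
        pos[300:303, 0, :] = np.nan          # short gap: interpolated
        pos[800:850, 0, :] = np.nan          # long gap: cycle dropped
        trial2 = an.MarkerTrial(trial.marker_names, pos, trial.rate_hz, spec)
        res = an.tension_from_markers(trial2, boundaries=an.segment_gait_cycles(trial))
        assert res.n_cycles_dropped >= 1
        full = an.tension_from_markers(trial, boundaries=an.segment_gait_cycles(trial))
        assert res.n_cycles_used == full.n_cycles_used - res.n_cycles_dropped


class TestPairedStats:
    def test_bonferroni_arithmetic(self):
        rng = np.random.default_rng(0)
        a = rng.normal(10, 1, 12)
        b = a + rng.normal(0.5, 0.3, 12)
        r = an.paired_comparison(a, b, m=4)
        assert r.p_corrected == pytest.approx(min(1.0, r.p_raw * 4))
        assert r.significant == (r.p_corrected < 0.05)

    def test_hand_computed_t_statistic(self):
        """5-subject toy table with a hand-computed paired t."""
        a = np.array([10.0, 11.0, 9.5, 10.5, 10.0])
        b = np.array([9.2, 10.1, 9.6, 9.9, 9.0])
        d = b - a
        t_hand = d.mean() / (d.std(ddof=1) / np.sqrt(5))
        r = an.paired_comparison(a, b, m=1)
        assert r.t_statistic == pytest.approx(t_hand, rel=1e-12)
        assert r.n == 5
        assert r.mean_difference == pytest.approx(d.mean())

    def test_shift_detected_with_power(self):
        rng = np.random.default_rng(1)
        a = rng.normal(10, 0.5, 30)
        b = a - 0.6 + rng.normal(0, 0.1, 30)
        r = an.paired_comparison(a, b, m=4)
        assert r.significant

    def test_missing_pairs_dropped_listwise(self):
        a = np.array([1.0, 2.0, np.nan, 4.0, 5.0])
        b = np.array([1.1, 2.2, 3.0, np.nan, 5.4])
        r = an.paired_comparison(a, b, m=1)
        assert r.n == 3

    def test_too_few_pairs(self):
        with pytest.raises(an.InsufficientDataError):
            an.paired_comparison([1.0, 2.0], [1.1, 2.1], m=1)

    def test_zero_variance_warns(self):
        with pytest.warns(RuntimeWarning):
            r = an.paired_comparison([1.0, 2.0, 3.0], [2.0, 3.0, 4.0], m=1)
        assert r.significant

    def test_track_family_uses_three_comparisons(self):
        df = synth.generate_track_sessions(n_runners=10, seed=2)
        res = an.track_session_compare(df)
        assert set(res) == {"time_s", "hr_bpm", "cadence_spm"}
        for r in res.values():
            assert r.m_comparisons == 3
        # identical sessions give zero differences
        df_id = df.copy()
        df_id.loc[df_id["condition"] == "exotendon",
                  ["time_s", "hr_bpm", "cadence_spm"]] = \
            df_id.loc[df_id["condition"] == "natural",
                      ["time_s", "hr_bpm", "cadence_spm"]].to_numpy()
        with pytest.warns(RuntimeWarning):
            res_id = an.track_session_compare(df_id)
        assert res_id["time_s"].mean_difference == 0.0

    def test_faster_exotendon_negative_time_difference(self):
        df = synth.generate_track_sessions(n_runners=10, seed=3,
                                           time_effect_s=-30.0, time_sd_s=1.0)
        res = an.track_session_compare(df)
        assert res["time_s"].mean_difference < 0
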