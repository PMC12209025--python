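import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from epmneg import (
    DecisionSeries,
    EffectSeries,
    RopeInterval,
    build_rope,
    contrast_over_time,
    decision_landmarks,
    default_conventional_config,
    default_params,
    fit_conventional_effects,
    fit_neg_effects,
    sexit,
    simulate_conventional,
    simulate_neg,
)


def effect_series(draws, times=None):
    draws = np.atleast_2d(np.asarray(draws, float))
    if draws.shape[0] == 1:
        draws = draws.T  # single timepoint column
    times = np.arange(draws.shape[1], dtype=float) if times is None else times
    return EffectSeries("a - b", times, draws, draws / 100.0)


class TestBuildRope:
    def test_linear_rule(self):
        rope = build_rope("linear", sd_y=50.0)
        assert (rope.low, rope.high) == (-5.0, 5.0)

    def test_growth_rule_is_published_band(self):
        rope = build_rope("growth")
        assert (rope.low, rope.high) == (-0.18, 0.18)
        assert rope.scale == "response"

    @pytest.mark.parametrize("sd", [None, 0.0, -1.0])
    def test_degenerate_linear_sd_rejected(self, sd):
        with pytest.raises(ValueError):
            build_rope("linear", sd_y=sd)

    def test_rope_must_straddle_zero(self):
        with pytest.raises(ValueError):
            RopeInterval(0.1, 0.2)


class TestSexit:
    def test_all_zero_draws_equivalent_with_pd_half(self):
        dec = sexit(effect_series(np.zeros((200, 3))), build_rope("growth"))
        assert list(dec.decision) == ["equivalent"] * 3
        assert np.all(dec.pd == 0.5)
        assert np.all(dec.rope_frac == 1.0)

    def test_large_effect_not_equivalent_with_pd_one(self):
        draws = np.full((200, 2), 10 * 18.0)  # ten ROPE widths, percent scale
        dec = sexit(effect_series(draws), build_rope("growth"))
        assert list(dec.decision) == ["not-equivalent"] * 2
        assert np.all(dec.pd == 1.0)

    def test_half_inside_is_undecided(self):
        draws = np.concatenate([np.zeros(100), np.full(100, 50.0)])[:, None]
        dec = sexit(effect_series(draws.T), build_rope("growth"))
        assert dec.decision[0] == "undecided"
        assert dec.rope_frac[0] == pytest.approx(0.5)

    @given(
        frac=st.floats(min_value=0.0, max_value=1.0),
        n=st.integers(min_value=40, max_value=400),
    )
    @settings(max_examples=50, deadline=None)
    def test_decision_partition_is_exact(self, frac, n):
        """Every inside-fraction maps to exactly one decision state."""
        k = int(round(frac * n))
        draws = np.concatenate([np.zeros(k), np.full(n - k, 100.0)])[:, None]
        dec = sexit(effect_series(draws.T), build_rope("growth"))
        inside = dec.rope_frac[0]
        expected = (
            "equivalent" if inside > 0.975
            else "not-equivalent" if inside < 0.025
            else "undecided"
        )
        assert dec.decision[0] == expected

    def test_hdi_mass_close_to_nominal(self):
        rng = np.random.default_rng(0)
        draws = rng.normal(0, 1, size=(4000, 1))
        dec = sexit(effect_series(draws), build_rope("growth"))
        inside = np.mean((draws[:, 0] >= dec.hdi_low[0]) & (draws[:, 0] <= dec.hdi_high[0]))
        assert abs(inside - 0.95) < 0.02

    def test_logit_scale_rope_uses_logit_draws(self):
        pct = np.full((100, 1), 30.0)
        series = EffectSeries("a - b", np.array([0.0]), pct, np.full((100, 1), 0.05))
        dec = sexit(series, RopeInterval(-0.18, 0.18, scale="logit"))
        assert dec.decision[0] == "equivalent"  # logit diff inside the band


class TestDecisionLandmarks:
    def make_decisions(self, states):
        n = len(states)
        z = np.zeros(n)
        return DecisionSeries(
            "c", np.arange(n, dtype=float), z, z, z, z + 0.5, z, np.array(states)
        )

    def test_always_equivalent_has_no_landmarks(self):
        lm = decision_landmarks(self.make_decisions(["equivalent"] * 10))
        assert lm["significance_onset"] is None
        assert lm["return_to_equivalence"] is None
        assert lm["initial_equivalent_duration"] == 9.0

    def test_step_series_landmarks_at_known_indices(self):
        states = ["equivalent"] * 5 + ["not-equivalent"] * 3 + ["equivalent"] * 4
        lm = decision_landmarks(self.make_decisions(states))
        assert lm["significance_onset"] == 5.0
        assert lm["return_to_equivalence"] == 8.0
        assert lm["initial_equivalent_duration"] == 5.0
        assert lm["state_durations"]["not-equivalent"] == 3.0


class TestNegEffectModel:
    @pytest.fixture(scope="class")
    def cohorts(self, geometry):
        return {
            p: simulate_neg(default_params(p), geometry, 6, seed=50 + i)
            for i, p in enumerate(("exploratory", "avoidant"))
        }

    def test_single_group_rejected(self, geometry, cohorts):
        with pytest.raises(ValueError):
            fit_neg_effects({"a": cohorts["avoidant"]["open"]}, 100)

    def test_unknown_group_label_rejected(self, geometry, cohorts):
        model = fit_neg_effects(
            {"exploratory": cohorts["exploratory"]["open"],
             "avoidant": cohorts["avoidant"]["open"]},
            n_segments=100, seed=0,
        )
        with pytest.raises(KeyError):
            contrast_over_time(model, ("exploratory", "bold"))

    def test_self_contrast_identically_zero(self, geometry, cohorts):
        model = fit_neg_effects(
            {"exploratory": cohorts["exploratory"]["open"],
             "avoidant": cohorts["avoidant"]["open"]},
            n_segments=100, seed=0,
        )
        eff = contrast_over_time(model, ("avoidant", "avoidant"))
        assert np.all(eff.draws_percent == 0)

    def test_contrast_linearity_identity(self, geometry):
        groups = {
            p: simulate_neg(default_params(p), geometry, 4, seed=60)["open"]
            for p in ("exploratory", "delayed", "avoidant")
        }
        model = fit_neg_effects(groups, n_segments=100, seed=1, n_draws=500)
        t = np.array([0.0, 100.0, 250.0])
        ab = contrast_over_time(model, ("exploratory", "delayed"), t).draws_percent
        bc = contrast_over_time(model, ("delayed", "avoidant"), t).draws_percent
        ac = contrast_over_time(model, ("exploratory", "avoidant"), t).draws_percent
        np.testing.assert_allclose(ab + bc, ac, atol=1e-9)

    def test_identical_groups_centred_at_zero_and_null_calibrated(self, geometry):
        """Two cohorts simulated from the same phenotype: the contrast stays
        centred at zero and almost never leaves the ROPE."""
        rates = []
        for seed in (0, 1, 2):
            a = simulate_neg(default_params("exploratory"), geometry, 6, seed=70 + seed)
            b = simulate_neg(default_params("exploratory"), geometry, 6, seed=170 + seed)
            model = fit_neg_effects(
                {"a": a["open"], "b": b["open"]}, n_segments=100, seed=seed
            )
            dec = sexit(contrast_over_time(model, ("a", "b")), build_rope("growth"))
            assert np.abs(np.median(dec.median)) < 10.0
            rates.append(np.mean(dec.decision == "not-equivalent"))
        assert np.mean(rates) <= 0.05

    def test_avoidant_arm_contrast_reaches_minus_closed(self, geometry):
        """For the avoidant phenotype the open - closed contrast approaches
        -100% of closed NEG and locks in as not-equivalent."""
        cohort = simulate_neg(default_params("avoidant"), geometry, 6, seed=80)
        model = fit_neg_effects(
            {"open": cohort["open"], "closed": cohort["closed"]},
            n_segments=100, seed=2,
        )
        dec = sexit(contrast_over_time(model, ("open", "closed")), build_rope("growth"))
        assert dec.median[-1] < -90.0
        lm = decision_landmarks(dec)
        assert lm["significance_onset"] is not None
        # Once the closed arms are explored past the ROPE width, the contrast
        # stays not-equivalent to the end of the test.
        onset_idx = np.nonzero(dec.decision == "not-equivalent")[0][0]
        assert np.all(dec.decision[onset_idx + 30 :] == "not-equivalent")


class TestPlotting:
    def test_decision_ribbon_renders(self):
        import matplotlib

        matplotlib.use("Agg")
        from epmneg import plot_decision_series

        n = 50
        times = np.arange(n, dtype=float)
        median = np.linspace(0, 40, n)
        dec = DecisionSeries(
            "a - b", times, median, median - 5, median + 5,
            np.full(n, 0.9), np.linspace(1, 0, n),
            np.where(median > 18, "not-equivalent", "equivalent"),
        )
        ax = plot_decision_series(dec)
        assert ax.get_xlabel() == "time (s)"
        assert len(ax.lines) >= 3


class TestConventionalEffects:
    @pytest.fixture(scope="class")
    def decisions(self):
        draws = simulate_conventional(default_conventional_config(), seed=5)
        return fit_conventional_effects(draws, seed=6)

    def test_avoidant_differs_on_all_measures(self, decisions):
        for measure in ("latency_open", "entries_open", "time_open"):
            for pair, dec in decisions[measure].items():
                if "avoidant" in pair:
                    assert dec.decision[0] == "not-equivalent", (measure, pair)

    def test_delayed_exploratory_differ_only_in_latency(self, decisions):
        key = "exploratory vs delayed"
        assert decisions["latency_open"][key].decision[0] == "not-equivalent"
        assert decisions["entries_open"][key].decision[0] == "equivalent"
        assert decisions["time_open"][key].decision[0] == "equivalent"

    def test_pd_bounded_in_half_one(self, decisions):
        for measure in decisions.values():
            for dec in measure.values():
                assert 0.5 <= dec.pd[0] <= 1.0
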