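import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tavicea import (
    IntervalProbabilityTable,
    TimeInterval,
    ValidationError,
    extend_event_rates,
    extrapolate_mortality,
    interval_to_cycle_probability,
    load_parameter_set,
)
from tavicea.parameters import cycle_sequence

MORT_BANDS = [(1, 1), (2, 6), (7, 12), (13, 24), (25, 36), (37, 48), (49, 60)]


def mortality_table(band_probs, arm="tavi"):
    return IntervalProbabilityTable(
        event="mortality",
        arm=arm,
        entries=tuple(
            (TimeInterval(s, e), p) for (s, e), p in zip(MORT_BANDS, band_probs)
        ),
    )


class TestIntervalToCycle:
    @pytest.mark.parametrize(
        "p, n, expected",
        [
            (0.039, 5, 0.007924607421869068),  # 1 - 0.961**(1/5)
            (0.0, 7, 0.0),
            (0.25, 1, 0.25),
            (1.0, 1, 1.0),
            (1.0, 12, 1.0),  # certain event stays certain per cycle
        ],
    )
    def test_values(self, p, n, expected):
        assert interval_to_cycle_probability(p, n) == pytest.approx(expected, abs=1e-15)

    @pytest.mark.parametrize("p, n", [(-0.1, 3), (1.1, 3), (0.5, 0)])
    def test_rejects_bad_inputs(self, p, n):
        with pytest.raises(ValueError):
            interval_to_cycle_probability(p, n)

    @given(
        p=st.floats(min_value=0.0, max_value=0.999),
        n=st.integers(min_value=1, max_value=60),
    )
    @settings(max_examples=200, deadline=None)
    def test_round_trip(self, p, n):
        """Compounding the per-cycle probability over the interval recovers
        the interval probability."""
        pc = interval_to_cycle_probability(p, n)
        assert 0.0 <= pc <= 1.0
        assert 1.0 - (1.0 - pc) ** n == pytest.approx(p, abs=1e-12)


class TestMortalityExtrapolation:
    def test_flat_annual_trend_stays_flat(self):
        table = mortality_table([0.008, 0.04, 0.05, 0.10, 0.10, 0.10, 0.10])
        seq, warnings = extrapolate_mortality(table, 180)
        monthly = interval_to_cycle_probability(0.10, 12)
        assert seq.shape == (180,)
        assert not warnings
        # years 6-15 continue the constant 10%/year
        assert np.allclose(seq[60:], monthly, atol=1e-12)

    def test_hand_least_squares_fit(self):
        """Annual probabilities 8.0/8.7/9.5/10.5% over years 2-5 give a
        year-6 value of 11.25% on the hand-fitted line."""
        table = mortality_table([0.01, 0.04, 0.04, 0.080, 0.087, 0.095, 0.105])
        seq, _ = extrapolate_mortality(table, 180)
        year6_monthly = interval_to_cycle_probability(0.1125, 12)
        assert seq[60:72] == pytest.approx(year6_monthly, abs=1e-12)

    def test_observed_window_uses_interval_conversion(self):
        table = mortality_table([0.02, 0.10, 0.08, 0.12, 0.12, 0.12, 0.12])
        seq, _ = extrapolate_mortality(table, 180)
        assert seq[0] == 0.02
        assert seq[1:6] == pytest.approx(interval_to_cycle_probability(0.10, 5))
        assert seq[6:12] == pytest.approx(interval_to_cycle_probability(0.08, 6))

    def test_trend_clamped_at_certainty(self):
        table = mortality_table([0.05, 0.2, 0.2, 0.40, 0.55, 0.70, 0.85])
        seq, warnings = extrapolate_mortality(table, 180)
        assert warnings, "clamping should be reported"
        # once the fitted annual trend passes 1, cycles are certain death
        assert seq[-12:] == pytest.approx(1.0)
        assert seq.max() <= 1.0 and seq.min() >= 0.0

    def test_cumulative_mode_monotone(self):
        table = mortality_table([0.02, 0.05, 0.05, 0.08, 0.09, 0.10, 0.11])
        seq, _ = extrapolate_mortality(table, 180, mode="cumulative")
        surv = np.cumprod(1.0 - seq)
        assert seq.min() >= 0 and seq.max() <= 1
        assert np.all(np.diff(surv) <= 1e-15)

    def test_horizon_shorter_than_observation(self):
        table = mortality_table([0.02, 0.05, 0.05, 0.08, 0.09, 0.10, 0.11])
        seq, _ = extrapolate_mortality(table, 24)
        assert seq.shape == (24,)


class TestEventCarryForward:
    def test_degenerate_single_band(self):
        table = IntervalProbabilityTable(
            "hosp_as", "tavi", ((TimeInterval(1, 24), 0.05),)
        )
        seq = extend_event_rates(table, 60)
        monthly = interval_to_cycle_probability(0.05, 24)
        assert np.allclose(seq, monthly)

    def test_all_zero(self):
        table = IntervalProbabilityTable(
            "hosp_as", "tavi",
            ((TimeInterval(1, 1), 0.0), (TimeInterval(2, 24), 0.0)),
        )
        assert not extend_event_rates(table, 180).any()

    def test_fixture_pacemaker_carry_forward(self, intermediate_base):
        """Beyond month 24 the TAVI pacemaker rate equals the converted
        13-24-month band value (0.1% over 12 months)."""
        table = intermediate_base.events["tavi"]["new_pacemaker"]
        seq = extend_event_rates(table, 180)
        expected = interval_to_cycle_probability(0.001, 12)
        assert np.allclose(seq[24:], expected, atol=1e-15)

    def test_empty_table_rejected(self):
        table = IntervalProbabilityTable("hosp_as", "tavi", ())
        with pytest.raises(ValidationError):
            extend_event_rates(table, 10)

    @given(
        probs=st.lists(st.floats(0.0, 1.0), min_size=4, max_size=4),
        horizon=st.integers(min_value=24, max_value=240),
    )
    @settings(max_examples=100, deadline=None)
    def test_sequence_bounds_and_length(self, probs, horizon):
        bands = [(1, 1), (2, 6), (7, 12), (13, 24)]
        table = IntervalProbabilityTable(
            "hosp_as", "tavi",
            tuple((TimeInterval(s, e), p) for (s, e), p in zip(bands, probs)),
        )
        seq = extend_event_rates(table, horizon)
        assert seq.shape == (horizon,)
        assert seq.min() >= 0.0 and seq.max() <= 1.0


class TestLoader:
    def test_intermediate_index_costs(self, intermediate_base):
        assert intermediate_base.costs.index_costs["tavi"] == 30634
        assert intermediate_base.costs.index_costs["savr"] == 24675

    def test_inoperable_valvuloplasty_month1(self, inoperable_base):
        table = inoperable_base.events["medical"]["balloon_valvuloplasty"]
        (iv, p) = table.entries[0]
        assert (iv.start_month, iv.end_month) == (1, 1)
        assert p == pytest.approx(0.67)

    def test_medical_arm_has_no_procedure_cost(self, inoperable_base):
        assert inoperable_base.costs.index_costs["medical"] == 0.0

    def test_unknown_fixture(self):
        with pytest.raises(ValidationError, match="unknown fixture"):
            load_parameter_set("nope")

    def test_unknown_risk_group(self):
        with pytest.raises(ValidationError):
            load_parameter_set("intermediate_base", overrides={"risk_group": "low"})

    def test_stroke_cost_present(self, intermediate_base):
        assert intermediate_base.costs.unit_costs["major_stroke"] == 19624


class TestValidation:
    def test_probability_out_of_range(self, intermediate_base):
        bad = intermediate_base.copy()
        table = bad.events["tavi"]["mortality"]
        probs = [p for _, p in table.entries]
        probs[0] = 1.2
        bad.events["tavi"]["mortality"] = table.with_probabilities(probs)
        with pytest.raises(ValidationError, match="mortality/tavi"):
            bad.validate()

    def test_non_contiguous_bands(self):
        with pytest.raises(ValidationError, match="not contiguous"):
            IntervalProbabilityTable(
                "hosp_as", "tavi",
                ((TimeInterval(1, 1), 0.1), (TimeInterval(3, 24), 0.1)),
            ).validate()

    def test_missing_event_column(self, intermediate_base):
        bad = intermediate_base.copy()
        del bad.events["tavi"]["endocarditis"]
        with pytest.raises(ValidationError, match="endocarditis"):
            bad.validate()

    @given(data=st.data())
    @settings(max_examples=30, deadline=None)
    def test_random_violations_rejected(self, data, intermediate_base):
        """Any single injected invariant violation fails the validate() gate."""
        bad = intermediate_base.copy()
        kind = data.draw(st.sampled_from(
            ["prob_range", "negative_cost", "utility_order", "nyha_rows"]
        ))
        if kind == "prob_range":
            arm = data.draw(st.sampled_from(bad.settings.arms))
            event = data.draw(st.sampled_from(sorted(bad.events[arm])))
            table = bad.events[arm][event]
            i = data.draw(st.integers(0, len(table.entries) - 1))
            probs = [p for _, p in table.entries]
            probs[i] = data.draw(st.sampled_from([-0.1, 1.5]))
            bad.events[arm][event] = table.with_probabilities(probs)
        elif kind == "negative_cost":
            item = data.draw(st.sampled_from(sorted(bad.costs.unit_costs)))
            bad.costs.unit_costs[item] = -1.0
        elif kind == "utility_order":
            arm = data.draw(st.sampled_from(bad.settings.arms))
            nyha = data.draw(st.integers(1, 4))
            bad.utilities.values[(nyha, True, arm)] = (
                bad.utilities.values[(nyha, False, arm)] + 0.05
            )
            if bad.utilities.values[(nyha, True, arm)] > 1.0:
                bad.utilities.values[(nyha, False, arm)] -= 0.1
        else:
            arm = data.draw(st.sampled_from(bad.settings.arms))
            m = np.array(bad.nyha_transitions[arm], copy=True)
            m[0, 0, 0] += 0.2
            bad.nyha_transitions[arm] = m
        with pytest.raises(ValidationError):
            bad.validate()

    def test_percent_and_fraction_scales_agree(self, tmp_path, intermediate_base):
        from tavicea.synthetic_data import write_parameter_csvs

        paths = write_parameter_csvs(intermediate_base, tmp_path)
        loaded = load_parameter_set({
            "risk_group": "intermediate",
            "events": str(paths["events"]),
            "costs": str(paths["costs"]),
            "utilities": str(paths["utilities"]),
            "nyha_transitions": str(paths["nyha_transitions"]),
            "percent": False,
        })
        orig = intermediate_base.events["tavi"]["mortality"].entries
        assert loaded.events["tavi"]["mortality"].entries == orig
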