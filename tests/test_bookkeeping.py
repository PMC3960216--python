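import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pemrelease.bookkeeping import (
    CoatingRun,
    CoatingStep,
    DrugContent,
    SamplingProtocol,
    cumulative_mass_released,
    drug_loading,
    encapsulation_efficiency,
    loss_adjusted_release,
    loss_summary,
    mean_total_loss,
    percent_release,
    read_coating_runs,
    render_percent,
    summarize_coating_runs,
)
from tests._oracles import brute_force_cumulative, explicit_loss_ledger


class TestCumulativeRelease:
    def test_single_time_point_is_vessel_mass(self):
        p = SamplingProtocol(V_total=1.0, V_aliquot=0.1, times=(1.0,))
        assert cumulative_mass_released([3.0], p).tolist() == [3.0]

    def test_all_zero_concentrations(self):
        p = SamplingProtocol(V_total=1.0, V_aliquot=0.1, times=(1.0, 2.0, 3.0))
        assert cumulative_mass_released([0, 0, 0], p).tolist() == [0, 0, 0]

    def test_three_point_schedule_matches_mass_balance_oracle(self):
        p = SamplingProtocol(V_total=1.0, V_aliquot=0.2, times=(1.0, 2.0, 3.0))
        conc = [5.0, 3.0, 7.0]
        np.testing.assert_allclose(
            cumulative_mass_released(conc, p),
            brute_force_cumulative(conc, 1.0, 0.2),
        )

    @settings(max_examples=1000, derandomize=True)
    @given(
        conc=st.lists(st.floats(0.0, 100.0), min_size=1, max_size=12),
        v_total=st.floats(0.5, 10.0),
        frac=st.floats(0.01, 1.0),
    )
    def test_equals_withdraw_replenish_simulation(self, conc, v_total, frac):
        v_aliquot = frac * v_total
        times = tuple(float(i + 1) for i in range(len(conc)))
        p = SamplingProtocol(V_total=v_total, V_aliquot=v_aliquot, times=times)
        np.testing.assert_allclose(
            cumulative_mass_released(conc, p),
            brute_force_cumulative(conc, v_total, v_aliquot),
            rtol=1e-12, atol=1e-12,
        )

    def test_uncorrected_mode_reports_vessel_mass_only(self):
        p = SamplingProtocol(V_total=2.0, V_aliquot=0.5, times=(1.0, 2.0))
        out = cumulative_mass_released([1.0, 1.0], p, correct_for_sampling=False)
        assert out.tolist() == [2.0, 2.0]

    def test_negative_concentration_is_data_error(self):
        p = SamplingProtocol(V_total=1.0, V_aliquot=0.1, times=(1.0,))
        with pytest.raises(ValueError, match="non-negative"):
            cumulative_mass_released([-0.1], p)

    def test_requires_one_concentration_per_time(self):
        p = SamplingProtocol(V_total=1.0, V_aliquot=0.1, times=(1.0, 2.0))
        with pytest.raises(ValueError, match="one concentration"):
            cumulative_mass_released([1.0], p)

    def test_protocol_validation(self):
        with pytest.raises(ValueError, match="V_aliquot"):
            SamplingProtocol(V_total=1.0, V_aliquot=2.0, times=(1.0,))
        with pytest.raises(ValueError, match="increasing"):
            SamplingProtocol(V_total=1.0, V_aliquot=0.1, times=(2.0, 1.0))


class TestPercentages:
    def test_twenty_micrograms_of_hundred_reads_twenty_percent(self):
        assert render_percent(percent_release(20.0, 100.0)) == "20.0"

    def test_five_micrograms_of_postloss_content_reads_5_9(self):
        assert render_percent(percent_release(5.0, 85.0)) == "5.9"

    def test_zero_release_is_zero_percent(self):
        assert percent_release(0.0, 50.0) == 0.0

    def test_zero_content_is_undefined(self):
        with pytest.raises(ValueError, match="content"):
            percent_release(5.0, 0.0)

    def test_loss_adjustment_reproduces_masquerade_illustration(self):
        # 100 ug load: 20 ug released reads 20%; lose 15 ug during coating and
        # a 5 ug release reads 5.9% of the remaining 85 ug
        assert render_percent(loss_adjusted_release(5.0, 100.0, 15.0)) == "5.9"

    def test_no_loss_reduces_to_plain_percent(self):
        assert loss_adjusted_release(7.0, 140.0, 0.0) == percent_release(7.0, 140.0)

    @settings(max_examples=200, derandomize=True)
    @given(
        release=st.floats(0.0, 50.0),
        content=st.floats(60.0, 500.0),
        loss_pct=st.floats(0.0, 60.0),
    )
    def test_loss_adjustment_agrees_with_explicit_ledger(self, release, content, loss_pct):
        loss_mass = content * loss_pct / 100.0
        assert loss_adjusted_release(release, content, loss_pct) == pytest.approx(
            explicit_loss_ledger(release, content, loss_mass)
        )

    def test_total_loss_is_rejected(self):
        with pytest.raises(ValueError, match="loss_percent"):
            loss_adjusted_release(1.0, 100.0, 100.0)

    @settings(max_examples=200, derandomize=True)
    @given(
        drug=st.floats(0.1, 100.0),
        particles=st.floats(0.1, 1000.0),
        scale=st.floats(1e-3, 1e3),
    )
    def test_percentages_are_scale_invariant(self, drug, particles, scale):
        a = DrugContent(mass_drug=drug, mass_particles=particles, theoretical_mass=2 * drug)
        b = DrugContent(
            mass_drug=drug * scale,
            mass_particles=particles * scale,
            theoretical_mass=2 * drug * scale,
        )
        assert drug_loading(a) == pytest.approx(drug_loading(b))
        assert encapsulation_efficiency(a) == pytest.approx(encapsulation_efficiency(b))
        assert percent_release(drug, particles) == pytest.approx(
            percent_release(drug * scale, particles * scale)
        )

    def test_loading_and_efficiency_definitions(self):
        content = DrugContent(mass_drug=7.6, mass_particles=100.0, theoretical_mass=11.18)
        assert drug_loading(content) == pytest.approx(7.6)
        assert encapsulation_efficiency(content) == pytest.approx(67.98, abs=0.01)

    def test_loading_bounds(self):
        full = DrugContent(mass_drug=5.0, mass_particles=5.0, theoretical_mass=5.0)
        assert drug_loading(full) == 100.0
        empty = DrugContent(mass_drug=0.0, mass_particles=5.0, theoretical_mass=5.0)
        assert drug_loading(empty) == 0.0
        assert encapsulation_efficiency(empty) == 0.0

    def test_zero_denominators_are_errors(self):
        c = DrugContent(mass_drug=1.0, mass_particles=0.0, theoretical_mass=0.0)
        with pytest.raises(ValueError):
            drug_loading(c)
        with pytest.raises(ValueError):
            encapsulation_efficiency(c)

    def test_overload_flagged_not_fatal(self):
        c = DrugContent(mass_drug=12.0, mass_particles=100.0, theoretical_mass=10.0)
        assert c.content_exceeds_theoretical


class TestRendering:
    @pytest.mark.parametrize(
        "value,expected",
        [
            (5.882352941, "5.9"),
            (20.0, "20.0"),
            (5.43333, "5.4"),
            (2.4, "2.4"),
            (0.2, "0.2"),
            (1.4, "1.4"),
            (1.9, "1.9"),
            (0.25, "0.3"),  # half rounds away from zero
            (-0.25, "-0.3"),
        ],
    )
    def test_one_decimal_half_away_from_zero(self, value, expected):
        assert render_percent(value) == expected


class TestCoatingLoss:
    def _run(self, steps, content=100.0, condition="PAH/PSS @ 9"):
        return CoatingRun(condition=condition, steps=steps, content_basis=content)

    def test_high_ph_signature_wash_below_adsorption(self):
        run = self._run([CoatingStep("adsorption", 1, 2.4), CoatingStep("wash", 1, 0.2)])
        summary = loss_summary(run)
        assert summary.per_step["percent"].tolist() == [2.4, 0.2]
        assert not summary.wash_exceeds_adsorption

    def test_low_ph_signature_wash_above_adsorption(self):
        run = self._run(
            [CoatingStep("adsorption", 1, 1.4), CoatingStep("wash", 1, 1.9)],
            condition="PAH/PSS @ 4",
        )
        summary = loss_summary(run)
        assert summary.per_step["percent"].tolist() == [1.4, 1.9]
        assert summary.wash_exceeds_adsorption

    def test_zero_loss_run_totals_zero(self):
        run = self._run([CoatingStep("adsorption", 1, 0.0)])
        assert loss_summary(run).total_percent == 0.0

    def test_empty_run_gives_empty_summary(self):
        summary = loss_summary(self._run([]))
        assert summary.per_step.empty and summary.total_percent == 0.0

    def test_per_layer_totals_sum_steps(self):
        run = self._run(
            [
                CoatingStep("adsorption", 1, 2.0),
                CoatingStep("wash", 1, 1.0),
                CoatingStep("adsorption", 2, 0.5),
            ]
        )
        summary = loss_summary(run)
        assert summary.per_layer.set_index("layer")["percent"].to_dict() == {1: 3.0, 2: 0.5}
        assert summary.total_percent == pytest.approx(3.5)

    def test_printed_totals_average_to_5_4(self):
        assert render_percent(mean_total_loss([8.0, 5.4, 6.8, 3.7, 5.0, 3.7])) == "5.4"

    def test_mean_of_single_and_equal_values(self):
        assert mean_total_loss([4.2]) == 4.2
        assert mean_total_loss([3.0, 3.0, 3.0]) == 3.0

    def test_mean_of_nothing_is_an_error(self):
        with pytest.raises(ValueError):
            mean_total_loss([])

    def test_step_and_run_validation(self):
        with pytest.raises(ValueError, match="kind"):
            CoatingStep("rinse", 1, 0.1)
        with pytest.raises(ValueError, match="non-decreasing"):
            CoatingRun(
                "x",
                (CoatingStep("adsorption", 2, 0.1), CoatingStep("wash", 1, 0.1)),
                content_basis=100.0,
            )

    def test_csv_round_trip_and_grid_summary(self, tmp_path):
        csv = tmp_path / "runs.csv"
        csv.write_text(
            "condition,layer,step,loss_mass\n"
            "PAH/PSS @ NA,1,adsorption,5.0\n"
            "PAH/PSS @ NA,1,wash,3.0\n"
            "PLL/DES @ 4,1,adsorption,1.4\n"
            "PLL/DES @ 4,1,wash,2.3\n"
        )
        runs = read_coating_runs(csv, content_basis=100.0)
        assert [r.condition for r in runs] == ["PAH/PSS @ NA", "PLL/DES @ 4"]
        grid = summarize_coating_runs(runs)
        assert grid.loc["NA", "PAH/PSS"] == pytest.approx(8.0)
        assert grid.loc["4", "PLL/DES"] == pytest.approx(3.7)
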