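"""Activity budgets, daily energy expenditure and tagged/untagged ratios."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import tagburden as tb
from tagburden.energetics import DAY_LENGTH_S
from tagburden.errors import BudgetError, UndefinedRatioError

AREA_GEOM = tb.SharkGeometry(fork_length=2.95, frontal_area=0.12)


class TestBuildBudget:
    def test_no_burst_endpoint(self):
        b = tb.build_budget(0.0, 3.6)
        assert b.glide_fraction == 0.07
        assert b.burst_fraction == 0.0
        assert b.cruise_fraction == pytest.approx(0.93, abs=1e-12)

    def test_max_default_burst(self):
        assert tb.build_budget(0.20, 9.1).cruise_fraction == pytest.approx(0.73)

    def test_boundary_all_burst(self):
        assert tb.build_budget(0.93, 3.6).cruise_fraction == 0.0

    def test_overfull_budget_rejected(self):
        with pytest.raises(BudgetError):
            tb.build_budget(0.95, 3.6)

    def test_burst_slower_than_cruise_rejected(self):
        with pytest.raises(BudgetError):
            tb.build_budget(0.1, burst_speed=0.5, cruise_speed=1.0)


class TestDailyEnergy:
    def test_cruise_only_hand_evaluation(self, fluid, tables):
        """0.93 day cruising against a 6.027 N drag force at 1 m/s."""
        b = tb.build_budget(0.0, 3.6)
        res = tb.daily_energy(b, tables["none"], fluid, AREA_GEOM)
        assert res.energy_per_behaviour["glide"] == 0.0
        assert res.energy_per_behaviour["burst"] == 0.0
        assert res.total_energy == pytest.approx(4.8428e5, rel=1e-4)

    def test_glide_always_zero_and_total_is_sum(self, fluid, tables):
        b = tb.build_budget(0.10, 5.0)
        res = tb.daily_energy(b, tables["fin_mount"], fluid, AREA_GEOM)
        assert res.energy_per_behaviour["glide"] == 0.0
        assert res.total_energy == pytest.approx(
            sum(res.energy_per_behaviour.values())
        )
        assert all(v >= 0 for v in res.energy_per_behaviour.values())

    def test_all_glide_gives_zero(self, fluid, tables):
        b = tb.ActivityBudget(
            glide_fraction=1.0, burst_fraction=0.0, cruise_fraction=0.0
        )
        assert tb.daily_energy(b, tables["none"], fluid, AREA_GEOM).total_energy == 0.0

    def test_linear_in_day_length(self, fluid, tables):
        b1 = tb.build_budget(0.05, 3.6)
        b2 = tb.build_budget(0.05, 3.6, day_length=2 * DAY_LENGTH_S)
        e1 = tb.daily_energy(b1, tables["none"], fluid, AREA_GEOM).total_energy
        e2 = tb.daily_energy(b2, tables["none"], fluid, AREA_GEOM).total_energy
        assert e2 == pytest.approx(2 * e1, rel=1e-12)


class TestEnergyIncrease:
    def test_fin_mount_cruise_only(self, fluid, tables):
        """The cruise-only fin-mount penalty is the 1 m/s coefficient ratio."""
        b = tb.build_budget(0.0, 3.6)
        pct = tb.energy_increase(b, tables["none"], tables["fin_mount"], fluid, AREA_GEOM)
        assert pct == pytest.approx(100 * (0.118 / 0.098 - 1), rel=1e-9)
        assert pct == pytest.approx(20.41, abs=0.005)

    def test_archival_cruise_only_zero_at_table_precision(self, fluid, tables):
        b = tb.build_budget(0.0, 3.6)
        pct = tb.energy_increase(
            b, tables["none"], tables["archival_body"], fluid, AREA_GEOM
        )
        assert pct == pytest.approx(0.0, abs=1e-9)

    def test_identical_tables_zero(self, fluid, tables):
        b = tb.build_budget(0.10, 5.0)
        assert tb.energy_increase(
            b, tables["none"], tables["none"], fluid, AREA_GEOM
        ) == pytest.approx(0.0)

    def test_all_glide_undefined(self, fluid, tables):
        b = tb.ActivityBudget(
            glide_fraction=1.0, burst_fraction=0.0, cruise_fraction=0.0
        )
        with pytest.raises(UndefinedRatioError):
            tb.energy_increase(b, tables["none"], tables["fin_mount"], fluid, AREA_GEOM)

    @given(
        area=st.floats(0.01, 1.0),
        rho=st.floats(500.0, 1500.0),
        day=st.floats(1.0, 1e6),
        fb=st.floats(0.0, 0.2),
    )
    def test_area_density_daylength_cancel(self, tables, area, rho, day, fb):
        """Percent energy increase is bit-identical under any positive
        rescaling of frontal area, water density or day length."""
        b = tb.build_budget(fb, 9.1, day_length=day)
        geom = tb.SharkGeometry(fork_length=2.95, frontal_area=area)
        fluid = tb.FluidProperties(density=rho)
        pct = tb.energy_increase(b, tables["none"], tables["fin_mount"], fluid, geom)
        b_ref = tb.build_budget(fb, 9.1)
        ref = tb.energy_increase(
            b_ref,
            tables["none"],
            tables["fin_mount"],
            tb.FluidProperties(),
            tb.SharkGeometry(2.95, 0.12),
        )
        assert pct == pytest.approx(ref, rel=1e-12)

    def test_monotone_and_saturating_in_burst_fraction(self, fluid, tables):
        """When the burst-speed coefficient ratio exceeds the cruise ratio,
        the increase grows with burst time but with diminishing returns."""
        fracs = np.arange(0.0, 0.21, 0.01)
        pct = [
            tb.energy_increase(
                tb.build_budget(f, 9.1), tables["none"], tables["fin_mount"],
                fluid, AREA_GEOM,
            )
            for f in fracs
        ]
        diffs = np.diff(pct)
        assert np.all(diffs > 0)
        assert np.all(np.diff(diffs) < 0)  # concave: marginal gain shrinks

    def test_fin_mount_exceeds_archival_everywhere(self, fluid, tables):
        for vb in (3.6, 5.0, 7.8, 9.1):
            for f in (0.0, 0.05, 0.20):
                b = tb.build_budget(f, vb)
                fin = tb.energy_increase(
                    b, tables["none"], tables["fin_mount"], fluid, AREA_GEOM
                )
                arch = tb.energy_increase(
                    b, tables["none"], tables["archival_body"], fluid, AREA_GEOM
                )
                assert fin > arch


class TestScenarioGrid:
    def test_cardinality_and_columns(self, fluid, tables):
        grid = tb.scenario_grid(
            tables["none"], tables["fin_mount"], fluid, AREA_GEOM,
            burst_speeds=[3.6, 5.0, 7.8, 9.1],
            burst_fractions=[0.0, 0.1, 0.2],
        )
        assert len(grid) == 12
        assert {
            "scenario_id", "size_m", "tag_config", "burst_speed",
            "burst_fraction", "e_untagged_j", "e_tagged_j", "pct_increase",
        } <= set(grid.columns)

    def test_zero_fraction_reduces_to_cruise_comparison(self, fluid, tables):
        grid = tb.scenario_grid(
            tables["none"], tables["fin_mount"], fluid, AREA_GEOM,
            burst_speeds=[3.6, 9.1], burst_fractions=[0.0],
        )
        assert grid.pct_increase.nunique() == 1
        assert grid.pct_increase.iloc[0] == pytest.approx(20.41, abs=0.005)

    def test_summary_statistics(self, fluid, tables):
        grid = tb.scenario_grid(tables["none"], tables["fin_mount"], fluid, AREA_GEOM)
        summary = tb.grid_summary(grid)
        assert len(summary) == 4  # one row per default burst speed
        sub = grid[grid.burst_speed == 3.6].pct_increase
        row = summary[summary.burst_speed == 3.6].iloc[0]
        assert row["mean"] == pytest.approx(sub.mean())
        assert row["median"] == pytest.approx(sub.median())
        assert row["q25"] == pytest.approx(sub.quantile(0.25))

    def test_empty_grid_rejected(self, fluid, tables):
        with pytest.raises(BudgetError):
            tb.scenario_grid(
                tables["none"], tables["fin_mount"], fluid, AREA_GEOM,
                burst_speeds=[],
            )
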