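"""Core stock-flow model: drivers, flows, and the annual simulation."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ltcisim import (
    ModelParameters,
    compound_growth,
    expenditure_flow,
    project_state,
    revenue_flows,
    simulate,
)

REL = 0.002  # published values are rounded to 3-4 significant figures


class TestCompoundGrowth:
    @pytest.mark.parametrize(
        "x0, rate, n, expected",
        [
            (2_738_800, 0.06, 11, 5_199_100),  # employee pool 2019 -> 2030
            (55_870, 0.08, 11, 130_262),  # disposable income 2019 -> 2030
        ],
    )
    def test_matches_spreadsheet_oracle(self, x0, rate, n, expected):
        assert compound_growth(x0, rate, n) == pytest.approx(expected, rel=1e-3)

    def test_zero_rate_identity(self):
        assert compound_growth(148, 0.0, 7) == 148

    def test_negative_steps_rejected(self):
        with pytest.raises(ValueError):
            compound_growth(100.0, 0.05, -1)


class TestProjectState:
    def test_base_year_returns_base_values(self, params):
        s = project_state(params, 2019)
        assert (s.n_emp, s.n_res, s.di, s.gdp) == (
            2_738_800,
            1_480_000,
            55_870,
            142_739,
        )

    def test_final_year_total_insured(self, params):
        s = project_state(params, 2030)
        assert s.n_insured == pytest.approx(7_979_600, rel=1e-3)

    def test_zero_growth_leaves_base_values(self):
        p = ModelParameters(g_emp=0, g_res=0, g_di=0, g_gdp=0)
        for year in (2019, 2024, 2030):
            s = project_state(p, year)
            assert (s.n_emp, s.n_res, s.di, s.gdp) == (
                p.n_emp0,
                p.n_res0,
                p.di0,
                p.gdp0,
            )

    def test_out_of_horizon_rejected(self, params):
        with pytest.raises(ValueError):
            project_state(params, 2031)
        with pytest.raises(ValueError):
            project_state(params, 2018)


class TestFlows:
    def test_base_year_revenue_hand_arithmetic(self, params):
        s = project_state(params, 2019)
        rev_ind, rev_ent, rev_gov, rev_total = revenue_flows(s, params)
        # 4,218,800 insured x 0.06% x 55,870 yuan etc., worked by hand
        assert rev_ind == pytest.approx(141.4e6, rel=1e-3)
        assert rev_ent == pytest.approx(156.4e6, rel=1e-3)
        assert rev_gov == pytest.approx(84.5e6, rel=1e-3)
        assert rev_total == rev_ind + rev_ent + rev_gov

    def test_final_year_revenue_components(self, params):
        s = project_state(params, 2030)
        rev_ind, rev_ent, rev_gov, _ = revenue_flows(s, params)
        assert rev_ind == pytest.approx(623.7e6, rel=1e-3)
        assert rev_ent + rev_gov == pytest.approx(779.2e6, rel=1e-3)

    def test_zero_rates_give_zero_revenue(self):
        p = ModelParameters(r_ind=0, r_ent=0, r_gov=0)
        s = project_state(p, 2025)
        assert revenue_flows(s, p) == (0, 0, 0, 0)

    def test_base_year_expenditure_hand_arithmetic(self, params):
        # net per-disabled cost (0.03*30000 + 0.97*18000)*0.7 = 12,852 yuan
        assert params.net_cost_per_disabled == pytest.approx(12_852)
        s = project_state(params, 2019)
        assert expenditure_flow(s, params) == pytest.approx(162.7e6, rel=1e-3)

    def test_final_year_expenditure_with_calibrated_esc(self, calibrated_params):
        s = project_state(calibrated_params, 2030)
        assert expenditure_flow(s, calibrated_params) == pytest.approx(
            1_437e6, rel=1e-3
        )

    def test_zero_reimbursement_zeroes_expenditure(self):
        p = ModelParameters(reimb=0.0)
        s = project_state(p, 2025)
        assert expenditure_flow(s, p) == 0.0


class TestSimulate:
    def test_horizon_shape(self, params):
        t = simulate(params)
        assert len(t) == 12
        assert t.years == list(range(2019, 2031))

    def test_final_year_deficit(self, calibrated_params):
        t = simulate(calibrated_params)
        assert t.record(2030).balance_annual == pytest.approx(-34.05e6, rel=REL)

    def test_revenue_multiplier(self, params):
        t = simulate(params)
        ratio = t.record(2030).rev_total / t.record(2019).rev_total
        assert ratio == pytest.approx(3.7, rel=0.03)

    def test_frozen_drivers_freeze_all_flows(self):
        p = ModelParameters(g_emp=0, g_res=0, g_di=0, g_gdp=0, esc=0)
        t = simulate(p)
        first = t.record(p.year_start)
        for rec in t:
            for f in (
                "rev_individual",
                "rev_enterprise",
                "rev_government",
                "rev_total",
                "expenditure",
                "balance_annual",
            ):
                assert getattr(rec, f) == pytest.approx(getattr(first, f))

    def test_conservation_and_prefix_sum(self, calibrated_params):
        t = simulate(calibrated_params)
        running = 0.0
        for rec in t:
            assert rec.rev_total == pytest.approx(
                rec.rev_individual + rec.rev_enterprise + rec.rev_government,
                abs=1.0,
            )
            assert rec.balance_annual == pytest.approx(
                rec.rev_total - rec.expenditure, abs=1.0
            )
            running += rec.balance_annual
            assert rec.balance_cumulative == pytest.approx(running)

    def test_recurrence_agrees_with_closed_form(self, calibrated_params):
        """The year-stepped recurrence and the compounding closed form are
        independent routes to the same flows."""
        t = simulate(calibrated_params)
        for rec in t:
            s = project_state(calibrated_params, rec.year)
            _, _, _, rev_total = revenue_flows(s, calibrated_params)
            assert rec.rev_total == pytest.approx(rev_total, rel=1e-12)
            assert rec.expenditure == pytest.approx(
                expenditure_flow(s, calibrated_params), rel=1e-12
            )

    def test_monotone_growth(self, calibrated_params):
        t = simulate(calibrated_params)
        for a, b in zip(t.records, t.records[1:]):
            assert b.rev_total >= a.rev_total
            assert b.expenditure >= a.expenditure


class TestParameterValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_emp0": 0},
            {"di0": -1},
            {"reimb": 1.5},
            {"d_sev": -0.1},
            {"g_emp": 1.5},
            {"p_inst": 0.5, "p_home": 0.4},
            {"year_end": 2018},
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ModelParameters(**kwargs)


@settings(max_examples=50, deadline=None)
@given(
    r_ind=st.floats(1e-5, 0.01),
    reimb=st.floats(0.1, 1.0),
    d_sev=st.floats(1e-4, 0.05),
    factor=st.floats(1.1, 3.0),
)
def test_flows_scale_linearly_in_their_rates(r_ind, reimb, d_sev, factor):
    """Expenditure is proportional to reimb and d_sev; individual revenue to
    r_ind: scaling any of them scales the matching flow in every year."""
    base = ModelParameters(r_ind=r_ind, reimb=reimb, d_sev=d_sev)
    t0 = simulate(base)
    for lever, flow in (
        ("r_ind", "rev_individual"),
        ("reimb", "expenditure"),
        ("d_sev", "expenditure"),
    ):
        scaled = base.replace(**{lever: min(getattr(base, lever) * factor, 1.0)})
        eff = getattr(scaled, lever) / getattr(base, lever)
        t1 = simulate(scaled)
        for r0, r1 in zip(t0, t1):
            assert getattr(r1, flow) == pytest.approx(
                getattr(r0, flow) * eff, rel=1e-9
            )
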