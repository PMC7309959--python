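"""Outcome/cost accrual, cost-category arithmetic, ICER and NMB logic."""

import numpy as np
import pytest

import ra223cea as r
from ra223cea.economics import (
    ae_cost,
    drug_and_admin_cost,
    facility_costs,
    management_cost,
    sse_event_cost,
    terminal_and_secondline_costs,
)


def make_trace(n_cycles=52, **occupancy):
    """A hand-built trace with constant occupancy (no events by default)."""
    weeks = np.arange(n_cycles + 1, dtype=float)
    occ = {
        s: np.full(n_cycles + 1, occupancy.get(s, 0.0))
        for s in ("pf_no_sse", "pf_sse", "prog_no_sse", "prog_sse", "dead")
    }
    zero = np.zeros(n_cycles)
    return r.CohortTrace(
        weeks=weeks,
        **occ,
        new_deaths=occupancy.get("new_deaths", zero.copy()),
        new_progressions=occupancy.get("new_progressions", zero.copy()),
        new_first_sse=occupancy.get("new_first_sse", zero.copy()),
    )


class TestDiscounting:
    def test_one_year_at_three_percent(self):
        assert r.discount_factor(52.0, 0.03) == pytest.approx(1.0 / 1.03, rel=1e-12)

    def test_zero_rate_is_unity(self):
        assert r.discount_factor(123.0, 0.0) == 1.0

    def test_ten_years(self):
        assert r.discount_factor(520.0, 0.03) == pytest.approx(1.03**-10, rel=1e-12)
        assert r.discount_factor(520.0, 0.03) == pytest.approx(0.744094, abs=1e-6)


class TestOutcomeAccrual:
    def test_unit_utilities_equal_discounted_life_years(self, radium_trace):
        utilities = dict.fromkeys(
            ("pf_no_sse", "pf_sse", "prog_no_sse", "prog_sse"), 1.0
        )
        q = r.accrue_qalys(radium_trace, utilities, 0.03)
        assert q == pytest.approx(r.accrue_life_years(radium_trace, 0.03), rel=1e-12)

    def test_zero_utilities_give_zero(self, radium_trace):
        utilities = dict.fromkeys(
            ("pf_no_sse", "pf_sse", "prog_no_sse", "prog_sse"), 0.0
        )
        assert r.accrue_qalys(radium_trace, utilities, 0.03) == 0.0

    def test_qalys_never_exceed_discounted_life_years(self, radium_trace, bsc_trace):
        rng = np.random.default_rng(5)
        for trace in (radium_trace, bsc_trace):
            utilities = {
                s: float(rng.uniform(0, 1))
                for s in ("pf_no_sse", "pf_sse", "prog_no_sse", "prog_sse")
            }
            q = r.accrue_qalys(trace, utilities, 0.03)
            assert q <= r.accrue_life_years(trace, 0.03) + 1e-12

    def test_qalys_decrease_with_discount_rate(self, base_config):
        qalys = []
        for rate in (0.0, 0.03, 0.05):
            cfg = r.override(base_config, "discount_rate_annual", rate)
            res = r.evaluate_base(cfg)
            qalys.append((res.reference.qalys, res.comparator.qalys))
        for a, b in zip(qalys, qalys[1:]):
            assert b[0] < a[0] and b[1] < a[1]

    def test_missing_utility_rejected(self, radium_trace):
        with pytest.raises(ValueError, match="pf_sse"):
            r.accrue_qalys(radium_trace, {"pf_no_sse": 0.6}, 0.03)

    def test_dead_at_start_accrues_nothing(self):
        trace = make_trace(dead=1.0)
        assert r.accrue_life_years(trace, 0.0) == 0.0

    def test_life_years_match_restricted_mean(self, base_config, radium_trace):
        rmst = r.restricted_mean(base_config.curve("OS", r.ARM_RADIUM), 520.0, 0.0)
        # half-cycle-corrected accrual is a trapezoid rule: tight agreement
        assert r.accrue_life_years(radium_trace, 0.0, half_cycle=True) == pytest.approx(
            rmst, rel=5e-4
        )
        # cycle-start accrual overstates by about half a cycle (0.5/52 years)
        bias = r.accrue_life_years(radium_trace, 0.0) - rmst
        assert 0.0 < bias < 0.012


class TestCosts:
    def test_drug_cost_exact_product(self, base_config):
        drug, admin = drug_and_admin_cost(base_config, r.ARM_RADIUM)
        assert drug == pytest.approx(6.00 * 4532.50, abs=1e-9)
        assert drug == pytest.approx(27_195.00, abs=0.01)

    def test_bsc_gets_no_drug_cost(self, base_config):
        assert drug_and_admin_cost(base_config, r.ARM_BSC) == (0.0, 0.0)

    def test_admin_cost_linear_in_unit_cost(self, base_config):
        doubled = r.override(
            base_config,
            "administration_cost_per_injection",
            2 * base_config["administration_cost_per_injection"],
        )
        _, admin1 = drug_and_admin_cost(base_config, r.ARM_RADIUM)
        _, admin2 = drug_and_admin_cost(doubled, r.ARM_RADIUM)
        assert admin2 == pytest.approx(2 * admin1, rel=1e-12)

    def test_management_single_resource_toy(self, base_config):
        # fully progressed cohort, 4 weeks, r=0: 4 x 0.25 x 81.02 = 81.02
        cfg = base_config.to_dict()
        for phase in ("stable", "progressed"):
            for res in cfg["management_frequencies"][phase]:
                cfg["management_frequencies"][phase][res] = 0.0
            cfg["management_other_weekly_cost"][phase] = 0.0
        cfg["management_frequencies"]["progressed"]["physician_outpatient_visit"] = 0.25
        config = r.load_config(cfg)
        trace = make_trace(n_cycles=4, prog_no_sse=1.0)
        assert management_cost(trace, config, 0.0) == pytest.approx(81.02, rel=1e-12)

    def test_facility_toy_full_occupancy(self, base_config):
        # 52 weeks fully in one cell at 10 hospital days/year -> 10 x 443.61
        cfg = base_config.to_dict()
        use = cfg["facility_use"]
        for resource in use:
            for phase in use[resource]:
                for sse in use[resource][phase]:
                    for arm in use[resource][phase][sse]:
                        use[resource][phase][sse][arm] = 0.0
        use["hospitalization_days"]["stable"]["no_sse"]["radium223"] = 10.0
        config = r.load_config(cfg)
        trace = make_trace(n_cycles=52, pf_no_sse=1.0)
        hosp, day, visits = facility_costs(trace, config, 0.0, r.ARM_RADIUM)
        assert hosp == pytest.approx(10 * 443.61, rel=1e-12)
        assert day == 0.0 and visits == 0.0

    def test_ae_single_event_toy(self, base_config):
        # one AE at 0.01/week, no hospitalization, 100 EUR outpatient,
        # 10-week window, full progression-free occupancy, r=0 -> 10 EUR
        cfg = base_config.to_dict()
        for name in cfg["ae_weekly_rates"]:
            for arm in cfg["ae_weekly_rates"][name]:
                cfg["ae_weekly_rates"][name][arm] = 0.0
            cfg["ae_hospitalization_proportion"][name] = 0.0
            cfg["ae_outpatient_cost"][name] = 0.0
        cfg["ae_weekly_rates"]["nausea"]["bsc"] = 0.01
        cfg["ae_outpatient_cost"]["nausea"] = 100.0
        cfg["treatment_window_weeks"] = 10
        config = r.load_config(cfg)
        trace = make_trace(n_cycles=52, pf_no_sse=1.0)
        assert ae_cost(trace, config, 0.0, r.ARM_BSC) == pytest.approx(10.0, rel=1e-12)

    def test_ae_mismatched_tables_rejected(self, base_config, radium_trace):
        cfg = base_config.to_dict()
        del cfg["ae_outpatient_cost"]["nausea"]
        bad = r.ModelConfig(values=cfg)
        with pytest.raises(ValueError, match="nausea"):
            ae_cost(radium_trace, bad, 0.03, r.ARM_RADIUM)

    def test_sse_cost_zero_incidence(self, base_config):
        trace = make_trace(pf_no_sse=1.0)
        assert sse_event_cost(trace.new_first_sse, trace, base_config, 0.03, r.ARM_BSC) == 0.0

    def test_sse_cost_single_cohortwide_event(self, base_config):
        # everyone has an all-radiotherapy SSE in the first cycle, r=0
        cfg = base_config.to_dict()
        for t in cfg["sse_type_distribution"]:
            for arm in cfg["sse_type_distribution"][t]:
                cfg["sse_type_distribution"][t][arm] = 0.0
        cfg["sse_type_distribution"]["external_beam_radiation"]["bsc"] = 1.0
        cfg["sse_type_distribution"]["external_beam_radiation"]["radium223"] = 1.0
        config = r.ModelConfig(values=cfg)
        trace = make_trace(n_cycles=4, pf_no_sse=1.0)
        trace.new_first_sse[0] = 1.0
        assert sse_event_cost(
            trace.new_first_sse, trace, config, 0.0, r.ARM_BSC
        ) == pytest.approx(2427.72, rel=1e-12)

    def test_immortal_cohort_no_terminal_cost(self, base_config):
        trace = make_trace(pf_no_sse=1.0)
        eol, second = terminal_and_secondline_costs(trace, base_config, 0.03, r.ARM_BSC)
        assert eol == 0.0 and second == 0.0

    def test_everyone_dies_in_first_cycle(self, base_config):
        trace = make_trace(n_cycles=4, dead=1.0)
        trace.new_deaths[0] = 1.0
        eol, _ = terminal_and_secondline_costs(trace, base_config, 0.0, r.ARM_BSC)
        assert eol == pytest.approx(4181.67, rel=1e-12)

    @pytest.mark.parametrize(
        "path,category",
        [
            ("unit_costs.end_of_life", "end_of_life"),
            ("unit_costs.daycare_day", "day_care"),
            ("second_line.cost_per_patient", "second_line"),
            ("drug_price_per_injection", "drug"),
        ],
    )
    def test_cost_homogeneity_in_unit_costs(self, base_config, path, category):
        base = r.evaluate_arm(base_config, r.ARM_RADIUM).costs.as_dict()[category]
        scaled_cfg = r.override(base_config, path, 3.0 * base_config[path])
        scaled = r.evaluate_arm(scaled_cfg, r.ARM_RADIUM).costs.as_dict()[category]
        assert scaled == pytest.approx(3.0 * base, rel=1e-9)

    def test_total_is_sum_of_categories(self, base_result):
        for arm_result in (base_result.reference, base_result.comparator):
            d = arm_result.costs.as_dict()
            assert d.pop("total") == pytest.approx(sum(d.values()), abs=0.01)

    def test_zero_cost_config_totals_zero(self, base_config):
        cfg = base_config
        for spec in list(cfg.iter_params()):
            section = spec.path.split(".")[0]
            if "cost" in spec.path or section in ("unit_costs", "drug_price_per_injection"):
                cfg = r.override(cfg, spec.path, 0.0)
        res = r.evaluate_arm(cfg, r.ARM_BSC)
        assert res.total_cost == pytest.approx(0.0, abs=1e-9)


class TestICER:
    def _arm(self, arm, cost, qalys, ly=1.0):
        return r.ArmResult(
            arm=arm,
            life_years=ly,
            life_years_discounted=ly,
            qalys=qalys,
            costs=r.CostBreakdown(drug=cost),
        )

    def test_simple_ratio(self):
        res = r.compute_icer(self._arm("radium223", 100.0, 0.5), self._arm("bsc", 0.0, 0.0))
        assert res.icer == pytest.approx(200.0)

    def test_dominant_label(self):
        res = r.compute_icer(self._arm("radium223", 0.0, 0.1), self._arm("bsc", 1.0, 0.0))
        assert res.icer == "dominant"

    def test_dominated_label(self):
        res = r.compute_icer(self._arm("radium223", 1.0, 0.0), self._arm("bsc", 0.0, 0.1))
        assert res.icer == "dominated"

    def test_zero_effect_undefined(self):
        res = r.compute_icer(self._arm("radium223", 1.0, 0.5), self._arm("bsc", 0.0, 0.5))
        assert res.icer == "undefined"

    def test_antisymmetric_under_arm_swap(self, base_result):
        swapped = r.compute_icer(base_result.comparator, base_result.reference)
        assert swapped.delta_cost == pytest.approx(-base_result.delta_cost)
        assert swapped.delta_qalys == pytest.approx(-base_result.delta_qalys)
        assert swapped.icer == pytest.approx(base_result.icer)  # ratio of two sign flips


class TestNMB:
    def test_zero_wtp_is_negative_delta_cost(self, base_result):
        assert r.net_monetary_benefit(base_result, 0.0) == pytest.approx(
            -base_result.delta_cost
        )

    def test_zero_exactly_at_icer(self, base_result):
        assert r.net_monetary_benefit(base_result, base_result.icer) == pytest.approx(
            0.0, abs=1e-6
        )

    def test_published_increments_arithmetic(self):
        ref = r.ArmResult("radium223", 1.88, 1.8, 1.12, r.CostBreakdown(drug=9631.0))
        comp = r.ArmResult("bsc", 1.48, 1.4, 0.77, r.CostBreakdown())
        res = r.compute_icer(ref, comp)
        assert r.net_monetary_benefit(res, 30_000.0) == pytest.approx(869.0, abs=1e-9)
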