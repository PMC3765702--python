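import numpy as np
import pytest

from afcua.cohort import SharedStreams, generate_cohort
from afcua.engine import (
    accrue_day,
    events_per_100py,
    run_arm,
    run_study,
    simulate_cohort,
    simulate_individual,
)
from afcua.parameters import apply_overrides


def _closed_form(arm, params):
    """Independent no-event accrual sums."""
    d = np.arange(params.horizon_days)
    disc = (1 + params.discount_annual) ** (-d / 365)
    if arm == "dab150":
        daily = np.full_like(disc, params.cost_dab_daily)
        day0 = 0.0
    else:
        monthly = np.where(
            d < 365,
            params.cost_inr_month_sdw_y1 if arm == "sdw" else params.cost_inr_month_gtw_y1,
            params.cost_inr_month_later,
        )
        daily = params.cost_warfarin_daily + monthly / 30
        day0 = params.cost_lmwh_course + (
            params.cost_genotyping if arm == "gtw" else 0.0
        )
    cost = float(np.sum(daily * disc)) + day0
    qaly = float(np.sum(0.95 / 365 * disc))
    return cost, qaly


class TestZeroRiskClosedForm:
    @pytest.mark.parametrize("arm", ["sdw", "gtw", "dab150"])
    def test_full_horizon(self, zero_risk_params, arm):
        streams = SharedStreams(5, 0, 2, zero_risk_params.horizon_days)
        res = simulate_cohort(2, arm, zero_risk_params, streams)
        cost, qaly = _closed_form(arm, zero_risk_params)
        assert res.cost == pytest.approx(cost, rel=1e-9)
        assert res.qaly == pytest.approx(qaly, rel=1e-9)
        assert (res.person_days == zero_risk_params.horizon_days).all()
        assert res.alive_at_end.all()
        assert (res.n_bleeds == 0).all()
        assert (res.n_te == 0).all()

    def test_undiscounted_equals_raw_sum(self, zero_risk_params):
        p = apply_overrides(zero_risk_params, {"discount_annual": 0.0, "horizon_days": 400})
        streams = SharedStreams(5, 0, 1, 400)
        res = simulate_cohort(1, "dab150", p, streams)
        assert res.cost[0] == pytest.approx(3.20 * 400, rel=1e-12)
        assert res.qaly[0] == pytest.approx(0.95 * 400 / 365, rel=1e-12)


class TestAccrueDay:
    def test_day0_gtw_includes_genotyping(self, params):
        cost, *_ = accrue_day(0, "gtw", 0.95, True, 0, 1, params)
        assert cost == pytest.approx(
            615 + 27.90 + 0.074 + 5.00 / 30
        )

    def test_dab_day_d_discounted(self, params):
        d = 250
        _, _, disc_cost, _ = accrue_day(d, "dab150", 0.95, True, 0, 1, params)
        assert disc_cost == pytest.approx(3.20 * 1.03 ** (-d / 365), rel=1e-12)

    def test_zero_discount_identity(self, params):
        p = apply_overrides(params, {"discount_annual": 0.0})
        cost, util, disc_cost, disc_qaly = accrue_day(100, "sdw", 0.95, True, 0, 1, p)
        assert disc_cost == cost
        assert disc_qaly == pytest.approx(0.95 / 365)

    def test_sequela_monthly_cost(self, params):
        cost_none, *_ = accrue_day(40, "sdw", 0.39, True, 0, 1, params)
        cost_sev, *_ = accrue_day(40, "sdw", 0.39, True, 2, 1, params)
        assert cost_sev - cost_none == pytest.approx(6259 / 30)

    def test_off_treatment_no_drug_cost(self, params):
        cost, *_ = accrue_day(40, "dab150", 0.95, False, 0, 1, params)
        assert cost == 0.0


class TestDeterminismAndDeath:
    def test_same_streams_identical(self, short_params):
        streams = SharedStreams(2, 0, 100, 90)
        a = simulate_cohort(100, "sdw", short_params, streams)
        b = simulate_cohort(100, "sdw", short_params, streams)
        assert np.array_equal(a.cost, b.cost)
        assert np.array_equal(a.qaly, b.qaly)
        assert np.array_equal(a.n_bleeds, b.n_bleeds)

    def test_forced_death_day0(self, params):
        # certain bleed, always intracranial, always fatal
        p = apply_overrides(
            params,
            {
                "p_bleed_annual_inrange": 1.0,
                "bleed_split_warfarin": {"intracranial": 1.0, "extracranial": 0.0},
                "ich_outcomes": {
                    "no_deficit": 0.0, "mild": 0.0, "severe": 0.0,
                    "death_first_month": 1.0,
                },
                "horizon_days": 120,
            },
        )
        streams = SharedStreams(8, 0, 50, 120)
        res = simulate_cohort(50, "sdw", p, streams)
        assert (res.person_days <= 30).all()
        assert (~res.alive_at_end).all()
        assert (res.qaly < 30 / 365).all()

    def test_simulate_individual_matches_n1_cohort(self, short_params):
        cohort = generate_cohort(1, 0, 77)
        streams = SharedStreams(77, 0, 1, 90)
        traj = simulate_individual(cohort.individuals[0], "gtw", short_params, streams)
        res = run_arm(cohort, "gtw", short_params)
        assert traj.discounted_cost == pytest.approx(res.cost[0], rel=1e-12)
        assert traj.discounted_qalys == pytest.approx(res.qaly[0], rel=1e-12)
        assert traj.person_days == res.person_days[0]

    def test_qaly_upper_bound(self, short_params):
        streams = SharedStreams(3, 0, 2000, 90)
        res = simulate_cohort(2000, "sdw", short_params, streams)
        d = np.arange(90)
        bound = float(np.sum(0.95 / 365 * 1.03 ** (-d / 365)))
        assert (res.qaly <= bound + 1e-12).all()


class TestCRNContract:
    def test_unit_rrs_identical_event_days(self, params):
        """With all dabigatran RRs at 1 and shared streams, the two arms see
        identical event days. Event *resolution* is arm-salted by design, so
        outcome branches that feed back into the dynamics (fatalities,
        bleed-subtype-dependent cessation) are made deterministic here."""
        p = apply_overrides(
            params,
            {
                "rr_bleed_dab": 1.0,
                "rr_te_dab": {"stroke": 1.0, "mi": 1.0, "pe": 1.0, "dvt": 1.0},
                "bleed_split_dab_raw": {"intracranial": 1.0, "extracranial": 0.0},
                "bleed_split_warfarin": {"intracranial": 1.0, "extracranial": 0.0},
                "ich_outcomes": {
                    "no_deficit": 0.2, "mild": 0.3, "severe": 0.5,
                    "death_first_month": 0.0,
                },
                "stroke_outcomes": {
                    "death_m1": 0.0, "death_m2": 0.0, "death_m3": 0.0,
                    "severe": 0.402, "mild": 0.425, "none": 0.091,
                },
                "p_death_pe": 0.0, "p_death_dvt": 0.0, "p_death_mi": 0.0,
                "p_death_extracranial": 0.0,
                "horizon_days": 365,
            },
        )
        streams = SharedStreams(4, 0, 5000, 365)
        sdw = simulate_cohort(5000, "sdw", p, streams, collect_events=True)
        dab = simulate_cohort(5000, "dab150", p, streams, collect_events=True)
        sdw_days = sdw.events[["individual", "day"]].drop_duplicates()
        dab_days = dab.events[["individual", "day"]].drop_duplicates()
        assert sdw_days.reset_index(drop=True).equals(dab_days.reset_index(drop=True))

    def test_crn_reduces_delta_variance(self, short_params):
        deltas_crn, deltas_ind = [], []
        p = apply_overrides(short_params, {"horizon_days": 60})
        for rep in range(60):
            shared = SharedStreams(10, rep, 400, 60, crn=True)
            indep = SharedStreams(10, rep, 400, 60, crn=False)
            a = simulate_cohort(400, "sdw", p, shared)
            b = simulate_cohort(400, "gtw", p, shared)
            deltas_crn.append(b.mean_cost - a.mean_cost)
            a = simulate_cohort(400, "sdw", p, indep)
            b = simulate_cohort(400, "gtw", p, indep)
            deltas_ind.append(b.mean_cost - a.mean_cost)
        assert np.var(deltas_crn) < np.var(deltas_ind)


class TestMonotonicity:
    def test_te_hazard_monotone_in_probability(self, params):
        """Non-fatal TE leaves future hazards unchanged, so raising the TE
        probability with fixed streams can only add events."""
        base = apply_overrides(
            params,
            {
                "horizon_days": 365,
                "p_bleed_annual_inrange": 0.0,
                "stroke_outcomes": {
                    "death_m1": 0.0, "death_m2": 0.0, "death_m3": 0.0,
                    "severe": 0.402, "mild": 0.425, "none": 0.091,
                },
                "p_death_pe": 0.0, "p_death_dvt": 0.0, "p_death_mi": 0.0,
            },
        )
        higher = apply_overrides(base, {"p_te_annual_inrange": 0.10})
        streams = SharedStreams(6, 0, 3000, 365)
        lo = simulate_cohort(3000, "sdw", base, streams)
        hi = simulate_cohort(3000, "sdw", higher, streams)
        assert (hi.n_te >= lo.n_te).all()
        assert hi.n_te.sum() > lo.n_te.sum()

    def test_discount_rate_monotone(self, short_params):
        higher = apply_overrides(short_params, {"discount_annual": 0.10})
        streams = SharedStreams(6, 0, 500, 90)
        a = simulate_cohort(500, "dab150", short_params, streams)
        b = simulate_cohort(500, "dab150", higher, streams)
        assert (b.cost <= a.cost + 1e-12).all()
        assert (b.qaly <= a.qaly + 1e-12).all()


class TestRates:
    def test_events_per_100py(self):
        assert events_per_100py(321, 3650000) == pytest.approx(3.21)
        assert events_per_100py(0, 1000) == 0.0
        assert events_per_100py(181, 10000 * 365) == pytest.approx(1.81)

    def test_zero_person_time_rejected(self):
        with pytest.raises(ValueError):
            events_per_100py(1, 0)


class TestRunStudy:
    def test_shared_cohort_across_arms(self, short_params):
        summaries, table = run_study(
            short_params, n_individuals=200, n_replicates=2, master_seed=5
        )
        assert set(summaries) == {"sdw", "gtw", "dab150"}
        assert len(table) == 6
        for s in summaries.values():
            assert s.n_individuals == 200
            assert s.se_cost >= 0 and s.se_qaly >= 0
            assert s.bleeds_per_100py >= 0 and s.te_per_100py >= 0

    def test_replicate_se_consistency(self, short_params):
        p = apply_overrides(short_params, {"horizon_days": 30})
        summaries, table = run_study(
            p, arms=("sdw",), n_individuals=100, n_replicates=50, master_seed=1
        )
        means = table[table.arm == "sdw"].mean_cost.to_numpy()
        assert summaries["sdw"].se_cost == pytest.approx(
            means.std(ddof=1) / np.sqrt(50), rel=1e-9
        )
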