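"""Cohort engine: transition rows, trace invariants, closed forms, and
agreement with the independent individual-level simulator."""

import numpy as np
import pytest

import genequit as gq
from genequit.markov import Layout, build_transition_matrix, build_transition_row
from genequit.parameters import RelapseSchedule, UtilitySet
from tests.conftest import assert_microsim_agreement, randomized_config


def _zero_risk_config(base_config):
    """No mortality, no cancer, no relapse, utilities all 1."""
    epi = gq.make_epi_tables()
    for sex in epi.mortality:
        epi.mortality[sex] = np.zeros_like(epi.mortality[sex])
        epi.incidence[sex] = np.zeros_like(epi.incidence[sex])
    return base_config.copy_with(
        epi=epi, discount_rate=0.0,
        relapse=RelapseSchedule.from_bands(0.0, 0.0),
        utilities=UtilitySet(no_lung_cancer=1.0, early_lc=1.0, advanced_lc=1.0))


class TestTransitionRows:
    def test_dead_is_absorbing(self, base_config):
        L = Layout(base_config.tunnel_years)
        row = build_transition_row(L.DEAD, 3, base_config.usc, base_config,
                                   base_config.epi, L)
        expect = np.zeros(L.n)
        expect[L.DEAD] = 1.0
        np.testing.assert_array_equal(row, expect)

    def test_relapse_component_in_early_band(self, base_config):
        # cycle 3 = three years since quit -> 10% band of the relapse schedule
        L = Layout(base_config.tunnel_years)
        row = build_transition_row(L.QUIT, 3, base_config.usc, base_config,
                                   base_config.epi, L)
        survivors_no_cancer = row[L.QUIT] + row[L.SMOKE]
        assert row[L.SMOKE] / survivors_no_cancer == pytest.approx(0.10, rel=1e-12)

    def test_smoker_cancer_onset_at_age_65(self, base_config):
        # incidence 0.0018024 x RR 6.609, split 20/80 early/advanced
        cfg = base_config
        L = Layout(cfg.tunnel_years)
        cycle = 65 - cfg.cohort_start_age
        row = build_transition_row(L.SMOKE, cycle, cfg.usc, cfg, cfg.epi, L)
        q = cfg.epi.mortality_at(65, "both")
        onset = (row[L.EARLY[0]] + row[L.ADV[0]]) / (1 - q)
        assert onset == pytest.approx(0.0018024 * 6.609, rel=1e-12)
        assert onset == pytest.approx(0.011912, abs=5e-7)
        assert row[L.EARLY[0]] / (1 - q) == pytest.approx(0.0023824, abs=1e-7)
        assert row[L.ADV[0]] / (1 - q) == pytest.approx(0.0095297, abs=1e-7)

    def test_every_row_sums_to_one(self, random_config):
        cfg = random_config
        L = Layout(cfg.tunnel_years)
        for cycle in (0, 5, 20, cfg.horizon - 1):
            M = build_transition_matrix(cycle, cfg.gt, cfg, cfg.epi, L)
            np.testing.assert_allclose(M.sum(axis=1), 1.0, atol=1e-12)
            assert np.all(M >= 0)


class TestClosedForms:
    def test_no_risk_cohort_accrues_horizon_qalys(self, base_config):
        cfg = _zero_risk_config(base_config)
        trace = gq.run_cohort(cfg.usc, cfg)
        assert trace.total_qaly == pytest.approx(cfg.horizon, rel=1e-12)

    def test_constant_mortality_gives_geometric_life_years(self, base_config):
        q = 0.05
        cfg = _zero_risk_config(base_config)
        for sex in cfg.epi.mortality:
            cfg.epi.mortality[sex] = np.full_like(cfg.epi.mortality[sex], q)
        trace = gq.run_cohort(cfg.usc, cfg)
        expect = sum((1 - q) ** t for t in range(cfg.horizon))
        assert trace.total_qaly == pytest.approx(expect, rel=1e-12)
        assert expect == pytest.approx((1 - (1 - q) ** 35) / q, rel=1e-12)


class TestTraceInvariants:
    def test_mass_conserved_and_dead_monotone(self, random_config):
        for strat in (random_config.usc, random_config.gt):
            trace = gq.run_cohort(strat, random_config)
            np.testing.assert_allclose(trace.occupancy.sum(axis=1), 1.0, atol=1e-12)
            assert np.all(trace.occupancy >= -1e-15)
            assert np.all(np.diff(trace.occupancy[:, -1]) >= -1e-15)

    def test_higher_quit_rate_never_lowers_qalys(self, base_config):
        qalys = []
        for q in (0.0, 0.06, 0.11, 0.3, 0.8):
            strat = base_config.usc.model_copy(update={"quit_rate_12m": q})
            qalys.append(gq.run_cohort(strat, base_config).total_qaly)
        assert all(b >= a for a, b in zip(qalys, qalys[1:]))

    def test_higher_mortality_never_raises_qalys(self, base_config):
        import genequit.synthetic_epi as se
        lo = se.make_epi_tables({"mortality_anchor_rate": 0.005})
        hi = se.make_epi_tables({"mortality_anchor_rate": 0.02})
        t_lo = gq.run_cohort(base_config.usc, base_config.copy_with(epi=lo))
        t_hi = gq.run_cohort(base_config.usc, base_config.copy_with(epi=hi))
        assert t_hi.total_qaly < t_lo.total_qaly

    def test_discounting_identity_and_monotonicity(self, base_config):
        t0 = gq.run_cohort(base_config.usc, base_config.copy_with(discount_rate=0.0))
        t5 = gq.run_cohort(base_config.usc, base_config)
        t10 = gq.run_cohort(base_config.usc, base_config.copy_with(discount_rate=0.10))
        assert t0.total_qaly > t5.total_qaly > t10.total_qaly
        assert t0.total_cost > t5.total_cost > t10.total_cost

    def test_equal_strategies_leave_only_intervention_cost(self, base_config):
        gt_like_usc = base_config.gt.model_copy(update={
            "quit_rate_12m": base_config.usc.quit_rate_12m,
            "relapse_multiplier": base_config.usc.relapse_multiplier})
        cfg = base_config.copy_with(gt=gt_like_usc)
        res, _, _ = gq.evaluate(cfg)
        assert res.delta_effect == 0.0
        assert res.delta_cost == pytest.approx(355.90, abs=1e-9)

    def test_half_cycle_correction_flag_changes_totals(self, base_config):
        on = base_config.copy_with(half_cycle_correction=True)
        t_off = gq.run_cohort(base_config.usc, base_config)
        t_on = gq.run_cohort(base_config.usc, on)
        assert t_on.total_qaly != pytest.approx(t_off.total_qaly, rel=1e-9)


class TestCumulativeRelapse:
    def test_closed_form_without_mortality(self, base_config):
        frac = gq.cumulative_relapse(base_config.relapse, 35)
        assert frac == pytest.approx(1 - 0.9 ** 5 * 0.96 ** 29, rel=1e-12)

    def test_zero_schedule_gives_zero(self):
        sched = RelapseSchedule.from_bands(0.0, 0.0)
        assert gq.cumulative_relapse(sched, 35) == 0.0

    def test_mortality_strictly_reduces_lifetime_relapse(self, base_config):
        no_mort = gq.cumulative_relapse(base_config.relapse, 35)
        with_mort = gq.cumulative_relapse(base_config.relapse, 35, config=base_config)
        assert with_mort < no_mort


class TestMicrosimOracle:
    """The deterministic trace must match the mean of the individual-level
    simulator within Monte-Carlo error (see conftest for the exact band)."""

    def test_base_case_both_arms(self, base_config):
        assert_microsim_agreement(base_config, base_config.usc, seed=12345)
        assert_microsim_agreement(base_config, base_config.gt, seed=54321)

    @pytest.mark.parametrize("seed", [7, 8, 9])
    def test_randomized_configurations(self, seed):
        cfg = randomized_config(1000 + seed)
        assert_microsim_agreement(cfg, cfg.gt, seed=seed)


def test_trace_tidy_export_shapes(base_config):
    trace = gq.run_cohort(base_config.usc, base_config)
    df = trace.to_frame()
    n_comp = Layout(base_config.tunnel_years).n
    assert len(df) == (base_config.horizon + 1) * n_comp
    assert set(df.columns) >= {"cycle", "age", "compartment", "occupancy", "strategy"}
    # per-cycle occupancies still sum to 1 in the export
    sums = df.groupby("cycle")["occupancy"].sum()
    np.testing.assert_allclose(sums, 1.0, atol=1e-12)
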