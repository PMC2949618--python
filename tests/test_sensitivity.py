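"""One-way sweeps, threshold and break-even searches, scenario runs."""

import numpy as np
import pytest

import genequit as gq
from genequit import sensitivity as sens
from genequit.parameters import set_parameter


def grid_scan_sign_change(f, lo, hi, step=1e-3):
    """Brute-force root bracketing used as an independent check on bisection."""
    xs = np.arange(lo, hi + step, step)
    prev = f(xs[0])
    for x in xs[1:]:
        cur = f(x)
        if (prev < 0) != (cur < 0):
            return x - step, x
        prev = cur
    return None


class TestOneWay:
    def test_icer_strictly_decreasing_in_gt_quit_rate(self, base_config):
        df = sens.one_way(base_config, "quit_rate_gt", 0.07, 0.22, steps=6)
        icers = df["icer"].to_numpy(float)
        assert np.all(np.diff(icers) < 0)

    def test_halving_test_cost_cuts_icer_by_more_than_40pct(self, base_config):
        base, _, _ = gq.evaluate(base_config)
        df = sens.one_way(base_config, "cost_genetic_test", 155.50, 466.50, steps=3)
        low_icer = float(df.loc[df["value"] == 155.50, "icer"].iloc[0])
        assert low_icer < 0.6 * base.icer

    def test_zero_width_range_gives_constant_row(self, base_config):
        df = sens.one_way(base_config, "utility_early_lc", 0.73, 0.73, steps=4)
        assert df["icer"].nunique() == 1

    def test_unknown_parameter_rejected(self, base_config):
        with pytest.raises(KeyError, match="no_such"):
            sens.one_way(base_config, "no_such", 0.0, 1.0)


class TestThresholdQuitRate:
    def test_bisection_matches_grid_scan(self, base_config):
        res = sens.threshold_quit_rate(base_config)
        assert res.status == "found"

        def f(q):
            cfg = set_parameter(base_config, "quit_rate_gt", q)
            r, _, _ = gq.evaluate(cfg)
            return r.incremental_nmb

        bracket = grid_scan_sign_change(f, 0.06, 0.25)
        assert bracket is not None
        assert bracket[0] - 1e-3 <= res.value <= bracket[1] + 1e-3

    def test_huge_wtp_pushes_threshold_to_usc_rate(self, base_config):
        res = sens.threshold_quit_rate(base_config, wtp=1e9)
        assert res.status == "found"
        assert base_config.usc.quit_rate_12m < res.value < base_config.usc.quit_rate_12m + 0.005

    def test_free_test_makes_gt_always_cost_effective(self, base_config):
        cfg = base_config.copy_with(gt=base_config.gt.model_copy(
            update={"cost_items": base_config.usc.cost_items}))
        res = sens.threshold_quit_rate(
            cfg, bracket=(cfg.usc.quit_rate_12m + 1e-4, 0.99))
        assert res.status == "always"


class TestThresholdRelapse:
    def test_bisection_matches_grid_scan(self, base_config):
        res = sens.threshold_relapse_reduction(base_config)
        assert res.status == "found"

        def f(m):
            cfg = set_parameter(base_config, "relapse_multiplier_gt", m)
            r, _, _ = gq.evaluate(cfg)
            return r.incremental_nmb

        bracket = grid_scan_sign_change(f, 0.0, 1.0)
        assert bracket is not None
        m_star = 1.0 - res.value
        assert bracket[0] - 1e-3 <= m_star <= bracket[1] + 1e-3

    def test_already_cost_effective_needs_no_reduction(self, base_config):
        cfg = set_parameter(base_config, "quit_rate_gt", 0.30)
        res = sens.threshold_relapse_reduction(cfg)
        assert res.value == 0.0


class TestBreakeven:
    def test_bisection_matches_grid_scan(self, base_config):
        res = sens.breakeven_quit_rate(base_config)
        assert res.status == "found"

        def delta_cost(q):
            r, _, _ = gq.evaluate(set_parameter(base_config, "quit_rate_gt", q))
            return r.delta_cost

        bracket = grid_scan_sign_change(delta_cost, 0.25, 0.45)
        assert bracket is not None
        assert bracket[0] - 1e-3 <= res.value <= bracket[1] + 1e-3
        # at the break-even rate GT is (weakly) dominant: cheaper and more effective
        r, _, _ = gq.evaluate(set_parameter(base_config, "quit_rate_gt",
                                            res.value + 1e-4))
        assert r.delta_cost < 0 and r.delta_effect > 0

    def test_no_extra_cost_means_any_higher_quit_rate_dominates(self, base_config):
        cfg = base_config.copy_with(gt=base_config.gt.model_copy(
            update={"cost_items": base_config.usc.cost_items}))
        res = sens.breakeven_quit_rate(cfg, bracket=(cfg.usc.quit_rate_12m + 1e-4, 0.999))
        assert res.status == "always"

    def test_zero_relapse_lowers_the_breakeven_rate(self, base_config):
        base_be = sens.breakeven_quit_rate(base_config).value
        cfg = base_config.copy_with(relapse=base_config.relapse.scaled(0.0))
        zero_be = sens.breakeven_quit_rate(cfg).value
        assert zero_be < base_be


class TestScenarios:
    def test_older_cohorts_have_lower_icers(self, base_config):
        i30 = sens.scenario(base_config, "age30", start_age=30).icer
        i50, _, _ = gq.evaluate(base_config)
        i60 = sens.scenario(base_config, "age60", start_age=60).icer
        assert i60 < i50.icer < i30

    def test_men_cheaper_per_qaly_than_women(self, base_config):
        men = sens.scenario(base_config, "men", sex="male").icer
        women = sens.scenario(base_config, "women", sex="female").icer
        assert men < women

    def test_halved_relapse_lowers_icer(self, base_config):
        base, _, _ = gq.evaluate(base_config)
        halved = sens.scenario(base_config, "halved relapse",
                               relapse_multiplier_both_arms=0.5)
        assert halved.icer < base.icer

    def test_no_override_reproduces_base_bitwise(self, base_config):
        base, _, _ = gq.evaluate(base_config)
        again = sens.scenario(base_config, "noop")
        assert again.cost_usc == base.cost_usc
        assert again.cost_gt == base.cost_gt
        assert again.qaly_usc == base.qaly_usc
        assert again.qaly_gt == base.qaly_gt


def test_two_way_grid_shape_and_favourable_corner(base_config):
    df = sens.two_way(base_config, "quit_rate_gt", [0.11, 0.22],
                      "quit_rate_usc", [0.06, 0.12])
    assert len(df) == 4
    best = df[(df["quit_rate_gt"] == 0.22) & (df["quit_rate_usc"] == 0.12)]
    base = df[(df["quit_rate_gt"] == 0.11) & (df["quit_rate_usc"] == 0.06)]
    assert float(best["icer"].iloc[0]) < float(base["icer"].iloc[0])
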