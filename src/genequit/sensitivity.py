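"""Deterministic sensitivity analyses: one-way/two-way sweeps, threshold
searches on the genetic-test arm's behavioural parameters, break-even
(dominance) analysis, and scenario re-runs (cohort age, sex, halved relapse).

Threshold searches use bisection on the incremental net monetary benefit
(quit rate; NMB is increasing in the genetic-test quit rate) or on the
incremental cost (break-even), with tight tolerances; every search can be
cross-checked against an exhaustive grid scan (see tests).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import pandas as pd

from .economics import CEResult, evaluate
from .parameters import ModelConfig, get_parameter, set_parameter

BISECT_XTOL = 1e-7
BISECT_FTOL = 1e-6       # dollars of incremental NMB
MAX_ITER = 200


def _inmb_at_quit_rate(config: ModelConfig, q: float, wtp: float) -> float:
    cfg = set_parameter(config, "quit_rate_gt", q).copy_with(wtp=wtp)
    res, _, _ = evaluate(cfg)
    return res.incremental_nmb


def one_way(config: ModelConfig, parameter: str,
            low: float, high: float, steps: int = 3) -> pd.DataFrame:
    """ICER at ``steps`` grid points of one parameter, others at base case.

    The base-case value is always included, so the output is tornado-ready
    (ICER at low / base / high).
    """
    base_value = get_parameter(config, parameter)
    grid = sorted({low, high, base_value}
                  | {low + (high - low) * i / max(steps - 1, 1) for i in range(steps)})
    rows = []
    for v in grid:
        res, _, _ = evaluate(set_parameter(config, parameter, v), label=parameter)
        d = res.as_dict()
        rows.append({"parameter": parameter, "value": v,
                     "is_base": abs(v - base_value) < 1e-15,
                     "icer": d["icer_raw"] if d["icer_raw"] is not None else d["icer"],
                     "delta_cost": d["delta_cost"], "delta_effect": d["delta_effect"]})
    return pd.DataFrame(rows)


def two_way(config: ModelConfig, param_a: str, values_a, param_b: str, values_b
            ) -> pd.DataFrame:
    rows = []
    for va in values_a:
        cfg_a = set_parameter(config, param_a, va)
        for vb in values_b:
            res, _, _ = evaluate(set_parameter(cfg_a, param_b, vb))
            d = res.as_dict()
            rows.append({param_a: va, param_b: vb,
                         "icer": d["icer_raw"] if d["icer_raw"] is not None else d["icer"],
                         "dominance": d["dominance"]})
    return pd.DataFrame(rows)


@dataclass
class ThresholdResult:
    value: Optional[float]
    status: str            # "found" | "always" | "never"
    wtp: float
    parameter: str


def _bisect(f, lo: float, hi: float) -> float:
    flo = f(lo)
    for _ in range(MAX_ITER):
        mid = 0.5 * (lo + hi)
        fmid = f(mid)
        if abs(fmid) < BISECT_FTOL or hi - lo < BISECT_XTOL:
            return mid
        if (fmid > 0) == (flo > 0):
            lo, flo = mid, fmid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def threshold_quit_rate(config: ModelConfig, wtp: float | None = None,
                        bracket: tuple[float, float] | None = None) -> ThresholdResult:
    """Genetic-test 12-month quit rate at which the two arms break even in
    net benefit at the given willingness-to-pay."""
    wtp = config.wtp if wtp is None else wtp
    lo, hi = bracket or (config.usc.quit_rate_12m, 0.99)
    f = lambda q: _inmb_at_quit_rate(config, q, wtp)
    flo, fhi = f(lo), f(hi)
    if flo > 0 and fhi > 0:
        return ThresholdResult(None, "always", wtp, "quit_rate_gt")
    if flo < 0 and fhi < 0:
        return ThresholdResult(None, "never", wtp, "quit_rate_gt")
    return ThresholdResult(_bisect(f, lo, hi), "found", wtp, "quit_rate_gt")


def threshold_relapse_reduction(config: ModelConfig, wtp: float | None = None
                                ) -> ThresholdResult:
    """Relative relapse reduction in the genetic-test arm (1 - relapse
    multiplier) at which the two arms break even in net benefit."""
    wtp = config.wtp if wtp is None else wtp

    def f(m: float) -> float:
        cfg = set_parameter(config, "relapse_multiplier_gt", m).copy_with(wtp=wtp)
        res, _, _ = evaluate(cfg)
        return res.incremental_nmb

    f0, f1 = f(0.0), f(1.0)
    if f1 > 0:                       # already cost-effective with equal relapse
        return ThresholdResult(0.0 if f0 > 0 else None,
                               "always" if f0 > 0 else "found", wtp,
                               "relapse_reduction_gt")
    if f0 < 0:
        return ThresholdResult(None, "never", wtp, "relapse_reduction_gt")
    m_star = _bisect(f, 0.0, 1.0)
    return ThresholdResult(1.0 - m_star, "found", wtp, "relapse_reduction_gt")


def breakeven_quit_rate(config: ModelConfig,
                        bracket: tuple[float, float] | None = None) -> ThresholdResult:
    """Smallest genetic-test quit rate at which GT dominates usual care
    (cancer-treatment savings fully offset the extra intervention cost)."""
    lo, hi = bracket or (config.usc.quit_rate_12m, 0.999)

    def delta_cost(q: float) -> float:
        res, _, _ = evaluate(set_parameter(config, "quit_rate_gt", q))
        return res.delta_cost

    if delta_cost(lo) < 0:
        return ThresholdResult(lo, "always", float("nan"), "quit_rate_gt")
    if delta_cost(hi) > 0:
        return ThresholdResult(None, "never", float("nan"), "quit_rate_gt")
    q_star = _bisect(delta_cost, lo, hi)
    return ThresholdResult(q_star, "found", float("nan"), "quit_rate_gt")


def scenario(config: ModelConfig, label: str, *,
             start_age: int | None = None, sex: str | None = None,
             relapse_multiplier_both_arms: float | None = None,
             quit_rate_gt: float | None = None,
             quit_rate_usc: float | None = None) -> CEResult:
    """Re-run the full pipeline under a structural override.

    An age override keeps the 35-year (or configured) horizon, re-anchored
    to the new start age.  A relapse multiplier here scales the shared
    schedule in *both* arms (the halved-relapse scenario), unlike the
    per-arm multiplier used in threshold analysis.
    """
    cfg = config
    if start_age is not None:
        cfg = cfg.copy_with(cohort_start_age=start_age)
    if sex is not None:
        cfg = cfg.copy_with(sex=sex)
    if relapse_multiplier_both_arms is not None:
        cfg = cfg.copy_with(relapse=cfg.relapse.scaled(relapse_multiplier_both_arms))
    if quit_rate_gt is not None:
        cfg = set_parameter(cfg, "quit_rate_gt", quit_rate_gt)
    if quit_rate_usc is not None:
        cfg = set_parameter(cfg, "quit_rate_usc", quit_rate_usc)
    res, _, _ = evaluate(cfg, label=label)
    return res
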