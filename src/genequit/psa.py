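"""Probabilistic sensitivity analysis.

Each uncertain parameter carries a :class:`~genequit.parameters.DistributionSpec`
(beta for probabilities and utilities, gamma for costs, or fixed).  Beta and
gamma parameters are moment-matched: the mean is the base-case value and the
standard deviation is (high - low) / (2 * 1.96), reading the published range
as a central 95% interval.

Per draw the full two-arm model is re-run; the summary ICER is the ratio of
the mean incremental cost to the mean incremental effect over all draws
(ratio of means, the conventional expected-value estimator for a simulated
ICER, which generally differs from the deterministic all-parameters-at-mean
ICER).  The CEAC at each willingness-to-pay is the fraction of draws with
positive incremental net monetary benefit — never an average of raw ratios,
so draws in any quadrant are handled coherently.

Draws are made from a single seeded generator, parameters in the documented
order of the configuration's ``psa_distributions`` mapping, so a given seed
reproduces a run bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .economics import evaluate, icer, nmb
from .parameters import DistributionSpec, ModelConfig, set_parameter

DEFAULT_WTP_GRID = tuple(range(0, 105000, 5000))


def interval_sd(spec: DistributionSpec) -> float:
    return (spec.high - spec.low) / (2.0 * 1.959963984540054)


def beta_params(mean: float, sd: float) -> tuple[float, float]:
    """Shape parameters of a beta with the given mean and sd (moment match)."""
    if not 0.0 < mean < 1.0:
        raise ValueError(f"beta mean must be in (0,1), got {mean}")
    var = sd * sd
    max_var = mean * (1.0 - mean)
    if var >= max_var:
        raise ValueError(
            f"variance {var:.4g} infeasible for beta with mean {mean} "
            f"(must be < {max_var:.4g})")
    nu = max_var / var - 1.0
    return mean * nu, (1.0 - mean) * nu


def gamma_params(mean: float, sd: float) -> tuple[float, float]:
    """(shape, scale) of a gamma with the given mean and sd."""
    if mean <= 0 or sd <= 0:
        raise ValueError("gamma mean and sd must be positive")
    var = sd * sd
    return mean * mean / var, var / mean


def draw_one(spec: DistributionSpec, rng: np.random.Generator) -> float:
    if spec.family == "fixed":
        return spec.mean
    sd = interval_sd(spec)
    if spec.family == "beta":
        a, b = beta_params(spec.mean, sd)
        return float(rng.beta(a, b))
    a, scale = gamma_params(spec.mean, sd)
    return float(rng.gamma(a, scale))


def sample_parameters(config: ModelConfig, rng: np.random.Generator) -> dict[str, float]:
    """One joint draw of every uncertain parameter, in documented order."""
    return {name: draw_one(spec, rng)
            for name, spec in config.psa_distributions.items()}


@dataclass
class PsaResult:
    delta_cost: np.ndarray
    delta_effect: np.ndarray
    seed: int
    n_iterations: int
    wtp_grid: tuple
    ceac: dict[float, float] = field(default_factory=dict)

    @property
    def mean_icer(self) -> float | str:
        return icer(float(self.delta_cost.mean()), float(self.delta_effect.mean()))

    def icer_ci95(self) -> tuple[float, float, int]:
        """Percentile 95% interval of per-draw ICERs restricted to draws with
        positive incremental effect (ratio-relevant quadrants); the count of
        such draws is returned alongside."""
        mask = self.delta_effect > 0
        ratios = self.delta_cost[mask] / self.delta_effect[mask]
        if ratios.size == 0:
            return float("nan"), float("nan"), 0
        lo, hi = np.percentile(ratios, [2.5, 97.5])
        return float(lo), float(hi), int(ratios.size)

    def quadrant_counts(self) -> dict[str, int]:
        dc, de = self.delta_cost, self.delta_effect
        return {"NE_tradeoff": int(np.sum((de > 0) & (dc > 0))),
                "SE_dominant": int(np.sum((de > 0) & (dc <= 0))),
                "NW_dominated": int(np.sum((de < 0) & (dc >= 0))),
                "SW_tradeoff": int(np.sum((de < 0) & (dc < 0))),
                "zero_effect": int(np.sum(de == 0))}

    def prob_cost_effective(self, wtp: float) -> float:
        inmb = wtp * self.delta_effect - self.delta_cost
        return float(np.mean(inmb > 0))

    def draws_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"draw": np.arange(self.n_iterations),
                             "delta_cost": self.delta_cost,
                             "delta_qaly": self.delta_effect})

    def ceac_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"wtp": list(self.ceac), "probability": list(self.ceac.values())})


def apply_draw(config: ModelConfig, draw: dict[str, float]) -> ModelConfig:
    cfg = config
    for name, value in draw.items():
        cfg = set_parameter(cfg, name, value)
    return cfg


def run_psa(config: ModelConfig, n: int = 10_000, seed: int = 0,
            wtp_grid=DEFAULT_WTP_GRID) -> PsaResult:
    """n joint parameter draws, each re-running the two-arm model."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    dc = np.empty(n)
    de = np.empty(n)
    for i in range(n):
        draw = sample_parameters(config, rng)
        res, _, _ = evaluate(apply_draw(config, draw))
        dc[i] = res.delta_cost
        de[i] = res.delta_effect
    result = PsaResult(delta_cost=dc, delta_effect=de, seed=seed,
                       n_iterations=n, wtp_grid=tuple(wtp_grid))
    result.ceac = {float(w): result.prob_cost_effective(w) for w in wtp_grid}
    return result
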