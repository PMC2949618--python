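"""Annual-cycle Markov cohort engine with cancer tunnel states.

Five health states — no lung cancer (quit), no lung cancer (still smoking),
early-stage lung cancer, advanced-stage lung cancer, dead — expanded into
compartments: each cancer stage carries a 5-year tunnel (year since
diagnosis governs the death probability and first-year treatment cost)
followed by a long-term "stable" compartment with ongoing cost and
background mortality only.

Timing conventions (fixed, recorded in run metadata):

* quit happens at cycle 0, so years-since-quit equals the cycle index for
  everyone in the quit state; relapsers never re-quit, so no quit-time
  tunnel is needed;
* within a cycle, events are ordered: background death first, then cancer
  onset, then relapse among the remaining;
* state rewards (utility, state-linked cost) are taken on start-of-cycle
  occupancy and discounted by 1/(1+r)^t; transition-linked costs
  (progression, terminal care) are charged in the cycle the transition
  occurs; the intervention cost is charged once at cycle 0, undiscounted;
* no half-cycle correction by default (flag available).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .parameters import ModelConfig, StrategyDefinition, intervention_cost
from .synthetic_epi import EpiTables

MASS_TOL = 1e-9


class Layout:
    """Compartment indexing for a given tunnel length T (>= 5)."""

    def __init__(self, tunnel_years: int = 5):
        if tunnel_years < 5:
            raise ValueError("tunnel must cover the 5-year survival table")
        self.T = tunnel_years
        self.QUIT = 0
        self.SMOKE = 1
        self.EARLY = list(range(2, 2 + tunnel_years))                 # steps 1..T
        self.ADV = list(range(2 + tunnel_years, 2 + 2 * tunnel_years))
        self.EARLY_STABLE = 2 + 2 * tunnel_years
        self.ADV_STABLE = self.EARLY_STABLE + 1
        self.DEAD = self.ADV_STABLE + 1
        self.n = self.DEAD + 1

    def labels(self) -> list[str]:
        out = ["no_lc_quit", "no_lc_smoke"]
        out += [f"early_lc_year{k}" for k in range(1, self.T + 1)]
        out += [f"advanced_lc_year{k}" for k in range(1, self.T + 1)]
        out += ["early_lc_stable", "advanced_lc_stable", "dead"]
        return out


def build_transition_row(compartment: int, cycle: int, strategy: StrategyDefinition,
                         config: ModelConfig, epi: EpiTables,
                         layout: Layout | None = None) -> np.ndarray:
    """One row of the cycle-``cycle`` transition matrix.

    Probabilities are constructed to sum to exactly 1; a row summing outside
    ``1 +/- 1e-9`` raises (model-construction error, never renormalised).
    """
    L = layout or Layout(config.tunnel_years)
    age = config.cohort_start_age + cycle
    sex = config.sex
    q = epi.mortality_at(age, sex)
    row = np.zeros(L.n)

    if compartment == L.DEAD:
        row[L.DEAD] = 1.0
    elif compartment in (L.QUIT, L.SMOKE):
        if compartment == L.QUIT:
            rr = epi.rr_ex_at(age, years_since_quit=cycle, sex=sex)
            p_rel = config.relapse.prob(cycle) * strategy.relapse_multiplier
            q_eff = q
        else:
            rr = epi.rr_current_smoker[sex]
            p_rel = 0.0
            q_eff = min(1.0, q * config.smoker_mortality_multiplier)
        p_onset = epi.incidence_at(age, sex) * rr
        if p_onset > 1.0:
            raise ValueError(f"cancer onset probability {p_onset} > 1 at age {age}")
        alive = 1.0 - q_eff
        row[L.DEAD] = q_eff
        row[L.EARLY[0]] = alive * p_onset * config.stage_split_early
        row[L.ADV[0]] = alive * p_onset * config.stage_split_advanced
        no_onset = alive * (1.0 - p_onset)
        if compartment == L.QUIT:
            row[L.SMOKE] = no_onset * p_rel
            row[L.QUIT] = no_onset * (1.0 - p_rel)
        else:
            row[L.SMOKE] = no_onset
    elif compartment in L.EARLY or compartment in L.ADV:
        early = compartment in L.EARLY
        step = (L.EARLY.index(compartment) if early else L.ADV.index(compartment)) + 1
        stage = "early" if early else "advanced"
        p_c = epi.cancer_death_at(stage, step)
        p_die = 1.0 - (1.0 - q) * (1.0 - p_c)
        survive = 1.0 - p_die
        row[L.DEAD] = p_die
        if early:
            p_prog = config.progression_prob_early
            nxt_early = L.EARLY[step] if step < L.T else L.EARLY_STABLE
            nxt_adv = L.ADV[step] if step < L.T else L.ADV_STABLE
            row[nxt_adv] = survive * p_prog
            row[nxt_early] = survive * (1.0 - p_prog)
        else:
            nxt = L.ADV[step] if step < L.T else L.ADV_STABLE
            row[nxt] = survive
    elif compartment in (L.EARLY_STABLE, L.ADV_STABLE):
        row[L.DEAD] = q
        row[compartment] = 1.0 - q
    else:
        raise ValueError(f"unknown compartment index {compartment}")

    total = row.sum()
    if not (1.0 - MASS_TOL <= total <= 1.0 + MASS_TOL):
        raise ValueError(f"transition row sums to {total}, not 1")
    return row


def build_transition_matrix(cycle: int, strategy: StrategyDefinition,
                            config: ModelConfig, epi: EpiTables,
                            layout: Layout) -> np.ndarray:
    return np.vstack([build_transition_row(c, cycle, strategy, config, epi, layout)
                      for c in range(layout.n)])


@dataclass
class CohortTrace:
    """Per-cycle occupancy and discounted reward streams for one strategy."""
    strategy_name: str
    start_age: int
    occupancy: np.ndarray            # (horizon + 1, n_compartments)
    labels: list[str]
    disc_cost: np.ndarray            # (horizon,) incl. intervention cost at t=0
    disc_qaly: np.ndarray            # (horizon,)
    relapse_flow: np.ndarray         # (horizon,) cohort fraction relapsing in cycle t

    @property
    def total_cost(self) -> float:
        return float(self.disc_cost.sum())

    @property
    def total_qaly(self) -> float:
        return float(self.disc_qaly.sum())

    def validate(self) -> None:
        sums = self.occupancy.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-12):
            raise ValueError("occupancy mass not conserved")
        if np.any(self.occupancy < -1e-15) or np.any(self.occupancy > 1 + 1e-12):
            raise ValueError("occupancy outside [0,1]")
        dead = self.occupancy[:, -1]
        if np.any(np.diff(dead) < -1e-15):
            raise ValueError("dead occupancy must be non-decreasing")

    def to_frame(self) -> pd.DataFrame:
        """Tidy export: one row per (cycle, compartment)."""
        H, n = self.occupancy.shape
        cycles = np.repeat(np.arange(H), n)
        recs = pd.DataFrame({
            "cycle": cycles,
            "age": self.start_age + cycles,
            "compartment": self.labels * H,
            "occupancy": self.occupancy.ravel(),
        })
        recs["strategy"] = self.strategy_name
        return recs


def run_cohort(strategy: StrategyDefinition, config: ModelConfig,
               epi: EpiTables | None = None) -> CohortTrace:
    """Propagate the cohort over the horizon, accumulating discounted rewards.

    Cycle 0 starts with ``quit_rate_12m`` of the cohort in the quit state and
    the remainder still smoking, all cancer-free.
    """
    epi = epi if epi is not None else config.epi
    if epi is None:
        raise ValueError("no epidemiological tables supplied")
    L = Layout(config.tunnel_years)
    H = config.horizon
    occ = np.zeros((H + 1, L.n))
    occ[0, L.QUIT] = strategy.quit_rate_12m
    occ[0, L.SMOKE] = 1.0 - strategy.quit_rate_12m

    u = config.utilities
    util = np.zeros(L.n)
    util[L.QUIT] = util[L.SMOKE] = u.no_lung_cancer
    for c in L.EARLY:
        util[c] = u.early_lc
    for c in L.ADV:
        util[c] = u.advanced_lc
    util[L.EARLY_STABLE] = u.early_lc
    util[L.ADV_STABLE] = u.advanced_lc

    cc = config.cancer_costs
    state_cost = np.zeros(L.n)
    state_cost[L.EARLY[0]] = cc.early_first_year
    state_cost[L.ADV[0]] = cc.advanced_first_year
    for c in L.EARLY[1:] + L.ADV[1:]:
        state_cost[c] = cc.ongoing_stable
    state_cost[L.EARLY_STABLE] = state_cost[L.ADV_STABLE] = cc.ongoing_stable

    r = config.discount_rate
    disc = (1.0 + r) ** -np.arange(H)
    disc_cost = np.zeros(H)
    disc_qaly = np.zeros(H)
    relapse_flow = np.zeros(H)
    disc_cost[0] += float(intervention_cost(strategy))

    for t in range(H):
        M = build_transition_matrix(t, strategy, config, epi, L)
        occ[t + 1] = occ[t] @ M

        # transition-linked flows during cycle t
        age = config.cohort_start_age + t
        q = epi.mortality_at(age, config.sex)
        prog_flow = sum(occ[t, c] * M[c, L.ADV[k] if (k := L.EARLY.index(c) + 1) < L.T
                                      else L.ADV_STABLE]
                        for c in L.EARLY)
        cancer_death_flow = 0.0
        for stage, comps in (("early", L.EARLY), ("advanced", L.ADV)):
            for j, c in enumerate(comps):
                p_c = epi.cancer_death_at(stage, j + 1)
                cancer_death_flow += occ[t, c] * (1.0 - q) * p_c
        relapse_flow[t] = occ[t, L.QUIT] * build_transition_row(
            L.QUIT, t, strategy, config, epi, L)[L.SMOKE]

        occ_reward = occ[t]
        if config.half_cycle_correction:
            occ_reward = 0.5 * (occ[t] + occ[t + 1])
        disc_qaly[t] = disc[t] * float(occ_reward @ util)
        disc_cost[t] += disc[t] * (float(occ_reward @ state_cost)
                                   + prog_flow * cc.progressive
                                   + cancer_death_flow * cc.terminal_final_year)

    trace = CohortTrace(strategy_name=strategy.name, start_age=config.cohort_start_age,
                        occupancy=occ, labels=L.labels(),
                        disc_cost=disc_cost, disc_qaly=disc_qaly,
                        relapse_flow=relapse_flow)
    trace.validate()
    return trace


def cumulative_relapse(schedule, horizon: int, *, multiplier: float = 1.0,
                       config: ModelConfig | None = None) -> float:
    """Fraction of initial quitters who ever relapse over the horizon.

    Without mortality (``config is None``) this is the closed form
    ``1 - prod_{t=2..horizon} (1 - p_t)``.  With a config supplied, the
    fraction is read off the cohort trace (relapse flows summed), so
    quitters who die first never relapse and the result is strictly lower.
    """
    if config is None:
        prod = 1.0
        for t in range(2, horizon + 1):
            prod *= 1.0 - schedule.prob(t) * multiplier
        return 1.0 - prod
    strat = config.gt.model_copy(update={"quit_rate_12m": 1.0,
                                         "relapse_multiplier": multiplier})
    cfg = config.copy_with(relapse=schedule, horizon=horizon)
    trace = run_cohort(strat, cfg)
    return float(trace.relapse_flow.sum())
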