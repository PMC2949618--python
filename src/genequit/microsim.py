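"""Individual-level Monte-Carlo simulator used to validate the cohort engine.

This walks N simulated smokers through the same health states with the same
event ordering (death, then cancer onset, then relapse) by sampling each
transition per individual, without ever constructing a transition matrix.
The law of large numbers then makes its mean occupancy an independent check
on the deterministic cohort trace: per compartment and cycle the two should
agree within Monte-Carlo error.

States are coded QUIT=0, SMOKE=1, EARLY=2, ADV=3, EARLY_STABLE=4,
ADV_STABLE=5, DEAD=6, with a separate years-since-diagnosis counter for the
cancer states (the tunnel clock).
"""

from __future__ import annotations

import numpy as np

from .parameters import ModelConfig, StrategyDefinition
from .synthetic_epi import EpiTables

QUIT, SMOKE, EARLY, ADV, EARLY_STABLE, ADV_STABLE, DEAD = range(7)


def simulate_occupancy(strategy: StrategyDefinition, config: ModelConfig,
                       n: int, seed: int,
                       epi: EpiTables | None = None) -> np.ndarray:
    """Mean occupancy matrix (horizon+1, compartments) over n individuals.

    Compartment columns match ``markov.Layout`` ordering: quit, smoke,
    early tunnel years 1..T, advanced tunnel years 1..T, early stable,
    advanced stable, dead.
    """
    epi = epi if epi is not None else config.epi
    rng = np.random.default_rng(seed)
    H, T = config.horizon, config.tunnel_years
    sex = config.sex
    split_early = config.stage_split_early

    state = np.where(rng.random(n) < strategy.quit_rate_12m, QUIT, SMOKE).astype(np.int8)
    dx_year = np.zeros(n, dtype=np.int16)     # years since diagnosis (1-based in tunnel)

    n_comp = 2 + 2 * T + 3
    counts = np.zeros((H + 1, n_comp))

    def tally(t: int) -> None:
        counts[t, 0] = np.sum(state == QUIT)
        counts[t, 1] = np.sum(state == SMOKE)
        for k in range(1, T + 1):
            counts[t, 1 + k] = np.sum((state == EARLY) & (dx_year == k))
            counts[t, 1 + T + k] = np.sum((state == ADV) & (dx_year == k))
        counts[t, 2 + 2 * T] = np.sum(state == EARLY_STABLE)
        counts[t, 2 + 2 * T + 1] = np.sum(state == ADV_STABLE)
        counts[t, 2 + 2 * T + 2] = np.sum(state == DEAD)

    tally(0)
    for t in range(H):
        age = config.cohort_start_age + t
        q = epi.mortality_at(age, sex)
        inc = epi.incidence_at(age, sex)
        new_state = state.copy()
        new_dx = dx_year.copy()

        # --- no-cancer states: death, onset, relapse (in that order) -----
        for s in (QUIT, SMOKE):
            idx = np.flatnonzero(state == s)
            if idx.size == 0:
                continue
            if s == QUIT:
                rr = epi.rr_ex_at(age, years_since_quit=t, sex=sex)
                p_rel = config.relapse.prob(t) * strategy.relapse_multiplier
                q_eff = q
            else:
                rr = epi.rr_current_smoker[sex]
                p_rel = 0.0
                q_eff = min(1.0, q * config.smoker_mortality_multiplier)
            dies = rng.random(idx.size) < q_eff
            new_state[idx[dies]] = DEAD
            alive = idx[~dies]
            onset = rng.random(alive.size) < inc * rr
            cases = alive[onset]
            early_case = rng.random(cases.size) < split_early
            new_state[cases[early_case]] = EARLY
            new_state[cases[~early_case]] = ADV
            new_dx[cases] = 1
            rest = alive[~onset]
            if p_rel > 0.0:
                rel = rng.random(rest.size) < p_rel
                new_state[rest[rel]] = SMOKE

        # --- cancer tunnels: combined death, then progression/advance ----
        for s, stage in ((EARLY, "early"), (ADV, "advanced")):
            idx = np.flatnonzero(state == s)
            if idx.size == 0:
                continue
            k = dx_year[idx]
            p_c = np.array([epi.cancer_death_at(stage, int(kk)) for kk in k])
            p_die = 1.0 - (1.0 - q) * (1.0 - p_c)
            dies = rng.random(idx.size) < p_die
            new_state[idx[dies]] = DEAD
            surv = idx[~dies]
            if s == EARLY and surv.size:
                prog = rng.random(surv.size) < config.progression_prob_early
                new_state[surv[prog]] = ADV
            adv1 = surv
            new_dx[adv1] = dx_year[adv1] + 1
            grads = adv1[new_dx[adv1] > T]
            for g in grads:
                new_state[g] = EARLY_STABLE if new_state[g] == EARLY else ADV_STABLE

        # --- stable survivors: background mortality only ------------------
        idx = np.flatnonzero((state == EARLY_STABLE) | (state == ADV_STABLE))
        if idx.size:
            dies = rng.random(idx.size) < q
            new_state[idx[dies]] = DEAD

        state, dx_year = new_state, new_dx
        tally(t + 1)

    return counts / n
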