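"""Anchored synthetic epidemiological tables.

The cohort model needs four age-indexed inputs that are normally taken from
national statistics: background all-cause mortality, background lung-cancer
incidence, relative risks of lung cancer for current and ex-smokers, and
lung-cancer survival by year since diagnosis.  This module generates those
tables from smooth parametric forms pinned exactly to published anchor
values, so the whole pipeline runs from a handful of scalars:

* all-cause mortality  — Gompertz: ``q(a) = q0 * exp(slope * (a - a0))``,
  anchored at q(65) = 0.00936;
* lung-cancer incidence — exponential in age, anchored at
  i(65) = 0.0018024;
* current-smoker relative risk — 6.609 (heavy smokers vs. general
  population);
* ex-smoker relative risk — exponential decay from the current-smoker RR
  toward a floor > 1 (risk stays elevated indefinitely), passing through
  RR = 4.75 for the 50-55 age group at the anchor years-since-quit;
* lung-cancer survival — cumulative survival 36% at 1 year falling to 12%
  at 5 years, log-linearly interpolated in between, decomposed into early
  and advanced stage curves whose case-mix-weighted average reproduces the
  printed curve.

Every anchor is reproduced exactly by construction; the functional forms and
shape parameters are this package's own modelling choices (see
docs/methods.md).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

AGE_MIN = 30
AGE_MAX = 100
AGES = np.arange(AGE_MIN, AGE_MAX + 1)
SEXES = ("both", "male", "female")

#: years-since-quit axis for the ex-smoker RR table (0 = quit this year)
YSQ_MAX = 85

#: 5-year age groups used for the ex-smoker RR table
AGE_GROUPS = [f"{a}-{a + 5}" for a in range(AGE_MIN, AGE_MAX, 5)]

TUNNEL_YEARS = 5


def _age_group_index(age: float) -> int:
    idx = int((min(max(age, AGE_MIN), AGE_MAX - 1) - AGE_MIN) // 5)
    return min(idx, len(AGE_GROUPS) - 1)


def make_mortality_table(anchor_age: float = 65.0,
                         anchor_rate: float = 0.00936,
                         slope: float = 0.09) -> np.ndarray:
    """Gompertz all-cause annual death probability for ages 30..100.

    ``q(age) = min(1, anchor_rate * exp(slope * (age - anchor_age)))``.
    ``slope = 0`` gives a constant table (useful for degenerate checks).
    """
    if not 0.0 < anchor_rate < 1.0:
        raise ValueError(f"anchor_rate must be in (0,1), got {anchor_rate}")
    if slope < 0:
        raise ValueError(f"slope must be non-negative, got {slope}")
    return np.minimum(1.0, anchor_rate * np.exp(slope * (AGES - anchor_age)))


def make_incidence_table(anchor_age: float = 65.0,
                         anchor_rate: float = 0.0018024,
                         slope: float = 0.08) -> np.ndarray:
    """Background annual lung-cancer incidence probability, exponential in age."""
    if not 0.0 < anchor_rate < 1.0:
        raise ValueError(f"anchor_rate must be in (0,1), got {anchor_rate}")
    if slope < 0:
        raise ValueError(f"slope must be non-negative, got {slope}")
    return np.minimum(1.0, anchor_rate * np.exp(slope * (AGES - anchor_age)))


def make_ex_smoker_rr(rr_smoker: float = 6.609,
                      anchor_value: float = 4.75,
                      anchor_ysq: int = 5,
                      floor: float = 1.5) -> np.ndarray:
    """Ex-smoker relative risk by (age group, years since quit).

    The curve starts at the current-smoker RR at 0 years since quit, decays
    exponentially, and asymptotes to ``floor`` (> 1: the excess risk never
    fully disappears).  The decay constant is solved so the curve passes
    exactly through ``anchor_value`` at ``anchor_ysq`` years since quit.
    The same curve is used for every age group (the published anchor is for
    ages 50-55; no age gradient is imposed).

    Returns an array of shape ``(len(AGE_GROUPS), YSQ_MAX + 1)``.
    """
    if not (rr_smoker >= anchor_value >= floor >= 1.0):
        raise ValueError(
            "require rr_smoker >= anchor >= floor >= 1, got "
            f"{rr_smoker} / {anchor_value} / {floor}")
    ysq = np.arange(YSQ_MAX + 1, dtype=float)
    if anchor_value == rr_smoker:
        curve = np.full_like(ysq, rr_smoker)
    else:
        # solve  floor + (rr - floor) * exp(-k * anchor_ysq) = anchor_value
        k = -np.log((anchor_value - floor) / (rr_smoker - floor)) / anchor_ysq
        curve = floor + (rr_smoker - floor) * np.exp(-k * ysq)
    return np.tile(curve, (len(AGE_GROUPS), 1))


def survival_to_conditional_death(survival: dict[int, float],
                                  n_years: int = TUNNEL_YEARS) -> tuple[np.ndarray, np.ndarray]:
    """Turn cumulative survival anchors into per-year conditional death probabilities.

    ``survival`` maps year-since-diagnosis to cumulative survival fraction
    (with S(0) = 1 implied).  Years between anchors are filled by log-linear
    interpolation of S; the conditional death probability in year k is
    ``1 - S(k)/S(k-1)``.  Beyond ``n_years`` the excess cancer hazard is
    taken to be zero (stable-disease survivorship; background mortality
    only), which is the engine's tail rule.

    Returns ``(S, p_death)`` where ``S`` has indices 0..n_years and
    ``p_death`` indices 0..n_years with ``p_death[0] = 0`` unused.
    """
    anchors = dict(sorted(survival.items()))
    for year, s in anchors.items():
        if not 0.0 < s <= 1.0:
            raise ValueError(f"survival S({year})={s} outside (0,1]")
    years = [0] + list(anchors)
    vals = [1.0] + list(anchors.values())
    if any(v2 > v1 for v1, v2 in zip(vals, vals[1:])):
        raise ValueError("cumulative survival must be non-increasing")
    grid = np.arange(n_years + 1, dtype=float)
    S = np.exp(np.interp(grid, years, np.log(vals)))
    p_death = np.zeros(n_years + 1)
    p_death[1:] = 1.0 - S[1:] / S[:-1]
    return S, p_death


def split_stage_survival(S_all: np.ndarray,
                         prop_early: float = 0.20,
                         advanced_power: float = 1.25) -> dict[str, np.ndarray]:
    """Decompose an all-stage survival curve into early/advanced stage curves.

    Advanced-stage survival is ``S_all ** advanced_power`` (a proportional
    log-survival penalty, power > 1 = worse); early-stage survival is then
    solved so the case mix at diagnosis (``prop_early`` early) reproduces the
    all-stage curve exactly:
    ``prop_early * S_early + (1 - prop_early) * S_adv = S_all``.
    """
    if advanced_power < 1.0:
        raise ValueError("advanced_power must be >= 1 (advanced survival is worse)")
    S_adv = S_all ** advanced_power
    S_early = (S_all - (1.0 - prop_early) * S_adv) / prop_early
    if np.any(S_early > 1.0 + 1e-12) or np.any(np.diff(S_early) >= 0):
        raise ValueError("early-stage survival decomposition not monotone in (0,1]; "
                         "reduce advanced_power")
    return {"all": S_all, "early": S_early, "advanced": S_adv}


@dataclass
class EpiTables:
    """Age-indexed epidemiological inputs consumed by the Markov engine.

    All per-age arrays are indexed by ``AGES`` (30..100); queries beyond the
    table are clamped to the last age.  ``sex`` keys are ``both``, ``male``,
    ``female``.
    """

    mortality: dict[str, np.ndarray]
    incidence: dict[str, np.ndarray]
    rr_current_smoker: dict[str, float]
    rr_ex_smoker: dict[str, np.ndarray]          # (age_group, years_since_quit)
    lc_survival: dict[str, np.ndarray]           # stage -> S[0..5]
    cancer_death: dict[str, np.ndarray]          # stage -> p_death[0..5]
    recipe: dict = field(default_factory=dict)   # provenance for rebuilds

    # -- queries ----------------------------------------------------------
    def _ai(self, age: float) -> int:
        if age < AGE_MIN:
            raise ValueError(f"age {age} below table minimum {AGE_MIN}")
        return int(min(age, AGE_MAX)) - AGE_MIN

    def mortality_at(self, age: float, sex: str = "both") -> float:
        return float(self.mortality[sex][self._ai(age)])

    def incidence_at(self, age: float, sex: str = "both") -> float:
        return float(self.incidence[sex][self._ai(age)])

    def rr_ex_at(self, age: float, years_since_quit: int, sex: str = "both") -> float:
        ysq = min(int(years_since_quit), YSQ_MAX)
        return float(self.rr_ex_smoker[sex][_age_group_index(age), ysq])

    def cancer_death_at(self, stage: str, year_since_dx: int) -> float:
        """Conditional cancer death probability; zero beyond the tunnel."""
        if year_since_dx < 1:
            raise ValueError("year_since_dx starts at 1")
        arr = self.cancer_death[stage]
        if year_since_dx >= len(arr):
            return 0.0
        return float(arr[year_since_dx])

    # -- validation -------------------------------------------------------
    def validate(self) -> None:
        for sex in SEXES:
            q, i = self.mortality[sex], self.incidence[sex]
            if np.any((q < 0) | (q > 1)) or np.any((i < 0) | (i > 1)):
                raise ValueError(f"probabilities outside [0,1] for sex={sex}")
            rr_s = self.rr_current_smoker[sex]
            rr_ex = self.rr_ex_smoker[sex]
            if np.any(rr_ex > rr_s + 1e-12):
                raise ValueError(f"ex-smoker RR exceeds current-smoker RR (sex={sex})")
            if np.any(rr_ex < 1.0):
                raise ValueError(f"ex-smoker RR falls below 1 (sex={sex})")
            if np.any(np.diff(rr_ex, axis=1) > 1e-12):
                raise ValueError(f"ex-smoker RR not non-increasing in years since quit (sex={sex})")
            if np.any(i * rr_s > 1.0):
                raise ValueError(f"RR x incidence exceeds 1 (sex={sex})")
        # male risk dominates female risk
        if np.any(self.incidence["male"] < self.incidence["female"]):
            raise ValueError("male incidence must dominate female incidence")
        for stage, S in self.lc_survival.items():
            if np.any(np.diff(S) >= 0):
                raise ValueError(f"{stage} survival not strictly decreasing")
            if np.any((S <= 0) | (S > 1)):
                raise ValueError(f"{stage} survival outside (0,1]")

    # -- I/O ---------------------------------------------------------------
    def to_dir(self, path: str | Path) -> None:
        """Write the tables as plain CSVs plus a JSON sidecar of scalars."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        rows = [(int(a), sex, float(self.mortality[sex][j]))
                for sex in SEXES for j, a in enumerate(AGES)]
        pd.DataFrame(rows, columns=["age", "sex", "value"]).to_csv(
            path / "mortality.csv", index=False)
        rows = [(int(a), sex, float(self.incidence[sex][j]))
                for sex in SEXES for j, a in enumerate(AGES)]
        pd.DataFrame(rows, columns=["age", "sex", "value"]).to_csv(
            path / "incidence.csv", index=False)
        rows = [(g, ysq, sex, float(self.rr_ex_smoker[sex][gi, ysq]))
                for sex in SEXES for gi, g in enumerate(AGE_GROUPS)
                for ysq in range(YSQ_MAX + 1)]
        pd.DataFrame(rows, columns=["age_group", "years_since_quit", "sex", "value"]
                     ).to_csv(path / "rr_ex_smoker.csv", index=False)
        rows = [(stage, k, float(S[k]))
                for stage, S in self.lc_survival.items() for k in range(len(S))]
        pd.DataFrame(rows, columns=["stage", "year_since_diagnosis", "cumulative_survival"]
                     ).to_csv(path / "lc_survival.csv", index=False)
        meta = {"rr_current_smoker": self.rr_current_smoker, "recipe": self.recipe}
        (path / "scalars.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def from_dir(cls, path: str | Path) -> "EpiTables":
        path = Path(path)
        meta = json.loads((path / "scalars.json").read_text())

        def per_sex(fname: str) -> dict[str, np.ndarray]:
            df = pd.read_csv(path / fname)
            out = {}
            for sex, grp in df.groupby("sex"):
                grp = grp.sort_values("age")
                if list(grp["age"]) != list(AGES):
                    raise ValueError(f"{fname}: ages must cover {AGE_MIN}..{AGE_MAX} for sex={sex}")
                out[sex] = grp["value"].to_numpy(float)
            return out

        rr_df = pd.read_csv(path / "rr_ex_smoker.csv")
        rr_ex = {}
        for sex, grp in rr_df.groupby("sex"):
            arr = np.empty((len(AGE_GROUPS), YSQ_MAX + 1))
            piv = grp.pivot(index="age_group", columns="years_since_quit", values="value")
            for gi, g in enumerate(AGE_GROUPS):
                arr[gi] = piv.loc[g].sort_index().to_numpy(float)
            rr_ex[sex] = arr
        surv_df = pd.read_csv(path / "lc_survival.csv")
        lc_survival, cancer_death = {}, {}
        for stage, grp in surv_df.groupby("stage"):
            S = grp.sort_values("year_since_diagnosis")["cumulative_survival"].to_numpy(float)
            lc_survival[stage] = S
            p = np.zeros(len(S))
            p[1:] = 1.0 - S[1:] / S[:-1]
            cancer_death[stage] = p
        tables = cls(mortality=per_sex("mortality.csv"),
                     incidence=per_sex("incidence.csv"),
                     rr_current_smoker={k: float(v) for k, v in meta["rr_current_smoker"].items()},
                     rr_ex_smoker=rr_ex,
                     lc_survival=lc_survival,
                     cancer_death=cancer_death,
                     recipe=meta.get("recipe", {}))
        tables.validate()
        return tables


DEFAULT_RECIPE: dict = {
    "mortality_anchor_age": 65, "mortality_anchor_rate": 0.00936, "mortality_slope": 0.09,
    "incidence_anchor_age": 65, "incidence_anchor_rate": 0.0018024, "incidence_slope": 0.08,
    "rr_current_smoker": 6.609,
    "ex_smoker_anchor_value": 4.75, "ex_smoker_anchor_ysq": 5, "rr_floor": 1.5,
    "lc_survival_anchors": {1: 0.36, 5: 0.12},
    "prop_early": 0.20, "advanced_power": 1.25,
    "male_incidence_multiplier": 1.30, "female_incidence_multiplier": 0.70,
    "male_mortality_multiplier": 1.15, "female_mortality_multiplier": 0.85,
}


def make_epi_tables(recipe: dict | None = None) -> EpiTables:
    """Build the full anchored table set from a deterministic, seed-free recipe.

    Unspecified entries fall back to :data:`DEFAULT_RECIPE`.  The "both"
    tables carry the anchors exactly; male/female tables apply the per-sex
    multipliers (male risk >= female risk).
    """
    r = {**DEFAULT_RECIPE, **(recipe or {})}
    # JSON round-trips turn int keys into strings
    surv_anchors = {int(k): float(v) for k, v in r["lc_survival_anchors"].items()}

    mort = make_mortality_table(r["mortality_anchor_age"], r["mortality_anchor_rate"],
                                r["mortality_slope"])
    inc = make_incidence_table(r["incidence_anchor_age"], r["incidence_anchor_rate"],
                               r["incidence_slope"])
    mortality = {"both": mort,
                 "male": np.minimum(1.0, mort * r["male_mortality_multiplier"]),
                 "female": np.minimum(1.0, mort * r["female_mortality_multiplier"])}
    incidence = {"both": inc,
                 "male": np.minimum(1.0, inc * r["male_incidence_multiplier"]),
                 "female": np.minimum(1.0, inc * r["female_incidence_multiplier"])}
    rr_ex = make_ex_smoker_rr(r["rr_current_smoker"], r["ex_smoker_anchor_value"],
                              r["ex_smoker_anchor_ysq"], r["rr_floor"])
    S_all, _ = survival_to_conditional_death(surv_anchors)
    lc_survival = split_stage_survival(S_all, r["prop_early"], r["advanced_power"])
    cancer_death = {}
    for stage, S in lc_survival.items():
        p = np.zeros(len(S))
        p[1:] = 1.0 - S[1:] / S[:-1]
        cancer_death[stage] = p
    tables = EpiTables(
        mortality=mortality,
        incidence=incidence,
        rr_current_smoker={s: float(r["rr_current_smoker"]) for s in SEXES},
        rr_ex_smoker={s: rr_ex.copy() for s in SEXES},
        lc_survival=lc_survival,
        cancer_death=cancer_death,
        recipe=r,
    )
    tables.validate()
    return tables
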