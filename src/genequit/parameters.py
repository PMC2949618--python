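"""Typed model inputs: strategies, costs, utilities, relapse, configuration.

Monetary line items are held as exact decimals so intervention cost totals
are exact to the cent; the cohort engine's accumulators are ordinary floats.

The configuration is one YAML document.  The age-indexed epidemiological
tables are referenced from it either as a directory of sidecar CSVs
(``epi: {tables_dir: ...}``) or as a deterministic synthetic recipe
(``epi: {synthetic: {...}}``) handed to :func:`genequit.synthetic_epi.make_epi_tables`.
"""

from __future__ import annotations

import copy
from decimal import Decimal
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

from . import synthetic_epi
from .synthetic_epi import EpiTables

Sex = Literal["both", "male", "female"]


class CostItem(BaseModel):
    """One intervention cost line: quantity x unit cost (2009 AU$)."""
    label: str
    quantity: int = Field(ge=0)
    unit_cost: Decimal = Field(ge=0)

    @property
    def total(self) -> Decimal:
        return self.quantity * self.unit_cost


class StrategyDefinition(BaseModel):
    """A named intervention arm: its cost build-up and behavioural effect."""
    name: str
    cost_items: list[CostItem] = Field(default_factory=list)
    quit_rate_12m: float = Field(ge=0.0, le=1.0)
    relapse_multiplier: float = Field(default=1.0, ge=0.0, le=1.0)


def intervention_cost(strategy: StrategyDefinition) -> Decimal:
    """Per-person intervention cost: exact sum of quantity x unit cost."""
    return sum((item.total for item in strategy.cost_items), Decimal("0"))


class RelapseSchedule(BaseModel):
    """Annual relapse probability among sustained quitters, by years since quit.

    Relapse applies from year 2 onward (the first year is the 12-month
    abstinence window that defines a quitter).  The canonical base case is
    10% in years 2-6 and 4% thereafter.
    """
    annual_probability: dict[int, float]

    @field_validator("annual_probability")
    @classmethod
    def _check(cls, v: dict[int, float]) -> dict[int, float]:
        for year, p in v.items():
            if year < 2:
                raise ValueError(f"relapse schedule years start at 2, got {year}")
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"relapse probability for year {year} = {p} outside [0,1]")
        return dict(sorted(v.items()))

    @classmethod
    def from_bands(cls, early: float = 0.10, late: float = 0.04,
                   early_through_year: int = 6, max_year: int = 120) -> "RelapseSchedule":
        probs = {y: (early if y <= early_through_year else late)
                 for y in range(2, max_year + 1)}
        return cls(annual_probability=probs)

    def prob(self, years_since_quit: int) -> float:
        if years_since_quit < 2:
            return 0.0
        try:
            return self.annual_probability[years_since_quit]
        except KeyError:
            raise ValueError(
                f"relapse schedule does not cover year {years_since_quit}") from None

    def covers(self, horizon: int) -> bool:
        return all(y in self.annual_probability for y in range(2, horizon + 1))

    def scaled(self, factor: float) -> "RelapseSchedule":
        return RelapseSchedule(annual_probability={
            y: min(1.0, p * factor) for y, p in self.annual_probability.items()})


class UtilitySet(BaseModel):
    no_lung_cancer: float = Field(default=1.0, ge=0.0, le=1.0)
    early_lc: float = Field(default=0.73, ge=0.0, le=1.0)
    advanced_lc: float = Field(default=0.66, ge=0.0, le=1.0)
    dead: float = 0.0

    @field_validator("dead")
    @classmethod
    def _dead_zero(cls, v: float) -> float:
        if v != 0.0:
            raise ValueError("utility of death is fixed at 0")
        return v


class CancerCostSchedule(BaseModel):
    """Annual lung-cancer healthcare costs (2009 AU$) by phase of care."""
    early_first_year: float = Field(default=44274.0, ge=0)
    advanced_first_year: float = Field(default=27057.0, ge=0)
    ongoing_stable: float = Field(default=7115.0, ge=0)
    progressive: float = Field(default=10945.0, ge=0)
    terminal_final_year: float = Field(default=9961.0, ge=0)


class DistributionSpec(BaseModel):
    """Uncertainty assignment for one parameter.

    ``low``/``high`` are read as a central 95% interval; beta (probabilities,
    utilities) and gamma (costs) parameters are obtained by moment matching
    with sd = (high - low) / (2 * 1.96).
    """
    family: Literal["beta", "gamma", "fixed"]
    mean: float
    low: Optional[float] = None
    high: Optional[float] = None

    @model_validator(mode="after")
    def _check(self) -> "DistributionSpec":
        if self.family != "fixed":
            if self.low is None or self.high is None:
                raise ValueError(f"{self.family} distribution needs low and high")
            if not self.low <= self.mean <= self.high:
                raise ValueError(
                    f"need low <= mean <= high, got {self.low}/{self.mean}/{self.high}")
            if self.family == "beta" and not (0 <= self.low and self.high <= 1):
                raise ValueError("beta support must lie in [0,1]")
            if self.family == "gamma" and self.low < 0:
                raise ValueError("gamma support must be non-negative")
        return self


class ModelConfig(BaseModel):
    """Everything needed for one model run (both arms)."""
    model_config = ConfigDict(arbitrary_types_allowed=True)

    cohort_start_age: int = Field(default=50, ge=synthetic_epi.AGE_MIN)
    horizon: int = Field(default=35, ge=1)
    cycle_length: Literal[1] = 1
    discount_rate: float = Field(default=0.05, ge=0.0, lt=1.0)
    wtp: float = Field(default=20000.0, ge=0.0)
    stage_split_early: float = Field(default=0.20, ge=0.0, le=1.0)
    sex: Sex = "both"
    usc: StrategyDefinition
    gt: StrategyDefinition
    relapse: RelapseSchedule
    utilities: UtilitySet = UtilitySet()
    cancer_costs: CancerCostSchedule = CancerCostSchedule()
    progression_prob_early: float = Field(default=0.15, ge=0.0, le=1.0)
    tunnel_years: int = Field(default=5, ge=5)
    half_cycle_correction: bool = False
    smoker_mortality_multiplier: float = Field(default=1.0, ge=1.0)
    psa_distributions: dict[str, DistributionSpec] = Field(default_factory=dict)
    epi: Optional[EpiTables] = Field(default=None, repr=False)
    epi_source: dict = Field(default_factory=dict)   # how epi was obtained

    @model_validator(mode="after")
    def _check(self) -> "ModelConfig":
        if not self.relapse.covers(self.horizon):
            raise ValueError("relapse schedule does not cover the model horizon")
        for name in self.psa_distributions:
            if name not in PARAMETERS:
                raise ValueError(f"psa distribution assigned to unknown parameter '{name}'")
        return self

    @property
    def stage_split_advanced(self) -> float:
        return 1.0 - self.stage_split_early

    def end_age(self) -> int:
        return self.cohort_start_age + self.horizon

    def copy_with(self, **updates) -> "ModelConfig":
        """Deep copy with top-level field updates (epi shared by reference)."""
        data = {f: copy.deepcopy(getattr(self, f)) for f in type(self).model_fields
                if f != "epi"}
        data["epi"] = self.epi
        data.update(updates)
        return ModelConfig(**data)


# ---------------------------------------------------------------------------
# parameter registry: dotted names used by sensitivity analysis and the PSA
# ---------------------------------------------------------------------------

def _set_relapse_band(cfg: ModelConfig, band: str, value: float) -> ModelConfig:
    sched = cfg.relapse.annual_probability
    years = [y for y in sched if (y <= 6) == (band == "early")]
    new = dict(sched)
    for y in years:
        new[y] = value
    return cfg.copy_with(relapse=RelapseSchedule(annual_probability=new))


def _set_item_cost(cfg: ModelConfig, arm: str, label: str, value: float) -> ModelConfig:
    strat = copy.deepcopy(getattr(cfg, arm))
    hits = [it for it in strat.cost_items if it.label == label]
    if not hits:
        raise KeyError(f"no cost item labelled '{label}' in arm '{arm}'")
    for it in hits:
        it.unit_cost = Decimal(str(round(value, 2)))
    return cfg.copy_with(**{arm: strat})


def _is_test_item(label: str) -> bool:
    """The genetic-test assay line itself (not clinic visits or booklets)."""
    low = label.lower()
    return ("genetic" in low or low == "test") and "booklet" not in low and "visit" not in low


def _scale_rr(cfg: ModelConfig, value: float) -> ModelConfig:
    """Set the current-smoker RR; the ex-smoker curve is rebuilt (synthetic
    recipe) or rescaled proportionally with a floor of 1 (loaded tables)."""
    epi = cfg.epi
    if epi.recipe:
        recipe = {**epi.recipe, "rr_current_smoker": value,
                  "ex_smoker_anchor_value": min(epi.recipe["ex_smoker_anchor_value"],
                                                value)}
        new_epi = synthetic_epi.make_epi_tables(recipe)
    else:
        import numpy as np
        new_epi = copy.deepcopy(epi)
        for sex in new_epi.rr_current_smoker:
            factor = value / new_epi.rr_current_smoker[sex]
            new_epi.rr_current_smoker[sex] = value
            new_epi.rr_ex_smoker[sex] = np.maximum(1.0, new_epi.rr_ex_smoker[sex] * factor)
    return cfg.copy_with(epi=new_epi)


#: name -> (getter, setter); the sensitivity module sweeps these, the PSA
#: samples them.  Every name here resolves to an existing model parameter.
PARAMETERS: dict = {
    "quit_rate_gt": (
        lambda c: c.gt.quit_rate_12m,
        lambda c, v: c.copy_with(gt=c.gt.model_copy(update={"quit_rate_12m": v}))),
    "quit_rate_usc": (
        lambda c: c.usc.quit_rate_12m,
        lambda c, v: c.copy_with(usc=c.usc.model_copy(update={"quit_rate_12m": v}))),
    "relapse_multiplier_gt": (
        lambda c: c.gt.relapse_multiplier,
        lambda c, v: c.copy_with(gt=c.gt.model_copy(update={"relapse_multiplier": v}))),
    "relapse_prob_early_years": (
        lambda c: c.relapse.prob(2),
        lambda c, v: _set_relapse_band(c, "early", v)),
    "relapse_prob_late_years": (
        lambda c: c.relapse.prob(7),
        lambda c, v: _set_relapse_band(c, "late", v)),
    "stage_split_early": (
        lambda c: c.stage_split_early,
        lambda c, v: c.copy_with(stage_split_early=v)),
    "utility_early_lc": (
        lambda c: c.utilities.early_lc,
        lambda c, v: c.copy_with(utilities=c.utilities.model_copy(update={"early_lc": v}))),
    "utility_advanced_lc": (
        lambda c: c.utilities.advanced_lc,
        lambda c, v: c.copy_with(utilities=c.utilities.model_copy(update={"advanced_lc": v}))),
    "cost_early_first_year": (
        lambda c: c.cancer_costs.early_first_year,
        lambda c, v: c.copy_with(cancer_costs=c.cancer_costs.model_copy(
            update={"early_first_year": v}))),
    "cost_advanced_first_year": (
        lambda c: c.cancer_costs.advanced_first_year,
        lambda c, v: c.copy_with(cancer_costs=c.cancer_costs.model_copy(
            update={"advanced_first_year": v}))),
    "cost_ongoing_stable": (
        lambda c: c.cancer_costs.ongoing_stable,
        lambda c, v: c.copy_with(cancer_costs=c.cancer_costs.model_copy(
            update={"ongoing_stable": v}))),
    "cost_progressive": (
        lambda c: c.cancer_costs.progressive,
        lambda c, v: c.copy_with(cancer_costs=c.cancer_costs.model_copy(
            update={"progressive": v}))),
    "cost_terminal": (
        lambda c: c.cancer_costs.terminal_final_year,
        lambda c, v: c.copy_with(cancer_costs=c.cancer_costs.model_copy(
            update={"terminal_final_year": v}))),
    "cost_genetic_test": (
        lambda c: float(next(it.unit_cost for it in c.gt.cost_items
                             if _is_test_item(it.label))),
        lambda c, v: _set_item_cost(
            c, "gt", next(it.label for it in c.gt.cost_items if _is_test_item(it.label)),
            v)),
    "rr_current_smoker": (
        lambda c: c.epi.rr_current_smoker[c.sex],
        _scale_rr),
    "progression_prob_early": (
        lambda c: c.progression_prob_early,
        lambda c, v: c.copy_with(progression_prob_early=v)),
    "discount_rate": (
        lambda c: c.discount_rate,
        lambda c, v: c.copy_with(discount_rate=v)),
}


def get_parameter(config: ModelConfig, name: str) -> float:
    try:
        getter, _ = PARAMETERS[name]
    except KeyError:
        raise KeyError(f"unknown model parameter '{name}'") from None
    return float(getter(config))


def set_parameter(config: ModelConfig, name: str, value: float) -> ModelConfig:
    try:
        _, setter = PARAMETERS[name]
    except KeyError:
        raise KeyError(f"unknown model parameter '{name}'") from None
    return setter(config, value)


# ---------------------------------------------------------------------------
# YAML I/O
# ---------------------------------------------------------------------------

def _strategy_to_dict(s: StrategyDefinition) -> dict:
    return {"name": s.name,
            "quit_rate_12m": s.quit_rate_12m,
            "relapse_multiplier": s.relapse_multiplier,
            "cost_items": [{"label": it.label, "quantity": it.quantity,
                            "unit_cost": str(it.unit_cost)} for it in s.cost_items]}


def config_to_dict(config: ModelConfig) -> dict:
    """Plain-dict (YAML-ready) form of the configuration."""
    relapse = config.relapse.annual_probability
    bands = None
    if relapse:
        early = {p for y, p in relapse.items() if y <= 6}
        late = {p for y, p in relapse.items() if y > 6}
        if len(early) == 1 and len(late) <= 1:
            bands = {"early": early.pop(), "late": (late.pop() if late else None),
                     "early_through_year": 6, "max_year": max(relapse)}
    doc = {
        "cohort": {"start_age": config.cohort_start_age, "horizon": config.horizon,
                   "sex": config.sex},
        "economics": {"discount_rate": config.discount_rate, "wtp": config.wtp},
        "strategies": {"usc": _strategy_to_dict(config.usc),
                       "gt": _strategy_to_dict(config.gt)},
        "relapse": ({"bands": bands} if bands else
                    {"annual_probability": {int(k): float(v) for k, v in relapse.items()}}),
        "utilities": {"no_lung_cancer": config.utilities.no_lung_cancer,
                      "early_lc": config.utilities.early_lc,
                      "advanced_lc": config.utilities.advanced_lc},
        "cancer_costs": config.cancer_costs.model_dump(),
        "stage_split_early": config.stage_split_early,
        "progression_prob_early": config.progression_prob_early,
        "tunnel_years": config.tunnel_years,
        "half_cycle_correction": config.half_cycle_correction,
        "smoker_mortality_multiplier": config.smoker_mortality_multiplier,
        "psa_distributions": {k: v.model_dump() for k, v in config.psa_distributions.items()},
        "epi": config.epi_source or {"synthetic": {}},
    }
    return doc


def config_from_dict(doc: dict, base_dir: Path | None = None) -> ModelConfig:
    try:
        cohort = doc.get("cohort", {})
        econ = doc.get("economics", {})
        strat = doc["strategies"]
        relapse_doc = doc.get("relapse", {})
        if "bands" in relapse_doc:
            b = relapse_doc["bands"]
            relapse = RelapseSchedule.from_bands(
                early=b["early"], late=b.get("late", b["early"]),
                early_through_year=b.get("early_through_year", 6),
                max_year=b.get("max_year", 120))
        else:
            relapse = RelapseSchedule(annual_probability={
                int(k): float(v) for k, v in relapse_doc["annual_probability"].items()})
        epi_doc = doc.get("epi", {"synthetic": {}})
        if "tables_dir" in epi_doc:
            tdir = Path(epi_doc["tables_dir"])
            if base_dir is not None and not tdir.is_absolute():
                tdir = base_dir / tdir
            epi = EpiTables.from_dir(tdir)
        else:
            epi = synthetic_epi.make_epi_tables(epi_doc.get("synthetic") or {})
        config = ModelConfig(
            cohort_start_age=cohort.get("start_age", 50),
            horizon=cohort.get("horizon", 35),
            sex=cohort.get("sex", "both"),
            discount_rate=econ.get("discount_rate", 0.05),
            wtp=econ.get("wtp", 20000.0),
            usc=StrategyDefinition(**strat["usc"]),
            gt=StrategyDefinition(**strat["gt"]),
            relapse=relapse,
            utilities=UtilitySet(**doc.get("utilities", {})),
            cancer_costs=CancerCostSchedule(**doc.get("cancer_costs", {})),
            stage_split_early=doc.get("stage_split_early", 0.20),
            progression_prob_early=doc.get("progression_prob_early", 0.15),
            tunnel_years=doc.get("tunnel_years", 5),
            half_cycle_correction=doc.get("half_cycle_correction", False),
            smoker_mortality_multiplier=doc.get("smoker_mortality_multiplier", 1.0),
            psa_distributions={k: DistributionSpec(**v)
                               for k, v in doc.get("psa_distributions", {}).items()},
            epi=epi,
            epi_source=epi_doc,
        )
    except KeyError as exc:
        raise ValueError(f"configuration missing required field: {exc}") from exc
    return config


def load_config(path: str | Path) -> ModelConfig:
    """Load and fully validate a model configuration from YAML."""
    path = Path(path)
    doc = yaml.safe_load(path.read_text())
    return config_from_dict(doc, base_dir=path.parent)


def write_config(config: ModelConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config_to_dict(config), sort_keys=False))


def basecase_path() -> Path:
    """Path of the packaged base-case configuration."""
    return Path(__file__).parent / "data" / "basecase.yaml"


def load_basecase() -> ModelConfig:
    return load_config(basecase_path())
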