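"""Configuration objects for the bread-fibre pipeline.

All tunable parameters of the pipeline live in pydantic models so that a run
is fully described by one YAML/JSON document: the synthetic-survey generator
(:class:`CohortConfig`), the wholegrain fibre threshold model
(:class:`ThresholdModel`), the habitual-intake estimator
(:class:`HabitualModelSpec`), the substitution scenarios (:class:`Scenario`)
and the end-to-end pipeline (:class:`PipelineConfig`).
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, Field, field_validator, model_validator

#: The five bread categories, in fixed declaration order.  This order also
#: breaks ties when ranking category contributions.
BREAD_CATEGORIES = ("white_wheat", "half_white_wheat", "dark_wheat", "mixed", "wholegrain")

AGE_GROUPS = ("adolescent", "adult", "older_adult")
SEXES = ("male", "female")

SIMPLEX_TOL = 1e-9


class ConfigError(ValueError):
    """A configuration field violates its invariant."""


def _check_simplex(name: str, weights: dict) -> None:
    total = sum(weights.values())
    if abs(total - 1.0) > SIMPLEX_TOL:
        raise ConfigError(f"{name}: weights must sum to 1 (got {total!r})")
    if any(w < 0 for w in weights.values()):
        raise ConfigError(f"{name}: weights must be non-negative")


class CohortConfig(BaseModel):
    """Parameters of the synthetic dietary-recall survey generator.

    Daily consumption of each bread category is zero-inflated: a Bernoulli
    consumption indicator per (person, day, category), with the person-level
    probability obtained as a logistic function of a latent person factor
    around the configured marginal probability, and a log-normal amount on
    consumption days with person-level (between) and day-level (within)
    variance components on the log scale.
    """

    n_persons: int = Field(gt=0)
    n_recall_days: int = Field(default=2, ge=1)
    age_group_weights: dict[str, float]
    sex_weights: dict[str, float]
    #: (age_group, sex, category) -> probability that the person consumes the
    #: category on a given day (marginal over the latent person factor).
    category_preference: dict[tuple[str, str, str], float]
    #: (age_group, sex, category) -> mean of log(amount in grams) on
    #: consumption days (before person/day random effects).
    amount_log_mean: dict[tuple[str, str, str], float]
    amount_log_sd_between: float = Field(gt=0)
    amount_log_sd_within: float = Field(gt=0)
    #: scale of the latent person factor on the logit of consumption.
    propensity_sd: float = Field(default=1.0, ge=0)
    #: correlation between the consumption-propensity factor and the
    #: amount person effect (the two parts may share one Gaussian factor).
    propensity_amount_corr: float = Field(default=0.0, ge=-1.0, le=1.0)
    covariate_weights: dict[str, dict[str, float]] = Field(default_factory=dict)
    seed: int = 0

    model_config = {"frozen": True}

    @field_validator("age_group_weights")
    @classmethod
    def _age_simplex(cls, v):
        _check_simplex("age_group_weights", v)
        if set(v) - set(AGE_GROUPS):
            raise ConfigError(f"age_group_weights: unknown groups {set(v) - set(AGE_GROUPS)}")
        return v

    @field_validator("sex_weights")
    @classmethod
    def _sex_simplex(cls, v):
        _check_simplex("sex_weights", v)
        if set(v) - set(SEXES):
            raise ConfigError(f"sex_weights: unknown sexes {set(v) - set(SEXES)}")
        return v

    @field_validator("category_preference")
    @classmethod
    def _probs(cls, v):
        for key, p in v.items():
            if not (0.0 <= p <= 1.0):
                raise ConfigError(f"category_preference[{key}]: probability {p} outside [0, 1]")
            if key[2] not in BREAD_CATEGORIES:
                raise ConfigError(
                    f"category_preference[{key}]: unknown category {key[2]!r}; "
                    f"allowed: {BREAD_CATEGORIES}"
                )
        return v

    @field_validator("covariate_weights")
    @classmethod
    def _cov_simplices(cls, v):
        for name, weights in v.items():
            _check_simplex(f"covariate_weights[{name}]", weights)
        return v


class ThresholdModel(BaseModel):
    """Minimum plausible fibre density of a regulation-compliant wholegrain bread.

    The threshold blends the fibre contents of wholegrain and white wheat
    flour at the regulatory minimum wholegrain share and dilutes by the
    maximum practical water uptake of the dough:

        T = (p * F_wg + (1 - p) * F_w) / (1 + w)    [g fibre / 100 g bread]

    with ``p`` the wholegrain flour fraction, ``F_wg``/``F_w`` the flour
    fibre densities (g/100 g flour) and ``w`` grams of water per gram flour.
    """

    p_wholegrain_flour: float = Field(default=0.8, ge=0.0, le=1.0)
    fibre_wholegrain_flour: float = Field(default=10.6, ge=0.0)
    fibre_white_flour: float = Field(default=2.7, ge=0.0)
    water_ratio: float = Field(default=0.7, ge=0.0)
    #: fibre exactly equal to the threshold still counts as wholegrain.
    boundary_inclusive: bool = True

    model_config = {"frozen": True}

    @model_validator(mode="after")
    def _flour_order(self):
        if self.fibre_wholegrain_flour < self.fibre_white_flour:
            raise ConfigError(
                "fibre_wholegrain_flour must be >= fibre_white_flour "
                f"({self.fibre_wholegrain_flour} < {self.fibre_white_flour})"
            )
        return self


class HabitualModelSpec(BaseModel):
    """Specification of the two-part habitual-intake estimator."""

    transform: Literal["log1p", "box_cox", "identity"] = "log1p"
    box_cox_lambda: float = 0.0
    covariates: tuple[str, ...] = ("age_group", "sex", "reporting_frequency")
    min_days: int = Field(default=2, ge=1)
    shrink: bool = True

    model_config = {"frozen": True}

    @field_validator("box_cox_lambda")
    @classmethod
    def _finite(cls, v):
        import math

        if not math.isfinite(v):
            raise ConfigError("box_cox_lambda must be finite")
        return v


class Scenario(BaseModel):
    """Partial replacement of one bread category by another."""

    name: str
    source_category: str = "white_wheat"
    target_category: str = "wholegrain"
    replace_fraction: float = Field(ge=0.0, le=1.0)

    model_config = {"frozen": True}

    @model_validator(mode="after")
    def _distinct(self):
        if self.source_category == self.target_category:
            raise ConfigError("source and target categories must differ")
        for cat in (self.source_category, self.target_category):
            if cat not in BREAD_CATEGORIES:
                raise ConfigError(f"unknown category {cat!r}; allowed: {BREAD_CATEGORIES}")
        return self


#: The two scenarios shipped by default: 30% and 50% replacement of white
#: wheat bread by wholegrain bread.
SCENARIO_A = Scenario(name="A", replace_fraction=0.3)
SCENARIO_B = Scenario(name="B", replace_fraction=0.5)


class PipelineConfig(BaseModel):
    """End-to-end pipeline run description."""

    samples_csv: Optional[Path] = None
    persons_csv: Optional[Path] = None
    events_csv: Optional[Path] = None
    simulate: Optional[CohortConfig] = None
    threshold: ThresholdModel = ThresholdModel()
    habitual: HabitualModelSpec = HabitualModelSpec()
    scenarios: tuple[Scenario, ...] = (SCENARIO_A, SCENARIO_B)
    density_override: Optional[dict[str, float]] = None
    out_dir: Path = Path("fibresub_out")
    seed: int = 0
    log_level: str = "INFO"

    @model_validator(mode="after")
    def _one_source(self):
        has_paths = self.persons_csv is not None and self.events_csv is not None
        has_sim = self.simulate is not None
        if has_paths == has_sim:
            raise ConfigError(
                "exactly one of {persons_csv+events_csv, simulate} must be given"
            )
        return self


def _tuple_keys(mapping: dict) -> dict:
    """YAML maps use 'age|sex|category' string keys; convert to tuples."""
    out = {}
    for k, v in mapping.items():
        out[tuple(k.split("|")) if isinstance(k, str) else tuple(k)] = v
    return out


def load_config(path: str | Path, model: type[BaseModel] = PipelineConfig) -> BaseModel:
    """Load a pydantic config from a YAML (or JSON) file."""
    raw = yaml.safe_load(Path(path).read_text())
    if model is CohortConfig or (model is PipelineConfig and raw.get("simulate")):
        block = raw if model is CohortConfig else raw["simulate"]
        for key in ("category_preference", "amount_log_mean"):
            if key in block:
                block[key] = _tuple_keys(block[key])
    return model.model_validate(raw)


def dump_config(cfg: BaseModel, path: str | Path) -> None:
    """Write a fully-resolved config (defaults included) as YAML."""
    data = cfg.model_dump(mode="python")

    def _stringify(obj):
        if isinstance(obj, dict):
            return {
                ("|".join(k) if isinstance(k, tuple) else str(k)): _stringify(v)
                for k, v in obj.items()
            }
        if isinstance(obj, (list, tuple)):
            return [_stringify(v) for v in obj]
        if isinstance(obj, Path):
            return str(obj)
        return obj

    Path(path).write_text(yaml.safe_dump(_stringify(data), sort_keys=True))
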