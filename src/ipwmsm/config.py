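"""Configuration objects for the synthetic cohort generator and the analysis pipeline.

The simulation configuration encodes the data-generating process of a new-user
post-stroke cohort: confounded treatment initiation inside a 90-day window,
covariate-dependent early (90-day) mortality, monthly discrete hazards for the
outcome of interest and for censoring, a time-varying "deterioration" state that
drives both treatment discontinuation and the outcome, and a configurable true
log hazard ratio for current treatment.  All per-interval hazards are logistic:
``P(event in interval) = expit(logit(base) + sum(coef * covariate))``.
"""
from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict, dataclass, field, replace
from typing import Optional

import yaml

from .errors import ConfigurationError

#: outcome event labels recognised throughout the pipeline
OUTCOME_LABELS = ("dementia", "CHD", "fracture", "peptic_ulcer")
#: labels used as control outcomes (dementia is the primary outcome)
CONTROL_OUTCOMES = ("CHD", "fracture", "peptic_ulcer")

LN = math.log


def _check_prob(name: str, p: float, upper_open: bool = False) -> None:
    hi_ok = p < 1.0 if upper_open else p <= 1.0
    if not (0.0 <= p and hi_ok):
        raise ConfigurationError(f"{name} must be a probability in [0, 1{')' if upper_open else ']'}: got {p}")


@dataclass
class LogisticHazard:
    """Per-interval event probability: expit(logit(base) + x'coef).

    ``base`` is the probability at the covariate reference (all covariates 0);
    ``coef`` maps design-column names (plus the special keys ``a0``, ``treat``
    and ``deter``) to log-odds effects.
    """

    base: float
    coef: dict[str, float] = field(default_factory=dict)

    def validate(self, name: str) -> None:
        _check_prob(f"{name}.base", self.base, upper_open=True)
        for k, v in self.coef.items():
            if not math.isfinite(v):
                raise ConfigurationError(f"{name}.coef[{k}] must be finite")


@dataclass
class BaselineSpec:
    """Baseline covariate distribution (age, sex, comorbidities, lifestyle, IMD, subtype)."""

    age_mean: float = 71.9
    age_sd: float = 12.5
    bmi_mean: float = 26.1
    bmi_sd: float = 4.8
    consult_mean: float = 28.0
    consult_sd: float = 12.0
    prevalence: dict[str, float] = field(
        default_factory=lambda: {
            "female": 0.519,
            "af": 0.182,
            "chd": 0.114,
            "diabetes": 0.092,
            "heart_failure": 0.061,
            "hypertension": 0.508,
        }
    )
    # (current, former, never)
    smoking: tuple[float, float, float] = (0.205, 0.304, 0.491)
    # IMD quintiles 1 (least deprived) .. 5
    imd: tuple[float, ...] = (0.216, 0.189, 0.218, 0.200, 0.177)
    # (ischaemic, unspecified, haemorrhagic); unspecified pooled with ischaemic by default
    subtype: tuple[float, float, float] = (0.475, 0.432, 0.093)

    def validate(self) -> None:
        for nm in ("age_sd", "bmi_sd", "consult_sd"):
            if getattr(self, nm) <= 0:
                raise ConfigurationError(f"baseline.{nm} must be > 0")
        for k, v in self.prevalence.items():
            _check_prob(f"baseline.prevalence[{k}]", v)
        for nm in ("smoking", "imd", "subtype"):
            probs = getattr(self, nm)
            for p in probs:
                _check_prob(f"baseline.{nm}", p)
            if abs(sum(probs) - 1.0) > 1e-9:
                raise ConfigurationError(f"baseline.{nm} must sum to 1")


@dataclass
class IneligibleSpec:
    """Rates at which records violating eligibility rules are injected, so that
    exclusion logic is exercised on every generated cohort."""

    prior_statin: float = 0.15
    prior_dementia: float = 0.03
    short_history: float = 0.05
    missing_smoking: float = 0.01
    missing_bmi: float = 0.12
    prior_fracture: float = 0.31
    prior_ulcer: float = 0.065

    def validate(self) -> None:
        for k, v in asdict(self).items():
            _check_prob(f"ineligible.{k}", v)


@dataclass
class TreatmentSpec:
    """Statin initiation within [0, window]: logistic in baseline covariates.

    If ``intercept`` is None it is calibrated so the marginal initiation
    proportion matches ``target``.
    """

    target: float = 0.56
    intercept: Optional[float] = None
    coef: dict[str, float] = field(
        default_factory=lambda: {
            "age_std": -0.45,
            "female": -0.20,
            "af": -0.50,
            "chd": -0.60,
            "diabetes": -0.30,
            "heart_failure": -0.90,
            "hypertension": -0.10,
            "smoke_current": 0.30,
            "bmi_std": 0.15,
            "consult_std": -0.25,
            "haemorrhagic": -1.90,
        }
    )

    def validate(self) -> None:
        _check_prob("treatment.target", self.target, upper_open=True)
        if self.target <= 0:
            raise ConfigurationError("treatment.target must be in (0, 1)")


@dataclass
class PersistenceSpec:
    """Monthly hazards of deviating from the initial strategy."""

    discontinuation: LogisticHazard = field(
        default_factory=lambda: LogisticHazard(0.020, {"deter": LN(2.0)})
    )
    crossover: LogisticHazard = field(
        default_factory=lambda: LogisticHazard(0.004, {"deter": 0.5})
    )

    def validate(self) -> None:
        self.discontinuation.validate("persistence.discontinuation")
        self.crossover.validate("persistence.crossover")


@dataclass
class OutcomeSpec:
    """One outcome process: monthly baseline hazard, treatment log-HR, covariate effects."""

    hazard: LogisticHazard
    log_hr: float = 0.0

    def validate(self, name: str) -> None:
        self.hazard.validate(f"outcomes[{name}].hazard")
        if not math.isfinite(self.log_hr):
            raise ConfigurationError(f"outcomes[{name}].log_hr must be finite")


def _default_outcomes() -> dict[str, OutcomeSpec]:
    return {
        "dementia": OutcomeSpec(
            LogisticHazard(
                0.0025,
                {"age_std": 0.5, "diabetes": 0.3, "heart_failure": 0.3, "af": 0.2, "deter": 0.7},
            ),
            log_hr=LN(0.70),
        ),
        "CHD": OutcomeSpec(
            LogisticHazard(0.0018, {"age_std": 0.4, "chd": 0.8, "diabetes": 0.3}),
            log_hr=LN(0.80),
        ),
        "fracture": OutcomeSpec(
            LogisticHazard(0.0022, {"age_std": 0.5, "female": 0.3}),
            log_hr=0.0,
        ),
        "peptic_ulcer": OutcomeSpec(
            LogisticHazard(0.0006, {"age_std": 0.2}),
            log_hr=0.0,
        ),
    }


@dataclass
class SimulationConfig:
    """All data-generating parameters, including the true treatment effect and seed.

    Identical config + seed yields byte-identical cohorts; each patient's
    randomness comes from a dedicated substream keyed by (seed, patient id), so
    a patient's record is invariant to cohort size and generation order.
    """

    n_patients: int = 20_000
    seed: int = 0
    max_months: int = 120
    baseline: BaselineSpec = field(default_factory=BaselineSpec)
    ineligible: IneligibleSpec = field(default_factory=IneligibleSpec)
    treatment: TreatmentSpec = field(default_factory=TreatmentSpec)
    #: probability of death/transfer before day 91 ("gone"), logistic in (L0, A0)
    selection: LogisticHazard = field(
        default_factory=lambda: LogisticHazard(
            0.16,
            {"a0": -2.2, "age_std": 0.8, "heart_failure": 0.7, "af": 0.3,
             "diabetes": 0.3, "haemorrhagic": 0.8},
        )
    )
    #: among 90-day losses, fraction that are deaths (remainder transfer out)
    selection_death_fraction: float = 0.81
    #: monthly hazard of leaving follow-up (death or transfer), logistic in (L0, treat, deter);
    #: effect sizes kept moderate so cumulative follow-up weights stay well distributed
    #: (mean ~1, no extreme values), matching the weight diagnostics a well-behaved
    #: cohort of this design exhibits
    followup_exit: LogisticHazard = field(
        default_factory=lambda: LogisticHazard(
            0.0055, {"treat": -0.2, "age_std": 0.4, "heart_failure": 0.3, "deter": 0.5}
        )
    )
    followup_death_fraction: float = 0.75
    #: monthly onset hazard of the binary deterioration state (absorbing)
    deterioration: LogisticHazard = field(
        default_factory=lambda: LogisticHazard(0.010, {"age_std": 0.3})
    )
    persistence: PersistenceSpec = field(default_factory=PersistenceSpec)
    outcomes: dict[str, OutcomeSpec] = field(default_factory=_default_outcomes)
    linkage_rate: float = 0.58
    history_days_range: tuple[int, int] = (400, 5000)

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ConfigurationError("n_patients must be >= 1")
        if self.max_months < 1:
            raise ConfigurationError("max_months must be >= 1")
        self.baseline.validate()
        self.ineligible.validate()
        self.treatment.validate()
        self.selection.validate("selection")
        _check_prob("selection_death_fraction", self.selection_death_fraction)
        self.followup_exit.validate("followup_exit")
        _check_prob("followup_death_fraction", self.followup_death_fraction)
        self.deterioration.validate("deterioration")
        self.persistence.validate()
        for name, spec in self.outcomes.items():
            if name not in OUTCOME_LABELS:
                raise ConfigurationError(f"unknown outcome label {name!r}")
            spec.validate(name)
        _check_prob("linkage_rate", self.linkage_rate)

    # -- serialisation -------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(json.loads(json.dumps(self.to_dict())), fh, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)

        def _haz(x):
            return LogisticHazard(**x) if isinstance(x, dict) and "base" in x else x

        if "baseline" in d:
            b = dict(d["baseline"])
            for k in ("smoking", "imd", "subtype"):
                if k in b:
                    b[k] = tuple(b[k])
            d["baseline"] = BaselineSpec(**b)
        if "ineligible" in d:
            d["ineligible"] = IneligibleSpec(**d["ineligible"])
        if "treatment" in d:
            d["treatment"] = TreatmentSpec(**d["treatment"])
        for k in ("selection", "followup_exit", "deterioration"):
            if k in d:
                d[k] = _haz(d[k])
        if "persistence" in d:
            p = d["persistence"]
            d["persistence"] = PersistenceSpec(
                discontinuation=_haz(p["discontinuation"]), crossover=_haz(p["crossover"])
            )
        if "outcomes" in d:
            d["outcomes"] = {
                k: OutcomeSpec(hazard=_haz(v["hazard"]), log_hr=v.get("log_hr", 0.0))
                for k, v in d["outcomes"].items()
            }
        if "history_days_range" in d:
            d["history_days_range"] = tuple(d["history_days_range"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=float)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def replace(self, **kw) -> "SimulationConfig":
        return replace(self, **kw)


def recovery_config(**overrides) -> SimulationConfig:
    """A confounded cohort with perfect treatment persistence.

    With discontinuation and crossover switched off, initiation at day 0 versus
    never coincides with the observed initiation strategies, so the ITT-analogue
    Model 3 estimate targets exactly the contrast of the counterfactual oracle.
    """
    cfg = SimulationConfig(**overrides)
    cfg.persistence = PersistenceSpec(
        discontinuation=LogisticHazard(0.0), crossover=LogisticHazard(0.0)
    )
    return cfg


@dataclass
class AnalysisOptions:
    """Tunable analysis-side parameters shared across pipeline stages."""

    window_days: int = 90          # initiation ascertainment window [0, window]
    supply_days: int = 30          # assumed days-supply when a prescription lacks one
    grace_days: int = 90           # grace period for declaring discontinuation
    max_months: int = 120          # administrative follow-up cap (10 years)
    truncation: str = "pct_1_99"   # pct_1_99 | pct_05_995 | fixed_0.1_10 | none
    time_kind: str = "rcs"         # rcs | linear | bins6 | categorical | none
    numerator_l0: bool = False     # include L0 in censoring-weight numerators
    separate_unspecified: bool = False
    impute_missing: Optional[str] = None  # None | "p5" | "p95"
    linked_only: bool = False
    exclude_months_4_6: bool = False
    extra_weight_covariates: tuple[str, ...] = ()

    def validate(self) -> None:
        if self.truncation not in ("pct_1_99", "pct_05_995", "fixed_0.1_10", "none"):
            raise ConfigurationError(f"unknown truncation method {self.truncation!r}")
        if self.time_kind not in ("rcs", "linear", "bins6", "categorical", "none"):
            raise ConfigurationError(f"unknown time function {self.time_kind!r}")
        if self.impute_missing not in (None, "p5", "p95"):
            raise ConfigurationError(f"impute_missing must be None, 'p5' or 'p95'")
        for nm in ("window_days", "supply_days", "grace_days", "max_months"):
            if getattr(self, nm) < 1:
                raise ConfigurationError(f"{nm} must be >= 1")
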