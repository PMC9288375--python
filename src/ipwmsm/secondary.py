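"""Control-outcome calibration, subgroup interactions, and sensitivity battery.

Control outcomes (CHD as positive control, fracture and peptic ulcer as
negative controls) share measured and unmeasured confounders with the primary
outcome; re-running the full weighted pipeline on them probes residual
confounding.  Indirect adjustment rescales the primary hazard ratio by a
negative-control hazard ratio under the assumption that unmeasured
confounding affects both associations with similar magnitude.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import apply_eligibility, build_person_intervals, outcome_model_rows
from .config import CONTROL_OUTCOMES, AnalysisOptions
from .design import default_knots, time_basis
from .errors import ConfigurationError, EstimationError
from .outcome import Z95, EffectEstimate, _fit_weighted_logit, run_nested_models
from .records import Cohort
from . import weights as wmod


def effect_from_ci(hr: float, lo: float, hi: float, outcome: str = "",
                   analysis: str = "", model: str = "3") -> EffectEstimate:
    """Reconstruct an estimate (with log-scale SE) from a printed HR and 95% CI."""
    if not (0 < lo <= hr <= hi):
        raise ConfigurationError("require 0 < lower <= HR <= upper")
    se = (np.log(hi) - np.log(lo)) / (2 * Z95)
    return EffectEstimate(outcome, analysis, model, hr, lo, hi, float(se), 0, 0, 0.0)


@dataclass
class AdjustedEstimate:
    hr: float
    ci_lower: float
    ci_upper: float
    se_log_hr: float
    method: str = "delta"


@dataclass
class CalibrationResult:
    """Primary estimate alongside control-outcome estimates and the
    indirectly adjusted hazard ratio."""

    primary: EffectEstimate
    controls: dict[str, EffectEstimate] = field(default_factory=dict)
    adjusted: Optional[AdjustedEstimate] = None
    note: str = ("Indirect adjustment assumes unmeasured confounding of similar "
                 "magnitude for the primary and negative-control outcomes, and "
                 "independent estimation errors between the two models.")


def indirect_adjustment(
    hr_primary: EffectEstimate,
    hr_negative_control: EffectEstimate,
    method: str = "delta",
    n_boot: int = 10_000,
    seed: int = 0,
) -> AdjustedEstimate:
    """Rescale the primary HR by a negative-control HR.

    Point estimate: primary / control.  With ``method='delta'`` the log-scale
    SE is sqrt(SE1^2 + SE2^2) assuming independent errors; ``'bootstrap'``
    draws the two log-HRs from independent normals and takes percentile
    bounds (an approximation with the same independence assumption).
    """
    for e in (hr_primary, hr_negative_control):
        if e.hr <= 0:
            raise ConfigurationError("hazard ratios must be positive")
    log_ratio = np.log(hr_primary.hr) - np.log(hr_negative_control.hr)
    se = float(np.sqrt(hr_primary.se_log_hr ** 2 + hr_negative_control.se_log_hr ** 2))
    if method == "delta":
        lo, hi = np.exp(log_ratio - Z95 * se), np.exp(log_ratio + Z95 * se)
    elif method == "bootstrap":
        rng = np.random.default_rng(seed)
        draws = (rng.normal(np.log(hr_primary.hr), hr_primary.se_log_hr, n_boot)
                 - rng.normal(np.log(hr_negative_control.hr),
                              hr_negative_control.se_log_hr, n_boot))
        lo, hi = np.exp(np.quantile(draws, [0.025, 0.975]))
    else:
        raise ConfigurationError(f"unknown CI method {method!r}")
    return AdjustedEstimate(float(np.exp(log_ratio)), float(lo), float(hi), se, method)


def run_control_outcomes(
    cohort: Cohort,
    analysis: str = "ITT",
    outcomes: tuple[str, ...] = CONTROL_OUTCOMES,
    options: AnalysisOptions | None = None,
) -> dict[str, list[EffectEstimate]]:
    """Full nested-model pipeline per control outcome, weights re-estimated.

    Eligibility is re-applied per outcome (patients with a prior occurrence
    of that control outcome are excluded from its cohort only).
    """
    results = {}
    for out in outcomes:
        if out not in CONTROL_OUTCOMES:
            raise ConfigurationError(f"{out!r} is not a control outcome")
        results[out] = run_nested_models(cohort, out, analysis, options)
    return results


def bonferroni_threshold(n_subgroups: int = 11, alpha: float = 0.05) -> float:
    return alpha / n_subgroups


_AGE_BINS = ((18, 64), (65, 74), (75, 84), (85, 200))


def subgroup_values(patients: pd.DataFrame, variable: str) -> pd.Series:
    """Categorical subgroup labels for a baseline covariate."""
    col = patients[variable]
    if variable == "age":
        age = pd.to_numeric(col)
        labels = pd.Series("", index=patients.index, dtype=object)
        for lo, hi in _AGE_BINS:
            labels[(age >= lo) & (age <= hi)] = f"{lo}-{hi if hi < 200 else '+'}"
        return labels
    if variable == "subtype":
        return col.where(col == "haemorrhagic", "ischaemic")
    return col.astype(str)


@dataclass
class SubgroupResult:
    variable: str
    strata: pd.DataFrame               # per-stratum HR + CI
    p_interaction: float
    threshold: float
    significant: bool


def subgroup_analysis(
    cohort: Cohort,
    variable: str,
    analysis: str = "ITT",
    outcome: str = "dementia",
    options: AnalysisOptions | None = None,
    n_subgroups: int = 11,
) -> SubgroupResult:
    """Model-3 fit with an exposure x subgroup interaction, overall weights.

    The interaction enters the primary full-adjustment model; the weights are
    the overall Model-3 weights, not subgroup-specific ones.  The Wald test
    of the interaction coefficients is compared against the Bonferroni
    threshold alpha / n_subgroups.  Per-stratum HRs are linear combinations
    from the interaction model, with robust covariance.
    """
    options = options or AnalysisOptions()
    elig, _ = apply_eligibility(cohort, outcome, options)
    intervals = build_person_intervals(elig, analysis, outcome, options)
    ws = wmod.estimate_weights(elig, intervals, analysis, options)
    rows = outcome_model_rows(intervals)
    w = ws.combined(3).loc[rows.index].to_numpy()

    pat = elig.patients_frame().set_index("patient_id")
    groups = subgroup_values(pat, variable)
    g_rows = groups.loc[rows["patient_id"]].reset_index(drop=True)
    levels = sorted(g_rows.unique())
    if len(levels) < 2:
        raise EstimationError(f"subgroup variable {variable!r} has a single level")
    # drop strata without events in both arms
    kept = []
    for lev in levels:
        m = (g_rows == lev).to_numpy()
        y, a = rows["y"].to_numpy()[m], rows["a0"].to_numpy()[m]
        if y[a == 1].sum() > 0 and y[a == 0].sum() > 0:
            kept.append(lev)
        else:
            import warnings

            warnings.warn(f"stratum {variable}={lev}: zero events in an arm; omitted",
                          stacklevel=2)
    if len(kept) < 2:
        raise EstimationError("fewer than two informative strata")
    mask = g_rows.isin(kept).to_numpy()
    rows, g_rows, w = rows.loc[mask].reset_index(drop=True), \
        g_rows[mask].reset_index(drop=True), w[mask]

    a = rows["a0"].to_numpy(dtype=float)
    knots = default_knots(rows["t"].to_numpy()) if options.time_kind == "rcs" else None
    tb = time_basis(rows["t"].to_numpy(), kind=options.time_kind, knots=knots)
    tb.index = pd.RangeIndex(len(rows))
    X = pd.DataFrame({"a0": a})
    ref, others = kept[0], kept[1:]
    for lev in others:
        d = (g_rows == lev).astype(float).to_numpy()
        X[f"g_{lev}"] = d
        X[f"a0_x_{lev}"] = a * d
    X = pd.concat([X, tb], axis=1)
    params, cov = _fit_weighted_logit(X, rows["y"].to_numpy(dtype=float), w,
                                      rows["patient_id"].to_numpy())
    int_names = [f"a0_x_{lev}" for lev in others]
    beta = params[int_names].to_numpy()
    V = cov.loc[int_names, int_names].to_numpy()
    wald = float(beta @ np.linalg.solve(V, beta))
    p_int = float(stats.chi2.sf(wald, df=len(int_names)))
    strata_rows = []
    for lev in kept:
        if lev == ref:
            b = float(params["a0"])
            var = float(cov.loc["a0", "a0"])
        else:
            nm = f"a0_x_{lev}"
            b = float(params["a0"] + params[nm])
            var = float(cov.loc["a0", "a0"] + cov.loc[nm, nm] + 2 * cov.loc["a0", nm])
        se = np.sqrt(var)
        strata_rows.append({
            "stratum": lev, "hr": np.exp(b),
            "ci_lower": np.exp(b - Z95 * se), "ci_upper": np.exp(b + Z95 * se),
        })
    thr = bonferroni_threshold(n_subgroups)
    return SubgroupResult(variable, pd.DataFrame(strata_rows), p_int, thr, p_int < thr)


DEFAULT_VARIANTS: dict[str, dict] = {
    "trunc_none": {"truncation": "none"},
    "trunc_pct_05_995": {"truncation": "pct_05_995"},
    "trunc_fixed_0.1_10": {"truncation": "fixed_0.1_10"},
    "impute_p5": {"impute_missing": "p5"},
    "impute_p95": {"impute_missing": "p95"},
    "separate_unspecified": {"separate_unspecified": True},
    "linked_only": {"linked_only": True},
    "exclude_months_4_6": {"exclude_months_4_6": True},
    "window_30": {"window_days": 30},
    "window_180": {"window_days": 180},
    "grace_30": {"grace_days": 30},
    "grace_150": {"grace_days": 150},
    "fracture_in_weights": {"extra_weight_covariates": ("fracture",)},
}


def run_sensitivity_battery(
    cohort: Cohort,
    analyses: tuple[str, ...] = ("ITT", "PP"),
    variants: dict[str, dict] | None = None,
    base_options: AnalysisOptions | None = None,
    outcome: str = "dementia",
) -> pd.DataFrame:
    """Execute the sensitivity-analysis variants, weights re-estimated per variant.

    Every variant runs through the identical pipeline code path
    (:func:`run_nested_models`) with modified options; a variant's failure is
    recorded and does not abort the battery.  The fracture-in-weights variant
    additionally reports the indirectly adjusted HR against the fracture
    control outcome.
    """
    from dataclasses import replace as dc_replace

    variants = DEFAULT_VARIANTS if variants is None else variants
    base = base_options or AnalysisOptions()
    rows = []
    for name, overrides in variants.items():
        opts = dc_replace(base, **overrides)
        try:
            opts.validate()
        except ConfigurationError as exc:
            rows.append({"variant": name, "error": str(exc)})
            continue
        for analysis in analyses:
            try:
                ests = run_nested_models(cohort, outcome, analysis, opts)
                m3 = next(e for e in ests if e.model == "3")
                row = {
                    "variant": name, "analysis": analysis,
                    "hr": m3.hr, "ci_lower": m3.ci_lower, "ci_upper": m3.ci_upper,
                    "n_patients": m3.n_patients, "n_events": m3.n_events,
                    "options_hash": _options_hash(opts), "error": None,
                }
                if name == "fracture_in_weights":
                    ctrl = run_nested_models(cohort, "fracture", analysis, opts)
                    c3 = next(e for e in ctrl if e.model == "3")
                    adj = indirect_adjustment(m3, c3)
                    row.update({"adjusted_hr": adj.hr,
                                "adjusted_ci_lower": adj.ci_lower,
                                "adjusted_ci_upper": adj.ci_upper})
                rows.append(row)
            except Exception as exc:  # keep going: one variant must not sink the rest
                rows.append({"variant": name, "analysis": analysis, "error": str(exc)})
    return pd.DataFrame(rows)


def _options_hash(options: AnalysisOptions) -> str:
    import hashlib
    import json
    from dataclasses import asdict

    blob = json.dumps(asdict(options), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]
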