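"""Weighted pooled logistic outcome models with cluster-robust variance.

The discrete-time hazard of the analysis outcome is modelled by logistic
regression on person-interval rows: outcome indicator regressed on the
baseline exposure-group indicator and a flexible function of follow-up time,
with each row weighted by the final stabilised IP weight.  With short
intervals and a rare outcome the exposure coefficient approximates the log
hazard ratio of a time-dependent Cox model.  Standard errors come from a
sandwich (robust) variance estimator with scores aggregated within patients,
accounting for the correlation induced by weighting and repeated rows.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import weights as wmod
from ._glm import fit_logit
from .cohort import apply_eligibility, build_person_intervals, outcome_model_rows, person_years
from .config import AnalysisOptions
from .design import default_knots, time_basis
from .errors import ConfigurationError, EstimationError
from .records import Cohort

Z95 = 1.959963984540054


@dataclass
class EffectEstimate:
    """One hazard-ratio estimate: outcome x analysis x adjustment level."""

    outcome: str
    analysis: str                  # "ITT" | "PP"
    model: str                     # "crude" | "1" | "2" | "3"
    hr: float
    ci_lower: float
    ci_upper: float
    se_log_hr: float
    n_patients: int
    n_events: int
    person_years: float
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "outcome": self.outcome, "analysis": self.analysis, "model": self.model,
            "hr": self.hr, "ci_lower": self.ci_lower, "ci_upper": self.ci_upper,
            "se_log_hr": self.se_log_hr, "n_patients": self.n_patients,
            "n_events": self.n_events, "person_years": self.person_years,
        }


def robust_variance(X: np.ndarray, y: np.ndarray, mu: np.ndarray,
                    weights: np.ndarray, clusters: np.ndarray) -> np.ndarray:
    """Cluster-robust sandwich covariance for a weighted logistic fit.

    Bread: inverse weighted Fisher information.  Meat: outer products of
    per-cluster sums of the weighted score contributions w * x * (y - mu),
    with the usual G/(G-1) * (N-1)/(N-k) small-sample factor.
    """
    X = np.asarray(X, dtype=float)
    resid = np.asarray(weights) * (np.asarray(y) - np.asarray(mu))
    scores = X * resid[:, None]
    df = pd.DataFrame(scores)
    grouped = df.groupby(np.asarray(clusters)).sum().to_numpy()
    G = grouped.shape[0]
    if G < 2:
        raise EstimationError("robust variance needs at least two clusters")
    info = X.T @ (X * (np.asarray(weights) * mu * (1 - mu))[:, None])
    bread = np.linalg.inv(info)
    meat = grouped.T @ grouped
    n, k = X.shape
    corr = (G / (G - 1)) * ((n - 1) / max(n - k, 1))
    return bread @ meat @ bread * corr


def _fit_weighted_logit(X: pd.DataFrame, y: np.ndarray, w: np.ndarray,
                        clusters: np.ndarray):
    """Weighted logistic fit returning (params Series, robust cov DataFrame)."""
    names = ["const"] + list(X.columns)
    Xc = np.column_stack([np.ones(len(X)), X.to_numpy(dtype=np.float64)])
    b, mu, converged = fit_logit(Xc, y, w)
    if not converged:
        raise EstimationError("outcome model did not converge")
    mu = np.clip(mu, 1e-12, 1 - 1e-12)
    cov = robust_variance(Xc, y, mu, w, clusters)
    params = pd.Series(b, index=names)
    covdf = pd.DataFrame(cov, index=names, columns=names)
    return params, covdf


def fit_pooled_logistic(
    rows: pd.DataFrame,
    weights: Optional[pd.Series] = None,
    outcome: str = "dementia",
    analysis: str = "ITT",
    model: str = "3",
    time_kind: str = "rcs",
) -> EffectEstimate:
    """Fit the weighted pooled logistic model on person-interval rows.

    ``rows`` should already be restricted to the rows entering the outcome
    model (see :func:`ipwmsm.cohort.outcome_model_rows`).  ``weights`` of
    None means unit weights (the crude model).
    """
    if rows.empty:
        raise EstimationError("no person-interval rows supplied")
    y = rows["y"].to_numpy(dtype=float)
    a = rows["a0"].to_numpy(dtype=float)
    for g in (0, 1):
        if y[a == g].sum() == 0:
            raise EstimationError(
                f"zero outcome events in exposure group a0={g} "
                f"({int((a == g).sum())} rows); cannot estimate a hazard ratio")
    w = np.ones(len(rows)) if weights is None else np.asarray(weights, dtype=float)
    if np.any(w <= 0) or not np.all(np.isfinite(w)):
        raise ConfigurationError("weights must be positive and finite")
    knots = default_knots(rows["t"].to_numpy()) if time_kind == "rcs" else None
    tb = time_basis(rows["t"].to_numpy(), kind=time_kind, knots=knots)
    tb.index = pd.RangeIndex(len(rows))
    X = pd.concat([pd.DataFrame({"a0": a}), tb], axis=1)
    params, cov = _fit_weighted_logit(X, y, w, rows["patient_id"].to_numpy())
    b = float(params["a0"])
    se = float(np.sqrt(cov.loc["a0", "a0"]))
    return EffectEstimate(
        outcome=outcome, analysis=analysis, model=model,
        hr=float(np.exp(b)),
        ci_lower=float(np.exp(b - Z95 * se)),
        ci_upper=float(np.exp(b + Z95 * se)),
        se_log_hr=se,
        n_patients=int(rows["patient_id"].nunique()),
        n_events=int(y.sum()),
        person_years=person_years(rows),
        extra={"log_hr": b},
    )


def run_nested_models(
    cohort: Cohort,
    outcome: str = "dementia",
    analysis: str = "ITT",
    options: AnalysisOptions | None = None,
    eligible: bool = False,
) -> list[EffectEstimate]:
    """Crude and Model 1/2/3 estimates for one outcome and analysis type.

    Applies eligibility (unless ``eligible`` says the cohort already is),
    builds the person-interval table (with artificial censoring applied in
    all PP models), estimates all weight components, and fits the outcome
    model with the per-level combined truncated weights.  The crude model
    uses unit weights on the same rows.
    """
    options = options or AnalysisOptions()
    if eligible:
        elig = cohort
    else:
        elig, _ = apply_eligibility(cohort, outcome, options)
    intervals = build_person_intervals(elig, analysis, outcome, options)
    if intervals.empty:
        raise EstimationError("no person-intervals after cohort construction")
    ws = wmod.estimate_weights(elig, intervals, analysis, options)
    rows = outcome_model_rows(intervals)
    results = [
        fit_pooled_logistic(rows, None, outcome, analysis, "crude", options.time_kind)
    ]
    for level in (1, 2, 3):
        w_rows = ws.combined(level).loc[rows.index]
        est = fit_pooled_logistic(rows, w_rows, outcome, analysis, str(level),
                                  options.time_kind)
        est.extra["truncation"] = ws.meta.get(f"truncation_model{level}")
        results.append(est)
    return results


def estimates_frame(estimates: list[EffectEstimate]) -> pd.DataFrame:
    """Long table of estimates mirroring the published effect tables."""
    return pd.DataFrame([e.to_dict() for e in estimates])
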