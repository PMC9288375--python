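"""Stabilised inverse-probability weights for the marginal structural models.

Four components, each a ratio of a marginal (numerator) to a
covariate-conditional (denominator) probability of the observed history:

* baseline treatment weights — confounding of initiation by L0;
* baseline selection weights — the requirement to survive the first 90 days;
* follow-up (censoring) weights — informative loss to follow-up, cumulative
  over intervals;
* treatment persistence weights — artificial censoring at deviation from the
  initial strategy (PP analysis only), cumulative over intervals and fitted
  separately per exposure group because "deviation" means opposite actions in
  the two groups.

All component models are main-effects logistic regressions; fitted
probabilities are clipped to [1e-6, 1 - 1e-6] before ratio formation.  The
final combined weight per adjustment level is truncated (percentile or fixed
bounds) across all person-intervals entering that outcome model.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from ._glm import fit_logit
from .cohort import classify_exposure, INITIATOR
from .config import AnalysisOptions
from .design import baseline_design, default_knots, time_basis
from .errors import ConfigurationError, EstimationError
from .records import Cohort

_CLIP = 1e-6
#: time-varying covariates offered to interval-level denominator models
_TV_COLS = ("l_deter",)


def _fit_probs(y: np.ndarray, X: pd.DataFrame, what: str) -> np.ndarray:
    """Fit a logistic regression and return clipped fitted probabilities."""
    y = np.asarray(y, dtype=float)
    if y.min() == y.max():
        # degenerate: outcome constant -> probability is the constant itself
        return np.full(len(y), np.clip(y.mean(), _CLIP, 1 - _CLIP))
    names = ["const"] + list(X.columns)
    Xc = np.column_stack([np.ones(len(X)), X.to_numpy(dtype=np.float64)])
    try:
        params, mu, converged = fit_logit(Xc, y)
    except EstimationError as exc:
        raise EstimationError(f"{what}: {exc}") from exc
    bad = np.abs(params) > 15.0
    if bad.any():
        culprit = [nm for nm, b in zip(names, bad) if b]
        raise EstimationError(f"{what}: separation suspected (covariates {culprit})")
    if not converged:
        raise EstimationError(f"{what}: logistic fit did not converge")
    return np.clip(mu, _CLIP, 1 - _CLIP)


def fit_baseline_treatment_weights(X0: pd.DataFrame, a0: pd.Series) -> pd.Series:
    """Stabilised baseline treatment weights, one per eligible patient.

    Denominator: fitted P(A0 = observed | L0) from logistic regression over
    all eligible patients.  Numerator: the marginal proportion of the
    patient's own group.
    """
    a = np.asarray(a0, dtype=float)
    if a.min() == a.max():
        raise EstimationError("treatment weights need both exposure groups present")
    p1 = _fit_probs(a, X0, "baseline treatment model")
    pa1 = a.mean()
    num = np.where(a == 1, pa1, 1 - pa1)
    den = np.where(a == 1, p1, 1 - p1)
    return pd.Series(num / den, index=a0.index, name="sw_treat")


def fit_baseline_selection_weights(X0: pd.DataFrame, a0: pd.Series,
                                   s: pd.Series) -> pd.Series:
    """Stabilised baseline selection weights for 90-day survivors.

    S indicates being alive and under observation at the start of time at
    risk.  Denominator: P(S=1 | L0, A0); numerator: P(S=1 | A0).  All
    eligible patients contribute to fitting; weights are returned for
    everyone (only survivors' weights are used downstream).
    """
    sv = np.asarray(s, dtype=float)
    a = np.asarray(a0, dtype=float)
    if sv.min() == sv.max():
        warnings.warn("no 90-day losses: selection weights set to 1", stacklevel=2)
        return pd.Series(1.0, index=a0.index, name="sw_select")
    Xden = X0.copy()
    Xden["a0"] = a
    den = _fit_probs(sv, Xden, "baseline selection model (denominator)")
    num = _fit_probs(sv, pd.DataFrame({"a0": a}, index=X0.index),
                     "baseline selection model (numerator)")
    return pd.Series(num / den, index=a0.index, name="sw_select")


def _interval_design(rows: pd.DataFrame, X0: pd.DataFrame, include_l0: bool,
                     include_tv: bool, time_kind: str, knots,
                     extra_tv: tuple[str, ...] = ()) -> pd.DataFrame:
    parts = [pd.DataFrame({"a0": rows["a0"].to_numpy(dtype=float)})]
    if include_l0:
        parts.append(X0.loc[rows["patient_id"]].reset_index(drop=True))
    if include_tv:
        for c in _TV_COLS + tuple(extra_tv):
            parts.append(pd.DataFrame({c: rows[c].to_numpy(dtype=float)}))
    tb = time_basis(rows["t"].to_numpy(), kind=time_kind, knots=knots)
    tb.index = pd.RangeIndex(len(rows))
    parts.append(tb)
    X = pd.concat(parts, axis=1)
    # drop columns constant over these rows (e.g. a0 within one exposure group)
    keep = [c for c in X.columns if X[c].nunique() > 1]
    return X[keep]


def _cumulative_ratio(rows: pd.DataFrame, num: np.ndarray, den: np.ndarray,
                      name: str) -> pd.Series:
    """Cumulative stabilised weight, lagged one interval.

    Within an interval the outcome takes precedence over censoring, so a row
    at interval t requires remaining uncensored only through the *start* of
    t; its weight is the product of the stabilised factors for intervals
    1..t-1 (1 for the first interval).  Using the un-lagged product would
    differentially over-weight event rows in strata with high censoring
    hazard.
    """
    factor = pd.Series(num / den, index=rows.index)
    cum = factor.groupby(rows["patient_id"]).cumprod()
    return cum.groupby(rows["patient_id"]).shift(1).fillna(1.0).rename(name)


def fit_followup_censoring_weights(
    rows: pd.DataFrame, X0: pd.DataFrame,
    time_kind: str = "rcs", numerator_l0: bool = False,
    extra_tv: tuple[str, ...] = (),
) -> pd.Series:
    """Cumulative stabilised follow-up (censoring) weights per person-interval.

    Models remaining uncensored (1 - C_t, death/transfer only; administrative
    censoring is treated as non-informative) on (A0, L0, L_t, time) for the
    denominator and (A0, time) for the numerator; the weight at interval t is
    the cumulative product of numerator/denominator probabilities over the
    intervals before t (see :func:`_cumulative_ratio` for the alignment).
    """
    uncens = 1.0 - rows["c_dt"].to_numpy(dtype=float)
    if uncens.min() == uncens.max():
        warnings.warn("no death/transfer censoring events: follow-up weights set to 1",
                      stacklevel=2)
        return pd.Series(1.0, index=rows.index, name="sw_cens")
    knots = default_knots(rows["t"].to_numpy()) if time_kind == "rcs" else None
    Xden = _interval_design(rows, X0, True, True, time_kind, knots, extra_tv)
    Xnum = _interval_design(rows, X0, numerator_l0, False, time_kind, knots)
    den = _fit_probs(uncens, Xden, "follow-up censoring model (denominator)")
    num = _fit_probs(uncens, Xnum, "follow-up censoring model (numerator)")
    return _cumulative_ratio(rows, num, den, "sw_cens")


def fit_persistence_weights(
    rows: pd.DataFrame, X0: pd.DataFrame,
    time_kind: str = "rcs", extra_tv: tuple[str, ...] = (),
) -> pd.Series:
    """Cumulative stabilised treatment-persistence weights (PP analysis).

    Models remaining on the assigned strategy (1 - AC_t) on (L0, L_t, time),
    fitted separately within each exposure group; numerator conditions on
    time only (A0 is constant within group).  A group with zero deviations
    receives unit weights with a warning.
    """
    out = pd.Series(1.0, index=rows.index, name="sw_pers")
    for g, sub in rows.groupby("a0"):
        stay = 1.0 - sub["ac"].to_numpy(dtype=float)
        if stay.min() == stay.max():
            warnings.warn(f"exposure group a0={g}: no strategy deviations; "
                          "persistence weights set to 1", stacklevel=2)
            continue
        knots = default_knots(sub["t"].to_numpy()) if time_kind == "rcs" else None
        Xden = _interval_design(sub, X0, True, True, time_kind, knots, extra_tv)
        Xnum = _interval_design(sub, X0, False, False, time_kind, knots)
        den = _fit_probs(stay, Xden, f"persistence model a0={g} (denominator)")
        num = _fit_probs(stay, Xnum, f"persistence model a0={g} (numerator)")
        out.loc[sub.index] = _cumulative_ratio(sub, num, den, "sw_pers")
    return out


def combine_weights(level: int, analysis: str, sw_treat: pd.Series,
                    sw_select: Optional[pd.Series] = None,
                    sw_cens: Optional[pd.Series] = None,
                    sw_pers: Optional[pd.Series] = None) -> pd.Series:
    """Combined weight per adjustment level.

    Level 1: treatment weight only.  Level 2: x selection.  Level 3 (ITT):
    x follow-up.  Level 3 (PP): x persistence as well.
    """
    if analysis not in ("ITT", "PP"):
        raise ConfigurationError(f"analysis must be ITT or PP, got {analysis!r}")
    if analysis == "ITT" and sw_pers is not None:
        raise ConfigurationError("persistence weights are not defined for ITT analysis")
    if level not in (1, 2, 3):
        raise ConfigurationError(f"model level must be 1, 2 or 3, got {level!r}")
    w = sw_treat.copy()
    if level >= 2:
        if sw_select is None:
            raise ConfigurationError("level >= 2 requires selection weights")
        w = w * sw_select
    if level >= 3:
        if sw_cens is None:
            raise ConfigurationError("level 3 requires follow-up weights")
        w = w * sw_cens
        if analysis == "PP":
            if sw_pers is None:
                raise ConfigurationError("PP level 3 requires persistence weights")
            w = w * sw_pers
    return w.rename(f"w_model{level}")


def truncate_weights(weights, method: str = "pct_1_99"):
    """Truncate a weight vector; returns (truncated array, metadata dict)."""
    w = np.asarray(weights, dtype=float)
    if w.size == 0:
        raise ConfigurationError("empty weight vector")
    if method == "none":
        return w.copy(), {"method": method, "lower": None, "upper": None, "n_truncated": 0}
    if method == "pct_1_99":
        lo, hi = np.quantile(w, [0.01, 0.99])
    elif method == "pct_05_995":
        lo, hi = np.quantile(w, [0.005, 0.995])
    elif method == "fixed_0.1_10":
        lo, hi = 0.1, 10.0
    else:
        raise ConfigurationError(f"unknown truncation method {method!r}")
    n_trunc = int(np.sum((w < lo) | (w > hi)))
    return np.clip(w, lo, hi), {"method": method, "lower": float(lo),
                                "upper": float(hi), "n_truncated": n_trunc}


@dataclass
class WeightSet:
    """Per person-interval weight components for one analysis.

    ``frame`` is aligned row-for-row with the person-interval table and holds
    sw_treat, sw_select, sw_cens and (PP) sw_pers.
    """

    frame: pd.DataFrame
    analysis: str
    truncation: str = "pct_1_99"
    meta: dict = field(default_factory=dict)

    def combined(self, level: int, truncate: bool | None = None):
        """Final (optionally truncated) weight per row for a model level."""
        w = combine_weights(
            level, self.analysis,
            self.frame["sw_treat"],
            self.frame.get("sw_select"),
            self.frame.get("sw_cens"),
            self.frame.get("sw_pers") if self.analysis == "PP" else None,
        )
        if truncate is None:
            truncate = True
        if truncate:
            arr, meta = truncate_weights(w.to_numpy(), self.truncation)
            self.meta[f"truncation_model{level}"] = meta
            return pd.Series(arr, index=w.index, name=w.name)
        return w

    def diagnostics(self) -> pd.DataFrame:
        """Mean/SD/min/max/percentiles per component and per combined product."""
        rows = []
        cols = [c for c in ("sw_treat", "sw_select", "sw_cens", "sw_pers")
                if c in self.frame.columns]
        series = {c: self.frame[c] for c in cols}
        for lvl in (1, 2, 3):
            try:
                series[f"w_model{lvl}"] = self.combined(lvl, truncate=False)
            except ConfigurationError:
                pass
        for name, s in series.items():
            v = s.to_numpy(dtype=float)
            rows.append({
                "weight": name, "mean": v.mean(), "sd": v.std(ddof=1),
                "min": v.min(), "p1": np.quantile(v, 0.01),
                "p99": np.quantile(v, 0.99), "max": v.max(),
            })
        return pd.DataFrame(rows)


def estimate_weights(
    eligible: Cohort,
    intervals: pd.DataFrame,
    analysis: str = "ITT",
    options: AnalysisOptions | None = None,
) -> WeightSet:
    """Fit all stabilised weight components for one analysis.

    The full eligible cohort (including patients lost before day 91)
    contributes to the treatment and selection models; interval-level models
    are fitted on the supplied person-interval table.
    """
    options = options or AnalysisOptions()
    pat = eligible.patients_frame().set_index("patient_id")
    extra_base: tuple[str, ...] = ()
    extra_tv: tuple[str, ...] = ()
    if "fracture" in options.extra_weight_covariates:
        pat["prior_fracture"] = [
            1.0 if any(lab == "fracture" and d < 0 for lab, d in r.events) else 0.0
            for r in eligible.records
        ]
        extra_base = ("prior_fracture",)
        extra_tv = ("l_fracture",)
    X0 = baseline_design(pat, options.separate_unspecified, extra=extra_base)
    a0 = pd.Series(
        [1 if classify_exposure(r, options.window_days) == INITIATOR else 0
         for r in eligible.records],
        index=pat.index, name="a0",
    )
    risk_start = options.window_days + 1
    death = pd.to_numeric(pat["death_day"]).fillna(np.inf)
    transfer = pd.to_numeric(pat["transfer_day"]).fillna(np.inf)
    s = pd.Series((np.minimum(death, transfer) >= risk_start).astype(float),
                  index=pat.index, name="s")

    sw_treat = fit_baseline_treatment_weights(X0, a0)
    sw_select = fit_baseline_selection_weights(X0, a0, s)
    sw_cens = fit_followup_censoring_weights(
        intervals, X0, time_kind=options.time_kind,
        numerator_l0=options.numerator_l0, extra_tv=extra_tv)

    frame = pd.DataFrame(index=intervals.index)
    pid = intervals["patient_id"]
    frame["sw_treat"] = sw_treat.loc[pid].to_numpy()
    frame["sw_select"] = sw_select.loc[pid].to_numpy()
    frame["sw_cens"] = sw_cens
    if analysis == "PP":
        frame["sw_pers"] = fit_persistence_weights(
            intervals, X0, time_kind=options.time_kind, extra_tv=extra_tv)
    ws = WeightSet(frame=frame, analysis=analysis, truncation=options.truncation)
    ws.meta["patient_sw_treat_mean"] = float(sw_treat.mean())
    ws.meta["patient_sw_select_mean"] = float(sw_select[s == 1].mean())
    return ws
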