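"""New-user cohort construction: eligibility, exposure, follow-up intervals.

Conventions (index stroke = day 0):

* initiation window is the closed interval [0, window_days] (default 90);
* time at risk starts the day after the window (day 91) and is split into
  30-day intervals, interval t covering days [91 + 30(t-1), 90 + 30t];
* an event or censoring day maps to the interval containing it, with
  same-interval precedence outcome > artificial censoring > other censoring;
* patients lost before the start of time at risk contribute zero intervals
  but remain available to the baseline selection-weight model.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .config import CONTROL_OUTCOMES, OUTCOME_LABELS, AnalysisOptions
from .errors import ConfigurationError
from .records import BASE_RAW_COLUMNS, Cohort, PatientRecord

INITIATOR, NON_INITIATOR = "initiator", "non_initiator"


@dataclass
class EligibilityReport:
    """Sequential exclusion counts; eligible + sum(excluded) = n_input."""

    n_input: int = 0
    excluded: dict[str, int] = field(default_factory=dict)
    n_eligible: int = 0
    outcome_label: str = "dementia"

    def to_json(self, path=None) -> str:
        blob = json.dumps(
            {"n_input": self.n_input, "excluded": self.excluded,
             "n_eligible": self.n_eligible, "outcome_label": self.outcome_label},
            indent=2,
        )
        if path is not None:
            with open(path, "w") as fh:
                fh.write(blob)
        return blob


def apply_eligibility(
    cohort: Cohort,
    analysis_outcome: str = "dementia",
    options: AnalysisOptions | None = None,
) -> tuple[Cohort, EligibilityReport]:
    """Apply the new-user exclusion rules in sequence.

    Order: dementia before or within day 90; statin prescription within 365
    days pre-index; under 365 days of pre-index history; missing baseline
    smoking/BMI (unless imputation is enabled, in which case missing BMI is
    set to the 5th or 95th percentile of the observed values and missing
    smoking to never); for control outcomes, prior or early (<= day 90)
    occurrence of that outcome.
    """
    options = options or AnalysisOptions()
    if analysis_outcome not in OUTCOME_LABELS:
        raise ConfigurationError(f"unknown outcome label {analysis_outcome!r}")
    report = EligibilityReport(n_input=len(cohort), outcome_label=analysis_outcome)
    remaining = list(cohort.records)
    # dementia exclusion window extends to the risk start when the initiation
    # window is longer than 90 days (no pre-risk outcomes can remain)
    dem_end = max(90, options.window_days)

    def _exclude(rule: str, pred) -> None:
        nonlocal remaining
        keep = [r for r in remaining if not pred(r)]
        report.excluded[rule] = len(remaining) - len(keep)
        remaining = keep

    _exclude("prior_dementia",
             lambda r: (d := r.first_event_day("dementia")) is not None and d <= dem_end)
    _exclude("prior_statin",
             lambda r: any(-365 <= d <= -1 for d in r.rx_days()))
    _exclude("short_history", lambda r: r.registration_start < 365)
    if options.impute_missing is None:
        _exclude("missing_covariates",
                 lambda r: r.covariates.get("smoking") is None or r.covariates.get("bmi") is None)
    else:
        from dataclasses import replace as dc_replace

        observed = [r.covariates["bmi"] for r in remaining if r.covariates.get("bmi") is not None]
        q = 0.05 if options.impute_missing == "p5" else 0.95
        fill = float(np.quantile(observed, q)) if observed else 25.0
        imputed = []
        for r in remaining:
            cov = r.covariates
            if cov.get("bmi") is None or cov.get("smoking") is None:
                cov = dict(cov)
                if cov.get("bmi") is None:
                    cov["bmi"] = fill
                if cov.get("smoking") is None:
                    cov["smoking"] = "never"
                r = dc_replace(r, covariates=cov)  # leave the input cohort untouched
            imputed.append(r)
        remaining = imputed
        report.excluded["missing_covariates"] = 0
    if analysis_outcome in CONTROL_OUTCOMES:
        _exclude(f"prior_{analysis_outcome}",
                 lambda r: (d := r.first_event_day(analysis_outcome)) is not None and d <= 90)
    report.n_eligible = len(remaining)
    return cohort.subset(remaining), report


def classify_exposure(patient: PatientRecord, window_days: int = 90) -> str:
    """Initiator iff any statin prescription day falls in [0, window_days]."""
    return INITIATOR if any(0 <= d <= window_days for d in patient.rx_days()) else NON_INITIATOR


def persistence_end(
    prescriptions: list[tuple[int, int]],
    supply_days: int = 30,
    grace_days: int = 90,
    followup_end: Optional[int] = None,
) -> Optional[int]:
    """First day treatment counts as discontinued, or None.

    Use is sustained until no further prescription arrives within the expected
    end of days-supply of the previous one plus the grace period; the
    discontinuation day is ``last_rx_day + supply + grace``.  Recorded
    days-supply is honoured when present.  If the projected day falls after
    ``followup_end`` (when given), the patient never discontinues in view.
    """
    post = sorted((d, s) for d, s in prescriptions if d >= 0)
    if not post:
        raise ConfigurationError("persistence_end called with no post-index prescriptions")
    disc = None
    for (day, supply), (nxt, _) in zip(post, post[1:]):
        cover = day + (supply or supply_days) + grace_days
        if nxt > cover:
            disc = cover
            break
    if disc is None:
        last_day, last_supply = post[-1]
        disc = last_day + (last_supply or supply_days) + grace_days
    if followup_end is not None and disc > followup_end:
        return None
    return disc


def artificial_censor_day(
    patient: PatientRecord,
    group: str,
    window_days: int = 90,
    supply_days: int = 30,
    grace_days: int = 90,
    followup_end: Optional[int] = None,
) -> Optional[int]:
    """Day PP follow-up is artificially censored, or None if no deviation.

    Initiators: the persistence-rule discontinuation day (None when the
    projected day falls beyond ``followup_end``, i.e. refills cover the whole
    observed follow-up).  Non-initiators: the day of the first statin
    prescription after the window.
    """
    if group == INITIATOR:
        return persistence_end(patient.prescriptions, supply_days, grace_days,
                               followup_end=followup_end)
    later = [d for d in patient.rx_days() if d > window_days]
    return min(later) if later else None


def interval_index(day: int, risk_start: int) -> int:
    """1-based 30-day interval containing ``day`` (day >= risk_start)."""
    return (day - risk_start) // 30 + 1


def build_person_intervals(
    cohort: Cohort,
    analysis: str = "ITT",
    outcome_label: str = "dementia",
    options: AnalysisOptions | None = None,
) -> pd.DataFrame:
    """Split follow-up into 30-day person-intervals.

    Returns one row per patient-interval with the baseline exposure group
    ``a0`` (1 = initiator), the analysis outcome indicator ``y``, censoring
    indicators ``c`` (any), ``c_dt`` (death/transfer, the informative part)
    and ``ac`` (artificial censoring, PP only), time-varying covariates as of
    the interval start (``l_deter``, ``l_fracture``), exact days contributed,
    and the raw baseline covariates.  Terminal-interval flags obey the
    precedence Y > AC > C.
    """
    options = options or AnalysisOptions()
    if analysis not in ("ITT", "PP"):
        raise ConfigurationError(f"analysis must be 'ITT' or 'PP', got {analysis!r}")
    risk_start = options.window_days + 1
    admin_end = risk_start - 1 + 30 * options.max_months
    pat = cohort.patients_frame().set_index("patient_id")

    cols: dict[str, list] = {k: [] for k in (
        "patient_id", "t", "start_day", "days", "a0", "y", "ac", "c", "c_dt",
        "c_admin", "persistent", "l_deter", "l_fracture")}
    for r in cohort.records:
        if options.linked_only and not r.linked:
            continue
        group = classify_exposure(r, options.window_days)
        a0 = 1 if group == INITIATOR else 0
        death = r.death_day if r.death_day is not None else np.inf
        transfer = r.transfer_day if r.transfer_day is not None else np.inf
        if min(death, transfer) < risk_start:
            continue  # lost before time at risk: zero intervals
        ev = r.first_event_day(outcome_label)
        event_day = ev if ev is not None and ev >= risk_start else np.inf
        if options.exclude_months_4_6 and outcome_label == "dementia" \
                and ev is not None and 91 <= ev <= 180:
            continue
        cens_day = min(death, transfer, admin_end)
        is_admin = cens_day == admin_end and death > admin_end and transfer > admin_end
        t_y = interval_index(event_day, risk_start) if np.isfinite(event_day) else np.inf
        t_c = interval_index(int(cens_day), risk_start)
        ac_day = np.inf
        t_ac = np.inf
        if analysis == "PP":
            acd = artificial_censor_day(r, group, options.window_days,
                                        options.supply_days, options.grace_days)
            if acd is not None:
                ac_day = max(acd, risk_start)
                t_ac = interval_index(int(ac_day), risk_start)
        T = int(min(t_y, t_ac, t_c, options.max_months))
        if T < 1:
            continue
        # terminal flag with precedence Y > AC > C
        term_y = t_y <= T
        term_ac = (not term_y) and t_ac <= T
        term_c = not (term_y or term_ac)
        deter_day = r.deterioration_day if r.deterioration_day is not None else np.inf
        frac_day = r.first_event_day("fracture")
        frac_day = frac_day if frac_day is not None else np.inf
        dev_t = t_ac  # first interval no longer following A0 (approx: AC interval)
        for t in range(1, T + 1):
            start = risk_start + 30 * (t - 1)
            is_term = t == T
            if is_term:
                if term_y:
                    end = int(event_day)
                elif term_ac:
                    end = int(min(ac_day, cens_day))
                elif is_admin:
                    end = start + 29
                else:
                    end = int(cens_day)
            else:
                end = start + 29
            cols["patient_id"].append(r.patient_id)
            cols["t"].append(t)
            cols["start_day"].append(start)
            cols["days"].append(max(end - start + 1, 1))
            cols["a0"].append(a0)
            cols["y"].append(int(is_term and term_y))
            cols["ac"].append(int(is_term and term_ac))
            c_flag = int(is_term and term_c)
            cols["c"].append(c_flag)
            cols["c_admin"].append(int(c_flag and is_admin))
            cols["c_dt"].append(int(c_flag and not is_admin))
            cols["persistent"].append(bool(t < dev_t))
            cols["l_deter"].append(int(deter_day <= start))
            cols["l_fracture"].append(int(frac_day < start))
    df = pd.DataFrame(cols)
    if df.empty:
        return df
    base = pat.loc[:, list(BASE_RAW_COLUMNS) + ["linked"]].copy()
    for c in ("smoking", "subtype"):
        base[c] = base[c].astype("category")
    df = df.join(base, on="patient_id")
    return df


def outcome_model_rows(intervals: pd.DataFrame) -> pd.DataFrame:
    """Rows entering the pooled-logistic outcome model.

    Every person-interval is at risk at its start, and within an interval the
    outcome takes precedence over censoring, so censored terminal intervals
    contribute as event-free at-risk rows and nothing is dropped.  (Weights
    are aligned to this convention: a row's cumulative weight covers the
    intervals before it.)  Kept as an explicit stage so the row-selection
    convention has a single home.
    """
    return intervals


def person_years(intervals: pd.DataFrame) -> float:
    """Exact person-years from days contributed (days / 365.25)."""
    return float(intervals["days"].sum() / 365.25)
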