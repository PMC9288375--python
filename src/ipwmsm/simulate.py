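"""Synthetic post-stroke cohort generator and counterfactual oracle.

The generator emulates the longitudinal structure a new-user target-trial
emulation assumes:

* baseline covariates (demographics, comorbidities, lifestyle, deprivation,
  stroke subtype, healthcare utilisation) drawn from configurable marginals;
* confounded statin initiation inside the 90-day window, with the intercept
  calibrated to a target marginal initiation proportion;
* covariate- and treatment-dependent loss (death/transfer) within the first
  90 days, creating baseline selection bias;
* monthly discrete hazards thereafter for the outcome processes, for leaving
  follow-up, for onset of a binary "deterioration" state (the time-varying
  confounder), and for deviation from the initial strategy (discontinuation
  among initiators, crossover among non-initiators);
* records violating eligibility rules (pre-index statins, prior dementia,
  short history, missing covariates) injected at configurable rates.

Every patient draws from a dedicated random substream keyed by
``(seed, stream, patient_id)``, so records are byte-identical across runs and
invariant to cohort size.  :func:`counterfactual_truth` simulates each oracle
patient under both static strategies (always treated from day 0 / never
treated) with selection, censoring and non-persistence switched off, sharing
the outcome uniforms between arms to reduce Monte-Carlo error, and returns the
marginal hazard ratio from an unadjusted discrete-time (pooled logistic) fit.
"""
from __future__ import annotations

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit, logit

from .config import LogisticHazard, SimulationConfig
from .errors import ConfigurationError, EstimationError
from .records import Cohort, PatientRecord

# substream tags
_STREAM_COHORT = 1
_STREAM_CALIBRATE = 2
_STREAM_ORACLE = 3

# indices into each patient's uniform vector
(_U_FEMALE, _U_AF, _U_CHD, _U_DIAB, _U_HF, _U_HTN, _U_SMOKE, _U_IMD, _U_SUBTYPE,
 _U_SHORTHIST, _U_HISTLEN, _U_PRIOR_STATIN, _U_PRIOR_STATIN_DAY, _U_PRIOR_DEM,
 _U_PRIOR_DEM_DAY, _U_MISS_SMOKE, _U_MISS_BMI, _U_PRIOR_FRAC, _U_PRIOR_FRAC_DAY,
 _U_PRIOR_ULC, _U_PRIOR_ULC_DAY, _U_PRIOR_CHD_DAY, _U_LINK, _U_TREAT, _U_INIT_DAY,
 _U_GONE90, _U_CAUSE90, _U_DAY90) = range(28)
_N_UNIFORMS = 28

# monthly channels for the cohort stream
_M_EXIT, _M_CAUSE, _M_DETER, _M_DEV, _M_DEM, _M_CHD, _M_FRAC, _M_ULC = range(8)
_OUTCOME_CHANNEL = {"dementia": _M_DEM, "CHD": _M_CHD, "fracture": _M_FRAC,
                    "peptic_ulcer": _M_ULC}


def _draw_patients(seed: int, stream: int, n: int, lam_consult, months: int = 0,
                   n_channels: int = 0):
    """Per-patient substream draws: uniforms, normals, consultations, monthly grid."""
    U = np.empty((n, _N_UNIFORMS))
    Z = np.empty((n, 2))
    consult = np.empty(n, dtype=np.int64)
    # monthly grid stored float32: resolution ~1e-7 vs hazards >= 1e-4
    M = np.empty((n, months, n_channels), dtype=np.float32) if n_channels else None
    for i in range(n):
        rng = np.random.default_rng(np.random.SeedSequence((seed, stream, i)))
        U[i] = rng.random(_N_UNIFORMS)
        Z[i] = rng.standard_normal(2)
        consult[i] = rng.poisson(lam_consult)
        if n_channels:
            M[i] = rng.random((months, n_channels), dtype=np.float32)
    return U, Z, consult, M


def _categorical(u: np.ndarray, probs) -> np.ndarray:
    return np.searchsorted(np.cumsum(probs), u, side="right")


def _raw_baseline(cfg: SimulationConfig, U, Z, consult) -> dict[str, np.ndarray]:
    b = cfg.baseline
    raw = {
        "age": np.round(b.age_mean + b.age_sd * Z[:, 0], 1),
        "bmi": np.round(b.bmi_mean + b.bmi_sd * Z[:, 1], 1),
        "consultations": consult,
        "smoking_code": _categorical(U[:, _U_SMOKE], b.smoking),      # 0 cur, 1 former, 2 never
        "imd": _categorical(U[:, _U_IMD], b.imd) + 1,
        "subtype_code": _categorical(U[:, _U_SUBTYPE], b.subtype),    # 0 isch, 1 unspec, 2 haem
    }
    for name, p in b.prevalence.items():
        idx = {"female": _U_FEMALE, "af": _U_AF, "chd": _U_CHD, "diabetes": _U_DIAB,
               "heart_failure": _U_HF, "hypertension": _U_HTN}[name]
        raw[name] = (U[:, idx] < p).astype(float)
    return raw


def _design_arrays(cfg: SimulationConfig, raw: dict) -> dict[str, np.ndarray]:
    """Named design columns on the generation scale (config-referenced standardisation)."""
    b = cfg.baseline
    d = {
        "age_std": (raw["age"] - b.age_mean) / b.age_sd,
        "bmi_std": (raw["bmi"] - b.bmi_mean) / b.bmi_sd,
        "consult_std": (raw["consultations"] - b.consult_mean) / b.consult_sd,
        "female": raw["female"], "af": raw["af"], "chd": raw["chd"],
        "diabetes": raw["diabetes"], "heart_failure": raw["heart_failure"],
        "hypertension": raw["hypertension"],
        "smoke_current": (raw["smoking_code"] == 0).astype(float),
        "smoke_former": (raw["smoking_code"] == 1).astype(float),
        "haemorrhagic": (raw["subtype_code"] == 2).astype(float),
        "unspecified": (raw["subtype_code"] == 1).astype(float),
    }
    for g in (2, 3, 4, 5):
        d[f"imd_{g}"] = (raw["imd"] == g).astype(float)
    return d


_DYNAMIC_KEYS = ("a0", "treat", "deter")


def _static_lp(haz: LogisticHazard, design: dict, n: int) -> tuple[np.ndarray, dict]:
    """Split a hazard into its static linear predictor and dynamic coefficients."""
    lp = np.full(n, logit(haz.base) if haz.base > 0 else -np.inf)
    dyn = {}
    for k, c in haz.coef.items():
        if k in _DYNAMIC_KEYS:
            dyn[k] = c
        elif k in design:
            lp = lp + c * design[k]
        else:
            raise ConfigurationError(f"hazard coefficient references unknown covariate {k!r}")
    return lp, dyn


def calibrate_initiation_intercept(cfg: SimulationConfig, n_probe: int = 50_000) -> float:
    """Solve for the initiation-model intercept hitting the target marginal proportion."""
    U, Z, consult, _ = _draw_patients(cfg.seed, _STREAM_CALIBRATE, n_probe,
                                      cfg.baseline.consult_mean)
    design = _design_arrays(cfg, _raw_baseline(cfg, U, Z, consult))
    eta = np.zeros(n_probe)
    for k, c in cfg.treatment.coef.items():
        eta += c * design[k]

    def gap(b0):
        return float(expit(b0 + eta).mean() - cfg.treatment.target)

    return float(brentq(gap, -15.0, 15.0, xtol=1e-8))


def generate_cohort(cfg: SimulationConfig) -> Cohort:
    """Simulate ``cfg.n_patients`` longitudinal patient records."""
    cfg.validate()
    n, months = cfg.n_patients, cfg.max_months
    U, Z, consult, M = _draw_patients(cfg.seed, _STREAM_COHORT, n,
                                      cfg.baseline.consult_mean, months, 8)
    raw = _raw_baseline(cfg, U, Z, consult)
    design = _design_arrays(cfg, raw)

    # -- treatment assignment within the window ------------------------
    b0 = cfg.treatment.intercept
    if b0 is None:
        b0 = calibrate_initiation_intercept(cfg)
    eta = np.full(n, b0)
    for k, c in cfg.treatment.coef.items():
        eta += c * design[k]
    a0 = (U[:, _U_TREAT] < expit(eta)).astype(int)

    # -- 90-day selection (death/transfer before day 91) ----------------
    lp_sel, dyn_sel = _static_lp(cfg.selection, design, n)
    p_gone = expit(lp_sel + dyn_sel.get("a0", 0.0) * a0)
    gone90 = U[:, _U_GONE90] < p_gone
    gone_death = gone90 & (U[:, _U_CAUSE90] < cfg.selection_death_fraction)
    day90 = np.floor(U[:, _U_DAY90] * 91).astype(int)
    init_cap = np.where(gone90, np.minimum(90, day90), 90)
    init_day = np.floor(U[:, _U_INIT_DAY] * (init_cap + 1)).astype(int)

    # -- monthly follow-up process (90-day survivors only) ---------------
    lp_exit, dyn_exit = _static_lp(cfg.followup_exit, design, n)
    lp_det, _ = _static_lp(cfg.deterioration, design, n)
    lp_disc, dyn_disc = _static_lp(cfg.persistence.discontinuation, design, n)
    lp_cross, dyn_cross = _static_lp(cfg.persistence.crossover, design, n)
    out_lp, out_dyn = {}, {}
    for label, spec in cfg.outcomes.items():
        lp, dyn = _static_lp(spec.hazard, design, n)
        dyn.setdefault("treat", spec.log_hr)
        out_lp[label], out_dyn[label] = lp, dyn

    active = ~gone90
    deter = np.zeros(n, dtype=bool)
    on_rx = (a0 == 1) & active
    deter_month = np.zeros(n, dtype=int)        # 0 = never
    stop_month = np.zeros(n, dtype=int)         # initiator latent discontinuation month
    cross_month = np.zeros(n, dtype=int)        # non-initiator crossover month
    exit_month = np.zeros(n, dtype=int)
    exit_death = np.zeros(n, dtype=bool)
    event_month = {lab: np.zeros(n, dtype=int) for lab in cfg.outcomes}

    for t in range(1, months + 1):
        if not active.any():
            break
        u = M[:, t - 1, :]
        # deterioration onset at interval start
        onset = active & ~deter & (u[:, _M_DETER] < expit(lp_det))
        deter |= onset
        deter_month[onset] = t
        # strategy deviation decided at interval start
        p_disc = expit(lp_disc + dyn_disc.get("deter", 0.0) * deter)
        p_cross = expit(lp_cross + dyn_cross.get("deter", 0.0) * deter)
        disc = active & (a0 == 1) & on_rx & (u[:, _M_DEV] < p_disc)
        on_rx[disc] = False
        stop_month[disc] = t
        cross = active & (a0 == 0) & ~on_rx & (cross_month == 0) & (u[:, _M_DEV] < p_cross)
        on_rx[cross] = True
        cross_month[cross] = t
        # outcome processes (first occurrence per label, follow-up continues)
        for lab in cfg.outcomes:
            dyn = out_dyn[lab]
            p = expit(out_lp[lab] + dyn.get("treat", 0.0) * on_rx
                      + dyn.get("deter", 0.0) * deter + dyn.get("a0", 0.0) * a0)
            hit = active & (event_month[lab] == 0) & (u[:, _OUTCOME_CHANNEL[lab]] < p)
            event_month[lab][hit] = t
        # leaving follow-up (death or transfer)
        p_exit = expit(lp_exit + dyn_exit.get("treat", 0.0) * on_rx
                       + dyn_exit.get("deter", 0.0) * deter + dyn_exit.get("a0", 0.0) * a0)
        ex = active & (u[:, _M_EXIT] < p_exit)
        exit_month[ex] = t
        exit_death[ex] = u[ex, _M_CAUSE] < cfg.followup_death_fraction
        active &= ~ex

    # -- assemble records ------------------------------------------------
    ie = cfg.ineligible
    short_hist = U[:, _U_SHORTHIST] < ie.short_history
    lo, hi = cfg.history_days_range
    hist = np.where(
        short_hist,
        30 + np.floor(U[:, _U_HISTLEN] * 335),
        lo + np.floor(U[:, _U_HISTLEN] * (hi - lo + 1)),
    ).astype(int)
    prior_statin = U[:, _U_PRIOR_STATIN] < ie.prior_statin
    prior_statin_day = (-365 + np.floor(U[:, _U_PRIOR_STATIN_DAY] * 336)).astype(int)
    prior_dem = U[:, _U_PRIOR_DEM] < ie.prior_dementia
    prior_dem_day = (-700 + np.floor(U[:, _U_PRIOR_DEM_DAY] * 791)).astype(int)
    prior_frac = U[:, _U_PRIOR_FRAC] < ie.prior_fracture
    prior_frac_day = (-2000 + np.floor(U[:, _U_PRIOR_FRAC_DAY] * 1999)).astype(int)
    prior_ulc = U[:, _U_PRIOR_ULC] < ie.prior_ulcer
    prior_ulc_day = (-2000 + np.floor(U[:, _U_PRIOR_ULC_DAY] * 1999)).astype(int)
    prior_chd_day = (-2000 + np.floor(U[:, _U_PRIOR_CHD_DAY] * 1999)).astype(int)
    miss_smoke = U[:, _U_MISS_SMOKE] < ie.missing_smoking
    miss_bmi = U[:, _U_MISS_BMI] < ie.missing_bmi
    linked = U[:, _U_LINK] < cfg.linkage_rate

    smoking_lab = np.array(["current", "former", "never"], dtype=object)
    subtype_lab = np.array(["ischaemic", "unspecified", "haemorrhagic"], dtype=object)

    def start_day(t):
        return 91 + 30 * (t - 1)

    records = []
    for i in range(n):
        cov = {
            "age": float(raw["age"][i]),
            "female": int(raw["female"][i]),
            "af": int(raw["af"][i]),
            "chd": int(raw["chd"][i]),
            "diabetes": int(raw["diabetes"][i]),
            "heart_failure": int(raw["heart_failure"][i]),
            "hypertension": int(raw["hypertension"][i]),
            "smoking": None if miss_smoke[i] else smoking_lab[raw["smoking_code"][i]],
            "bmi": None if miss_bmi[i] else float(raw["bmi"][i]),
            "imd": int(raw["imd"][i]),
            "subtype": subtype_lab[raw["subtype_code"][i]],
            "consultations": int(raw["consultations"][i]),
        }
        last_m = exit_month[i] if exit_month[i] else months
        rx: list[tuple[int, int]] = []
        if prior_statin[i]:
            rx.append((int(prior_statin_day[i]), 30))
        if a0[i]:
            rx.append((int(init_day[i]), 30))
            if not gone90[i]:
                stop = stop_month[i] if stop_month[i] else months + 1
                rx += [(start_day(t), 30) for t in range(1, last_m + 1) if t < stop]
        elif cross_month[i] and not gone90[i]:
            rx += [(start_day(t), 30) for t in range(cross_month[i], last_m + 1)]
        events: list[tuple[str, int]] = []
        if prior_dem[i]:
            events.append(("dementia", int(prior_dem_day[i])))
        if prior_frac[i]:
            events.append(("fracture", int(prior_frac_day[i])))
        if prior_ulc[i]:
            events.append(("peptic_ulcer", int(prior_ulc_day[i])))
        if raw["chd"][i]:
            events.append(("CHD", int(prior_chd_day[i])))
        for lab in cfg.outcomes:
            m = event_month[lab][i]
            if m and not any(e[0] == lab for e in events):
                events.append((lab, start_day(m) + 14))
        death_day = transfer_day = None
        if gone90[i]:
            if gone_death[i]:
                death_day = int(day90[i])
            else:
                transfer_day = int(day90[i])
        elif exit_month[i]:
            d = start_day(exit_month[i]) + 15
            if exit_death[i]:
                death_day = d
            else:
                transfer_day = d
        records.append(
            PatientRecord(
                patient_id=i,
                registration_start=int(hist[i]),
                covariates=cov,
                prescriptions=rx,
                events=events,
                death_day=death_day,
                transfer_day=transfer_day,
                linked=bool(linked[i]),
                deterioration_day=start_day(deter_month[i]) if deter_month[i] else None,
            )
        )
    return Cohort(records, config=cfg)


def counterfactual_truth(cfg: SimulationConfig, n_mc: int, outcome_label: str = "dementia") -> float:
    """True marginal hazard ratio by paired counterfactual Monte Carlo.

    Each oracle patient is simulated under both static strategies — treated
    from day 0 versus never treated — with selection, censoring and
    non-persistence switched off.  The two arms share the per-month outcome
    uniforms, so the event processes are maximally coupled and the Monte-Carlo
    error of the contrast is far below that of independent arms.  The marginal
    HR is the exponentiated treatment coefficient of an unadjusted pooled
    logistic (discrete-time hazard) model on the stacked counterfactual data.
    """
    cfg.validate()
    if n_mc < 1:
        raise ConfigurationError("n_mc must be >= 1")
    if outcome_label not in cfg.outcomes:
        raise ConfigurationError(f"no outcome spec for {outcome_label!r}")
    months = cfg.max_months
    U, Z, consult, M = _draw_patients(cfg.seed, _STREAM_ORACLE, n_mc,
                                      cfg.baseline.consult_mean, months, 2)
    design = _design_arrays(cfg, _raw_baseline(cfg, U, Z, consult))
    spec = cfg.outcomes[outcome_label]
    lp, dyn = _static_lp(spec.hazard, design, n_mc)
    theta = dyn.get("treat", spec.log_hr)
    deter_coef = dyn.get("deter", 0.0)
    lp_det, _ = _static_lp(cfg.deterioration, design, n_mc)

    deter = np.zeros(n_mc, dtype=bool)
    at_risk = {1: np.ones(n_mc, dtype=bool), 0: np.ones(n_mc, dtype=bool)}
    events = {1: np.zeros(months), 0: np.zeros(months)}
    intervals = {1: np.zeros(months), 0: np.zeros(months)}
    for t in range(1, months + 1):
        onset = ~deter & (M[:, t - 1, 0] < expit(lp_det))
        deter |= onset
        u = M[:, t - 1, 1]
        for arm in (1, 0):
            risk = at_risk[arm]
            if not risk.any():
                continue
            p = expit(lp + theta * arm + deter_coef * deter)
            hit = risk & (u < p)
            events[arm][t - 1] = hit.sum()
            intervals[arm][t - 1] = risk.sum()
            at_risk[arm] = risk & ~hit
    for arm in (1, 0):
        if events[arm].sum() == 0:
            raise EstimationError(
                f"counterfactual oracle: zero events in arm {arm} "
                f"({int(intervals[arm].sum())} person-intervals); increase n_mc or hazards"
            )
    # pooled logistic on the counterfactual person-intervals: treatment-arm
    # indicator plus the baseline-hazard time terms (no covariate adjustment),
    # mirroring the time function of the factual outcome model; fitted on the
    # aggregated (arm, month) binomial cells, which is the identical MLE
    from ._glm import fit_logit
    from .design import default_knots, rcs_basis

    tvals = np.arange(1, months + 1, dtype=float)
    tb = rcs_basis(tvals, default_knots(tvals))
    X, y, w = [], [], []
    for arm in (1, 0):
        for i in range(months):
            if intervals[arm][i] == 0:
                continue
            row = [1.0, float(arm), *tb[i]]
            X.append(row)
            y.append(1.0)
            w.append(events[arm][i])
            X.append(row)
            y.append(0.0)
            w.append(intervals[arm][i] - events[arm][i])
    beta, _, converged = fit_logit(np.asarray(X), np.asarray(y), np.asarray(w))
    if not converged:
        raise EstimationError("counterfactual oracle: pooled logistic did not converge")
    return float(np.exp(beta[1]))
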