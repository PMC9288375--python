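"""Covariate balance (standardised mean differences) and incidence rates.

SMD conventions follow common practice in pharmacoepidemiology: two-proportion
SMD for binary covariates, pooled-SD SMD for continuous covariates, and the
Mahalanobis-type multivariate SMD for categorical covariates with three or
more levels.  |SMD| > 0.1 conventionally flags meaningful imbalance.
"""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .errors import ConfigurationError


def smd_binary(x1: float, n1: float, x2: float, n2: float) -> float:
    """|p1 - p2| / sqrt((p1(1-p1) + p2(1-p2)) / 2)."""
    if n1 <= 0 or n2 <= 0:
        raise ConfigurationError("group sizes must be positive")
    p1, p2 = x1 / n1, x2 / n2
    denom = np.sqrt((p1 * (1 - p1) + p2 * (1 - p2)) / 2.0)
    if denom == 0:
        if p1 == p2:
            return 0.0
        raise ConfigurationError("degenerate proportions with unequal means")
    return float(abs(p1 - p2) / denom)


def smd_continuous(m1: float, s1: float, m2: float, s2: float) -> float:
    """|m1 - m2| / sqrt((s1^2 + s2^2) / 2)."""
    if s1 < 0 or s2 < 0:
        raise ConfigurationError("standard deviations must be non-negative")
    denom = np.sqrt((s1 ** 2 + s2 ** 2) / 2.0)
    if denom == 0:
        if m1 == m2:
            return 0.0
        raise ConfigurationError("zero spread with unequal means")
    return float(abs(m1 - m2) / denom)


def smd_categorical(counts1, counts2) -> float:
    """Mahalanobis-type SMD for a K-category covariate.

    Drops one reference category, forms d = p1 - p2 over the remaining K-1
    proportions and S = the average of the two multinomial covariance
    matrices; returns sqrt(d' S^-1 d).  Categories empty in both groups are
    dropped with a warning.
    """
    c1 = np.asarray(counts1, dtype=float)
    c2 = np.asarray(counts2, dtype=float)
    if c1.shape != c2.shape or c1.ndim != 1 or len(c1) < 2:
        raise ConfigurationError("need equal-length count vectors with >= 2 categories")
    n1, n2 = c1.sum(), c2.sum()
    if n1 <= 0 or n2 <= 0:
        raise ConfigurationError("group totals must be positive")
    empty = (c1 == 0) & (c2 == 0)
    if empty.any():
        warnings.warn("dropping categories empty in both groups", stacklevel=2)
        c1, c2 = c1[~empty], c2[~empty]
        if len(c1) < 2:
            return 0.0
    p1, p2 = c1 / n1, c2 / n2
    # drop the last category as reference
    d = (p1 - p2)[:-1]
    def cov(p):
        q = p[:-1]
        return np.diag(q) - np.outer(q, q)
    S = (cov(p1) + cov(p2)) / 2.0
    sol = np.linalg.solve(S, d)
    return float(np.sqrt(max(d @ sol, 0.0)))


def incidence_rate(events: float, person_years: float) -> float:
    """Events per 1000 person-years."""
    if person_years <= 0:
        raise ConfigurationError("person_years must be positive")
    if events < 0:
        raise ConfigurationError("events must be non-negative")
    return 1000.0 * events / person_years


def _wmean(x, w):
    return float(np.average(x, weights=w))


def weighted_smd_binary(x: np.ndarray, a: np.ndarray, w: np.ndarray | None = None) -> float:
    """SMD of a binary covariate between a=1 and a=0, optionally weighted."""
    x = np.asarray(x, dtype=float)
    a = np.asarray(a)
    w = np.ones(len(x)) if w is None else np.asarray(w, dtype=float)
    p1 = _wmean(x[a == 1], w[a == 1])
    p2 = _wmean(x[a == 0], w[a == 0])
    denom = np.sqrt((p1 * (1 - p1) + p2 * (1 - p2)) / 2.0)
    return 0.0 if denom == 0 else abs(p1 - p2) / denom


def weighted_smd_continuous(x: np.ndarray, a: np.ndarray, w: np.ndarray | None = None) -> float:
    x = np.asarray(x, dtype=float)
    a = np.asarray(a)
    w = np.ones(len(x)) if w is None else np.asarray(w, dtype=float)
    out = []
    for g in (1, 0):
        xi, wi = x[a == g], w[a == g]
        m = _wmean(xi, wi)
        v = _wmean((xi - m) ** 2, wi)
        out.append((m, v))
    (m1, v1), (m2, v2) = out
    denom = np.sqrt((v1 + v2) / 2.0)
    return 0.0 if denom == 0 else abs(m1 - m2) / denom


#: covariates reported in the balance table: (name, kind)
BALANCE_COVARIATES = (
    ("age", "continuous"), ("female", "binary"), ("af", "binary"), ("chd", "binary"),
    ("diabetes", "binary"), ("heart_failure", "binary"), ("hypertension", "binary"),
    ("smoking", "categorical"), ("bmi", "continuous"), ("imd", "categorical"),
    ("subtype", "categorical"), ("consultations", "continuous"),
)


def balance_table(patients: pd.DataFrame, a0: pd.Series,
                  weights: pd.Series | None = None) -> pd.DataFrame:
    """Table-1-style balance report: per-covariate group summaries and SMD."""
    a = a0.to_numpy()
    w = None if weights is None else weights.to_numpy()
    rows = []
    for name, kind in BALANCE_COVARIATES:
        col = patients[name]
        if kind == "binary":
            x = pd.to_numeric(col).to_numpy()
            smd = weighted_smd_binary(x, a, w)
            s1 = float(np.average(x[a == 1], weights=None if w is None else w[a == 1]))
            s2 = float(np.average(x[a == 0], weights=None if w is None else w[a == 0]))
            summ1, summ2 = f"{100 * s1:.1f}%", f"{100 * s2:.1f}%"
        elif kind == "continuous":
            x = pd.to_numeric(col).to_numpy(dtype=float)
            smd = weighted_smd_continuous(x, a, w)
            summ1 = f"{np.mean(x[a == 1]):.1f}"
            summ2 = f"{np.mean(x[a == 0]):.1f}"
        else:
            cats = pd.unique(col.dropna())
            c1 = np.array([np.sum((col == c) & (a == 1)) for c in cats], dtype=float)
            c2 = np.array([np.sum((col == c) & (a == 0)) for c in cats], dtype=float)
            if w is not None:
                c1 = np.array([w[(col == c) & (a == 1)].sum() for c in cats])
                c2 = np.array([w[(col == c) & (a == 0)].sum() for c in cats])
            smd = smd_categorical(c1, c2) if len(cats) >= 2 else 0.0
            summ1 = "/".join(f"{v:.0f}" for v in c1)
            summ2 = "/".join(f"{v:.0f}" for v in c2)
        rows.append({"covariate": name, "group1": summ1, "group0": summ2, "smd": smd})
    return pd.DataFrame(rows)


def rate_table(intervals: pd.DataFrame, by: str = "a0") -> pd.DataFrame:
    """Table-2-style events / person-years / rate per 1000 PY by exposure group."""
    rows = []
    for g, sub in intervals.groupby(by):
        py = sub["days"].sum() / 365.25
        ev = int(sub["y"].sum())
        rows.append({
            by: g,
            "n_patients": sub["patient_id"].nunique(),
            "events": ev,
            "person_years": py,
            "rate_per_1000py": incidence_rate(ev, py) if py > 0 else float("nan"),
        })
    return pd.DataFrame(rows)
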