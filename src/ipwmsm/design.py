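"""Design-matrix construction: baseline covariates and follow-up time bases."""
from __future__ import annotations

import numpy as np
import pandas as pd

#: baseline design columns (standardised/dummied), in model order
BASE_DESIGN_COLUMNS = (
    "age_std", "female", "af", "chd", "diabetes", "heart_failure", "hypertension",
    "smoke_current", "smoke_former", "bmi_std", "consult_std",
    "imd_2", "imd_3", "imd_4", "imd_5", "haemorrhagic",
)


def _std(x: pd.Series) -> pd.Series:
    x = pd.to_numeric(x, errors="coerce")
    sd = x.std(ddof=0)
    return (x - x.mean()) / (sd if sd > 0 else 1.0)


def baseline_design(df: pd.DataFrame, separate_unspecified: bool = False,
                    extra: tuple[str, ...] = ()) -> pd.DataFrame:
    """Numeric baseline design (no intercept) from raw patient columns.

    Continuous covariates are standardised on the supplied sample; categorical
    covariates are dummy-coded against their reference level (never-smoker,
    IMD group 1, ischaemic stroke).  Unspecified stroke subtype is pooled with
    ischaemic unless ``separate_unspecified``.
    """
    out = pd.DataFrame(index=df.index)
    out["age_std"] = _std(df["age"])
    for c in ("female", "af", "chd", "diabetes", "heart_failure", "hypertension"):
        out[c] = pd.to_numeric(df[c]).astype(float)
    smoking = df["smoking"].astype(object)
    out["smoke_current"] = (smoking == "current").astype(float)
    out["smoke_former"] = (smoking == "former").astype(float)
    out["bmi_std"] = _std(df["bmi"])
    out["consult_std"] = _std(df["consultations"])
    imd = pd.to_numeric(df["imd"])
    for g in (2, 3, 4, 5):
        out[f"imd_{g}"] = (imd == g).astype(float)
    subtype = df["subtype"].astype(object)
    out["haemorrhagic"] = (subtype == "haemorrhagic").astype(float)
    if separate_unspecified:
        out["unspecified"] = (subtype == "unspecified").astype(float)
    for c in extra:
        out[c] = pd.to_numeric(df[c]).astype(float)
    return out


def rcs_basis(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Restricted (natural) cubic spline basis: linear term + k-2 curvature terms."""
    x = np.asarray(x, dtype=float)
    knots = np.asarray(knots, dtype=float)
    k = len(knots)
    if k < 3:
        return x[:, None]
    t1, tk1, tk = knots[0], knots[-2], knots[-1]
    scale = (tk - t1) ** 2

    def cub(u):
        return np.clip(u, 0.0, None) ** 3

    cols = [x]
    for j in range(k - 2):
        tj = knots[j]
        term = (
            cub(x - tj)
            - cub(x - tk1) * (tk - tj) / (tk - tk1)
            + cub(x - tk) * (tk1 - tj) / (tk - tk1)
        ) / scale
        cols.append(term)
    return np.column_stack(cols)


def default_knots(t: np.ndarray, n_knots: int = 4) -> np.ndarray:
    qs = np.linspace(0.05, 0.95, n_knots)
    knots = np.unique(np.quantile(np.asarray(t, dtype=float), qs))
    return knots


def time_basis(t: np.ndarray, kind: str = "rcs", knots: np.ndarray | None = None) -> pd.DataFrame:
    """Follow-up time terms for interval-level models.

    kinds: 'rcs' (restricted cubic spline, 4 knots), 'linear', 'bins6'
    (six-month bins, dummy-coded), 'categorical' (dummy per interval), 'none'.
    """
    t = np.asarray(t, dtype=float)
    if kind == "none":
        return pd.DataFrame(index=pd.RangeIndex(len(t)))
    if kind == "linear":
        return pd.DataFrame({"t": t})
    if kind == "rcs":
        if knots is None:
            knots = default_knots(t)
        if len(knots) < 3:
            return pd.DataFrame({"t": t})
        basis = rcs_basis(t, knots)
        return pd.DataFrame({f"t_rcs{i}": basis[:, i] for i in range(basis.shape[1])})
    if kind == "bins6":
        bins = np.floor((t - 1) / 6).astype(int)
        out = pd.DataFrame(index=pd.RangeIndex(len(t)))
        for b in sorted(np.unique(bins))[1:]:
            out[f"t_bin{b}"] = (bins == b).astype(float)
        return out
    if kind == "categorical":
        out = pd.DataFrame(index=pd.RangeIndex(len(t)))
        for v in sorted(np.unique(t))[1:]:
            out[f"t_{int(v)}"] = (t == v).astype(float)
        return out
    raise ValueError(f"unknown time basis kind {kind!r}")
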