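"""Cohort data preparation.

Trait corrections for medication use, derived lipids (Friedewald), rank-based
inverse-normal transformation, residual-method energy adjustment, food-intake
-level exclusions, plausibility-bound outlier removal, and predictor filtering
(zero variance, pairwise correlation, variance inflation).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "MedicationConstants",
    "medication_correction",
    "friedewald_ldl",
    "inverse_normal_transform",
    "energy_adjust_residual",
    "fil_exclusion",
    "filter_predictors",
    "vif_filter",
    "outlier_removal",
]

#: Friedewald estimation is invalid above this triglyceride level
#: (4.52 mmol/L = 400 mg/dL).
FRIEDEWALD_TG_BOUND = 4.52


@dataclass(frozen=True)
class MedicationConstants:
    """Additive corrections applied to treated subjects' measured values.

    Literature constants for the average treatment effect of lipid-lowering
    and antihypertensive medication, added back to approximate the untreated
    value. Units: lipids mmol/L, blood pressure mm Hg.
    """

    tg_add: float = 0.208
    tc_add: float = 1.347
    hdl_add: float = -0.060
    ldl_add: float = 1.290
    sbp_add: float = 15.0
    dbp_add: float = 10.0


LIPID_CORRECTIONS = {"tg": "tg_add", "tc": "tc_add", "hdl": "hdl_add", "ldl": "ldl_add"}
BP_CORRECTIONS = {"sbp": "sbp_add", "dbp": "dbp_add"}


def medication_correction(
    visit: pd.DataFrame,
    constants: MedicationConstants = MedicationConstants(),
    lipid_flag: str = "on_lipid_med",
    bp_flag: str = "on_bp_med",
) -> pd.DataFrame:
    """Correct measured traits of treated subjects by the published constants.

    Missing flags are treated as untreated (and logged). Applied exactly once
    per table: a ``medication_corrected`` provenance attr guards re-entry.
    """
    if visit.attrs.get("medication_corrected"):
        raise ValueError("medication_correction already applied to this table")
    out = visit.copy()
    for flag, mapping in ((lipid_flag, LIPID_CORRECTIONS), (bp_flag, BP_CORRECTIONS)):
        if flag not in out.columns:
            logger.warning("flag column %r absent; subjects treated as untreated", flag)
            continue
        f = out[flag]
        n_missing = int(f.isna().sum())
        if n_missing:
            logger.warning("%d missing %r flags treated as untreated", n_missing, flag)
        treated = f.fillna(0).astype(bool)
        for trait, const_name in mapping.items():
            if trait in out.columns:
                out.loc[treated, trait] = out.loc[treated, trait] + getattr(constants, const_name)
    out.attrs["medication_corrected"] = True
    return out


def friedewald_ldl(tc, hdl, tg):
    """LDL-C (mmol/L) from total cholesterol, HDL-C and triglycerides.

    ldl = tc - hdl - tg / 2.2 (mmol/L form). Returns NaN where
    tg >= 4.52 mmol/L (400 mg/dL), beyond which the estimate is invalid.
    Accepts scalars or array-likes.
    """
    tc = np.asarray(tc, dtype=float)
    hdl = np.asarray(hdl, dtype=float)
    tg = np.asarray(tg, dtype=float)
    ldl = tc - hdl - tg / 2.2
    ldl = np.where(tg >= FRIEDEWALD_TG_BOUND, np.nan, ldl)
    return float(ldl) if ldl.ndim == 0 else ldl


def inverse_normal_transform(x, offset: float = 3.0 / 8.0):
    """Rank-based inverse-normal transform with the Blom offset.

    Maps values to standard-normal quantiles of (r - 3/8)/(n + 1/4), where r
    are mid-ranks (ties averaged) among non-missing values. Rank order is
    preserved; missing values stay missing.
    """
    arr = np.asarray(x, dtype=float)
    out = np.full(arr.shape, np.nan)
    obs = ~np.isnan(arr)
    vals = arr[obs]
    n = vals.size
    if n < 3:
        raise ValueError("need at least 3 non-missing values")
    if np.all(vals == vals[0]):
        raise ValueError("constant vector: ranks undefined for the transform")
    ranks = stats.rankdata(vals)
    out[obs] = stats.norm.ppf((ranks - offset) / (n + 1.0 - 2.0 * offset))
    if isinstance(x, pd.Series):
        return pd.Series(out, index=x.index, name=x.name)
    return out


def energy_adjust_residual(nutrient, tei):
    """Residual-method adjustment of a nutrient for total energy intake.

    Returns the residual of OLS(nutrient ~ TEI) plus the nutrient mean, so the
    adjusted variable is exactly uncorrelated with TEI and keeps the original
    mean. Rows with missing nutrient are propagated as missing.
    """
    nutrient = np.asarray(nutrient, dtype=float)
    tei = np.asarray(tei, dtype=float)
    if nutrient.shape != tei.shape:
        raise ValueError("nutrient and tei must have the same length")
    obs = ~(np.isnan(nutrient) | np.isnan(tei))
    t = tei[obs]
    if np.ptp(t) == 0:
        raise ValueError("TEI has zero variance; residual adjustment undefined")
    y = nutrient[obs]
    slope, intercept = np.polyfit(t, y, 1)
    out = np.full(nutrient.shape, np.nan)
    out[obs] = y - (intercept + slope * t) + y.mean()
    return out


def fil_exclusion(tei, bmr, lower_pct: float = 5.0, upper_pct: float = 97.5):
    """Keep-mask for plausible energy reporters based on food intake level.

    FIL = TEI / BMR; subjects strictly below the cohort's ``lower_pct``
    percentile or strictly above its ``upper_pct`` percentile are flagged for
    exclusion (mask False).
    """
    tei = np.asarray(tei, dtype=float)
    bmr = np.asarray(bmr, dtype=float)
    if np.any(bmr <= 0):
        raise ValueError("BMR must be positive")
    fil = tei / bmr
    if fil.size < 40:
        warnings.warn("fewer than 40 subjects: FIL percentile estimates are unstable")
    lo, hi = np.percentile(fil, [lower_pct, upper_pct])
    return (fil >= lo) & (fil <= hi)


def filter_predictors(X: pd.DataFrame, corr_threshold: float = 0.80) -> list[str]:
    """Drop zero-variance columns, then greedily break |corr| > threshold pairs.

    For each offending pair (visited in order of decreasing |corr|, ties by
    column order) the member with the larger mean absolute correlation to all
    remaining columns is dropped. Deterministic; the surviving set has all
    pairwise |corr| <= threshold.
    """
    keep = [c for c in X.columns if X[c].nunique(dropna=True) > 1]
    if not keep:
        raise ValueError("all predictors have zero variance")
    corr = X[keep].corr().abs().to_numpy()
    np.fill_diagonal(corr, 0.0)
    corr = np.nan_to_num(corr)
    active = np.ones(len(keep), dtype=bool)
    while True:
        sub = corr * np.outer(active, active)
        i, j = np.unravel_index(np.argmax(sub), sub.shape)
        if sub[i, j] <= corr_threshold:
            break
        mean_i = corr[i, active].mean()
        mean_j = corr[j, active].mean()
        drop = i if mean_i >= mean_j else j
        active[drop] = False
    kept = [c for c, a in zip(keep, active) if a]
    if not kept:
        raise ValueError("correlation filter removed every predictor")
    return kept


def _vif(X: np.ndarray, j: int) -> float:
    y = X[:, j]
    others = np.delete(X, j, axis=1)
    A = np.column_stack([np.ones(len(y)), others])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ coef
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0:
        return np.inf
    r2 = 1.0 - ss_res / ss_tot
    return np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)


def vif_filter(X: pd.DataFrame, threshold: float = 10.0) -> list[str]:
    """Iteratively drop the column with the largest VIF until all VIF <= threshold.

    VIF_j = 1/(1 - R^2_j) from regressing column j on the others; exact
    collinearity yields an infinite VIF and is removed first.
    """
    cols = list(X.columns)
    if len(X) <= len(cols):
        raise ValueError("need more rows than columns for VIF estimation")
    M = X.to_numpy(dtype=float)
    while len(cols) > 1:
        vifs = np.array([_vif(M, j) for j in range(M.shape[1])])
        worst = int(np.argmax(vifs))
        if vifs[worst] <= threshold:
            break
        M = np.delete(M, worst, axis=1)
        cols.pop(worst)
    return cols


def outlier_removal(visit: pd.DataFrame, bounds: dict[str, tuple[float, float]]) -> pd.DataFrame:
    """Set trait values outside configured plausibility bounds to missing.

    ``bounds`` maps column name -> (low, high); the interval is closed, so a
    value exactly at a bound is kept. Counts of removed values are logged.
    """
    out = visit.copy()
    for col, (low, high) in bounds.items():
        if low >= high:
            raise ValueError(f"invalid bounds for {col}: low {low} >= high {high}")
        if col not in out.columns:
            continue
        bad = (out[col] < low) | (out[col] > high)
        n_bad = int(bad.sum())
        if n_bad:
            logger.info("outlier_removal: %d values of %r outside [%s, %s]", n_bad, col, low, high)
        out.loc[bad, col] = np.nan
    return out
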