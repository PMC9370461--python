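"""Incremental predictive value of the sensitivity flag over a risk score.

Two nested logistic regressions are compared by ROC AUC: outcome ~ baseline
risk score, versus outcome ~ baseline risk score + sensitivity indicator.
Published clinical risk algorithms are external documents; the module
exposes a pluggable ``base_score`` interface and ships a synthetic baseline
(logistic in age, sex and either SBP + total cholesterol or BMI).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "AucComparison",
    "fit_logistic",
    "roc_auc",
    "compare_with_sensitivity",
    "synthetic_base_score",
]


@dataclass
class AucComparison:
    auc_base: float
    auc_with_sensitivity: float
    delta_auc: float
    n: int
    n_events: int


@dataclass
class LogisticFit:
    """Coefficients (intercept first), their SEs, and the linear predictor."""

    coef: np.ndarray
    se: np.ndarray
    linear_predictor: np.ndarray
    converged: bool

    def conf_int(self, alpha: float = 0.05) -> np.ndarray:
        z = stats.norm.ppf(1 - alpha / 2)
        return np.column_stack([self.coef - z * self.se, self.coef + z * self.se])


def fit_logistic(outcome, predictors) -> LogisticFit:
    """Maximum-likelihood logistic regression (IRLS).

    Perfect separation is flagged as non-converged rather than raising.
    """
    y = np.asarray(outcome, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("outcome must contain both classes")
    X = np.asarray(predictors, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    Xc = sm.add_constant(X, has_constant="add")
    converged = True
    try:
        import warnings as _warnings
        from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

        model = sm.GLM(y, Xc, family=sm.families.Binomial())
        with _warnings.catch_warnings(record=True) as caught:
            _warnings.simplefilter("always")
            res = model.fit(maxiter=100, tol=1e-10)
        separated = any(issubclass(w.category, PerfectSeparationWarning) for w in caught)
        coef = np.asarray(res.params)
        se = np.asarray(res.bse)
        if not res.converged or separated or np.abs(coef).max() > 1e3:
            converged = False
    except Exception:  # separation or singular design
        converged = False
        coef = np.full(Xc.shape[1], np.nan)
        se = np.full(Xc.shape[1], np.nan)
    eta = Xc @ coef if converged else np.full(len(y), np.nan)
    return LogisticFit(coef, se, eta, converged)


def roc_auc(scores, outcomes) -> float:
    """Area under the ROC curve as the tie-corrected Mann–Whitney probability.

    AUC = P(score_case > score_control) + 0.5 P(tie), computed from mid-ranks.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(outcomes).astype(int)
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("both outcome classes required for AUC")
    ranks = stats.rankdata(s)
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def compare_with_sensitivity(base_score, sensitivity_flag, outcomes) -> AucComparison:
    """AUC of outcome ~ base score vs outcome ~ base score + sensitivity flag."""
    base_score = np.asarray(base_score, dtype=float)
    flag = np.asarray(sensitivity_flag, dtype=float)
    y = np.asarray(outcomes).astype(int)
    if not (len(base_score) == len(flag) == len(y)):
        raise ValueError("inputs must be aligned")
    base_fit = fit_logistic(y, base_score)
    full_fit = fit_logistic(y, np.column_stack([base_score, flag]))
    if not (base_fit.converged and full_fit.converged):
        raise RuntimeError("logistic model did not converge")
    a0 = roc_auc(base_fit.linear_predictor, y)
    a1 = roc_auc(full_fit.linear_predictor, y)
    return AucComparison(a0, a1, a1 - a0, len(y), int(y.sum()))


#: default coefficients of the synthetic baseline score (per-unit log-odds)
_SYNTH_COEF = {"age": 0.06, "sex": 0.4, "sbp": 0.02, "tc": 0.2, "bmi": 0.08}


def synthetic_base_score(df: pd.DataFrame, laboratory: bool = True) -> np.ndarray:
    """Synthetic stand-in for a published cardiovascular risk score.

    A fixed logistic-style linear predictor in age and sex plus either SBP
    and total cholesterol (laboratory) or BMI (non-laboratory), standardized
    within the cohort. Deterministic given the input table.
    """
    terms = ["age", "sex"] + (["sbp", "tc"] if laboratory else ["bmi"])
    score = np.zeros(len(df))
    for t in terms:
        if t not in df.columns:
            continue
        col = np.asarray(df[t], dtype=float)
        sd = col.std()
        z = (col - col.mean()) / sd if sd > 0 else col * 0.0
        score = score + _SYNTH_COEF[t] * z
    return score
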