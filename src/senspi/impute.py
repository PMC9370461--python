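"""Iterative random-forest imputation of mixed-type predictor tables.

Reimplements the missForest algorithm: initialize missing cells with the
column mean (continuous) or mode (categorical), then cycle through columns in
order of increasing missingness, refitting a random forest of each column on
all others and re-predicting its missing cells, until the change in the
imputed values first increases; the previous iterate is returned. Columns
with >= 50% missingness are excluded from imputation. Out-of-bag MSE
(continuous) and proportion falsely classified (categorical) are reported as
imputation-quality diagnostics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor

__all__ = ["ImputationResult", "rf_impute"]

MAX_MISSING_FRACTION = 0.5


@dataclass
class ImputationResult:
    """Completed table plus convergence and error diagnostics."""

    table: pd.DataFrame
    n_iterations: int
    mse: dict = field(default_factory=dict)       # per continuous column, OOB
    pfc: dict = field(default_factory=dict)       # per categorical column, OOB
    excluded: list = field(default_factory=list)  # columns >= 50% missing


def _is_categorical(s: pd.Series) -> bool:
    return s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype) or s.dtype == bool


def rf_impute(
    table: pd.DataFrame,
    n_trees: int = 100,
    max_iter: int = 10,
    seed: int = 0,
) -> ImputationResult:
    """missForest-style completion of a table with missing cells.

    Parameters
    ----------
    table : DataFrame with NaN for missing entries; continuous and
        categorical (object/categorical dtype) columns are both handled.
    n_trees : trees per per-column forest.
    max_iter : iteration cap for the update cycle.
    seed : reproducibility seed.
    """
    if table.shape[1] < 2:
        raise ValueError("need at least 2 columns to impute")
    rng = np.random.default_rng(seed)
    miss = table.isna()
    frac = miss.mean()
    if (frac >= 1.0).any():
        raise ValueError(f"all-missing column(s): {list(frac.index[frac >= 1.0])}")
    excluded = list(frac.index[frac >= MAX_MISSING_FRACTION])
    if excluded:
        warnings.warn(f"columns with >=50% missingness not imputed: {excluded}")
    impute_cols = [c for c in table.columns if c not in excluded and miss[c].any()]
    cat_cols = {c for c in table.columns if _is_categorical(table[c])}

    if not impute_cols:
        return ImputationResult(table.copy(), 0, excluded=excluded)

    # initial fill: mean / mode
    cur = table.copy()
    for c in impute_cols:
        if c in cat_cols:
            cur[c] = cur[c].fillna(cur[c].mode(dropna=True).iloc[0])
        else:
            cur[c] = cur[c].fillna(cur[c].mean())

    # predictors: every non-excluded column; categorical predictors one-hot
    pred_cols = [c for c in table.columns if c not in excluded]

    def design(df: pd.DataFrame, exclude: str) -> np.ndarray:
        cols = [c for c in pred_cols if c != exclude]
        parts = []
        for c in cols:
            if c in cat_cols:
                parts.append(pd.get_dummies(df[c], prefix=c, dtype=float))
            else:
                parts.append(df[[c]].astype(float))
        return pd.concat(parts, axis=1).to_numpy()

    order = sorted(impute_cols, key=lambda c: (frac[c], table.columns.get_loc(c)))
    mse: dict = {}
    pfc: dict = {}
    delta_cont_prev = np.inf
    delta_cat_prev = np.inf
    n_done = 0
    for _ in range(max_iter):
        new = cur.copy()
        it_mse, it_pfc = {}, {}
        for c in order:
            m = miss[c].to_numpy()
            Xfull = design(new, c)
            y = new[c]
            rs = int(rng.integers(0, 2**31 - 1))
            if c in cat_cols:
                forest = RandomForestClassifier(
                    n_estimators=n_trees, random_state=rs, oob_score=True, n_jobs=1
                )
                forest.fit(Xfull[~m], y[~m])
                new.loc[m, c] = forest.predict(Xfull[m])
                it_pfc[c] = float(1.0 - forest.oob_score_)
            else:
                forest = RandomForestRegressor(
                    n_estimators=n_trees, random_state=rs, oob_score=True, n_jobs=1
                )
                yv = y.astype(float).to_numpy()
                forest.fit(Xfull[~m], yv[~m])
                new.loc[m, c] = forest.predict(Xfull[m])
                oob_pred = forest.oob_prediction_
                it_mse[c] = float(np.mean((yv[~m] - oob_pred) ** 2))
        n_done += 1

        # missForest stopping rule: normalized squared change (continuous)
        # and fraction of changed categories (categorical)
        cont = [c for c in order if c not in cat_cols]
        cat = [c for c in order if c in cat_cols]
        delta_cont = 0.0
        if cont:
            num = den = 0.0
            for c in cont:
                m = miss[c].to_numpy()
                a = new.loc[m, c].astype(float).to_numpy()
                b = cur.loc[m, c].astype(float).to_numpy()
                num += float(((a - b) ** 2).sum())
                den += float((a**2).sum())
            delta_cont = num / den if den > 0 else 0.0
        delta_cat = 0.0
        if cat:
            changed = total = 0
            for c in cat:
                m = miss[c].to_numpy()
                changed += int((new.loc[m, c].to_numpy() != cur.loc[m, c].to_numpy()).sum())
                total += int(m.sum())
            delta_cat = changed / total if total else 0.0

        worse_cont = (not cont) or (delta_cont >= delta_cont_prev)
        worse_cat = (not cat) or (delta_cat >= delta_cat_prev)
        if n_done > 1 and worse_cont and worse_cat:
            # change increased: return the previous iterate
            return ImputationResult(cur, n_done - 1, mse, pfc, excluded)
        cur = new
        mse, pfc = it_mse, it_pfc
        delta_cont_prev, delta_cat_prev = delta_cont, delta_cat
    return ImputationResult(cur, n_done, mse, pfc, excluded)
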