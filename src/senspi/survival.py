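"""Cox proportional hazards regression with proportionality diagnostics.

The partial likelihood is maximized by Newton–Raphson with step halving,
using Efron's approximation for tied event times by default (Breslow
available). Standard errors come from the inverse observed information.
Proportional hazards are checked with the Grambsch–Therneau score test on
Schoenfeld residuals against a transform of event time.

The model object follows the statsmodels convention: ``CoxPH(df, ...)``
holds the data and design; ``fit()`` returns a :class:`CoxPHResults` with
estimates, their uncertainties and a ``summary()`` table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["CoxPH", "CoxPHResults", "schoenfeld_test", "cox_fit"]


class ConvergenceWarning(UserWarning):
    pass


class CoxPH:
    """Cox proportional hazards model.

    Parameters
    ----------
    data : DataFrame with one row per subject.
    duration_col, event_col : time-to-event (years) and 0/1 indicator columns.
    covariates : columns entering the linear predictor. Categorical columns
        are expanded to dummies; a column named ``label`` with values
        sensitive/resilient/neutral is expanded with *neutral as reference*.
    ties : "efron" (default) or "breslow".
    """

    def __init__(self, data: pd.DataFrame, duration_col: str = "time",
                 event_col: str = "event", covariates: list[str] | None = None,
                 ties: str = "efron"):
        if ties not in ("efron", "breslow"):
            raise ValueError("ties must be 'efron' or 'breslow'")
        self.ties = ties
        covariates = covariates or [
            c for c in data.columns if c not in (duration_col, event_col)
        ]
        t = np.asarray(data[duration_col], dtype=float)
        e = np.asarray(data[event_col], dtype=float).astype(int)
        if np.any(t <= 0):
            raise ValueError("event/censoring times must be positive")
        X, names = self._build_design(data, covariates)
        if e.sum() < 2:
            raise ValueError("need at least 2 events")
        order = np.argsort(t, kind="stable")
        self.time = t[order]
        self.event = e[order]
        self.X = X[order]
        self.names = names
        self.n, self.p = X.shape

    @staticmethod
    def _build_design(data: pd.DataFrame, covariates: list[str]):
        parts, names = [], []
        for c in covariates:
            col = data[c]
            if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
                levels = [lv for lv in pd.unique(col.dropna())]
                # neutral is the reference group when present
                if "neutral" in levels:
                    levels = ["neutral"] + sorted(lv for lv in levels if lv != "neutral")
                else:
                    levels = sorted(levels)
                for lv in levels[1:]:
                    parts.append((col == lv).astype(float).to_numpy())
                    names.append(f"{c}[{lv}]")
            else:
                parts.append(col.astype(float).to_numpy())
                names.append(c)
        X = np.column_stack(parts) if parts else np.empty((len(data), 0))
        return X, names

    # -- partial likelihood -------------------------------------------------
    def _loglik_grad_hess(self, beta: np.ndarray):
        """Efron/Breslow log partial likelihood, gradient and Hessian.

        Data are sorted by time ascending; risk-set sums are suffix sums.
        """
        X, event, time = self.X, self.event, self.time
        eta = X @ beta
        eta = eta - eta.max()  # guard overflow; partial lik is shift-invariant
        r = np.exp(eta)
        rx = r[:, None] * X
        rxx = np.einsum("i,ij,ik->ijk", r, X, X)
        # suffix sums: S*(t_i) over subjects with time >= t_i
        S0 = np.cumsum(r[::-1])[::-1]
        S1 = np.cumsum(rx[::-1], axis=0)[::-1]
        S2 = np.cumsum(rxx[::-1], axis=0)[::-1]

        ll = 0.0
        grad = np.zeros(self.p)
        hess = np.zeros((self.p, self.p))
        i = 0
        n = self.n
        while i < n:
            j = i
            while j < n and time[j] == time[i]:
                j += 1
            deaths = np.arange(i, j)[event[i:j] == 1]
            d = len(deaths)
            if d > 0:
                s0 = S0[i]
                s1 = S1[i]
                s2 = S2[i]
                d0 = r[deaths].sum()
                d1 = rx[deaths].sum(axis=0)
                d2 = rxx[deaths].sum(axis=0)
                ll += eta[deaths].sum()
                grad += X[deaths].sum(axis=0)
                if self.ties == "breslow":
                    fracs = np.zeros(d)
                else:
                    fracs = np.arange(d) / d
                for f in fracs:
                    phi0 = s0 - f * d0
                    phi1 = s1 - f * d1
                    phi2 = s2 - f * d2
                    z = phi1 / phi0
                    ll -= np.log(phi0)
                    grad -= z
                    hess -= phi2 / phi0 - np.outer(z, z)
            i = j
        return ll, grad, hess

    def fit(self, maxiter: int = 50, tol: float = 1e-8) -> "CoxPHResults":
        beta = np.zeros(self.p)
        ll, grad, hess = self._loglik_grad_hess(beta)
        converged = False
        for _ in range(maxiter):
            if np.linalg.norm(grad) < tol:
                converged = True
                break
            try:
                step = np.linalg.solve(-hess, grad)
            except np.linalg.LinAlgError:
                step = np.linalg.lstsq(-hess, grad, rcond=None)[0]
            # step halving on likelihood decrease; the acceptance slack is
            # relative, so float-level noise near the optimum cannot spin
            scale = 1.0
            slack = 1e-10 * (1.0 + abs(ll))
            for _ in range(20):
                cand = beta + scale * step
                ll_new, grad_new, hess_new = self._loglik_grad_hess(cand)
                if np.isfinite(ll_new) and ll_new >= ll - slack:
                    break
                scale *= 0.5
            stalled = abs(ll_new - ll) < 1e-13 * (1.0 + abs(ll))
            beta, ll, grad, hess = cand, ll_new, grad_new, hess_new
            if stalled:
                # numerical optimum reached; accept if the score is tiny on
                # the likelihood scale even when it misses the strict tol —
                # unless the estimate is running away (monotone likelihood)
                converged = bool(
                    np.linalg.norm(grad) < 1e-5 * (1.0 + abs(ll))
                    and np.abs(beta).max() < 20
                )
                break
            if np.abs(beta).max() > 50:
                break  # monotone likelihood; estimates diverge
        if np.abs(beta).max() > 20:
            # the flattening tail of a monotone likelihood can satisfy the
            # gradient criterion at an absurd estimate; flag it instead
            converged = False
        if not converged:
            warnings.warn(
                "Cox partial likelihood did not converge (possible monotone "
                "likelihood, e.g. a category with no events)",
                ConvergenceWarning,
            )
        try:
            cov = np.linalg.inv(-hess)
        except np.linalg.LinAlgError:
            cov = np.full((self.p, self.p), np.nan)
        return CoxPHResults(self, beta, cov, ll, converged)


class CoxPHResults:
    """Fitted Cox model: log-HRs, SEs, Wald CIs/p-values, diagnostics."""

    def __init__(self, model: CoxPH, beta, cov, loglik, converged):
        self.model = model
        self.params = pd.Series(beta, index=model.names, name="log_hr")
        self.cov = pd.DataFrame(cov, index=model.names, columns=model.names)
        self.bse = pd.Series(np.sqrt(np.diag(cov)), index=model.names, name="se")
        self.loglik = float(loglik)
        self.converged = bool(converged)
        self.n = model.n
        self.n_events = int(model.event.sum())

    @property
    def hazard_ratios(self) -> pd.Series:
        return np.exp(self.params).rename("hr")

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        z = stats.norm.ppf(1 - alpha / 2)
        lo = np.exp(self.params - z * self.bse)
        hi = np.exp(self.params + z * self.bse)
        return pd.DataFrame({"hr_lower": lo, "hr_upper": hi})

    @property
    def pvalues(self) -> pd.Series:
        z = self.params / self.bse
        return pd.Series(2 * stats.norm.sf(np.abs(z)), index=self.params.index, name="p")

    def summary(self) -> pd.DataFrame:
        ci = self.conf_int()
        tab = pd.DataFrame(
            {
                "log_hr": self.params,
                "se": self.bse,
                "hr": self.hazard_ratios,
                "hr_lower": ci["hr_lower"],
                "hr_upper": ci["hr_upper"],
                "p": self.pvalues,
            }
        )
        tab.attrs["n"] = self.n
        tab.attrs["n_events"] = self.n_events
        tab.attrs["converged"] = self.converged
        return tab

    def to_dict(self) -> dict:
        ci = self.conf_int()
        return {
            "converged": self.converged,
            "n": self.n,
            "n_events": self.n_events,
            "loglik": self.loglik,
            "coefficients": {
                name: {
                    "log_hr": float(self.params[name]),
                    "se": float(self.bse[name]),
                    "hr": float(self.hazard_ratios[name]),
                    "hr_lower": float(ci.loc[name, "hr_lower"]),
                    "hr_upper": float(ci.loc[name, "hr_upper"]),
                    "p": float(self.pvalues[name]),
                }
                for name in self.params.index
            },
        }

    # -- Schoenfeld residual PH test ----------------------------------------
    def schoenfeld_residuals(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-event Schoenfeld residuals and the corresponding event times.

        s_k = x_k - xbar(t_k), the covariates of the subject failing at t_k
        minus the risk-set average weighted by exp(eta).
        """
        m = self.model
        eta = m.X @ self.params.to_numpy()
        r = np.exp(eta - eta.max())
        S0 = np.cumsum(r[::-1])[::-1]
        S1 = np.cumsum((r[:, None] * m.X)[::-1], axis=0)[::-1]
        # map each subject to the first index of its (tied) time group
        first = np.zeros(m.n, dtype=int)
        i = 0
        while i < m.n:
            j = i
            while j < m.n and m.time[j] == m.time[i]:
                j += 1
            first[i:j] = i
            i = j
        deaths = np.where(m.event == 1)[0]
        xbar = S1[first[deaths]] / S0[first[deaths], None]
        resid = m.X[deaths] - xbar
        return resid, m.time[deaths]

    def schoenfeld_test(self, transform: str = "identity") -> pd.DataFrame:
        """Grambsch–Therneau score test for proportional hazards.

        Regresses scaled Schoenfeld residuals on g(event time) (identity or
        rank transform) and tests zero slope per covariate plus globally.
        Returns chi2, df and p per covariate with a final GLOBAL row.
        """
        m = self.model
        if self.n_events < 2:
            raise ValueError("need at least 2 events for the PH test")
        if self.n_events < 10:
            warnings.warn("fewer than 10 events: PH test is unreliable")
        resid, times = self.schoenfeld_residuals()
        if transform == "identity":
            g = times.astype(float)
        elif transform == "rank":
            g = stats.rankdata(times).astype(float)
        else:
            raise ValueError("transform must be 'identity' or 'rank'")
        g = g - g.mean()
        d = len(times)
        V = self.cov.to_numpy()  # inverse information
        u = resid.T @ g          # p-vector
        gg = float(g @ g)
        vu = V @ u
        chi2 = d * vu**2 / (np.diag(V) * gg)
        pvals = stats.chi2.sf(chi2, 1)
        global_chi2 = float(d * (u @ V @ u) / gg)
        global_p = float(stats.chi2.sf(global_chi2, m.p))
        out = pd.DataFrame(
            {"chi2": np.append(chi2, global_chi2),
             "df": [1] * m.p + [m.p],
             "p": np.append(pvals, global_p)},
            index=m.names + ["GLOBAL"],
        )
        return out


def cox_fit(records: pd.DataFrame, covariates=None, duration_col="time",
            event_col="event", ties="efron") -> CoxPHResults:
    """Functional wrapper: fit a Cox model on a record table."""
    return CoxPH(records, duration_col, event_col, covariates, ties).fit()


def schoenfeld_test(fit: CoxPHResults, transform: str = "identity") -> pd.DataFrame:
    """Functional wrapper over :meth:`CoxPHResults.schoenfeld_test`."""
    return fit.schoenfeld_test(transform)
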