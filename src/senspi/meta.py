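"""Random-effects meta-analysis of per-cohort hazard estimates.

Inverse-variance pooling with the DerSimonian–Laird moment estimator of the
between-study variance tau^2, Cochran's Q heterogeneity statistic, and a
one-degree-of-freedom Q test for differences between two pooled subgroups
(sensitive vs resilient). Confidence intervals use the normal approximation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "StudyEstimate",
    "MetaResult",
    "RandomEffectsMeta",
    "dl_pool",
    "cochran_q_test",
    "subgroup_difference_test",
]


@dataclass(frozen=True)
class StudyEstimate:
    """One cohort's log hazard ratio with its standard error."""

    cohort: str
    log_hr: float
    se: float
    category: str = "sensitive"   # sensitive | resilient
    trait: str = ""
    outcome: str = ""

    def __post_init__(self):
        if self.se <= 0:
            raise ValueError("SE must be positive")


@dataclass
class MetaResult:
    """Pooled estimate with heterogeneity statistics."""

    log_hr: float
    se: float
    tau2: float
    q: float
    q_df: int
    q_p: float
    k: int
    method: str = "random"
    fixed_log_hr: float = field(default=np.nan)
    fixed_se: float = field(default=np.nan)

    @property
    def hr(self) -> float:
        return float(np.exp(self.log_hr))

    def conf_int(self, alpha: float = 0.05) -> tuple[float, float]:
        z = stats.norm.ppf(1 - alpha / 2)
        return (float(np.exp(self.log_hr - z * self.se)),
                float(np.exp(self.log_hr + z * self.se)))

    def to_dict(self) -> dict:
        lo, hi = self.conf_int()
        return {
            "hr": self.hr, "hr_lower": lo, "hr_upper": hi,
            "log_hr": self.log_hr, "se": self.se, "tau2": self.tau2,
            "q": self.q, "q_df": self.q_df, "q_p": self.q_p, "k": self.k,
            "method": self.method,
        }


class RandomEffectsMeta:
    """DerSimonian–Laird random-effects pooling model.

    ``estimates`` is a list of :class:`StudyEstimate` (or (log_hr, se)
    pairs); ``fit()`` returns a :class:`MetaResult`.
    """

    def __init__(self, estimates):
        est = []
        for e in estimates:
            if isinstance(e, StudyEstimate):
                est.append((e.log_hr, e.se))
            else:
                est.append((float(e[0]), float(e[1])))
        if not est:
            raise ValueError("need at least one study estimate")
        self.theta = np.array([a for a, _ in est])
        self.se = np.array([b for _, b in est])
        if np.any(self.se <= 0):
            raise ValueError("all SEs must be positive")
        self.k = len(est)

    def fit(self, method: str = "random") -> MetaResult:
        w = 1.0 / self.se**2
        theta_fixed = float(np.sum(w * self.theta) / np.sum(w))
        se_fixed = float(np.sqrt(1.0 / np.sum(w)))
        q = float(np.sum(w * (self.theta - theta_fixed) ** 2))
        df = self.k - 1
        q_p = float(stats.chi2.sf(q, df)) if df > 0 else 1.0
        if df > 0:
            denom = np.sum(w) - np.sum(w**2) / np.sum(w)
            tau2 = max(0.0, (q - df) / denom)
        else:
            tau2 = 0.0
        if method == "fixed":
            pooled, se = theta_fixed, se_fixed
        else:
            wr = 1.0 / (self.se**2 + tau2)
            pooled = float(np.sum(wr * self.theta) / np.sum(wr))
            se = float(np.sqrt(1.0 / np.sum(wr)))
        return MetaResult(pooled, se, tau2, q, df, q_p, self.k, method,
                          fixed_log_hr=theta_fixed, fixed_se=se_fixed)


def dl_pool(estimates, method: str = "random") -> MetaResult:
    """Pool study estimates under the DerSimonian–Laird random-effects model."""
    return RandomEffectsMeta(estimates).fit(method)


def cochran_q_test(estimates) -> tuple[float, int, float]:
    """Cochran's Q heterogeneity test; returns (Q, df, p)."""
    model = RandomEffectsMeta(estimates)
    if model.k < 2:
        raise ValueError("need at least 2 studies for a heterogeneity test")
    res = model.fit()
    return res.q, res.q_df, res.q_p


def subgroup_difference_test(pooled_a: MetaResult | None,
                             pooled_b: MetaResult | None):
    """df=1 Q test for a difference between two pooled subgroup estimates.

    Returns (Q, p); (nan, nan) when either subgroup could not be pooled
    (mirroring missing cells in sparse categories).
    """
    if pooled_a is None or pooled_b is None:
        return (float("nan"), float("nan"))
    z = (pooled_a.log_hr - pooled_b.log_hr) / np.sqrt(pooled_a.se**2 + pooled_b.se**2)
    q = float(z**2)
    return q, float(stats.chi2.sf(q, 1))


def pool_table(estimates: list[StudyEstimate]) -> pd.DataFrame:
    """Pool a flat list of study estimates by (trait, outcome, category).

    Returns one row per combination with the pooled HR, CI, tau^2, Q and
    the sensitive-vs-resilient subgroup test where both groups exist —
    the shape of a trait-by-category hazard summary table.
    """
    df = pd.DataFrame([e.__dict__ for e in estimates])
    rows = []
    for (trait, outcome), grp in df.groupby(["trait", "outcome"], sort=True):
        pooled = {}
        for cat, sub in grp.groupby("category"):
            res = dl_pool(list(zip(sub["log_hr"], sub["se"])))
            pooled[cat] = res
            lo, hi = res.conf_int()
            rows.append({
                "trait": trait, "outcome": outcome, "category": cat,
                "k": res.k, "hr": res.hr, "hr_lower": lo, "hr_upper": hi,
                "tau2": res.tau2, "q": res.q, "q_p": res.q_p,
            })
        q_sub, p_sub = subgroup_difference_test(
            pooled.get("resilient"), pooled.get("sensitive")
        )
        for r in rows[-len(pooled):]:
            r["subgroup_q"] = q_sub
            r["subgroup_p"] = p_sub
    return pd.DataFrame(rows)
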