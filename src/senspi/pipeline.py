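"""End-to-end orchestration: simulate/load -> preprocess -> impute -> split ->
fit QRF -> classify -> Cox -> pool -> AUC.

The pipeline mirrors a two-cohort precision-prevention study: within each
cohort the training half fits a quantile regression forest for the trait,
the testing half receives conditional prediction intervals and sensitivity
labels, and the labelled test subjects feed the time-to-event analysis.
Per-cohort hazard estimates are pooled across cohorts under a random-effects
model, and the incremental predictive value of the sensitivity flag over a
baseline risk score is quantified by ROC AUC.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from . import classify as _classify
from . import meta as _meta
from . import preprocess as _pre
from . import riskscore as _risk
from .impute import rf_impute
from .qrf import QuantileForest
from .survival import CoxPH
from .synth import SynthConfig, SyntheticCohort, simulate_cohort

logger = logging.getLogger(__name__)

__all__ = ["CohortSpec", "PipelineConfig", "PipelineResults", "split_train_test", "run_pipeline"]


@dataclass
class CohortSpec:
    """One cohort in the study: its name, labelling mode, and generator."""

    name: str
    mode: str = "persistent"  # persistent (two visits) | single_visit
    synth: SynthConfig = field(default_factory=SynthConfig)


@dataclass
class PipelineConfig:
    """Study-level configuration.

    alpha is the prediction-interval miscoverage (0.10 -> 90% PI);
    split_fraction the training share of the subject-level partition.
    """

    cohorts: list = field(default_factory=lambda: [
        CohortSpec("cohort_a", "persistent"),
        CohortSpec("cohort_b", "single_visit"),
    ])
    trait: str = "trait"
    outcome: str = "CVD"           # CVD | T2D | death | any
    alpha: float = 0.10
    split_fraction: float = 0.50
    n_trees: int = 500
    min_node_size: int = 5
    mtry: int | None = None
    adverse_direction: str = "high"
    corr_threshold: float = 0.80
    vif_threshold: float = 10.0
    survival_covariates: tuple = ("age", "sex")
    qrf_covariates: tuple = ("age", "age2", "sex", "ffq_version", "fasting_status")
    impute_enabled: bool = True
    impute_max_iter: int = 5
    impute_n_trees: int = 50
    auc_horizon: float = 10.0
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.split_fraction < 1):
            raise ValueError("split_fraction must lie in (0, 1)")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(open(path)) or {}
        cohorts = []
        for c in raw.pop("cohorts", []):
            synth = SynthConfig(**c.pop("synth", {}))
            cohorts.append(CohortSpec(synth=synth, **c))
        cfg = cls(**raw)
        if cohorts:
            cfg.cohorts = cohorts
        return cfg


@dataclass
class PipelineResults:
    """Bundle of every stage's output plus a run manifest."""

    labels: pd.DataFrame
    cox: dict
    estimates: list
    pooled: pd.DataFrame
    auc: dict
    manifest: dict

    def pooled_result(self, category: str = "sensitive"):
        sub = self.pooled[self.pooled["category"] == category]
        return sub.iloc[0] if len(sub) else None


def split_train_test(subject_ids, fraction: float = 0.5, seed: int = 0):
    """Subject-level random partition into (train_ids, test_ids).

    Both visits of a subject land on the same side; the two sets are
    disjoint and exhaustive.
    """
    ids = np.asarray(subject_ids)
    if not (0 < fraction < 1):
        raise ValueError("fraction must lie in (0, 1)")
    if len(ids) < 10:
        raise ValueError("need at least 10 subjects to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    n_train = int(round(fraction * len(ids)))
    return ids[perm[:n_train]], ids[perm[n_train:]]


def _prepare_exposures(cohort: SyntheticCohort, cfg: PipelineConfig, manifest: dict):
    """Transform and filter exposure columns; returns kept column names.

    Continuous exposures are inverse-normal transformed (visit-wise); columns
    failing the correlation filter on visit-1 data are dropped from both
    visits. Dummy columns (two observed levels) are left untransformed.
    """
    visits = cohort.visits
    exp_cols = cohort.exposure_cols
    for col in exp_cols:
        for v in (1, 2):
            sel = visits["visit_index"] == v
            vals = visits.loc[sel, col]
            if vals.dropna().nunique() > 2:
                visits.loc[sel, col] = _pre.inverse_normal_transform(vals)
    v1 = visits[visits["visit_index"] == 1]
    kept = _pre.filter_predictors(v1[exp_cols], cfg.corr_threshold)
    manifest["n_exposures_initial"] = len(exp_cols)
    manifest["n_exposures_after_corr_filter"] = len(kept)
    return kept


def _design_matrix(df: pd.DataFrame, exposure_cols, cfg: PipelineConfig):
    X = df[list(exposure_cols)].copy()
    for cov in cfg.qrf_covariates:
        if cov == "age2":
            X["age2"] = df["age"].astype(float) ** 2
        elif cov in df.columns:
            X[cov] = df[cov].astype(float)
    return X


def _run_cohort(spec: CohortSpec, cfg: PipelineConfig, seed: int):
    manifest: dict = {"cohort": spec.name, "mode": spec.mode}
    synth_cfg = replace(spec.synth, seed=seed)
    cohort = simulate_cohort(synth_cfg)
    manifest["n_subjects"] = synth_cfg.n_subjects

    # energy-reporting exclusion on visit-1 TEI/BMR
    v1 = cohort.visit(1)
    keep_mask = _pre.fil_exclusion(v1["tei"], v1["bmr"])
    keep_ids = v1.index[keep_mask]
    cohort.visits = cohort.visits[cohort.visits["subject_id"].isin(keep_ids)].reset_index(drop=True)
    manifest["n_after_fil_exclusion"] = len(keep_ids)

    exp_cols = _prepare_exposures(cohort, cfg, manifest)

    # imputation of any missing exposure cells
    if cfg.impute_enabled and cohort.visits[exp_cols].isna().any().any():
        for v in (1, 2):
            sel = cohort.visits["visit_index"] == v
            block = cohort.visits.loc[sel, exp_cols]
            res = rf_impute(block, n_trees=cfg.impute_n_trees,
                            max_iter=cfg.impute_max_iter, seed=seed + v)
            cohort.visits.loc[sel, exp_cols] = res.table.values
        manifest["imputed"] = True

    ids = cohort.visit(1).index.to_numpy()
    train_ids, test_ids = split_train_test(ids, cfg.split_fraction, seed)
    manifest["n_train"], manifest["n_test"] = len(train_ids), len(test_ids)

    v1 = cohort.visit(1)
    v2 = cohort.visit(2)
    tr = v1.loc[train_ids]
    X_train = _design_matrix(tr, exp_cols, cfg)
    kept = _pre.vif_filter(X_train, cfg.vif_threshold)
    X_train = X_train[kept]
    manifest["n_design_columns"] = len(kept)

    forest = QuantileForest(
        tr[cfg.trait], X_train,
        n_trees=cfg.n_trees, mtry=cfg.mtry, min_node_size=cfg.min_node_size,
        seed=seed, trait_name=cfg.trait,
    ).fit()

    te1 = v1.loc[test_ids]
    observed = {1: te1[cfg.trait].to_numpy()}
    intervals = {1: forest.prediction_interval(_design_matrix(te1, exp_cols, cfg)[kept], cfg.alpha)}
    if spec.mode == "persistent":
        te2 = v2.loc[test_ids]
        observed[2] = te2[cfg.trait].to_numpy()
        intervals[2] = forest.prediction_interval(_design_matrix(te2, exp_cols, cfg)[kept], cfg.alpha)
    labels = _classify.label_cohort(
        test_ids, observed, intervals, cfg.trait,
        adverse_direction=cfg.adverse_direction,
        mode=spec.mode if spec.mode == "single_visit" else "persistent",
    )
    labels["cohort"] = spec.name
    counts = labels["label"].value_counts().to_dict()
    manifest["label_counts"] = {str(k): int(v) for k, v in counts.items()}

    # survival records of labelled test subjects
    surv = cohort.survival.loc[test_ids].copy()
    if cfg.outcome != "any":
        surv["event"] = ((surv["event"] == 1) & (surv["event_type"] == cfg.outcome)).astype(int)
    rec = surv.join(te1[list(cfg.survival_covariates)])
    rec["label"] = labels.set_index("subject_id")["label"]
    rec = rec[rec["label"].notna()]
    manifest["n_events"] = int(rec["event"].sum())

    cox_res = None
    estimates = []
    try:
        cox_res = CoxPH(
            rec, "time", "event",
            covariates=["label"] + list(cfg.survival_covariates),
        ).fit()
        for cat in ("sensitive", "resilient"):
            name = f"label[{cat}]"
            if cox_res.converged and name in cox_res.params.index:
                estimates.append(_meta.StudyEstimate(
                    spec.name, float(cox_res.params[name]), float(cox_res.bse[name]),
                    category=cat, trait=cfg.trait, outcome=cfg.outcome,
                ))
    except ValueError as exc:
        logger.warning("survival stage skipped for %s: %s", spec.name, exc)

    # incremental AUC of the sensitivity flag over the synthetic base score
    auc = None
    horizon_event = ((cohort.survival.loc[test_ids, "time"] <= cfg.auc_horizon)
                     & (cohort.survival.loc[test_ids, "event"] == 1)).astype(int)
    flag = (labels.set_index("subject_id")["label"] == "sensitive").astype(int)
    base = _risk.synthetic_base_score(te1.assign(sbp=te1[cfg.trait]) if "sbp" not in te1 else te1)
    try:
        auc = _risk.compare_with_sensitivity(base, flag.loc[test_ids], horizon_event)
    except (ValueError, RuntimeError) as exc:
        logger.warning("AUC stage skipped for %s: %s", spec.name, exc)

    return labels, cox_res, estimates, auc, manifest, cohort


def run_pipeline(config: PipelineConfig, return_cohorts: bool = False):
    """Execute every stage for every cohort and pool across cohorts."""
    all_labels, cox, estimates, auc, manifests = [], {}, [], {}, []
    cohorts = {}
    rng = np.random.default_rng(config.seed)
    for spec in config.cohorts:
        seed = int(rng.integers(0, 2**31 - 1))
        lab, cfit, est, a, man, cohort = _run_cohort(spec, config, seed)
        all_labels.append(lab)
        cox[spec.name] = cfit
        estimates.extend(est)
        auc[spec.name] = a
        manifests.append(man)
        cohorts[spec.name] = cohort
    pooled = _meta.pool_table(estimates) if estimates else pd.DataFrame()
    results = PipelineResults(
        labels=pd.concat(all_labels, ignore_index=True),
        cox=cox, estimates=estimates, pooled=pooled, auc=auc,
        manifest={"cohorts": manifests, "seed": config.seed,
                  "alpha": config.alpha, "outcome": config.outcome},
    )
    if return_cohorts:
        return results, cohorts
    return results
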