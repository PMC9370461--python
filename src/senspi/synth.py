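"""Synthetic cohort generator.

Emulates the statistical structure the downstream analysis assumes: blocks of
correlated lifestyle exposures, cardiometabolic traits that are linear
functions of exposures plus Gaussian noise, a latent persistent sensitivity
class that shifts a subject's traits beyond their conditional quantiles, two
examination visits roughly a decade apart, and exponential time-to-event
outcomes with a hazard multiplier for the sensitive class plus administrative
censoring.

No attempt is made to mimic real cohort marginal distributions or food-
frequency item semantics; the generator reproduces the *dependence structure*
that the prediction-interval classification and the Cox/meta stages rely on.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SynthConfig",
    "SyntheticCohort",
    "generate_exposures",
    "generate_traits",
    "generate_survival",
    "inject_missingness",
    "simulate_cohort",
]

LATENT_CLASSES = ("neutral", "sensitive", "resilient")
EVENT_TYPES = ("CVD", "T2D", "death")


@dataclass
class SynthConfig:
    """Parameters of the synthetic data-generating process.

    Attributes
    ----------
    n_subjects : int
        Number of subjects; each contributes two visits.
    n_exposures : int
        Number of exposure variables per visit.
    block_size : int
        Exposures are grouped into consecutive blocks of this size with
        exchangeable within-block correlation ``block_correlation``.
    block_correlation : float in [0, 1)
        Within-block latent (Gaussian copula) correlation.
    dichotomize_fraction : float
        Fraction of exposures thresholded at their median into 0/1 dummies,
        emulating dichotomized categorical questionnaire items.
    effect_vector : array or None
        Exposure -> trait coefficients. ``None`` gives 0.4 on the first third
        of the exposures and 0 elsewhere.
    noise_sd : float
        SD of the homoscedastic Gaussian trait noise (residual scale).
    prop_sensitive, prop_resilient : float
        Latent class proportions; the remainder is neutral.
    shift_multiplier : float
        Latent-class trait shift in units of ``noise_sd`` (+ for sensitive,
        - for resilient in the adverse-high convention).
    hazard_log_hr : float
        Planted log hazard ratio for the sensitive class.
    baseline_hazard : float
        Exponential baseline event rate per year.
    censor_horizon : float
        Administrative end of follow-up, years from baseline.
    visit_gap : float
        Years between the two examinations (age advances by this much).
    ar_coefficient : float
        AR(1) coefficient carrying visit-1 exposures into visit 2.
    event_type_probs : tuple
        Multinomial split of events over (CVD, T2D, death).
    """

    n_subjects: int = 4000
    n_exposures: int = 30
    block_size: int = 5
    block_correlation: float = 0.5
    dichotomize_fraction: float = 0.2
    effect_vector: np.ndarray | None = None
    noise_sd: float = 1.0
    prop_sensitive: float = 0.08
    prop_resilient: float = 0.08
    shift_multiplier: float = 2.5
    hazard_log_hr: float = float(np.log(2.0))
    covariate_log_hrs: dict = field(default_factory=lambda: {"age": 0.03, "sex": 0.3})
    baseline_hazard: float = 0.03
    censor_horizon: float = 15.0
    visit_gap: float = 10.0
    ar_coefficient: float = 0.8
    event_type_probs: tuple = (0.6, 0.25, 0.15)
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.block_correlation < 1.0):
            raise ValueError("block_correlation must lie in [0, 1)")
        if self.prop_sensitive + self.prop_resilient >= 1.0:
            raise ValueError("prop_sensitive + prop_resilient must be < 1")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be > 0")
        if abs(sum(self.event_type_probs) - 1.0) > 1e-9:
            raise ValueError("event_type_probs must sum to 1")

    def effects(self) -> np.ndarray:
        if self.effect_vector is not None:
            eff = np.asarray(self.effect_vector, dtype=float)
            if eff.shape != (self.n_exposures,):
                raise ValueError(
                    f"effect_vector has length {eff.size}, expected {self.n_exposures}"
                )
            return eff
        eff = np.zeros(self.n_exposures)
        eff[: max(1, self.n_exposures // 3)] = 0.4
        return eff


@dataclass
class SyntheticCohort:
    """A simulated two-visit cohort with ground truth attached."""

    visits: pd.DataFrame            # one row per subject-visit
    latent_class: pd.Series         # per subject, indexed by subject_id
    survival: pd.DataFrame          # per subject: time, event, event_type
    config: SynthConfig

    @property
    def exposure_cols(self) -> list[str]:
        return [c for c in self.visits.columns if c.startswith("exp_")]

    def visit(self, index: int) -> pd.DataFrame:
        return self.visits[self.visits["visit_index"] == index].set_index("subject_id")

    def write(self, outdir: str | Path) -> None:
        """Write visit tables, survival table, and a ground-truth sidecar."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for v in (1, 2):
            self.visits[self.visits["visit_index"] == v].to_csv(
                outdir / f"visit{v}.csv", index=False
            )
        self.survival.to_csv(outdir / "survival.csv", index=True)
        cfg = {
            k: (v.tolist() if isinstance(v, np.ndarray) else v)
            for k, v in asdict(self.config).items()
        }
        cfg["event_type_probs"] = list(self.config.event_type_probs)
        sidecar = {
            "config": cfg,
            "latent_class": self.latent_class.to_dict(),
        }
        (outdir / "truth.json").write_text(json.dumps(sidecar, indent=1))


def _block_correlation_matrix(p: int, block_size: int, rho: float) -> np.ndarray:
    corr = np.eye(p)
    for start in range(0, p, block_size):
        stop = min(start + block_size, p)
        corr[start:stop, start:stop] = rho
    np.fill_diagonal(corr, 1.0)
    return corr


def generate_exposures(cfg: SynthConfig, rng: np.random.Generator | None = None):
    """Draw exposures for both visits from a block-correlated Gaussian copula.

    Visit 2 follows visit 1 through an AR(1) on the latent Gaussians, so the
    two examinations are realistically correlated; a configurable fraction of
    columns is dichotomized at zero (the latent median) to emulate dummy
    variables.

    Returns ``(X1, X2)``, each ``(n_subjects, n_exposures)``.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    p = cfg.n_exposures
    corr = _block_correlation_matrix(p, cfg.block_size, cfg.block_correlation)
    chol = np.linalg.cholesky(corr)
    z1 = rng.standard_normal((cfg.n_subjects, p)) @ chol.T
    innov = rng.standard_normal((cfg.n_subjects, p)) @ chol.T
    a = cfg.ar_coefficient
    z2 = a * z1 + np.sqrt(max(0.0, 1.0 - a * a)) * innov

    n_binary = int(round(cfg.dichotomize_fraction * p))
    X1, X2 = z1.copy(), z2.copy()
    if n_binary:
        bin_cols = np.arange(p - n_binary, p)  # last columns are the dummies
        X1[:, bin_cols] = (z1[:, bin_cols] > 0).astype(float)
        X2[:, bin_cols] = (z2[:, bin_cols] > 0).astype(float)
    return X1, X2


def assign_latent_classes(cfg: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    """Assign each subject a persistent latent class by iid multinomial draw."""
    u = rng.random(cfg.n_subjects)
    cls = np.full(cfg.n_subjects, "neutral", dtype=object)
    cls[u < cfg.prop_sensitive] = "sensitive"
    cls[(u >= cfg.prop_sensitive) & (u < cfg.prop_sensitive + cfg.prop_resilient)] = "resilient"
    return cls


def generate_traits(
    exposures: np.ndarray,
    latent_class: np.ndarray,
    cfg: SynthConfig,
    rng: np.random.Generator | None = None,
    adverse_high: bool = True,
) -> np.ndarray:
    """Trait = effect_vector . exposures + latent-class shift + N(0, noise_sd).

    The sensitive class is shifted by ``+shift_multiplier * noise_sd`` in the
    adverse direction (resilient mirrored), placing those subjects beyond
    their conditional quantiles by construction. ``adverse_high=False`` flips
    the sign convention (HDL-C-like traits where low is adverse).
    """
    exposures = np.asarray(exposures, dtype=float)
    eff = cfg.effects()
    if exposures.shape[1] != eff.size:
        raise ValueError(
            f"effect_vector length {eff.size} does not match {exposures.shape[1]} exposures"
        )
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    latent_class = np.asarray(latent_class)
    shift = np.zeros(len(latent_class))
    delta = cfg.shift_multiplier * cfg.noise_sd
    shift[latent_class == "sensitive"] = delta
    shift[latent_class == "resilient"] = -delta
    if not adverse_high:
        shift = -shift
    noise = rng.standard_normal(exposures.shape[0]) * cfg.noise_sd
    return exposures @ eff + shift + noise


def generate_survival(
    latent_class: np.ndarray,
    covariates: pd.DataFrame | None,
    cfg: SynthConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Exponential event times with a hazard multiplier for the sensitive class.

    rate_i = baseline_hazard * exp(beta_S * 1[sensitive] + gamma' covariates),
    censored administratively at min(censor_horizon, staggered entry time).
    Covariates enter centered so the baseline hazard stays interpretable.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    latent_class = np.asarray(latent_class)
    n = len(latent_class)
    eta = cfg.hazard_log_hr * (latent_class == "sensitive").astype(float)
    if covariates is not None:
        for name, gamma in cfg.covariate_log_hrs.items():
            if name in covariates:
                col = np.asarray(covariates[name], dtype=float)
                eta = eta + gamma * (col - col.mean())
    rate = cfg.baseline_hazard * np.exp(eta)
    t_event = rng.exponential(1.0 / rate)
    # staggered administrative censoring: every subject observed at least half
    # the horizon, none beyond it
    c_admin = rng.uniform(0.5, 1.0, size=n) * cfg.censor_horizon
    time = np.minimum(t_event, c_admin)
    event = (t_event <= c_admin).astype(int)
    event_type = np.where(
        event == 1,
        rng.choice(EVENT_TYPES, size=n, p=cfg.event_type_probs),
        "",
    )
    return pd.DataFrame({"time": time, "event": event, "event_type": event_type})


def inject_missingness(
    table: pd.DataFrame,
    rate: float,
    seed: int,
    columns: list[str] | None = None,
):
    """Set cells missing completely at random at the given rate.

    Returns ``(table_with_nans, mask)`` where ``mask`` is a boolean DataFrame
    marking the removed cells; the original values stay available in the
    input for imputation-error scoring.
    """
    if not (0.0 <= rate < 1.0):
        raise ValueError("missingness rate must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    out = table.copy()
    cols = list(columns) if columns is not None else list(table.columns)
    mask = pd.DataFrame(False, index=table.index, columns=table.columns)
    if rate > 0:
        hit = rng.random((len(table), len(cols))) < rate
        for j, c in enumerate(cols):
            out.loc[hit[:, j], c] = np.nan
            mask[c] = hit[:, j]
    return out, mask


def simulate_cohort(cfg: SynthConfig) -> SyntheticCohort:
    """Generate a full two-visit cohort: exposures, traits, covariates, survival.

    One primary trait (``trait``) is generated from the exposures; covariates
    age / sex / fasting status / FFQ version / TEI / BMR are drawn
    independently of the latent class (age and sex also drive the hazard).
    """
    rng = np.random.default_rng(cfg.seed)
    X1, X2 = generate_exposures(cfg, rng)
    latent = assign_latent_classes(cfg, rng)

    age1 = rng.uniform(35, 60, cfg.n_subjects)
    sex = rng.integers(0, 2, cfg.n_subjects)
    fasting = np.ones(cfg.n_subjects, dtype=int)
    ffq_version = rng.integers(0, 2, cfg.n_subjects)
    tei = rng.normal(2200, 450, cfg.n_subjects).clip(800, 5000)
    bmr = rng.normal(1500, 180, cfg.n_subjects).clip(900, 2500)

    subject_id = np.arange(cfg.n_subjects)
    frames = []
    for v, X in ((1, X1), (2, X2)):
        y = generate_traits(X, latent, cfg, rng)
        df = pd.DataFrame(X, columns=[f"exp_{j}" for j in range(cfg.n_exposures)])
        df.insert(0, "subject_id", subject_id)
        df.insert(1, "visit_index", v)
        df["trait"] = y
        df["age"] = age1 + (v - 1) * cfg.visit_gap
        df["sex"] = sex
        df["fasting_status"] = fasting
        df["ffq_version"] = ffq_version
        df["tei"] = tei
        df["bmr"] = bmr
        frames.append(df)
    visits = pd.concat(frames, ignore_index=True)

    cov = pd.DataFrame({"age": age1, "sex": sex})
    survival = generate_survival(latent, cov, cfg, rng)
    survival.index = pd.Index(subject_id, name="subject_id")
    latent_s = pd.Series(latent, index=pd.Index(subject_id, name="subject_id"), name="latent_class")
    return SyntheticCohort(visits=visits, latent_class=latent_s, survival=survival, config=cfg)
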