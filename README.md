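# senspi

**Who is unusually sensitive — or resilient — to their lifestyle?**

Two people with the same diet, activity, smoking and drinking habits can end
up with very different blood pressure, lipids or glucose. `senspi`
implements a precision-prevention analysis that makes this notion
operational: a quantile regression forest (QRF) learns, from lifestyle
exposures, the *personal* 90% prediction interval of each cardiometabolic
trait, and each person is then classified by where their observed value
falls relative to their own interval:

- **sensitive** — observed trait beyond the interval in the adverse
  direction (above the 95th conditional percentile for blood pressure,
  lipids, glucose, BMI; below the 5th for HDL-C),
- **resilient** — beyond the interval in the protective direction,
- **neutral** — inside the interval.

Downstream, the package estimates the excess hazard of disease (CVD, type 2
diabetes, death) carried by each class with Cox proportional hazards
models, pools per-cohort hazard ratios under a DerSimonian–Laird
random-effects meta-analysis, and quantifies the incremental predictive
value of the sensitivity flag over a baseline risk score by ROC AUC.

## The model

For a trait *Y* and exposure vector *X*, Meinshausen's quantile regression
forest estimates the conditional distribution

&nbsp;&nbsp;&nbsp;&nbsp;*F̂*(y | X = x) = Σᵢ wᵢ(x) 𝟙{yᵢ ≤ y},

where the weights wᵢ(x) average, over the trees of a bagged CART ensemble,
the indicator that training point *i* shares the leaf containing *x*,
normalized by leaf size. The 90% prediction interval is the pair of
conditional quantiles

&nbsp;&nbsp;&nbsp;&nbsp;*I*(x) = [q₀.₀₅(Y | X = x), q₀.₉₅(Y | X = x)].

Sensitivity labels feed a Cox model with the neutral class as reference,
log-HRs are pooled across cohorts with inverse-variance weights and the
DerSimonian–Laird between-study variance τ², and heterogeneity is assessed
with Cochran's Q.

Because individual-level cohort data of this kind are access-restricted,
the package ships a first-class synthetic cohort generator (`senspi.synth`)
that reproduces the statistical structure the analysis assumes — correlated
exposure blocks, traits as exposure functions plus noise, a latent
persistent sensitivity class, two visits a decade apart, exponential
survival with a planted hazard ratio — so every stage is testable end to
end with known ground truth.

## Worked example

```python
from senspi import PipelineConfig, CohortSpec, SynthConfig, run_pipeline

config = PipelineConfig(
    cohorts=[
        CohortSpec("vhu", "persistent",   SynthConfig(n_subjects=4000, n_exposures=12)),
        CohortSpec("mdcs", "single_visit", SynthConfig(n_subjects=4000, n_exposures=12)),
    ],
    n_trees=200, outcome="any", seed=0,
)
results = run_pipeline(config)
print(results.pooled[["category", "k", "hr", "hr_lower", "hr_upper", "tau2"]])
```

prints

```
    category  k        hr  hr_lower  hr_upper  tau2
0  resilient  2  0.984003  0.683418  1.416793   0.0
1  sensitive  2  1.850188  1.414213  2.420567   0.0
```

Each cohort plants a true hazard ratio of 2.0 for the latent sensitive
class. The pipeline — which never sees the latent classes — recovers a
pooled sensitive-vs-neutral HR of 1.85 (95% CI 1.41–2.42): elevated and
significant, attenuated toward the null by classification noise, exactly as
expected when labels are derived from estimated intervals. The resilient
class carries no planted hazard and its CI covers 1.

The same pipeline is scriptable from the shell:

```bash
senspi simulate --config synth.yaml --out cohort/ --seed 1
senspi run-all --out results/ --seed 1
```

## Package layout

| module | contents |
| --- | --- |
| `senspi.synth` | synthetic cohort generator with planted ground truth |
| `senspi.preprocess` | medication corrections, Friedewald LDL-C, inverse-normal transform, residual energy adjustment, FIL exclusion, correlation/VIF predictor filters |
| `senspi.impute` | iterative random-forest (missForest-style) imputation with OOB MSE/PFC |
| `senspi.qrf` | quantile regression forest: `QuantileForest(...).fit()` → quantiles, prediction intervals, %IncMSE / IncNodePurity importances |
| `senspi.classify` | sensitive/resilient/neutral rules, two-visit persistence |
| `senspi.survival` | Cox partial likelihood (Efron/Breslow), Schoenfeld residual PH test |
| `senspi.meta` | DerSimonian–Laird pooling, Cochran's Q, subgroup difference test |
| `senspi.riskscore` | logistic models and ROC AUC comparison with/without the flag |
| `senspi.pipeline`, `senspi.cli` | orchestration and the `senspi` command |

See `docs/methods.md` for the statistical details and design choices.
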