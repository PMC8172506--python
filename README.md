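# proirm

Item-based pharmacometric analysis of daily patient-reported-outcome (PRO)
diaries, built around a 14-item COPD symptom instrument: a graded-response
item model driven by a latent disease trajectory with a continuous-time
Markov dependence layer, two-step maximum-likelihood estimation, visual
predictive checks, clinical-trial simulation under parameter uncertainty,
and go/stop decision-confidence analytics (sample-size fold, decision
probability tables, PPV/NPV, power curves, ROC/AUC) for comparing the
item-level analysis against a total-score comparator supplied as printed
summary statistics.

## Model

- **Items** (`proirm.scales`, `proirm.irt_core`): 14 ordinal items (nine
  scored 0–4, five 0–3). `P(y >= k) = expit(a (psi - b_k))` with ordered
  difficulties. An 11-item respiratory subtotal (0–40) with three subscales
  and a 0–100 total via a pluggable score-to-measure table.
- **Trajectory**: latent severity `psi(t)` per subject follows a linear,
  power, asymptotic, Weibull, or step time course, with per-arm fixed
  effects and inter-individual variability (additive or lognormal).
- **Markov layer**: responses on successive days re-equilibrate toward each
  day's marginal distribution with mean equilibrium time
  `MET(t) = met0 + met_slope * t` (kernel
  `P(dt) = lam I + (1 - lam) 1 pi^T`, `lam = exp(-dt / MET)`).
- **Estimation** (`proirm.estimation`): step 1 fits the item curves by
  marginal ML over independent pseudo-occasions (dense Gauss–Hermite
  quadrature, analytic gradients, baseline anchored at N(0,1)); step 2
  fixes them and fits the trajectory + Markov parameters by per-subject
  Laplace approximation. Model comparison by LRT (5%) / AIC.
- **Simulation and decisions** (`proirm.trial_sim`, `proirm.decision`):
  parameter uncertainty (normal fixed effects, scaled inverse-chi-square
  variances with SE-matched degrees of freedom) is propagated through large
  simulated trials into the end-of-study arm-difference distribution; the
  resulting sigma feeds closed-form and Monte-Carlo decision tables under
  a 80/20 mixture prior for the true effect.

## CLI

```bash
proirm synth generate --fixture recovery-40x120 --out data/
proirm fit icfs --data data/diary.csv --out step1/
proirm fit longitudinal --data data/diary.csv --items step1/items_fitted.csv --out step2/
proirm vpc --data data/diary.csv --items step1/items_fitted.csv \
    --model-json step2/fit_longitudinal.json --kind total --out vpc/
proirm simulate endpoints --items step1/items_fitted.csv \
    --model-json step2/fit_longitudinal.json --n-subj 1000 --n-rep 200 --out endpoints/
proirm decide table --tv -2 --sigma 2.70
proirm decide power --tv -2 --sigma 1.74
proirm decide roc --drug-mean -2 --drug-se 1 --placebo-mean 0 --placebo-se 1
proirm decide samplesize --ci-ref="-4.77:2.04" --ci-alt="-3.16:0.48"
proirm run --config pipeline.yaml    # staged pipeline with seeds + logging
```

A pipeline YAML enables stages in a fixed order (`generate`, `fit_icfs`,
`fit_longitudinal`, `vpc`, `simulate`, `decide`) and records seeds, timings
and a config hash beside the outputs.

## Data formats

Long-format diary CSV (`subject_id, arm, day, item_id, score`), whole-day
missingness encoded by absent rows; item parameters CSV
(`item_id, a, b_1..b_4`); score map CSV (`raw_sum, measure_0_100`); fit
reports and decision outputs as JSON; VPC results as tidy CSV.
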