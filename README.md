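# survselect

Prediction-oriented prognostic biomarker selection for right-censored
survival data.

In cancer genomics a central task is to find, among thousands of candidate
markers (expression, copy number, microbiome abundances, ...), the small
panel that is genuinely predictive of patient survival. `survselect`
implements and benchmarks two prediction-oriented selection strategies
around Cox-model machine learners:

* **PROMISE-Cox** — a penalized Cox model (lasso or elastic net) whose
  penalty is tuned by cross-validated predictive performance and whose final
  panel is chosen by bootstrap **stability selection**: feature *j* is kept
  when its nonzero-coefficient frequency across resamples reaches a
  threshold π.
* **CV + top-k selection** — for nonlinear learners (gradient-boosted Cox
  trees via XGBoost/LightGBM with this package's exact partial-likelihood
  gradient/curvature as the custom objective, and random survival forests):
  the panel size *k* is tuned by refitting each learner on its own top-*k*
  most important features inside cross-validation; the final panel is the
  top-*k\** of a full-data fit.

## The model

Observations are triples (tᵢ, xᵢ, δᵢ): observed time, feature vector and
event indicator. The Cox model sets the hazard to

    λ(t | x) = λ₀(t) · exp{H(x)}

with risk-score function H(·) (linear x'β for the penalized model, a tree
ensemble for the boosted learners). Fitting minimizes the negative log
partial likelihood

    −log PL = −Σ_{i: δᵢ=1} [ H(xᵢ) − log Σ_{k ∈ R(tᵢ)} exp{H(x_k)} ]

(with Breslow handling of ties), optionally plus a lasso/elastic-net
penalty. For boosting, the package supplies the per-sample gradient gᵢ and
diagonal curvature sᵢ of this loss, so each round solves the weighted
least-squares problem with targets −gᵢ/sᵢ and weights sᵢ.

Evaluation uses Harrell's concordance index, the IPCW (inverse probability
of censoring weighted) Brier score and its time integral (IBS) with the
censoring distribution Ĝ estimated by Kaplan–Meier on flipped indicators,
and — on synthetic data with known signals — the selection TPR/FPR.

Five synthetic scenarios of increasing complexity (linear, quadratic,
nonlinear without interactions, nonlinear with interactions, and a
three-population risk-group cohort) are generated by `survselect.simdata`
with ground-truth signal labels, so the whole benchmark runs without any
external data.

## Worked example

```python
import numpy as np
from survselect import (SimulationConfig, simulate, PromiseConfig, TopKConfig,
                        LearnerSpec, promise_cox_select, topk_select,
                        refit_on_selected, concordance_index, selection_tpr_fpr)

# a linear-hazard cohort with 10 true signals among 100 features
data = simulate(SimulationConfig("linear", n=1000, p=100, q=10, seed=7))
train, test = data.subset(np.arange(800)), data.subset(np.arange(800, 1000))

res = promise_cox_select(train, PromiseConfig(seed=7))
tpr, fpr = selection_tpr_fpr(res.selected, data.true_signals, data.p)
print(f"PROMISE-Cox: tuned lambda={res.chosen['lambda']}, "
      f"{len(res.selected)} features selected, TPR={tpr:.2f}, FPR={fpr:.3f}")

model = refit_on_selected(train, res.selected,
                          LearnerSpec("penalized_cox", {"lam": res.chosen["lambda"]}))
scores = model.predict_risk(test.X[:, res.selected])
print(f"held-out C-index: {concordance_index(scores, test.time, test.event):.3f}")

# nonlinear signals: the boosted top-k selector succeeds where the linear model cannot
quad = simulate(SimulationConfig("quadratic", n=1000, p=100, q=10, seed=7))
sel = topk_select(quad, TopKConfig(learner=LearnerSpec("lgb_cox"),
                                   k_grid=[5, 10, 20, 40], seed=7))
tpr, fpr = selection_tpr_fpr(sel.selected, quad.true_signals, quad.p)
print(f"LGB-Cox top-k on quadratic data: k*={sel.chosen['k']}, "
      f"TPR={tpr:.2f}, FPR={fpr:.3f}")
```

Output:

```
PROMISE-Cox: tuned lambda=0.02, 11 features selected, TPR=1.00, FPR=0.011
held-out C-index: 0.884
LGB-Cox top-k on quadratic data: k*=10, TPR=1.00, FPR=0.000
```

On the linear cohort PROMISE-Cox recovers all 10 signals with one false
positive and the refit panel ranks held-out survival well (C-index 0.88);
on the quadratic cohort the boosted top-k selector recovers all 10 signals
exactly, a regime in which a linear selector finds nothing.

## Command line

```sh
survselect simulate  --scenario nonlinear --n 5000 --p 100 --q 10 --seed 1 --out cohort.tsv
survselect select    --method promise --in cohort.tsv --seed 1 --out panel.json
survselect evaluate  --in cohort.tsv --selection panel.json --seed 1 --out report.json
survselect benchmark --config bench.json --seed 1 --out-dir results/
```

Datasets travel as TSV (time, status, features) plus a JSON manifest; every
output embeds its seed and resolved configuration.

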