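# tgfnn — interpretable fuzzy rule networks for clinical risk prediction

`tgfnn` implements a tropical-geometry-smoothed fuzzy neural network for
tabular clinical risk prediction — the setting it was built for is
predicting, from the data of one heart-failure hospitalization, whether a
patient will need advanced therapies (heart transplantation or an LVAD)
at the next hospitalization.  Unlike black-box models, the fitted network
*is* a set of clinical rules: it can print "IF systolic blood pressure is
low AND ejection fraction is low, THEN refer", tell you numerically where
"low" ends, and show which rules fired for an individual patient.

It is aimed at clinical ML researchers who need transparent decision
support on longitudinal EHR-style cohorts, and ships a synthetic cohort
generator with planted rules so every part of the pipeline can be
exercised and validated without access to protected health data.

## The model

Each continuous feature `x_i` is encoded into three graded concepts
("low", "medium", "high") by smoothed trapezoidal membership functions
built from differences of the scaled softplus

    f_eps(x) = eps * log(1 + exp(x / eps)),

parameterized by four learnable cutoffs `a_{i,1} <= ... <= a_{i,4}`.
Categorical features use their one-hot level indicators as concepts.
A three-layer network then computes, for K rules and C classes:

* attended degrees `x~_{i,k} = sum_d A[i,d,k] * concept_d(x_i)` with an
  attention tensor `A in [0,1]^(N x D x K)`;
* firing strengths through a parameterized T-norm with connection
  exponents `M in [0,1]^(N x K)`:

      r_k = ( sum_i x~_{i,k}^(M_ik * (eps-1)/eps) - N + 1 )^(eps/(eps-1))

* class scores through a parameterized T-conorm with a non-negative
  inference matrix `W in R^(K x C)`:

      O_c = ( sum_k (W_kc * r_k)^(1/eps) )^eps

The T-norm interpolates between the product (`eps -> 1`) and the minimum
(`eps -> 0`); the T-conorm between addition and the maximum.  `eps`
starts at 0.99 and is annealed geometrically during training, so the
network converges toward the tropical (min/max) limit where it reads as
crisp rule logic.  Training minimizes a class-weighted cross-entropy
plus an L1 sparsity penalty on `A` and `M` and a pairwise decorrelation
penalty on the contribution matrix `S = A * M`.

The full experimental protocol is patient-wise: expert rules initialize
the network for each of 5 cross-validation folds; rules extracted from
the folds are filtered by firing strength and mutual correlation,
ensembled, and used to re-initialize a final model trained on all
training patients and evaluated once on held-out patients.

## Worked example

```python
from tgfnn import SimSpec, TrainConfig, simulate_cohort
from tgfnn.evaluation import run_full_protocol, default_clinical_rules
from tgfnn.rules import render_rules
from tgfnn.interpret import critical_values

encounters, truth = simulate_cohort(seed=1)   # ~300 patients, ~557 pairs
result = run_full_protocol(encounters, TrainConfig(seed=1),
                           default_clinical_rules(), seed=1)
h = result.holdout_metrics
print(f"holdout AUC {h['auc']:.3f}  AUPRC {h['auprc']:.3f}  "
      f"F1 {h['f1']:.3f}  MCC {h['mcc']:.3f}")
print(render_rules(result.ruleset, result.params.standardization)[0])
```

prints

```
holdout AUC 0.866  AUPRC 0.753  F1 0.785  MCC 0.649
Rule 1: IF sodium [mmol/L] is low AND lvef [%] is low, THEN refer for heart transplantation/ LVAD
  strength=0.204  class_weights=0.010/5.520
Rule 2: IF sbp [mmHg] is low AND lvef [%] is low, THEN refer for heart transplantation/ LVAD
  strength=0.182  class_weights=0.008/5.859
```

The two extracted rules are exactly the two conjunctions planted by the
generator (`sbp < 104 ∧ lvef < 20` and `lvef < 20 ∧ sodium < 135.5`,
OR-ed and flipped with 10% label noise).  `critical_values(result.params)`
then reports where the learned concepts transition, in clinical units —
for the signal-carrying features the learned boundaries recover the
generating thresholds closely:

```
 feature    low  medium_left  medium_right   high   unit
     sbp  103.1        103.1         103.7  103.7   mmHg
  sodium  135.1        135.1         135.8  135.8 mmol/L
    lvef   19.5         19.5          22.1   22.1      %
```

(Features that carry no label signal keep arbitrary boundaries — nothing
pushes their membership cutoffs anywhere.)

The same pipeline is available from the shell:

```bash
tgfnn simulate --seed 1 --out run/
tgfnn full run/cohort.csv --seed 1 --out run/model/
tgfnn ranges run/model/model.json --out run/model/
tgfnn explain run/model/model.json run/cohort.csv \
      --rules run/model/rules.json --row 0
```

## Layout

| module | contents |
| --- | --- |
| `tgfnn.fuzzy_core` | smoothed hinge, membership functions, T-norm/T-conorm, eps annealing |
| `tgfnn.network` | schema, parameters, encoding/rule/inference layers, checkpoints |
| `tgfnn.training` | losses, Adam fitting with eps annealing, random hyperparameter search |
| `tgfnn.rules` | symbolic rules: knowledge init, extraction, ensembling, rendering |
| `tgfnn.interpret` | range inference, membership curves, per-sample explanations |
| `tgfnn.cohort` | pairing, derived features, imputation, filters, splits, simulator |
| `tgfnn.evaluation` | metric panel, CV driver, full protocol |
| `tgfnn.autodiff` | minimal reverse-mode autodiff over NumPy |

See `docs/methods.md` for modeling assumptions, defaults and limitations.
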