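# Methods

## Model

A sample is a vector of N mixed features: continuous measurements
(standardized to z-scores on the training rows) and categorical /
binary comorbidities (integer level codes, one-hot inside the model).

**Fuzzy encoding.** Each continuous feature is mapped to degrees of
membership in three ordered concepts.  With the scaled softplus
`f_eps(x) = eps*log(1+exp(x/eps))` and cutoffs `a1<=a2<=a3<=a4`
(standardized units), the memberships are the gap-normalized softplus
differences

```
low(x)    = f((a2-x)/(a2-a1)) - f((a1-x)/(a2-a1))
medium(x) = f((x-a1)/(a2-a1)) - f((x-a2)/(a2-a1))
          - f((a3-x)/(a4-a3)) + f((a4-x)/(a4-a3)) - 1
high(x)   = f((x-a3)/(a4-a3)) - f((x-a4)/(a4-a3))
```

As `eps -> 0` these converge to crisp trapezoids forming a partition of
unity.  For moderate `eps` they can overshoot [0,1] by O(eps); we do not
clip inside the membership functions (keeping them faithful and smooth)
and instead clamp at the T-norm input.

**Rule and inference layers.** The attention tensor `A` (N x D x K)
selects concepts per rule, the connection matrix `M` (N x K) weights
features as exponents inside the parameterized T-norm, and the inference
matrix `W` (K x C >= 0) aggregates rule firing strengths per class
through the parameterized T-conorm.  Class probabilities are
`softmax(O)`; the raw scores `O_c` are non-negative and unbounded above,
so a bare normalization would be unstable — softmax also pairs naturally
with the weighted cross-entropy loss.  Whether the source of the scores
should instead be min-max normalized is genuinely open; softmax is our
choice and is recorded in the checkpoint semantics.

**Numerical form of the T-norm.** With inputs clamped to
`[1e-6, 1]` and exponents in [0,1], every term
`x^(M*(eps-1)/eps)` is >= 1, so the inner base `sum - N + 1` is >= 1
*structurally*.  We therefore evaluate the T-norm entirely in log space
(`logsumexp` plus a `log(1 - (N-1)exp(-L))` correction): this is exact,
cannot overflow even as `eps -> 0.01` where direct powers exceed
float64 range, and never needs the negative-base clamp that a naive
evaluation would require.  The public `tnorm` keeps a `clamp=False` mode
that evaluates the raw formula and raises on a negative base.  The
T-conorm is evaluated in log space for the same reason (inputs raised to
`1/eps` would underflow).

**Constraints by reparameterization.** `A` and `M` are stored
unconstrained and passed through a sigmoid; `W` through a softplus;
cutoffs as a free `a1` plus three softplus-transformed gaps floored at
1e-3 so the ramp denominators `a2-a1` and `a4-a3` never vanish.
Gradients stay smooth everywhere, unlike hard projection.
`project_params` additionally offers an idempotent repair (clip + sort)
for externally supplied constrained arrays.

**Smoothness schedule.** One shared `eps` drives memberships, T-norm and
T-conorm.  It starts at 0.99 and is multiplied by `gamma = 0.999` after
every optimizer step, floored at `eps_min = 0.01`.  `gamma` and
`eps_min` are config-exposed; the defaults anneal a 200-epoch run on a
,550-pair cohort to `eps ~ 0.25-0.3`, smooth enough to keep gradients
alive, crisp enough that extracted rules are sharp.

## Loss and training

```
loss = weighted_CE + lambda1 * (||vec(A)||_1 + ||vec(M)||_1)
     + lambda2 * sum_{k<j} <vec(S[:,:,k]), vec(S[:,:,j])>,   S = A * M
```

Class weights default to inverse class frequency (positives upweighted
under imbalance).  `lambda1 = lambda2 = 1e-3` by default — mild pressure
toward few-term, non-duplicated rules; both are searchable.  Parameters
are updated with Adam (lr 1e-2, default moment decays), 200 epochs,
batch 64.  Gradients come from a small reverse-mode autodiff engine over
NumPy (`tgfnn.autodiff`); with < 1k parameters a step costs ~1 ms, and
the analytic gradients are verified against central finite differences
to < 1e-4 relative error across all parameter groups.  Training is
bit-reproducible given the config seed.  Optional patience-based early
stopping on a validation split is off by default.

Structurally-unused concept slots (continuous features have 3 concepts,
binary features 2, while the concept axis is sized to the maximum) are
masked out of the forward pass and of both regularizers.

## Rules

* **Initialization.** An expert rule sets attention 0.9 on its
  (feature, concept) slots and 0.05 elsewhere in its column, connection
  0.9/0.05, and a high positive-class inference weight; the remaining
  columns start at small random magnitudes (0.02–0.15).  0.9/0.05 biases
  training toward the clinical prior without pinning it.  Membership
  cutoffs start at the 20/40/60/80% quantiles of the training data.
* **Extraction.** Rule strength = mean firing over a reference dataset
  (mean rather than max: robust to single outlier rows).  Rules below
  strength 0.1 are dropped; among survivors, if two contribution columns
  have cosine similarity > 0.9 the weaker is dropped; terms with
  contribution `S >= 0.2` are kept, at most one concept per feature (the
  strongest slot).  All three thresholds are config-exposed.  Cosine
  similarity (scale-free) is used for pruning even though the training
  penalty uses the raw inner product, because pruning needs a
  magnitude-independent score.
* **Ensembling.** Fold rules are pooled, sorted by strength and kept
  greedily while pairwise term-vector cosine similarity stays <= 0.9 and
  at most `max_rules` survive; the operation is idempotent.
* **Reporting.** Each rule renders as an IF/AND/THEN sentence; both the
  mean firing strength and the per-class inference weights are reported
  as the rule's "contribution" — the two summaries rank rules slightly
  differently and we deliberately show both rather than pick one.

## Range inference

A concept boundary is reported where a membership ramp crosses 0.5,
found by bracketed bisection (tolerance 1e-6 standardized units, bracket
= cutoff span ± 50%) and mapped to clinical units with the stored
standardization statistics.  With near-crisp memberships the
0.5-crossing coincides with the intersection of adjacent curves; the
0.5 convention remains well defined when smooth curves do not intersect
cleanly, and it is recorded in the range-table metadata.  Features whose
ramps never reach 0.5 (very smooth or degenerate memberships — typical
for features the training never sharpened) are flagged and omitted.
Ordering of the four boundaries is enforced against root-solver jitter
(~1e-7) by a running maximum.

## Cohort pipeline

Pairs of consecutive hospitalizations form the samples: features from
the first encounter, the binary advanced-therapy label from the second.
Derived features: MAP = DBP + (SBP−DBP)/3 (the standard clinical
estimate), pulse pressure = SBP − DBP, and percent change
100·(last−first)/first for BNP and creatinine (zero denominators masked
as missing, with a positive delta meaning an increase).  Filters: drop
features > 60% missing (echo measures exempt — too central to
heart-failure staging to lose), then patients with > 10 missing cells,
then eligibility rows (age 18–80, LVEF <= 35, BMI <= 50) where those
columns exist.  Missing values are completed by within-patient
carry-forward followed by a single seeded chained-equations completion
(scikit-learn's IterativeImputer with posterior sampling); the
imputation model is fit on training-role rows only, as are the
standardization statistics — both guarded by assertions in the CV
driver.  Splits are patient-wise: a 20% patient holdout, then 5
stratified folds on the rest, stratifying on the patient-level label
(any positive pair makes the patient positive).

## Synthetic cohort

The generator emulates the scale and texture of an advanced
heart-failure referral cohort: 300 patients; encounters per patient
drawn from {2: 0.523, 3: 0.22, 4: 0.15, 5: 0.07, 6: 0.037} (~557 pairs);
a latent per-patient severity that jointly shifts blood pressure,
ejection fraction, sodium, hemoglobin and BNP and drifts mildly across
encounters; marginal feature means/SDs chosen to match published
heart-failure cohort tables (e.g. SBP 115 ± 22 mmHg, LVEF 20 ± 8%).
Labels are the OR of two planted conjunctions — `sbp < 104 ∧ lvef < 20`
and `lvef < 20 ∧ sodium < 135.5` — evaluated crisply on the first
encounter of each pair and flipped with 10% probability; the thresholds
were calibrated once against those marginals so that ~35% of pairs are
positive, and are fixed.  Missingness is punched in completely at
random per feature, concentrated in echo measures (LVIDd and mitral
regurgitation 40%).  LVEF itself gets only 15%: a recorded ejection
fraction is an eligibility requirement for this kind of cohort, so it is
largely observed in eligible encounters.

What the simulator does **not** emulate — and hence what passing tests
do not establish about real data: informative (non-random) missingness,
measurement drift and unit errors, label definitions entangled with the
features (urgent-status adjudication), patients exiting the cohort after
transplant, and correlations beyond the single severity factor.  Results
on the synthetic cohort validate the machinery, not clinical
performance.

With 10% label-flip noise the achievable holdout AUC is capped around
0.89 (an oracle scoring the true rule indicator cannot rank flipped
pairs), and holdout sets of ~110 pairs add sampling noise of ±0.04;
end-to-end discrimination in the high 0.8s is therefore the expected
regime, not a shortfall of fit.

## Problem sizes

Default experiments run the full protocol (5-fold CV + retrain) on the
~557-pair cohort in ~30 s on one CPU; the test suite uses smaller
cohorts (40–150 patients) and shorter fits where the property under test
does not need the full scale.

## Known limitations

* Binary classification only (C = 2 is what the protocol exercises;
  the layers themselves are written for general C).
* The T-norm input clamp at `[1e-6, 1]` zeroes gradients for attended
  degrees above 1 (softplus overshoot at large eps); in practice the
  annealing schedule leaves that regime quickly.
* `eps` is scheduled, not learned, and shared across the three roles;
  per-role overrides exist in the config but are untested territory.
* Rule extraction reads conjunctions only; negated or disjunctive
  concepts inside a single rule are out of scope.
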