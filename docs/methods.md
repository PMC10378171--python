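# Methods

## The optimizer

The Jellyfish Search Optimizer maintains `nPop` candidate positions inside
a box `[Lb, Ub]^d` and minimises a black-box cost. Per member and
iteration a time-control value `c(t) = (1 − t/Maxt)(2·rand − 1)` is drawn;
`c(t) > 0.5` triggers an ocean-current drift
`x + r₁(X* − β·r₂·μ)` (`X*` best-so-far, `μ` swarm mean), otherwise a group
move. Inside a group move a second draw `u` decides the branch: passive
local search `x + γ·r·(Ub − Lb)` when `u > 1 − c(t)`, else an active move
relative to a uniformly chosen partner — toward it when the partner's cost
is lower, away otherwise. Because the envelope of `c(t)` decays linearly
to zero, ocean drift stops entirely once `1 − t/Maxt < 0.5` and the passive
branch becomes rare late in the run, leaving active contraction as the
terminal dynamics.

Assumptions: the objective is evaluable everywhere in the box and finite
(non-finite values abort with a diagnostic); box constraints only.

### Parameters

| name | default | meaning |
|---|---|---|
| `pop_size` (nPop) | 30 | swarm size |
| `max_iter` (Maxt) | 100 | iteration budget; `pop_size·(max_iter+1)` evaluations |
| `beta` (β) | 3 | ocean-current strength, the customary value |
| `gamma` (γ) | 0.1 | passive step as a fraction of box width, customary value |
| `switch_threshold` | 0.5 | ocean-vs-group comparison point for `c(t)` |
| `abs_time_control` | off | use `|c(t)|` instead of the signed value |
| `boundary_mode` | clip | clip / reflect (fold) / wrap (toroidal) repair |
| `init_mode` | uniform | uniform random, or a logistic-chaotic-map lattice |
| `replacement` | greedy | accept a move only if it improves the member |

### Design choices that were genuinely open

* **Replacement rule.** With unconditional position updates the
  away-from-worse active moves keep re-inflating the swarm, and once the
  ocean-current phase ends (t > Maxt/2) the best cost stalls: on the
  10-dimensional sphere benchmark the median final cost over 10 seeds is
  ~1.9. Greedy acceptance — a member keeps its position unless the
  proposal is strictly better — lets the swarm contract and reaches
  ~7·10⁻³³ on the same budget. Greedy is therefore the default; the
  `replacement="always"` mode restores the naive variant. Global-best
  elitism is tracked separately in both modes, so the reported optimum and
  the iteration trace are non-increasing either way.
* **Merit direction in the active move.** Move toward the partner exactly
  when the partner's cost is lower. This is the food-seeking reading;
  the opposite convention turns the move into systematic flight from good
  solutions.
* **Signed time control** is the default; the absolute-value variant,
  common in descriptions of this optimizer family, is a flag. With the
  signed form, negative `c(t)` simply means the passive branch cannot fire
  (its probability is `max(c(t), 0)`).
* **Draw order.** Per member: the `c(t)` draw; then, for a group move, the
  branch draw `u`; then the step draw(s); active moves draw the partner
  index before the step draw. Fixing this order makes runs bit-reproducible
  from the seed.
* **Boundary handling** defaults to coordinate-wise clipping; reflect and
  wrap are available. Degenerate (zero-width) dimensions collapse to their
  single feasible value under all modes.

## Binary wrapper selection

Positions live in `[−4, 4]^p`, spanning sigmoid activations ≈ [0.018,
0.982]; the deterministic transfer includes feature `j` iff
`x_j ≥ 0`, and a stochastic rule (include iff `draw < s_j`) is available.
An all-excluded outcome forces the highest-activation coordinate on, so
masks are never empty. The fitness of a mask is

```
cost = w_err · (stratified 5-fold CV misclassification rate) + w_size · |mask|/p
```

with `w_err = 1, w_size = 0` by default — consistent with reported
best-cost traces near zero at high accuracy. An RMSE-of-predictions cost
mode is provided as an alternative. The initial population is seeded with
the all-ones position, so the full-feature mask is always evaluated and the
returned cost can never exceed it. Mask costs are memoised by bit pattern;
at p = 8 a typical run evaluates well under the 255 possible masks. The
default wrapper classifier is the decision tree (cheap, scale-invariant);
any of the four classifier ids can drive the fitness.

The inner 5-fold evaluation inside the fitness is separate from the outer
protocol used for reported metrics, so the selection signal does not leak
into the final scores.

## Evaluation protocol

Positive class is target = 1 (disease); sensitivity = TP/(TP+FN),
specificity = TN/(TN+FP), accuracy = (TP+TN)/n, AUC = trapezoidal ROC area
(equal to the Mann–Whitney probability with ties counted half, delegated to
scikit-learn). Zero-denominator metrics return NaN rather than raising.
Two protocols: stratified 70/30 holdout (default, the mode under which the
headline comparisons are narrated) and stratified k-fold (default k = 10)
with macro-averaged per-fold metrics plus the pooled confusion matrix —
both appear in descriptions of this workflow and the choice is exposed.
Classifier hyperparameters are pinned in `classifier_defaults.yaml`
(one-hidden-layer MLP, impurity decision tree, AdaBoost over stumps,
RBF-SVM with C = 1); no tuning claims are made. ROC scores come from
class-1 probabilities where available and the decision function for the
SVM. A fold whose training or test part contains a single class is an
error naming the fold; a classifier that refuses to fit a useless mask
(AdaBoost's worse-than-random guard) scores that fold as total error
inside the fitness instead of aborting the search.

## Synthetic data generator

The generator emulates the Cleveland schema: five continuous features
drawn from truncated normals inside the documented ranges (mean at the
range midpoint, SD = range/6 before shifts) and eight integer-coded
categorical features from per-class multinomials over the enumerated
codes. Informative continuous features get a between-class mean shift of
`effect_size` pooled SDs (default 2.0, a strong clinical signal);
informative categorical features get `categorical_shift` probability mass
tilted in opposite directions for the two classes (default 0.6, giving a
per-feature class-association AUC ≈ 0.75 while every code remains observed
in both classes). Non-informative features are identically distributed
across classes. The default composition is 526 healthy vs 499 disease
rows (1025 total); the default informative set is `cp`, `thalach`,
`oldpeak`. Optional missingness is injected only into `ca`/`thal`, the
columns where the real cohort has nulls.

What the generator does **not** emulate: feature–feature correlations
(real clinical variables are correlated; here features are class-
conditionally independent), duplicated records (the widely circulated
1025-row file is a duplicate-expanded version of the 303-row original,
which inflates holdout and CV accuracy), non-Gaussian marginals, and
informative missingness. Tests passing on this generator therefore
demonstrate the correctness and behavior of the machinery — not clinical
performance on real data, and not the very high accuracies reported for
duplicate-expanded files.

## Problem sizes and numerical choices

The studies run at deliberately modest sizes chosen to characterise
behavior well: the convergence benchmark uses the 10-dimensional sphere
with nPop = 30 and Maxt = 500 over 10 seeds against an equal-budget random
search; the wrapper-optimality study uses one n = 300, p = 8 dataset where
all 255 non-empty masks can be enumerated exactly and 10 optimizer seeds;
recovery, neutrality, chance-level and uplift studies use 10 seeds each at
n = 200–300; the full-cohort evaluation uses the default 1025-row
composition. Exact-equality assertions are used where arithmetic is exact
(metric formulas, determinism); AUC is compared to the pairwise oracle at
1e−12; stochastic properties use the count thresholds stated with each
study.

## Known limitations

* Recovery of *weakly* informative categorical features is not guaranteed:
  across fresh dataset draws the wrapper's genuinely optimal mask excludes
  the categorical informative feature in roughly a quarter of draws at
  `categorical_shift = 0.6` — the wrapper is faithful to its cost, and the
  cost sometimes says the feature is dispensable for a greedy tree.
* The optimizer offers no constraint handling beyond the box, no
  multi-objective mode, and evaluates the population serially.
* Wrapper selection inherits the variance of its inner CV estimate; with a
  single inner seed, ties between masks within ~1 fold-vote are resolved
  arbitrarily.
* The reader validates ranges but deliberately keeps out-of-range rows
  (warning only), since documented ranges describe the original cohort
  rather than hard physiological limits.
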