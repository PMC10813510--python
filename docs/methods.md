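# Methods

This note documents the models and procedures implemented in
`batscreen`, the parameter choices that matter, and the judgement calls
made where the design was genuinely open.

## Data model and preprocessing

The canonical record has 21 attributes: ten binary questionnaire items
(A1–A10), age, gender, ethnicity, jaundice at birth, family history of
pervasive developmental disorder, respondent type, country, prior
screening-app use, an age-group code (0 toddler, 1 child, 2 adolescent,
3 adult), a screening score equal to the item sum, and the binary class.
CSV is the canonical interchange format (`yes`/`no` accepted for
booleans, `?` for missing). Missing values are imputed by default
(categorical mode, numeric median) so row counts stay stable for
splitting; a drop-rows mode exists. A loader-side consistency check
warns when the score column disagrees with the item sum rather than
failing, since real spreadsheets contain such rows.

Categorical columns are label-encoded in lexicographic category order —
an arbitrary but deterministic convention that makes encodings
reproducible across runs and platforms. Features are min–max scaled to
[0, 1] with statistics computed on the fitting partition only; test rows
transformed with training statistics may leave [0, 1] and are flagged,
not clipped. A z-score mode is available behind the `scaling` switch for
users who prefer standardisation; min–max is the default because the
binary items are already {0, 1} and the bounded range keeps KNN
distances interpretable. Constant columns scale to 0 by convention.

Train/test and k-fold splits are stratified by class. Fold assignment
uses per-class round-robin with a rotating offset, which guarantees an
exact partition with fold sizes differing by at most one.

## Dataset evaluation

Each categorical/binary attribute is cross-tabulated against the class
and tested with Pearson's chi-squared statistic, Σ(O−E)²/E with
E = (row total)(column total)/N, no continuity correction. The p-value
is the upper-tail chi-squared mass Q(df/2, s/2) computed via the
regularised upper incomplete gamma function, df = (r−1)(c−1).
Significance is flagged at 0.05; an expected cell below 5 raises a
warning, not a refusal, because screening data routinely has sparse
demographic levels. No multiple-testing correction is applied — the
report is a per-attribute screening diagnostic, not a confirmatory
analysis.

## Bat algorithm

Minimisation over a box. Per bat and iteration: frequency
`freq = F_min + (F_max − F_min)β` with β ~ U[0, 1]; velocity
`v ← v + (x − x*)·freq`; position `x + v` clipped to the box. With
probability `1 − r_k` the candidate is replaced by a local search around
the global best, `x* + ε·⟨A⟩`, ε ~ U[−1, 1] per dimension, ⟨A⟩ the
swarm-average loudness. An improving candidate is accepted with
probability min(1, A_k); on acceptance `A_k ← αA_k` and
`r_k = r₀(1 − e^{−γn_k})` with n_k the bat's acceptance count. The
global best is tracked elitistically over every evaluated candidate, so
the best-fitness trajectory is non-increasing by construction.

Defaults: population 30, `F_max = 2`, `F_min = 0`, `α = γ = 0.9`,
`A₀ = 2`, `r₀ = 1`. A quoted "parameter K = 5" attaches to no update
rule and is not used. With `r₀ = 1` and `γ = 0.9` the pulse rate
saturates after a handful of acceptances, which almost switches off the
classic algorithm's local search in late iterations; measured on the
5-dimensional sphere (population 30, 500 iterations, 20 seeds) the
classic BA therefore plateaus around 0.26 (all seeds below 0.5) rather
than converging to machine precision. This is a property of the stated
parameterisation, and it is precisely the weakness the modified
algorithm addresses; the test suite freezes the plateau-level threshold
rather than pretending the classic algorithm converges finely.

## Modified bat algorithm

Four changes, orchestrated per iteration t of T_max:

1. **Convergence factor** `a(t) = 2 − (t/T_max)²(e − 1)`, strictly
   decreasing from 2 to 3 − e. The quadratic form is used because the
   decay should be gentle early and steep late.
2. **Expansion coefficient** `L = a(2b − 1)`, b ~ U[0, 1], so
   |L| ≤ a. By default L multiplies the classic attraction term
   (`v ← v + L(x − x*)·freq`, mode `scaled_attraction`); a `literal`
   mode adds `L·freq` to every component for fidelity experiments with
   the update rule exactly as printed, which drops the attraction term.
3. **Spiral local search**, triggered with probability `r_k` (note:
   rising with acceptances, the opposite gate of the classic algorithm —
   this restores strong late exploitation):
   `x_new = x* + D_k·e^{l−1}·sin(πl)` with `D_k = |x − 2b·x*|`,
   l ~ U[−1, 1]; l = 0 or 1 lands exactly on the best. An `exp_l`
   exponent mode exists.
4. **Random perturbation** applied to every candidate:
   `x' = x + per·μ·(x − x_rand)` with μ ~ U[0, 1], a uniformly chosen
   peer, and `per(t) = per_min + (per_max − per_min)·
   cos((π/2)(t−1)/(T_max−1))` ramping from per_max (1.0) down to
   per_min (0.1). The coefficient formula is a reconstruction: the
   printed form is constant in t while the surrounding text requires a
   decrease, so the cosine ramp satisfies the stated endpoints and
   monotonicity. The perturbed candidate is kept only if it improves, so
   the step can never worsen a bat.

Acceptance, loudness decay and pulse-rate updates are shared with the
classic algorithm. Two objective evaluations per bat per iteration
(candidate + perturbed candidate).

## Classifiers

**ANN.** Fully connected network, ReLU hidden activations, sigmoid
output, trained by mini-batch Adam on binary cross-entropy (squared
error selectable). Cross-entropy is the default because the output unit
is a sigmoid probability. Defaults: two hidden layers of 15, learning
rate 0.001, batch 64, 100 epochs. Weights initialise uniform
[−0.5, 0.5] scaled by 1/√fan-in, seed-controlled.

**Weight-optimised ANN.** The same network trained without gradients by
a teaching–learning population search over flattened weight vectors
(default hidden layers 50 and 15, population 20, 50 generations):
teacher phase `In_i + rand·(In_teacher − TF·IN_mean)` with the teaching
factor TF = round(1 + u) ∈ {1, 2} redrawn per member and greedy
replacement; a learner phase on random pairs where the worse member
moves toward the better and the better moves away (the printed pairwise
rule has its direction inverted relative to the method's own logic, so
the canonical direction is used); elitism reinjecting the best-ever
vector over the current worst; duplicate members mutated by resetting a
quarter of their coordinates to the population mid-range; stopping on
the generation cap or a fitness plateau. Fitness is the training-set
cross-entropy of the assembled network. An optional Adam warm-start can
seed one member; it is off by default so the population method stands
alone.

**Decision tree.** Gini impurity 1 − Σp², exhaustive search over
feature × midpoint-of-consecutive-unique-values splits, ties broken by
lowest feature index then lowest threshold, stopping on max depth 10,
min samples to split 2, min samples per leaf 1. Leaf label is the
majority class, ties to class 0.

**KNN.** Euclidean distance, k = 5 by default, distance ties resolved
toward the lower training index (stable sort), vote ties toward the
lower class label. A treated/untreated uplift variant sometimes
described alongside this algorithm family is out of scope: screening
data has no treatment variable.

## Tuning

A classifier configuration is a point in a box: integers decode by
rounding, log-reals as 10^x, mask bits by a strict > 0.5 threshold, and
continuous per-feature (or per-group) distance weights pass through.
Fitness is 1 − accuracy on a stratified inner holdout (25% of the
training split; an inner k-fold is available); the test split is
touched exactly once, after tuning, by the refit best configuration.
Candidates decoding to the same configuration are cached, and all seeds
derive deterministically from the experiment seed, so runs are
bit-reproducible and tuning provably cannot see test labels (asserted
in the tests by poisoning them).

Default spaces: KNN — k ∈ [1, 25] plus log-scaled distance weights
(10^[−3, 0]) per feature group; decision tree — max depth ∈ [1, 20],
min samples per leaf ∈ [1, 10]; ANN — hidden sizes ∈ [4, 64], learning
rate 10^[−4, −1]; weight-optimised ANN — hidden sizes plus feature-group
mask bits. Feature groups (items / score / demographics) keep the KNN
space four-dimensional; log-scaling the weights matters because useful
relative importances span decades and a log box gives the sparse,
score-dominant corners enough volume for a swarm to find. Reduced
training budgets are used while searching (e.g. fewer population
generations) and full budgets for the final refit.

## Synthetic generator

Threshold mode draws the ten items i.i.d. Bernoulli(0.4), sets the score
to the item sum and the class to [score ≥ 4] — the established
Q-CHAT-10 screening convention — then optionally flips labels at a
configured rate. Item probability 0.4 puts roughly balanced mass on
both sides of the threshold, giving near-balanced classes.
Probabilistic mode draws the class first at a configured prevalence and
items with class-conditional probabilities; with equal probabilities it
is the exact null for chi-squared calibration. Demographics are sampled
independently of the class (a dependence knob exists for power
studies), from generic category lists; the generator makes no attempt
to match the demographic distributions of any real cohort.

What passing tests on this generator do and do not show: threshold mode
reproduces the *leakage structure* of real screening spreadsheets — the
class is a deterministic function of recorded features — so perfect
held-out accuracy demonstrates that the pipeline can discover and
exploit that structure, not that any classifier would achieve perfect
accuracy on clinically labelled data. Demographic realism, respondent
behaviour and item correlations are explicitly not modelled.

## Numerical choices and degenerate inputs

Positions are clipped to the box after every move. Non-finite objective
values and features abort with the offending location. Sigmoids are
evaluated in the numerically stable split form; cross-entropy clips
probabilities at 1e-12. Metric denominators of zero yield 0.0 with an
explicit undefined flag so batch reports never abort. Reports round
half-up to two decimals to match screening-table conventions; machine
precision is retained in CSV/JSON output. The pulse-rate sequence
saturates to r₀ in float64 around t ≈ 40 at γ = 0.9; tests assert
strict monotonicity only over the resolvable range.

## Problem sizes used in the checks

The end-to-end checks run the tuned pipeline at n = 600 records
(480 train / 120 test) over ten seeds per classifier family, and the
optimiser comparison at dimension 10, population 30, 300 iterations,
20 paired seeds — sizes chosen so the full suite completes comfortably
on a single CPU while leaving the claimed effects unambiguous.

## Known limitations

Binary classification only; no GPU path; no post-pruning of trees
beyond the stopping rules; no nested cross-validation for unbiased
error of the tuning step itself; chi-squared evaluation applies no
multiple-testing correction; the classic BA's convergence ceiling under
the stated parameters is documented above rather than patched.
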