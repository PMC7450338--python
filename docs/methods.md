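# Methods

## Model and orchestration

The optimizer is a population method over a box-bounded real space with all
fitness minimized. Three best agents (α, β, δ) lead; the worst of the
remaining ω agents calibrates each agent's modulation index

    τ_i = (m − f_i) / (m − f_worst),  m = mean(f_α, f_β, f_δ),

clipped to [0, 1]. The clip is a deliberate choice: the ratio is negative
for any agent better than the leader mean (including α itself), and
clamping to 0 keeps both schedules inside their nominal ranges ([0, step_max] and [0, a_o]), giving
near-leader agents the smallest late-run cuckoo steps and the fastest
decay of the wolf attack radius. A degenerate population (|m − f_worst| <
1e-12) defaults to τ = 1, and 0^0 := 1 so the last generation with τ = 0 is
well defined. These guard constants live in `schedules.py`.

Per generation the hybrid ranks leaders once, then updates each agent in
index order with three moves — adaptive cuckoo step toward/away from the
live α (1 evaluation, greedy-kept), biased selective random walk (1
evaluation, greedy-kept), and the three-candidate wolf update (3
evaluations, unconditional replacement) — five evaluations per agent per
generation. The generation count is derived from the evaluation budget,
`gen_max = ⌊(fe_budget − n)/(5n)⌋`, so the schedule argument `gen/gen_max`
sweeps [0, 1] over the run; schedules are evaluated at the pre-update
generation index starting at 0. The per-generation sequencing of the
three moves is a design choice of this package; it is isolated in one loop
in `hybrid.py` so alternative orderings are one-line changes.

The wolf update replaces the agent with the best of its three encircling
candidates *without* comparing to the incumbent — the update rule contains
no such comparison — so an agent can worsen; the best-so-far solution is
tracked separately and the reported convergence log is therefore
non-increasing by construction. An `elitist_idgwo` flag adds the incumbent
comparison for experimentation; it is off by default. Encircling
coefficients A and C are drawn per dimension and independently for each of
the three candidates; the per-agent `a` is shared by all three.

Within the hybrid, the cuckoo branch uses the normally-perturbed adaptive
step with one independent standard-normal draw per dimension (the standard
shape for such perturbations); the Lévy-flight walk survives only in the
standard-CS baseline. Mantegna's scheme generates the Lévy steps there,
with ε, φ drawn mean-0 standard-normal as in the established construction;
the closed-form scale coefficient at λ = 1.5 is 0.696575.

## Binary front-end

Positions live in [0, 1]^N (uniform initialization). Each evaluation maps
coordinate x through the steep sigmoid S = 1/(1+e^{−10(x−0.5)}) and
thresholds stochastically. The default `as_printed` convention sets
bit = 0 if rand < S, so P(select) = 1 − S and low coordinates select
features; the usual binary-swarm rule (bit = 1 if rand < S) is available as
`standard`. Since the two conventions only reverse the search direction
along each axis, the dynamics are equivalent. An all-zero mask is repaired by
switching one uniformly chosen bit on (rejection would waste budget
evaluations; a penalty would distort the fitness scale).

Subset fitness is `α_w·|R|/|N| − β_w·acc` with α_w = 0.2, β_w = 0.8; both
terms normalized to [0, 1], so fitness ranges over [−0.8, 0.2]. Accuracy is
the mean over stratified k folds of a scikit-learn classifier (default
linear-kernel SVM) refit per fold on the selected columns. The fold
partition is frozen per run (seeded `StratifiedKFold`) so a mask's fitness
is deterministic; k is configurable and defaults to 10. Every candidate
evaluation counts one FE even when
a mask recurs — no memoization — matching a plain reading of a
10000-evaluation budget.

## Parameters

| Parameter | Default | Meaning |
|---|---|---|
| n | 30 | population size (agents) |
| fe_budget | 10000 | objective evaluations, the stopping rule |
| step_max | 1 | ceiling of the cuckoo step schedule (position units) |
| a_o | 1 | initial wolf control parameter; a_o = 1 keeps A in [−1, 1] (pure attack) |
| p_a | 0.25 | abandonment probability per coordinate |
| α₀, λ | 0.01, 1.5 | standard-CS Lévy scale and exponent (baseline only) |
| α_w, β_w | 0.2, 0.8 | subset-size and accuracy weights of the selection fitness |
| k | 10 | CV folds (5 in the desk-scale recovery experiment) |
| n_runs | 10 | repetitions of the selection protocol, seeds base_seed + i |

## Synthetic data

The generator emulates two-class omics-style data: informative columns are
class-conditional Gaussians with means ±class_sep/2 (unit variance;
default class_sep = 3, a strong univariate marker), redundant columns are
unit-norm random linear combinations of the informative ones plus
`noise_sd`-scaled Gaussian noise (linear redundancy mirrors co-expression),
remaining columns are pure noise; classes are balanced, columns shuffled
with ground truth recorded. Six shape presets cover the classic two-class
benchmark regimes from 30×569 (long) to 7129×60 (wide), with a scale knob
shrinking the two widest for desk-scale work.

What the generator does **not** emulate: heavy-tailed and heteroscedastic
expression distributions, batch effects, correlated noise, label noise and
class imbalance. Passing recovery tests therefore demonstrates that the
search machinery finds planted low-dimensional signal under a size
penalty — not that it ranks features correctly under realistic microarray
noise.

## Problem sizes and numerical choices

The shipped experiments are sized for a single desktop CPU: convergence
checks use the 10-d sphere (n = 30, 10000 evaluations, 10 seeds); the
recovery experiment uses 200 samples × 100 features, 5 informative, a
3000-evaluation budget, k = 5, 10 seeded runs. Full-scale runs (10000
evaluations on 7129-feature data) are a matter of budget, not code.

Ties break toward the lower agent/candidate index everywhere; positions
are clipped to the box before every evaluation; each agent's 5-evaluation
update is atomic with respect to the budget (a final generation may stop
mid-population but never mid-agent). The Wilcoxon rank-sum test uses exact
enumeration of rank assignments for min(n, m) ≤ 8 (midranks under ties)
and otherwise a normal approximation with midranks, tie-corrected variance
and continuity correction; the z statistic always comes from the
approximation. Ranking tables use competition ("1224") ranking, ties
sharing the best rank. Tie- and continuity-correction conventions vary
between rank-sum implementations, so exact z agreement with other software
is not guaranteed; p-values agree to the approximation error.

## Limitations

Single-threaded; box constraints only; two-class labels only; no
missing-value handling (validation rejects NaNs); the wrapper cost is
dominated by classifier refits (5 × k fits per generation × agent), so
expensive classifiers need a reduced budget; competitor selectors (binary
GA/PSO/ant-colony and cuckoo variants) are not implemented here — the
comparison tooling accepts any result set laid out in the documented CSV
format.
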