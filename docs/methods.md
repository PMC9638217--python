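# Methods

## Problem and model

`ssdfs` solves wrapper feature selection for binary classification: given an
`n × d` feature table with labels in {0,1} (in the motivating application,
deep features of mammogram mass patches labelled benign/malignant), find the
binary column mask minimizing

    Fitness = w·α + (1 − w)·|s|/|d|,

with `α` the hold-out error of a KNN on the selected columns, `|s|` the
selected count and `|d| = d`. The objective is implemented verbatim; note
its algebra: the *size* term carries weight `1 − w`, so the default
`w = 0.2` puts 0.8 of the weight on parsimony (0.8/d per kept column) and
0.2 on error. `w` is a first-class parameter because different sources quote
different effective weightings (0.2 vs. 0.98 "weight for accuracy") and the
two regimes behave very differently; see "Known limitations".

### SSD dynamics

Agents hold a binary location, a real velocity, and a personal best. The
attractors are the personal best and MGB, the element-wise mean of the three
best *distinct* masks found so far (an archive, not the current population's
top three; ties break toward fewer selected features, then the
lexicographically smallest bit tuple — this stabilizes MGB when fitness
plateaus). The velocity update has no inertia term: it is purely
`h·f(r₁)·(PB − L) + f(r₂)·(MGB − L)` with `f ∈ {sin, cos}` chosen once per
update by a fair coin and fresh uniforms per dimension per term. `h` starts
at `h₀ = 100` and decays by `r = 0.9` per iteration; velocities are not
clamped since the V-shaped transfer `|x|/√(1+x²)` saturates on its own
(early iterations therefore behave like aggressive bit-flipping
exploration, late ones like fine-tuning).

Binarization flips bit `j` with probability `V(v_j)` (flip-the-complement
semantics, the standard V-shaped transfer-function reading); a result with
no selected feature is repaired by switching one uniformly chosen bit on.
The continuous position-update rule is superseded by this binarization:
agents never carry a real-valued location, while PB/MGB arithmetic treats
bits as reals.

### ABHC refinement

Each agent, every iteration, gets `MT` strict-improvement proposals. A
proposal relaxes the mask to reals, perturbs every coordinate by
`± rand·N(z)` with `N(z) = 1 − (z/MT)^{1/c}`, keeps each incumbent
coordinate with probability `Beta(z) = Mi + (Ma − Mi)·z/MT` (as printed:
*keep* with probability `Beta > rand`, which inverts the usual
β-hill-climbing convention — flagged here for users), clips to [0,1] and
thresholds at 0.5 (ties → 1). Acceptance requires strictly lower fitness,
so refinement never worsens and equal-fitness drift is impossible.

## Parameters

| Parameter | Default | Meaning / why |
|---|---|---|
| population_size | 20 | study setting; ≥3 required by the top-3 attractor |
| max_iterations | 100 | study setting |
| h₀, r | 100, 0.9 | exploration weight and its geometric decay (study setting) |
| w | 0.2 | fitness weight on error (study setting); exposed because its semantics are contested |
| k (KNN) | 5 | unspecified upstream; standard wrapper-FS choice, odd enforced so binary votes cannot tie |
| MT, c, Mi, Ma | 10, 2, 0.01, 0.5 | ABHC budget and schedule; unspecified upstream, small MT keeps cost `PS·(1+iters·(1+MT))` practical |
| test_fraction | 0.2 | stratified hold-out used inside the fitness (the 80/10/10 split quoted upstream concerns DL training, and the wrapper-stage split is never stated; a configurable 80/20 hold-out keeps each evaluation cheap) |

Determinism: one master seed spawns an independent RNG stream per agent
(`numpy.random.SeedSequence.spawn`), so results do not depend on agent
iteration order and identical configurations replay bit-identically. KNN is
fully deterministic: stable argsort breaks distance ties toward lower
training-row index, and a (forced) vote tie resolves to the nearest
neighbour's class. Fitness values are memoized per mask; `n_evaluations`
counts distinct KNN fits.

## Synthetic data

`generate_table` emulates a deep-feature table with unambiguous ground
truth: informative columns are unit-variance normals whose class means
differ by `class_separation` (default 3) SD; redundant columns are noisy
copies (SD 0.1) of informative ones — copies rather than general linear
combinations so that recovery scoring is well defined; noise columns are
label-independent standard normals. Labels are balanced exactly and rows
shuffled per seed. `generate_blob_images` produces smoothed-noise
backgrounds with (positives only) one bright Gaussian blob, a cartoon of
mass vs. no-mass patches.

What this does *not* emulate: correlated noise, batch effects, class
imbalance (the real DDSM collection is 86/14), non-Gaussian deep-feature
marginals, and features whose usefulness is only joint, not marginal.
Passing tests on this generator show the optimizer finds optima of its
objective on well-separated signals; they do not certify mammography
performance.

## Evaluation protocol

`repeat_experiment` fixes one split, reruns the optimizer with consecutive
seeds, refits the KNN with each run's best mask and reports per-run
accuracy/precision/recall (%) and selected count with mean ± sample (n−1)
SD — sample SD is the convention that reproduces the reference protocol's
printed 96.07 ± 0.37 from its five per-run accuracies. Mann–Whitney U uses
midranks; for `n₁+n₂ ≤ 12` the two-sided p is exact by enumeration of all
rank assignments (scipy's exact method refuses ties, so the enumeration is
our own; scipy's tie-corrected normal approximation serves above that).
Recovery scoring counts a planted source as recalled if the source or any
of its redundant copies is selected.

## Problem sizes used in tests and the acceptance script

Desk-scale settings chosen so the whole suite and the acceptance script run
in seconds on one CPU: oracle equivalence on `d = 8` (255 enumerable masks,
n = 200, PS = 10, 30 iterations); recovery on `d = 64` (n = 300, PS = 10,
40 iterations); five seeds per experiment, mirroring the five-simulation
reporting protocol. The extractor's structural tests run at 64 × 64 input
with a 0.125 channel-width multiplier (the bottleneck width, 128, is what
the selector consumes and is kept at full size).

## The deep extractor

A numpy implementation of the attention-aided VGG16 head: 13 frozen 3×3
conv layers + 5 max-pools (He-initialized from the seed; ImageNet weights
may be loaded from `.npz` when available, and random weights are the
offline default), a 1×1 *locally connected* attention layer (independent
weights per spatial position) with sigmoid activation — sigmoid guarantees
strictly positive weights so the weighted average is always defined — whose
single-channel map is broadcast across all feature channels in a weighted
GAP `Σ a·f / Σ a`, then dropout 0.5 → dense 128 bottleneck → dropout 0.25 →
sigmoid unit, trained with BCE/Adam (lr 1e-2, halved after epoch 3, batch
64). The two dropouts bracket the bottleneck; their exact placement is an
open choice upstream and is flagged as such. The bottleneck width 128 is the
dimensionally consistent reading of "25% of features" with ~32 selected.
Only the head trains (analytic gradients, verified against finite
differences in the tests); frozen-backbone activations are cached per image
during `fit`, which makes training equivalent and much cheaper. Grayscale
input is replicated to 3 channels; mismatched sizes are bilinearly
resampled and logged.

## Known limitations

* With `w = 0.2` the parsimony term dominates whenever single columns are
  strongly informative: on the d=64 recovery benchmark the optimizer
  provably prefers 1–2 of the 8 planted columns (their lone-column error
  ≈ 3–7% is cheaper than 0.0125/column), so "recall all planted features"
  is not an objective this fitness encodes — measured mean informative
  recall is 0.125 at w = 0.2, 0.25 at w = 0.98, and only 0.53 even with the
  size term removed entirely (w = 1), because 2–3 separation-3 columns
  already achieve zero hold-out error. The optimizer is verified instead by
  exhaustive-oracle equivalence: it attains the true global optimum of its
  objective on 5/5 seeds at d = 8.
* Hold-out (not cross-validated) fitness: cheap but higher-variance;
  plateaus of equal fitness are common at small test sets and strict-
  improvement acceptance then freezes the incumbent.
* The exhaustive oracle is limited to d ≤ 16 by its 2^d cost.
* LAHC (an alternative local search in the reference comparisons) is not
  implemented — it is undefined in the source material; `abhc_refine` is the
  single local-search plug-in point.
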