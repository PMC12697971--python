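# Methods

This note records the model choices, defaults and numerical conventions
behind `hmfw`, and what the synthetic-data tests do and do not demonstrate.

## Problem setting and assumptions

The target data are samples × features expression matrices with far more
features than samples (60–260 samples, 2,000–25,000 features, 2–5 classes in
the benchmark regime the package emulates). The method assumes features are
real-valued, labels categorical, and that a small subset of features carries
most of the class signal while many others are redundant correlates or
noise. All features are min-max normalized to [0, 1] before any scoring
(constant columns map to 0); under the nested cross-validation protocol the
normalization statistics are instead refit inside each outer training fold.

## Scoring conventions

* **Entropy / information gain** (tree pre-screening criterion) use base-2
  logarithms.
* **Mutual information** (bivariate filter) is the plug-in estimate over the
  empirical joint distribution with the *natural* logarithm and each
  distinct value as its own category. This convention is what makes the two
  reference worked examples exact: MI({0..4}, {0.2,0.8,2.3,3.6,4.8}) =
  ln 5 = 1.609 (all ten values distinct, a 5-point bijection) and
  MI({0..4}, {0.2,0.4,0.2,0.4,0.2}) = H(3/5, 2/5) = 0.673 nats. Because
  distinct-value binning degenerates to log n on continuous columns where
  every value is unique, the pipeline discretizes continuous features into
  equal-width bins before MI scoring (`mi_bins`, default 10; set to `None`
  for categorical data).
* **Spearman redundancy** ranks with average ranks for ties and plugs the
  rank differences into the classical `1 − 6Σd²/(n(n²−1))` formula *without*
  a tie-correction term. On the reference pair this yields 0.384; the
  tie-corrected (Pearson-of-ranks) estimator would not. With no ties the two
  coincide, which a property test checks against `scipy.stats.spearmanr`.
* **Fitness comparison** is lexicographic: higher mean CV accuracy, then
  shorter subset, then lexicographically smaller sorted index tuple. The
  last clause extends "lowest index wins" to a total order, which the
  leader-sorting code requires.

## Feature budgets

Both filter stages draw their output size from
`K = RandnumA + (f·rand()/e)·cos(p·e)`, `rand() ∈ (1, 10)`, `p = 0.8`,
rounded and clamped to `[k_min = 5, ⌈k_max_fraction · available⌉]`. The
baseline `RandnumA` is uniform on [10, 20] for the bivariate stage and on
[100, 200] (×10) for the pre-screen. The grouping of the formula and the
baseline ranges are design choices (only the cosine argument and the ranges
of `rand()` and `p` are externally fixed); they were chosen so typical K1
lands in the low hundreds and K2 in the teens on benchmark-sized inputs.
Note the cosine makes the budget genuinely sample-size dependent, including
sign flips: the clamp absorbs negative draws.

## Wrapper search

* Search box: per run, the lower bound is drawn uniformly from [−1, −0.3]
  and the upper bound from [0.3, 1]. Positions are clipped to the box after
  every move (boundary handling is otherwise unspecified).
* Binarization: a wolf's mask is `component > median(own components)`
  (mean-of-middle-two for even length). A constant vector selects the
  ⌈J/2⌉ lowest-index features. If ties make the strict comparison empty
  (possible only when at least half the components equal the maximum), the
  comparison relaxes to `>=`, which is provably non-empty and non-full for
  any non-constant vector. The alternative literal reading — comparing fresh
  random numbers to the median — would make selection independent of
  position and is not used.
* Grey-wolf update: standard three-leader guidance with convergence factor
  `a = 2(1 − t/T)`, `A ∈ [−a, a]`, `C ∈ [0, 2]` drawn per wolf per
  dimension from a seeded generator.
* Dung-beetle refinement: per leader, a sub-swarm (default 10 beetles × 5
  steps; the reduced-budget profile uses 4 × 2) starts at the leader
  perturbed per component by `(2δ − 1) · 0.1 · (u − l)` with δ from the
  beetle's own logistic stream — the perturbation scale is a design choice;
  each step moves by `δ·sign(x* − x)·ln(1 + |x* − x|)` with a fresh scalar δ
  per beetle per step, `sign(0) = 0`. The best-so-far position x* starts at
  the leader, so refinement can only improve the leader (elitist).
* Chaos: every agent owns an independent logistic stream
  `x ← 3.9·x·(1 − x)` seeded from the master generator with an initial
  state in (0.05, 0.95); orbits stay in (0, 1) with maximum 3.9/4. Note the
  map is symmetric in x ↔ 1 − x, so mirrored initial states coincide after
  one step.

## Restart controller

AIR is computed over the best-fitness history since the last restart. A step
increments CAD when its AIR dropped below the previous AIR *or* is
non-positive; the disjunct makes a flat (stalled) search accumulate CAD and
eventually restart, which a pure "decrease" reading would not. AIR is
guarded against non-positive fitness values (taken as 0 for that step);
accuracy fitness is positive in practice.

Patience thresholds are derived from the intensity trace
`I(t) = I0 + Σ A_i sin(2π f_i t + φ_i)` (the printed model omits the time
variable; it is restored multiplying f_i, without which the trace is
constant): local extrema over one fundamental period are located on a dense
grid (10,000 points, periodic closure), and their |I − I0| values are
affinely scaled to integers in [3, 12], sorted and deduplicated. Under the
default parameters this yields 8 extrema, collapsing to 4 distinct
thresholds; an explicit integer list in the configuration overrides the
derivation entirely. Equal-magnitude extrema (e.g. a single sine) dedupe to
one threshold. `I0` only shifts the trace, so its default (1.0) is
inconsequential. The cursor starts at the smallest threshold; 3 consecutive
AIR increases move it up, 2 consecutive non-positive AIRs move it down.

The global iteration budget T (default 100) is counted *across* restarts, so
every run costs the same number of wrapper iterations, and the filter's
(s, y) weights follow this global counter. The number of filter executions
is exactly restarts + 1. The elite best is archived outside the population
and never injected into a restarted population (diversity first); the
reported best is therefore monotone across the whole run.

## Synthetic data

The generator plants `n_informative` features with class-dependent means
separated by `class_separation × noise_sd` (default 2.0 — a strong but not
trivial univariate effect), `n_redundant_per_informative` correlated copies
per planted feature (`rho × standardized parent + √(1 − rho²) × noise`,
default rho 0.8), and pure Gaussian noise elsewhere. Planted columns are
scattered uniformly so column order carries no signal. Classes are balanced.
It does **not** emulate heavy-tailed expression distributions, batch
effects, feature-block correlation beyond parent-copy pairs, or label noise
— so passing recovery tests show the machinery finds planted univariate
signal under Gaussian noise, not that it handles real microarray pathology.

## Problem sizes in tests

Default study-scale parameters (population 30, 100 iterations, 10-fold CV,
10 repeats) are desk-heavy, so the test and acceptance suites run a
reduced-budget profile chosen once: population 8–10, 15–20 iterations,
5-fold CV, a 2×2 (C, γ) grid {1, 32} × {2⁻⁴, 2⁻¹}, and 3–4 beetles × 2
steps, on 60-sample matrices with 500–2,000 features. Fitness results are
cached per feature-index tuple, so repeated masks cost nothing.

## Known limitations

* The budget formula's grouping and baseline ranges cannot be validated
  beyond qualitative magnitude checks.
* Plug-in MI with 10 equal-width bins is biased upward at these sample
  sizes; it is used for ranking only, where the bias largely cancels.
* The wrapper's fitness landscape is evaluated on one fold split per run;
  reported accuracies are therefore optimistically biased relative to the
  nested protocol, which exists precisely to quantify that gap.
* The controller's thresholds are a schedule heuristic; no claim is made
  that the specific intensity-trace parameters are optimal.
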