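# Methods

## Problem and model

`sandcatfs` addresses wrapper feature selection on two-class expression
matrices: find a small subset of genes whose linear-SVM classifier
generalizes well under cross-validation. A candidate subset is a binary
inclusion vector of length D; the search is a binary sand cat swarm with
two enhancement operators, run after a univariate
differential-expression gate.

The objective optimized is the mean Cohen's kappa over repeated
stratified CV folds, not raw accuracy: the target datasets are
unbalanced (≈ 2:1), and kappa corrects for the chance agreement a
majority-class classifier would earn. Accuracy is recorded alongside in
every `FitnessResult` and reported in summaries, since panels are
conventionally compared on accuracy.

## The swarm loop

State between iterations is strictly binary. Each iteration:

1. **Evaluate & archive.** Every individual is scored; the elitist
   archive (`Xbest`) is replaced whenever any evaluated vector —
   population member, crossover offspring, or opposition candidate —
   *strictly* improves it. "Strictly better" means higher kappa, or
   equal kappa with fewer selected genes. A rescan-only reading of
   "determine the best" could let the best regress when the population
   drifts; the archive reading makes convergence traces non-decreasing
   by construction and matches the guarded replacements of the
   enhancement operators.
2. **Position update.** Per individual, one phase draw
   R ~ U(−r_g, r_g) and one sensitivity draw r ~ U(0, r_g), with
   r_g = s_M(1 − t/T) and s_M = 2 by default. Exploitation
   (|R| ≤ 1) moves each coordinate toward the archive along a random
   angle; exploration moves it relative to a random peer, with the
   peer index redrawn per dimension and read from the in-place-updated
   population matrix. Every continuous value is immediately passed
   through tansig + a fresh uniform threshold, so only bits persist.
3. **Enhancement** (enhanced variant only). Per individual, a fair coin
   (probability 0.5) picks single-point crossover of the archive with
   the individual's row (offspring can replace the archive only; the
   row is untouched, though `crossover_writes_row` exists for
   experimentation) or the pinhole opposition candidate
   `(NOT row) AND best`, which on strict improvement replaces both the
   archive and the row.

The stop criterion is the iteration budget alone; there is no early
stopping. The trace has T + 1 entries: the initial all-ones evaluation
plus one per iteration.

### Design choices where the construction was open

* **Distance magnitude in exploitation.** The update uses
  `|u1*best_j − x_ij|`; a strict-literal variant without the absolute
  value is available (`abs_distance=False`). The magnitude form keeps
  the "distance to the best" semantics of the continuous original.
* **Phase test.** Default is |R| ≤ 1 (exploitation), matching the
  stated trade-off description; `phase_test="unit_interval"` gives the
  stricter 0 < R < 1 variant. Which variant is "right" is
  unknowable from the method's description; both are first-class.
* **Angle selection.** The roulette wheel over angles is unweighted, so
  it degenerates to a uniform draw over [0°, 360°]; angles are converted
  to radians before the cosine.
* **Binarizing the opposition value.** In binary space the pinhole
  reverse of a bit is 10.5 or −9.5; the AND step needs bits, so the
  reverse is thresholded at 0.5 (configurable), making it exactly the
  complement. A tansig-based stochastic binarization would saturate to
  the same behaviour at these magnitudes.
* **Initialization at all-ones** means the search proceeds top-down:
  the first archive is the full post-gate panel and improvement comes
  almost entirely from shrinking at equal kappa. This matches the
  method's stated initialization and explains the strong parsimony
  pressure observed in practice.

## Fitness details

* SVM: `sklearn.svm.SVC(kernel="linear", C=1)`; no class weights, no
  hyperparameter search. Stratified `RepeatedStratifiedKFold` with 10
  folds × 3 repeats by default (the repeated protocol is also used
  inside the loop; a single-pass 10-fold can be had with
  `n_repeats=1`).
* **Frozen folds.** One seed per run fixes the fold assignment, so all
  candidates in a run are scored on identical splits — otherwise
  fitness comparisons across the population would be noise-coupled.
* **Empty subsets** get a sentinel kappa of −1 (worst possible) rather
  than raising, so degenerate opposition candidates degrade gracefully.
* **Kappa convention:** when the chance agreement p_e is 1 (both sides
  constant), kappa is defined as 0. This is why kappa is computed
  directly from the contingency table rather than delegated.
* **Memoization** keyed on the exact bit pattern avoids re-training on
  re-proposed subsets; the `evaluations` counter in a `RunRecord`
  counts actual classifier trainings (cache misses × folds), and
  `fitness_queries` counts lookups. Queries per iteration are bounded
  by 3N (N refresh + at most 2 per individual in enhancement).

## Differential-expression gate

The gate is a per-gene Welch two-sample t-test on the z-scored
(assumed log-scale) matrix with Benjamini–Hochberg adjustment across
genes, keeping adjusted p < α (default 0.05) with an optional
|log2FC| floor; logFC is the difference of group means, which is the
log2 fold-change when the input is already log-scale (a CLI flag applies
log2(x+1) for count-like input). This is a deliberate surrogate for
moderated-t pipelines (limma-style empirical-Bayes variance shrinkage is
out of scope): the optimizer is agnostic to which gate produced its
input, and the Welch/BH gate preserves the pipeline role — an
FDR-controlled shrink of the search space. Zero-variance genes receive
p = 1 and are flagged, never fatal. Z-scoring uses the sample standard
deviation (ddof = 1).

## Synthetic study conditions

The generator draws all genes i.i.d. Gaussian with standard deviation
`noise_sd` and adds an additive mean shift of `effect_size × noise_sd`
to the planted genes in the positive class. Defaults: 60 samples, 500
genes, 10 planted, effect size 2.0, class balance 0.65, noise sd 1 —
the sample size, imbalance and planted-panel scale of the classic
~62-sample two-class microarray benchmarks, at a desk-scale gene count.
The signal is additive because the pipeline assumes log-scale
intensities.

What the generator does **not** emulate: gene–gene correlation, batch
effects, heavy-tailed or count noise, and technical missingness.
Passing tests therefore demonstrate the mechanics and calibration of the
pipeline (FDR control under the null, recovery of independent additive
signals, determinism, convergence bookkeeping), not robustness on real
microarray or RNA-seq data.

A consequence of these conditions worth stating plainly: ten independent
2-sd genes are jointly ≈ 6.3 sd separable, so 60-sample CV kappa
saturates at 1.0 already for the full post-gate panel and for many 2–4
gene subsets. With the fewer-genes tie-break, the optimizer then
lawfully shrinks the panel to ~3–4 genes with perfect kappa and perfect
precision against the planted set, but with recall of the *full* planted
set around 0.3–0.4 — selected panels are correct and minimal, not
exhaustive. A recall target on the final panel is only meaningful under
conditions where kappa does not saturate below the full planted set.

## Problem sizes and numerics

Tests and the acceptance script use the swarm at N = 20 individuals and
T = 15 iterations (5 seeds, paired across the enhanced and plain
variants) on the default conditions above; a full-scale run
(N = 100, T = 50) is the library default. Determinism: all randomness
in a run flows from one `numpy` generator seeded by the run seed, and
the CV seed is derived from it modulo 2³¹; identical seeds reproduce
traces, panels and evaluation counts byte-for-byte, including through
the CLI. Floating-point: the tansig transfer is computed via `tanh`
(the rational form overflows for v < −355); exact-kappa ties are the
only ties the ordering must break, and they are broken
deterministically by panel size.

## Known limitations

* Two classes only; no multi-class or survival objectives.
* No class weighting; heavy imbalance beyond stratification is the
  user's problem.
* The per-dimension Python/NumPy update loop targets desk-scale D
  (≤ a few hundred post-gate genes); very large D without a gate will
  be slow.
* The gate is univariate: genes informative only in combination are
  invisible to it and never reach the swarm.
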