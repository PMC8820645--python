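# Methods

## Model and training

The network maps the input omics matrix X (N×p) through a tanh
multilayer encoder to an r-dimensional bottleneck E, concatenates the
confounder design matrix C (N×s, possibly empty), and decodes through a
tanh stack to a linear q-unit output reconstructing Y. The loss is the
mean squared error over all Y entries; "prediction error" for a
continuous output is read as MSE throughout. Optimization is minibatch
Adam (β₁ = 0.9, β₂ = 0.999), batch size 64, learning rate 3·10⁻³. The
rate was set so that the optimizer reaches the holdout-error minimum
well inside the default epoch budget at the sample sizes the package
targets (N ≈ 10²–10⁴); at 10⁻³ convergence is slow enough that epoch
selection can truncate training before nonlinear structure is found.

Layer sizes follow one of three modes: explicit lists; a shrinkage
factor γ ∈ (0,1) applied repeatedly from p down to r (encoder) and from
q down to r+s (decoder); or a layer count L from which γ = (r/p)^(1/L)
is solved so the L-th layer lands exactly on the bottleneck. Dropout is
either flat or graded linearly from `dropout_max` at the outermost
layer to 0 at the bottleneck; the decoder mirrors the schedule and the
linear output layer is never dropped.

Epoch selection: a seeded 80/20 split, training up to `max_epochs`
(default 300) recording the holdout reconstruction MSE each epoch; the
1-based argmin (earliest on ties) is selected, optionally with
patience-based early stopping (disabled by default). The final model is
retrained from a fresh initialization (seed+1) on all N samples for
exactly that many epochs. Identical seeds give bitwise-identical
histories and weights on any platform.

Weights use Glorot-uniform initialization. Hidden activations are tanh
(bounded, matching inputs in (−0.5, 0.5) and standardized outputs);
`linear` and `relu` are available, and the linear option is what the
closed-form permutation tests exercise.

## Permutation importance

With the trained parameters frozen, one input column at a time is
permuted across samples (a seeded, feature-major permutation schedule
that is part of the public contract, `draw_permutations`). The global
score of feature j is the sum over samples of squared Euclidean
displacement of the embedding rows, averaged over permutations; pair
scores accumulate, in the same permutation, the squared change of each
reconstructed output. One permutation per feature is the default;
scores from repeated independent fits can be averaged, with the mean
pairwise Pearson correlation across runs reported as a stability
diagnostic. Scores are computed in inference mode (no dropout), so a
constant column scores exactly zero.

## Local false discovery rate

Scores are modelled as a two-group mixture with a gamma null. The
overall density f is a Gaussian KDE with Silverman bandwidth, reflected
at 0, evaluated on a 512-point grid over [0, max score]. For each
candidate π0 in {0.60, ..., 0.99} the scores below the π0-quantile are
treated as (mostly) null and the gamma parameters are estimated by
**truncated maximum likelihood** — the likelihood includes the
−n·log G(cut) truncation term. A complete-sample fit here biases the
shape upward and, when the quantile window reaches into the non-null
component, lets that mass corrupt the null; the truncated fit recovers
the generating parameters whenever the window is clean.

The candidate discrepancy (step 3) is the sum of squared differences,
on the grid points at or below the KDE mode, between the π0-scaled
null density and f — with the candidate gamma first pushed through the
*same* reflected kernel as the data. The KDE is a biased estimate near
the boundary and at the peak; comparing a raw gamma against it rewards
whichever candidate mimics that bias (empirically collapsing the fit
toward π0 → 0.99 and zero recall on shifted mixtures), whereas the
kernel-matched comparison is unbiased and recovers π0 = 0.90 on a
90/10 mixture almost exactly.

fdr(z) = min(1, π0·f0(z)/f(z)) is evaluated at the observed scores,
made nonincreasing above the mode by a running minimum (the
single-threshold semantics presume a monotone tail), and the threshold
is the smallest score with fdr below the cutoff. Per-input pair
selection reuses the machinery on each selected input's row of pair
scores, topping up to `min_per_input` (default 10) outputs by score
when fewer pass, flagged `passed_fdr=False`; rows shorter than 50 fall
back to the top-10 directly since the density fit is meaningless there.

Known behavior: on a pure gamma null of 2000 scores, about 5% exceed
the threshold at cutoff 0.05 (KDE tail noise makes the estimated fdr
dip early in the extreme tail); stricter cutoffs are proportionally
cleaner and 0.001 selects essentially nothing.

## Hyperparameter tuning

Candidates are compared on the average absolute pairwise correlation of
embedding columns (duplicated components are discarded at threshold 0.5
by default) and Mardia's statistics, computed with the 1/N covariance
convention via the whitened third-moment tensor (O(N·r²) memory,
identical to the literal double sum to 10⁻¹⁰). Survivors are ranked by
b1 descending and by |b2 − r(r+2)| descending; the best mean rank wins,
ties to larger b1. Ranking kurtosis by *distance from* the normal
reference is an interpretation: the selection goal is an embedding far
from multivariate normal, and departure can occur in either direction.
Per-candidate seeds derive from a hash of the settings themselves, so
the choice is invariant to candidate ordering. The selection report
writes one embedding scatter page per candidate plus the metric table.

## Simulation generator

X is compound-symmetry multivariate normal (unit variances, common
correlation ρ) mapped through the standard normal CDF minus 0.5 —
"inverse-normal transform, then subtract 0.5" is read as the
probability-integral transform, the only elementwise map of a standard
normal bounded in (−0.5, 0.5). Under it an input pair with latent
correlation ρ has correlation (6/π)·arcsin(ρ/2), which the tests check
in closed form. Three latent factors combine the first k columns with
coefficients uniform on [−2,−1] ∪ [1,2]; each of the mk affected
outputs takes a coefficient combination of the factors, rescaled by
(r − mean)/(3·sd), and passes through one link: identity, |r|,
sin(5(r+0.5)π), (2r)², or the indicator of the interquartile range
(inclusive; for distinct values and N divisible by 4 exactly half the
points land inside). A `prop_linear` fraction keeps the identity link;
the rest draw uniformly among the four nonlinear forms. Gaussian noise
with variance one tenth of the realized signal variance is added, the
remaining outputs are compound-symmetry noise, and every Y column is
standardized (1/N convention). m·k must be integral; fractional
products are rejected rather than rounded.

The confounded variant adds a balanced binary label that shifts 20% of
the non-contributing X columns and 20% of the null Y columns by 1.5
within-group standard deviations — a strong batch-style factor driving
both data types, chosen once as a realistic magnitude for a dominant
clinical covariate. Because the confounded X columns predict the
confounded Y block, an unadjusted embedding encodes the label (label
k-NN purity ≈ 1.0 at these defaults); injecting the label at the
bottleneck lets the decoder absorb the block and returns purity to
chance while leaving recovery of the genuine features intact.

What the generator does *not* emulate: count-distribution (negative
binomial) noise, library-size effects, zero inflation, or realistic
gene-gene correlation structure beyond compound symmetry. Passing
recovery benchmarks here demonstrates the machinery, not performance on
sequencing data.

## Evaluation metrics

PR-AUC integrates precision over recall step-wise (average-precision
convention) with tied scores entering as a group; trapezoidal
interpolation of the PR curve is avoided as positively biased. The
implementation agrees with an exhaustive threshold sweep and with
scikit-learn's average precision to 10⁻¹². k-NN purity uses Euclidean
distances in embedding space, self excluded, ties broken by sample
index. The linear baseline ranks inputs by Σ_l corr(x_j, y_l)² — a
deliberately simple linear reference, not a reimplementation of CCA or
PLS loadings.

## Benchmark scales and behavior

The recovery benchmarks run at N = 1000, p = 100, q = 300, k = 10,
m = 12, ρ = 0.3 — sizes chosen so a replicate fits in seconds on one
CPU while the mixed-signal regime is comfortably solvable (median
PR-AUC 1.0 against prevalence 0.10). The purely nonlinear regime at
this sample size sits at the edge of learnability: holdout
reconstruction error often never improves (the even links |r|, (2r)²
and the step have no first-order correlation with any linear feature),
epoch selection then stops early, and single replicates range from
chance to near-perfect depending on whether a holdout dip is found.
The median over replicates stays ahead of the linear baseline, and at
N = 5000 recovery is reliably perfect — the nonlinear capability needs
the larger sample, consistent with the sample-size dependence the
simulation study is designed to expose.

## Numerical choices and degenerate inputs

- CV filtering: a zero-mean feature has undefined CV and is excluded
  with a warning (on nonnegative data this is the all-zero feature).
  Filters evaluate on the matrix as given; the CLI applies them before
  the log transform and records the order in run metadata.
- Categorical confounders drop the first sorted level; numeric ones are
  standardized with the N−1 convention. Single-level categoricals and
  constant numerics are errors.
- Epoch-selection ties take the earliest epoch (smallest capacity).
- Singular embedding covariance (duplicated components) raises rather
  than silently regularizing; constant embedding columns likewise.
- fdr fits require ≥ 50 finite nonnegative scores and reject
  constant score vectors; gamma-fit failures name the offending π0.
- The fdr machinery is scale-equivariant: rescaling all scores by c > 0
  rescales the gamma scale and threshold by c and leaves the selected
  set unchanged.

## Limitations

- Two data types at a time; no joint embedding of three or more.
- Importance is permutation-based only; no gradient saliency, and no
  importance for confounder columns.
- The local-fdr tail behavior depends on the KDE in the extreme tail;
  at liberal cutoffs on small score vectors selection is permissive
  (see the worked example in the README).
- Correlated inputs share credit: with compound-symmetry ρ > 0, columns
  correlated with contributing features have genuinely nonzero
  importance, so score-based selection cannot separate "contributing"
  from "correlated with contributing".
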