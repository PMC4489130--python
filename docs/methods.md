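# Methods

This note documents the models, algorithms and numerical choices behind
`divprof`, in the order the library's modules build on each other.

## Clonal frequency distributions and preprocessing

The unit of analysis is the clonal frequency distribution of one
repertoire sample: clones (clonotypes) are sets of sequencing reads
sharing a clonal identifier — by default the exact CDR3 amino-acid
sequence — and `f_i = count_i / total_reads` with `sum f_i = 1`.

Preprocessing of clonotype tables follows standard AIRR-seq practice:

1. keep only productive rearrangements;
2. require a CDR3 of at least 4 amino acids;
3. aggregate read counts by exact (100 % identity) amino-acid sequence;
4. require a minimum aggregated abundance of 2 reads.

Aggregation deliberately happens *before* the abundance filter: the
abundance threshold applies to clones, not to table rows, so two
single-read rows of the same CDR3 survive as one clone with two reads.
CDR3 length is measured in amino acids of the identifier string;
non-standard characters (`*`, `X`) are retained unless the productive
flag removes the record, since functionality filtering is the annotation
tool's job, not the parser's.

## Hill diversity and evenness

The order-`alpha` Hill diversity is `D_a(f) = (sum_i f_i^a)^(1/(1-a))`,
the effective number of equally abundant clones.  Special cases are
hard-coded rather than approached numerically:

- `alpha = 0`: species richness `n` (all observed frequencies are
  positive by construction, so `0^0` never arises);
- `alpha = 1`: the closed-form L'Hopital limit `exp(-sum f_i ln f_i)`
  (exponential Shannon entropy), exact instead of a numerical limit;
- `alpha = inf`: the Hill-number limit `1 / max_i f_i` (inverse
  Berger-Parker).  Note that the *Renyi entropy* at this order is
  `-ln max f_i`; the library exposes `renyi_entropy` separately so the
  two scales cannot be confused.

Evenness divides out richness, `E_a = D_a / SR`, isolating the shape of
the distribution (degree of clonal expansion) from its size.

Profiles are evaluated on the default grid `alpha = 0, 0.2, ..., 10`
(51 values); the range is where empirical repertoire profiles level
off.  Power sums for repertoires above 1e5 clones use compensated
(`math.fsum`) summation; below that double precision is already exact to
well under the tolerances used anywhere in the package.

## Zipf-Mandelbrot simulation

Clone probabilities follow the Zipf-Mandelbrot type density
`g(p) = C p^(-a-1)` on `0 <= p <= B` with shape `a` in (0,1) and
top-clone probability `B` in (0,1).  Integrating gives the number of
types above probability `p`, `G(p) = (C/a)(p^-a - B^-a)`, and inverting
the count law at integer ranks gives

    pi_k = (a (k-1) / C + B^-a)^(-1/a),  k = 1, 2, ...

so `pi_1 = B` exactly — `B` *is* the probability of the most frequent
clone.  `C` is fixed by `sum_k pi_k = 1`; the series has the Hurwitz-zeta
closed form `(C/a)^(1/a) * zeta(1/a, C B^-a / a)`, which is solved for
`C` by Brent root-finding on `log C` (the total is strictly increasing
in `C`).  The support is truncated at the smallest rank whose zeta tail
carries less than 1e-9 of the mass, capped at 1e7 ranks, and
renormalized.  For `a` near 1 the series converges so slowly that the
cap truncates non-negligible mass and `pi_1` is inflated above `B` after
renormalization (about +19 % at `a = 0.9, B = 0.1`); the study
conditions use `a = 0.1`, where the truncation error is below 1e-9 and
`pi_1 = B` to machine precision.

Reads are drawn in one multinomial draw (not per-read loops).
Subsampling to a depth fraction is multivariate *hypergeometric* —
drawing without replacement from the fixed observed read pool, which is
what downsampling a sequencing run means — and drops clones with zero
sampled reads.

Cohorts spread `B` across `[0.001, 0.1]` (two decades of
clonal-expansion states).  `simulate_cohort` spaces `B`
log-equidistantly by default, with `linear` and `uniform-random`
spacings available; the clustering-fidelity experiment below uses random
draws (see its paragraph for why).  All per-repertoire seeds derive from
one `SeedSequence`, so every cohort is reproducible from a single
integer.

## Profile intersection and sub-repertoire delineation

Two diversity profiles intersect when their difference changes sign
along the alpha grid with magnitude above a tolerance of `1e-6` times
the larger profile value on both flanks — the tolerance suppresses
floating-point pseudo-crossings between near-identical profiles — and
the crossing alpha is located by linear interpolation between the
flanking grid points.

Because Hill diversities are Schur-concave, intersecting profiles imply
intersecting rank-ordered *cumulative* frequency curves.  Comparing the
cumulative curves rank by rank therefore delineates differentially
expanded sub-repertoires: maximal rank intervals on which one repertoire
has the higher cumulative frequency, with the per-rank difference in
percentage points as the expansion effect size.  Tie ranks (difference
below 1e-12) are merged into the preceding segment.
`schur_consistency_check` asserts the implication pair-by-pair and is
exercised over hundreds of random distribution pairs in the test suite;
a counterexample would indicate a bug, not new mathematics.

## Depth robustness

For a cohort at full depth and a list of depth fractions, each
repertoire is subsampled and profiles recomputed.  Two published-style
summaries are reported per fraction:

- *qualitative robustness*: the probability that a repertoire pair's
  intersection status differs from its full-depth status (and, as a
  companion, the raw intersection probability);
- *quantitative robustness*: the Euclidean distance between each
  repertoire's subsampled and full-depth profile, averaged over
  repertoires, plus a normalized variant (distance divided by the
  full-depth profile norm).

The exact statistics behind the original robustness figures are defined
in supplementary material that is not part of this package's inputs;
the two operationalizations above are this package's documented choices,
consistent with the Euclidean metric used for profile clustering.  On
simulated cohorts (20 repertoires, 1e6 reads), diversity-profile
intersection status is stable (change probability 0) from 10 % depth
onward, matching the published qualitative claim.

## Hierarchical clustering and cophenetic fidelity

Profiles or distributions are clustered by complete-linkage
agglomeration (scipy) on one of two distances: Euclidean (shape and
magnitude — used for diversity profiles) or Pearson correlation
distance `1 - r` (scale-invariant — used for evenness profiles).
Agreement between two dendrograms over the same samples is the Pearson
correlation between their cophenetic distance vectors (the merge height
at which two leaves first join).  Leaf orders are aligned before
correlating; `r(t, t) = 1` exactly.

The fidelity sweep asks how many alpha values a profile needs before
profile clustering reproduces distribution clustering: cluster the
(equal-composition) frequency matrix once as reference, then cluster the
profile matrix restricted to a growing alpha subset and record the
cophenetic correlation.  Two design choices here were genuinely open:

- *Subset rule*: alphas accumulate in grid order from `alpha = 0`
  upward (`n = 2` uses `{0, 0.2}`); an evenly-spread subset mode is
  provided as an alternative.
- *Clustering rendered "correlation-based"*: the sweep applies the
  Euclidean/complete-linkage algorithm to the *rows of the
  sample-sample Pearson correlation matrix* — i.e., clustering is
  performed on the correlation matrix, as the standard R heatmap
  pipeline does.  The direct `1 - r` distance is available as an
  option, but its cophenetic correlations are erratic across simulation
  seeds (complete-linkage merge heights on a smooth one-parameter
  continuum are noise-dominated), whereas the correlation-matrix-row
  representation characterizes each sample by its correlation pattern
  to the whole cohort and yields stable sweep curves.

With cohorts of Zipf-Mandelbrot distributions (`a = 0.1`, `B` drawn
uniformly at random from `[0.001, 0.1]` — random draws create genuine
cluster structure; equidistant spacing produces a featureless continuum
whose tree comparisons are unstable), the sweep reproducibly shows
`r ~ 0` at 2 alphas (Pearson correlation between 2-vectors is always
±1, so 2-alpha profile "distances" carry almost no information) rising
to a stable plateau of `r ~ 0.8` from a handful of alphas onward.  The
isolated published maximum near 40 alphas does not emerge under any
examined reading and is treated as specific to the original single
run.  The acceptance script runs this sweep at 1000 repertoires and
1e5 reads per repertoire — read depth reduced from 1e6 as the package's
desk-scale choice; the sweep values are depth-insensitive in the range
3e4–1e6 (pilot seeds 1–3) — and averages each cophenetic correlation
over three replicate cohorts to reduce the Monte-Carlo error of the
tree comparison.

## Status classification

Diversity/Evenness profiles share one alpha grid, so samples form a
feature matrix (rows samples, columns alphas).  The classifier is a
sparse linear model minimizing

    c * sum_i max(0, 1 - y_i w.x_i)^2  +  eps * ||w||_1

on features standardized to zero mean and unit variance *on the
training data of each fold only*.  `c` (cost) weighs misclassification,
`eps` drives embedded feature selection; "selected alpha values" are the
exact-zero-complement support of `w`.  The decision function carries no
intercept: with standardized features the all-zero model then predicts
one class constantly, scoring a balanced accuracy of exactly 50 %.  (An
unpenalized intercept tracks the training majority class, and under
leave-one-out that systematically votes *against* the held-out sample —
the classic below-chance LOOCV artifact; omitting the intercept keeps
chance-level data at chance-level BACC, which is the behaviour a
balanced-accuracy protocol assumes.)

Hyperparameters follow fixed grids: `c` in {1, 5, 9, 13, 17} and `eps`
in {2^i : i = -3..4}.  Nested leave-one-out cross-validation holds out
one sample in the outer loop; the inner loop scores every `(c, eps)`
pair by LOOCV over the remaining samples, excludes pairs for which more
than 3 inner models select more than 20 alpha values, picks the best
surviving pair by inner balanced accuracy (ties broken toward larger
`eps`, then smaller `c` — the compacter model), refits it on the inner
data and predicts the held-out sample.  Pooled outer predictions give
sensitivity, specificity and BACC = (sensitivity + specificity)/2.  If
every pair is excluded for some fold, a `NoAdmissibleModelError` is
raised rather than silently relaxing the cap.

Significance: the permutation test shuffles the label vector (1000
times by default), reruns the entire nested procedure per shuffle, and
reports `p = #(null BACC > observed BACC) / n_permutations` with strict
exceedance; the conventional significance call is fewer than 10
exceedances in 1000 (`p < 0.01`), so a count of exactly 10 is *not*
significant.

### Solver

The objective is solved by an own proximal method compiled with numba:
FISTA (Nesterov momentum, gradient-mapping adaptive restart, step from
the power-iteration Lipschitz bound `2c lambda_max(X^T X)`) alternating
with cyclic coordinate descent (exact per-coordinate Newton step,
Armijo backtracking, active-set shrinking with full-pass verification).
The two phases have complementary failure modes on the near-collinear
alpha grid: cold FISTA spreads tiny weights across twin columns and
crawls in the very sparse regime, while cyclic coordinate updates
zigzag in the dense regime.  Alternation continues until the
subgradient optimality residual falls below `1e-6 (2cn + eps)`; both
phases produce exact zeros, so the selected support is reliable.  On
random and profile data across the full hyperparameter grid the solver
matches the reference L1-penalized squared-hinge optimum (scikit-learn
LinearSVC, used purely as a test oracle) to ~1e-11 relative objective
error.  Inner-loop scoring fits run a capped budget (two cycles) and
warm-start each fold from the converged full-inner-set solution of the
same hyperparameter pair; a pair's fold loop stops as soon as its
exclusion is already decided (an exact shortcut), and any outer fold
whose pairs were all excluded under the capped budget is rescored once
at high precision before the no-admissible-model error is raised —
capped fits can transiently overcount the support on the near-collinear
alpha grid, and the rescoring distinguishes that artifact from genuine
exclusion.  The refits that produce predictions use the full budget.

### What the synthetic cohorts do and do not show

Synthetic two-regime cohorts (classes defined by disjoint `B` ranges,
e.g. `[0.001, 0.01]` vs `[0.05, 0.1]`) verify that the pipeline recovers
a clonal-expansion signal at the published >= 80 % BACC level, and
label-shuffled/noise cohorts verify chance-level calibration and
permutation-test validity.  These cohorts emulate the clonal-expansion
axis of real repertoires but not batch effects, V(D)J composition
biases, isotype structure, or inter-individual richness variation, so
passing them demonstrates correctness of the method's mechanics on data
matching its assumptions — not clinical performance, which in the
original study depends on external patient datasets that are outside
this package's inputs.

## Problem sizes

Defaults in tests and the acceptance script are chosen to keep a full
run on one CPU comfortable while preserving every qualitative result:
fidelity sweeps at 150–1000 repertoires and 3e4–1e5 reads, robustness at
20 repertoires and 1e5–1e6 reads, classification at 24 samples with
51-alpha profiles and 40–100 permutations.  Full-scale runs
(1000 repertoires × 1e6 reads) use the same code paths via the CLI.

## Known limitations

- Clonotyping is identity-based; similarity-based clonotype clustering
  is out of scope.
- No diversity estimators correcting for biological undersampling are
  provided; profiles describe the sample, not the organism.
- Zipf-Mandelbrot parameter *fitting* to real repertoires is not
  implemented (simulation only).
- For Zipf shape parameters near 1 the truncation cap biases `pi_1`
  (see above).
- The published clustering-fidelity maximum at 40 alphas is not
  reproduced; see the clustering section.
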