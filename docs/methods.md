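# Methods

This note records the statistical procedures the package implements, the
modeling choices behind the synthetic cohort generator, and the numerical
conventions that make results reproducible. It documents what the code does
and why; every empirical claim below is computed by the test suite or by
`scripts/acceptance.py`.

## Connectivity model

Functional connectivity between two regions is the Pearson correlation of
their time series; a subject's connectome is the symmetric R×R matrix with
unit diagonal. Statistics operate on the Fisher transform z = arctanh(r) of
the strict upper triangle, which stabilizes the variance of sample
correlations (approximately 1/(T−3) for T time points). The diagonal is
excluded before the transform (arctanh(1) is undefined). The canonical edge
order is the row-major upper triangle with 0-based region indices; for the
default 90-region atlas this gives E = 4005 edges, and `edge_index`/`pair_of`
form the shared bijection all modules use. Exact collinearity (|r| = 1) is
clipped to ±(1−10⁻¹²) only on the synthetic path, where it can arise by
construction; on the real-data path it raises, because it signals a data
problem (duplicated or constant region series).

## Atlas and network combinatorics

The default atlas is the 90-region cerebral parcellation in its conventional
numerical order (odd = left, even = right), with each bilateral region code
expanded to a .L/.R pair. Regions belong to one of six resting-state
networks — visual (14 regions), somatomotor (12), attention (15; dorsal and
ventral attention merged), frontoparietal (10), limbic (16), default mode
(23) — with the inferior temporal gyrus split by hemisphere (right in AN,
left in DMN). These sizes yield the within-network pair counts used for
standardization (e.g. C(23,2) = 253 DMN pairs; 680 within-network pairs in
total, 3325 between-network), and the acceptance tests verify the implied
percentages to two decimals.

## Univariate arm

Edgewise tests are pooled-variance (Student) two-sample t-tests with
n₁+n₂−2 degrees of freedom — the convention of the standard connectome
toolboxes, and exact under the generator's Gaussian model with equal group
covariances off the planted edges. The sign convention is t > 0 when the
control group mean is larger. Edges with zero pooled variance are flagged
invalid and excluded from all masks. Bonferroni uses p·E < α over the finite
p-values; FDR is Benjamini–Hochberg step-up (via statsmodels).

The network-based statistic thresholds the edgewise t at the two-tailed
cluster-defining level (default p < 0.001, i.e. one-tailed p < 0.0005 per
direction), splits suprathreshold edges by sign into the two contrast
directions, and forms connected components on the region graph per direction
(scipy's sparse graph machinery). Components are scored by extent (edge
count) — the original and most common choice; intensity scoring is out of
scope. The null is built by full group-size-preserving relabelings: per
permutation the maximal component extent over *both* directions is recorded,
which keeps the family-wise error valid across the two one-sided families.
Corrected p = proportion of null maxima ≥ the observed extent, floored at
1/n_perm. An `exact=True` mode enumerates all C(n, n₁) relabelings, used by
the tests to check the sampled p against exhaustive enumeration on 8
subjects. The permutation loop computes all t statistics by group-sum matrix
products in memory-bounded chunks, so 10,000 permutations at 4005 edges are
feasible on one CPU.

Demographic/clinical group comparisons reuse the same pooled t, with pairwise
missing-value exclusion; `two_sample_t_from_summary` recomputes t from group
means/SDs so published summary tables can be re-tested without subject data.

## MVPA arm

Classification is leave-one-subject-out: for each held-out subject, all
edges are ranked by the two-group one-way ANOVA F computed **on the training
subjects only** (F identically equals the squared pooled t; asserted to
1e−10), the top N% are kept (floor rounding — floor(0.10·4005) = 400 — with
ties in F broken by ascending edge index for cross-platform determinism),
and a soft-margin linear SVM (default C = 1, no feature standardization;
both exposed in the API) is trained on the selected columns. Held-out
decision values d = w·x + b use the label coding controls = +1,
patients = −1, so d > 0 predicts control and a positive weight marks an edge
whose larger value argues for the control class. Accuracy, sensitivity and
specificity (patients = positive class) are computed per grid point
N ∈ {10,…,100}; the final accuracy is the grid maximum, with ties resolved
to the smallest N (parsimony). ROC and AUC come from the pooled held-out
decision values at the best N, with rank-averaged tie handling (AUC equals
the normalized Mann–Whitney U; asserted against exhaustive pair counting).

The SVM is solved by libsvm. The permutation test refits on the order of
10⁵ small SVMs, where the estimator-level API overhead exceeds the solver
cost by ~30×, so the hot path calls the library's low-level binding
directly; the tests assert exact weight/bias agreement with the public
estimator across random problems, and independently against an SLSQP
solution of the SVM dual to 1e−4.

Inference: each permutation reruns the entire nested procedure (ranking,
selection, training) with exchanged labels over all grid points and records
the **maximum** accuracy over the grid; true accuracies are referred to this
null of maxima, giving family-wise-error-corrected p per grid point, floored
at 1/n_perm. Two exchange schemes are implemented:

* `within-fold` (default): inside every cross-validation fold the training
  labels are shuffled independently and held-out predictions are scored
  against the true labels — the scheme used by the common MVPA toolboxes.
* `global`: one label permutation per permutation step, applied before the
  cross-validation loop; predictions are scored against the permuted labels.
  This is the exactly exchangeable scheme.

The within-fold scheme is **anti-conservative in small, feature-poor
regimes**: in null simulations (28 edges, 16–42 subjects, n_perm = 200,
50-run probes) its familywise false-positive rate at the 0.05 level was
0.12–0.19 rather than 0.05, because the truth-scored LOOCV statistic has a
fatter upper tail under the null than the shuffled-training-labels
statistic. The global scheme was calibrated (0.04 at 16 subjects) and is
what the acceptance suite asserts at the ≈5% level. The default remains
`within-fold` for comparability with the toolbox convention, but `global`
is recommended whenever the p-value itself is the scientific claim.

Selected-edge aggregation takes the union of per-fold selections at the best
N; each edge's weight is the mean of its SVM weights over the folds that
selected it, and its selection frequency (folds selected / folds) is kept.

## Characterization

Weighted degrees sum, per region, the positive and the negative weights of
incident selected edges separately; each positive degree is flagged when it
exceeds the mean + 1 (or 2) SD of the positive degrees over all 90 regions
(zeros included), and symmetrically below mean − k·SD for negative degrees.
A signed convention is the default; an absolute-value mode applies the
thresholds to magnitudes of the negative degrees instead, since plots in the
literature are ambiguous on this point. The conservation identity (degrees
sum to twice the corresponding weight sums) is property-tested.

Network categorization classifies each selected edge by its endpoints'
networks into a symmetric 6×6 count table, standardized cell-wise by the
possible-pair counts (percent = 100·count/possible); the pooled intra
(inter) percentage divides total intra (inter) counts by the 680 (3325)
possible pairs. Edge–clinical correlations are Pearson r within the patient
group only, flagged at the uncorrected p < 0.005 convention used at these
sample sizes; BH-FDR flags are emitted alongside as a clearly-labeled safer
alternative for reuse.

## Synthetic cohort generator

The generator defines the study conditions under which the pipeline is
validated. Defaults: 21 subjects per group, 90 regions, 170 time points,
within-network correlation ρ_in = 0.3, between-network ρ_out = 0.1 (typical
magnitudes for band-passed resting-state region series), AR(1) temporal
coefficient 0.3 (band-passed BOLD is smooth; tests should not assume white
noise). Each subject's series is unit-variance AR(1) noise (50-sample
burn-in) spatially mixed by the Cholesky factor of the group correlation
matrix — mixing after temporal filtering leaves the population FC equal to
the target matrix regardless of the autocorrelation (verified by a
20,000-sample Monte-Carlo test).

The patient matrix adds `effect_delta` to the control matrix on
`effect_edges` and is projected to the nearest correlation matrix
(statsmodels' alternating-projection `corr_nearest`, iteration budget
capped; the cap is safe because repair quality is re-checked). The
generator then *verifies the achieved effects* and raises if the repair
eroded any planted delta by more than half — planted effects are honest or
the spec is rejected, never silently weakened. Consequently, large dense
effect sets must be structured: the acceptance suite plants its 400-edge,
delta = 0.5 pattern on a 29-region clique, because clique-shaped shifts
perturb the spectrum by at most about one delta while 400 arbitrary edges
at +0.5 make the matrix badly indefinite and are rejected.

Clinical variables use group-specific clipped-Gaussian marginals at
realistic ranges (e.g. patient AHI ≈ 54 ± 20 events/h clipped to [15, 120],
control AHI below 5; MMSE ≤ 30, ESS ≤ 24). A clinical link draws the
patient variable as r·z̃ + √(1−r²)·ε, where z̃ is the patient's standardized
Fisher-z value at the linked edge — a linear construction chosen over a
copula with skewed marginals because the Pearson correlation is exactly the
property downstream analyses consume, and monotone marginal transforms
would distort it. Round-trip tests recover planted links to ±0.1 at 200
patients.

What the generator does **not** emulate: head motion, physiological noise,
spatial smoothness/parcellation averaging, non-Gaussian BOLD marginals,
site/scanner effects, or any preprocessing artifacts. Passing tests
therefore demonstrate the statistical machinery is correct and calibrated
under the stated model — not that any real cohort will classify at a given
accuracy.

## Numerical conventions and scale choices

* All randomness flows through numpy Generators seeded explicitly; the
  pipeline expands one global seed into independent per-stage streams
  (cohort, NBS, MVPA) via `SeedSequence`, so stages rerun in isolation
  reproduce exactly and full reruns are byte-identical (asserted on the
  written TSV/JSON files).
* Permutation p-values are floored at 1/n_perm; NBS and MVPA nulls are
  sampled without enforcing uniqueness of relabelings.
* Grid/selection determinism: stable sorts everywhere; best-percentage ties
  go to the smallest percentage; F ties to the lowest edge index.
* Test and acceptance workloads are scaled to single-CPU minutes: null
  calibrations use 8–15 region cohorts (28–105 edges) with 100/50 simulation
  runs and n_perm = 200/1000; the planted-pattern recovery and the
  acceptance script run at full study scale (90 regions, 42 subjects,
  T = 170) where one LOOCV grid pass takes well under a minute.

## Known limitations

* Covariate adjustment (age, BMI regression) is deliberately absent from the
  univariate arm; group comparability is reported, not modeled.
* The NBS implements extent scoring with a fixed cluster-defining threshold;
  threshold-free and intensity variants are out of scope.
* The within-fold permutation default trades type-I exactness for toolbox
  comparability (see above); use `mode="global"` for calibrated inference.
* Sensitivity/specificity assume patients are the positive class; with
  equal group sizes the mapping of the two reported rates is otherwise
  ambiguous.
* The atlas is fixed at the 90-region parcellation with the six-network
  assignment; alternative atlases would need a new `RegionAtlas` table (the
  TSV import exists for that purpose).
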