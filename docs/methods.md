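# Methods

## Problem setting

Clinical prognosis data is imbalanced twice over. The outcome worth
predicting — in-hospital death, death within five years of a cancer
diagnosis — is the rare class (we call it C1; the majority class is C0),
and the patients are unevenly distributed over demographic subgroups
(race, age group, sex). A classifier trained on the pooled data can post
high overall accuracy and AUC-ROC while recalling far fewer C1 cases in
small subgroups, because both of those aggregates are dominated by the
majority class and the majority demographic. The corrections implemented
here address one specific source of that gap: *representation*. They
assume outcome noise is the same across subgroups and do not correct
measurement bias, underdiagnosis, or label bias.

## Double-prioritized (DP) bias correction

DP prioritizes along both axes at once: it replicates only the training
rows that are simultaneously minority-class and members of one target
demographic group g. One *unit* of enrichment appends one full copy of
all C1 ∩ g training rows. Sweeping units u = 0..n (default n = 19) gives
n + 1 candidate training sets, the original included, each of which
trains one candidate classifier under identical architecture and
hyperparameters — candidates differ only through their data.

Each candidate's validation scores are calibrated by isotonic regression
and a decision threshold is tuned on the whole validation population
(see below). Selection is two-stage: candidates are ranked by
whole-population validation balanced accuracy, the top three are kept,
and among them the candidate with the highest C1 precision-recall AUC on
validation rows of g is selected as M\*. Ties resolve toward the smaller
unit at both stages, preferring less intervention when metrics cannot
distinguish candidates. Balanced accuracy used for ranking is
whole-population rather than subgroup-restricted: subgroup validation
slices are often a few dozen rows, and ranking on them overfits the
validation set. Calibration is refit per candidate, since each
candidate's score distribution differs.

At deployment the enriched group and the test group are matched (g' =
g): the model enriched with Black C1 cases predicts new Black patients.
The cross-group matrix quantifies what happens when they are mismatched.

Validation and test splits are never resampled or reweighted, by
construction: a new patient's outcome is unknown, so any correction that
touches evaluation data would be unrealizable in practice. The test
split's content hash is checked before and after every experiment run.

## Comparison correctors

Eight whole-population samplers are implemented with the contracts fixed
as follows. All undersamplers return |C0| = |C1|; all oversamplers
return |C1| = |C0|.

- **RUS** — uniformly remove C0 rows.
- **NearMiss-1** — keep the |C1| majority rows with the smallest mean
  Euclidean distance to their k nearest minority rows (k = 3).
- **NearMiss-3** — stage 1 retains each minority row's m = 3 nearest
  majority rows as candidates; stage 2 keeps the candidates with the
  *largest* mean distance to their k nearest minority rows. A candidate
  pool smaller than |C1| is kept whole, with a warning.
- **Distant** — mirror of NearMiss-1 (largest mean distance kept).
- **ROS** — duplicate uniformly chosen C1 rows with replacement.
- **SMOTE** — synthesize x + λ(x′ − x) with x′ one of the k = 5 nearest
  minority neighbors and λ ~ U[0,1].
- **ADASYN** — SMOTE-style generation with the per-row budget
  proportional to r_i = (majority neighbors among the k nearest overall)
  / k, rounded by largest remainder so the total is exactly |C0| − |C1|;
  all r_i = 0 falls back to a uniform allocation.
- **Gamma** — SMOTE-style generation with λ ~ Gamma(shape 4, scale
  0.125), resampled into [0,1]. The defaults give E[λ] = 0.5 and are
  deliberately provisional: the underlying method's parameterization is
  exposed as configuration rather than asserted.

Numerical choices shared by the distance-based samplers: distances are
Euclidean on the encoded feature matrix after per-column standardization
fitted on the input training data (the scale of one-hot columns and lab
values should not silently dominate); distance ties break by ascending
row position; synthetic points inherit the demographics of their seed
row, and interpolation happens in raw (unstandardized) feature space. A
single-row minority class degrades SMOTE-family methods to replication,
with a warning.

Two reweighters produce per-row weights instead of resampling.
*Standard reweighting* assigns class c the weight N/(2·N_c), which
equalizes the class totals at N/2 each and preserves the overall total
at N; this normalization is what makes a 12.7% minority produce the
weight pair 3.94 / 0.57. *Prioritized reweighting* multiplies the
default weight 1 of C1 ∩ g rows by an integer unit (1..20) and feeds the
resulting models through the same selection loop as DP. For an exactly
optimized convex weighted learner, weight n is identical to training
with n copies, so prioritized reweighting is DP's weighting twin; the
package asserts this equivalence on effectively unpenalized logistic
fits (the equivalence is exact only when the objective is affine-
invariant, which per-fit feature standardization breaks for penalized
fits).

## Calibration and threshold tuning

Raw scores are calibrated with isotonic regression (pool-adjacent-
violators, squared error, monotone nondecreasing) fitted on the
validation split and applied to validation and test scores alike.
Out-of-domain scores clamp to the boundary fitted values.

Threshold tuning is two-stage over the candidate grid formed by every
unique calibrated score plus {0, 1}: top three thresholds by minority-
class F1, then the one among them with the highest balanced accuracy.
The prediction rule is C1 iff score ≥ threshold, and every tie resolves
toward the lower threshold — both choices deliberately favor minority-
class recall. F1 at degenerate thresholds (no predicted positives) is
taken as 0 rather than excluded. Per-subgroup threshold tuning exists
for the whole-group-vs-subgroup comparison; it flags subgroups under 30
validation rows, where a tuned threshold mostly memorizes the slice.

## Metrics and fairness reporting

The panel per subgroup: recall, precision, AUC-PR and F1 for each class,
accuracy, balanced accuracy = (Rec_C0 + Rec_C1)/2, AUC-ROC, and MCC.
AUC-PR is computed as average precision (the step-function integral),
not trapezoidal interpolation, which is optimistic for PR curves.
Precision and F1 are 0 when their denominators vanish; threshold-free
metrics on single-class slices are *undefined* and serialize as empty,
never as 0 — fabricating zeros would manufacture disparity.

Relative disparity for one metric across subgroups is R1/R2, the highest
subgroup value over the lowest; values below 1.25 (the four-fifths rule
for disparate impact) are flagged fair. A non-positive minimum (possible
for MCC) yields an infinite ratio with a note rather than a number that
would average quietly. Subgroups with no C1 rows are excluded from
ratios with a logged reason.

SHAP-style per-column importances are aggregated to source features by
mean (avg variant) and by sum, using the dataset's column map; one-hot
encoding keeps all levels precisely so this aggregation is well defined.
Computing the attributions themselves is out of scope — any per-column
importance vector can be supplied.

## Synthetic cohorts

The generator emulates the *marginal structure* of the real cohorts this
methodology is aimed at, without containing patient data: demographics
are drawn independently from configurable race/age/sex mixes, continuous
features are standard normal, categorical features uniform then one-hot
encoded, and the outcome follows a logistic model
sigmoid(intercept_s + coef_s·x + ε), ε ~ N(0, 0.5), where s is the
row's subgroup pattern. The intercept of each pattern group is solved by
bisection so the group's expected prevalence hits its target within
5·10⁻⁴ (solver tolerance 10⁻¹⁰; the 0.005 contract bound holds with
large margin). The logistic link is the simplest choice that admits
exact prevalence control; label noise is identical across subgroups, so
representational imbalance is the only bias present by construction.

Subgroup-specific signal enters as *deviation vectors* added to the
shared coefficients for deviating groups. The shipped presets put the
deviations on marker features (x4..x7) that carry no signal in the rest
of the population: a pooled fit dilutes those coefficients by the
group's small population share, so the pooled model systematically
under-uses the group's own predictive signal — precisely the situation
subgroup-targeted enrichment repairs, and a pattern documented in real
cohorts whenever a risk factor is informative only within a subgroup.

Two presets fix the study conditions. `ihm_like` (hospital-mortality-
like): C1 prevalence 0.135; race mix white 0.706, Black 0.096, Hispanic
0.04, Asian 0.03, other 0.128 (the two fractions beyond white/Black are
arbitrary fill, exposed as parameters); 76% of age mass in [50,90); sex
0.451/0.549; deviations on race=Black and age 90+. `bcs_like` (breast-
cancer-survivability-like): C1 prevalence 0.127; white 0.81; male 0.006;
70% of age mass in [40,70); deviations on race=Hispanic (strong),
race=Asian and age [40,50) (moderate). Age groups use half-open [X, Y)
bins with edges 30..90.

What the generator does *not* emulate: time-series dynamics, censoring,
missingness, measurement bias, or correlation between demographics and
features beyond the outcome model. Passing tests on these cohorts
demonstrate that the machinery behaves as specified under controlled
representational imbalance; they do not certify performance on real
clinical data.

## Classifiers

The DP loop is classifier-agnostic behind a two-method contract (fit
with optional per-row weights and a seed; score probabilities). The
reference learner is L2-regularized logistic regression solved to
tolerance 10⁻¹⁰ — deterministic, convex, and weight-exact, which makes
every selection and equivalence test reproducible bit-for-bit. A small
fixed-architecture feed-forward network (one hidden layer of 16 units)
is provided for nonlinear signal; it accepts integer weights by exact
row replication (all prioritized-reweighting units are integers) and
rejects non-integer weights, for which the logistic learner is the
appropriate tool. Candidate u trains with a seed derived from (run seed,
u) through an independent seed sequence, so candidates differ only
through their data, not through incidental RNG coupling.

## Problem sizes and numerical conventions

Experiment defaults in the test suite and the reproduction script use
cohorts of 2,000–20,000 rows: 20,000 rows to verify preset marginals
(binomial error ≈ 0.3 pp), 4,000 rows × 10 replicate cohorts for the
DP-vs-original recall comparison and the cross-group matrix, with the
full 20-candidate sweep (n = 19). These sizes were chosen so the
qualitative phenomena — dilution of subgroup markers, recovery under
enrichment — are resolvable above recall granularity while a full run
stays interactive on a laptop. Stratified splitting (default
0.70/0.15/0.15) stratifies jointly on label × demographics where cells
have ≥ 3 rows, falls back to label-only strata below that, and carries
fractional allocations across strata so realized split sizes stay within
±1 of the requested fractions. Replicate summaries use the sample
(n − 1) standard deviation.

## Known limitations

- The selection rule inherits whole-population balanced accuracy for
  ranking; when enrichment of a tiny group cannot move that aggregate,
  stage 1 rather than stage 2 decides, and DP converges to the original
  model. This is faithful to the method's design and visible in the
  candidate table.
- Linear learners cannot express subgroup-specific *reversals* of shared
  effects; with such signal, enrichment strictly trades whole-group fit
  against group fit. The synthetic presets therefore model subgroup
  signal as additional markers, which both linear and nonlinear learners
  can exploit.
- Relative disparity on recall over small test subgroups is chunky (a
  handful of C1 cases per group); disparity numbers from small synthetic
  cohorts should be read as illustrative, not as estimates with error
  bars.
- The gamma sampler's λ distribution is a configurable stand-in for an
  unpinned upstream parameterization.
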