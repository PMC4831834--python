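# Methods

## Model

The grading model is a conditional linear Gaussian (CLG) Bayesian network
over one discrete grade node `G` (states `low`, `high`), one discrete
enhancement node `T` (states `negative`, `slight`, `apparent`) and up to
nine continuous feature nodes (five normalized perfusion parameters, four
metabolite ratios). Discrete nodes have multinomial CPDs indexed by their
discrete parents. A continuous node with discrete parents `D` and
continuous parents `C` follows `N(β₀⁽ᵈ⁾ + β⁽ᵈ⁾ᵀ x_C, σ²⁽ᵈ⁾)` per
configuration `d` of `D`. CLG admissibility (no continuous parent of a
discrete node) is enforced structurally; it guarantees that conditioning
on a full discrete configuration leaves a joint multivariate Gaussian
over the continuous nodes, which the inference engine compiles in
topological order (`μ_child = β₀ + βᵀ μ_parents`; covariance rows pushed
through the same linear map, residual variance added on the diagonal).

The "Gaussian node" modelling choice is an approximation: several
features (notably Lac/Cr, Lip13/Cr) are heavily right-skewed, and the
per-grade Gaussian is a deliberate simplification of the kind routinely
made in small-cohort hybrid networks. The network is small (≤ 10 nodes),
so inference enumerates discrete configurations exactly — six at most —
and no approximate algorithm is ever used.

### Inference

For evidence `e` (any mixture of discrete states and real values), each
full discrete configuration contributes
`w = Π P(d_i | pa) · φ(e_cont; μ_S, Σ_S)`, where `S` is the observed
continuous subset and `(μ_S, Σ_S)` the corresponding rows/columns of the
compiled joint Gaussian — marginalizing an unobserved continuous node is
exactly dropping its row and column. Weights are accumulated in log space
(log-sum-exp); the grade posterior is the normalized sum over non-grade
configurations, and the normalizer is returned as the log evidence.
Prediction takes the posterior argmax; an exact tie (difference < 1e-12)
resolves to high grade, the clinically conservative call. Evidence with
zero likelihood under every configuration raises an error rather than
returning an arbitrary posterior.

### Parameter estimation

Maximum likelihood throughout, fitted per family on available cases (rows
where the child and all its parents are observed): relative frequencies
for discrete nodes (optional add-k smoothing, off by default — zero
probabilities are legitimate MLE and the cohort sizes here do not produce
empty observed grade cells), and per-configuration ordinary least squares
with MLE residual variance (divide by n, not n−1) for continuous nodes.
Two guardrails handle small strata: a discrete-parent configuration with
no rows (or fewer rows than coefficients + 2 for a regression) falls back
to the configuration-marginal (pooled) fit and is recorded in
`fit_metadata`; residual variances are floored at 1e-6 (squared feature
units) so a degenerate stratum cannot produce a zero-variance density.
A family with fewer complete rows than coefficients + 2 overall is a
hard error naming the family.

## Structure learning

K2 greedy search over a fixed ordering: each node starts parentless and
repeatedly adds the single admissible predecessor that most increases the
family score, stopping when no addition helps or `max_parents` (default
3) is reached. Candidate parents are restricted to predecessors in the
ordering, so every result is acyclic by construction; ties between
candidates go to the earlier node in the ordering, making the search
deterministic. The classical K2 metric applies only to all-discrete data;
this network is hybrid, so the score is BIC over the CLG likelihood
(available-case family log likelihood − ½·k·log n with k the free
parameter count, discrete configurations counted in full). BIC is
decomposable and consistent and needs no hyperparameter. K2 assumes
complete data, so the search first restricts its table to rows complete
for the nodes in the ordering. `exhaustive_best_dag` computes the exact
score optimum over all order-consistent DAGs for ≤ 5 nodes and serves as
the oracle in the tests.

The default ordering puts grade first, then the enhancement category,
then the retained features by ascending screening p-value (name as tie
break) — grade can then only ever be a parent, which matches the
intended causal reading (grade drives the imaging phenotype).

## Two-part construction and evaluation

Only 21 of 56 patients carry both PWI and MRSI, too few for a joint K2
run, so the network is learned in two parts: {grade, T1W+C, retained
perfusion features} on the 51 perfusion-complete rows and {grade,
retained MRSI features} on the 26 MRSI-complete rows. The parts are
merged by node/edge union on the shared grade node; since grade leads
both orderings the merge cannot create a cycle (re-validated anyway).

Evaluation is leave-one-out: the structure is held fixed across folds
(the protocol refits only parameters; a stricter structure-relearning
variant would multiply cost without changing the questions asked here)
and parameters are refitted per fold on the remaining rows,
available-case per family. An *observation pattern* names the modalities
read as evidence; its *required* subset defines the denominator (only
cases carrying those modalities are scored), while optional modalities
(marked `?` in the string form) contribute evidence when present. This
reproduces the standard reporting blocks — all 56 cases with whatever
each carries, the 51 perfusion-complete cases, the 26 MRSI-complete
cases — within one mechanism.

ROC curves come from a threshold sweep over the posterior P(high); tied
scores advance diagonally, so the trapezoidal area equals the
Mann–Whitney statistic with ties counted one half (asserted to 1e-12 in
the tests). With enhancement-only evidence the score takes at most three
distinct values and the ROC has three interior points — a coarse but
well-defined curve. LOOCV accuracy can sit below the score's AUC-implied
quality when classes are balanced: the held-out case is always the
training minority, a known LOOCV artifact that the tests exploit
deliberately in the chance-level check.

## Feature screening

Two-group Kruskal–Wallis (equivalent to a two-sided Wilcoxon rank-sum up
to the approximation): tie-corrected statistic
`H / (1 − Σ(t³−t)/(N³−N))`, p from chi-square with 1 df. A feature is
dropped when p > α (default 0.05; p exactly at α is kept). Screening is
available-case per feature; a feature observed in fewer than two cases of
either grade group is flagged un-screenable and excluded with a reason.
The discrete enhancement node is never screened by this test. The
chi-square p is a large-sample approximation: exhaustive enumeration
shows it tracks the exact permutation law (mid-p convention) within 0.02
only from balanced N = 10 upward — at the 51- and 26-case screening sizes
used here it is comfortably accurate, but it should not be trusted for
groups of a handful of cases.

## Synthetic cohort generator

The generator emulates the reference study design — 56 patients
(30 high / 26 low), 51 with PWI, 26 with MRSI, 21 with both — with
grade-conditional moments for each continuous feature matching published
group statistics (e.g. nrCBV 3.762 ± 2.234 high vs 1.482 ± 0.624 low;
Lac/Cr 109.598 ± 206.765 vs 1.462 ± 2.919). Features are drawn
independently given grade: plain Gaussians for most, moment-matched
log-normals for the nonnegative heavy-tailed ratios Lac/Cr and Lip13/Cr
(σ² = log(1 + (sd/mean)²), μ = log mean − σ²/2, so the analytic mean and
SD equal the targets exactly; truncating a Gaussian at zero was rejected
because it would distort the very moments being matched). The
grade-conditional enhancement frequencies are **not** published; the
defaults (high: 0.10/0.17/0.73, low: 0.62/0.23/0.15 over
negative/slight/apparent) are an invented, configurable choice that makes
enhancement a usefully-but-imperfectly informative grader. Modality
missingness is allocated by a shuffled draw honoring the exact counts,
independent of grade (no grade-by-modality cross-tabulation is
published). Randomness flows from one master seed through named
per-feature substreams (stable under feature-list edits); identical spec
⇒ byte-identical table.

What the generator does *not* emulate: correlations between features
beyond grade-conditioning (none are published — so learned intra-modality
edges on synthetic data reflect sampling noise, not physiology), the
skew/kurtosis of the Gaussian-modelled features, measurement error, or
any image-level process. Consequently, passing end-to-end tests shows the
*pipeline* behaves correctly on data with the study's statistical shape —
it does not certify clinical accuracy on real patients, where the
generator's independence and distributional assumptions fail to varying
degrees. Synthetic accuracies also run higher than is realistic: the
generator's grade-conditional families coincide with the model's, the
best case for the classifier.

## Problem sizes in the validation suite

Inference is checked against an independent grid-integration oracle
(trapezoid rule, 801 points per latent dimension, windows from forward
samples ± 8 SD) on 200 random hybrid networks of ≤ 5 nodes; parameter
recovery uses 5,000 forward samples × 20 replicates; K2 is compared with
exhaustive search on 100 random 4-node datasets (n = 300) and chain
recovery on 100 replicates; screening calibration uses 10,000 null
replicates at the cohort's 25/26 group sizes; the AUC identity uses 1,000
random tied score vectors; the end-to-end comparison uses 50 default
cohorts. These sizes make the statistical assertions sharp while keeping
the full suite under a minute of compute.

## Known limitations

* No EM: families are fitted on available cases only; rows missing part
  of a family contribute nothing to that family's fit.
* Structure learned on modality-complete subsets cannot discover
  cross-modality feature edges (perfusion ↔ MRSI), by design.
* The BIC/CLG score is a package choice; the original K2 formulation's
  score for hybrid data is not uniquely defined in the literature.
* Posterior probabilities are uncalibrated in the formal sense; they are
  exact under the fitted model, not validated against outcome
  frequencies.
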