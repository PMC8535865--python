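# Methods

## Data model

A dataset is a samples × SNPs table of genotype categories (two-letter
strings over {A,C,G,T}, heterozygotes canonicalized alphabetically) with
a binary phenotype aligned to the sample order (1 = case/chronic,
0 = control/acute).  Per SNP the major allele is the more frequent one
(alphabetical on an exact tie), defining the additive coding 0/1/2 as
the minor-allele count.  Missing genotypes (`NN`/`NA`) are accepted on
read; the analysis engines require complete data and a
`drop_incomplete` utility is applied first — how the motivating cohort
handled missingness is not public, so no imputation is attempted.
PLINK `.raw` files carry only the counted allele letter, so round-trips
through `.raw` are defined (and tested) on identifiers, additive codes
and phenotype rather than genotype letters.

## Association layer

For a genotype grouping (one category, or set of categories, per SNP;
a sample is exposed iff it matches at every SNP) the 2×2 table
(a,b,c,d) = (exposed controls, exposed cases, unexposed controls,
unexposed cases) yields:

* odds ratio: the cross-product (b·c)/(a·d); with any empty cell the
  Haldane–Anscombe +0.5 correction is applied to all four cells and
  flagged;
* two-sided Fisher exact p: point-probability rule (total probability
  of margin-preserving tables no more probable than the observed one),
  delegated to scipy and cross-checked in the tests against an
  exhaustive hypergeometric enumeration for every table with N ≤ 40;
* intervals: Wald exp(ln OR ± z·√(1/a+1/b+1/c+1/d));
  exact-conditional by inversion of noncentral hypergeometric tails
  (scipy; brackets the conditional MLE); and profile likelihood from
  the saturated 2×2 logistic model (own implementation: bounded 1-D
  profiling of the nuisance intercept, Brent root of the profile
  deviance at χ²₁(0.95)/2);
* the Wald z-test on ln(OR) — the p-value `summary(glm(...))` prints
  for a binary exposure.

Published per-table statistics in this literature are often produced by
a logistic-regression summary even when labeled "Fisher exact"; this
cohort's printed values are a case in point.  All eight printed odds
ratios follow from the cross-product; the printed intervals are
reproduced by the *profile* construction (Wald gives e.g. 1.55–6.94 and
conditional-exact 1.46–7.55 where 1.57–7.09 is printed) and the printed
p-values by the *Wald z-test* (genuine Fisher p differs for six of the
eight tables, e.g. 0.352 vs printed 0.282).  The package therefore
reports Fisher and Wald p side by side and exposes all three interval
methods; the default `ci_method` is exact-conditional, the most common
convention for a test named Fisher.

## MDR

For a SNP subset, every multilocus genotype cell is labeled high-risk
iff (cases in cell)/(controls in cell) ≥ T, where T defaults to the
case/control ratio of the training data — 1 on the balanced simulation,
33/238 on the imbalanced cohort.  Cells with cases but no controls are
high-risk; empty cells are low-risk and flagged unobserved (conservative
toward the majority class).  Under stratified k-fold cross-validation
(default 10 folds, the canonical MDR setting; the fold assignment is
seeded) labels are learned on each training fold and misclassification
is measured on the training and testing portions.  For each order n the
subset minimizing average training error is kept; the final model
minimizes average testing (prediction) error across the per-order
winners, with ties broken by higher cross-validation consistency (folds
in which the winner is also the fold-best subset), then smaller n, then
SNP ids.  The exhaustive search is vectorised over subsets (cells are
integer-encoded and counted with `bincount` per fold) and refuses to
exceed 5·10⁶ subset×fold evaluations — C(872,3) is beyond desk scale —
in which case a marginal Fisher-p pre-filter (`marginal_prefilter`,
exposed on the pipeline and CLI) should be applied first.

## MARS

The regression-mode model is f̂(x) = C₀ + Σ Cᵢ Bᵢ(x) fitted by least
squares to the 0/1 phenotype (classification by thresholding f̂ at 0.5).
Basis functions are products of atoms over distinct SNPs.  Atoms are
genotype-category indicators — each observed category plus the pooled
non-wild-type (carrier) set for three-category SNPs — because genotype-
level risk combinations ("CC and CC") are the object of interest; hinge
atoms max(0, ±(x−t)) on the additive coding with knots at the observed
codes {0,1,2} are available behind `include_hinges` for dose-response
signals.

**Forward pass.**  Candidates at every step are single atoms, direct
products of two atoms from different SNPs, and — above degree 2 —
products of an in-model basis function with a new atom.  Classical MARS
only admits parent-in-model × atom; for strictly marginal-effect-free
epistasis the degree-1 causal atoms carry *zero* signal, so the
classical rule cannot reach the interaction reliably, and direct pair
candidates are the natural specialisation for categorical interaction
screening.  Candidate gains are evaluated in closed form against the
orthonormalised current design; the all-pairs block uses Gram-matrix
identities (uᵀD_r v, Σu²v², uᵀD_q v), so no product matrix is ever
materialised and cohort-scale SNP counts are feasible.  Two guards
govern admission: a *minimum support* of 10 observations on which the
candidate is nonzero (the analogue of MARS minspan — a basis function
supported by a handful of samples is an artefact), and a *universal
screening threshold*: the gain must exceed σ̂²·(2 ln C + margin) for C
candidates, with margin 6 by default.  The 2 ln C term is the classical
universal-threshold multiplicity correction; the margin was fixed by a
null calibration of the generator design (null data must stop the pass
immediately in ≫90% of replicates, and the planted corner's gain of
6.18 — deterministic given the generator's exact cell counts — must
clear the threshold of ≈5.8 in every replicate).  At this default the
pass is a conservative screen; `stop_margin` can be lowered (or
`stop_gain` fixed) for exploratory cohort-scale runs, with the caveat
that findings in that regime are not family-wise defensible — on
cohort-sized candidate spaces (~10⁶ pairs) a 46-sample cell with a gain
of ≈1.9 (z ≈ 4.2) is real but below any universal threshold, which is
why the pipeline treats cohort MARS screening as exploratory.

**Backward pass.**  One term is deleted at a time (the deletion
minimizing GCV at each size, coefficients refit at every step) and the
model along the path with the lowest GCV is returned.  GCV is computed
exactly as RSS/(1 − C/N)² with C = 1 + p·k — deliberately with no 1/N
prefactor; the factor is constant per dataset and cannot change model
selection, and this form matches the convention used in the motivating
analysis.  The per-basis-function penalty p defaults to 3 when
interactions are allowed and 2 otherwise (the classical costs);
max_terms defaults to 30.

**Extraction.**  Distinct SNP sets among degree-≥2 terms of the pruned
model, ordered by their RSS contribution (the RSS increase when the
set's terms are removed, coefficients refit); per set, the reported
high-risk genotype combination maximizes the terms' total contribution
to predicted risk — for positive-coefficient indicator products, the
indicated categories.

## RF-LR

A scikit-learn random forest (500 trees, bootstrap samples, √p features
per split, majority voting) on additive codes supplies mean-decrease-
in-impurity importances; ties in the ranking break by SNP id for
determinism.  The top k (default 5 — "the first few" is necessarily a
choice; exposed in config) enter a pairwise scan of the interaction
logistic model fitted by maximum likelihood (statsmodels).  The
interaction p-value is the Wald test on β₃; the minimum-p pair is
reported if p < α (default 0.05, no multiplicity correction across
pairs, matching the motivating analysis whose selected pair had
p = 0.034).  Non-converged fits — (quasi-)separation — are skipped with
a warning.

## Pipeline

`run_detectors` turns each detector's finding into at most one
candidate: MARS's top-contribution interaction with its risk
combination; MDR's final model (when of order ≥ 2) with its highest-OR
observed high-risk cell; RF-LR's best pair with the genotype cell
maximizing the fitted log-odds.  `select_improved` keeps a candidate
iff its combined-genotype OR *strictly* exceeds the best single-genotype
marginal OR of every constituent SNP (odds ratio only; p-values are
reported but not filtered on, following the workflow's stated rule).
The marginal grouping per SNP is its highest-OR single genotype — the
rule that regenerates the published per-SNP exposed rows.  Surviving
SNP sets are pooled (candidate order, lexicographic within a set) and a
CART tree (Gini impurity on genotype-category indicator splits — an
indicator split is exactly a genotype-subset split; minimum leaf 3 so
that small high-risk leaves like a 6-patient node remain reachable;
cost-complexity α = 0.01; empirical priors) is fitted and evaluated by
stratified 5-fold cross-validation with per-fold refitting (the
standard reading of "evaluated by stratified 5-fold CV"), pooling the
confusion counts before computing sensitivity, specificity, accuracy
and balanced accuracy = (sensitivity+specificity)/2, chronic positive.

Determinism: all randomness (fold assignments, forests, tree
tie-breaks, CV shuffling) derives from the master seed by fixed
offsets.

## Synthetic data

**Planted-epistasis simulation (250 × 25).**  125 cases / 125 controls;
SNP4 and SNP9 are the causal pair, all other SNPs Hardy–Weinberg noise
(MAF ~ U(0.1, 0.4)) independent of the phenotype.  The minority
genotype of a causal SNP is its rare homozygote, with *exact* counts
52/250 and 57/250 (implied minor-allele frequencies ≈ 0.46/0.48, so the
causal SNPs have well-populated three-category distributions).  The
two-locus genotype counts are fixed cell-exactly
(rows SNP4 = 0/1/2 dose, columns SNP9):

    25  37  12        0.750  0.457  0.113
    34  71  19   with 0.438  0.633  0.113   as the penetrance table.
     9  17  26        0.038  0.038  0.962

The penetrance combines a strong rare-hom × rare-hom corner (25/26)
with protective rare-hom margins and a crossing pattern over the common
block; the free entries are solved so that every row and column of
counts × penetrance sums to exactly half the genotype count — the
no-marginal-effect constraint, enforced at validation to 1e-9.  Case
labels are realised by largest-remainder rounding of counts ×
penetrance (seeded tie-break), so totals and the corner cell are exact
in every replicate.  This hybrid is the calibration the study design
requires: the corner gives MARS a deterministic screening gain (6.18)
above the universal-threshold noise ceiling; the dispersed crossing
gives the forest conditional splits in both partner branches (a
corner-only design leaves the causal SNPs ranked *below* the noise by
Gini importance) and gives the logistic scan a strong linear×linear
component; near-extreme but impure cells keep the logistic MLE finite.
With these defaults all three detectors recover the planted pair in
100/100 perturbation replicates at both doses of the robustness
protocol (asserted in the acceptance tests).

**Perturbation protocol.**  `permute_observations(k)` selects k rows
and, for every non-protected SNP column, replaces those rows' genotypes
with independent draws from the column's empirical distribution;
protected columns, unselected rows and the phenotype are bit-identical
to the input.  Resampling (rather than an in-column swap) is used
because with k=2 a swap can be a no-op, defeating the intended noise
dose.

**Anchored cohort (271 × 872).**  33 chronic / 238 acute.  Five SNPs
and three SNP-combinations are anchored to the published 2×2 counts;
a greedy constructive allocator assigns per-sample exposure patterns
per phenotype class — combination cores first (largest first, reusing
already-exposed samples when a single-SNP margin forces overlap), then
round-robin filling of single-SNP remainders, never letting a pattern
complete a combination it is not counted in — with seeded retries and
an exact verification pass; infeasible anchor sets raise a constraint
error naming the violated count.  Non-exposed genotypes at anchored
SNPs and the remaining 867 SNPs are phenotype-independent draws.  Every
anchored table is exact for every seed (tested).

**What the fixtures do and do not show.**  The generators reproduce the
published *margins* (class sizes, anchored 2×2 tables, minority-genotype
frequencies) but necessarily invent everything unpublished: the joint
genotype distribution across anchored SNPs beyond the anchored cells,
linkage disequilibrium (none is simulated), population structure and
genotyping error (neither modelled).  Detector recovery on the planted
simulation therefore demonstrates correctness and robustness of the
engines under the stated design, not power on real LD-structured data;
and the cohort fixture supports exact reproduction of the published
association statistics, but *not* of the published cross-validated tree
metrics (42.4/90.3/86.3/66.4%), which depend on the unpublished 5-SNP
joint distribution — the pipeline reports its own CV metrics on the
fixture for comparison, and the balanced-accuracy identity is asserted
instead.  Likewise the published decision-tree topology is only
structurally emulated.

## Numerical choices and degenerate inputs

Forward-pass candidate gains are guarded by a denominator floor (1e-9)
against collinear candidates and an absolute gain floor (1e-8 × initial
RSS) against re-entering terms after a near-perfect fit.  GCV with
C ≥ N raises a degenerate-model error.  Zero-cell tables use the
Haldane correction (flagged).  Constant responses, single-class
phenotypes, empty feature lists, folds that cannot contain both
classes, and over-budget searches all raise typed errors rather than
degrading silently.  Exact .5 ties in largest-remainder rounding are
broken by an infinitesimal seeded jitter so replicate averages match
expectations.

## Known limitations

* The MARS engine is a faithful re-implementation of the
  forward/backward/GCV scheme specialised to genotypes, not an
  emulation of any commercial engine; categorical basis construction in
  proprietary engines is undocumented, and Friedman's fast update
  tricks are not implemented (the Gram-identity evaluation makes them
  unnecessary at these scales).
* MDR significance is not assessed by permutation testing of the final
  model; the search is selection-only, as in the motivating workflow.
* RF-LR carries the known weaknesses of impurity importance (bias
  toward high-entropy predictors) and of unpenalised logistic fits near
  separation; both are documented behaviors, not bugs, and surface as
  skipped pairs or missed rankings on adversarial designs.
* The cohort allocator is a greedy constructive search with retries; it
  handles the published anchor family and moderate variations, but a
  heavily over-constrained custom anchor set may be rejected as
  infeasible even when a clever assignment exists.
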