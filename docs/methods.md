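# Methods

This note documents the models and procedures implemented in `tnlike`,
the defaults they use, and what the synthetic data do and do not emulate.

## Synthetic cohort generator (`tnlike.synth`)

The generator produces the joint structure the downstream analysis
assumes; it is first-class, tested code, not a fixture.

**Expression.** Proteins are simulated on the log2 intensity scale:
baseline `N(26, 2²)` per protein plus unit-variance residuals, correlated
in block-diagonal modules of 10 proteins with intra-module correlation
0.4 (a stated assumption — real within-group correlation structure is
unknown; both knobs are configurable). Of `n_proteins` (default 1095),
`n_differential` (default 224) carry a TNBC-vs-ER+ mean shift of
`effect_size` standard units (default 1.5) with random sign. The TN-like
group carries the same shift on an `overlap_fraction` (default 0.55)
subset — those are the proteins that separate TN-like from ER-true *and*
belong to the TNBC signature — plus `n_tnlike_extra` (default 20)
TN-like-specific differential proteins outside the TNBC signature. This
mirrors the observed overlap pattern between the two differential sets in
the motivating application; making TN-like and TNBC disagree in direction
on the non-overlap proteins would, by construction, prevent any TN-like
tumour from co-clustering with TNBC.

**Missingness.** Dropout is missing-not-at-random: the dropout probability
is logistic in the pooled abundance rank (steepness 8 by default), with
the intercept calibrated by bisection so the expected missing fraction
equals `missing_rate` (default 0.10). This produces the left-censoring
that justifies downshifted-normal imputation.

**Batch and miRNAs.** A two-batch additive shift (default 0.5 z-units) is
applied; batches are assigned round-robin over a shuffled sample order.
Each of the 90 synthetic miRNAs is a noisy linear readout of one protein
module's mean with a random sign (noise sd 0.5), emulating the positive
and negative miRNA-activity correlations seen in practice; no mechanistic
claim is intended.

**Survival.** Distant-metastasis-free survival is exponential with
constant monthly hazard `λ_g = −ln(S5_g)/60`, calibrated to the 5-year
survival probabilities (default 0.882 / 0.714 / 0.654 for ER-true /
TN-like / TNBC). A `censor_rate` fraction (default 0.3) of samples get a
uniform censoring time on (0, 120] months, and follow-up is capped at 120
months. The exponential form is a single-parameter choice with
closed-form calibration; nothing downstream depends on its shape beyond
the 5-year probabilities.

**Randomness.** One global seed is split into independent substreams
(expression, miRNA, missingness, survival) via `SeedSequence.spawn`, so
runs are bit-reproducible and stages can be regenerated independently.

**What passing tests do not show.** The generator has Gaussian residuals,
exchangeable samples within groups, exact group labels and a clean MNAR
mechanism. Real label-free data have heavier tails, peptide-level
structure, correlated batch/abundance effects and ambiguous receptor
status; results on synthetic data demonstrate the machinery is correct,
not that effect sizes transfer to any real cohort.

## Preprocessing (`tnlike.preprocess`)

Fixed stage order: quantifiability filter → log2 → downshifted imputation
→ per-feature z-score → batch adjustment. The filter keeps features with
≥2 unique peptides detected in ≥75% of samples of at least one group.
Imputation draws each missing entry from
`N(μ_s − shift·σ_s, (width·σ_s)²)` using the sample column's observed
moments, with the widely used defaults shift = 1.8, width = 0.3.
Z-scoring uses the population (n-denominator) standard deviation; the
choice is arbitrary but fixed and documented for reproducibility, and
zero-variance features are set to zero with a warning rather than NaN.
Batch adjustment is a per-feature location/scale standardisation of each
batch onto the pooled feature distribution — a moment-matching correction
chosen because it is exactly testable (post-condition: equal batch means
to 1e-9); an empirical-Bayes correction can be substituted upstream since
stages exchange plain matrices. Whether z-scoring precedes or follows
batch correction is genuinely ambiguous in practice; the default order
applies z-score first and is configurable by calling the steps directly.

SRM quantification reduces three light/heavy transitions to a protein
value by the median light/heavy ratio after discarding transitions with
either channel ≤ 10 intensity units; interference-flagged transition sets
may carry fewer than three.

## Differential expression (`tnlike.diffexp`)

The SAM d statistic divides the mean difference by the pooled standard
error plus a fudge factor `s0`. `s0` is chosen over the 0, 5, …, 100th
percentiles of the per-feature standard errors to minimise the
coefficient of variation of the median |d| across ten standard-error
quantile windows. The permutation null shuffles labels (plain, not
balanced, since group sizes are typically unequal); if fewer distinct
label arrangements exist than requested permutations they are enumerated
exactly, making the result deterministic. `π0` is estimated as the
fraction of observed d inside the central 50% of the permuted null,
divided by 0.5 and capped at 1. Per-feature q-values are running minima
of FDR over thresholds, hence monotone in |d|; all-constant features get
q = 1 by convention.

Sample clustering uses 1 − Pearson correlation distance with average
linkage and cuts the dendrogram at the root into exactly two clusters;
the cut rule is a design choice (the dendrogram's "two main clusters").
The cluster holding the TNBC majority defines the TN-like side; an exact
tie is refused rather than broken arbitrarily.

## Graphical models (`tnlike.network`)

All features (proteins and miRNAs, z-scored) are treated as jointly
Gaussian. The forest stage is Kruskal's algorithm over candidate edges
scored by `ΔBIC = n ln(1 − r²) + ln n`; only negative-gain edges that
join distinct components are added, which provably minimises total BIC
among forests because the decomposable BIC is edge-separable on forests.
The stepwise stage adds, among absent edges whose addition keeps the
graph chordal (checked with a chordality test), the edge with the most
negative exact BIC difference computed from the clique/separator
determinant decomposition `n(Σ_C ln det R_C − Σ_S ln det R_S) + |E| ln n`;
it is forward-only (no deletions), matching the behaviour of standard
stepwise decomposable selection, and stops when no addition lowers BIC.
The stepwise search recomputes the full decomposition per candidate and
is therefore intended for the moderate feature sets that reach it (the
pipeline applies it only below 40 features by default).

Functional nodes are connected components; components larger than
`max_size` (default 30 — our construction, the original splitting rule
being unspecified) are split by repeatedly removing the
highest-betweenness edge. Node activity is the per-sample mean of member
*protein* expression; miRNA members are excluded from the mean and
instead tested for Pearson correlation with the activity. Group
comparisons of activity use the Mann-Whitney U by default (robust to
non-normal activity distributions), with Welch's t available.

## Compound covariate classifier (`tnlike.classify`)

Per-feature variances are shrunk toward an inverse-gamma prior fitted
across features by the method of moments (shape `a = 2 + 1/CV²`, scale
calibrated so the prior mean variance matches the observed mean); the
shrunken variance `σ̃² = ((n−2)s² + 2ab)/(n−2+2a)` is a weighted average
of `s²` and `b`, and the t statistic uses `df = n−2+2a`. Fitting the
observed `s²` rather than the latent variances slightly inflates the
estimated dispersion, which only makes the shrinkage conservative. With
fewer than 50 features, or degenerate moments, the fit falls back to no
shrinkage (`a = 0`, the ordinary pooled t-test).

The classifier selects features at p < 0.05, scores samples by the
t-weighted sum, and thresholds at the midpoint of the two class-mean
scores. LOOCV repeats prior fitting, selection and fitting in every fold;
folds with empty selection count as misclassifications. The permutation
p-value uses the add-one estimator `(1 + hits)/(1 + n_perm)` with ties
(permuted error ≤ observed) counted as hits, so p is never zero. External
application drops absent features (at least half must be present) and
recomputes the threshold from stored per-feature class means.

## E-Flux FBA (`tnlike.fba`)

GPR rules are parsed with "and" binding tighter than "or" and evaluated
with OR = sum, AND = min. Genes missing from the abundance map are
dropped from their parent operator — "no evidence", not zero — because a
zero would block every complex containing an unmeasured subunit; a rule
with no measured gene leaves its reaction unconstrained. Per tumour, rule
values are divided by their maximum and cap the bounds (upper `v·U`,
lower `−v·U` if reversible else 0, with U = 1 dimensionless), so
objective values are comparable *between* tumours only, not absolute
growth rates. The LP is solved with HiGHS; the objective value is the
contract, while flux vectors are generally non-unique and only asserted
where an oracle proves uniqueness.

The bundled `toy_warburg` network lumps glycolysis, glutaminolysis,
lactate export, an oxidative (TCA + OXPHOS) step, precursor synthesis, a
biomass sink, and an ATP-maintenance reaction carrying a constant, highly
expressed housekeeping GPR. The housekeeping rule anchors each tumour's
normalisation maximum: without it, uniformly elevated glycolytic
expression would cancel out of the per-tumour normalisation (and depress
the *relative* oxidative cap), a genuine property of max-normalised
E-Flux worth remembering when interpreting results. With the oxidative
step capped, ATP demand forces glycolytic flux beyond the oxidative
capacity and the surplus pyruvate must exit as lactate — the Warburg
overflow is then a mass-balance necessity, checkable by LP and by vertex
enumeration.

## Survival (`tnlike.survival`) and cohort tables (`tnlike.cohort`)

Kaplan-Meier, log-rank and Cox regression delegate to lifelines; ties use
Efron's method (more accurate than Breslow when event times coincide on
a monthly grid) and p-values are Wald by default. Time is in months and
the 5-year endpoint is S(60) of the right-continuous step function; if
follow-up ends earlier the last value is returned with a warning. Cohort
tables print counts with integer percentages rounded half-away-from-zero;
an exhaustive partition's percentages therefore sum to 100 within one
point per category.

## Pipeline and problem sizes

`run_pipeline` chains the stages on a synthetic cohort and writes TSV/JSON
artifacts plus a manifest (versions, seed, config hash, per-stage shapes);
identical configs reproduce byte-identical numeric outputs. Defaults per
run: 97 tumours × 1095 proteins, 300 SAM permutations, stepwise search
only below 40 network features, classifier permutations off. The
acceptance script uses 310 tumours (150/80/80) for the pipeline metrics —
comfortable power for the survival and growth comparisons — and 5000 per
group for the survival-calibration check; these sizes are the package's
own choices balancing Monte-Carlo error against quick reproducibility.

## Known limitations

* Batch correction is moment matching, not empirical Bayes; with few
  samples per batch it over-fits batch moments.
* The stepwise graphical-model search is exact but O(p²) per added edge;
  it is not meant for thousands of features.
* The variance-prior fit uses moments, not maximum likelihood; with very
  heavy-tailed variance distributions it under-shrinks.
* The toy metabolic network is a deliberately small caricature for exact
  testing; genome-scale analyses should load an SBML reconstruction and
  supply their own gene-identifier mapping.
* Synthetic miRNAs are linear module readouts; no claim of biogenesis or
  targeting mechanism is made.
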