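# Methods

## Model and procedure

The pipeline treats a case-control study with three linked data layers:
a participants × food-groups intake table (g/day, from a food-frequency
questionnaire aggregated to ~33 groups), a samples × genera 16S
relative-abundance table, and a covariate/outcome table. Five stages run
in sequence; each is usable on its own.

**Dietary networks.** Intakes are transformed x ↦ log10(x + 1) (zero
intake maps to exactly 0) and summarized by their correlation matrix S —
the penalty range 0.96–0.09 is only meaningful on a standardized scale,
so S is always a correlation matrix. The graphical lasso minimizes
−log det Θ + tr(SΘ) + λΣ_{i≠j}|θ_ij| (diagonal unpenalized, matching the
scikit-learn solver that backs `fit_glasso`) at every λ of a log-spaced
decreasing path. Three selection rules are provided: `fixed` (reproduce
an externally chosen λ*, e.g. a published 0.37), `ebic` (extended BIC,
γ = 0.5, the default in the analysis scripts: fast and accurate in the
edge-recovery benchmark), and `stability` (StARS: subsample edge
instability 2θ̄(1−θ̄) averaged over edges, monotonized along the path,
smallest λ below the 0.05 instability threshold). Edges are the exact
nonzeros of the selected Θ converted to partial correlations; no extra
pruning — sparsity comes from the penalty. Patterns are connected
components with ≥ 2 nodes; node strength sums |edge weights| (networks
contain negative edges, and the standard strength-centrality convention
uses magnitudes; a signed sum would let opposite-sign edges cancel).

**Pattern scores.** score = log10 Σ_g intake_g · strength_g over the
pattern's food groups, with raw g/day intakes inside the sum ("lg" is
read as log10, consistent with the intake transform). A zero weighted
sum has no defined log; such participants are flagged missing and
excluded from tertiles rather than imputed. Tertile cuts are type-7
(linear interpolation) quantiles of the control scores at 1/3 and 2/3;
all participants are assigned by the same cuts, ties going to the lower
tertile.

**Co-occurrence screen.** Abundances are quantile-binned into n_bins = 4
ordinal levels (coarse nominal categories in the spirit of the
checkerboard score; configurable). For binned vectors x, y the NC-score
is (C − D)/(C + D) over all C(n,2) sample pairs, where C counts
covariations ((x_{s1}−x_{s2})(y_{s1}−y_{s2}) > 0) and D coexclusions
(< 0); tied pairs are excluded from the denominator. This
rank-concordance normalization (a Goodman–Kruskal gamma on binned data)
preserves the documented [−1, 1] range and the covariation/coexclusion
semantics; the original CCREPE package's normalization differs in
detail, and its bootstrap-vs-permutation z-comparison is deliberately
not replicated — a pure permutation null gives exact add-one p-values.
Each null iteration permutes *every* genus column independently,
renormalizes each sample row to sum 1 (breaking associations while
keeping compositional closure), and recomputes the score;
p = (1 + #{|null| ≥ |obs|})/(B + 1), B = 999 by default (199 in the
bundled smoke runs). When screening all pairs, one permuted table per
iteration serves every pair. Genera absent in > 95% of samples are
skipped as non-informative. BH q-values are computed over informative
pairs; candidates are the union of genera in pairs with q < 0.05 and
|NC| > 0.30, both strict.

**Dysbiosis index.** Fold change = mean relative abundance in cases /
mean in controls, on the post-normalization relative scale. Strict
partition at 1 (exactly 1, or an undefined ratio from a zero control
mean, is excluded). MDI = log10((Σ increased + ε)/(Σ decreased + ε))
with ε = half the smallest nonzero abundance in the table — a standard
pseudocount that keeps the index finite when one side is absent from a
sample. Log base 10 is used for consistency with every other log in the
pipeline, and is configurable since the published tertile cut points
(≈3–4.5) cannot disambiguate the base without the raw abundances.
Swapping the increased/decreased sets negates the index exactly (as
ε → 0); multiplying a sample by a constant leaves it unchanged exactly
when ε is scaled along, and to ~ε/Σ otherwise.

**Association models.** Crude ORs use the 2×2 cross-product with Woolf
CIs exp(ln OR ± 1.96√Σ1/cell) and the Haldane–Anscombe +0.5 on every
cell iff any cell is zero — this convention reproduces published
contingency-table CIs to print rounding. Adjusted ORs come from
maximum-likelihood unconditional logistic regression with
indicator-coded exposure levels (Wald CIs); constant covariate columns
are dropped with a warning, suspected separation raises a named error,
and missingness is handled by complete-case analysis with logged
exclusion counts. The trend test replaces the tertile with its median
exposure value (over all participants by default; a controls-only
option exists since either reading of "the median values per tertile"
is defensible) as one continuous covariate and reports its Wald p. The
combined pattern×MDI analysis dichotomizes both exposures (MDI cut from
config; pattern cut defaults to the control median, as no published
convention exists) and contrasts three cells against the joint-low
reference. Interaction is 2·(ll_full − ll_reduced) on one product term
against χ²(1). No multiplicity correction is applied across the many OR
tables; this mirrors common practice in the field and is a documented
limitation.

## Synthetic data: what it emulates, what it does not

`gen_intake` draws latent vectors from N(0, Ω⁻¹) with a known sparse
symmetric positive-definite Ω and maps each coordinate z ↦ 10^(0.4z + 1) − 1
clipped at 0, so the log transform recovers the Gaussian scale and the
planted partial correlations; location 1 and scale 0.4 put intakes in
realistic food-group magnitudes (tens to a few hundred g/day) without
overflow. `gen_microbiome` uses log-normal absolute abundances (σ = 1,
heavy-tailed like 16S genus profiles; baseline means spread over three
decades) with case means shifted by log(fold change), optional latent
factors planting genus co-variation, and per-sample renormalization.
`gen_cohort` draws binary exposures Bernoulli(0.5) and outcomes from a
logistic model with planted main-effect and interaction log ORs; a
continuous covariate can be given an outcome effect and an
exposure-dependence to create genuine confounding. By default it has
neither, so the marginal 2×2 OR equals the planted conditional OR and
crude-table recovery is exact in expectation (with covariate effects a
logistic marginal is non-collapsible and attenuates by a few percent).
One global seed fans out to fixed per-generator substreams, so each
stage can be re-drawn independently and reproducibly.

Not emulated: read-level 16S error, item-level (106-item) questionnaire
structure, zero inflation beyond what log-normal + renormalization
produces, age/sex frequency matching, and real covariate correlation
structure. Passing recovery tests therefore shows the estimators are
correct under their assumed models, not that those models capture every
feature of field data.

## Problem sizes and numerical choices

The test suite and acceptance script size their simulations to run on a
single CPU in minutes: edge recovery at n = 600, p = 33 (a 20-point
penalty path, EBIC); solver cross-checks at p ≤ 5 against a from-scratch
block coordinate-descent implementation (agreement ≲ 1e-10 when the
scikit-learn inner tolerance is tightened to the outer `tol`; the
default `enet_tol` of 1e-4 limits accuracy to ~1e-3); permutation size
checks at 550 null pairs with B = 199; dysbiosis separation at
300/300 samples; logistic recovery at n = 20,000 and calibration over
500 replicates of n = 1,500. The graphical-lasso wrapper treats a
negative reported dual gap as converged (it is roundoff noise at the
optimum) and raises only on a positive gap above √tol. Stability
selection uses a loose subsample tolerance (1e-4) since only edge
indicators are consumed. End-to-end runs are byte-reproducible given a
config and seed; every artifact is plain TSV/GraphML/JSON.

## Known limitations

- Permutation p-values within one table share permuted tables across
  pairs; this is exchangeable but introduces mild dependence between
  pair p-values (as in the original compositional-permutation scheme).
- The NC-score normalization is a gamma-type concordance, not the
  original package's exact variant; absolute score values are therefore
  not directly comparable to that implementation, though the selection
  thresholds operate on the same [−1, 1] scale.
- Adjusted-OR columns of published tables require the raw cohort
  (individual-level covariates) and are not reproducible from printed
  counts; the pipeline's adjusted models are validated by parameter
  recovery on synthetic cohorts instead.
- Fold-change partitioning ignores estimation uncertainty: a genus with
  fold change 1.001 is "increased". This follows the published
  definition; a shrunken or tested variant would change the MDI.
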