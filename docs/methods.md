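# Methods

This note documents the models, conventions and numerical choices behind
`nmrpath`, and what the synthetic-data tests do and do not establish.

## Input model and preprocessing

The pipeline starts from bucketed 1D ¹H spectra: a samples × buckets
intensity table on a strictly decreasing, uniform ppm axis (default
δ 9.00–0.00 at 0.001 ppm, 9000 buckets). Upstream steps — FID processing,
phasing, baseline correction, chemical-shift referencing — are assumed
done and are out of scope.

Default processing order is **exclude → align → normalize**:

* `exclude_region(4.6, 5.7)` sets the residual-water buckets exactly to
  zero (zeroing, not deletion, so the axis geometry is preserved and the
  operation is idempotent).
* `align_segments` applies, per ppm segment, the integer circular bucket
  shift (|shift| ≤ `max_shift`, default 5) maximizing cross-correlation
  with the pointwise **median** spectrum; ties prefer the smallest shift.
  The pipeline tiles the axis into ~0.1-ppm segments so that
  signal-specific misalignment is corrected, not just a global shift. This
  is a deliberately simplified, fully specified stand-in for interval
  correlation-shifting alignment; sub-bucket misalignment (≤ half a
  bucket) remains by construction.
* `normalize_total_sum` scales each spectrum to a constant integral of
  100. Normalizing after exclusion guarantees the water region contributes
  nothing to the total. The order is configurable; normalization is
  scale-per-row and alignment is shift-per-segment, so the two nearly
  commute — the choice matters only through the median reference.

Total-sum normalization **closes** the data: bucket values become shares
of the total. Two consequences surface repeatedly and are intentional,
since any total-sum-normalized study has them: (i) relative integrals
track c/Σc, not c; (ii) a strong group effect on a few metabolites induces
an anti-correlated "closure" response in all others, which is a genuinely
class-linked signal (it survives a class-orthogonal filter, correctly).

All operations are pure; provenance (operation + parameters) accumulates
in the matrix metadata.

## SRV clustering

The coupling landscape is the Pearson correlation, across samples, of each
consecutive bucket pair; zero-variance buckets contribute correlation 0
(which breaks runs). Clusters are maximal runs of boundaries at or above
`landscape_threshold` (default 0.8); a run of k boundaries spans k + 1
buckets and is kept only if it spans at least
`round(singlet_size / resolution)` buckets (0.01 ppm / 0.001 ppm = 10).
Cluster intensity is the **sum** of member buckets, preserving integral
semantics under the normalization. The threshold can instead be calibrated
as the 95th percentile of boundary correlations inside a declared noise
region. The published supercluster-merging refinement of SRV is not
implemented; this run-merging rule reproduces SRV's role here (dimension
reduction to peak-coherent variables) with a fully testable definition.

Known limitation: when the Lorentzian half-width is ≲ 2 buckets and
residual misalignment is ~half a bucket, the two flank buckets straddling
a peak apex respond with opposite sign to the residual shift, the apex
boundary correlation dips, and one peak can split into two clusters (the
halves then carry jitter-driven intensity noise). Real high-resolution
data show the same behavior. Recovery-style tests therefore render peaks
at a line-to-bucket ratio of ~4, i.e. well-resolved peaks; coarser test
axes scale the linewidth and jitter proportionally so the geometry matches
the default axis.

## Chemometrics

Variables are autoscaled columns (mean 0, sd 1 with ddof = 1);
zero-variance columns are dropped with a warning and recorded.

* **PCA**: NIPALS, deterministic initialization (column of greatest
  variance), convergence when the relative score change is < 1e-10 (max
  500 iterations). Q²(cum) uses naive row-wise cross-validation (7
  contiguous folds after a seeded shuffle; held-out rows are projected on
  the training loadings and PRESS pooled). This Q² is optimistic relative
  to element-wise schemes but ranks models the same way.
* **PLS-DA**: PLS1 on y ∈ {−1, +1} (control coded −1), centered; Q² by the
  same 7-fold scheme predicting held-out y. The response permutation test
  refits under permuted y (X intact), records (|corr(y_perm, y)|, R², Q²)
  per permutation plus the original at corr = 1, and fits regression lines
  through all points. Verdict *valid* iff the original Q² exceeds every
  permuted Q² **and** the Q²-line intercept is below zero.
* **OPLS-DA**: orthogonal components by the orthogonal-projection
  procedure (w ∝ X′y; orthogonal weight = loading minus its projection on
  w; deflate), then a single predictive component tp1 on the deflated
  matrix, oriented so corr(tp1, y) ≥ 0. One orthogonal component is the
  default. VIP is computed on the predictive component only,
  VIP_j = √NV · |ŵ_j|, so mean(VIP²) = 1 exactly. `loading_r` is the
  Pearson correlation of each (autoscaled, undeflated) variable with tp1.
* **Differential rule**: very significant iff VIP > 1 and
  |r| > r\*(0.01); significant iff VIP > 1 and r\*(0.05) < |r| ≤ r\*(0.01);
  otherwise NS. r\* = √(t²/(t² + df)), df = n₁ + n₂ − 2, reported to three
  decimals. Direction is the sign of `loading_r` (tp1 points toward the
  +1 class).

  Because r is measured against a *fitted* score, the rule is
  anti-conservative under the null when variables are few relative to
  samples: with ~40 variables at 43 samples the false-very-significant
  rate is ~5%, falling to ~1.5% at the study-typical dimensionality of
  ~150 SRV clusters. Null-calibration tests therefore run at 150
  variables, 11 vs 32 samples.
* Component loading vectors are signed so their largest-magnitude element
  is positive; scores plots are reproducible only up to this convention.
* The univariate battery uses one-way ANOVA (scipy) with Tukey–Kramer
  multiple comparisons (statsmodels, studentized range with unequal n) and
  a metabolite-wise z-score matrix (ddof = 1) for heatmaps. The linear
  classifier boundary on 2-D score spaces is an equal-covariance linear
  discriminant (scikit-learn, SVD solver); a flag records when the pooled
  covariance was effectively singular.

## R-STOCSY and OR-STOCSY

C = X′X/(NS − 1) on the autoscaled cluster matrix equals pairwise Pearson
correlation; it is clipped to [−1, 1], symmetrized and given a unit
diagonal to absorb roundoff. Edges are all pairs with |r| ≥ 0.9 (the
threshold applies to |r|; the sign is retained for display). Cluster →
metabolite assignment is by maximal ppm-window overlap, ties toward the
nearer window midpoint; clusters overlapping no window are *unassigned*.
Inter-metabolite edges are deduplicated to unique metabolite pairs
(strongest |r| kept) for the network stage.

The **orthogonal filter** is an orthogonal signal correction: each column
of X is projected onto the orthogonal complement of y, the leading
principal component of that projection is the orthogonal score (exactly
uncorrelated with y by construction), and its rank-one contribution is
deflated from X; columns are then re-autoscaled so C stays a true
correlation matrix. This PCA-based extraction was chosen over the
OPLS-style one deliberately: the OPLS orthogonal weight is derived from
the predictive loading and only captures orthogonal variation that leaks
into the predictive score, so a strong confounder uncorrelated with X′y
is provably left in place; the principal-component form targets dominant
systemic variation directly, which is the filter's purpose. The filter
removes the *linear* part of a latent factor — a log-normal factor with
large log-sd keeps a shared nonlinear remainder (for log-sd 0.4, ~8% of
the variance), so near-perfect removal requires factors in the near-linear
regime (log-sd ≲ 0.2).

## Networks and pathway impact

KGML-dialect files contribute compound nodes, enzyme nodes (gene/ortholog
entries collapse to enzymes; map/group entries are skipped) and
compound–enzyme edges from reactions (an enzyme links to each substrate
and product) and compound-typed relation elements. Fragments merge by node
id into one bipartite biograph; pathway membership accumulates on nodes
and edges; conflicting node types across files are an error. Edges are
unweighted and undirected.

A stage's perturbed network is the union of **all** shortest paths (not
one arbitrary path) between each correlated metabolite pair — determinism
and the multiple-intermediates structure require the full set. Pairs
beyond `max_len` (default unlimited) or unreachable are skipped and
reported. Metabolites absent from the pathway files (lipoprotein signals
and the like) stay as *external* nodes holding only their correlation
edges. Node roles: correlated-measured (pair endpoints), intermediate
(interior metabolites = NMR-invisible), enzyme, external.

Pathway impact works on the pathway's metabolite projection (metabolites
adjacent iff they share an enzyme in that pathway): impact = Σ betweenness
over hit metabolites ÷ Σ betweenness over all pathway metabolites, with
unordered-pair betweenness (the convention cancels in the ratio); if every
centrality is zero (complete or 2-node pathways) the fallback is
hits/size. The hit set is the measured-and-correlated metabolites of the
stage's network, not intermediates (configurable). Enrichment p is the
hypergeometric upper tail with the biograph's metabolite set as the
universe; no multiple-testing correction by default (a Benjamini–Hochberg
column is optional). A pathway is significantly altered when impact ≥ 0.3
and it has at least one hit.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the statistical structure the analysis assumes:

| parameter | default | meaning |
|---|---|---|
| group sizes | 32/11/15/15/11 | control + four stages, unbalanced |
| axis | δ 9.00–0.00, 0.001 ppm | 9000 buckets |
| lineshape | Lorentzian, half-width 0.002 ppm | multiplets of 1–3 peaks |
| concentrations | log-normal, base log-sd 0.3, residual log-sd 0.2 | positivity, realistic skew |
| group effects | multiplicative on the log-mean | stage-graded up/down shifts |
| correlations | latent factors on log-concentrations | factor-model closed form available |
| jitter | per-sample, per-metabolite ppm offset, sd 0.002 | exercises alignment |
| noise | additive Gaussian, sd 0.005 | ~100:1 peak SNR, typical of serum CPMG |
| background | unassigned broad signatures | keeps SRV coverage < 100% |

Factor-mate residual log-sds default lower (0.05) so planted correlations
survive the log-normal transform above |r| = 0.95: for loadings l₁, l₂,
factor sd s and residual sds r₁, r₂ the log-scale correlation is
l₁l₂s² / √((l₁²s²+r₁²)(l₂²s²+r₂²)), and the concentration-scale value is
slightly attenuated by exponentiation.

Not emulated: FID-domain effects (phase and baseline distortion), J-coupling
fine structure beyond fixed multiplet amplitude patterns, chemical-shift
dependence on pH/ionic strength, and real biochemical correlation networks.
Passing the recovery tests therefore shows the inference chain is correct
*given* the assumed spectral and statistical model — not that the model
captures all failure modes of real sera.

Toy pathway files chain measured metabolites with unmeasured intermediate
compounds (measured–measured graph distance 4), with shared compounds
between consecutive pathways, so shortest-path extraction, intermediate
recovery and impact scoring are all exercised with known answers.

## Test and acceptance problem sizes

Recovery studies run at two groups of 200 samples, 12–24 single-peak
metabolites, a 0.002-ppm axis with 0.008-ppm half-widths (the well-resolved
regime discussed above), 10 seeded replicates; the pathway-recovery study
uses two groups of 50 and four toy pathways over 10 seeds; null
calibration uses 50 replicates of 11-vs-32 samples with 150 variables;
permutation tests use 100–200 permutations. These sizes keep the full
suite around a minute while leaving the statistical margins wide.

## Known limitations

* The SRV rule implements run-merging only; no supercluster aggregation.
* PCA Q² is the naive projection form.
* The differential rule's null rate depends on NV/NS (see above); treat
  very-significant calls at small NV with caution.
* The orthogonal filter removes linear factor structure only.
* Multi-class discrimination is out of scope; all supervised analyses are
  pairwise stage-vs-control, as the workflow prescribes.
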