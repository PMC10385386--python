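# Methods

This note defines every quantity the package computes, the conventions and
defaults behind them, and the numerical choices that matter. Units are
given at first use; all defaults are surfaced as named keys on
`pipeline.RunConfig`.

## Data model

A **feature** is one ion observed by ion-mobility mass spectrometry:
an m/z (Th), a collision cross section (CCS, Å², drift-tube, N₂), and one
abundance (counts) per substance extract. `matrix.FeatureMatrix` holds the
features × substances table plus per-feature metadata (optional molecular
formula and homologous-series id). Ions are treated as protonated
molecules `[M+H]+`; the neutral mass is `mz − 1.007276466621`
(charge-exchange `M+.` is available via `proton_offset=0`).

## Chemical characterization

**Abundance filter.** A feature is retained if it reaches 5000 counts in
at least one substance (`filter_by_abundance`).

**Anchor matching.** Known constituents (name, formula, reference m/z and
CCS) are matched to features when both `|Δm/z| ≤ 5 ppm` and
`|ΔCCS| ≤ 1 %` (inclusive). Assignment is one-to-one, greedy by ppm
distance with CCS distance as tie-break.

**Homologous series and formula propagation.** Features are grouped by
the Kendrick mass defect of their neutral mass,

```
KM  = m × 14 / 14.01565        (CH2 Kendrick base)
KMD = round(KM) − KM
```

with single-linkage grouping at a 0.0005 tolerance. Exact CH₂ homologues
share a KMD, so each group is a candidate alkylation series. Within a
series containing an anchored feature, each member's formula is the anchor
formula ± k CH₂ where `k = round((m − m_ref)/14.0156500641)` (the *exact*
CH₂ mass; the rounded literature constant is used only for the Kendrick
rescaling), accepted when the mass residual is within 5 ppm. A series
whose CCS is not strictly increasing with mass fails physical validation:
its features keep their series id but formulas are withheld.

**Double bond equivalence.** `DBE = #C + 1 − #H/2 + #N/2`; divalent O and
S do not contribute.

**Composition bookkeeping.** Abundances are normalized per substance to
percent of total (sums to 100 within 1e−9). Features fall into three
half-open bins — `[1 %, ∞)`, `[0.1 %, 1 %)`, `[0, 0.1 %)` — that
partition the feature set. The share of abundance carried by ≥1 %
features is compared against the 80 % characterization rule used for
complex-substance registration. Class-level presentations aggregate
percent abundance by carbon number × DBE (`carbon_dbe_profile`) or by
homologous series (`series_share_profiles`).

## Bioassay normalization and points of departure

**Normalization.** Every well is expressed as percent of the mean of the
method-blank wells on the same plate × endpoint:
`normalized = raw / mean(blank) × 100`, so the vehicle level is 100 %.
QC gates: vehicle controls within ±10 % of 100, and duplicate-plate
Pearson and Spearman correlations > 0.8 with p < 0.05.

**Hill fit.** Pooled concentration series (µg/mL; 5 half-log dilutions,
1000→0.1 generally, 500→0.05 for neurons) are fitted with
`R(c) = bottom + (top − bottom)/(1 + (c/EC50)^s)` on log10 concentration,
slope bounded in [0.1, 10], three EC50 starts. A series whose observed
span is below 5 % is flat (not converged).

**EC10 POD.** The POD is the smallest concentration where the fitted
response departs 10 % from the vehicle mean, solved analytically from the
fitted parameters in both directions. Censoring conventions:

- *No 10 % departure at or below the highest tested concentration* (or a
  flat series near the vehicle level): right-censored at 10 × the highest
  tested concentration, placing the substance at the least-bioactive end
  of downstream scaling.
- *Departure already present at the lowest tested concentration* —
  including a flat series far from the vehicle level, i.e. fully
  responding everywhere in range: POD floored at the lowest tested
  concentration, uncensored. Maximal observed potency must never be
  mapped to the inactive end; an early version of the workflow made that
  error and it inverts every downstream ranking whenever one very potent
  substance is present.

Uncensored PODs therefore always lie within the tested range.

## Potency indexing (ToxPi)

Per endpoint, with `POD_min`/`POD_max` the panel extremes (censored
values included at their censoring value):

```
value = 1 − (log10 POD − log10 POD_min) / (log10 POD_max − log10 POD_min)
```

so the most potent substance scores 1, the least 0, and the geometric
midpoint 0.5; a degenerate range scores 0. Endpoints are grouped by cell
type into equally weighted slices; the cell-type score is the weighted
slice mean. The overall score log10 min–max rescales each cell-type score
across substances (zero scores map to 0 directly, as log-undefined
no-activity) and averages them with equal weights.

## Grouping

Substances are clustered agglomeratively (`scipy.cluster.hierarchy`;
Euclidean distance, complete linkage by default) on standardized
homologous-series share profiles. Raw per-feature percent profiles are
deliberately not used: independent per-feature abundance noise and any
strongly co-varying feature cluster dominate Euclidean distances and bury
class-level composition (measured: ARI ≈ 0 against planted categories on
raw profiles vs ≈ 0.84 on standardized series shares). Dendrograms export
to Newick; flat cuts use `fcluster(..., maxclust)`; concordance with
reference categories is scored by adjusted Rand index plus per-cluster
purity.

## Chemistry → bioactivity association

**Model.** Multivariate ridge regression `B = (XᵀX + λI)⁻¹XᵀY` with
X the substances × features matrix of percent abundances (features > 1 %
in at least one substance, strictly), Y the substances × scores matrix
(cell-type scores plus overall). Columns are centered and scaled to unit
variance (sample SD, n−1). For p ≫ n the equivalent dual form
`B = Xᵀ(XXᵀ + λI)⁻¹Y` is used (n × n solve instead of p × p).

**Tuning.** λ is selected from `10^(−1.0 … 6.0)` in 0.1 steps (71 values)
by leave-one-out cross-validation minimizing the pooled standardized MSPE
across responses.

**Scaling inside the CV loop.** Predictor columns are re-centered and
re-scaled *within each training fold*, and the held-out row is transformed
with the training-fold statistics. Scaling X once on the full data is
exactly degenerate at this scale: after full-data centering with p ≫ n,
the held-out row equals minus the sum of the training rows, so small-λ
ridge reproduces the held-out value identically (measured null CV
correlation 0.99998 at n=25, p=200). Responses are scaled once on the full
data — this is permutation-invariant and avoids the complementary
artifact where fold-dependent response back-transformation anticorrelates
predictions with held-out values at large λ. The full-data X-scaling
variant remains available (`scale_in_fold=False`) for comparison.

**Inference.** Substance labels of Y are permuted `n_perm` times
(default 1000; identity excluded), the entire tuning + LOOCV procedure is
re-run per permutation, and the observed per-response CV Pearson
correlation r is reduced to `z = (r − E_null r)/SD_null r`, referred to a
standard normal, two-sided, floored at `1/(n_perm + 1)`. Responses are
corrected by Benjamini–Hochberg (significance at q < 0.1). Per-fold
eigendecompositions of the leave-one-out Gram matrices depend only on X,
so they are computed once and reused across the λ grid and all
permutations; 200 permutations over the full grid take ~0.1 s at n=25,
p=200. Feature attribution is deliberately simple: per-feature Pearson
correlation with each score, ranked by |r| against the overall score.
The reverse analysis (predicting chemistry from bioactivity) reuses the
identical machinery with roles swapped.

## Synthetic data generator

The generator exists to exercise the workflow with known ground truth,
not to emulate any instrument. A panel is 25 substances in two categories
(four subcategories sized 7/6/6/6). Features are CH₂ series from eight
base formulas (paraffinic to five-ring aromatic, 12 extensions each by
default); CCS follows `a + b·mass^(2/3)` within a series with 0.3 %
noise; abundances are lognormal(8.5, 1.2) with an `exp(−0.12 k)`
alkylation envelope. Two planted structures carry signal: high-DBE
(≥ 7) series are enriched ×4 in the second category (the between-category
compositional difference), and one short heavy-aromatic series (C₂₂H₁₂ + 6
homologues, 7 features) co-varies across substances through a shared
lognormal(0, 1) content factor — a realistic co-occurring constituent
cluster and the default bioactivity driver set. Plate simulation maps the
standardized driver burden z to `log10 EC50 = 1.5 − z` (+ per-endpoint
jitter, SD 0.1), generates decreasing Hill responses (slope 1.5) with
multiplicative lognormal noise, duplicate plates, method-blank/DMSO/media
control wells, and exports the analytic EC10 as recoverable truth.

## Numerical notes

- Ridge solves use `solve`/Cholesky-backed linear algebra, never explicit
  inverses; λ = 0 is allowed only for full-rank XᵀX.
- Permutation p-values are exact-normal approximations on z, not
  empirical tail counts; with n_perm ≥ 200 the null rejection rate at
  α = 0.05 calibrates to 5 % ± 2 % (verified over 400 null datasets).
- All generator randomness flows from one integer seed through named
  `SeedSequence` spawn keys, so each stream (features, CCS, plates) is
  independently reproducible.
- Constant predictions (e.g. at very large λ) get correlation 0 rather
  than NaN.

## Limitations

- The generator's noise model is simplistic (i.i.d. lognormal abundances,
  no instrument drift, no missing features), so it cannot benchmark
  peak-picking or alignment — only the downstream workflow.
- Formula propagation requires at least one correct anchor per series;
  series sharing a KMD within tolerance (e.g. two CnH2n+2 families) merge
  and fail CCS validation rather than splitting.
- The permutation test treats responses as exchangeable across
  substances; hierarchical panel structure (e.g. replicated substances)
  is not modeled in the null.
- Attribution by marginal correlation inherits compositional-closure
  shadows: features anti-correlated with a true driver through the
  percent constraint can rank high with the opposite sign.
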