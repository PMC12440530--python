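# Methods

This note records the statistical model behind each stage, the defaults and
why they were chosen, what the synthetic generators do and do not emulate,
and the numerical conventions.

## Two-sample MR model

Each instrument j has a true effect γ_j on the exposure and, under the
linear causal model with horizontal pleiotropy α_j, an outcome effect
β·γ_j + α_j. The observed summary statistics are
β̂_Xj ~ N(γ_j, se_Xj²) and β̂_Yj ~ N(β·γ_j + α_j, se_Yj²), with the two
GWAS samples independent. Exposures are in SD units, binary outcomes on the
log-odds scale, so β is a log-OR per SD and exp(β) an OR.

Instrument validity requires relevance (enforced by the p-threshold and the
F = β̂²/SE² ≥ 10 filter), independence from confounders, and exclusion
restriction (no α_j). Because the last is untestable per variant, the
pipeline layers diagnostics: Cochran's Q for heterogeneity, the Egger
intercept for directional pleiotropy, and MR-PRESSO for outlying variants,
and additionally removes instruments associated with the outcome at
p < 5×10⁻⁶ before estimation.

## Instrument selection and harmonization

* Primary threshold 5×10⁻⁸; if fewer than 3 instruments survive clumping
  and the F filter, selection restarts from scratch at 5×10⁻⁶ (the relaxed
  set supersedes the primary one; the tier is recorded per exposure).
* Greedy clumping: repeatedly retain the smallest-p unretired variant and
  retire same-chromosome variants within ±10,000 kb with r² ≥ 0.001. Ties
  on p break by position then rsid, making the result order-independent. A
  missing r² for a within-window pair counts as r² = 1 (retired): with
  "stringent" clumping intended, silently keeping a possibly correlated
  variant is the worse error.
* Palindromic (A/T, G/C) variants are ambiguous when the exposure
  effect-allele frequency lies in [0.42, 0.58] or is missing; those are
  dropped. Outside the band, orientation comes from allele labels and a
  strand flip is inferred when the aligned outcome frequency falls on the
  opposite side of 0.5. Strand-complement resolution is attempted only for
  non-palindromic pairs, where it is unambiguous.
* No proxy variants: instruments absent from the outcome table are dropped
  and logged.

## Estimators

* **IVW**: weighted regression through the origin with weights 1/se_Y².
  The primary model is multiplicative random effects — the fixed-effects SE
  times max(1, √(Q/(k−1))) — which inflates uncertainty under
  heterogeneity but never deflates it; p-values are normal.
* **MR-Egger**: the same regression with an intercept, after orienting
  every variant to β̂_X ≥ 0. Slope and intercept p-values use the t
  distribution with k−2 df (an intercept is estimated from few points).
  The intercept test assumes exposure-side measurement error is small
  relative to the spread of instrument strengths (the NOME condition,
  I²_GX near 1). When instrument strength is nearly uniform — all
  instruments hovering just above the selection threshold — regression
  dilution leaks the causal slope into the intercept and the test
  over-rejects; the calibration study below therefore simulates strong,
  spread-out instruments, and users with low I²_GX should read the
  intercept test cautiously.
* **Weighted median**: ratio estimates r_j = β̂_Yj/β̂_Xj with first-order
  inverse-variance weights w_j = β̂_Xj²/se_Yj² (exposure-side error ignored
  in the weight, the common default); the estimate interpolates the
  weighted CDF at 0.5. The SE is a parametric bootstrap (default 1000
  draws; both β̂_X and β̂_Y are resampled with their SEs) with a mandatory
  seed — there is no hidden global random state anywhere in the package.
* **Cochran's Q**: Σ w_j (r_j − β̂_IVW)², computed in the algebraically
  identical form Σ ((β̂_Yj − β̂·β̂_Xj)/se_Yj)², which remains defined for a
  zero exposure effect; p from χ²(k−1).
* **MR-PRESSO**: the observed residual sum of squares sums
  (β̂_Yj − β̂₍₋j₎·β̂_Xj)² over leave-one-out fixed-effects IVW slopes
  β̂₍₋j₎. Simulations redraw both sides from their reported SEs under the
  no-pleiotropy model; Monte-Carlo p-values carry the +1 correction, so the
  smallest attainable global p is 1/(n_sim+1) and the smallest per-variant
  Bonferroni-corrected outlier p is k/(n_sim+1) — with the default
  n_sim = 1000 an outlier can clear α = 0.05 up to k = 50 instruments
  (n_sim = 300 could not even at k = 20). Variants are canonicalized
  (oriented β̂_X ≥ 0, lexicographically sorted) before the draws so the
  simulated p-values are exactly invariant to input order and joint sign
  flips; outlier indices are reported in input order. The distortion test
  compares the raw-minus-corrected slope shift with shifts from removing
  equally many random variants (1000 subsets, two-sided); with no outliers
  flagged the corrected estimate equals the raw one and the distortion p
  is 1 by convention.

## Meta-analysis and the exclusion cascade

Cohort-level estimates pool per method with inverse-variance fixed-effects
weights; heterogeneity across cohorts is again Cochran's Q. Before pooling,
a cohort analysis is excluded when its Egger intercept p < .05, PRESSO
global p < .05, or it used fewer than 4 instruments (PRESSO's minimum).
After pooling, the IVW meta-estimate is flagged inconsistent when a
nominally significant (p < .05) weighted-median or Egger meta-estimate has
the opposite sign — an operationalization of "consistency with sensitivity
analyses" chosen because it is deterministic and conservative; the
sensitivity methods act as consistency checks and are not pooled into the
headline estimate. Bonferroni families (416 taxa, 1178 metabolites by
default) are configurable; labels are significant (p < α/m), suggestive
(α/m ≤ p < α), null.

## LD-score regression

For variant j with LD score ℓ_j, E[z²_j] = n·h²·ℓ_j/M + 1 and
E[z₁j·z₂j] = √(n₁n₂)·rg·√(h²₁h²₂)·ℓ_j/M + c. Three weighted regressions on
ℓ (free intercepts; weights the 1/max(ℓ,1) heteroskedasticity heuristic —
the reference implementation's iterative weighting is deliberately out of
scope) give h²₁, h²₂ and the genetic covariance; rg = gcov/√(h²₁h²₂). The
SE is a delete-one jackknife over 200 contiguous equal-size blocks (rows
sorted by genomic position, or generation order for synthetic data)
applied to the full rg pipeline; p is two-sided normal. QC before merging:
non-SNP alleles, MAF < 0.01, duplicate rsids (first kept), strand-ambiguous
variants. Binary traits stay on the observed scale (no liability
conversion). A nonpositive heritability slope leaves rg undefined with an
`unstable_h2` flag — mirroring real microbiome traits whose heritability is
too weak for LDSC — and out-of-range rg is flagged, never truncated.

## Mediation

ME = EM×MO with first-order delta-method SE
√(MO²·se_EM² + EM²·se_MO²); the second-order term se_EM²·se_MO² is omitted
because the first-order form reproduces published mediation tables computed
the same way, and the term is negligible at these SE magnitudes. The
mediated proportion ME/EO is reported as a percentage and never clipped;
sign-discordant ME vs EO and proportions above 1 are flagged. When
replaying a published table, path SEs are recovered from printed 95% CIs as
half-width/1.96, and the printed-style proportion divides the 4-dp-rounded
ME by the printed total effect (published tables round before dividing;
full-precision proportions are reported alongside). The mediation
qualification gate in the pipeline requires nominal significance (p < .05)
on both legs with clean diagnostics.

## Synthetic data

The generators emulate the summary-statistics layout of a three-layer
study: a microbiome-scale exposure GWAS (n = 5959, SD units,
se = 1/√(2n·eaf(1−eaf))), a metabolite-scale mediator GWAS (n = 8299), and
large binary outcome cohorts (n = 420,000, log-odds scale, constant
se = 0.02 — the effective-sample-size SE of a ~2% case-rate GWAS of this
size at intermediate frequency). Instrument true effects draw |z| uniform
in 6.5–11: strong enough to pass 5×10⁻⁸ with high probability, weak enough
that true causal signals do not trip the outcome-association exclusion
filter. Pleiotropy scenarios: none, balanced N(0, sd), directional
N(mean, sd), or planted outliers of ±magnitude×se_Y at recorded indices.
Three structural variants are planted deterministically (an ambiguous A/T
palindrome at frequency 0.5, a swapped allele orientation in every outcome
table, an r² = 0.95 duplicate inside the clumping window) so harmonization
and clumping are exercised with exact expected outcomes. The mediation
chain plants two instrument blocks — the exposure's and the mediator's —
with the mediator block reaching the outcome only through the mediator; an
exposure instrument may occasionally reach genome-wide significance on the
mediator through the causal path, which is left in deliberately (real
two-step MR has the same feature). Everything is seeded and
byte-reproducible.

Not emulated: realistic LD panels (LD is an explicit input matrix),
genotype-level sampling, winner's-curse selection beyond the built-in
threshold effect, sample overlap between GWAS, and compositional
microbiome structure. Passing tests therefore demonstrate correctness of
the estimators and plumbing under the stated model, not robustness to
these real-data complications.

## Validation sizes and numerical conventions

The acceptance battery uses: 1000 replicates for IVW, Egger-intercept and
Cochran-Q null calibration (two-sided band 5% ± 2 Monte-Carlo SEs), 500
for PRESSO-global (n_sim = 200, k = 10) and LDSC-rg (M = 2000, 50 blocks)
nulls, 500 for IVW unbiasedness, 200 for end-to-end mediated-proportion
recovery (30 instruments per block), 100 for PRESSO outlier detection
(k = 20, 10× outlier, n_sim = 1000), and 100/50 for LDSC rg recovery
(M = 20,000, 200 blocks). These sizes keep the full battery under a minute
on one CPU while leaving the Monte-Carlo bands tight enough to detect real
miscalibration.

Conventions: positions are 1-based and the clump window is inclusive;
p-values are clamped into (0, 1] where a downstream classifier requires
it; Monte-Carlo p-values always use the +1 correction; the weighted-median
interpolation uses standardized midpoint cumulative weights
(S_j = (cum_j − w_j/2)/Σw); 95% intervals use z = 1.959963984540054;
degenerate exact-fit Egger regressions report p = 1 for a zero coefficient
rather than dividing by a zero SE; seeds are mandatory arguments for every
stochastic routine, and the pipeline derives per-task seeds from the study
seed by hashing (stable across runs and platforms, below 2³¹).

## Known limitations

* The LDSC stage uses the closed-form weighting heuristic, not iterative
  weights or an intercept constraint; estimates are consistent under the
  model but less efficient than the reference implementation.
* The Egger intercept test requires instrument-strength spread (see above).
* Fixed-effects meta-analysis only, matching the target design; no
  random-effects synthesis.
* The distortion test conditions on the number of flagged outliers rather
  than re-running the outlier search per random subset.
* `--threads` is accepted but computation is single-threaded; results are
  independent of its value by construction.
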