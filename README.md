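# mrchain

Two-sample Mendelian randomization (MR) for GWAS summary statistics, with
cross-cohort meta-analysis, LD-score genetic correlation, and two-step
mediation analysis. The package targets studies that chain three layers of
traits — e.g. gut-microbiome taxa → plasma metabolites → a disease such as
osteoporosis — where each causal leg is estimated from a separate GWAS and
the indirect (mediated) effect is assembled by the product-of-coefficients
rule.

## Who it is for

Genetic epidemiologists who have per-variant association tables (rsid,
alleles, effect, SE, p, frequency, n) for an exposure, an outcome in one or
more independent cohorts, and optionally a mediator, and who want the
standard summary-data MR workflow as a tested, scriptable library instead of
an ad-hoc analysis.

## What it computes

**Instruments.** Variants associated with the exposure at p < 5×10⁻⁸
(relaxed to 5×10⁻⁶ when fewer than 3 survive), greedily LD-clumped
(±10,000 kb, r² < 0.001), and filtered on instrument strength
F = β²/SE² ≥ 10. Exposure and outcome effects are harmonized onto a common
effect allele: swapped orientations are flipped, strand complements
resolved, ambiguous palindromic variants (A/T, G/C with allele frequency
near 0.5) dropped, and variants associated with the outcome at p < 5×10⁻⁶
removed to protect the exclusion-restriction assumption.

**Estimators.** For harmonized effects (β̂_Xj, β̂_Yj) with weights
w_j = 1/se(β̂_Yj)²:

* IVW: β̂ = Σ w_j β̂_Xj β̂_Yj / Σ w_j β̂_Xj² — weighted least squares through
  the origin; multiplicative random effects inflate the SE by
  max(1, √(Q/(k−1))).
* MR-Egger: the same regression with a free intercept; a nonzero intercept
  indicates directional pleiotropy (t test, k−2 df).
* Weighted median: the 0.5-quantile of the weight-ordered per-variant ratio
  estimates β̂_Yj/β̂_Xj, SE by parametric bootstrap.
* MR-PRESSO: simulation-based global residual-sum-of-squares pleiotropy
  test, per-variant outlier test, outlier-corrected IVW, distortion test
  (requires ≥ 4 instruments).
* Cochran's Q heterogeneity of the ratio estimates.

**Synthesis.** Per-method fixed-effects meta-analysis across outcome
cohorts, after excluding any cohort analysis with Egger intercept p < .05,
PRESSO global p < .05, or fewer than 4 variants; Bonferroni classification
(significant / suggestive / null) per test family.

**Genetic correlation.** Cross-trait LD-score regression: z₁z₂ (and z², z²)
regressed on LD scores, rg = gcov/√(h²₁·h²₂), SE by delete-one block
jackknife.

**Mediation.** With EM the exposure→mediator effect, MO the
mediator→outcome effect and EO the total effect, the mediation effect is
ME = EM × MO with first-order delta-method SE
√(MO²·se(EM)² + EM²·se(MO)²), Wald 95% CI, and mediated proportion ME/EO.

## Worked example

Reproduce a published mediation row from its printed path estimates
(order *Desulfovibrionales* → the androgen metabolite
5α-androstan-3α,17β-diol monosulfate → osteoporosis):

```python
from mrchain import replay_table

row = dict(exposure="Desulfovibrionales", mediator="3a-diol MS",
           eo=0.1453, eo_lo=0.0064, eo_hi=0.2842,     # total effect (log-OR)
           em=-0.2687, em_lo=-0.4624, em_hi=-0.0751,  # exposure -> mediator
           mo=-0.0494, mo_lo=-0.0772, mo_hi=-0.0216)  # mediator -> outcome
print(replay_table([row])[0])
```

prints

```
{'exposure': 'Desulfovibrionales', 'mediator': '3a-diol MS',
 'me': 0.01327378, 'me_lo': 0.00113652, 'me_hi': 0.02541104,
 'me_p': 0.03207355, 'prop_pct': 9.1354, 'prop_pct_printed': 9.15, 'flags': ''}
```

i.e. a mediation effect of 0.0133 (95% CI 0.0011–0.0254, p = .032): higher
abundance of this sulfate-reducing taxon lowers the metabolite (EM < 0),
lower metabolite raises osteoporosis risk (MO < 0), so about 9.15% of the
taxon's total risk effect flows through the metabolite
(`prop_pct_printed` follows the 4-dp rounding chain of published tables;
`prop_pct` is full precision).

A full synthetic study runs from the shell:

```bash
mrchain simulate-fixtures --out toy --seed 7
mrchain forward-mr --config toy/study.yaml --out toy/results
mrchain mediate    --config toy/study.yaml --out toy/results
mrchain ldsc       --config toy/study.yaml --out toy/results --n-blocks 2
```

`forward_meta.csv` then contains, per exposure and method, the pooled
log-OR, OR with 95% CI, meta-heterogeneity p, and the Bonferroni label;
`mediation.csv` mirrors the mediation table layout above.

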