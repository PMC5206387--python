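# cardioburden

Rare-variant carrier burden, pedigree segregation, survival and matched-pair
expression analysis for congenital heart disease cohorts.

## The problem

Hypoplastic left heart syndrome (HLHS) is a severe congenital heart defect
with strong evidence of genetic contribution but, in most cases, no known
cause. A productive study design for such diseases is a *family-to-cohort*
pipeline: find a candidate gene by filtering variants that segregate with
disease in one multiplex family, then ask whether rare, damaging variants in
that gene are enriched in an unrelated case cohort versus population
controls, and finally ask whether carrier status predicts clinical outcome
and altered expression of related genes. This package implements that whole
pipeline as a tested, reusable library for the α-myosin heavy chain gene
(*MYH6*, encoding α-MHC) in HLHS — but every stage is configurable and works
for any gene and cohort in the same formats.

The stages, and the statistics at their core:

1. **Pedigree segregation filter** — a variant passes iff the alt allele is
   present in every required (affected) relative and confidently absent in
   every excluded (unaffected) relative, under a dominant model; survivors
   collapse to candidate genes (interval map) and are prioritised by heart
   expression.
2. **Carrier burden association** — subjects collapse to carrier status
   (≥ 1 rare, damaging variant in the gene); the 2×2 carrier table
   (a, b; c, d) is tested with a from-scratch two-sided Fisher exact test
   (probability-mass definition, log-factorial arithmetic), with the sample
   odds ratio OR = ad/bc, Woolf 95 % CI
   exp(ln OR ± 1.96·√(1/a + 1/b + 1/c + 1/d)), and percent enrichment
   100·(a/(a+b))/(c/(c+d)).
3. **Transplant-free survival** — Kaplan-Meier curves
   S(t_j) = Π_{i≤j}(1 − d_i/n_i) per genotype group and the Gehan-Breslow
   (generalized Wilcoxon) test, U = Σ_j n_j (d_{1j} − d_j n_{1j}/n_j),
   Var = Σ_j d_j (n_j − d_j) n_{1j} n_{2j}/(n_j − 1), U²/Var ~ χ²(1); the
   at-risk weight n_j emphasises early deaths.
4. **Matched-pair expression** — TPM-normalised transcript levels in
   mutant/wild-type tissue pairs, compared per gene by a paired t-test on
   log₂ ratios (geometric-mean fold change, Benjamini-Hochberg q-values);
   protein-band densitometry is fit with a pair-blocked linear model on
   log(band/GAPDH), reporting the genotype effect as a percent increase.

Because patient-level data for such studies are protected, the package ships
a **synthetic-data module** that generates every input with the statistical
structure the analysis assumes (carrier frequencies 10.5 % vs 2.9 %, a
dominant variant segregating through two affected sibs and an affected
great aunt with an unaffected mother, a 10-vs-62 survival cohort, 8 tissue
pairs with MYH7 planted at 3.46-fold, 4×5 densitometry with a +62 % effect),
together with truth records so every stage can be scored in closed loop.

A transcription of the published table of 21 observed *MYH6* variants (19
distinct) is packaged as `src/cardioburden/data/table1_myh6_variants.tsv`.

## Worked example

```python
from cardioburden import CarrierBurdenModel

res = CarrierBurdenModel.from_counts(20, 170, 31, 1032, gene="MYH6").fit()
print(res.summary())
```

prints

```
Carrier burden test — MYH6
========================================
cases:       20 carriers /   190  (10.5%)
controls:    31 carriers /  1063  (2.9%)
enrichment: 361.0%
Fisher exact (two-sided) p = 1.64e-05
odds ratio = 3.92 (95% CI 2.18–7.03)
```

i.e. carriers of a rare, damaging *MYH6* variant are about 3.6× as frequent
among HLHS cases (10.5 %) as in the reference controls (2.9 %); the exact
test rejects chance at p ≈ 1.6 × 10⁻⁵, and the odds of being a carrier are
about 3.9-fold higher in cases, with a confidence interval well above 1.

The whole pipeline, on synthetic data, from the shell:

```bash
cardioburden all-stages --seed 1 --out demo/
cardioburden table1-report
cardioburden simulate survival --seed 3 --out sim/
cardioburden survival --table sim/survival.tsv --min-age 6
```

`all-stages` runs segregation filtering (recovering the planted gene),
the burden test, the Gehan-Breslow survival comparison and both expression
analyses, writing a combined report.

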