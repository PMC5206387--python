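# Methods

This note documents the models, rules and numerical choices behind each
stage of the pipeline, the assumptions of the synthetic-data generators, and
the limits of what the test suite demonstrates.

## Variant annotation

Variants are described at the protein level (`R443P`, `K850-`, `E1754X`);
the residue number is parsed from the name, and the functional consequence
is classified as *nonsense* (name ends in `X`), *in-frame deletion* (deleted
reference run with length divisible by 3), *missense* (single-residue
substitution) or *other*. α-MHC (1,939 residues) is partitioned into
head/motor (1–778), neck (779–840) and coiled-coil tail (841–1939); the
boundaries are configurable, and any partition consistent with the packaged
table's printed domain labels is accepted — `annotate` raises if the
configured partition contradicts a printed label, since that indicates the
boundaries are wrong for the protein at hand.

**Damaging rule.** Protein-truncating and in-frame indel consequences always
qualify. Missense variants qualify disjunctively: PolyPhen-2 ≥ `pp2_min`
(default 0.5) OR SIFT ≤ `sift_max` (default 0.05). These are the loosest
conventional thresholds under which every record of the packaged table
qualifies (one variant has PP2 0.65 with SIFT 0.11, forcing `pp2_min` ≤ 0.65;
another has SIFT 0.12 with high PP2, forcing the OR-combination). A missense
variant with both scores missing is *indeterminate*, a third state distinct
from benign, because absence of a prediction is not evidence of harmlessness.

**Rarity.** A variant is rare if flagged novel or if its population
frequency is at most `max_freq_percent` (default 0.5 %, comfortably above
the largest frequency in the packaged table, 0.22 %). "Novel" is modelled as
a flag with frequency *missing*, not zero: unobserved is not proven absent.

Coordinates are 1-based inclusive throughout. The in-frame deletion is
stored as printed (`ref="CTT"`, `alt="-"`); `to_vcf_style` converts to
left-aligned VCF convention given an anchor base.

## Pedigree segregation filter

A dominant, incompletely penetrant model: sharing requires allele
*presence* (count ≥ 1), never matched zygosity. Missingness is asymmetric by
design: an untyped **required** member fails the variant (reason
`untyped-required`) because sharing cannot be established, whereas an
untyped **excluded** member does not fail it (subtracting on absent evidence
would be anti-conservative in the other direction) but is logged. The filter
is anti-monotone — adding a required or excluded member can only shrink the
passing set — and order-independent; both are property-tested.

Gene reduction uses 1-based fully-closed intervals; a variant overlapping
several gene intervals is assigned to all of them, and variants outside
every interval are counted, not silently dropped. Expression prioritisation
keeps candidates at ≥ `min_tpm` (default 10 TPM) ranked descending; genes
absent from the expression table are returned in an `unknown` bucket.

Inheritance classification from trio allele counts follows the
evidence-preserving convention: a typed carrier parent implicates that
parent; a typed non-carrier parent with the other parent untyped yields
`nonmaternal`/`nonpaternal`; both typed reference yields `de_novo`; both
carriers `biparental`; both untyped `unknown`. Compound heterozygosity is
flagged for ≥ 2 distinct carried sites in a gene, with phase summarised as
`trans-supported` when two calls constrain alleles to different parental
origins (e.g. maternal + nonmaternal), `cis-likely` when two calls agree on
one origin with none opposing, else `phase-unknown`.

## Carrier burden association

The unit of analysis is the subject, not the allele: a subject is a carrier
iff it holds ≥ 1 qualifying variant in the gene, so compound heterozygotes
count once. The two-sided Fisher exact p-value uses the probability-mass
definition — the sum over the full hypergeometric support (fixed margins) of
probabilities at most the observed one — computed in log space from a
cached cumulative log-factorial table (no gamma-function dependency), with a
relative tie tolerance of 1e-7 guarding floating-point equality. The test
suite checks this implementation against independent hypergeometric
enumeration to 1e-10 relative over hundreds of random tables.

The effect size is the *sample* odds ratio ad/bc with a Woolf interval;
a zero cell either raises (default) or receives the Haldane +0.5 correction
to all cells. Multi-gene scans report raw p-values with a
Bonferroni-adjusted threshold α/n_genes — the simplest defensible control
when candidates are tested individually.

Reconstructing the published cohort (20/190 case carriers; the control
count consistent with "2.9 % of 1,063" is 31) gives enrichment 361 %,
OR 3.92 (CI 2.18–7.03) and exact p = 1.64 × 10⁻⁵. The published OR of 4.1
(CI 2.3–7.4) is not reproducible from these counts; the package reports the
sample OR and does not force agreement. Known limitation inherited from the
design: the controls are an external reference panel, so population
stratification and differential sequencing depth are uncorrected.

## Survival analysis

Kaplan-Meier estimation follows the defining product-limit formula with
Greenwood's variance; at tied times events are processed before censorings
(a subject censored at t remains at risk at t). The two-group test is the
Gehan-Breslow weighted log-rank with weight w_j = n_j (total at risk),
which emphasises early event times; U²/Var is referred to χ²(1), two-sided,
without continuity correction. Setting w_j = 1 recovers the standard
log-rank, cross-checked against lifelines. Zero variance (no informative
event times) returns p = 1 with a `DegenerateStatisticsWarning` rather than
NaN. The patient-level event times behind the published survival figure are
not available, so the test suite validates the statistic against an
exhaustive permutation oracle (8 uncensored subjects, where U reduces
exactly to Gehan's pairwise comparison score) and calibrates the type-I
error over 2,000 null simulations of 20-per-arm cohorts with 20 % censoring.

The age-eligibility floor (subjects ≥ 6 years, matching the study design)
is applied at model construction when an `age_years` column is present; a
filter that empties a group is an error, not a silent degenerate test.

## Expression analysis

TPM is computed per sample as 10⁶·(c_g/l_g)/Σ_h(c_h/l_h); each column sums
to 10⁶ exactly. Matched-pair comparison uses a paired t-test on
log₂((MUT+ε)/(WT+ε)) with pseudocount ε = 0.5 TPM (tunable); the reported
fold change is the geometric mean of per-pair ratios, which is equivariant
under scaling of the mutant samples. Scans over many genes report
Benjamini-Hochberg q-values alongside raw p; the default call thresholds
are fold ≥ 3 and raw p ≤ 5 × 10⁻³. The burden gene itself (*MYH6* by
default) is reported separately from the call list: its transcript level is
a distinct scientific question from its variant burden, and pooling it with
the scan would double-count the hypothesis. A pair with zero expression in
both members is dropped for that gene with a warning; at least three usable
pairs are required.

Densitometry is modelled as log(band/GAPDH) ~ intercept + pair + genotype,
fit by OLS. Pair blocking absorbs per-pair multiplicative batch factors
exactly (property-tested), and GAPDH normalisation makes the estimate
invariant to global loading rescaling. The genotype coefficient β reports
as 100·(e^β − 1) percent with delta-method standard error 100·e^β·se(β).

## Synthetic-data generators

All generators take a `seed` and are fully deterministic given it; each
returns a truth record sufficient to score the downstream stage.

* **Cohort**: subject-level carrier draws (Bernoulli at 0.105 for 190 cases,
  0.029 for 1,063 controls); carriers receive one template variant drawn
  from the packaged table's 19 distinct records. Subject-level simulation
  matches the carrier-collapsing test; allele-level simulation is out of
  scope.
* **Family**: five genotyped members (two affected sibs, affected father,
  affected great aunt, unaffected mother). The planted dominant variant is
  set by construction in all affecteds and absent in the mother. Background
  variants draw founder genotypes binomially at frequency 0.01 (default) and
  transmit Mendelianly; the closed-form leakage expectation
  n·[1−(1−f)²]·(1−f)²·[f(1−f)/2 + f²] is exported for calibration tests.
  The default frequency keeps the paper-shaped run essentially leak-free;
  calibration tests raise it to obtain a testable expectation.
* **Survival**: exponential event times (baseline hazard 0.05/yr for
  wild-type, hazard ratio 3 by default for carriers, group sizes 10 vs 62);
  a configurable fraction of subjects is censored at a uniform time before
  their latent event, which realises the censoring fraction exactly in
  expectation.
* **Expression**: per-gene baseline log₂ level ~ U(3, 10), per-pair
  intercept SD 1.0 (shared within a pair, hence absorbed by pairing),
  per-sample residual SD 0.2 log₂ units (~15 % CV — realistic for strongly
  expressed sarcomere genes once between-subject variation is absorbed by
  matching); planted genes (default MYH7 at 3.46-fold) gain log₂(fold) in
  mutant members only. 8 pairs: 5 atrial septum, 3 right ventricle.
* **Densitometry**: log band/GAPDH = pair intercept (SD 0.5) + log(1.62) for
  mutant + N(0, 0.3). The residual SD 0.3 is pinned by the reported ±0.15
  standard error of the +62 % effect with 4 pairs × 5 replicates.

What the generators do **not** emulate: linkage disequilibrium and
relatedness beyond the single family, sequencing/genotyping error,
count-level (negative-binomial) RNA-seq noise and length biases, informative
censoring, and covariate confounding. Passing closed-loop tests therefore
demonstrates the correctness and calibration of the statistics under their
assumed models, not robustness to those real-data complications.

## Numerical choices and degenerate inputs

* Fisher ties: relative tolerance 1e-7 on the observed table probability.
* Log-factorials cached and grown geometrically; no SciPy dependency in the
  exact-test arithmetic itself (SciPy is the independent oracle in tests).
* Zero-variance paired tests: p = 1 when the mean ratio is 0, p = 0
  otherwise, always with a warning.
* Greenwood variance is set to 0 where S(t) = 0.
* All readers reject malformed input with `InputError` naming the offending
  line/column; the CLI maps these to exit code 2, and degenerate-statistics
  warnings escalate to exit 3 under `--strict`.

## Problem sizes used in the test suite

Stochastic calibration tests use 100–2,000 replicates at the study's own
dimensions (190/1,063 subjects, 10/62 survival arms, 8 pairs, 4×5 blots),
scaled by replicate count so the default run completes in well under a
minute per module; the expression recovery loop simulates 10-gene matrices
per replicate since the single-gene paired test does not depend on matrix
width, while the genome-scale scan tests use 1,000–2,000 genes.
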