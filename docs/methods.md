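# Methods

## The score

The package computes a log-additive genetic risk score for type 1 diabetes
(T1D). Each locus contributes its risk-allele dosage weighted by the natural
log of its published case-control odds ratio; the HLA-DR-DQ class-II region,
whose risk is strongly non-additive across haplotype combinations, enters as
a single categorical diplotype term:

    GRS = ( Σᵢ βᵢ sᵢ + H_l ) / ((n + 1) × 2)

- `βᵢ = ln ORᵢ`, dimensionless log odds ratio for locus *i*;
- `sᵢ ∈ {0,1,2}`, risk-allele dosage; X-chromosome SNPs in males are
  hemizygous and counted 0 or 2 (dominant-risk convention);
- `H_l`, log odds ratio of the subject's six-category diplotype
  (DR3/DR4, DR4/DR4, DR3/DR3, DR4/X, DR3/X, X/X);
- `n`, the number of β-weighted loci scored; the `+1` is the diplotype
  slot. Dividing by `(n+1)×2` normalizes per allele tested, which keeps
  scores comparable between samples with different call counts.

The β-weighted loci are the non-HLA SNPs plus three risk-oriented HLA
haplotype dosages — non-DR15-DQ6, A24, non-B57 — imputed from tag SNPs.
DR15-DQ6 and B57 are protective, so their tag dosages are complemented
(`2 − x`) once, at imputation time; downstream code only ever sees
risk-oriented dosages.

### Missing-data policy

`n` counts only the loci actually called for a sample (`per_sample_n`,
default), so a few missing calls do not deflate the score; a strict
`panel_n` alternative fixes `n` at the panel size. Both are implemented
because "number of alleles tested" is ambiguous between the two readings.

### HLA imputation and conflicts

Two tag SNPs (one per high-risk haplotype) map dosage pairs to the six
diplotype categories. Dosage pairs with DR3 + DR4 > 2 are impossible on two
haplotypes under perfect tagging — exactly (2,1), (1,2), (2,2) of the nine
pairs. These are assigned the highest-risk compatible category (DR3/DR4)
and flagged rather than dropped, keeping the sample analyzable while the
flag surfaces in every scored output. No published rule exists for this
situation; the policy is explicit and local to one function.

### Decomposition

The numerator splits exactly (same summation order, fixed to panel order
for bit-reproducibility) into an HLA part (H_l + haplotype loci) and a
non-HLA part (SNPs); component scores are reported over the same
denominator as the full score so they are directly comparable. This is the
machinery behind the age-at-diagnosis attribution analysis.

## Quality control

Before scoring, samples are excluded if any HLA tag SNP is uncalled or if
fewer than 90% of the non-HLA panel SNPs are called. The boundary is
inclusive (exactly 90% is retained). A sample failing both rules is counted
once, under the HLA rule, so the QC report partitions the input exactly.

## Weights

Weights are data, not code: a JSON config of per-locus odds ratios (plus
the diplotype table and the tag-SNP wiring) converted to ln at load time.
The shipped default config (`src/t1dgrs/data/default_weights.json`) is
populated from the published Caucasian case-control odds ratios of the
reference cohort the defaults emulate (the external consortium weights used
in clinical implementations are not redistributable here). Under these
defaults with the default generator, group mean scores land around 0.14–0.19 —
inside the plausible 0.05–0.45 band for this normalization, though below
the 0.23–0.28 means published for the real cohort, whose weights came
from an external consortium model. All ordering and discrimination
properties are insensitive to this overall scale.

## Statistics

Conventions are fixed and documented because packages differ:

- **2×2 odds ratios** are cross-products `(ad)/(bc)`; a zero cross product
  yields a null (undefined) OR, matching the em-dashes in published tables;
  an optional Haldane-Anscombe +0.5 mode exists but is off by default.
- **Confidence intervals** are 95% Woolf intervals,
  `exp(ln OR ± 1.96·√(1/a+1/b+1/c+1/d))`. For frequency-derived ORs the
  point estimate uses the frequencies directly and the CI reconstructs
  allele counts as `round(freq × 2N)` — approximate wherever per-locus
  missingness existed in the source data.
- **Fisher's exact test** is two-sided by the small-p rule (sum of
  hypergeometric probabilities ≤ the observed table's), delegated to
  `scipy.stats.fisher_exact`; the test suite checks it against an exact
  rational enumeration oracle on all small tables.
- **AUROC** is trapezoidal over all distinct thresholds and equals the
  all-pairs statistic P(case > control) + ½P(tie); verified against a
  brute-force pair-counting oracle.
- **Balanced accuracy** = (sensitivity + specificity)/2, predicting "case"
  when score ≥ threshold (higher score always predicts case; no
  auto-flip). The scan grid takes midpoints between consecutive distinct
  scores plus ∓∞ sentinels, which is exhaustive because no threshold
  between two adjacent scores can change any prediction; ties at the peak
  resolve to the lowest threshold. Note the peak coincides with the
  Youden-J operating point, since balanced accuracy = (J+1)/2.
- **Contingency-table convention** for the diplotype-by-age-at-diagnosis
  analysis: each cell's 2×2 is {this diplotype vs all others} × {this age
  bin vs all others}, with age bins [0,8), [8,16), [16,∞). This convention
  reproduces every published odds ratio of the reference table to two decimals
  and is fixed as the default. Significance marks: † p<0.05, ‡ p<0.01.
- **Quantiles** interpolate linearly between order statistics.
- **Group comparisons** use the Kruskal-Wallis omnibus (scipy) plus Dunn's
  pairwise rank tests with tie correction, implemented here because no
  installed package provides them; the multiplicity adjustment
  ("bonferroni" default, "none") is a parameter since the published
  variant is unstated.
- **Regression with prediction band**: OLS with the standard two-sided
  prediction band `ŷ ± t_{(1+γ)/2, n−2}·s·√(1 + 1/n + (x−x̄)²/Sxx)` at
  γ = 0.99 by default; patients whose score falls *below* the lower band
  are flagged as low-GRS outliers (the differential-diagnosis signal).

## The synthetic-data generator

No subject-level data are available for the reference cohort, so the
generator emulates its statistical structure from published group-specific
summary frequencies:

- **Diplotypes** are subject-level categoricals; T1D and control
  probabilities are the published case/control diplotype frequencies per
  race stratum (they sum to 1 within rounding and are renormalized at
  sampling time).
- **Haplotype loci** sum two independent risk-haplotype draws; **SNPs**
  are Binomial(2, p) under Hardy-Weinberg equilibrium, with the published
  risk-allele frequencies; X-chromosome SNPs in males are a single draw
  recorded 0/2.
- **Ages at diagnosis** are lognormal with geometric mean 8.94 years and
  geometric SD 2.18 (the published cohort summary). Optionally age is
  drawn conditional on diplotype using the published diplotype-by-age-bin
  proportions (bin selection + rejection sampling within the bin); this is
  the construction used to test the HLA-driven age association, since by
  design age is then independent of the non-HLA score.
- **Relative groups** have no published frequencies. In
  `group_frequencies` mode they interpolate control→T1D frequencies with
  mixing weights 0.25 (2°), 0.5 (1°), 0.95 (at-risk) — a graded version of
  the midpoint rule that represents the expected risk dilution across
  relative classes. Ages at donation for non-patients are uniform on a
  configurable window (default 1–50 y), and autoantibody counts are labels
  only (at-risk fixed at 2; others 0/1 with configurable probability).
- **`liability_family` mode** is the principled alternative for relatives:
  population genotypes are drawn from control frequencies, disease follows
  `P(case|g) = logistic(α + Σβᵢsᵢ + H_l)` with α calibrated by bisection
  to a target prevalence (±2% relative), and relatives arise by explicit
  Mendelian transmission — siblings share the case's two simulated
  parents, half-siblings add one meiosis via a new co-parent. The DR-DQ
  region is modeled as one three-allele locus (DR3, DR4, X) with haplotype
  frequencies back-solved from the control diplotype table
  (h_X = √f(X/X), h₃ = f(DR3/X)/2h_X, h₄ = f(DR4/X)/2h_X, renormalized),
  which is what makes transmission well-defined. In this mode controls are
  unconditioned population draws, so estimated effect sizes approach the
  per-allele odds ratios only in the rare-disease limit; X SNPs are
  transmitted as diploid and re-coded 0/2 for males at emission.

**What the generator does not emulate:** linkage disequilibrium between
loci (all loci independent), ancestry admixture (race/ethnicity are sampled
labels used only for stratification plumbing), serology (no autoantibody
model), and any environmental or age-dependent effects. Consequently,
passing tests demonstrate that the pipeline's statistics are correct and
that its qualitative orderings (patients > at-risk/first-degree relatives >
controls; T1D-vs-control AUROC > T1D-vs-relative AUROC; HLA-driven age
association) follow from the published frequency structure — they do not
certify performance numbers on real, LD-structured, admixed cohorts.

## Problem sizes and numerics

Simulation-based tests use 5,000 subjects per group for frequency-recovery
and Woolf-CI coverage checks (≥90% of ~37 loci must cover their generating
odds ratio; nominal per-locus coverage is ~95%, so the property is asserted
on three fixed seeds to avoid single-draw tail sensitivity), 2,000 per
group for ordering and age-association constructions, and 10,000 draws for
the age-model calibration check (3-standard-error acceptance on the log
scale). All randomness flows through `numpy.random.default_rng` seeded from
the simulation config; identical seeds reproduce cohorts byte-for-byte.
Bisection for the liability intercept runs on [−60, 10] with a 2% relative
tolerance. Score summation order is fixed to panel order; the decomposition
identity (numerator = HLA part + non-HLA part) is exact in floating point
by construction.

## Known limitations

- Default weights are cohort-derived rather than the external consortium
  model; absolute score scale differs from published group means (ordering
  and AUROC structure are unaffected).
- Allelic odds-ratio recovery in family mode carries the usual logistic
  non-collapsibility bias at non-negligible prevalence.
- Tag-SNP imputation assumes perfect tagging; the conflict policy for
  impossible dosage pairs is a package choice, not a published rule.
- The worked example in the README was produced by the snippet below:

```python
import t1dgrs as t
weights = t.default_weights()
models = t.default_group_models("CAU", age_by_diplotype=True)
config = t.SimulationConfig(
    group_sizes={"t1d": 500, "relative1": 400, "control": 400}, seed=7)
cohort = t.simulate_cohort(models, config, weights)
report = t.run_analysis_from_cohort(cohort, weights)
ctrl = report["contrasts"]["t1d_vs_control"]
print(f"T1D vs control: AUROC = {ctrl['auc']:.3f}")
print(f"  peak balanced accuracy = {ctrl['peak_balanced_accuracy']:.3f} "
      f"at GRS threshold {ctrl['peak_threshold']:.3f}")
print(f"  sensitivity / specificity at peak = "
      f"{ctrl['sensitivity_at_peak']:.3f} / {ctrl['specificity_at_peak']:.3f}")
rel = report["contrasts"]["t1d_vs_relative1"]
print(f"T1D vs 1st-degree relatives: AUROC = {rel['auc']:.3f}")
for group in ("t1d", "relative1", "control"):
    s = report["group_summaries"][group]
    print(f"mean GRS {group:10s} = {s['mean']:.3f} +/- {s['sd']:.3f} (n={s['n']})")
fit = report["age_assoc"]["fits"]
print(f"age at diagnosis vs full GRS: r = {fit['full']['pearson_r']:.3f} "
      f"(p = {fit['full']['p_value']:.2e})")
print(f"                non-HLA GRS: r = {fit['nonhla_only']['pearson_r']:.3f} "
      f"(p = {fit['nonhla_only']['p_value']:.2f})")
```
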