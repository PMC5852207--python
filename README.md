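# t1dgrs

A tested Python implementation of the type 1 diabetes (T1D) genetic risk
score (GRS) analysis pipeline: tag-SNP imputation of HLA-DR-DQ diplotypes,
log-additive risk scoring with an HLA / non-HLA decomposition, cohort
discrimination statistics (ROC/AUROC, balanced-accuracy threshold scans),
per-locus case-control odds-ratio tables, and HLA-by-age-at-diagnosis
contingency analysis. A synthetic-cohort generator built from published
group-specific frequencies makes every stage testable end-to-end without
access to patient data.

## Who this is for

Researchers evaluating polygenic risk stratification for islet autoimmunity
— e.g. screening pipelines that rank relatives of T1D patients, or
differential-diagnosis aids that flag clinically diagnosed patients with
implausibly low genetic risk (possible type 2 or monogenic diabetes).

## The score

For a subject genotyped on a panel of risk loci,

```
GRS = ( Σᵢ βᵢ·sᵢ + H_l ) / ((n + 1) × 2)
```

where `βᵢ = ln(ORᵢ)` is the log odds ratio of locus *i*, `sᵢ ∈ {0, 1, 2}`
its risk-allele dosage, and `n` the number of β-weighted loci scored. The
HLA class-II locus does not fit a per-allele log-additive model, so it
enters as a single diplotype term `H_l`: two tag SNPs assign each subject
one of six DR3-DQ2 / DR4-DQ8 / X diplotype categories, each carrying its
own log odds ratio. Three further tag SNPs contribute risk-oriented
haplotype dosages (non-DR15-DQ6, A24, non-B57) inside the Σ. X-chromosome
SNPs in males are hemizygous and scored 0 or 2 (dominant risk). The
denominator normalizes by allele slots: `n` loci plus one diplotype slot,
two alleles each.

The score decomposes exactly into an HLA-only part (diplotype + haplotype
loci) and a non-HLA part (SNPs) over a shared denominator, which is what
lets the pipeline attribute the age-at-diagnosis association to the HLA
component.

## Worked example

```python
import t1dgrs as t

weights = t.default_weights()                    # shipped per-locus ln(OR) config
models = t.default_group_models("CAU", age_by_diplotype=True)
config = t.SimulationConfig(
    group_sizes={"t1d": 500, "relative1": 400, "control": 400}, seed=7)
cohort = t.simulate_cohort(models, config, weights)
report = t.run_analysis_from_cohort(cohort, weights)
```

Output (printed from the report dict by the snippet in `docs/methods.md`):

```
T1D vs control: AUROC = 0.864
  peak balanced accuracy = 0.795 at GRS threshold 0.159
  sensitivity / specificity at peak = 0.808 / 0.782
T1D vs 1st-degree relatives: AUROC = 0.709
mean GRS t1d        = 0.185 +/- 0.031 (n=500)
mean GRS relative1  = 0.161 +/- 0.033 (n=400)
mean GRS control    = 0.138 +/- 0.029 (n=400)
age at diagnosis vs full GRS: r = -0.121 (p = 6.67e-03)
                non-HLA GRS: r = 0.012 (p = 0.78)
```

Reading it: patients separate well from unrelated controls (AUROC 0.86)
and much less well from first-degree relatives (0.71), who share half
their genome with a patient — the synthetic cohort reproduces exactly the
qualitative pattern reported for real cohorts. The balanced-accuracy scan
picks the GRS threshold that best balances sensitivity and specificity
(this peak coincides with the Youden-J operating point). Because patient
age at diagnosis was generated conditional on HLA diplotype, the full GRS
correlates negatively with age while the non-HLA component does not.

## Command line

```bash
t1dgrs simulate --config sim.yaml --out cohort/
t1dgrs score    --genotypes cohort/genotypes.tsv --meta cohort/metadata.tsv --out scored.tsv
t1dgrs analyze  --genotypes cohort/genotypes.tsv --meta cohort/metadata.tsv --out report.json
t1dgrs tables   --report report.json --out tables/
```

Genotypes are wide TSV (`sample_id` + one rsID column each, cells
`0/1/2/NA`) or VCF 4.x matched on ID and oriented to the configured risk
allele; metadata is a TSV sidecar keyed by `sample_id`; weights are a JSON
config of per-locus odds ratios (converted to ln at load time).

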