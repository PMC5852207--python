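"""Log-additive genetic risk score (GRS) for type 1 diabetes.

The score for one subject is

    GRS = (sum_i beta_i * s_i + H_l) / ((n + 1) * 2)

where ``beta_i = ln(OR_i)`` is the per-locus log odds ratio, ``s_i`` the
risk-allele dosage (0, 1 or 2) at locus ``i``, ``H_l`` the log odds ratio of
the subject's six-category HLA-DR-DQ diplotype (the HLA locus does not fit a
per-allele log-additive model, so it enters as a single diplotype term), and
``n`` the number of beta-weighted loci scored. The denominator normalizes
the summed log-odds by the number of allele slots: n loci plus one slot for
the diplotype term, two alleles each.

X-chromosome SNPs in males are hemizygous and scored 0 or 2 (dominant risk
in the hemizygous state). The beta-weighted loci are the non-HLA SNPs plus
three risk-oriented haplotype loci (non-DQ6, A24, non-B57); the "+1" refers
solely to the diplotype term.

The score decomposes exactly into an HLA-only part (diplotype + haplotype
loci) and a non-HLA part (SNPs), both reported over the same denominator as
the full score so the components are directly comparable.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Optional

import pandas as pd

from .hla_imputation import DIPLOTYPE_CATEGORIES, HlaCall, call_hla

if TYPE_CHECKING:  # pragma: no cover - typing only
    from .cohort_io import Cohort, SampleRecord

__all__ = [
    "WeightConfig",
    "GrsResult",
    "GrsConfigurationError",
    "HAPLOTYPE_LOCI",
    "effective_dosage",
    "compute_grs",
    "score_cohort",
    "score_bounds",
]

HAPLOTYPE_LOCI = ("non_dq6", "a24", "non_b57")

_MISSING_POLICIES = ("per_sample_n", "panel_n")


class GrsConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class WeightConfig:
    """Per-locus log-odds weights plus the HLA tag-SNP wiring.

    ``snp_betas`` preserves insertion order; summation follows it for
    bit-reproducibility.
    """

    snp_betas: dict[str, float]
    hla_diplotype_beta: dict[str, float]
    haplotype_betas: dict[str, float]
    snp_chromosomes: dict[str, str] = field(default_factory=dict)
    risk_alleles: dict[str, str] = field(default_factory=dict)
    #: role -> rsID for roles dr3, dr4, dq6, a24, b57
    hla_tags: dict[str, str] = field(default_factory=dict)
    tag_alleles: dict[str, str] = field(default_factory=dict)
    #: tag rsIDs whose stored dosage counts the *protective* haplotype
    protective_tags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        missing = [c for c in DIPLOTYPE_CATEGORIES
                   if c not in self.hla_diplotype_beta]
        if missing:
            raise GrsConfigurationError(
                f"hla_diplotype_beta missing categories: {missing}")
        unknown = [h for h in self.haplotype_betas
                   if h not in HAPLOTYPE_LOCI]
        if unknown:
            raise GrsConfigurationError(
                f"haplotype_betas has unknown loci: {unknown}")

    @property
    def n_panel(self) -> int:
        """Number of beta-weighted loci: non-HLA SNPs + configured
        haplotype loci (toy configs may omit the haplotype set)."""
        return len(self.snp_betas) + len(self.haplotype_betas)

    def is_x(self, snp_id: str) -> bool:
        return str(self.snp_chromosomes.get(snp_id, "")).upper() == "X"


@dataclass(frozen=True)
class GrsResult:
    """Score and its HLA / non-HLA decomposition for one subject."""

    grs: float
    grs_hla_only: float
    grs_nonhla_only: float
    n_used: int
    numerator: float
    numerator_hla: float
    numerator_nonhla: float
    diplotype: str
    conflict_flag: bool = False


def effective_dosage(raw_dosage: int, chromosome: str, sex: str) -> int:
    """Dosage actually scored: identity except X-chromosome males, whose
    hemizygous call is counted 0 or 2 (dominant risk)."""
    is_x = str(chromosome).upper().lstrip("CHR") == "X"
    if not is_x:
        return raw_dosage
    if sex == "male":
        return 2 if raw_dosage >= 1 else 0
    if sex == "unknown":
        warnings.warn(
            "X-chromosome dosage scored as diploid for sample of unknown sex",
            stacklevel=2)
    return raw_dosage


def compute_grs(sample: "SampleRecord", hla: HlaCall, weights: WeightConfig,
                missing_policy: str = "per_sample_n") -> GrsResult:
    """Score one QC-passed sample.

    ``missing_policy`` controls the ``n`` in the denominator ``(n+1)*2``:
    ``per_sample_n`` (default) counts only the loci actually called for this
    sample; ``panel_n`` fixes it at the panel size for strict comparability
    across samples.
    """
    if missing_policy not in _MISSING_POLICIES:
        raise GrsConfigurationError(
            f"missing_policy must be one of {_MISSING_POLICIES}")

    numerator_nonhla = 0.0
    n_called = 0
    for snp_id, beta in weights.snp_betas.items():  # fixed panel order
        dosage = sample.dosages.get(snp_id)
        if dosage is None:
            continue
        eff = effective_dosage(
            dosage, weights.snp_chromosomes.get(snp_id, "."), sample.sex)
        numerator_nonhla += beta * eff
        n_called += 1

    hap_dosages = {"non_dq6": hla.non_dq6_dosage, "a24": hla.a24_dosage,
                   "non_b57": hla.non_b57_dosage}
    numerator_hla = 0.0
    for locus in HAPLOTYPE_LOCI:
        if locus not in weights.haplotype_betas:
            continue
        numerator_hla += weights.haplotype_betas[locus] * hap_dosages[locus]
        n_called += 1
    numerator_hla += weights.hla_diplotype_beta[hla.diplotype.category]

    n = n_called if missing_policy == "per_sample_n" else weights.n_panel
    denominator = (n + 1) * 2
    numerator = numerator_hla + numerator_nonhla
    return GrsResult(
        grs=numerator / denominator,
        grs_hla_only=numerator_hla / denominator,
        grs_nonhla_only=numerator_nonhla / denominator,
        n_used=n_called,
        numerator=numerator,
        numerator_hla=numerator_hla,
        numerator_nonhla=numerator_nonhla,
        diplotype=hla.diplotype.category,
        conflict_flag=hla.conflict_flag,
    )


def _hla_call_for(sample: "SampleRecord", weights: WeightConfig) -> HlaCall:
    tags = weights.hla_tags
    required = ("dr3", "dr4", "dq6", "a24", "b57")
    missing = [r for r in required if r not in tags]
    if missing:
        raise GrsConfigurationError(
            f"weight config lacks HLA tag wiring for: {missing}")

    def tag_dosage(role):
        snp_id = tags[role]
        d = sample.dosages.get(snp_id)
        if d is None:
            raise GrsConfigurationError(
                f"{sample.sample_id}: HLA tag {snp_id} is missing "
                "(sample should have been excluded by QC)")
        return d

    return call_hla(tag_dosage("dr3"), tag_dosage("dr4"),
                    tag_dosage("dq6"), tag_dosage("a24"), tag_dosage("b57"))


def score_cohort(cohort: "Cohort", weights: WeightConfig,
                 missing_policy: str = "per_sample_n") -> pd.DataFrame:
    """Score every sample; returns a table indexed by sample_id.

    Columns: grs, grs_hla_only, grs_nonhla_only, n_used, diplotype,
    conflict_flag. Deterministic given inputs; order-invariant per sample.
    """
    tag_ids = set(weights.hla_tags.values())
    unweighted = [p.snp_id for p in cohort.panel
                  if not p.is_hla_tag and p.snp_id not in tag_ids
                  and p.snp_id not in weights.snp_betas]
    if unweighted:
        raise GrsConfigurationError(
            f"no weight configured for panel SNP(s): {sorted(unweighted)}")
    rows = {}
    for sample in cohort.samples:
        try:
            hla = _hla_call_for(sample, weights)
            result = compute_grs(sample, hla, weights, missing_policy)
        except (GrsConfigurationError, ValueError) as exc:
            raise GrsConfigurationError(
                f"scoring failed for sample {sample.sample_id}: {exc}"
            ) from exc
        rows[sample.sample_id] = {
            "grs": result.grs,
            "grs_hla_only": result.grs_hla_only,
            "grs_nonhla_only": result.grs_nonhla_only,
            "n_used": result.n_used,
            "diplotype": result.diplotype,
            "conflict_flag": result.conflict_flag,
        }
    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame.index.name = "sample_id"
    return frame


def score_bounds(weights: WeightConfig,
                 n_used: Optional[int] = None) -> tuple[float, float]:
    """Attainable [min, max] GRS for a config at a given denominator size.

    Extreme dosages are 0 or 2 per beta-weighted locus; the diplotype term
    ranges over the six categories.
    """
    n = weights.n_panel if n_used is None else n_used
    denominator = (n + 1) * 2
    lo = hi = 0.0
    for beta in list(weights.snp_betas.values()) + list(
            weights.haplotype_betas.values()):
        lo += min(0.0, 2 * beta)
        hi += max(0.0, 2 * beta)
    lo += min(weights.hla_diplotype_beta.values())
    hi += max(weights.hla_diplotype_beta.values())
    return lo / denominator, hi / denominator
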