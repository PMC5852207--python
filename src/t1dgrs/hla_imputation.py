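"""Tag-SNP imputation of HLA-DR-DQ diplotypes and class-I/DR15 haplotypes.

Two tag SNPs proxy the high-risk class-II haplotypes: one tags DR3-DQ2, the
other DR4-DQ8. Their risk-allele dosages (each 0, 1 or 2) jointly determine
one of six diplotype categories over {DR3-DQ2, DR4-DQ8, X}, where X is any
other DR-DQ haplotype. Three further tags proxy the protective DR15-DQ6 and
B57 haplotypes and the susceptible A24 haplotype; the protective ones are
re-oriented here so that downstream scoring only ever sees risk-oriented
dosages (non-DQ6 = 2 - DQ6, non-B57 = 2 - B57).
"""
from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "DIPLOTYPE_CATEGORIES",
    "HlaDiplotype",
    "HlaCall",
    "ImputationError",
    "impute_diplotype",
    "impute_haplotypes",
]

#: The six diplotype categories, highest risk first.
DIPLOTYPE_CATEGORIES = (
    "DR3_DR4", "DR4_DR4", "DR3_DR3", "DR4_X", "DR3_X", "X_X",
)

_VALID_DOSAGES = (0, 1, 2)


class ImputationError(ValueError):
    """Raised when tag dosages required for imputation are missing/invalid."""


@dataclass(frozen=True)
class HlaDiplotype:
    """One of the six DR3-DQ2/DR4-DQ8 diplotype categories."""

    category: str

    def __post_init__(self) -> None:
        if self.category not in DIPLOTYPE_CATEGORIES:
            raise ValueError(f"unknown diplotype category: {self.category!r}")


@dataclass(frozen=True)
class HlaCall:
    """Imputed HLA state for one sample.

    All haplotype dosages are risk-oriented: ``non_dq6_dosage`` counts
    non-DR15-DQ6 haplotypes, ``non_b57_dosage`` counts non-B57 haplotypes,
    ``a24_dosage`` counts A24 haplotypes. ``conflict_flag`` marks tag-dosage
    combinations incompatible with two haplotypes (DR3 + DR4 dosage > 2).
    """

    diplotype: HlaDiplotype
    non_dq6_dosage: int
    a24_dosage: int
    non_b57_dosage: int
    conflict_flag: bool = False


def _check_dosage(value, name: str) -> int:
    if value is None:
        raise ImputationError(f"{name} dosage is missing (sample should have "
                              "been excluded by QC)")
    if value not in _VALID_DOSAGES:
        raise ImputationError(f"{name} dosage must be 0, 1 or 2; got {value!r}")
    return int(value)


def impute_diplotype(dr3_tag_dosage, dr4_tag_dosage) -> tuple[HlaDiplotype, bool]:
    """Map (DR3 tag dosage, DR4 tag dosage) to a diplotype category.

    A subject carries exactly two DR-DQ haplotypes, so dosage pairs with
    dr3 + dr4 > 2 — (2, 1), (1, 2) and (2, 2) — are biologically impossible
    under perfect tagging. Those are assigned the highest-risk compatible
    category (DR3/DR4) and flagged rather than dropped, so they stay
    analyzable and visible in reports.

    Returns
    -------
    (HlaDiplotype, conflict_flag)
    """
    d3 = _check_dosage(dr3_tag_dosage, "DR3 tag")
    d4 = _check_dosage(dr4_tag_dosage, "DR4 tag")
    if d3 + d4 > 2:
        return HlaDiplotype("DR3_DR4"), True
    if d3 >= 1 and d4 >= 1:
        return HlaDiplotype("DR3_DR4"), False
    if d3 == 2:
        return HlaDiplotype("DR3_DR3"), False
    if d4 == 2:
        return HlaDiplotype("DR4_DR4"), False
    if d3 == 1:
        return HlaDiplotype("DR3_X"), False
    if d4 == 1:
        return HlaDiplotype("DR4_X"), False
    return HlaDiplotype("X_X"), False


def impute_haplotypes(dr15_tag_dosage, a24_tag_dosage,
                      b57_tag_dosage) -> tuple[int, int, int]:
    """Re-orient haplotype tag dosages to the risk direction.

    DR15-DQ6 and B57 are protective, so their dosages are complemented
    (2 - x); A24 is already risk-oriented and passes through.

    Returns
    -------
    (non_dq6_dosage, a24_dosage, non_b57_dosage)
    """
    dq6 = _check_dosage(dr15_tag_dosage, "DR15-DQ6 tag")
    a24 = _check_dosage(a24_tag_dosage, "A24 tag")
    b57 = _check_dosage(b57_tag_dosage, "B57 tag")
    return 2 - dq6, a24, 2 - b57


def call_hla(dr3_tag_dosage, dr4_tag_dosage, dr15_tag_dosage,
             a24_tag_dosage, b57_tag_dosage) -> HlaCall:
    """Full HLA call for one sample from its five tag-SNP dosages."""
    diplotype, conflict = impute_diplotype(dr3_tag_dosage, dr4_tag_dosage)
    non_dq6, a24, non_b57 = impute_haplotypes(
        dr15_tag_dosage, a24_tag_dosage, b57_tag_dosage)
    return HlaCall(diplotype=diplotype, non_dq6_dosage=non_dq6,
                   a24_dosage=a24, non_b57_dosage=non_b57,
                   conflict_flag=conflict)
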