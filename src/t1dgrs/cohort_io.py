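"""Cohort input/output: genotype tables, metadata sidecars, QC, weights.

The internal currency is the risk-allele *dosage* (0, 1, 2 or missing), never
genotype strings; VCF genotypes are oriented to the configured risk allele at
read time. Sample-level QC drops subjects missing any HLA tag-SNP call or
with fewer than 90% of the non-HLA panel called, mirroring the genotyping QC
a tag-SNP risk panel requires before scoring.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .grs_core import WeightConfig
from .hla_imputation import DIPLOTYPE_CATEGORIES

__all__ = [
    "GROUPS",
    "SnpDefinition",
    "SampleRecord",
    "Cohort",
    "QcReport",
    "CohortValidationError",
    "FormatError",
    "OrientationError",
    "read_genotypes",
    "write_genotypes",
    "read_metadata",
    "write_metadata",
    "apply_qc",
    "read_weights",
    "default_weights",
    "default_panel",
]

GROUPS = ("control", "relative2", "relative1", "at_risk", "t1d")
_SEXES = ("male", "female", "unknown")
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

_DATA_DIR = Path(__file__).parent / "data"


class CohortValidationError(ValueError):
    pass


class FormatError(ValueError):
    pass


class OrientationError(ValueError):
    """A VCF record's alleles cannot be oriented to the panel risk allele."""


@dataclass(frozen=True)
class SnpDefinition:
    """One panel SNP: identity, risk allele and role."""

    snp_id: str
    risk_allele: str
    chromosome: str = "."
    locus: str = ""
    candidate_genes: tuple[str, ...] = ()
    is_hla_tag: bool = False

    def __post_init__(self) -> None:
        if self.risk_allele not in ("A", "C", "G", "T"):
            raise CohortValidationError(
                f"{self.snp_id}: risk allele must be a nucleotide, got "
                f"{self.risk_allele!r}")

    @property
    def is_x(self) -> bool:
        return str(self.chromosome).upper().lstrip("CHR") == "X"


@dataclass
class SampleRecord:
    """One subject: risk-allele dosages plus study metadata."""

    sample_id: str
    dosages: dict[str, Optional[int]] = field(default_factory=dict)
    sex: str = "unknown"
    group: Optional[str] = None
    race: Optional[str] = None
    ethnicity: Optional[str] = None
    age_at_diagnosis: Optional[float] = None
    age_at_donation: Optional[float] = None
    aab_count: Optional[int] = None

    def __post_init__(self) -> None:
        if self.sex not in _SEXES:
            raise CohortValidationError(
                f"{self.sample_id}: sex must be one of {_SEXES}")
        if self.group is not None and self.group not in GROUPS:
            raise CohortValidationError(
                f"{self.sample_id}: group must be one of {GROUPS}")
        for snp, d in self.dosages.items():
            if d is not None and d not in (0, 1, 2):
                raise CohortValidationError(
                    f"{self.sample_id}: dosage for {snp} must be 0/1/2 or "
                    f"missing, got {d!r}")


@dataclass
class Cohort:
    """A set of samples genotyped on a shared SNP panel."""

    samples: list[SampleRecord]
    panel: list[SnpDefinition]

    def __post_init__(self) -> None:
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise CohortValidationError(f"duplicate sample_id(s): {dup}")
        panel_ids = {p.snp_id for p in self.panel}
        for s in self.samples:
            extra = set(s.dosages) - panel_ids
            if extra:
                raise CohortValidationError(
                    f"{s.sample_id}: dosages for SNPs not in panel: "
                    f"{sorted(extra)}")

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def snp_ids(self) -> list[str]:
        return [p.snp_id for p in self.panel]

    def panel_by_id(self) -> dict[str, SnpDefinition]:
        return {p.snp_id: p for p in self.panel}

    def dosage_frame(self) -> pd.DataFrame:
        """Samples x SNPs dosage matrix; missing as NaN, panel column order."""
        data = {
            s.sample_id: [
                (math.nan if s.dosages.get(snp) is None else s.dosages[snp])
                for snp in self.snp_ids
            ]
            for s in self.samples
        }
        return pd.DataFrame.from_dict(
            data, orient="index", columns=self.snp_ids, dtype=float)

    def metadata_frame(self) -> pd.DataFrame:
        rows = [
            {
                "sample_id": s.sample_id, "group": s.group, "race": s.race,
                "ethnicity": s.ethnicity, "sex": s.sex,
                "age_at_diagnosis": s.age_at_diagnosis,
                "age_at_donation": s.age_at_donation,
                "aab_count": s.aab_count,
            }
            for s in self.samples
        ]
        return pd.DataFrame(rows).set_index("sample_id")


@dataclass
class QcReport:
    """Partition of input samples by QC outcome.

    A sample failing both rules is counted once, under the HLA rule, so
    ``n_input == n_retained + n_excluded_missing_hla + n_excluded_low_call``
    always reconciles.
    """

    n_input: int
    n_retained: int
    n_excluded_missing_hla: int
    n_excluded_low_call: int
    excluded_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        total = (self.n_retained + self.n_excluded_missing_hla
                 + self.n_excluded_low_call)
        if total != self.n_input:
            raise CohortValidationError(
                f"QC counts do not reconcile: {total} != {self.n_input}")


# ---------------------------------------------------------------------------
# genotype tables

def _parse_cell(value) -> Optional[int]:
    if value is None:
        return None
    if isinstance(value, float) and math.isnan(value):
        return None
    text = str(value).strip()
    if text in ("", "NA", "NaN", "nan", ".", "None"):
        return None
    try:
        num = float(text)
    except ValueError:
        return None  # unparseable calls become missing
    if num in (0.0, 1.0, 2.0):
        return int(num)
    return None


def _infer_panel(snp_ids: Sequence[str],
                 weights: Optional[WeightConfig]) -> list[SnpDefinition]:
    if weights is not None:
        by_id = {p.snp_id: p for p in panel_from_weights(weights)}
        return [by_id.get(s, SnpDefinition(s, "A")) for s in snp_ids]
    return [SnpDefinition(s, "A") for s in snp_ids]


def read_genotypes(path, format: str = "wide_tsv",
                   panel: Optional[Sequence[SnpDefinition]] = None,
                   metadata_path=None) -> Cohort:
    """Read a genotype table into a Cohort of risk-allele dosages.

    Parameters
    ----------
    path:
        Wide TSV/CSV (first column ``sample_id``, one column per rsID,
        cells in {0,1,2,NA}) or a VCF 4.x file matched on the ID field.
    format:
        ``"wide_tsv"`` or ``"vcf"``.
    panel:
        SNP definitions. Required for VCF (orientation needs the risk
        allele); optional for wide tables, where it defaults to nominal
        definitions inferred from the header.
    metadata_path:
        Optional metadata sidecar TSV merged by sample_id.
    """
    if format == "wide_tsv":
        cohort = _read_wide(path, panel)
    elif format == "vcf":
        if panel is None:
            raise FormatError("VCF input requires an explicit SNP panel")
        cohort = _read_vcf(path, panel)
    else:
        raise FormatError(f"unknown genotype format: {format!r}")
    if metadata_path is not None:
        attach_metadata(cohort, read_metadata(metadata_path))
    return cohort


def _read_wide(path, panel) -> Cohort:
    sep = "," if str(path).endswith(".csv") else "\t"
    frame = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    if frame.columns[0] != "sample_id":
        raise FormatError("wide genotype table must start with a "
                          "'sample_id' column")
    snp_ids = list(frame.columns[1:])
    if panel is None:
        panel = _infer_panel(snp_ids, None)
    samples = []
    for _, row in frame.iterrows():
        dosages = {snp: _parse_cell(row[snp]) for snp in snp_ids}
        samples.append(SampleRecord(sample_id=row["sample_id"],
                                    dosages=dosages))
    return Cohort(samples=samples, panel=list(panel))


def _read_vcf(path, panel: Sequence[SnpDefinition]) -> Cohort:
    from cyvcf2 import VCF

    by_id = {p.snp_id: p for p in panel}
    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    dosages: dict[str, dict[str, Optional[int]]] = {
        s: {} for s in sample_ids}
    for record in vcf:
        snp = by_id.get(record.ID)
        if snp is None:
            continue
        ref, alts = record.REF.upper(), [a.upper() for a in record.ALT]
        alt = alts[0] if alts else None
        risk = snp.risk_allele
        comp = _COMPLEMENT[risk]
        if risk in (ref, alt):
            count_alt = risk == alt
        elif comp in (ref, alt):
            count_alt = comp == alt
        else:
            raise OrientationError(
                f"{snp.snp_id}: risk allele {risk} (or complement {comp}) "
                f"matches neither REF={ref} nor ALT={alt}")
        for i, gt in enumerate(record.genotypes):
            alleles = [a for a in gt[:-1] if a is not None]
            # unphased diploid only; half-calls and missing GT -> missing
            if len(alleles) != 2 or any(a < 0 for a in alleles):
                dosages[sample_ids[i]][snp.snp_id] = None
                continue
            n_alt = sum(1 for a in alleles if a > 0)
            dosages[sample_ids[i]][snp.snp_id] = (
                n_alt if count_alt else 2 - n_alt)
    samples = [SampleRecord(sample_id=s, dosages=dosages[s])
               for s in sample_ids]
    return Cohort(samples=samples, panel=list(panel))


def write_genotypes(cohort: Cohort, path) -> None:
    """Write the wide TSV/CSV that :func:`read_genotypes` reads back."""
    sep = "," if str(path).endswith(".csv") else "\t"
    frame = cohort.dosage_frame()
    out = frame.map(lambda v: "NA" if math.isnan(v) else str(int(v)))
    out.index.name = "sample_id"
    out.to_csv(path, sep=sep)


# ---------------------------------------------------------------------------
# metadata sidecar

_META_COLUMNS = ("sample_id", "group", "race", "ethnicity", "sex",
                 "age_at_diagnosis", "age_at_donation", "aab_count")


def read_metadata(path) -> pd.DataFrame:
    sep = "," if str(path).endswith(".csv") else "\t"
    meta = pd.read_csv(path, sep=sep)
    if "sample_id" not in meta.columns:
        raise FormatError("metadata sidecar must have a 'sample_id' column")
    return meta.set_index("sample_id")


def write_metadata(cohort: Cohort, path) -> None:
    sep = "," if str(path).endswith(".csv") else "\t"
    cohort.metadata_frame().to_csv(path, sep=sep)


def attach_metadata(cohort: Cohort, meta: pd.DataFrame) -> None:
    """Merge sidecar fields into samples in place; absent fields stay null."""
    for sample in cohort.samples:
        if sample.sample_id not in meta.index:
            continue
        row = meta.loc[sample.sample_id]

        def get(col):
            if col not in meta.columns:
                return None
            val = row[col]
            if pd.isna(val):
                return None
            return val

        group = get("group")
        if group is not None:
            sample.group = str(group)
        sex = get("sex")
        if sex is not None:
            sample.sex = str(sex)
        for col in ("race", "ethnicity"):
            val = get(col)
            if val is not None:
                setattr(sample, col, str(val))
        for col in ("age_at_diagnosis", "age_at_donation"):
            val = get(col)
            if val is not None:
                setattr(sample, col, float(val))
        aab = get("aab_count")
        if aab is not None:
            sample.aab_count = int(aab)


# ---------------------------------------------------------------------------
# QC

def apply_qc(cohort: Cohort,
             min_nonhla_call_fraction: float = 0.9) -> tuple[Cohort, QcReport]:
    """Sample-level QC: all HLA tags called, >=90% of non-HLA SNPs called.

    The boundary is inclusive: a sample with exactly 90% of non-HLA panel
    SNPs called is retained. Idempotent by construction.
    """
    hla_ids = [p.snp_id for p in cohort.panel if p.is_hla_tag]
    nonhla_ids = [p.snp_id for p in cohort.panel if not p.is_hla_tag]
    retained, excluded_hla, excluded_low = [], [], []
    for sample in cohort.samples:
        if any(sample.dosages.get(snp) is None for snp in hla_ids):
            excluded_hla.append(sample)
            continue
        if nonhla_ids:
            called = sum(1 for snp in nonhla_ids
                         if sample.dosages.get(snp) is not None)
            if called / len(nonhla_ids) < min_nonhla_call_fraction:
                excluded_low.append(sample)
                continue
        retained.append(sample)
    report = QcReport(
        n_input=len(cohort.samples),
        n_retained=len(retained),
        n_excluded_missing_hla=len(excluded_hla),
        n_excluded_low_call=len(excluded_low),
        excluded_ids=[s.sample_id for s in excluded_hla + excluded_low],
    )
    return Cohort(samples=retained, panel=cohort.panel), report


# ---------------------------------------------------------------------------
# weight configuration

def _beta(odds_ratio, label: str) -> float:
    try:
        odds_ratio = float(odds_ratio)
    except (TypeError, ValueError):
        raise CohortValidationError(f"{label}: OR must be a number")
    if not odds_ratio > 0 or not math.isfinite(odds_ratio):
        raise CohortValidationError(
            f"{label}: OR must be finite and > 0, got {odds_ratio}")
    return math.log(odds_ratio)


def _weights_from_dict(cfg: Mapping) -> WeightConfig:
    snps = cfg.get("snps", [])
    snp_betas, snp_chromosomes, risk_alleles = {}, {}, {}
    for rec in snps:
        snp_id = rec["snp_id"]
        snp_betas[snp_id] = _beta(rec["or"], snp_id)
        snp_chromosomes[snp_id] = str(rec.get("chromosome", "."))
        risk_alleles[snp_id] = rec.get("risk_allele", "A")
    hla_or = cfg.get("hla_diplotype_or", {})
    missing = [c for c in DIPLOTYPE_CATEGORIES if c not in hla_or]
    if missing:
        raise CohortValidationError(
            f"weight config missing HLA diplotype categories: {missing}")
    hla_betas = {c: _beta(hla_or[c], f"diplotype {c}")
                 for c in DIPLOTYPE_CATEGORIES}
    hap_or = cfg.get("haplotype_or", {})
    missing = [h for h in ("non_dq6", "a24", "non_b57") if h not in hap_or]
    if missing:
        raise CohortValidationError(
            f"weight config missing haplotype loci: {missing}")
    haplotype_betas = {h: _beta(hap_or[h], f"haplotype {h}")
                       for h in ("non_dq6", "a24", "non_b57")}
    return WeightConfig(
        snp_betas=snp_betas,
        hla_diplotype_beta=hla_betas,
        haplotype_betas=haplotype_betas,
        snp_chromosomes=snp_chromosomes,
        risk_alleles=risk_alleles,
        hla_tags=dict(cfg.get("hla_tags", {})),
        tag_alleles=dict(cfg.get("tag_alleles", {})),
        protective_tags=tuple(cfg.get("protective_tags", ())),
    )


def read_weights(path) -> WeightConfig:
    """Load a weight config (JSON or CSV) and convert every OR to ln(OR).

    JSON layout::

        {"snps": [{"snp_id", "risk_allele", "or", "chromosome"}, ...],
         "haplotype_or": {"non_dq6": ..., "a24": ..., "non_b57": ...},
         "hla_diplotype_or": {"DR3_DR4": ..., ..., "X_X": ...},
         "hla_tags": {"dr3": rsID, "dr4": rsID, "dq6": rsID,
                      "a24": rsID, "b57": rsID}}
    """
    path = Path(path)
    if path.suffix.lower() == ".csv":
        return _weights_from_csv(path)
    with open(path) as fh:
        return _weights_from_dict(json.load(fh))


def _weights_from_csv(path) -> WeightConfig:
    # CSV layout: columns kind,name,risk_allele,or,chromosome where kind is
    # snp | diplotype | haplotype; tag wiring uses kind=tag rows
    frame = pd.read_csv(path)
    cfg: dict = {"snps": [], "hla_diplotype_or": {}, "haplotype_or": {},
                 "hla_tags": {}, "tag_alleles": {}, "protective_tags": []}
    for _, row in frame.iterrows():
        kind = row["kind"]
        if kind == "snp":
            cfg["snps"].append({
                "snp_id": row["name"], "or": row["or"],
                "risk_allele": row.get("risk_allele", "A"),
                "chromosome": row.get("chromosome", "."),
            })
        elif kind == "diplotype":
            cfg["hla_diplotype_or"][row["name"]] = row["or"]
        elif kind == "haplotype":
            cfg["haplotype_or"][row["name"]] = row["or"]
        elif kind == "tag":
            cfg["hla_tags"][row["name"]] = row["risk_allele"]
        else:
            raise CohortValidationError(f"unknown weight row kind: {kind!r}")
    return _weights_from_dict(cfg)


def default_weights() -> WeightConfig:
    """The shipped default weight config (ORs from the published
    Caucasian case-control comparison)."""
    with open(_DATA_DIR / "default_weights.json") as fh:
        return _weights_from_dict(json.load(fh))


def panel_from_weights(weights: WeightConfig) -> list[SnpDefinition]:
    """Full genotyping panel implied by a weight config: non-HLA SNPs plus
    the five HLA tag SNPs."""
    panel = [
        SnpDefinition(snp_id=snp, risk_allele=weights.risk_alleles.get(snp, "A"),
                      chromosome=weights.snp_chromosomes.get(snp, "."))
        for snp in weights.snp_betas
    ]
    for tag_id in weights.hla_tags.values():
        panel.append(SnpDefinition(
            snp_id=tag_id,
            risk_allele=weights.tag_alleles.get(tag_id, "A"),
            chromosome="6",
            is_hla_tag=True,
        ))
    return panel


def default_panel() -> list[SnpDefinition]:
    return panel_from_weights(default_weights())
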