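"""End-to-end analysis: QC -> HLA imputation -> GRS -> statistics -> report.

The report mirrors the study design: per-group score summaries with
centiles, ROC and balanced-accuracy threshold scans for the T1D-vs-control
and T1D-vs-first-degree-relative contrasts, a diplotype x age-at-diagnosis
contingency table with per-cell odds ratios and Fisher tests, per-locus
case/control frequency-and-OR tables by race stratum, and the age-at-
diagnosis regressions for the full, HLA-only and non-HLA-only scores
(including low-score patients falling below the 99% prediction band, the
flag used to surface possible non-autoimmune diabetes).

Note the balanced-accuracy peak coincides with the Youden-J operating point:
balanced accuracy = (J + 1) / 2, so both rules select the same threshold.
"""
from __future__ import annotations

import json
import logging
import math
from dataclasses import asdict
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .association_stats import (Table2x2, balanced_accuracy_scan,
                                fraction_above, odds_ratio_from_counts,
                                rank_group_comparison, regression_with_band,
                                roc_auc, score_centiles)
from .cohort_io import (Cohort, QcReport, apply_qc, panel_from_weights,
                        read_genotypes, read_metadata, attach_metadata,
                        read_weights)
from .grs_core import WeightConfig, score_cohort
from .hla_imputation import DIPLOTYPE_CATEGORIES

logger = logging.getLogger(__name__)

__all__ = [
    "SCHEMA_VERSION",
    "AGE_BIN_LABELS",
    "AGE_BIN_EDGES",
    "significance_mark",
    "build_table1_from_counts",
    "build_table1",
    "build_table2",
    "age_association",
    "run_analysis",
    "run_analysis_from_cohort",
    "write_report",
    "render_tables",
]

SCHEMA_VERSION = "1"

AGE_BIN_LABELS = ("<8", "8-16", ">=16")
AGE_BIN_EDGES = (0.0, 8.0, 16.0, math.inf)

DEFAULT_CONTRASTS = (("t1d", "control"), ("t1d", "relative1"))


def significance_mark(p: Optional[float]) -> str:
    """The study's table convention: dagger for p<0.05, double for p<0.01."""
    if p is None:
        return ""
    if p < 0.01:
        return "‡"
    if p < 0.05:
        return "†"
    return ""


def _bin_age(age: float) -> int:
    for i in range(3):
        if AGE_BIN_EDGES[i] <= age < AGE_BIN_EDGES[i + 1]:
            return i
    raise ValueError(f"age out of range: {age}")


# ---------------------------------------------------------------------------
# Table 1: diplotype x age-at-diagnosis contingency

def build_table1_from_counts(counts: Mapping[str, Sequence[int]]) -> dict:
    """Per-cell ORs and Fisher tests for a 6 x 3 diplotype-by-age-bin grid.

    Each cell's 2x2 is {this diplotype vs all others} x {this age bin vs all
    other bins}; the cross-product OR under that convention reproduces the
    published values. Zero cross products give null ORs.
    """
    grid = {c: list(counts.get(c, [0, 0, 0])) for c in DIPLOTYPE_CATEGORIES}
    total = sum(sum(v) for v in grid.values())
    cells = {}
    for category in DIPLOTYPE_CATEGORIES:
        row_total = sum(grid[category])
        for j, bin_label in enumerate(AGE_BIN_LABELS):
            a = grid[category][j]
            b = row_total - a
            col_total = sum(grid[c][j] for c in DIPLOTYPE_CATEGORIES)
            c_cell = col_total - a
            d_cell = total - row_total - c_cell
            est = odds_ratio_from_counts(Table2x2(a, b, c_cell, d_cell))
            cells[(category, bin_label)] = {
                "n": a,
                "odds_ratio": est.odds_ratio,
                "ci_low": est.ci_low,
                "ci_high": est.ci_high,
                "p_value": est.p_value,
                "mark": significance_mark(est.p_value),
            }
    return {
        "age_bins": list(AGE_BIN_LABELS),
        "counts": grid,
        "cells": {f"{cat}|{b}": v for (cat, b), v in cells.items()},
        "n_total": total,
    }


def build_table1(diplotypes: Iterable[str], ages: Iterable[float]) -> dict:
    """Bin patient ages at diagnosis and build the contingency block."""
    counts = {c: [0, 0, 0] for c in DIPLOTYPE_CATEGORIES}
    for category, age in zip(diplotypes, ages):
        counts[category][_bin_age(float(age))] += 1
    return build_table1_from_counts(counts)


# ---------------------------------------------------------------------------
# Table 2: per-locus case/control frequencies and ORs by race stratum

def _allele_stats(case_dosages: np.ndarray,
                  ctrl_dosages: np.ndarray) -> Optional[dict]:
    """Risk-allele frequency and allele-level 2x2 OR from dosage vectors
    (missing entries NaN)."""
    case = case_dosages[~np.isnan(case_dosages)]
    ctrl = ctrl_dosages[~np.isnan(ctrl_dosages)]
    if case.size == 0 or ctrl.size == 0:
        return None
    a = int(case.sum())
    b = 2 * case.size - a
    c = int(ctrl.sum())
    d = 2 * ctrl.size - c
    est = odds_ratio_from_counts(Table2x2(a, b, c, d))
    return {
        "t1d_freq": a / (2 * case.size),
        "control_freq": c / (2 * ctrl.size),
        "odds_ratio": est.odds_ratio,
        "ci_low": est.ci_low,
        "ci_high": est.ci_high,
        "p_value": est.p_value,
    }


def build_table2(cohort: Cohort, weights: WeightConfig,
                 scored: Optional[pd.DataFrame] = None,
                 races: Sequence[str] = ("CAU", "AFR")) -> dict:
    """Per-locus frequency/OR/CI/p for T1D vs control, per race stratum.

    Diplotype rows are subject-level (category vs rest); haplotype rows use
    the risk-oriented tag dosages; SNP rows are allele-level under the
    diploid allele-count convention. Strata without both cases and controls
    are skipped with a warning.
    """
    if scored is None:
        scored = score_cohort(cohort, weights)
    meta = cohort.metadata_frame()
    dosage = cohort.dosage_frame()
    tags = weights.hla_tags
    out: dict = {}
    for race in races:
        in_race = meta["race"] == race
        case_ids = meta.index[(meta["group"] == "t1d") & in_race]
        ctrl_ids = meta.index[(meta["group"] == "control") & in_race]
        if len(case_ids) == 0 or len(ctrl_ids) == 0:
            logger.warning("table2: stratum %s lacks cases or controls; "
                           "skipped", race)
            continue
        rows = []
        # diplotype rows, subject level
        dip_case = scored.loc[case_ids, "diplotype"]
        dip_ctrl = scored.loc[ctrl_ids, "diplotype"]
        for category in DIPLOTYPE_CATEGORIES:
            a = int((dip_case == category).sum())
            b = len(case_ids) - a
            c = int((dip_ctrl == category).sum())
            d = len(ctrl_ids) - c
            est = odds_ratio_from_counts(Table2x2(a, b, c, d))
            rows.append({
                "name": category, "kind": "diplotype",
                "t1d_freq": a / len(case_ids),
                "control_freq": c / len(ctrl_ids),
                "odds_ratio": est.odds_ratio, "ci_low": est.ci_low,
                "ci_high": est.ci_high, "p_value": est.p_value,
            })
        # haplotype rows, allele level in risk orientation
        for locus, role in (("non_dq6", "dq6"), ("a24", "a24"),
                            ("non_b57", "b57")):
            col = dosage[tags[role]]
            vals_case = col.loc[case_ids].to_numpy(dtype=float)
            vals_ctrl = col.loc[ctrl_ids].to_numpy(dtype=float)
            if role in ("dq6", "b57"):  # stored protective; re-orient
                vals_case, vals_ctrl = 2 - vals_case, 2 - vals_ctrl
            stats = _allele_stats(vals_case, vals_ctrl)
            if stats is not None:
                rows.append({"name": locus, "kind": "haplotype", **stats})
        # SNP rows, allele level
        for snp_id in weights.snp_betas:
            stats = _allele_stats(
                dosage[snp_id].loc[case_ids].to_numpy(dtype=float),
                dosage[snp_id].loc[ctrl_ids].to_numpy(dtype=float))
            if stats is not None:
                rows.append({"name": snp_id, "kind": "snp", **stats})
        out[race] = {"n_t1d": int(len(case_ids)),
                     "n_control": int(len(ctrl_ids)), "rows": rows}
    return out


# ---------------------------------------------------------------------------
# age association

def age_association(scored: pd.DataFrame, ages: pd.Series,
                    band_level: float = 0.99) -> dict:
    """Regressions of the full, HLA-only and non-HLA-only scores on age at
    diagnosis, plus per-age-bin score summaries and low-score outliers."""
    joined = scored.join(ages.rename("age"), how="inner").dropna(
        subset=["age"])
    if len(joined) < 3:
        raise ValueError("need >= 3 patients with known age at diagnosis")
    x = joined["age"].to_numpy()
    ids = list(joined.index)
    fits = {}
    for key, column in (("full", "grs"), ("hla_only", "grs_hla_only"),
                        ("nonhla_only", "grs_nonhla_only")):
        fit = regression_with_band(x, joined[column].to_numpy(),
                                   band_level=band_level, sample_ids=ids)
        fits[key] = {
            "slope": fit.slope, "intercept": fit.intercept,
            "pearson_r": fit.pearson_r, "p_value": fit.p_value,
            "band_level": band_level, "n": fit.n,
            "outlier_ids": list(fit.outlier_ids),
        }
    bins = [_bin_age(a) for a in x]
    bin_summary = {}
    for j, label in enumerate(AGE_BIN_LABELS):
        mask = np.array(bins) == j
        vals = joined["grs"].to_numpy()[mask]
        bin_summary[label] = {
            "n": int(mask.sum()),
            "mean": float(vals.mean()) if mask.any() else None,
            "sd": float(vals.std(ddof=1)) if mask.sum() > 1 else None,
        }
    return {"fits": fits, "by_age_bin": bin_summary,
            "outliers": fits["full"]["outlier_ids"]}


# ---------------------------------------------------------------------------
# full analysis

def _group_summaries(scored: pd.DataFrame, meta: pd.DataFrame) -> dict:
    out = {}
    t1d_ids = meta.index[meta["group"] == "t1d"]
    t1d_centiles = (score_centiles(scored.loc[t1d_ids, "grs"])
                    if len(t1d_ids) else None)
    for group, ids in meta.groupby("group").groups.items():
        vals = scored.loc[ids, "grs"]
        entry = {
            "n": int(len(ids)),
            "mean": float(vals.mean()),
            "sd": float(vals.std(ddof=1)) if len(ids) > 1 else None,
            "centiles": score_centiles(vals),
        }
        if t1d_centiles is not None:
            entry["fraction_above_t1d_median"] = fraction_above(
                vals, t1d_centiles[50.0])
        out[group] = entry
    if t1d_centiles is not None:
        out["_t1d_centile_reference"] = t1d_centiles
    return out


def _contrast_block(scored: pd.DataFrame, meta: pd.DataFrame,
                    positive: str, negative: str) -> Optional[dict]:
    pos_ids = meta.index[meta["group"] == positive]
    neg_ids = meta.index[meta["group"] == negative]
    if len(pos_ids) == 0 or len(neg_ids) == 0:
        logger.warning("contrast %s vs %s skipped: empty group",
                       positive, negative)
        return None
    scores = np.concatenate([scored.loc[pos_ids, "grs"],
                             scored.loc[neg_ids, "grs"]])
    labels = np.concatenate([np.ones(len(pos_ids), dtype=int),
                             np.zeros(len(neg_ids), dtype=int)])
    roc = roc_auc(scores, labels)
    scan = balanced_accuracy_scan(scores, labels)
    return {
        "positive": positive, "negative": negative,
        "n_positive": int(len(pos_ids)), "n_negative": int(len(neg_ids)),
        "auc": roc.auc,
        "peak_threshold": scan.peak_threshold,
        "peak_balanced_accuracy": scan.peak_accuracy,
        "sensitivity_at_peak": scan.peak_sensitivity,
        "specificity_at_peak": scan.peak_specificity,
    }


def run_analysis_from_cohort(cohort: Cohort, weights: WeightConfig,
                             race: Optional[str] = None,
                             ethnicity: Optional[str] = None,
                             contrasts: Sequence[tuple[str, str]] = DEFAULT_CONTRASTS,
                             qc_report: Optional[QcReport] = None) -> dict:
    """Run QC, scoring and all statistics on an in-memory cohort."""
    if qc_report is None:
        cohort, qc_report = apply_qc(cohort)
        logger.info("QC: %d in, %d retained", qc_report.n_input,
                    qc_report.n_retained)
    if race is not None or ethnicity is not None:
        kept = [s for s in cohort.samples
                if (race is None or s.race == race)
                and (ethnicity is None or s.ethnicity == ethnicity)]
        logger.info("stratum filter race=%s ethnicity=%s: %d -> %d samples",
                    race, ethnicity, len(cohort.samples), len(kept))
        cohort = Cohort(samples=kept, panel=cohort.panel)
    meta = cohort.metadata_frame()
    groups_present = meta["group"].dropna().unique()
    if len(groups_present) < 2:
        raise ValueError("need at least two groups after filtering")
    scored = score_cohort(cohort, weights)
    logger.info("scored %d samples", len(scored))

    report: dict = {
        "schema_version": SCHEMA_VERSION,
        "strata": {"race": race, "ethnicity": ethnicity},
        "qc": asdict(qc_report),
        "n_analyzed": int(len(scored)),
        "group_summaries": _group_summaries(scored, meta),
    }
    contrasts_block = {}
    for positive, negative in contrasts:
        block = _contrast_block(scored, meta, positive, negative)
        if block is not None:
            contrasts_block[f"{positive}_vs_{negative}"] = block
    report["contrasts"] = contrasts_block

    group_scores = {g: scored.loc[meta.index[meta["group"] == g], "grs"]
                    for g in groups_present}
    comparison = rank_group_comparison(group_scores)
    report["group_rank_tests"] = {
        ("omnibus" if k == "omnibus" else f"{k[0]}_vs_{k[1]}"): v
        for k, v in comparison.items()
    }

    t1d_ids = meta.index[meta["group"] == "t1d"]
    t1d_scored = scored.loc[t1d_ids]
    ages = meta.loc[t1d_ids, "age_at_diagnosis"].dropna()
    if len(ages) >= 3:
        dip = t1d_scored.loc[ages.index, "diplotype"]
        report["table1"] = build_table1(dip, ages.loc[dip.index])
        report["age_assoc"] = age_association(t1d_scored, ages)
        report["outliers"] = report["age_assoc"]["outliers"]
    report["table2"] = build_table2(cohort, weights, scored=scored)
    return _to_jsonable(report)


def run_analysis(cohort_path, metadata_path, weights_path,
                 race: Optional[str] = None,
                 ethnicity: Optional[str] = None,
                 format: str = "wide_tsv",
                 contrasts: Sequence[tuple[str, str]] = DEFAULT_CONTRASTS) -> dict:
    """File-based entry point: read genotypes + metadata + weights, then
    run the full analysis."""
    weights = read_weights(weights_path)
    panel = panel_from_weights(weights)
    cohort = read_genotypes(cohort_path, format=format, panel=panel)
    attach_metadata(cohort, read_metadata(metadata_path))
    return run_analysis_from_cohort(cohort, weights, race=race,
                                    ethnicity=ethnicity, contrasts=contrasts)


# ---------------------------------------------------------------------------
# serialization

def _to_jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, float) and math.isnan(obj):
        return None
    return obj


def write_report(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(_to_jsonable(report), fh, indent=1)


def render_tables(report: dict, out_dir) -> list[str]:
    """Write TSV renderings of the contingency and per-locus tables from a
    report dict; returns the paths written."""
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    if "table1" in report:
        t1 = report["table1"]
        rows = []
        for category in DIPLOTYPE_CATEGORIES:
            row = {"diplotype": category}
            for bin_label in t1["age_bins"]:
                cell = t1["cells"][f"{category}|{bin_label}"]
                orr = cell["odds_ratio"]
                text = "-" if orr is None else f"{orr:.2f}{cell['mark']}"
                row[f"N {bin_label}"] = cell["n"]
                row[f"OR {bin_label}"] = text
            rows.append(row)
        path = out_dir / "table1_hla_by_age.tsv"
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
        written.append(str(path))
    for race, block in report.get("table2", {}).items():
        frame = pd.DataFrame(block["rows"])
        path = out_dir / f"table2_loci_{race}.tsv"
        frame.to_csv(path, sep="\t", index=False)
        written.append(str(path))
    return written
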