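"""Synthetic cohorts with the statistical structure the GRS analysis assumes.

Two generative modes:

* ``group_frequencies`` — each study group (control, relatives, at-risk,
  T1D) gets its own marginal model: a subject-level categorical over the six
  HLA diplotypes, independent risk-haplotype frequencies for the three
  haplotype loci, per-SNP risk-allele frequencies under Hardy-Weinberg
  equilibrium, and a lognormal age-at-diagnosis model for patients. T1D and
  control frequencies come from published case/control tables;
  relative-group frequencies are interpolated between them (risk dilution).
* ``liability_family`` — a principled alternative for relatives: population
  genotypes are drawn from control frequencies, disease status follows a
  logistic liability on the raw log-odds sum with the intercept calibrated
  to a target prevalence, and relatives are produced by explicit Mendelian
  transmission (siblings share both simulated parents; half-siblings share
  one).

Loci are simulated independently: there is no linkage disequilibrium, no
admixture, and no serology model — see docs/methods.md for what that does
and does not let the tests conclude.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np

from .cohort_io import (Cohort, SampleRecord, SnpDefinition, default_weights,
                        panel_from_weights)
from .grs_core import HAPLOTYPE_LOCI, WeightConfig
from .hla_imputation import DIPLOTYPE_CATEGORIES

__all__ = [
    "AGE_GEOMETRIC_MEAN",
    "AGE_GEOMETRIC_SD",
    "GroupModel",
    "SimulationConfig",
    "default_group_models",
    "simulate_cohort",
    "simulate_liability_family",
    "sample_ages",
]

#: Geometric mean / multiplicative SD (years) of T1D age at diagnosis.
AGE_GEOMETRIC_MEAN = 8.94
AGE_GEOMETRIC_SD = 2.18

#: Mixing weight (control -> T1D) used to synthesize relative-group
#: frequencies, graded to mirror the expected risk dilution.
RELATIVE_MIX = {"control": 0.0, "relative2": 0.25, "relative1": 0.5,
                "at_risk": 0.95, "t1d": 1.0}

_AGE_BIN_EDGES = (0.0, 8.0, 16.0, math.inf)

_DATA_DIR = Path(__file__).parent / "data"


@dataclass
class GroupModel:
    """Marginal generative model for one cohort group."""

    label: str
    diplotype_freqs: dict[str, float]
    haplotype_freqs: dict[str, float]
    snp_freqs: dict[str, float]
    age_model: Optional[dict[str, float]] = None  # geometric_mean/_sd, years
    age_by_diplotype: Optional[dict[str, Sequence[float]]] = None
    race: str = "CAU"

    def __post_init__(self) -> None:
        total = sum(self.diplotype_freqs.get(c, 0.0)
                    for c in DIPLOTYPE_CATEGORIES)
        if abs(total - 1.0) > 0.002:
            raise ValueError(
                f"{self.label}: diplotype frequencies sum to {total:.4f}, "
                "expected 1 within rounding")
        for name, freqs in (("haplotype", self.haplotype_freqs),
                            ("SNP", self.snp_freqs)):
            for key, p in freqs.items():
                if not 0.0 <= p <= 1.0:
                    raise ValueError(
                        f"{self.label}: {name} frequency for {key} outside "
                        f"[0, 1]: {p}")

    def normalized_diplotype_probs(self) -> np.ndarray:
        probs = np.array([self.diplotype_freqs.get(c, 0.0)
                          for c in DIPLOTYPE_CATEGORIES], dtype=float)
        return probs / probs.sum()


@dataclass
class SimulationConfig:
    group_sizes: dict[str, int]
    seed: int = 0
    sex_ratio: float = 0.5  # fraction male
    mode: str = "group_frequencies"
    hispanic_fraction: float = 0.135
    donation_age_window: tuple[float, float] = (1.0, 50.0)
    aab1_prob: float = 0.2  # P(one autoantibody) for non-at-risk groups

    def __post_init__(self) -> None:
        for label, n in self.group_sizes.items():
            if n < 0:
                raise ValueError(f"group size for {label!r} must be >= 0")


def _interp(p_ctrl: float, p_t1d: float, w: float) -> float:
    return p_ctrl + w * (p_t1d - p_ctrl)


def default_group_models(race: str = "CAU",
                         age_by_diplotype: bool = False
                         ) -> dict[str, GroupModel]:
    """Group models populated from the published frequency tables.

    T1D and control models use the published case/control frequencies for
    the requested race verbatim; relative groups interpolate between them
    with the graded :data:`RELATIVE_MIX` weights (no relative-group
    frequencies are published). ``age_by_diplotype=True`` additionally ties
    patient age at diagnosis to diplotype via the published diplotype-by-age
    contingency proportions.
    """
    if race not in ("CAU", "AFR"):
        raise ValueError(f"unsupported race stratum: {race!r}")
    with open(_DATA_DIR / "table2_frequencies.json") as fh:
        table2 = json.load(fh)
    with open(_DATA_DIR / "table1_counts.json") as fh:
        table1 = json.load(fh)

    dip_t1d = {c: table2["diplotypes"][c][race]["t1d_freq"]
               for c in DIPLOTYPE_CATEGORIES}
    dip_ctrl = {c: table2["diplotypes"][c][race]["control_freq"]
                for c in DIPLOTYPE_CATEGORIES}
    hap_t1d = {h: table2["haplotypes"][h][race]["t1d_freq"]
               for h in HAPLOTYPE_LOCI}
    hap_ctrl = {h: table2["haplotypes"][h][race]["control_freq"]
                for h in HAPLOTYPE_LOCI}
    snp_t1d = {r["snp_id"]: r[race]["t1d_freq"] for r in table2["snps"]}
    snp_ctrl = {r["snp_id"]: r[race]["control_freq"] for r in table2["snps"]}

    age_bins = None
    if age_by_diplotype:
        age_bins = {c: (np.asarray(v, dtype=float)
                        / np.sum(v)).tolist()
                    for c, v in table1["counts"].items()}

    models = {}
    for label, w in RELATIVE_MIX.items():
        dip = {c: _interp(dip_ctrl[c], dip_t1d[c], w)
               for c in DIPLOTYPE_CATEGORIES}
        hap = {h: _interp(hap_ctrl[h], hap_t1d[h], w)
               for h in HAPLOTYPE_LOCI}
        snp = {s: _interp(snp_ctrl[s], snp_t1d[s], w) for s in snp_t1d}
        models[label] = GroupModel(
            label=label,
            diplotype_freqs=dip,
            haplotype_freqs=hap,
            snp_freqs=snp,
            age_model=({"geometric_mean": AGE_GEOMETRIC_MEAN,
                        "geometric_sd": AGE_GEOMETRIC_SD}
                       if label == "t1d" else None),
            age_by_diplotype=age_bins if label == "t1d" else None,
            race=race,
        )
    return models


# ---------------------------------------------------------------------------
# age sampling

def sample_ages(rng: np.random.Generator, n: int,
                geometric_mean: float = AGE_GEOMETRIC_MEAN,
                geometric_sd: float = AGE_GEOMETRIC_SD) -> np.ndarray:
    """Lognormal ages: ln(age) ~ Normal(ln gm, ln gsd)."""
    return rng.lognormal(math.log(geometric_mean), math.log(geometric_sd),
                         size=n)


def _sample_age_in_bin(rng: np.random.Generator, bin_idx: int,
                       geometric_mean: float, geometric_sd: float) -> float:
    lo, hi = _AGE_BIN_EDGES[bin_idx], _AGE_BIN_EDGES[bin_idx + 1]
    # rejection from the lognormal; every bin holds >20% mass under the
    # default parameters so this terminates quickly
    for _ in range(10000):
        age = float(rng.lognormal(math.log(geometric_mean),
                                  math.log(geometric_sd)))
        if lo <= age < hi:
            return age
    raise RuntimeError("age rejection sampling failed to hit the bin")


# ---------------------------------------------------------------------------
# group-frequency simulation

_DIP_TO_TAGS = {
    "DR3_DR4": (1, 1), "DR4_DR4": (0, 2), "DR3_DR3": (2, 0),
    "DR4_X": (0, 1), "DR3_X": (1, 0), "X_X": (0, 0),
}


def _emit_tag_dosages(weights: WeightConfig, dr3: int, dr4: int,
                      non_dq6: int, a24: int, non_b57: int) -> dict[str, int]:
    """Genotype-table dosages for the five HLA tag SNPs. Protective tags
    (DQ6, B57) are stored in their own orientation; the imputation module
    re-orients them to risk."""
    tags = weights.hla_tags
    return {
        tags["dr3"]: dr3,
        tags["dr4"]: dr4,
        tags["dq6"]: 2 - non_dq6,
        tags["a24"]: a24,
        tags["b57"]: 2 - non_b57,
    }


def simulate_cohort(models: Mapping[str, GroupModel],
                    config: SimulationConfig,
                    weights: Optional[WeightConfig] = None) -> Cohort:
    """Draw a cohort from per-group marginal models.

    Per sample: diplotype ~ categorical; each haplotype locus is the sum of
    two independent risk-haplotype draws; each autosomal SNP dosage ~
    Binomial(2, p) (HWE); X SNPs in males are a single draw recorded 0/2;
    patient ages are lognormal, optionally re-binned by diplotype.
    Deterministic for a fixed config seed.
    """
    weights = weights or default_weights()
    panel = panel_from_weights(weights)
    rng = np.random.default_rng(config.seed)
    snp_ids = list(weights.snp_betas)
    samples = []
    for label, n in config.group_sizes.items():
        if n == 0:
            continue
        model = models[label]
        probs = model.normalized_diplotype_probs()
        dip_idx = rng.choice(len(DIPLOTYPE_CATEGORIES), size=n, p=probs)
        sexes = np.where(rng.random(n) < config.sex_ratio, "male", "female")
        hap_dosages = {
            h: rng.binomial(2, model.haplotype_freqs[h], size=n)
            for h in HAPLOTYPE_LOCI
        }
        snp_dosages = {}
        for snp in snp_ids:
            p = model.snp_freqs[snp]
            dosage = rng.binomial(2, p, size=n)
            if weights.is_x(snp):
                male = sexes == "male"
                dosage[male] = 2 * rng.binomial(1, p, size=int(male.sum()))
            snp_dosages[snp] = dosage
        donation_ages = rng.uniform(*config.donation_age_window, size=n)
        hispanic = rng.random(n) < config.hispanic_fraction

        gm = gsd = None
        if model.age_model is not None:
            gm = model.age_model["geometric_mean"]
            gsd = model.age_model["geometric_sd"]

        for i in range(n):
            category = DIPLOTYPE_CATEGORIES[dip_idx[i]]
            dr3, dr4 = _DIP_TO_TAGS[category]
            dosages = {snp: int(snp_dosages[snp][i]) for snp in snp_ids}
            dosages.update(_emit_tag_dosages(
                weights, dr3, dr4,
                int(hap_dosages["non_dq6"][i]),
                int(hap_dosages["a24"][i]),
                int(hap_dosages["non_b57"][i])))
            age_dx = None
            if gm is not None:
                if model.age_by_diplotype is not None:
                    bin_probs = model.age_by_diplotype[category]
                    bin_idx = int(rng.choice(3, p=np.asarray(bin_probs)
                                             / np.sum(bin_probs)))
                    age_dx = _sample_age_in_bin(rng, bin_idx, gm, gsd)
                else:
                    age_dx = float(rng.lognormal(math.log(gm),
                                                 math.log(gsd)))
            if label == "at_risk":
                aab = 2
            elif label == "t1d":
                aab = 2
            else:
                aab = int(rng.random() < config.aab1_prob)
            samples.append(SampleRecord(
                sample_id=f"{label}_{i:05d}",
                dosages=dosages,
                sex=str(sexes[i]),
                group=label,
                race=model.race,
                ethnicity="hispanic" if hispanic[i] else "non_hispanic",
                age_at_diagnosis=age_dx,
                age_at_donation=float(donation_ages[i]),
                aab_count=aab,
            ))
    return Cohort(samples=samples, panel=panel)


# ---------------------------------------------------------------------------
# liability-family simulation

# DR-DQ region as one three-allele locus; allele codes:
_DR3, _DR4, _DRX = 0, 1, 2


def _dr_haplotype_freqs(diplotype_freqs: Mapping[str, float]) -> np.ndarray:
    """Back-solve (DR3, DR4, X) haplotype frequencies from subject-level
    diplotype frequencies under random haplotype union."""
    h_x = math.sqrt(diplotype_freqs["X_X"])
    if h_x == 0.0:
        raise ValueError("cannot solve haplotype frequencies with f(X/X)=0")
    h3 = diplotype_freqs["DR3_X"] / (2.0 * h_x)
    h4 = diplotype_freqs["DR4_X"] / (2.0 * h_x)
    freqs = np.array([h3, h4, h_x])
    return freqs / freqs.sum()


def _dr_pair_to_category(pair: np.ndarray) -> np.ndarray:
    """(n, 2) allele-code pairs -> diplotype category indices."""
    n3 = np.sum(pair == _DR3, axis=1)
    n4 = np.sum(pair == _DR4, axis=1)
    cats = np.empty(pair.shape[0], dtype=object)
    cats[(n3 >= 1) & (n4 >= 1)] = "DR3_DR4"
    cats[(n3 == 2)] = "DR3_DR3"
    cats[(n4 == 2)] = "DR4_DR4"
    cats[(n3 == 1) & (n4 == 0)] = "DR3_X"
    cats[(n3 == 0) & (n4 == 1)] = "DR4_X"
    cats[(n3 == 0) & (n4 == 0)] = "X_X"
    return cats


class _FamilyEngine:
    """Vectorized genotype draws and Mendelian transmission.

    Genotypes are allele-pair arrays: ``dr`` (n, 2) with three-allele codes,
    ``hap`` (n, 3, 2) and ``snp`` (n, S, 2) holding 0/1 risk-allele
    indicators. All loci segregate independently (no linkage).
    """

    def __init__(self, model: GroupModel, weights: WeightConfig,
                 rng: np.random.Generator):
        self.rng = rng
        self.weights = weights
        self.snp_ids = list(weights.snp_betas)
        self.dr_freqs = _dr_haplotype_freqs(model.diplotype_freqs)
        self.hap_freqs = np.array([model.haplotype_freqs[h]
                                   for h in HAPLOTYPE_LOCI])
        self.snp_freqs = np.array([model.snp_freqs[s] for s in self.snp_ids])
        self.snp_betas = np.array([weights.snp_betas[s]
                                   for s in self.snp_ids])
        self.hap_betas = np.array([weights.haplotype_betas.get(h, 0.0)
                                   for h in HAPLOTYPE_LOCI])
        self.dip_beta = weights.hla_diplotype_beta

    def draw_population(self, n: int):
        dr = self.rng.choice(3, size=(n, 2), p=self.dr_freqs)
        hap = (self.rng.random((n, len(HAPLOTYPE_LOCI), 2))
               < self.hap_freqs[None, :, None]).astype(np.int8)
        snp = (self.rng.random((n, len(self.snp_ids), 2))
               < self.snp_freqs[None, :, None]).astype(np.int8)
        return dr, hap, snp

    def transmit(self, parent_a, parent_b):
        """One child per parent pair: one random allele from each parent at
        every locus, independently (one meiosis per parent)."""
        dr_a, hap_a, snp_a = parent_a
        dr_b, hap_b, snp_b = parent_b
        n = dr_a.shape[0]
        rng = self.rng

        def pick(pair_arr):
            # pair_arr shape (n, ..., 2); choose one allele per row/locus
            idx = rng.integers(0, 2, size=pair_arr.shape[:-1])
            return np.take_along_axis(pair_arr, idx[..., None],
                                      axis=-1)[..., 0]

        dr = np.stack([pick(dr_a), pick(dr_b)], axis=-1)
        hap = np.stack([pick(hap_a), pick(hap_b)], axis=-1)
        snp = np.stack([pick(snp_a), pick(snp_b)], axis=-1)
        return dr, hap, snp

    def log_odds(self, genotype) -> np.ndarray:
        """Raw log-odds sum (the unnormalized GRS numerator) per sample."""
        dr, hap, snp = genotype
        cats = _dr_pair_to_category(dr)
        h_l = np.array([self.dip_beta[c] for c in cats])
        hap_dosage = hap.sum(axis=-1)
        snp_dosage = snp.sum(axis=-1)
        return (snp_dosage @ self.snp_betas + hap_dosage @ self.hap_betas
                + h_l)

    def to_records(self, genotype, label: str, offset: int,
                   config: SimulationConfig,
                   age_model: Optional[dict[str, float]]) -> list[SampleRecord]:
        dr, hap, snp = genotype
        n = dr.shape[0]
        cats = _dr_pair_to_category(dr)
        hap_dosage = hap.sum(axis=-1)
        snp_dosage = snp.sum(axis=-1)
        sexes = np.where(self.rng.random(n) < config.sex_ratio,
                         "male", "female")
        donation = self.rng.uniform(*config.donation_age_window, size=n)
        hispanic = self.rng.random(n) < config.hispanic_fraction
        records = []
        for i in range(n):
            dr3, dr4 = _DIP_TO_TAGS[cats[i]]
            dosages = {s: int(snp_dosage[i, j])
                       for j, s in enumerate(self.snp_ids)}
            for j, s in enumerate(self.snp_ids):
                if self.weights.is_x(s) and sexes[i] == "male":
                    # hemizygous: record the maternal copy as 0/2
                    dosages[s] = 2 * int(snp[i, j, 0])
            dosages.update(_emit_tag_dosages(
                self.weights, dr3, dr4,
                int(hap_dosage[i, 0]), int(hap_dosage[i, 1]),
                int(hap_dosage[i, 2])))
            age_dx = None
            if age_model is not None and label == "t1d":
                age_dx = float(self.rng.lognormal(
                    math.log(age_model["geometric_mean"]),
                    math.log(age_model["geometric_sd"])))
            records.append(SampleRecord(
                sample_id=f"{label}_{offset + i:05d}",
                dosages=dosages,
                sex=str(sexes[i]),
                group=label,
                race="CAU",
                ethnicity="hispanic" if hispanic[i] else "non_hispanic",
                age_at_diagnosis=age_dx,
                age_at_donation=float(donation[i]),
                aab_count=2 if label in ("t1d", "at_risk") else 0,
            ))
        return records


def _calibrate_alpha(engine: _FamilyEngine, prevalence: float,
                     n_calibration: int = 20000,
                     tolerance: float = 0.02) -> float:
    """Bisect the logistic intercept so the marginal case rate matches the
    target prevalence within a relative tolerance."""
    log_odds = engine.log_odds(engine.draw_population(n_calibration))

    def case_rate(alpha: float) -> float:
        return float(np.mean(1.0 / (1.0 + np.exp(-(alpha + log_odds)))))

    lo, hi = -60.0, 10.0
    if not case_rate(lo) <= prevalence <= case_rate(hi):
        raise ValueError(
            f"prevalence {prevalence} unattainable for this weight range")
    for _ in range(200):
        mid = (lo + hi) / 2.0
        rate = case_rate(mid)
        if abs(rate - prevalence) <= tolerance * prevalence:
            return mid
        if rate < prevalence:
            lo = mid
        else:
            hi = mid
    raise ValueError("intercept calibration did not converge")


def simulate_liability_family(population_model: GroupModel,
                              weights: WeightConfig,
                              prevalence: float,
                              config: SimulationConfig) -> Cohort:
    """Cohort with cases, siblings and half-siblings under a logistic
    liability model.

    Cases are population draws thinned by ``P(case | g) = logistic(alpha +
    log-odds(g))`` with ``alpha`` calibrated by bisection to the requested
    prevalence. Each accepted case gets simulated parents consistent with
    Mendelian transmission; ``relative1`` samples are full siblings (same
    two parents), ``relative2`` adds one meiosis (half-siblings via a new
    co-parent). ``control`` samples are unconditioned population draws.
    """
    if not 0.0 < prevalence < 0.5:
        raise ValueError("prevalence must be in (0, 0.5)")
    rng = np.random.default_rng(config.seed)
    engine = _FamilyEngine(population_model, weights, rng)
    alpha = _calibrate_alpha(engine, prevalence)

    quotas = {label: config.group_sizes.get(label, 0)
              for label in ("t1d", "relative1", "relative2", "control")}
    need_families = max(quotas["t1d"], quotas["relative1"],
                        quotas["relative2"])
    case_genotypes, sib_genotypes, half_genotypes = [], [], []
    n_found = 0
    batch = max(200, int(need_families / max(prevalence, 1e-3) / 10))
    max_draws = 400 * max(need_families, 1) / max(prevalence, 1e-4)
    drawn = 0
    while n_found < need_families:
        parent_a = engine.draw_population(batch)
        parent_b = engine.draw_population(batch)
        children = engine.transmit(parent_a, parent_b)
        p_case = 1.0 / (1.0 + np.exp(-(alpha + engine.log_odds(children))))
        accepted = rng.random(batch) < p_case
        idx = np.nonzero(accepted)[0]
        drawn += batch
        if idx.size:
            take = idx[: need_families - n_found]

            def sel(geno, rows):
                return tuple(arr[rows] for arr in geno)

            case_genotypes.append(sel(children, take))
            parents_a = sel(parent_a, take)
            parents_b = sel(parent_b, take)
            sib_genotypes.append(engine.transmit(parents_a, parents_b))
            co_parent = engine.draw_population(take.size)
            half_genotypes.append(engine.transmit(parents_a, co_parent))
            n_found += take.size
        if drawn > max_draws:
            raise RuntimeError("case sampling budget exhausted; prevalence "
                               "too low for the requested cohort size")

    def concat(parts):
        return tuple(np.concatenate([p[k] for p in parts], axis=0)
                     for k in range(3))

    samples: list[SampleRecord] = []
    age_model = population_model.age_model or {
        "geometric_mean": AGE_GEOMETRIC_MEAN,
        "geometric_sd": AGE_GEOMETRIC_SD,
    }
    if need_families:
        cases = concat(case_genotypes)
        sibs = concat(sib_genotypes)
        halves = concat(half_genotypes)

        def head(geno, n):
            return tuple(arr[:n] for arr in geno)

        samples += engine.to_records(head(cases, quotas["t1d"]), "t1d", 0,
                                     config, age_model)
        samples += engine.to_records(head(sibs, quotas["relative1"]),
                                     "relative1", 0, config, None)
        samples += engine.to_records(head(halves, quotas["relative2"]),
                                     "relative2", 0, config, None)
    if quotas["control"]:
        controls = engine.draw_population(quotas["control"])
        samples += engine.to_records(controls, "control", 0, config, None)
    return Cohort(samples=samples, panel=panel_from_weights(weights))
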