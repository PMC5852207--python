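"""Case-control association statistics for GRS cohort analyses.

Conventions, fixed here because they differ between packages:

* 2x2 odds ratios are the cross-product ``(a*d)/(b*c)`` with rows =
  {category, rest} and columns = {outcome, rest}; a zero cross product makes
  the OR undefined (reported as null, the table's em-dash), unless the
  optional Haldane-Anscombe +0.5 correction is requested.
* 95% CIs are Woolf intervals: ``exp(ln OR +/- 1.96 * sqrt(sum 1/cell))``.
* Fisher's exact p is two-sided by the "small-p" rule (sum of hypergeometric
  table probabilities <= the observed table's), as implemented by scipy.
* AUROC is the trapezoidal area over all distinct thresholds, which equals
  the pair statistic P(case score > control score) + 0.5 P(equal).
* Balanced accuracy = (sensitivity + specificity) / 2 with predicted-case
  defined as score >= threshold; higher score always predicts case.
* Quantiles interpolate linearly between order statistics.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "Table2x2",
    "OrEstimate",
    "RocCurve",
    "ThresholdScan",
    "RegressionFit",
    "odds_ratio_from_counts",
    "odds_ratio_from_freqs",
    "fisher_exact_2x2",
    "roc_auc",
    "balanced_accuracy_scan",
    "score_centiles",
    "fraction_above",
    "regression_with_band",
    "rank_group_comparison",
]

Z_95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass(frozen=True)
class Table2x2:
    """Counts: a = category & outcome, b = category & not-outcome,
    c = rest & outcome, d = rest & not-outcome."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        counts = (self.a, self.b, self.c, self.d)
        if any(x < 0 for x in counts):
            raise ValueError(f"counts must be non-negative: {counts}")
        if sum(counts) == 0:
            raise ValueError("table total must be positive")

    def transposed(self) -> "Table2x2":
        return Table2x2(self.a, self.c, self.b, self.d)


@dataclass(frozen=True)
class OrEstimate:
    odds_ratio: Optional[float]
    ci_low: Optional[float]
    ci_high: Optional[float]
    p_value: Optional[float]


def fisher_exact_2x2(t: Table2x2) -> float:
    """Two-sided Fisher's exact p for a 2x2 table."""
    return float(stats.fisher_exact([[t.a, t.b], [t.c, t.d]],
                                    alternative="two-sided")[1])


def _woolf_ci(log_or: float, cells: Sequence[float]) -> tuple[float, float]:
    se = math.sqrt(sum(1.0 / x for x in cells))
    return math.exp(log_or - Z_95 * se), math.exp(log_or + Z_95 * se)


def odds_ratio_from_counts(t: Table2x2,
                           haldane_anscombe: bool = False) -> OrEstimate:
    """Cross-product OR with Woolf CI and two-sided Fisher p.

    With a zero cell the OR is undefined and reported as null unless
    ``haldane_anscombe`` adds 0.5 to every cell.
    """
    a, b, c, d = float(t.a), float(t.b), float(t.c), float(t.d)
    p_value = fisher_exact_2x2(t)
    if haldane_anscombe and 0.0 in (a, b, c, d):
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    if a * d == 0.0 or b * c == 0.0:
        return OrEstimate(None, None, None, p_value)
    odds_ratio = (a * d) / (b * c)
    lo, hi = _woolf_ci(math.log(odds_ratio), (a, b, c, d))
    return OrEstimate(odds_ratio, lo, hi, p_value)


def odds_ratio_from_freqs(p_case: float, p_ctrl: float,
                          n_case_alleles: Optional[int] = None,
                          n_ctrl_alleles: Optional[int] = None) -> OrEstimate:
    """OR from the two group frequencies: odds(p_case)/odds(p_ctrl).

    The point estimate uses the frequencies directly. When the group allele
    totals are supplied, counts are reconstructed as round(freq * total) to
    attach a Woolf CI and a Fisher p; the reconstruction is approximate when
    per-locus missingness existed in the real data.
    """
    for p in (p_case, p_ctrl):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"frequency outside [0, 1]: {p}")
    if p_case in (0.0, 1.0) or p_ctrl in (0.0, 1.0):
        p_value = None
        if n_case_alleles and n_ctrl_alleles:
            a = round(p_case * n_case_alleles)
            c = round(p_ctrl * n_ctrl_alleles)
            p_value = fisher_exact_2x2(Table2x2(
                a, n_case_alleles - a, c, n_ctrl_alleles - c))
        return OrEstimate(None, None, None, p_value)
    odds_ratio = (p_case / (1 - p_case)) / (p_ctrl / (1 - p_ctrl))
    if not (n_case_alleles and n_ctrl_alleles):
        return OrEstimate(odds_ratio, None, None, None)
    a = round(p_case * n_case_alleles)
    b = n_case_alleles - a
    c = round(p_ctrl * n_ctrl_alleles)
    d = n_ctrl_alleles - c
    p_value = fisher_exact_2x2(Table2x2(a, b, c, d))
    if 0 in (a, b, c, d):
        return OrEstimate(odds_ratio, None, None, p_value)
    lo, hi = _woolf_ci(math.log(odds_ratio), (a, b, c, d))
    return OrEstimate(odds_ratio, lo, hi, p_value)


# ---------------------------------------------------------------------------
# discrimination

@dataclass(frozen=True)
class RocCurve:
    thresholds: np.ndarray  # descending score cutoffs (predict case if >=)
    sens: np.ndarray
    spec: np.ndarray
    auc: float


def _check_two_classes(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(labels).astype(bool)
    if labels.all() or (~labels).all():
        raise ValueError("both classes must be present")
    return labels, ~labels


def roc_auc(scores: Iterable[float], labels: Iterable[int]) -> RocCurve:
    """ROC curve and AUC; labels are truthy for cases.

    The curve steps at every distinct score; trapezoidal integration over it
    equals the all-pairs statistic with ties counted half.
    """
    scores = np.asarray(list(scores), dtype=float)
    is_case, is_ctrl = _check_two_classes(list(labels))
    n_case, n_ctrl = int(is_case.sum()), int(is_ctrl.sum())

    thresholds = np.unique(scores)[::-1]  # descending
    # counts >= each threshold
    sens = np.array([np.sum(scores[is_case] >= t) for t in thresholds],
                    dtype=float) / n_case
    fpr = np.array([np.sum(scores[is_ctrl] >= t) for t in thresholds],
                   dtype=float) / n_ctrl
    # prepend the all-negative operating point
    sens_full = np.concatenate([[0.0], sens])
    fpr_full = np.concatenate([[0.0], fpr])
    auc = float(np.trapezoid(sens_full, fpr_full))
    return RocCurve(thresholds=thresholds, sens=sens, spec=1.0 - fpr,
                    auc=auc)


@dataclass(frozen=True)
class ThresholdScan:
    grid: np.ndarray
    balanced_accuracy: np.ndarray
    peak_threshold: float
    peak_accuracy: float
    peak_sensitivity: float
    peak_specificity: float


def balanced_accuracy_scan(scores: Iterable[float], labels: Iterable[int],
                           grid_policy: str = "midpoints") -> ThresholdScan:
    """Scan classification thresholds and report the balanced-accuracy peak.

    Balanced accuracy = (sensitivity + specificity)/2 with predicted-case
    defined as score >= threshold. The default grid takes midpoints between
    consecutive distinct scores plus -inf/+inf sentinels (no threshold
    between two adjacent scores can change any prediction, so this grid is
    exhaustive). Ties at the peak resolve to the lowest threshold.
    """
    scores = np.asarray(list(scores), dtype=float)
    is_case, is_ctrl = _check_two_classes(list(labels))
    uniq = np.unique(scores)
    if grid_policy == "midpoints":
        mids = (uniq[:-1] + uniq[1:]) / 2.0
        grid = np.concatenate([[-np.inf], mids, [np.inf]])
    elif grid_policy == "observed":
        grid = uniq
    else:
        raise ValueError(f"unknown grid_policy: {grid_policy!r}")

    n_case, n_ctrl = is_case.sum(), is_ctrl.sum()
    sens = np.array([np.sum(scores[is_case] >= t) for t in grid]) / n_case
    spec = np.array([np.sum(scores[is_ctrl] < t) for t in grid]) / n_ctrl
    bacc = (sens + spec) / 2.0
    peak_idx = int(np.argmax(bacc))  # argmax takes the first (lowest) tie
    return ThresholdScan(
        grid=grid, balanced_accuracy=bacc,
        peak_threshold=float(grid[peak_idx]),
        peak_accuracy=float(bacc[peak_idx]),
        peak_sensitivity=float(sens[peak_idx]),
        peak_specificity=float(spec[peak_idx]),
    )


def score_centiles(scores: Iterable[float],
                   centiles: Sequence[float] = (25, 50, 75)) -> dict[float, float]:
    """Linear-interpolation centiles of a score distribution."""
    scores = np.asarray(list(scores), dtype=float)
    if scores.size == 0:
        raise ValueError("empty score set")
    values = np.percentile(scores, centiles, method="linear")
    return {float(c): float(v) for c, v in zip(centiles, values)}


def fraction_above(scores: Iterable[float], threshold: float) -> float:
    """Fraction of scores strictly above a reference value (e.g. the share
    of a second group above another group's median)."""
    scores = np.asarray(list(scores), dtype=float)
    if scores.size == 0:
        raise ValueError("empty score set")
    return float(np.mean(scores > threshold))


# ---------------------------------------------------------------------------
# regression with prediction band

@dataclass(frozen=True)
class RegressionFit:
    """OLS fit of score on age with a symmetric prediction band."""

    slope: float
    intercept: float
    pearson_r: float
    p_value: float
    band_level: float
    n: int
    outlier_ids: tuple = ()
    _resid_scale: float = 0.0
    _x_mean: float = 0.0
    _sxx: float = 0.0
    _t_crit: float = 0.0

    def predict(self, x) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(x, dtype=float)

    def band(self, x) -> tuple[np.ndarray, np.ndarray]:
        """Lower/upper prediction band at the requested level."""
        x = np.asarray(x, dtype=float)
        half = self._t_crit * self._resid_scale * np.sqrt(
            1.0 + 1.0 / self.n + (x - self._x_mean) ** 2 / self._sxx)
        center = self.predict(x)
        return center - half, center + half


def regression_with_band(x: Iterable[float], y: Iterable[float],
                         band_level: float = 0.99,
                         sample_ids: Optional[Sequence] = None) -> RegressionFit:
    """OLS of y on x, Pearson r with two-sided p, and a prediction band.

    The band is ``yhat +/- t_{(1+level)/2, n-2} * s * sqrt(1 + 1/n +
    (x - xbar)^2 / Sxx)``; points with y below the lower band are flagged
    as outliers (low scores relative to the fitted age trend).
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0.0:
        raise ValueError("x is constant; fit is degenerate")
    fit = stats.linregress(x, y)
    resid = y - (fit.intercept + fit.slope * x)
    s = math.sqrt(float(np.sum(resid ** 2)) / (n - 2))
    sxx = float(np.sum((x - x.mean()) ** 2))
    t_crit = float(stats.t.ppf((1 + band_level) / 2, n - 2))
    result = RegressionFit(
        slope=float(fit.slope), intercept=float(fit.intercept),
        pearson_r=float(fit.rvalue), p_value=float(fit.pvalue),
        band_level=band_level, n=n,
        _resid_scale=s, _x_mean=float(x.mean()), _sxx=sxx, _t_crit=t_crit,
    )
    lower, _ = result.band(x)
    below = np.nonzero(y < lower)[0]
    ids = (tuple(sample_ids[i] for i in below) if sample_ids is not None
           else tuple(int(i) for i in below))
    return RegressionFit(
        slope=result.slope, intercept=result.intercept,
        pearson_r=result.pearson_r, p_value=result.p_value,
        band_level=band_level, n=n, outlier_ids=ids,
        _resid_scale=s, _x_mean=float(x.mean()), _sxx=sxx, _t_crit=t_crit,
    )


# ---------------------------------------------------------------------------
# rank-based group comparison

def _dunn_pairwise(groups: Mapping[str, np.ndarray],
                   adjust: str) -> dict[tuple[str, str], float]:
    labels = list(groups)
    pooled = np.concatenate([groups[g] for g in labels])
    ranks = stats.rankdata(pooled)
    big_n = pooled.size
    mean_ranks, sizes, start = {}, {}, 0
    for g in labels:
        n_g = groups[g].size
        mean_ranks[g] = ranks[start:start + n_g].mean()
        sizes[g] = n_g
        start += n_g
    # tie correction
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts ** 3 - tie_counts)) / (12.0 * (big_n - 1))
    variance_base = big_n * (big_n + 1) / 12.0 - tie_term
    pairs = list(combinations(labels, 2))
    out = {}
    for g1, g2 in pairs:
        se = math.sqrt(variance_base * (1.0 / sizes[g1] + 1.0 / sizes[g2]))
        if se == 0.0:
            out[(g1, g2)] = 1.0
            continue
        z = (mean_ranks[g1] - mean_ranks[g2]) / se
        p = 2.0 * stats.norm.sf(abs(z))
        if adjust == "bonferroni":
            p = min(1.0, p * len(pairs))
        elif adjust != "none":
            raise ValueError(f"unknown adjustment: {adjust!r}")
        out[(g1, g2)] = float(p)
    return out


def rank_group_comparison(groups: Mapping[str, Iterable[float]],
                          adjust: str = "bonferroni") -> dict:
    """Kruskal-Wallis omnibus plus Dunn's pairwise rank post-hoc tests.

    Returns a mapping with an ``"omnibus"`` entry (Kruskal-Wallis p) and one
    ``(label_a, label_b)`` entry per pair, two-sided, adjusted per
    ``adjust`` ("bonferroni" or "none").
    """
    arrays = {g: np.asarray(list(v), dtype=float) for g, v in groups.items()}
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    for g, v in arrays.items():
        if v.size == 0:
            raise ValueError(f"group {g!r} is empty")
    if all(np.ptp(np.concatenate(list(arrays.values()))) == 0.0
           for _ in (0,)):
        omnibus = 1.0  # all values identical; no rank information
    else:
        omnibus = float(stats.kruskal(*arrays.values()).pvalue)
    result: dict = {"omnibus": omnibus}
    result.update(_dunn_pairwise(arrays, adjust))
    return result
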