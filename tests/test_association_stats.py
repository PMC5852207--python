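"""Odds ratios, Fisher tests, ROC/AUC, threshold scans, regression bands."""
import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from t1dgrs.association_stats import (Table2x2, balanced_accuracy_scan,
                                      fisher_exact_2x2, fraction_above,
                                      odds_ratio_from_counts,
                                      odds_ratio_from_freqs,
                                      rank_group_comparison,
                                      regression_with_band, roc_auc,
                                      score_centiles)

# ---------------------------------------------------------------------------
# independent oracles

def fisher_oracle(a, b, c, d):
    """Exhaustive two-sided Fisher p by exact rational enumeration over all
    tables with the observed margins (small-p rule)."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    weight_obs = math.comb(r1, a) * math.comb(r2, c1 - a)
    total = math.comb(n, c1)
    acc = 0
    for k in range(max(0, c1 - r2), min(r1, c1) + 1):
        w = math.comb(r1, k) * math.comb(r2, c1 - k)
        if w <= weight_obs:
            acc += w
    return float(Fraction(acc, total))


def auc_pair_oracle(scores, labels):
    """Brute-force all-pairs statistic: P(case > control) + 0.5 P(tie)."""
    cases = [s for s, y in zip(scores, labels) if y]
    ctrls = [s for s, y in zip(scores, labels) if not y]
    wins = sum((c > k) + 0.5 * (c == k) for c in cases for k in ctrls)
    return wins / (len(cases) * len(ctrls))


def scan_oracle(scores, labels):
    """Exhaustive balanced-accuracy maximum: the step function only changes
    at observed scores, so observed values, midpoints and sentinels cover
    every piece of the threshold axis."""
    uniq = sorted(set(scores))
    candidates = ([-math.inf, math.inf] + uniq
                  + [(x + y) / 2 for x, y in zip(uniq, uniq[1:])])
    best = -1.0
    n1 = sum(labels)
    n0 = len(labels) - n1
    for t in candidates:
        sens = sum(1 for s, y in zip(scores, labels) if y and s >= t) / n1
        spec = sum(1 for s, y in zip(scores, labels)
                   if not y and s < t) / n0
        best = max(best, (sens + spec) / 2)
    return best


# ---------------------------------------------------------------------------
# odds ratios from counts

def test_printed_contingency_ors_reproduce():
    assert odds_ratio_from_counts(
        Table2x2(56, 70, 94, 231)).odds_ratio == pytest.approx(1.97,
                                                               abs=0.005)
    assert odds_ratio_from_counts(
        Table2x2(29, 12, 200, 210)).odds_ratio == pytest.approx(2.54,
                                                                abs=0.005)


def test_uniform_table_gives_null_association():
    est = odds_ratio_from_counts(Table2x2(7, 7, 7, 7))
    assert est.odds_ratio == pytest.approx(1.0)
    assert est.p_value == pytest.approx(1.0)


def test_zero_cell_or_undefined_unless_corrected():
    est = odds_ratio_from_counts(Table2x2(5, 0, 3, 7))
    assert est.odds_ratio is None and est.ci_low is None
    assert est.p_value is not None
    corrected = odds_ratio_from_counts(Table2x2(5, 0, 3, 7),
                                       haldane_anscombe=True)
    assert corrected.odds_ratio is not None


def test_negative_counts_rejected():
    with pytest.raises(ValueError):
        Table2x2(-1, 2, 3, 4)


@settings(deadline=None, max_examples=60)
@given(st.tuples(*[st.integers(1, 30)] * 4))
def test_or_symmetry_under_table_rearrangements(cells):
    t = Table2x2(*cells)
    est = odds_ratio_from_counts(t)
    # exchanging exposure with outcome (matrix transpose) keeps the OR
    est_t = odds_ratio_from_counts(t.transposed())
    assert est_t.odds_ratio == pytest.approx(est.odds_ratio)
    # flipping the outcome columns inverts it
    a, b, c, d = cells
    est_flip = odds_ratio_from_counts(Table2x2(b, a, d, c))
    assert est_flip.odds_ratio == pytest.approx(1.0 / est.odds_ratio)
    # Fisher p is invariant under row/column swaps
    a, b, c, d = cells
    assert fisher_exact_2x2(Table2x2(c, d, a, b)) == pytest.approx(
        fisher_exact_2x2(t))
    assert fisher_exact_2x2(Table2x2(b, a, d, c)) == pytest.approx(
        fisher_exact_2x2(t))


def test_woolf_ci_contains_estimate_and_scales_with_counts():
    est = odds_ratio_from_counts(Table2x2(20, 30, 15, 40))
    assert est.ci_low <= est.odds_ratio <= est.ci_high
    est4 = odds_ratio_from_counts(Table2x2(80, 120, 60, 160))
    width = math.log(est.ci_high) - math.log(est.ci_low)
    width4 = math.log(est4.ci_high) - math.log(est4.ci_low)
    assert width4 == pytest.approx(width / 2)


@settings(deadline=None, max_examples=150)
@given(st.tuples(*[st.integers(0, 6)] * 4).filter(
    lambda t: 0 < sum(t) <= 12))
def test_fisher_matches_exact_enumeration_on_small_tables(cells):
    p = fisher_exact_2x2(Table2x2(*cells))
    assert p == pytest.approx(fisher_oracle(*cells), abs=1e-8)


# ---------------------------------------------------------------------------
# odds ratios from frequencies

def test_printed_frequency_ors_reproduce():
    assert odds_ratio_from_freqs(0.1542, 0.0734).odds_ratio == pytest.approx(
        2.30, abs=0.005)
    assert odds_ratio_from_freqs(0.1429, 0.0538).odds_ratio == pytest.approx(
        2.93, abs=0.005)


def test_equal_frequencies_give_unit_or():
    assert odds_ratio_from_freqs(0.3, 0.3).odds_ratio == pytest.approx(1.0)


def test_boundary_frequency_gives_undefined_or():
    assert odds_ratio_from_freqs(0.0, 0.2).odds_ratio is None
    assert odds_ratio_from_freqs(0.5, 1.0).odds_ratio is None


def test_invalid_frequency_rejected():
    with pytest.raises(ValueError):
        odds_ratio_from_freqs(1.2, 0.5)


def test_reconstructed_count_ci_matches_printed_interval():
    """Allele counts rebuilt as freq x 2N give the printed 95% CI for the
    strongest non-HLA locus (N = 478 cases / 290 controls)."""
    est = odds_ratio_from_freqs(0.1542, 0.0734, n_case_alleles=956,
                                n_ctrl_alleles=580)
    assert est.odds_ratio == pytest.approx(2.30, abs=0.005)
    assert est.ci_low == pytest.approx(1.61, abs=0.005)
    assert est.ci_high == pytest.approx(3.29, abs=0.005)
    assert est.p_value < 1e-5


# ---------------------------------------------------------------------------
# ROC / AUC

def test_perfect_separation_gives_unit_auc():
    roc = roc_auc([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
    assert roc.auc == pytest.approx(1.0)
    assert np.all(roc.sens >= 0) and np.all(roc.sens <= 1)
    assert np.all(roc.spec >= 0) and np.all(roc.spec <= 1)


def test_identical_scores_give_chance_auc():
    roc = roc_auc([5, 5, 5, 5], [0, 1, 0, 1])
    assert roc.auc == pytest.approx(0.5)


def test_single_class_rejected():
    with pytest.raises(ValueError):
        roc_auc([1, 2, 3], [1, 1, 1])


@settings(deadline=None, max_examples=120)
@given(st.data())
def test_auc_equals_pair_counting_oracle(data):
    n = data.draw(st.integers(4, 12))
    scores = data.draw(st.lists(st.integers(0, 5), min_size=n, max_size=n))
    labels = data.draw(st.lists(st.booleans(), min_size=n, max_size=n)
                       .filter(lambda L: 0 < sum(L) < len(L)))
    auc = roc_auc(scores, labels).auc
    assert auc == pytest.approx(auc_pair_oracle(scores, labels), abs=1e-12)


def test_auc_invariant_under_strictly_monotone_transform():
    rng = np.random.default_rng(0)
    scores = rng.normal(size=40)
    labels = rng.random(40) < 0.5
    labels[0], labels[1] = True, False
    assert roc_auc(np.exp(scores), labels).auc == roc_auc(scores, labels).auc


# ---------------------------------------------------------------------------
# balanced-accuracy scan

def test_separable_scores_reach_perfect_accuracy():
    scan = balanced_accuracy_scan([1, 2, 3, 4], [0, 0, 1, 1])
    assert scan.peak_accuracy == pytest.approx(1.0)
    assert 2 < scan.peak_threshold < 3


def test_constant_scores_give_chance_accuracy():
    scan = balanced_accuracy_scan([2, 2, 2, 2], [0, 1, 0, 1])
    assert scan.peak_accuracy == pytest.approx(0.5)


@settings(deadline=None, max_examples=120)
@given(st.data())
def test_scan_peak_equals_exhaustive_threshold_evaluation(data):
    n = data.draw(st.integers(4, 10))
    scores = data.draw(st.lists(
        st.floats(0, 1, allow_nan=False, width=32), min_size=n, max_size=n))
    labels = data.draw(st.lists(st.booleans(), min_size=n, max_size=n)
                       .filter(lambda L: 0 < sum(L) < len(L)))
    scan = balanced_accuracy_scan(scores, labels)
    assert scan.peak_accuracy == pytest.approx(scan_oracle(scores, labels),
                                               abs=1e-12)
    assert scan.peak_accuracy >= 0.5


def test_peak_ties_resolve_to_lowest_threshold():
    # any threshold below all scores ties the all-positive sentinel
    scan = balanced_accuracy_scan([1.0, 2.0], [1, 0])
    grid_peaks = scan.grid[np.isclose(scan.balanced_accuracy,
                                      scan.peak_accuracy)]
    assert scan.peak_threshold == grid_peaks.min()


# ---------------------------------------------------------------------------
# centiles

def test_centiles_interpolate_linearly():
    centiles = score_centiles(range(1, 101), (25, 50, 75))
    assert centiles[50.0] == pytest.approx(50.5)
    assert centiles[25.0] == pytest.approx(25.75)


def test_constant_scores_collapse_centiles():
    centiles = score_centiles([3.0] * 10)
    assert set(centiles.values()) == {3.0}


def test_identical_distribution_half_above_reference_median():
    rng = np.random.default_rng(42)
    group_a = rng.normal(size=1000)
    group_b = rng.normal(size=1000)
    median_a = score_centiles(group_a)[50.0]
    assert fraction_above(group_b, median_a) == pytest.approx(0.5, abs=0.05)


# ---------------------------------------------------------------------------
# regression with prediction band

def test_noiseless_line_gives_unit_correlation_and_no_outliers():
    x = np.arange(10, dtype=float)
    fit = regression_with_band(x, 3.0 - 0.5 * x)
    assert fit.pearson_r == pytest.approx(-1.0)
    assert fit.outlier_ids == ()


def test_band_coverage_near_nominal_level():
    rng = np.random.default_rng(7)
    x = rng.uniform(0, 30, size=500)
    y = rng.normal(size=500)
    fit = regression_with_band(x, y, band_level=0.99)
    lower, upper = fit.band(x)
    outside = np.mean((y < lower) | (y > upper))
    assert 0.0 <= outside <= 0.03  # ~1% expected outside a 99% band
    assert abs(fit.pearson_r) < 0.15


def test_constructed_low_point_is_flagged():
    x = np.linspace(0, 20, 40)
    y = -x + np.zeros_like(x)
    y[13] -= 30.0
    fit = regression_with_band(x, y, sample_ids=[f"s{i}" for i in range(40)])
    assert "s13" in fit.outlier_ids


def test_band_widens_away_from_mean():
    rng = np.random.default_rng(1)
    x = rng.uniform(0, 10, 50)
    fit = regression_with_band(x, 2 * x + rng.normal(size=50))
    lo_center, hi_center = fit.band(np.mean(x))
    lo_edge, hi_edge = fit.band(np.max(x) + 5)
    assert (hi_edge - lo_edge) > (hi_center - lo_center)


def test_degenerate_regression_inputs_rejected():
    with pytest.raises(ValueError):
        regression_with_band([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
    with pytest.raises(ValueError):
        regression_with_band([1.0, 2.0], [1.0, 2.0])


# ---------------------------------------------------------------------------
# rank-based group comparisons

def test_identical_groups_not_significant():
    values = list(range(30))
    result = rank_group_comparison({"a": values, "b": values})
    assert result["omnibus"] > 0.9
    assert result[("a", "b")] > 0.9


def test_widely_separated_groups_significant():
    rng = np.random.default_rng(3)
    result = rank_group_comparison({
        "low": rng.normal(0, 1, 50), "high": rng.normal(10, 1, 50)})
    assert result["omnibus"] < 1e-3
    assert result[("low", "high")] < 1e-3


def test_only_shifted_group_flags_in_three_way_comparison():
    rng = np.random.default_rng(9)
    groups = {
        "a": rng.normal(0, 1, 100),
        "b": rng.normal(0, 1, 100),
        "c": rng.normal(2.0, 1, 100),
    }
    result = rank_group_comparison(groups)
    assert result[("a", "b")] > 0.05
    assert result[("a", "c")] < 0.05
    assert result[("b", "c")] < 0.05


def test_empty_group_rejected():
    with pytest.raises(ValueError):
        rank_group_comparison({"a": [1.0], "b": []})
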