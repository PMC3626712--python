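"""Contingency tables, classification metrics, OR, CI and p-values.

Expected values for the printed-table rows were re-derived by direct
arithmetic from the printed count pairs (C = 220 cases, N = 334 controls).
"""

import math

import numpy as np
import pytest
from statsmodels.stats.contingency_tables import Table2x2

from epibb import (
    ContingencyTable,
    MatchCounts,
    association_p_value,
    classification_metrics,
    compute_metrics,
    genotype_vs_reference_table,
    odds_ratio,
    odds_ratio_ci,
    pattern_vs_rest_table,
)
from epibb.stats import round_half_away

from conftest import single_snp_dataset


def test_pattern_vs_rest_layout():
    t = pattern_vs_rest_table(MatchCounts(controls_matched=4, cases_matched=11),
                              n_cases=220, n_controls=334)
    assert (t.tp, t.fp, t.fn, t.tn) == (11, 4, 209, 330)
    t0 = pattern_vs_rest_table(MatchCounts(0, 0), 220, 334)
    assert (t0.tp, t0.fp, t0.fn, t0.tn) == (0, 0, 220, 334)
    with pytest.raises(ValueError):
        pattern_vs_rest_table(MatchCounts(400, 0), 220, 334)


def test_pattern_vs_rest_cells_resum_to_totals():
    rng = np.random.default_rng(0)
    for _ in range(50):
        fp, tp = int(rng.integers(0, 335)), int(rng.integers(0, 221))
        t = pattern_vs_rest_table(MatchCounts(fp, tp), 220, 334)
        assert t.tp + t.fn == 220 and t.fp + t.tn == 334


# (controls_matched, cases_matched) -> printed OR, from the report tables
PRINTED_ORS = [
    (4, 11, 4.342),
    (137, 69, 0.657),
    (20, 29, 2.384),
    (9, 17, 3.024),
    (1, 4, 6.167),
    (24, 5, 0.300),
    (9, 1, 0.165),
    (97, 66, 1.047),
    (5, 10, 3.133),
]


@pytest.mark.parametrize("fp,tp,expected", PRINTED_ORS)
def test_printed_odds_ratios_reproduce(fp, tp, expected):
    t = pattern_vs_rest_table(MatchCounts(fp, tp), 220, 334)
    assert round_half_away(odds_ratio(t)) == expected


def test_printed_metrics_rows_reproduce():
    # two-SNP high-risk row: 0.616 / 0.050 / 0.988 / 0.551
    m = classification_metrics(ContingencyTable(11, 4, 209, 330))
    rounded = tuple(round_half_away(v) for v in m)
    assert rounded == (0.616, 0.050, 0.988, 0.551)
    # three-SNP high-risk row: 0.619 / 0.132 / 0.940
    m2 = classification_metrics(ContingencyTable(29, 20, 191, 314))
    assert round_half_away(m2.cc) == 0.619
    assert round_half_away(m2.sn) == 0.132
    assert round_half_away(m2.sp) == 0.940
    # the same counts appear with SP printed as both 0.589 and 0.600 in the
    # source tables; the arithmetic gives 197/334 = 0.590
    m3 = classification_metrics(ContingencyTable(69, 137, 151, 197))
    assert round_half_away(m3.sp) == 0.590


def test_perfect_classifier_metrics():
    m = classification_metrics(ContingencyTable(220, 0, 0, 334))
    assert m == (1.0, 1.0, 1.0, 1.0)


def test_degenerate_metrics_are_not_estimable():
    m = classification_metrics(ContingencyTable(0, 0, 0, 0))
    assert m.cc is None and m.average is None


def test_genotype_vs_reference_reproduces_baseline_or():
    # rs12812942: AT 141 controls/76 cases vs AA reference 174/128 -> 0.733
    ds = single_snp_dataset(
        {1: (174, 128), 2: (141, 76), 3: (19, 16)}, n_cases=220, n_controls=334
    )
    t = genotype_vs_reference_table(ds, 0, genotype_code=2)
    assert (t.tp, t.fp, t.fn, t.tn) == (76, 141, 128, 174)
    assert round_half_away(odds_ratio(t)) == 0.733
    empty = single_snp_dataset({1: (5, 5)}, n_cases=6, n_controls=6)
    t2 = genotype_vs_reference_table(empty, 0, genotype_code=3)
    assert t2.tp == 0 and t2.fp == 0
    with pytest.raises(ValueError):
        genotype_vs_reference_table(ds, 0, genotype_code=1, reference_code=1)


def test_zero_cell_or_not_estimable_and_correction():
    t = ContingencyTable(4, 0, 216, 334)  # six-SNP row: 0 matching controls
    assert odds_ratio(t) is None
    corrected = odds_ratio(t, zero_correction=True)
    assert corrected == pytest.approx(4.5 * 334.5 / (216.5 * 0.5))


def test_or_inverts_when_roles_swap():
    t = ContingencyTable(11, 4, 209, 330)
    assert odds_ratio(t.swapped_roles()) == pytest.approx(1 / odds_ratio(t))


def test_woolf_ci_closed_form():
    t = ContingencyTable(11, 4, 209, 330)
    lo, hi = odds_ratio_ci(t, method="woolf")
    se = math.sqrt(1 / 11 + 1 / 4 + 1 / 209 + 1 / 330)
    z = 1.959963984540054
    assert lo == pytest.approx(math.exp(math.log(4.342105263) - z * se))
    assert hi == pytest.approx(math.exp(math.log(4.342105263) + z * se))
    # agrees with the statsmodels log-OR interval
    sm_lo, sm_hi = Table2x2(t.as_array()).oddsratio_confint(0.05)
    assert (lo, hi) == (pytest.approx(sm_lo), pytest.approx(sm_hi))
    assert odds_ratio_ci(ContingencyTable(0, 4, 216, 330), method="woolf") is None


def test_woolf_ci_contains_point_and_widens_with_level():
    t = ContingencyTable(29, 20, 191, 314)
    or_ = odds_ratio(t)
    lo95, hi95 = odds_ratio_ci(t, method="woolf", level=0.95)
    lo99, hi99 = odds_ratio_ci(t, method="woolf", level=0.99)
    assert lo95 < or_ < hi95
    assert lo99 < lo95 and hi99 > hi95


def test_symmetric_table_ci_straddles_one():
    t = ContingencyTable(30, 30, 70, 70)
    for method in ("woolf", "exact"):
        lo, hi = odds_ratio_ci(t, method=method)
        assert lo < 1 < hi


def test_exact_ci_near_printed_lower_bounds():
    # printed lower bounds: 0.452 for the (69,137,151,197) table,
    # 1.259 for the (11,4,209,330) table; spec tolerance +/- 0.02
    lo, _ = odds_ratio_ci(ContingencyTable(69, 137, 151, 197), method="exact")
    assert lo == pytest.approx(0.452, abs=0.02)
    lo2, _ = odds_ratio_ci(ContingencyTable(11, 4, 209, 330), method="exact")
    assert lo2 == pytest.approx(1.259, abs=0.02)
    with pytest.raises(ValueError):
        odds_ratio_ci(ContingencyTable(1, 1, 1, 1), method="bogus")


def test_fisher_p_matches_printed_value():
    assert association_p_value(
        ContingencyTable(69, 137, 151, 197)
    ) == pytest.approx(0.025, abs=0.005)
    assert association_p_value(
        ContingencyTable(11, 4, 209, 330)
    ) == pytest.approx(0.013, abs=0.005)


def test_chi2_statistic_identity():
    # n(ad-bc)^2 / ((a+b)(c+d)(a+c)(b+d)) for the (69,137;151,197) table
    a, b, c, d = 69, 137, 151, 197
    n = a + b + c + d
    stat = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
    assert stat == pytest.approx(5.29, abs=0.01)
    from scipy.stats import chi2

    expected_p = float(chi2.sf(stat, 1))
    assert association_p_value(
        ContingencyTable(a, b, c, d), method="chi2"
    ) == pytest.approx(expected_p)


def test_independence_table_p_near_one():
    # cells exactly at the margins' independence expectation
    t = ContingencyTable(20, 30, 40, 60)
    assert association_p_value(t) == pytest.approx(1.0, abs=1e-9)
    assert association_p_value(ContingencyTable(0, 0, 5, 5)) is None
    with pytest.raises(ValueError):
        association_p_value(t, method="bogus")


def test_metrics_result_ne_propagation():
    # zero matching controls: OR not estimable, Average suppressed
    t = ContingencyTable(4, 0, 216, 334)
    mr = compute_metrics(t)
    assert mr.odds_ratio is None
    assert mr.average is None
    assert mr.sp == 1.0
    # estimable table keeps its average
    mr2 = compute_metrics(ContingencyTable(11, 4, 209, 330))
    assert round_half_away(mr2.average) == 0.551


def test_rounding_is_half_away_from_zero():
    assert round_half_away(0.0005) == 0.001
    assert round_half_away(-0.0005) == -0.001
    assert round_half_away(2.3835) == 2.384
    assert math.isinf(round_half_away(math.inf))


def test_metric_bounds_on_random_tables():
    rng = np.random.default_rng(1)
    for _ in range(200):
        cells = rng.integers(0, 50, size=4)
        t = ContingencyTable(*map(int, cells))
        m = classification_metrics(t)
        for v in m:
            assert v is None or 0.0 <= v <= 1.0
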