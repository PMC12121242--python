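"""Agreement statistics against brute-force oracles and known values."""

import math
import warnings

import numpy as np
import pytest
from scipy import stats

from mrsdat import (
    PairedSample,
    agreement_summary,
    assign_tertiles,
    bland_altman,
    concordance_report,
    lins_ccc,
    paired_compare,
    sensitivity_with_outlier,
    weighted_kappa,
)
from mrsdat.concordance import bonferroni, tertile_crosstab
from mrsdat.errors import DegenerateInputError


# ---------------------------------------------------------------------------
# oracles (independent, loop-based implementations)


def ccc_oracle(x, y):
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sx2 = sum((v - mx) ** 2 for v in x) / n
    sy2 = sum((v - my) ** 2 for v in y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y)) / n
    return 2 * sxy / (sx2 + sy2 + (mx - my) ** 2)


def ols_slope_oracle(m, d):
    """Normal equations for d ~ a + b m, with the two-sided t-test p for b."""
    n = len(m)
    mbar = sum(m) / n
    dbar = sum(d) / n
    sxx = sum((v - mbar) ** 2 for v in m)
    sxy = sum((a - mbar) * (b - dbar) for a, b in zip(m, d))
    slope = sxy / sxx
    intercept = dbar - slope * mbar
    rss = sum((b - intercept - slope * a) ** 2 for a, b in zip(m, d))
    se = math.sqrt(rss / (n - 2) / sxx)
    t = slope / se
    p = 2 * stats.t.sf(abs(t), n - 2)
    return slope, p


def kappa_oracle(t_x, t_y, weights="linear"):
    table = [[0] * 3 for _ in range(3)]
    for a, b in zip(t_x, t_y):
        table[a - 1][b - 1] += 1
    n = len(t_x)
    row = [sum(table[i]) for i in range(3)]
    col = [sum(table[i][j] for i in range(3)) for j in range(3)]
    po = pe = 0.0
    for i in range(3):
        for j in range(3):
            w = 1 - abs(i - j) / 2 if weights == "linear" else 1 - (abs(i - j) / 2) ** 2
            po += w * table[i][j] / n
            pe += w * row[i] * col[j] / n**2
    return (po - pe) / (1 - pe)


def t_oracle(x, y):
    d = [a - b for a, b in zip(x, y)]
    n = len(d)
    mean = sum(d) / n
    sd = math.sqrt(sum((v - mean) ** 2 for v in d) / (n - 1))
    t = mean / (sd / math.sqrt(n))
    return mean, 2 * stats.t.sf(abs(t), n - 1)


# ---------------------------------------------------------------------------
# Lin's CCC


def test_ccc_perfect_concordance():
    x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0, 9.0, 10.0])
    rc, ci = lins_ccc(x, x.copy())
    assert rc == pytest.approx(1.0)
    assert ci[0] <= rc <= ci[1]


def test_ccc_hand_computed_values():
    with pytest.warns(UserWarning, match="robust"):
        rc, _ = lins_ccc(np.array([1.0, 2, 3]), np.array([3.0, 2, 1]))
    assert rc == pytest.approx(-1.0)
    with pytest.warns(UserWarning, match="robust"):
        rc, _ = lins_ccc(np.array([1.0, 2, 3]), np.array([2.0, 3, 4]))
    assert rc == pytest.approx(4.0 / 7.0)


def test_ccc_degenerate_inputs_error():
    with pytest.raises(DegenerateInputError):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            lins_ccc(np.ones(12), np.arange(12.0))


def test_ccc_matches_oracle_symmetry_and_pearson_bound():
    rng = np.random.default_rng(42)
    for _ in range(50):
        n = int(rng.integers(10, 50))
        x = rng.normal(50, 10, n)
        y = 0.6 * x + rng.normal(0, 8, n) + rng.normal(0, 3)
        rc, ci = lins_ccc(x, y)
        assert rc == pytest.approx(ccc_oracle(list(x), list(y)), rel=1e-12)
        assert lins_ccc(y, x)[0] == pytest.approx(rc, rel=1e-12)
        r = stats.pearsonr(x, y).statistic
        assert abs(rc) <= abs(r) + 1e-12
        assert ci[0] - 1e-12 <= rc <= ci[1] + 1e-12
        assert -1 <= ci[0] <= ci[1] <= 1


def test_ccc_equals_pearson_when_moments_match():
    rng = np.random.default_rng(3)
    x = rng.normal(0, 1, 40)
    y = rng.permutation(x)  # identical mean and variance
    rc, _ = lins_ccc(x, y)
    assert rc == pytest.approx(stats.pearsonr(x, y).statistic, abs=1e-12)


def test_ccc_invariant_to_participant_relabeling():
    rng = np.random.default_rng(8)
    x = rng.normal(50, 10, 30)
    y = x + rng.normal(0, 5, 30)
    perm = rng.permutation(30)
    assert lins_ccc(x[perm], y[perm])[0] == pytest.approx(lins_ccc(x, y)[0], rel=1e-12)


# ---------------------------------------------------------------------------
# Bland-Altman


def test_ba_identical_methods():
    x = np.array([1.0, 2, 3, 4, 5])
    bias, loa, slope, slope_p = bland_altman(x, x.copy())
    assert bias == 0.0
    assert loa == (0.0, 0.0)
    assert slope == 0.0


def test_ba_constant_offset():
    x = np.array([3.0, 5, 7, 9])
    bias, loa, slope, _ = bland_altman(x, x - 2.0)
    assert bias == pytest.approx(2.0)
    assert loa == pytest.approx((2.0, 2.0))
    assert slope == 0.0


def test_ba_small_fixture_matches_normal_equations():
    x = np.array([52.1, 47.3, 60.8, 39.5, 55.0, 44.2])
    y = np.array([49.8, 50.1, 55.4, 42.0, 58.3, 40.7])
    bias, loa, slope, slope_p = bland_altman(x, y)
    d = x - y
    assert bias == pytest.approx(d.mean(), rel=1e-12)
    sd = d.std(ddof=1)
    assert loa == pytest.approx((bias - 1.96 * sd, bias + 1.96 * sd), rel=1e-12)
    o_slope, o_p = ols_slope_oracle(list((x + y) / 2), list(d))
    assert slope == pytest.approx(o_slope, rel=1e-10)
    assert slope_p == pytest.approx(o_p, rel=1e-10)


def test_ba_constant_means_error():
    with pytest.raises(DegenerateInputError):
        bland_altman(np.array([1.0, 2, 3]), np.array([3.0, 2, 1]))


def test_ba_loa_order_invariant():
    rng = np.random.default_rng(11)
    x = rng.normal(50, 12, 100)
    y = x + rng.normal(1.0, 6, 100)
    bias, loa, *_ = bland_altman(x, y)
    assert loa[0] <= bias <= loa[1]


# ---------------------------------------------------------------------------
# tertiles, kappa, agreement


def test_tertiles_nine_distinct_split_evenly():
    labels = assign_tertiles(np.arange(1.0, 10.0))
    assert sorted(np.bincount(labels)[1:]) == [3, 3, 3]


def test_tertiles_one_to_ten_convention():
    labels = assign_tertiles(np.arange(1.0, 11.0))
    counts = np.bincount(labels)[1:]
    assert list(counts) == [4, 3, 3]


def test_tertiles_all_tied_warns_and_assigns_one():
    with pytest.warns(UserWarning, match="tied"):
        labels = assign_tertiles(np.full(9, 2.5))
    assert (labels == 1).all()


def test_tertiles_stable_under_participant_order():
    rng = np.random.default_rng(5)
    v = rng.normal(size=30)
    perm = rng.permutation(30)
    assert (assign_tertiles(v)[perm] == assign_tertiles(v[perm])).all()


def test_kappa_identical_labelings():
    t = np.array([1, 2, 3, 1, 2, 3, 2, 1, 3])
    assert weighted_kappa(t, t) == pytest.approx(1.0)


def test_kappa_uniform_independence_is_zero():
    t_x = np.repeat([1, 2, 3], 3)
    t_y = np.tile([1, 2, 3], 3)
    assert weighted_kappa(t_x, t_y) == pytest.approx(0.0, abs=1e-12)


def test_kappa_fixed_crosstab_hand_value():
    # cross-table [[5,2,0],[1,6,2],[0,3,5]]: po = 5/6, pe = 338/576
    table = [[5, 2, 0], [1, 6, 2], [0, 3, 5]]
    t_x, t_y = [], []
    for i in range(3):
        for j in range(3):
            t_x += [i + 1] * table[i][j]
            t_y += [j + 1] * table[i][j]
    kappa = weighted_kappa(np.array(t_x), np.array(t_y))
    assert kappa == pytest.approx(71.0 / 119.0, rel=1e-12)
    assert (tertile_crosstab(t_x, t_y) == np.array(table)).all()


def test_kappa_matches_oracle_and_sklearn_on_random_labels():
    sklearn_metrics = pytest.importorskip("sklearn.metrics")
    rng = np.random.default_rng(17)
    for _ in range(20):
        n = int(rng.integers(12, 60))
        t_x = rng.integers(1, 4, n)
        t_y = np.where(rng.random(n) < 0.6, t_x, rng.integers(1, 4, n))
        if len(np.unique(t_x)) < 3 or len(np.unique(t_y)) < 3:
            continue
        ours = weighted_kappa(t_x, t_y)
        assert ours == pytest.approx(kappa_oracle(list(t_x), list(t_y)), rel=1e-12)
        assert ours == pytest.approx(
            sklearn_metrics.cohen_kappa_score(t_x, t_y, weights="linear"), rel=1e-9
        )
        assert -1.0 <= ours <= 1.0
        quad = weighted_kappa(t_x, t_y, weights="quadratic")
        assert quad == pytest.approx(
            sklearn_metrics.cohen_kappa_score(t_x, t_y, weights="quadratic"), rel=1e-9
        )


def test_agreement_summary_cases():
    t = np.array([1, 2, 3, 1, 2])
    assert agreement_summary(t, t) == (100.0, 0.0, 0)
    t_x = np.array([1] + [2] * 9)
    t_y = np.array([3] + [2] * 9)
    same, adjacent, gross = agreement_summary(t_x, t_y)
    assert gross == 1
    assert same + adjacent + 100.0 * gross / len(t_x) == pytest.approx(100.0)


def test_agreement_percentages_partition():
    rng = np.random.default_rng(23)
    t_x = rng.integers(1, 4, 500)
    t_y = rng.integers(1, 4, 500)
    same, adjacent, gross = agreement_summary(t_x, t_y)
    assert same + adjacent + 100.0 * gross / 500 == pytest.approx(100.0)


# ---------------------------------------------------------------------------
# paired tests


def test_paired_t_identical_vectors():
    x = np.array([1.0, 2, 3, 4])
    res = paired_compare(x, x.copy(), test="t", m=7)
    assert res.statistic == 0.0
    assert res.p_adjusted == 1.0


def test_bonferroni_cap():
    assert bonferroni(0.01, 7) == pytest.approx(0.07)
    assert bonferroni(0.5, 7) == 1.0


def test_paired_t_matches_oracle():
    rng = np.random.default_rng(31)
    x = rng.normal(50, 10, 25)
    y = x + rng.normal(1, 4, 25)
    res = paired_compare(x, y, test="t", m=3)
    mean, p = t_oracle(list(x), list(y))
    assert res.statistic == pytest.approx(mean, rel=1e-12)
    assert res.p_raw == pytest.approx(p, rel=1e-10)
    assert res.p_adjusted == pytest.approx(min(1.0, 3 * p), rel=1e-10)
    assert res.p_adjusted >= res.p_raw


def test_wilcoxon_matches_scipy_normal_approximation():
    rng = np.random.default_rng(37)
    for _ in range(20):
        n = int(rng.integers(8, 40))
        x = rng.normal(50, 10, n)
        y = x + rng.choice([-2.0, -1.0, 0.0, 1.0, 2.0], n)  # ties and zeros
        if (x == y).all():
            continue
        res = paired_compare(x, y, test="wilcoxon", m=1)
        ref = stats.wilcoxon(
            x, y, zero_method="wilcox", correction=False, method="approx"
        )
        assert res.p_raw == pytest.approx(ref.pvalue, rel=1e-9)
        assert res.statistic_kind == "wilcoxon_z"
        # |z| reproduces the scipy p-value through the normal tail
        assert 2 * stats.norm.sf(abs(res.statistic)) == pytest.approx(
            ref.pvalue, rel=1e-9
        )


def test_wilcoxon_all_zero_differences_degenerate():
    x = np.array([1.0, 2, 3])
    with pytest.raises(DegenerateInputError):
        paired_compare(x, x.copy(), test="wilcoxon")


# ---------------------------------------------------------------------------
# full report and sensitivity analysis


def _sample(n=40, seed=2, outlier=False):
    rng = np.random.default_rng(seed)
    x = rng.normal(50, 11, n)
    y = 0.8 * x + rng.normal(10, 6, n)
    ids = [f"p{i}" for i in range(n)]
    if outlier:
        x = np.append(x, 5.0)
        y = np.append(y, 60.0)
        ids.append("outlier")
    return PairedSample(participant_ids=tuple(ids), x=x, y=y)


def test_report_internal_consistency():
    rep = concordance_report(_sample())
    assert rep.tertile_table.sum() == rep.n
    assert rep.loa[0] <= rep.bias <= rep.loa[1]
    assert rep.rc_ci[0] <= rep.rc <= rep.rc_ci[1]
    total = rep.pct_same_tertile + rep.pct_adjacent + 100.0 * rep.n_gross / rep.n
    assert total == pytest.approx(100.0)


def test_sensitivity_no_flags_identical():
    sample = _sample()
    with_all, without, deltas = sensitivity_with_outlier(sample, [])
    assert with_all.rc == without.rc
    assert deltas == {"rc": 0.0, "bias": 0.0, "kappa_w": 0.0}


def test_sensitivity_excludes_flagged_participant():
    sample = _sample(outlier=True)
    with_all, without, deltas = sensitivity_with_outlier(sample, ["outlier"])
    assert with_all.n == without.n + 1
    assert deltas["rc"] == pytest.approx(with_all.rc - without.rc)
    assert deltas["rc"] != 0.0
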