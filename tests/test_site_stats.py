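"""Descriptive summaries and exact nonparametric tests against oracles."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats

from ohpcb.site_stats import (
    RegressionFit,
    gm_gsd,
    loglog_fit,
    mann_whitney_exact,
    pearson_log,
    ratio_ohpcb_pcb,
    spearman_exact,
    summarize,
)


def test_gm_examples():
    assert gm_gsd([12.0, 12.0])["gm"] == pytest.approx(12.0)
    assert gm_gsd([1.0, 100.0])["gm"] == pytest.approx(10.0)


def test_gm_matches_product_oracle():
    rng = np.random.default_rng(1)
    for _ in range(20):
        vals = rng.lognormal(0, 1, size=rng.integers(2, 9))
        oracle = float(np.prod(vals) ** (1.0 / vals.size))
        assert gm_gsd(vals)["gm"] == pytest.approx(oracle)


def test_gm_never_exceeds_arithmetic_mean():
    rng = np.random.default_rng(2)
    for _ in range(20):
        vals = rng.lognormal(0, 1, size=6)
        assert gm_gsd(vals)["gm"] <= vals.mean() + 1e-12


def test_gm_rejects_nonpositive():
    with pytest.raises(ValueError):
        gm_gsd([1.0, 0.0])


def test_summarize_excludes_zeros_from_gm_only():
    s = summarize([0.0, 1.0, 100.0])
    assert s.n == 3
    assert s.n_zero_excluded == 1
    assert s.gm == pytest.approx(10.0)
    assert s.mean == pytest.approx(101.0 / 3.0)


def test_ratio_worked_example():
    # printed totals of the low-concentration site: 0.058 and 20 ug/g
    assert ratio_ohpcb_pcb(0.058, 20.0) == pytest.approx(0.29)
    assert ratio_ohpcb_pcb(0.0, 5.0) == 0.0
    assert ratio_ohpcb_pcb(3.0, 7.0) == pytest.approx(ratio_ohpcb_pcb(30.0, 70.0))
    with pytest.raises(ValueError):
        ratio_ohpcb_pcb(1.0, 0.0)


def test_mann_whitney_complete_separation_five_vs_five():
    res = mann_whitney_exact([9.9, 12.0, 14.0, 16.0, 18.0],
                             [0.039, 0.5, 1.0, 2.0, 2.6])
    assert res.method == "exact"
    assert res.p_value == pytest.approx(2.0 / 252.0)


def test_mann_whitney_identical_groups_p_one():
    res = mann_whitney_exact([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert res.p_value == 1.0


def _mw_oracle(x, y):
    """Independent enumeration oracle built on the U statistic from raw values."""
    pooled = list(x) + list(y)
    nx, n = len(x), len(pooled)

    def u_stat(xs, ys):
        u = 0.0
        for a in xs:
            for b in ys:
                u += 1.0 if a > b else (0.5 if a == b else 0.0)
        return u

    u_obs = u_stat(x, y)
    n_le = n_ge = total = 0
    for combo in itertools.combinations(range(n), nx):
        xs = [pooled[i] for i in combo]
        ys = [pooled[i] for i in range(n) if i not in combo]
        u = u_stat(xs, ys)
        total += 1
        n_le += u <= u_obs + 1e-9
        n_ge += u >= u_obs - 1e-9
    return min(1.0, 2.0 * min(n_le / total, n_ge / total))


@pytest.mark.parametrize("nx,ny", [(2, 3), (3, 3), (4, 5), (5, 5), (6, 6)])
def test_mann_whitney_matches_enumeration_oracle(nx, ny):
    rng = np.random.default_rng(100 * nx + ny)
    for case in range(3):
        x = rng.normal(size=nx)
        y = rng.normal(loc=0.5, size=ny)
        if case == 2:  # ties
            x = np.round(x)
            y = np.round(y)
        assert mann_whitney_exact(x, y).p_value == pytest.approx(_mw_oracle(x, y))


def test_mann_whitney_matches_scipy_exact_without_ties():
    rng = np.random.default_rng(9)
    for _ in range(5):
        x, y = rng.normal(size=5), rng.normal(size=6)
        ours = mann_whitney_exact(x, y).p_value
        ref = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue
        assert ours == pytest.approx(float(ref))


def test_mann_whitney_large_groups_use_approximation():
    rng = np.random.default_rng(3)
    res = mann_whitney_exact(rng.normal(size=10), rng.normal(size=10))
    assert res.method == "normal-approx"


def test_spearman_perfect_agreement_and_reversal():
    up = spearman_exact([1, 2, 3, 4, 5], [2, 4, 9, 16, 30])
    assert up.estimate == pytest.approx(1.0)
    assert up.p_value == pytest.approx(2.0 / 120.0)
    down = spearman_exact([1, 2, 3, 4, 5], [30, 16, 9, 4, 2])
    assert down.estimate == pytest.approx(-1.0)
    assert down.p_value == pytest.approx(2.0 / 120.0)


def _spearman_oracle(x, y):
    """Full-permutation oracle using scipy's rho on each permuted pairing."""
    rho_obs = abs(stats.spearmanr(x, y).statistic)
    n = len(y)
    count = 0
    for perm in itertools.permutations(range(n)):
        rho = stats.spearmanr(x, [y[i] for i in perm]).statistic
        count += abs(rho) >= rho_obs - 1e-12
    return count / math.factorial(n)


@pytest.mark.parametrize("n", [4, 5])
def test_spearman_matches_permutation_oracle(n):
    rng = np.random.default_rng(40 + n)
    for case in range(2):
        x = rng.normal(size=n)
        y = rng.normal(size=n)
        if case == 1:
            y = np.round(y)  # ties via midranks
        res = spearman_exact(x, y)
        assert res.p_value == pytest.approx(_spearman_oracle(list(x), list(y)))
        assert res.estimate == pytest.approx(float(stats.spearmanr(x, y).statistic))


def test_spearman_constant_vector_rejected():
    with pytest.raises(ValueError):
        spearman_exact([1, 1, 1, 1], [1, 2, 3, 4])


def test_pearson_log_collinear_and_scale_invariant():
    x = np.array([1.0, 2.0, 4.0, 8.0])
    y = x**0.7
    res = pearson_log(x, y)
    assert res.estimate == pytest.approx(1.0)
    r1 = pearson_log(x, y).estimate
    r2 = pearson_log(5.0 * x, 0.3 * y).estimate
    assert r1 == pytest.approx(r2)
    with pytest.raises(ValueError):
        pearson_log([1.0, -1.0, 2.0], [1.0, 2.0, 3.0])


def test_pearson_log_null_p_values_uniform():
    """Under independence the p-values are uniform (KS check at 0.01)."""
    rng = np.random.default_rng(8)
    pvals = [
        pearson_log(rng.lognormal(0, 1, 20), rng.lognormal(0, 1, 20)).p_value
        for _ in range(200)
    ]
    assert stats.kstest(pvals, "uniform").pvalue > 0.01


def test_fold_change_worked_examples():
    assert RegressionFit(0.0, 0.61, 0.002, 5).fold_change(2.0) == pytest.approx(
        1.5, abs=0.03
    )
    assert RegressionFit(0.0, 1.0, 0.01, 5).fold_change(2.0) == pytest.approx(2.0)


def test_loglog_fit_recovers_generating_slope():
    rng = np.random.default_rng(12)
    pcb = rng.lognormal(3, 1, size=50)
    oh = np.exp(-1.0 + 0.6 * np.log(pcb) + rng.normal(0, 0.1, 50))
    fit = loglog_fit(pcb, oh)
    assert fit.beta1 == pytest.approx(0.6, abs=0.05)
    oracle = np.polyfit(np.log(pcb), np.log(oh), 1)[0]
    assert fit.beta1 == pytest.approx(oracle)
    assert fit.n == 50


def test_loglog_fit_degenerate_x_rejected():
    with pytest.raises(ValueError):
        loglog_fit([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])


def test_exact_null_rejection_rates_near_nominal():
    """Simulated exchangeable data: rejection at alpha=0.05 within 0.05+-0.02."""
    rng = np.random.default_rng(77)
    mw_rej = sum(
        mann_whitney_exact(rng.normal(size=6), rng.normal(size=6)).p_value <= 0.05
        for _ in range(1000)
    )
    assert 0.03 <= mw_rej / 1000 <= 0.07
    sp_rej = sum(
        spearman_exact(rng.normal(size=7), rng.normal(size=7)).p_value <= 0.05
        for _ in range(1000)
    )
    assert 0.03 <= sp_rej / 1000 <= 0.07


def test_exact_p_values_in_unit_interval():
    rng = np.random.default_rng(5)
    for _ in range(20):
        p = mann_whitney_exact(rng.normal(size=4), rng.normal(size=4)).p_value
        assert 0.0 < p <= 1.0
        p = spearman_exact(rng.normal(size=5), rng.normal(size=5)).p_value
        assert 0.0 < p <= 1.0
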