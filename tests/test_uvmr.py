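"""Univariable MR estimators against hand and regression oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import statsmodels.api as sm

from mrmediation.errors import InsufficientInstrumentsError
from mrmediation.uvmr import (
    _weighted_median_core,
    cochran_q,
    egger,
    ivw,
    outlier_report,
    wald_ratios,
    weighted_median,
)

from conftest import make_panel


def _fixture20(rng):
    bx = rng.normal(0.1, 0.03, 20)
    bx[np.abs(bx) < 1e-3] = 0.05
    sx = np.full(20, 0.005)
    by = 0.4 * bx + rng.normal(0, 0.02, 20)
    sy = rng.uniform(0.01, 0.05, 20)
    return make_panel(bx, sx, by, sy)


def test_wald_ratio_arithmetic():
    panel = make_panel([0.1, -0.1], [0.01, 0.01], [0.05, 0.05], [0.01, 0.02])
    r = wald_ratios(panel)
    assert r.loc["rs1", "ratio"] == pytest.approx(0.5)
    assert r.loc["rs1", "se"] == pytest.approx(0.1)
    assert r.loc["rs2", "ratio"] == pytest.approx(-0.5)
    assert r.loc["rs2", "se"] == pytest.approx(0.2)


def test_wald_excludes_zero_exposure_beta():
    panel = make_panel([0.1, 0.0], [0.01, 0.01], [0.05, 0.05], [0.01, 0.01])
    with pytest.warns(UserWarning, match="zero exposure beta"):
        r = wald_ratios(panel)
    assert list(r.index) == ["rs1"]


def test_five_snp_ratios_match_hand_division(rng):
    bx = np.array([0.1, 0.2, -0.15, 0.05, 0.3])
    by = np.array([0.05, 0.09, -0.06, 0.01, 0.16])
    sy = np.array([0.01, 0.02, 0.01, 0.03, 0.02])
    panel = make_panel(bx, 0.01 * np.ones(5), by, sy)
    r = wald_ratios(panel)
    np.testing.assert_allclose(r["ratio"], by / bx)
    np.testing.assert_allclose(r["se"], sy / np.abs(bx))


def test_ivw_homogeneous_ratios():
    # by/bx identical for all SNPs -> beta is that ratio, Q = 0
    panel = make_panel([0.1, 0.2, 0.4], [0.01] * 3,
                       [0.05, 0.10, 0.20], [0.01] * 3)
    fixed = ivw(panel, re_model="fixed")
    random = ivw(panel, re_model="multiplicative_random")
    assert fixed.beta == pytest.approx(0.5)
    assert fixed.se == pytest.approx(random.se)
    assert cochran_q(panel).q_stat == pytest.approx(0.0, abs=1e-20)


def test_ivw_two_snp_symmetry():
    panel = make_panel([0.1, 0.1], [0.01, 0.01], [0.02, 0.04], [0.01, 0.01])
    # equal ratio SEs -> midpoint of ratios 0.2 and 0.4
    assert ivw(panel).beta == pytest.approx(0.3)


def test_ivw_equals_weighted_regression_through_origin(rng):
    panel = _fixture20(rng)
    est = ivw(panel, re_model="fixed")
    bx = panel.beta_matrix["X"].to_numpy()
    by = panel.beta_matrix["Y"].to_numpy()
    sy = panel.se_matrix["Y"].to_numpy()
    fit = sm.WLS(by, bx[:, None], weights=1 / sy**2).fit()
    assert est.beta == pytest.approx(fit.params[0], abs=1e-10)
    # fixed-effect SE corresponds to the unit-dispersion weighted model
    assert est.se == pytest.approx(
        float(np.sqrt(1.0 / np.sum(bx**2 / sy**2))), abs=1e-12
    )


def test_ivw_single_snp_equals_wald_ratio():
    panel = make_panel([0.1], [0.01], [0.05], [0.01])
    with pytest.raises(InsufficientInstrumentsError):
        ivw(panel)
    est = ivw(panel, allow_single=True)
    assert est.beta == pytest.approx(0.5)
    assert est.se == pytest.approx(0.1)


def test_ivw_or_scale_iff_binary():
    panel = make_panel([0.1, 0.2], [0.01] * 2, [0.05, 0.1], [0.01] * 2)
    assert ivw(panel).or_scale is None
    est = ivw(panel, binary_outcome=True)
    assert est.or_scale[0] == pytest.approx(np.exp(est.beta))
    lo, hi = est.ci95
    assert est.ci95 == (pytest.approx(est.beta - 1.96 * est.se),
                        pytest.approx(est.beta + 1.96 * est.se))
    assert lo < hi


def test_egger_matches_weighted_regression(rng):
    panel = _fixture20(rng)
    est, rep = egger(panel)
    bx = panel.beta_matrix["X"].to_numpy()
    by = panel.beta_matrix["Y"].to_numpy()
    sy = panel.se_matrix["Y"].to_numpy()
    s = np.sign(bx)
    x, y = bx * s, by * s
    fit = sm.WLS(y, sm.add_constant(x), weights=1 / sy**2).fit()
    assert est.beta == pytest.approx(fit.params[1], abs=1e-10)
    assert rep.egger_intercept == pytest.approx(fit.params[0], abs=1e-10)


def test_egger_reduces_to_ivw_without_pleiotropy():
    # noise-free proportional effects: intercept 0, slope = IVW beta
    bx = np.array([0.05, 0.1, 0.2, 0.3])
    panel = make_panel(bx, 0.01 * np.ones(4), 0.4 * bx, 0.01 * np.ones(4))
    est, rep = egger(panel)
    assert est.beta == pytest.approx(ivw(panel).beta, abs=1e-6)
    assert rep.egger_intercept == pytest.approx(0.0, abs=1e-10)


def test_egger_recovers_directional_pleiotropy():
    bx = np.array([0.05, 0.1, 0.2, 0.3])
    by = 0.4 * bx + 0.01  # constant pleiotropic shift per SNP
    panel = make_panel(bx, 0.01 * np.ones(4), by, 0.01 * np.ones(4))
    est, rep = egger(panel)
    assert rep.egger_intercept == pytest.approx(0.01, abs=1e-10)
    assert est.beta == pytest.approx(0.4, abs=1e-10)


def test_weighted_median_plain_median_with_equal_weights():
    panel = make_panel([0.1, 0.1, 0.1], [0.01] * 3,
                       [0.01, 0.02, 0.09], [0.01] * 3)
    est = weighted_median(panel, n_boot=50, seed=1)
    assert est.beta == pytest.approx(0.2)


def test_weighted_median_dominant_snp():
    # first SNP holds > 50% of inverse-variance weight -> its ratio wins
    bx = np.array([0.5, 0.1, 0.1])
    by = np.array([0.35, 0.02, 0.09])
    panel = make_panel(bx, 0.01 * np.ones(3), by, 0.01 * np.ones(3))
    est = weighted_median(panel, n_boot=50, seed=1)
    assert est.beta == pytest.approx(0.7)


def test_weighted_median_matches_cumulative_weight_oracle():
    # 5 SNPs, unequal weights; brute-force cumulative-weight walk
    r = np.array([0.1, 0.15, 0.2, 0.3, 0.5])
    w = np.array([0.10, 0.15, 0.20, 0.25, 0.30])

    def brute(r, w):
        order = np.argsort(r)
        r, w = r[order], w[order] / w.sum()
        acc = 0.0
        for i in range(len(r)):
            acc += w[i]
            if np.isclose(acc, 0.5) and i < len(r) - 1:
                return 0.5 * (r[i] + r[i + 1])
            if acc >= 0.5:
                return r[i]

    assert _weighted_median_core(r, w) == pytest.approx(brute(r, w))
    # exact 0.5 crossing averages the bracketing ratios
    assert _weighted_median_core(
        np.array([0.1, 0.3]), np.array([0.5, 0.5])
    ) == pytest.approx(0.2)

    # panel whose ratio weights reproduce w: bx = sqrt(w), sy = 1
    bx = np.sqrt(w)
    panel = make_panel(bx, 0.001 * np.ones(5), r * bx, np.ones(5))
    est = weighted_median(panel, n_boot=50, seed=1)
    assert est.beta == pytest.approx(brute(r, w), abs=1e-12)


def test_weighted_median_bootstrap_deterministic():
    panel = make_panel([0.1, 0.2, 0.3, 0.15], [0.01] * 4,
                       [0.05, 0.09, 0.14, 0.06], [0.02] * 4)
    a = weighted_median(panel, n_boot=200, seed=7)
    b = weighted_median(panel, n_boot=200, seed=7)
    assert a.se == b.se and a.se > 0


def test_cochran_q_two_snp_hand_value():
    # ratios 0 and 1, both ratio SE 1 -> w = 1, beta = 0.5, Q = 0.5
    panel = make_panel([1.0, 1.0], [0.001] * 2, [0.0, 1.0], [1.0, 1.0])
    rep = cochran_q(panel)
    assert rep.q_stat == pytest.approx(0.5)
    assert rep.q_df == 1


def test_cochran_q_equals_direct_summation(rng):
    panel = _fixture20(rng)
    rep = cochran_q(panel)
    r = wald_ratios(panel)
    w = 1 / r["se"] ** 2
    beta = np.sum(w * r["ratio"]) / np.sum(w)
    assert rep.q_stat == pytest.approx(
        float(np.sum(w * (r["ratio"] - beta) ** 2)), abs=1e-10
    )


def test_fixed_se_never_exceeds_multiplicative_random(rng):
    for seed in range(5):
        panel = _fixture20(np.random.default_rng(seed))
        f = ivw(panel, re_model="fixed")
        m = ivw(panel, re_model="multiplicative_random")
        q = cochran_q(panel)
        assert f.se <= m.se + 1e-15
        if q.q_stat <= q.q_df:
            assert f.se == pytest.approx(m.se)
        else:
            assert m.se > f.se


@settings(deadline=None, max_examples=25, derandomize=True)
@given(st.integers(0, 10_000))
def test_estimators_invariant_to_joint_sign_flip(seed):
    """Flipping a SNP's exposure AND outcome betas together (allele
    relabelling) changes no estimate."""
    rng = np.random.default_rng(seed)
    panel = _fixture20(rng)
    flip = rng.integers(0, 2, 20) * 2 - 1
    flipped = make_panel(
        panel.beta_matrix["X"].to_numpy() * flip,
        panel.se_matrix["X"].to_numpy(),
        panel.beta_matrix["Y"].to_numpy() * flip,
        panel.se_matrix["Y"].to_numpy(),
    )
    assert ivw(panel).beta == pytest.approx(ivw(flipped).beta, abs=1e-12)
    assert egger(panel)[0].beta == pytest.approx(egger(flipped)[0].beta, abs=1e-12)
    assert weighted_median(panel, n_boot=10, seed=0).beta == pytest.approx(
        weighted_median(flipped, n_boot=10, seed=0).beta, abs=1e-12
    )
    assert cochran_q(panel).q_stat == pytest.approx(
        cochran_q(flipped).q_stat, abs=1e-10
    )


def test_outlier_report_flags_injected_outlier(rng):
    panel = _fixture20(rng)
    by = panel.beta_matrix["Y"].copy()
    by.iloc[0] = by.iloc[0] + 1.0  # gross outlier
    bad = make_panel(
        panel.beta_matrix["X"].to_numpy(), panel.se_matrix["X"].to_numpy(),
        by.to_numpy(), panel.se_matrix["Y"].to_numpy(),
    )
    rep = outlier_report(bad)
    assert bool(rep["flagged"].iloc[0])
    assert rep["flagged"].sum() <= 3  # no mass flagging, and never removal


def test_insufficient_instruments_errors():
    panel2 = make_panel([0.1, 0.2], [0.01] * 2, [0.05, 0.1], [0.01] * 2)
    with pytest.raises(InsufficientInstrumentsError):
        egger(panel2)
    with pytest.raises(InsufficientInstrumentsError):
        weighted_median(panel2)
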