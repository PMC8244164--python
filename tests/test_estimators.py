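"""MR estimators against independent oracles: scalar IVW, hand-rolled GLS,
weighted least squares, and parameter-recovery simulations."""
import math

import numpy as np
import pytest
from scipy import special

from mrphewas import (
    EstimatorError,
    InstrumentSet,
    SyntheticTruth,
    egger,
    estimate_auto,
    instrument_panel,
    ivw,
    linear_beta_to_or,
    mvmr,
    or_to_linear_beta,
    simulate_pair,
    wald_ratio,
)

from conftest import make_assoc


def _pair_lists(x, y, s_out, s_exp=0.01, corr=None):
    """Build an aligned (InstrumentSet, outcomes) pair from raw arrays."""
    members = tuple(
        make_assoc(f"rs{i}", beta=float(b), se=s_exp) for i, b in enumerate(x)
    )
    outs = [
        make_assoc(f"rs{i}", beta=float(b), se=float(s))
        for i, (b, s) in enumerate(zip(y, s_out))
    ]
    inst = InstrumentSet("t", members, None if corr is None else np.asarray(corr))
    return inst, outs


# ---------------------------------------------------------------------------
# Wald ratio


def test_wald_ratio_point_and_se():
    est = wald_ratio(make_assoc(beta=-0.5, se=0.1), make_assoc(beta=0.5, se=0.01))
    assert est.beta_hat == pytest.approx(-1.0)
    assert est.se_hat == pytest.approx(0.2)
    assert est.method == "wald" and est.n_snps == 1
    assert est.ci_low < est.beta_hat < est.ci_high


def test_wald_ratio_identity():
    est = wald_ratio(make_assoc(beta=0.37, se=0.1), make_assoc(beta=0.37, se=0.02))
    assert est.beta_hat == pytest.approx(1.0)


def test_wald_se_is_first_order_term_of_delta_method():
    out = make_assoc(beta=0.3, se=0.05)
    exp = make_assoc(beta=-0.6, se=0.02)
    est = wald_ratio(out, exp)
    first_order = 0.05 / 0.6
    # full (second-order) delta variance adds the exposure-uncertainty term
    full = math.sqrt(
        out.se**2 / exp.beta**2 + out.beta**2 * exp.se**2 / exp.beta**4
    )
    assert est.se_hat == pytest.approx(first_order)
    assert est.se_hat <= full


def test_wald_ratio_rejects_zero_exposure_beta():
    with pytest.raises(EstimatorError, match="undefined"):
        wald_ratio(make_assoc(beta=0.1), make_assoc(beta=0.0))


# ---------------------------------------------------------------------------
# IVW


def test_ivw_two_identical_ratios_equal_weights():
    inst, outs = _pair_lists([0.2, 0.2], [0.1, 0.1], [0.05, 0.05])
    est = ivw(inst, outs, random_effects=False)
    assert est.beta_hat == pytest.approx(0.5)
    assert est.heterogeneity_q == pytest.approx(0.0, abs=1e-12)
    assert est.method == "ivw_fixed"


def test_ivw_identity_equals_scalar_weighted_mean(rng):
    for j in (2, 3, 5, 10, 56):
        x = rng.normal(0.1, 0.05, j)
        x[np.abs(x) < 0.02] = 0.05
        y = rng.normal(0, 0.1, j)
        s = rng.uniform(0.01, 0.2, j)
        inst, outs = _pair_lists(x, y, s)
        est = ivw(inst, outs)
        # independent scalar route: weighted mean of Wald ratios with
        # weights (x/s)^2
        w = (x / s) ** 2
        ratio = y / x
        expected = float(np.sum(w * ratio) / np.sum(w))
        assert est.beta_hat == pytest.approx(expected, rel=1e-10)


def _gls_by_gaussian_elimination(x, y, omega):
    """Oracle: solve the origin-GLS normal equations with hand elimination."""
    j = len(x)
    aug = [list(map(float, row)) + [float(x[i]), float(y[i])]
           for i, row in enumerate(omega)]
    # forward elimination with partial pivoting
    for col in range(j):
        piv = max(range(col, j), key=lambda r: abs(aug[r][col]))
        aug[col], aug[piv] = aug[piv], aug[col]
        for r in range(col + 1, j):
            f = aug[r][col] / aug[col][col]
            for c in range(col, j + 2):
                aug[r][c] -= f * aug[col][c]
    # back substitution for Omega^-1 x and Omega^-1 y simultaneously
    oix, oiy = [0.0] * j, [0.0] * j
    for r in range(j - 1, -1, -1):
        sx = aug[r][j] - sum(aug[r][c] * oix[c] for c in range(r + 1, j))
        sy = aug[r][j + 1] - sum(aug[r][c] * oiy[c] for c in range(r + 1, j))
        oix[r] = sx / aug[r][r]
        oiy[r] = sy / aug[r][r]
    xox = sum(x[i] * oix[i] for i in range(j))
    xoy = sum(x[i] * oiy[i] for i in range(j))
    return xoy / xox, 1.0 / math.sqrt(xox)


@pytest.mark.parametrize("trial", range(4))
def test_ivw_correlated_matches_elimination_oracle(trial):
    rng = np.random.default_rng(900 + trial)
    j = 4
    corr = np.corrcoef(rng.normal(size=(60, j)), rowvar=False)
    x = rng.normal(0.1, 0.03, j)
    y = rng.normal(0.0, 0.05, j)
    s = rng.uniform(0.02, 0.1, j)
    inst, outs = _pair_lists(x, y, s, corr=corr)
    est = ivw(inst, outs, random_effects=False)
    omega = np.outer(s, s) * corr
    beta_o, se_o = _gls_by_gaussian_elimination(x, y, omega)
    assert est.beta_hat == pytest.approx(beta_o, rel=1e-10)
    assert est.se_hat == pytest.approx(se_o, rel=1e-10)


def test_ivw_invariant_under_joint_permutation(rng):
    j = 6
    corr = np.corrcoef(rng.normal(size=(80, j)), rowvar=False)
    x, y = rng.normal(0.1, 0.03, j), rng.normal(0, 0.05, j)
    s = rng.uniform(0.02, 0.1, j)
    perm = rng.permutation(j)
    est = ivw(*_pair_lists(x, y, s, corr=corr))
    est_p = ivw(*_pair_lists(x[perm], y[perm], s[perm], corr=corr[np.ix_(perm, perm)]))
    assert est_p.beta_hat == pytest.approx(est.beta_hat, rel=1e-12)
    assert est_p.se_hat == pytest.approx(est.se_hat, rel=1e-12)


@pytest.mark.parametrize("c", [0.5, 2.0, -3.0])
def test_unit_equivariance_of_estimators(c, rng):
    j = 10
    x = rng.uniform(0.05, 0.2, j)
    y = rng.normal(0, 0.05, j)
    s = rng.uniform(0.02, 0.1, j)
    for fn in (
        lambda xx: ivw(*_pair_lists(xx, y, s)),
        lambda xx: egger(*_pair_lists(xx, y, s)),
    ):
        base, scaled = fn(x), fn(c * x)
        assert scaled.beta_hat == pytest.approx(base.beta_hat / c, rel=1e-9)
    w_base = wald_ratio(make_assoc(beta=y[0], se=s[0]), make_assoc(beta=x[0]))
    w_scaled = wald_ratio(make_assoc(beta=y[0], se=s[0]), make_assoc(beta=c * x[0]))
    assert w_scaled.beta_hat == pytest.approx(w_base.beta_hat / c, rel=1e-12)


def test_ivw_near_singular_correlation_names_pair():
    corr = np.array([[1.0, 1.0 - 1e-12], [1.0 - 1e-12, 1.0]])
    inst, outs = _pair_lists([0.1, 0.1], [0.05, 0.05], [0.02, 0.02], corr=corr)
    with pytest.raises(EstimatorError, match="near-singular"):
        ivw(inst, outs)


def test_ivw_single_instrument_directs_to_wald():
    inst, outs = _pair_lists([0.1], [0.05], [0.02])
    with pytest.raises(EstimatorError, match="wald"):
        ivw(inst, outs)


# ---------------------------------------------------------------------------
# MR-Egger


def test_egger_exact_fit_recovers_line():
    x = np.array([0.1, 0.2, 0.3])
    y = 0.5 * x + 0.1
    est = egger(*_pair_lists(x, y, [0.05, 0.04, 0.03]))
    assert est.beta_hat == pytest.approx(0.5, rel=1e-9)
    assert est.egger_intercept == pytest.approx(0.1, rel=1e-9)
    assert est.heterogeneity_q == pytest.approx(0.0, abs=1e-12)
    assert est.dispersion_phi == 1.0  # floor applied at Q = 0


def test_egger_matches_weighted_least_squares_oracle(rng):
    j = 10
    x = rng.uniform(0.05, 0.3, j)
    y = rng.normal(0.2 * x + 0.05, 0.05)
    s = rng.uniform(0.02, 0.1, j)
    est = egger(*_pair_lists(x, y, s))
    # independent scalar WLS-with-intercept formulas
    w = 1.0 / s**2
    sw, swx, swy = w.sum(), (w * x).sum(), (w * y).sum()
    swxx, swxy = (w * x * x).sum(), (w * x * y).sum()
    det = sw * swxx - swx**2
    slope_o = (sw * swxy - swx * swy) / det
    int_o = (swxx * swy - swx * swxy) / det
    q = float((w * (y - int_o - slope_o * x) ** 2).sum())
    phi = max(1.0, q / (j - 2))
    se_slope_o = math.sqrt(phi * sw / det)
    se_int_o = math.sqrt(phi * swxx / det)
    assert est.beta_hat == pytest.approx(slope_o, rel=1e-10)
    assert est.egger_intercept == pytest.approx(int_o, rel=1e-10)
    assert est.se_hat == pytest.approx(se_slope_o, rel=1e-10)
    assert est.egger_intercept_se == pytest.approx(se_int_o, rel=1e-10)


def test_egger_orientation_invariance(rng):
    # flipping the sign of an (x, y) pair must not change the fit
    j = 8
    x = rng.uniform(0.05, 0.3, j)
    y = rng.normal(0.3 * x, 0.05)
    s = rng.uniform(0.02, 0.1, j)
    flip = np.ones(j)
    flip[::2] = -1
    est = egger(*_pair_lists(x, y, s))
    est_f = egger(*_pair_lists(x * flip, y * flip, s))
    assert est_f.beta_hat == pytest.approx(est.beta_hat, rel=1e-12)
    assert est_f.egger_intercept == pytest.approx(est.egger_intercept, rel=1e-12)


def test_egger_needs_three_instruments():
    with pytest.raises(EstimatorError, match="3"):
        egger(*_pair_lists([0.1, 0.2], [0.1, 0.1], [0.05, 0.05]))


def test_egger_and_ivw_slopes_converge_without_pleiotropy():
    """With no pleiotropy both estimators target the same slope; at J = 200
    their per-replicate difference averages to zero."""
    truth = SyntheticTruth(
        n_instruments=200, theta={"both": -1.0}, seed=31
    )
    inst = instrument_panel(truth)
    rng = np.random.default_rng(77)
    diffs = []
    for _ in range(500):
        _, outs = simulate_pair(truth, rng=rng)
        diffs.append(egger(inst, outs).beta_hat - ivw(inst, outs).beta_hat)
    diffs = np.array(diffs)
    mc_se = diffs.std(ddof=1) / math.sqrt(len(diffs))
    assert abs(diffs.mean()) < 3 * mc_se


# ---------------------------------------------------------------------------
# Multivariable MR


def test_mvmr_zero_column_reduces_to_univariable(rng):
    j = 12
    x = rng.uniform(0.05, 0.2, j)
    y = rng.normal(-0.8 * x, 0.05)
    s = rng.uniform(0.02, 0.1, j)
    _, outs = _pair_lists(x, y, s)
    bmat = np.column_stack([x, np.zeros(j)])
    first, second = mvmr(bmat, np.full_like(bmat, 0.01), outs)
    uni = ivw(*_pair_lists(x, y, s), random_effects=False)
    assert first.beta_hat == pytest.approx(uni.beta_hat, rel=1e-10)
    assert second.beta_hat == 0.0 and second.pval == 1.0


def test_mvmr_recovers_two_exposures(rng):
    j, theta = 20, np.array([-1.0, 0.5])
    bmat = rng.uniform(0.05, 0.2, size=(j, 2))
    s = np.full(j, 0.02)
    y = bmat @ theta + rng.normal(0, 0.02, j)
    _, outs = _pair_lists(bmat[:, 0], y, s)
    ests = mvmr(bmat, np.full_like(bmat, 0.01), outs)
    for est, t in zip(ests, theta):
        assert abs(est.beta_hat - t) < 2 * est.se_hat


def test_mvmr_duplicated_column_is_rank_error(rng):
    j = 10
    x = rng.uniform(0.05, 0.2, j)
    _, outs = _pair_lists(x, x, np.full(j, 0.05))
    with pytest.raises(EstimatorError, match="collinear"):
        mvmr(np.column_stack([x, x]), np.full((j, 2), 0.01), outs)


def test_mvmr_needs_more_instruments_than_exposures(rng):
    x = rng.uniform(0.05, 0.2, 2)
    _, outs = _pair_lists(x, x, np.full(2, 0.05))
    with pytest.raises(EstimatorError, match="J=2"):
        mvmr(np.column_stack([x, 2 * x + 1]), np.full((2, 2), 0.01), outs)


# ---------------------------------------------------------------------------
# OR conversion


def test_zero_beta_gives_unit_or():
    est = ivw(*_pair_lists([0.1, 0.2], [0.0, 0.0], [0.05, 0.05]))
    res = linear_beta_to_or(est, 0.37)
    assert res.odds_ratio == pytest.approx(1.0)


def test_or_conversion_quarter_scaling():
    est = wald_ratio(make_assoc(beta=0.01, se=0.004), make_assoc(beta=1.0, se=0.01))
    res = linear_beta_to_or(est, 0.5)  # k(1-k) = 0.25
    assert math.log(res.odds_ratio) == pytest.approx(0.04)


def test_or_ci_is_log_symmetric():
    est = wald_ratio(make_assoc(beta=0.02, se=0.004), make_assoc(beta=0.5, se=0.01))
    res = linear_beta_to_or(est, 0.2)
    assert math.log(res.ci_high / res.odds_ratio) == pytest.approx(
        math.log(res.odds_ratio / res.ci_low)
    )


def test_or_round_trips_to_linear_beta():
    est = wald_ratio(make_assoc(beta=0.013, se=0.004), make_assoc(beta=0.5, se=0.01))
    res = linear_beta_to_or(est, 0.1)
    beta, se = or_to_linear_beta(res)
    assert beta == pytest.approx(est.beta_hat, rel=1e-12)
    assert se == pytest.approx(est.se_hat, rel=1e-12)


@pytest.mark.parametrize("k", [0.0, 1.0, -0.1, 1.5])
def test_or_conversion_rejects_degenerate_case_fraction(k):
    est = wald_ratio(make_assoc(beta=0.1, se=0.05), make_assoc(beta=0.5))
    with pytest.raises(EstimatorError):
        linear_beta_to_or(est, k)


# ---------------------------------------------------------------------------
# Dispatch


def test_dispatch_single_instrument_is_wald():
    inst, outs = _pair_lists([0.2], [0.1], [0.05])
    assert estimate_auto(inst, outs).method == "wald"


def test_dispatch_two_instruments_fixed_effect():
    inst, outs = _pair_lists([0.2, 0.1], [0.1, 0.04], [0.05, 0.05])
    est = estimate_auto(inst, outs)
    assert est.method == "ivw_fixed" and est.dispersion_phi == 1.0


def test_dispatch_three_instruments_applies_phi_floor():
    # nearly-collinear ratios: Q/(J-1) < 1, so phi floors at 1
    x = np.array([0.1, 0.2, 0.3])
    y = 0.5 * x + np.array([1e-4, -1e-4, 0.0])
    inst, outs = _pair_lists(x, y, [0.05, 0.05, 0.05])
    est = estimate_auto(inst, outs)
    assert est.method == "ivw_mre"
    assert est.heterogeneity_q / 2 < 1
    assert est.dispersion_phi == 1.0


def test_dispatch_equals_direct_ivw_on_correlated_set():
    truth = SyntheticTruth(
        n_instruments=6, ld_blocks=((6, 0.5),), theta={"both": -1.0}, seed=13
    )
    inst, outs = simulate_pair(truth)
    assert estimate_auto(inst, outs) == ivw(inst, outs, random_effects=True)


def test_dispatch_empty_set_errors():
    with pytest.raises(EstimatorError, match="empty"):
        estimate_auto(InstrumentSet("t", ()), [])
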