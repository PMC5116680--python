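import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import placeboiv as piv
from placeboiv import (
    DegenerateInstrumentError,
    TrialDataset,
    adjust_observed_confounders,
    itt_estimates,
    multi_mediator_two_step,
    placebo_effect_iv,
    regression_comparator,
    residualize_placebo,
    sample_covariance,
    treatment_effect_two_step,
    treatment_effect_unadjusted,
    wald_ace_binary,
)
from placeboiv.estimators import instrument_diagnostics

from conftest import null_blinded_params


def _dataset(Q, M, Y, Z=None, X=None):
    n = len(Y)
    Z = np.asarray(Z if Z is not None else np.arange(n) % 2)
    X = np.asarray(X if X is not None else Z)
    return TrialDataset(Z=Z, Q=np.asarray(Q), X=X, M=np.asarray(M), Y=np.asarray(Y))


# -- sample covariance ------------------------------------------------------


def test_sample_covariance_examples():
    assert sample_covariance([0, 0, 1, 1], [0, 0, 1, 1]) == pytest.approx(1 / 3)
    assert sample_covariance([1, 2, 3], [5, 5, 5]) == 0.0
    # two-pass oracle value computed by hand: deviations products sum to 2.10
    assert sample_covariance([0, 1, 0, 1, 1], [1.0, 2.0, 0.5, 3.0, 2.5]) == pytest.approx(
        0.525, abs=1e-12
    )


@settings(deadline=None, max_examples=50)
@given(
    st.lists(st.floats(-1e3, 1e3), min_size=2, max_size=30),
    st.integers(0, 2**31 - 1),
)
def test_sample_covariance_symmetric_and_matches_loop_oracle(a, seed):
    b = np.random.default_rng(seed).normal(size=len(a)).tolist()
    left, right = sample_covariance(a, b), sample_covariance(b, a)
    assert left == right
    am, bm = np.mean(a), np.mean(b)
    oracle = sum((x - am) * (y - bm) for x, y in zip(a, b)) / (len(a) - 1)
    assert left == pytest.approx(oracle, rel=1e-9, abs=1e-9)


def test_sample_covariance_rejects_bad_shapes():
    with pytest.raises(ValueError):
        sample_covariance([1, 2], [1, 2, 3])
    with pytest.raises(ValueError):
        sample_covariance([1.0], [2.0])


# -- placebo effect ---------------------------------------------------------


def test_placebo_effect_proportional_outcome():
    d = _dataset(Q=[0, 0, 1, 1], M=[0, 0, 1, 1], Y=[0, 0, 3, 3])
    est = placebo_effect_iv(d)
    assert est.value == pytest.approx(3.0)
    assert est.value == pytest.approx(est.numerator / est.denominator)


def test_placebo_effect_zero_for_constant_outcome():
    d = _dataset(Q=[0, 0, 1, 1], M=[0.5, 1.5, 2.0, 3.0], Y=[7.0] * 4)
    assert placebo_effect_iv(d).value == 0.0


def test_placebo_effect_equals_wald_group_means_oracle():
    rng = np.random.default_rng(8)
    q = np.array([0, 0, 0, 0, 1, 1, 1, 1])
    m = rng.normal(size=8)
    y = rng.normal(size=8)
    d = _dataset(Q=q, M=m, Y=y)
    wald = (y[q == 1].mean() - y[q == 0].mean()) / (m[q == 1].mean() - m[q == 0].mean())
    assert placebo_effect_iv(d).value == pytest.approx(wald, abs=1e-12)


def test_placebo_effect_degenerate_instrument_fails():
    d = _dataset(Q=[0, 0, 1, 1], M=[2.0, 2.0, 2.0, 2.0], Y=[1.0, 2.0, 3.0, 4.0])
    with pytest.raises(DegenerateInstrumentError):
        placebo_effect_iv(d)


# -- residuals and treatment effects ----------------------------------------


def test_residualize_identity_and_exact_removal(fixed_dataset):
    np.testing.assert_array_equal(residualize_placebo(fixed_dataset, 0.0), fixed_dataset.Y)
    d = _dataset(Q=[0, 1, 0, 1], M=[1.0, 2.0, 3.0, 4.0], Y=[2.0, 4.0, 6.0, 8.0])
    np.testing.assert_allclose(residualize_placebo(d, 2.0), np.zeros(4), atol=1e-14)


def test_residualize_matches_elementwise_loop(fixed_dataset):
    psi = 1.7
    oracle = np.array([y - psi * m for y, m in zip(fixed_dataset.Y, fixed_dataset.M)])
    np.testing.assert_allclose(residualize_placebo(fixed_dataset, psi), oracle)


def test_two_step_perfect_compliance_is_group_mean_difference():
    rng = np.random.default_rng(3)
    z = np.array([0, 1] * 5)
    y = rng.normal(size=10)
    d = _dataset(Q=np.array([0, 0, 1, 1, 0, 1, 0, 1, 1, 0]), M=rng.normal(size=10), Y=y, Z=z, X=z)
    est = treatment_effect_two_step(d, psi_hat=0.0)
    assert est.value == pytest.approx(y[z == 1].mean() - y[z == 0].mean(), abs=1e-12)


def test_two_step_zero_for_constant_residuals():
    d = _dataset(Q=[0, 1, 0, 1], M=[1.0, 2.0, 3.0, 4.0], Y=[2.0, 4.0, 6.0, 8.0])
    assert treatment_effect_two_step(d, psi_hat=2.0).value == 0.0


def test_two_step_matches_covariance_composition_oracle(fixed_dataset):
    psi = 0.8
    est = treatment_effect_two_step(fixed_dataset, psi)
    r = fixed_dataset.Y - psi * fixed_dataset.M
    oracle = np.cov(fixed_dataset.Z, r, ddof=1)[0, 1] / np.cov(
        fixed_dataset.Z, fixed_dataset.X, ddof=1
    )[0, 1]
    assert est.value == pytest.approx(oracle, abs=1e-12)
    assert est.diagnostics["psi_hat"] == psi


def test_unadjusted_equals_two_step_at_zero_psi(simulated_alt):
    assert treatment_effect_unadjusted(simulated_alt).value == pytest.approx(
        treatment_effect_two_step(simulated_alt, 0.0).value, abs=1e-14
    )


def test_unadjusted_exact_ratio_under_proportionality():
    z = np.array([0, 1, 1, 0, 1, 0])
    d = _dataset(Q=[0, 1, 0, 1, 1, 0], M=[0.1, 0.9, 0.2, 1.1, 0.8, 0.3], Y=5.0 * z, Z=z, X=z)
    assert treatment_effect_unadjusted(d).value == pytest.approx(5.0, abs=1e-12)


def test_unadjusted_centered_at_zero_under_null():
    # null simulation: Y carries no treatment or placebo effect
    estimates = []
    for seed in range(2000):
        data = piv.simulate_trial(null_blinded_params(n=120), seed=seed)
        try:
            estimates.append(treatment_effect_unadjusted(data).value)
        except DegenerateInstrumentError:
            # binary X can tie its group means exactly by chance
            continue
    estimates = np.asarray(estimates)
    se = estimates.std(ddof=1) / np.sqrt(len(estimates))
    assert abs(estimates.mean()) < 3 * se


# -- ITT and Wald forms ------------------------------------------------------


def test_itt_identities_and_group_means_oracle():
    rng = np.random.default_rng(12)
    q = np.array([0, 1] * 6)
    z = np.array([0, 0, 1, 1] * 3)
    m, y = rng.normal(size=12) + q, rng.normal(size=12)
    x = np.array([0, 0, 1, 0, 1, 1, 0, 1, 1, 0, 1, 1], dtype=float)
    d = TrialDataset(Z=z, Q=q, X=x, M=m, Y=y)
    psi_hat = placebo_effect_iv(d).value
    itt = itt_estimates(d, psi_hat)
    # defining identities against the covariance-ratio estimates
    assert itt.itt_psi == pytest.approx(psi_hat * itt.K1, abs=1e-12)
    beta_hat = treatment_effect_two_step(d, psi_hat).value
    assert itt.itt_beta == pytest.approx(beta_hat * itt.K2, abs=1e-12)
    # group means by hand enumeration
    assert itt.itt_psi == pytest.approx(y[q == 1].mean() - y[q == 0].mean())
    r = y - psi_hat * m
    assert itt.itt_beta == pytest.approx(r[z == 1].mean() - r[z == 0].mean())


def test_wald_ace_examples_and_covariance_identity():
    assert wald_ace_binary([0, 1], [0.0, 1.0]) == 1.0
    assert wald_ace_binary([0, 1, 0, 1], [2.0] * 4) == 0.0
    rng = np.random.default_rng(5)
    instr = rng.binomial(1, 0.4, 50).astype(float)
    target = rng.normal(size=50)
    n, n1 = 50, int(instr.sum())
    n0 = n - n1
    identity = sample_covariance(instr, target) * n * (n - 1) / (n1 * n0)
    assert wald_ace_binary(instr, target) == pytest.approx(identity, abs=1e-12)
    with pytest.raises(DegenerateInstrumentError):
        wald_ace_binary(np.ones(6), target[:6])


# -- observed-confounder adjustment -----------------------------------------


def test_adjustment_with_orthogonal_covariate_only_centers():
    cols = dict(
        Z=np.array([0, 1, 0, 1]),
        Q=np.array([0, 0, 1, 1]),
        X=np.array([0, 1, 0, 1]),
        M=np.array([1.0, -1.0, 1.0, -1.0]),
        Y=np.array([3.0, 1.0, 3.0, 1.0]),
    )
    c = np.array([1.0, 1.0, -1.0, -1.0])  # exactly orthogonal to M and Y deviations
    data = TrialDataset(covariates={"c": c}, **cols)
    adjusted = adjust_observed_confounders(data, ["c"], ["M", "Y"])
    np.testing.assert_allclose(adjusted.M, cols["M"] - cols["M"].mean(), atol=1e-12)
    np.testing.assert_allclose(adjusted.Y, cols["Y"] - cols["Y"].mean(), atol=1e-12)


def test_adjustment_removes_target_equal_to_covariate(fixed_dataset):
    data = TrialDataset(
        Z=fixed_dataset.Z,
        Q=fixed_dataset.Q,
        X=fixed_dataset.X,
        M=fixed_dataset.M,
        Y=fixed_dataset.Y,
        covariates={"c": fixed_dataset.Y.copy()},
    )
    adjusted = adjust_observed_confounders(data, ["c"], ["Y"])
    np.testing.assert_allclose(adjusted.Y, np.zeros(data.n), atol=1e-10)


def test_adjustment_refuses_instruments_and_rank_deficiency(fixed_dataset):
    data = TrialDataset(
        Z=fixed_dataset.Z,
        Q=fixed_dataset.Q,
        X=fixed_dataset.X,
        M=fixed_dataset.M,
        Y=fixed_dataset.Y,
        covariates={"c": np.ones(fixed_dataset.n)},
    )
    with pytest.raises(ValueError, match="instrument"):
        adjust_observed_confounders(data, ["c"], ["Q"])
    with pytest.raises(ValueError, match="rank"):
        adjust_observed_confounders(data, ["c"], ["Y"])


def test_adjusting_for_received_treatment_reduces_placebo_variance_unblinded():
    """In unblinded trials X confounds the placebo channel; residualizing
    M and Y on X before the IV step should shrink the Monte-Carlo spread
    of the placebo estimate."""
    params = piv.ReducedModelParameters.with_constant_loadings(
        1.0, n=800, beta=1.0, psi=1.0, theta_EX=1.5, blinded=False,
        theta_DQ=2.0, theta_MD=2.0, theta_ME=2.0,
    )
    plain, adjusted = [], []
    for seed in range(500):
        data = piv.simulate_trial(params, seed=10_000 + seed)
        with_x = TrialDataset(
            Z=data.Z, Q=data.Q, X=data.X, M=data.M, Y=data.Y, covariates={"x": data.X.copy()}
        )
        try:
            plain.append(placebo_effect_iv(data).value)
            adj = adjust_observed_confounders(with_x, ["x"], ["M", "Y"])
            adjusted.append(placebo_effect_iv(adj).value)
        except DegenerateInstrumentError:
            continue
    assert np.var(adjusted) < np.var(plain)


# -- multiple mediators ------------------------------------------------------


def _multi_mediator_dataset():
    reps = 4
    q = np.tile([0, 1], 8 * reps // 2)
    w = np.tile([0, 0, 1, 1], 8 * reps // 4)
    z = np.tile([0, 1, 1, 0, 1, 0, 0, 1], reps)
    m = q.astype(float)
    a = w.astype(float)
    y = 2.0 * m + 3.0 * a
    return TrialDataset(Z=z, Q=q, X=z, M=m, Y=y, A=a, W=w)


def test_multi_mediator_exact_construction():
    est = multi_mediator_two_step(_multi_mediator_dataset())
    assert est.diagnostics["psi_hat"] == pytest.approx(2.0, abs=1e-12)
    assert est.diagnostics["kappa_hat"] == pytest.approx(3.0, abs=1e-12)
    assert est.value == pytest.approx(0.0, abs=1e-12)


def test_multi_mediator_matches_sequential_composition(simulated_alt):
    rng = np.random.default_rng(77)
    d = simulated_alt
    w = rng.binomial(1, 0.5, d.n).astype(float)
    a = 1.5 * w + rng.standard_normal(d.n)
    y = d.Y + 2.0 * a
    data = TrialDataset(Z=d.Z, Q=d.Q, X=d.X, M=d.M, Y=y, A=a, W=w)
    est = multi_mediator_two_step(data)
    psi = placebo_effect_iv(data).value
    kappa = piv.extra_mediator_effect_iv(data).value
    r = y - psi * data.M - kappa * a
    oracle = np.cov(data.Z, r, ddof=1)[0, 1] / np.cov(data.Z, data.X, ddof=1)[0, 1]
    assert est.value == pytest.approx(oracle, abs=1e-12)


def test_multi_mediator_reduces_to_single_mediator_for_null_extra_channel():
    params = piv.ReducedModelParameters.with_constant_loadings(
        1.0, n=100_000, beta=1.0, psi=1.0, theta_EX=1.0, blinded=False, kappa=0.0
    )
    data = piv.simulate_trial(params, seed=99)
    multi = multi_mediator_two_step(data).value
    single = treatment_effect_two_step(data, placebo_effect_iv(data).value).value
    assert multi == pytest.approx(single, abs=0.05)


# -- regression comparator ---------------------------------------------------


def test_regression_recovers_noiseless_coefficients():
    rng = np.random.default_rng(4)
    x = rng.binomial(1, 0.5, 30).astype(float)
    m = rng.normal(size=30)
    d = _dataset(Q=rng.binomial(1, 0.5, 30), M=m, Y=1.0 + 2.0 * x + 3.0 * m, X=x, Z=x)
    fit = regression_comparator(d)
    assert (fit.mu_hat, fit.beta_hat, fit.psi_hat) == pytest.approx((1.0, 2.0, 3.0), abs=1e-10)
    assert fit.beta_pvalue < 1e-12 and fit.psi_pvalue < 1e-12


def test_regression_row_permutation_invariance(fixed_dataset):
    fit = regression_comparator(fixed_dataset)
    perm = np.random.default_rng(1).permutation(fixed_dataset.n)
    permuted = TrialDataset(
        Z=fixed_dataset.Z[perm],
        Q=fixed_dataset.Q[perm],
        X=fixed_dataset.X[perm],
        M=fixed_dataset.M[perm],
        Y=fixed_dataset.Y[perm],
    )
    fit2 = regression_comparator(permuted)
    assert fit2.beta_hat == pytest.approx(fit.beta_hat, abs=1e-12)
    assert fit2.psi_hat == pytest.approx(fit.psi_hat, abs=1e-12)


def test_regression_matches_normal_equations_oracle(simulated_alt):
    fit = regression_comparator(simulated_alt)
    design = np.column_stack(
        [np.ones(simulated_alt.n), simulated_alt.X, simulated_alt.M]
    )
    coef = np.linalg.solve(design.T @ design, design.T @ simulated_alt.Y)
    assert (fit.mu_hat, fit.beta_hat, fit.psi_hat) == pytest.approx(tuple(coef), abs=1e-10)


# -- diagnostics and global invariants ---------------------------------------


def test_instrument_diagnostics_perfect_and_weak():
    q = np.array([0, 1, 0, 1, 1, 0])
    d = TrialDataset(Z=q, Q=q, X=q, M=q.astype(float), Y=np.arange(6, dtype=float))
    diag = instrument_diagnostics(d)
    assert diag["corr_QM"] == pytest.approx(1.0)
    assert diag["corr_ZX"] == pytest.approx(1.0)
    assert not diag["weak_instrument"]["corr_ZX"]
    rng = np.random.default_rng(10)
    big = TrialDataset(
        Z=rng.binomial(1, 0.5, 10_000),
        Q=rng.binomial(1, 0.5, 10_000),
        X=rng.binomial(1, 0.5, 10_000),
        M=rng.normal(size=10_000),
        Y=rng.normal(size=10_000),
    )
    assert abs(instrument_diagnostics(big)["corr_QM"]) < 0.05


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_wald_identity_for_binary_instruments(seed):
    """Covariance-ratio estimator equals the ratio of group-mean gaps exactly."""
    data = piv.simulate_trial(null_blinded_params(n=150), seed=seed)
    psi_hat = placebo_effect_iv(data).value
    dm = data.M[data.Q == 1].mean() - data.M[data.Q == 0].mean()
    dy = data.Y[data.Q == 1].mean() - data.Y[data.Q == 0].mean()
    assert psi_hat == pytest.approx(dy / dm, abs=1e-12)


@pytest.mark.parametrize("c", [2.0, -0.5])
def test_scale_equivariance(simulated_alt, c):
    psi0 = placebo_effect_iv(simulated_alt).value
    beta0 = treatment_effect_two_step(simulated_alt, psi0).value
    scaled_y = simulated_alt.replace_column("Y", c * simulated_alt.Y)
    psi_y = placebo_effect_iv(scaled_y).value
    assert psi_y == pytest.approx(c * psi0, rel=1e-12)
    assert treatment_effect_two_step(scaled_y, psi_y).value == pytest.approx(
        c * beta0, rel=1e-10
    )
    scaled_m = simulated_alt.replace_column("M", c * simulated_alt.M)
    psi_m = placebo_effect_iv(scaled_m).value
    assert psi_m == pytest.approx(psi0 / c, rel=1e-12)
    assert treatment_effect_two_step(scaled_m, psi_m).value == pytest.approx(
        beta0, rel=1e-10
    )


def test_row_permutation_invariance(simulated_alt):
    perm = np.random.default_rng(2).permutation(simulated_alt.n)
    permuted = TrialDataset(
        Z=simulated_alt.Z[perm],
        Q=simulated_alt.Q[perm],
        X=simulated_alt.X[perm],
        M=simulated_alt.M[perm],
        Y=simulated_alt.Y[perm],
    )
    assert placebo_effect_iv(permuted).value == pytest.approx(
        placebo_effect_iv(simulated_alt).value, abs=1e-12
    )
    assert treatment_effect_unadjusted(permuted).value == pytest.approx(
        treatment_effect_unadjusted(simulated_alt).value, abs=1e-12
    )
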