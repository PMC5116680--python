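"""Covariance-ratio IV estimators of placebo and treatment effects.

The design randomizes two instruments: the treatment assignment ``Z``
(an instrument for the received treatment ``X``) and a psychological
encouragement ``Q`` that raises the desire for symptom improvement and
thereby the emotion level ``M`` (an instrument for ``M``).  Under a
linear outcome model with additive confounding,

    psi = Cov(Q, Y) / Cov(Q, M)      (net placebo effect of M on Y)
    beta = Cov(Z, Y - psi*M) / Cov(Z, X)   (treatment effect of X on Y)

both identified despite unmeasured confounders because the instruments
are randomized.  Estimation replaces each covariance with its sample
analogue; the treatment effect uses a two-step plug-in of the estimated
placebo effect.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm

from .dataset import TrialDataset

__all__ = [
    "DegenerateInstrumentError",
    "EffectEstimate",
    "ITTEstimates",
    "RegressionFit",
    "sample_covariance",
    "placebo_effect_iv",
    "residualize_placebo",
    "treatment_effect_two_step",
    "treatment_effect_unadjusted",
    "itt_estimates",
    "wald_ace_binary",
    "adjust_observed_confounders",
    "extra_mediator_effect_iv",
    "multi_mediator_two_step",
    "regression_comparator",
    "instrument_diagnostics",
]

#: relative degeneracy tolerance for covariance denominators
DEGENERACY_RTOL = 1e-10

#: default |correlation| below which an instrument is flagged as weak
WEAK_INSTRUMENT_THRESHOLD = 0.1


class DegenerateInstrumentError(ValueError):
    """A covariance denominator is numerically zero.

    Ratio estimators can produce highly inflated estimates when the
    instrument barely moves its target (Cov ~ 0), so construction fails
    instead of returning a number.
    """


def sample_covariance(a, b) -> float:
    """Sample covariance of two equal-length vectors (n-1 denominator)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("inputs must be one-dimensional vectors of equal length")
    if a.shape[0] < 2:
        raise ValueError("sample covariance needs at least 2 observations")
    return float((a - a.mean()) @ (b - b.mean()) / (a.shape[0] - 1))


def _checked_ratio(
    num_a, num_b, den_a, den_b, *, what: str
) -> tuple[float, float, float]:
    """(numerator, denominator, ratio) with a degeneracy guard on the denominator."""
    num = sample_covariance(num_a, num_b)
    den = sample_covariance(den_a, den_b)
    tol = DEGENERACY_RTOL * float(np.std(den_a, ddof=1) * np.std(den_b, ddof=1))
    if abs(den) <= tol:
        raise DegenerateInstrumentError(
            f"{what}: denominator covariance {den:.3g} is degenerate "
            "(weak or non-varying instrument; the ratio estimator would be inflated)"
        )
    return num, den, num / den


def _corr(a, b) -> float:
    sa = np.std(a, ddof=1)
    sb = np.std(b, ddof=1)
    if sa == 0 or sb == 0:
        return float("nan")
    return sample_covariance(a, b) / float(sa * sb)


@dataclass(frozen=True)
class EffectEstimate:
    """A causal-effect point estimate with its covariance components."""

    effect_kind: str
    value: float
    numerator: float
    denominator: float
    diagnostics: dict = field(default_factory=dict)

    def to_json_record(self) -> dict:
        return {
            "effect_kind": self.effect_kind,
            "value": self.value,
            "numerator": self.numerator,
            "denominator": self.denominator,
            "diagnostics": self.diagnostics,
        }


@dataclass(frozen=True)
class ITTEstimates:
    """Intention-to-treat effects and the constants linking them to the IV estimates.

    ``itt_psi = psi_hat * K1`` and ``itt_beta = beta_hat * K2`` hold exactly;
    K1 and K2 depend only on (Q, M) and (Z, X), so they are constant across
    permutations of the response in a randomization test.
    """

    itt_psi: float
    K1: float
    itt_beta: float
    K2: float


@dataclass(frozen=True)
class RegressionFit:
    """OLS comparator fit of Y on (1, X, M) with analytic t-tests."""

    mu_hat: float
    beta_hat: float
    psi_hat: float
    beta_se: float
    psi_se: float
    beta_t: float
    psi_t: float
    beta_pvalue: float
    psi_pvalue: float


def instrument_diagnostics(
    data: TrialDataset, threshold: float = WEAK_INSTRUMENT_THRESHOLD
) -> dict:
    """Instrument-strength correlations with advisory weak-instrument flags.

    Reports corr(Q, M) (does encouragement move emotion?), corr(Z, X)
    (compliance) and, when desire was measured, corr(Q, D) (did the
    encouragement raise desire?).
    """
    out: dict = {"corr_QM": _corr(data.Q, data.M), "corr_ZX": _corr(data.Z, data.X)}
    if data.has("D"):
        out["corr_QD"] = _corr(data.Q, data.D)
    out["weak_instrument"] = {
        k: (np.isnan(v) or abs(v) < threshold)
        for k, v in out.items()
        if k.startswith("corr_")
    }
    return out


def placebo_effect_iv(data: TrialDataset) -> EffectEstimate:
    """Estimate the net placebo effect psi as Cov(Q, Y) / Cov(Q, M).

    Uses only Q, M and Y — expectation and desire measurements, when
    present, inform diagnostics but never enter the estimator.
    """
    num, den, value = _checked_ratio(
        data.Q, data.Y, data.Q, data.M, what="placebo effect Cov(Q,M)"
    )
    return EffectEstimate(
        "placebo", value, num, den, diagnostics=instrument_diagnostics(data)
    )


def residualize_placebo(data: TrialDataset, psi: float) -> np.ndarray:
    """Outcome residuals R = Y - psi*M after removing the placebo contribution."""
    return data.Y - float(psi) * data.M


def treatment_effect_two_step(data: TrialDataset, psi_hat: float) -> EffectEstimate:
    """Two-step treatment effect: Cov(Z, Y - psi_hat*M) / Cov(Z, X)."""
    r = residualize_placebo(data, psi_hat)
    num, den, value = _checked_ratio(
        data.Z, r, data.Z, data.X, what="treatment effect Cov(Z,X) (non-compliance)"
    )
    diags = instrument_diagnostics(data)
    diags["psi_hat"] = float(psi_hat)
    return EffectEstimate("treatment_two_step", value, num, den, diagnostics=diags)


def treatment_effect_unadjusted(data: TrialDataset) -> EffectEstimate:
    """Simple IV treatment effect Cov(Z, Y) / Cov(Z, X), ignoring placebo effects."""
    num, den, value = _checked_ratio(
        data.Z, data.Y, data.Z, data.X, what="treatment effect Cov(Z,X) (non-compliance)"
    )
    return EffectEstimate(
        "treatment_unadjusted", value, num, den, diagnostics=instrument_diagnostics(data)
    )


def wald_ace_binary(instrument, target) -> float:
    """Difference of target means between the two levels of a binary instrument.

    This is the large-sample non-parametric average-causal-effect
    estimator for a randomized binary instrument; it is proportional to
    ``sample_covariance(instrument, target)`` by the factor
    ``n * (n - 1) / (n1 * n0)`` with ``n1``, ``n0`` the group sizes.
    """
    instrument = np.asarray(instrument, dtype=float)
    target = np.asarray(target, dtype=float)
    on = instrument == 1
    if not on.any() or on.all():
        raise DegenerateInstrumentError(
            "binary instrument has a single observed level; group contrast undefined"
        )
    return float(target[on].mean() - target[~on].mean())


def itt_estimates(data: TrialDataset, psi_hat: float) -> ITTEstimates:
    """ITT effects for both instruments together with the constants K1, K2.

    ``itt_psi`` is the mean-outcome gap between encouraged and
    non-encouraged groups; ``itt_beta`` the mean gap of the placebo-free
    residuals between assigned arms.  K1 = E[M|Q=1]-E[M|Q=0] and
    K2 = E[X|Z=1]-E[X|Z=0] convert the covariance-ratio estimates to the
    ITT scale.
    """
    itt_psi = wald_ace_binary(data.Q, data.Y)
    k1 = wald_ace_binary(data.Q, data.M)
    r = residualize_placebo(data, psi_hat)
    itt_beta = wald_ace_binary(data.Z, r)
    k2 = wald_ace_binary(data.Z, data.X)
    return ITTEstimates(itt_psi=itt_psi, K1=k1, itt_beta=itt_beta, K2=k2)


def adjust_observed_confounders(
    data: TrialDataset, covariates: list[str], targets: list[str]
) -> TrialDataset:
    """Replace target columns by least-squares residuals on observed confounders.

    Each target column (typically X and Y, or M and Y) is separately
    regressed on the named covariate columns plus an intercept and
    replaced by the residuals.  Instruments are randomized, hence never
    residualized.  Adjustment is optional for consistency but can reduce
    the Monte-Carlo variance of the estimates.
    """
    if not covariates:
        raise ValueError("at least one covariate column is required")
    for t in targets:
        if t in ("Z", "Q", "W"):
            raise ValueError(f"instrument {t!r} must not be residualized")
    design = np.column_stack(
        [np.ones(data.n)] + [data.column(c) for c in covariates]
    )
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("covariate block is rank deficient")
    out = data
    for t in targets:
        y = data.column(t)
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        out = out.replace_column(t, y - design @ coef)
    return out


def extra_mediator_effect_iv(data: TrialDataset) -> EffectEstimate:
    """Effect of an extra placebo mediator A on Y via its instrument W."""
    num, den, value = _checked_ratio(
        data.W, data.Y, data.W, data.A, what="extra mediator Cov(W,A)"
    )
    return EffectEstimate("mediator_extra", value, num, den)


def multi_mediator_two_step(data: TrialDataset) -> EffectEstimate:
    """Two-step treatment effect when the placebo channel has two mediators.

    Estimates psi_hat = Cov(Q,Y)/Cov(Q,M) and kappa_hat = Cov(W,Y)/Cov(W,A),
    removes both mediated contributions from the outcome, and applies the
    IV ratio on the doubly-residualized outcome:
    Cov(Z, Y - psi_hat*M - kappa_hat*A) / Cov(Z, X).
    """
    psi_hat = placebo_effect_iv(data).value
    kappa_hat = extra_mediator_effect_iv(data).value
    r = data.Y - psi_hat * data.M - kappa_hat * data.A
    num, den, value = _checked_ratio(
        data.Z, r, data.Z, data.X, what="treatment effect Cov(Z,X) (non-compliance)"
    )
    diags = instrument_diagnostics(data)
    diags["psi_hat"] = psi_hat
    diags["kappa_hat"] = kappa_hat
    return EffectEstimate("treatment_two_step", value, num, den, diagnostics=diags)


def regression_comparator(data: TrialDataset) -> RegressionFit:
    """OLS of Y on (1, X, M), the naive comparator to the IV approach.

    Consistent only when no unmeasured confounder links X or M with Y;
    under confounding its t-tests reject far above the nominal level.
    """
    if data.n <= 3:
        raise ValueError("regression comparator needs n > 3 (n - 3 df)")
    design = sm.add_constant(np.column_stack([data.X, data.M]), has_constant="add")
    if np.linalg.matrix_rank(design) < 3:
        raise ValueError("design (1, X, M) is rank deficient (collinear X and M)")
    fit = sm.OLS(data.Y, design).fit()
    return RegressionFit(
        mu_hat=float(fit.params[0]),
        beta_hat=float(fit.params[1]),
        psi_hat=float(fit.params[2]),
        beta_se=float(fit.bse[1]),
        psi_se=float(fit.bse[2]),
        beta_t=float(fit.tvalues[1]),
        psi_t=float(fit.tvalues[2]),
        beta_pvalue=float(fit.pvalues[1]),
        psi_pvalue=float(fit.pvalues[2]),
    )
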