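"""Exact randomization tests and test-inversion confidence intervals.

The tests re-shuffle the response against the intact instrument pairs
((Q, M) for placebo effects, (Z, X) for treatment effects), re-computing
the covariance-ratio statistic on every shuffle.  Because the
instruments are randomized, shuffling the response is a re-randomization
consistent with the design, which makes the placebo test (and the
treatment test in blinded trials) exact at every nominal level.

Confidence intervals come from inverting shifted-null tests: the null
H0: theta = theta_j is equivalent to a zero intention-to-treat (ITT)
effect after adding ``theta_j * K`` to each response in the assigned
control group, where K is the group-mean gap of the instrumented
variable (K1 for psi, K2 for beta) and is constant across response
permutations.  The null distribution shuffles the hypothesis-consistent
residual (response minus theta_j times the instrumented variable), the
quantity H0 makes independent of the instrument, so the shifted tests
keep the exactness of the zero-null tests at every theta_j.  Walking
theta_j outward from the observed estimate gives a one-sided p-value
profile from which the interval at any level is read off.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations as _iter_permutations

import numpy as np

from .dataset import TrialDataset
from .estimators import (
    DegenerateInstrumentError,
    placebo_effect_iv,
    residualize_placebo,
    sample_covariance,
    wald_ace_binary,
)

__all__ = [
    "RandomizationTestResult",
    "PValueProfile",
    "ConfidenceInterval",
    "draw_permutations",
    "placebo_randomization_test",
    "treatment_randomization_test",
    "shifted_itt_test",
    "pvalue_profile",
    "confidence_interval",
]

#: largest n for which the full n! shuffle space is enumerated exactly
EXHAUSTIVE_LIMIT = 7


@dataclass(frozen=True)
class RandomizationTestResult:
    effect_kind: str
    observed_statistic: float
    n_permutations: int
    alternative: str
    p_value: float
    seed: int | None
    exact: bool  # True when the shuffle space was enumerated exhaustively

    @property
    def at_floor(self) -> bool:
        """True when no shuffle (other than the identity, if enumerated) was as extreme."""
        if self.exact:
            return self.p_value <= 1.0 / self.n_permutations + 1e-15
        return self.p_value <= 1.0 / (self.n_permutations + 1) + 1e-15


@dataclass(frozen=True)
class PValueProfile:
    """One-sided shifted-null p-values on a grid around the observed estimate."""

    effect_kind: str
    observed_estimate: float
    shift_constant: float  # K1 for psi, K2 for beta
    step: float
    grid: list  # (theta_j, side, p_value), thetas ascending within each side

    def side(self, side: str) -> tuple[np.ndarray, np.ndarray]:
        """(thetas, p-values) for one side, thetas ascending."""
        pairs = sorted((t, p) for t, s, p in self.grid if s == side)
        thetas = np.array([t for t, _ in pairs])
        ps = np.array([p for _, p in pairs])
        return thetas, ps


@dataclass(frozen=True)
class ConfidenceInterval:
    level: float
    lower: float
    upper: float


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def draw_permutations(
    n: int, B: int, seed=None, exhaustive_limit: int = EXHAUSTIVE_LIMIT
) -> tuple[np.ndarray, bool]:
    """Index matrix of response shuffles; exhaustive n! enumeration for small n.

    Returns ``(perms, exact)`` where ``perms`` has one permutation of
    ``range(n)`` per row.  For ``n <= exhaustive_limit`` every one of the n!
    permutations is returned once (``exact=True``); otherwise ``B`` uniform
    draws with replacement from the shuffle space.
    """
    if n <= exhaustive_limit:
        return np.array(list(_iter_permutations(range(n))), dtype=np.intp), True
    if B < 1:
        raise ValueError("B must be at least 1")
    perms = np.tile(np.arange(n, dtype=np.intp), (B, 1))
    _rng(seed).permuted(perms, axis=1, out=perms)
    return perms, False


def _tie_tol(obs: float, null: np.ndarray) -> float:
    # permutations that reproduce the observed statistic must count as "as
    # extreme" even when a different summation order perturbs the last ulp
    scale = max(abs(obs), float(np.max(np.abs(null), initial=0.0)), 1e-300)
    return 1e-9 * scale


def _pvalue(obs: float, null: np.ndarray, alternative: str, exact: bool) -> float:
    tol = _tie_tol(obs, null)
    if alternative == "two_sided":
        count = int((np.abs(null) >= abs(obs) - tol).sum())
    elif alternative == "greater":
        count = int((null >= obs - tol).sum())
    elif alternative == "less":
        count = int((null <= obs + tol).sum())
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    if exact:
        # the identity permutation is in the enumeration, so count >= 1
        return count / null.shape[0]
    return (1 + count) / (null.shape[0] + 1)


def _cov_ratio_stats(
    instrument: np.ndarray,
    anchor: np.ndarray,
    response: np.ndarray,
    perms: np.ndarray,
    statistic: str,
):
    """Observed and permuted test statistics for a zero-effect null.

    ``statistic='iv'`` uses the covariance ratio Cov(instr, response_perm)
    / Cov(instr, anchor); ``statistic='itt'`` uses the group-mean gap of
    the permuted response.  The two are proportional through a
    permutation-constant factor, so they produce identical p-values on
    shared permutations (exactly equal counts for two-sided tests, and
    for one-sided tests whenever the constant is positive).
    """
    n = instrument.shape[0]
    if statistic == "iv":
        den = sample_covariance(instrument, anchor)
        qc = (instrument - instrument.mean()) / ((n - 1) * den)
    elif statistic == "itt":
        on = instrument == 1
        if not on.any() or on.all():
            raise DegenerateInstrumentError("instrument has a single observed level")
        qc = np.where(on, 1.0 / on.sum(), -1.0 / (~on).sum())
    else:
        raise ValueError(f"unknown statistic {statistic!r}")
    obs = float(response @ qc)
    null = response[perms] @ qc
    return obs, null


def placebo_randomization_test(
    data: TrialDataset,
    B: int = 1000,
    seed=None,
    alternative: str = "two_sided",
    permutations: np.ndarray | None = None,
    statistic: str = "iv",
) -> RandomizationTestResult:
    """Test H0: psi = 0 by shuffling Y against the intact (Q, M) pairs.

    The (Q, M) connection is preserved so the association between
    encouragement and emotion — the instrument's first stage — is kept in
    every null draw.
    """
    placebo_effect_iv(data)  # validates Cov(Q, M) in the observed data
    if permutations is None:
        perms, exact = draw_permutations(data.n, B, seed)
    else:
        perms, exact = permutations, False
    # observed and permuted statistics share one code path so that the
    # identity permutation ties the observed value bit-for-bit
    obs, null = _cov_ratio_stats(data.Q, data.M, data.Y, perms, statistic)
    return RandomizationTestResult(
        effect_kind="placebo",
        observed_statistic=obs,
        n_permutations=perms.shape[0],
        alternative=alternative,
        p_value=_pvalue(obs, null, alternative, exact),
        seed=seed if isinstance(seed, int) else None,
        exact=exact,
    )


def treatment_randomization_test(
    data: TrialDataset,
    B: int = 1000,
    seed=None,
    alternative: str = "two_sided",
    psi: float | None = None,
    permutations: np.ndarray | None = None,
    statistic: str = "iv",
) -> RandomizationTestResult:
    """Test H0: beta = 0 by shuffling residuals against the intact (Z, X) pairs.

    ``psi=None`` runs the two-step test: the placebo effect is estimated
    once on the observed (never permuted) data and the fixed residual
    vector R = Y - psi_hat*M is shuffled.  ``psi=0`` gives the unadjusted
    test on Y itself; passing the generating psi gives the oracle
    true-psi-adjusted test used in simulation benchmarks.
    """
    if psi is None:
        psi = placebo_effect_iv(data).value
    r = residualize_placebo(data, psi)
    if permutations is None:
        perms, exact = draw_permutations(data.n, B, seed)
    else:
        perms, exact = permutations, False
    obs, null = _cov_ratio_stats(data.Z, data.X, r, perms, statistic)
    return RandomizationTestResult(
        effect_kind="treatment",
        observed_statistic=obs,
        n_permutations=perms.shape[0],
        alternative=alternative,
        p_value=_pvalue(obs, null, alternative, exact),
        seed=seed if isinstance(seed, int) else None,
        exact=exact,
    )


def _shift_setup(data: TrialDataset, effect_kind: str, psi_hat: float | None):
    """(instrument, response, anchor, K, observed estimate) for one effect.

    The anchor is the instrumented variable (M for psi, X for beta): under
    H0: theta = theta_j the hypothesis-consistent residual
    ``response - theta_j * anchor`` is independent of the instrument, so
    shuffling it is a re-randomization and the shifted test stays exact.
    """
    if effect_kind == "psi":
        instr, resp, anchor = data.Q, data.Y, data.M
        k = wald_ace_binary(data.Q, data.M)
        est = placebo_effect_iv(data).value
    elif effect_kind == "beta":
        if psi_hat is None:
            psi_hat = placebo_effect_iv(data).value
        instr = data.Z
        resp = residualize_placebo(data, psi_hat)
        anchor = data.X
        k = wald_ace_binary(data.Z, data.X)
        est = sample_covariance(data.Z, resp) / sample_covariance(data.Z, data.X)
    else:
        raise ValueError(f"unknown effect_kind {effect_kind!r}")
    if k == 0:
        raise DegenerateInstrumentError(
            "shift constant K is zero; the instrumented variable does not differ between arms"
        )
    return instr, resp, anchor, k, est


def _itt_weights(instrument: np.ndarray) -> np.ndarray:
    on = instrument == 1
    if not on.any() or on.all():
        raise DegenerateInstrumentError("instrument has a single observed level")
    return np.where(on, 1.0 / on.sum(), -1.0 / (~on).sum())


def shifted_itt_test(
    data: TrialDataset,
    effect_kind: str,
    theta0: float,
    side: str,
    B: int = 1000,
    seed=None,
    psi_hat: float | None = None,
    permutations: np.ndarray | None = None,
) -> float:
    """One-sided randomization p-value for H0: theta = theta0.

    The observed statistic is the zero-ITT statistic of the shifted data
    (``theta0 * K`` added to every response in the assigned control
    group), which turns the shifted null into a two-sample location
    problem; it equals ``(estimate - theta0) * K`` exactly.  Null draws
    shuffle the hypothesis-consistent residual ``response - theta0 *
    anchor`` — the quantity that H0 makes independent of the instrument —
    against the intact instrument pairs, which keeps the test exact at
    every theta0, not just 0.  All statistics are divided by the
    permutation-constant K, so ``side='greater'`` always means evidence
    for theta > theta0 (and 'less' the reverse) irrespective of K's sign.
    """
    instr, resp, anchor, k, est = _shift_setup(data, effect_kind, psi_hat)
    if permutations is None:
        perms, exact = draw_permutations(data.n, B, seed)
    else:
        perms, exact = permutations, False
    resid = resp - theta0 * anchor
    w = _itt_weights(instr)
    obs = float(resid @ w) / k  # equals est - theta0 (the shifted-data ITT / K)
    null = (resid[perms] @ w) / k
    if side not in ("greater", "less"):
        raise ValueError("side must be 'greater' or 'less'")
    return _pvalue(obs, null, side, exact)


def pvalue_profile(
    data: TrialDataset,
    effect_kind: str,
    step: float | None = None,
    B: int = 1000,
    seed=None,
    psi_hat: float | None = None,
    max_steps: int = 20000,
) -> PValueProfile:
    """One-sided p-value profile around the observed estimate.

    From the observed estimate, theta_j walks down in increments of
    ``step`` computing p-values against H1: theta > theta_j, until the
    p-value can decrease no further (for a strong instrument this is the
    Monte-Carlo analogue of "p-value equal to zero"); then up, against
    H1: theta < theta_j.  One permutation set, drawn once, is shared by
    every grid point, which makes the profile monotone outward and lets a
    confidence interval at any level be read from it.

    When the instrument is weak, permutations whose shuffled first-stage
    contrast exceeds the observed one (h > 1 below) remain "as extreme"
    under arbitrarily large shifts, so the one-sided p-values level off
    at a positive floor instead of reaching zero: the exact confidence
    set is then unbounded at levels below that floor, the ratio-estimator
    analogue of weak-instrument confidence sets covering the whole line.

    The default step is |estimate|/20, floored at 0.01 so near-zero
    estimates still get a usable grid.
    """
    instr, resp, anchor, k, est = _shift_setup(data, effect_kind, psi_hat)
    if step is None:
        step = max(abs(est) / 20.0, 0.01)
    if step <= 0:
        raise ValueError("step must be positive")
    perms, exact = draw_permutations(data.n, B, seed)
    w = _itt_weights(instr)
    # ITT of the permuted residual (resp - theta*anchor) / K is linear in
    # theta: a[b] - theta * h[b]; the observed statistic is est - theta.
    a = (resp[perms] @ w) / k
    h = (anchor[perms] @ w) / k
    n_perm = perms.shape[0]
    floor_count = 1 if exact else 0
    # Both the permuted and the observed statistic are linear in theta, so
    # each permutation changes its "as extreme" status exactly once, at
    # theta* = (a - est)/(h - 1).  Beyond the outermost breakpoints the
    # p-value is constant, so the walk can stop there; the 0.1% most
    # extreme breakpoints are ignored to keep near-degenerate h ~ 1
    # permutations (which flip absurdly far out, moving p by ~1/B) from
    # forcing an unbounded walk.
    den = h - 1.0
    finite = np.abs(den) > 1e-12 * max(1.0, float(np.max(np.abs(h))))
    if finite.any():
        breakpoints = (a[finite] - est) / den[finite]
        stop_lo = float(np.quantile(breakpoints, 0.001))
        stop_hi = float(np.quantile(breakpoints, 0.999))
    else:
        stop_lo = stop_hi = est

    def one_sided_p(theta: float, side: str) -> tuple[float, int]:
        null = a - theta * h
        obs = est - theta
        tol = _tie_tol(obs, null)
        if side == "greater":
            count = int((null >= obs - tol).sum())
        else:
            count = int((null <= obs + tol).sum())
        p = count / n_perm if exact else (1 + count) / (n_perm + 1)
        return p, count

    grid: list[tuple[float, str, float]] = []
    for side, direction, stop in (("greater", -1.0, stop_lo), ("less", +1.0, stop_hi)):
        for j in range(max_steps + 1):
            theta = est + direction * j * step
            p, count = one_sided_p(theta, side)
            grid.append((theta, side, p))
            if count <= floor_count or direction * (theta - stop) > 0:
                break
    return PValueProfile(
        effect_kind=effect_kind,
        observed_estimate=est,
        shift_constant=k,
        step=step,
        grid=grid,
    )


def confidence_interval(profile: PValueProfile, alpha: float) -> ConfidenceInterval:
    """100(1-2*alpha)% interval read from a p-value profile.

    Each bound is found by walking outward from the observed estimate to
    the first grid theta rejected at ``alpha`` (the test/interval
    correspondence): the bound is the last accepted theta before that
    first rejection.  Under a weak instrument the one-sided p-values can
    level off above alpha without ever rejecting; such a side yields an
    infinite bound, the ratio-estimator analogue of weak-instrument
    confidence sets covering the whole line.
    """
    if not 0 < alpha < 0.5:
        raise ValueError("alpha must be in (0, 0.5)")
    t_lo, p_lo = profile.side("greater")
    t_hi, p_hi = profile.side("less")
    if p_lo.size == 0 or p_hi.size == 0:
        raise ValueError("profile has an empty side")
    if p_lo[-1] <= alpha or p_hi[0] <= alpha:
        raise ValueError("profile too coarse to bracket alpha on both sides")
    # greater side: thetas ascend toward the estimate; walk outward = descend
    rejected_lo = np.nonzero(p_lo <= alpha)[0]
    lower = float(t_lo[rejected_lo.max() + 1]) if rejected_lo.size else float("-inf")
    rejected_hi = np.nonzero(p_hi <= alpha)[0]
    upper = float(t_hi[rejected_hi.min() - 1]) if rejected_hi.size else float("inf")
    return ConfidenceInterval(level=1.0 - 2.0 * alpha, lower=lower, upper=upper)
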