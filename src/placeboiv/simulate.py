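"""Synthetic encouragement-design trials from structural causal models.

Two generators are provided.  ``simulate_trial`` draws from the reduced
observed-variable model: instruments Z and Q are fair coins, the binary
received treatment X, expectation E and desire D follow probit-style
threshold models, emotion M and outcome Y are linear with standard
normal errors, and every unordered pair of the endogenous variables
{X, E, D, M, Y} may share a standard-normal confounder entering both
members' equations.  ``simulate_full_model`` additionally builds the
outcome through the latent somatic state S (targeted by the treatment)
and psychosomatic state P (driven by emotion), whose path coefficients
(eta, lambda, tau, delta, phi) imply the reduced effects
beta = eta*lambda and psi = phi*tau + phi*delta*lambda.

Parameter designs for simulation studies use maximin-optimized Latin
hypercube sampling so each study covers its parameter ranges evenly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist
from scipy.stats import qmc

from .dataset import TrialDataset

__all__ = [
    "ReducedModelParameters",
    "FullModelParameters",
    "LatinHypercubeDesign",
    "CONFOUNDER_PAIRS",
    "simulate_trial",
    "simulate_full_model",
    "reduced_effects_from_full",
    "latin_hypercube_design",
    "default_parameter_ranges",
    "params_from_point",
    "add_measurement_error",
]

#: the 10 unordered pairs of endogenous observed variables that may share
#: an unmeasured confounder (order fixed for reproducibility)
_ENDOGENOUS = ("X", "E", "D", "M", "Y")
CONFOUNDER_PAIRS = tuple(
    _ENDOGENOUS[i] + _ENDOGENOUS[j]
    for i in range(len(_ENDOGENOUS))
    for j in range(i + 1, len(_ENDOGENOUS))
)


def _loadings(value: float) -> dict[str, tuple[float, float]]:
    return {pair: (value, value) for pair in CONFOUNDER_PAIRS}


@dataclass(frozen=True)
class ReducedModelParameters:
    """Structural coefficients of the reduced observed-variable model.

    ``confounder_loadings`` maps each pair name (e.g. ``"XY"``) to the two
    loadings with which the shared standard-normal confounder enters the
    first and second member's equation.  ``blinded`` trials force
    ``theta_EX = 0`` (participants cannot react to a treatment they do not
    know they receive); ``confounded=False`` forces all loadings to zero.

    ``kappa`` (with ``theta_AW``) optionally switches on a second placebo
    mediator A instrumented by a fair-coin W, with A = theta_AW*W + noise
    and a kappa*A term added to the outcome.
    """

    n: int = 500
    theta_XZ: float = 1.0
    theta_EX: float = 0.0
    theta_DQ: float = 1.0
    theta_ME: float = 1.0
    theta_MD: float = 1.0
    theta_MI: float = 1.0
    beta: float = 0.0
    psi: float = 0.0
    confounder_loadings: dict[str, tuple[float, float]] = field(
        default_factory=lambda: _loadings(0.0)
    )
    blinded: bool = True
    confounded: bool = False
    kappa: float | None = None
    theta_AW: float = 1.0

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("sample size n must be at least 2")
        unknown = set(self.confounder_loadings) - set(CONFOUNDER_PAIRS)
        if unknown:
            raise ValueError(f"unknown confounder pairs: {sorted(unknown)}")
        if self.blinded and self.theta_EX != 0:
            raise ValueError("a blinded trial has no X -> E path (theta_EX must be 0)")
        if not self.confounded and any(
            v != 0 for pair in self.confounder_loadings.values() for v in pair
        ):
            raise ValueError("confounded=False requires all confounder loadings to be 0")

    @classmethod
    def with_constant_loadings(cls, value: float, **kwargs) -> "ReducedModelParameters":
        kwargs.setdefault("confounded", value != 0)
        return cls(confounder_loadings=_loadings(value), **kwargs)


@dataclass(frozen=True)
class FullModelParameters(ReducedModelParameters):
    """Reduced-model observed layer plus the latent S/P outcome pathway.

    ``eta``: X -> S, ``lam``: S -> Y, ``tau``: P -> Y (direct),
    ``delta``: P -> S, ``phi``: M -> P.  The ``beta`` and ``psi`` fields of
    the base class are ignored; the implied reduced effects are
    ``beta = eta*lam`` and ``psi = phi*tau + phi*delta*lam``.
    """

    eta: float = 1.0
    lam: float = 1.0
    tau: float = 1.0
    delta: float = 1.0
    phi: float = 1.0


def reduced_effects_from_full(params: FullModelParameters) -> tuple[float, float]:
    """Implied (beta, psi) of the reduced outcome model."""
    beta = params.eta * params.lam
    psi = params.phi * params.tau + params.phi * params.delta * params.lam
    return beta, psi


def _confounder_terms(
    params: ReducedModelParameters, rng: np.random.Generator, n: int
) -> dict[str, np.ndarray]:
    """Per-variable sums of loaded confounder draws (one N(0,1) draw per pair)."""
    terms = {v: np.zeros(n) for v in _ENDOGENOUS}
    for pair in CONFOUNDER_PAIRS:  # fixed order: draws are seed-stable
        load = params.confounder_loadings.get(pair, (0.0, 0.0))
        c = rng.standard_normal(n)
        terms[pair[0]] += load[0] * c
        terms[pair[1]] += load[1] * c
    return terms


def _observed_layer(params: ReducedModelParameters, rng: np.random.Generator):
    """Everything up to (and excluding) the outcome equation."""
    n = params.n
    z = rng.binomial(1, 0.5, n).astype(float)
    q = rng.binomial(1, 0.5, n).astype(float)
    conf = _confounder_terms(params, rng, n)
    x = (params.theta_XZ * z + conf["X"] + rng.standard_normal(n) > 0).astype(float)
    e = (params.theta_EX * x + conf["E"] + rng.standard_normal(n) > 0).astype(float)
    d = (params.theta_DQ * q + conf["D"] + rng.standard_normal(n) > 0).astype(float)
    i = e * d
    m = (
        params.theta_ME * e
        + params.theta_MD * d
        + params.theta_MI * i
        + conf["M"]
        + rng.standard_normal(n)
    )
    return z, q, x, e, d, i, m, conf


def _extra_mediator(params: ReducedModelParameters, rng: np.random.Generator):
    w = rng.binomial(1, 0.5, params.n).astype(float)
    a = params.theta_AW * w + rng.standard_normal(params.n)
    return a, w


def simulate_trial(params: ReducedModelParameters, seed=None) -> TrialDataset:
    """Draw one trial from the reduced model; deterministic given (params, seed)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    z, q, x, e, d, i, m, conf = _observed_layer(params, rng)
    y = params.beta * x + params.psi * m + conf["Y"] + rng.standard_normal(params.n)
    a = w = None
    if params.kappa is not None:
        a, w = _extra_mediator(params, rng)
        y = y + params.kappa * a
    return TrialDataset(Z=z, Q=q, X=x, M=m, Y=y, E=e, D=d, A=a, W=w)


def simulate_full_model(
    params: FullModelParameters, seed=None, return_latent: bool = False
):
    """Draw one trial with the outcome built through the latent S/P states.

    With ``return_latent=True`` also returns ``{"S": ..., "P": ...}`` for
    checks that regress the outcome on the latent states directly.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    z, q, x, e, d, i, m, conf = _observed_layer(params, rng)
    n = params.n
    p = params.phi * m + rng.standard_normal(n)
    s = params.eta * x + params.delta * p + rng.standard_normal(n)
    y = params.lam * s + params.tau * p + conf["Y"] + rng.standard_normal(n)
    data = TrialDataset(Z=z, Q=q, X=x, M=m, Y=y, E=e, D=d)
    if return_latent:
        return data, {"S": s, "P": p}
    return data


def add_measurement_error(data: TrialDataset, sd: float, seed=None) -> TrialDataset:
    """Contaminate the emotion level with additive Normal(0, sd^2) noise.

    Emotion is self-reported and therefore the column most exposed to
    measurement error; all other columns are untouched.
    """
    if sd < 0:
        raise ValueError("measurement-error sd must be non-negative")
    if sd == 0:
        return data
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return data.replace_column("M", data.M + rng.normal(0.0, sd, data.n))


# ---------------------------------------------------------------------------
# Latin hypercube parameter designs


@dataclass(frozen=True)
class LatinHypercubeDesign:
    """Maximin-optimized Latin hypercube over declared parameter ranges."""

    names: tuple[str, ...]
    ranges: dict
    n_points: int
    matrix: pd.DataFrame  # n_points rows, one column per parameter
    maximin_score: float  # min pairwise distance of the varying columns, unit cube


def _split_ranges(ranges: dict):
    varying, fixed = {}, {}
    for name, spec in ranges.items():
        if isinstance(spec, (int, float)):
            fixed[name] = float(spec)
        elif isinstance(spec, tuple) and len(spec) == 2:
            lo, hi = float(spec[0]), float(spec[1])
            if hi < lo:
                raise ValueError(f"empty range for {name!r}")
            if hi == lo:
                fixed[name] = lo
            else:
                varying[name] = ("real", lo, hi)
        elif isinstance(spec, (list, np.ndarray, range)):
            values = np.asarray(list(spec))
            if values.size == 0:
                raise ValueError(f"empty value set for {name!r}")
            if values.size == 1:
                fixed[name] = float(values[0])
            else:
                varying[name] = ("grid", values)
        else:
            raise ValueError(f"unsupported range spec for {name!r}: {spec!r}")
    return varying, fixed


def latin_hypercube_design(
    ranges: dict, n_points: int, seed=None, restarts: int = 50
) -> LatinHypercubeDesign:
    """Latin hypercube with one point per equal-probability stratum per column.

    ``ranges`` maps parameter names to a ``(low, high)`` tuple (continuous),
    a list/range of discrete values (snapped to the grid), or a bare number
    (held fixed).  Among ``restarts`` random candidates the one maximizing
    the minimum pairwise distance on the unit cube is kept.
    """
    if n_points < 2:
        raise ValueError("n_points must be at least 2")
    varying, fixed = _split_ranges(ranges)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if varying:
        sampler_dim = len(varying)
        best_unit, best_score = None, -np.inf
        for _ in range(max(1, restarts)):
            unit = qmc.LatinHypercube(d=sampler_dim, rng=rng).random(n_points)
            score = float(pdist(unit).min())
            if score > best_score:
                best_unit, best_score = unit, score
    else:
        best_unit, best_score = np.empty((n_points, 0)), float("inf")
    cols: dict[str, np.ndarray] = {}
    for j, (name, spec) in enumerate(varying.items()):
        u = best_unit[:, j]
        if spec[0] == "real":
            _, lo, hi = spec
            cols[name] = lo + u * (hi - lo)
        else:
            values = spec[1]
            cols[name] = values[np.minimum((u * values.size).astype(int), values.size - 1)]
    for name, value in fixed.items():
        cols[name] = np.full(n_points, value)
    matrix = pd.DataFrame({name: cols[name] for name in ranges})
    return LatinHypercubeDesign(
        names=tuple(ranges),
        ranges=dict(ranges),
        n_points=n_points,
        matrix=matrix,
        maximin_score=best_score,
    )


def default_parameter_ranges(
    setting: str,
    confounded: bool,
    beta_hypothesis: str = "null",
    psi_hypothesis: str = "null",
) -> dict:
    """Parameter ranges of the benchmark simulation studies.

    Confounder loadings vary on [-2, 2] when ``confounded`` (else 0);
    instrument and mediator effects on [1, 2]; theta_EX is 0 when
    ``setting='blinded'`` and on [1, 2] when unblinded; beta and psi are 0
    under their null hypothesis and on [-2, 2] under the alternative; the
    sample size covers the practical grid {100, ..., 1000}.
    """
    if setting not in ("blinded", "unblinded"):
        raise ValueError("setting must be 'blinded' or 'unblinded'")
    for hyp in (beta_hypothesis, psi_hypothesis):
        if hyp not in ("null", "alt"):
            raise ValueError("hypothesis labels must be 'null' or 'alt'")
    ranges: dict = {"n": range(100, 1001)}
    for name in ("theta_XZ", "theta_DQ", "theta_ME", "theta_MD", "theta_MI"):
        ranges[name] = (1.0, 2.0)
    ranges["theta_EX"] = 0.0 if setting == "blinded" else (1.0, 2.0)
    ranges["beta"] = 0.0 if beta_hypothesis == "null" else (-2.0, 2.0)
    ranges["psi"] = 0.0 if psi_hypothesis == "null" else (-2.0, 2.0)
    for pair in CONFOUNDER_PAIRS:
        for member in (pair[0], pair[1]):
            ranges[f"c_{pair}_{member}"] = (-2.0, 2.0) if confounded else 0.0
    return ranges


def params_from_point(point: dict, setting: str, confounded: bool) -> ReducedModelParameters:
    """Build reduced-model parameters from one design-matrix row."""
    loadings = {
        pair: (
            float(point.get(f"c_{pair}_{pair[0]}", 0.0)),
            float(point.get(f"c_{pair}_{pair[1]}", 0.0)),
        )
        for pair in CONFOUNDER_PAIRS
    }
    return ReducedModelParameters(
        n=int(point["n"]),
        theta_XZ=float(point["theta_XZ"]),
        theta_EX=float(point.get("theta_EX", 0.0)),
        theta_DQ=float(point["theta_DQ"]),
        theta_ME=float(point["theta_ME"]),
        theta_MD=float(point["theta_MD"]),
        theta_MI=float(point["theta_MI"]),
        beta=float(point.get("beta", 0.0)),
        psi=float(point.get("psi", 0.0)),
        confounder_loadings=loadings,
        blinded=(setting == "blinded"),
        confounded=confounded,
    )
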