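"""Likelihoods, random-effect priors and the joint log posterior.

The model shared by all three count families is a log-linear rate model on an
area x quarter grid.  For area ``i`` and quarter ``t`` the incidence rate
``rho_it`` satisfies

    nu_it = log rho_it = alpha + gamma_i + delta_t + beta_i * I_it

with expected count ``lambda_it = rho_it * eps_it`` where ``eps_it`` is the
population offset.  ``gamma_i`` are exchangeable (IID Gaussian) area effects,
``delta_t`` follows a random walk of order two (RW2: Gaussian second
differences), and ``beta_i`` are exchangeable per-area covariate slopes.  The
count ``y_it`` is Poisson, zero-inflated Poisson (a structural point mass at
zero with weight ``pi``), or negative binomial with scale ``phi`` and variance
``lambda + lambda**2 / phi``.

The RW2 prior is improper in level and slope, so ``delta`` is identified by
the two linear constraints sum(delta) = 0 and zero best-fit linear trend; the
removed level and slope are absorbed by ``alpha`` (the model has no global
slope term).  Helper functions for that constraint subspace live here too.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, gammaln, logit

from .panel import PanelData

__all__ = [
    "FAMILIES",
    "SpecificationError",
    "PriorSettings",
    "ModelSpec",
    "ParameterState",
    "LikelihoodTerms",
    "linear_predictor",
    "poisson_loglik",
    "zip_loglik",
    "negbin_loglik",
    "loglik_cells",
    "family_loglik",
    "iid_logprior",
    "rw2_logprior",
    "joint_logposterior",
    "rw2_constraint_basis",
    "project_delta",
]

FAMILIES = ("poisson", "zip", "negbin")

_LOG_2PI = math.log(2.0 * math.pi)


class SpecificationError(ValueError):
    """Raised when a parameter state and a model specification disagree."""


@dataclass(frozen=True)
class PriorSettings:
    """Hyperprior settings.

    Precisions tau_gamma, tau_delta, tau_beta get Gamma(shape, rate) priors
    (equivalently a log-gamma prior on the log precision); the intercept is
    Gaussian; the zero-inflation weight is Gaussian on the logit scale and
    the negative-binomial scale Gaussian on the log scale.  Defaults mirror
    the weakly informative conventions of standard latent-Gaussian software.
    """

    tau_shape: float = 1.0
    tau_rate: float = 5e-5
    alpha_mean: float = 0.0
    alpha_var: float = 1000.0
    logit_pi_mean: float = -1.0
    logit_pi_var: float = 1.0
    log_phi_mean: float = 0.0
    log_phi_var: float = 1.0


@dataclass(frozen=True)
class ModelSpec:
    """Likelihood family plus prior and structural choices.

    ``include_spatial`` / ``include_temporal`` / ``include_slopes`` clamp the
    corresponding random effect to zero when False (used for intercept-only
    reference fits).  ``fixed_pi`` / ``fixed_phi`` pin the mixture weight or
    scale at a known value instead of sampling it.
    """

    family: str
    priors: PriorSettings = field(default_factory=PriorSettings)
    include_spatial: bool = True
    include_temporal: bool = True
    include_slopes: bool = True
    fixed_pi: float | None = None
    fixed_phi: float | None = None

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise SpecificationError(
                f"unknown family {self.family!r}; expected one of {FAMILIES}"
            )
        if self.fixed_pi is not None and not 0.0 <= self.fixed_pi < 1.0:
            raise ValueError("fixed_pi must lie in [0, 1)")
        if self.fixed_phi is not None and self.fixed_phi <= 0.0:
            raise ValueError("fixed_phi must be positive")


@dataclass
class ParameterState:
    """One point in parameter space.

    Effect vectors are ``None`` when the corresponding component is clamped
    to zero; ``pi`` is present only for the ZIP family and ``phi`` only for
    the negative binomial.
    """

    alpha: float
    gamma: np.ndarray | None = None
    delta: np.ndarray | None = None
    beta: np.ndarray | None = None
    tau_gamma: float | None = None
    tau_delta: float | None = None
    tau_beta: float | None = None
    pi: float | None = None
    phi: float | None = None

    def validate(self, spec: ModelSpec, atol: float = 1e-8) -> None:
        """Check family consistency and the delta identification constraints."""
        if spec.family == "zip":
            if self.pi is None and spec.fixed_pi is None:
                raise SpecificationError("ZIP spec requires pi (or fixed_pi)")
        elif self.pi is not None:
            raise SpecificationError(f"pi set on a {spec.family} spec")
        if spec.family == "negbin":
            if self.phi is None and spec.fixed_phi is None:
                raise SpecificationError("negbin spec requires phi (or fixed_phi)")
        elif self.phi is not None:
            raise SpecificationError(f"phi set on a {spec.family} spec")
        for name, flag, vec, tau in (
            ("gamma", spec.include_spatial, self.gamma, self.tau_gamma),
            ("delta", spec.include_temporal, self.delta, self.tau_delta),
            ("beta", spec.include_slopes, self.beta, self.tau_beta),
        ):
            if flag and (vec is None or tau is None):
                raise SpecificationError(f"spec includes {name} but state lacks it")
        if self.delta is not None:
            d = np.asarray(self.delta, dtype=float)
            t = np.arange(d.size) - (d.size - 1) / 2.0
            scale = max(1.0, float(np.abs(d).max()))
            if abs(d.sum()) > atol * scale * d.size:
                raise SpecificationError("delta violates the sum-to-zero constraint")
            if abs(float(t @ d)) > atol * scale * d.size * d.size:
                raise SpecificationError("delta violates the zero-linear-trend constraint")


@dataclass
class LikelihoodTerms:
    """The linear predictor and its derived surfaces.

    ``nu`` is the log incidence rate, ``rho = exp(nu)`` the rate per
    person-quarter, ``lam = rho * offset`` the expected count.
    """

    nu: np.ndarray
    rho: np.ndarray
    lam: np.ndarray


def linear_predictor(state: ParameterState, panel: PanelData) -> LikelihoodTerms:
    """Evaluate nu, rho and lambda on the panel grid.

    Raises a ``FloatingPointError`` naming the first offending cell if any
    expected count overflows to a non-finite value.
    """
    n, T = panel.counts.shape
    nu = np.full((n, T), state.alpha, dtype=float)
    if state.gamma is not None:
        g = np.asarray(state.gamma, dtype=float)
        if g.shape != (n,):
            raise ValueError(f"gamma has shape {g.shape}, expected ({n},)")
        nu += g[:, None]
    if state.delta is not None:
        d = np.asarray(state.delta, dtype=float)
        if d.shape != (T,):
            raise ValueError(f"delta has shape {d.shape}, expected ({T},)")
        nu += d[None, :]
    if state.beta is not None:
        b = np.asarray(state.beta, dtype=float)
        if b.shape != (n,):
            raise ValueError(f"beta has shape {b.shape}, expected ({n},)")
        nu += b[:, None] * panel.covariate
    with np.errstate(over="raise"):
        try:
            rho = np.exp(nu)
            lam = rho * panel.offset
        except FloatingPointError:
            i, t = np.unravel_index(int(np.argmax(nu)), nu.shape)
            raise FloatingPointError(
                f"linear predictor overflows at area {panel.area_ids[i]!r}, "
                f"quarter {t + 1} (nu = {nu[i, t]:.2f})"
            ) from None
    if not np.all(np.isfinite(lam)):
        i, t = np.unravel_index(int(np.argmax(~np.isfinite(lam))), lam.shape)
        raise FloatingPointError(
            f"non-finite expected count at area {panel.area_ids[i]!r}, quarter {t + 1}"
        )
    return LikelihoodTerms(nu=nu, rho=rho, lam=lam)


def _check_counts(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y, dtype=float)
    if np.any(y < 0):
        raise ValueError("counts must be non-negative")
    return y


def _poisson_cells(y: np.ndarray, lam: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        out = y * np.log(lam) - lam - gammaln(y + 1.0)
    # y == 0 cells with lam -> 0 would give 0 * -inf; the mass there is exp(-lam)
    return np.where((y == 0), -lam, out)


def _zip_cells(y: np.ndarray, lam: np.ndarray, pi: float) -> np.ndarray:
    base = _poisson_cells(y, lam)
    if pi == 0.0:
        return base
    lam = np.asarray(lam, dtype=float)
    zero_branch = np.logaddexp(math.log(pi), math.log1p(-pi) - lam)
    return np.where(y == 0, zero_branch, math.log1p(-pi) + base)


def _negbin_cells(y: np.ndarray, lam: np.ndarray, phi: float) -> np.ndarray:
    lam = np.asarray(lam, dtype=float)
    log_denom = np.log(phi + lam)
    out = (
        gammaln(y + phi)
        - gammaln(phi)
        - gammaln(y + 1.0)
        + phi * (math.log(phi) - log_denom)
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        tail = y * (np.log(lam) - log_denom)
    return out + np.where(y == 0, 0.0, tail)


def loglik_cells(
    y: np.ndarray,
    lam: np.ndarray,
    family: str,
    pi: float | None = None,
    phi: float | None = None,
) -> np.ndarray:
    """Per-cell log-mass matrix for the given family (full masses, with all
    combinatorial constants, so criteria are comparable across families)."""
    y = _check_counts(y)
    lam = np.asarray(lam, dtype=float)
    if np.any(lam <= 0):
        raise ValueError("expected counts must be strictly positive")
    if family == "poisson":
        return _poisson_cells(y, lam)
    if family == "zip":
        if pi is None or not 0.0 <= pi < 1.0:
            raise ValueError("zip requires a mixing weight pi in [0, 1)")
        return _zip_cells(y, lam, float(pi))
    if family == "negbin":
        if phi is None or phi <= 0.0:
            raise ValueError("negbin requires a positive scale phi")
        return _negbin_cells(y, lam, float(phi))
    raise SpecificationError(f"unknown family {family!r}")


def poisson_loglik(y: np.ndarray, lam: np.ndarray) -> float:
    """Total Poisson log likelihood: sum of y*log(lam) - lam - log(y!)."""
    return float(loglik_cells(y, lam, "poisson").sum())


def zip_loglik(y: np.ndarray, lam: np.ndarray, pi: float) -> float:
    """Total zero-inflated Poisson log likelihood.

    A zero cell contributes log(pi + (1 - pi) e^{-lam}) (computed by
    log-sum-exp); a positive cell contributes log(1 - pi) plus the Poisson
    log-mass.  ``pi = 0`` reduces exactly to the Poisson likelihood.
    """
    return float(loglik_cells(y, lam, "zip", pi=pi).sum())


def negbin_loglik(y: np.ndarray, lam: np.ndarray, phi: float) -> float:
    """Total negative-binomial log likelihood, mean/scale parameterization.

    Success probability p = phi / (phi + lam) with size phi, so the variance
    is lam + lam**2 / phi; phi -> infinity recovers the Poisson model.
    """
    return float(loglik_cells(y, lam, "negbin", phi=phi).sum())


def family_loglik(
    y: np.ndarray,
    lam: np.ndarray,
    spec: ModelSpec,
    state: ParameterState,
) -> float:
    pi = state.pi if state.pi is not None else spec.fixed_pi
    phi = state.phi if state.phi is not None else spec.fixed_phi
    return float(loglik_cells(y, lam, spec.family, pi=pi, phi=phi).sum())


def iid_logprior(v: np.ndarray, tau: float) -> float:
    """Log density of IID Normal(0, 1/tau) effects (normalized)."""
    if tau <= 0:
        raise ValueError("precision tau must be positive")
    v = np.asarray(v, dtype=float)
    m = v.size
    return float(0.5 * m * (math.log(tau) - _LOG_2PI) - 0.5 * tau * np.sum(v * v))


def rw2_logprior(delta: np.ndarray, tau: float) -> float:
    """Improper RW2 log density up to an additive constant.

    (T-2)/2 * log(tau) - tau/2 * sum of squared second differences; invariant
    to adding any linear trend a + b*t to delta.
    """
    if tau <= 0:
        raise ValueError("precision tau must be positive")
    delta = np.asarray(delta, dtype=float)
    T = delta.size
    if T < 3:
        raise ValueError("RW2 prior requires at least 3 time points")
    d2 = np.diff(delta, n=2)
    return float(0.5 * (T - 2) * math.log(tau) - 0.5 * tau * np.sum(d2 * d2))


def _gamma_logpdf(x: float, shape: float, rate: float) -> float:
    if x <= 0:
        return -math.inf
    return (
        shape * math.log(rate)
        - gammaln(shape)
        + (shape - 1.0) * math.log(x)
        - rate * x
    )


def _normal_logpdf(x: float, mean: float, var: float) -> float:
    return -0.5 * (_LOG_2PI + math.log(var)) - 0.5 * (x - mean) ** 2 / var


def joint_logposterior(
    state: ParameterState, panel: PanelData, spec: ModelSpec
) -> float:
    """Unnormalized joint log posterior.

    Likelihood + IID priors on gamma and beta + RW2 prior on delta + Gamma
    hyperpriors on the precisions + Gaussian prior on alpha + Gaussian priors
    on logit(pi) and log(phi).  The mixture weight and scale are measured on
    their unconstrained scales (logit / log), matching the parameterization
    the sampler moves in.
    """
    state.validate(spec)
    terms = linear_predictor(state, panel)
    pr = spec.priors
    lp = family_loglik(panel.counts, terms.lam, spec, state)
    lp += _normal_logpdf(state.alpha, pr.alpha_mean, pr.alpha_var)
    if spec.include_spatial:
        lp += iid_logprior(state.gamma, state.tau_gamma)
        lp += _gamma_logpdf(state.tau_gamma, pr.tau_shape, pr.tau_rate)
    if spec.include_temporal:
        lp += rw2_logprior(state.delta, state.tau_delta)
        lp += _gamma_logpdf(state.tau_delta, pr.tau_shape, pr.tau_rate)
    if spec.include_slopes:
        lp += iid_logprior(state.beta, state.tau_beta)
        lp += _gamma_logpdf(state.tau_beta, pr.tau_shape, pr.tau_rate)
    if spec.family == "zip" and state.pi is not None:
        lp += _normal_logpdf(float(logit(state.pi)), pr.logit_pi_mean, pr.logit_pi_var)
    if spec.family == "negbin" and state.phi is not None:
        lp += _normal_logpdf(math.log(state.phi), pr.log_phi_mean, pr.log_phi_var)
    return float(lp)


def rw2_constraint_basis(T: int) -> np.ndarray:
    """Orthonormal basis (T x (T-2)) of the identified RW2 subspace.

    Columns span the orthogonal complement of {1, t}, i.e. every delta = B z
    has zero sum and zero best-fit linear trend.
    """
    if T < 3:
        raise ValueError("need at least 3 time points")
    t = np.arange(T, dtype=float)
    X = np.column_stack([np.ones(T), t - t.mean()])
    q, _ = np.linalg.qr(X, mode="complete")
    return q[:, 2:]


def project_delta(delta: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Remove the best-fit line from delta.

    Returns ``(projected, level, slope)`` where ``projected`` satisfies both
    identification constraints and ``delta = projected + level + slope * t_c``
    with ``t_c`` the centered time index.
    """
    delta = np.asarray(delta, dtype=float)
    T = delta.size
    t = np.arange(T, dtype=float)
    tc = t - t.mean()
    level = float(delta.mean())
    slope = float(tc @ delta / (tc @ tc))
    return delta - level - slope * tc, level, slope
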