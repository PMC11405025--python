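"""Posterior computation by adaptive Metropolis-within-Gibbs.

The sampler targets the joint posterior defined in :mod:`arealrisk.models`:

* precisions ``tau_gamma``, ``tau_beta`` — exact Gamma Gibbs draws from
  their conjugate full conditionals; ``tau_delta`` likewise, using the RW2
  quadratic form with rank T - 2;
* the intercept ``alpha``, the mixture weight (on the logit scale) and the
  negative-binomial scale (on the log scale) — scalar adaptive random-walk
  Metropolis, target acceptance 0.44;
* the area effects ``gamma`` and slopes ``beta`` — vectorised single-site
  adaptive Metropolis: the likelihood factorises over areas given everything
  else, so all n proposals are evaluated and accepted/rejected independently
  in one pass;
* a vectorised (gamma_i, beta_i) ridge move — the covariate often varies
  little within an area, leaving the slope and the area effect nearly
  confounded; shifting beta_i and compensating gamma_i through the area-mean
  covariate travels along that ridge cheaply;
* the temporal effect ``delta`` — a blocked adaptive random-walk proposal in
  the (T-2)-dimensional orthonormal basis of the {sum = 0, zero linear
  trend} subspace (target acceptance 0.234), so every stored draw satisfies
  the identification constraints exactly.

Proposal scales adapt by Robbins-Monro during burn-in only and are frozen
afterwards, preserving ergodicity.  One root seed spawns one independent
stream per chain, so runs are bit-reproducible given (seed, n_chains,
n_iter).
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd
from scipy.special import expit, gammaln, logit

from .models import (
    ModelSpec,
    ParameterState,
    SpecificationError,
    joint_logposterior,
    linear_predictor,
    rw2_constraint_basis,
)
from .panel import PanelData

__all__ = [
    "PosteriorDraws",
    "Diagnostics",
    "InitializationError",
    "fit",
    "diagnose",
    "sample_precision",
    "save_draws",
    "load_draws",
]


class InitializationError(RuntimeError):
    """The log posterior is not finite at the starting state."""


@dataclass
class PosteriorDraws:
    """Retained MCMC states, stacked as (chain, draw[, component]) arrays."""

    spec: ModelSpec
    seed: int
    n_chains: int
    n_kept: int
    area_ids: list[str]
    n_quarters: int
    alpha: np.ndarray
    gamma: np.ndarray | None = None
    delta: np.ndarray | None = None
    beta: np.ndarray | None = None
    tau_gamma: np.ndarray | None = None
    tau_delta: np.ndarray | None = None
    tau_beta: np.ndarray | None = None
    pi: np.ndarray | None = None
    phi: np.ndarray | None = None
    acceptance_rates: dict[str, float] = field(default_factory=dict)

    @property
    def n_draws(self) -> int:
        return self.n_chains * self.n_kept

    def combined(self, name: str) -> np.ndarray:
        """Chain-flattened draws of one parameter: (n_draws,) or (n_draws, m)."""
        arr = getattr(self, name)
        if arr is None:
            raise KeyError(f"parameter {name!r} was not sampled")
        return arr.reshape(self.n_draws, *arr.shape[2:])

    def states(self) -> Iterator[ParameterState]:
        """Iterate over draws as ParameterState snapshots (chain-major)."""
        for c in range(self.n_chains):
            for k in range(self.n_kept):
                yield ParameterState(
                    alpha=float(self.alpha[c, k]),
                    gamma=None if self.gamma is None else self.gamma[c, k],
                    delta=None if self.delta is None else self.delta[c, k],
                    beta=None if self.beta is None else self.beta[c, k],
                    tau_gamma=None if self.tau_gamma is None else float(self.tau_gamma[c, k]),
                    tau_delta=None if self.tau_delta is None else float(self.tau_delta[c, k]),
                    tau_beta=None if self.tau_beta is None else float(self.tau_beta[c, k]),
                    pi=None if self.pi is None else float(self.pi[c, k]),
                    phi=None if self.phi is None else float(self.phi[c, k]),
                )

    def scalar_arrays(self) -> dict[str, np.ndarray]:
        """Every scalar parameter as a (chain, draw) array, vector components
        expanded with bracketed names like ``gamma[05001]``."""
        out: dict[str, np.ndarray] = {"alpha": self.alpha}
        for name in ("tau_gamma", "tau_delta", "tau_beta", "pi", "phi"):
            arr = getattr(self, name)
            if arr is not None:
                out[name] = arr
        for name, labels in (
            ("gamma", self.area_ids),
            ("beta", self.area_ids),
            ("delta", [str(t + 1) for t in range(self.n_quarters)]),
        ):
            arr = getattr(self, name)
            if arr is not None:
                for j, lab in enumerate(labels):
                    out[f"{name}[{lab}]"] = arr[:, :, j]
        return out

    def to_frame(self) -> pd.DataFrame:
        """Long-format export: one row per (chain, iter, parameter)."""
        rows = []
        for name, arr in self.scalar_arrays().items():
            for c in range(self.n_chains):
                rows.append(
                    pd.DataFrame(
                        {
                            "chain": c,
                            "iter": np.arange(self.n_kept),
                            "parameter": name,
                            "value": arr[c],
                        }
                    )
                )
        return pd.concat(rows, ignore_index=True)


@dataclass
class Diagnostics:
    """Split-R-hat and effective sample size per scalar parameter."""

    rhat: dict[str, float]
    ess: dict[str, float]
    flags: list[str]
    warning: str | None = None


def sample_precision(
    rng: np.random.Generator,
    sum_sq: float,
    rank: int,
    shape: float,
    rate: float,
) -> float:
    """Gibbs draw of a precision from its Gamma full conditional.

    With prior tau ~ Gamma(shape, rate) and a Gaussian quadratic form of the
    given rank and sum of squares, the full conditional is
    Gamma(shape + rank/2, rate + sum_sq/2).
    """
    return float(rng.gamma(shape + 0.5 * rank, 1.0 / (rate + 0.5 * sum_sq)))


def _make_cells(y: np.ndarray, family: str, lgy: np.ndarray):
    """Per-cell log-mass as a function of (nu-derived) lambda slices.

    Non-finite inputs propagate to -inf so the Metropolis steps simply
    reject runaway proposals.
    """
    y0 = y == 0

    def cells(lam, loglam, rows=None, pi=None, phi=None):
        yy = y if rows is None else y[rows]
        gg = lgy if rows is None else lgy[rows]
        zz = y0 if rows is None else y0[rows]
        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            if family == "poisson":
                out = np.where(zz, -lam, yy * loglam - lam - gg)
            elif family == "zip":
                base = yy * loglam - lam - gg
                if pi == 0.0:
                    out = np.where(zz, -lam, base)
                else:
                    out = np.where(
                        zz,
                        np.logaddexp(math.log(pi), math.log1p(-pi) - lam),
                        math.log1p(-pi) + base,
                    )
            else:  # negbin
                log_denom = np.log(phi + lam)
                out = (
                    gammaln(yy + phi)
                    - gammaln(phi)
                    - gg
                    + phi * (math.log(phi) - log_denom)
                    + np.where(zz, 0.0, yy * (loglam - log_denom))
                )
        return np.where(np.isfinite(out), out, -np.inf)

    return cells


def _initial_state(panel: PanelData, spec: ModelSpec) -> ParameterState:
    total = panel.counts.sum()
    alpha0 = math.log((total if total > 0 else 0.5) / panel.offset.sum())
    n, T = panel.counts.shape
    return ParameterState(
        alpha=alpha0,
        gamma=np.zeros(n) if spec.include_spatial else None,
        delta=np.zeros(T) if spec.include_temporal else None,
        beta=np.zeros(n) if spec.include_slopes else None,
        tau_gamma=10.0 if spec.include_spatial else None,
        tau_delta=10.0 if spec.include_temporal else None,
        tau_beta=10.0 if spec.include_slopes else None,
        pi=(0.1 if spec.fixed_pi is None else None) if spec.family == "zip" else None,
        phi=(1.0 if spec.fixed_phi is None else None) if spec.family == "negbin" else None,
    )


def _run_chain(
    panel: PanelData,
    spec: ModelSpec,
    n_iter: int,
    n_burn: int,
    thin: int,
    rng: np.random.Generator,
    init: ParameterState,
):
    y = panel.counts.astype(float)
    eps = panel.offset
    I = panel.covariate
    log_eps = np.log(eps)
    lgy = gammaln(y + 1.0)
    n, T = y.shape
    pr = spec.priors
    family = spec.family
    cells = _make_cells(y, family, lgy)

    alpha = init.alpha
    gamma = None if init.gamma is None else init.gamma.astype(float).copy()
    beta = None if init.beta is None else init.beta.astype(float).copy()
    delta = None if init.delta is None else init.delta.astype(float).copy()
    tau_g, tau_d, tau_b = init.tau_gamma, init.tau_delta, init.tau_beta
    pi_cur = spec.fixed_pi if spec.fixed_pi is not None else init.pi
    phi_cur = spec.fixed_phi if spec.fixed_phi is not None else init.phi
    sample_pi = family == "zip" and spec.fixed_pi is None
    sample_phi = family == "negbin" and spec.fixed_phi is None
    lpi = None if pi_cur is None else float(logit(max(pi_cur, 1e-6)))
    lphi = None if phi_cur is None else math.log(phi_cur)

    B = rw2_constraint_basis(T) if delta is not None else None
    z = np.zeros(T - 2) if delta is not None else None
    if delta is not None:
        z = B.T @ delta
        delta = B @ z  # exact subspace representation
    D2 = np.diff(np.eye(T), n=2, axis=0) if delta is not None else None

    def predictor():
        nu = np.full((n, T), alpha)
        if gamma is not None:
            nu += gamma[:, None]
        if delta is not None:
            nu += delta[None, :]
        if beta is not None:
            nu += beta[:, None] * I
        return nu

    nu = predictor()
    lam = np.exp(nu) * eps
    ll_cells = cells(lam, nu + log_eps, pi=pi_cur, phi=phi_cur)
    row_ll = ll_cells.sum(axis=1)
    cur_ll = float(row_ll.sum())
    if not np.isfinite(cur_ll):
        raise InitializationError(
            "log likelihood not finite at the initial state (check offsets/counts)"
        )

    # adaptive proposal scales
    s_alpha, s_pi, s_phi, s_delta = 0.1, 0.3, 0.3, 0.1
    s_gamma = np.full(n, 0.3)
    s_beta = np.full(n, 0.5)
    s_ridge = np.full(n, 0.5)
    s_scale = 1.0
    I_rowmean = I.mean(axis=1)
    acc = {k: 0 for k in ("alpha", "gamma", "beta", "ridge", "scale", "delta", "pi", "phi")}
    tries = {k: 0 for k in acc}

    n_kept = (n_iter - n_burn) // thin
    keep = {
        "alpha": np.empty(n_kept),
        "gamma": np.empty((n_kept, n)) if gamma is not None else None,
        "delta": np.empty((n_kept, T)) if delta is not None else None,
        "beta": np.empty((n_kept, n)) if beta is not None else None,
        "tau_gamma": np.empty(n_kept) if gamma is not None else None,
        "tau_delta": np.empty(n_kept) if delta is not None else None,
        "tau_beta": np.empty(n_kept) if beta is not None else None,
        "pi": np.empty(n_kept) if sample_pi else None,
        "phi": np.empty(n_kept) if sample_phi else None,
    }
    kept = 0

    def full_ll(nu_new, pi_new=None, phi_new=None):
        with np.errstate(over="ignore"):
            lam_new = np.exp(nu_new) * eps
        return cells(
            lam_new,
            nu_new + log_eps,
            pi=pi_cur if pi_new is None else pi_new,
            phi=phi_cur if phi_new is None else phi_new,
        )

    for it in range(1, n_iter + 1):
        adapting = it <= n_burn
        step = 2.0 * it ** -0.6  # Robbins-Monro gain

        # --- alpha: scalar adaptive RW ---
        prop = alpha + s_alpha * rng.normal()
        cand = full_ll(nu + (prop - alpha))
        logr = (
            float(cand.sum()) - cur_ll
            - 0.5 * (prop - pr.alpha_mean) ** 2 / pr.alpha_var
            + 0.5 * (alpha - pr.alpha_mean) ** 2 / pr.alpha_var
        )
        tries["alpha"] += 1
        accepted = math.log(rng.random()) < logr
        if accepted:
            nu = nu + (prop - alpha)
            alpha = prop
            ll_cells = cand
            row_ll = ll_cells.sum(axis=1)
            cur_ll = float(row_ll.sum())
            acc["alpha"] += 1
        if adapting:
            s_alpha *= math.exp(step * ((1.0 if accepted else 0.0) - 0.44))

        # --- gamma: vectorised single-site Metropolis ---
        if gamma is not None:
            d = s_gamma * rng.normal(size=n)
            nu_p = nu + d[:, None]
            cand = full_ll(nu_p)
            rowp = cand.sum(axis=1)
            gp = gamma + d
            logr_v = rowp - row_ll - 0.5 * tau_g * (gp * gp - gamma * gamma)
            acc_mask = np.log(rng.random(size=n)) < logr_v
            if acc_mask.any():
                gamma[acc_mask] = gp[acc_mask]
                nu[acc_mask] = nu_p[acc_mask]
                ll_cells[acc_mask] = cand[acc_mask]
                row_ll[acc_mask] = rowp[acc_mask]
                cur_ll = float(row_ll.sum())
            tries["gamma"] += n
            acc["gamma"] += int(acc_mask.sum())
            if adapting:
                s_gamma *= np.exp(step * (acc_mask.astype(float) - 0.44))
            tau_g = sample_precision(
                rng, float(gamma @ gamma), n, pr.tau_shape, pr.tau_rate
            )

        # --- beta: vectorised single-site Metropolis ---
        if beta is not None:
            d = s_beta * rng.normal(size=n)
            nu_p = nu + d[:, None] * I
            cand = full_ll(nu_p)
            rowp = cand.sum(axis=1)
            bp = beta + d
            logr_v = rowp - row_ll - 0.5 * tau_b * (bp * bp - beta * beta)
            acc_mask = np.log(rng.random(size=n)) < logr_v
            if acc_mask.any():
                beta[acc_mask] = bp[acc_mask]
                nu[acc_mask] = nu_p[acc_mask]
                ll_cells[acc_mask] = cand[acc_mask]
                row_ll[acc_mask] = rowp[acc_mask]
                cur_ll = float(row_ll.sum())
            tries["beta"] += n
            acc["beta"] += int(acc_mask.sum())
            if adapting:
                s_beta *= np.exp(step * (acc_mask.astype(float) - 0.44))
            tau_b = sample_precision(
                rng, float(beta @ beta), n, pr.tau_shape, pr.tau_rate
            )
            # interweaving scale move against the (tau_beta, beta) funnel:
            # propose tau on the log scale and rescale beta so the Gaussian
            # prior terms cancel; only the likelihood, the Gamma hyperprior
            # and the log-scale Jacobian enter the ratio
            lt_prop = math.log(tau_b) + s_scale * rng.normal()
            tau_prop = math.exp(lt_prop)
            c = math.sqrt(tau_b / tau_prop)
            bp = beta * c
            nu_p = nu + (bp - beta)[:, None] * I
            cand = full_ll(nu_p)
            logr = (
                float(cand.sum()) - cur_ll
                + pr.tau_shape * (lt_prop - math.log(tau_b))
                - pr.tau_rate * (tau_prop - tau_b)
            )
            tries["scale"] += 1
            accepted = math.log(rng.random()) < logr
            if accepted:
                beta = bp
                tau_b = tau_prop
                nu = nu_p
                ll_cells = cand
                row_ll = ll_cells.sum(axis=1)
                cur_ll = float(row_ll.sum())
                acc["scale"] += 1
            if adapting:
                s_scale *= math.exp(step * ((1.0 if accepted else 0.0) - 0.44))

        # --- gamma/beta ridge move: beta_i shifts compensated through the
        # area-mean covariate leave the predictor almost unchanged, so this
        # move travels along the near-confounded (gamma_i, beta_i) ridge ---
        if gamma is not None and beta is not None:
            d = s_ridge * rng.normal(size=n)
            bp = beta + d
            gp = gamma - d * I_rowmean
            nu_p = nu + d[:, None] * (I - I_rowmean[:, None])
            cand = full_ll(nu_p)
            rowp = cand.sum(axis=1)
            logr_v = (
                rowp - row_ll
                - 0.5 * tau_b * (bp * bp - beta * beta)
                - 0.5 * tau_g * (gp * gp - gamma * gamma)
            )
            acc_mask = np.log(rng.random(size=n)) < logr_v
            if acc_mask.any():
                beta[acc_mask] = bp[acc_mask]
                gamma[acc_mask] = gp[acc_mask]
                nu[acc_mask] = nu_p[acc_mask]
                ll_cells[acc_mask] = cand[acc_mask]
                row_ll[acc_mask] = rowp[acc_mask]
                cur_ll = float(row_ll.sum())
            tries["ridge"] += n
            acc["ridge"] += int(acc_mask.sum())
            if adapting:
                s_ridge *= np.exp(step * (acc_mask.astype(float) - 0.44))

        # --- delta: blocked RW in the constraint subspace ---
        if delta is not None:
            zp = z + s_delta * rng.normal(size=T - 2)
            dp = B @ zp
            nu_p = nu + (dp - delta)[None, :]
            cand = full_ll(nu_p)
            q_old = D2 @ delta
            q_new = D2 @ dp
            logr = (
                float(cand.sum()) - cur_ll
                - 0.5 * tau_d * (q_new @ q_new - q_old @ q_old)
            )
            tries["delta"] += 1
            accepted = math.log(rng.random()) < logr
            if accepted:
                z, delta = zp, dp
                nu = nu_p
                ll_cells = cand
                row_ll = ll_cells.sum(axis=1)
                cur_ll = float(row_ll.sum())
                acc["delta"] += 1
            if adapting:
                s_delta *= math.exp(step * ((1.0 if accepted else 0.0) - 0.234))
            q = D2 @ delta
            tau_d = sample_precision(
                rng, float(q @ q), T - 2, pr.tau_shape, pr.tau_rate
            )

        # --- zero-inflation weight on the logit scale ---
        if sample_pi:
            prop_l = lpi + s_pi * rng.normal()
            prop_pi = float(expit(prop_l))
            cand = full_ll(nu, pi_new=prop_pi)
            logr = (
                float(cand.sum()) - cur_ll
                - 0.5 * (prop_l - pr.logit_pi_mean) ** 2 / pr.logit_pi_var
                + 0.5 * (lpi - pr.logit_pi_mean) ** 2 / pr.logit_pi_var
            )
            tries["pi"] += 1
            accepted = math.log(rng.random()) < logr
            if accepted:
                lpi, pi_cur = prop_l, prop_pi
                ll_cells = cand
                row_ll = ll_cells.sum(axis=1)
                cur_ll = float(row_ll.sum())
                acc["pi"] += 1
            if adapting:
                s_pi *= math.exp(step * ((1.0 if accepted else 0.0) - 0.44))

        # --- negative-binomial scale on the log scale ---
        if sample_phi:
            prop_l = lphi + s_phi * rng.normal()
            prop_phi = math.exp(prop_l)
            cand = full_ll(nu, phi_new=prop_phi)
            logr = (
                float(cand.sum()) - cur_ll
                - 0.5 * (prop_l - pr.log_phi_mean) ** 2 / pr.log_phi_var
                + 0.5 * (lphi - pr.log_phi_mean) ** 2 / pr.log_phi_var
            )
            tries["phi"] += 1
            accepted = math.log(rng.random()) < logr
            if accepted:
                lphi, phi_cur = prop_l, prop_phi
                ll_cells = cand
                row_ll = ll_cells.sum(axis=1)
                cur_ll = float(row_ll.sum())
                acc["phi"] += 1
            if adapting:
                s_phi *= math.exp(step * ((1.0 if accepted else 0.0) - 0.44))

        if it > n_burn and (it - n_burn) % thin == 0:
            keep["alpha"][kept] = alpha
            if gamma is not None:
                keep["gamma"][kept] = gamma
                keep["tau_gamma"][kept] = tau_g
            if delta is not None:
                keep["delta"][kept] = delta
                keep["tau_delta"][kept] = tau_d
            if beta is not None:
                keep["beta"][kept] = beta
                keep["tau_beta"][kept] = tau_b
            if sample_pi:
                keep["pi"][kept] = pi_cur
            if sample_phi:
                keep["phi"][kept] = phi_cur
            kept += 1

    rates = {k: acc[k] / tries[k] for k in acc if tries[k] > 0}
    return keep, rates


def fit(
    panel: PanelData,
    spec: ModelSpec,
    n_chains: int = 2,
    n_iter: int = 4000,
    n_burn: int | None = None,
    thin: int = 5,
    seed: int = 0,
    init: ParameterState | None = None,
) -> PosteriorDraws:
    """Sample the joint posterior for one panel and model specification.

    Burn-in defaults to half of ``n_iter``; kept draws are thinned by
    ``thin``.  ``init`` overrides the moment-matched default start (alpha at
    the crude log rate, effects at zero, precisions at 10).  The returned
    draws are deterministic given (seed, n_chains, n_iter).
    """
    if n_burn is None:
        n_burn = n_iter // 2
    if not 0 <= n_burn < n_iter:
        raise ValueError("need 0 <= n_burn < n_iter")
    start = init if init is not None else _initial_state(panel, spec)
    start.validate(spec)
    try:
        lp0 = joint_logposterior(start, panel, spec)
    except FloatingPointError as exc:
        raise InitializationError(f"non-finite log posterior at start: {exc}") from exc
    if not math.isfinite(lp0):
        raise InitializationError(
            f"joint log posterior is {lp0} at the initial state"
        )
    streams = np.random.SeedSequence(seed).spawn(n_chains)
    chains = []
    rates_all: dict[str, list[float]] = {}
    for stream in streams:
        keep, rates = _run_chain(
            panel, spec, n_iter, n_burn, thin, np.random.default_rng(stream), start
        )
        chains.append(keep)
        for k, v in rates.items():
            rates_all.setdefault(k, []).append(v)
    n_kept = (n_iter - n_burn) // thin

    def stack(name):
        if chains[0][name] is None:
            return None
        return np.stack([c[name] for c in chains])

    return PosteriorDraws(
        spec=spec,
        seed=seed,
        n_chains=n_chains,
        n_kept=n_kept,
        area_ids=list(panel.area_ids),
        n_quarters=panel.n_quarters,
        alpha=stack("alpha"),
        gamma=stack("gamma"),
        delta=stack("delta"),
        beta=stack("beta"),
        tau_gamma=stack("tau_gamma"),
        tau_delta=stack("tau_delta"),
        tau_beta=stack("tau_beta"),
        pi=stack("pi"),
        phi=stack("phi"),
        acceptance_rates={k: float(np.mean(v)) for k, v in rates_all.items()},
    )


def diagnose(draws: PosteriorDraws, rhat_threshold: float = 1.05) -> Diagnostics:
    """Split-R-hat and effective sample size per scalar parameter via arviz.

    Parameters whose R-hat exceeds the threshold, or is undefined because a
    chain is constant (zero variance), are listed in ``flags``.  With a
    single chain R-hat is undefined and a warning-level result is returned.
    """
    import arviz as az

    arrays = draws.scalar_arrays()
    if draws.n_chains < 2:
        return Diagnostics(
            rhat={},
            ess={},
            flags=[],
            warning="single chain: split-R-hat undefined; run >= 2 chains",
        )
    rhat: dict[str, float] = {}
    ess: dict[str, float] = {}
    flags: list[str] = []
    warning = None
    if draws.n_kept < 50:
        warning = f"only {draws.n_kept} kept draws per chain; diagnostics are noisy"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for name, arr in arrays.items():
            if np.allclose(arr.var(axis=1), 0.0):
                rhat[name] = float("nan")
                ess[name] = float("nan")
                flags.append(f"{name}: R-hat undefined (constant chain)")
                continue
            rhat[name] = float(az.rhat(az.convert_to_dataset(arr))["x"])
            ess[name] = float(az.ess(az.convert_to_dataset(arr))["x"])
            if rhat[name] > rhat_threshold or not np.isfinite(rhat[name]):
                flags.append(f"{name}: R-hat {rhat[name]:.3f} > {rhat_threshold}")
    return Diagnostics(rhat=rhat, ess=ess, flags=flags, warning=warning)


def save_draws(draws: PosteriorDraws, prefix: str | Path) -> None:
    """Write draws as ``<prefix>.csv`` (chain, iter, parameter, value) plus a
    JSON sidecar with the specification, seed and diagnostics summary."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    draws.to_frame().to_csv(prefix.with_suffix(".csv"), index=False)
    diag = diagnose(draws) if draws.n_chains >= 2 else None
    sidecar = {
        "family": draws.spec.family,
        "include_spatial": draws.spec.include_spatial,
        "include_temporal": draws.spec.include_temporal,
        "include_slopes": draws.spec.include_slopes,
        "fixed_pi": draws.spec.fixed_pi,
        "fixed_phi": draws.spec.fixed_phi,
        "seed": draws.seed,
        "n_chains": draws.n_chains,
        "n_kept": draws.n_kept,
        "area_ids": draws.area_ids,
        "n_quarters": draws.n_quarters,
        "acceptance_rates": draws.acceptance_rates,
        "max_rhat": None if diag is None else float(np.nanmax(list(diag.rhat.values()))),
        "flags": None if diag is None else diag.flags,
    }
    prefix.with_suffix(".json").write_text(
        json.dumps(sidecar, indent=2, sort_keys=True) + "\n"
    )


def load_draws(prefix: str | Path) -> PosteriorDraws:
    """Reload draws written by :func:`save_draws`."""
    prefix = Path(prefix)
    meta = json.loads(prefix.with_suffix(".json").read_text())
    frame = pd.read_csv(prefix.with_suffix(".csv"))
    spec = ModelSpec(
        family=meta["family"],
        include_spatial=meta["include_spatial"],
        include_temporal=meta["include_temporal"],
        include_slopes=meta["include_slopes"],
        fixed_pi=meta["fixed_pi"],
        fixed_phi=meta["fixed_phi"],
    )
    n_chains, n_kept = meta["n_chains"], meta["n_kept"]
    area_ids = [str(a) for a in meta["area_ids"]]
    T = meta["n_quarters"]
    wide = frame.pivot_table(
        index=["chain", "iter"], columns="parameter", values="value", sort=False
    )

    def grab(name):
        if name not in wide.columns:
            return None
        return wide[name].to_numpy().reshape(n_chains, n_kept)

    def grab_vec(name, labels):
        cols = [f"{name}[{lab}]" for lab in labels]
        if cols[0] not in wide.columns:
            return None
        return wide[cols].to_numpy().reshape(n_chains, n_kept, len(cols))

    return PosteriorDraws(
        spec=spec,
        seed=meta["seed"],
        n_chains=n_chains,
        n_kept=n_kept,
        area_ids=area_ids,
        n_quarters=T,
        alpha=grab("alpha"),
        gamma=grab_vec("gamma", area_ids),
        delta=grab_vec("delta", [str(t + 1) for t in range(T)]),
        beta=grab_vec("beta", area_ids),
        tau_gamma=grab("tau_gamma"),
        tau_delta=grab("tau_delta"),
        tau_beta=grab("tau_beta"),
        pi=grab("pi"),
        phi=grab("phi"),
        acceptance_rates=meta["acceptance_rates"],
    )
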