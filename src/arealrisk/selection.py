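"""DIC and WAIC from posterior draws, and lowest-DIC family selection.

Both criteria use full likelihood masses (all combinatorial constants
included) so they are comparable across the Poisson, zero-inflated Poisson
and negative-binomial families fitted to the same panel.

DIC uses the deviance D(theta) = -2 log p(y | theta) with a plug-in point
built from the posterior mean of the expected-count surface lambda (the
mixture weight averaged on the logit scale, the negative-binomial scale on
the log scale):  DIC = 2 * mean(D) - D(plug-in), p_DIC = mean(D) - D(plug-in).

WAIC is computed pointwise: lppd_cell = log(mean_s p(y_cell | theta_s))
(log-sum-exp stabilized), p_cell = Var_s(log p(y_cell | theta_s)), and
WAIC = -2 * sum(lppd_cell - p_cell) on the deviance scale.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, logit, logsumexp

from .inference import PosteriorDraws
from .models import ModelSpec, SpecificationError, linear_predictor, loglik_cells
from .panel import AgeGroup, PanelData

__all__ = [
    "FamilyCriteria",
    "SelectionReport",
    "ComparabilityError",
    "compute_dic",
    "compute_waic",
    "compute_criteria",
    "select_model",
]

logger = logging.getLogger(__name__)

#: Tie-break preference: simplest family first.
TIE_ORDER = ("poisson", "negbin", "zip")


class ComparabilityError(ValueError):
    """Criteria being compared were not computed on the same panel."""


def _panel_fingerprint(panel: PanelData) -> str:
    h = hashlib.sha1()
    h.update(",".join(panel.area_ids).encode())
    h.update(np.ascontiguousarray(panel.counts).tobytes())
    h.update(np.ascontiguousarray(panel.offset).tobytes())
    return h.hexdigest()


@dataclass(frozen=True)
class FamilyCriteria:
    family: str
    dic: float
    p_dic: float
    waic: float
    p_waic: float
    lppd: float
    panel_fingerprint: str


@dataclass
class SelectionReport:
    per_family: dict[str, FamilyCriteria]
    selected_family: str
    age_group: AgeGroup
    tie_note: str | None = None


def _check_match(draws: PosteriorDraws, spec: ModelSpec) -> None:
    if draws.spec.family != spec.family:
        raise SpecificationError(
            f"draws were sampled under {draws.spec.family!r}, criteria requested "
            f"for {spec.family!r}"
        )


def _draw_iter(draws: PosteriorDraws, panel: PanelData, spec: ModelSpec):
    """Yield the lambda surface and (pi, phi) of every retained draw."""
    for state in draws.states():
        lam = linear_predictor(state, panel).lam
        pi = state.pi if state.pi is not None else spec.fixed_pi
        phi = state.phi if state.phi is not None else spec.fixed_phi
        yield lam, pi, phi


def compute_dic(
    draws: PosteriorDraws, panel: PanelData, spec: ModelSpec
) -> tuple[float, float]:
    """Deviance information criterion and its effective-parameter count."""
    _check_match(draws, spec)
    if draws.n_draws < 1:
        raise ValueError("DIC needs at least one draw")
    y = panel.counts
    mean_dev = 0.0
    lam_sum = np.zeros_like(panel.offset)
    lpi_sum = 0.0
    lphi_sum = 0.0
    S = draws.n_draws
    for lam, pi, phi in _draw_iter(draws, panel, spec):
        mean_dev += -2.0 * float(loglik_cells(y, lam, spec.family, pi=pi, phi=phi).sum())
        lam_sum += lam
        if spec.family == "zip":
            lpi_sum += float(logit(pi)) if pi > 0 else -np.inf
        if spec.family == "negbin":
            lphi_sum += np.log(phi)
    mean_dev /= S
    lam_bar = lam_sum / S
    pi_bar = float(expit(lpi_sum / S)) if spec.family == "zip" else None
    phi_bar = float(np.exp(lphi_sum / S)) if spec.family == "negbin" else None
    plug_dev = -2.0 * float(
        loglik_cells(y, lam_bar, spec.family, pi=pi_bar, phi=phi_bar).sum()
    )
    p_dic = mean_dev - plug_dev
    if p_dic < 0:
        logger.warning("negative p_DIC (%.3f); chains may be poorly mixed", p_dic)
    return 2.0 * mean_dev - plug_dev, p_dic


def compute_waic(
    draws: PosteriorDraws, panel: PanelData, spec: ModelSpec
) -> tuple[float, float, float]:
    """WAIC (deviance scale), effective parameters p_waic, and total lppd."""
    _check_match(draws, spec)
    S = draws.n_draws
    if S < 2:
        raise ValueError("WAIC needs at least two draws (pointwise variance)")
    y = panel.counts
    logmass = np.empty((S, y.size))
    for s, (lam, pi, phi) in enumerate(_draw_iter(draws, panel, spec)):
        logmass[s] = loglik_cells(y, lam, spec.family, pi=pi, phi=phi).ravel()
    lppd_cells = logsumexp(logmass, axis=0) - np.log(S)
    p_cells = logmass.var(axis=0)
    lppd = float(lppd_cells.sum())
    p_waic = float(p_cells.sum())
    return -2.0 * (lppd - p_waic), p_waic, lppd


def compute_criteria(
    draws: PosteriorDraws, panel: PanelData, spec: ModelSpec
) -> FamilyCriteria:
    dic, p_dic = compute_dic(draws, panel, spec)
    waic, p_waic, lppd = compute_waic(draws, panel, spec)
    return FamilyCriteria(
        family=spec.family,
        dic=dic,
        p_dic=p_dic,
        waic=waic,
        p_waic=p_waic,
        lppd=lppd,
        panel_fingerprint=_panel_fingerprint(panel),
    )


def select_model(
    reports: dict[str, FamilyCriteria] | list[FamilyCriteria],
    age_group: AgeGroup,
) -> SelectionReport:
    """Pick the family with the lowest DIC; ties go to the simpler family in
    the order poisson < negbin < zip (noted in the report and the log)."""
    if isinstance(reports, dict):
        crits = list(reports.values())
    else:
        crits = list(reports)
    if len(crits) < 2:
        raise ComparabilityError("model selection needs at least two fitted families")
    fingerprints = {c.panel_fingerprint for c in crits}
    if len(fingerprints) > 1:
        raise ComparabilityError(
            "criteria were computed on different panels; DIC values are not comparable"
        )
    per_family = {c.family: c for c in crits}
    best_dic = min(c.dic for c in crits)
    tied = [c.family for c in crits if c.dic == best_dic]
    selected = min(tied, key=TIE_ORDER.index)
    tie_note = None
    if len(tied) > 1:
        tie_note = f"DIC tie among {sorted(tied)}; selected {selected} by simplicity"
        logger.info(tie_note)
    return SelectionReport(
        per_family=per_family,
        selected_family=selected,
        age_group=age_group,
        tie_note=tie_note,
    )
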