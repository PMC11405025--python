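"""Shared fixtures: small panels and the session-scoped recovery experiment."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pytest

from arealrisk import (
    ModelSpec,
    PanelData,
    ScenarioConfig,
    exceedance_probabilities,
    fit,
    simulate_panel,
    simulate_truth,
    temporal_effect_curve,
)
from arealrisk.panel import AGE_GROUPS

warnings.filterwarnings("ignore", category=FutureWarning)

N_REPLICATES = 20
N_PLANTED = 3
RECOVERY_KW = dict(n_chains=2, n_iter=3000, thin=5)


@pytest.fixture()
def tiny_panel() -> PanelData:
    """A deterministic 3x4 Poisson panel for fast unit tests."""
    cfg = ScenarioConfig(n_areas=3, n_quarters=4)
    truth = simulate_truth(cfg, seed=42)
    return simulate_panel(truth, cfg)


@dataclass
class RecoveryResults:
    """Per-replicate outcomes of the synthetic parameter-recovery study."""

    alpha_covered: list[bool] = field(default_factory=list)
    alpha_abs_err: list[float] = field(default_factory=list)
    gamma_coverage: list[float] = field(default_factory=list)
    planted_flagged: list[int] = field(default_factory=list)  # of N_PLANTED
    flag_precision: list[float] = field(default_factory=list)


def _one_replicate(rep: int, planted: bool) -> dict:
    cfg = ScenarioConfig(n_areas=60, n_quarters=12)
    planted_gamma = {i: 1.0 for i in range(N_PLANTED)} if planted else None
    truth = simulate_truth(
        cfg,
        alpha=-9.0,
        tau_gamma=4.0,
        tau_delta=25.0,
        tau_beta=4.0,
        seed=1000 * (2 if planted else 1) + rep,
        planted_gamma=planted_gamma,
    )
    panel = simulate_panel(truth, cfg)
    draws = fit(
        panel,
        ModelSpec("poisson"),
        seed=5000 * (2 if planted else 1) + rep,
        **RECOVERY_KW,
    )
    return {"truth": truth, "draws": draws}


@pytest.fixture(scope="session")
def recovery_experiment() -> RecoveryResults:
    """Twenty plain replicates of the recovery scenario (n=60 areas, T=12
    quarters, Poisson truth, alpha=-9, tau_gamma=4, tau_delta=25, tau_beta=4)
    plus twenty matching replicates with three area effects pinned at +1 for
    exceedance-flag calibration."""
    res = RecoveryResults()
    for rep in range(N_REPLICATES):
        out = _one_replicate(rep, planted=False)
        truth, draws = out["truth"], out["draws"]
        a = draws.combined("alpha")
        lo, hi = np.quantile(a, [0.025, 0.975])
        res.alpha_covered.append(bool(lo <= truth.alpha <= hi))
        res.alpha_abs_err.append(abs(float(a.mean()) - truth.alpha))
        g = draws.combined("gamma")
        ci_lo = np.quantile(g, 0.025, axis=0)
        ci_hi = np.quantile(g, 0.975, axis=0)
        res.gamma_coverage.append(
            float(((ci_lo <= truth.gamma) & (truth.gamma <= ci_hi)).mean())
        )
    for rep in range(N_REPLICATES):
        out = _one_replicate(rep, planted=True)
        truth, draws = out["truth"], out["draws"]
        risk = exceedance_probabilities(draws, threshold=0.8)
        probs = risk.table["exceedance_probability"].to_numpy()
        res.planted_flagged.append(int((probs[:N_PLANTED] > 0.8).sum()))
        flagged = probs > 0.8
        if flagged.any():
            res.flag_precision.append(float((truth.gamma[flagged] > 0).mean()))
    return res
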