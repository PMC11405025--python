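"""Result surfaces: risk tables, incidence summaries, effect curves, maps.

Turns posterior draws and panels into the outputs a surveillance analyst
consumes: per-area exceedance probabilities and high-risk flags with
per-state rollups, the fixed-effect incidence per 100,000 inhabitants, the
spatial-effect surface (relative risk or combined incidence), the temporal
effect curve, per-area covariate significance calls by 95% credible
interval, descriptive incidence series, and choropleth-ready GeoJSON.
"""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .ingest import LineListRecord
from .inference import PosteriorDraws
from .panel import AgeGroup, PanelData

__all__ = [
    "RiskTable",
    "exceedance_probabilities",
    "fixed_effect_incidence",
    "spatial_effect_surface",
    "temporal_effect_curve",
    "covariate_significance",
    "descriptive_incidence",
    "export_maps",
]

PER_100K = 1e5


@dataclass
class RiskTable:
    """Per-area exceedance probabilities with per-state rollups.

    The exceedance event is gamma_i > 0, i.e. area relative risk exp(gamma_i)
    above 1; an area is flagged high-risk when the posterior probability of
    that event exceeds the threshold (default 0.8).  States are the first two
    characters of the 5-digit municipality code.
    """

    table: pd.DataFrame  # columns: area_id, exceedance_probability, high_risk, state
    threshold: float
    age_group: AgeGroup | None

    @property
    def n_high_risk(self) -> int:
        return int(self.table["high_risk"].sum())

    def state_rollup(self) -> pd.DataFrame:
        g = self.table.groupby("state")
        out = g.agg(
            n_high_risk=("high_risk", "sum"), n_total=("area_id", "count")
        ).reset_index()
        out["n_high_risk"] = out["n_high_risk"].astype(int)
        return out


def exceedance_probabilities(
    draws: PosteriorDraws,
    threshold: float = 0.8,
    age_group: AgeGroup | None = None,
) -> RiskTable:
    """Posterior probability per area that the spatial effect is positive."""
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must lie in (0, 1), got {threshold}")
    if draws.gamma is None:
        raise ValueError("draws contain no spatial effect")
    gamma = draws.combined("gamma")  # (S, n)
    prob = (gamma > 0.0).mean(axis=0)
    table = pd.DataFrame(
        {
            "area_id": draws.area_ids,
            "exceedance_probability": prob,
            "high_risk": prob > threshold,
            "state": [a[:2] for a in draws.area_ids],
        }
    )
    return RiskTable(table=table, threshold=threshold, age_group=age_group)


def _summary(values: np.ndarray) -> dict[str, float]:
    return {
        "mean": float(values.mean()),
        "median": float(np.median(values)),
        "q025": float(np.quantile(values, 0.025)),
        "q975": float(np.quantile(values, 0.975)),
    }


def fixed_effect_incidence(draws: PosteriorDraws) -> dict[str, float]:
    """Posterior summary of exp(alpha) * 100,000 — the baseline incidence per
    100,000 inhabitants per quarter shared by all areas."""
    alpha = draws.combined("alpha")
    if alpha.size == 0:
        raise ValueError("no draws")
    return _summary(np.exp(alpha) * PER_100K)


def spatial_effect_surface(draws: PosteriorDraws, mode: str = "relative_risk") -> pd.Series:
    """Per-area posterior mean surface attributable to the spatial effect.

    ``relative_risk``: mean of exp(gamma_i).  ``incidence``: mean of
    exp(alpha + gamma_i) * 100,000, i.e. the area's baseline incidence per
    100,000 per quarter with the covariate and temporal effects at zero.
    """
    if mode not in ("relative_risk", "incidence"):
        raise ValueError(f"unknown mode {mode!r}")
    if draws.gamma is None:
        raise ValueError("draws contain no spatial effect")
    gamma = draws.combined("gamma")
    if mode == "relative_risk":
        values = np.exp(gamma).mean(axis=0)
    else:
        alpha = draws.combined("alpha")[:, None]
        values = (np.exp(alpha + gamma) * PER_100K).mean(axis=0)
    return pd.Series(values, index=draws.area_ids, name=mode)


def temporal_effect_curve(draws: PosteriorDraws) -> pd.DataFrame:
    """Per-quarter posterior mean and 95% band of exp(delta_t)."""
    if draws.delta is None:
        raise ValueError("draws contain no temporal effect")
    ed = np.exp(draws.combined("delta"))  # (S, T)
    return pd.DataFrame(
        {
            "quarter": np.arange(1, ed.shape[1] + 1),
            "mean": ed.mean(axis=0),
            "q025": np.quantile(ed, 0.025, axis=0),
            "q975": np.quantile(ed, 0.975, axis=0),
        }
    )


def covariate_significance(draws: PosteriorDraws) -> pd.DataFrame:
    """95% credible interval per area slope; significant iff the interval
    excludes zero, with the shared sign reported."""
    if draws.beta is None:
        raise ValueError("draws contain no covariate slopes")
    beta = draws.combined("beta")
    q025 = np.quantile(beta, 0.025, axis=0)
    q975 = np.quantile(beta, 0.975, axis=0)
    significant = (q025 > 0) | (q975 < 0)
    sign = np.where(~significant, "", np.where(q025 > 0, "positive", "negative"))
    return pd.DataFrame(
        {
            "area_id": draws.area_ids,
            "q025": q025,
            "q975": q975,
            "significant": significant,
            "sign": sign,
        }
    )


def _panel_incidence(
    panel: PanelData, grouping: str, by_area: bool
) -> pd.DataFrame:
    if grouping not in ("quarter", "year"):
        raise ValueError("panel-based series support grouping 'quarter' or 'year'")
    T = panel.n_quarters
    if grouping == "quarter":
        labels = [f"Q{t}" for t in range(1, T + 1)]
        groups = [[t] for t in range(T)]
    else:
        labels = [f"Y{k + 1}" for k in range((T + 3) // 4)]
        groups = [list(range(4 * k, min(4 * k + 4, T))) for k in range(len(labels))]
    pop_area = panel.offset[:, 0]  # constant over quarters by construction
    rows = []
    for label, ts in zip(labels, groups):
        cases_area = panel.counts[:, ts].sum(axis=1)
        if by_area:
            for i, area in enumerate(panel.area_ids):
                rows.append((label, area, int(cases_area[i]), float(pop_area[i])))
        else:
            rows.append((label, None, int(cases_area.sum()), float(pop_area.sum())))
    df = pd.DataFrame(rows, columns=["period", "area_id", "cases", "population"])
    if not by_area:
        df = df.drop(columns="area_id")
    return df


def _record_incidence(
    records: Iterable[LineListRecord],
    population: pd.DataFrame | float,
    grouping: str,
    by_area: bool,
) -> pd.DataFrame:
    def period(d: dt.date) -> str:
        if grouping == "month":
            return f"{d.year}-{d.month:02d}"
        if grouping == "quarter":
            return f"{d.year}Q{(d.month + 2) // 3}"
        if grouping == "year":
            return str(d.year)
        raise ValueError(f"unknown grouping {grouping!r}")

    rows = [(period(r.notification_date), r.municipality_code) for r in records]
    df = pd.DataFrame(rows, columns=["period", "area_id"])
    if isinstance(population, pd.DataFrame):
        pop = (
            population.assign(
                municipality_code=lambda d: d["municipality_code"].map(
                    lambda c: str(c).strip().zfill(5)
                )
            )
            .groupby("municipality_code")["population"]
            .sum()
        )
    else:
        pop = None
    if by_area:
        out = df.groupby(["period", "area_id"]).size().rename("cases").reset_index()
        if pop is not None:
            out["population"] = out["area_id"].map(pop).fillna(0.0)
        else:
            raise ValueError("per-area series need a population table")
    else:
        out = df.groupby("period").size().rename("cases").reset_index()
        total = float(pop.sum()) if pop is not None else float(population)
        out["population"] = total
    return out


def descriptive_incidence(
    data: PanelData | Iterable[LineListRecord],
    population: pd.DataFrame | float | None = None,
    grouping: str = "quarter",
    by_area: bool = False,
) -> pd.DataFrame:
    """Cases and incidence per 100,000 by period (and optionally area).

    Accepts either an aggregated panel (grouping by quarter or year, with the
    panel's own offsets as population) or raw line-list records with a
    population table/total (grouping by month, quarter or year).  Periods
    with zero population are flagged and their rate left undefined.
    """
    if isinstance(data, PanelData):
        df = _panel_incidence(data, grouping, by_area)
    else:
        if population is None:
            raise ValueError("record-based series need population information")
        df = _record_incidence(data, population, grouping, by_area)
    zero = df["population"] <= 0
    df["rate_per_100k"] = np.where(
        zero, np.nan, PER_100K * df["cases"] / df["population"].where(~zero, np.nan)
    )
    df["flagged"] = zero
    return df


def export_maps(
    table: pd.DataFrame,
    boundaries: dict | str | Path,
    out: str | Path,
    key_property: str = "municipality_code",
    area_column: str = "area_id",
) -> dict:
    """Join a per-area table onto GeoJSON features and write the result.

    Every feature whose ``key_property`` matches a row of ``table`` gains
    that row's remaining columns as properties.  Unmatched codes on either
    side are returned in the join report; output bytes are deterministic
    (sorted keys, fixed separators), so re-export of identical inputs is
    byte-identical.
    """
    if isinstance(boundaries, (str, Path)):
        geo = json.loads(Path(boundaries).read_text())
    else:
        geo = json.loads(json.dumps(boundaries))  # private copy
    features = geo.get("features", [])
    if not any(key_property in f.get("properties", {}) for f in features):
        raise KeyError(
            f"no GeoJSON feature has the key property {key_property!r}"
        )
    indexed = table.set_index(table[area_column].astype(str).str.zfill(5))
    value_cols = [c for c in table.columns if c != area_column]
    matched: set[str] = set()
    unmatched_features: list[str] = []
    for f in features:
        props = f.setdefault("properties", {})
        code = str(props.get(key_property, "")).zfill(5)
        if code in indexed.index:
            row = indexed.loc[code]
            for col in value_cols:
                val = row[col]
                props[col] = val.item() if hasattr(val, "item") else val
            matched.add(code)
        else:
            unmatched_features.append(code)
    unmatched_table = sorted(set(indexed.index) - matched)
    out = Path(out)
    out.parent.mkdir(parents=True, exist_ok=True)
    out.write_text(
        json.dumps(geo, sort_keys=True, separators=(",", ":")) + "\n"
    )
    return {
        "n_matched": len(matched),
        "unmatched_table_codes": unmatched_table,
        "unmatched_feature_codes": unmatched_features,
    }
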