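"""Shared data containers for areal count panels.

A panel holds, for one age group, the quarterly event counts of every
administrative area together with the population at risk (the offset) and a
per-area, per-quarter covariate.  All downstream modules — the likelihoods,
the sampler, the reports — consume this one container.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = ["AgeGroup", "AGE_GROUPS", "PanelData", "save_panel", "load_panel"]


@dataclass(frozen=True)
class AgeGroup:
    """A half-open age bracket; ``upper is None`` means unbounded above."""

    label: str
    lower: int
    upper: int | None

    def contains(self, age: int) -> bool:
        if age < self.lower:
            return False
        return self.upper is None or age <= self.upper


#: The six analysis brackets, disjoint and ordered; ages below 5 are excluded.
AGE_GROUPS: tuple[AgeGroup, ...] = (
    AgeGroup("5-9", 5, 9),
    AgeGroup("10-14", 10, 14),
    AgeGroup("15-19", 15, 19),
    AgeGroup("20-24", 20, 24),
    AgeGroup("25-59", 25, 59),
    AgeGroup("gt59", 60, None),
)

_GROUPS_BY_LABEL = {g.label: g for g in AGE_GROUPS}


def age_group_by_label(label: str) -> AgeGroup:
    try:
        return _GROUPS_BY_LABEL[label]
    except KeyError:
        raise KeyError(
            f"unknown age group {label!r}; expected one of "
            f"{sorted(_GROUPS_BY_LABEL)}"
        ) from None


@dataclass
class PanelData:
    """Counts, offsets and covariate on an area x quarter grid for one age group.

    ``counts[i, t]`` is the number of events in area ``area_ids[i]`` during
    quarter ``t+1``; ``offset[i, t]`` is the person-quarters of population at
    risk (strictly positive by construction — zero-population areas are
    dropped upstream); ``covariate[i, t]`` is the exposure covariate
    (fixed-internet points per inhabitant in the motivating application).
    """

    area_ids: list[str]
    age_group: AgeGroup
    counts: np.ndarray
    offset: np.ndarray
    covariate: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.offset = np.asarray(self.offset, dtype=float)
        self.covariate = np.asarray(self.covariate, dtype=float)
        n = len(self.area_ids)
        if self.counts.ndim != 2 or self.counts.shape[0] != n:
            raise ValueError(
                f"counts must be (n_areas, n_quarters) = ({n}, T); "
                f"got {self.counts.shape}"
            )
        if self.offset.shape != self.counts.shape:
            raise ValueError("offset shape differs from counts shape")
        if self.covariate.shape != self.counts.shape:
            raise ValueError("covariate shape differs from counts shape")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if not np.all(self.offset > 0):
            bad = [self.area_ids[i] for i in np.where(~(self.offset > 0).all(axis=1))[0]]
            raise ValueError(f"offset must be strictly positive; zero/negative in areas {bad}")
        if np.any(self.covariate < 0):
            raise ValueError("covariate must be non-negative")
        if len(set(self.area_ids)) != n:
            raise ValueError("area_ids must be unique")

    @property
    def n_areas(self) -> int:
        return len(self.area_ids)

    @property
    def n_quarters(self) -> int:
        return self.counts.shape[1]

    def total_counts(self) -> int:
        return int(self.counts.sum())


def save_panel(panel: PanelData, out_dir: str | Path) -> None:
    """Write a panel as three wide CSVs plus a small JSON sidecar."""
    import json

    import pandas as pd

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cols = [f"t{t}" for t in range(1, panel.n_quarters + 1)]
    for name, mat in (
        ("counts", panel.counts),
        ("offset", panel.offset),
        ("covariate", panel.covariate),
    ):
        pd.DataFrame(mat, index=panel.area_ids, columns=cols).rename_axis(
            "municipality_code"
        ).to_csv(out / f"{name}.csv")
    meta = {
        "age_group": panel.age_group.label,
        "n_areas": panel.n_areas,
        "n_quarters": panel.n_quarters,
    }
    (out / "panel.json").write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")


def load_panel(in_dir: str | Path) -> PanelData:
    import json

    import pandas as pd

    src = Path(in_dir)
    meta = json.loads((src / "panel.json").read_text())
    frames = {
        name: pd.read_csv(src / f"{name}.csv", index_col=0, dtype={0: str})
        for name in ("counts", "offset", "covariate")
    }
    area_ids = [str(c).zfill(5) for c in frames["counts"].index]
    return PanelData(
        area_ids=area_ids,
        age_group=age_group_by_label(meta["age_group"]),
        counts=frames["counts"].to_numpy(dtype=int),
        offset=frames["offset"].to_numpy(dtype=float),
        covariate=frames["covariate"].to_numpy(dtype=float),
    )
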