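"""Risk tables, incidence summaries, effect curves, maps and dip recovery."""

import datetime as dt
import json
import math

import numpy as np
import pandas as pd
import pytest

from arealrisk.ingest import LineListRecord
from arealrisk.inference import PosteriorDraws, fit
from arealrisk.models import ModelSpec, project_delta
from arealrisk.panel import AGE_GROUPS, PanelData
from arealrisk.reporting import (
    covariate_significance,
    descriptive_incidence,
    exceedance_probabilities,
    export_maps,
    fixed_effect_incidence,
    spatial_effect_surface,
    temporal_effect_curve,
)
from arealrisk.synthetic import ScenarioConfig, simulate_panel, simulate_truth

SPEC = ModelSpec("poisson")


def _draws(alpha=None, gamma=None, delta=None, beta=None, area_ids=None):
    """Hand-built draw container: arrays are (n_draws,) or (n_draws, m)."""
    def shape2(a):
        return None if a is None else np.asarray(a, float)[None, ...]

    first = next(a for a in (alpha, gamma, delta, beta) if a is not None)
    S = np.asarray(first).shape[0]
    if alpha is None:
        alpha = np.zeros(S)
    n_quarters = 1 if delta is None else np.asarray(delta).shape[1]
    if area_ids is None:
        m = 1
        for a in (gamma, beta):
            if a is not None:
                m = np.asarray(a).shape[1]
        area_ids = [f"05{i:03d}" for i in range(1, m + 1)]
    return PosteriorDraws(
        spec=SPEC, seed=0, n_chains=1, n_kept=S, area_ids=area_ids,
        n_quarters=n_quarters, alpha=shape2(alpha), gamma=shape2(gamma),
        delta=shape2(delta), beta=shape2(beta),
    )


class TestExceedance:
    def test_counting_example(self):
        draws = _draws(gamma=np.array([[0.5], [-0.1], [0.2], [0.3]]))
        risk = exceedance_probabilities(draws)
        assert risk.table["exceedance_probability"].iloc[0] == pytest.approx(0.75)
        assert not risk.table["high_risk"].iloc[0]

    def test_all_negative_not_flagged(self):
        draws = _draws(gamma=np.full((10, 1), -0.2))
        risk = exceedance_probabilities(draws)
        assert risk.table["exceedance_probability"].iloc[0] == 0.0
        assert risk.n_high_risk == 0

    def test_threshold_validation(self):
        draws = _draws(gamma=np.zeros((4, 1)))
        with pytest.raises(ValueError):
            exceedance_probabilities(draws, threshold=1.5)

    def test_permutation_invariant(self):
        rng = np.random.default_rng(0)
        g = rng.normal(size=(200, 3))
        p1 = exceedance_probabilities(_draws(gamma=g)).table
        p2 = exceedance_probabilities(_draws(gamma=g[rng.permutation(200)])).table
        pd.testing.assert_frame_equal(p1, p2)

    def test_state_rollup_conserves_counts(self):
        rng = np.random.default_rng(1)
        ids = [f"{s:02d}{i:03d}" for s in (5, 11, 25) for i in range(1, 5)]
        g = rng.normal(0.3, 0.5, size=(300, 12))
        risk = exceedance_probabilities(_draws(gamma=g, area_ids=ids))
        roll = risk.state_rollup()
        assert roll["n_high_risk"].sum() == risk.n_high_risk
        assert roll["n_total"].sum() == 12
        assert set(roll["state"]) == {"05", "11", "25"}


class TestFixedEffectIncidence:
    def test_point_mass_recovers_printed_scale(self):
        # all draws at log(8.77e-5) -> 8.77 per 100,000
        draws = _draws(alpha=np.full(50, math.log(8.77e-5)))
        out = fixed_effect_incidence(draws)
        assert out["mean"] == pytest.approx(8.77, rel=1e-10)
        assert out["q025"] == pytest.approx(8.77, rel=1e-10)
        draws1 = _draws(alpha=np.full(50, math.log(1e-5)))
        assert fixed_effect_incidence(draws1)["median"] == pytest.approx(1.0)

    def test_monotone_in_alpha_shift(self):
        rng = np.random.default_rng(3)
        a = rng.normal(math.log(1e-4), 0.1, size=200)
        lo = fixed_effect_incidence(_draws(alpha=a))
        hi = fixed_effect_incidence(_draws(alpha=a + 0.3))
        assert all(hi[k] > lo[k] for k in ("mean", "median", "q025", "q975"))


class TestSpatialSurface:
    def test_null_effect_gives_unit_relative_risk(self):
        draws = _draws(alpha=np.full(20, -9.0), gamma=np.zeros((20, 4)))
        rr = spatial_effect_surface(draws, "relative_risk")
        np.testing.assert_allclose(rr.values, 1.0)

    def test_incidence_mode_combines_alpha(self):
        draws = _draws(alpha=np.full(10, math.log(1e-4)),
                       gamma=np.full((10, 2), math.log(2.0)))
        inc = spatial_effect_surface(draws, "incidence")
        np.testing.assert_allclose(inc.values, 20.0, rtol=1e-10)

    def test_modes_rank_areas_identically(self):
        rng = np.random.default_rng(5)
        draws = _draws(alpha=rng.normal(-9, 0.05, 300),
                       gamma=rng.normal(0, 0.4, size=(300, 8)))
        rr = spatial_effect_surface(draws, "relative_risk")
        inc = spatial_effect_surface(draws, "incidence")
        assert (rr.rank() == inc.rank()).all()

    def test_unknown_mode(self):
        with pytest.raises(ValueError):
            spatial_effect_surface(_draws(gamma=np.zeros((2, 1))), "log_odds")


class TestTemporalCurve:
    def test_flat_effect_gives_unit_curve(self):
        draws = _draws(delta=np.zeros((30, 6)))
        curve = temporal_effect_curve(draws)
        np.testing.assert_allclose(curve["mean"], 1.0)
        np.testing.assert_allclose(curve[["q025", "q975"]], 1.0)

    def test_identified_draws_have_unit_geometric_mean(self):
        rng = np.random.default_rng(6)
        deltas = np.stack([project_delta(rng.normal(0, 0.2, 8))[0] for _ in range(100)])
        curve = temporal_effect_curve(_draws(delta=deltas))
        geo = np.exp(np.log(curve["mean"]).mean())
        assert geo == pytest.approx(1.0, abs=0.02)

    def test_single_elevated_quarter(self):
        base = np.full(4, -math.log(2.0) / 3.0)
        base[0] = math.log(2.0)
        draws = _draws(delta=np.tile(base, (20, 1)))
        curve = temporal_effect_curve(draws)
        assert curve["mean"].iloc[0] == pytest.approx(2.0, rel=1e-10)


class TestCovariateSignificance:
    def test_interval_rules(self):
        S = 1000
        grid = np.linspace(0.025, 0.975, S)  # uniform quantile grid
        beta = np.column_stack([
            -0.2 + 0.5 * grid,   # interval ~(-0.19, 0.29): spans zero
            0.1 + 0.3 * grid,    # positive interval
            -0.4 + 0.3 * grid,   # negative interval
        ])
        out = covariate_significance(_draws(beta=beta))
        assert list(out["significant"]) == [False, True, True]
        assert list(out["sign"]) == ["", "positive", "negative"]


class TestDescriptiveIncidence:
    def test_rate_definition(self):
        recs = [LineListRecord(dt.date(2019, 3, 1), "05001", 20, "F")] * 50
        out = descriptive_incidence(recs, population=100_000.0, grouping="year")
        assert out["rate_per_100k"].iloc[0] == pytest.approx(50.0)

    def test_year_total_equals_sum_of_months(self):
        rng = np.random.default_rng(7)
        recs = [
            LineListRecord(dt.date(2019, int(m), 15), "05001", 20, "F")
            for m in rng.integers(1, 13, size=300)
        ]
        monthly = descriptive_incidence(recs, population=1e6, grouping="month")
        yearly = descriptive_incidence(recs, population=1e6, grouping="year")
        assert monthly["cases"].sum() == yearly["cases"].iloc[0] == 300

    def test_panel_national_sums_area_series(self, tiny_panel):
        nat = descriptive_incidence(tiny_panel, grouping="quarter")
        per_area = descriptive_incidence(tiny_panel, grouping="quarter", by_area=True)
        merged = per_area.groupby("period")[["cases", "population"]].sum()
        assert (merged["cases"].values == nat["cases"].values).all()
        np.testing.assert_allclose(merged["population"], nat["population"])

    def test_zero_population_flagged(self):
        recs = [LineListRecord(dt.date(2019, 3, 1), "05001", 20, "F")]
        pop = pd.DataFrame(
            [("99001", "15-19", 1000)],
            columns=["municipality_code", "age_group", "population"],
        )
        out = descriptive_incidence(recs, population=pop, grouping="year",
                                    by_area=True)
        assert out["flagged"].iloc[0]
        assert np.isnan(out["rate_per_100k"].iloc[0])

    def test_generator_rate_recovered(self):
        """The descriptive series reproduces the configured incidence of a
        flat synthetic panel within binomial error."""
        cfg = ScenarioConfig(n_areas=300, n_quarters=4,
                             population_range=(50_000, 50_000),
                             covariate_trajectory="constant")
        truth = simulate_truth(cfg, alpha=math.log(2e-4), tau_gamma=1e12,
                               tau_delta=1e12, tau_beta=1e12, seed=10)
        panel = simulate_panel(truth, cfg)
        out = descriptive_incidence(panel, grouping="quarter")
        expected = 20.0  # 2e-4 * 1e5 per quarter
        se = 100.0 * math.sqrt(2e-4 * 300 * 50_000) / (300 * 50_000) * 1e3
        assert np.abs(out["rate_per_100k"] - expected).max() < 4 * se


class TestExportMaps:
    def _geo(self, codes):
        return {
            "type": "FeatureCollection",
            "features": [
                {
                    "type": "Feature",
                    "properties": {"municipality_code": c},
                    "geometry": {"type": "Point", "coordinates": [0.0, float(i)]},
                }
                for i, c in enumerate(codes)
            ],
        }

    def test_full_match(self, tmp_path):
        table = pd.DataFrame({"area_id": ["05001", "05002", "11001"],
                              "relative_risk": [1.2, 0.8, 1.0]})
        out = tmp_path / "map.geojson"
        join = export_maps(table, self._geo(["05001", "05002", "11001"]), out)
        assert join["n_matched"] == 3
        assert not join["unmatched_table_codes"] and not join["unmatched_feature_codes"]
        geo = json.loads(out.read_text())
        assert geo["features"][0]["properties"]["relative_risk"] == 1.2

    def test_partial_match_reported_but_written(self, tmp_path):
        table = pd.DataFrame({"area_id": ["05001", "99999"], "v": [1.0, 2.0]})
        out = tmp_path / "map.geojson"
        join = export_maps(table, self._geo(["05001", "05002"]), out)
        assert join["unmatched_table_codes"] == ["99999"]
        assert join["unmatched_feature_codes"] == ["05002"]
        assert out.exists()

    def test_reexport_is_byte_identical(self, tmp_path):
        table = pd.DataFrame({"area_id": ["05001"], "v": [1.5]})
        a, b = tmp_path / "a.geojson", tmp_path / "b.geojson"
        export_maps(table, self._geo(["05001"]), a)
        export_maps(table, self._geo(["05001"]), b)
        assert a.read_bytes() == b.read_bytes()

    def test_missing_key_property(self, tmp_path):
        geo = self._geo(["05001"])
        for f in geo["features"]:
            f["properties"] = {"code": "05001"}
        with pytest.raises(KeyError):
            export_maps(pd.DataFrame({"area_id": ["05001"], "v": [1.0]}), geo,
                        tmp_path / "x.geojson")


class TestDipRecovery:
    def test_fitted_temporal_effect_shows_the_dip(self):
        """Ten replicates of a smooth-trend panel with a mid-window
        notification dip: the fitted exp(delta_t) mean over the dip quarters
        falls below the pre-dip mean in at least nine."""
        hits = 0
        for rep in range(10):
            cfg = ScenarioConfig(n_areas=40, n_quarters=12, dip=(10, 11, 0.4),
                                 population_range=(50_000, 200_000))
            truth = simulate_truth(cfg, tau_delta=400.0, seed=500 + rep)
            panel = simulate_panel(truth, cfg)
            draws = fit(panel, ModelSpec("poisson"), n_chains=2, n_iter=3000,
                        seed=600 + rep)
            curve = temporal_effect_curve(draws)
            hits += curve["mean"][9:11].mean() < curve["mean"][:8].mean()
        assert hits >= 9
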