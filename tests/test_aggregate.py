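"""Taxonomic/spatial aggregation and the proxy chain."""

import numpy as np
import pandas as pd
import pytest

from fragcf.aggregate import (
    aggregate_spatial,
    aggregate_taxa,
    aggregate_to_countries,
    fill_gaps,
    proxy_biome,
    proxy_country,
    proxy_gep,
    proxy_intensity,
    weighted_mean_sd,
)


class TestAggregateTaxa:
    def test_two_step_equal_weights(self):
        cf = {"plants": 0.2, "amphibians": 0.1, "birds": 0.2,
              "mammals": 0.3, "reptiles": 0.4}
        assert aggregate_taxa(cf) == pytest.approx(0.5 * (0.2 + 0.25))

    def test_idempotent_on_equal_inputs(self):
        cf = {g: 0.07 for g in ("plants", "birds", "mammals")}
        assert aggregate_taxa(cf) == pytest.approx(0.07)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_two_step_oracle(self, seed):
        rng = np.random.default_rng(seed)
        groups = ["plants", "amphibians", "birds", "mammals", "reptiles"]
        cf = {g: float(rng.uniform(0, 1e-10)) for g in groups}
        verts = [cf[g] for g in groups if g != "plants"]
        oracle = (cf["plants"] + sum(verts) / len(verts)) / 2
        assert aggregate_taxa(cf) == pytest.approx(oracle, rel=1e-12)

    def test_missing_kingdom_raises(self):
        with pytest.raises(KeyError):
            aggregate_taxa({"birds": 0.1})
        with pytest.raises(KeyError):
            aggregate_taxa({"plants": 0.1})


class TestAggregateSpatial:
    def test_single_input_passthrough(self):
        mean, rel = aggregate_spatial([2e-12], [5.0])
        assert mean == pytest.approx(2e-12)
        assert rel == 0.0

    def test_weighted_mean(self):
        mean, _ = aggregate_spatial([1e-12, 3e-12], [1.0, 3.0])
        assert mean == pytest.approx(2.5e-12)

    def test_convex_combination_bounds(self):
        rng = np.random.default_rng(1)
        vals = rng.uniform(0, 1, 10)
        w = rng.uniform(0.1, 2, 10)
        mean, _ = aggregate_spatial(vals, w)
        assert vals.min() <= mean <= vals.max()

    def test_sd_zero_iff_equal(self):
        _, sd = weighted_mean_sd(np.array([3.0, 3.0, 3.0]), np.array([1, 2, 5.0]))
        assert sd == 0.0
        _, sd2 = weighted_mean_sd(np.array([3.0, 4.0]), np.array([1.0, 1.0]))
        assert sd2 > 0.0

    def test_all_zero_weights_error(self):
        with pytest.raises(ValueError):
            aggregate_spatial([1.0, 2.0], [0.0, 0.0])


def cf_row(eco, group="plants", lu="cropland", m="intense", value=1e-12,
           extent="regional", approach="average", kind="occupation", proxy=False):
    return {
        "ecoregion": eco, "group": group, "land_use": lu, "intensity": m,
        "approach": approach, "extent": extent, "kind": kind, "value": value,
        "unit": "PDF/m2", "proxy_flag": proxy, "rel_weighted_sd": np.nan,
    }


class TestCountryAggregation:
    def test_single_country_weighted_mean(self):
        cfs = pd.DataFrame([cf_row("e1", value=1e-12), cf_row("e2", value=3e-12)])
        overlaps = pd.DataFrame([
            {"ecoregion": "e1", "country": "c1", "overlap_m2": 1.0},
            {"ecoregion": "e2", "country": "c1", "overlap_m2": 3.0},
        ])
        out = aggregate_to_countries(cfs, overlaps)
        assert len(out) == 1
        assert out["value"].iloc[0] == pytest.approx(2.5e-12)
        assert out["rel_weighted_sd"].iloc[0] > 0


class TestProxyIntensity:
    @staticmethod
    def affinity(group, eco, lu, m):
        return {"minimal": 0.8, "light": 0.6, "intense": 0.2}[m]

    def test_rescales_and_flags(self):
        cfs = pd.DataFrame([cf_row("e1", m="light", value=2e-12)])
        out = proxy_intensity(cfs, self.affinity, "e1", "plants", "cropland",
                              "intense")
        assert out is not None
        assert bool(out["proxy_flag"].all())
        # impact scales with the (1 - h) unsuitability ratio
        assert out["value"].iloc[0] == pytest.approx(2e-12 * (1 - 0.2) / (1 - 0.6))

    def test_nearest_sibling_selected(self):
        cfs = pd.DataFrame([
            cf_row("e1", m="minimal", value=1e-12),
            cf_row("e1", m="light", value=2e-12),
        ])
        out = proxy_intensity(cfs, self.affinity, "e1", "plants", "cropland",
                              "intense")
        # light is nearer to intense than minimal
        assert out["value"].iloc[0] == pytest.approx(2e-12 * (1 - 0.2) / (1 - 0.6))

    def test_no_sibling_returns_none(self):
        cfs = pd.DataFrame([cf_row("e1", lu="pasture")])
        assert proxy_intensity(cfs, self.affinity, "e1", "plants", "cropland",
                               "light") is None


class TestProxyBiome:
    def setup_method(self):
        self.biomes = pd.DataFrame({
            "ecoregion": ["e1", "e2", "e3"], "biome": ["b1", "b1", "b1"]})

    def test_mean_times_gep(self):
        cfs = pd.DataFrame([
            cf_row("e1", value=2e-12), cf_row("e2", value=4e-12)])
        out = proxy_biome(cfs, self.biomes, 0.01, "e3", "plants", "cropland",
                          "intense")
        reg = out[out["extent"] == "regional"]["value"].iloc[0]
        glo = out[out["extent"] == "global"]["value"].iloc[0]
        assert reg == pytest.approx(3e-12)
        assert glo == pytest.approx(3e-14)
        assert bool(out["proxy_flag"].all())

    def test_proxy_donors_excluded(self):
        cfs = pd.DataFrame([
            cf_row("e1", value=2e-12),
            cf_row("e2", value=400e-12, proxy=True),  # must not poison the pool
        ])
        out = proxy_biome(cfs, self.biomes, 1.0, "e3", "plants", "cropland",
                          "intense")
        assert out[out["extent"] == "regional"]["value"].iloc[0] == pytest.approx(2e-12)

    def test_empty_biome_stays_missing(self):
        cfs = pd.DataFrame([cf_row("e9", value=1e-12)])
        assert proxy_biome(cfs, self.biomes, 0.5, "e3", "plants", "plantation",
                          "minimal") is None


class TestProxyGep:
    def test_density_mean_times_area(self):
        geps = pd.DataFrame([
            {"group": "plants", "ecoregion": "e1", "gep": 1e-3},
            {"group": "plants", "ecoregion": "e2", "gep": 3e-3},
        ])
        biomes = pd.DataFrame({"ecoregion": ["e1", "e2", "e3"],
                               "biome": ["b", "b", "b"]})
        areas = pd.DataFrame({"ecoregion": ["e1", "e2", "e3"],
                              "area_m2": [1e6, 1e6, 1e6]})
        got = proxy_gep(geps, biomes, areas, "plants", "e3")
        assert got == pytest.approx(2e-3)

    def test_single_donor_same_area(self):
        geps = pd.DataFrame([{"group": "plants", "ecoregion": "e1", "gep": 0.02}])
        biomes = pd.DataFrame({"ecoregion": ["e1", "e2"], "biome": ["b", "b"]})
        areas = pd.DataFrame({"ecoregion": ["e1", "e2"], "area_m2": [5e6, 5e6]})
        assert proxy_gep(geps, biomes, areas, "plants", "e2") == pytest.approx(0.02)


class TestProxyCountry:
    def country_table(self, values, sds=None):
        sds = sds or [np.nan] * len(values)
        return pd.DataFrame([
            {"country": f"c{i}", "group": "plants", "land_use": "cropland",
             "intensity": "intense", "approach": "average", "extent": "regional",
             "kind": "occupation", "value": v, "unit": "PDF/m2",
             "proxy_flag": False, "rel_weighted_sd": s}
            for i, (v, s) in enumerate(zip(values, sds))
        ])

    def centroids(self, coords):
        return pd.DataFrame([
            {"country": f"c{i}", "x": x, "y": y} for i, (x, y) in enumerate(coords)
        ] + [{"country": "target", "x": 0.0, "y": 0.0}])

    def test_simple_mean_of_three_nearest(self):
        cfs = self.country_table([1e-12, 2e-12, 3e-12, 99e-12])
        cents = self.centroids([(1, 0), (0, 1), (1, 1), (9, 9)])
        out = proxy_country(cfs, cents, "target")
        assert out["value"].iloc[0] == pytest.approx(2e-12)
        assert bool(out["proxy_flag"].all())

    def test_identical_neighbours_preserve_sd(self):
        cfs = self.country_table([2e-12] * 3, sds=[0.5] * 3)
        cents = self.centroids([(1, 0), (0, 1), (1, 1)])
        out = proxy_country(cfs, cents, "target")
        assert out["value"].iloc[0] == pytest.approx(2e-12)
        assert out["rel_weighted_sd"].iloc[0] == pytest.approx(0.5)

    def test_nearest_selection_vs_brute_force(self):
        rng = np.random.default_rng(2)
        coords = [(float(x), float(y)) for x, y in rng.uniform(-5, 5, (8, 2))]
        values = [float(v) for v in rng.uniform(1, 9, 8)]
        cfs = self.country_table(values)
        cents = self.centroids(coords)
        out = proxy_country(cfs, cents, "target")
        dists = sorted((np.hypot(x, y), f"c{i}") for i, (x, y) in enumerate(coords))
        expected = np.mean([values[int(c[1:])] for _d, c in dists[:3]])
        assert out["value"].iloc[0] == pytest.approx(expected)

    def test_fewer_than_three_warns_and_uses_all(self):
        cfs = self.country_table([1e-12, 3e-12])
        cents = self.centroids([(1, 0), (0, 1)])
        with pytest.warns(UserWarning):
            out = proxy_country(cfs, cents, "target")
        assert out["value"].iloc[0] == pytest.approx(2e-12)


class TestFillGaps:
    def test_native_rows_never_overwritten(self):
        cfs = pd.DataFrame([cf_row("e1", m="light", value=2e-12)])
        gaps = pd.DataFrame([
            {"ecoregion": "e1", "group": "plants", "land_use": "cropland",
             "intensity": "light"},  # already present natively
            {"ecoregion": "e1", "group": "plants", "land_use": "cropland",
             "intensity": "intense"},
        ])
        biomes = pd.DataFrame({"ecoregion": ["e1"], "biome": ["b"]})
        out = fill_gaps(cfs, gaps, TestProxyIntensity.affinity, biomes,
                        lambda g, e: 0.01)
        native = out[(out["intensity"] == "light")]
        assert len(native) == 1 and not native["proxy_flag"].iloc[0]
        proxied = out[(out["intensity"] == "intense")]
        assert len(proxied) == 1 and bool(proxied["proxy_flag"].iloc[0])
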