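import dataclasses

import numpy as np
import pandas as pd
import pytest

from richdet import synthetic as syn
from richdet.variables import REGION_TARGETS, VARIABLE_NAMES
from richdet.weights import build_distance_band_weights, morans_i


def _single_stratum(n, seed=0, **kw):
    stratum = syn.StratumSpec("QTR", (0.0, 1500.0, 0.0, 1500.0), 1.0, REGION_TARGETS["QTR"])
    return dataclasses.replace(
        syn.GeneratorConfig(),
        n_units=n,
        strata_layout=(stratum,),
        cross_correlations=(),
        seed=seed,
        **kw,
    )


class TestCounties:
    def test_area_moments_near_targets(self):
        cfg = dataclasses.replace(syn.GeneratorConfig(), n_units=2000, seed=5)
        c = syn.generate_counties(cfg)
        mean, sd = cfg.area_lognormal
        assert abs(c.area_km2.mean() - mean) / mean < 0.15
        assert abs(c.area_km2.std() - sd) / sd < 0.15

    def test_single_stratum_trivial(self):
        cfg = _single_stratum(10)
        c = syn.generate_counties(cfg)
        assert len(c) == 10
        assert set(c.stratum) == {"QTR"}

    def test_centroids_inside_extents(self):
        cfg = dataclasses.replace(syn.GeneratorConfig(), n_units=300, seed=2)
        c = syn.generate_counties(cfg)
        for spec in cfg.strata_layout:
            sub = c[c.stratum == spec.label]
            xmin, xmax, ymin, ymax = spec.extent
            assert sub.x_km.between(xmin, xmax).all()
            assert sub.y_km.between(ymin, ymax).all()

    def test_deterministic_under_seed(self):
        cfg = dataclasses.replace(syn.GeneratorConfig(), n_units=50, seed=9)
        a = syn.generate_counties(cfg)
        b = syn.generate_counties(cfg)
        pd.testing.assert_frame_equal(a, b)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            syn.generate_counties(dataclasses.replace(syn.GeneratorConfig(), n_units=5))
        bad = syn.StratumSpec("X", (10.0, 0.0, 0.0, 1.0), 1.0, {})
        with pytest.raises(ValueError):
            syn.generate_counties(
                dataclasses.replace(syn.GeneratorConfig(), strata_layout=(bad,))
            )
        with pytest.raises(ValueError):
            syn.generate_counties(
                dataclasses.replace(syn.GeneratorConfig(), beta_true={"no_such": 1.0})
            )


class TestEnvFields:
    def test_qtr_elevational_range_moments(self):
        cfg = _single_stratum(500, seed=4)
        c = syn.generate_counties(cfg)
        env = syn.generate_env_fields(c, cfg)
        vals = env.data["elevational_range"].to_numpy()
        assert abs(vals.mean() - 3060.8) / 3060.8 < 0.10
        assert abs(vals.std() - 1211.3) / 1211.3 < 0.10

    def test_nar_ndvi_precipitation_correlation(self, small_landscape):
        _, counties, _, env, _ = small_landscape
        mask = (counties.stratum == "NAR").to_numpy()
        r = np.corrcoef(
            env.data["ndvi"].to_numpy()[mask],
            env.data["mean_annual_precipitation"].to_numpy()[mask],
        )[0, 1]
        assert abs(r - 0.77) < 0.1

    def test_rho_zero_fields_pass_permutation_null(self):
        cfg = _single_stratum(120, seed=6, env_rho=0.0)
        c = syn.generate_counties(cfg)
        w = build_distance_band_weights(
            c[["x_km", "y_km"]].to_numpy(), cfg.spatial_range_km, ids=c["id"].to_numpy()
        )
        env = syn.generate_env_fields(c, cfg, w)
        _, p = morans_i(
            env.data["mean_annual_precipitation"].to_numpy(), w,
            permutations=999, seed=0,
        )
        assert p > 0.05

    def test_positive_spatial_rho_detected(self, small_landscape):
        _, counties, w, env, _ = small_landscape
        i, p = morans_i(env.data["mean_elevation"].to_numpy(), w, permutations=199, seed=0)
        assert i > 0 and p < 0.05

    def test_all_19_variables_with_tags(self, small_landscape):
        _, _, _, env, _ = small_landscape
        assert tuple(env.variables) == VARIABLE_NAMES
        assert set(env.categories.values()) == {
            "water_energy", "ambient_energy", "productivity", "stability", "heterogeneity",
        }

    def test_unknown_correlation_variable_rejected(self):
        with pytest.raises(ValueError):
            dataclasses.replace(
                syn.GeneratorConfig(),
                cross_correlations=(("nope", "ndvi", None, 0.5),),
            ).validate()

    def test_deterministic_under_seed(self):
        cfg = _single_stratum(60, seed=13)
        c = syn.generate_counties(cfg)
        a = syn.generate_env_fields(c, cfg)
        b = syn.generate_env_fields(c, cfg)
        pd.testing.assert_frame_equal(a.data, b.data)


class TestDerivedVariables:
    def test_dryness_is_map_over_pet(self, small_landscape):
        _, _, _, env, _ = small_landscape
        expected = (
            env.data["mean_annual_precipitation"] / env.data["annual_potential_evapotranspiration"]
        )
        pd.testing.assert_series_equal(
            env.data["mean_annual_dryness"], expected, check_names=False
        )

    @pytest.mark.parametrize(
        "map_val,pet,expected",
        [(921.3, 1055.8, 921.3 / 1055.8), (0.0, 500.0, 0.0), (700.0, 700.0, 1.0)],
    )
    def test_dryness_examples(self, map_val, pet, expected):
        df = pd.DataFrame(
            {
                "mean_annual_precipitation": [map_val],
                "annual_potential_evapotranspiration": [pet],
            },
            index=[0],
        )
        env = syn.EnvMatrix(
            df,
            {c: "water_energy" for c in df.columns},
            {c: "log10" for c in df.columns},
        )
        out = syn.derive_variables(env)
        assert out.data["mean_annual_dryness"].iloc[0] == pytest.approx(expected)
        # inputs untouched
        assert out.data["mean_annual_precipitation"].iloc[0] == map_val

    def test_nonpositive_pet_rejected(self):
        df = pd.DataFrame(
            {"mean_annual_precipitation": [10.0], "annual_potential_evapotranspiration": [0.0]}
        )
        env = syn.EnvMatrix(df, {c: "x" for c in df.columns}, {c: "none" for c in df.columns})
        with pytest.raises(ValueError, match="evapotranspiration"):
            syn.derive_variables(env)


class TestRichness:
    def test_noiseless_intercept_only_closed_form(self):
        cfg = _single_stratum(
            40, seed=1, beta_true={}, gamma_area=0.0, sigma=0.0, intercept=2.0
        )
        c = syn.generate_counties(cfg)
        w = build_distance_band_weights(
            c[["x_km", "y_km"]].to_numpy(), 200.0, ids=c["id"].to_numpy()
        )
        env = syn.generate_env_fields(c, cfg, w)
        r = syn.generate_richness(c, env, w, cfg)
        assert np.all(r == 100)

    def test_default_calibration_max_of_order_3e3(self):
        cfg = dataclasses.replace(syn.GeneratorConfig(), n_units=2376, seed=0)
        c = syn.generate_counties(cfg)
        w = build_distance_band_weights(
            c[["x_km", "y_km"]].to_numpy(), cfg.spatial_range_km, ids=c["id"].to_numpy()
        )
        env = syn.generate_env_fields(c, cfg, w)
        r = syn.generate_richness(c, env, w, cfg)
        assert 1000 < r.max() < 10000
        assert np.median(r) < r.max() / 3

    def test_breakpoint_roundtrip_with_splitline(self):
        from richdet.splitline import fit_split_line

        bp = syn.BreakpointSpec("elevational_range", 1900.0, 4e-4, 0.0)
        cfg = _single_stratum(
            300, seed=8, beta_true={"elevational_range": 0.0}, gamma_area=0.0,
            sigma=0.0, intercept=2.0, breakpoint=bp,
        )
        c = syn.generate_counties(cfg)
        w = build_distance_band_weights(
            c[["x_km", "y_km"]].to_numpy(), 200.0, ids=c["id"].to_numpy()
        )
        env = syn.generate_env_fields(c, cfg, w)
        r = syn.generate_richness(c, env, w, cfg)
        x = env.data["elevational_range"].to_numpy()
        fit = fit_split_line(x, np.log10(r), grid=np.arange(500.0, 5000.0, 50.0))
        # rounding to integer richness leaves ~1 grid step of slack
        assert abs(fit.breakpoint - 1900.0) <= 50.0
        assert abs(fit.post.slope) < 1e-5

    def test_nonstationary_lambda_rejected(self):
        with pytest.raises(ValueError):
            dataclasses.replace(syn.GeneratorConfig(), lambda_true=1.0).validate()


class TestDegradeSurvey:
    def test_zero_omission_identity(self):
        r = np.array([10, 200, 3000])
        obs, score = syn.degrade_survey(r, np.zeros(3), seed=0)
        assert np.array_equal(obs, r)
        assert np.all(score == 0)

    def test_binomial_moments(self):
        r = np.full(200, 1000)
        obs, score = syn.degrade_survey(r, np.full(200, 0.5), seed=1)
        sd = np.sqrt(1000 * 0.25)
        assert abs(obs.mean() - 500) < 3 * sd / np.sqrt(200)
        assert np.all(np.abs(obs - 500) < 6 * sd)

    def test_deterministic_and_validated(self):
        r = np.array([50, 60])
        a = syn.degrade_survey(r, np.array([0.3, 0.7]), seed=3)
        b = syn.degrade_survey(r, np.array([0.3, 0.7]), seed=3)
        assert np.array_equal(a[0], b[0])
        with pytest.raises(ValueError):
            syn.degrade_survey(r, np.array([0.5, 1.5]))


class TestZonal:
    def test_range_mean_majority_examples(self):
        raster = syn.PixelRaster(
            county_id=np.array([1, 1, 1, 2, 2, 2, 2]),
            elevation=np.array([100.0, 500.0, 2600.0, 1.0, 2.0, 3.0, 4.0]),
            land_cover=np.array([3, 3, 5, 1, 1, 2, 4]),
        )
        rng = syn.zonal_aggregate(raster, "range")
        assert rng.loc[1] == 2500.0
        mean = syn.zonal_aggregate(raster, "mean")
        assert mean.loc[2] == pytest.approx(2.5)
        maj = syn.zonal_aggregate(raster, "majority", field_name="land_cover")
        assert maj.loc[1] == 3 and maj.loc[2] == 1

    def test_missing_county_named_in_error(self):
        raster = syn.PixelRaster(
            county_id=np.array([1, 1]),
            elevation=np.array([5.0, 6.0]),
            land_cover=np.array([1, 1]),
        )
        with pytest.raises(ValueError, match="7"):
            syn.zonal_aggregate(raster, "mean", county_ids=np.array([1, 7]))

    def test_generated_raster_covers_every_county(self, small_landscape):
        cfg, counties, _, _, _ = small_landscape
        raster = syn.generate_pixel_raster(counties, cfg, pixel_km=100.0)
        assert np.all(raster.elevation >= 0)
        per_county = syn.zonal_aggregate(
            raster, "range", county_ids=counties["id"].to_numpy()
        )
        assert len(per_county) == len(counties)


class TestIO:
    def test_tables_roundtrip(self, tmp_path, small_landscape):
        _, counties, _, env, _ = small_landscape
        syn.write_county_table(counties, tmp_path / "c.tsv", seed=11)
        c2 = syn.read_county_table(tmp_path / "c.tsv")
        pd.testing.assert_frame_equal(counties, c2)
        syn.write_env_matrix(env, tmp_path / "e.tsv", seed=11)
        e2 = syn.read_env_matrix(tmp_path / "e.tsv")
        assert e2.categories == env.categories
        assert e2.transforms == env.transforms
        np.testing.assert_allclose(env.data.to_numpy(), e2.data.to_numpy(), rtol=1e-12)


class TestGeoJSON:
    def test_point_feature_collection(self, tmp_path, small_landscape):
        _, counties, _, _, _ = small_landscape
        path = tmp_path / "counties.geojson"
        syn.write_geojson(counties, path, seed=11)
        import json

        payload = json.loads(path.read_text())
        assert payload["type"] == "FeatureCollection"
        assert len(payload["features"]) == len(counties)
        first = payload["features"][0]
        assert first["geometry"]["type"] == "Point"
        assert set(first["properties"]) == {"id", "stratum", "area_km2"}
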