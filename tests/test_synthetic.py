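"""Generator ground truth, determinism, and physical-range invariants."""

import numpy as np
import pandas as pd
import pytest

from hydrotraits import optical
from hydrotraits.pressure_volume import closed_form_tlp
from hydrotraits.synthetic import (
    DAMAGE_METRICS,
    GeneratorConfig,
    SpeciesParams,
    gen_damage_survey,
    gen_embolism_campaign,
    gen_field_campaign,
    gen_image_stack,
    gen_precip,
    gen_pv_series,
    logistic_threshold,
    pv_forward,
)
from hydrotraits.vulnerability import px


class TestSpeciesParams:
    def test_rejects_nonnegative_steepness(self):
        with pytest.raises(ValueError, match="steepness"):
            SpeciesParams("x", a=0.5, b=-5.0, psi_osm_ft=1.0, eps=4.0)

    def test_rejects_rigidity_below_osmotic_potential(self):
        # eps <= psi_osm means turgor pressure never reaches zero: no TLP
        with pytest.raises(ValueError, match="turgor"):
            SpeciesParams("x", a=-2.0, b=-5.0, psi_osm_ft=3.0, eps=2.0)


class TestEmbolismThresholds:
    def test_median_threshold_is_p50(self):
        assert logistic_threshold(0.5, -2.23, -8.02) == pytest.approx(-8.02)

    def test_closed_form_inverse_matches_px(self, species):
        # u = 0.12 quantile threshold equals the P12 water potential
        p = species["Euclea"]
        psi_u = logistic_threshold(0.12, p.a, p.b)
        assert psi_u == pytest.approx(-7.1265, abs=1e-3)
        assert psi_u == pytest.approx(px(p.a, p.b, 12.0), abs=1e-12)

    def test_half_the_events_fall_above_p50(self, species, cfg):
        p = species["Schotia"]
        events, psych, meta = gen_embolism_campaign(p, cfg)
        psi_frame = np.interp(
            events["time_min"], psych["time_min"], psych["psi_mpa"]
        )
        frac = np.average(psi_frame >= p.b, weights=events["n_pixels"])
        # binomial error at n = 2000
        assert frac == pytest.approx(0.5, abs=3 * 0.5 / np.sqrt(cfg.n_pixels))

    def test_rejects_tiny_campaigns(self, species):
        with pytest.raises(ValueError, match="n_pixels"):
            gen_embolism_campaign(species["Euclea"], GeneratorConfig(n_pixels=5))

    def test_psychrometer_trace_is_monotone_negative(self, species, cfg):
        _, psych, _ = gen_embolism_campaign(species["Euclea"], cfg)
        psi = psych["psi_mpa"].to_numpy()
        assert (psi < 0).all()
        assert (np.diff(psi) < 0).all()


class TestImageStack:
    def test_constructed_events_round_trip_through_differencing(self):
        events = pd.DataFrame(
            {"frame_idx": [2, 4, 9], "time_min": [10.0, 20.0, 45.0], "n_pixels": [5, 5, 5]}
        )
        stack = gen_image_stack(events, frame_shape=(16, 16), n_frames=12)
        series = optical.diff_stack(stack, binarize_threshold=10)
        nz = series[series["changed_pixels"] > 0]
        assert dict(zip(nz["frame_idx"], nz["changed_pixels"])) == {2: 5, 4: 5, 9: 5}

    def test_no_events_means_identical_frames(self):
        events = pd.DataFrame({"frame_idx": [], "time_min": [], "n_pixels": []})
        stack = gen_image_stack(events, frame_shape=(8, 8), n_frames=4)
        assert optical.diff_stack(stack)["changed_pixels"].sum() == 0

    def test_overflowing_frame_area_rejected(self):
        events = pd.DataFrame({"frame_idx": [1], "time_min": [5.0], "n_pixels": [100]})
        with pytest.raises(ValueError, match="pixels"):
            gen_image_stack(events, frame_shape=(8, 8), n_frames=3)


class TestPVSeries:
    def test_full_turgor_water_potential_is_zero(self):
        assert pv_forward(1.0, 2.92, 12.43) == pytest.approx(0.0)

    @pytest.mark.parametrize(
        "name, expected_tlp",
        [("Euclea", -3.816), ("Boscia", -1.949)],
    )
    def test_ground_truth_tlp_matches_closed_form(self, species, cfg, name, expected_tlp):
        _, meta = gen_pv_series(species[name], cfg)
        assert meta["tlp_true"] == pytest.approx(expected_tlp, abs=1e-3)
        p = species[name]
        assert meta["tlp_true"] == closed_form_tlp(p.psi_osm_ft, p.eps)

    def test_at_least_three_points_beyond_turgor_loss(self, species, cfg):
        table, meta = gen_pv_series(species["Pappea"], cfg)
        beyond = (table["psi_mpa"] <= meta["tlp_true"] + 1e-12).sum()
        assert beyond >= 3


class TestFieldCampaign:
    def test_zero_sd_collapses_to_the_mean(self, cfg):
        p = SpeciesParams(
            "x", a=-2.0, b=-5.0, psi_osm_ft=1.0, eps=4.0,
            psi_min_by_period={"dry": (-4.2, 0.0)},
        )
        field = gen_field_campaign([p], ["dry"], cfg)
        assert (field["psi_md_mpa"] == -4.2).all()

    def test_large_sample_mean_recovers_the_target(self):
        p = SpeciesParams(
            "x", a=-2.0, b=-5.0, psi_osm_ft=1.0, eps=4.0,
            psi_min_by_period={"dry": (-5.33, 0.5)},
        )
        field = gen_field_campaign(
            [p], ["dry"], GeneratorConfig(seed=0, n_individuals=10_000)
        )
        assert field["psi_md_mpa"].mean() == pytest.approx(-5.33, abs=0.02)

    def test_period_labels_preserved_and_psi_negative(self, species, cfg):
        field = gen_field_campaign(
            list(species.values()), ["2020-dry", "2022-wet"], cfg
        )
        assert set(field["period"]) == {"2020-dry", "2022-wet"}
        assert (field["psi_md_mpa"] < 0).all()


class TestDamageSurvey:
    def test_intercept_only_model_gives_constant_metric(self, cfg):
        traits = pd.DataFrame({"species": ["a", "b"], "p50": [-5.0, -8.0]})
        coefs = {"crown_extent": {"intercept": np.log(50.0)}}
        out = gen_damage_survey(traits, coefs, noise_sd=0.0, cfg=cfg)
        assert out["crown_extent"].tolist() == pytest.approx([50.0, 50.0])

    def test_expected_values_above_100_are_clipped(self, cfg):
        traits = pd.DataFrame({"species": ["a"], "p50": [-5.0]})
        coefs = {"foliage": {"intercept": np.log(140.0)}}
        out = gen_damage_survey(traits, coefs, noise_sd=0.0, cfg=cfg)
        assert out["foliage"].iloc[0] == pytest.approx(100.0)

    def test_unknown_trait_lists_available_columns(self, cfg):
        traits = pd.DataFrame({"species": ["a"], "p50": [-5.0]})
        with pytest.raises(KeyError, match="p50"):
            gen_damage_survey(
                traits, {"foliage": {"intercept": 1.0, "nope": 2.0}}, 0.0, cfg
            )

    def test_metrics_stay_in_percent_range_under_noise(self, cfg, species):
        traits = pd.DataFrame(
            {"species": [p.name for p in species.values()],
             "p50": [p.b for p in species.values()]}
        )
        coefs = {m: {"intercept": 4.6, "p50": -0.02} for m in DAMAGE_METRICS}
        out = gen_damage_survey(traits, coefs, noise_sd=20.0, cfg=cfg)
        for m in DAMAGE_METRICS:
            assert out[m].between(0, 100).all()


class TestPrecip:
    def test_zero_scale_gives_dry_series(self):
        out = gen_precip(GeneratorConfig(seed=0, n_years=3, gamma_scale=0.0))
        assert (out["mm"] == 0).all()

    def test_gamma_mean_recovered(self):
        out = gen_precip(
            GeneratorConfig(seed=1, n_years=100, gamma_shape=2.0, gamma_scale=50.0)
        )
        assert out["mm"].mean() == pytest.approx(100.0, abs=3.0)

    def test_drought_block_sums_rank_in_lower_tail(self):
        cfg = GeneratorConfig(seed=2, n_years=40)
        start = 12 * 35
        out = gen_precip(cfg, drought_block=(start, 12), drought_factor=0.3)
        annual = out.groupby("year")["mm"].sum()
        drought_year = out["year"].iloc[start]
        assert annual.rank()[drought_year] <= 3


class TestDeterminism:
    def test_identical_config_gives_identical_outputs(self, species):
        p = species["Polygala"]
        for gen in (
            lambda c: gen_embolism_campaign(p, c)[0],
            lambda c: gen_pv_series(p, c)[0],
            lambda c: gen_field_campaign([p], ["2020-dry"], c),
            lambda c: gen_precip(c),
        ):
            a = gen(GeneratorConfig(seed=11))
            b = gen(GeneratorConfig(seed=11))
            pd.testing.assert_frame_equal(a, b)
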