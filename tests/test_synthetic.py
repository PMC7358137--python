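import numpy as np
import pandas as pd
import pytest

from simap import liquid as lq
from simap import pipeline, plates, synthetic
from simap.errors import ConfigurationError
from simap.synthetic import (SentinelProfile, SimulationConfig,
                             generate_variant_panel, simulate_calibration_series,
                             simulate_growth_curves, simulate_miniarray,
                             simulate_sdl_screen)


class TestVariantPanel:
    def test_degenerate_mix_all_wtlike(self):
        panel = generate_variant_panel(4, {"wtlike": 1.0}, threshold_path=0.5)
        variants = [v for v in panel if v.variant_id not in ("wt", "vector")]
        assert all(v.f == 1.0 and not v.pathogenic for v in variants)

    def test_same_seed_identical(self):
        mix = {"lof": 0.25, "partial": 0.25, "wtlike": 0.25, "gof": 0.25}
        assert generate_variant_panel(50, mix, seed=7) == \
            generate_variant_panel(50, mix, seed=7)

    def test_pathogenic_fraction_matches_closed_form(self):
        """lof (f=0) always pathogenic; partial (f~U(0,1)) pathogenic w.p. 0.5
        at threshold 0.5 -> expected fraction 0.25 + 0.25*0.5 = 0.375."""
        mix = {"lof": 0.25, "partial": 0.25, "wtlike": 0.25, "gof": 0.25}
        panel = generate_variant_panel(1000, mix, threshold_path=0.5, seed=3)
        variants = [v for v in panel if v.variant_id not in ("wt", "vector")]
        frac = np.mean([v.pathogenic for v in variants])
        # 4 sigma binomial tolerance at n=1000
        assert abs(frac - 0.375) < 4 * np.sqrt(0.375 * 0.625 / 1000)

    def test_reserved_records_appended(self):
        panel = generate_variant_panel(2, {"wtlike": 1.0})
        by_id = {v.variant_id: v for v in panel}
        assert by_id["wt"].f == 1.0 and by_id["vector"].f == 0.0

    def test_invalid_fractions_name_the_field(self):
        with pytest.raises(ConfigurationError, match="mix"):
            generate_variant_panel(5, {"wtlike": 0.7, "lof": 0.7})

    def test_label_noise_flips_labels(self):
        mix = {"lof": 0.5, "wtlike": 0.5}
        panel = generate_variant_panel(400, mix, label_noise=0.2, seed=9)
        variants = [v for v in panel if v.variant_id not in ("wt", "vector")]
        flips = np.mean([v.pathogenic != v.label_observed for v in variants])
        assert abs(flips - 0.2) < 4 * np.sqrt(0.2 * 0.8 / 400)


class TestSdlSimulation:
    def test_noiseless_planted_ratio(self, noiseless_cfg):
        screen = simulate_sdl_screen(40, 5, defect_range=(0.5, 0.5), cfg=noiseless_cfg)
        truth = screen.truth.set_index("strain_id")
        merged = screen.strain_map.merge(screen.plus_tables[0],
                                         left_on=["row", "col"], right_on=["row", "col"])
        areas_plus = merged.set_index("strain_id")["area_px"]
        areas_minus = screen.strain_map.merge(
            screen.minus_tables[0], on=["row", "col"]).set_index("strain_id")["area_px"]
        ratio = areas_plus / areas_minus
        sensitive = truth[truth["sensitive"]].index
        assert np.allclose(ratio[sensitive], 0.5)
        assert np.allclose(ratio.drop(sensitive), 1.0)

    def test_no_planted_strains_all_unity(self, noiseless_cfg):
        screen = simulate_sdl_screen(30, 0, cfg=noiseless_cfg)
        assert (screen.truth["delta"] == 0).all()

    def test_too_many_sensitive_rejected(self):
        with pytest.raises(ConfigurationError):
            simulate_sdl_screen(10, 11)

    def test_replicate_count(self, noiseless_cfg):
        screen = simulate_sdl_screen(20, 2, replicates_per_screen=3, screens=2,
                                     cfg=noiseless_cfg)
        assert len(screen.plus_tables) == len(screen.minus_tables) == 6


class TestMiniarraySimulation:
    def _layout(self):
        return plates.build_layout_mi2([f"s{i}" for i in range(8)],
                                       [f"v{i}" for i in range(7)])

    def test_noiseless_expected_areas(self, noiseless_cfg):
        lay = self._layout()
        sentinels = {f"s{i}": SentinelProfile(f"s{i}", base_area=100.0, d=0.5)
                     for i in range(8)}
        panel = [synthetic.VariantTruth(f"v{i}", 1.0, False, False) for i in range(7)]
        table = simulate_miniarray(lay, panel, sentinels, noiseless_cfg)
        merged = lay.to_frame().merge(table, on=["plate_id", "row", "col"])
        # wt-like query (f=1): variant area = 0.5*base = paired wt-control area
        assert np.allclose(merged.loc[merged["role"] == "variant", "area_px"], 50.0)
        assert np.allclose(merged.loc[merged["role"] == "wt_control", "area_px"], 50.0)
        # vector (f=0): full base area
        assert np.allclose(merged.loc[merged["role"] == "vector_control", "area_px"], 100.0)

    def test_unknown_strain_rejected(self, noiseless_cfg):
        lay = self._layout()
        with pytest.raises(synthetic.LayoutError):
            simulate_miniarray(lay, [], {"s0": SentinelProfile("s0")}, noiseless_cfg)

    def test_partial_function_scorer_closure(self, noiseless_cfg):
        """f=0.25 with d=0.5 must come back from the scorer as lof=0.75."""
        lay = plates.build_layout_mi2([f"s{i}" for i in range(8)],
                                      ["vq"] + [f"pad{i}" for i in range(6)])
        sentinels = {f"s{i}": SentinelProfile(f"s{i}", d=0.5) for i in range(8)}
        panel = [synthetic.VariantTruth("vq", 0.25, True, True)] + \
                [synthetic.VariantTruth(f"pad{i}", 1.0, False, False) for i in range(6)]
        table = simulate_miniarray(lay, panel, sentinels, noiseless_cfg)
        scores = pipeline.run_miniarray(table, [lay])
        vq = scores[scores["variant_id"] == "vq"]
        assert np.allclose(vq["lof"], 0.75, atol=1e-9)


class TestCalibrationSeries:
    def test_identity_calibration(self):
        table = simulate_calibration_series([0.1, 0.5, 1.0], (0, 0, 1, 0))
        assert np.allclose(table["a600"], table["relative_cells"])

    def test_noiseless_round_trip(self):
        coeffs = (0.5, 0.2, 1.0, 0.0)
        counts = np.linspace(0.05, 5.0, 12)
        table = simulate_calibration_series(counts, coeffs, sigma=0.0)
        back = lq.evaluate_cubic(coeffs, table["a600"].to_numpy())
        assert np.allclose(back, counts, rtol=1e-9)

    def test_inversion_matches_grid_search(self):
        coeffs, y = (0.5, 0.2, 1.0, 0.0), 1.7
        x = float(lq.invert_cubic(coeffs, y)[0])
        grid = np.linspace(0.0, 3.0, 3_000_001)
        brute = grid[np.argmin(np.abs(lq.evaluate_cubic(coeffs, grid) - y))]
        assert abs(x - brute) < 1e-6

    def test_non_monotone_rejected_naming_range(self):
        with pytest.raises(ConfigurationError, match="increasing"):
            simulate_calibration_series([1.0], (-1.0, 0.0, 0.5, 0.0))


class TestGrowthCurves:
    def test_rate_ratio_equals_one_minus_r(self, noiseless_cfg):
        sent = SentinelProfile("s", k0=0.5, r=0.4)
        panel = [synthetic.VariantTruth("full", 1.0, False, False),
                 synthetic.VariantTruth("none", 0.0, True, True)]
        curves = simulate_growth_curves(panel, sent, noiseless_cfg,
                                        wells_per_variant=1)
        model = lq.CalibrationModel(noiseless_cfg.calib_coeffs, (0.0, 2.0))
        ks = {}
        for vid, grp in curves.groupby("variant_id"):
            y = lq.apply_calibration(model, grp["a600"].to_numpy())
            ks[vid] = lq.fit_exponential(grp["time_min"], y / y[0]).k
        assert ks["full"] / ks["none"] == pytest.approx(1 - 0.4, abs=1e-9)

    def test_f_zero_matches_vector_control(self, noiseless_cfg):
        sent = SentinelProfile("s")
        panel = [synthetic.VariantTruth("dead", 0.0, True, True),
                 synthetic.VariantTruth("vector", 0.0, True, True)]
        curves = simulate_growth_curves(panel, sent, noiseless_cfg, wells_per_variant=1)
        wide = curves.pivot_table(index="time_min", columns="variant_id", values="a600")
        assert np.allclose(wide["dead"], wide["vector"])

    def test_same_seed_identical_matrix(self):
        cfg = SimulationConfig(seed=11)
        sent = SentinelProfile("s")
        panel = [synthetic.VariantTruth("v", 0.5, True, True)]
        a = simulate_growth_curves(panel, sent, cfg, wells_per_variant=8)
        b = simulate_growth_curves(panel, sent, cfg, wells_per_variant=8)
        pd.testing.assert_frame_equal(a, b)

    def test_timestamps_every_four_minutes(self, noiseless_cfg):
        curves = simulate_growth_curves(
            [synthetic.VariantTruth("v", 1.0, False, False)],
            SentinelProfile("s"), noiseless_cfg, wells_per_variant=1)
        assert np.allclose(np.diff(curves["time_min"]), 4.0)
        assert curves["time_min"].iloc[0] == 0.0

    @pytest.mark.parametrize("kwargs", [{"interval_min": 0}, {"duration_h": -1}])
    def test_invalid_grid_rejected(self, noiseless_cfg, kwargs):
        with pytest.raises(ConfigurationError):
            simulate_growth_curves([synthetic.VariantTruth("v", 1.0, False, False)],
                                   SentinelProfile("s"), noiseless_cfg, **kwargs)


class TestDeterminism:
    def test_full_study_byte_identical(self, tmp_path):
        cfg = SimulationConfig(seed=13, n_variants=8)
        for sub in ("a", "b"):
            pipeline.write_study(pipeline.simulate_study(cfg), tmp_path / sub)
        for name in ("truth.tsv", "miniarray_spots.tsv", "growth_curves.tsv",
                     "calibration.tsv"):
            assert (tmp_path / "a" / name).read_bytes() == \
                (tmp_path / "b" / name).read_bytes()
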