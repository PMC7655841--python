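"""Micro-pillar compression reduction: normalization, fits, detections."""

import numpy as np
import pandas as pd
import pytest

from calcmech import (
    PillarGeometry,
    compute_max_strength,
    detect_strain_burst,
    detect_yield,
    fit_modulus,
    normalize_curve,
    reduce_curve,
    summarize_cohort,
)
from calcmech.compression import load_geometry, load_record

from conftest import curve_from_stress


def record(force_mn, depth_nm):
    return pd.DataFrame({"force_mN": force_mn, "depth_nm": depth_nm})


class TestNormalization:
    def test_zero_force_gives_zero_stress_and_zero_depth_zero_strain(self):
        geom = PillarGeometry(2.0, 2.5, 6.0)
        curve = normalize_curve(record([0.0, 1.0], [0.0, 50.0]), geom)
        assert curve.stress_gpa[0] == 0.0
        assert curve.strain[0] == 0.0

    def test_taper_corrected_stress_value(self):
        # hand evaluation of the two-term coefficient:
        # 4/(pi*2*2.5) + 0.91/(2.5*6) = 0.254648 + 0.060667 GPa/mN
        geom = PillarGeometry(2.0, 2.5, 6.0, poisson_ratio=0.3)
        curve = normalize_curve(record([1.0], [0.0]), geom)
        assert curve.stress_gpa[0] == pytest.approx(0.315315, rel=1e-5)

    def test_strain_is_depth_over_height(self):
        geom = PillarGeometry(2.0, 2.5, 6.0)
        curve = normalize_curve(record([1.0], [600.0]), geom)  # 600 nm / 6 um
        assert curve.strain[0] == pytest.approx(0.1, rel=1e-12)

    def test_default_poisson_ratio_is_calcite_average(self):
        assert PillarGeometry(2.0, 2.5, 6.0).poisson_ratio == 0.3

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(top_diameter_um=-1.0, bottom_diameter_um=2.0, height_um=6.0),
            dict(top_diameter_um=2.0, bottom_diameter_um=1.5, height_um=6.0),
            dict(top_diameter_um=2.0, bottom_diameter_um=2.5, height_um=0.0),
            dict(top_diameter_um=2.0, bottom_diameter_um=2.5, height_um=6.0, poisson_ratio=0.6),
            dict(top_diameter_um=2.0, bottom_diameter_um=2.5, height_um=6.0, taper_deg=10.0),
        ],
    )
    def test_invalid_geometry_rejected(self, kwargs):
        with pytest.raises(ValueError):
            PillarGeometry(**kwargs)

    def test_mismatched_series_lengths_rejected(self):
        geom = PillarGeometry(2.0, 2.5, 6.0)
        with pytest.raises(ValueError):
            normalize_curve(
                pd.DataFrame({"force_mN": [1.0, 2.0], "depth_nm": [1.0]}), geom
            )

    def test_tall_pillar_limit_drops_substrate_term(self):
        # as h -> infinity the coefficient tends to 4 F / (pi D1 D2)
        geom = PillarGeometry(2.0, 2.5, 1e6)
        curve = normalize_curve(record([1.0], [0.0]), geom)
        limit = 4.0 / (np.pi * 2.0 * 2.5)  # GPa/mN in um units
        assert curve.stress_gpa[0] == pytest.approx(limit, rel=1e-4)

    def test_untapered_pillar_by_direct_substitution(self):
        d, h, nu, f = 2.0, 6.0, 0.3, 1.5
        geom = PillarGeometry(d, d, h, poisson_ratio=nu)
        curve = normalize_curve(record([f], [0.0]), geom)
        expected = (4.0 / (np.pi * d**2) + (1.0 - nu**2) / (d * h)) * f
        assert curve.stress_gpa[0] == pytest.approx(expected, rel=1e-12)


class TestModulus:
    def test_exactly_linear_curve(self, geometry):
        strain = np.linspace(0.0, 0.03, 200)
        curve = curve_from_stress(strain, 40.0 * strain, geometry)
        fit = fit_modulus(curve)
        assert fit.modulus_gpa == pytest.approx(40.0, rel=1e-9)
        assert fit.r_squared == pytest.approx(1.0)

    def test_bilinear_curve_window_excludes_post_knee(self, geometry):
        strain = np.arange(0.0, 0.05, 1e-4)
        knee = 0.02
        stress = np.where(strain <= knee, 40.0 * strain, 40.0 * knee + 10.0 * (strain - knee))
        curve = curve_from_stress(strain, stress, geometry)
        fit = fit_modulus(curve)
        assert fit.modulus_gpa == pytest.approx(40.0, rel=1e-6)

    def test_noisy_linear_recovery_within_one_percent(self, geometry):
        rng = np.random.default_rng(0)
        strain = np.arange(0.0, 0.03, 1e-4)
        stress = 34.4 * strain + rng.normal(0.0, 0.005, strain.size)
        curve = curve_from_stress(strain, np.clip(stress, 0, None), geometry)
        assert fit_modulus(curve).modulus_gpa == pytest.approx(34.4, rel=0.01)

    def test_insufficient_points_error(self, geometry):
        curve = curve_from_stress([0.0, 0.01], [0.0, 0.4], geometry)
        with pytest.raises(ValueError, match="fewer than 3"):
            fit_modulus(curve)


class TestYield:
    def test_purely_elastic_curve_flags_no_yield(self, geometry):
        strain = np.linspace(0.0, 0.03, 300)
        curve = curve_from_stress(strain, 40.0 * strain, geometry)
        assert not detect_yield(curve, 40.0).detected

    def test_top_section_yield_stress_arithmetic(self):
        # sigma_Y = 4 F_Y / (pi D1^2) with F_Y = 3.644 mN, D1 = 2 um
        geom = PillarGeometry(2.0, 2.5, 6.0)
        assert 3.644 * geom.yield_stress_coefficient_gpa_per_mn == pytest.approx(
            1.15992, rel=1e-4
        )

    def test_bilinear_knee_detected_within_one_step(self, geometry):
        step = 1e-4
        strain = np.arange(0.0, 0.06, step)
        knee = 0.0337
        stress = np.where(strain <= knee, 34.4 * strain, 34.4 * knee + 4.0 * (strain - knee))
        curve = curve_from_stress(strain, stress, geometry)
        res = detect_yield(curve, 34.4)
        assert res.detected
        assert abs(res.elastic_limit - knee) <= 2 * step

    def test_vanishing_tolerance_matches_brute_force_scan(self, geometry):
        step = 1e-4
        strain = np.arange(0.0, 0.06, step)
        knee = 0.02
        stress = np.where(strain <= knee, 40.0 * strain, 40.0 * knee + 5.0 * (strain - knee))
        curve = curve_from_stress(strain, stress, geometry)
        tol = 1e-9
        res = detect_yield(curve, 40.0, offset_tolerance=tol)
        # oracle: scan every point for the first relative deviation > tol
        dev = (40.0 * strain - stress) / np.maximum(40.0 * strain, 0.5 * stress.max())
        first = int(np.flatnonzero(dev > tol)[0])
        assert res.detected
        assert abs(res.elastic_limit - strain[first - 1]) <= 2 * step
        assert abs(res.elastic_limit - knee) <= 2 * step


class TestMaxStrength:
    def test_top_section_max_stress_arithmetic(self):
        geom = PillarGeometry(2.0, 2.5, 6.0)
        assert 4.15 * geom.yield_stress_coefficient_gpa_per_mn == pytest.approx(
            1.32097, rel=1e-4
        )

    def test_hardening_curve_max_exceeds_yield(self, geometry):
        strain = np.arange(0.0, 0.06, 1e-4)
        stress = np.where(strain <= 0.03, 40.0 * strain, 1.2 + 5.0 * (strain - 0.03))
        curve = curve_from_stress(strain, stress, geometry)
        yld = detect_yield(curve, 40.0)
        mx = compute_max_strength(curve)
        assert mx.max_strength_gpa >= yld.yield_strength_gpa

    def test_programmed_fracture_strain_recovered(self, geometry):
        step = 1e-4
        eps_f = 0.074
        strain = np.arange(0.0, eps_f + step / 2, step)
        stress = 17.8 * strain  # rises to ~1.32
        strain = np.append(strain, strain[-1] + step)
        stress = np.append(stress, 0.01)  # abrupt terminal collapse
        curve = curve_from_stress(strain, stress, geometry)
        mx = compute_max_strength(curve)
        assert mx.failure_detected
        assert abs(mx.failure_strain - eps_f) <= 2 * step

    def test_no_terminal_drop_flagged(self, geometry):
        strain = np.linspace(0.0, 0.03, 200)
        curve = curve_from_stress(strain, 40.0 * strain, geometry)
        mx = compute_max_strength(curve)
        assert not mx.failure_detected
        assert mx.failure_strain is None


class TestBurst:
    def test_hardening_curve_has_no_burst(self, geometry):
        strain = np.arange(0.0, 0.05, 1e-4)
        stress = np.where(strain <= 0.03, 40.0 * strain, 1.2 + 5.0 * (strain - 0.03))
        curve = curve_from_stress(strain, stress, geometry)
        assert not detect_strain_burst(curve, 40.0).detected

    def test_programmed_jump_size_recovered(self, geometry):
        step = 1e-4
        pre = np.arange(0.0, 0.02, step)
        post = np.arange(0.02 + 0.01, 0.05, step)  # one-step jump of 0.01
        strain = np.concatenate([pre, post])
        stress = np.concatenate([48.0 * pre, np.full(post.size, 0.47)])
        curve = curve_from_stress(strain, stress, geometry)
        res = detect_strain_burst(curve, 48.0)
        assert res.detected
        assert res.burst_strain == pytest.approx(0.01, abs=2 * step)
        assert res.flow_strength_gpa == pytest.approx(0.47, rel=1e-6)


class TestCohort:
    def _summary(self, label, sigma_y, modulus=34.4):
        from calcmech import MechanicalSummary

        return MechanicalSummary(
            modulus_gpa=modulus,
            yield_strength_gpa=sigma_y,
            max_strength_gpa=sigma_y + 0.1,
            elastic_limit=sigma_y / modulus,
            failure_strain=0.07,
            label=label,
        )

    def test_identical_values_have_zero_sd(self):
        stats, _ = summarize_cohort([self._summary("a", 1.0), self._summary("a", 1.0)])
        sd = stats.loc[stats["property"] == "yield_strength_gpa", "sd"].item()
        assert sd == 0.0

    def test_equal_group_means_give_zero_t(self):
        group_a = [self._summary("a", 1.0), self._summary("a", 1.2)]
        group_b = [self._summary("b", 1.2), self._summary("b", 1.0)]
        _, tests = summarize_cohort(group_a + group_b)
        t = tests.loc[tests["property"] == "yield_strength_gpa", "t"].item()
        assert t == pytest.approx(0.0, abs=1e-12)

    def test_single_observation_flagged_nan_sd(self):
        stats, _ = summarize_cohort([self._summary("a", 1.0)])
        assert stats["sd"].isna().all()

    def test_biogenic_cohort_stronger_than_geological(self, geometry):
        from calcmech import draw_cohort_spec, generate_curve

        rng = np.random.default_rng(10)
        summaries = []
        for material, n in (("biogenic", 12), ("geological", 12)):
            for _ in range(n):
                spec = draw_cohort_spec(material, rng)
                summaries.append(
                    reduce_curve(generate_curve(spec, geometry), geometry, label=material)
                )
        stats, _ = summarize_cohort(summaries)
        sy = stats[stats["property"] == "yield_strength_gpa"].set_index("group")["mean"]
        assert sy["biogenic"] > sy["geological"]


class TestRoundTrip:
    def test_noise_free_generation_reduction_recovers_parameters(self, geometry):
        """100 random biogenic parameter draws, noise-free, each within 2%."""
        from dataclasses import replace

        from calcmech import draw_cohort_spec, generate_curve

        rng = np.random.default_rng(42)
        for _ in range(100):
            spec = replace(draw_cohort_spec("biogenic", rng), noise_sd_gpa=0.0)
            out = reduce_curve(generate_curve(spec, geometry), geometry)
            assert out.modulus_gpa == pytest.approx(spec.modulus_gpa, rel=0.02)
            assert out.yield_strength_gpa == pytest.approx(spec.yield_strength_gpa, rel=0.02)
            assert out.max_strength_gpa == pytest.approx(spec.max_strength_gpa, rel=0.02)
            assert out.elastic_limit == pytest.approx(spec.elastic_limit, rel=0.02)
            assert out.failure_strain == pytest.approx(spec.failure_strain, rel=0.02)


class TestIO:
    def test_record_and_geometry_round_trip(self, tmp_path):
        rec = pd.DataFrame(
            {"time_s": [0.0, 1.0], "force_mN": [0.0, 1.0], "depth_nm": [0.0, 10.0]}
        )
        p = tmp_path / "curve.csv"
        rec.to_csv(p, index=False)
        loaded = load_record(p)
        assert list(loaded.columns) == ["time_s", "force_mN", "depth_nm"]

        g = tmp_path / "geom.txt"
        g.write_text("D1_um = 2.0\nD2_um = 2.524\nh_um = 6.0\ntaper_deg = 2.5\npoisson = 0.3\n")
        geom = load_geometry(g)
        assert geom.top_diameter_um == 2.0
        assert geom.taper_deg == 2.5

    def test_missing_columns_rejected(self, tmp_path):
        p = tmp_path / "bad.csv"
        pd.DataFrame({"force_mN": [1.0]}).to_csv(p, index=False)
        with pytest.raises(ValueError, match="depth_nm"):
            load_record(p)
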