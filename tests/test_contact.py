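"""Contact-mechanics force laws, contact detection and modulus extraction."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from nanomech import (
    CantileverCalibration,
    PoorFitError,
    RawForceCurve,
    SampleClassSettings,
    build_indentation,
    correct_baseline,
    find_contact_point,
    fit_modulus,
    hertz_force,
    sneddon_force,
)
from nanomech import IndentationModel
from nanomech import synthetic as syn
from nanomech.contact import _contact_objective


class TestForceLaws:
    def test_sneddon_reference_value(self):
        # independent evaluation: (2/pi)*1000/0.91*tan(20 deg)*(1e-6)^2
        assert sneddon_force(1000.0, 0.3, 20.0, 1e-6) == pytest.approx(
            2.546270853704671e-10, rel=1e-12
        )

    def test_hertz_reference_value(self):
        # (4/3)*1000/0.91*sqrt(5e-7)*(1e-7)^1.5
        assert hertz_force(1000.0, 0.3, 500e-9, 100e-9) == pytest.approx(
            3.27629007692277e-11, rel=1e-12
        )

    def test_zero_indentation_zero_force(self):
        assert sneddon_force(1e3, 0.3, 18.0, 0.0) == 0.0
        assert hertz_force(1e3, 0.3, 500e-9, 0.0) == 0.0

    def test_negative_indentation_rejected(self):
        with pytest.raises(ValueError):
            sneddon_force(1e3, 0.3, 18.0, -1e-9)
        with pytest.raises(ValueError):
            hertz_force(1e3, 0.3, 500e-9, -1e-9)

    @given(
        e=st.floats(min_value=10.0, max_value=1e8),
        nu=st.floats(min_value=0.0, max_value=0.49),
        delta=st.floats(min_value=1e-9, max_value=5e-6),
    )
    def test_linearity_in_modulus(self, e, nu, delta):
        assert sneddon_force(2 * e, nu, 18.0, delta) == pytest.approx(
            2 * sneddon_force(e, nu, 18.0, delta), rel=1e-12
        )
        assert hertz_force(2 * e, nu, 500e-9, delta) == pytest.approx(
            2 * hertz_force(e, nu, 500e-9, delta), rel=1e-12
        )

    @given(delta=st.floats(min_value=1e-9, max_value=2e-6))
    def test_hertz_power_law(self, delta):
        ratio = hertz_force(1e3, 0.3, 500e-9, 2 * delta) / hertz_force(
            1e3, 0.3, 500e-9, delta
        )
        assert ratio == pytest.approx(2**1.5, rel=1e-9)

    def test_closed_forms_match_independent_sweep(self):
        """1,000-point parameter sweep against per-point math evaluation."""
        rng = np.random.default_rng(12)
        for _ in range(1000):
            e = 10 ** rng.uniform(1, 8)
            nu = rng.uniform(0.0, 0.49)
            delta = 10 ** rng.uniform(-9, -5.3)
            alpha = rng.uniform(5.0, 45.0)
            radius = 10 ** rng.uniform(-8, -6)
            expect_s = (
                (2.0 / math.pi)
                * e
                / (1.0 - nu * nu)
                * math.tan(math.radians(alpha))
                * delta
                * delta
            )
            expect_h = (
                (4.0 / 3.0) * e / (1.0 - nu * nu) * math.sqrt(radius) * delta**1.5
            )
            assert sneddon_force(e, nu, alpha, delta) == pytest.approx(
                expect_s, rel=1e-12
            )
            assert hertz_force(e, nu, radius, delta) == pytest.approx(
                expect_h, rel=1e-12
            )

    def test_prefactor_switch_scales_by_pi_squared(self):
        canonical = sneddon_force(1e3, 0.3, 18.0, 1e-6)
        literal = sneddon_force(1e3, 0.3, 18.0, 1e-6, prefactor_two_pi=True)
        assert literal / canonical == pytest.approx(math.pi**2, rel=1e-12)


class TestBaselineCorrection:
    def test_tilt_removed(self, cell_settings):
        curve = syn.simulate_curve(
            4e3, cell_settings, baseline_slope_n_per_m=1e-10, contact_index=700
        )
        corrected = correct_baseline(curve, 0.3)
        force_pre = 0.4 * corrected.deflection_m()[:600]
        assert abs(force_pre.mean()) < 1e-16
        slope = np.polyfit(corrected.z_m[:600], force_pre, 1)[0]
        assert abs(slope) < 1e-12  # N per m, vs the injected 1e-10

    def test_flat_curve_unchanged(self, noiseless_cell_curve):
        corrected = correct_baseline(noiseless_cell_curve, 0.25)
        np.testing.assert_allclose(
            corrected.deflection_m(),
            noiseless_cell_curve.deflection_m(),
            atol=1e-15,
        )

    def test_pure_noise_zero_mean(self, cell_settings):
        rng = np.random.default_rng(5)
        curve = syn.simulate_curve(4e3, cell_settings, contact_index=700)
        curve = curve.with_deflection_m(rng.normal(0, 1e-9, curve.n_samples))
        corrected = correct_baseline(curve, 0.5)
        n = curve.n_samples // 2
        assert abs(corrected.deflection_m()[:n].mean()) < 1e-10


class TestContactPoint:
    def test_noiseless_exact(self, cell_settings):
        curve = syn.simulate_curve(10e3, cell_settings, contact_index=700)
        corrected = correct_baseline(curve, 0.3)
        j = find_contact_point(corrected, curve.tip, cell_settings)
        assert abs(j - 700) <= 1

    def test_noisy_localization(self, cell_settings):
        """At 2% force noise the detected contact stays near the truth.

        The piezo step here is ~1.6 nm, so sample-index precision is limited
        by the noise floor around the gentle quadratic onset; the detected
        index lands within a couple of tens of samples (a few nm of z).
        """
        curve = syn.simulate_curve(
            10e3, cell_settings, noise_force_frac=0.02, seed=3, contact_index=700
        )
        corrected = correct_baseline(curve, 0.3)
        j = find_contact_point(corrected, curve.tip, cell_settings)
        assert abs(j - 700) <= 16

    def test_all_zero_curve_poor_fit(self, cell_settings, noiseless_cell_curve):
        flat = noiseless_cell_curve.with_deflection_m(
            np.zeros(noiseless_cell_curve.n_samples)
        )
        with pytest.raises(PoorFitError):
            find_contact_point(flat, flat.tip, cell_settings)

    def test_exhaustive_search_equivalence(self, cell_settings):
        """Coarse-to-fine index search equals brute-force enumeration.

        100 random 64-sample instances; the oracle evaluates every candidate
        index with the same closed-form per-index modulus.
        """
        rng = np.random.default_rng(99)
        for _ in range(100):
            e_true = 10 ** rng.uniform(3, 4.5)
            ci = int(rng.integers(10, 40))
            curve = syn.simulate_curve(
                e_true,
                cell_settings,
                noise_force_frac=0.01,
                seed=int(rng.integers(0, 2**31)),
                contact_index=ci,
                n_samples=64,
            )
            corrected = correct_baseline(curve, max(0.1, 0.8 * ci / 64))
            j = find_contact_point(corrected, curve.tip, cell_settings)
            d = corrected.deflection_m()
            z = corrected.z_m
            force = 0.4 * d
            best_ss, best_j = np.inf, None
            for jj in range(2, 64 - 10):
                ss, _ = _contact_objective(
                    force, z, d, jj, curve.tip, cell_settings
                )
                if ss < best_ss:
                    best_ss, best_j = ss, jj
            assert j == best_j


class TestBuildIndentation:
    def test_rigid_substrate_zero_indentation(self, cell_settings):
        n, z0_idx = 256, 100
        z = np.linspace(0, 1e-6, n)
        d = np.clip(z - z[z0_idx], 0, None)
        curve = RawForceCurve(
            z_m=z,
            deflection=d,
            deflection_unit="meters",
            direction="approach",
            tip=syn.default_tip("cell_2d"),
            calibration=syn.default_calibration("cell_2d"),
        )
        indent = build_indentation(curve, z0_idx)
        np.testing.assert_allclose(indent.delta_m, 0.0, atol=1e-18)

    def test_matches_generator_indentation(self, cell_settings):
        curve = syn.simulate_curve(4e3, cell_settings, contact_index=700)
        indent = build_indentation(curve, 700)
        d = curve.deflection_m()[700:]
        delta_expected = (curve.z_m[700:] - curve.z_m[700]) - d
        np.testing.assert_allclose(indent.delta_m, delta_expected, rtol=1e-12)
        np.testing.assert_allclose(indent.force_n, 0.4 * d, rtol=1e-12)

    def test_force_is_spring_constant_times_deflection(self, cell_settings):
        curve = syn.simulate_curve(4e3, cell_settings, contact_index=700)
        idx = 1500
        indent = build_indentation(curve, 700)
        d = curve.deflection_m()[idx]
        assert indent.force_n[idx - 700] == pytest.approx(0.4 * d, rel=1e-12)

    def test_volts_without_sensitivity_errors(self, cell_settings):
        curve = syn.simulate_curve(4e3, cell_settings, contact_index=700)
        curve.deflection_unit = "volts"
        curve.calibration = CantileverCalibration(0.4)
        with pytest.raises(ValueError):
            build_indentation(curve, 700)


NOISELESS_CASES = [
    ("cell_2d", 0.5e3),
    ("cell_2d", 4e3),
    ("cell_2d", 10e3),
    ("cryosection", 10e3),
    ("cryosection", 12e6),
    ("cryosection", 16e6),
    ("hsr_whole", 0.5e3),
    ("hsr_whole", 15e6),
    ("hsr_whole", 16e6),
]


class TestFitModulus:
    @pytest.mark.parametrize("cls,e_true", NOISELESS_CASES)
    def test_noiseless_round_trip(self, cls, e_true):
        """fit_modulus(simulate_curve(E)) returns E to 1e-6 relative."""
        settings = SampleClassSettings(sample_class=cls)
        curve = syn.simulate_curve(e_true, settings, contact_index=700)
        fit = fit_modulus(curve, settings)
        assert fit.valid
        assert fit.modulus_pa == pytest.approx(e_true, rel=1e-6)

    def test_noisy_median_recovery(self, cryo_settings):
        """Median modulus over >=100 noisy cryosection curves within 3%."""
        rng = np.random.default_rng(4)
        moduli = []
        for _ in range(128):
            curve = syn.simulate_curve(
                10e3,
                cryo_settings,
                noise_force_frac=0.02,
                seed=int(rng.integers(0, 2**31)),
                contact_index=700,
            )
            fit = fit_modulus(curve, cryo_settings)
            if fit.valid:
                moduli.append(fit.modulus_pa)
        assert len(moduli) >= 120
        assert np.median(moduli) == pytest.approx(10e3, rel=0.03)

    def test_window_restriction_invariance(self, cell_settings):
        """Shrinking the fit window on a homogeneous noiseless curve leaves
        the modulus unchanged (depth-consistency)."""
        curve = syn.simulate_curve(4e3, cell_settings, contact_index=700)
        full = fit_modulus(curve, cell_settings)
        narrow_settings = SampleClassSettings(
            sample_class="cell_2d", max_indentation_m=1e-6
        )
        narrow = fit_modulus(curve, narrow_settings)
        assert narrow.modulus_pa == pytest.approx(full.modulus_pa, rel=1e-6)

    def test_model_tip_mismatch_rejected(self, cell_settings):
        curve = syn.simulate_curve(4e3, cell_settings, contact_index=700)
        hertz_settings = SampleClassSettings(
            sample_class="cell_2d", model="hertz"
        )
        with pytest.raises(ValueError, match="spherical"):
            IndentationModel(curve, hertz_settings)

    def test_thickness_rule_flags(self):
        settings = SampleClassSettings(
            sample_class="cryosection", thickness_m=1e-6
        )  # 700 nm window > 1 um / 3
        curve = syn.simulate_curve(10e3, settings, contact_index=700)
        fit = fit_modulus(curve, settings)
        assert "thickness_rule_violated" in fit.flags
        assert "apparent_modulus_Ea" in fit.flags

    def test_thickness_unknown_noted(self, cryo_settings):
        curve = syn.simulate_curve(10e3, cryo_settings, contact_index=700)
        fit = fit_modulus(curve, cryo_settings)
        assert "thickness" in fit.note
        assert "thickness_rule_violated" not in fit.flags

    def test_all_zero_curve_poor_fit(self, cell_settings, noiseless_cell_curve):
        flat = noiseless_cell_curve.with_deflection_m(
            np.zeros(noiseless_cell_curve.n_samples)
        )
        fit = fit_modulus(flat, cell_settings)
        assert "poor_fit" in fit.flags
        assert not fit.valid

    def test_summary_reports_kpa(self, cell_settings, noiseless_cell_curve):
        res = IndentationModel(noiseless_cell_curve, cell_settings).fit()
        text = res.summary()
        assert "kPa" in text and "sneddon" in text
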