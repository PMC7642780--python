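"""Forward model: fractional indices, interference factor, spectra, mosaic
texture, water background and whole-panel renders."""

import numpy as np
import pytest

from stillsolver.geometry import (
    Beam,
    UnitCell,
    angstrom_to_ev,
    b_matrix,
    kahn_polarization,
    pixel_lab_position,
    random_rotation,
    single_panel_detector,
    solid_angle,
)
from stillsolver.simulate import (
    GroundTruthCrystal,
    MosaicTexture,
    SimConfig,
    Spectrum,
    _UM2_TO_A2,
    bragg_photons_truth,
    fractional_index,
    interference,
    interference_r2_cutoff,
    precompute_static_geometry,
    reflection_set,
    render_shot,
    sample_ground_truth_crystal,
    sample_mosaic_texture,
    sample_spectrum,
    water_amplitude,
    water_background_pixel,
    water_molecule_count,
)
from stillsolver.geometry import R_E_SQUARED_A2
from stillsolver.symmetry import StructureFactorTable, map_to_asu


class TestFractionalIndex:
    def test_zero_q(self):
        U = np.eye(3)
        B = b_matrix(UnitCell(79.1, 38.4))
        h_frac, h_int, dh = fractional_index(U, B, np.zeros((1, 3)))
        assert np.allclose(h_frac, 0) and np.allclose(dh, 0)

    def test_reciprocal_basis_vector_maps_to_unit_index(self):
        rng = np.random.default_rng(0)
        U = random_rotation(rng)
        B = b_matrix(UnitCell(50.0, 20.0))
        A = U @ B
        q = np.array([1.0, 0.0, 0.0]) @ np.linalg.inv(A)  # solves A^T q = e1
        h_frac, h_int, dh = fractional_index(U, B, q[None])
        assert np.allclose(h_frac, [1, 0, 0], atol=1e-12)
        assert np.allclose(dh, 0, atol=1e-12)

    def test_round_trip_oracle(self):
        rng = np.random.default_rng(1)
        U = random_rotation(rng)
        B = b_matrix(UnitCell(50.0, 20.0))
        q = rng.normal(size=(20, 3)) * 0.1
        h_frac, h_int, dh = fractional_index(U, B, q)
        # map h_frac back through the reciprocal basis
        q_back = h_frac @ np.linalg.inv(U @ B)
        assert np.allclose(q_back, q, atol=1e-12)
        assert np.all(np.abs(dh) <= 0.5)

    def test_half_away_rounding_deterministic(self):
        from stillsolver.simulate import round_half_away

        assert np.array_equal(round_half_away([0.5, -0.5, 1.5, -2.5]), [1, -1, 2, -3])


class TestInterference:
    def test_peak_is_m_sixth(self):
        assert np.isclose(interference(np.zeros(3), 10.0, 3.175), 1e6)

    def test_half_maximum_radius(self):
        m, C = 10.0, 3.175
        r_half = np.sqrt(np.log(2) / C) / m
        val = interference(np.array([r_half, 0, 0]), m, C)
        assert np.isclose(val, 0.5e6, rtol=1e-12)
        assert np.isclose(r_half, 0.0467, atol=5e-4)

    def test_doubling_c_shrinks_half_width_by_sqrt2(self):
        m = 8.0
        r1 = np.sqrt(np.log(2) / 3.175) / m
        r2 = np.sqrt(np.log(2) / 6.35) / m
        assert np.isclose(r1 / r2, np.sqrt(2))

    def test_monotone_decreasing_and_m_sharpening(self):
        r = np.linspace(0, 0.2, 50)
        vals = interference(np.stack([r, 0 * r, 0 * r], axis=1), 10.0, 3.175)
        assert np.all(np.diff(vals) < 0)
        # larger m: brighter peak, faster relative falloff
        lo = interference(np.array([0.05, 0, 0]), 8.0, 3.175) / 8.0 ** 6
        hi = interference(np.array([0.05, 0, 0]), 12.0, 3.175) / 12.0 ** 6
        assert hi < lo


class TestSampleSpectrum:
    def test_monochromatic_limit(self):
        cfg = SimConfig(n_modes=1, bandwidth=0.0, fluence_jitter=0.0)
        sp = sample_spectrum(np.random.default_rng(0), cfg)
        assert len(sp.wavelengths) == 1
        assert np.isclose(float(angstrom_to_ev(sp.wavelengths[0])), 9034.0)

    def test_ensemble_mean_total_photons(self):
        cfg = SimConfig()
        rng = np.random.default_rng(1)
        area = np.pi * (cfg.beam_diameter_um / 2) ** 2
        totals = [sample_spectrum(rng, cfg).total_fluence * area for _ in range(10_000)]
        se = np.std(totals) / np.sqrt(len(totals))
        assert abs(np.mean(totals) - 8e10) < 3 * se

    def test_central_energy_near_mean(self):
        cfg = SimConfig()
        rng = np.random.default_rng(2)
        centrals = [
            float(angstrom_to_ev(sample_spectrum(rng, cfg).central_wavelength))
            for _ in range(500)
        ]
        tol = cfg.bandwidth * cfg.mean_energy_ev / np.sqrt(cfg.n_modes) * 3
        assert abs(np.mean(centrals) - 9034.0) < tol

    def test_two_column_text_round_trip(self):
        sp = sample_spectrum(np.random.default_rng(3), SimConfig(n_modes=5))
        back = Spectrum.from_text(sp.to_text())
        assert np.allclose(back.fluences, sp.fluences, rtol=1e-6)
        assert np.allclose(back.wavelengths, sp.wavelengths, rtol=1e-6)


class TestMosaicTexture:
    def test_zero_spread_all_identity(self):
        tex = sample_mosaic_texture(np.random.default_rng(0), 20, 0.0)
        assert np.allclose(tex.rotations, np.eye(3))

    def test_rms_angle_matches_spread(self):
        tex = sample_mosaic_texture(np.random.default_rng(1), 100, 0.01)
        tr = np.trace(tex.rotations, axis1=1, axis2=2)
        angles = np.degrees(np.arccos(np.clip((tr - 1) / 2, -1, 1)))
        rms = np.sqrt(np.mean(angles ** 2))
        assert abs(rms - 0.01) / 0.01 < 0.2

    def test_same_seed_same_texture(self):
        a = sample_mosaic_texture(np.random.default_rng(5), 10, 0.01)
        b = sample_mosaic_texture(np.random.default_rng(5), 10, 0.01)
        assert np.array_equal(a.rotations, b.rotations)


class TestWaterBackground:
    def test_zero_path_gives_zero(self):
        cfg = SimConfig(water_path_um=0.0)
        det = single_panel_detector(n_fast=8, n_slow=8)
        sp = sample_spectrum(np.random.default_rng(0), cfg)
        assert water_background_pixel(det[0], Beam(), 4, 4, sp, cfg) == 0.0

    def test_linear_in_volume(self):
        det = single_panel_detector(n_fast=8, n_slow=8)
        sp = sample_spectrum(np.random.default_rng(1), SimConfig())
        t1 = water_background_pixel(det[0], Beam(), 2, 5, sp, SimConfig(water_path_um=5))
        t2 = water_background_pixel(det[0], Beam(), 2, 5, sp, SimConfig(water_path_um=10))
        assert np.isclose(t2, 2 * t1)

    def test_hand_computed_product(self):
        cfg = SimConfig()
        det = single_panel_detector(n_fast=16, n_slow=16)
        beam = Beam()
        sp = Spectrum(wavelengths=[1.372], fluences=[1e11])
        f, s = 3, 12
        got = water_background_pixel(det[0], beam, f, s, sp, cfg)
        pos = pixel_lab_position(det[0], f, s)
        q = np.linalg.norm(pos / np.linalg.norm(pos) - beam.direction) / 1.372
        expected = (
            solid_angle(det[0], f, s)
            * kahn_polarization(pos, beam)
            * 1e11 * _UM2_TO_A2
            * R_E_SQUARED_A2
            * water_amplitude(q) ** 2
            * water_molecule_count(cfg)
        )
        assert np.isclose(got, expected, rtol=1e-12)

    def test_curve_peak_near_3p2_angstrom(self):
        q = np.linspace(0.05, 0.8, 400)
        fw = water_amplitude(q)
        assert abs(1.0 / q[np.argmax(fw)] - 3.2) < 0.3


def _exact_bragg_scene():
    """A pixel placed exactly at the Bragg condition for index (1, 0, 0)."""
    det = single_panel_detector(n_fast=32, n_slow=32, distance=60.0)
    beam = Beam()
    f, s = 25, 9
    pos = pixel_lab_position(det[0], f, s)
    lam = 1.372
    q = (pos / np.linalg.norm(pos) - beam.direction) / lam
    a = 1.0 / np.linalg.norm(q)  # then (1,0,0) satisfies |y| = |q|
    cell = UnitCell(a, a / 2)
    # rotation taking the aligned reciprocal vector (1/a, 0, 0) onto q
    e1 = q / np.linalg.norm(q)
    tmp = np.array([0.0, 0.0, 1.0])
    e2 = np.cross(tmp, e1); e2 /= np.linalg.norm(e2)
    e3 = np.cross(e1, e2)
    U = np.stack([e1, e2, e3], axis=1)
    canon, _ = map_to_asu(np.array([1, 0, 0]))
    F = StructureFactorTable(canon[None], [123.0], cell, a * 0.9)
    texture = MosaicTexture(np.eye(3)[None])
    crystal = GroundTruthCrystal(U=U, B=b_matrix(cell), m=10.0, Z=1150.0, texture=texture)
    spectrum = Spectrum(wavelengths=[lam], fluences=[2e11])
    return det, beam, f, s, crystal, F, spectrum


class TestBraggPhotonsTruth:
    def test_zero_fluence_zero_photons(self):
        det, beam, f, s, crystal, F, sp = _exact_bragg_scene()
        sp0 = Spectrum(wavelengths=sp.wavelengths, fluences=[1e-300])
        assert bragg_photons_truth(det[0], beam, f, s, sp0, crystal, F) < 1e-250

    def test_linear_in_crystal_scale(self):
        det, beam, f, s, crystal, F, sp = _exact_bragg_scene()
        i1 = bragg_photons_truth(det[0], beam, f, s, sp, crystal, F)
        crystal2 = GroundTruthCrystal(
            U=crystal.U, B=crystal.B, m=crystal.m, Z=2 * crystal.Z, texture=crystal.texture
        )
        i2 = bragg_photons_truth(det[0], beam, f, s, sp, crystal2, F)
        assert np.isclose(i2, 2 * i1, rtol=1e-12)

    def test_exact_bragg_closed_form(self):
        det, beam, f, s, crystal, F, sp = _exact_bragg_scene()
        got = bragg_photons_truth(det[0], beam, f, s, sp, crystal, F)
        pos = pixel_lab_position(det[0], f, s)
        expected = (
            solid_angle(det[0], f, s)
            * kahn_polarization(pos, beam)
            * sp.fluences[0] * _UM2_TO_A2
            * R_E_SQUARED_A2
            * crystal.Z
            * 123.0 ** 2
            * crystal.m ** 6
        )
        assert np.isclose(got, expected, rtol=1e-10)


@pytest.fixture(scope="module")
def desk_scene():
    rng = np.random.default_rng(11)
    cfg = SimConfig(d_min=4.5)
    det = single_panel_detector()
    beam = Beam()
    from stillsolver.symmetry import random_toy_structure, toy_structure_factors

    structure = random_toy_structure(rng)
    F = toy_structure_factors(structure, cfg.cell, cfg.d_min)
    texture = sample_mosaic_texture(rng, cfg.n_domains, cfg.mosaic_spread_deg)
    static = precompute_static_geometry(det, beam, cfg.oversample)
    refl = reflection_set(F)
    return dict(rng=rng, cfg=cfg, det=det, beam=beam, F=F, texture=texture,
                static=static, refl=refl)


class TestRenderShot:
    def test_zero_table_gives_background_only(self, desk_scene):
        d = desk_scene
        cfg = d["cfg"]
        crystal = sample_ground_truth_crystal(np.random.default_rng(0), cfg, d["texture"])
        sp = sample_spectrum(np.random.default_rng(1), cfg)
        F0 = StructureFactorTable(
            d["F"].hkl, np.zeros(len(d["F"])), d["F"].cell, d["F"].d_min
        )
        img = render_shot(d["det"], d["beam"], cfg, F0, crystal, sp,
                          d["static"], reflection_set(F0))[0]
        bg = render_shot(d["det"], d["beam"], cfg, F0, crystal, sp,
                         d["static"], reflection_set(F0), include_background=True)[0]
        assert np.allclose(img, bg)
        assert img.min() > 0  # pure water background everywhere

    def test_bragg_total_linear_in_fluence(self, desk_scene):
        d = desk_scene
        cfg = d["cfg"]
        crystal = sample_ground_truth_crystal(np.random.default_rng(2), cfg, d["texture"])
        sp = sample_spectrum(np.random.default_rng(3), cfg)
        sp2 = Spectrum(wavelengths=sp.wavelengths, fluences=3.0 * sp.fluences)
        i1 = render_shot(d["det"], d["beam"], cfg, d["F"], crystal, sp,
                         d["static"], d["refl"], include_background=False)[0]
        i2 = render_shot(d["det"], d["beam"], cfg, d["F"], crystal, sp2,
                         d["static"], d["refl"], include_background=False)[0]
        assert np.allclose(i2, 3.0 * i1, rtol=1e-12)

    def test_finite_and_non_negative_over_random_shots(self, desk_scene):
        d = desk_scene
        cfg = d["cfg"]
        rng = np.random.default_rng(4)
        for _ in range(5):
            crystal = sample_ground_truth_crystal(rng, cfg, d["texture"])
            sp = sample_spectrum(rng, cfg)
            img = render_shot(d["det"], d["beam"], cfg, d["F"], crystal, sp,
                              d["static"], d["refl"])[0]
            assert np.all(np.isfinite(img)) and np.all(img >= 0)

    def test_matches_direct_per_pixel_sum(self, desk_scene):
        d = desk_scene
        cfg = d["cfg"]
        crystal = sample_ground_truth_crystal(np.random.default_rng(5), cfg, d["texture"])
        sp = sample_spectrum(np.random.default_rng(6), cfg)
        img = render_shot(d["det"], d["beam"], cfg, d["F"], crystal, sp,
                          d["static"], d["refl"], include_background=False)[0]
        sl, fa = np.unravel_index(np.argmax(img), img.shape)
        direct = bragg_photons_truth(
            d["det"][0], d["beam"], int(fa), int(sl), sp, crystal, d["F"],
            cfg.C, cfg.oversample,
        )
        assert np.isclose(img[sl, fa], direct, rtol=1e-12)

    def test_oversample_convergence_on_smooth_background(self, desk_scene):
        d = desk_scene
        cfg = d["cfg"]
        sp = sample_spectrum(np.random.default_rng(7), cfg)
        t1 = water_background_pixel(d["det"][0], d["beam"], 100, 100, sp, cfg, oversample=1)
        t4 = water_background_pixel(d["det"][0], d["beam"], 100, 100, sp, cfg, oversample=4)
        assert abs(t1 - t4) / t4 < 1e-3

    def test_spot_profile_matches_pure_gaussian_along_cut(self, desk_scene):
        # one channel, no mosaic spread: the profile along any cut must be the
        # interference Gaussian evaluated at each pixel's Ewald offset
        d = desk_scene
        cfg = d["cfg"]
        texture0 = MosaicTexture(np.eye(3)[None])
        crystal = GroundTruthCrystal(
            U=random_rotation(np.random.default_rng(8)),
            B=b_matrix(cfg.cell), m=10.0, Z=1150.0, texture=texture0,
        )
        sp = Spectrum(wavelengths=[1.372], fluences=[1.0e11])
        img = render_shot(d["det"], d["beam"], cfg, d["F"], crystal, sp,
                          d["static"], d["refl"], include_background=False)[0]
        sl, fa = np.unravel_index(np.argmax(img), img.shape)
        peak = img[sl, fa]
        cut = img[sl, max(fa - 5, 0):fa + 6]
        # model values from the per-pixel truth sum (pure Eq.-form evaluation)
        model = np.array([
            bragg_photons_truth(d["det"][0], d["beam"], int(f), int(sl), sp,
                                crystal, d["F"], cfg.C, cfg.oversample)
            for f in range(max(fa - 5, 0), fa + 6)
        ])
        assert np.sqrt(np.mean((cut - model) ** 2)) < 1e-6 * peak
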