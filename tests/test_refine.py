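"""Likelihood, analytic gradients, reparameterization and the two-stage
refinement protocol."""

from dataclasses import replace

import numpy as np
import pytest

from stillsolver.noise import NoiseParams
from stillsolver.refine import (
    BoundedReparam,
    LinearReparam,
    ShotParams,
    Stage1Result,
    filter_shots,
    model_photons,
    negative_log_likelihood,
    reparameterize,
    shot_nll_and_grads,
    stage1_refine,
    stage2_refine,
)


class TestReparameterize:
    def test_initial_value_at_x_equal_one(self):
        for rp in (reparameterize(5.0, 0.1), reparameterize(5.0, 0.1, 0.0)):
            assert np.isclose(float(rp.theta(1.0)), 5.0)

    def test_bounded_map_respects_lower_bound(self):
        rp = reparameterize(5.0, 1.0, 2.0)
        assert float(rp.theta(-300.0)) >= 2.0
        assert float(rp.theta(-30.0)) > 2.0
        x = np.linspace(-5, 5, 101)
        assert np.all(rp.theta(x) > 2.0)

    def test_bounded_requires_start_above_bound(self):
        with pytest.raises(ValueError):
            BoundedReparam(1.0, 1.0, 2.0)

    @pytest.mark.parametrize("factory", [
        lambda: LinearReparam(3.0, 0.7),
        lambda: BoundedReparam(3.0, 0.7, 0.5),
    ])
    def test_derivative_matches_finite_differences(self, factory):
        rp = factory()
        for x in [-1.0, 0.3, 1.0, 2.5]:
            h = 1e-7
            fd = (float(rp.theta(x + h)) - float(rp.theta(x - h))) / (2 * h)
            assert np.isclose(float(rp.dtheta_dx(x)), fd, rtol=1e-7)

    def test_round_trip_x_of(self):
        for rp in (LinearReparam(3.0, 0.7), BoundedReparam(3.0, 0.7, 0.5)):
            for theta in [1.0, 3.0, 10.0]:
                assert np.isclose(float(rp.theta(rp.x_of(theta))), theta)


NOISE = NoiseParams()
C = 3.175


def random_state(rng, scene):
    return ShotParams(
        U0=scene.estimate.U0,
        angles_deg=rng.normal(0, 0.02, 3),
        a=scene.config.sim.cell_a + rng.normal(0, 0.05),
        c=scene.config.sim.cell_c + rng.normal(0, 0.03),
        G=float(np.exp(rng.normal(np.log(1000.0), 0.7))),
        m=float(10.0 * np.exp(rng.normal(0, 0.15))),
    )


class TestGradients:
    """Analytic derivatives against central finite differences — the
    module's cardinal correctness check, over every parameter type."""

    @pytest.mark.parametrize("scene_name,n_states", [
        ("small_scene", 12), ("small_scene_noiseless", 8),
    ])
    def test_all_parameter_types_match_finite_differences(
        self, scene_name, n_states, request
    ):
        scene = request.getfixturevalue(scene_name)
        sd = scene.shot_data
        amps = scene.F.amplitudes
        rng = np.random.default_rng(hash(scene_name) % 2 ** 31)
        for _ in range(n_states):
            p = random_state(rng, scene)
            nll, g = shot_nll_and_grads(
                sd, p, amps, NOISE, C, active=("angles", "cell", "G", "m"),
                grad_F=True, n_global_F=len(scene.F),
            )

            def nll_at(pp, aa=amps):
                return shot_nll_and_grads(sd, pp, aa, NOISE, C, active=())[0]

            checks = {}
            for i in range(3):
                h = 1e-6
                up = p.angles_deg.copy(); up[i] += h
                dn = p.angles_deg.copy(); dn[i] -= h
                checks[f"angle{i}"] = (
                    g["angles"][i],
                    (nll_at(replace(p, angles_deg=up)) - nll_at(replace(p, angles_deg=dn)))
                    / (2 * h),
                )
            for name, step in [("a", 1e-6), ("c", 1e-6), ("G", p.G * 1e-6), ("m", 1e-6)]:
                up = replace(p, **{name: getattr(p, name) + step})
                dn = replace(p, **{name: getattr(p, name) - step})
                checks[name] = (g[name], (nll_at(up) - nll_at(dn)) / (2 * step))
            nz = np.flatnonzero(np.abs(g["F"]) > 1e-3)
            if len(nz):
                j = nz[np.argmax(np.abs(g["F"][nz]))]
                step = max(amps[j] * 1e-6, 1e-6)
                up = amps.copy(); up[j] += step
                dn = amps.copy(); dn[j] -= step
                checks["F"] = (g["F"][j], (nll_at(p, up) - nll_at(p, dn)) / (2 * step))
            for name, (ga, gf) in checks.items():
                rel = abs(ga - gf) / max(abs(gf), 1e-8)
                assert rel < 1e-5, f"{name}: analytic {ga} vs fd {gf} (rel {rel})"

    def test_dn_dG_is_bragg_over_G(self, small_scene):
        sd = small_scene.shot_data
        p = ShotParams(U0=small_scene.estimate.U0, G=500.0, m=10.0)
        n, cache = model_photons(sd, p, small_scene.F.amplitudes, C, with_cache=True)
        bragg_px = cache["bragg_sub"].reshape(-1, cache["os2"]).sum(axis=1)
        T = sd.T
        assert np.allclose(bragg_px, n - T, atol=1e-12)

    def test_vanishing_scale_leaves_background(self, small_scene):
        sd = small_scene.shot_data
        p = ShotParams(U0=small_scene.estimate.U0, G=1e-30, m=10.0)
        n = model_photons(sd, p, small_scene.F.amplitudes, C)
        assert np.allclose(n, sd.T, atol=1e-15)


class TestLikelihood:
    def test_perfect_fit_leaves_log_terms(self, small_scene):
        n = np.array([0.5, 3.0, 100.0])
        v = NOISE.sigma_r ** 2 + n + NOISE.sigma_g ** 2 * n * n
        assert np.isclose(
            negative_log_likelihood(n, n, NOISE), 0.5 * np.log(2 * np.pi * v).sum()
        )

    def test_quadratic_response_to_data_perturbation(self):
        n = np.array([10.0])
        v = float(NOISE.sigma_r ** 2 + 10.0 + NOISE.sigma_g ** 2 * 100.0)
        delta = 0.3
        d_nll = negative_log_likelihood(n + delta, n, NOISE) - negative_log_likelihood(
            n, n, NOISE
        )
        assert np.isclose(d_nll, delta ** 2 / (2 * v))

    def test_truth_beats_misoriented_model_on_noiseless_data(
        self, small_scene_noiseless
    ):
        scene = small_scene_noiseless
        sd = scene.shot_data
        amps = scene.F.amplitudes
        truth = ShotParams(
            U0=scene.crystal.U, a=scene.config.sim.cell_a, c=scene.config.sim.cell_c,
            G=scene.crystal.Z, m=scene.config.sim.m,
        )
        # shoeboxes were predicted from the indexing estimate; rebase on truth
        sd2 = scene.shot_data
        nll_truth, _ = shot_nll_and_grads(sd2, truth, amps, NOISE, C, active=())
        rotated = replace(truth, angles_deg=np.array([0.1, 0.0, 0.0]))
        nll_rot, _ = shot_nll_and_grads(sd2, rotated, amps, NOISE, C, active=())
        assert nll_truth < nll_rot

    def test_gauge_invariance_of_scale_and_amplitudes(self, small_scene):
        scene = small_scene
        sd = scene.shot_data
        p = ShotParams(U0=scene.estimate.U0, G=800.0, m=10.0)
        amps = scene.F.amplitudes
        nll1, _ = shot_nll_and_grads(sd, p, amps, NOISE, C, active=())
        gamma = 7.3
        p2 = replace(p, G=gamma * p.G)
        nll2, _ = shot_nll_and_grads(sd, p2, amps / np.sqrt(gamma), NOISE, C, active=())
        assert abs(nll1 - nll2) / abs(nll1) < 1e-10


class TestStage1:
    def test_exact_model_data_stays_at_truth(self, small_scene_noiseless):
        # data rendered by the same monochromatic single-domain model: the
        # optimizer must not move away (movement < 0.1 internal units)
        scene = small_scene_noiseless
        import stillsolver.simulate as sim_mod
        from stillsolver.refine import ShotData
        from stillsolver.shoebox import extract_pixels, predict_shoeboxes

        cfg = scene.config.sim
        # bright-signal conditions: the likelihood's weak-signal bias
        # (~half a photon per pixel) is negligible relative to the signal
        spectrum = sim_mod.Spectrum(wavelengths=[1.372], fluences=[1e14])
        texture = sim_mod.MosaicTexture(np.eye(3)[None])
        crystal = sim_mod.GroundTruthCrystal(
            U=scene.crystal.U, B=scene.crystal.B, m=cfg.m, Z=scene.crystal.Z,
            texture=texture,
        )
        cfg_mono = replace(cfg, water_path_um=0.0)
        img = sim_mod.render_shot(
            scene.detector, scene.beam, cfg_mono, scene.F, crystal, spectrum,
            scene.static,
        )[0]
        boxes = predict_shoeboxes(
            crystal.U, crystal.B, scene.detector, scene.beam, 1.372, cfg.d_min,
            reflections=scene.refl["hkl"], cell=cfg.cell,
        )
        for sb in boxes:
            extract_pixels(sb, img)
            sb.tilt = np.zeros(3)
            sb.tilt_covariance = np.zeros((3, 3))
            sb.snr = 100.0
        sd = ShotData(0, boxes, scene.static, 1e14, 1.372, cfg.oversample)
        sd.link_table(scene.F)
        init = ShotParams(
            U0=crystal.U, a=cfg.cell_a, c=cfg.cell_c, G=crystal.Z, m=cfg.m
        )
        res = stage1_refine(sd, init, scene.F.amplitudes, NOISE, C, cfg.d_min)
        assert res.ok
        assert np.all(np.abs(res.params.angles_deg) < 0.1 * 0.001)
        assert abs(res.params.a - cfg.cell_a) < 0.1 * 0.1
        assert abs(np.log(res.params.m / cfg.m)) < 0.1 * 0.1

    def test_too_few_qualifying_boxes_flags_unrefinable(self, small_scene):
        scene = small_scene
        sd = scene.shot_data
        saved = sd.snr.copy()
        sd.snr = np.full_like(sd.snr, -1.0)  # nothing passes the SNR cut
        try:
            res = stage1_refine(
                sd, scene.estimate, scene.F.amplitudes, NOISE, C, scene.config.sim.d_min
            )
            assert not res.ok
        finally:
            sd.snr = saved


class TestFilterShots:
    def _results(self, values):
        out = {}
        for i, (a, c, m, G) in enumerate(values):
            p = ShotParams(U0=np.eye(3), a=a, c=c, G=G, m=m)
            out[i] = Stage1Result(params=p, ok=True)
        return out

    def test_identical_shots_all_survive(self):
        res = self._results([(79.1, 38.4, 10.0, 1000.0)] * 6)
        assert filter_shots(res) == list(range(6))

    def test_displaced_shot_removed(self):
        rng = np.random.default_rng(0)
        rows = [
            (79.1 + rng.normal(0, 0.01), 38.4 + rng.normal(0, 0.01),
             10 + rng.normal(0, 0.05), 1000 * np.exp(rng.normal(0, 0.05)))
            for _ in range(20)
        ]
        rows.append((82.0, 38.4, 10.0, 1000.0))  # ~10 robust sd away in a
        res = self._results(rows)
        surviving = filter_shots(res)
        assert 20 not in surviving
        assert len(surviving) == 20

    def test_failed_shots_never_survive(self):
        res = self._results([(79.1, 38.4, 10.0, 1000.0)] * 3)
        res[99] = Stage1Result(params=res[0].params, ok=False)
        assert 99 not in filter_shots(res)


class TestStage2:
    def test_single_spot_closed_loop_recovery(self, small_scene_noiseless):
        """Noiseless single-reflection refinement recovers the amplitude-scale
        product G |F|^2 to high accuracy (idealized noise model: no gain or
        readout terms, so the variance-induced bias is negligible)."""
        scene = small_scene_noiseless
        import stillsolver.simulate as sim_mod
        from stillsolver.refine import ShotData
        from stillsolver.shoebox import extract_pixels, predict_shoeboxes
        from stillsolver.symmetry import StructureFactorTable

        cfg = scene.config.sim
        # very bright spot: the likelihood's per-pixel half-photon bias
        # (delta ~ 1/(2 n-bar)) must sit far below the 1e-4 tolerance
        spectrum = sim_mod.Spectrum(wavelengths=[1.372], fluences=[1e14])
        texture = sim_mod.MosaicTexture(np.eye(3)[None])
        crystal = sim_mod.GroundTruthCrystal(
            U=scene.crystal.U, B=scene.crystal.B, m=cfg.m, Z=1000.0, texture=texture
        )
        cfg_mono = replace(cfg, water_path_um=0.0)
        img = sim_mod.render_shot(
            scene.detector, scene.beam, cfg_mono, scene.F, crystal, spectrum,
            scene.static,
        )[0]
        boxes = predict_shoeboxes(
            crystal.U, crystal.B, scene.detector, scene.beam, 1.372, cfg.d_min,
            reflections=scene.refl["hkl"], cell=cfg.cell, delta_pred=0.05,
        )
        # keep the brightest single spot
        sums = [img[s0:s1, f0:f1].sum() for (f0, f1, s0, s1) in (b.bbox for b in boxes)]
        sb = boxes[int(np.argmax(sums))]
        extract_pixels(sb, img)
        sb.tilt = np.zeros(3)
        sb.tilt_covariance = np.zeros((3, 3))
        sb.snr = 100.0
        sd = ShotData(0, [sb], scene.static, 1e14, 1.372, cfg.oversample)
        truth_amp = scene.F.lookup(sb.hkl)
        F_init = StructureFactorTable(
            sb.hkl[None], [truth_amp * 3.0], cfg.cell, cfg.d_min
        )
        quiet = NoiseParams(sigma_g=0.0, sigma_r=1e-3)
        init = ShotParams(U0=crystal.U, a=cfg.cell_a, c=cfg.cell_c, G=300.0, m=cfg.m)
        res = stage2_refine(
            {0: sd}, {0: init}, F_init, quiet, C, cfg.d_min, max_iter=300
        )
        got = res.shot_params[0].G * res.F.amplitudes[0] ** 2
        expected = crystal.Z * truth_amp ** 2
        assert abs(got - expected) / expected < 1e-4

    def test_unmeasured_amplitudes_keep_initial_values(self, small_scene):
        scene = small_scene
        from stillsolver.symmetry import StructureFactorTable

        F_init = StructureFactorTable(
            scene.F.hkl, np.maximum(scene.F.amplitudes, 1.0),
            scene.F.cell, scene.F.d_min,
        )
        init = ShotParams(U0=scene.estimate.U0, G=1000.0, m=10.0)
        res = stage2_refine(
            {0: scene.shot_data}, {0: init}, F_init, NOISE, C,
            scene.config.sim.d_min, max_iter=15,
        )
        measured = np.zeros(len(F_init), dtype=bool)
        mask = scene.shot_data.pixel_mask(snr_min=0.2, d_min=scene.config.sim.d_min)
        measured[np.unique(scene.shot_data.f_pos[mask])] = True
        assert np.any(~measured)
        assert np.array_equal(
            res.F.amplitudes[~measured], F_init.amplitudes[~measured]
        )
        assert np.any(res.F.amplitudes[measured] != F_init.amplitudes[measured])

    def test_nll_non_increasing_over_accepted_iterates(self, small_scene):
        scene = small_scene
        from stillsolver.symmetry import StructureFactorTable

        F_init = StructureFactorTable(
            scene.F.hkl, np.maximum(scene.F.amplitudes, 1.0),
            scene.F.cell, scene.F.d_min,
        )
        init = ShotParams(U0=scene.estimate.U0, G=1000.0, m=10.0)
        accepted = []
        res = stage2_refine(
            {0: scene.shot_data}, {0: init}, F_init, NOISE, C,
            scene.config.sim.d_min, max_iter=25,
            callback=lambda xk: accepted.append(1),
        )
        # the recorded trace contains line-search evaluations; the monotone
        # subsequence of accepted values is reconstructed as running minima
        trace = np.array(res.nll_trace)
        running = np.minimum.accumulate(trace)
        assert running[-1] <= running[0]
        assert res.nll_trace[-1] == min(res.nll_trace)
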