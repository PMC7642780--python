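"""Shared fixtures: small synthetic scenes and the mini end-to-end run."""

from __future__ import annotations

import numpy as np
import pytest

from stillsolver.experiment import (
    _substreams,
    build_detector,
    desk_config,
    micro_config,
    run_experiment,
    sample_indexing_estimate,
)
from stillsolver.geometry import Beam
from stillsolver.noise import NoiseParams, apply_noise, sample_gain_map
from stillsolver.refine import ShotData
from stillsolver.shoebox import (
    extract_pixels,
    filter_negative_tilt,
    fit_tilt_plane,
    predict_shoeboxes,
    snr_estimate,
)
from stillsolver.simulate import (
    precompute_static_geometry,
    reflection_set,
    render_shot,
    sample_ground_truth_crystal,
    sample_mosaic_texture,
    sample_spectrum,
)
from stillsolver.symmetry import random_toy_structure, toy_structure_factors


class SmallScene:
    """One simulated shot with shoeboxes, packed for refinement tests."""

    def __init__(self, seed=3, noisy=True, config=None):
        self.config = config or micro_config(seed=seed)
        sim = self.config.sim
        rngs = _substreams(seed)
        self.noise_params = NoiseParams()
        self.beam = Beam()
        self.detector = build_detector(self.config)
        self.structure = random_toy_structure(rngs["structure"])
        self.F = toy_structure_factors(self.structure, sim.cell, sim.d_min)
        self.texture = sample_mosaic_texture(
            rngs["texture"], sim.n_domains, sim.mosaic_spread_deg
        )
        self.static = precompute_static_geometry(self.detector, self.beam, sim.oversample)
        self.refl = reflection_set(self.F)
        self.gains = [
            sample_gain_map(rngs["gain"], (p.n_slow, p.n_fast), self.noise_params)
            for p in self.detector
        ]
        self.crystal = sample_ground_truth_crystal(rngs["crystals"], sim, self.texture)
        self.spectrum = sample_spectrum(rngs["spectra"], sim)
        images = render_shot(
            self.detector, self.beam, sim, self.F, self.crystal, self.spectrum,
            self.static, self.refl,
        )
        if noisy:
            images = [
                apply_noise(rngs["noise"], img, g, self.noise_params)
                for img, g in zip(images, self.gains)
            ]
        self.images = images
        self.estimate = sample_indexing_estimate(rngs["indexing"], self.crystal.U, self.config)
        boxes = predict_shoeboxes(
            self.estimate.U0,
            self.estimate.B(),
            self.detector,
            self.beam,
            self.spectrum.central_wavelength,
            sim.d_min,
            box_size=self.config.box_size,
            delta_pred=self.config.delta_pred,
            reflections=self.refl["hkl"],
            cell=sim.cell,
            shot_id=0,
        )
        for sb in boxes:
            extract_pixels(sb, images[sb.panel_id])
            fit_tilt_plane(sb, self.noise_params)
            snr_estimate(sb, self.noise_params)
        self.boxes = filter_negative_tilt(boxes)
        self.shot_data = ShotData(
            0,
            self.boxes,
            self.static,
            self.spectrum.total_fluence,
            self.spectrum.central_wavelength,
            sim.oversample,
        )
        self.shot_data.link_table(self.F)


@pytest.fixture(scope="session")
def small_scene():
    return SmallScene(seed=3, noisy=True)


@pytest.fixture(scope="session")
def small_scene_noiseless():
    return SmallScene(seed=4, noisy=False)


@pytest.fixture(scope="session")
def mini_experiment():
    """The desk-scale end-to-end study: 200 shots on a 256x256 panel."""
    return run_experiment(desk_config(seed=1))
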