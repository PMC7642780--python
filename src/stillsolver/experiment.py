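"""End-to-end experiment driver.

Pipeline: synthesize shots (ground-truth structure factors, random crystal
orientations and scales, SASE-like spectra, water background, explicit pixel
noise) -> indexing surrogate (ground-truth orientations and cells perturbed
to emulate conventional indexing output) -> shoebox prediction, tilt planes,
SNR and filtering -> integration baseline (summation integration plus
Monte-Carlo merging) -> stage 1 per-shot refinement -> outlier-shot removal
-> model-derived partiality correction of the integrated observations ->
stage 2 global refinement -> ground-truth metrics for every amplitude set.

All randomness flows from one root seed through named substreams, so a run
is exactly reproducible.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict

import numpy as np

from .geometry import Beam, cspad_like_detector, perturb_orientation, single_panel_detector
from .merge import (
    IntegratedObservation,
    integrate_shoebox,
    merge_monte_carlo,
    partiality_correct,
)
from .metrics import cc_ano, misorientation_summary, r_gt
from .noise import NoiseParams, apply_noise, sample_gain_map
from .refine import (
    ShotData,
    ShotParams,
    Stage1Result,
    filter_shots,
    stage1_refine,
    stage2_refine,
)
from .shoebox import (
    extract_pixels,
    filter_negative_tilt,
    fit_tilt_plane,
    predict_shoeboxes,
    snr_estimate,
)
from .simulate import (
    SimConfig,
    precompute_static_geometry,
    reflection_set,
    render_shot,
    sample_ground_truth_crystal,
    sample_mosaic_texture,
    sample_spectrum,
)
from .symmetry import (
    StructureFactorTable,
    d_spacing,
    heavy_only_anomalous_table,
    random_toy_structure,
    toy_structure_factors,
)

# substream labels hashed off the root seed
_STREAMS = ("structure", "texture", "crystals", "spectra", "noise", "indexing", "gain")


@dataclass
class ExperimentConfig:
    """Study configuration; the defaults are the desk-scale preset."""

    preset: str = "desk"
    n_shots: int = 200
    sim: SimConfig = field(default_factory=lambda: SimConfig(d_min=4.5))
    detector: str = "single"  # "single" or "cspad"
    detector_distance: float = 60.0
    detector_n_pixels: int = 256
    box_size: int = 11
    delta_pred: float = 0.15
    n_light_asu: int = 12
    n_heavy_asu: int = 2
    indexing_misorientation_median_deg: float = 0.038
    indexing_cell_sd_a: float = 0.05
    indexing_cell_sd_c: float = 0.025
    init_m: float = 13.7
    init_G: float = 1.0e6
    min_multiplicity: int = 3
    n_cycles: int = 2
    final_stage1_polish: bool = True
    stage1_max_iter: int = 100
    stage2_max_iter: int = 250
    seed: int = 0

    def to_dict(self):
        return asdict(self)


def desk_config(seed: int = 0, n_shots: int = 200) -> ExperimentConfig:
    """Desk-scale preset: one 256x256 panel at 60 mm, cutoff 4.5 A."""
    return ExperimentConfig(seed=seed, n_shots=n_shots)


def paper_config(seed: int = 0, n_shots: int = 2048) -> ExperimentConfig:
    """Full-scale preset: 32-panel camera at 124 mm, cutoff 2.1 A.

    This is cluster-scale work (hours on a multi-core node); the desk preset
    is the supported single-CPU configuration.
    """
    return ExperimentConfig(
        preset="paper",
        n_shots=n_shots,
        sim=SimConfig(d_min=2.1),
        detector="cspad",
        detector_distance=124.0,
        box_size=15,
        n_cycles=1,
        stage2_max_iter=500,
        seed=seed,
    )


def micro_config(seed: int = 0, n_shots: int = 6) -> ExperimentConfig:
    """Tiny smoke-scale preset for fast functional checks only."""
    return ExperimentConfig(
        preset="micro",
        n_shots=n_shots,
        sim=SimConfig(d_min=6.0, n_modes=8, n_domains=10),
        detector_n_pixels=128,
        detector_distance=45.0,
        stage1_max_iter=40,
        stage2_max_iter=40,
        seed=seed,
    )


def _substreams(seed: int) -> dict[str, np.random.Generator]:
    root = np.random.SeedSequence(seed)
    children = root.spawn(len(_STREAMS))
    return {name: np.random.default_rng(s) for name, s in zip(_STREAMS, children)}


def build_detector(config: ExperimentConfig):
    if config.detector == "cspad":
        return cspad_like_detector(distance=config.detector_distance)
    return single_panel_detector(
        n_fast=config.detector_n_pixels,
        n_slow=config.detector_n_pixels,
        distance=config.detector_distance,
    )


def sample_indexing_estimate(rng: np.random.Generator, U_true, config: ExperimentConfig):
    """Indexing surrogate: a perturbed orientation and cell.

    Misorientation angles follow a half-normal whose median equals the
    configured value (sigma = median / 0.6745); cell edges get independent
    Gaussian errors, emulating the spread of conventional indexing results.
    """
    sigma_ang = config.indexing_misorientation_median_deg / 0.6745
    angle = abs(rng.normal(0.0, sigma_ang))
    U0 = perturb_orientation(rng, U_true, angle)
    a = config.sim.cell_a + rng.normal(0.0, config.indexing_cell_sd_a)
    c = config.sim.cell_c + rng.normal(0.0, config.indexing_cell_sd_c)
    return ShotParams(
        U0=U0, a=float(a), c=float(c), G=config.init_G, m=config.init_m
    )


def complete_table(
    merged: StructureFactorTable, full_hkl, cell, d_min, n_shells: int = 10
) -> StructureFactorTable:
    """Extend a merged table to the full index set.

    Unmeasured indices receive the median measured amplitude of their
    resolution shell (zero-gradient parameters must still start somewhere
    strictly positive for the bounded reparameterization); measured zeros
    are floored the same way the refinement floors them.
    """
    d_all = d_spacing(full_hkl, cell)
    pos = merged.positions(full_hkl)
    amps = np.where(pos >= 0, merged.amplitudes[np.maximum(pos, 0)], np.nan)
    d_meas = d_all[pos >= 0]
    edges = np.quantile(d_meas, np.linspace(0, 1, n_shells + 1)) if len(d_meas) else [0, 1]
    for i in range(len(edges) - 1):
        lo, hi = edges[i], edges[i + 1]
        in_shell = (d_all >= lo) & (d_all <= hi if i == len(edges) - 2 else d_all < hi)
        meas = in_shell & ~np.isnan(amps)
        fill = np.nanmedian(amps[meas]) if np.any(meas) else np.nanmedian(amps)
        amps[in_shell & np.isnan(amps)] = fill
    amps[np.isnan(amps)] = np.nanmedian(merged.amplitudes) if len(merged) else 1.0
    return StructureFactorTable(full_hkl, amps, cell, d_min)


def reduce_shot(
    images,
    estimate: ShotParams,
    spectrum,
    config: ExperimentConfig,
    detector,
    beam: Beam,
    static,
    refl_hkl,
    noise_params: NoiseParams,
    shot_id: int,
):
    """Predict, extract, background-fit and filter one shot's shoeboxes.

    Returns (surviving shoeboxes, packed ShotData, number removed by the
    negative-tilt filter).
    """
    sim = config.sim
    boxes = predict_shoeboxes(
        estimate.U0,
        estimate.B(),
        detector,
        beam,
        spectrum.central_wavelength,
        sim.d_min,
        box_size=config.box_size,
        delta_pred=config.delta_pred,
        reflections=refl_hkl,
        cell=sim.cell,
        shot_id=shot_id,
    )
    for sb in boxes:
        extract_pixels(sb, images[sb.panel_id])
        fit_tilt_plane(sb, noise_params)
        snr_estimate(sb, noise_params)
    n_before = len(boxes)
    boxes = filter_negative_tilt(boxes)
    data = ShotData(
        shot_id,
        boxes,
        static,
        spectrum.total_fluence,
        spectrum.central_wavelength,
        sim.oversample,
    )
    return boxes, data, n_before - len(boxes)


def refine_dataset(
    shot_data: dict,
    init_params: dict,
    F_init: StructureFactorTable,
    config: ExperimentConfig,
    noise_params: NoiseParams,
    log=lambda msg: None,
):
    """Alternating per-shot / global refinement cycles plus the final polish.

    Returns (F_refined, per-shot params, last stage-1 results, last stage-2
    result, surviving shot ids).
    """
    sim = config.sim
    F_current = F_init
    current_params = dict(init_params)
    survivors = None
    stage1: dict[int, Stage1Result] = {}
    stage2 = None
    for cycle in range(config.n_cycles):
        for s in shot_data:
            shot_data[s].link_table(F_current)
        final_cycle = cycle == config.n_cycles - 1
        for s in sorted(shot_data):
            res = stage1_refine(
                shot_data[s],
                current_params[s],
                F_current.amplitudes,
                noise_params,
                sim.C,
                sim.d_min,
                max_iter=config.stage1_max_iter,
                # with a refined amplitude set the block alternation is run
                # to its floor; the integration-grade first pass is not
                n_alternations=2 if cycle > 0 else 1,
            )
            stage1[s] = res
            if res.ok:
                current_params[s] = res.params
        if survivors is None:
            survivors = filter_shots(stage1)
        log(
            f"cycle {cycle + 1}: stage 1 complete; "
            f"{len(survivors)}/{len(shot_data)} shots survive"
        )
        stage2 = stage2_refine(
            {s: shot_data[s] for s in survivors},
            {s: current_params[s] for s in survivors},
            F_current,
            noise_params,
            sim.C,
            sim.d_min,
            # intermediate amplitude sets only need to be refinement-grade
            max_iter=config.stage2_max_iter if final_cycle
            else min(100, config.stage2_max_iter),
        )
        F_current = stage2.F
        for s in survivors:
            current_params[s] = stage2.shot_params[s]
        log(f"cycle {cycle + 1}: stage 2 complete after {stage2.n_iterations} iterations")

    if config.final_stage1_polish:
        # last per-shot pass against the converged amplitude set: this is
        # what the orientation/cell metrics (and partiality corrections)
        # report, and what a further cycle would start from
        for s in shot_data:
            shot_data[s].link_table(F_current)
        for s in sorted(shot_data):
            res = stage1_refine(
                shot_data[s],
                current_params[s],
                F_current.amplitudes,
                noise_params,
                sim.C,
                sim.d_min,
                max_iter=config.stage1_max_iter,
                n_alternations=2,
            )
            stage1[s] = res
            if res.ok:
                current_params[s] = res.params
        log("final per-shot polish complete")
    return F_current, current_params, stage1, stage2, survivors


def run_experiment(config: ExperimentConfig, progress=None) -> dict:
    """Run the full pipeline and return a machine-parseable report dict."""
    t_start = time.time()
    log = progress or (lambda msg: None)
    rngs = _substreams(config.seed)
    sim = config.sim
    cell = sim.cell
    noise_params = NoiseParams()
    beam = Beam()
    detector = build_detector(config)

    # ground truth
    structure = random_toy_structure(
        rngs["structure"], n_light_asu=config.n_light_asu, n_heavy_asu=config.n_heavy_asu
    )
    F_truth = toy_structure_factors(structure, cell, sim.d_min)
    F_truth_heavy = heavy_only_anomalous_table(structure, cell, sim.d_min)
    texture = sample_mosaic_texture(rngs["texture"], sim.n_domains, sim.mosaic_spread_deg)
    static = precompute_static_geometry(detector, beam, sim.oversample)
    refl = reflection_set(F_truth)
    gains = [
        sample_gain_map(rngs["gain"], (p.n_slow, p.n_fast), noise_params)
        for p in detector
    ]
    log(f"setup done ({len(F_truth)} unique reflections)")

    # synthesize, index (surrogate), extract shoeboxes
    truth_crystals = {}
    init_params = {}
    shot_data = {}
    spectra = {}
    observations: list[IntegratedObservation] = []
    n_boxes_total = 0
    n_removed_tilt = 0
    for s in range(config.n_shots):
        crystal = sample_ground_truth_crystal(rngs["crystals"], sim, texture)
        spectrum = sample_spectrum(rngs["spectra"], sim)
        images = render_shot(detector, beam, sim, F_truth, crystal, spectrum, static, refl)
        images = [
            apply_noise(rngs["noise"], img, g, noise_params)
            for img, g in zip(images, gains)
        ]
        truth_crystals[s] = crystal
        spectra[s] = spectrum
        est = sample_indexing_estimate(rngs["indexing"], crystal.U, config)
        init_params[s] = est
        boxes, shot_data[s], n_removed = reduce_shot(
            images, est, spectrum, config, detector, beam, static, refl["hkl"],
            noise_params, s,
        )
        n_removed_tilt += n_removed
        n_boxes_total += len(boxes)
        observations.extend(integrate_shoebox(sb, noise_params) for sb in boxes)
        if (s + 1) % 50 == 0:
            log(f"simulated {s + 1}/{config.n_shots} shots")

    # integration baseline
    merged_baseline = merge_monte_carlo(
        observations, cell, sim.d_min, min_multiplicity=config.min_multiplicity
    )
    log(f"baseline merge: {len(merged_baseline.table)} indices from "
        f"{len(observations)} observations")

    # alternating per-shot (stage 1) and global (stage 2) refinement; with an
    # integration-grade starting table the orientation/cell part of stage 1
    # only becomes effective once a refined amplitude set exists, so the
    # default protocol runs two full cycles plus a closing per-shot polish
    F_init = complete_table(merged_baseline.table, F_truth.hkl, cell, sim.d_min)
    F_current, current_params, stage1, stage2, survivors = refine_dataset(
        shot_data, init_params, F_init, config, noise_params, log
    )

    # partiality-corrected integration (final stage-1 model applied to the
    # integrated observations)
    shot_states = {
        s: {
            "U": stage1[s].params.orientation(),
            "B": stage1[s].params.B(),
            "m": stage1[s].params.m,
            "central_wavelength": spectra[s].central_wavelength,
        }
        for s in survivors
        if stage1[s].ok
    }
    corrected = partiality_correct(observations, shot_states, sim.C, beam.direction)
    merged_corrected = merge_monte_carlo(
        corrected, cell, sim.d_min, min_multiplicity=config.min_multiplicity
    )

    # restrict the refined table to indices actually measured (matching the
    # baseline's footprint) for like-for-like metrics
    measured = merged_baseline.table.hkl
    pos = stage2.F.positions(measured)
    F_ml = StructureFactorTable(measured, stage2.F.amplitudes[pos], cell, sim.d_min)

    # metrics
    truth_Us = [truth_crystals[s].U for s in sorted(truth_crystals)]
    init_Us = [init_params[s].U0 for s in sorted(truth_crystals)]
    stage1_Us = [stage1[s].params.orientation() for s in sorted(truth_crystals)]
    mis_init = misorientation_summary(init_Us, truth_Us)
    mis_stage1 = misorientation_summary(stage1_Us, truth_Us)

    failures = []

    def _try(label, fn, *args):
        try:
            return fn(*args)
        except ValueError as err:
            failures.append(f"{label}: {err}")
            return None

    rk_base = _try("r_gt_baseline", r_gt, merged_baseline.table, F_truth)
    rk_corr = _try("r_gt_partiality_corrected", r_gt, merged_corrected.table, F_truth)
    rk_ml = _try("r_gt_ml", r_gt, F_ml, F_truth)
    r_base, k_base = rk_base if rk_base else (np.nan, np.nan)
    r_corr = rk_corr[0] if rk_corr else np.nan
    r_ml, k_ml = rk_ml if rk_ml else (np.nan, np.nan)
    cc_base = _try("cc_ano_baseline", cc_ano, merged_baseline.table, F_truth_heavy)
    cc_corr = _try("cc_ano_partiality_corrected", cc_ano, merged_corrected.table, F_truth_heavy)
    cc_ml = _try("cc_ano_ml", cc_ano, F_ml, F_truth_heavy)
    cc_base = np.nan if cc_base is None else cc_base
    cc_corr = np.nan if cc_corr is None else cc_corr
    cc_ml = np.nan if cc_ml is None else cc_ml

    m_truth = sim.m
    report = {
        "config": config.to_dict(),
        "n_shots": config.n_shots,
        "n_shots_surviving": len(survivors),
        "n_unique_reflections": len(F_truth),
        "n_observations": len(observations),
        "n_shoeboxes_mean_per_shot": n_boxes_total / config.n_shots,
        "n_shoeboxes_removed_negative_tilt_per_shot": n_removed_tilt / config.n_shots,
        "misorientation_median_init_deg": mis_init["median"],
        "misorientation_median_stage1_deg": mis_stage1["median"],
        "misorientation_improvement_factor": (
            mis_init["median"] / mis_stage1["median"]
            if mis_stage1["median"] > 0
            else np.inf
        ),
        "stage1_median_m": float(np.median([stage1[s].params.m for s in survivors])),
        "stage1_median_a": float(np.median([stage1[s].params.a for s in survivors])),
        "stage1_median_c": float(np.median([stage1[s].params.c for s in survivors])),
        "m_truth": m_truth,
        "r_gt_baseline": r_base,
        "r_gt_partiality_corrected": r_corr,
        "r_gt_ml": r_ml,
        "r_gt_relative_improvement": (r_base - r_ml) / r_base if r_base else np.nan,
        "failed_metrics": failures,
        "cc_ano_baseline": cc_base,
        "cc_ano_partiality_corrected": cc_corr,
        "cc_ano_ml": cc_ml,
        "scale_k_baseline": k_base,
        "scale_k_ml": k_ml,
        "stage2_iterations": stage2.n_iterations,
        "stage2_final_nll": stage2.nll_trace[-1] if stage2.nll_trace else np.nan,
        "runtime_seconds": time.time() - t_start,
    }
    report["_objects"] = {
        "F_truth": F_truth,
        "F_truth_heavy": F_truth_heavy,
        "merged_baseline": merged_baseline,
        "merged_corrected": merged_corrected,
        "F_ml": F_ml,
        "stage1": stage1,
        "stage2": stage2,
        "init_params": init_params,
        "truth_crystals": truth_crystals,
        "survivors": survivors,
    }
    return report


def report_to_json(report: dict) -> str:
    clean = {k: v for k, v in report.items() if not k.startswith("_")}
    return json.dumps(clean, indent=1, default=float)


def report_to_text(report: dict) -> str:
    lines = [
        "stillsolver experiment report",
        f"shots: {report['n_shots']} ({report['n_shots_surviving']} after filtering)",
        f"unique reflections: {report['n_unique_reflections']}",
        f"median misorientation: {report['misorientation_median_init_deg']:.4f} deg -> "
        f"{report['misorientation_median_stage1_deg']:.4f} deg "
        f"({report['misorientation_improvement_factor']:.1f}x)",
        f"R_GT: integration {100 * report['r_gt_baseline']:.1f}% | "
        f"partiality-corrected {100 * report['r_gt_partiality_corrected']:.1f}% | "
        f"max likelihood {100 * report['r_gt_ml']:.1f}%",
        f"CC_ano: integration {report['cc_ano_baseline']:.3f} | "
        f"partiality-corrected {report['cc_ano_partiality_corrected']:.3f} | "
        f"max likelihood {report['cc_ano_ml']:.3f}",
        f"runtime: {report['runtime_seconds']:.1f} s",
    ]
    return "\n".join(lines) + "\n"
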