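"""Conventional integrate-then-merge baseline and partiality correction.

This is the comparator and initializer for the pixel-level refinement: each
surviving shoebox is reduced to a single background-subtracted intensity,
per-shot scales are removed by a few rounds of least-squares scaling against
the running per-index means, and symmetry-equivalent observations are
averaged ("Monte Carlo" merging). Amplitudes are the square roots of the
clamped-positive merged intensities.

The partiality correction divides each integrated intensity by the
model-derived partiality P = I0(dh_bar, m_s) / m_s^6 in (0, 1] evaluated
with the shot's refined crystal state at the pulse's central wavelength.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .noise import NoiseParams
from .shoebox import Shoebox, integrated_intensity
from .simulate import interference_r2_cutoff
from .symmetry import StructureFactorTable, UnitCell


@dataclass
class IntegratedObservation:
    shot_id: int
    hkl: np.ndarray  # canonical ASU index
    hkl_obs: np.ndarray
    intensity: float
    sigma: float
    d: float

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")


@dataclass
class MergedAmplitudes:
    table: StructureFactorTable
    multiplicity: np.ndarray
    sigma: np.ndarray

    def write_hkl(self, path_or_buf):
        self.table.write_hkl(
            path_or_buf,
            extra_columns={"mult": self.multiplicity, "sigma": self.sigma},
        )


def integrate_shoebox(shoebox: Shoebox, params: NoiseParams) -> IntegratedObservation:
    """Summation integration: foreground sum minus the fitted plane."""
    I, sig = integrated_intensity(shoebox, params)
    return IntegratedObservation(
        shot_id=shoebox.shot_id,
        hkl=shoebox.hkl,
        hkl_obs=shoebox.hkl_obs,
        intensity=I,
        sigma=sig,
        d=shoebox.d,
    )


def merge_monte_carlo(
    observations: list[IntegratedObservation],
    cell: UnitCell,
    d_min: float,
    min_multiplicity: int = 3,
    n_scaling_rounds: int = 3,
) -> MergedAmplitudes:
    """Scale shots to the running means, then average per index.

    Per-index means are inverse-variance weighted; negative merged
    intensities are clamped to zero before the square root.
    """
    if not observations:
        raise ValueError("no observations to merge")
    hkl = np.array([o.hkl for o in observations])
    I = np.array([o.intensity for o in observations])
    sig = np.array([o.sigma for o in observations])
    shots = np.array([o.shot_id for o in observations])

    uniq_hkl, idx = np.unique(hkl, axis=0, return_inverse=True)
    uniq_shots, sidx = np.unique(shots, return_inverse=True)

    scale = np.ones(len(uniq_shots))
    for _ in range(n_scaling_rounds):
        Is = I / scale[sidx]
        sigs = sig / scale[sidx]
        w = 1.0 / sigs ** 2
        mean_num = np.bincount(idx, weights=w * Is, minlength=len(uniq_hkl))
        mean_den = np.bincount(idx, weights=w, minlength=len(uniq_hkl))
        means = mean_num / mean_den
        # least-squares scale of each shot's raw observations onto the means
        ref = means[idx]
        num = np.bincount(sidx, weights=I * ref, minlength=len(uniq_shots))
        den = np.bincount(sidx, weights=ref * ref, minlength=len(uniq_shots))
        new_scale = np.where(den > 0, num / np.maximum(den, 1e-300), 1.0)
        scale = np.where(new_scale > 0, new_scale, scale)

    Is = I / scale[sidx]
    sigs = sig / scale[sidx]
    w = 1.0 / sigs ** 2
    mean_num = np.bincount(idx, weights=w * Is, minlength=len(uniq_hkl))
    mean_den = np.bincount(idx, weights=w, minlength=len(uniq_hkl))
    means = mean_num / mean_den
    mult = np.bincount(idx, minlength=len(uniq_hkl))
    mean_sig = 1.0 / np.sqrt(mean_den)

    keep = mult >= min_multiplicity
    amps = np.sqrt(np.clip(means[keep], 0.0, None))
    table = StructureFactorTable(uniq_hkl[keep], amps, cell, d_min)
    return MergedAmplitudes(
        table=table, multiplicity=mult[keep], sigma=mean_sig[keep]
    )


def model_partiality(
    hkl_obs, U, B, m: float, central_wavelength: float, C: float, beam_direction
) -> float:
    """P = I0(dh_bar, m)/m^6 for a reflection under the monochromatic model."""
    A = np.asarray(U) @ np.asarray(B)
    q_h = np.asarray(hkl_obs, dtype=float) @ np.linalg.inv(A)
    k_out = q_h + np.asarray(beam_direction) / central_wavelength
    s_hat = k_out / np.linalg.norm(k_out)
    q_probe = (s_hat - np.asarray(beam_direction)) / central_wavelength
    dh = q_probe @ A - np.asarray(hkl_obs, dtype=float)
    r2 = float(dh @ dh)
    if r2 > interference_r2_cutoff(m, C):
        return 0.0
    return float(np.exp(-C * m * m * r2))


def partiality_correct(
    observations: list[IntegratedObservation],
    shot_states: dict,
    C: float,
    beam_direction=(0.0, 0.0, 1.0),
    p_min: float = 0.05,
) -> list[IntegratedObservation]:
    """Divide each observation by its model partiality, floored at p_min.

    ``shot_states`` maps shot_id to a dict with keys U, B, m and
    central_wavelength (the stage-1 refined per-shot model).
    """
    corrected = []
    for obs in observations:
        st = shot_states.get(obs.shot_id)
        if st is None:
            continue
        P = model_partiality(
            obs.hkl_obs, st["U"], st["B"], st["m"], st["central_wavelength"], C, beam_direction
        )
        P = max(P, p_min)
        corrected.append(
            IntegratedObservation(
                shot_id=obs.shot_id,
                hkl=obs.hkl,
                hkl_obs=obs.hkl_obs,
                intensity=obs.intensity / P,
                sigma=obs.sigma / P,
                d=obs.d,
            )
        )
    return corrected
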