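"""Reflection prediction, shoebox extraction, tilt-plane backgrounds and SNR.

A shoebox is a square pixel sub-region assigned to one predicted reflection.
Its peripheral pixels (the outer two-pixel ring) are fitted with a weighted
tilt plane T(x, y) = t1 x + t2 y + t3, the weights being reciprocal crude
variance estimates v_crude = sigma_r^2 + max(X, 0) + sigma_g^2 max(X, 0)^2
(the model variance with the single observed value standing in for the
expectation; the clamp at zero keeps weights monotone for readout-dominated
negative readings). The spot intensity estimate is the background-subtracted
foreground sum, with the tilt-plane parameter covariance propagated into its
variance for the signal-to-noise estimate.

Shoeboxes whose fitted plane dips below zero anywhere in the box are
discarded: a negative background model would break the positivity of the
likelihood's model variance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import Beam
from .noise import NoiseParams
from .simulate import _predict_on_panel
from .symmetry import d_spacing, map_to_asu

DEFAULT_DELTA_PRED = 0.15
BACKGROUND_RING_WIDTH = 2


@dataclass
class Shoebox:
    """One predicted reflection's pixel sub-region on one shot."""

    shot_id: int
    panel_id: int
    bbox: tuple  # (fast0, fast1, slow0, slow1), half-open
    hkl: np.ndarray  # canonical ASU index
    hkl_obs: np.ndarray  # the as-predicted (unreduced) index
    d: float
    X: np.ndarray | None = None  # (n_slow, n_fast) pixel values, photon units
    background_mask: np.ndarray | None = None
    tilt: np.ndarray | None = None
    tilt_covariance: np.ndarray | None = None
    snr: float = np.nan
    centroid: tuple = (np.nan, np.nan)

    @property
    def shape(self):
        f0, f1, s0, s1 = self.bbox
        return (s1 - s0, f1 - f0)

    def pixel_coords(self):
        """Absolute (fast, slow) coordinate grids of the box pixels."""
        f0, f1, s0, s1 = self.bbox
        ff, ss = np.meshgrid(np.arange(f0, f1), np.arange(s0, s1), indexing="xy")
        return ff, ss

    def tilt_values(self):
        """Background plane evaluated on every pixel of the box."""
        if self.tilt is None:
            raise ValueError("tilt plane not fitted")
        ff, ss = self.pixel_coords()
        return self.tilt[0] * ff + self.tilt[1] * ss + self.tilt[2]


def _ring_mask(n_slow: int, n_fast: int, width: int = BACKGROUND_RING_WIDTH):
    mask = np.zeros((n_slow, n_fast), dtype=bool)
    mask[:width, :] = True
    mask[-width:, :] = True
    mask[:, :width] = True
    mask[:, -width:] = True
    return mask


def predict_shoeboxes(
    U,
    B,
    detector,
    beam: Beam,
    central_wavelength: float,
    d_min: float,
    box_size: int = 11,
    delta_pred: float = DEFAULT_DELTA_PRED,
    reflections: np.ndarray | None = None,
    cell=None,
    shot_id: int = 0,
) -> list[Shoebox]:
    """Shoebox skeletons for reflections near the Ewald sphere.

    A reflection is predicted when its monochromatic Ewald offset satisfies
    |dh|_inf < delta_pred and d >= d_min; over-prediction is deliberate and
    harmless for likelihood refinement. Boxes are centered on the predicted
    centroid and truncated at panel edges (dropped if fewer than
    (2*ring + 1)^2 pixels survive).
    """
    from .symmetry import full_reflection_list
    from .geometry import UnitCell

    if cell is None:
        cell = UnitCell(B[0, 0], B[2, 2])
    if reflections is None:
        reflections = full_reflection_list(cell, d_min)
    A = np.asarray(U, dtype=float) @ np.asarray(B, dtype=float)
    d_all = d_spacing(reflections, cell)
    half = box_size // 2
    min_extent = 2 * BACKGROUND_RING_WIDTH + 1
    boxes: list[Shoebox] = []
    for panel_id, panel in enumerate(detector):
        on_panel, fast, slow, dh_inf = _predict_on_panel(
            panel, beam, A, reflections, central_wavelength
        )
        sel = np.flatnonzero(on_panel & (dh_inf < delta_pred) & (d_all >= d_min))
        for i in sel:
            cf = int(np.floor(fast[i]))
            cs = int(np.floor(slow[i]))
            f0 = max(cf - half, 0)
            f1 = min(cf + half + 1, panel.n_fast)
            s0 = max(cs - half, 0)
            s1 = min(cs + half + 1, panel.n_slow)
            if f1 - f0 < min_extent or s1 - s0 < min_extent:
                continue
            canon, _ = map_to_asu(reflections[i])
            boxes.append(
                Shoebox(
                    shot_id=shot_id,
                    panel_id=panel_id,
                    bbox=(f0, f1, s0, s1),
                    hkl=canon,
                    hkl_obs=reflections[i].copy(),
                    d=float(d_all[i]),
                    centroid=(float(fast[i]), float(slow[i])),
                )
            )
    return boxes


def extract_pixels(shoebox: Shoebox, image: np.ndarray) -> Shoebox:
    """Fill a skeleton with pixel values and the peripheral background mask."""
    f0, f1, s0, s1 = shoebox.bbox
    shoebox.X = np.asarray(image[s0:s1, f0:f1], dtype=float).copy()
    shoebox.background_mask = _ring_mask(s1 - s0, f1 - f0)
    return shoebox


def crude_variance(X, params: NoiseParams):
    """v_crude = sigma_r^2 + max(X, 0) + sigma_g^2 max(X, 0)^2."""
    Xc = np.maximum(np.asarray(X, dtype=float), 0.0)
    return params.sigma_r ** 2 + Xc + params.sigma_g ** 2 * Xc * Xc


def fit_tilt_plane(
    shoebox: Shoebox,
    params: NoiseParams,
    n_iterations: int = 30,
    tol: float = 1e-9,
) -> Shoebox:
    """Weighted least-squares tilt plane over the background ring.

    Solves t = (A^T W A)^-1 A^T W b with rows (x_i, y_i, 1) and
    W = diag(1 / v_crude); stores t and its covariance (A^T W A)^-1.

    The first pass weights with v_crude evaluated at the observed values
    (the single-measurement variance guess). At photon-scale backgrounds
    those weights are strongly biased — downward-fluctuating pixels get far
    more weight than upward ones, dragging the plane toward zero — so
    subsequent passes re-evaluate v_crude at the current plane prediction
    (iteratively reweighted least squares), stopping when the coefficients
    change by less than ``tol`` (relative) or after ``n_iterations`` passes.
    ``n_iterations=1`` reproduces the plain one-step weighted solve.
    """
    if shoebox.X is None or shoebox.background_mask is None:
        raise ValueError("shoebox pixels not extracted")
    ff, ss = shoebox.pixel_coords()
    mask = shoebox.background_mask
    x = ff[mask].astype(float)
    y = ss[mask].astype(float)
    b = shoebox.X[mask]
    if len(b) < 3:
        raise ValueError(f"too few background pixels in shoebox {shoebox.bbox}")
    A = np.stack([x, y, np.ones_like(x)], axis=1)
    ref = b
    cov = None
    t_prev = None
    for _ in range(max(n_iterations, 1)):
        w = 1.0 / crude_variance(ref, params)
        AtWA = A.T @ (A * w[:, None])
        try:
            cov = np.linalg.inv(AtWA)
        except np.linalg.LinAlgError as err:
            raise ValueError(
                f"rank-deficient background in shoebox {shoebox.bbox}"
            ) from err
        t = cov @ (A.T @ (w * b))
        ref = A @ t  # next pass: variance at the plane prediction
        if t_prev is not None and np.max(np.abs(t - t_prev)) <= tol * (
            1.0 + np.max(np.abs(t))
        ):
            break
        t_prev = t
    shoebox.tilt = t
    shoebox.tilt_covariance = cov
    return shoebox


def snr_estimate(shoebox: Shoebox, params: NoiseParams) -> float:
    """Background-subtracted foreground sum over its propagated sigma.

    var(I) = sum_fg v_crude + p^T Cov(t) p, where p accumulates the plane's
    evaluation vectors over the foreground.
    """
    if shoebox.tilt is None:
        raise ValueError("tilt plane not fitted")
    ff, ss = shoebox.pixel_coords()
    fg = ~shoebox.background_mask
    T = shoebox.tilt_values()
    I = float((shoebox.X[fg] - T[fg]).sum())
    p = np.array([ff[fg].sum(), ss[fg].sum(), fg.sum()], dtype=float)
    var = float(crude_variance(shoebox.X[fg], params).sum() + p @ shoebox.tilt_covariance @ p)
    shoebox.snr = I / np.sqrt(var)
    return shoebox.snr


def integrated_intensity(shoebox: Shoebox, params: NoiseParams):
    """(I, sigma): foreground sum minus plane, and its propagated sigma."""
    if shoebox.tilt is None:
        raise ValueError("tilt plane not fitted")
    ff, ss = shoebox.pixel_coords()
    fg = ~shoebox.background_mask
    T = shoebox.tilt_values()
    I = float((shoebox.X[fg] - T[fg]).sum())
    p = np.array([ff[fg].sum(), ss[fg].sum(), fg.sum()], dtype=float)
    var = float(crude_variance(shoebox.X[fg], params).sum() + p @ shoebox.tilt_covariance @ p)
    return I, float(np.sqrt(var))


def filter_negative_tilt(shoeboxes: list[Shoebox]) -> list[Shoebox]:
    """Keep only shoeboxes whose plane is non-negative over the whole box.

    The plane is linear, so its minimum over the box is attained at a corner.
    """
    kept = []
    for sb in shoeboxes:
        if sb.tilt is None:
            raise ValueError("tilt plane not fitted")
        f0, f1, s0, s1 = sb.bbox
        corners = [
            sb.tilt[0] * f + sb.tilt[1] * s + sb.tilt[2]
            for f in (f0, f1 - 1)
            for s in (s0, s1 - 1)
        ]
        if min(corners) >= 0:
            kept.append(sb)
    return kept


def shoeboxes_to_frame(shoeboxes: list[Shoebox]):
    """Flat pandas table (shot, h, k, l, d, SNR, t1, t2, t3) for inspection."""
    import pandas as pd

    rows = [
        {
            "shot": sb.shot_id,
            "panel": sb.panel_id,
            "h": int(sb.hkl[0]),
            "k": int(sb.hkl[1]),
            "l": int(sb.hkl[2]),
            "d": sb.d,
            "snr": sb.snr,
            "t1": np.nan if sb.tilt is None else sb.tilt[0],
            "t2": np.nan if sb.tilt is None else sb.tilt[1],
            "t3": np.nan if sb.tilt is None else sb.tilt[2],
        }
        for sb in shoeboxes
    ]
    return pd.DataFrame(rows)
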