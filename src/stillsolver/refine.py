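"""Pixel-level maximum-likelihood refinement of per-shot crystal parameters
and global structure-factor amplitudes.

The photon model for a shoebox pixel i of shot s is monochromatic and
single-domain:

    n_i(Theta) = T_i + dOmega_i J_s r_e^2 kappa_i G_s |F_h|^2 I0(dh_i, m_s)

with T_i the frozen tilt-plane background, J_s the total pulse fluence,
dh_i the Ewald offset at the pulse's central wavelength under the shot's
current (U_s, B_s), and I0 the truncated Gaussian interference factor. The
negative log likelihood treats each pixel as normal with mean n and variance
v(n) = sigma_r^2 + n + sigma_g^2 n^2, so

    dNLL/dn = (1 + 2 sigma_g^2 n) / (2 v) * (1 - (X - n)^2 / v) - (X - n)/v.

All derivatives are analytic and composed through per-parameter
reparameterizations x -> theta chosen so every optimizer coordinate starts
at 1 with unit expected variation; bounded parameters (G, m, |F|) use an
exponential map that keeps them strictly above their lower bound.

Refinement protocol: stage 1 refines each shot alone ((G_s, m_s) on
low-resolution high-SNR shoeboxes, then orientation and cell edges on all
usable shoeboxes); outlier shots are removed by a robust median/MAD rule;
stage 2 resets m_s and G_s to their medians and refines {|F_h|} plus all
G_s globally with L-BFGS (memory 10).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize

from .geometry import R_E_SQUARED_A2, orientation_and_derivatives
from .noise import NoiseParams
from .shoebox import Shoebox
from .simulate import interference_r2_cutoff, _UM2_TO_A2
from .symmetry import StructureFactorTable

# expected parameter variations (sigma_theta) used in the reparameterization
SIGMA_U_DEG = 0.001
SIGMA_CELL_A = 0.1
SIGMA_G = 1.0
SIGMA_M = 0.1
SIGMA_F = 1.0

STAGE1_LOWRES_D = 5.0
STAGE1_LOWRES_SNR = 3.0
STAGE_SNR_CUT = 0.2
LBFGS_MEMORY = 10
GRAD_TOL = 1e-3


# ---------------------------------------------------------------------------
# reparameterization
# ---------------------------------------------------------------------------

class LinearReparam:
    """theta = theta_o + sigma (x - 1); unbounded."""

    def __init__(self, theta_o: float, sigma: float):
        if sigma <= 0:
            raise ValueError("sigma must be positive")
        self.theta_o = float(theta_o)
        self.sigma = float(sigma)

    def theta(self, x):
        return self.theta_o + self.sigma * (np.asarray(x, dtype=float) - 1.0)

    def dtheta_dx(self, x):
        return np.full_like(np.asarray(x, dtype=float), self.sigma)

    def x_of(self, theta):
        return 1.0 + (np.asarray(theta, dtype=float) - self.theta_o) / self.sigma


class BoundedReparam:
    """theta = theta_min + (theta_o - theta_min) exp(sigma (x - 1)) > theta_min."""

    def __init__(self, theta_o: float, sigma: float, theta_min: float = 0.0):
        if sigma <= 0:
            raise ValueError("sigma must be positive")
        if theta_min < 0:
            raise ValueError("theta_min must be >= 0")
        if theta_o <= theta_min:
            raise ValueError("initial value must exceed the lower bound")
        self.theta_o = float(theta_o)
        self.sigma = float(sigma)
        self.theta_min = float(theta_min)

    def theta(self, x):
        # clip the exponent so extreme line-search trial points cannot
        # underflow the parameter onto its bound (the map must stay > min)
        arg = np.clip(self.sigma * (np.asarray(x, dtype=float) - 1.0), -500.0, 500.0)
        return self.theta_min + (self.theta_o - self.theta_min) * np.exp(arg)

    def dtheta_dx(self, x):
        return self.sigma * (self.theta(x) - self.theta_min)

    def x_of(self, theta):
        return 1.0 + np.log(
            (np.asarray(theta, dtype=float) - self.theta_min)
            / (self.theta_o - self.theta_min)
        ) / self.sigma


def reparameterize(theta_o: float, sigma: float, theta_min: float | None = None):
    """Factory: unbounded linear map, or exponential map above theta_min."""
    if theta_min is None:
        return LinearReparam(theta_o, sigma)
    return BoundedReparam(theta_o, sigma, theta_min)


# ---------------------------------------------------------------------------
# per-shot parameter set and packed pixel data
# ---------------------------------------------------------------------------

@dataclass
class ShotParams:
    """Gamma_s: three orientation angles (deg, about lab axes, relative to the
    reference orientation U0), cell edges, scale and mosaic parameter."""

    U0: np.ndarray
    angles_deg: np.ndarray = field(default_factory=lambda: np.zeros(3))
    a: float = 79.1
    c: float = 38.4
    G: float = 1.0e6
    m: float = 13.7

    def __post_init__(self):
        self.U0 = np.asarray(self.U0, dtype=float)
        self.angles_deg = np.asarray(self.angles_deg, dtype=float)
        if self.a <= 0 or self.c <= 0 or self.G <= 0 or self.m <= 0:
            raise ValueError("cell edges, G and m must be positive")

    def orientation(self):
        U, _ = orientation_and_derivatives(self.angles_deg, self.U0)
        return U

    def B(self):
        return np.diag([self.a, self.a, self.c])


class ShotData:
    """Packed pixel data of one shot's shoeboxes for fast model evaluation.

    Subpixels are ordered box-major then pixel-major; every pixel carries
    exactly os^2 subpixels, so per-pixel quantities broadcast by reshape.
    """

    def __init__(
        self,
        shot_id: int,
        shoeboxes: list[Shoebox],
        static,
        total_fluence_per_um2: float,
        central_wavelength: float,
        oversample: int,
    ):
        self.shot_id = shot_id
        self.central_wavelength = float(central_wavelength)
        self.oversample = oversample
        os2 = oversample * oversample
        u0_parts, pref_parts = [], []
        T_parts, X_parts = [], []
        h_parts, d_parts, snr_parts, box_parts = [], [], [], []
        key_parts, dist_parts = [], []
        for bi, sb in enumerate(shoeboxes):
            f0, f1, s0, s1 = sb.bbox
            st = static[sb.panel_id]
            u0 = st["u0"][s0:s1, f0:f1].reshape(-1, os2, 3)
            pref = st["prefac"][s0:s1, f0:f1].reshape(-1, os2)
            n_px = u0.shape[0]
            u0_parts.append(u0.reshape(-1, 3))
            pref_parts.append(pref.reshape(-1))
            T_parts.append(sb.tilt_values().reshape(-1))
            X_parts.append(sb.X.reshape(-1))
            h_parts.append(np.broadcast_to(sb.hkl_obs.astype(float), (n_px, 3)))
            d_parts.append(np.full(n_px, sb.d))
            snr_parts.append(np.full(n_px, sb.snr))
            box_parts.append(np.full(n_px, bi, dtype=np.int64))
            ff, ss = np.meshgrid(np.arange(f0, f1), np.arange(s0, s1), indexing="xy")
            key_parts.append(
                (np.int64(sb.panel_id) << 40)
                + (ss.ravel().astype(np.int64) << 20)
                + ff.ravel().astype(np.int64)
            )
            cf, cs = sb.centroid
            dist_parts.append(
                (ff.ravel() + 0.5 - cf) ** 2 + (ss.ravel() + 0.5 - cs) ** 2
            )
        self.n_boxes = len(shoeboxes)
        self.u0 = np.concatenate(u0_parts)
        J_A2 = total_fluence_per_um2 * _UM2_TO_A2
        self.prefac = np.concatenate(pref_parts) * J_A2 * R_E_SQUARED_A2
        self.T = np.concatenate(T_parts)
        self.X = np.concatenate(X_parts)
        self.h_obs = np.ascontiguousarray(np.concatenate(h_parts))
        self.d = np.concatenate(d_parts)
        self.snr = np.concatenate(snr_parts)
        self.box_of_px = np.concatenate(box_parts)
        self.n_px = len(self.X)
        # where predicted boxes overlap, a physical pixel is owned by the box
        # with the nearest predicted centroid; the other copies are excluded
        # from the likelihood (their reflection is unmodeled at that pixel)
        keys = np.concatenate(key_parts) if key_parts else np.empty(0, np.int64)
        dists = np.concatenate(dist_parts) if dist_parts else np.empty(0)
        self.owned = np.ones(self.n_px, dtype=bool)
        if self.n_px:
            order = np.lexsort((dists, keys))
            sk = keys[order]
            first = np.ones(len(sk), dtype=bool)
            first[1:] = sk[1:] != sk[:-1]
            owned_sorted = first
            self.owned[order] = owned_sorted
        # global structure-factor table positions, filled by link_table()
        self.f_pos = None
        self.shoeboxes = shoeboxes

    def link_table(self, table: StructureFactorTable):
        """Resolve each pixel's canonical index to a row of the global table."""
        box_hkl = np.array([sb.hkl for sb in self.shoeboxes], dtype=np.int64)
        box_pos = table.positions(box_hkl) if len(box_hkl) else np.empty(0, np.int64)
        self.f_pos = box_pos[self.box_of_px]

    def pixel_mask(self, snr_min=None, d_min=None, d_max=None):
        mask = self.owned.copy()
        if snr_min is not None:
            mask &= self.snr > snr_min
        if d_min is not None:
            mask &= self.d >= d_min
        if d_max is not None:
            mask &= self.d > d_max  # "low resolution": d above the threshold
        return mask


# ---------------------------------------------------------------------------
# model and likelihood
# ---------------------------------------------------------------------------

def _sub_expand(mask_px, os2):
    return np.repeat(mask_px, os2)


def model_photons(
    data: ShotData,
    params: ShotParams,
    F_amps: np.ndarray,
    C: float,
    px_mask=None,
    with_cache: bool = False,
):
    """Expected photons per selected pixel under the monochromatic model."""
    os2 = data.oversample ** 2
    if px_mask is None:
        px_mask = np.ones(data.n_px, dtype=bool)
    sub_mask = _sub_expand(px_mask, os2)
    u0 = data.u0[sub_mask]
    pref = data.prefac[sub_mask]
    h = np.repeat(data.h_obs[px_mask], os2, axis=0)
    U = params.orientation()
    w = (u0 @ U) / data.central_wavelength  # rows of U^T q
    diag = np.array([params.a, params.a, params.c])
    dh = w * diag - h
    r2 = np.einsum("ij,ij->i", dh, dh)
    cut = interference_r2_cutoff(params.m, C)
    cm2 = C * params.m ** 2
    i0 = np.where(r2 <= cut, params.m ** 6 * np.exp(-cm2 * r2), 0.0)
    famp = F_amps[data.f_pos[px_mask]]
    famp_sub = np.repeat(famp, os2)
    bragg_sub = pref * params.G * famp_sub ** 2 * i0
    n = data.T[px_mask] + bragg_sub.reshape(-1, os2).sum(axis=1)
    if not with_cache:
        return n
    cache = {
        "bragg_sub": bragg_sub,
        "r2": r2,
        "w": w,
        "dh": dh,
        "famp_sub": famp_sub,
        "os2": os2,
        "px_mask": px_mask,
        "sub_mask": sub_mask,
    }
    return n, cache


def negative_log_likelihood(X, n, noise: NoiseParams):
    """Sum over pixels of 0.5 log(2 pi v) + (X - n)^2 / (2 v)."""
    v = noise.sigma_r ** 2 + n + noise.sigma_g ** 2 * n * n
    if np.any(v <= 0):
        raise ValueError("non-positive model variance in likelihood")
    return float(np.sum(0.5 * np.log(2.0 * np.pi * v) + (X - n) ** 2 / (2.0 * v)))


def _dnll_dn(X, n, noise: NoiseParams):
    v = noise.sigma_r ** 2 + n + noise.sigma_g ** 2 * n * n
    if np.any(v <= 0):
        raise ValueError("non-positive model variance in likelihood")
    resid = X - n
    dv_dn = 1.0 + 2.0 * noise.sigma_g ** 2 * n
    return dv_dn / (2.0 * v) * (1.0 - resid ** 2 / v) - resid / v


def shot_nll_and_grads(
    data: ShotData,
    params: ShotParams,
    F_amps: np.ndarray,
    noise: NoiseParams,
    C: float,
    px_mask=None,
    active=("angles", "cell", "G", "m"),
    grad_F: bool = False,
    n_global_F: int = 0,
):
    """NLL over the selected pixels and analytic gradients in theta-space.

    Returns (nll, grads) where grads holds, per request: 'angles' (3,),
    'a', 'c', 'G', 'm' scalars, and 'F' (n_global_F,) accumulated via the
    pixel-to-table assignment.
    """
    n, cache = model_photons(data, params, F_amps, C, px_mask, with_cache=True)
    px_mask = cache["px_mask"]
    X = data.X[px_mask]
    nll = negative_log_likelihood(X, n, noise)
    dn = _dnll_dn(X, n, noise)  # per pixel
    os2 = cache["os2"]
    dn_sub = np.repeat(dn, os2)
    bragg_sub = cache["bragg_sub"]
    dh = cache["dh"]
    w = cache["w"]
    cm2 = C * params.m ** 2
    grads = {}
    base = dn_sub * bragg_sub  # common factor for log-derivative parameters
    if "G" in active:
        grads["G"] = float(base.sum() / params.G)
    if "m" in active:
        r2 = cache["r2"]
        grads["m"] = float(np.sum(base * (6.0 / params.m - 2.0 * C * params.m * r2)))
    if "cell" in active:
        grads["a"] = float(
            np.sum(base * (-2.0 * cm2) * (dh[:, 0] * w[:, 0] + dh[:, 1] * w[:, 1]))
        )
        grads["c"] = float(np.sum(base * (-2.0 * cm2) * dh[:, 2] * w[:, 2]))
    if "angles" in active:
        _, dUs = orientation_and_derivatives(params.angles_deg, params.U0)
        u0 = data.u0[cache["sub_mask"]]
        diag = np.array([params.a, params.a, params.c])
        g_ang = np.empty(3)
        for i, dU in enumerate(dUs):
            dw = (u0 @ dU) / data.central_wavelength
            dhf = dw * diag
            g_ang[i] = np.sum(base * (-2.0 * cm2) * np.einsum("ij,ij->i", dh, dhf))
        grads["angles"] = g_ang
    if grad_F:
        famp_sub = cache["famp_sub"]
        wts = np.where(famp_sub > 0, 2.0 * base / np.where(famp_sub > 0, famp_sub, 1.0), 0.0)
        fpos_sub = np.repeat(data.f_pos[px_mask], os2)
        grads["F"] = np.bincount(fpos_sub, weights=wts, minlength=n_global_F)
    return nll, grads


# ---------------------------------------------------------------------------
# stage 1: per-shot refinement
# ---------------------------------------------------------------------------

@dataclass
class Stage1Result:
    params: ShotParams
    ok: bool
    nll_trace: list = field(default_factory=list)
    message: str = ""


def stage1_refine(
    data: ShotData,
    init: ShotParams,
    F_amps: np.ndarray,
    noise: NoiseParams,
    C: float,
    d_min: float,
    lowres_d: float = STAGE1_LOWRES_D,
    lowres_snr: float = STAGE1_LOWRES_SNR,
    snr_cut: float = STAGE_SNR_CUT,
    max_iter: int = 100,
    n_alternations: int = 1,
) -> Stage1Result:
    """Two-part per-shot refinement with all other parameters fixed.

    Part 1: (G_s, m_s) on low-resolution (d > lowres_d) shoeboxes with
    SNR > lowres_snr. Part 2: orientation angles and cell edges on all
    shoeboxes with SNR > snr_cut and d >= d_min. The two parts are block
    coordinate descent; ``n_alternations`` repeats the part-1/part-2 pair
    (a second alternation is what brings the orientation block to its
    converged floor once a refined amplitude set is available).
    """
    params = replace(init, angles_deg=init.angles_deg.copy())
    trace = []

    mask1 = data.pixel_mask(snr_min=lowres_snr, d_max=lowres_d)
    n_boxes1 = len(np.unique(data.box_of_px[mask1]))
    if n_boxes1 < 3:
        return Stage1Result(params=params, ok=False, message="too few low-res shoeboxes")

    mask2 = data.pixel_mask(snr_min=snr_cut, d_min=d_min)
    if not np.any(mask2):
        return Stage1Result(params=params, ok=False, message="no usable shoeboxes")

    for _ in range(max(n_alternations, 1)):
        params = _stage1_part1(
            data, params, F_amps, noise, C, mask1, max_iter, trace
        )
        params = _stage1_part2(
            data, params, F_amps, noise, C, mask2, max_iter, trace
        )
    return Stage1Result(params=params, ok=True, nll_trace=trace)


def _stage1_part1(data, params, F_amps, noise, C, mask1, max_iter, trace):
    rp_G = reparameterize(params.G, SIGMA_G, 0.0)
    rp_m = reparameterize(params.m, SIGMA_M, 0.0)

    def fg1(x):
        p = replace(params, G=float(rp_G.theta(x[0])), m=float(rp_m.theta(x[1])))
        nll, g = shot_nll_and_grads(
            data, p, F_amps, noise, C, px_mask=mask1, active=("G", "m")
        )
        if not np.isfinite(nll):
            return 1e300, np.zeros(2)
        trace.append(nll)
        return nll, np.array(
            [g["G"] * rp_G.dtheta_dx(x[0]), g["m"] * rp_m.dtheta_dx(x[1])]
        )

    res1 = minimize(
        fg1,
        np.array([1.0, 1.0]),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": max_iter, "maxcor": LBFGS_MEMORY, "gtol": GRAD_TOL},
    )
    return replace(
        params, G=float(rp_G.theta(res1.x[0])), m=float(rp_m.theta(res1.x[1]))
    )


def _stage1_part2(data, params, F_amps, noise, C, mask2, max_iter, trace):
    rp_ang = [reparameterize(params.angles_deg[i], SIGMA_U_DEG) for i in range(3)]
    rp_a = reparameterize(params.a, SIGMA_CELL_A)
    rp_c = reparameterize(params.c, SIGMA_CELL_A)

    def fg2(x):
        ang = np.array([rp_ang[i].theta(x[i]) for i in range(3)])
        p = replace(
            params,
            angles_deg=ang,
            a=float(rp_a.theta(x[3])),
            c=float(rp_c.theta(x[4])),
        )
        nll, g = shot_nll_and_grads(
            data, p, F_amps, noise, C, px_mask=mask2, active=("angles", "cell")
        )
        if not np.isfinite(nll):
            return 1e300, np.zeros(5)
        trace.append(nll)
        grad = np.empty(5)
        for i in range(3):
            grad[i] = g["angles"][i] * rp_ang[i].dtheta_dx(x[i])
        grad[3] = g["a"] * rp_a.dtheta_dx(x[3])
        grad[4] = g["c"] * rp_c.dtheta_dx(x[4])
        return nll, grad

    res2 = minimize(
        fg2,
        np.ones(5),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": max_iter, "maxcor": LBFGS_MEMORY, "gtol": GRAD_TOL},
    )
    return replace(
        params,
        angles_deg=np.array([rp_ang[i].theta(res2.x[i]) for i in range(3)]),
        a=float(rp_a.theta(res2.x[3])),
        c=float(rp_c.theta(res2.x[4])),
    )


def filter_shots(results: dict[int, Stage1Result], n_mad: float = 4.0) -> list[int]:
    """Surviving shot ids: every one of a, c, m, log G within median +/-
    n_mad robust standard deviations (1.4826 MAD) of its distribution."""
    ids = [sid for sid, r in results.items() if r.ok]
    if not ids:
        return []
    feats = np.array(
        [
            [results[sid].params.a, results[sid].params.c, results[sid].params.m,
             np.log(results[sid].params.G)]
            for sid in ids
        ]
    )
    med = np.median(feats, axis=0)
    mad = np.median(np.abs(feats - med), axis=0)
    lim = n_mad * 1.4826 * mad
    ok = np.all(np.abs(feats - med) <= lim, axis=1)
    return [sid for sid, good in zip(ids, ok) if good]


# ---------------------------------------------------------------------------
# stage 2: global refinement
# ---------------------------------------------------------------------------

@dataclass
class Stage2Result:
    F: StructureFactorTable
    shot_params: dict
    nll_trace: list
    n_iterations: int


def stage2_refine(
    shot_data: dict[int, ShotData],
    stage1_params: dict[int, ShotParams],
    F_init: StructureFactorTable,
    noise: NoiseParams,
    C: float,
    d_min: float,
    snr_cut: float = STAGE_SNR_CUT,
    max_iter: int = 500,
    callback=None,
) -> Stage2Result:
    """Global refinement of {|F_h|} and per-shot scales G_s.

    At entry every m_s and G_s is reset to its across-shot median (the two
    parameters are strongly correlated per shot; the medians give a common
    well-conditioned starting point); m_s then stays fixed while G_s and the
    amplitudes refine. Structure factors without any measured pixel keep
    their initial values exactly (zero gradient through the bounded map).
    """
    sids = sorted(shot_data)
    if not sids:
        raise ValueError("no shots to refine")
    m_med = float(np.median([stage1_params[s].m for s in sids]))
    G_med = float(np.median([stage1_params[s].G for s in sids]))
    params = {
        s: replace(stage1_params[s], m=m_med, G=G_med,
                   angles_deg=stage1_params[s].angles_deg.copy())
        for s in sids
    }

    n_F = len(F_init)
    # strictly positive starting amplitudes for the exponential bound map
    amps0 = F_init.amplitudes.copy()
    floor = max(1e-3 * np.median(amps0[amps0 > 0]), 1e-6) if np.any(amps0 > 0) else 1e-6
    amps0 = np.maximum(amps0, floor)

    masks = {s: shot_data[s].pixel_mask(snr_min=snr_cut, d_min=d_min) for s in sids}
    for s in sids:
        shot_data[s].link_table(F_init)

    rp_G = {s: reparameterize(params[s].G, SIGMA_G, 0.0) for s in sids}
    rp_F = BoundedVectorReparam(amps0, SIGMA_F, 0.0)

    n_shots = len(sids)
    trace = []

    def fg(x):
        xg = x[:n_shots]
        xf = x[n_shots:]
        F_amps = rp_F.theta(xf)
        total = 0.0
        grad = np.zeros_like(x)
        gF_total = np.zeros(n_F)
        for i, s in enumerate(sids):
            p = replace(params[s], G=float(rp_G[s].theta(xg[i])))
            nll, g = shot_nll_and_grads(
                shot_data[s], p, F_amps, noise, C,
                px_mask=masks[s], active=("G",), grad_F=True, n_global_F=n_F,
            )
            total += nll
            grad[i] = g["G"] * rp_G[s].dtheta_dx(xg[i])
            gF_total += g["F"]
        grad[n_shots:] = gF_total * rp_F.dtheta_dx(xf)
        if not np.isfinite(total):
            # overflowed line-search trial: report a huge value so the
            # optimizer backtracks (a non-finite accepted state aborts below)
            return 1e300, np.zeros_like(x)
        trace.append(total)
        return total, grad

    x0 = np.ones(n_shots + n_F)
    res = minimize(
        fg,
        x0,
        jac=True,
        method="L-BFGS-B",
        callback=callback,
        options={"maxiter": max_iter, "maxcor": LBFGS_MEMORY, "gtol": GRAD_TOL},
    )
    if not np.isfinite(res.fun):
        raise FloatingPointError(
            f"divergent negative log-likelihood in stage 2 (state: {res.message})"
        )
    F_refined = StructureFactorTable(
        F_init.hkl, rp_F.theta(res.x[n_shots:]), F_init.cell, F_init.d_min
    )
    out_params = {
        s: replace(params[s], G=float(rp_G[s].theta(res.x[i])))
        for i, s in enumerate(sids)
    }
    return Stage2Result(
        F=F_refined, shot_params=out_params, nll_trace=trace, n_iterations=res.nit
    )


class BoundedVectorReparam:
    """Vectorized exponential bound map for the amplitude block."""

    def __init__(self, theta_o: np.ndarray, sigma: float, theta_min: float = 0.0):
        theta_o = np.asarray(theta_o, dtype=float)
        if np.any(theta_o <= theta_min):
            raise ValueError("initial values must exceed the lower bound")
        self.theta_o = theta_o
        self.sigma = float(sigma)
        self.theta_min = float(theta_min)

    def theta(self, x):
        arg = np.clip(self.sigma * (np.asarray(x, dtype=float) - 1.0), -500.0, 500.0)
        return self.theta_min + (self.theta_o - self.theta_min) * np.exp(arg)

    def dtheta_dx(self, x):
        return self.sigma * (self.theta(x) - self.theta_min)
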