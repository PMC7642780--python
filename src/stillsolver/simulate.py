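"""Kinematic forward model for still diffraction images.

Expected Bragg photons in pixel i of shot s:

    I_i = dOmega_i * sum_lambda J_s(lambda) * [ r_e^2 kappa_i * (Z_s / N_j)
          * sum_j |F_h(i,j,lambda)|^2 * I0(dh_{i,j,lambda}, m) ]

with the Gaussian lattice-interference factor

    I0(dh, m) = m^6 exp(-C m^2 dh.dh),

whose peak m^6 is the squared number of unit cells in a mosaic block and
whose width constant C = 3.175 matches the full width at half maximum of a
parallelepiped block. dh is the Ewald offset: the residual between the
fractional Miller index (U B)^T q probed by the pixel and the nearest integer
index. Mosaic texture is an average over N_j misoriented domains; the
polychromatic pulse is a sum over spectrum channels.

Water background follows the same cross-section structure with an isotropic
per-molecule amplitude curve and the irradiated liquid volume (jet path x
beam cross-section).

The interference factor is evaluated only where it exceeds ~1e-11 of its
peak (a hard support cutoff, identical in the simulator and the refinement
model, so the two agree pixel for pixel).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
from numba import njit

from .geometry import (
    Beam,
    DetectorPanel,
    R_E_SQUARED_A2,
    UnitCell,
    angstrom_to_ev,
    b_matrix,
    ev_to_angstrom,
    panel_subpixel_grids,
    random_rotation,
    rotation_about_axis,
)
from .symmetry import StructureFactorTable, full_reflection_list, map_to_asu

AVOGADRO = 6.02214076e23
WATER_MOLAR_MASS = 18.01528  # g/mol
WATER_DENSITY = 1.0  # g/cm^3

#: interference support: evaluate while exp(-C m^2 r2) >= exp(-EXP_CUTOFF)
EXP_CUTOFF = 25.0
#: never evaluate beyond |dh| = 0.45 (nearest-integer residual domain)
MAX_R_CUT = 0.45


# ---------------------------------------------------------------------------
# configuration and domain types
# ---------------------------------------------------------------------------

@dataclass
class SimConfig:
    """Synthetic-data study conditions.

    Defaults are the conditions of the simulated experiment: tetragonal cell
    79.1/38.4 A, mosaic parameter m = 10 (1000 unit cells per domain), 100
    texture domains of 0.01 deg spread, crystal scale Z ~ Normal(1150, 115),
    8e10 photons per pulse in a 1 um beam at 9034 eV with a spiky SASE-like
    spectrum, 5 um of water background, 2 x 2 pixel oversampling and
    interference-width constant C = 3.175.
    """

    cell_a: float = 79.1
    cell_c: float = 38.4
    d_min: float = 2.1
    C: float = 3.175
    oversample: int = 2
    m: float = 10.0
    mu_Z: float = 1150.0
    sigma_Z: float = 115.0
    mosaic_spread_deg: float = 0.01
    n_domains: int = 100
    mean_photons_per_pulse: float = 8.0e10
    fluence_jitter: float = 0.15
    mean_energy_ev: float = 9034.0
    bandwidth: float = 0.002  # relative sd of SASE mode centers
    n_modes: int = 30
    mode_width: float = 0.0002  # relative width of one SASE mode (see note)
    water_path_um: float = 5.0
    beam_diameter_um: float = 1.0
    rng_seed: int | None = None

    def __post_init__(self):
        if self.oversample < 1:
            raise ValueError("oversample must be >= 1")
        for name in ("C", "m", "mu_Z", "mean_photons_per_pulse", "mean_energy_ev"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.water_path_um < 0:
            raise ValueError("water path must be non-negative")

    @property
    def cell(self) -> UnitCell:
        return UnitCell(self.cell_a, self.cell_c)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class Spectrum:
    """Discrete pulse spectrum: wavelength channels (A) and per-channel
    fluence (photons/um^2). SASE modes are far narrower than the lattice
    interference width, so each mode is carried as a single channel."""

    wavelengths: np.ndarray
    fluences: np.ndarray

    def __post_init__(self):
        self.wavelengths = np.atleast_1d(np.asarray(self.wavelengths, dtype=float))
        self.fluences = np.atleast_1d(np.asarray(self.fluences, dtype=float))
        if len(self.wavelengths) != len(self.fluences):
            raise ValueError("wavelengths and fluences must match")
        if np.any(self.fluences < 0) or not np.any(self.fluences > 0):
            raise ValueError("fluences must be >= 0 with at least one positive")

    @property
    def total_fluence(self) -> float:
        """Total photons/um^2 in the pulse."""
        return float(self.fluences.sum())

    @property
    def central_wavelength(self) -> float:
        """Flux-weighted mean wavelength (A)."""
        return float((self.wavelengths * self.fluences).sum() / self.fluences.sum())

    def to_text(self) -> str:
        """Two-column export: photon energy (eV) and channel fluence."""
        lines = ["# energy_eV  fluence_photons_per_um2"]
        for wl, fl in zip(self.wavelengths, self.fluences):
            lines.append(f"{float(angstrom_to_ev(wl)):.4f}  {fl:.8g}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "Spectrum":
        rows = [
            line.split()
            for line in text.splitlines()
            if line.strip() and not line.startswith("#")
        ]
        ev = np.array([float(r[0]) for r in rows])
        fl = np.array([float(r[1]) for r in rows])
        return cls(wavelengths=ev_to_angstrom(ev), fluences=fl)


@dataclass
class MosaicTexture:
    """N_j misorientation matrices about the nominal crystal orientation."""

    rotations: np.ndarray  # (N_j, 3, 3)

    def __post_init__(self):
        self.rotations = np.asarray(self.rotations, dtype=float)
        if self.rotations.ndim != 3 or self.rotations.shape[1:] != (3, 3):
            raise ValueError("rotations must be (N, 3, 3)")
        if len(self.rotations) < 1:
            raise ValueError("texture needs at least one domain")

    def __len__(self):
        return len(self.rotations)

    @property
    def max_angle_deg(self) -> float:
        tr = np.trace(self.rotations, axis1=1, axis2=2)
        cos = np.clip((tr - 1.0) / 2.0, -1.0, 1.0)
        return float(np.degrees(np.arccos(cos)).max())


@dataclass
class GroundTruthCrystal:
    U: np.ndarray
    B: np.ndarray
    m: float
    Z: float
    texture: MosaicTexture

    def __post_init__(self):
        if self.m <= 0 or self.Z <= 0:
            raise ValueError("m and Z must be positive")


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def round_half_away(x):
    """Componentwise nearest integer, ties away from zero (deterministic)."""
    x = np.asarray(x, dtype=float)
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def fractional_index(U, B, q):
    """h_frac = (U B)^T q, its nearest integer index and the residual dh."""
    A = np.asarray(U, dtype=float) @ np.asarray(B, dtype=float)
    if abs(np.linalg.det(A)) < 1e-300:
        raise np.linalg.LinAlgError("singular crystal matrix")
    q = np.asarray(q, dtype=float)
    h_frac = q @ A  # == A.T @ q for each row
    h_int = round_half_away(h_frac)
    return h_frac, h_int.astype(np.int64), h_frac - h_int


def interference(dh, m: float, C: float):
    """I0 = m^6 exp(-C m^2 dh.dh) — peak m^6 at dh = 0."""
    if m <= 0:
        raise ValueError("mosaic parameter m must be positive")
    dh = np.asarray(dh, dtype=float)
    r2 = np.sum(dh * dh, axis=-1)
    return m ** 6 * np.exp(-C * m * m * r2)


def interference_r2_cutoff(m: float, C: float) -> float:
    """Squared support radius of the truncated interference factor."""
    return min(EXP_CUTOFF / (C * m * m), MAX_R_CUT ** 2)


def interference_truncated(r2, m: float, C: float):
    """Interference factor with the shared hard support cutoff applied."""
    r2 = np.asarray(r2, dtype=float)
    cut = interference_r2_cutoff(m, C)
    return np.where(r2 <= cut, m ** 6 * np.exp(-C * m * m * r2), 0.0)


# ---------------------------------------------------------------------------
# water background
# ---------------------------------------------------------------------------

# Isotropic per-molecule amplitude |F_H2O(q)| (electrons) versus
# q = 2 sin(theta)/lambda (1/A): a smooth synthetic stand-in curve with the
# characteristic broad liquid-water maximum near d ~ 3.2 A.
_WATER_Q_KNOTS = np.array(
    [0.0, 0.05, 0.10, 0.15, 0.20, 0.25, 0.30, 0.3125, 0.35, 0.40, 0.50, 0.60, 0.80, 1.20]
)
_WATER_F_KNOTS = np.array(
    [2.0, 2.0, 2.2, 2.6, 3.2, 4.2, 5.4, 5.6, 5.3, 4.5, 3.6, 3.2, 2.8, 2.4]
)


def water_amplitude(q_mag):
    """|F_H2O| (electrons/molecule) by linear interpolation between knots."""
    return np.interp(np.asarray(q_mag, dtype=float), _WATER_Q_KNOTS, _WATER_F_KNOTS)


def water_molecule_count(config: SimConfig) -> float:
    """Molecules in the irradiated cylinder (jet path x beam cross-section)."""
    volume_um3 = config.water_path_um * math.pi * (config.beam_diameter_um / 2.0) ** 2
    volume_cm3 = volume_um3 * 1e-12
    return volume_cm3 * WATER_DENSITY * AVOGADRO / WATER_MOLAR_MASS


def fluence_per_um2(photons_per_pulse: float, config: SimConfig) -> float:
    area_um2 = math.pi * (config.beam_diameter_um / 2.0) ** 2
    return photons_per_pulse / area_um2

#: photons/um^2 -> photons/A^2
_UM2_TO_A2 = 1.0e-8


# ---------------------------------------------------------------------------
# per-pixel reference operations (direct, used as oracles and for API access)
# ---------------------------------------------------------------------------

def _pixel_subgeometry(panel: DetectorPanel, beam: Beam, fast: int, slow: int, oversample: int):
    u0, prefac = panel_subpixel_grids(panel, beam, oversample)
    return u0[slow, fast], prefac[slow, fast]


def bragg_photons_truth(
    panel: DetectorPanel,
    beam: Beam,
    fast: int,
    slow: int,
    spectrum: Spectrum,
    crystal: GroundTruthCrystal,
    F: StructureFactorTable,
    C: float = 3.175,
    oversample: int = 1,
) -> float:
    """Expected Bragg photons in one pixel by direct channel/domain summation."""
    u0, prefac = _pixel_subgeometry(panel, beam, fast, slow, oversample)
    total = 0.0
    n_j = len(crystal.texture)
    cut = interference_r2_cutoff(crystal.m, C)
    for wl, fl in zip(spectrum.wavelengths, spectrum.fluences):
        if fl == 0:
            continue
        q = u0 / wl  # (os2, 3)
        for rot in crystal.texture.rotations:
            A = rot @ crystal.U @ crystal.B
            h_frac = q @ A
            h_int = round_half_away(h_frac)
            dh = h_frac - h_int
            r2 = np.sum(dh * dh, axis=-1)
            i0 = np.where(r2 <= cut, crystal.m ** 6 * np.exp(-C * crystal.m ** 2 * r2), 0.0)
            f2 = np.zeros(len(h_int))
            for idx, h in enumerate(h_int.astype(int).tolist()):
                if h != [0, 0, 0] and h_int[idx] in F:
                    f2[idx] = F.lookup(h_int[idx]) ** 2
            total += float(
                np.sum(prefac * fl * _UM2_TO_A2 * R_E_SQUARED_A2 * (crystal.Z / n_j) * f2 * i0)
            )
    return total


def water_background_pixel(
    panel: DetectorPanel,
    beam: Beam,
    fast: int,
    slow: int,
    spectrum: Spectrum,
    config: SimConfig,
    oversample: int = 1,
) -> float:
    """Expected water-scatter photons in one pixel (direct summation)."""
    u0, prefac = _pixel_subgeometry(panel, beam, fast, slow, oversample)
    n_mol = water_molecule_count(config)
    u0n = np.linalg.norm(u0, axis=-1)
    total = 0.0
    for wl, fl in zip(spectrum.wavelengths, spectrum.fluences):
        q_mag = u0n / wl
        fw = water_amplitude(q_mag)
        total += float(np.sum(prefac * fl * _UM2_TO_A2 * R_E_SQUARED_A2 * fw ** 2 * n_mol))
    return total


# ---------------------------------------------------------------------------
# random samplers
# ---------------------------------------------------------------------------

def sample_spectrum(rng: np.random.Generator, config: SimConfig) -> Spectrum:
    """Spiky SASE-like pulse: n_modes narrow modes with random centers within
    the bandwidth and exponentially distributed weights; total fluence jitters
    about the mean pulse energy."""
    k = max(1, config.n_modes)
    energies = rng.normal(
        config.mean_energy_ev, config.bandwidth * config.mean_energy_ev, size=k
    )
    if k == 1 and config.bandwidth == 0:
        energies = np.array([config.mean_energy_ev])
    weights = rng.exponential(1.0, size=k) if k > 1 else np.ones(1)
    weights /= weights.sum()
    photons = config.mean_photons_per_pulse
    if config.fluence_jitter > 0:
        photons = photons * (1.0 + config.fluence_jitter * rng.normal())
        photons = abs(photons)
    total = fluence_per_um2(photons, config)
    order = np.argsort(energies)[::-1]  # ascending wavelength
    return Spectrum(
        wavelengths=ev_to_angstrom(energies[order]), fluences=total * weights[order]
    )


def sample_mosaic_texture(
    rng: np.random.Generator, n_domains: int, spread_deg: float
) -> MosaicTexture:
    """Domain misorientations: random axes, Normal(0, spread) angles."""
    if n_domains < 1:
        raise ValueError("need at least one domain")
    if spread_deg < 0:
        raise ValueError("spread must be non-negative")
    if spread_deg == 0:
        return MosaicTexture(np.broadcast_to(np.eye(3), (n_domains, 3, 3)).copy())
    rots = np.empty((n_domains, 3, 3))
    for j in range(n_domains):
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        rots[j] = rotation_about_axis(axis, rng.normal(0.0, spread_deg))
    return MosaicTexture(rots)


def sample_ground_truth_crystal(
    rng: np.random.Generator, config: SimConfig, texture: MosaicTexture
) -> GroundTruthCrystal:
    """Random orientation and truncated-normal crystal scale Z."""
    U = random_rotation(rng)
    Z = rng.normal(config.mu_Z, config.sigma_Z)
    while Z <= 0:
        Z = rng.normal(config.mu_Z, config.sigma_Z)
    return GroundTruthCrystal(
        U=U, B=b_matrix(config.cell), m=config.m, Z=Z, texture=texture
    )


# ---------------------------------------------------------------------------
# fast whole-panel render
# ---------------------------------------------------------------------------

@njit(cache=True, fastmath=True)
def _bragg_kernel(
    out, u0, prefac, inv_lams, J, AT, AjT, H, F2, bounds, r2cut_core, r2cut_refl,
    zr, m6, cm2,
):  # pragma: no cover - exercised via render_shot
    n_refl = H.shape[0]
    n_chan = inv_lams.shape[0]
    n_dom = AjT.shape[0]
    os2 = u0.shape[2]
    vx = np.empty(n_dom)
    vy = np.empty(n_dom)
    vz = np.empty(n_dom)
    for r in range(n_refl):
        h0 = H[r, 0]
        h1 = H[r, 1]
        h2 = H[r, 2]
        f2 = F2[r]
        chh = h0 * h0 + h1 * h1 + h2 * h2
        cut = r2cut_refl[r]
        for ss in range(bounds[r, 0], bounds[r, 1]):
            for ff in range(bounds[r, 2], bounds[r, 3]):
                acc_px = 0.0
                for p in range(os2):
                    ux = u0[ss, ff, p, 0]
                    uy = u0[ss, ff, p, 1]
                    uz = u0[ss, ff, p, 2]
                    wx = AT[0, 0] * ux + AT[0, 1] * uy + AT[0, 2] * uz
                    wy = AT[1, 0] * ux + AT[1, 1] * uy + AT[1, 2] * uz
                    wz = AT[2, 0] * ux + AT[2, 1] * uy + AT[2, 2] * uz
                    aa = wx * wx + wy * wy + wz * wz
                    bb = wx * h0 + wy * h1 + wz * h2
                    # closest approach of the wavelength line to h
                    if chh - bb * bb / aa > cut:
                        continue
                    for j in range(n_dom):
                        vx[j] = AjT[j, 0, 0] * ux + AjT[j, 0, 1] * uy + AjT[j, 0, 2] * uz
                        vy[j] = AjT[j, 1, 0] * ux + AjT[j, 1, 1] * uy + AjT[j, 1, 2] * uz
                        vz[j] = AjT[j, 2, 0] * ux + AjT[j, 2, 1] * uy + AjT[j, 2, 2] * uz
                    acc = 0.0
                    for kk in range(n_chan):
                        il = inv_lams[kk]
                        if aa * il * il - 2.0 * bb * il + chh > cut:
                            continue
                        sk = 0.0
                        for j in range(n_dom):
                            hfx = vx[j] * il - h0
                            hfy = vy[j] * il - h1
                            hfz = vz[j] * il - h2
                            r2 = hfx * hfx + hfy * hfy + hfz * hfz
                            if r2 <= r2cut_core:
                                sk += math.exp(-cm2 * r2)
                        acc += J[kk] * sk
                    acc_px += prefac[ss, ff, p] * acc
                out[ss, ff] += acc_px * zr * f2 * m6


def precompute_static_geometry(detector, beam: Beam, oversample: int):
    """Per-panel subpixel direction/solid-angle grids, computed once per run."""
    static = []
    for panel in detector:
        u0, prefac = panel_subpixel_grids(panel, beam, oversample)
        static.append(
            {
                "u0": np.ascontiguousarray(u0),
                "prefac": np.ascontiguousarray(prefac),
                "u0_norm": np.linalg.norm(u0, axis=-1),
            }
        )
    return static


def reflection_set(F: StructureFactorTable):
    """Full-sphere reflection list with squared amplitudes from the table."""
    hkl = full_reflection_list(F.cell, F.d_min)
    canon, _ = map_to_asu(hkl)
    pos = F.positions(canon)
    f2 = np.where(pos >= 0, F.amplitudes[np.maximum(pos, 0)] ** 2, 0.0)
    return {"hkl": hkl, "F2": f2}


def _predict_on_panel(panel, beam, A, hkl, wavelength):
    """Scattered-ray panel intersections and monochromatic Ewald offsets.

    Returns (on_panel, fast, slow, dh_inf) for each reflection; the predicted
    centroid is the intersection of the scattered ray with the panel plane.
    """
    q_h = hkl @ np.linalg.inv(A)  # rows solve A^T q = h
    k_out = q_h + beam.direction / wavelength
    norm = np.linalg.norm(k_out, axis=1)
    ok = norm > 0
    s_hat = k_out / np.where(ok, norm, 1.0)[:, None]
    # Ewald offset of the reflection along its closest detector direction
    q_probe = (s_hat - beam.direction) / wavelength
    h_frac = q_probe @ A
    dh = h_frac - hkl
    dh_inf = np.max(np.abs(dh), axis=1)
    # ray-plane intersection
    normal = panel.normal
    denom = s_hat @ normal
    d0 = panel.origin @ normal
    with np.errstate(divide="ignore", invalid="ignore"):
        t = d0 / denom
    hit = ok & (denom * np.sign(d0) > 1e-9) & (t > 0)
    pt = t[:, None] * s_hat
    rel = pt - panel.origin
    fast = (rel @ panel.fast_axis) / panel.pixel_size
    slow = (rel @ panel.slow_axis) / panel.pixel_size
    on_panel = hit & (fast >= 0) & (fast < panel.n_fast) & (slow >= 0) & (slow < panel.n_slow)
    return on_panel, fast, slow, dh_inf


def render_shot(
    detector,
    beam: Beam,
    config: SimConfig,
    F: StructureFactorTable,
    crystal: GroundTruthCrystal,
    spectrum: Spectrum,
    static=None,
    reflections=None,
    include_background: bool = True,
):
    """Noiseless expected-photon images (one array per panel).

    Bragg scattering is evaluated per predicted reflection over a local pixel
    region; the support cutoff of the interference factor guarantees that a
    pixel region assignment is equivalent to the nearest-integer Ewald
    residual of the full model. Background is the isotropic water term.
    """
    if static is None:
        static = precompute_static_geometry(detector, beam, config.oversample)
    if reflections is None:
        reflections = reflection_set(F)
    hkl = reflections["hkl"]
    F2_all = reflections["F2"]

    lam_bar = spectrum.central_wavelength
    inv_lams = np.ascontiguousarray(1.0 / spectrum.wavelengths)
    J = np.ascontiguousarray(spectrum.fluences * _UM2_TO_A2)
    rel_spread = float(np.max(np.abs(inv_lams * lam_bar - 1.0))) if len(inv_lams) else 0.0

    A = crystal.U @ crystal.B
    AT = np.ascontiguousarray(A.T)
    AjT = np.ascontiguousarray(
        np.einsum("jab,bc->jca", crystal.texture.rotations @ crystal.U, crystal.B)
    )  # (N_j, 3, 3): (U_j U B)^T
    n_j = len(crystal.texture)
    zr = R_E_SQUARED_A2 * crystal.Z / n_j
    cm2 = config.C * crystal.m ** 2
    m6 = crystal.m ** 6
    r2cut_core = interference_r2_cutoff(crystal.m, config.C)
    r_core = math.sqrt(r2cut_core)
    mosaic_margin = math.radians(crystal.texture.max_angle_deg)

    h_norm = np.linalg.norm(hkl, axis=1)
    # screen radius: interference support + mosaic drift (screens use the
    # nominal A and exact channel wavelengths, so no spectral margin needed)
    r2cut_refl_all = (r_core + h_norm * mosaic_margin + 0.01) ** 2
    # prediction window (central wavelength): spectral drift enters here
    keep_window = r_core + h_norm * (rel_spread + mosaic_margin) + 0.05

    max_recip = max(1.0 / F.cell.a, 1.0 / F.cell.c)

    images = []
    for panel, st in zip(detector, static):
        out = np.zeros((panel.n_slow, panel.n_fast))
        on_panel, fast, slow, dh_inf = _predict_on_panel(panel, beam, A, hkl, lam_bar)
        sel = on_panel & (dh_inf < keep_window) & (F2_all > 0)
        if np.any(sel):
            dist = np.linalg.norm(
                panel.origin
                + 0.5 * panel.n_fast * panel.pixel_size * panel.fast_axis
                + 0.5 * panel.n_slow * panel.pixel_size * panel.slow_axis
            )
            # detector extent of a spot: interference support + mosaic drift
            # (in q via a conservative operator bound) + spectral radial drift
            q_extent = (
                (r_core + mosaic_margin * h_norm[sel].max()) * max_recip
                + (2.0 / F.d_min) * rel_spread
            )
            half_px = int(math.ceil(1.5 * q_extent * lam_bar * dist / panel.pixel_size)) + 2
            cf = fast[sel]
            cs = slow[sel]
            s0 = np.clip(np.floor(cs).astype(np.int64) - half_px, 0, panel.n_slow)
            s1 = np.clip(np.floor(cs).astype(np.int64) + half_px + 1, 0, panel.n_slow)
            f0 = np.clip(np.floor(cf).astype(np.int64) - half_px, 0, panel.n_fast)
            f1 = np.clip(np.floor(cf).astype(np.int64) + half_px + 1, 0, panel.n_fast)
            bounds = np.stack([s0, s1, f0, f1], axis=1)
            _bragg_kernel(
                out,
                st["u0"],
                st["prefac"],
                inv_lams,
                J,
                AT,
                AjT,
                hkl[sel].astype(np.float64),
                F2_all[sel],
                bounds,
                r2cut_core,
                r2cut_refl_all[sel],
                zr,
                m6,
                cm2,
            )
        if include_background and config.water_path_um > 0:
            n_mol = water_molecule_count(config)
            bg_sub = np.zeros_like(st["prefac"])
            for il, jf in zip(inv_lams, J):
                fw = water_amplitude(st["u0_norm"] * il)
                bg_sub += jf * fw * fw
            out += (st["prefac"] * bg_sub).sum(axis=2) * R_E_SQUARED_A2 * n_mol
        images.append(out)
    return images
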