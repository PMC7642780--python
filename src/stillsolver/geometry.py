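"""Detector, beam and crystal-frame mathematics.

Conventions used throughout the package:

* lab frame: right-handed, beam travelling along +z, detector downstream at
  positive z; geometry lengths in mm;
* wavelengths and d-spacings in Angstrom; momentum transfer q = 2 sin(theta) /
  lambda in 1/Angstrom (crystallographic convention, no 2*pi);
* the crystal setting follows the Busing-Levy factorization A = U B, where B
  is upper triangular with columns equal to the direct-lattice basis vectors
  of the aligned cell and U is a proper rotation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

#: classical electron radius squared, in Angstrom^2 (r_e = 2.8179403262e-5 A)
R_E_SQUARED_A2 = 2.8179403262e-5 ** 2

#: conversion between photon energy in eV and wavelength in Angstrom
HC_EV_ANGSTROM = 12398.419843320026


def ev_to_angstrom(energy_ev):
    return HC_EV_ANGSTROM / np.asarray(energy_ev, dtype=float)


def angstrom_to_ev(wavelength):
    return HC_EV_ANGSTROM / np.asarray(wavelength, dtype=float)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class UnitCell:
    """Tetragonal unit cell (b == a, all angles 90 deg), edges in Angstrom."""

    a: float
    c: float

    def __post_init__(self):
        if not (self.a > 0 and self.c > 0):
            raise ValueError(f"cell edges must be positive, got a={self.a}, c={self.c}")

    @property
    def volume(self) -> float:
        return self.a * self.a * self.c


@dataclass(frozen=True)
class DetectorPanel:
    """A rectangular pixel-array panel.

    ``origin`` is the lab-frame position (mm) of the corner of pixel (0, 0);
    ``fast_axis``/``slow_axis`` are unit vectors along the fast- and
    slow-scan directions; ``pixel_size`` is in mm.
    """

    origin: np.ndarray
    fast_axis: np.ndarray
    slow_axis: np.ndarray
    n_fast: int
    n_slow: int
    pixel_size: float

    def __post_init__(self):
        object.__setattr__(self, "origin", np.asarray(self.origin, dtype=float))
        object.__setattr__(self, "fast_axis", np.asarray(self.fast_axis, dtype=float))
        object.__setattr__(self, "slow_axis", np.asarray(self.slow_axis, dtype=float))
        for name in ("fast_axis", "slow_axis"):
            v = getattr(self, name)
            if abs(v @ v - 1.0) > 1e-12:
                raise ValueError(f"{name} must be a unit vector")
        if abs(self.fast_axis @ self.slow_axis) > 1e-9:
            raise ValueError("fast_axis and slow_axis must be orthogonal")
        if self.n_fast < 1 or self.n_slow < 1 or self.pixel_size <= 0:
            raise ValueError("invalid panel dimensions")

    @property
    def normal(self) -> np.ndarray:
        return np.cross(self.fast_axis, self.slow_axis)


@dataclass(frozen=True)
class Beam:
    """Incident beam: direction s0-hat, polarization axis and fraction.

    ``polarization_fraction`` f in [0, 1] is the fraction of intensity
    polarized along ``polarization_axis``; f = 0.5 is unpolarized, f = 1 fully
    polarized along the axis.
    """

    direction: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    polarization_axis: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.0, 0.0]))
    polarization_fraction: float = 1.0

    def __post_init__(self):
        object.__setattr__(self, "direction", np.asarray(self.direction, dtype=float))
        object.__setattr__(
            self, "polarization_axis", np.asarray(self.polarization_axis, dtype=float)
        )
        if abs(self.direction @ self.direction - 1.0) > 1e-12:
            raise ValueError("beam direction must be a unit vector")
        if abs(self.direction @ self.polarization_axis) > 1e-9:
            raise ValueError("polarization axis must be perpendicular to the beam")
        if not 0.0 <= self.polarization_fraction <= 1.0:
            raise ValueError("polarization fraction must lie in [0, 1]")


def _check_orthonormal(U, tol=1e-10):
    U = np.asarray(U, dtype=float)
    if U.shape != (3, 3):
        raise ValueError("orientation must be a 3x3 matrix")
    if not np.allclose(U.T @ U, np.eye(3), atol=tol):
        raise ValueError("orientation matrix is not orthonormal")
    if abs(np.linalg.det(U) - 1.0) > tol:
        raise ValueError("orientation matrix must be a proper rotation (det +1)")
    return U


@dataclass(frozen=True)
class Orientation:
    """A proper rotation matrix U (crystal setting relative to aligned cell)."""

    U: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "U", _check_orthonormal(self.U))


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def b_matrix(cell: UnitCell) -> np.ndarray:
    """Busing-Levy B matrix of the aligned tetragonal cell: diag(a, a, c)."""
    return np.diag([cell.a, cell.a, cell.c]).astype(float)


def pixel_lab_position(panel: DetectorPanel, fast, slow, subpixel_offset=(0.5, 0.5)):
    """Lab-frame position (mm) of a (sub)pixel; offset (0.5, 0.5) is the center."""
    fast = np.asarray(fast)
    slow = np.asarray(slow)
    if np.any(fast < 0) or np.any(fast >= panel.n_fast):
        raise IndexError("fast index out of range")
    if np.any(slow < 0) or np.any(slow >= panel.n_slow):
        raise IndexError("slow index out of range")
    off_f, off_s = subpixel_offset
    return (
        panel.origin
        + np.multiply.outer(fast + off_f, panel.pixel_size * panel.fast_axis)
        + np.multiply.outer(slow + off_s, panel.pixel_size * panel.slow_axis)
    )


def momentum_transfer(pixel_pos, beam: Beam, wavelength: float) -> np.ndarray:
    """q = (s-hat - s0-hat) / lambda in 1/Angstrom; |q| = 2 sin(theta)/lambda."""
    if wavelength <= 0:
        raise ValueError("wavelength must be positive")
    pos = np.asarray(pixel_pos, dtype=float)
    norm = np.linalg.norm(pos, axis=-1, keepdims=True)
    if np.any(norm == 0):
        raise ValueError("pixel position must not coincide with the interaction point")
    s_hat = pos / norm
    return (s_hat - beam.direction) / wavelength


def solid_angle(panel: DetectorPanel, fast: int, slow: int) -> float:
    """Solid angle (sr) of a pixel: pixel_size^2 cos(alpha) / r^2."""
    pos = pixel_lab_position(panel, fast, slow)
    r = np.linalg.norm(pos)
    cos_alpha = abs(pos @ panel.normal) / r
    return panel.pixel_size ** 2 * cos_alpha / r ** 2


def kahn_polarization(pixel_pos, beam: Beam) -> float:
    """Kahn polarization factor kappa in [0, 1]; equals 1 at 2theta = 0.

    kappa = 0.5 * (1 + cos^2 2t - K cos(2 psi) sin^2 2t) with K = 2 f - 1 and
    psi the azimuth of the scattered ray about the beam, measured from the
    polarization axis.
    """
    pos = np.asarray(pixel_pos, dtype=float)
    norm = np.linalg.norm(pos, axis=-1, keepdims=True)
    s_hat = pos / norm
    cos_2t = np.clip(s_hat @ beam.direction, -1.0, 1.0)
    sin2_2t = 1.0 - cos_2t ** 2
    # transverse component of the scattered direction
    trans = s_hat - cos_2t[..., None] * beam.direction
    tnorm = np.linalg.norm(trans, axis=-1)
    pol2 = np.cross(beam.direction, beam.polarization_axis)
    with np.errstate(invalid="ignore", divide="ignore"):
        cos_psi = (trans @ beam.polarization_axis) / tnorm
        sin_psi = (trans @ pol2) / tnorm
        cos_2psi = cos_psi ** 2 - sin_psi ** 2
    cos_2psi = np.where(tnorm > 0, cos_2psi, 1.0)
    big_k = 2.0 * beam.polarization_fraction - 1.0
    return 0.5 * (1.0 + cos_2t ** 2 - big_k * cos_2psi * sin2_2t)


def misorientation_angle(U1, U2) -> float:
    """Angle (degrees, in [0, 180]) of the rotation taking U1 into U2."""
    if isinstance(U1, Orientation):
        U1 = U1.U
    if isinstance(U2, Orientation):
        U2 = U2.U
    U1 = _check_orthonormal(U1)
    U2 = _check_orthonormal(U2)
    R = U1.T @ U2
    cos_ang = np.clip((np.trace(R) - 1.0) / 2.0, -1.0, 1.0)
    return float(np.degrees(np.arccos(cos_ang)))


# ---------------------------------------------------------------------------
# rotation helpers
# ---------------------------------------------------------------------------

def rotation_about_axis(axis, angle_deg: float) -> np.ndarray:
    """Rodrigues rotation matrix about an arbitrary axis (degrees)."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    t = np.radians(angle_deg)
    K = np.array(
        [
            [0.0, -axis[2], axis[1]],
            [axis[2], 0.0, -axis[0]],
            [-axis[1], axis[0], 0.0],
        ]
    )
    return np.eye(3) + np.sin(t) * K + (1.0 - np.cos(t)) * (K @ K)


_AXES = np.eye(3)


def _axis_rotation_and_derivative(axis_index: int, angle_deg: float):
    """Rotation about a lab axis and its exact derivative w.r.t. the angle in deg."""
    a = _AXES[axis_index]
    t = np.radians(angle_deg)
    K = np.array(
        [[0.0, -a[2], a[1]], [a[2], 0.0, -a[0]], [-a[1], a[0], 0.0]]
    )
    K2 = K @ K
    R = np.eye(3) + np.sin(t) * K + (1.0 - np.cos(t)) * K2
    dR = (np.cos(t) * K + np.sin(t) * K2) * (np.pi / 180.0)
    return R, dR


def orientation_from_angles(angles_deg, U0) -> np.ndarray:
    """U = Rx(tx) Ry(ty) Rz(tz) U0 — small-angle lab-axis parameterization."""
    Rx, _ = _axis_rotation_and_derivative(0, angles_deg[0])
    Ry, _ = _axis_rotation_and_derivative(1, angles_deg[1])
    Rz, _ = _axis_rotation_and_derivative(2, angles_deg[2])
    return Rx @ Ry @ Rz @ np.asarray(U0, dtype=float)


def orientation_and_derivatives(angles_deg, U0):
    """Return U(angles) and the three exact derivatives dU/d(angle_deg)."""
    Rx, dRx = _axis_rotation_and_derivative(0, angles_deg[0])
    Ry, dRy = _axis_rotation_and_derivative(1, angles_deg[1])
    Rz, dRz = _axis_rotation_and_derivative(2, angles_deg[2])
    U0 = np.asarray(U0, dtype=float)
    U = Rx @ Ry @ Rz @ U0
    dU = [dRx @ Ry @ Rz @ U0, Rx @ dRy @ Rz @ U0, Rx @ Ry @ dRz @ U0]
    return U, dU


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniformly distributed proper rotation (via random unit quaternion)."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def perturb_orientation(rng: np.random.Generator, U, angle_deg: float) -> np.ndarray:
    """Compose U with a rotation of the given angle about a random axis."""
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    return rotation_about_axis(axis, angle_deg) @ np.asarray(U, dtype=float)


# ---------------------------------------------------------------------------
# detectors
# ---------------------------------------------------------------------------

GEOMETRY_FORMAT_VERSION = 1


def single_panel_detector(
    n_fast: int = 256,
    n_slow: int = 256,
    pixel_size: float = 0.10992,
    distance: float = 60.0,
) -> list[DetectorPanel]:
    """Idealized face-on single panel, centered on the beam axis."""
    origin = np.array(
        [-0.5 * n_fast * pixel_size, -0.5 * n_slow * pixel_size, distance]
    )
    return [
        DetectorPanel(
            origin=origin,
            fast_axis=np.array([1.0, 0.0, 0.0]),
            slow_axis=np.array([0.0, 1.0, 0.0]),
            n_fast=n_fast,
            n_slow=n_slow,
            pixel_size=pixel_size,
        )
    ]


def cspad_like_detector(
    distance: float = 124.0,
    pixel_size: float = 0.10992,
    tilt_sd_deg: float = 0.0,
    rng: np.random.Generator | None = None,
) -> list[DetectorPanel]:
    """Idealized coplanar 32-panel layout (185 x 388 pixels per panel).

    Panels are arranged on a 4 x 8 grid with small gaps around the beam
    center; optional small random tilts emulate an imperfectly coplanar
    camera. This is a stand-in layout: the real instrument's panel rotations
    are metrology-specific and are not modeled here.
    """
    n_fast, n_slow = 185, 388
    gap = 0.6  # mm between panels
    panels = []
    width = n_fast * pixel_size
    height = n_slow * pixel_size
    for row in range(4):
        for col in range(8):
            x0 = (col - 4) * (width + gap) + gap / 2
            y0 = (row - 2) * (height + gap) + gap / 2
            fast = np.array([1.0, 0.0, 0.0])
            slow = np.array([0.0, 1.0, 0.0])
            origin = np.array([x0, y0, distance])
            if tilt_sd_deg > 0 and rng is not None:
                R = perturb_orientation(rng, np.eye(3), rng.normal(0.0, tilt_sd_deg))
                fast = R @ fast
                slow = R @ slow
            panels.append(
                DetectorPanel(
                    origin=origin,
                    fast_axis=fast,
                    slow_axis=slow,
                    n_fast=n_fast,
                    n_slow=n_slow,
                    pixel_size=pixel_size,
                )
            )
    return panels


def detector_to_json(panels: list[DetectorPanel]) -> str:
    doc = {
        "version": GEOMETRY_FORMAT_VERSION,
        "panels": [
            {
                "origin": p.origin.tolist(),
                "fast_axis": p.fast_axis.tolist(),
                "slow_axis": p.slow_axis.tolist(),
                "n_fast": p.n_fast,
                "n_slow": p.n_slow,
                "pixel_size": p.pixel_size,
            }
            for p in panels
        ],
    }
    return json.dumps(doc, indent=1)


def detector_from_json(text: str) -> list[DetectorPanel]:
    doc = json.loads(text)
    if "version" not in doc:
        raise ValueError("geometry document lacks a version field")
    return [DetectorPanel(**p) for p in doc["panels"]]


def panel_subpixel_grids(panel: DetectorPanel, beam: Beam, oversample: int = 1):
    """Static per-(sub)pixel geometry used by both the simulator and the model.

    Returns ``(u0, prefac)`` where ``u0[slow, fast, sub, :] = s_hat - s0_hat``
    (multiply by 1/lambda to obtain q) and ``prefac = dOmega_sub * kappa`` with
    ``dOmega_sub`` the subpixel solid angle in steradian.
    """
    os2 = oversample * oversample
    step = 1.0 / oversample
    offs = (np.arange(oversample) + 0.5) * step
    off_f, off_s = np.meshgrid(offs, offs, indexing="ij")
    off_f = off_f.ravel()
    off_s = off_s.ravel()

    fast_idx = np.arange(panel.n_fast)
    slow_idx = np.arange(panel.n_slow)
    ff, ss = np.meshgrid(fast_idx, slow_idx, indexing="xy")  # (n_slow, n_fast)
    pos = (
        panel.origin[None, None, None, :]
        + (ff[..., None, None] + off_f[None, None, :, None])
        * panel.pixel_size
        * panel.fast_axis
        + (ss[..., None, None] + off_s[None, None, :, None])
        * panel.pixel_size
        * panel.slow_axis
    )  # (n_slow, n_fast, os2, 3)
    r = np.linalg.norm(pos, axis=-1)
    s_hat = pos / r[..., None]
    cos_alpha = np.abs(s_hat @ panel.normal)
    d_omega = (panel.pixel_size / oversample) ** 2 * cos_alpha / r ** 2
    kappa = kahn_polarization(pos.reshape(-1, 3), beam).reshape(pos.shape[:-1])
    u0 = s_hat - beam.direction
    return u0, d_omega * kappa
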