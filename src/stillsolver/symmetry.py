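"""Miller-index bookkeeping under point group 422 with Friedel mates distinct.

The asymmetric-unit convention is purely lexicographic: the canonical
representative of an index is the lexicographically greatest of its eight
images under the 422 rotations. Because -I is not an element of 422, an index
and its Friedel mate map to different representatives unless a 422 rotation
relates them (centric reflections), which is exactly the bookkeeping needed
for anomalous-difference work.

Only point-group symmetry acts on indices; translational (space-group)
symmetry and systematic absences are not modeled.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np

from .geometry import UnitCell

#: the 8 rotation matrices of point group 422 acting on row vectors (h, k, l)
OPS_422 = np.array(
    [
        [[1, 0, 0], [0, 1, 0], [0, 0, 1]],
        [[0, -1, 0], [1, 0, 0], [0, 0, 1]],
        [[-1, 0, 0], [0, -1, 0], [0, 0, 1]],
        [[0, 1, 0], [-1, 0, 0], [0, 0, 1]],
        [[1, 0, 0], [0, -1, 0], [0, 0, -1]],
        [[0, 1, 0], [1, 0, 0], [0, 0, -1]],
        [[-1, 0, 0], [0, 1, 0], [0, 0, -1]],
        [[0, -1, 0], [-1, 0, 0], [0, 0, -1]],
    ],
    dtype=np.int64,
)


def d_spacing(hkl, cell: UnitCell):
    """Tetragonal d-spacing: 1/d^2 = (h^2 + k^2)/a^2 + l^2/c^2."""
    hkl = np.asarray(hkl)
    h, k, l = hkl[..., 0], hkl[..., 1], hkl[..., 2]
    inv_d2 = (h * h + k * k) / cell.a ** 2 + l * l / cell.c ** 2
    if np.any(inv_d2 == 0):
        raise ValueError("d-spacing undefined for (0, 0, 0)")
    return 1.0 / np.sqrt(inv_d2)


def _images(hkl):
    """All 8 images of (...,3) integer indices under 422: shape (..., 8, 3)."""
    hkl = np.asarray(hkl, dtype=np.int64)
    return np.einsum("...j,oji->...oi", hkl, OPS_422)


def map_to_asu(hkl):
    """Canonical (lexicographically greatest) 422 image and the op index.

    Accepts a single (3,) index or an (N, 3) array; returns (canonical,
    op_index) with matching shape.
    """
    hkl = np.asarray(hkl, dtype=np.int64)
    single = hkl.ndim == 1
    imgs = _images(np.atleast_2d(hkl))  # (N, 8, 3)
    key = (
        imgs[..., 0].astype(np.int64) * 10 ** 10
        + imgs[..., 1] * 10 ** 5
        + imgs[..., 2]
    )
    op = np.argmax(key, axis=-1)
    canon = imgs[np.arange(len(imgs)), op]
    if single:
        return canon[0], int(op[0])
    return canon, op


def enumerate_unique(cell: UnitCell, d_min: float) -> np.ndarray:
    """All canonical 422 indices (Friedel-separate) with d >= d_min.

    Returns an (N, 3) integer array sorted lexicographically (descending).
    """
    if d_min <= 0:
        raise ValueError("d_min must be positive")
    hmax = int(cell.a / d_min) + 1
    lmax = int(cell.c / d_min) + 1
    h = np.arange(-hmax, hmax + 1)
    l = np.arange(-lmax, lmax + 1)
    H, K, L = np.meshgrid(h, h, l, indexing="ij")
    hkl = np.stack([H.ravel(), K.ravel(), L.ravel()], axis=1)
    nonzero = np.any(hkl != 0, axis=1)
    hkl = hkl[nonzero]
    inv_d2 = (hkl[:, 0] ** 2 + hkl[:, 1] ** 2) / cell.a ** 2 + hkl[:, 2] ** 2 / cell.c ** 2
    hkl = hkl[inv_d2 <= 1.0 / d_min ** 2 + 1e-12]
    canon, _ = map_to_asu(hkl)
    uniq = np.unique(canon, axis=0)
    order = np.lexsort((uniq[:, 2], uniq[:, 1], uniq[:, 0]))[::-1]
    return uniq[order]


def full_reflection_list(cell: UnitCell, d_min: float) -> np.ndarray:
    """Every integer index (whole sphere, Friedel mates included) to d_min."""
    hmax = int(cell.a / d_min) + 1
    lmax = int(cell.c / d_min) + 1
    h = np.arange(-hmax, hmax + 1)
    l = np.arange(-lmax, lmax + 1)
    H, K, L = np.meshgrid(h, h, l, indexing="ij")
    hkl = np.stack([H.ravel(), K.ravel(), L.ravel()], axis=1)
    nonzero = np.any(hkl != 0, axis=1)
    hkl = hkl[nonzero]
    inv_d2 = (hkl[:, 0] ** 2 + hkl[:, 1] ** 2) / cell.a ** 2 + hkl[:, 2] ** 2 / cell.c ** 2
    return hkl[inv_d2 <= 1.0 / d_min ** 2 + 1e-12]


# ---------------------------------------------------------------------------
# structure-factor table
# ---------------------------------------------------------------------------

class StructureFactorTable:
    """Amplitudes |F_h| (electrons) keyed by canonical ASU index.

    Friedel mates are stored as distinct entries. ``hkl`` is an (N, 3) integer
    array of canonical indices, ``amplitudes`` the matching (N,) array.
    """

    def __init__(self, hkl, amplitudes, cell: UnitCell, d_min: float):
        hkl = np.asarray(hkl, dtype=np.int64)
        amplitudes = np.asarray(amplitudes, dtype=float)
        if hkl.ndim != 2 or hkl.shape[1] != 3 or len(hkl) != len(amplitudes):
            raise ValueError("hkl must be (N, 3) matching amplitudes")
        if np.any(amplitudes < 0):
            raise ValueError("amplitudes must be non-negative")
        canon, _ = map_to_asu(hkl)
        if np.any(canon != hkl):
            raise ValueError("all keys must be canonical ASU representatives")
        self.hkl = hkl
        self.amplitudes = amplitudes
        self.cell = cell
        self.d_min = float(d_min)
        self._index = {tuple(h): i for i, h in enumerate(hkl.tolist())}

    def __len__(self):
        return len(self.hkl)

    def __contains__(self, hkl):
        canon, _ = map_to_asu(np.asarray(hkl))
        return tuple(canon.tolist()) in self._index

    def lookup(self, hkl) -> float:
        """Amplitude of an arbitrary index (mapped to its ASU representative)."""
        canon, _ = map_to_asu(np.asarray(hkl))
        return float(self.amplitudes[self._index[tuple(canon.tolist())]])

    def positions(self, canonical_hkl) -> np.ndarray:
        """Row positions of already-canonical (N, 3) indices; -1 when absent."""
        out = np.full(len(canonical_hkl), -1, dtype=np.int64)
        for i, h in enumerate(np.asarray(canonical_hkl, dtype=np.int64).tolist()):
            out[i] = self._index.get(tuple(h), -1)
        return out

    def friedel_mate_positions(self) -> np.ndarray:
        """Position of the canonical Friedel mate of each entry (-1 if absent)."""
        mates, _ = map_to_asu(-self.hkl)
        return self.positions(mates)

    def d_spacings(self) -> np.ndarray:
        return d_spacing(self.hkl, self.cell)

    # -- plain-text round trip ------------------------------------------------

    def write_hkl(self, path_or_buf, extra_columns: dict | None = None):
        """Whitespace-delimited text: ``h k l F [extra...]`` with a header."""
        close = False
        if isinstance(path_or_buf, (str, bytes)):
            buf = open(path_or_buf, "w")
            close = True
        else:
            buf = path_or_buf
        try:
            names = list(extra_columns) if extra_columns else []
            buf.write(
                f"# stillsolver hkl a={self.cell.a:.6g} c={self.cell.c:.6g} "
                f"d_min={self.d_min:.6g}\n"
            )
            buf.write("#   h    k    l            F" + "".join(f" {n:>12}" for n in names) + "\n")
            for i, (h, k, l) in enumerate(self.hkl.tolist()):
                row = f"{h:5d}{k:5d}{l:5d} {self.amplitudes[i]:12.6g}"
                for n in names:
                    row += f" {extra_columns[n][i]:12.6g}"
                buf.write(row + "\n")
        finally:
            if close:
                buf.close()

    @classmethod
    def read_hkl(cls, path_or_buf):
        if isinstance(path_or_buf, (str, bytes)):
            with open(path_or_buf) as fh:
                text = fh.read()
        else:
            text = path_or_buf.read()
        lines = text.splitlines()
        header = lines[0]
        meta = dict(
            kv.split("=") for kv in header.replace("#", "").split() if "=" in kv
        )
        cell = UnitCell(a=float(meta["a"]), c=float(meta["c"]))
        d_min = float(meta["d_min"])
        data = np.loadtxt(io.StringIO("\n".join(l for l in lines if not l.startswith("#"))))
        data = np.atleast_2d(data)
        hkl = data[:, :3].astype(np.int64)
        return cls(hkl, data[:, 3], cell, d_min)


# ---------------------------------------------------------------------------
# toy anomalous structure
# ---------------------------------------------------------------------------

@dataclass
class ToyStructure:
    """Point-scatterer stand-in for a protein with anomalous heavy sites.

    Light atoms carry a flat real scattering factor ``light_f0`` (plus an
    optional absorptive term ``light_fpp``, zero by default); heavy sites carry
    ``heavy_f0 + heavy_fp + i heavy_fpp``. All positions are fractional.
    """

    light_positions: np.ndarray
    light_f0: float = 20.0
    light_fpp: float = 0.0
    heavy_positions: np.ndarray = field(default_factory=lambda: np.empty((0, 3)))
    heavy_f0: float = 60.0
    heavy_fp: float = -8.0
    heavy_fpp: float = 10.0

    def __post_init__(self):
        self.light_positions = np.asarray(self.light_positions, dtype=float) % 1.0
        self.heavy_positions = np.asarray(self.heavy_positions, dtype=float) % 1.0
        if self.heavy_fpp < 0:
            raise ValueError("f'' must be non-negative")
        if len(self.light_positions) + len(self.heavy_positions) == 0:
            raise ValueError("structure must contain at least one atom")


def _apply_ops_to_positions(frac_positions) -> np.ndarray:
    """Expand fractional positions by the 8 rotations of 422 (about the origin)."""
    pos = np.asarray(frac_positions, dtype=float)
    return np.einsum("oij,nj->noi", OPS_422.astype(float), pos).reshape(-1, 3) % 1.0


def random_toy_structure(
    rng: np.random.Generator,
    n_light_asu: int = 12,
    n_heavy_asu: int = 2,
    light_f0: float = 20.0,
    heavy_f0: float = 60.0,
    heavy_fp: float = -8.0,
    heavy_fpp: float = 10.0,
) -> ToyStructure:
    """Random 422-symmetric toy structure (~112 atoms with the defaults).

    Atom sets are generated per asymmetric unit and expanded by the 8 point
    group rotations, so the resulting amplitudes are exactly 422-symmetric and
    the symmetric merge of the synthetic data is self-consistent.
    """
    light = _apply_ops_to_positions(rng.random((n_light_asu, 3)))
    heavy = _apply_ops_to_positions(rng.random((n_heavy_asu, 3)))
    return ToyStructure(
        light_positions=light,
        light_f0=light_f0,
        heavy_positions=heavy,
        heavy_f0=heavy_f0,
        heavy_fp=heavy_fp,
        heavy_fpp=heavy_fpp,
    )


def _complex_f(hkl, structure: ToyStructure, heavy_only_anomalous: bool):
    hkl = np.asarray(hkl, dtype=float)
    light_fpp = 0.0 if heavy_only_anomalous else structure.light_fpp
    f_light = structure.light_f0 + 1j * light_fpp
    f_heavy = structure.heavy_f0 + structure.heavy_fp + 1j * structure.heavy_fpp
    F = np.zeros(len(hkl), dtype=complex)
    if len(structure.light_positions):
        phase = np.exp(2j * np.pi * hkl @ structure.light_positions.T)
        F += f_light * phase.sum(axis=1)
    if len(structure.heavy_positions):
        phase = np.exp(2j * np.pi * hkl @ structure.heavy_positions.T)
        F += f_heavy * phase.sum(axis=1)
    return F


def toy_structure_factors(
    structure: ToyStructure,
    cell: UnitCell,
    d_min: float,
    heavy_only_anomalous: bool = False,
) -> StructureFactorTable:
    """|F_h| = |sum_j f_j exp(2 pi i h.x_j)| over the Friedel-separate ASU.

    With ``heavy_only_anomalous`` the light-atom f'' is forced to zero,
    producing the anomalous-difference ground truth in which only the
    absorptive heavy sites contribute to Friedel differences.
    """
    if d_min <= 0:
        raise ValueError("d_min must be positive")
    hkl = enumerate_unique(cell, d_min)
    amps = np.abs(_complex_f(hkl, structure, heavy_only_anomalous))
    return StructureFactorTable(hkl, amps, cell, d_min)


def heavy_only_anomalous_table(
    structure: ToyStructure, cell: UnitCell, d_min: float
) -> StructureFactorTable:
    """Ground-truth table for anomalous-difference correlation metrics."""
    return toy_structure_factors(structure, cell, d_min, heavy_only_anomalous=True)
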