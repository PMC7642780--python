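"""Ground-truth quality metrics for refined amplitude sets.

* R_GT: sum_h | |F_h| - k |F_h,GT| | / sum_h k |F_h,GT| with the scale k
  chosen to minimize the numerator (adaptive Nelder-Mead, started from the
  ratio of sums). Insensitive to the overall amplitude gauge.
* CC_ano: Pearson correlation between estimated and ground-truth Friedel
  amplitude differences dF = |F(h)| - |F(-h)|, the ground truth carrying
  only the absorptive heavy-atom anomalous signal; proportional to the
  anomalous difference map peak height at the heavy sites.
* misorientation summaries of refined versus true crystal orientations.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize

from .geometry import misorientation_angle
from .symmetry import StructureFactorTable


def _common(est: StructureFactorTable, ref: StructureFactorTable):
    pos = ref.positions(est.hkl)
    sel = pos >= 0
    return est.amplitudes[sel], ref.amplitudes[pos[sel]], est.hkl[sel]


def r_gt(est: StructureFactorTable, truth: StructureFactorTable, d_bins=None):
    """(R_GT, k) over the common index set; optionally also per-d-shell.

    With ``d_bins`` (a list of (d_high, d_low) shells) returns
    (R_GT, k, shell_values) where each shell reuses the global k.
    """
    f, f_gt, hkl = _common(est, truth)
    if len(f) == 0:
        raise ValueError("no common reflections between estimate and truth")

    def objective(logk):
        k = np.exp(logk[0])
        return np.abs(f - k * f_gt).sum() / (k * f_gt.sum())

    k0 = f.sum() / f_gt.sum()
    res = minimize(
        objective, np.array([np.log(k0)]), method="Nelder-Mead",
        options={"adaptive": True, "xatol": 1e-12, "fatol": 1e-14},
    )
    k = float(np.exp(res.x[0]))
    r = float(np.abs(f - k * f_gt).sum() / (k * f_gt.sum()))
    if d_bins is None:
        return r, k
    from .symmetry import d_spacing

    d = d_spacing(hkl, truth.cell)
    shells = []
    for d_hi, d_lo in d_bins:
        sel = (d <= d_hi) & (d > d_lo)
        if np.any(sel):
            shells.append(
                float(np.abs(f[sel] - k * f_gt[sel]).sum() / (k * f_gt[sel].sum()))
            )
        else:
            shells.append(np.nan)
    return r, k, shells


def anomalous_differences(table: StructureFactorTable):
    """(hkl_plus, dF) over acentric entries whose Friedel mate is present.

    Each unordered pair appears once, keyed by its lexicographically greater
    member.
    """
    mate_pos = table.friedel_mate_positions()
    out_hkl, out_df = [], []
    seen = set()
    for i, j in enumerate(mate_pos):
        if j < 0 or j == i:  # mate unmeasured, or centric (self-mate)
            continue
        key = (min(i, j), max(i, j))
        if key in seen:
            continue
        seen.add(key)
        a, b = (i, j) if tuple(table.hkl[i]) > tuple(table.hkl[j]) else (j, i)
        out_hkl.append(table.hkl[a])
        out_df.append(table.amplitudes[a] - table.amplitudes[b])
    return np.array(out_hkl).reshape(-1, 3), np.array(out_df)


def cc_ano(est: StructureFactorTable, truth_heavy: StructureFactorTable) -> float:
    """Pearson correlation of Friedel differences against the heavy-only truth."""
    hkl_e, df_e = anomalous_differences(est)
    if len(df_e) == 0:
        raise ValueError("estimate contains no measured Friedel pairs")
    hkl_t, df_t = anomalous_differences(truth_heavy)
    index_t = {tuple(h): i for i, h in enumerate(hkl_t.tolist())}
    pairs = [(i, index_t[tuple(h)]) for i, h in enumerate(hkl_e.tolist()) if tuple(h) in index_t]
    if len(pairs) < 2:
        raise ValueError("fewer than two common Friedel pairs")
    ie, it = zip(*pairs)
    x = df_e[list(ie)]
    y = df_t[list(it)]
    return float(np.corrcoef(x, y)[0, 1])


def misorientation_summary(refined_Us, truth_Us):
    """Per-shot misorientations plus median and quartiles (degrees)."""
    if len(refined_Us) != len(truth_Us):
        raise ValueError("orientation lists must have equal length")
    angles = np.array(
        [misorientation_angle(u, v) for u, v in zip(refined_Us, truth_Us)]
    )
    return {
        "angles_deg": angles,
        "median": float(np.median(angles)),
        "q25": float(np.percentile(angles, 25)),
        "q75": float(np.percentile(angles, 75)),
    }


def equal_volume_bins(d_min: float, d_max: float, n_bins: int = 10):
    """Resolution shells of equal reciprocal-space volume, as (d_hi, d_lo)."""
    s3 = np.linspace(1.0 / d_max ** 3, 1.0 / d_min ** 3, n_bins + 1)
    edges = s3 ** (-1.0 / 3.0)
    return [(float(edges[i]), float(edges[i + 1])) for i in range(n_bins)]
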