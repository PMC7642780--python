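"""Chunked-array container I/O for synthetic shot stacks.

Layout of the HDF5 file:

* ``/data``      (shots, panels, slow, fast) observed pixel values (photons)
* ``/spectra``   (shots, channels, 2): wavelength (A) and fluence per channel
* ``/truth/U``   (shots, 3, 3), ``/truth/Z`` (shots,), ``/truth/m``, ``/truth/cell``
* ``/gain_map``  (panels, slow, fast)

A JSON manifest (same stem, ``.manifest.json``) records the configuration
and seed so a stack is exactly reproducible.
"""

from __future__ import annotations

import json

import h5py
import numpy as np

from .simulate import Spectrum


def write_image_stack(
    path,
    images,  # list over shots of list over panels of 2-D arrays
    spectra: list[Spectrum],
    truth_U,
    truth_Z,
    truth_m,
    cell_edges,
    gain_maps=None,
    manifest: dict | None = None,
):
    images = np.asarray(images)
    n_chan = max(len(sp.wavelengths) for sp in spectra)
    spec_arr = np.zeros((len(spectra), n_chan, 2))
    for i, sp in enumerate(spectra):
        spec_arr[i, : len(sp.wavelengths), 0] = sp.wavelengths
        spec_arr[i, : len(sp.wavelengths), 1] = sp.fluences
    with h5py.File(path, "w") as fh:
        fh.create_dataset(
            "data", data=images, chunks=(1,) + images.shape[1:], compression="gzip"
        )
        fh.create_dataset("spectra", data=spec_arr)
        g = fh.create_group("truth")
        g.create_dataset("U", data=np.asarray(truth_U))
        g.create_dataset("Z", data=np.asarray(truth_Z))
        g.create_dataset("m", data=np.asarray(truth_m))
        g.create_dataset("cell", data=np.asarray(cell_edges))
        if gain_maps is not None:
            fh.create_dataset("gain_map", data=np.asarray(gain_maps))
    if manifest is not None:
        with open(str(path) + ".manifest.json", "w") as mf:
            json.dump(manifest, mf, indent=1, default=float)


def append_shoeboxes(path, shot_id: int, shoeboxes):
    """Serialize one shot's shoeboxes into the container (/shoeboxes/<s>)."""
    with h5py.File(path, "r+") as fh:
        grp = fh.require_group("shoeboxes")
        name = str(shot_id)
        if name in grp:
            del grp[name]
        g = grp.create_group(name)
        if not shoeboxes:
            return
        g.create_dataset("bbox", data=np.array([sb.bbox for sb in shoeboxes]))
        g.create_dataset("panel", data=np.array([sb.panel_id for sb in shoeboxes]))
        g.create_dataset("hkl", data=np.array([sb.hkl for sb in shoeboxes]))
        g.create_dataset("hkl_obs", data=np.array([sb.hkl_obs for sb in shoeboxes]))
        g.create_dataset("d", data=np.array([sb.d for sb in shoeboxes]))
        g.create_dataset("snr", data=np.array([sb.snr for sb in shoeboxes]))
        g.create_dataset(
            "tilt",
            data=np.array(
                [sb.tilt if sb.tilt is not None else [np.nan] * 3 for sb in shoeboxes]
            ),
        )


def read_image_stack(path):
    with h5py.File(path, "r") as fh:
        out = {
            "data": fh["data"][()],
            "truth_U": fh["truth/U"][()],
            "truth_Z": fh["truth/Z"][()],
            "truth_m": fh["truth/m"][()],
            "cell": fh["truth/cell"][()],
            "gain_map": fh["gain_map"][()] if "gain_map" in fh else None,
        }
        spec_arr = fh["spectra"][()]
    spectra = []
    for row in spec_arr:
        mask = row[:, 1] > 0
        spectra.append(Spectrum(wavelengths=row[mask, 0], fluences=row[mask, 1]))
    out["spectra"] = spectra
    return out
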