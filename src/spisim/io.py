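"""File I/O: HDF5 snapshot archives, HDF5/CCP4 volumes, YAML configs.

Snapshot sets use a CXI-style HDF5 layout::

    entry/data/counts, indices, indptr   # CSR photon counts
    entry/orientation                    # (N, 4) true quaternions
    entry/mask                           # (rows, cols) beamstop mask
    entry/geometry/*                     # detector attributes
    entry/provenance                     # JSON string

Volumes are stored as HDF5 (values + voxel size + metadata) and can be
exported as CCP4/MRC maps through gemmi for viewing in standard map tools.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import yaml
from scipy import sparse

from .diffraction import IntensityVolume, PatternSet
from .geometry import DetectorGeometry
from .noise import NoiseModel

__all__ = [
    "save_patterns",
    "load_patterns",
    "save_volume",
    "load_volume",
    "write_ccp4_map",
    "save_noise_model",
    "load_noise_model",
]


def save_patterns(path, patterns: PatternSet) -> None:
    """Write a PatternSet to an HDF5 file (CSR photon storage)."""
    csr = patterns.photons.tocsr()
    with h5py.File(path, "w") as f:
        g = f.create_group("entry/data")
        g.create_dataset("counts", data=csr.data.astype(np.int32),
                         compression="gzip")
        g.create_dataset("indices", data=csr.indices.astype(np.int64),
                         compression="gzip")
        g.create_dataset("indptr", data=csr.indptr.astype(np.int64))
        g.attrs["n_pixels"] = csr.shape[1]
        f.create_dataset("entry/orientation", data=patterns.orientations)
        f.create_dataset("entry/mask", data=patterns.beamstop_mask)
        geo = f.create_group("entry/geometry")
        d = patterns.geometry
        geo.attrs.update(
            sdd=d.sdd, pixel_size=d.pixel_size, shape=d.shape,
            photon_energy=d.photon_energy, beam_center=d.beam_center,
            beamstop_radius=d.beamstop_radius,
        )
        f.create_dataset(
            "entry/provenance",
            data=json.dumps(patterns.provenance, default=str),
        )


def load_patterns(path) -> PatternSet:
    """Read a PatternSet written by :func:`save_patterns`."""
    with h5py.File(path, "r") as f:
        g = f["entry/data"]
        csr = sparse.csr_matrix(
            (g["counts"][:], g["indices"][:], g["indptr"][:]),
            shape=(len(g["indptr"]) - 1, int(g.attrs["n_pixels"])),
        )
        quats = f["entry/orientation"][:]
        mask = f["entry/mask"][:].astype(bool)
        ga = f["entry/geometry"].attrs
        geometry = DetectorGeometry(
            sdd=float(ga["sdd"]),
            pixel_size=float(ga["pixel_size"]),
            shape=tuple(int(s) for s in ga["shape"]),
            photon_energy=float(ga["photon_energy"]),
            beam_center=tuple(float(c) for c in ga["beam_center"]),
            beamstop_radius=float(ga["beamstop_radius"]),
        )
        prov = json.loads(f["entry/provenance"][()])
    return PatternSet(
        photons=csr, orientations=quats, beamstop_mask=mask,
        geometry=geometry, provenance=prov,
    )


def save_volume(path, volume: IntensityVolume) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("volume/values", data=volume.values, compression="gzip")
        f["volume"].attrs["voxel_size"] = volume.voxel_size
        if volume.mask is not None:
            f.create_dataset("volume/mask", data=volume.mask, compression="gzip")
        f.create_dataset(
            "volume/metadata", data=json.dumps(volume.metadata, default=str)
        )


def load_volume(path) -> IntensityVolume:
    with h5py.File(path, "r") as f:
        values = f["volume/values"][:]
        vox = float(f["volume"].attrs["voxel_size"])
        mask = f["volume/mask"][:].astype(bool) if "volume/mask" in f else None
        meta = json.loads(f["volume/metadata"][()]) if "volume/metadata" in f else {}
    return IntensityVolume(values=values, voxel_size=vox, mask=mask, metadata=meta)


def write_ccp4_map(path, values: np.ndarray, voxel_size_angstrom: float) -> None:
    """Export a cubic volume as a CCP4/MRC map (voxel size in the header)."""
    import gemmi

    grid = gemmi.FloatGrid(np.ascontiguousarray(values, dtype=np.float32))
    n = values.shape[0]
    edge = n * voxel_size_angstrom
    grid.set_unit_cell(gemmi.UnitCell(edge, edge, edge, 90, 90, 90))
    m = gemmi.Ccp4Map()
    m.grid = grid
    m.update_ccp4_header()
    m.write_ccp4_map(str(path))


def save_noise_model(path, noise: NoiseModel) -> None:
    """Write a noise model as YAML (peaks_keV, sigmas_keV, sigma_avg_keV...)."""
    doc = {
        "label": noise.label,
        "peaks_keV": list(noise.peaks_kev),
        "sigmas_keV": list(noise.sigmas_kev),
        "sigma_avg_keV": noise.sigma_avg,
        "photon_energy_keV": noise.photon_energy,
        "sigma_from_fit": noise.sigma_from_fit,
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_noise_model(path) -> NoiseModel:
    doc = yaml.safe_load(Path(path).read_text())
    return NoiseModel(
        peaks_kev=tuple(doc["peaks_keV"]),
        sigmas_kev=tuple(doc["sigmas_keV"]),
        sigma_avg=float(doc["sigma_avg_keV"]),
        photon_energy=float(doc.get("photon_energy_keV", 8.0)),
        label=doc.get("label", "custom"),
        sigma_from_fit=bool(doc.get("sigma_from_fit", False)),
    )
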