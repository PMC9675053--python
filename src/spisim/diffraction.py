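"""Coherent-diffraction forward model for single-particle snapshots.

The expected photon count in a detector pixel subtending solid angle
:math:`\\Omega` at scattering vector :math:`q` is

    mu(q) = Omega * (d sigma_T / d Omega) * n_in * |F(q)|^2,

with ``n_in`` the incident fluence (photons/cm^2) and ``F`` the molecular
structure factor, ``F(q) = sum_i f_i(|q|) exp(i q . r_i)`` over atoms with
Cromer-Mann form factors ``f_i``.  Radiation damage and shot-to-shot
intensity fluctuation are not modelled, so the time integral collapses to a
single term with the total pulse fluence.  Observed counts are Poisson draws
of ``mu``; detector corruption is applied afterwards by :mod:`spisim.noise`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import gemmi
import numpy as np
from scipy import sparse

from .geometry import BeamParameters, DetectorGeometry, QMap
from .rotations import quaternions_to_matrices, random_quaternion

__all__ = [
    "AtomicModel",
    "DiffractionPattern",
    "PatternSet",
    "load_model",
    "structure_factor",
    "atomic_form_factor",
    "sample_orientation",
    "expected_pattern",
    "simulate_pattern",
    "IntensityVolume",
    "build_ideal_volume",
    "voxel_size_for",
]


@dataclass
class AtomicModel:
    """Point-atom model: element symbols plus Cartesian coordinates in Angstrom."""

    elements: list[str]
    coordinates: np.ndarray  #: (n_atoms, 3) Angstrom
    label: str = "model"

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise ValueError("coordinates must be (n_atoms, 3)")
        if len(self.elements) != len(self.coordinates):
            raise ValueError("elements and coordinates length mismatch")
        if len(self.elements) == 0:
            raise ValueError("empty atomic model")
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("non-finite coordinates")
        bad = [e for e in self.elements if gemmi.Element(e).atomic_number == 0]
        if bad:
            raise ValueError(f"unknown element symbols: {sorted(set(bad))}")

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    @property
    def atomic_numbers(self) -> np.ndarray:
        return np.array([gemmi.Element(e).atomic_number for e in self.elements])

    @property
    def total_electrons(self) -> int:
        return int(self.atomic_numbers.sum())

    @property
    def extent(self) -> float:
        """Largest bounding-box edge in Angstrom (the particle size L)."""
        span = self.coordinates.max(axis=0) - self.coordinates.min(axis=0)
        return float(span.max())

    def centered(self) -> "AtomicModel":
        """Copy with the electron-weighted centre of mass at the origin."""
        z = self.atomic_numbers.astype(float)
        com = (self.coordinates * z[:, None]).sum(axis=0) / z.sum()
        return AtomicModel(
            elements=list(self.elements),
            coordinates=self.coordinates - com,
            label=self.label,
        )


def load_model(pdb_source, strip_het: bool = True) -> AtomicModel:
    """Load an atomic model from a PDB/mmCIF file path or PDB-format string.

    With ``strip_het`` (default), non-polymer heteroatom groups — ligands,
    ions and waters — are removed, leaving the bare polymer (for a ribosome
    model this is "with the antibiotics removed").
    """
    if hasattr(pdb_source, "read"):
        pdb_source = pdb_source.read()
    text = None
    if isinstance(pdb_source, str) and "\n" in pdb_source:
        text = pdb_source
    if text is not None:
        st = gemmi.read_pdb_string(text)
    else:
        st = gemmi.read_structure(str(pdb_source))
    st.setup_entities()
    if strip_het:
        st.remove_ligands_and_waters()
    elements: list[str] = []
    coords: list[tuple[float, float, float]] = []
    unknown: list[str] = []
    for model in st:
        for chain in model:
            for res in chain:
                for atom in res:
                    if atom.element.atomic_number == 0:
                        unknown.append(f"{chain.name}/{res.name}/{atom.name}")
                        continue
                    elements.append(atom.element.name)
                    pos = atom.pos
                    coords.append((pos.x, pos.y, pos.z))
        break  # first model only
    if unknown:
        raise ValueError(f"unknown element for records: {unknown[:10]}")
    if not elements:
        raise ValueError("no atoms found in model")
    return AtomicModel(elements=elements, coordinates=np.array(coords), label=st.name)


def atomic_form_factor(element: str, q_magnitudes: np.ndarray) -> np.ndarray:
    """Cromer-Mann (IT92 4-Gaussian) elastic form factor f(|q|), electrons.

    Uses ``s^2 = (|q| / 4 pi)^2 = (sin theta / lambda)^2``; anomalous
    dispersion is neglected (light elements dominate biomolecules at keV
    energies).
    """
    coef = gemmi.Element(element).it92
    if coef is None:
        raise ValueError(f"no form-factor coefficients for element {element!r}")
    q = np.asarray(q_magnitudes, dtype=float)
    stol2 = (q / (4.0 * np.pi)) ** 2
    a = np.array(coef.a)
    b = np.array(coef.b)
    return np.exp(-stol2[..., None] * b).dot(a) + coef.c


def structure_factor(model: AtomicModel, q_points: np.ndarray) -> np.ndarray:
    """Molecular structure factor F(q) at arbitrary q points (1/A).

    ``F(q) = sum_i f_i(|q|) exp(i q . r_i)``; ``F(0)`` equals the total
    electron count (real).  Atoms are grouped by element so each form
    factor is evaluated once per element.
    """
    q = np.asarray(q_points, dtype=float)
    flat = q.reshape(-1, 3)
    qmag = np.linalg.norm(flat, axis=1)
    out = np.zeros(len(flat), dtype=complex)
    elems = np.asarray(model.elements)
    # chunk q to bound the (n_q, n_atoms) phase matrix
    chunk = max(1, int(4e7 // max(model.n_atoms, 1)))
    for sym in np.unique(elems):
        rows = model.coordinates[elems == sym]
        f = atomic_form_factor(sym, qmag)
        for lo in range(0, len(flat), chunk):
            sl = slice(lo, lo + chunk)
            phase = flat[sl] @ rows.T
            out[sl] += f[sl] * np.exp(1j * phase).sum(axis=1)
    return out.reshape(q.shape[:-1])


def sample_orientation(rng: np.random.Generator) -> np.ndarray:
    """Haar-uniform random orientation as a unit quaternion (w, x, y, z)."""
    return random_quaternion(rng)


class EwaldSliceSimulator:
    """Cached per-detector forward model.

    Form factors depend only on |q|, which is fixed per pixel, so they are
    evaluated once per element; each orientation then costs one phase-matrix
    product.  Used by the dataset generator where thousands of orientations
    share one detector.
    """

    def __init__(self, model: AtomicModel, qmap: QMap, beam: BeamParameters,
                 fluence_override: float | None = None):
        self.model = model
        self.qmap = qmap
        self.q_lab = qmap.flat_q()
        qmag = np.linalg.norm(self.q_lab, axis=1)
        elems = np.asarray(model.elements)
        self._groups = [
            (model.coordinates[elems == sym], atomic_form_factor(sym, qmag))
            for sym in np.unique(elems)
        ]
        flu = beam.fluence if fluence_override is None else fluence_override
        self._weights = qmap.pixel_weights.reshape(-1) * flu
        self.fluence = flu

    def expected(self, orientation: np.ndarray) -> np.ndarray:
        """Expected photon map mu(pixel) for one orientation quaternion."""
        rot = quaternions_to_matrices(np.asarray(orientation, dtype=float))
        q = self.q_lab @ rot.T
        f_total = np.zeros(len(q), dtype=complex)
        for coords, f in self._groups:
            f_total += f * np.exp(1j * (q @ coords.T)).sum(axis=1)
        mu = self._weights * np.abs(f_total) ** 2
        return mu.reshape(self.qmap.q_magnitudes.shape)


@dataclass
class DiffractionPattern:
    """One photon-counting snapshot with its ground-truth orientation.

    ``photons`` holds -1 on beamstop pixels (masked sentinel, not zero).
    """

    photons: np.ndarray  #: (rows, cols) int64, -1 = masked
    orientation: np.ndarray  #: unit quaternion (w, x, y, z)
    beamstop_mask: np.ndarray  #: (rows, cols) bool, True = masked
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.orientation = np.asarray(self.orientation, dtype=float)
        if abs(np.linalg.norm(self.orientation) - 1.0) > 1e-9:
            raise ValueError("orientation quaternion must be unit norm")
        valid = self.photons[~self.beamstop_mask]
        if valid.size and valid.min() < 0:
            raise ValueError("negative photon count on unmasked pixel")

    @property
    def mean_photons(self) -> float:
        """Mean photons per unmasked pixel."""
        return float(self.photons[~self.beamstop_mask].mean())


@dataclass
class PatternSet:
    """A stack of snapshots sharing one detector geometry.

    Photons are stored sparsely (CSR over flattened pixels) since occupancy
    in the photon-sparse regime is ~0.1 photons/pixel.
    """

    photons: sparse.csr_matrix  #: (n_patterns, n_pixels) photon counts
    orientations: np.ndarray  #: (n_patterns, 4) unit quaternions
    beamstop_mask: np.ndarray  #: (rows, cols) bool
    geometry: DetectorGeometry
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return self.photons.shape[0]

    @property
    def mean_photons(self) -> float:
        """Mean photons per unmasked pixel over the whole set."""
        n_valid = int((~self.beamstop_mask).sum())
        if len(self) == 0 or n_valid == 0:
            return 0.0
        return float(self.photons.sum() / (len(self) * n_valid))

    def pattern(self, i: int) -> DiffractionPattern:
        img = np.asarray(self.photons[i].todense()).reshape(
            self.beamstop_mask.shape
        ).astype(np.int64)
        img[self.beamstop_mask] = -1
        return DiffractionPattern(
            photons=img,
            orientation=self.orientations[i],
            beamstop_mask=self.beamstop_mask,
            metadata={"index": i, **self.provenance},
        )


def expected_pattern(
    model: AtomicModel,
    qmap: QMap,
    beam: BeamParameters,
    orientation: np.ndarray | None = None,
    fluence_override: float | None = None,
) -> np.ndarray:
    """Expected photon map mu(pixel) for one orientation (no noise).

    The orientation quaternion maps laboratory-frame scattering vectors into
    the model frame: ``mu = Omega * thomson * fluence * |F(R q_lab)|^2``.
    """
    qpix = qmap.flat_q()
    if orientation is not None:
        rot = quaternions_to_matrices(np.asarray(orientation, dtype=float))
        qpix = qpix @ rot.T
    flu = beam.fluence if fluence_override is None else fluence_override
    f2 = np.abs(structure_factor(model, qpix)) ** 2
    mu = qmap.pixel_weights.reshape(-1) * flu * f2
    return mu.reshape(qmap.q_magnitudes.shape)


def simulate_pattern(
    model: AtomicModel,
    qmap: QMap,
    beam: BeamParameters,
    orientation: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
    fluence_override: float | None = None,
) -> DiffractionPattern:
    """Simulate one snapshot: Poisson draw of the expected photon map.

    If ``orientation`` is None a Haar-uniform one is drawn first.
    """
    rng = np.random.default_rng() if rng is None else rng
    if orientation is None:
        orientation = sample_orientation(rng)
    mu = expected_pattern(model, qmap, beam, orientation, fluence_override)
    if not np.all(np.isfinite(mu)):
        raise OverflowError("expected photon map overflowed")
    photons = rng.poisson(mu).astype(np.int64)
    mask = qmap.beamstop_mask
    photons[mask] = -1
    return DiffractionPattern(
        photons=photons,
        orientation=np.asarray(orientation, dtype=float),
        beamstop_mask=mask,
        metadata={"fluence": float(
            beam.fluence if fluence_override is None else fluence_override
        )},
    )


@dataclass
class IntensityVolume:
    """3D reciprocal-space intensities on a cubic grid.

    The zero-frequency voxel sits at index ``edge // 2`` on each axis (the
    exact midpoint for the odd grids EMC reconstructs on; the FFT centre
    for the even grids produced by binning).  ``voxel_size`` is the q step
    per voxel in 1/A.  ``values`` are nonnegative; an optional boolean
    ``mask`` marks voxels excluded from constraints and comparisons
    (beamstop, never-visited).  ``metadata`` records the intensity
    prefactor so absolute scales remain traceable.
    """

    values: np.ndarray
    voxel_size: float
    mask: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.ndim != 3 or len(set(v.shape)) != 1:
            raise ValueError("volume must be a cube")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be > 0")
        self.values = v

    @property
    def edge(self) -> int:
        return self.values.shape[0]

    @property
    def center(self) -> int:
        return self.edge // 2

    def q_grid(self) -> np.ndarray:
        """(edge,) 1D coordinate axis in 1/A (same for all three axes)."""
        return (np.arange(self.edge) - self.center) * self.voxel_size

    def q_magnitudes(self) -> np.ndarray:
        ax = self.q_grid()
        return np.sqrt(
            ax[:, None, None] ** 2 + ax[None, :, None] ** 2 + ax[None, None, :] ** 2
        )


def voxel_size_for(geometry: DetectorGeometry, grid_edge: int) -> float:
    """Voxel size Delta-q (1/A) placing the detector-corner q at the grid corner.

    Convention: ``Delta q = q_max / (edge//2 - 1)`` — the corner q lands one
    voxel inside the half-grid so every detector pixel stays trilinearly
    interpolable after any rotation.
    """
    if grid_edge < 5 or grid_edge % 2 == 0:
        raise ValueError("grid edge must be odd and >= 5")
    return geometry.q_max() / (grid_edge // 2 - 1)


def build_ideal_volume(
    model: AtomicModel,
    grid_edge: int,
    voxel_size: float,
    prefactor: float = 1.0,
    max_voxels: int = 400**3,
) -> IntensityVolume:
    """Noise-free |F(q)|^2 sampled on a cubic reciprocal-space grid.

    This is the ideal reference intensity used by the R-factor analysis.
    ``prefactor`` (e.g. the per-pixel ``Omega * thomson * fluence`` constant)
    multiplies the intensities and is recorded in metadata.
    """
    if grid_edge % 2 == 0:
        raise ValueError("grid edge must be odd")
    if grid_edge**3 > max_voxels:
        raise MemoryError(
            f"grid {grid_edge}^3 exceeds the {max_voxels}-voxel budget"
        )
    ax = (np.arange(grid_edge) - grid_edge // 2) * voxel_size
    gx, gy, gz = np.meshgrid(ax, ax, ax, indexing="ij")
    pts = np.stack([gx, gy, gz], axis=-1)
    f = structure_factor(model, pts)
    vals = prefactor * np.abs(f) ** 2
    return IntensityVolume(
        values=vals,
        voxel_size=voxel_size,
        metadata={"prefactor": prefactor, "model": model.label},
    )
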