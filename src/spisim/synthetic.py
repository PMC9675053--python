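"""Generators for every input the pipeline needs, with ground truth attached.

Desk-scale stand-ins for a real experiment: atom-cluster phantoms in place
of a deposited macromolecule, Gaussian-mixture calibration samples in place
of measured fluorescence histograms, and complete noisy snapshot datasets
(uniform orientations -> Poisson photons -> optional detector corruption and
photonization -> beamstop mask) with true orientations stored.

The defaults emulate the study conditions of the photon-sparse regime: a
128x128-pixel detector cutout, ~0.1 photons per pixel per snapshot, and the
three noise cases (Poisson only, standard detector, low-noise detector).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse

from .diffraction import (
    AtomicModel,
    EwaldSliceSimulator,
    PatternSet,
    expected_pattern,
    sample_orientation,
)
from .geometry import BeamParameters, DetectorGeometry, QMap
from .noise import CalibrationHistogram, NoiseModel, corrupt, photonize

__all__ = [
    "PhantomSpec",
    "make_phantom",
    "make_calibration_samples",
    "fluence_for_occupancy",
    "make_dataset",
    "desk_geometry",
    "desk_beam",
]

#: element weights approximating protein/RNA composition
DEFAULT_ELEMENT_MIX = {"C": 0.60, "O": 0.20, "N": 0.15, "P": 0.05}

MIN_SPACING_A = 1.2  #: covalent-bond-scale minimum atom spacing, Angstrom


@dataclass(frozen=True)
class PhantomSpec:
    """Specification of a random atom-cluster phantom.

    ``extent_nm`` is the diameter of the bounding sphere; atoms are placed
    with a blue-noise-like rejection process at >= 1.2 A spacing, so the
    phantom scatters like a coarse molecular cluster of the requested size.
    """

    n_atoms: int = 40
    extent_nm: float = 4.0
    element_mix: tuple[tuple[str, float], ...] = tuple(DEFAULT_ELEMENT_MIX.items())
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_atoms < 1:
            raise ValueError("n_atoms must be >= 1")
        if self.extent_nm <= 0:
            raise ValueError("extent must be > 0")
        total = sum(w for _, w in self.element_mix)
        if total <= 0:
            raise ValueError("element mix weights must sum > 0")
        object.__setattr__(
            self,
            "element_mix",
            tuple((e, w / total) for e, w in self.element_mix),
        )


def make_phantom(spec: PhantomSpec) -> AtomicModel:
    """Deterministic random phantom: atoms in a sphere at >= 1.2 A spacing."""
    rng = np.random.default_rng(spec.seed)
    radius = spec.extent_nm * 10.0 / 2.0  # nm -> A
    if spec.n_atoms == 1:
        coords = np.zeros((1, 3))
    else:
        # feasibility: sphere packing at the requested spacing
        capacity = (radius / MIN_SPACING_A) ** 3 * 2.0
        if spec.n_atoms > capacity:
            raise ValueError(
                f"cannot place {spec.n_atoms} atoms at {MIN_SPACING_A} A "
                f"spacing inside a {spec.extent_nm} nm sphere"
            )
        placed: list[np.ndarray] = []
        attempts = 0
        while len(placed) < spec.n_atoms:
            attempts += 1
            if attempts > 200000:
                raise ValueError("rejection sampling failed; spacing infeasible")
            p = rng.uniform(-radius, radius, 3)
            if np.linalg.norm(p) > radius:
                continue
            if placed and np.min(
                np.linalg.norm(np.array(placed) - p, axis=1)
            ) < MIN_SPACING_A:
                continue
            placed.append(p)
        coords = np.array(placed)
        coords -= coords.mean(axis=0)
    symbols = [e for e, _ in spec.element_mix]
    weights = np.array([w for _, w in spec.element_mix])
    elements = list(rng.choice(symbols, size=spec.n_atoms, p=weights))
    return AtomicModel(
        elements=elements, coordinates=coords, label=f"phantom-{spec.seed}"
    )


def make_calibration_samples(
    noise: NoiseModel,
    occupancy: float,
    n: int,
    seed: int = 0,
) -> CalibrationHistogram:
    """Emulated single-pixel calibration readouts.

    Each sample draws a photon count k ~ Poisson(occupancy), then a keV
    value from ``Normal(peak_position(k), sigma(k))`` — the flat-field
    fluorescence histogram a photon-peak calibration fits.
    """
    if occupancy < 0:
        raise ValueError("occupancy must be >= 0")
    rng = np.random.default_rng(seed)
    k = rng.poisson(occupancy, size=n)
    values = corrupt(k, noise, rng) if n else np.empty(0)
    return CalibrationHistogram(samples=values, label=f"synthetic-{noise.label}")


def desk_geometry(
    shape: tuple[int, int] = (128, 128),
    beamstop_radius: float = 3.0,
    photon_energy: float = 6.0,
) -> DetectorGeometry:
    """Reduced detector cutout preserving the full-scale q range per pixel.

    Pixels are enlarged so the cutout's edge q matches what a 550-pixel
    half-width covers at 200 um: the speckle sampling (oversampling per
    speckle) is then set by the phantom size instead.
    """
    scale = 550.0 / min(shape)
    return DetectorGeometry(
        sdd=0.25,
        pixel_size=200e-6 * scale,
        shape=shape,
        photon_energy=photon_energy,
        beamstop_radius=beamstop_radius,
    )


def desk_beam(photon_energy: float = 6.0) -> BeamParameters:
    """Beam with the full-scale pulse parameters (fluence rescaled later
    per-dataset to hit a target occupancy)."""
    return BeamParameters(
        pulse_energy=4e-3,
        optics_efficiency=0.38,
        focus_fwhm=(250e-9, 150e-9),
        photon_energy=photon_energy,
    )


def fluence_for_occupancy(
    model: AtomicModel,
    qmap: QMap,
    beam: BeamParameters,
    target_occupancy: float = 0.1,
    n_orientations: int = 8,
    seed: int = 0,
) -> float:
    """Fluence giving ``target_occupancy`` mean photons per unmasked pixel.

    The expected pattern is linear in fluence, so the mean over a few
    random orientations at unit fluence fixes the scale.
    """
    rng = np.random.default_rng(seed)
    valid = ~qmap.beamstop_mask
    mean_mu = 0.0
    for _ in range(n_orientations):
        mu = expected_pattern(
            model, qmap, beam, sample_orientation(rng), fluence_override=1.0
        )
        mean_mu += mu[valid].mean()
    mean_mu /= n_orientations
    if mean_mu <= 0:
        raise ValueError("zero expected intensity; cannot tune fluence")
    return target_occupancy / mean_mu


def make_dataset(
    model: AtomicModel,
    qmap: QMap,
    beam: BeamParameters,
    n_patterns: int,
    noise_case: str = "poisson_only",
    noise_model: NoiseModel | None = None,
    fluence_override: float | None = None,
    seed: int = 0,
) -> PatternSet:
    """Generate a complete snapshot dataset with ground-truth orientations.

    ``noise_case`` is one of ``poisson_only``, ``standard``, ``low_noise``
    or ``custom`` (then ``noise_model`` must be given, already scaled to the
    beam photon energy).  For the detector cases each Poisson pattern is
    corrupted to keV readouts and photonized back to integers, so the two
    members of a seed-matched pair differ only where detector noise crossed
    a photonization threshold.
    """
    from .noise import get_noise_model, scale_to_photon_energy

    if noise_case == "custom":
        if noise_model is None:
            raise ValueError("custom noise case requires a noise_model")
        nm = noise_model
    elif noise_case == "poisson_only":
        nm = None
    else:
        nm = scale_to_photon_energy(get_noise_model(noise_case), beam.photon_energy)

    # separate child streams so that seed-matched datasets share the
    # orientation and Poisson stages exactly and differ only in the
    # detector-noise stage
    seq = np.random.SeedSequence(seed)
    rng, rng_det = (np.random.default_rng(s) for s in seq.spawn(2))
    mask = qmap.beamstop_mask
    shape = mask.shape
    sim = EwaldSliceSimulator(model, qmap, beam, fluence_override)
    rows, data, indptr = [], [], [0]
    quats = np.empty((n_patterns, 4))
    for i in range(n_patterns):
        quat = sample_orientation(rng)
        mu = sim.expected(quat)
        photons = rng.poisson(mu)
        if nm is not None:
            photons = photonize(corrupt(photons, nm, rng_det), nm)
        photons[mask] = 0  # stored sparsely; the mask marks them invalid
        flat = photons.reshape(-1)
        nz = np.flatnonzero(flat)
        rows.append(nz)
        data.append(flat[nz])
        indptr.append(indptr[-1] + nz.size)
        quats[i] = quat
    photons_csr = sparse.csr_matrix(
        (
            np.concatenate(data) if data else np.empty(0),
            np.concatenate(rows) if rows else np.empty(0, dtype=int),
            np.array(indptr),
        ),
        shape=(n_patterns, int(np.prod(shape))),
    )
    return PatternSet(
        photons=photons_csr,
        orientations=quats,
        beamstop_mask=mask,
        geometry=qmap.geometry,
        provenance={
            "model": model.label,
            "noise_case": noise_case,
            "noise_label": None if nm is None else nm.label,
            "seed": seed,
            "n_patterns": n_patterns,
            "fluence": float(
                beam.fluence if fluence_override is None else fluence_override
            ),
        },
    )
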