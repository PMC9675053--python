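"""Shared fixtures: phantoms, desk-scale geometries, and the expensive
end-to-end reconstructions reused by the acceptance tests."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import ndimage

from spisim.diffraction import build_ideal_volume
from spisim.emc import EMCConfig, run_emc
from spisim.geometry import BeamParameters, DetectorGeometry, build_qmap
from spisim.synthetic import (
    PhantomSpec,
    desk_beam,
    desk_geometry,
    fluence_for_occupancy,
    make_dataset,
    make_phantom,
)


@pytest.fixture(scope="session")
def phantom40():
    """The 40-atom, 4 nm phantom used throughout the desk-scale suite."""
    return make_phantom(PhantomSpec(n_atoms=40, extent_nm=4.0, seed=0))


@pytest.fixture(scope="session")
def paper_geometry():
    """Full-scale detector: 550x550, 200 um pixels, SDD 0.25 m, 6 keV."""
    return DetectorGeometry(
        sdd=0.25,
        pixel_size=200e-6,
        shape=(550, 550),
        photon_energy=6.0,
        beamstop_radius=5.0,
    )


@pytest.fixture(scope="session")
def paper_beam():
    return BeamParameters(
        pulse_energy=4e-3,
        optics_efficiency=0.38,
        focus_fwhm=(250e-9, 150e-9),
        photon_energy=6.0,
    )


@pytest.fixture(scope="session")
def emc_recovery(phantom40):
    """Desk-scale EMC recovery: 1500 noise-free snapshots of the phantom on
    a 64x64 detector cutout, reconstructed on a 65^3 grid.

    Returns a dict with the pattern set, the EMC result, the matching ideal
    volume and the detector q map; shared by the EMC and acceptance tests.
    """
    geometry = desk_geometry(shape=(64, 64), beamstop_radius=2.0)
    qmap = build_qmap(geometry)
    beam = desk_beam()
    flu = fluence_for_occupancy(phantom40, qmap, beam, 0.1, seed=0)
    patterns = make_dataset(
        phantom40, qmap, beam, 1500, noise_case="poisson_only",
        fluence_override=flu, seed=1,
    )
    config = EMCConfig(
        grid_edge=65,
        total_iterations=34,
        rotation_schedule=((0, 4), (22, 5), (28, 6)),
        beta_start=0.04,
        beta_factor=2.0,
        beta_period=4,
        seed=0,
    )
    result = run_emc(patterns, qmap, config)
    ideal = build_ideal_volume(phantom40, 65, result.volume.voxel_size)
    return {
        "geometry": geometry,
        "qmap": qmap,
        "beam": beam,
        "fluence": flu,
        "patterns": patterns,
        "result": result,
        "ideal": ideal,
    }


@pytest.fixture(scope="session")
def blob_phantom_volume(phantom40):
    """Smooth compact phantom density and its noise-free diffraction
    magnitudes: Gaussian blobs (sigma 1.2 voxels) at the phantom atom
    positions on a 48^3 grid, oversampling 3 per dimension."""
    n = 48
    scale = (n / 3.0) / phantom40.extent  # voxels per Angstrom
    rho = np.zeros((n,) * 3)
    idx = np.round(phantom40.coordinates * scale + n // 2).astype(int)
    for (i, j, k), z in zip(idx, phantom40.atomic_numbers):
        rho[i, j, k] += z
    rho = ndimage.gaussian_filter(rho, 1.2)
    amps = np.fft.fftshift(np.fft.fftn(np.fft.ifftshift(rho)))
    return {"density": rho, "intensities": np.abs(amps) ** 2}
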