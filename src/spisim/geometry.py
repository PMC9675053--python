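"""Detector and beam geometry for a flat area detector on an XFEL beamline.

Everything downstream (forward simulation, EMC, R-factor shells) consumes the
per-pixel scattering vectors, solid angles and Thomson factors produced here.
Conventions:

* the incident beam travels along +z; the detector is a flat ``rows x cols``
  pixel grid perpendicular to the beam at distance ``sdd``;
* scattering vectors carry the crystallographic :math:`2\\pi` convention,
  ``|q| = 4 pi sin(theta) / lambda`` in 1/Angstrom, and lie on the Ewald
  sphere of radius ``2 pi / lambda``;
* wavelength is derived from photon energy as ``lambda[A] = 12.3984 / E[keV]``
  (the CODATA hc constant rounded to the keV*A value used throughout).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "HC_KEV_ANGSTROM",
    "CLASSICAL_ELECTRON_RADIUS_CM",
    "DetectorGeometry",
    "BeamParameters",
    "QMap",
    "build_qmap",
    "oversampling_ratio",
    "fluence",
    "pixel_solid_angle_exact",
    "beamstop_diameter",
]

#: hc in keV * Angstrom; fixed so that derived wavelengths are bit-stable.
HC_KEV_ANGSTROM = 12.3984

#: classical electron radius r_e in cm (Thomson scattering length).
CLASSICAL_ELECTRON_RADIUS_CM = 2.8179403262e-13

KEV_TO_JOULE = 1.602176634e-16


class InvalidGeometryError(ValueError):
    """Raised for non-physical detector or beam parameters."""


def wavelength_from_energy(photon_energy_kev: float) -> float:
    """Wavelength in Angstrom for a photon energy in keV."""
    if photon_energy_kev <= 0:
        raise InvalidGeometryError(
            f"photon energy must be positive, got {photon_energy_kev}"
        )
    return HC_KEV_ANGSTROM / photon_energy_kev


@dataclass(frozen=True)
class DetectorGeometry:
    """Flat-detector geometry.

    Parameters
    ----------
    sdd : float
        Sample-to-detector distance in metres.
    pixel_size : float
        Square pixel edge in metres.
    shape : tuple of int
        ``(rows, cols)`` pixel counts.
    photon_energy : float
        Photon energy in keV.
    beam_center : tuple of float, optional
        Fractional pixel coordinates ``(row, col)`` of the direct beam.
        Defaults to the array centre ``((rows-1)/2, (cols-1)/2)`` so an even
        array is symmetric about the centre (pixel centres sit at integer
        coordinates).
    beamstop_radius : float
        Radius of the masked central disc in pixels.
    """

    sdd: float
    pixel_size: float
    shape: tuple[int, int]
    photon_energy: float
    beam_center: tuple[float, float] | None = None
    beamstop_radius: float = 0.0

    def __post_init__(self) -> None:
        if self.sdd <= 0:
            raise InvalidGeometryError(f"sdd must be > 0, got {self.sdd}")
        if self.pixel_size <= 0:
            raise InvalidGeometryError(
                f"pixel_size must be > 0, got {self.pixel_size}"
            )
        if len(self.shape) != 2 or any(s < 1 for s in self.shape):
            raise InvalidGeometryError(f"bad detector shape {self.shape}")
        if self.beamstop_radius < 0:
            raise InvalidGeometryError("beamstop_radius must be >= 0")
        if self.beam_center is None:
            object.__setattr__(
                self,
                "beam_center",
                ((self.shape[0] - 1) / 2.0, (self.shape[1] - 1) / 2.0),
            )
        # force plain tuples so the dataclass stays hashable
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "beam_center", tuple(map(float, self.beam_center)))

    @property
    def wavelength(self) -> float:
        """X-ray wavelength in Angstrom."""
        return wavelength_from_energy(self.photon_energy)

    @property
    def n_pixels(self) -> int:
        return self.shape[0] * self.shape[1]

    def q_at_radius(self, radius_pixels: float) -> float:
        """``|q|`` (1/A) at a given pixel distance from the beam centre."""
        two_theta = np.arctan2(radius_pixels * self.pixel_size, self.sdd)
        return 4.0 * np.pi * np.sin(two_theta / 2.0) / self.wavelength

    def resolution_at_radius(self, radius_pixels: float) -> float:
        """Full-period resolution ``2 pi / |q|`` in nm at a pixel radius.

        Returns ``inf`` at the beam centre (forward-scattering limit).
        """
        q = self.q_at_radius(radius_pixels)
        if q == 0:
            return float("inf")
        return 2.0 * np.pi / q / 10.0  # A -> nm

    def edge_resolution(self) -> float:
        """Full-period resolution (nm) at the edge midpoint of the array."""
        half = min(self.shape) / 2.0
        return self.resolution_at_radius(half)

    def corner_resolution(self) -> float:
        """Full-period resolution (nm) at the detector corner."""
        r = np.hypot(self.shape[0] / 2.0, self.shape[1] / 2.0)
        return self.resolution_at_radius(r)

    def q_max(self) -> float:
        """``|q|`` at the detector corner, the largest q on the array (1/A)."""
        r = np.hypot(self.shape[0] / 2.0, self.shape[1] / 2.0)
        return self.q_at_radius(r)


def beamstop_diameter(geometry: DetectorGeometry) -> float:
    """Physical diameter of the circular beamstop in metres.

    A 5-pixel radius at 200 um pixels corresponds to the ~2 mm central gap of
    the AGIPD detector.
    """
    return 2.0 * geometry.beamstop_radius * geometry.pixel_size


@dataclass(frozen=True)
class BeamParameters:
    """Pulse parameters of the focused XFEL beam.

    ``fluence`` treats the focus as a flat-top rectangle of the two FWHM
    values; that convention reproduces printed photons/cm^2 numbers for
    mJ-class pulses at stated focus sizes.
    """

    pulse_energy: float  #: J
    optics_efficiency: float  #: fraction of pulse energy reaching the sample
    focus_fwhm: tuple[float, float]  #: (x, y) in metres
    photon_energy: float  #: keV

    def __post_init__(self) -> None:
        if not 0 < self.optics_efficiency <= 1:
            raise InvalidGeometryError(
                f"optics efficiency must be in (0, 1], got {self.optics_efficiency}"
            )
        if self.photon_energy <= 0:
            raise InvalidGeometryError("photon_energy must be > 0")
        if self.pulse_energy < 0:
            raise InvalidGeometryError("pulse_energy must be >= 0")
        if any(f <= 0 for f in self.focus_fwhm):
            raise InvalidGeometryError("focus FWHM must be > 0")
        object.__setattr__(self, "focus_fwhm", tuple(map(float, self.focus_fwhm)))

    @property
    def photons_per_pulse(self) -> float:
        return (
            self.pulse_energy
            * self.optics_efficiency
            / (self.photon_energy * KEV_TO_JOULE)
        )

    @property
    def fluence(self) -> float:
        """Photons per cm^2 on the sample."""
        return fluence(self)


def fluence(beam: BeamParameters) -> float:
    """Fluence in photons/cm^2: pulse photons over the FWHM focus rectangle."""
    area_cm2 = (beam.focus_fwhm[0] * 100.0) * (beam.focus_fwhm[1] * 100.0)
    return beam.photons_per_pulse / area_cm2


def oversampling_ratio(geometry: DetectorGeometry, particle_size: float) -> float:
    """Linear oversampling ratio ``SDD * lambda / (pixel_size * L)``.

    Parameters
    ----------
    particle_size : float
        Largest particle dimension L in metres.
    """
    if particle_size <= 0:
        raise ValueError(f"particle size must be > 0, got {particle_size}")
    wavelength_m = geometry.wavelength * 1e-10
    return geometry.sdd * wavelength_m / (geometry.pixel_size * particle_size)


@dataclass
class QMap:
    """Per-pixel reciprocal-space map of a detector.

    Attributes
    ----------
    q_vectors : (rows, cols, 3) float64
        Scattering vectors on the Ewald sphere, 1/A, z along the beam.
    q_magnitudes : (rows, cols) float64
        ``|q| = 4 pi sin(theta) / lambda`` in 1/A.
    solid_angles : (rows, cols) float64
        Pixel solid angles in steradian.
    thomson_factors : (rows, cols) float64
        Differential Thomson cross sections in cm^2/sr (<= r_e^2).
    """

    geometry: DetectorGeometry
    polarization: str
    q_vectors: np.ndarray
    q_magnitudes: np.ndarray
    solid_angles: np.ndarray
    thomson_factors: np.ndarray
    beamstop_mask: np.ndarray = field(repr=False, default=None)

    @property
    def pixel_weights(self) -> np.ndarray:
        """Solid angle times Thomson factor, cm^2 per pixel."""
        return self.solid_angles * self.thomson_factors

    def flat_q(self) -> np.ndarray:
        """Scattering vectors as an (n_pixels, 3) array."""
        return self.q_vectors.reshape(-1, 3)


def build_qmap(
    geometry: DetectorGeometry, polarization: str = "horizontal"
) -> QMap:
    """Build the per-pixel q-vector / solid-angle / Thomson-factor map.

    Parameters
    ----------
    polarization : {"horizontal", "vertical", "unpolarized"}
        XFEL beams are linearly polarized in the horizontal plane, which is
        the default; "unpolarized" applies ``(1 + cos^2 2theta)/2``.
    """
    if polarization not in ("horizontal", "vertical", "unpolarized"):
        raise ValueError(f"unknown polarization {polarization!r}")

    rows, cols = geometry.shape
    cy, cx = geometry.beam_center
    lam = geometry.wavelength

    yy = (np.arange(rows)[:, None] - cy) * geometry.pixel_size  # vertical
    xx = (np.arange(cols)[None, :] - cx) * geometry.pixel_size  # horizontal
    xx, yy = np.broadcast_arrays(xx, yy)
    dist = np.sqrt(xx**2 + yy**2 + geometry.sdd**2)

    # unit vector towards each pixel; q = (2 pi / lambda) (s_hat - z_hat)
    k = 2.0 * np.pi / lam
    q = np.empty((rows, cols, 3))
    q[..., 0] = k * xx / dist
    q[..., 1] = k * yy / dist
    q[..., 2] = k * (geometry.sdd / dist - 1.0)
    qmag = np.sqrt(np.sum(q**2, axis=-1))

    cos_2t = geometry.sdd / dist
    sin_2t = np.hypot(xx, yy) / dist
    # azimuth measured from the horizontal (polarization) axis
    phi = np.arctan2(yy, xx)
    if polarization == "horizontal":
        pol = 1.0 - (sin_2t * np.cos(phi)) ** 2
    elif polarization == "vertical":
        pol = 1.0 - (sin_2t * np.sin(phi)) ** 2
    else:
        pol = 0.5 * (1.0 + cos_2t**2)

    omega = geometry.pixel_size**2 * cos_2t**3 / geometry.sdd**2
    thomson = CLASSICAL_ELECTRON_RADIUS_CM**2 * pol

    rr = np.hypot(
        np.arange(rows)[:, None] - cy, np.arange(cols)[None, :] - cx
    )
    mask = rr <= geometry.beamstop_radius

    return QMap(
        geometry=geometry,
        polarization=polarization,
        q_vectors=q,
        q_magnitudes=qmag,
        solid_angles=omega,
        thomson_factors=thomson,
        beamstop_mask=mask,
    )


def pixel_solid_angle_exact(
    geometry: DetectorGeometry, row: float, col: float
) -> float:
    """Exact solid angle of one square pixel via the rectangular-pyramid formula.

    Decomposes the pixel into four corner rectangles sharing the foot of the
    detector normal and applies ``Omega = atan(ab / (d sqrt(a^2+b^2+d^2)))``
    to each with sign bookkeeping.  Used as the oracle against the
    ``cos^3`` small-angle approximation stored in :class:`QMap`.
    """
    cy, cx = geometry.beam_center
    p = geometry.pixel_size
    d = geometry.sdd
    x0 = (col - cx) * p - p / 2
    x1 = x0 + p
    y0 = (row - cy) * p - p / 2
    y1 = y0 + p

    def corner(a: float, b: float) -> float:
        return np.arctan2(a * b, d * np.sqrt(a * a + b * b + d * d))

    return float(
        corner(x1, y1) - corner(x0, y1) - corner(x1, y0) + corner(x0, y0)
    )
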