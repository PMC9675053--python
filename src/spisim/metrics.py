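"""Reconstruction quality metrics.

The central metric is the reciprocal-space residual factor

    R(D) = sum_{|q| <= 2 pi / D} | I(q)/S - I_ideal(q)/S_ideal |,

where each intensity set is normalized by its own sum S over the voxels
inside the cutoff.  R is 0 for identical (up to scale) volumes and bounded
by 2 (the L1 distance between two probability vectors).  The achievable
full-period resolution is read off where R(D) first crosses a threshold
(0.2, the customary confidence level) coming from low q.

Volumes reconstructed from snapshots of unknown orientation come back in an
arbitrary global rotation, so a rotational registration against the
reference volume precedes any R-factor comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from .diffraction import IntensityVolume
from .emc import _gather_trilinear
from .rotations import rotation_group

__all__ = [
    "RFactorCurve",
    "ResolutionEstimate",
    "register_rotation",
    "rotate_volume",
    "r_factor",
    "resolution_at_threshold",
]


@dataclass
class RFactorCurve:
    """R(D) sampled on a descending-resolution (ascending-q) grid."""

    resolutions_nm: np.ndarray  #: full-period D values, strictly decreasing
    r_values: np.ndarray
    n_voxels: np.ndarray  #: voxels inside each cutoff

    def __post_init__(self) -> None:
        self.resolutions_nm = np.asarray(self.resolutions_nm, dtype=float)
        self.r_values = np.asarray(self.r_values, dtype=float)
        self.n_voxels = np.asarray(self.n_voxels, dtype=int)
        if not np.all(np.diff(self.resolutions_nm) < 0):
            raise ValueError("resolution grid must be strictly decreasing")

    def __len__(self) -> int:
        return len(self.resolutions_nm)


@dataclass
class ResolutionEstimate:
    """Threshold crossing of an R-factor curve.

    ``flag`` is "resolved" for an interpolated crossing, "detector-limited"
    when R stays below threshold over the whole grid (the finest D is
    returned), "unresolved" when it never drops below it.
    """

    resolution_nm: float
    flag: str
    threshold: float


def _volume_sample_points(
    volume: IntensityVolume, n_points: int, rng: np.random.Generator
) -> np.ndarray:
    """Random voxel-centre q points inside the inscribed sphere, q != 0."""
    qmag = volume.q_magnitudes()
    qmax = (volume.edge // 2) * volume.voxel_size
    ok = (qmag > 0) & (qmag <= 0.9 * qmax)
    if volume.mask is not None:
        ok &= ~volume.mask
    idx = np.flatnonzero(ok.ravel())
    if idx.size == 0:
        raise ValueError("no usable voxels for registration")
    take = min(n_points, idx.size)
    sel = rng.choice(idx, size=take, replace=False)
    coords = np.stack(np.unravel_index(sel, volume.values.shape), axis=0)
    return (coords - volume.center) * volume.voxel_size  # (3, n)


def _gather(volume: IntensityVolume, rot: np.ndarray, qpts: np.ndarray) -> np.ndarray:
    out = np.empty(qpts.shape[1])
    _gather_trilinear(
        np.ascontiguousarray(volume.values, dtype=np.float64),
        np.ascontiguousarray(rot, dtype=np.float64),
        np.ascontiguousarray(qpts, dtype=np.float64),
        1.0 / volume.voxel_size,
        float(volume.center),
        out,
    )
    return out


def _masked_corr(a: np.ndarray, b: np.ndarray) -> float:
    ok = np.isfinite(a) & np.isfinite(b)
    if ok.sum() < 10:
        return -1.0
    a, b = a[ok], b[ok]
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        raise ValueError("degenerate (constant) volume in registration")
    return float(np.corrcoef(a, b)[0, 1])


def rotate_volume(volume: IntensityVolume, rot: np.ndarray) -> IntensityVolume:
    """Resample a volume under rotation: out(q) = in(R q), trilinear."""
    n = volume.edge
    ax = np.arange(n, dtype=float) - volume.center
    gx, gy, gz = np.meshgrid(ax, ax, ax, indexing="ij")
    pts = np.stack([gx.ravel(), gy.ravel(), gz.ravel()]) * volume.voxel_size
    vals = _gather(volume, rot, pts)
    vals = np.nan_to_num(vals, nan=0.0).reshape(volume.values.shape)
    return IntensityVolume(
        values=vals, voxel_size=volume.voxel_size, mask=volume.mask,
        metadata=dict(volume.metadata),
    )


def register_rotation(
    volume: IntensityVolume,
    reference: IntensityVolume,
    level: int = 4,
    n_points: int = 12000,
    seed: int = 0,
    log_intensities: bool = True,
) -> tuple[np.ndarray, IntensityVolume]:
    """Find the proper rotation aligning ``volume`` onto ``reference``.

    Searches a quasi-uniform rotation grid for the R maximizing the Pearson
    correlation between ``volume(R q)`` and ``reference(q)`` on a random
    subsample of voxels, then polishes with a local rotation-vector
    optimization.  Correlations are computed on log intensities by default
    (speckle contrast spans decades).  Returns the rotation matrix and the
    resampled volume.
    """
    if volume.values.shape != reference.values.shape:
        raise ValueError("volume/reference shape mismatch")
    rng = np.random.default_rng(seed)
    qpts = _volume_sample_points(reference, n_points, rng)
    ref_vals = _gather(reference, np.eye(3), qpts)

    def transform(x: np.ndarray) -> np.ndarray:
        return np.log1p(np.maximum(x, 0.0)) if log_intensities else x

    ref_t = transform(ref_vals)
    if np.std(ref_t[np.isfinite(ref_t)]) == 0:
        raise ValueError("degenerate (constant) reference volume")

    group = rotation_group(level)
    mats = group.matrices()
    best_corr, best_idx = -np.inf, 0
    for j, rot in enumerate(mats):
        c = _masked_corr(transform(_gather(volume, rot, qpts)), ref_t)
        if c > best_corr:
            best_corr, best_idx = c, j

    def objective(rotvec: np.ndarray) -> float:
        rot = Rotation.from_rotvec(rotvec).as_matrix()
        return -_masked_corr(transform(_gather(volume, rot, qpts)), ref_t)

    x0 = Rotation.from_matrix(mats[best_idx]).as_rotvec()
    res = minimize(objective, x0, method="Nelder-Mead",
                   options={"xatol": 1e-4, "fatol": 1e-8, "maxiter": 400})
    rot = Rotation.from_rotvec(res.x).as_matrix()
    if -res.fun < best_corr:  # keep the grid winner if polish regressed
        rot = mats[best_idx]
    return rot, rotate_volume(volume, rot)


def r_factor(
    volume: IntensityVolume,
    ideal: IntensityVolume,
    d_grid_nm,
    exclude_beamstop: float | None = None,
) -> RFactorCurve:
    """R-factor curve between a reconstructed and an ideal intensity volume.

    Both volumes must share grid shape, voxel size and orientation (run
    :func:`register_rotation` first).  For each full-period resolution D
    the sums run over voxels with ``|q| <= 2 pi / D``; voxels under either
    volume's mask — or inside ``exclude_beamstop`` voxel radius of the
    centre — are excluded from both normalizations.
    """
    if volume.values.shape != ideal.values.shape:
        raise ValueError("volume/ideal shape mismatch")
    if abs(volume.voxel_size - ideal.voxel_size) > 1e-12 * ideal.voxel_size:
        raise ValueError("voxel size mismatch")
    d_grid = np.asarray(d_grid_nm, dtype=float)
    if d_grid.size == 0:
        raise ValueError("empty resolution grid")
    d_grid = np.sort(d_grid)[::-1]

    qmag = volume.q_magnitudes()
    keep = np.ones(volume.values.shape, dtype=bool)
    if volume.mask is not None:
        keep &= ~volume.mask
    if ideal.mask is not None:
        keep &= ~ideal.mask
    if exclude_beamstop is not None:
        from .phasing import spherical_mask

        keep &= ~spherical_mask(volume.values.shape, exclude_beamstop)

    i_vol = np.maximum(volume.values, 0.0)
    i_ref = np.maximum(ideal.values, 0.0)

    r_vals = np.empty(d_grid.size)
    n_vox = np.empty(d_grid.size, dtype=int)
    for i, d in enumerate(d_grid):
        cutoff = 2.0 * np.pi / (d * 10.0)  # nm -> A
        sel = keep & (qmag <= cutoff)
        n_vox[i] = int(sel.sum())
        s_vol = i_vol[sel].sum()
        s_ref = i_ref[sel].sum()
        if s_vol <= 0 or s_ref <= 0:
            raise ValueError(f"zero total intensity inside cutoff D={d} nm")
        r_vals[i] = np.abs(i_vol[sel] / s_vol - i_ref[sel] / s_ref).sum()
    return RFactorCurve(resolutions_nm=d_grid, r_values=r_vals, n_voxels=n_vox)


def resolution_at_threshold(
    curve: RFactorCurve, threshold: float = 0.2
) -> ResolutionEstimate:
    """Resolution where R(D) first crosses the threshold from low q.

    The crossing is linearly interpolated in (1/D, R) — i.e. in the q
    cutoff — between the bracketing grid points.  If R never reaches the
    threshold the finest grid D is returned flagged "detector-limited"; if
    it starts above it, the coarsest D flagged "unresolved".
    """
    if len(curve) == 0:
        raise ValueError("empty R-factor curve")
    d = curve.resolutions_nm
    r = curve.r_values
    if r[0] >= threshold:
        return ResolutionEstimate(float(d[0]), "unresolved", threshold)
    above = np.flatnonzero(r >= threshold)
    if above.size == 0:
        return ResolutionEstimate(float(d[-1]), "detector-limited", threshold)
    hi = above[0]
    lo = hi - 1
    x0, x1 = 1.0 / d[lo], 1.0 / d[hi]
    frac = (threshold - r[lo]) / (r[hi] - r[lo])
    x = x0 + frac * (x1 - x0)
    return ResolutionEstimate(float(1.0 / x), "resolved", threshold)
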