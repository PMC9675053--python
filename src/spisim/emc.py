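"""Expand-maximize-compress (EMC) orientation recovery.

EMC merges photon-sparse 2D snapshots of unknown orientation into a 3D
reciprocal-space intensity model.  Each iteration

* **expands** the current model into tomograms — Ewald-sphere slices, one
  per candidate rotation of a quasi-uniform SO(3) grid;
* **maximizes**: computes responsibilities of every rotation for every
  pattern from the Poisson log-likelihood, tempered by a deterministic-
  annealing factor beta, and forms the responsibility-weighted mean pattern
  per rotation (the EM update);
* **compresses** the updated tomograms back onto the 3D grid with trilinear
  weights.

Annealing starts at a small beta and multiplies it by ``beta_factor`` every
10 iterations until it is clipped at 1; the rotation grid is refined on a
schedule so low-q speckles converge before fine orientation structure is
resolved.  The model is Friedel-symmetrized after every compress since the
intensities are centrosymmetric.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numba
import numpy as np
from scipy import sparse
from scipy.special import logsumexp

from .diffraction import IntensityVolume, PatternSet
from .geometry import QMap
from .rotations import RotationGroup, rotation_group

__all__ = [
    "EMCConfig",
    "beta_at_iteration",
    "expand",
    "maximize",
    "compress",
    "run_emc",
    "friedel_symmetrize",
]


@dataclass(frozen=True)
class EMCConfig:
    """EMC run configuration.

    ``rotation_schedule`` maps the first iteration index (0-based) at which
    each refinement level becomes active; beta multiplies by ``beta_factor``
    every 10 iterations starting from ``beta_start`` and is clipped at 1.
    The full-scale protocol is 200 coarse iterations at level 6 followed by
    levels 9..24 every 20 iterations (300 total) on a 951^3 grid; desk-scale
    defaults are far smaller.
    """

    grid_edge: int = 65
    voxel_size: float | None = None  #: 1/A; default from detector q_max
    total_iterations: int = 60
    rotation_schedule: tuple[tuple[int, int], ...] = ((0, 4), (30, 5), (45, 6))
    beta_start: float = 0.001
    beta_factor: float = np.sqrt(2.0)
    beta_period: int = 10
    seed: int = 0
    symmetrize_friedel: bool = True

    def __post_init__(self) -> None:
        if self.grid_edge % 2 == 0 or self.grid_edge < 3:
            raise ValueError("grid_edge must be odd and >= 3")
        if self.total_iterations < 1:
            raise ValueError("total_iterations must be >= 1")
        its = [it for it, _ in self.rotation_schedule]
        if its != sorted(its) or its[0] != 0:
            raise ValueError("rotation_schedule must start at 0 and be increasing")
        if not (0 < self.beta_start <= 1):
            raise ValueError("beta_start must be in (0, 1]")

    def level_at(self, iteration: int) -> int:
        lvl = self.rotation_schedule[0][1]
        for start, level in self.rotation_schedule:
            if iteration >= start:
                lvl = level
        return lvl


def beta_at_iteration(
    iteration: int,
    beta_start: float = 0.001,
    beta_factor: float = np.sqrt(2.0),
    period: int = 10,
) -> float:
    """Annealing beta at a (0-based) iteration: start * factor^(it//period),
    clipped at 1.  With start 0.001 and factor sqrt(2) beta reaches 1 at
    iteration 200."""
    return float(min(1.0, beta_start * beta_factor ** (iteration // period)))


@numba.njit(cache=True, fastmath=True)
def _gather_trilinear(vol, rot, qpix, inv_vox, center, out):
    """Sample vol (edge^3) at rot @ q / vox + center for all pixels."""
    n = vol.shape[0]
    npix = qpix.shape[1]
    for p in range(npix):
        qx = qpix[0, p]
        qy = qpix[1, p]
        qz = qpix[2, p]
        x = (rot[0, 0] * qx + rot[0, 1] * qy + rot[0, 2] * qz) * inv_vox + center
        y = (rot[1, 0] * qx + rot[1, 1] * qy + rot[1, 2] * qz) * inv_vox + center
        z = (rot[2, 0] * qx + rot[2, 1] * qy + rot[2, 2] * qz) * inv_vox + center
        i0 = int(np.floor(x))
        j0 = int(np.floor(y))
        k0 = int(np.floor(z))
        if i0 < 0 or j0 < 0 or k0 < 0 or i0 >= n - 1 or j0 >= n - 1 or k0 >= n - 1:
            out[p] = np.nan
            continue
        fx = x - i0
        fy = y - j0
        fz = z - k0
        c00 = vol[i0, j0, k0] * (1 - fz) + vol[i0, j0, k0 + 1] * fz
        c01 = vol[i0, j0 + 1, k0] * (1 - fz) + vol[i0, j0 + 1, k0 + 1] * fz
        c10 = vol[i0 + 1, j0, k0] * (1 - fz) + vol[i0 + 1, j0, k0 + 1] * fz
        c11 = vol[i0 + 1, j0 + 1, k0] * (1 - fz) + vol[i0 + 1, j0 + 1, k0 + 1] * fz
        c0 = c00 * (1 - fy) + c01 * fy
        c1 = c10 * (1 - fy) + c11 * fy
        out[p] = c0 * (1 - fx) + c1 * fx


def _valid_pixels(patterns: PatternSet, qmap: QMap) -> np.ndarray:
    return ~patterns.beamstop_mask.reshape(-1)


def expand(
    model: IntensityVolume,
    rotations: RotationGroup,
    qmap: QMap,
    valid: np.ndarray | None = None,
) -> np.ndarray:
    """Expand a 3D model into tomograms, one Ewald slice per rotation.

    Returns a float64 array (n_rotations, n_valid_pixels): tomogram_j(p) =
    trilinear sample of the model at ``R_j . q(p)``.  Raises if any valid
    pixel rotates outside the grid.
    """
    qpix = qmap.flat_q().T.copy()
    if valid is not None:
        qpix = qpix[:, valid]
    mats = rotations.matrices()
    npix = qpix.shape[1]
    out = np.empty((len(mats), npix))
    vol = np.ascontiguousarray(model.values, dtype=np.float64)
    inv_vox = 1.0 / model.voxel_size
    center = float(model.center)
    row = np.empty(npix)
    for j in range(len(mats)):
        _gather_trilinear(vol, mats[j], qpix, inv_vox, center, row)
        if np.isnan(row).any():
            pix = int(np.flatnonzero(np.isnan(row))[0])
            raise ValueError(
                f"rotation {j} maps pixel {pix} outside the {model.edge}^3 grid"
            )
        out[j] = row
    return out


def maximize(
    counts: sparse.csr_matrix,
    tomograms: np.ndarray,
    beta: float = 1.0,
    weights: np.ndarray | None = None,
    min_tomo: float = 1e-20,
    counts_t: sparse.csr_matrix | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """One EM step: responsibilities and updated tomograms.

    Parameters
    ----------
    counts : (n_patterns, n_pixels) sparse photon counts (valid pixels only).
    tomograms : (n_rotations, n_pixels) expected intensities W_j.
    beta : annealing factor multiplying the log-likelihood.

    Returns
    -------
    responsibilities : (n_patterns, n_rotations), rows summing to 1.
    new_tomograms : responsibility-weighted mean patterns, same shape as
        ``tomograms``.
    log_likelihood : un-annealed sum over patterns of
        ``log sum_j w_j exp(R_jk)`` (Poisson terms, k! omitted).
    """
    n_rot, n_pix = tomograms.shape
    n_pat = counts.shape[0]
    if counts.shape[1] != n_pix:
        raise ValueError("pattern/tomogram pixel count mismatch")
    w = np.full(n_rot, 1.0 / n_rot) if weights is None else weights
    logw = np.log(w)

    tomo = np.maximum(tomograms, min_tomo)
    # R_jk = sum_p K_kp log W_jp - sum_p W_jp.  The working precision
    # follows the dtype of ``counts``: float32 is ample for responsibilities
    # (renormalized row-wise below) and halves the cost of the two sparse
    # products that dominate an EMC iteration; pass float64 counts when an
    # exactly monotone likelihood trace is required.
    work_dtype = counts.dtype
    log_t = np.log(tomo, dtype=work_dtype)
    ll = np.asarray(counts @ np.ascontiguousarray(log_t.T), dtype=np.float64)
    ll -= tomo.sum(axis=1)[None, :]
    ll += logw[None, :]
    total_ll = float(logsumexp(ll, axis=1).sum())

    resp = ll if beta == 1.0 else beta * ll
    resp -= resp.max(axis=1, keepdims=True)
    np.exp(resp, out=resp)
    norm = resp.sum(axis=1, keepdims=True)
    if not np.all(norm > 0):
        raise FloatingPointError("all-zero responsibilities (underflow)")
    resp /= norm
    # flush negligible responsibilities: subnormal float32 operands make
    # the sparse products orders of magnitude slower on x86
    resp[resp < 1e-30] = 0.0

    occupancy = resp.sum(axis=0)  # (n_rot,)
    # counts^T @ resp through the fast CSR-multivector kernel
    ct = counts_t if counts_t is not None else counts.T.tocsr()
    num = np.asarray(
        ct @ np.ascontiguousarray(resp, dtype=work_dtype), dtype=np.float64
    ).T
    new_tomo = num / np.maximum(occupancy, 1e-300)[:, None]
    # rotations with no responsibility keep their expanded values
    empty = occupancy <= 1e-12
    if empty.any():
        new_tomo[empty] = tomograms[empty]
    return resp, new_tomo, total_ll


def compress(
    tomograms: np.ndarray,
    rotations: RotationGroup,
    qmap: QMap,
    grid_edge: int,
    voxel_size: float,
    valid: np.ndarray | None = None,
    previous: IntensityVolume | None = None,
    occupancy: np.ndarray | None = None,
) -> IntensityVolume:
    """Scatter tomograms back into a 3D intensity volume.

    Voxel values are trilinear-weight-normalized averages of all tomogram
    samples landing there (weighted additionally by rotation occupancy when
    given); voxels never touched keep the previous model's value (or 0).
    """
    if tomograms.size == 0:
        raise ValueError("empty tomogram stack")
    qpix = qmap.flat_q().T.copy()
    if valid is not None:
        qpix = qpix[:, valid]
    if tomograms.shape[1] != qpix.shape[1]:
        raise ValueError("tomogram/pixel count mismatch")
    mats = rotations.matrices()
    num = np.zeros((grid_edge,) * 3)
    den = np.zeros((grid_edge,) * 3)
    inv_vox = 1.0 / voxel_size
    center = float(grid_edge // 2)
    for j in range(len(mats)):
        occ = 1.0 if occupancy is None else float(occupancy[j])
        if occ <= 0:
            continue
        vals = np.ascontiguousarray(tomograms[j], dtype=np.float64)
        _scatter_trilinear_weighted(
            vals, occ, mats[j], qpix, inv_vox, center, num, den
        )
    touched = den > 0
    values = np.zeros_like(num)
    values[touched] = num[touched] / den[touched]
    if previous is not None:
        values[~touched] = previous.values[~touched]
    return IntensityVolume(values=values, voxel_size=voxel_size)


@numba.njit(cache=True, fastmath=True)
def _scatter_trilinear_weighted(vals, occ, rot, qpix, inv_vox, center, num, den):
    n = num.shape[0]
    npix = qpix.shape[1]
    for p in range(npix):
        v = vals[p]
        qx = qpix[0, p]
        qy = qpix[1, p]
        qz = qpix[2, p]
        x = (rot[0, 0] * qx + rot[0, 1] * qy + rot[0, 2] * qz) * inv_vox + center
        y = (rot[1, 0] * qx + rot[1, 1] * qy + rot[1, 2] * qz) * inv_vox + center
        z = (rot[2, 0] * qx + rot[2, 1] * qy + rot[2, 2] * qz) * inv_vox + center
        i0 = int(np.floor(x))
        j0 = int(np.floor(y))
        k0 = int(np.floor(z))
        if i0 < 0 or j0 < 0 or k0 < 0 or i0 >= n - 1 or j0 >= n - 1 or k0 >= n - 1:
            continue
        fx = x - i0
        fy = y - j0
        fz = z - k0
        for di in range(2):
            wi = fx if di == 1 else 1 - fx
            for dj in range(2):
                wj = fy if dj == 1 else 1 - fy
                for dk in range(2):
                    wk = fz if dk == 1 else 1 - fz
                    w = wi * wj * wk * occ
                    num[i0 + di, j0 + dj, k0 + dk] += w * v
                    den[i0 + di, j0 + dj, k0 + dk] += w


def friedel_symmetrize(volume: IntensityVolume) -> IntensityVolume:
    """Average the volume with its point reflection about the centre voxel."""
    v = volume.values
    return replace(volume, values=0.5 * (v + v[::-1, ::-1, ::-1]))


@dataclass
class EMCResult:
    volume: IntensityVolume
    log_likelihood: list[float]
    beta_trace: list[float]
    level_trace: list[int]
    config: EMCConfig


def run_emc(
    patterns: PatternSet,
    qmap: QMap,
    config: EMCConfig,
    rng: np.random.Generator | None = None,
    verbose: bool = False,
) -> EMCResult:
    """Run the full EMC loop on a pattern set.

    Starts from a random positive model, then iterates expand / maximize /
    compress under the beta-annealing and rotation-refinement schedules.
    Returns the final intensity volume plus per-iteration traces.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    from .diffraction import voxel_size_for

    vox = config.voxel_size
    if vox is None:
        vox = voxel_size_for(patterns.geometry, config.grid_edge)

    valid = ~patterns.beamstop_mask.reshape(-1)
    counts = sparse.csr_matrix(patterns.photons[:, valid], dtype=np.float32)
    counts_t = counts.T.tocsr()
    mean_photon = counts.sum() / max(counts.shape[0] * counts.shape[1], 1)

    model = IntensityVolume(
        values=rng.uniform(0.5, 1.5, (config.grid_edge,) * 3) * max(mean_photon, 1e-6),
        voxel_size=vox,
    )

    ll_trace: list[float] = []
    beta_trace: list[float] = []
    level_trace: list[int] = []
    group_cache: dict[int, RotationGroup] = {}

    for it in range(config.total_iterations):
        beta = beta_at_iteration(
            it, config.beta_start, config.beta_factor, config.beta_period
        )
        level = config.level_at(it)
        group = group_cache.setdefault(level, rotation_group(level))

        tomo = expand(model, group, qmap, valid)
        resp, new_tomo, ll = maximize(counts, tomo, beta=beta, counts_t=counts_t)
        occupancy = resp.sum(axis=0)
        model = compress(
            new_tomo,
            group,
            qmap,
            config.grid_edge,
            vox,
            valid=None if valid.all() else valid,
            previous=model,
            occupancy=occupancy,
        )
        if config.symmetrize_friedel:
            model = friedel_symmetrize(model)
        if not np.all(np.isfinite(model.values)):
            raise FloatingPointError(f"model diverged (NaN) at iteration {it}")
        ll_trace.append(ll)
        beta_trace.append(beta)
        level_trace.append(level)
        if verbose:
            print(
                f"iter {it:3d} level {level} beta {beta:.4g} "
                f"loglik {ll:.6g}",
                flush=True,
            )
    model.metadata.update(
        {"iterations": config.total_iterations, "voxel_size": vox}
    )
    return EMCResult(
        volume=model,
        log_likelihood=ll_trace,
        beta_trace=beta_trace,
        level_trace=level_trace,
        config=config,
    )
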