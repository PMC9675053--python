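"""Quasi-uniform sampling of SO(3) by refinement of the 600-cell.

The 600-cell is the regular 4-polytope whose 120 vertices are unit
quaternions (the binary icosahedral group).  Subdividing each of its 600
tetrahedral cells ``n``-fold in barycentric coordinates and projecting the
points back to the unit 3-sphere gives ``20 (5 n^3 + n)`` quaternions;
identifying antipodes (q and -q are the same rotation) leaves

    N(n) = 10 (5 n^3 + n)

quasi-uniform rotations: 60 at n=1, 10 860 at n=6, 691 440 at n=24.  This
is the standard sampling used for orientation recovery of single-particle
diffraction snapshots, where the refinement level n trades angular
resolution against the cost of the EM orientation search.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from itertools import combinations, permutations, product

import numpy as np

__all__ = [
    "RotationGroup",
    "rotation_group",
    "rotation_count",
    "quaternions_to_matrices",
    "random_quaternion",
    "quaternion_multiply",
    "rotation_angle",
]

GOLDEN = (1.0 + np.sqrt(5.0)) / 2.0


def rotation_count(level: int) -> int:
    """Number of rotations at refinement level ``n``: ``10 (5 n^3 + n)``."""
    if level < 1:
        raise ValueError(f"refinement level must be >= 1, got {level}")
    return 10 * (5 * level**3 + level)


def _parity(perm: tuple[int, ...]) -> int:
    p = list(perm)
    parity = 1
    for i in range(len(p)):
        while p[i] != i:
            j = p[i]
            p[i], p[j] = p[j], p[i]
            parity = -parity
    return parity


@lru_cache(maxsize=1)
def _cell_vertices() -> np.ndarray:
    """The 600 tetrahedral cells of the 600-cell, as (600, 4, 4) vertex arrays."""
    verts: list[tuple[float, float, float, float]] = []
    # 8 unit-axis vertices
    for axis in range(4):
        for s in (1.0, -1.0):
            v = [0.0] * 4
            v[axis] = s
            verts.append(tuple(v))
    # 16 half-integer vertices
    for signs in product((0.5, -0.5), repeat=4):
        verts.append(signs)
    # 96 even permutations of (phi, 1, 1/phi, 0)/2 with free signs on nonzeros
    base = (GOLDEN / 2.0, 0.5, 0.5 / GOLDEN, 0.0)
    seen: set[tuple[float, ...]] = set()
    for perm in permutations(range(4)):
        if _parity(perm) != 1:
            continue
        arranged = tuple(base[perm.index(i)] for i in range(4))
        for signs in product((1.0, -1.0), repeat=4):
            v = tuple(round(s * a, 12) for s, a in zip(signs, arranged))
            if v not in seen:
                seen.add(v)
                verts.append(v)
    v = np.array(verts)
    assert v.shape == (120, 4)

    # adjacency: nearest vertices are at dot product phi/2 = cos 36 deg
    dots = v @ v.T
    adj = np.abs(dots - GOLDEN / 2.0) < 1e-9
    neighbors = [np.flatnonzero(adj[i]) for i in range(120)]
    cells = []
    for i in range(120):
        nbrs = neighbors[i][neighbors[i] > i]
        for a, b, c in combinations(nbrs, 3):
            if adj[a, b] and adj[a, c] and adj[b, c]:
                cells.append((i, a, b, c))
    cells_arr = v[np.array(cells)]
    assert cells_arr.shape == (600, 4, 4)
    return cells_arr


def _canonical_hemisphere(quats: np.ndarray) -> np.ndarray:
    """Flip each quaternion so its first nonzero component is positive."""
    q = quats.copy()
    sign = np.zeros(len(q))
    for k in range(4):
        undecided = sign == 0
        if not undecided.any():
            break
        comp = q[undecided, k]
        s = np.sign(comp)
        s[np.abs(comp) < 1e-12] = 0.0
        sign[undecided] = s
    sign[sign == 0] = 1.0
    return q * sign[:, None]


@dataclass(frozen=True)
class RotationGroup:
    """A quasi-uniform sample of SO(3).

    Attributes
    ----------
    level : int
        Refinement level n of the 600-cell subdivision.
    quaternions : (N, 4) float64
        Unit quaternions (w, x, y, z), one hemisphere of S^3.
    weights : (N,) float64
        Quadrature weights summing to 1 (uniform).
    """

    level: int
    quaternions: np.ndarray
    weights: np.ndarray

    def __len__(self) -> int:
        return len(self.quaternions)

    def matrices(self) -> np.ndarray:
        """Rotation matrices, shape (N, 3, 3)."""
        return quaternions_to_matrices(self.quaternions)


@lru_cache(maxsize=8)
def _group_quaternions(level: int) -> np.ndarray:
    cells = _cell_vertices()  # (600, 4, 4)
    n = level
    bary = np.array(
        [
            (i, j, k, n - i - j - k)
            for i in range(n + 1)
            for j in range(n + 1 - i)
            for k in range(n + 1 - i - j)
        ],
        dtype=float,
    )
    pts = np.einsum("bw,cwd->cbd", bary, cells).reshape(-1, 4)
    pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    pts = _canonical_hemisphere(pts)
    uniq = np.unique(np.round(pts, 9), axis=0)
    # re-normalize after rounding
    uniq /= np.linalg.norm(uniq, axis=1, keepdims=True)
    return uniq


def rotation_group(level: int) -> RotationGroup:
    """Quasi-uniform SO(3) sample at refinement level ``n >= 1``.

    The returned group has exactly ``10 (5 n^3 + n)`` rotations.
    """
    expected = rotation_count(int(level))
    quats = _group_quaternions(int(level))
    if len(quats) != expected:
        raise RuntimeError(
            f"level {level}: got {len(quats)} rotations, expected {expected}"
        )
    w = np.full(len(quats), 1.0 / len(quats))
    return RotationGroup(level=int(level), quaternions=quats, weights=w)


def quaternions_to_matrices(quats: np.ndarray) -> np.ndarray:
    """Rotation matrices from unit quaternions (w, x, y, z); shape (..., 3, 3)."""
    q = np.asarray(quats, dtype=float)
    single = q.ndim == 1
    q = np.atleast_2d(q)
    w, x, y, z = q[:, 0], q[:, 1], q[:, 2], q[:, 3]
    m = np.empty(q.shape[:-1] + (3, 3))
    m[:, 0, 0] = 1 - 2 * (y * y + z * z)
    m[:, 0, 1] = 2 * (x * y - w * z)
    m[:, 0, 2] = 2 * (x * z + w * y)
    m[:, 1, 0] = 2 * (x * y + w * z)
    m[:, 1, 1] = 1 - 2 * (x * x + z * z)
    m[:, 1, 2] = 2 * (y * z - w * x)
    m[:, 2, 0] = 2 * (x * z - w * y)
    m[:, 2, 1] = 2 * (y * z + w * x)
    m[:, 2, 2] = 1 - 2 * (x * x + y * y)
    return m[0] if single else m


def random_quaternion(rng: np.random.Generator) -> np.ndarray:
    """One Haar-uniform rotation as a unit quaternion (w, x, y, z).

    A 4D standard normal projected to the unit sphere is uniform on S^3,
    hence Haar-uniform on SO(3) after antipodal identification.
    """
    q = rng.standard_normal(4)
    q /= np.linalg.norm(q)
    if q[0] < 0:
        q = -q
    return q


def quaternion_multiply(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Hamilton product a*b of (w, x, y, z) quaternions."""
    w1, x1, y1, z1 = a
    w2, x2, y2, z2 = b
    return np.array(
        [
            w1 * w2 - x1 * x2 - y1 * y2 - z1 * z2,
            w1 * x2 + x1 * w2 + y1 * z2 - z1 * y2,
            w1 * y2 - x1 * z2 + y1 * w2 + z1 * x2,
            w1 * z2 + x1 * y2 - y1 * x2 + z1 * w2,
        ]
    )


def rotation_angle(quat: np.ndarray) -> float:
    """Rotation angle in [0, pi] represented by a unit quaternion."""
    return float(2.0 * np.arccos(np.clip(abs(quat[0]), -1.0, 1.0)))
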