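"""Deterministic streamline tractography on diffusion-tensor fields.

Streamlines are traced by bidirectional Euler integration along the principal
eigenvector of the (trilinearly interpolated) diffusion tensor, seeded on a
dense regular grid ("super-resolution" seeding, default 0.5 mm spacing).
Propagation stops when fractional anisotropy (FA) drops below a threshold
(default 0.2), when the turning angle between consecutive steps exceeds a
threshold (default 40 degrees), when the trajectory leaves the tracking mask,
or when a maximum length is reached.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "TensorField",
    "TrackingParams",
    "Streamline",
    "StreamlineSet",
    "tensor_eigen",
    "fractional_anisotropy",
    "trace",
    "track_whole_volume",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class TensorField:
    """Voxel grid of symmetric diffusion tensors.

    Parameters
    ----------
    tensors : ndarray, shape (X, Y, Z, 3, 3)
        Per-voxel symmetric diffusion tensor (mm^2/s).
    voxel_size : float
        Isotropic voxel edge length in mm.
    affine : ndarray, shape (4, 4), optional
        Voxel-to-world (mm) transform.  Defaults to a pure scaling by
        ``voxel_size`` with the origin at the corner voxel centre.
    mask : ndarray of bool, shape (X, Y, Z), optional
        Voxels eligible for tracking.  Defaults to all True.
    """

    tensors: np.ndarray
    voxel_size: float = 1.0
    affine: Optional[np.ndarray] = None
    mask: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.tensors = np.asarray(self.tensors, dtype=float)
        if self.tensors.ndim != 5 or self.tensors.shape[-2:] != (3, 3):
            raise ValueError("tensors must have shape (X, Y, Z, 3, 3)")
        if not np.isfinite(self.tensors).all():
            raise ValueError("non-finite tensor entries")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")
        asym = np.abs(self.tensors - np.swapaxes(self.tensors, -1, -2))
        if asym.max() > 1e-9:
            raise ValueError("tensors must be symmetric within 1e-9")
        if self.affine is None:
            aff = np.eye(4)
            aff[0, 0] = aff[1, 1] = aff[2, 2] = self.voxel_size
            self.affine = aff
        else:
            self.affine = np.asarray(self.affine, dtype=float)
        if self.mask is None:
            self.mask = np.ones(self.grid_shape, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.grid_shape:
                raise ValueError("mask shape must match grid shape")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.tensors.shape[:3]

    # -- coordinate transforms ---------------------------------------------
    @property
    def _inv_affine(self) -> np.ndarray:
        cached = getattr(self, "_inv_affine_cache", None)
        if cached is None:
            cached = np.linalg.inv(self.affine)
            object.__setattr__(self, "_inv_affine_cache", cached)
        return cached

    def world_to_voxel(self, pts_mm: np.ndarray) -> np.ndarray:
        inv = self._inv_affine
        pts = np.atleast_2d(pts_mm)
        vox = pts @ inv[:3, :3].T + inv[:3, 3]
        return vox if np.asarray(pts_mm).ndim == 2 else vox[0]

    def voxel_to_world(self, vox: np.ndarray) -> np.ndarray:
        v = np.atleast_2d(vox)
        mm = v @ self.affine[:3, :3].T + self.affine[:3, 3]
        return mm if np.asarray(vox).ndim == 2 else mm[0]


@dataclass
class TrackingParams:
    """Seeding / propagation / termination settings (units: mm, degrees)."""

    seed_grid_spacing: float = 0.5
    step_size: float = 0.5
    fa_threshold: float = 0.2
    angle_threshold: float = 40.0
    max_length: float = 250.0

    def __post_init__(self) -> None:
        for name in ("seed_grid_spacing", "step_size", "fa_threshold",
                     "angle_threshold", "max_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.angle_threshold <= 90:
            raise ValueError("angle_threshold must lie in (0, 90]")


@dataclass
class Streamline:
    """Ordered 3-D polyline in world (mm) coordinates."""

    points: np.ndarray  # (n_points, 3)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("points must have shape (n, 3)")
        if len(self.points) < 2:
            raise ValueError("a streamline needs at least 2 points")

    @property
    def length(self) -> float:
        """Total length in mm (sum of segment lengths)."""
        return float(np.linalg.norm(np.diff(self.points, axis=0), axis=1).sum())

    @property
    def endpoints(self) -> tuple[np.ndarray, np.ndarray]:
        return self.points[0], self.points[-1]


@dataclass
class StreamlineSet:
    """A collection of streamlines plus tracking provenance."""

    streamlines: list
    params: Optional[TrackingParams] = None
    n_seeds: int = 0
    extra: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.streamlines)

    def __iter__(self):
        return iter(self.streamlines)

    def lengths(self) -> np.ndarray:
        return np.array([s.length for s in self.streamlines])


# ---------------------------------------------------------------------------
# Tensor eigen-analysis
# ---------------------------------------------------------------------------

def fractional_anisotropy(eigvals: np.ndarray) -> np.ndarray:
    """FA from eigenvalues, standard normalised-variance form.

    FA = sqrt(3/2) * ||lambda - mean(lambda)|| / ||lambda||; 0 for null tensors.
    """
    ev = np.asarray(eigvals, dtype=float)
    mean = ev.mean(axis=-1, keepdims=True)
    num = np.sqrt(((ev - mean) ** 2).sum(axis=-1))
    den = np.sqrt((ev ** 2).sum(axis=-1))
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5) * num / den
    return np.where(den > 0, fa, 0.0)


def tensor_eigen(fld: TensorField) -> tuple[np.ndarray, np.ndarray]:
    """Per-voxel FA and principal eigenvector of a tensor field.

    Returns
    -------
    fa : ndarray (X, Y, Z)
    v1 : ndarray (X, Y, Z, 3), unit norm (zero where the tensor is null)
    """
    if not np.isfinite(fld.tensors).all():
        raise ValueError("non-finite tensor entries")
    vals, vecs = np.linalg.eigh(fld.tensors)  # ascending eigenvalues
    fa = fractional_anisotropy(vals)
    v1 = vecs[..., :, 2]  # eigenvector of the largest eigenvalue
    norm = np.linalg.norm(v1, axis=-1, keepdims=True)
    v1 = np.where(norm > 0, v1 / np.where(norm == 0, 1, norm), 0.0)
    return fa, v1


# ---------------------------------------------------------------------------
# Interpolation helpers
# ---------------------------------------------------------------------------

_TRI_ORDER = [(0, 0), (0, 1), (1, 1), (0, 2), (1, 2), (2, 2)]  # lower triangle


def _comp6(fld: TensorField) -> np.ndarray:
    """Cached flat (n_vox, 6) view of the unique tensor components."""
    cached = getattr(fld, "_comp6_cache", None)
    if cached is None:
        comp = np.stack([fld.tensors[..., i, j] for i, j in _TRI_ORDER], axis=-1)
        cached = np.ascontiguousarray(comp.reshape(-1, 6))
        object.__setattr__(fld, "_comp6_cache", cached)
    return cached


def _interp_tensor(fld: TensorField, vox: np.ndarray) -> np.ndarray:
    """Trilinear interpolation of the 6 unique tensor components at a voxel
    coordinate; indices are clamped to the grid edge so points within the
    outer half-voxel shell remain usable."""
    X, Y, Z = fld.grid_shape
    flat = _comp6(fld)
    x, y, z = float(vox[0]), float(vox[1]), float(vox[2])
    x0, y0, z0 = int(np.floor(x)), int(np.floor(y)), int(np.floor(z))
    fx, fy, fz = x - x0, y - y0, z - z0
    acc = np.zeros(6)
    wx = (1.0 - fx, fx)
    wy = (1.0 - fy, fy)
    wz = (1.0 - fz, fz)
    for dx in (0, 1):
        if wx[dx] == 0.0:
            continue
        ix = min(max(x0 + dx, 0), X - 1)
        for dy in (0, 1):
            wxy = wx[dx] * wy[dy]
            if wxy == 0.0:
                continue
            iy = min(max(y0 + dy, 0), Y - 1)
            for dz in (0, 1):
                w = wxy * wz[dz]
                if w == 0.0:
                    continue
                iz = min(max(z0 + dz, 0), Z - 1)
                acc += w * flat[(ix * Y + iy) * Z + iz]
    tensor = np.empty((3, 3))
    tensor[0, 0] = acc[0]
    tensor[0, 1] = tensor[1, 0] = acc[1]
    tensor[1, 1] = acc[2]
    tensor[0, 2] = tensor[2, 0] = acc[3]
    tensor[1, 2] = tensor[2, 1] = acc[4]
    tensor[2, 2] = acc[5]
    return tensor


def _fa_v1_at(fld: TensorField, vox: np.ndarray) -> tuple[float, np.ndarray]:
    t = _interp_tensor(fld, vox)
    vals, vecs = np.linalg.eigh(t)
    l1, l2, l3 = float(vals[0]), float(vals[1]), float(vals[2])
    m = (l1 + l2 + l3) / 3.0
    den = l1 * l1 + l2 * l2 + l3 * l3
    if den <= 0.0:
        return 0.0, vecs[:, 2]
    num = (l1 - m) ** 2 + (l2 - m) ** 2 + (l3 - m) ** 2
    fa = float(np.sqrt(1.5 * num / den))
    return fa, vecs[:, 2]


def _inside(fld: TensorField, vox: np.ndarray) -> bool:
    idx = np.rint(vox).astype(int)
    if np.any(idx < 0) or np.any(idx >= fld.grid_shape):
        return False
    return bool(fld.mask[idx[0], idx[1], idx[2]])


# ---------------------------------------------------------------------------
# Tracing
# ---------------------------------------------------------------------------

def _march(fld: TensorField, start_mm: np.ndarray, direction: np.ndarray,
           params: TrackingParams, budget: float) -> list:
    """One-directional Euler march from start_mm along `direction`.

    Returns the list of points *after* the start point.  `budget` caps the
    arc length of this half.
    """
    cos_cut = np.cos(np.deg2rad(params.angle_threshold))
    pts: list = []
    pos = np.array(start_mm, dtype=float)
    prev_dir = np.array(direction, dtype=float)
    travelled = 0.0
    while travelled + params.step_size <= budget:
        new_pos = pos + params.step_size * prev_dir
        vox = fld.world_to_voxel(new_pos)
        if not _inside(fld, vox):
            break
        fa, v1 = _fa_v1_at(fld, vox)
        if fa < params.fa_threshold:
            break
        # sign continuity: keep the hemisphere of the previous direction
        if np.dot(v1, prev_dir) < 0:
            v1 = -v1
        if np.dot(v1, prev_dir) < cos_cut:
            break
        pts.append(new_pos)
        pos = new_pos
        prev_dir = v1
        travelled += params.step_size
    return pts


def trace(seed_mm: np.ndarray, fld: TensorField,
          params: Optional[TrackingParams] = None) -> Optional[Streamline]:
    """Trace a single bidirectional streamline from a seed point (world mm).

    Returns None when the seed is rejected (FA below threshold) or the result
    would degenerate to a single point.  Raises for seeds outside the volume.
    """
    params = params or TrackingParams()
    seed_mm = np.asarray(seed_mm, dtype=float)
    vox = fld.world_to_voxel(seed_mm)
    idx = np.rint(vox).astype(int)
    if np.any(idx < 0) or np.any(idx >= fld.grid_shape):
        raise ValueError(f"seed {seed_mm} outside the volume")
    if not _inside(fld, vox):
        return None
    fa, v1 = _fa_v1_at(fld, vox)
    if fa < params.fa_threshold:
        return None
    half = params.max_length / 2.0
    fwd = _march(fld, seed_mm, v1, params, half)
    bwd = _march(fld, seed_mm, -v1, params, half)
    pts = bwd[::-1] + [seed_mm] + fwd
    if len(pts) < 2:
        return None
    return Streamline(np.array(pts))


def track_whole_volume(fld: TensorField,
                       params: Optional[TrackingParams] = None) -> StreamlineSet:
    """Seed a regular grid across the masked volume and trace every seed.

    Seeds are placed at multiples of ``seed_grid_spacing`` (world mm) covering
    the volume; a seed is attempted iff its nearest voxel is inside the mask.
    Deterministic: no randomness anywhere.
    """
    params = params or TrackingParams()
    if not fld.mask.any():
        raise ValueError("empty tracking mask")
    # world-space bounding box of the voxel grid
    shape = np.array(fld.grid_shape)
    corners_vox = np.array([[0, 0, 0], shape - 1]).astype(float)
    corners_mm = fld.voxel_to_world(corners_vox)
    lo = corners_mm.min(axis=0)
    hi = corners_mm.max(axis=0)
    sp = params.seed_grid_spacing
    axes = [np.arange(np.ceil(lo[a] / sp), np.floor(hi[a] / sp) + 1) * sp
            for a in range(3)]
    streamlines = []
    n_seeds = 0
    for x in axes[0]:
        for y in axes[1]:
            for z in axes[2]:
                seed = np.array([x, y, z])
                vox = fld.world_to_voxel(seed)
                if not _inside(fld, vox):
                    continue
                n_seeds += 1
                sl = trace(seed, fld, params)
                if sl is not None:
                    streamlines.append(sl)
    return StreamlineSet(streamlines, params=params, n_seeds=n_seeds)
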