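"""Voxel grids shared across the pipeline.

All positions are in mm in the patient frame (x = left-right, y =
dorsal-ventral, z = cranial-caudal).  A grid is defined by its ``origin``
(the mm coordinate of the *corner* of voxel (0,0,0)) and ``spacing``;
voxel centers therefore sit at ``origin + (index + 0.5) * spacing``.
The working grid throughout the margin pipeline is 1x1x1 mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage


class GridMismatchError(ValueError):
    """Two masks that must share a grid do not."""


@dataclass
class VoxelMask:
    """Binary structure volume (CTV, spinal cord, skin...) on a regular grid."""

    voxels: np.ndarray  # bool, shape (nx, ny, nz)
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    spacing: np.ndarray = field(default_factory=lambda: np.ones(3))

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=bool)
        self.origin = np.asarray(self.origin, dtype=float)
        self.spacing = np.asarray(self.spacing, dtype=float)
        if self.voxels.ndim != 3:
            raise ValueError("mask must be a 3-D volume")
        if np.any(self.spacing <= 0):
            raise ValueError("spacing must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def volume_ml(self) -> float:
        """Foreground volume in ml (1000 mm^3 = 1 ml)."""
        return int(self.voxels.sum()) * self.voxel_volume_mm3 / 1000.0

    def same_grid(self, other: "VoxelMask") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.origin, other.origin)
            and np.allclose(self.spacing, other.spacing)
        )

    def require_same_grid(self, other: "VoxelMask") -> None:
        if not self.same_grid(other):
            raise GridMismatchError("masks are not defined on the same grid")

    def foreground_points(self) -> np.ndarray:
        """Centers (mm) of all foreground voxels, shape (n, 3)."""
        idx = np.argwhere(self.voxels)
        return self.origin + (idx + 0.5) * self.spacing

    def points_to_indices(self, points: np.ndarray) -> np.ndarray:
        """Voxel indices containing the given mm points (may be out of range)."""
        return np.floor((np.asarray(points) - self.origin) / self.spacing).astype(int)

    def copy(self) -> "VoxelMask":
        return VoxelMask(self.voxels.copy(), self.origin.copy(), self.spacing.copy())

    def like(self, voxels: np.ndarray) -> "VoxelMask":
        """A new mask with the same grid and the given voxel array."""
        return VoxelMask(voxels, self.origin.copy(), self.spacing.copy())

    def surface(self) -> np.ndarray:
        """Boolean array marking foreground voxels with a 6-neighbour background."""
        eroded = ndimage.binary_erosion(
            self.voxels, structure=ndimage.generate_binary_structure(3, 1)
        )
        return self.voxels & ~eroded


@dataclass
class IntensityVolume:
    """Scalar intensity volume (synthetic CT) on a regular grid."""

    values: np.ndarray
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    spacing: np.ndarray = field(default_factory=lambda: np.ones(3))

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        self.spacing = np.asarray(self.spacing, dtype=float)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def index_to_mm(self, idx: np.ndarray) -> np.ndarray:
        return self.origin + (np.asarray(idx) + 0.5) * self.spacing

    def mm_to_index(self, pos: np.ndarray) -> np.ndarray:
        return np.floor((np.asarray(pos) - self.origin) / self.spacing).astype(int)


def inverse_warp_mask(
    mask: VoxelMask,
    displacement_fn,
    pad_mm: float = 25.0,
    iterations: int = 3,
) -> VoxelMask:
    """Warp a binary mask through a *forward* displacement field, exactly.

    For every voxel center y in a padded region of interest the forward
    warp ``T(x) = x + u(x)`` is inverted by fixed-point iteration
    ``x <- y - u(x)`` (converges for the smooth, sub-unit-gradient fields
    of pose deformation) and the output takes the source voxel at x.
    This center-sampling rasterization is exact for rigid motions and
    volume-faithful under smooth warps, unlike forward point splatting.

    ``displacement_fn(points) -> (n, 3)`` evaluates u in mm.
    """
    idx = np.argwhere(mask.voxels)
    out = np.zeros(mask.shape, dtype=bool)
    if len(idx) == 0:
        return mask.like(out)
    pad = int(np.ceil(pad_mm / mask.spacing.min()))
    lo = np.maximum(idx.min(axis=0) - pad, 0)
    hi = np.minimum(idx.max(axis=0) + 1 + pad, np.array(mask.shape))
    grids = np.meshgrid(*[np.arange(l, h) for l, h in zip(lo, hi)], indexing="ij")
    roi_idx = np.stack([g.ravel() for g in grids], axis=1)
    y = mask.origin + (roi_idx + 0.5) * mask.spacing
    # first displacement evaluation bounds the reachable band: a voxel
    # farther from the foreground than the largest displacement stays empty
    u0 = displacement_fn(y)
    umax = float(np.linalg.norm(u0, axis=1).max())
    roi_fg = mask.voxels[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    edt = ndimage.distance_transform_edt(~roi_fg, sampling=mask.spacing).ravel()
    active = edt <= umax + mask.spacing.max()
    y = y[active]
    x = y - u0[active]
    for _ in range(iterations - 1):
        x = y - displacement_fn(x)
    src = np.floor((x - mask.origin) / mask.spacing).astype(int)
    ok = np.all((src >= 0) & (src < np.array(mask.shape)), axis=1)
    vals = np.zeros(len(src), dtype=bool)
    vals[ok] = mask.voxels[src[ok, 0], src[ok, 1], src[ok, 2]]
    ridx = roi_idx[active]
    out[ridx[:, 0], ridx[:, 1], ridx[:, 2]] = vals
    return mask.like(out)


def deposit_points(points: np.ndarray, template: VoxelMask, close: bool = True) -> VoxelMask:
    """Rasterize mm points onto ``template``'s grid by nearest-voxel deposition.

    A single pass of 6-connected morphological closing seals sub-voxel
    pinholes left by forward warping; points falling outside the grid are
    dropped.
    """
    out = np.zeros(template.shape, dtype=bool)
    if len(points):
        idx = template.points_to_indices(points)
        ok = np.all((idx >= 0) & (idx < np.array(template.shape)), axis=1)
        idx = idx[ok]
        out[idx[:, 0], idx[:, 1], idx[:, 2]] = True
    if close:
        structure = ndimage.generate_binary_structure(3, 1)
        out = ndimage.binary_closing(out, structure=structure)
    return template.like(out)
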