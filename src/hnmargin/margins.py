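"""The three competing CTV-to-ITV margin generators.

1. ``margin_constant`` — clinical practice: isotropic morphological
   dilation of the CTV by a 3 mm sphere.
2. ``margin_distance_field`` + ``margin_distance`` — distance-weighted
   variable margin: per-landmark residual-error statistics from the rest
   of the cohort are interpolated over the CTV surface by inverse-distance
   weights ``r(x) = sum_i w_i m_i`` and applied as a spatially varying
   (per-axis, ellipsoidal) dilation.  Per-landmark margins follow either
   the 95 % confidence-interval form (1.96 sigma per axis) or the
   systematic/random recipe ``m_i = 2.5 Sigma_i + 0.7 sigma_i``.
3. ``margin_fem`` — biomechanical scenario sampling: pose scenarios drawn
   from the cohort pose model are solved with the FE model, the CTV is
   propagated through every scenario DVF, and the ITV keeps the voxels hit
   in more than ``hit_threshold`` (default 5 %) of scenarios.

All masks live on the 1 mm^3 working grid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import ndimage

from .fem import DisplacementField, MaskWarper
from .grids import VoxelMask

logger = logging.getLogger(__name__)

DEFAULT_CONSTANT_RADIUS_MM = 3.0
DEFAULT_HIT_THRESHOLD = 0.05
CI_Z_95 = 1.96

#: radii are quantized to 1/8 voxel when building ellipsoidal structuring
#: elements, so that equal-margin surface points share one element
_RADIUS_QUANTUM = 0.125


@dataclass
class LocalMarginField:
    """Per-axis margin radii attached to CTV surface voxels."""

    surface_indices: np.ndarray  # (S, 3) int voxel indices into the CTV grid
    radii: np.ndarray  # (S, 3) mm, >= 0

    def __post_init__(self) -> None:
        self.surface_indices = np.asarray(self.surface_indices, dtype=int)
        self.radii = np.asarray(self.radii, dtype=float)
        if np.any(self.radii < 0) or not np.all(np.isfinite(self.radii)):
            raise ValueError("margin radii must be finite and non-negative")

    @classmethod
    def constant(cls, ctv: VoxelMask, radius: float) -> "LocalMarginField":
        idx = np.argwhere(ctv.surface())
        return cls(idx, np.full((len(idx), 3), float(radius)))


def _ball_offsets(radii: tuple[float, float, float]) -> np.ndarray:
    """Integer voxel offsets inside the (possibly anisotropic) ellipsoid."""
    r = np.asarray(radii, dtype=float)
    ext = np.floor(r + 1e-9).astype(int)
    grids = np.meshgrid(*[np.arange(-e, e + 1) for e in ext], indexing="ij")
    o = np.stack([g.ravel() for g in grids], axis=1)
    safe = np.maximum(r, 1e-12)
    inside = np.sum((o / safe) ** 2, axis=1) <= 1.0 + 1e-9
    return o[inside]


@lru_cache(maxsize=4096)
def _cached_offsets(key: tuple[float, float, float]) -> np.ndarray:
    return _ball_offsets(key)


def margin_constant(ctv: VoxelMask, radius: float = DEFAULT_CONSTANT_RADIUS_MM) -> VoxelMask:
    """Isotropic constant margin: binary dilation by a discretized sphere."""
    if radius < 0:
        raise ValueError("radius must be >= 0")
    r_vox = radius / ctv.spacing  # allows anisotropic spacing, though 1 mm is standard
    offs = _ball_offsets(tuple(r_vox))
    ext = np.abs(offs).max(axis=0) if len(offs) else np.zeros(3, int)
    structure = np.zeros(2 * ext + 1, dtype=bool)
    structure[tuple((offs + ext).T)] = True
    return ctv.like(ndimage.binary_dilation(ctv.voxels, structure=structure))


def margin_distance_field(
    ctv: VoxelMask,
    landmark_positions: np.ndarray,
    random_sd: np.ndarray,
    systematic_sd: np.ndarray | None = None,
    mode: str = "ci",
    ci_z: float = CI_Z_95,
    weight_exponent: float = 3.0,
) -> LocalMarginField:
    """Interpolate per-landmark margins over the CTV surface.

    Parameters
    ----------
    landmark_positions : (L, 3) mm
    random_sd : (L, 3)
        Per-axis random-error standard deviations sigma_i over the
        training cohort (leave the target patient out upstream).
    systematic_sd : (L, 3), optional
        Per-axis systematic-error SDs Sigma_i; required for ``mode='yang'``.
    mode : 'ci' or 'yang'
        Per-landmark margin ``m_i = ci_z * sigma_i`` (95 % CI by default)
        or ``m_i = 2.5 Sigma_i + 0.7 sigma_i``.
    weight_exponent : p in the inverse-distance weights w_i ~ 1/d^p.
    """
    lm = np.atleast_2d(np.asarray(landmark_positions, dtype=float))
    sig = np.atleast_2d(np.asarray(random_sd, dtype=float))
    if mode == "ci":
        m = ci_z * sig
    elif mode == "yang":
        if systematic_sd is None:
            raise ValueError("mode='yang' requires systematic SDs")
        m = 2.5 * np.atleast_2d(np.asarray(systematic_sd, dtype=float)) + 0.7 * sig
    else:
        raise ValueError(f"unknown margin mode {mode!r}")
    if len(lm) < 1:
        raise ValueError("need at least one landmark with statistics")

    idx = np.argwhere(ctv.surface())
    pts = ctv.origin + (idx + 0.5) * ctv.spacing
    d = np.linalg.norm(pts[:, None, :] - lm[None, :, :], axis=2)  # (S, L)
    radii = np.empty((len(pts), 3))
    coincident = d.min(axis=1) < 1e-9
    if coincident.any():
        nearest = d[coincident].argmin(axis=1)
        radii[coincident] = m[nearest]
    rest = ~coincident
    if rest.any():
        w = d[rest] ** (-weight_exponent)
        w /= w.sum(axis=1, keepdims=True)
        radii[rest] = w @ m
    return LocalMarginField(idx, radii)


def margin_distance(ctv: VoxelMask, field: LocalMarginField) -> VoxelMask:
    """Spatially varying (ellipsoidal, per-axis) dilation of the CTV surface.

    Each surface voxel is expanded by its local per-axis radii; the union
    with the CTV is the ITV.  Where the field is constant this reproduces
    ``margin_constant`` of that radius voxel-for-voxel.
    """
    out = ctv.voxels.copy()
    shape = np.array(ctv.shape)
    r_vox = field.radii / ctv.spacing
    keys = np.round(r_vox / _RADIUS_QUANTUM) * _RADIUS_QUANTUM
    for i in range(len(field.surface_indices)):
        offs = _cached_offsets(tuple(keys[i]))
        tgt = field.surface_indices[i] + offs
        ok = np.all((tgt >= 0) & (tgt < shape), axis=1)
        tgt = tgt[ok]
        out[tgt[:, 0], tgt[:, 1], tgt[:, 2]] = True
    return ctv.like(out)


def margin_fem(
    ctv: VoxelMask,
    scenario_fields: list[DisplacementField],
    hit_threshold: float = DEFAULT_HIT_THRESHOLD,
    warper: MaskWarper | None = None,
    return_counts: bool = False,
):
    """Scenario-accumulation margin: keep voxels hit in > threshold of scenarios.

    The CTV is forward-propagated through every sampled-pose displacement
    field; per-voxel hit counts are accumulated and the ITV keeps voxels
    with ``count > hit_threshold * N`` (strict inequality, matching the
    'more than 5 %' rule).
    """
    if not scenario_fields:
        raise ValueError("need at least one scenario field")
    if not (0 <= hit_threshold < 1):
        raise ValueError("hit_threshold must be in [0, 1)")
    warper = warper or MaskWarper(ctv, scenario_fields[0].mesh)
    counts = np.zeros(ctv.shape, dtype=np.int32)
    for f in scenario_fields:
        counts += warper.warp(f).voxels
    itv = ctv.like(counts > hit_threshold * len(scenario_fields))
    if return_counts:
        return itv, counts
    return itv
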