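"""Landmark tracking, outlier rejection and rigid couch-correction simulation.

The daily pose of a head-and-neck patient is represented by named bony
landmarks.  Fractions are matched to the planning image by normalized
cross-correlation template tracking; implausible correspondences are
rejected with a rigid-body geometric model (Mahalanobis gating); the
rigid component of the daily setup error — which image guidance corrects
with the treatment couch — is removed by a rigid Procrustes alignment on
the skull landmark subset.  What remains per landmark is the residual
*deformation* that internal margins must cover.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.linalg import svd
from skimage.feature import match_template

from .grids import IntensityVolume

logger = logging.getLogger(__name__)

REGIONS = ("skull", "spine", "shoulder")

#: NCC score below which a correspondence is considered doubtful and dropped.
DEFAULT_NCC_THRESHOLD = 0.7
#: Mahalanobis gate for head-region (skull + spine) landmarks.
DEFAULT_HEAD_THRESHOLD = 15.0
#: Mahalanobis gate for shoulder landmarks.
DEFAULT_SHOULDER_THRESHOLD = 60.0


class TrackingFailureError(RuntimeError):
    """Template matching cannot be evaluated (flat template / empty window)."""


class AlignmentError(RuntimeError):
    """Procrustes alignment is impossible (too few / degenerate references)."""


@dataclass
class LandmarkSet:
    """Named 3-D landmark positions for one image (planning or fraction)."""

    names: list[str]
    positions: np.ndarray  # (M, 3) mm, patient frame
    region: list[str]
    valid: np.ndarray = None  # (M,) bool
    fraction_id: int = 0  # 0 = planning

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.valid is None:
            self.valid = np.ones(len(self.names), dtype=bool)
        self.valid = np.asarray(self.valid, dtype=bool)
        if len(set(self.names)) != len(self.names):
            raise ValueError("landmark names must be unique")
        if self.positions.shape != (len(self.names), 3):
            raise ValueError("positions must be (M, 3)")
        if not np.all(np.isfinite(self.positions[self.valid])):
            raise ValueError("valid landmarks must have finite positions")
        for r in self.region:
            if r not in REGIONS:
                raise ValueError(f"unknown region tag {r!r}")

    def __len__(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        return self.names.index(name)

    def position(self, name: str) -> np.ndarray:
        return self.positions[self.index(name)]

    def region_mask(self, region: str) -> np.ndarray:
        return np.array([r == region for r in self.region])

    def copy(self) -> "LandmarkSet":
        return replace(
            self,
            names=list(self.names),
            positions=self.positions.copy(),
            region=list(self.region),
            valid=self.valid.copy(),
        )


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion x -> R x + t (no scaling, no reflection)."""

    rotation: np.ndarray  # (3, 3)
    translation: np.ndarray  # (3,)

    def __post_init__(self) -> None:
        object.__setattr__(self, "rotation", np.asarray(self.rotation, dtype=float))
        object.__setattr__(self, "translation", np.asarray(self.translation, dtype=float))
        R = self.rotation
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-10):
            raise ValueError("rotation is not orthogonal")
        if np.linalg.det(R) < 0:
            raise ValueError("reflections are not rigid motions")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points) @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self o other (apply ``other`` first)."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    def apply_to_set(self, lms: LandmarkSet) -> LandmarkSet:
        out = lms.copy()
        out.positions = self.apply(out.positions)
        return out


@dataclass
class GeometricLandmarkModel:
    """Rigid-body gating model: inter-landmark difference-vector statistics.

    Landmarks on the same bone cannot change their relative position; the
    distribution of their planning-frame difference vectors over a training
    set therefore concentrates tightly, and a fraction observation far from
    it (in Mahalanobis distance) flags a mistracked landmark.
    """

    edges: list[tuple[str, str]]
    means: dict[tuple[str, str], np.ndarray]  # 3-vector per edge
    covariances: dict[tuple[str, str], np.ndarray]  # (3,3) per edge, regularized SPD
    head_threshold: float = DEFAULT_HEAD_THRESHOLD
    shoulder_threshold: float = DEFAULT_SHOULDER_THRESHOLD
    shoulder_direction: str = "higher"  # remove when distance 'higher'/'lower' than gate

    def __post_init__(self) -> None:
        for e in self.edges:
            C = self.covariances[e]
            if not np.allclose(C, C.T, atol=1e-9):
                raise ValueError(f"covariance for edge {e} not symmetric")
            if np.min(np.linalg.eigvalsh(C)) < -1e-9:
                raise ValueError(f"covariance for edge {e} not PSD")

    def edge_distance(self, edge: tuple[str, str], diff: np.ndarray) -> float:
        """Mahalanobis distance of an observed difference vector on one edge."""
        d = np.asarray(diff) - self.means[edge]
        return float(np.sqrt(d @ np.linalg.solve(self.covariances[edge], d)))


# ---------------------------------------------------------------------------
# NCC tracking


def ncc_track(
    template: np.ndarray,
    volume: IntensityVolume,
    window: tuple[np.ndarray, np.ndarray],
) -> tuple[np.ndarray, float]:
    """Track one landmark by normalized cross-correlation template matching.

    Parameters
    ----------
    template:
        Intensity patch cut around the planning landmark (odd-sized array);
        the tracked position refers to the patch center.
    volume:
        Fraction intensity volume.
    window:
        ``(lo, hi)`` voxel-index corners (inclusive lo, exclusive hi) of the
        axis-aligned search region within ``volume``.

    Returns
    -------
    position : (3,) mm position of the best-matching template center.
    score : maximum normalized cross-correlation in [-1, 1].

    The caller is responsible for flagging the landmark invalid when
    ``score`` falls below the acceptance threshold (default 0.7).  Ties in
    the score map are broken by first occurrence in C (lexicographic voxel)
    order.
    """
    template = np.asarray(template, dtype=float)
    if template.std() == 0:
        raise TrackingFailureError("template has zero intensity variance")
    lo = np.maximum(np.asarray(window[0], dtype=int), 0)
    hi = np.minimum(np.asarray(window[1], dtype=int), np.array(volume.shape))
    if np.any(hi - lo < np.array(template.shape)):
        raise TrackingFailureError("search window smaller than template (or out of volume)")
    search = volume.values[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    scores = match_template(search, template)  # 'valid' correlation map
    flat = int(np.argmax(scores))
    offset = np.array(np.unravel_index(flat, scores.shape))
    center_idx = lo + offset + (np.array(template.shape) - 1) / 2.0
    position = volume.origin + (center_idx + 0.5) * volume.spacing
    return position, float(scores.flat[flat])


def extract_template(
    volume: IntensityVolume, position_mm: np.ndarray, half_size: int
) -> np.ndarray:
    """Cut a cubic (2*half_size+1)^3 patch centered on the voxel holding ``position_mm``."""
    c = volume.mm_to_index(position_mm)
    lo = c - half_size
    hi = c + half_size + 1
    if np.any(lo < 0) or np.any(hi > np.array(volume.shape)):
        raise TrackingFailureError("template window leaves the volume")
    return volume.values[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]].copy()


# ---------------------------------------------------------------------------
# Geometric model / Mahalanobis gating

#: covariance regularization floor, mm^2 (small training sets are singular)
COV_REGULARIZATION = 1e-6


def fit_geometric_model(
    training_sets: list[LandmarkSet],
    bone_assignment: dict[str, str],
    *,
    head_threshold: float = DEFAULT_HEAD_THRESHOLD,
    shoulder_threshold: float = DEFAULT_SHOULDER_THRESHOLD,
    shoulder_direction: str = "higher",
) -> GeometricLandmarkModel:
    """Estimate per-edge difference statistics over a training set.

    Edges connect every pair of landmarks assigned to the same bone.  An
    edge observed jointly in fewer than 3 training sets is dropped with a
    warning.  Covariances get an ``eps * I`` floor so they stay invertible.
    """
    if len(training_sets) < 3:
        raise ValueError("need at least 3 training sets")
    names = training_sets[0].names
    by_bone: dict[str, list[str]] = {}
    for n in names:
        if n in bone_assignment:
            by_bone.setdefault(bone_assignment[n], []).append(n)
    candidate_edges = [
        (a, b)
        for members in by_bone.values()
        for i, a in enumerate(members)
        for b in members[i + 1:]
    ]

    edges, means, covs = [], {}, {}
    for a, b in candidate_edges:
        diffs = []
        for s in training_sets:
            ia, ib = s.index(a), s.index(b)
            if s.valid[ia] and s.valid[ib]:
                diffs.append(s.positions[ia] - s.positions[ib])
        if len(diffs) < 3:
            logger.warning("edge (%s, %s) observed in <3 training sets; dropped", a, b)
            continue
        D = np.array(diffs)
        edges.append((a, b))
        means[(a, b)] = D.mean(axis=0)
        covs[(a, b)] = np.cov(D.T, bias=False) + COV_REGULARIZATION * np.eye(3)
    return GeometricLandmarkModel(
        edges, means, covs,
        head_threshold=head_threshold,
        shoulder_threshold=shoulder_threshold,
        shoulder_direction=shoulder_direction,
    )


def flag_outliers(lms: LandmarkSet, model: GeometricLandmarkModel) -> LandmarkSet:
    """Invalidate landmarks whose neighbor-relative displacement is implausible.

    Per landmark the Mahalanobis distances of all its incident edge
    difference vectors are computed and aggregated by the minimum (a
    correctly tracked landmark keeps at least one consistent neighbor even
    when another neighbor is corrupt).  Head-region (skull/spine) landmarks
    are removed when the distance strictly exceeds the head gate; shoulder
    landmarks per the shoulder rule.  Thresholds are exclusive.
    """
    out = lms.copy()
    dist: dict[str, float] = {}
    for a, b in model.edges:
        ia, ib = lms.index(a), lms.index(b)
        if not (lms.valid[ia] and lms.valid[ib]):
            continue
        d = model.edge_distance((a, b), lms.positions[ia] - lms.positions[ib])
        for n in (a, b):
            dist[n] = min(dist.get(n, np.inf), d)
    for i, n in enumerate(lms.names):
        if not lms.valid[i]:
            continue
        if n not in dist:
            logger.warning("landmark %s has no valid neighbors; left unchanged", n)
            continue
        if lms.region[i] == "shoulder":
            if model.shoulder_direction == "higher":
                remove = dist[n] > model.shoulder_threshold
            else:
                remove = dist[n] < model.shoulder_threshold
        else:
            remove = dist[n] > model.head_threshold
        if remove:
            out.valid[i] = False
            logger.info("landmark %s removed (Mahalanobis %.2f)", n, dist[n])
    return out


# ---------------------------------------------------------------------------
# Procrustes couch-correction simulation


def procrustes_align(
    planning: LandmarkSet,
    fraction: LandmarkSet,
    reference_region: str = "skull",
) -> RigidTransform:
    """Rigid Procrustes transform taking the fraction onto the planning pose.

    Only rotation + translation, no scaling — a treatment couch cannot
    scale a patient — and reflections are excluded by the SVD sign
    correction.  The least-squares fit uses the shared valid landmarks in
    ``reference_region`` (skull by default); the caller applies the result
    to *all* landmarks.
    """
    shared = [
        n for n in planning.names
        if n in fraction.names
        and planning.region[planning.index(n)] == reference_region
        and planning.valid[planning.index(n)]
        and fraction.valid[fraction.index(n)]
    ]
    if len(shared) < 3:
        raise AlignmentError(
            f"need >=3 shared valid {reference_region} landmarks, got {len(shared)}"
        )
    P = np.array([planning.position(n) for n in shared])
    F = np.array([fraction.position(n) for n in shared])
    Pc, Fc = P - P.mean(axis=0), F - F.mean(axis=0)
    # collinearity check: centered points must span a plane
    if np.linalg.matrix_rank(Pc, tol=1e-8 * max(1.0, np.abs(Pc).max())) < 2:
        raise AlignmentError("reference landmarks are collinear")
    H = Fc.T @ Pc
    U, _, Vt = svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = P.mean(axis=0) - R @ F.mean(axis=0)
    return RigidTransform(R, t)


def residual_displacements(
    planning: LandmarkSet, aligned_fraction: LandmarkSet
) -> dict[str, np.ndarray]:
    """Per-landmark residual deformation after couch correction.

    Returns ``{name: fraction - planning}`` (mm) for landmarks valid in
    both sets; invalid or unshared landmarks are simply absent.
    """
    out: dict[str, np.ndarray] = {}
    for i, n in enumerate(planning.names):
        if n not in aligned_fraction.names:
            continue
        j = aligned_fraction.index(n)
        if planning.valid[i] and aligned_fraction.valid[j]:
            out[n] = aligned_fraction.positions[j] - planning.positions[i]
    if not out:
        logger.warning("no shared valid landmarks; empty residual set")
    return out
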