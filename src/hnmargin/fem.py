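"""Co-rotational tetrahedral FEM for pose deformation modelling.

A patient-specific tetrahedral mesh of the body is deformed from the
planning pose toward fraction landmark positions.  Each landmark is tied
to its containing tetrahedron by a spring: the force ``f_i = k * d_i``
pulls the (barycentrically embedded) material point toward the observed
fraction position and is re-evaluated continuously as the mesh deforms.
The elastic response is homogeneous isotropic linear material in a
co-rotational formulation — per-element rotations are factored out by
polar decomposition so large rigid rotations produce no spurious strain,
which a purely linear small-strain model cannot do.

Units: mm, N, MPa (= N/mm^2); spring stiffness k in N/mm.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import spsolve
from scipy.spatial import cKDTree

from .grids import VoxelMask

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Types


@dataclass
class TetMesh:
    """Tetrahedral mesh: node positions (mm) and 4-tuples of node indices."""

    node_positions: np.ndarray  # (N, 3)
    tetrahedra: np.ndarray  # (T, 4) int

    def __post_init__(self) -> None:
        self.node_positions = np.asarray(self.node_positions, dtype=float)
        self.tetrahedra = np.asarray(self.tetrahedra, dtype=int)
        if self.tetrahedra.size == 0:
            raise ValueError("mesh has no tetrahedra")
        if self.tetrahedra.min() < 0 or self.tetrahedra.max() >= len(self.node_positions):
            raise ValueError("tetrahedron node index out of range")
        vols = self.volumes()
        if np.any(vols <= 0):
            raise ValueError(f"{np.sum(vols <= 0)} tetrahedra have non-positive volume")

    @property
    def n_nodes(self) -> int:
        return len(self.node_positions)

    @property
    def n_tets(self) -> int:
        return len(self.tetrahedra)

    def edge_matrices(self, positions: np.ndarray | None = None) -> np.ndarray:
        """Per-tet 3x3 edge matrices [v1-v0, v2-v0, v3-v0] as columns, (T,3,3)."""
        x = self.node_positions if positions is None else positions
        v = x[self.tetrahedra]  # (T, 4, 3)
        return np.stack([v[:, 1] - v[:, 0], v[:, 2] - v[:, 0], v[:, 3] - v[:, 0]], axis=2)

    def volumes(self, positions: np.ndarray | None = None) -> np.ndarray:
        return np.linalg.det(self.edge_matrices(positions)) / 6.0

    def connected_components(self) -> int:
        import scipy.sparse.csgraph as csgraph

        i = np.repeat(self.tetrahedra[:, :1], 3, axis=1).ravel()
        j = self.tetrahedra[:, 1:].ravel()
        a = sparse.coo_matrix(
            (np.ones(len(i)), (i, j)), shape=(self.n_nodes, self.n_nodes)
        )
        n, _ = csgraph.connected_components(a, directed=False)
        return n


@dataclass
class MaterialParams:
    """Homogeneous isotropic linear elastic material."""

    young_modulus: float = 10.0  # MPa
    poisson_ratio: float = 0.45

    def __post_init__(self) -> None:
        if self.young_modulus <= 0:
            raise ValueError("Young's modulus must be positive")
        if not (0 <= self.poisson_ratio < 0.5):
            raise ValueError("Poisson's ratio must be in [0, 0.5)")

    @property
    def lame(self) -> tuple[float, float]:
        e, nu = self.young_modulus, self.poisson_ratio
        lam = e * nu / ((1 + nu) * (1 - 2 * nu))
        mu = e / (2 * (1 + nu))
        return lam, mu


@dataclass
class SpringBC:
    """Spring boundary conditions tying landmark material points to targets."""

    tet_indices: np.ndarray  # (L,) int
    barycentric: np.ndarray  # (L, 4), non-negative, rows sum to 1
    targets: np.ndarray  # (L, 3) mm
    stiffness: float  # N/mm

    def __post_init__(self) -> None:
        self.tet_indices = np.asarray(self.tet_indices, dtype=int)
        self.barycentric = np.asarray(self.barycentric, dtype=float)
        self.targets = np.asarray(self.targets, dtype=float)
        if self.stiffness <= 0:
            raise ValueError("spring stiffness must be positive")
        if np.any(self.barycentric < -1e-9):
            raise ValueError("barycentric coordinates must be non-negative")
        if not np.allclose(self.barycentric.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("barycentric coordinates must sum to 1")

    @property
    def n_springs(self) -> int:
        return len(self.tet_indices)

    def attachment_points(self, mesh: TetMesh, displacements: np.ndarray) -> np.ndarray:
        """Current (deformed) positions of the spring attachment points."""
        nodes = mesh.tetrahedra[self.tet_indices]  # (L, 4)
        pos = mesh.node_positions[nodes] + displacements[nodes]  # (L, 4, 3)
        return np.einsum("lk,lkd->ld", self.barycentric, pos)


@dataclass
class SolveReport:
    converged: bool
    iterations: int
    max_residual_force: float  # N
    inverted_elements: int = 0


@dataclass
class DisplacementField:
    """Per-node displacements over a rest mesh, defining a DVF by barycentric mapping."""

    mesh: TetMesh
    node_displacements: np.ndarray  # (N, 3) mm
    report: SolveReport | None = None

    def __post_init__(self) -> None:
        self.node_displacements = np.asarray(self.node_displacements, dtype=float)
        if self.node_displacements.shape != (self.mesh.n_nodes, 3):
            raise ValueError("one displacement per node required")
        if not np.all(np.isfinite(self.node_displacements)):
            raise ValueError("displacements must be finite")


# ---------------------------------------------------------------------------
# Point location / barycentric embedding


class MeshLocator:
    """Locate points in a tet mesh (KD-tree over centroids + exact bary test)."""

    def __init__(self, mesh: TetMesh):
        self.mesh = mesh
        self._dm_inv = np.linalg.inv(mesh.edge_matrices())
        self._v0 = mesh.node_positions[mesh.tetrahedra[:, 0]]
        centroids = mesh.node_positions[mesh.tetrahedra].mean(axis=1)
        self._tree = cKDTree(centroids)

    def _bary(self, tets: np.ndarray, points: np.ndarray) -> np.ndarray:
        """Barycentric coords of points[i] in tets[i], (n, 4)."""
        lam = np.einsum(
            "nij,nj->ni", self._dm_inv[tets], points - self._v0[tets]
        )
        return np.column_stack([1.0 - lam.sum(axis=1), lam])

    def locate(
        self, points: np.ndarray, k: int = 24, tol: float = 1e-9
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Containing tet, barycentric coords and exterior flag per point.

        Points outside the mesh get the candidate tetrahedron whose
        barycentric coordinates are least violated, clamped to the simplex,
        and ``exterior=True``.
        """
        points = np.atleast_2d(np.asarray(points, dtype=float))
        n = len(points)
        k = min(k, self.mesh.n_tets)
        _, cand = self._tree.query(points, k=k)
        cand = np.atleast_2d(cand)
        best_tet = np.zeros(n, dtype=int)
        best_bary = np.zeros((n, 4))
        best_min = np.full(n, -np.inf)
        remaining = np.arange(n)
        for c in range(cand.shape[1]):
            if len(remaining) == 0:
                break
            tets = cand[remaining, c]
            bary = self._bary(tets, points[remaining])
            m = bary.min(axis=1)
            upd = m > best_min[remaining]
            ridx = remaining[upd]
            best_tet[ridx] = tets[upd]
            best_bary[ridx] = bary[upd]
            best_min[ridx] = m[upd]
            remaining = remaining[best_min[remaining] < -tol]
        if len(remaining):
            # widened second pass for stubborn points (usually exterior);
            # beyond 64 candidate tets the best clamped assignment is kept
            k2 = min(64, self.mesh.n_tets)
            _, cand2 = self._tree.query(points[remaining], k=k2)
            cand2 = np.atleast_2d(cand2)
            for c in range(cand2.shape[1]):
                tets = cand2[:, c]
                bary = self._bary(tets, points[remaining])
                m = bary.min(axis=1)
                upd = m > best_min[remaining]
                ridx = remaining[upd]
                best_tet[ridx] = tets[upd]
                best_bary[ridx] = bary[upd]
                best_min[ridx] = m[upd]
        exterior = best_min < -tol
        if exterior.any():
            b = np.clip(best_bary[exterior], 0.0, None)
            best_bary[exterior] = b / b.sum(axis=1, keepdims=True)
        return best_tet, best_bary, exterior


def locate_in_mesh(point: np.ndarray, mesh: TetMesh) -> tuple[int, np.ndarray]:
    """Containing tetrahedron and barycentric coordinates of a single point."""
    tet, bary, _ = MeshLocator(mesh).locate(np.asarray(point)[None, :])
    return int(tet[0]), bary[0]


def make_spring_bc(
    mesh: TetMesh,
    landmark_positions: np.ndarray,
    targets: np.ndarray,
    stiffness: float,
    locator: MeshLocator | None = None,
) -> SpringBC:
    """Embed landmarks in the mesh and attach springs toward ``targets``."""
    locator = locator or MeshLocator(mesh)
    tets, bary, exterior = locator.locate(np.asarray(landmark_positions, dtype=float))
    if exterior.any():
        logger.warning("%d landmarks lie outside the mesh (clamped)", int(exterior.sum()))
    return SpringBC(tets, np.clip(bary, 0.0, None) /
                    np.clip(bary, 0.0, None).sum(axis=1, keepdims=True),
                    np.asarray(targets, dtype=float), stiffness)


# ---------------------------------------------------------------------------
# Element stiffness and energies


def _element_stiffness(mesh: TetMesh, material: MaterialParams) -> np.ndarray:
    """Per-element 12x12 linear tetrahedron stiffness matrices, (T,12,12)."""
    lam, mu = material.lame
    dm_inv = np.linalg.inv(mesh.edge_matrices())
    vols = mesh.volumes()
    T = mesh.n_tets
    # shape-function gradients: rows of dm_inv give grads of nodes 1..3
    grads = np.empty((T, 4, 3))
    grads[:, 1:, :] = np.transpose(dm_inv, (0, 2, 1))
    grads[:, 0, :] = -grads[:, 1:, :].sum(axis=1)
    # B matrix (T, 6, 12): engineering strain ordering xx,yy,zz,xy,yz,zx
    B = np.zeros((T, 6, 12))
    for a in range(4):
        gx, gy, gz = grads[:, a, 0], grads[:, a, 1], grads[:, a, 2]
        c = 3 * a
        B[:, 0, c + 0] = gx
        B[:, 1, c + 1] = gy
        B[:, 2, c + 2] = gz
        B[:, 3, c + 0], B[:, 3, c + 1] = gy, gx
        B[:, 4, c + 1], B[:, 4, c + 2] = gz, gy
        B[:, 5, c + 0], B[:, 5, c + 2] = gz, gx
    C = np.zeros((6, 6))
    C[:3, :3] = lam
    C[np.arange(3), np.arange(3)] += 2 * mu
    C[np.arange(3, 6), np.arange(3, 6)] = mu
    return vols[:, None, None] * np.einsum("tia,ij,tjb->tab", B, C, B)


def _inv3(M: np.ndarray) -> np.ndarray:
    """Batched adjugate inverse of (T,3,3) matrices (much faster than linalg.inv)."""
    a, b, c = M[:, 0, 0], M[:, 0, 1], M[:, 0, 2]
    d, e, f = M[:, 1, 0], M[:, 1, 1], M[:, 1, 2]
    g, h, i = M[:, 2, 0], M[:, 2, 1], M[:, 2, 2]
    A = e * i - f * h
    B = c * h - b * i
    C = b * f - c * e
    D = f * g - d * i
    E = a * i - c * g
    Ff = c * d - a * f
    G = d * h - e * g
    H = b * g - a * h
    I = a * e - b * d
    det = a * A + d * B + g * C
    out = np.empty_like(M)
    out[:, 0, 0], out[:, 0, 1], out[:, 0, 2] = A, B, C
    out[:, 1, 0], out[:, 1, 1], out[:, 1, 2] = D, E, Ff
    out[:, 2, 0], out[:, 2, 1], out[:, 2, 2] = G, H, I
    return out / det[:, None, None]


def _polar_rotations(F: np.ndarray) -> np.ndarray:
    """Rotation factors of deformation gradients.

    Higham's Newton iteration (quadratic convergence; our elements stay
    near-rigid) with an SVD fallback for inverted/degenerate elements.
    """
    det = np.linalg.det(F)
    bad = det <= 1e-8
    X = F.copy()
    if bad.any():
        X[bad] = np.eye(3)  # placeholder; fixed below by SVD
    for _ in range(12):
        Xn = 0.5 * (X + np.transpose(_inv3(X), (0, 2, 1)))
        if np.max(np.abs(Xn - X)) < 1e-12:
            X = Xn
            break
        X = Xn
    if bad.any():
        U, _, Vt = np.linalg.svd(F[bad])
        dsign = np.linalg.det(U @ Vt)
        U = U.copy()
        U[dsign < 0, :, -1] *= -1.0
        X[bad] = U @ Vt
    return X


def _element_rotations(mesh: TetMesh, displacements: np.ndarray,
                       dm_inv: np.ndarray) -> np.ndarray:
    """Per-element rotations from polar decomposition of the deformation gradient."""
    F = mesh.edge_matrices(mesh.node_positions + displacements) @ dm_inv
    return _polar_rotations(F)


def elastic_energy(
    mesh: TetMesh,
    material: MaterialParams,
    displacements: np.ndarray,
    corotational: bool = True,
    ke: np.ndarray | None = None,
) -> float:
    """Total elastic strain energy (N*mm) of a displacement state.

    With ``corotational=True`` each element's rotation is removed before
    the strain is measured, so rigid motions carry zero energy; with
    ``corotational=False`` the plain small-strain energy ``1/2 u^T K u``
    is returned.
    """
    ke = _element_stiffness(mesh, material) if ke is None else ke
    displacements = np.asarray(displacements, dtype=float)
    if corotational:
        dm_inv = np.linalg.inv(mesh.edge_matrices())
        R = _element_rotations(mesh, displacements, dm_inv)
        d = _corotational_strain_disp(mesh, displacements, R)
    else:
        d = displacements[mesh.tetrahedra].reshape(mesh.n_tets, 12)
    return float(0.5 * np.einsum("ti,tij,tj->", d, ke, d))


def _corotational_strain_disp(mesh: TetMesh, displacements: np.ndarray,
                              R: np.ndarray) -> np.ndarray:
    """Rotation-free nodal strain displacements R^T x - x0, (T, 12).

    A residual uniform translation per element remains in the result but
    lies in the stiffness null space, so energies and forces are exactly
    invariant under rigid motions.
    """
    x = (mesh.node_positions + displacements)[mesh.tetrahedra]  # (T,4,3)
    x0 = mesh.node_positions[mesh.tetrahedra]
    q = np.einsum("tji,tkj->tki", R, x)  # R^T applied to each node
    return (q - x0).reshape(mesh.n_tets, 12)


def _elastic_gradient(mesh: TetMesh, displacements: np.ndarray,
                      ke: np.ndarray, dm_inv: np.ndarray) -> np.ndarray:
    """Exact nodal gradient of the co-rotational elastic energy, (N, 3).

    The classical warped force ``R K (R^T x - x0)`` misses the sensitivity
    of the polar rotation to the nodal positions; that term grows with the
    strain and, with stiff landmark springs, breaks force-balance
    iterations.  Here the rotation term is included exactly: writing
    ``F = R S`` (polar), a rotation variation ``dR = R W`` with skew ``W``
    (axial vector ``w``) satisfies ``(tr S I - S) w = 2 axial(skew(R^T dF))``,
    which turns the energy sensitivity to ``R`` into an explicit per-element
    3x3 contribution.
    """
    x = (mesh.node_positions + displacements)[mesh.tetrahedra]
    fgrad = mesh.edge_matrices(mesh.node_positions + displacements) @ dm_inv
    R = _polar_rotations(fgrad)
    d = _corotational_strain_disp(mesh, displacements, R)
    kd = np.einsum("tij,tj->ti", ke, d).reshape(mesh.n_tets, 4, 3)
    g_direct = np.einsum("tij,tkj->tki", R, kd)
    # rotation-sensitivity term
    S = np.einsum("tji,tjk->tik", R, fgrad)
    X = np.einsum("tka,tkb->tab", x, kd)  # sum_a x_a (K d)_a^T
    A = np.einsum("tji,tjk->tik", R, X)
    y = 0.5 * np.stack(
        [A[:, 2, 1] - A[:, 1, 2], A[:, 0, 2] - A[:, 2, 0], A[:, 1, 0] - A[:, 0, 1]],
        axis=1,
    )
    trS = np.trace(S, axis1=1, axis2=2)
    M = trS[:, None, None] * np.eye(3)[None, :, :] - S
    # guard near-singular M (severely degenerate or inverted elements):
    # tiny Tikhonov keeps the solve defined, and the correction magnitude is
    # capped as if M had no eigenvalue below 0.05 (healthy elements have
    # S ~ I, eigenvalues ~ 2, and are untouched)
    M += 1e-9 * np.eye(3)[None, :, :]
    z = np.linalg.solve(M, y[:, :, None])[:, :, 0]
    zcap = np.linalg.norm(y, axis=1) / 0.05
    zn = np.linalg.norm(z, axis=1)
    over = zn > zcap
    if over.any():
        z[over] *= (zcap[over] / zn[over])[:, None]
    Z = np.zeros((mesh.n_tets, 3, 3))
    Z[:, 2, 1], Z[:, 1, 2] = z[:, 0], -z[:, 0]
    Z[:, 0, 2], Z[:, 2, 0] = z[:, 1], -z[:, 1]
    Z[:, 1, 0], Z[:, 0, 1] = z[:, 2], -z[:, 2]
    G = 2.0 * np.einsum("tij,tjk,tlk->til", R, Z, dm_inv)  # 2 R Z Dm^-T
    g_rot = np.zeros((mesh.n_tets, 4, 3))
    g_rot[:, 1:, :] = np.transpose(G, (0, 2, 1))
    g_rot[:, 0, :] = -g_rot[:, 1:, :].sum(axis=1)
    g = np.zeros_like(displacements)
    np.add.at(g, mesh.tetrahedra.ravel(), (g_direct + g_rot).reshape(-1, 3))
    return g


# ---------------------------------------------------------------------------
# Solver


def _spring_forces(mesh: TetMesh, bc: SpringBC, u: np.ndarray,
                   targets: np.ndarray) -> np.ndarray:
    """Nodal forces (N,3) from springs f_i = k (target_i - attachment_i)."""
    f = np.zeros_like(u)
    a = bc.attachment_points(mesh, u)
    fs = bc.stiffness * (targets - a)  # (L, 3)
    nodes = mesh.tetrahedra[bc.tet_indices]  # (L, 4)
    contrib = bc.barycentric[:, :, None] * fs[:, None, :]  # (L, 4, 3)
    np.add.at(f, nodes.ravel(), contrib.reshape(-1, 3))
    return f


class _Assembler:
    """Caches index structure for repeated sparse stiffness assembly."""

    def __init__(self, mesh: TetMesh, bc: SpringBC):
        self.mesh = mesh
        self.bc = bc
        ndof = 3 * mesh.n_nodes
        self.ndof = ndof
        dof = (3 * mesh.tetrahedra[:, :, None] + np.arange(3)).reshape(mesh.n_tets, 12)
        self.rows = np.repeat(dof, 12, axis=1).ravel()
        self.cols = np.tile(dof, (1, 12)).ravel()
        # spring stiffness block is constant: k * b_a b_b delta_ij
        nodes = mesh.tetrahedra[bc.tet_indices]
        sdof = (3 * nodes[:, :, None] + np.arange(3)).reshape(bc.n_springs, 12)
        bb = np.einsum("la,lb->lab", bc.barycentric, bc.barycentric)
        blocks = np.kron(bb, np.eye(3))  # (L, 12, 12)
        self.s_rows = np.repeat(sdof, 12, axis=1).ravel()
        self.s_cols = np.tile(sdof, (1, 12)).ravel()
        self.s_vals = bc.stiffness * blocks.ravel()

    def tangent(self, ke_rot: np.ndarray) -> sparse.csr_matrix:
        rows = np.concatenate([self.rows, self.s_rows])
        cols = np.concatenate([self.cols, self.s_cols])
        vals = np.concatenate([ke_rot.ravel(), self.s_vals])
        return sparse.coo_matrix((vals, (rows, cols)),
                                 shape=(self.ndof, self.ndof)).tocsr()


def _total_energy(mesh, bc, u, targets, ke, dm_inv) -> float:
    R = _element_rotations(mesh, u, dm_inv)
    d = _corotational_strain_disp(mesh, u, R)
    el = 0.5 * np.einsum("ti,tij,tj->", d, ke, d)
    a = bc.attachment_points(mesh, u)
    return float(el + 0.5 * bc.stiffness * np.sum((targets - a) ** 2))


def _residual(mesh, bc, u, targets, ke, dm_inv, corotational=True):
    """Out-of-balance nodal forces f_spring - grad(elastic energy), (N,3)."""
    f = _spring_forces(mesh, bc, u, targets)
    if corotational:
        f -= _elastic_gradient(mesh, u, ke, dm_inv)
    else:
        d = u[mesh.tetrahedra].reshape(mesh.n_tets, 12)
        fe = np.einsum("tij,tj->ti", ke, d).reshape(mesh.n_tets, 4, 3)
        np.add.at(f, mesh.tetrahedra.ravel(), -fe.reshape(-1, 3))
    return f


def _rigid_warm_start(mesh: TetMesh, bc: SpringBC) -> np.ndarray | None:
    """Best rigid motion taking the rest attachments toward the targets.

    Most fraction poses are rigid-dominated; starting the iteration from
    the Procrustes fit leaves only the genuine deformation to resolve.
    """
    a0 = bc.attachment_points(mesh, np.zeros((mesh.n_nodes, 3)))
    if len(a0) < 3:
        return None
    ca, cy = a0.mean(axis=0), bc.targets.mean(axis=0)
    P, Q = a0 - ca, bc.targets - cy
    if np.linalg.matrix_rank(P, tol=1e-8 * max(1.0, np.abs(P).max())) < 2:
        return None
    from scipy.linalg import svd as _svd

    U, _, Vt = _svd(P.T @ Q)
    dsign = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, dsign]) @ U.T
    # x -> R (x - ca) + cy
    return (mesh.node_positions - ca) @ R.T + cy - mesh.node_positions


def solve_pose_deformation(
    mesh: TetMesh,
    material: MaterialParams,
    bc: SpringBC,
    tolerance: float = 1e-3,
    max_iterations: int = 60,
    corotational: bool = True,
    load_step_mm: float = 25.0,
    initial_displacements: np.ndarray | None = None,
    cg_rtol: float = 0.2,
    cg_maxiter: int = 30,
) -> DisplacementField:
    """Static equilibrium of the spring-loaded co-rotational elastic model.

    The total energy (co-rotational elastic energy plus spring energy,
    with spring forces continuously re-evaluated at the deformed
    attachment positions) is minimized by an inexact Newton-Krylov
    method: Hessian-vector products are finite differences of the exact
    energy gradient, the Krylov solve is preconditioned by the
    spring-augmented warped stiffness ``R K R^T``, and steps are accepted
    by Armijo backtracking on the energy.  Convergence is declared when
    the largest nodal out-of-balance force falls below ``tolerance`` (N);
    otherwise the partial result carries a failed report.

    A rigid Procrustes warm start absorbs the rigid-dominated part of the
    pose change (``initial_displacements`` overrides it, e.g. to warm-
    start scenario solves from a neighbouring pose); any remaining pull
    larger than ``load_step_mm`` is applied in load steps.

    ``corotational=False`` performs the single linear small-strain solve
    of classical linear FEM — the comparison oracle for rigid-motion
    insensitivity.
    """
    if bc.n_springs < 1:
        raise ValueError("at least one spring attachment required")
    ke = _element_stiffness(mesh, material)
    dm_inv = np.linalg.inv(mesh.edge_matrices())
    asm = _Assembler(mesh, bc)
    n = mesh.n_nodes

    if not corotational:
        u = np.zeros((n, 3))
        f = _spring_forces(mesh, bc, u, bc.targets)
        K = asm.tangent(np.ascontiguousarray(ke))
        u = spsolve(K, f.ravel()).reshape(n, 3)
        res = _residual(mesh, bc, u, bc.targets, ke, dm_inv, corotational=False)
        rep = SolveReport(True, 1, float(np.linalg.norm(res, axis=1).max()),
                          _count_inverted(mesh, u))
        return DisplacementField(mesh, u, rep)

    if initial_displacements is not None:
        u = initial_displacements.copy()
    else:
        u = _rigid_warm_start(mesh, bc)
        if u is None:
            u = np.zeros((n, 3))
    a0 = bc.attachment_points(mesh, u)
    pulls = np.linalg.norm(bc.targets - a0, axis=1)
    n_steps = max(1, int(np.ceil(pulls.max() / load_step_mm))) if pulls.max() > 0 else 1
    total_iter = 0
    converged = True
    max_res = 0.0
    for s in range(1, n_steps + 1):
        targets = a0 + (bc.targets - a0) * (s / n_steps)
        u, it, ok, max_res = _newton_krylov(
            mesh, bc, u, targets, ke, dm_inv, asm,
            tolerance, max_iterations - total_iter, cg_rtol, cg_maxiter)
        total_iter += it
        if not ok and s == n_steps:
            converged = False
    rep = SolveReport(converged, total_iter, max_res, _count_inverted(mesh, u))
    if not converged:
        logger.warning("solver did not converge (max residual %.3g N)", max_res)
    return DisplacementField(mesh, u, rep)


def _newton_krylov(mesh, bc, u, targets, ke, dm_inv, asm,
                   tolerance, budget, cg_rtol, cg_maxiter):
    """Inexact Newton with FD Hessian-vector products and energy line search."""
    from scipy.sparse.linalg import LinearOperator, cg as cg_solve, splu

    n = mesh.n_nodes
    r = _residual(mesh, bc, u, targets, ke, dm_inv)
    max_res = float(np.linalg.norm(r, axis=1).max())
    energy = _total_energy(mesh, bc, u, targets, ke, dm_inv)
    it = 0
    lu = None
    last_alpha = 1.0
    while max_res > tolerance and it < budget:
        # the warped-stiffness preconditioner changes slowly; refresh it
        # only periodically or after a damped (alpha < 1) step
        if lu is None or last_alpha < 0.99 or it % 4 == 0:
            R = _element_rotations(mesh, u, dm_inv)
            Rb = np.zeros((mesh.n_tets, 12, 12))
            for a in range(4):
                Rb[:, 3 * a:3 * a + 3, 3 * a:3 * a + 3] = R
            K = asm.tangent(Rb @ ke @ np.transpose(Rb, (0, 2, 1)))
            lu = splu(K.tocsc())
        g = -r  # exact energy gradient

        def hess_vec(v):
            vv = v.reshape(n, 3)
            nv = np.linalg.norm(v)
            if nv == 0:
                return np.zeros_like(v)
            s = 1e-6 * max(1.0, np.linalg.norm(u)) / nv
            g_plus = -_residual(mesh, bc, u + s * vv, targets, ke, dm_inv)
            return ((g_plus - g) / s).ravel()

        H = LinearOperator((3 * n, 3 * n), matvec=hess_vec)
        M = LinearOperator((3 * n, 3 * n), matvec=lambda v: lu.solve(v))
        du, _ = cg_solve(H, r.ravel(), rtol=cg_rtol, maxiter=cg_maxiter, M=M)
        du = du.reshape(n, 3)
        slope = float(np.sum(g * du))
        if slope >= 0:  # CG direction not descent (indefinite Hessian far out)
            du = lu.solve(r.ravel()).reshape(n, 3)
            slope = float(np.sum(g * du))
        alpha, accepted = 1.0, False
        for _ in range(30):
            e_try = _total_energy(mesh, bc, u + alpha * du, targets, ke, dm_inv)
            if e_try <= energy + 1e-4 * alpha * slope:
                accepted = True
                break
            alpha *= 0.5
        if not accepted:
            break  # numerically flat
        u = u + alpha * du
        energy = e_try
        last_alpha = alpha
        r = _residual(mesh, bc, u, targets, ke, dm_inv)
        max_res = float(np.linalg.norm(r, axis=1).max())
        it += 1
    return u, it, max_res <= tolerance, max_res


def _count_inverted(mesh: TetMesh, u: np.ndarray) -> int:
    n = int(np.sum(mesh.volumes(mesh.node_positions + u) <= 0))
    if n:
        logger.warning("%d elements inverted in the deformed configuration", n)
    return n


# ---------------------------------------------------------------------------
# Landmark residuals / calibration


def landmark_residuals(field: DisplacementField, bc: SpringBC) -> tuple[np.ndarray, float]:
    """Distances between deformed attachment points and their targets (mm)."""
    a = bc.attachment_points(field.mesh, field.node_displacements)
    d = np.linalg.norm(bc.targets - a, axis=1)
    return d, float(d.mean())


@dataclass
class CalibrationReport:
    k_values: np.ndarray
    mean_residuals: np.ndarray  # mm, one per k (averaged over fractions)
    selected_k: float
    achieved: bool
    fit_target: float


def calibrate_spring_stiffness(
    mesh: TetMesh,
    material: MaterialParams,
    rest_landmarks: np.ndarray,
    fraction_target_sets: list[np.ndarray],
    candidate_ks: np.ndarray,
    fit_target: float = 0.5,
    **solve_kwargs,
) -> CalibrationReport:
    """Single parameter sweep for the landmark spring stiffness k.

    Returns the smallest k whose mean landmark residual over all fraction
    solves is at or below ``fit_target`` (mm, default 0.5).  The residual
    curve is expected to be monotone non-increasing in k; violations are
    logged, not raised.  If no k achieves the target the grid maximum is
    returned with ``achieved=False``.
    """
    ks = np.asarray(candidate_ks, dtype=float)
    if np.any(ks <= 0) or np.any(np.diff(ks) <= 0):
        raise ValueError("candidate k grid must be positive and strictly increasing")
    locator = MeshLocator(mesh)
    means = []
    for k in ks:
        res = []
        for targets in fraction_target_sets:
            bc = make_spring_bc(mesh, rest_landmarks, targets, k, locator)
            f = solve_pose_deformation(mesh, material, bc, **solve_kwargs)
            res.append(landmark_residuals(f, bc)[1])
        means.append(float(np.mean(res)))
    means = np.array(means)
    if np.any(np.diff(means) > 1e-9):
        logger.warning("residual-vs-k curve is not monotone non-increasing")
    ok = means <= fit_target
    if ok.any():
        i = int(np.argmax(ok))
        return CalibrationReport(ks, means, float(ks[i]), True, fit_target)
    return CalibrationReport(ks, means, float(ks[-1]), False, fit_target)


# ---------------------------------------------------------------------------
# Barycentric mapping / mask propagation


def barycentric_map(
    points: np.ndarray,
    field: DisplacementField,
    locator: MeshLocator | None = None,
    embedding: tuple[np.ndarray, np.ndarray] | None = None,
) -> np.ndarray:
    """Displace points by barycentric interpolation of nodal displacements.

    ``embedding`` may carry a precomputed ``(tet_indices, barycentric)``
    pair for the same points (the rest mesh does not change between
    scenarios, so the embedding can be reused).
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if embedding is None:
        locator = locator or MeshLocator(field.mesh)
        tets, bary, _ = locator.locate(points)
    else:
        tets, bary = embedding
    nodes = field.mesh.tetrahedra[tets]
    disp = np.einsum("pk,pkd->pd", bary, field.node_displacements[nodes])
    return points + disp


class MaskWarper:
    """Reusable mask warper for one mask on one rest mesh.

    The DVF is sampled once per field on a padded voxel grid around the
    mask (the mesh embedding of those voxel centers is cached, since the
    rest mesh does not change between scenarios); the warp itself inverts
    the forward field per output voxel center by fixed-point iteration
    and looks up the source voxel — exact for rigid motions and
    volume-faithful under smooth warps, with no pinholes to close.
    ``pad_mm`` bounds the displacement magnitude the region of interest
    can accommodate.
    """

    def __init__(self, mask: VoxelMask, mesh: TetMesh,
                 locator: MeshLocator | None = None, pad_mm: float = 25.0):
        self.mask = mask
        self.pad_mm = pad_mm
        idx = np.argwhere(mask.voxels)
        self.empty = len(idx) == 0
        if self.empty:
            return
        pad = int(np.ceil(pad_mm / mask.spacing.min()))
        self.lo = np.maximum(idx.min(axis=0) - pad, 0)
        self.hi = np.minimum(idx.max(axis=0) + 1 + pad, np.array(mask.shape))
        self.roi_shape = tuple(self.hi - self.lo)
        from scipy.ndimage import distance_transform_edt

        grids = np.meshgrid(*[np.arange(l, h) for l, h in zip(self.lo, self.hi)],
                            indexing="ij")
        self.roi_idx = np.stack([g.ravel() for g in grids], axis=1)
        centers = mask.origin + (self.roi_idx + 0.5) * mask.spacing
        self.centers = centers
        locator = locator or MeshLocator(mesh)
        tets, bary, exterior = locator.locate(centers)
        self.embedding = (tets, bary)
        self.all_exterior = bool(exterior.all())
        # distance (mm) from each ROI voxel to the mask foreground: a voxel
        # farther away than the largest displacement cannot become foreground
        roi_fg = mask.voxels[self.lo[0]:self.hi[0],
                             self.lo[1]:self.hi[1],
                             self.lo[2]:self.hi[2]]
        self.edt = distance_transform_edt(~roi_fg, sampling=mask.spacing).ravel()

    def warp(self, field: DisplacementField, iterations: int = 3) -> VoxelMask:
        from scipy.ndimage import map_coordinates

        if self.empty:
            return self.mask.copy()
        if self.all_exterior:
            logger.warning("mask lies entirely outside the mesh; returned unchanged")
            return self.mask.copy()
        tets, bary = self.embedding
        nodes = field.mesh.tetrahedra[tets]
        u = np.einsum("pk,pkd->pd", bary, field.node_displacements[nodes])
        umax = float(np.linalg.norm(u, axis=1).max())
        if umax > self.pad_mm - 2:
            logger.warning("displacement %.1f mm approaches the warp padding", umax)
        u_grid = u.reshape(*self.roi_shape, 3)
        mask = self.mask
        active = self.edt <= umax + mask.spacing.max()
        y = self.centers[active]
        x = y
        roi_origin = mask.origin + self.lo * mask.spacing
        for _ in range(iterations):
            coords = ((x - roi_origin) / mask.spacing - 0.5).T
            ux = np.stack([
                map_coordinates(u_grid[..., c], coords, order=1, mode="nearest")
                for c in range(3)
            ], axis=1)
            x = y - ux
        src = np.floor((x - mask.origin) / mask.spacing).astype(int)
        ok = np.all((src >= 0) & (src < np.array(mask.shape)), axis=1)
        vals = np.zeros(len(src), dtype=bool)
        vals[ok] = mask.voxels[src[ok, 0], src[ok, 1], src[ok, 2]]
        out = np.zeros(mask.shape, dtype=bool)
        ridx = self.roi_idx[active]
        out[ridx[:, 0], ridx[:, 1], ridx[:, 2]] = vals
        return mask.like(out)


def propagate_mask(
    mask: VoxelMask,
    field: DisplacementField,
    warper: MaskWarper | None = None,
) -> VoxelMask:
    """Warp a binary mask through the displacement field onto its own grid.

    Implemented by per-voxel inversion of the forward DVF (fixed-point
    iteration) and source lookup; see :class:`MaskWarper`.
    """
    warper = warper or MaskWarper(mask, field.mesh)
    return warper.warp(field)
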