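"""Margin-quality metrics and the leave-one-out cohort comparison.

Four measurements compare the margin concepts:

* ``internal_margin_volume`` — V_ITV\\CTV, the planning-phase margin
  volume (healthy tissue expected to be irradiated).
* ``healthy_tissue_hit`` — V_ITV\\fCTV per fraction, healthy tissue
  actually inside the ITV once the CTV has moved; can exceed the planning
  margin volume when the CTV leaves the ITV.
* ``missed_ctv`` — V_fCTV\\ITV per fraction, target volume escaping the
  ITV (coverage failure).
* ``distance_to_oar_slicewise`` — d_SC(z), per transversal ITV slice the
  3-D distance to the nearest spinal-cord voxel of that fraction.

``run_loocv_comparison`` applies all three margin engines to a cohort
with the leave-one-out protocol: statistics and pose models for one
patient are always fitted on the remaining patients only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from . import fem, margins, pose
from .config import PipelineConfig
from .grids import VoxelMask
from .landmarks import LandmarkSet, procrustes_align, residual_displacements

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Voxel metrics


def internal_margin_volume(itv: VoxelMask, ctv: VoxelMask) -> float:
    """V_ITV\\CTV in ml: voxels inside the ITV but not the CTV."""
    itv.require_same_grid(ctv)
    n = int(np.sum(itv.voxels & ~ctv.voxels))
    return n * itv.voxel_volume_mm3 / 1000.0


def healthy_tissue_hit(itv: VoxelMask, fctv: VoxelMask) -> float:
    """V_ITV\\fCTV in ml: ITV voxels outside the propagated fraction CTV."""
    itv.require_same_grid(fctv)
    n = int(np.sum(itv.voxels & ~fctv.voxels))
    return n * itv.voxel_volume_mm3 / 1000.0


def missed_ctv(itv: VoxelMask, fctv: VoxelMask) -> float:
    """V_fCTV\\ITV in ml: propagated CTV voxels escaping the ITV."""
    itv.require_same_grid(fctv)
    n = int(np.sum(fctv.voxels & ~itv.voxels))
    return n * itv.voxel_volume_mm3 / 1000.0


def distance_to_oar_slicewise(itv: VoxelMask, oar: VoxelMask) -> dict[int, float]:
    """d_SC(z): per transversal (z) ITV slice, min 3-D distance to the OAR.

    Distances are voxel-center-to-voxel-center in mm; slices without ITV
    voxels are absent from the profile.  The OAR mask should already be
    propagated to the fraction under evaluation.
    """
    itv.require_same_grid(oar)
    if not oar.voxels.any():
        raise ValueError("OAR mask is empty")
    oar_pts = oar.foreground_points()
    tree = cKDTree(oar_pts)
    idx = np.argwhere(itv.voxels)
    if len(idx) == 0:
        return {}
    pts = itv.origin + (idx + 0.5) * itv.spacing
    d, _ = tree.query(pts)
    profile: dict[int, float] = {}
    for z in np.unique(idx[:, 2]):
        profile[int(z)] = float(d[idx[:, 2] == z].min())
    return profile


# ---------------------------------------------------------------------------
# Cohort containers


@dataclass
class FractionData:
    """One treatment fraction of one patient."""

    fraction_id: int
    landmarks: LandmarkSet  # observed (tracked, possibly noisy/missing), raw frame
    true_fctv: VoxelMask  # ground-truth propagated CTV (couch-corrected frame)
    true_cord: VoxelMask  # ground-truth propagated spinal cord


@dataclass
class PatientData:
    """Planning data plus all fractions for one patient."""

    patient_id: int
    mesh: fem.TetMesh
    planning_landmarks: LandmarkSet
    ctv: VoxelMask
    cord: VoxelMask
    fractions: list[FractionData] = field(default_factory=list)


@dataclass
class MarginReport:
    """Cohort comparison tables (per-patient rows, cohort mean footer)."""

    margin_volume: pd.DataFrame  # V_ITV\CTV per approach [ml]
    healthy_tissue: pd.DataFrame  # mean V_ITV\fCTV per approach [ml]
    missed: pd.DataFrame  # mean V_fCTV\ITV per approach [ml]
    oar_distance: pd.DataFrame  # mean d_SC(z) per approach [mm]
    ctv_volumes: pd.Series  # V_CTV per patient [ml]

    def save(self, outdir) -> None:
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.margin_volume.to_csv(outdir / "margin_volume_ml.csv")
        self.healthy_tissue.to_csv(outdir / "healthy_tissue_ml.csv")
        self.missed.to_csv(outdir / "missed_ctv_ml.csv")
        self.oar_distance.to_csv(outdir / "oar_distance_mm.csv")
        self.ctv_volumes.to_csv(outdir / "ctv_volume_ml.csv")


# ---------------------------------------------------------------------------
# Residual extraction (couch-correction simulation per fraction)


def patient_residuals(
    patient: PatientData, reference_region: str = "skull"
) -> dict[int, dict[str, np.ndarray]]:
    """Per-fraction residual landmark displacements after Procrustes alignment."""
    out = {}
    for frac in patient.fractions:
        transform = procrustes_align(
            patient.planning_landmarks, frac.landmarks, reference_region
        )
        aligned = transform.apply_to_set(frac.landmarks)
        out[frac.fraction_id] = residual_displacements(
            patient.planning_landmarks, aligned
        )
    return out


def cohort_residual_statistics(
    residuals_by_patient: dict[int, dict[int, dict[str, np.ndarray]]],
    landmark_names: list[str],
) -> tuple[np.ndarray, np.ndarray]:
    """Per-landmark, per-axis systematic (Sigma) and random (sigma) SDs.

    Following the standard setup-error decomposition: Sigma is the SD over
    patients of the per-patient mean residual, sigma the root-mean-square
    of the per-patient SDs.  Landmarks never observed get zeros.
    """
    n_lm = len(landmark_names)
    patient_mean = []
    patient_sd = []
    for fractions in residuals_by_patient.values():
        arr = np.full((len(fractions), n_lm, 3), np.nan)
        for r, fid in enumerate(sorted(fractions)):
            for name, vec in fractions[fid].items():
                arr[r, landmark_names.index(name)] = vec
        with np.errstate(invalid="ignore"):
            patient_mean.append(np.nanmean(arr, axis=0))
            patient_sd.append(np.nanstd(arr, axis=0, ddof=1))
    pm = np.array(patient_mean)  # (P, M, 3)
    ps = np.array(patient_sd)
    with np.errstate(invalid="ignore"):
        systematic = np.nanstd(pm, axis=0, ddof=1)
        random = np.sqrt(np.nanmean(ps**2, axis=0))
    return np.nan_to_num(systematic), np.nan_to_num(random)


# ---------------------------------------------------------------------------
# Leave-one-out comparison


def run_loocv_comparison(
    cohort: list[PatientData],
    approaches: tuple[int, ...] = (1, 2, 3),
    config: PipelineConfig | None = None,
    seed: int | None = None,
) -> MarginReport:
    """Apply the margin engines to a cohort with leave-one-out statistics.

    For each patient the per-landmark statistics (approach 2) and the
    pose model (approach 3) are fitted using the other patients'
    fractions only.  Fraction-level ground truth (propagated CTV and
    cord) comes from the cohort data, so model error is measured rather
    than hidden.
    """
    cfg = config or PipelineConfig()
    if seed is None:
        seed = cfg.seed
    if len(cohort) < 3:
        raise ValueError("need >=3 patients for a leave-one-out comparison")
    for a in approaches:
        if a not in (1, 2, 3):
            raise ValueError(f"unknown approach {a}")

    names = list(cohort[0].planning_landmarks.names)
    all_residuals = {
        p.patient_id: patient_residuals(p, cfg.reference_region) for p in cohort
    }
    # aligned landmark positions p_i(f) = planning + residual, per patient
    positions_by_patient = {}
    for p in cohort:
        planning_pos = {n: p.planning_landmarks.position(n) for n in names}
        positions_by_patient[p.patient_id] = {
            fid: {n: planning_pos[n] + v for n, v in res.items()}
            for fid, res in all_residuals[p.patient_id].items()
        }

    rows: dict[str, dict[int, dict[int, float]]] = {
        k: {a: {} for a in approaches}
        for k in ("margin", "healthy", "missed", "dsc")
    }
    ctv_vol = {}
    rng = np.random.default_rng(seed)
    # synthetic cohorts share one phantom geometry; reuse the expensive
    # mesh locator / mask-warper caches across patients in that case
    shared: dict[tuple[int, int], tuple] = {}

    for p in cohort:
        pid = p.patient_id
        ctv_vol[pid] = p.ctv.volume_ml()
        others = [q.patient_id for q in cohort if q.patient_id != pid]
        itvs: dict[int, VoxelMask] = {}

        if 1 in approaches:
            itvs[1] = margins.margin_constant(p.ctv, cfg.constant_radius_mm)

        if 2 in approaches:
            loo_res = {q: all_residuals[q] for q in others}
            systematic, random_sd = cohort_residual_statistics(loo_res, names)
            lm_pos = np.array([p.planning_landmarks.position(n) for n in names])
            mfield = margins.margin_distance_field(
                p.ctv, lm_pos, random_sd, systematic,
                mode=cfg.margin_mode, ci_z=cfg.ci_z,
                weight_exponent=cfg.weight_exponent,
            )
            itvs[2] = margins.margin_distance(p.ctv, mfield)

        if 3 in approaches:
            key = (id(p.mesh), id(p.ctv))
            if key not in shared:
                locator = fem.MeshLocator(p.mesh)
                shared[key] = (locator, fem.MaskWarper(p.ctv, p.mesh, locator))
            itvs[3] = _fem_margin_for_patient(
                p, positions_by_patient, others, names, cfg,
                np.random.default_rng(rng.integers(2**31)),
                locator_warper=shared[key],
            )

        for a, itv in itvs.items():
            rows["margin"][a][pid] = internal_margin_volume(itv, p.ctv)
            hh, mm, dd = [], [], []
            for frac in p.fractions:
                hh.append(healthy_tissue_hit(itv, frac.true_fctv))
                mm.append(missed_ctv(itv, frac.true_fctv))
                prof = distance_to_oar_slicewise(itv, frac.true_cord)
                dd.append(float(np.mean(list(prof.values()))))
            rows["healthy"][a][pid] = float(np.mean(hh))
            rows["missed"][a][pid] = float(np.mean(mm))
            rows["dsc"][a][pid] = float(np.mean(dd))
        logger.info("patient %s evaluated", pid)

    def table(key: str) -> pd.DataFrame:
        df = pd.DataFrame(
            {f"approach_{a}": rows[key][a] for a in approaches}
        ).sort_index()
        means = df.mean()
        df.loc["mean"] = means
        if 1 in approaches:
            base = means["approach_1"]
            df.loc["pct_vs_approach_1"] = 100.0 * (means - base) / base if base else np.nan
        return df

    return MarginReport(
        margin_volume=table("margin"),
        healthy_tissue=table("healthy"),
        missed=table("missed"),
        oar_distance=table("dsc"),
        ctv_volumes=pd.Series(ctv_vol, name="ctv_ml").sort_index(),
    )


def _fem_margin_for_patient(
    patient: PatientData,
    positions_by_patient: dict,
    others: list[int],
    names: list[str],
    cfg: PipelineConfig,
    rng: np.random.Generator,
    locator_warper: tuple | None = None,
) -> VoxelMask:
    """Approach 3 for one patient: LOO pose model -> scenario FEM -> accumulation."""
    loo_positions = {q: positions_by_patient[q] for q in others}
    vectors = pose.build_pose_vectors(loo_positions, names)
    q_comp = min(cfg.n_components, len(vectors.values) - 1)
    model = pose.fit_ppca(vectors.values, n_components=q_comp)

    # denoised anchor: mean-pose model from the other patients, applied to
    # the target patient's own raw mean pose
    target_positions = positions_by_patient[patient.patient_id]
    target_vectors = pose.build_pose_vectors(
        {patient.patient_id: target_positions}, names
    )
    raw_mean = target_vectors.patient_means[patient.patient_id]
    if len(others) >= 2:
        q_mean = min(cfg.n_components, len(others) - 1)
        mean_model = pose.fit_ppca(
            np.array([vectors.patient_means[q] for q in others]),
            n_components=q_mean,
        )
        anchor = mean_model.reconstruct(raw_mean)[0]
    else:
        anchor = raw_mean

    scenarios = pose.sample_pose_scenarios(model, n=cfg.n_scenarios, rng=rng)
    # greedy nearest-neighbour ordering: consecutive scenarios are similar,
    # so each solve can warm-start from the previous solution (the
    # accumulation result is order-independent)
    order = _chain_order(scenarios)
    scenarios = scenarios[order]
    material = fem.MaterialParams(cfg.young_modulus_mpa, cfg.poisson_ratio)
    if locator_warper is None:
        locator = fem.MeshLocator(patient.mesh)
        warper = fem.MaskWarper(patient.ctv, patient.mesh, locator)
    else:
        locator, warper = locator_warper
    rest = np.array([patient.planning_landmarks.position(n) for n in names])
    anchor_targets = anchor.reshape(-1, 3)

    # anchor solve (mean pose) warm-starts every scenario; each scenario's
    # initial guess additionally carries the landmark target delta spread to
    # the nodes by smoothed inverse-square-distance weights
    bc0 = fem.make_spring_bc(patient.mesh, rest, anchor_targets,
                             cfg.spring_stiffness, locator)
    f0 = fem.solve_pose_deformation(
        patient.mesh, material, bc0, tolerance=cfg.scenario_tolerance,
        max_iterations=cfg.max_iterations, load_step_mm=cfg.load_step_mm)
    d = np.linalg.norm(
        patient.mesh.node_positions[:, None, :] - rest[None, :, :], axis=2)
    w = 1.0 / (d**2 + 25.0)
    w /= w.sum(axis=1, keepdims=True)

    fields = []
    prev_u, prev_targets = f0.node_displacements, anchor_targets
    for u in scenarios:
        targets = anchor_targets + u.reshape(-1, 3)
        bc = fem.make_spring_bc(patient.mesh, rest, targets,
                                cfg.spring_stiffness, locator)
        u0 = prev_u + w @ (targets - prev_targets)
        field = fem.solve_pose_deformation(
            patient.mesh, material, bc,
            tolerance=cfg.scenario_tolerance,
            max_iterations=cfg.max_iterations,
            load_step_mm=cfg.load_step_mm,
            initial_displacements=u0,
            cg_rtol=0.1, cg_maxiter=40,
        )
        fields.append(field)
        prev_u, prev_targets = field.node_displacements, targets
    return margins.margin_fem(
        patient.ctv, fields, hit_threshold=cfg.hit_threshold, warper=warper
    )


def _chain_order(vectors: np.ndarray) -> np.ndarray:
    """Greedy nearest-neighbour chain through the sample set (deterministic)."""
    n = len(vectors)
    remaining = list(range(n))
    order = [remaining.pop(0)]
    while remaining:
        last = vectors[order[-1]]
        d = np.linalg.norm(vectors[remaining] - last, axis=1)
        order.append(remaining.pop(int(np.argmin(d))))
    return np.array(order)
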