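"""Cohort statistical pose model.

Each fraction's couch-corrected landmark configuration is flattened into
a pose vector of length 3M (M landmarks).  Per patient the mean pose is
subtracted, and the pooled centered poses of the cohort are summarized by
probabilistic PCA (Tipping & Bishop): the top five eigenvectors of the
sample covariance carry the correlated deformation modes, the mean of the
discarded eigenvalues is the isotropic noise floor.  Sampling coefficients
from the per-component Gaussians synthesizes plausible new pose scenarios
for margin construction; a second PPCA across patients' mean poses
denoises the per-patient anchor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

DEFAULT_N_COMPONENTS = 5
DEFAULT_N_SCENARIOS = 400


@dataclass
class PoseVectors:
    """Centered pose vectors u_i(f) = p_i(f) - p_bar_i for one cohort."""

    landmark_names: list[str]
    patient_ids: np.ndarray  # (F,)
    fraction_ids: np.ndarray  # (F,)
    values: np.ndarray  # (F, 3M) centered poses, mm
    observed: np.ndarray  # (F, 3M) bool; False entries were mean-imputed
    patient_means: dict  # patient_id -> (3M,) mean landmark positions p_bar_i

    @property
    def dim(self) -> int:
        return self.values.shape[1]


@dataclass
class PoseModel:
    """PPCA pose model: mean, eigenvectors, per-component and noise variances."""

    mean_pose: np.ndarray  # (3M,)
    components: np.ndarray  # (q, 3M), orthonormal rows
    component_variances: np.ndarray  # (q,), mm^2, descending
    noise_variance: float  # mm^2

    def __post_init__(self) -> None:
        g = self.components @ self.components.T
        if not np.allclose(g, np.eye(len(self.components)), atol=1e-8):
            raise ValueError("components must be orthonormal")
        if np.any(self.component_variances < -1e-12):
            raise ValueError("variances must be non-negative")
        if np.any(np.diff(self.component_variances) > 1e-9):
            raise ValueError("variances must be sorted descending")

    @property
    def n_components(self) -> int:
        return len(self.components)

    def reconstruct(self, vectors: np.ndarray) -> np.ndarray:
        """Orthogonal projection of vectors onto the model's affine span."""
        c = np.atleast_2d(vectors) - self.mean_pose
        return self.mean_pose + (c @ self.components.T) @ self.components

    def save(self, path) -> None:
        np.savez(
            path,
            mean_pose=self.mean_pose,
            components=self.components,
            component_variances=self.component_variances,
            noise_variance=self.noise_variance,
        )

    @classmethod
    def load(cls, path) -> "PoseModel":
        d = np.load(path)
        return cls(
            d["mean_pose"], d["components"],
            d["component_variances"], float(d["noise_variance"]),
        )


def build_pose_vectors(
    residuals_by_patient: dict,
    landmark_names: list[str],
) -> PoseVectors:
    """Assemble centered pose vectors from per-fraction residual tables.

    Parameters
    ----------
    residuals_by_patient:
        ``{patient_id: {fraction_id: {landmark_name: 3-vector}}}`` —
        residual landmark displacements (or positions) after couch
        correction; missing landmarks are simply absent from a fraction's
        dict.
    landmark_names:
        Canonical landmark ordering defining the pose-vector layout.

    Missing coordinates are mean-imputed within the patient (flagged in
    ``observed``); a coordinate never observed for a patient is imputed at
    zero with a warning.
    """
    m = len(landmark_names)
    rows, obs, pids, fids = [], [], [], []
    patient_means = {}
    for pid, fractions in residuals_by_patient.items():
        if len(fractions) < 2:
            raise ValueError(f"patient {pid}: need >=2 fractions")
        raw = np.full((len(fractions), 3 * m), np.nan)
        f_ids = sorted(fractions)
        for r, fid in enumerate(f_ids):
            for name, vec in fractions[fid].items():
                j = landmark_names.index(name)
                raw[r, 3 * j:3 * j + 3] = vec
        col_mean = np.nanmean(raw, axis=0)
        never = np.isnan(col_mean)
        if never.any():
            logger.warning(
                "patient %s: %d coordinates never observed; imputed at 0",
                pid, int(never.sum()),
            )
            col_mean[never] = 0.0
        observed = ~np.isnan(raw)
        filled = np.where(observed, raw, col_mean)
        patient_means[pid] = col_mean
        rows.append(filled - col_mean)
        obs.append(observed)
        pids.extend([pid] * len(f_ids))
        fids.extend(f_ids)
    return PoseVectors(
        list(landmark_names),
        np.array(pids), np.array(fids),
        np.vstack(rows), np.vstack(obs), patient_means,
    )


def fit_ppca(
    vectors: np.ndarray,
    n_components: int = DEFAULT_N_COMPONENTS,
    mean_pose: np.ndarray | None = None,
) -> PoseModel:
    """Closed-form maximum-likelihood PPCA of pose vectors.

    Eigendecomposition of the sample covariance (the ambient dimension
    3M ~ 72 is small, so the Tipping-Bishop closed form is exact and
    deterministic): retained components span the top eigenspace,
    ``noise_variance`` is the mean of the discarded eigenvalues and each
    ``component_variance`` the corresponding eigenvalue minus the noise
    floor.  ``mean_pose`` defaults to the sample mean of ``vectors``.
    """
    X = np.asarray(vectors, dtype=float)
    n, d = X.shape
    if n <= n_components:
        raise ValueError("need more vectors than components")
    mu = X.mean(axis=0) if mean_pose is None else np.asarray(mean_pose, dtype=float)
    C = np.cov((X - mu).T, bias=False)
    evals, evecs = np.linalg.eigh(C)
    evals, evecs = evals[::-1], evecs[:, ::-1]
    evals = np.clip(evals, 0.0, None)
    rank = int(np.sum(evals > max(1e-12, 1e-12 * evals[0])))
    q = n_components
    if rank < q:
        logger.warning("data rank %d below %d components; reduced", rank, q)
        q = max(rank, 1)
    sigma2 = float(evals[q:].mean()) if q < d else 0.0
    return PoseModel(
        mean_pose=mu,
        components=evecs[:, :q].T,
        component_variances=np.clip(evals[:q] - sigma2, 0.0, None),
        noise_variance=sigma2,
    )


def denoise_mean_poses(
    mean_poses: dict,
    n_components: int = DEFAULT_N_COMPONENTS,
    model: PoseModel | None = None,
) -> dict:
    """Replace each patient's mean pose by its top-q PPCA reconstruction.

    Fitting across patients and reconstructing removes landmark-level
    estimation noise from the per-patient mean while keeping the across-
    patient anatomy. With a leave-one-out protocol pass ``model`` fitted on
    the remaining patients and this function only applies it.
    """
    ids = sorted(mean_poses)
    if model is None:
        if len(ids) < 2:
            raise ValueError("need >=2 patients")
        P = np.array([mean_poses[i] for i in ids])
        q = min(n_components, len(ids) - 1)
        if q < n_components:
            logger.warning("fewer patients than components; reduced to %d", q)
        model = fit_ppca(P, n_components=q)
    recon = model.reconstruct(np.array([mean_poses[i] for i in ids]))
    return {i: recon[r] for r, i in enumerate(ids)}


def sample_pose_scenarios(
    model: PoseModel,
    n: int = DEFAULT_N_SCENARIOS,
    rng: np.random.Generator | int | None = None,
    include_noise: bool = False,
) -> np.ndarray:
    """Draw synthetic pose vectors from the PPCA model, (n, 3M).

    Coefficients q_1..q_5 are independent zero-mean Gaussians with the
    model's component variances; each sample is ``components^T q + mean``.
    By default no isotropic noise is added (the retained modes alone
    define the reconstruction); ``include_noise`` adds N(0, noise_variance)
    residual per coordinate.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(rng)
    q = rng.standard_normal((n, model.n_components)) * np.sqrt(model.component_variances)
    samples = model.mean_pose + q @ model.components
    if include_noise and model.noise_variance > 0:
        samples = samples + rng.standard_normal(samples.shape) * np.sqrt(model.noise_variance)
    return samples
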