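"""Readers/writers for on-disk formats.

Masks and displacement fields travel as NIfTI (via nibabel), landmark
tables as CSV, tetrahedral meshes as legacy ASCII VTK unstructured
grids.  All spatial quantities are mm; masks are resampled to the 1 mm
working grid on read when needed (nearest neighbour, with a notice).
"""

from __future__ import annotations

import logging
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .fem import DisplacementField, TetMesh
from .grids import VoxelMask
from .landmarks import LandmarkSet

logger = logging.getLogger(__name__)

LANDMARK_COLUMNS = [
    "patient_id", "fraction_id", "name", "region", "x_mm", "y_mm", "z_mm",
    "valid", "ncc_score",
]


class FormatError(ValueError):
    """A file does not conform to the expected on-disk format."""


# ---------------------------------------------------------------------------
# Masks (NIfTI)


def write_mask(mask: VoxelMask, path) -> None:
    affine = np.eye(4)
    affine[:3, :3] = np.diag(mask.spacing)
    # NIfTI affine addresses voxel *centers*
    affine[:3, 3] = mask.origin + 0.5 * mask.spacing
    img = nib.Nifti1Image(mask.voxels.astype(np.uint8), affine)
    nib.save(img, str(path))


def read_mask(path, resample_to_1mm: bool = True) -> VoxelMask:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        img = nib.load(str(path))
        data = np.asarray(img.dataobj)
        affine = img.affine
    except Exception as exc:  # pragma: no cover - nibabel error classes vary
        raise FormatError(f"malformed mask file {path}: {exc}") from exc
    if not np.allclose(affine[:3, :3], np.diag(np.diag(affine[:3, :3]))):
        raise FormatError(f"{path}: only axis-aligned affines are supported")
    spacing = np.diag(affine[:3, :3]).copy()
    if np.any(spacing <= 0):
        raise FormatError(f"{path}: non-positive voxel spacing")
    origin = affine[:3, 3] - 0.5 * spacing
    mask = VoxelMask(data > 0, origin, spacing)
    if resample_to_1mm and not np.allclose(spacing, 1.0):
        logger.info("%s: resampling %s mm grid to 1 mm (nearest neighbour)", path, spacing)
        mask = resample_mask_to_1mm(mask)
    return mask


def resample_mask_to_1mm(mask: VoxelMask) -> VoxelMask:
    shape = np.ceil(np.array(mask.shape) * mask.spacing).astype(int)
    out = VoxelMask(np.zeros(shape, dtype=bool), mask.origin.copy(), np.ones(3))
    ii = np.stack(np.meshgrid(*[np.arange(s) for s in shape], indexing="ij"), axis=-1)
    centers = out.origin + (ii.reshape(-1, 3) + 0.5)
    src = np.floor((centers - mask.origin) / mask.spacing).astype(int)
    ok = np.all((src >= 0) & (src < np.array(mask.shape)), axis=1)
    vox = np.zeros(len(src), dtype=bool)
    vox[ok] = mask.voxels[src[ok, 0], src[ok, 1], src[ok, 2]]
    out.voxels = vox.reshape(shape)
    return out


# ---------------------------------------------------------------------------
# Displacement fields (NIfTI 3-vector volume sampled on a mask grid)


def write_dvf(field: DisplacementField, grid: VoxelMask, path) -> None:
    """Sample the DVF at every grid voxel center and save as a vector NIfTI."""
    from .fem import MeshLocator, barycentric_map

    ii = np.stack(np.meshgrid(*[np.arange(s) for s in grid.shape], indexing="ij"), axis=-1)
    pts = grid.origin + (ii.reshape(-1, 3) + 0.5) * grid.spacing
    disp = barycentric_map(pts, field, MeshLocator(field.mesh)) - pts
    vol = disp.reshape(*grid.shape, 3).astype(np.float32)
    affine = np.eye(4)
    affine[:3, :3] = np.diag(grid.spacing)
    affine[:3, 3] = grid.origin + 0.5 * grid.spacing
    nib.save(nib.Nifti1Image(vol, affine), str(path))


# ---------------------------------------------------------------------------
# Landmark tables (CSV)


def landmark_sets_to_frame(
    sets: list[LandmarkSet], patient_id: int, ncc_scores: dict | None = None
) -> pd.DataFrame:
    rows = []
    for s in sets:
        for i, n in enumerate(s.names):
            rows.append({
                "patient_id": patient_id,
                "fraction_id": s.fraction_id,
                "name": n,
                "region": s.region[i],
                "x_mm": s.positions[i, 0],
                "y_mm": s.positions[i, 1],
                "z_mm": s.positions[i, 2],
                "valid": bool(s.valid[i]),
                "ncc_score": (ncc_scores or {}).get((s.fraction_id, n), np.nan),
            })
    return pd.DataFrame(rows, columns=LANDMARK_COLUMNS)


def write_landmarks(frame: pd.DataFrame, path) -> None:
    missing = set(LANDMARK_COLUMNS) - set(frame.columns)
    if missing:
        raise FormatError(f"landmark table missing columns {sorted(missing)}")
    frame.to_csv(path, index=False)


def read_landmarks(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    frame = pd.read_csv(path)
    missing = set(LANDMARK_COLUMNS) - set(frame.columns)
    if missing:
        raise FormatError(f"{path}: missing required columns {sorted(missing)}")
    bad = []
    for c in ("x_mm", "y_mm", "z_mm"):
        col = pd.to_numeric(frame[c], errors="coerce")
        bad.extend((frame.index[col.isna() & frame[c].notna()] + 2).tolist())
        frame[c] = col
    if bad:
        raise FormatError(f"{path}: non-numeric coordinates in rows {sorted(set(bad))}")
    frame["valid"] = frame["valid"].astype(bool)
    return frame


def frame_to_landmark_sets(frame: pd.DataFrame, patient_id: int) -> list[LandmarkSet]:
    sets = []
    sub = frame[frame["patient_id"] == patient_id]
    for fid, g in sub.groupby("fraction_id"):
        sets.append(LandmarkSet(
            g["name"].tolist(),
            g[["x_mm", "y_mm", "z_mm"]].to_numpy(float),
            g["region"].tolist(),
            valid=g["valid"].to_numpy(bool),
            fraction_id=int(fid),
        ))
    return sets


# ---------------------------------------------------------------------------
# Tetrahedral meshes (legacy ASCII VTK unstructured grid)


def write_mesh(mesh: TetMesh, path) -> None:
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nhnmargin tetrahedral mesh (mm)\n")
        fh.write("ASCII\nDATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {mesh.n_nodes} double\n")
        for p in mesh.node_positions:
            fh.write(f"{p[0]:.9g} {p[1]:.9g} {p[2]:.9g}\n")
        fh.write(f"CELLS {mesh.n_tets} {5 * mesh.n_tets}\n")
        for t in mesh.tetrahedra:
            fh.write(f"4 {t[0]} {t[1]} {t[2]} {t[3]}\n")
        fh.write(f"CELL_TYPES {mesh.n_tets}\n")
        fh.write("\n".join(["10"] * mesh.n_tets) + "\n")


def read_mesh(path) -> TetMesh:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    tokens = path.read_text().split("\n")
    try:
        i = next(k for k, line in enumerate(tokens) if line.startswith("POINTS"))
        n_pts = int(tokens[i].split()[1])
        flat = " ".join(tokens[i + 1:]).split()
        pts = np.array(flat[: 3 * n_pts], dtype=float).reshape(n_pts, 3)
        j = next(k for k, line in enumerate(tokens) if line.startswith("CELLS"))
        n_cells = int(tokens[j].split()[1])
        flat = " ".join(tokens[j + 1:]).split()
        cells = np.array(flat[: 5 * n_cells], dtype=int).reshape(n_cells, 5)
        if np.any(cells[:, 0] != 4):
            raise ValueError("non-tetrahedral cells present")
    except (StopIteration, ValueError, IndexError) as exc:
        raise FormatError(f"malformed VTK mesh file {path}: {exc}") from exc
    return TetMesh(pts, cells[:, 1:])
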