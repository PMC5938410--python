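"""Lesion-mask I/O, voxel-matrix construction and descriptive maps.

All cohort masks live on one shared reference grid (e.g. MNI152 1 mm).
Per lesion type, subject masks are collapsed into a ``LesionTensor``:
a subjects x voxels binary matrix over the voxels lesioned in at least
one subject, plus per-subject full-mask volumes in ml.

Voxel indexing is 0-based and flat in C order over the grid.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "ReferenceGrid",
    "LesionTensor",
    "load_cohort",
    "load_manifest",
    "apply_min_subject_filter",
    "prevalence_map",
    "lesion_size_topology",
    "write_tensor",
    "save_map",
]

#: binary tolerance: mask values must be this close to 0 or 1
_BINARY_ATOL = 1e-3


@dataclass(eq=False)
class ReferenceGrid:
    """A shared voxel grid: shape, voxel size (mm) and affine."""

    shape: tuple[int, int, int]
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray | None = None
    space: str = ""

    def __post_init__(self) -> None:
        self.shape = tuple(int(s) for s in self.shape)
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if len(self.shape) != 3 or any(s < 1 for s in self.shape):
            raise ValueError(f"grid shape must be 3 positive integers, got {self.shape}")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError(f"voxel size must be positive, got {self.voxel_size}")
        if self.affine is None:
            aff = np.diag(list(self.voxel_size) + [1.0])
            self.affine = aff
        else:
            self.affine = np.asarray(self.affine, dtype=float)
            if self.affine.shape != (4, 4):
                raise ValueError("affine must be 4x4")

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size))

    @property
    def voxel_volume_ml(self) -> float:
        return self.voxel_volume_mm3 / 1000.0

    def matches(self, other: "ReferenceGrid", tol: float = 1e-4) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.affine, other.affine, atol=tol)
        )

    @classmethod
    def from_image(cls, img: nib.spatialimages.SpatialImage, space: str = "") -> "ReferenceGrid":
        zooms = img.header.get_zooms()[:3]
        return cls(shape=tuple(img.shape[:3]), voxel_size=tuple(float(z) for z in zooms),
                   affine=np.asarray(img.affine, dtype=float), space=space)

    def flat_to_ijk(self, flat: np.ndarray) -> np.ndarray:
        """Flat C-order indices -> (n, 3) grid coordinates."""
        return np.stack(np.unravel_index(np.asarray(flat), self.shape), axis=-1)

    def ijk_to_world(self, ijk: np.ndarray) -> np.ndarray:
        ijk = np.atleast_2d(ijk)
        homo = np.c_[ijk, np.ones(len(ijk))]
        return (self.affine @ homo.T).T[:, :3]


@dataclass
class LesionTensor:
    """Binary lesion status of one lesion type, subjects x retained voxels.

    ``volumes_ml`` always refers to the FULL per-subject mask (before any
    voxel filtering); it is the quantity used for volume control.
    """

    lesion_type: str
    grid: ReferenceGrid
    subject_ids: list[str]
    voxel_index: np.ndarray
    data: np.ndarray
    volumes_ml: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.subject_ids = [str(s) for s in self.subject_ids]
        self.voxel_index = np.asarray(self.voxel_index, dtype=np.int64)
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (subjects x voxels)")
        m, v = self.data.shape
        if m != len(self.subject_ids):
            raise ValueError("data row count does not match subject_ids")
        if v != self.voxel_index.size:
            raise ValueError("data column count does not match voxel_index")
        vals = np.unique(self.data)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError(f"lesion data must be binary, found values {vals[:5]}")
        self.data = self.data.astype(np.uint8)
        if self.voxel_index.size:
            if (np.diff(self.voxel_index) <= 0).any():
                raise ValueError("voxel_index must be strictly increasing")
            if self.voxel_index[0] < 0 or self.voxel_index[-1] >= self.grid.n_voxels:
                raise ValueError("voxel_index outside grid")
        if self.volumes_ml is None:
            # assume the retained voxels are the full masks
            self.volumes_ml = self.data.sum(axis=1) * self.grid.voxel_volume_ml
        self.volumes_ml = np.asarray(self.volumes_ml, dtype=float)
        if self.volumes_ml.shape != (m,):
            raise ValueError("volumes_ml length does not match subject count")

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.data.shape[1]

    def prevalence(self) -> np.ndarray:
        """Number of lesioned subjects per retained voxel."""
        return self.data.sum(axis=0).astype(np.int64)

    def retained_volumes_ml(self) -> np.ndarray:
        """Per-subject volume counting retained voxels only (reporting aid)."""
        return self.data.sum(axis=1) * self.grid.voxel_volume_ml


# ---------------------------------------------------------------------------
# loading


def _check_binary(arr: np.ndarray, subject: str, path: str | os.PathLike) -> np.ndarray:
    rounded = np.rint(arr)
    if not np.isin(np.unique(rounded), (0, 1)).all() or np.abs(arr - rounded).max(initial=0.0) > _BINARY_ATOL:
        bad = np.unique(arr)[:5]
        raise ValueError(
            f"mask for subject {subject!r} ({path}) is not binary "
            f"(values {bad}); probabilistic maps are not thresholded automatically"
        )
    return rounded.astype(np.uint8)


def load_manifest(manifest: str | os.PathLike | pd.DataFrame) -> pd.DataFrame:
    """Read a TSV manifest with columns id, lesion_type, path."""
    if isinstance(manifest, pd.DataFrame):
        df = manifest.copy()
    else:
        df = pd.read_csv(manifest, sep="\t", dtype=str)
    missing = {"id", "lesion_type", "path"} - set(df.columns)
    if missing:
        raise ValueError(f"manifest is missing columns: {sorted(missing)}")
    df["id"] = df["id"].astype(str)
    return df


def load_cohort(
    manifest: str | os.PathLike | pd.DataFrame,
    table_path: str | os.PathLike | pd.DataFrame,
    space: str = "",
) -> tuple[dict[str, LesionTensor], pd.DataFrame]:
    """Load per-subject masks (one file per lesion type) and the cohort table.

    Subject order is taken from the cohort table. The first mask of each run
    defines the reference grid; every other mask must match its shape and
    affine within 1e-4. Per-type ``<type>_volume_ml`` columns are recomputed
    into the table from the full masks.
    """
    man = load_manifest(manifest)
    if isinstance(table_path, pd.DataFrame):
        table = table_path.copy()
    else:
        table = pd.read_csv(table_path)
    if "id" not in table.columns:
        raise ValueError("cohort table must have an 'id' column")
    table["id"] = table["id"].astype(str)
    subject_ids = table["id"].tolist()

    grid: ReferenceGrid | None = None
    tensors: dict[str, LesionTensor] = {}
    for lesion_type, sub in man.groupby("lesion_type", sort=True):
        paths = dict(zip(sub["id"], sub["path"]))
        missing = [s for s in subject_ids if s not in paths]
        if missing:
            raise ValueError(f"manifest has no {lesion_type} mask for subjects {missing}")
        masks = []
        for sid in subject_ids:
            img = nib.load(paths[sid])
            g = ReferenceGrid.from_image(img, space=space)
            if grid is None:
                grid = g
            elif not grid.matches(g):
                raise ValueError(
                    f"grid mismatch for subject {sid!r} ({lesion_type}): "
                    f"shape {g.shape} / affine differ from reference {grid.shape}"
                )
            arr = _check_binary(np.asarray(img.dataobj, dtype=float), sid, paths[sid])
            masks.append(arr.reshape(-1))
        full = np.asarray(masks, dtype=np.uint8)
        volumes_ml = full.sum(axis=1) * grid.voxel_volume_ml
        voxel_index = np.flatnonzero(full.any(axis=0))
        tensors[str(lesion_type)] = LesionTensor(
            lesion_type=str(lesion_type),
            grid=grid,
            subject_ids=subject_ids,
            voxel_index=voxel_index,
            data=full[:, voxel_index],
            volumes_ml=volumes_ml,
        )
        table[f"{str(lesion_type).lower()}_volume_ml"] = volumes_ml
    return tensors, table


# ---------------------------------------------------------------------------
# filtering and descriptive maps


def apply_min_subject_filter(t: LesionTensor, k: int) -> LesionTensor:
    """Keep only voxels lesioned in at least ``k`` subjects.

    Subject (full) volumes are unchanged; idempotent for fixed ``k``.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    keep = t.prevalence() >= k
    if not keep.any():
        raise ValueError(
            f"no {t.lesion_type} voxel is lesioned in >= {k} subjects; "
            "lower k or add subjects"
        )
    return replace(t, voxel_index=t.voxel_index[keep], data=t.data[:, keep])


def prevalence_map(t: LesionTensor) -> np.ndarray:
    """Full-grid integer volume: subjects lesioned per voxel, 0 elsewhere."""
    out = np.zeros(t.grid.n_voxels, dtype=np.int64)
    out[t.voxel_index] = t.prevalence()
    return out.reshape(t.grid.shape)

def lesion_size_topology(t: LesionTensor) -> np.ndarray:
    """Full-grid map of the median full-mask volume (ml) of the subjects
    lesioned at each voxel; NaN where no subject is lesioned."""
    out = np.full(t.grid.n_voxels, np.nan)
    for j, vox in enumerate(t.voxel_index):
        hit = t.data[:, j] == 1
        if hit.any():
            out[vox] = float(np.median(t.volumes_ml[hit]))
    return out.reshape(t.grid.shape)


# ---------------------------------------------------------------------------
# writing


def write_tensor(t: LesionTensor, out_dir: str | os.PathLike,
                 pattern: str = "sub-{id}_{type}.nii.gz") -> list[Path]:
    """Write one full-grid NIfTI mask per subject; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for m, sid in enumerate(t.subject_ids):
        vol = np.zeros(t.grid.n_voxels, dtype=np.uint8)
        vol[t.voxel_index] = t.data[m]
        p = out_dir / pattern.format(id=sid, type=t.lesion_type.lower())
        nib.save(nib.Nifti1Image(vol.reshape(t.grid.shape), t.grid.affine), p)
        paths.append(p)
    return paths


def save_map(grid: ReferenceGrid, volume: np.ndarray, path: str | os.PathLike) -> Path:
    """Save a full-grid volume as NIfTI on the reference grid."""
    volume = np.asarray(volume)
    if volume.shape != grid.shape:
        raise ValueError(f"volume shape {volume.shape} does not match grid {grid.shape}")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if volume.dtype.kind == "f":
        volume = volume.astype(np.float32)
    elif volume.dtype != np.uint8:
        volume = volume.astype(np.int32)
    nib.save(nib.Nifti1Image(volume, grid.affine), path)
    return path
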