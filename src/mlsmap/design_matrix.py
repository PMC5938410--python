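"""Single- and multi-lesion design matrices with volume-control variants.

A design has one column per (lesion_type, voxel) pair, ordered as
contiguous per-type blocks (each block in ascending voxel index). Under
volume_mode "voxelwise" each subject's entries in a block are scaled by
1 / sqrt(that subject's full lesion volume of that type); under "none" and
"regress_out" the matrix stays binary (regress-out scaling acts on the
behavior score in behavior_prep, not here).

Volumes for the 1/sqrt scaling are in cubic millimeters of the full mask;
any other consistent unit rescales columns by a constant that the SVR box
constraint absorbs.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .lesion_io import LesionTensor, ReferenceGrid, apply_min_subject_filter

__all__ = ["MultiLesionDesign", "build_single_design", "build_multilesion_design",
           "VOLUME_MODES"]

VOLUME_MODES = ("none", "voxelwise", "regress_out")


@dataclass
class MultiLesionDesign:
    """Column-blocked lesion design matrix (subjects x retained voxels)."""

    columns: list[tuple[str, int]]
    matrix: np.ndarray
    volume_mode: str
    grid: ReferenceGrid
    subject_ids: list[str]
    block_slices: dict[str, slice] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.volume_mode not in VOLUME_MODES:
            raise ValueError(f"volume_mode must be one of {VOLUME_MODES}")
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (len(self.subject_ids), len(self.columns)):
            raise ValueError("matrix shape does not match subjects x columns")

    @property
    def n_subjects(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_columns(self) -> int:
        return self.matrix.shape[1]

    @property
    def lesion_types(self) -> list[str]:
        return list(self.block_slices)

    def block(self, lesion_type: str) -> np.ndarray:
        return self.matrix[:, self.block_slices[lesion_type]]

    def block_voxels(self, lesion_type: str) -> np.ndarray:
        sl = self.block_slices[lesion_type]
        return np.asarray([v for _, v in self.columns[sl]], dtype=np.int64)

    def export(self, path_prefix: str | Path) -> tuple[Path, Path]:
        """Write the matrix (CSV, gzip) plus a JSON sidecar of column metadata."""
        path_prefix = Path(path_prefix)
        mat_path = path_prefix.with_suffix(".csv.gz")
        meta_path = path_prefix.with_suffix(".json")
        import pandas as pd

        header = [f"{t}:{v}" for t, v in self.columns]
        pd.DataFrame(self.matrix, index=self.subject_ids, columns=header).to_csv(mat_path)
        ijk = self.grid.flat_to_ijk(np.asarray([v for _, v in self.columns]))
        meta = {
            "volume_mode": self.volume_mode,
            "grid_shape": list(self.grid.shape),
            "columns": [
                {"lesion_type": t, "voxel": int(v), "ijk": [int(c) for c in ijk[j]]}
                for j, (t, v) in enumerate(self.columns)
            ],
        }
        meta_path.write_text(json.dumps(meta, indent=1))
        return mat_path, meta_path


def _voxelwise_scale(volumes_mm3: np.ndarray, lesion_type: str) -> np.ndarray:
    scale = np.zeros_like(volumes_mm3, dtype=float)
    zero = volumes_mm3 <= 0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} subject(s) with zero {lesion_type} volume under "
            "voxelwise volume control: rows left all-zero", stacklevel=3)
    scale[~zero] = 1.0 / np.sqrt(volumes_mm3[~zero])
    return scale


def _one_block(t: LesionTensor, k: int, volume_mode: str) -> tuple[np.ndarray, list[tuple[str, int]]]:
    ft = apply_min_subject_filter(t, k)
    mat = ft.data.astype(float)
    if volume_mode == "voxelwise":
        vol_mm3 = ft.volumes_ml * 1000.0
        mat = mat * _voxelwise_scale(vol_mm3, ft.lesion_type)[:, None]
    cols = [(ft.lesion_type, int(v)) for v in ft.voxel_index]
    return mat, cols


def build_single_design(t: LesionTensor, k: int = 3,
                        volume_mode: str = "none") -> MultiLesionDesign:
    """One-block design over the voxels of a single lesion type that are
    lesioned in at least ``k`` subjects."""
    if volume_mode not in VOLUME_MODES:
        raise ValueError(f"volume_mode must be one of {VOLUME_MODES}")
    mat, cols = _one_block(t, k, volume_mode)
    return MultiLesionDesign(
        columns=cols, matrix=mat, volume_mode=volume_mode, grid=t.grid,
        subject_ids=list(t.subject_ids),
        block_slices={t.lesion_type: slice(0, len(cols))},
    )


def build_multilesion_design(ail: LesionTensor, wmh: LesionTensor, k: int = 3,
                             volume_mode: str = "none") -> MultiLesionDesign:
    """Two-block design [AIL | WMH], each block independently filtered at
    ``k`` and, under "voxelwise", scaled by its own lesion-type volume.

    A lesion type whose tensor has no voxel surviving the filter simply
    contributes an empty block, so an all-zero second tensor reduces the
    design to the single-lesion one column-for-column.
    """
    if volume_mode not in VOLUME_MODES:
        raise ValueError(f"volume_mode must be one of {VOLUME_MODES}")
    if ail.subject_ids != wmh.subject_ids:
        raise ValueError("tensors have different subject order")
    if not ail.grid.matches(wmh.grid):
        raise ValueError("tensors are on different grids")

    blocks: list[np.ndarray] = []
    columns: list[tuple[str, int]] = []
    block_slices: dict[str, slice] = {}
    for t in (ail, wmh):
        try:
            mat, cols = _one_block(t, k, volume_mode)
        except ValueError:  # no voxel survives: empty block
            mat = np.zeros((t.n_subjects, 0))
            cols = []
        start = len(columns)
        blocks.append(mat)
        columns.extend(cols)
        block_slices[t.lesion_type] = slice(start, len(columns))
    return MultiLesionDesign(
        columns=columns, matrix=np.hstack(blocks), volume_mode=volume_mode,
        grid=ail.grid, subject_ids=list(ail.subject_ids), block_slices=block_slices,
    )
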