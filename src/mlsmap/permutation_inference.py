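"""Permutation inference for SVR beta maps, thresholding, clustering and
atlas overlap reporting.

The null distribution is built by shuffling the deficit vector P times and
refitting the SVR with the hyperparameters selected on the unshuffled data
(held fixed across permutations). For the multi-lesion model the pseudo
weights of all lesion-type blocks come from the same shuffles, so AIL and
WMH voxels share one permutation stream. The default test is one-sided
toward large positive weights (larger deficit <=> positive weight under the
deficit-score convention); ties count against significance:

    p(voxel) = (1 + #{pseudo beta >= real beta}) / (P + 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .design_matrix import MultiLesionDesign
from .lesion_io import LesionTensor
from .svr_mapping import DEFAULT_EPSILON, extract_beta, fit_svr, _zscore

__all__ = [
    "PermutationPMaps",
    "Cluster",
    "ClusterSet",
    "permutation_p",
    "threshold_and_cluster",
    "atlas_overlap_report",
]


@dataclass
class PermutationPMaps:
    columns: list[tuple[str, int]]
    beta: np.ndarray                 # real weights, concatenated blocks
    exceed_count: np.ndarray         # #{pseudo >= real} per column
    p: np.ndarray
    n_permutations: int
    seed: int | None
    block_slices: dict[str, slice]
    grid: "object"
    alternative: str = "greater"
    hyperparams_retrained: bool = False  # always False: C (gamma) fixed across shuffles

    def block_p(self, lesion_type: str) -> np.ndarray:
        return self.p[self.block_slices[lesion_type]]

    def block_beta(self, lesion_type: str) -> np.ndarray:
        return self.beta[self.block_slices[lesion_type]]

    def block_voxels(self, lesion_type: str) -> np.ndarray:
        sl = self.block_slices[lesion_type]
        return np.asarray([v for _, v in self.columns[sl]], dtype=np.int64)


@dataclass
class Cluster:
    lesion_type: str
    voxels: np.ndarray               # flat grid indices
    n_voxels: int
    volume_ml: float
    peak_voxel: int                  # flat index of max |beta|
    peak_beta: float
    centroid: tuple[float, float, float]


@dataclass
class ClusterSet:
    clusters: dict[str, list[Cluster]] = field(default_factory=dict)
    alpha: float = 0.05
    connectivity: int = 26

    def union_voxels(self, lesion_type: str) -> np.ndarray:
        cls = self.clusters.get(lesion_type, [])
        if not cls:
            return np.empty(0, dtype=np.int64)
        return np.unique(np.concatenate([c.voxels for c in cls]))

    def n_clusters(self, lesion_type: str) -> int:
        return len(self.clusters.get(lesion_type, []))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for lt, cls in self.clusters.items():
            for i, c in enumerate(cls):
                rows.append({
                    "cluster_id": f"{lt}-{i + 1}", "lesion_type": lt,
                    "n_voxels": c.n_voxels, "volume_ml": c.volume_ml,
                    "peak_voxel": c.peak_voxel, "peak_beta": c.peak_beta,
                    "centroid_i": c.centroid[0], "centroid_j": c.centroid[1],
                    "centroid_k": c.centroid[2],
                })
        return pd.DataFrame(rows)


def permutation_p(
    design: MultiLesionDesign,
    deficit: np.ndarray,
    C: float,
    gamma: float | None = None,
    kernel: str = "linear",
    P: int = 1000,
    seed: int | None = 0,
    epsilon: float = DEFAULT_EPSILON,
    alternative: str = "greater",
    standardize: bool = True,
) -> PermutationPMaps:
    """Voxelwise permutation p values for the SVR beta map.

    ``alternative="greater"`` counts pseudo beta >= real beta (default);
    ``"two-sided"`` counts |pseudo| >= |real|.
    """
    if P < 100:
        warnings.warn(f"P={P} permutations is too coarse for p<0.05 thresholds",
                      stacklevel=2)
    y = _zscore(deficit) if standardize else np.asarray(deficit, dtype=float)
    real = extract_beta(fit_svr(design, y, kernel, C=C, gamma=gamma, epsilon=epsilon),
                        design).concatenated()
    stat = np.abs(real) if alternative == "two-sided" else real

    rng = np.random.default_rng(seed)
    exceed = np.zeros(design.n_columns)
    for _ in range(P):
        y_perm = y[rng.permutation(len(y))]
        pseudo = extract_beta(
            fit_svr(design, y_perm, kernel, C=C, gamma=gamma, epsilon=epsilon),
            design).concatenated()
        pstat = np.abs(pseudo) if alternative == "two-sided" else pseudo
        exceed += pstat >= stat

    p = (1.0 + exceed) / (P + 1.0)
    return PermutationPMaps(
        columns=list(design.columns), beta=real, exceed_count=exceed, p=p,
        n_permutations=P, seed=seed, block_slices=dict(design.block_slices),
        grid=design.grid, alternative=alternative,
    )


_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


def threshold_and_cluster(p_maps: PermutationPMaps, alpha: float = 0.05,
                          connectivity: int = 26) -> ClusterSet:
    """Binary mask p < alpha per lesion type, split into maximal connected
    components (26-connectivity by default). Empty result is allowed."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if connectivity not in _STRUCTURES:
        raise ValueError("connectivity must be 6, 18 or 26")
    grid = p_maps.grid
    out = ClusterSet(alpha=alpha, connectivity=connectivity)
    for lt in p_maps.block_slices:
        voxels = p_maps.block_voxels(lt)
        sig = voxels[p_maps.block_p(lt) < alpha]
        beta_by_voxel = dict(zip(voxels.tolist(), p_maps.block_beta(lt).tolist()))
        clusters: list[Cluster] = []
        if sig.size:
            vol = np.zeros(grid.n_voxels, dtype=bool)
            vol[sig] = True
            labels, n = ndimage.label(vol.reshape(grid.shape),
                                      structure=_STRUCTURES[connectivity])
            labels = labels.reshape(-1)
            for lab in range(1, n + 1):
                flat = np.flatnonzero(labels == lab)
                betas = np.asarray([beta_by_voxel[int(v)] for v in flat])
                peak = flat[int(np.argmax(np.abs(betas)))]
                ijk = grid.flat_to_ijk(flat).astype(float)
                clusters.append(Cluster(
                    lesion_type=lt, voxels=flat, n_voxels=int(flat.size),
                    volume_ml=float(flat.size * grid.voxel_volume_ml),
                    peak_voxel=int(peak),
                    peak_beta=float(betas[int(np.argmax(np.abs(betas)))]),
                    centroid=tuple(ijk.mean(axis=0)),
                ))
        out.clusters[lt] = clusters
    return out


def atlas_overlap_report(
    clusters: ClusterSet,
    atlas: np.ndarray,
    label_names: dict[int, str],
    tensors: dict[str, LesionTensor],
    p_maps: PermutationPMaps | None = None,
) -> pd.DataFrame:
    """Per atlas label and lesion type: region size, tested voxels,
    significant voxel count and percentage of region size, and the number
    of subjects whose lesion overlaps the region by at least one voxel.
    Significant voxels outside every label are reported in an "unlabeled"
    row, so per-label counts (plus unlabeled) partition the total."""
    atlas = np.asarray(atlas)
    rows = []
    for lt, tensor in tensors.items():
        if atlas.shape != tensor.grid.shape:
            raise ValueError("atlas grid does not match the lesion grid")
        flat_atlas = atlas.reshape(-1)
        sig = clusters.union_voxels(lt)
        tested = p_maps.block_voxels(lt) if p_maps is not None else tensor.voxel_index
        sig_labels = flat_atlas[sig] if sig.size else np.empty(0, dtype=flat_atlas.dtype)
        for lab, name in sorted(label_names.items()):
            region = flat_atlas == lab
            region_size = int(region.sum())
            n_sig = int((sig_labels == lab).sum())
            overlap_subjects = int(
                (tensor.data[:, region[tensor.voxel_index]].sum(axis=1) > 0).sum())
            rows.append({
                "lesion_type": lt, "label": int(lab), "region": name,
                "region_size_voxels": region_size,
                "tested_voxels": int(region[tested].sum()),
                "n_significant": n_sig,
                "pct_significant": 100.0 * n_sig / region_size if region_size else 0.0,
                "n_subjects_with_lesion": overlap_subjects,
            })
        labeled = np.isin(sig_labels, list(label_names))
        rows.append({
            "lesion_type": lt, "label": -1, "region": "unlabeled",
            "region_size_voxels": 0, "tested_voxels": 0,
            "n_significant": int((~labeled).sum()), "pct_significant": np.nan,
            "n_subjects_with_lesion": 0,
        })
    return pd.DataFrame(rows)
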