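"""End-to-end runs: load -> filter -> prepare -> design -> fit -> permute ->
cluster -> report, with resolved-config and provenance logging.

All randomness flows from one configured seed through named substreams, so
changing e.g. the permutation count does not perturb the simulation.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .behavior_prep import prepare_scores
from .design_matrix import build_multilesion_design, build_single_design
from .lesion_io import (LesionTensor, load_cohort, prevalence_map,
                        lesion_size_topology, save_map, write_tensor)
from .permutation_inference import permutation_p, threshold_and_cluster
from .simcohort import SimulationConfig, LesionSpec, sample_cohort
from .svr_mapping import train_and_fit
from .vlsm import vlsm_run

log = logging.getLogger("mlsmap")

_SUBSTREAM_PERMUTE, _SUBSTREAM_SIM = 101, 102


def substream(seed: int, stream: int) -> int:
    """Derive a named integer substream from the run seed."""
    return int(np.random.SeedSequence([int(seed), int(stream)]).generate_state(1)[0])


def _setup_run_dir(out_dir: Path, config: dict) -> Path:
    out_dir = Path(out_dir)
    for sub in ("maps", "clusters", "reports", "logs"):
        (out_dir / sub).mkdir(parents=True, exist_ok=True)
    (out_dir / "resolved_config.yaml").write_text(yaml.safe_dump(config, sort_keys=False))
    handler = logging.FileHandler(out_dir / "logs" / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    log.info("mlsmap %s", __version__)
    return out_dir


def simulation_config_from_dict(d: dict) -> SimulationConfig:
    d = dict(d)
    for key in ("ail_spec", "wmh_spec"):
        if key in d and isinstance(d[key], dict):
            d[key] = LesionSpec(**d[key])
    for key in ("strategic_ail", "strategic_wmh"):
        if key in d and d[key] is not None:
            d[key] = {int(k): float(v) for k, v in dict(d[key]).items()}
    for key in ("grid_shape", "voxel_size", "score_range", "age_range", "education_range"):
        if key in d and d[key] is not None:
            d[key] = tuple(d[key])
    return SimulationConfig(**d)


def run_simulate(config: SimulationConfig, out_dir: str | Path) -> Path:
    """Generate a cohort and write masks, cohort table, truth maps and the
    resolved config to ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cohort = sample_cohort(config)
    rows = []
    for tensor in (cohort.ail, cohort.wmh):
        paths = write_tensor(tensor, out_dir, pattern="{id}_{type}.nii.gz")
        rows += [{"id": sid, "lesion_type": tensor.lesion_type, "path": str(p)}
                 for sid, p in zip(tensor.subject_ids, paths)]
    pd.DataFrame(rows).to_csv(out_dir / "manifest.tsv", sep="\t", index=False)
    cohort.table.to_csv(out_dir / "cohort.csv", index=False)
    grid = config.grid
    save_map(grid, cohort.truth_beta_ail.reshape(grid.shape), out_dir / "truth_beta_ail.nii.gz")
    save_map(grid, cohort.truth_beta_wmh.reshape(grid.shape), out_dir / "truth_beta_wmh.nii.gz")
    resolved = asdict(config)
    resolved["brain_mask"] = None  # arrays are not YAML-serializable
    (out_dir / "resolved_config.yaml").write_text(
        yaml.safe_dump(json.loads(json.dumps(resolved, default=str)), sort_keys=False))
    return out_dir


def run_full(config: dict) -> Path:
    """Run one analysis described by a config mapping.

    Required keys: paths.manifest, paths.table, paths.out_dir and an
    ``analysis`` block (method, score, covariates, volume_control, kernel,
    k, P, alpha, connectivity, seed). Stage failures are re-raised with the
    stage name prepended.
    """
    paths = config["paths"]
    analysis = config["analysis"]
    out_dir = _setup_run_dir(Path(paths["out_dir"]), config)
    method = analysis["method"]
    seed = int(analysis.get("seed", 0))
    k = int(analysis.get("k", 3))
    P = int(analysis.get("P", 1000))
    alpha = float(analysis.get("alpha", 0.05))
    volume_control = analysis.get("volume_control", "none")
    score = analysis["score"]
    covariates = list(analysis.get("covariates", ["age", "sex", "education"]))
    manifest = {}

    def stage(name):
        log.info("stage: %s", name)
        manifest[name] = time.strftime("%Y-%m-%dT%H:%M:%S")

    try:
        stage("load")
        tensors, table = load_cohort(paths["manifest"], paths["table"])
    except Exception as e:
        raise RuntimeError(f"stage load failed: {e}") from e

    lesion_types = sorted(tensors)
    for lt, t in tensors.items():
        save_map(t.grid, prevalence_map(t), out_dir / "maps" / f"prevalence_{lt.lower()}.nii.gz")
        save_map(t.grid, lesion_size_topology(t),
                 out_dir / "maps" / f"size_topology_{lt.lower()}.nii.gz")

    try:
        stage("prepare")
        if volume_control == "regress_out":
            if method == "svr-mlsm":
                vol_cols = [f"{lt.lower()}_volume_ml" for lt in lesion_types]
            else:
                vol_cols = [f"{analysis.get('lesion_type', 'AIL').lower()}_volume_ml"]
        else:
            vol_cols = None
        prepared = prepare_scores(table, score, covariates, vol_cols,
                                  analysis.get("score_direction", "higher_is_better"))
    except Exception as e:
        raise RuntimeError(f"stage prepare failed: {e}") from e

    perm_seed = substream(seed, _SUBSTREAM_PERMUTE)
    if method == "vlsm":
        try:
            stage("vlsm")
            lt = analysis.get("lesion_type", "AIL")
            from .lesion_io import apply_min_subject_filter
            tensor = apply_min_subject_filter(tensors[lt], k)
            result = vlsm_run(prepared, tensor, P=P, seed=perm_seed,
                              volume_mode=volume_control)
        except Exception as e:
            raise RuntimeError(f"stage vlsm failed: {e}") from e
        grid = tensor.grid
        tmap = np.zeros(grid.n_voxels)
        pmap = np.ones(grid.n_voxels)
        tmap[result.voxel_index] = np.nan_to_num(result.t)
        pmap[result.voxel_index] = np.nan_to_num(result.p_fwe, nan=1.0)
        save_map(grid, tmap.reshape(grid.shape), out_dir / "maps" / "vlsm_t.nii.gz")
        save_map(grid, pmap.reshape(grid.shape), out_dir / "maps" / "vlsm_p_fwe.nii.gz")
        pd.DataFrame({
            "voxel": result.voxel_index, "t": result.t, "p_fwe": result.p_fwe,
            "p_unc": result.p_unc, "testable": result.testable,
        }).to_csv(out_dir / "reports" / "vlsm_voxels.tsv", sep="\t", index=False)
    elif method in ("svr-lsm", "svr-mlsm"):
        try:
            stage("design")
            if method == "svr-lsm":
                lt = analysis.get("lesion_type", "AIL")
                design = build_single_design(tensors[lt], k=k, volume_mode=volume_control)
            else:
                design = build_multilesion_design(tensors["AIL"], tensors["WMH"], k=k,
                                                  volume_mode=volume_control)
        except Exception as e:
            raise RuntimeError(f"stage design failed: {e}") from e
        try:
            stage("train")
            kernel = analysis.get("kernel", "linear")
            c_grid = np.asarray(analysis["c_grid"], float) if "c_grid" in analysis else None
            gamma_grid = (np.asarray(analysis["gamma_grid"], float)
                          if "gamma_grid" in analysis else None)
            report, model, betas = train_and_fit(design, prepared.deficit, kernel,
                                                 c_grid=c_grid, gamma_grid=gamma_grid)
            (out_dir / "reports" / "training.json").write_text(
                json.dumps(report.to_dict(), indent=1))
        except Exception as e:
            raise RuntimeError(f"stage train failed: {e}") from e
        try:
            stage("permute")
            pmaps = permutation_p(design, prepared.deficit, C=report.best_C,
                                  gamma=report.best_gamma, kernel=kernel, P=P,
                                  seed=perm_seed)
        except Exception as e:
            raise RuntimeError(f"stage permute failed: {e}") from e
        stage("cluster")
        clusters = threshold_and_cluster(pmaps, alpha=alpha,
                                         connectivity=int(analysis.get("connectivity", 26)))
        grid = design.grid
        for lt in pmaps.block_slices:
            vox = pmaps.block_voxels(lt)
            if vox.size == 0:
                continue
            pvol = np.ones(grid.n_voxels)
            bvol = np.zeros(grid.n_voxels)
            pvol[vox] = pmaps.block_p(lt)
            bvol[vox] = pmaps.block_beta(lt)
            save_map(grid, bvol.reshape(grid.shape),
                     out_dir / "maps" / f"beta_{lt.lower()}.nii.gz")
            save_map(grid, pvol.reshape(grid.shape),
                     out_dir / "maps" / f"p_{lt.lower()}.nii.gz")
            with np.errstate(divide="ignore"):
                save_map(grid, (-np.log10(pvol)).reshape(grid.shape),
                         out_dir / "maps" / f"neglog10p_{lt.lower()}.nii.gz")
            sigvol = np.zeros(grid.n_voxels, dtype=np.uint8)
            sigvol[clusters.union_voxels(lt)] = 1
            save_map(grid, sigvol.reshape(grid.shape),
                     out_dir / "maps" / f"significant_{lt.lower()}.nii.gz")
        clusters.to_frame().to_csv(out_dir / "clusters" / "clusters.tsv",
                                   sep="\t", index=False)
        if analysis.get("atlas_report") and not paths.get("atlas"):
            raise RuntimeError("stage report failed: atlas report requested but no "
                               "paths.atlas given")
    else:
        raise ValueError(f"unknown method {method!r}")

    stage("done")
    (out_dir / "manifest.json").write_text(json.dumps(
        {"version": __version__, "method": method, "seed": seed, "stages": manifest},
        indent=1))
    return out_dir
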