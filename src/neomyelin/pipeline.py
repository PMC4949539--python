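"""End-to-end pipeline: t2fit -> dwifit -> fuse -> roi -> stats.

Each stage reads/writes NIfTI maps in an output directory and is skipped on
re-runs when its outputs already exist (unless forced).  The resolved
configuration and package version are written next to the outputs, and a
markdown report summarizes the regional estimates.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import fusion, io
from .diffusion import DiffusionSettings, fit_dwi_volume
from .relaxometry import RelaxometrySettings, default_t2_grid, fit_volume
from .roi import WeightedROI, propagate_gratio_uncertainty, weighted_mean

log = logging.getLogger("neomyelin")

__all__ = ["run_pipeline", "t2fit_stage", "dwifit_stage", "fuse_stage", "roi_stage"]

T2_MAP_NAMES = ("v_mwf", "v_tissue", "v_iso", "tissue_t2", "flip_angle")
DWI_MAP_NAMES = ("s0", "v_in_prime", "v_ex_prime", "v_iso_prime", "gamma", "theta", "phi")
FUSED_MAP_NAMES = ("v_mwf", "v_in", "v_ex", "v_iso", "g_ratio")


def _stage_done(out_dir: Path, names) -> bool:
    return all((out_dir / f"{n}.nii.gz").exists() for n in names)


def _relax_settings(config: dict) -> RelaxometrySettings:
    g = config["t2_grid"]
    return RelaxometrySettings(
        grid=default_t2_grid(g["min"], g["max"], g["n"]),
        regularization=config["regularization"],
        t1=config["t1"],
        mwf_cutoff=config["mwf_cutoff"],
        iso_cutoff=config["iso_cutoff"],
    )


def t2fit_stage(echoes_path, mask_path, out_dir, config: dict, force: bool = False) -> Path:
    out_dir = Path(out_dir)
    if not force and _stage_done(out_dir, T2_MAP_NAMES):
        log.info("t2fit: outputs exist, skipping")
        return out_dir
    echo, affine = io.load_nifti(echoes_path)
    mask, _ = io.load_nifti(mask_path)
    maps = fit_volume(echo, mask > 0, config["te_spacing"], _relax_settings(config))
    io.save_maps(maps, affine, out_dir)
    return out_dir


def dwifit_stage(dwi_path, bvals_path, bvecs_path, mask_path, out_dir, config: dict, force: bool = False) -> Path:
    out_dir = Path(out_dir)
    if not force and _stage_done(out_dir, DWI_MAP_NAMES):
        log.info("dwifit: outputs exist, skipping")
        return out_dir
    dwi, affine = io.load_nifti(dwi_path)
    mask, _ = io.load_nifti(mask_path)
    protocol = io.read_bvals_bvecs(bvals_path, bvecs_path)
    settings = DiffusionSettings(d_par=config["d_par"], d_iso=config["d_iso"], n_starts=config["n_starts"])
    maps = fit_dwi_volume(dwi, mask > 0, protocol, settings)
    io.save_maps(maps, affine, out_dir)
    return out_dir


def fuse_stage(t2_dir, dwi_dir, mask_path, out_dir, config: dict, force: bool = False) -> Path:
    out_dir = Path(out_dir)
    if not force and _stage_done(out_dir, FUSED_MAP_NAMES):
        log.info("fuse: outputs exist, skipping")
        return out_dir
    t2_dir, dwi_dir = Path(t2_dir), Path(dwi_dir)
    v_mwf, affine = io.load_nifti(t2_dir / "v_mwf.nii.gz")
    diffusion_maps = {n: io.load_nifti(dwi_dir / f"{n}.nii.gz")[0] for n in ("v_in_prime", "v_ex_prime", "v_iso_prime")}
    mask, _ = io.load_nifti(mask_path)
    fused = fusion.fuse_maps({"v_mwf": v_mwf}, diffusion_maps, mask > 0, config["v_in_floor"])
    io.save_maps(fused, affine, out_dir)
    return out_dir


def roi_stage(map_dir, rois: dict[str, WeightedROI], out_csv, map_names=FUSED_MAP_NAMES) -> pd.DataFrame:
    """Aggregate maps over named weighted ROIs into a tidy CSV."""
    map_dir = Path(map_dir)
    rows = []
    for region, roi in rois.items():
        estimates = {}
        for name in map_names:
            arr, _ = io.load_nifti(map_dir / f"{name}.nii.gz")
            est = weighted_mean(arr, roi)
            estimates[name] = est
            rows.append(
                {"region": region, "parameter": name, "mean": est.mean, "ci": est.ci_halfwidth, "n_voxels": est.n_voxels}
            )
        if "v_mwf" in estimates and "v_in" in estimates:
            m, v = estimates["v_mwf"], estimates["v_in"]
            if np.isfinite(m.mean) and np.isfinite(v.mean) and v.mean > 0:
                gam, sig = propagate_gratio_uncertainty(m.mean, m.ci_halfwidth, v.mean, v.ci_halfwidth)
                rows.append(
                    {"region": region, "parameter": "g_ratio_propagated", "mean": gam, "ci": sig, "n_voxels": v.n_voxels}
                )
    df = pd.DataFrame(rows)
    if out_csv is not None:
        Path(out_csv).parent.mkdir(parents=True, exist_ok=True)
        df.to_csv(out_csv, index=False)
    return df


def run_pipeline(
    echoes_path,
    dwi_path,
    bvals_path,
    bvecs_path,
    mask_path,
    out_dir,
    config: dict,
    rois: dict[str, WeightedROI] | None = None,
    force: bool = False,
) -> dict:
    """Chain all stages; returns paths of the produced artifacts.

    Stages whose outputs already exist are skipped unless ``force``; any
    stage failure propagates with the stage name in the log.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    io.dump_resolved_config(config, out_dir)
    artifacts = {}
    try:
        log.info("stage t2fit")
        artifacts["t2"] = t2fit_stage(echoes_path, mask_path, out_dir / "t2", config, force)
        log.info("stage dwifit")
        artifacts["dwi"] = dwifit_stage(dwi_path, bvals_path, bvecs_path, mask_path, out_dir / "dwi", config, force)
        log.info("stage fuse")
        artifacts["fused"] = fuse_stage(artifacts["t2"], artifacts["dwi"], mask_path, out_dir / "fused", config, force)
        if rois:
            log.info("stage roi")
            artifacts["roi_csv"] = out_dir / "regions.csv"
            roi_table = roi_stage(artifacts["fused"], rois, artifacts["roi_csv"])
            artifacts["report"] = _write_report(out_dir, roi_table)
    except Exception:
        log.exception("pipeline stage failed")
        raise
    return artifacts


def _write_report(out_dir: Path, roi_table: pd.DataFrame) -> Path:
    lines = ["# neomyelin pipeline report", "", "## Regional estimates", ""]
    cols = list(roi_table.columns)
    lines.append("| " + " | ".join(cols) + " |")
    lines.append("|" + "---|" * len(cols))
    for _, row in roi_table.iterrows():
        cells = [f"{v:.4g}" if isinstance(v, float) else str(v) for v in row]
        lines.append("| " + " | ".join(cells) + " |")
    lines.append("")
    path = out_dir / "report.md"
    path.write_text("\n".join(lines))
    return path
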