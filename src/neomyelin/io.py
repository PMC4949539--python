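"""NIfTI, gradient-table and configuration file handling."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .diffusion import DiffusionProtocol

__all__ = [
    "load_nifti",
    "save_nifti",
    "save_maps",
    "read_bvals_bvecs",
    "write_bvals_bvecs",
    "load_config",
    "dump_resolved_config",
]


def load_nifti(path) -> tuple[np.ndarray, np.ndarray]:
    """Return (data, affine) from a NIfTI file."""
    img = nib.load(str(path))
    return np.asarray(img.get_fdata()), img.affine


def save_nifti(data: np.ndarray, affine: np.ndarray, path) -> None:
    """Write a float32 NIfTI preserving the supplied affine."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine), str(path))


def save_maps(maps: dict[str, np.ndarray], affine: np.ndarray, out_dir) -> dict[str, Path]:
    out_dir = Path(out_dir)
    paths = {}
    for name, arr in maps.items():
        p = out_dir / f"{name}.nii.gz"
        save_nifti(arr, affine, p)
        paths[name] = p
    return paths


def read_bvals_bvecs(bvals_path, bvecs_path) -> DiffusionProtocol:
    """Read FSL-style whitespace text gradient tables.

    bvecs may be written as 3 rows x N columns or N rows x 3 columns; the
    orientation is auto-detected.  Directions are taken as-is in image
    coordinates (no reorientation).
    """
    bvals = np.loadtxt(bvals_path).ravel()
    bvecs = np.atleast_2d(np.loadtxt(bvecs_path))
    if bvecs.shape[0] == 3 and bvecs.shape[1] != 3:
        bvecs = bvecs.T
    elif bvecs.shape[1] != 3:
        raise ValueError(f"cannot interpret bvecs of shape {bvecs.shape}")
    if bvecs.shape[0] != bvals.size:
        raise ValueError("bvals and bvecs describe different numbers of volumes")
    norms = np.linalg.norm(bvecs, axis=1)
    nonzero = norms > 0
    bvecs[nonzero] /= norms[nonzero, None]
    return DiffusionProtocol(bvals, bvecs)


def write_bvals_bvecs(protocol: DiffusionProtocol, bvals_path, bvecs_path) -> None:
    Path(bvals_path).parent.mkdir(parents=True, exist_ok=True)
    np.savetxt(bvals_path, protocol.bvals[None, :], fmt="%.1f")
    np.savetxt(bvecs_path, protocol.bvecs.T, fmt="%.8f")


_CONFIG_DEFAULTS = {
    "te_spacing": 12.0,
    "n_echoes": 32,
    "t2_grid": {"min": 15.0, "max": 2000.0, "n": 60},
    "mwf_cutoff": 50.0,
    "iso_cutoff": 350.0,
    "regularization": 0.0,
    "t1": 2000.0,
    "d_par": 1.9e-3,
    "d_iso": 3.0e-3,
    "n_starts": 6,
    "v_in_floor": 0.01,
    "seed": 0,
}


def load_config(path=None, overrides: dict | None = None) -> dict:
    """Load a YAML pipeline config, filling defaults and validating keys."""
    config = dict(_CONFIG_DEFAULTS)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        unknown = set(user) - set(_CONFIG_DEFAULTS) - {"paths"}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        config.update(user)
    if overrides:
        config.update({k: v for k, v in overrides.items() if v is not None})
    if config["te_spacing"] <= 0 or config["n_echoes"] < 3:
        raise ValueError("invalid echo-train configuration")
    if config["mwf_cutoff"] >= config["iso_cutoff"]:
        raise ValueError("mwf_cutoff must be below iso_cutoff")
    return config


def dump_resolved_config(config: dict, out_dir) -> Path:
    """Write the resolved configuration (and package version) next to outputs."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    payload = {"version": __version__, "config": config}
    path = out_dir / "neomyelin_config.json"
    path.write_text(json.dumps(payload, indent=2, default=str))
    return path
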