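"""Readers/writers for images, fields, click logs, diagnostics, manifests.

Supported formats: PNG (8/16-bit grayscale, unit spacing) for 2-D, NIfTI-1
(via nibabel) and NRRD (via SimpleITK) for 2-D/3-D with physical spacing.
Array axis order is (row, col[, slice]); intensities are read as float64
and fields are stored as float32 on disk (arithmetic stays float64 in
memory).  No operation mutates its inputs on disk.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import imageio.v3 as iio
import nibabel as nib
import numpy as np
import SimpleITK as sitk
import yaml

from .grid import Grid, LevelSetField, ScalarField

__all__ = [
    "read_image",
    "write_field",
    "write_mask",
    "write_outputs",
    "load_config",
    "sha256_file",
]

_PNG_SUFFIXES = {".png"}
_NIFTI_SUFFIXES = {".nii", ".nii.gz"}
_NRRD_SUFFIXES = {".nrrd", ".nhdr"}


def _suffix(path: Path) -> str:
    name = path.name.lower()
    if name.endswith(".nii.gz"):
        return ".nii.gz"
    return path.suffix.lower()


def read_image(path) -> ScalarField:
    """Read a 2-D or 3-D scalar image with its grid spacing.

    PNG carries unit spacing; NIfTI/NRRD spacing comes from the header.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = _suffix(path)
    if suffix in _PNG_SUFFIXES:
        data = np.asarray(iio.imread(path)).astype(np.float64)
        if data.ndim == 3:  # collapse RGB(A) to luminance
            data = data[..., :3].mean(axis=-1)
        grid = Grid(data.shape)
        return ScalarField(data, grid)
    if suffix in _NIFTI_SUFFIXES:
        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=np.float64)
        spacing = tuple(float(z) for z in img.header.get_zooms()[: data.ndim])
        return ScalarField(data, Grid(data.shape, spacing))
    if suffix in _NRRD_SUFFIXES:
        img = sitk.ReadImage(str(path))
        data = sitk.GetArrayFromImage(img).astype(np.float64)
        # SimpleITK returns (z, y, x); present as (row, col, slice)
        data = np.transpose(data, axes=tuple(reversed(range(data.ndim))))
        spacing = tuple(float(s) for s in img.GetSpacing())
        return ScalarField(data, Grid(data.shape, spacing))
    raise ValueError(f"unknown image format: {path.name}")


def write_field(path, field: ScalarField | LevelSetField) -> None:
    """Write a field as float32 (NIfTI/NRRD) or integer grayscale (PNG)."""
    path = Path(path)
    values = field.values
    grid = field.grid
    suffix = _suffix(path)
    if suffix in _PNG_SUFFIXES:
        if values.ndim != 2:
            raise ValueError("PNG output is 2-D only")
        arr = values
        if arr.dtype.kind == "f":
            if arr.min() < 0 or arr.max() > 65535 or not np.allclose(arr, np.round(arr)):
                raise ValueError("PNG needs integer-valued data in [0, 65535]; "
                                 "use write_mask or an NIfTI/NRRD path for fields")
            arr = np.round(arr)
        arr = arr.astype(np.uint16 if arr.max() > 255 else np.uint8)
        iio.imwrite(path, arr)
        return
    if suffix in _NIFTI_SUFFIXES:
        affine = np.diag(list(grid.spacing) + [1.0] * (4 - grid.ndim))
        nib.save(nib.Nifti1Image(values.astype(np.float32), affine), str(path))
        return
    if suffix in _NRRD_SUFFIXES:
        data = np.transpose(values.astype(np.float32),
                            axes=tuple(reversed(range(values.ndim))))
        img = sitk.GetImageFromArray(data)
        img.SetSpacing(tuple(grid.spacing))
        sitk.WriteImage(img, str(path))
        return
    raise ValueError(f"unknown output format: {path.name}")


def write_mask(path, phi: LevelSetField) -> None:
    """Write the interior label mask (phi > 0) in the requested format."""
    mask = phi.interior_mask().astype(np.uint8)
    path = Path(path)
    suffix = _suffix(path)
    if suffix in _PNG_SUFFIXES:
        iio.imwrite(path, (mask * 255).astype(np.uint8))
    else:
        write_field(path, ScalarField(mask.astype(np.float64), phi.grid))


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_outputs(outdir, result, image_format: str = ".png",
                  config_snapshot: dict | None = None,
                  input_checksums: dict | None = None,
                  seed: int | None = None) -> dict:
    """Write mask, field snapshots, diagnostics CSV, and a run manifest.

    The manifest (JSON) records the config snapshot, input checksums, seed
    and software version — enough to reproduce the run bit-exactly.
    Returns the manifest dict.
    """
    from . import __version__

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_mask(outdir / f"mask{image_format}", result.phi)
    write_field(outdir / "phi.nii.gz", result.phi)
    if result.psi_hat is not None:
        write_field(outdir / "psi_hat.nii.gz", result.psi_hat)
    if result.U is not None:
        write_field(outdir / "U.nii.gz", result.U.U)
    diag_path = outdir / "diagnostics.csv"
    result.diagnostics.to_dataframe().to_csv(diag_path, index=False)
    manifest = {
        "version": __version__,
        "seed": seed,
        "config": config_snapshot or {},
        "resolved": {k: (v if isinstance(v, (int, str, type(None))) else float(v))
                     for k, v in result.resolved.items()},
        "input_checksums": input_checksums or {},
        "diagnostics": diag_path.name,
        "steps": result.diagnostics.n_steps,
        "steady_step": result.diagnostics.steady_step,
    }
    with open(outdir / "manifest.json", "w") as f:
        json.dump(manifest, f, indent=2)
    return manifest


DEFAULT_CONFIG = {
    "model": {"kind": "global_means", "r_loc": 8.0, "lambda_smooth": 0.1},
    "control": {"lambda0": 1.0, "lambda1": 0.1, "rho": 0.5,
                "alpha": "auto", "U_M": "auto"},
    "session": {"mode": "closed_loop", "cfl": 0.45, "dt_max": 0.2,
                "redist_every": 5, "max_steps": 2000,
                "steady_tol": 1.0e-5, "steady_window": 50, "seed": 0},
    "inputs": {"sigma_x": 2.0, "sigma_I": "auto", "click_gain": "auto"},
}


def load_config(path=None) -> dict:
    """Load a YAML config, filling every omitted key from the defaults."""
    cfg = {k: dict(v) for k, v in DEFAULT_CONFIG.items()}
    if path is not None:
        with open(path) as f:
            user = yaml.safe_load(f) or {}
        for section, entries in user.items():
            if section not in cfg:
                raise ValueError(f"unknown config section {section!r}")
            for key, value in (entries or {}).items():
                if key not in cfg[section]:
                    raise ValueError(f"unknown config key {section}.{key}")
                cfg[section][key] = value
    return cfg


def build_session_config(cfg: dict):
    """Translate a config dict into SessionConfig (+ControlConfig if fixed)."""
    from .control import ControlConfig
    from .region import RegionModel
    from .session import SessionConfig

    model = RegionModel(**cfg["model"])
    ctrl_cfg = cfg["control"]
    control = None
    if ctrl_cfg.get("U_M") != "auto":
        alpha = ctrl_cfg.get("alpha")
        control = ControlConfig(
            lambda0=ctrl_cfg["lambda0"], lambda1=ctrl_cfg["lambda1"],
            rho=ctrl_cfg["rho"], U_M=float(ctrl_cfg["U_M"]),
            alpha=None if alpha == "auto" else alpha,
        )
    sess = cfg["session"]
    inputs = cfg["inputs"]
    return SessionConfig(
        model=model, control=control,
        lambda0=ctrl_cfg["lambda0"], lambda1=ctrl_cfg["lambda1"],
        rho=ctrl_cfg["rho"], mode=sess["mode"], cfl=sess["cfl"],
        dt_max=sess["dt_max"], redist_every=sess["redist_every"],
        max_steps=sess["max_steps"], steady_tol=sess["steady_tol"],
        steady_window=sess["steady_window"], seed=sess["seed"],
        sigma_x=inputs["sigma_x"],
        sigma_I=None if inputs["sigma_I"] == "auto" else inputs["sigma_I"],
        click_gain=None if inputs["click_gain"] == "auto" else inputs["click_gain"],
    )
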