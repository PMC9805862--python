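"""File formats: NIfTI-1 volumes, SPM rp_*.txt motion traces, design CSVs,
TSV result tables, and JSON provenance sidecars.

Round-trip contract: ``write(read(x))`` preserves data (float32 for BOLD
and maps, uint8 for masks), the affine, and the grid.  Grid/affine
mismatches across a session's files raise errors naming both files.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .simdata import BoldSeries, MaskSet, MotionTrace

__all__ = [
    "ensure_dir",
    "read_bold", "write_bold",
    "read_mask", "write_mask", "write_masks", "read_masks",
    "read_motion", "write_motion",
    "read_design", "write_table",
    "write_map", "read_map",
    "write_sidecar", "file_checksum",
]


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p


def write_bold(path, bold: BoldSeries) -> Path:
    img = nib.Nifti1Image(np.asarray(bold.data, dtype=np.float32), bold.affine)
    img.header.set_zooms(tuple(np.abs(np.diag(bold.affine)[:3])) + (bold.tr_s,))
    img.header.set_xyzt_units("mm", "sec")
    nib.save(img, str(path))
    return Path(path)


def read_bold(path, tr_s: float | None = None) -> BoldSeries:
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=np.float32)
    if data.ndim != 4:
        raise ValueError(f"{path}: expected 4D BOLD, got shape {data.shape}")
    if tr_s is None:
        zooms = img.header.get_zooms()
        tr_s = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 2.0
    return BoldSeries(data=data, affine=np.asarray(img.affine), tr_s=tr_s)


def write_mask(path, mask: np.ndarray, affine: np.ndarray) -> Path:
    img = nib.Nifti1Image(np.asarray(mask, dtype=np.uint8), affine)
    nib.save(img, str(path))
    return Path(path)


def read_mask(path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.get_fdata()) > 0.5, np.asarray(img.affine)


_MASK_NAMES = ("gm", "wm", "csf", "seed", "target")


def write_masks(out_dir, masks: MaskSet) -> dict:
    out_dir = ensure_dir(out_dir)
    paths = {}
    for name in _MASK_NAMES:
        paths[name] = write_mask(out_dir / f"mask_{name}.nii.gz",
                                 getattr(masks, name), masks.affine)
    for i, h in enumerate(masks.hubs):
        paths[f"hub{i}"] = write_mask(out_dir / f"mask_hub{i}.nii.gz", h, masks.affine)
    return paths


def read_masks(mask_dir) -> MaskSet:
    mask_dir = Path(mask_dir)
    arrays, affines = {}, {}
    for name in _MASK_NAMES:
        arrays[name], affines[name] = read_mask(mask_dir / f"mask_{name}.nii.gz")
    hubs = []
    i = 0
    while (mask_dir / f"mask_hub{i}.nii.gz").exists():
        h, _ = read_mask(mask_dir / f"mask_hub{i}.nii.gz")
        hubs.append(h)
        i += 1
    ref = affines["gm"]
    for name, aff in affines.items():
        if not np.allclose(aff, ref):
            raise ValueError(
                f"affine mismatch between {mask_dir / 'mask_gm.nii.gz'} and "
                f"{mask_dir / f'mask_{name}.nii.gz'}"
            )
    return MaskSet(gm=arrays["gm"], wm=arrays["wm"], csf=arrays["csf"],
                   seed=arrays["seed"], target=arrays["target"],
                   hubs=tuple(hubs), affine=ref)


def write_motion(path, motion: MotionTrace) -> Path:
    np.savetxt(str(path), motion.params, fmt="%.10g")
    return Path(path)


def read_motion(path) -> MotionTrace:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) != 6:
                raise ValueError(
                    f"{path}:{lineno}: expected 6 motion parameters, got {len(fields)}"
                )
            rows.append([float(v) for v in fields])
    if not rows:
        raise ValueError(f"{path}: empty motion file")
    return MotionTrace(np.asarray(rows))


def read_design(path, validate: bool = True) -> pd.DataFrame:
    df = pd.read_csv(path)
    if validate and len(df):
        from .stats import validate_design
        validate_design(df)
    return df


def write_table(path, df: pd.DataFrame) -> Path:
    df.to_csv(str(path), sep="\t", index=False)
    return Path(path)


def write_map(path, map3d: np.ndarray, affine: np.ndarray) -> Path:
    img = nib.Nifti1Image(np.asarray(map3d, dtype=np.float32), affine)
    nib.save(img, str(path))
    return Path(path)


def read_map(path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.get_fdata(), dtype=np.float32), np.asarray(img.affine)


def write_sidecar(data_path, provenance: dict) -> Path:
    """JSON provenance sidecar sufficient to re-run the producing stage."""
    side = Path(str(data_path) + ".json")
    with open(side, "w") as fh:
        json.dump(provenance, fh, indent=2, sort_keys=True, default=str)
    return side


def file_checksum(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def check_same_grid(bold: BoldSeries, mask: np.ndarray, bold_name: str, mask_name: str) -> None:
    if mask.shape != bold.grid_shape:
        raise ValueError(
            f"grid mismatch: {bold_name} has shape {bold.grid_shape}, "
            f"{mask_name} has shape {mask.shape}"
        )
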