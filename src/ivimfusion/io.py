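"""File formats: NIfTI DWI stacks with bval sidecars, PNG images and masks
with JSON grid metadata, control-point CSVs, transform JSON, summary CSVs.

Conventions: the DWI stack is one 3-D NIfTI with the b index on the third
axis and the b-values in an FSL-style single-row ``.bval`` text sidecar;
masks are 0/255 grayscale PNGs with a JSON sidecar carrying pixel size,
origin, label and zone; control points are CSV with header
``point_id,moving_x,moving_y,fixed_x,fixed_y`` (0-based pixel units,
x = column).
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from PIL import Image

from .core import AcquisitionScheme, IVIMParameterMap
from .registration import ControlPointSet, ROIMask

__all__ = [
    "write_dwi_nifti", "read_dwi_nifti",
    "write_mask", "read_mask",
    "write_control_points", "read_control_points",
    "write_image_png", "read_image_png",
    "write_parameter_maps", "write_roi_summaries",
    "write_fusion_overlay",
]


def write_dwi_nifti(path, stack: np.ndarray, scheme: AcquisitionScheme,
                    pixel_size: float = 1.0) -> None:
    """Write a (ny, nx, n_b) stack as NIfTI plus a ``.bval`` sidecar."""
    path = Path(path)
    affine = np.diag([pixel_size, pixel_size, 1.0, 1.0])
    nib.save(nib.Nifti1Image(np.asarray(stack, dtype=np.float32), affine), path)
    bval_path = path.with_suffix("").with_suffix(".bval") if path.suffix == ".gz" \
        else path.with_suffix(".bval")
    bval_path.write_text(" ".join(f"{b:g}" for b in scheme.b_values) + "\n")


def read_dwi_nifti(path):
    """Read a DWI stack and its bval sidecar; returns (stack, scheme,
    pixel_size)."""
    path = Path(path)
    img = nib.load(path)
    stack = np.asarray(img.get_fdata(), dtype=float)
    bval_path = path.with_suffix(".bval")
    b_values = tuple(float(v) for v in bval_path.read_text().split())
    pixel_size = float(img.affine[0, 0])
    return stack, AcquisitionScheme(b_values), pixel_size


def write_mask(path, mask: ROIMask) -> None:
    """Write an ROI mask as a 0/255 PNG plus a JSON geometry sidecar."""
    path = Path(path)
    Image.fromarray((mask.data.astype(np.uint8)) * 255).save(path)
    meta = {
        "pixel_size": mask.pixel_size,
        "origin": list(mask.origin),
        "label": mask.label,
        "zone": mask.zone,
        "shape": list(mask.data.shape),
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def read_mask(path) -> ROIMask:
    path = Path(path)
    data = np.asarray(Image.open(path)) > 127
    meta = json.loads(path.with_suffix(".json").read_text())
    return ROIMask(
        data, pixel_size=meta["pixel_size"], origin=tuple(meta["origin"]),
        label=meta.get("label", ""), zone=meta.get("zone", ""),
    )


def write_control_points(path, points: ControlPointSet) -> None:
    pd.DataFrame(
        {
            "point_id": points.ids,
            "moving_x": points.moving[:, 0],
            "moving_y": points.moving[:, 1],
            "fixed_x": points.fixed[:, 0],
            "fixed_y": points.fixed[:, 1],
        }
    ).to_csv(path, index=False)


def read_control_points(path) -> ControlPointSet:
    df = pd.read_csv(path)
    return ControlPointSet(
        moving=df[["moving_x", "moving_y"]].to_numpy(float),
        fixed=df[["fixed_x", "fixed_y"]].to_numpy(float),
        ids=[str(i) for i in df["point_id"]],
    )


def write_image_png(path, image: np.ndarray) -> None:
    """Write a float image in [0, 1] (or any range, rescaled) as 8-bit PNG."""
    img = np.asarray(image, dtype=float)
    lo, hi = float(img.min()), float(img.max())
    scaled = np.zeros_like(img) if hi == lo else (img - lo) / (hi - lo)
    Image.fromarray((scaled * 255).astype(np.uint8)).save(path)


def read_image_png(path) -> np.ndarray:
    return np.asarray(Image.open(path).convert("L"), dtype=float) / 255.0


def write_fusion_overlay(path, warped_histology: np.ndarray, t2: np.ndarray) -> None:
    """Two-channel fusion overlay: histology in red, T2 in green."""
    def norm(a):
        a = np.asarray(a, dtype=float)
        lo, hi = a.min(), a.max()
        return np.zeros_like(a) if hi == lo else (a - lo) / (hi - lo)

    rgb = np.stack(
        [norm(warped_histology), norm(t2), np.zeros_like(t2)], axis=-1
    )
    Image.fromarray((rgb * 255).astype(np.uint8)).save(path)


def write_parameter_maps(outdir, pmap: IVIMParameterMap, prefix: str = "ivim") -> list[Path]:
    """One NIfTI per parameter map (f, d, dstar, s0)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    affine = np.diag([pmap.pixel_size, pmap.pixel_size, 1.0, 1.0])
    paths = []
    for name in ("f", "d", "dstar", "s0"):
        p = outdir / f"{prefix}_{name}.nii"
        nib.save(nib.Nifti1Image(getattr(pmap, name).astype(np.float32), affine), p)
        paths.append(p)
    return paths


def write_roi_summaries(path, summaries) -> None:
    """Concatenate ROISummary tables to one CSV with columns
    roi,param,median,q1,q3,n_voxels."""
    pd.concat([s.table for s in summaries], ignore_index=True).to_csv(path, index=False)
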