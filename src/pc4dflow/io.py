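"""Readers and writers for the on-disk dataset layout.

A velocity dataset is three 4D NIfTI series (one per encoding axis:
``vel_x``, ``vel_y``, ``vel_z``; shape nx × ny × nz × nt, cm/s) plus a
JSON sidecar ``dataset.json`` with VENC and timing metadata::

    {"venc_cm_s": [150, 150, 150], "rr_interval_ms": 1000.0,
     "n_phases": 40, "description": "..."}

A single 5D NIfTI (nx × ny × nz × nt × 3, components last) is accepted
on read.  Planes, contours and background models are JSON; curves are
CSV with a footer metadata row.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .core import (
    AnalysisPlane,
    BackgroundModel,
    DatasetFormatError,
    FlowCurve,
    KECurve,
    Mask,
    MetadataError,
    VelocityField4D,
)

__all__ = [
    "read_velocity_dataset",
    "write_velocity_dataset",
    "read_mask",
    "write_mask",
    "read_plane",
    "write_plane",
    "read_contour",
    "write_contour",
    "read_background_model",
    "write_background_model",
    "write_flow_curve",
    "read_flow_curve",
    "write_ke_curve",
]

COMPONENT_NAMES = ("vel_x", "vel_y", "vel_z")
SIDECAR_NAME = "dataset.json"


def _check_affine_axis_aligned(affine: np.ndarray):
    if not np.allclose(affine[:3, :3], np.diag(np.diag(affine[:3, :3])), atol=1e-6):
        raise DatasetFormatError("only axis-aligned (diagonal) affines are supported")


def write_velocity_dataset(field: VelocityField4D, out_dir) -> dict[str, Path]:
    """Write a field as three 4D .nii.gz volumes plus a JSON sidecar.

    Returns a mapping of component/sidecar names to the written paths.
    ``read_velocity_dataset`` inverts this exactly.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    affine = field.affine
    paths: dict[str, Path] = {}
    for c, name in enumerate(COMPONENT_NAMES):
        img = nib.Nifti1Image(np.asarray(field.velocities[c], dtype=np.float64), affine)
        p = out / f"{name}.nii.gz"
        nib.save(img, p)
        paths[name] = p
    sidecar = {
        "venc_cm_s": [float(v) for v in field.venc],
        "rr_interval_ms": float(field.rr_interval),
        "n_phases": int(field.n_phases),
        "description": "pc4dflow velocity dataset (cm/s)",
    }
    sp = out / SIDECAR_NAME
    sp.write_text(json.dumps(sidecar, indent=2))
    paths["sidecar"] = sp
    return paths


def read_velocity_dataset(paths, sidecar=None) -> VelocityField4D:
    """Read a velocity dataset.

    ``paths`` may be a dataset directory, a sequence of the three
    component NIfTI files, or a single 5D NIfTI file.  ``sidecar``
    defaults to ``dataset.json`` next to the data.
    """
    if isinstance(paths, (str, Path)):
        p = Path(paths)
        if p.is_dir():
            component_paths = [p / f"{n}.nii.gz" for n in COMPONENT_NAMES]
            if not component_paths[0].exists():
                component_paths = [p / f"{n}.nii" for n in COMPONENT_NAMES]
            sidecar = sidecar or p / SIDECAR_NAME
            paths = component_paths
        else:
            sidecar = sidecar or p.parent / SIDECAR_NAME
            paths = [p]
    else:
        paths = [Path(q) for q in paths]
        if sidecar is None:
            sidecar = paths[0].parent / SIDECAR_NAME

    sidecar = Path(sidecar)
    if not sidecar.exists():
        raise MetadataError(f"sidecar not found: {sidecar}")
    meta = json.loads(sidecar.read_text())
    if "venc_cm_s" not in meta:
        raise MetadataError("sidecar is missing 'venc_cm_s'")
    if "rr_interval_ms" not in meta:
        raise MetadataError("sidecar is missing 'rr_interval_ms'")

    imgs = [nib.load(str(q)) for q in paths]
    if len(imgs) == 1 and imgs[0].ndim == 5:
        img = imgs[0]
        _check_affine_axis_aligned(img.affine)
        data = np.asarray(img.get_fdata(), dtype=float)
        if data.shape[4] != 3:
            raise DatasetFormatError(
                f"5D volume must have 3 components on the last axis; got {data.shape}"
            )
        vel = np.moveaxis(data, 4, 0)
        affine = img.affine
    elif len(imgs) == 3:
        shapes = {img.shape for img in imgs}
        if len(shapes) != 1:
            raise DatasetFormatError(f"component shapes differ: {sorted(shapes)}")
        for img in imgs[1:]:
            if not np.allclose(img.affine, imgs[0].affine, atol=1e-6):
                raise DatasetFormatError("component affines differ")
        _check_affine_axis_aligned(imgs[0].affine)
        arrs = [np.asarray(img.get_fdata(), dtype=float) for img in imgs]
        arrs = [a[..., np.newaxis] if a.ndim == 3 else a for a in arrs]
        if arrs[0].ndim != 4:
            raise DatasetFormatError("component volumes must be 4D (x, y, z, t)")
        vel = np.stack(arrs, axis=0)
        affine = imgs[0].affine
    else:
        raise DatasetFormatError(
            "expected three 4D component volumes or one 5D volume"
        )

    if "n_phases" in meta and int(meta["n_phases"]) != vel.shape[4]:
        raise DatasetFormatError(
            f"sidecar declares {meta['n_phases']} phases but data has {vel.shape[4]}"
        )
    return VelocityField4D(
        velocities=vel,
        voxel_spacing=np.diag(affine[:3, :3]).copy(),
        origin=affine[:3, 3].copy(),
        rr_interval=float(meta["rr_interval_ms"]),
        venc=np.asarray(meta["venc_cm_s"], dtype=float),
    )


def write_mask(mask: Mask, grid_like, path) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(mask.data.astype(np.uint8), grid_like.affine)
    img.header["descrip"] = mask.label.encode()[:79]
    nib.save(img, path)
    return path


def read_mask(path, label: str = "other") -> Mask:
    img = nib.load(str(path))
    return Mask(np.asarray(img.get_fdata()) > 0.5, label=label)


def write_plane(plane: AnalysisPlane, path) -> Path:
    path = Path(path)
    path.write_text(
        json.dumps(
            {
                "origin_mm": plane.origin.tolist(),
                "normal": plane.normal.tolist(),
                "in_plane_u": plane.in_plane_u.tolist(),
                "in_plane_v": plane.in_plane_v.tolist(),
                "pixel_spacing_mm": plane.pixel_spacing,
                "extent": list(plane.extent),
            },
            indent=2,
        )
    )
    return path


def read_plane(path) -> AnalysisPlane:
    d = json.loads(Path(path).read_text())
    return AnalysisPlane(
        origin=np.asarray(d["origin_mm"], dtype=float),
        normal=np.asarray(d["normal"], dtype=float),
        in_plane_u=np.asarray(d["in_plane_u"], dtype=float),
        in_plane_v=np.asarray(d["in_plane_v"], dtype=float),
        pixel_spacing=float(d["pixel_spacing_mm"]),
        extent=tuple(d["extent"]),
    )


def write_contour(contour, path) -> Path:
    path = Path(path)
    payload = {"vertices_mm": np.asarray(contour.vertices).tolist()}
    if contour.phase_vertices is not None:
        payload["phase_vertices_mm"] = [np.asarray(v).tolist() for v in contour.phase_vertices]
    path.write_text(json.dumps(payload, indent=2))
    return path


def read_contour(path):
    from .core import RoiContour

    d = json.loads(Path(path).read_text())
    pv = d.get("phase_vertices_mm")
    return RoiContour(
        np.asarray(d["vertices_mm"], dtype=float),
        phase_vertices=[np.asarray(v, dtype=float) for v in pv] if pv else None,
    )


def write_background_model(model: BackgroundModel, path) -> Path:
    path = Path(path)
    path.write_text(
        json.dumps(
            {
                "units": "a0 in cm/s; gradients in cm/s per mm (world frame)",
                "components": [
                    dict(zip(("a0", "ax", "ay", "az"), map(float, row)))
                    for row in model.coefficients
                ],
            },
            indent=2,
        )
    )
    return path


def read_background_model(path) -> BackgroundModel:
    d = json.loads(Path(path).read_text())
    coeff = [[c["a0"], c["ax"], c["ay"], c["az"]] for c in d["components"]]
    return BackgroundModel(np.asarray(coeff, dtype=float))


def write_flow_curve(curve: FlowCurve, path) -> Path:
    """CSV with phase_index, time_ms, flow_ml_s and a footer volume row."""
    path = Path(path)
    df = pd.DataFrame(
        {
            "phase_index": np.arange(curve.n_phases),
            "time_ms": curve.times,
            "flow_ml_s": curve.values,
        }
    )
    with open(path, "w") as fh:
        df.to_csv(fh, index=False)
        fh.write(f"# flow_volume_ml,{curve.flow_volume:.6f}\n")
        fh.write(f"# rr_interval_ms,{curve.rr_interval:.6f}\n")
    return path


def read_flow_curve(path) -> FlowCurve:
    path = Path(path)
    rr = None
    with open(path) as fh:
        lines = fh.readlines()
    for line in lines:
        if line.startswith("# rr_interval_ms"):
            rr = float(line.strip().split(",")[1])
    body = [ln for ln in lines if not ln.startswith("#")]
    df = pd.read_csv(pd.io.common.StringIO("".join(body)))
    if rr is None:
        raise MetadataError("flow curve CSV is missing the rr_interval_ms footer")
    return FlowCurve(values=df["flow_ml_s"].to_numpy(), rr_interval=rr)


def write_ke_curve(curve: KECurve, summary: dict | None, path) -> Path:
    path = Path(path)
    df = pd.DataFrame(
        {
            "phase_index": np.arange(curve.n_phases),
            "time_ms": curve.times,
            "ke_mJ": curve.values,
        }
    )
    with open(path, "w") as fh:
        df.to_csv(fh, index=False)
        fh.write(f"# density_g_ml,{curve.density:.4f}\n")
        if summary:
            for k, v in summary.items():
                fh.write(f"# {k},{v:.6f}\n")
    return path
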