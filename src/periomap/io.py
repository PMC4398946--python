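"""File I/O: NIfTI volumes, GIFTI surfaces/labels/maps, TSV tables.

Write-then-read is an identity for data and geometry. Interval-censored
p-value cells ("<1E-16") survive table round trips verbatim.
"""
from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from nibabel import gifti

from .core import GridSpec, VolumeSeries
from .synth import FIELD_NAMES, OTHER, FieldParcellation, SurfaceMesh


# ---------------------------------------------------------------------------
# NIfTI volumes


def write_volume(path, data: np.ndarray, grid: GridSpec, tr_s: float | None = None) -> None:
    """3D map or 4D series as NIfTI-1 with mm voxel sizes in the header."""
    img = nib.Nifti1Image(np.asarray(data), grid.affine)
    zooms = list(grid.voxel_size_mm)
    if data.ndim == 4:
        zooms.append(tr_s or 0.0)
        img.header.set_xyzt_units("mm", "sec")
    img.header.set_zooms(zooms)
    nib.save(img, str(path))


def read_volume(path) -> tuple[np.ndarray, GridSpec, float | None]:
    img = nib.load(str(path))
    aff = img.affine
    if not np.allclose(aff[:3, :3], np.diag(np.diag(aff[:3, :3]))):
        raise ValueError(f"{path}: affine is not axis-aligned (rotations unsupported)")
    vox = tuple(float(v) for v in np.diag(aff[:3, :3]))
    if any(v <= 0 for v in vox):
        raise ValueError(f"{path}: non-positive voxel sizes in affine")
    origin = tuple(float(o) for o in (aff[:3, 3] - 0.5 * np.asarray(vox)))
    data = np.asarray(img.dataobj, dtype=float)
    grid = GridSpec(shape=tuple(data.shape[:3]), voxel_size_mm=vox, origin_mm=origin)
    tr = float(img.header.get_zooms()[3]) if data.ndim == 4 else None
    return data, grid, tr


def write_series(path, series: VolumeSeries, dtype=None) -> None:
    data = series.data if dtype is None else series.data.astype(dtype)
    write_volume(path, data, series.grid, tr_s=series.tr_s)


def read_series(path) -> VolumeSeries:
    data, grid, tr = read_volume(path)
    if data.ndim != 4:
        raise ValueError(f"{path}: expected a 4D series")
    return VolumeSeries(data=data, grid=grid, tr_s=tr or 0.0)


# ---------------------------------------------------------------------------
# GIFTI surfaces


def write_mesh(path, mesh: SurfaceMesh) -> None:
    img = gifti.GiftiImage(
        darrays=[
            gifti.GiftiDataArray(
                mesh.vertices.astype(np.float32), intent="NIFTI_INTENT_POINTSET"
            ),
            gifti.GiftiDataArray(
                mesh.triangles.astype(np.int32), intent="NIFTI_INTENT_TRIANGLE"
            ),
        ]
    )
    img.meta["AnatomicalStructurePrimary"] = (
        "CortexLeft" if mesh.hemisphere == "left" else "CortexRight"
    )
    nib.save(img, str(path))


def read_mesh(path) -> SurfaceMesh:
    img = nib.load(str(path))
    verts = tris = None
    for da in img.darrays:
        if da.intent == nib.nifti1.intent_codes["NIFTI_INTENT_POINTSET"]:
            verts = np.asarray(da.data, dtype=float)
        elif da.intent == nib.nifti1.intent_codes["NIFTI_INTENT_TRIANGLE"]:
            tris = np.asarray(da.data, dtype=int)
    if verts is None or tris is None:
        raise ValueError(f"{path}: missing POINTSET or TRIANGLE array")
    hemi = "right" if img.meta.get("AnatomicalStructurePrimary") == "CortexRight" else "left"
    return SurfaceMesh(vertices=verts, triangles=tris, hemisphere=hemi)


def write_labels(path, parcellation: FieldParcellation) -> None:
    """Parcellation as a GIFTI label file with a label table."""
    names = [OTHER] + list(parcellation.field_names)
    keys = {name: i for i, name in enumerate(names)}
    data = np.asarray([keys[lab] for lab in parcellation.labels], dtype=np.int32)
    table = gifti.GiftiLabelTable()
    for name, key in keys.items():
        lab = gifti.GiftiLabel(key=key)
        lab.label = name
        table.labels.append(lab)
    img = gifti.GiftiImage(labeltable=table)
    img.add_gifti_data_array(
        gifti.GiftiDataArray(data, intent="NIFTI_INTENT_LABEL", datatype="NIFTI_TYPE_INT32")
    )
    nib.save(img, str(path))


def read_labels(path) -> FieldParcellation:
    img = nib.load(str(path))
    table = img.labeltable.get_labels_as_dict()
    data = np.asarray(img.darrays[0].data, dtype=int)
    labels = np.asarray([table[k] for k in data], dtype="U8")
    names = tuple(n for n in FIELD_NAMES if n in set(table.values()))
    return FieldParcellation(labels=labels, field_names=names or FIELD_NAMES)


def write_vertex_map(path, values: np.ndarray) -> None:
    """Per-vertex scalar map as a GIFTI functional file."""
    img = gifti.GiftiImage(
        darrays=[
            gifti.GiftiDataArray(
                np.asarray(values, dtype=np.float32), intent="NIFTI_INTENT_NONE"
            )
        ]
    )
    nib.save(img, str(path))


def read_vertex_map(path) -> np.ndarray:
    img = nib.load(str(path))
    return np.asarray(img.darrays[0].data, dtype=float)


# ---------------------------------------------------------------------------
# TSV tables


def write_table(path, table: pd.DataFrame) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    """Read a TSV keeping censored cells ("<1E-16") as strings.

    Numeric columns are converted; columns containing censored values stay
    object-typed so re-serialisation is byte-identical.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in df.columns:
        ser = df[col]
        if (ser.str.startswith("<")).any():
            continue
        converted = pd.to_numeric(ser.replace("", np.nan), errors="coerce")
        if converted.notna().sum() >= ser.replace("", np.nan).notna().sum():
            df[col] = converted
    return df


def censored_value(cell) -> tuple[float, bool]:
    """Parse a possibly censored table cell to (bound, is_censored)."""
    if isinstance(cell, str) and cell.startswith("<"):
        return float(cell[1:]), True
    return float(cell), False
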