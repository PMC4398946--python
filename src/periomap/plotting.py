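"""Minimal surface-map rendering: flat maps with gradient arrows."""
from __future__ import annotations

import numpy as np

from .gradients import flatten_field
from .synth import FieldParcellation, SurfaceMesh, sheet_uv


def plot_vertex_map(mesh: SurfaceMesh, values, ax=None, cmap="RdBu_r", **kwargs):
    """Scatter a per-vertex map on the flattened sheet (u anterior, v lateral)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    uv = sheet_uv(mesh)
    sc = ax.scatter(uv[:, 0], uv[:, 1], c=np.asarray(values, float), s=12, cmap=cmap, **kwargs)
    ax.set_xlabel("u (anterior, mm)")
    ax.set_ylabel("v (lateral, mm)")
    ax.set_aspect("equal")
    return sc


def plot_gradient_arrow(
    mesh: SurfaceMesh,
    parcellation: FieldParcellation,
    field_id: str,
    direction_deg: float,
    ax,
    length_mm: float = 4.0,
    **kwargs,
):
    """Arrow at a field's centre of mass pointing along a fitted gradient."""
    coords = flatten_field(mesh, parcellation, field_id)
    uv = sheet_uv(mesh)[coords.vertex_indices]
    cx, cy = uv.mean(axis=0)
    th = np.radians(direction_deg)
    ax.annotate(
        "", xy=(cx + length_mm * np.cos(th), cy + length_mm * np.sin(th)),
        xytext=(cx, cy), arrowprops={"arrowstyle": "->", "color": kwargs.pop("color", "green")},
    )
    ax.plot([cx], [cy], "o", ms=4, mfc="none", mec="green")
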