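"""Volume-to-surface projection by local sphere sampling.

Each surface vertex receives the data of the in-mask voxels whose centres
lie within a 1.6 mm sphere around it — a mean for scalar maps, a majority
vote for label maps. Projection is done after masking so baseline-only
voxels never dilute vertex values; vertices with no qualifying voxel are
reported missing (NaN for scalars, -1 for labels).
"""
from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

from .core import GridSpec
from .maps import NO_LABEL
from .synth import SurfaceMesh


def _sphere_members(grid: GridSpec, mesh: SurfaceMesh, radius_mm: float, mask):
    if radius_mm <= 0:
        raise ValueError("projection radius must be positive")
    centres = grid.voxel_centres()
    flat_mask = np.ones(grid.n_voxels, bool) if mask is None else np.asarray(mask, bool).ravel()
    keep = np.flatnonzero(flat_mask)
    tree = cKDTree(centres[keep])
    groups = tree.query_ball_point(mesh.vertices, r=radius_mm)
    return [keep[g] for g in groups]


def project_scalar(
    volume_map: np.ndarray,
    grid: GridSpec,
    mesh: SurfaceMesh,
    radius_mm: float = 1.6,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Mean of in-mask voxel values within ``radius_mm`` of each vertex."""
    flat = np.asarray(volume_map, dtype=float).ravel()
    out = np.full(mesh.n_vertices, np.nan)
    for i, members in enumerate(_sphere_members(grid, mesh, radius_mm, mask)):
        vals = flat[members]
        vals = vals[np.isfinite(vals)]
        if vals.size:
            out[i] = vals.mean()
    return out


def project_label(
    label_map: np.ndarray,
    grid: GridSpec,
    mesh: SurfaceMesh,
    radius_mm: float = 1.6,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Majority vote among enclosed voxel labels; ties go to the lower label.

    Labels are condition indices (ascending stimulus value), so the tie
    rule matches the best-map convention. ``NO_LABEL`` voxels do not vote.
    """
    flat = np.asarray(label_map).ravel()
    out = np.full(mesh.n_vertices, NO_LABEL, dtype=int)
    for i, members in enumerate(_sphere_members(grid, mesh, radius_mm, mask)):
        vals = flat[members]
        vals = vals[vals != NO_LABEL]
        if vals.size == 0:
            continue
        labels, counts = np.unique(vals, return_counts=True)  # ascending labels
        out[i] = labels[np.argmax(counts)]  # first max -> lowest label wins ties
    return out
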