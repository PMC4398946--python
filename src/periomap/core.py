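"""Shared containers: voxel grids, volume series, stimulus schedules.

Conventions used throughout the package (stated once, here):

* world coordinates are in mm, right handed, with +x = anterior and
  +y = lateral on the left hemisphere (right hemispheres are mirrored,
  so +y = medial there);
* voxel indexing is 0-based and a voxel's centre sits at
  ``origin + (index + 0.5) * voxel_size``;
* sphere membership (surface projection, tuning inheritance) is decided
  by voxel-centre distance.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: schedule label of the silent-baseline volumes
BASELINE = "baseline"


@dataclass(frozen=True)
class GridSpec:
    """Regular 3D voxel grid in mm world coordinates."""

    shape: tuple[int, int, int]
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(s) < 1 for s in self.shape):
            raise ValueError(f"grid shape must be three positive ints, got {self.shape}")
        if any(v <= 0 for v in self.voxel_size_mm):
            raise ValueError(f"voxel size must be positive, got {self.voxel_size_mm}")

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    def voxel_centres(self) -> np.ndarray:
        """(n_voxels, 3) array of voxel-centre world coordinates (C order)."""
        idx = np.indices(self.shape).reshape(3, -1).T
        return np.asarray(self.origin_mm) + (idx + 0.5) * np.asarray(self.voxel_size_mm)

    @property
    def affine(self) -> np.ndarray:
        """NIfTI-style affine mapping voxel indices to centre coordinates."""
        aff = np.diag(list(self.voxel_size_mm) + [1.0])
        aff[:3, 3] = np.asarray(self.origin_mm) + 0.5 * np.asarray(self.voxel_size_mm)
        return aff


@dataclass
class VolumeSeries:
    """4D BOLD series: ``data[x, y, z, t]`` on a :class:`GridSpec`.

    ``tr_s`` is the volume repetition time; ``ta_s`` the acquisition time
    within it (sparse designs leave a silent gap of ``tr_s - ta_s``).
    """

    data: np.ndarray
    grid: GridSpec
    tr_s: float
    ta_s: float | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("VolumeSeries data must be 4D (x, y, z, t)")
        if tuple(self.data.shape[:3]) != tuple(self.grid.shape):
            raise ValueError(
                f"data shape {self.data.shape[:3]} does not match grid {self.grid.shape}"
            )

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    def with_data(self, data: np.ndarray) -> "VolumeSeries":
        return VolumeSeries(data=data, grid=self.grid, tr_s=self.tr_s, ta_s=self.ta_s)


@dataclass
class StimulusSchedule:
    """Per-volume condition labels for a sparse design.

    ``condition_order`` fixes the (low-to-high stimulus value) ordering used
    for design-matrix columns and deterministic tie-breaking downstream.
    """

    labels: tuple[str, ...]
    condition_order: tuple[str, ...]
    tr_s: float = 10.0
    ta_s: float = 1.0

    def __post_init__(self) -> None:
        self.labels = tuple(self.labels)
        self.condition_order = tuple(self.condition_order)
        if not self.labels:
            raise ValueError("schedule is empty")
        present = set(self.labels)
        if BASELINE not in present:
            raise ValueError("schedule has no baseline volumes")
        if not (present - {BASELINE}):
            raise ValueError("schedule has no stimulus volumes")
        unknown = present - {BASELINE} - set(self.condition_order)
        if unknown:
            raise ValueError(f"labels not in condition_order: {sorted(unknown)}")

    @property
    def n_volumes(self) -> int:
        return len(self.labels)

    @property
    def conditions(self) -> tuple[str, ...]:
        """Conditions actually present, in ``condition_order``."""
        present = set(self.labels)
        return tuple(c for c in self.condition_order if c in present)

    def indicator(self, condition: str) -> np.ndarray:
        return np.asarray([lab == condition for lab in self.labels], dtype=float)

    def volume_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for lab in self.labels:
            counts[lab] = counts.get(lab, 0) + 1
        return counts


def condition_value(label: str) -> float:
    """Numeric stimulus value encoded in a condition label.

    Rate labels are plain numbers in Hz ("0.5", "32"); frequency-band labels
    are "lo-hi" in Hz ("500-1000") and map to the band's geometric centre.
    """
    if "-" in label:
        lo, hi = label.split("-")
        return float(np.sqrt(float(lo) * float(hi)))
    return float(label)
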