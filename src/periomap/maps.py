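"""Contrast maps and best-rate / best-frequency maps derived from GLM results.

The contrast map expresses preference polarity as the difference of mean
regression coefficients between a high and a low stimulus set (high minus
low; the sets used are recorded in the provenance so plots can flip the
sign without ambiguity). The best map is the voxelwise argmax of the
t-statistics across conditions. The two deliberately use different
statistics — betas for contrasts, t-values for winners — and both are kept.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import condition_value
from .glm import StatMaps

#: integer label for voxels outside the mask / with no defined winner
NO_LABEL = -1


@dataclass
class ContrastMap:
    """Signed voxel map (percent units) with its low/high provenance."""

    data: np.ndarray
    low_set: tuple[str, ...]
    high_set: tuple[str, ...]
    provenance: dict = field(default_factory=dict)


@dataclass
class BestMap:
    """Winning-condition index per voxel (NO_LABEL outside the mask)."""

    labels: np.ndarray  # int volume of condition indices
    condition_order: tuple[str, ...]

    def label_name(self, index: int) -> str:
        return self.condition_order[index]

    def label_dictionary(self) -> dict[int, str]:
        d = {i: c for i, c in enumerate(self.condition_order)}
        d[NO_LABEL] = "none"
        return d


def contrast_map(
    statmaps: StatMaps,
    low_set,
    high_set,
    mask: np.ndarray | None = None,
) -> ContrastMap:
    """``mean(beta over high_set) - mean(beta over low_set)`` per voxel.

    For the rate experiment the two lowest (0.5, 2 Hz) and two highest
    (128, 512 Hz) rates are averaged before subtracting; the frequency
    experiment contrasts the single high band against the single low band.
    Intermediate conditions are ignored. Voxels outside ``mask`` are NaN.
    """
    low_set = tuple(low_set)
    high_set = tuple(high_set)
    if not low_set or not high_set:
        raise ValueError("low and high sets must be non-empty")
    if set(low_set) & set(high_set):
        raise ValueError("low and high sets overlap")
    for c in low_set + high_set:
        if c not in statmaps.condition_order:
            raise ValueError(f"unknown condition {c!r}")
    high = np.mean([statmaps.betas[c] for c in high_set], axis=0)
    low = np.mean([statmaps.betas[c] for c in low_set], axis=0)
    data = high - low
    if mask is not None:
        data = np.where(mask, data, np.nan)
    return ContrastMap(
        data=data,
        low_set=low_set,
        high_set=high_set,
        provenance={"sign": "high-minus-low", "low": low_set, "high": high_set},
    )


def best_map(statmaps: StatMaps, mask: np.ndarray | None = None) -> BestMap:
    """Voxelwise argmax of condition t-values inside the mask.

    Conditions are scanned in ascending stimulus-value order, and ties on
    the maximal t go to the lower condition value (deterministic). Voxels
    where no finite winner exists are flagged ``NO_LABEL``.
    """
    order = sorted(statmaps.condition_order, key=condition_value)
    t = np.stack([statmaps.tvalues[c] for c in order], axis=0)
    finite_any = np.isfinite(t).any(axis=0)
    t_safe = np.where(np.isfinite(t), t, -np.inf)
    winner = np.argmax(t_safe, axis=0)  # first (= lowest-value) max wins ties
    labels = np.where(finite_any, winner, NO_LABEL)
    if mask is not None:
        labels = np.where(mask, labels, NO_LABEL)
    return BestMap(labels=labels.astype(int), condition_order=tuple(order))
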