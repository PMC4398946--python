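"""Sparse-design preprocessing and mass-univariate GLM.

Preprocessing follows the standard sparse-sampling recipe: 3D Gaussian
smoothing, global scaling of every volume to an in-brain mean of 100 (so
regression coefficients read as percent signal change), and slow-drift
removal via discrete-cosine regressors inside the design rather than
pre-filtering, which keeps the degrees of freedom exact.

Estimation is ordinary least squares per voxel, vectorised across the
grid; the silent baseline is the implicit intercept, so each condition
coefficient is directly the stimulus-vs-baseline effect, and the omnibus
F statistic tests all condition coefficients jointly.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats

from .core import BASELINE, GridSpec, StimulusSchedule, VolumeSeries

_FWHM_TO_SD = 2.0 * math.sqrt(2.0 * math.log(2.0))


def smooth_volumes(series: VolumeSeries, fwhm_mm: float) -> VolumeSeries:
    """Per-volume 3D Gaussian smoothing with the kernel given as FWHM in mm."""
    if fwhm_mm < 0:
        raise ValueError("fwhm must be non-negative")
    if fwhm_mm == 0:
        return series.with_data(series.data.copy())
    sigma_vox = [fwhm_mm / _FWHM_TO_SD / v for v in series.grid.voxel_size_mm]
    out = ndimage.gaussian_filter(series.data, sigma=sigma_vox + [0.0], mode="nearest")
    return series.with_data(out)


def in_brain_mask(data: np.ndarray, fraction: float = 0.125) -> np.ndarray:
    """Voxels whose temporal mean exceeds ``fraction`` of the grand mean."""
    tmean = data.mean(axis=-1)
    return tmean > fraction * tmean.mean()


def global_scale(series: VolumeSeries, target: float = 100.0) -> VolumeSeries:
    """Rescale each volume so its in-brain mean equals ``target``."""
    mask = in_brain_mask(series.data)
    if not mask.any():
        raise ValueError("no in-brain voxels found for global scaling")
    means = series.data[mask].mean(axis=0)
    if np.any(means <= 0):
        raise ValueError("non-positive global mean; cannot scale")
    return series.with_data(series.data * (target / means))


@dataclass
class DesignMatrix:
    """GLM design: condition indicators + DCT drift + constant."""

    matrix: np.ndarray
    columns: tuple[str, ...]
    condition_columns: tuple[str, ...]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape[1] != len(self.columns):
            raise ValueError("column names do not match matrix width")
        rank = np.linalg.matrix_rank(self.matrix)
        if rank < self.matrix.shape[1]:
            raise ValueError(self._collinearity_message())

    def _collinearity_message(self) -> str:
        bad = []
        for j in range(self.matrix.shape[1]):
            others = np.delete(self.matrix, j, axis=1)
            proj, *_ = np.linalg.lstsq(others, self.matrix[:, j], rcond=None)
            resid = self.matrix[:, j] - others @ proj
            if np.linalg.norm(resid) < 1e-8 * max(1.0, np.linalg.norm(self.matrix[:, j])):
                bad.append(self.columns[j])
        return f"design matrix is rank deficient; collinear columns: {bad}"

    @property
    def n_volumes(self) -> int:
        return self.matrix.shape[0]

    def column_index(self, name: str) -> int:
        return self.columns.index(name)


def dct_drift_basis(n_volumes: int, tr_s: float, cutoff_s: float) -> np.ndarray:
    """Discrete-cosine drift regressors with periods longer than ``cutoff_s``.

    Basis function k has period ``2 * n * TR / k``; the number of retained
    regressors is ``floor(2 * n * TR / cutoff)``.
    """
    if cutoff_s <= 0:
        raise ValueError("cutoff must be positive")
    n = n_volumes
    n_basis = int(math.floor(2.0 * n * tr_s / cutoff_s))
    t = np.arange(n)
    cols = [
        math.sqrt(2.0 / n) * np.cos(math.pi * k * (2 * t + 1) / (2.0 * n))
        for k in range(1, n_basis + 1)
    ]
    return np.column_stack(cols) if cols else np.empty((n, 0))


def build_design(schedule: StimulusSchedule, highpass_cutoff_s: float = 300.0) -> DesignMatrix:
    """Condition indicators (baseline implicit in the constant) + drift + constant."""
    conditions = schedule.conditions
    cols = [schedule.indicator(c) for c in conditions]
    names = list(conditions)
    drift = dct_drift_basis(schedule.n_volumes, schedule.tr_s, highpass_cutoff_s)
    for k in range(drift.shape[1]):
        cols.append(drift[:, k])
        names.append(f"drift_{k + 1}")
    cols.append(np.ones(schedule.n_volumes))
    names.append("constant")
    return DesignMatrix(
        matrix=np.column_stack(cols),
        columns=tuple(names),
        condition_columns=conditions,
    )


@dataclass
class StatMaps:
    """Per-voxel GLM results: betas, t, omnibus F and the significance mask.

    This is the results object of :class:`SparseGLM`; ``betas``/``tvalues``
    map condition name to a 3D volume in the units of the (scaled) series.
    """

    betas: dict[str, np.ndarray]
    tvalues: dict[str, np.ndarray]
    fvalues: np.ndarray
    fpvalues: np.ndarray
    df_num: int
    df_resid: int
    grid: GridSpec
    condition_order: tuple[str, ...]
    valid: np.ndarray  # voxels with positive residual variance

    def summary(self) -> str:
        lines = [
            "Sparse-design GLM results",
            f"  grid: {self.grid.shape}, {int(self.valid.sum())} valid voxels",
            f"  omnibus F df: ({self.df_num}, {self.df_resid})",
            f"  conditions: {', '.join(self.condition_order)}",
        ]
        for c in self.condition_order:
            b = self.betas[c][self.valid]
            lines.append(f"  beta[{c:>12}]: mean {b.mean():+.4f}  max {b.max():+.4f}")
        return "\n".join(lines)


class SparseGLM:
    """Mass-univariate OLS of a volume series against a design matrix.

    Mirrors the statsmodels model/results split: construct from data,
    call :meth:`fit` to obtain :class:`StatMaps`.
    """

    def __init__(self, series: VolumeSeries, design: DesignMatrix):
        if series.n_volumes != design.n_volumes:
            raise ValueError("series and design have different numbers of volumes")
        self.series = series
        self.design = design

    def fit(self) -> StatMaps:
        X = self.design.matrix
        n, p = X.shape
        Y = self.series.data.reshape(-1, n).T  # (n, voxels)
        pinvX = np.linalg.pinv(X)
        beta = pinvX @ Y
        resid = Y - X @ beta
        rank = np.linalg.matrix_rank(X)
        if rank < p:
            raise ValueError("singular design matrix")
        df_resid = n - rank
        rss = np.einsum("ij,ij->j", resid, resid)
        sigma2 = rss / df_resid
        xtx_inv = np.linalg.pinv(X.T @ X)

        scale = np.maximum(np.einsum("ij,ij->j", Y, Y) / n, 1e-30)
        zero_var = sigma2 <= 1e-18 * scale
        valid = ~zero_var

        cond_idx = [self.design.column_index(c) for c in self.design.condition_columns]
        shape3 = self.series.grid.shape
        betas: dict[str, np.ndarray] = {}
        tvals: dict[str, np.ndarray] = {}
        with np.errstate(divide="ignore", invalid="ignore"):
            for c, j in zip(self.design.condition_columns, cond_idx):
                se = np.sqrt(sigma2 * xtx_inv[j, j])
                t = np.where(se > 0, beta[j] / np.where(se > 0, se, 1.0), np.nan)
                betas[c] = beta[j].reshape(shape3)
                tvals[c] = t.reshape(shape3)

            C = np.zeros((len(cond_idx), p))
            for r, j in enumerate(cond_idx):
                C[r, j] = 1.0
            M = np.linalg.inv(C @ xtx_inv @ C.T)
            bc = beta[cond_idx]  # (q, voxels)
            num = np.einsum("qv,qr,rv->v", bc, M, bc) / len(cond_idx)
            F = np.where(valid, num / np.where(valid, sigma2, 1.0), np.nan)
        # exact-fit voxels: infinite evidence if any condition effect, else undefined
        effect = np.einsum("qv,qv->v", bc, bc) > 1e-12 * scale
        F[zero_var & effect] = np.inf
        F[zero_var & ~effect] = np.nan
        pvals = stats.f.sf(F, len(cond_idx), df_resid)
        pvals[np.isnan(F)] = np.nan
        pvals[np.isinf(F)] = 0.0

        return StatMaps(
            betas=betas,
            tvalues=tvals,
            fvalues=F.reshape(shape3),
            fpvalues=pvals.reshape(shape3),
            df_num=len(cond_idx),
            df_resid=df_resid,
            grid=self.series.grid,
            condition_order=self.design.condition_columns,
            valid=valid.reshape(shape3),
        )


def fit_glm(series: VolumeSeries, design: DesignMatrix) -> StatMaps:
    """OLS betas / t-values per condition vs baseline plus omnibus F."""
    return SparseGLM(series, design).fit()


def omnibus_mask(statmaps: StatMaps, alpha: float = 0.001, correction: str = "none") -> np.ndarray:
    """Boolean mask of voxels whose omnibus stimuli-vs-baseline F passes ``alpha``.

    ``correction='bonferroni'`` divides alpha by the number of testable
    voxels (family-wise error over the recorded volume). Voxels with
    undefined variance never pass.
    """
    if not (0.0 < alpha <= 1.0):
        raise ValueError("alpha must be in (0, 1]")
    if correction not in ("none", "bonferroni"):
        raise ValueError(f"unknown correction {correction!r}")
    p = statmaps.fpvalues
    testable = ~np.isnan(p)
    thr = alpha / testable.sum() if correction == "bonferroni" else alpha
    if thr >= 1.0:
        return testable
    return testable & (p < thr)
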