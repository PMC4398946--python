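"""Per-field 2D gradient regression, relative angles, and summary tables.

For each auditory field the surface map values are regressed on the
flattened spatial coordinates,

    value = b0 + bu * u + bv * v,

giving the main gradient direction ``atan2(bv, bu)`` (degrees, measured
from the anterior axis toward lateral, full [0, 360) so the sign of
increase matters), its magnitude, the coefficient of determination R**2,
and the p-value of the F-test of (bu, bv) jointly zero with (2, n - 3)
degrees of freedom.

The relative angle between the rate and frequency gradients of a field is
folded into [0, 180]; ~90 means orthogonal, ~180 anti-parallel. Tables
aggregate per-(animal, hemisphere, field) rows with Average and Std-dev
rows computed as plain arithmetic means and sample standard deviations.
Right-hemisphere coordinates are mirrored before fitting so the lateral
axis — and hence the reported angles — are comparable across hemispheres.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .synth import FieldParcellation, SurfaceMesh

#: p-values below this are printed interval-censored, "<1E-16"
P_FLOOR = 1e-16


@dataclass
class FlatCoords:
    """Planar (u, v) mm coordinates of one field's vertices.

    +u = anterior, +v = lateral (after hemisphere mirroring).
    """

    u: np.ndarray
    v: np.ndarray
    vertex_indices: np.ndarray

    @property
    def n(self) -> int:
        return len(self.u)


def flatten_field(
    mesh: SurfaceMesh,
    parcellation: FieldParcellation,
    field_id: str,
    hemisphere: str | None = None,
) -> FlatCoords:
    """Project a field's vertices onto its best-fit (principal-axes) plane.

    The plane's axes are rotated so +u is the in-plane anterior direction
    and +v the in-plane lateral direction; right-hemisphere v is negated so
    lateral is consistent across hemispheres.
    """
    hemisphere = hemisphere or mesh.hemisphere
    idx = parcellation.vertices_of(field_id)
    if idx.size < 4:
        raise ValueError(f"field {field_id!r} has fewer than 4 vertices")
    pts = mesh.vertices[idx]
    centred = pts - pts.mean(axis=0)
    _, svals, vt = np.linalg.svd(centred, full_matrices=False)
    if svals[1] < 1e-9 * max(svals[0], 1.0):
        raise ValueError(f"field {field_id!r} is degenerate (collinear vertices)")
    e1, e2 = vt[0], vt[1]  # in-plane orthonormal basis

    def _in_plane(world_axis: np.ndarray) -> np.ndarray:
        w = (world_axis @ e1) * e1 + (world_axis @ e2) * e2
        nrm = np.linalg.norm(w)
        if nrm < 1e-9:
            raise ValueError("anatomical axis is orthogonal to the field plane")
        return w / nrm

    u_axis = _in_plane(np.array([1.0, 0.0, 0.0]))  # anterior
    lateral_world = np.array([0.0, 1.0, 0.0]) if hemisphere == "left" else np.array([0.0, -1.0, 0.0])
    v_axis = lateral_world - (lateral_world @ u_axis) * u_axis
    v_axis = _in_plane(v_axis / np.linalg.norm(v_axis))
    return FlatCoords(u=centred @ u_axis, v=centred @ v_axis, vertex_indices=idx)


@dataclass
class GradientResults:
    """Fitted planar gradient of one map over one field."""

    direction_deg: float  # NaN when the fitted gradient has zero magnitude
    magnitude: float  # map units per mm
    r2: float
    pvalue: float
    n: int
    coef: tuple[float, float, float]  # (b0, bu, bv)
    ordinal: bool = False

    def summary(self) -> str:
        d = "missing" if np.isnan(self.direction_deg) else f"{self.direction_deg:6.1f} deg"
        p = format_pvalue(self.pvalue)
        kind = "ordinal " if self.ordinal else ""
        return (
            f"2D {kind}gradient fit: direction {d}, "
            f"|grad| {self.magnitude:.4g}/mm, R2 {self.r2:.3f}, p {p}, n {self.n}"
        )


class GradientOLS:
    """Least-squares planar fit of map values on flattened coordinates."""

    def __init__(self, coords: FlatCoords, values: np.ndarray, ordinal: bool = False):
        values = np.asarray(values, dtype=float)
        if len(values) != coords.n:
            raise ValueError("values and coordinates differ in length")
        ok = np.isfinite(values)
        if ok.sum() < 4:
            raise ValueError("need at least 4 non-missing vertices")
        self.u = coords.u[ok]
        self.v = coords.v[ok]
        self.values = values[ok]
        self.ordinal = ordinal

    def fit(self) -> GradientResults:
        n = len(self.values)
        X = np.column_stack([np.ones(n), self.u, self.v])
        beta, *_ = np.linalg.lstsq(X, self.values, rcond=None)
        fitted = X @ beta
        rss = float(np.sum((self.values - fitted) ** 2))
        tss = float(np.sum((self.values - self.values.mean()) ** 2))
        bu, bv = float(beta[1]), float(beta[2])
        magnitude = float(np.hypot(bu, bv))
        if tss <= 0 or magnitude < 1e-12:
            return GradientResults(
                direction_deg=np.nan, magnitude=0.0, r2=0.0, pvalue=1.0, n=n,
                coef=(float(beta[0]), bu, bv), ordinal=self.ordinal,
            )
        r2 = 1.0 - rss / tss
        df_resid = n - 3
        if rss <= 1e-18 * tss:
            pvalue = 0.0
        else:
            f = (r2 / 2.0) / ((1.0 - r2) / df_resid)
            pvalue = float(stats.f.sf(f, 2, df_resid))
        direction = float(np.degrees(np.arctan2(bv, bu)) % 360.0)
        return GradientResults(
            direction_deg=direction, magnitude=magnitude, r2=float(r2),
            pvalue=pvalue, n=n, coef=(float(beta[0]), bu, bv), ordinal=self.ordinal,
        )


def fit_gradient(coords: FlatCoords, values: np.ndarray) -> GradientResults:
    """Planar gradient of ``values`` over ``coords`` (see :class:`GradientOLS`)."""
    return GradientOLS(coords, values).fit()


def best_map_gradients(
    best_map_vertices: np.ndarray, coords: FlatCoords, no_label: int = -1
) -> GradientResults:
    """Gradient of a best-map, using ordinal condition ranks as values.

    Fields that feature a single best condition carry no spatial order, so
    no gradient can be specified and an error is raised.
    """
    vals = np.asarray(best_map_vertices, dtype=float)
    vals[vals == no_label] = np.nan
    present = np.unique(vals[np.isfinite(vals)])
    if present.size <= 1:
        raise ValueError("single-label field: no gradient can be specified")
    return GradientOLS(coords, vals, ordinal=True).fit()


def relative_angle(dir1_deg: float, dir2_deg: float) -> float:
    """Angle between two gradient directions, folded into [0, 180]."""
    if np.isnan(dir1_deg) or np.isnan(dir2_deg):
        return np.nan
    a = abs(float(dir1_deg) - float(dir2_deg)) % 360.0
    return min(a, 360.0 - a)


def format_pvalue(p: float) -> str:
    if np.isnan(p):
        return "NA"
    if p < P_FLOOR:
        return "<1E-16"
    return f"{p:.2E}"


# ---------------------------------------------------------------------------
# Table aggregation

TABLE_COLUMNS = (
    "animal", "hemisphere", "field", "alpha_deg",
    "freq_direction_deg", "freq_r2", "freq_p",
    "rate_direction_deg", "rate_r2", "rate_p", "n",
)
_NUMERIC = (
    "alpha_deg", "freq_direction_deg", "freq_r2",
    "rate_direction_deg", "rate_r2", "n",
)


@dataclass
class FieldDataset:
    """One hemisphere's surface data entering the gradient table."""

    mesh: SurfaceMesh
    parcellation: FieldParcellation
    rate_values: np.ndarray  # rate-contrast map on vertices
    freq_values: np.ndarray  # frequency-contrast map on vertices
    hemisphere: str | None = None


def field_gradient_table(
    datasets: dict[tuple[str, str], FieldDataset],
    fields=("A1", "R", "CL"),
) -> pd.DataFrame:
    """One row per (animal, hemisphere, field): both fits and their angle.

    ``datasets`` maps (animal, hemisphere) to that hemisphere's surface and
    projected contrast maps. Average / Std-dev rows per field are appended
    by :func:`append_field_summary`. Fields that cannot be fitted are
    skipped with a warning.
    """
    rows = []
    for (animal, hemi), ds in datasets.items():
        for fid in fields:
            try:
                coords = flatten_field(ds.mesh, ds.parcellation, fid, ds.hemisphere or hemi_name(hemi))
                freq_fit = fit_gradient(coords, ds.freq_values[coords.vertex_indices])
                rate_fit = fit_gradient(coords, ds.rate_values[coords.vertex_indices])
            except ValueError as err:
                warnings.warn(f"skipping field {fid!r} for ({animal}, {hemi}): {err}")
                continue
            rows.append(
                {
                    "animal": animal,
                    "hemisphere": hemi,
                    "field": fid,
                    "alpha_deg": relative_angle(freq_fit.direction_deg, rate_fit.direction_deg),
                    "freq_direction_deg": freq_fit.direction_deg,
                    "freq_r2": freq_fit.r2,
                    "freq_p": freq_fit.pvalue,
                    "rate_direction_deg": rate_fit.direction_deg,
                    "rate_r2": rate_fit.r2,
                    "rate_p": rate_fit.pvalue,
                    "n": freq_fit.n,
                }
            )
    return pd.DataFrame(rows, columns=list(TABLE_COLUMNS))


def hemi_name(h: str) -> str:
    return {"L": "left", "R": "right"}.get(h, h)


def summarize_values(values) -> tuple[float, float]:
    """Plain mean and sample SD (ddof=1); SD is NaN for a single value.

    Angle columns use plain (not circular) arithmetic, matching how the
    field reports table averages of printed directions.
    """
    arr = np.asarray([v for v in values if np.isfinite(v)], dtype=float)
    if arr.size == 0:
        return np.nan, np.nan
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1)) if arr.size > 1 else np.nan
    return mean, sd


def append_field_summary(table: pd.DataFrame, fields=None) -> pd.DataFrame:
    """Append per-field Average and Std-dev rows over the member rows."""
    fields = fields or list(dict.fromkeys(table["field"]))
    out = []
    for fid in fields:
        members = table[table["field"] == fid]
        if members.empty:
            continue
        out.append(members)
        avg = {"animal": "Average", "hemisphere": "", "field": fid}
        sd = {"animal": "Std dev", "hemisphere": "", "field": fid}
        for col in _NUMERIC:
            m, s = summarize_values(members[col])
            avg[col] = m
            sd[col] = s
        avg["freq_p"] = np.nan
        avg["rate_p"] = np.nan
        sd["freq_p"] = np.nan
        sd["rate_p"] = np.nan
        out.append(pd.DataFrame([avg, sd], columns=list(TABLE_COLUMNS)))
    return pd.concat(out, ignore_index=True)


def format_summary_table(table: pd.DataFrame) -> pd.DataFrame:
    """Human-readable formatting: 1 decimal for degrees, 2 for R**2."""
    out = table.copy()
    for col in ("alpha_deg", "freq_direction_deg", "rate_direction_deg"):
        out[col] = out[col].map(lambda x: "" if pd.isna(x) else f"{x:.1f}")
    for col in ("freq_r2", "rate_r2"):
        out[col] = out[col].map(lambda x: "" if pd.isna(x) else f"{x:.2f}")
    for col in ("freq_p", "rate_p"):
        out[col] = out[col].map(lambda x: "" if pd.isna(x) else format_pvalue(x))
    out["n"] = out["n"].map(lambda x: "" if pd.isna(x) else f"{x:.1f}".rstrip("0").rstrip("."))
    return out
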