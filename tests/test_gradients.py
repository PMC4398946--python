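"""Field flattening, 2D gradient regression, relative angles, tables."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import periomap as pm
from periomap.gradients import (
    FlatCoords,
    append_field_summary,
    best_map_gradients,
    fit_gradient,
    flatten_field,
    format_pvalue,
    relative_angle,
    summarize_values,
    TABLE_COLUMNS,
)
from periomap.synth import FieldParcellation, SurfaceMesh

from _reference import ALPHA_ROWS, ALPHA_SUMMARY


# ---------------------------------------------------------------------------
# flattening


def test_flattening_is_isometric_on_planar_fields(left_sheet):
    _spec, mesh, parc = left_sheet
    coords = flatten_field(mesh, parc, "A1")
    pts3d = mesh.vertices[coords.vertex_indices]
    flat = np.column_stack([coords.u, coords.v])
    for i in range(0, coords.n - 1, 7):
        d3 = np.linalg.norm(pts3d[i] - pts3d[i + 1])
        d2 = np.linalg.norm(flat[i] - flat[i + 1])
        assert d2 == pytest.approx(d3, abs=1e-9)


def test_mirrored_hemispheres_give_identical_flat_coords():
    for fid in ("A1", "CL"):
        coords = {}
        for hemi in ("left", "right"):
            spec = pm.default_sheet_spec(hemi)
            mesh, parc = pm.make_surface(spec)
            coords[hemi] = flatten_field(mesh, parc, fid)
        assert np.allclose(coords["left"].u, coords["right"].u, atol=1e-9)
        assert np.allclose(coords["left"].v, coords["right"].v, atol=1e-9)


def test_flattening_matches_eigendecomposition_oracle():
    """4-vertex tilted patch vs an explicit principal-plane projection."""
    verts = np.array([
        [0.0, 0.0, 0.0],
        [2.0, 0.0, 1.0],
        [0.0, 2.0, 0.5],
        [2.0, 2.0, 1.5],
    ])
    mesh = SurfaceMesh(vertices=verts, triangles=[[0, 1, 2], [1, 3, 2]])
    parc = FieldParcellation(labels=np.array(["A1"] * 4))
    coords = flatten_field(mesh, parc, "A1")
    # oracle: eigenvectors of the 3x3 scatter matrix define the plane
    centred = verts - verts.mean(axis=0)
    evals, evecs = np.linalg.eigh(centred.T @ centred)
    plane = evecs[:, 1:]  # two leading principal axes
    proj = centred @ plane @ plane.T  # points projected into the plane
    # distances within the plane must match the (u, v) distances exactly
    flat = np.column_stack([coords.u, coords.v])
    for i in range(4):
        for j in range(i + 1, 4):
            assert np.linalg.norm(flat[i] - flat[j]) == pytest.approx(
                np.linalg.norm(proj[i] - proj[j]), abs=1e-9
            )


def test_flattening_rejects_degenerate_fields():
    mesh = SurfaceMesh(
        vertices=[[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 1e-12, 0], [0, 5, 0]],
        triangles=[[0, 1, 4], [1, 2, 4], [2, 3, 4]],
    )
    parc = FieldParcellation(labels=np.array(["A1"] * 4 + ["other"]))
    with pytest.raises(ValueError, match="degenerate"):
        flatten_field(mesh, parc, "A1")
    with pytest.raises(ValueError, match="fewer than 4"):
        flatten_field(mesh, parc, "R")


# ---------------------------------------------------------------------------
# gradient fits


def _grid_coords(n=6):
    u, v = np.meshgrid(np.arange(n, dtype=float), np.arange(n, dtype=float), indexing="ij")
    return FlatCoords(u=u.ravel(), v=v.ravel(), vertex_indices=np.arange(n * n))


def test_axis_aligned_gradients():
    coords = _grid_coords()
    fit_u = fit_gradient(coords, coords.u)
    assert relative_angle(fit_u.direction_deg, 0.0) == pytest.approx(0.0, abs=1e-9)
    assert fit_u.r2 == pytest.approx(1.0)
    fit_v = fit_gradient(coords, coords.v)
    assert relative_angle(fit_v.direction_deg, 90.0) == pytest.approx(0.0, abs=1e-9)


def test_constant_field_reports_missing_direction():
    coords = _grid_coords()
    fit = fit_gradient(coords, np.zeros(coords.n))
    assert np.isnan(fit.direction_deg)
    assert fit.r2 == 0.0


def test_noisy_plane_matches_statsmodels_oracle(rng):
    """30 noisy samples of a 165-deg plane: full agreement with OLS + F."""
    import statsmodels.api as sm

    u = rng.uniform(-5, 5, 30)
    v = rng.uniform(-5, 5, 30)
    theta = np.radians(165.0)
    values = 2.0 + 0.4 * (np.cos(theta) * u + np.sin(theta) * v) + rng.normal(0, 0.5, 30)
    fit = fit_gradient(FlatCoords(u=u, v=v, vertex_indices=np.arange(30)), values)
    X = sm.add_constant(np.column_stack([u, v]))
    ref = sm.OLS(values, X).fit()
    assert fit.coef[1] == pytest.approx(ref.params[1], rel=1e-8)
    assert fit.coef[2] == pytest.approx(ref.params[2], rel=1e-8)
    assert fit.r2 == pytest.approx(ref.rsquared, rel=1e-8)
    assert fit.pvalue == pytest.approx(ref.f_pvalue, rel=1e-8)
    expected_dir = np.degrees(np.arctan2(ref.params[2], ref.params[1])) % 360
    assert fit.direction_deg == pytest.approx(expected_dir, abs=1e-8)
    assert abs(fit.direction_deg - 165.0) < 15  # recovered near the planted axis


def test_rotation_equivariance(rng):
    coords = _grid_coords()
    values = 0.3 * coords.u - 0.7 * coords.v + rng.normal(0, 0.2, coords.n)
    base = fit_gradient(coords, values)
    for theta in (30.0, 117.5, 260.0):
        t = np.radians(theta)
        u2 = np.cos(t) * coords.u - np.sin(t) * coords.v
        v2 = np.sin(t) * coords.u + np.cos(t) * coords.v
        rot = fit_gradient(FlatCoords(u=u2, v=v2, vertex_indices=coords.vertex_indices), values)
        assert rot.direction_deg == pytest.approx((base.direction_deg + theta) % 360, abs=1e-9)
        assert rot.r2 == pytest.approx(base.r2, abs=1e-9)
        assert rot.pvalue == pytest.approx(base.pvalue, abs=1e-9)
        assert rot.magnitude == pytest.approx(base.magnitude, abs=1e-9)


# ---------------------------------------------------------------------------
# relative angles


@pytest.mark.parametrize(
    "d1, d2, expected",
    [(162.0, 25.0, 137.0), (40.0, 40.0, 0.0), (10.0, 350.0, 20.0)],
)
def test_relative_angle_examples(d1, d2, expected):
    assert relative_angle(d1, d2) == pytest.approx(expected)


@settings(deadline=None, max_examples=200, derandomize=True)
@given(
    st.floats(0, 360, allow_nan=False), st.floats(0, 360, allow_nan=False),
    st.integers(-3, 3),
)
def test_relative_angle_symmetry_range_and_wraparound(d1, d2, k):
    a = relative_angle(d1, d2)
    assert 0.0 <= a <= 180.0
    assert a == pytest.approx(relative_angle(d2, d1))
    assert a == pytest.approx(relative_angle(d1 + 360.0 * k, d2), abs=1e-6)


def test_relative_angle_propagates_missing():
    assert np.isnan(relative_angle(np.nan, 10.0))


# ---------------------------------------------------------------------------
# tables


def test_summary_rows_reproduce_published_aggregates():
    for fid, rows in ALPHA_ROWS.items():
        mean, sd = summarize_values(rows)
        want_mean, want_sd = ALPHA_SUMMARY[fid]
        assert round(mean, 1) == want_mean
        assert round(sd, 1) == want_sd


def test_single_row_summary_has_missing_sd():
    mean, sd = summarize_values([120.0])
    assert mean == 120.0
    assert np.isnan(sd)


def test_append_field_summary_recomputable():
    rows = [
        {"animal": a, "hemisphere": h, "field": "A1", "alpha_deg": v,
         "freq_direction_deg": 160.0, "freq_r2": 0.8, "freq_p": 1e-20,
         "rate_direction_deg": 50.0, "rate_r2": 0.7, "rate_p": 1e-20, "n": 100}
        for (a, h), v in zip(
            [("M1", "L"), ("M1", "R"), ("M2", "L"), ("M2", "R"), ("M3", "L"), ("M3", "R")],
            ALPHA_ROWS["A1"],
        )
    ]
    table = pd.DataFrame(rows, columns=list(TABLE_COLUMNS))
    full = append_field_summary(table)
    avg = full[full["animal"] == "Average"].iloc[0]
    sd = full[full["animal"] == "Std dev"].iloc[0]
    assert round(avg["alpha_deg"], 1) == 118.7
    assert round(sd["alpha_deg"], 1) == 23.3


def test_pvalue_formatting_floor():
    assert format_pvalue(1e-17) == "<1E-16"
    assert format_pvalue(0.0014) == "1.40E-03"


# ---------------------------------------------------------------------------
# best-map gradients


def test_best_map_gradient_requires_multiple_labels():
    coords = _grid_coords()
    with pytest.raises(ValueError, match="no gradient can be specified"):
        best_map_gradients(np.full(coords.n, 2), coords)


def test_staircased_labels_recover_axis():
    coords = _grid_coords()
    labels = np.floor(coords.u / 2).astype(int)
    fit = best_map_gradients(labels, coords)
    assert fit.ordinal
    assert fit.direction_deg == pytest.approx(0.0, abs=1e-6)


def test_best_map_gradient_close_to_contrast_gradient_noiselessly(
    left_sheet, truth, noiseless_statmaps
):
    """Ordinal best-rate gradient agrees with the contrast gradient in A1."""
    spec, mesh, parc = left_sheet
    from periomap import maps as maps_mod
    from periomap.project import project_label, project_scalar

    stat = noiseless_statmaps
    cm = maps_mod.contrast_map(stat, ("0.5", "2"), ("128", "512"))
    bm = maps_mod.best_map(stat)
    coords = flatten_field(mesh, parc, "A1")
    contrast_fit = fit_gradient(coords, project_scalar(cm.data, spec.grid, mesh, 1.6)[coords.vertex_indices])
    labels = project_label(bm.labels, spec.grid, mesh, 1.6)
    ordinal_fit = best_map_gradients(labels[coords.vertex_indices], coords)
    assert relative_angle(contrast_fit.direction_deg, ordinal_fit.direction_deg) < 15.0
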