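"""Synthetic cortex generator: meshes, parcellation, truth maps, simulators."""
import warnings

import numpy as np
import pytest

import periomap as pm
from periomap import synth
from periomap.core import BASELINE, GridSpec
from periomap.synth import FIELD_NAMES, SheetSpec, sheet_uv


def _connected(mesh, vertex_set):
    """BFS over triangle edges restricted to vertex_set."""
    vs = set(int(v) for v in vertex_set)
    if not vs:
        return False
    adj = {v: set() for v in vs}
    for a, b, c in mesh.triangles:
        for x, y in ((a, b), (b, c), (a, c)):
            if x in adj and y in adj:
                adj[int(x)].add(int(y))
                adj[int(y)].add(int(x))
    seen = {next(iter(vs))}
    stack = [next(iter(vs))]
    while stack:
        for nb in adj[stack.pop()]:
            if nb not in seen:
                seen.add(nb)
                stack.append(nb)
    return seen == vs


@pytest.mark.parametrize(
    "extent, spacing, n_vertices, n_triangles",
    [((20.0, 30.0), 1.0, 21 * 31, 2 * 20 * 30), ((10.0, 10.0), 5.0, 9, 8)],
)
def test_mesh_counts_on_regular_grid(extent, spacing, n_vertices, n_triangles):
    spec = SheetSpec(extent_mm=extent, vertex_spacing_mm=spacing)
    mesh, _ = pm.make_surface(spec)
    assert mesh.n_vertices == n_vertices
    assert len(mesh.triangles) == n_triangles


@pytest.mark.parametrize("extent, spacing", [((30.0, 20.0), 1.0), ((10.0, 10.0), 5.0)])
def test_every_field_nonempty_and_connected(extent, spacing):
    mesh, parc = pm.make_surface(SheetSpec(extent_mm=extent, vertex_spacing_mm=spacing))
    for name in FIELD_NAMES:
        idx = parc.vertices_of(name)
        assert idx.size > 0, name
        assert _connected(mesh, idx), name


def test_invalid_sheet_specs_rejected():
    with pytest.raises(ValueError):
        SheetSpec(extent_mm=(10.0, 10.0), vertex_spacing_mm=7.0)  # does not divide
    with pytest.raises(ValueError):
        SheetSpec(extent_mm=(5.0, 5.0), vertex_spacing_mm=5.0)  # 2 vertices per side
    with pytest.raises(ValueError):
        SheetSpec(vertex_spacing_mm=-1.0)


def test_preferred_rate_decay_and_clipping(left_sheet, truth):
    _spec, mesh, _parc = left_sheet
    uv = sheet_uv(mesh)
    at = {tuple(p): i for i, p in enumerate(map(tuple, uv))}
    assert truth.pref_rate_hz[at[(0.0, 0.0)]] == 128.0  # concentric centre
    assert truth.pref_rate_hz[at[(4.0, 0.0)]] == 64.0  # one decay length
    assert truth.pref_rate_hz.max() <= 128.0  # 512 Hz never planted
    assert truth.pref_rate_hz.min() >= 0.5


def test_rate_concentricity(truth, left_sheet):
    _spec, mesh, _parc = left_sheet
    d = np.linalg.norm(sheet_uv(mesh), axis=1)
    order = np.argsort(d)
    assert np.all(np.diff(truth.pref_rate_hz[order]) <= 1e-12)


def test_tonotopic_reversals_across_core_borders(left_sheet, truth):
    """Sign of d(log2 f)/du flips exactly once per crossed band border."""
    spec, mesh, _parc = left_sheet
    uv = sheet_uv(mesh)
    row = np.flatnonzero(np.abs(uv[:, 1] - 10.0) < 1e-9)
    row = row[np.argsort(uv[row, 0])]
    u = uv[row, 0]
    keep = (u >= 4) & (u <= 23)  # avoid the clipped low-frequency rim
    diffs = np.diff(np.log2(truth.pref_freq_hz[row[keep]]))
    signs = np.sign(diffs)
    flips = np.flatnonzero(np.diff(signs) != 0)
    assert len(flips) == 2  # A1/R and R/RT


def test_ground_truth_relative_angle_matches_defaults(left_sheet, truth):
    """Planted A1 axes sit at 165/53 (mod 180): truth alpha is 112 deg."""
    _spec, mesh, parc = left_sheet
    coords = pm.flatten_field(mesh, parc, "A1")
    fr = pm.fit_gradient(coords, np.log2(truth.pref_freq_hz[coords.vertex_indices]))
    ra = pm.fit_gradient(coords, np.log2(truth.pref_rate_hz[coords.vertex_indices]))
    assert fr.direction_deg % 180.0 == pytest.approx(165.0, abs=1.0)
    assert ra.direction_deg % 180.0 == pytest.approx(53.0, abs=1.5)
    assert pm.relative_angle(fr.direction_deg, ra.direction_deg) == pytest.approx(112.0, abs=2.0)


def test_invalid_rate_decay_rejected():
    with pytest.raises(ValueError):
        synth.TopoParams(rate_decay_mm=0.0)


@pytest.mark.parametrize(
    "n_volumes, conditions, per_condition",
    [(540, synth.RATE_CONDITIONS, 45), (720, synth.FREQ_CONDITIONS, 120)],
)
def test_schedule_balance(n_volumes, conditions, per_condition):
    sched = synth.make_schedule(n_volumes, conditions, seed=3)
    counts = sched.volume_counts()
    assert counts[BASELINE] == n_volumes // 2
    for c in conditions:
        assert counts[c] == per_condition
    assert all(lab == BASELINE for lab in sched.labels[::2])  # alternation


def test_schedule_minimal_and_errors():
    sched = synth.make_schedule(4, ["a"], seed=0)
    assert list(sched.labels) == [BASELINE, "a", BASELINE, "a"]
    with pytest.raises(ValueError):
        synth.make_schedule(5, ["a"])  # odd
    with pytest.raises(ValueError):
        synth.make_schedule(8, ["a", "b", "c"])  # 4 stim slots over 3 conditions


def test_sparse_simulation_noiseless_values(left_sheet, truth):
    spec, mesh, _parc = left_sheet
    sched = synth.make_schedule(12, synth.RATE_CONDITIONS, seed=0)
    series = synth.simulate_sparse_experiment(
        truth, mesh, sched, noise=synth.NoiseParams(sd=0.0), grid=spec.grid
    )
    # energy accounting: baseline volumes are exactly the baseline level
    base = [t for t, lab in enumerate(sched.labels) if lab == BASELINE]
    assert np.all(series.data[..., base] == 100.0)
    # a voxel preferring 32 Hz responds with exactly baseline*(1 + a/100)
    has, rate, _f, amp, width = synth._voxel_tuning(truth, mesh, spec.grid)
    vi = np.flatnonzero(has & np.isclose(rate, 32.0, rtol=0.002) & (amp > 0))
    assert vi.size > 0
    t32 = sched.labels.index("32")
    val = series.data.reshape(-1, 12)[vi[0], t32]
    assert val == pytest.approx(100.0 * (1 + amp[vi[0]] / 100.0), rel=1e-4)


def test_sparse_simulation_seed_determinism(left_sheet, truth):
    spec, mesh, _parc = left_sheet
    sched = synth.make_schedule(12, synth.RATE_CONDITIONS, seed=0)
    noise = synth.NoiseParams(sd=5.0, ar1=0.3, seed=11)
    a = synth.simulate_sparse_experiment(truth, mesh, sched, noise=noise, grid=spec.grid)
    b = synth.simulate_sparse_experiment(truth, mesh, sched, noise=noise, grid=spec.grid)
    assert np.array_equal(a.data, b.data)


def test_condition_outside_domain_warns(left_sheet, truth):
    spec, mesh, _parc = left_sheet
    sched = synth.make_schedule(4, ["bad"], seed=0)
    with pytest.warns(UserWarning, match="outside tuning domain"):
        series = synth.simulate_sparse_experiment(
            truth, mesh, sched, conditions={"bad": -1.0},
            noise=synth.NoiseParams(sd=0.0), grid=spec.grid,
        )
    assert np.all(series.data == 100.0)  # zero response everywhere


def _cycle_response(series, voxel_flat, timing):
    """Fold one voxel's noiseless series over the stimulus cycle."""
    data = series.data.reshape(-1, series.n_volumes)[voxel_flat]
    t = np.arange(series.n_volumes) * timing.tr_s
    use = t < timing.n_cycles * timing.cycle_s
    phase = np.mod(t[use], timing.cycle_s)
    return phase, data[use]


def test_phase_runs_peak_timing(left_sheet, truth):
    spec, mesh, _parc = left_sheet
    timing = synth.PhaseTiming()
    runs = {
        d: synth.simulate_phase_runs(truth, mesh, timing, d, synth.NoiseParams(sd=0.0),
                                     grid=spec.grid)
        for d in ("low_to_high", "high_to_low")
    }
    has, _r, f, amp, _w = synth._voxel_tuning(truth, mesh, spec.grid)
    k = timing.nearest_index(f)

    def peak_phase(direction, voxel):
        ph, resp = _cycle_response(runs[direction], voxel, timing)
        order = np.argsort(ph)
        # phase of the circular-mean response peak, at TR resolution
        return ph[order][np.argmax(resp[order])]

    mid = np.flatnonzero(has & (amp > 0) & (k == 4))[0]
    assert peak_phase("low_to_high", mid) == pytest.approx(peak_phase("high_to_low", mid), abs=1.5)
    low = np.flatnonzero(has & (amp > 0) & (k == 0))[0]
    delta = peak_phase("high_to_low", low) - peak_phase("low_to_high", low)
    assert delta == pytest.approx(16.0, abs=1.5)


def test_phase_run_onset_volume_with_zero_delay(left_sheet, truth):
    """Delay 0 and TR-aligned blocks: first response volume = onset / TR."""
    spec, mesh, _parc = left_sheet
    timing = synth.PhaseTiming(tr_s=1.0, n_volumes=460, hemodynamic_delay_s=0.0)
    series = synth.simulate_phase_runs(
        truth, mesh, timing, "low_to_high", synth.NoiseParams(sd=0.0), grid=spec.grid
    )
    has, _r, f, amp, _w = synth._voxel_tuning(truth, mesh, spec.grid)
    k = timing.nearest_index(f)
    for step in (0, 3, 8):
        vox = np.flatnonzero(has & (amp > 0) & (k == step))[0]
        trace = series.data.reshape(-1, timing.n_volumes)[vox]
        onset_s = step * timing.tone_block_s
        first = np.flatnonzero(trace > 100.0)[0]
        assert first == int(onset_s // timing.tr_s)


def test_phase_timing_invariants():
    t = synth.PhaseTiming()
    assert t.progression_s == t.n_frequencies * t.tone_block_s
    assert t.cycle_s == t.progression_s + t.silence_s
    assert t.n_volumes * t.tr_s >= t.n_cycles * t.cycle_s
    assert np.allclose(t.frequency_ladder_hz[[0, 4, 8]], [500.0, 2000.0, 8000.0])
    with pytest.raises(ValueError):
        synth.PhaseTiming(n_volumes=100)  # shorter than the 15 cycles
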