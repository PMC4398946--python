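"""Synthetic auditory cortex: surfaces, ground-truth topographies, BOLD simulators.

The generator emulates the study conditions of a macaque auditory-cortex
mapping experiment:

* a flat rectangular cortical sheet standing in for the (nearly planar)
  superior temporal plane, parcellated into core fields (A1, R, RT) and
  surrounding belt fields (CL, ML, AL, CM);
* a periodotopic ground truth — preferred amplitude-modulation (AM) rate
  arranged in concentric iso-rate bands centred on the postero-medial
  corner, decaying as ``r(d) = 128 * 2**(-d / lambda)`` with distance ``d``;
* a tonotopic ground truth — log2 preferred frequency affine along a
  per-field axis, with the gradient sign reversing across the A1/R and
  R/RT borders;
* sparse-design BOLD series (10 s TR, 1 s acquisition, alternating silent
  baseline) for the 6-rate and 3-frequency-band experiments, and
  continuous phase-encoded runs (1.4 s TR, 9 half-octave tones in 2 s
  blocks, 18 s progression + 12 s silence, 15 cycles, both directions).

Neural tuning is modelled as a Gaussian in log2(stimulus); the vascular
response of the phase-encoded runs uses a gamma-shaped hemodynamic kernel.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .core import BASELINE, GridSpec, StimulusSchedule, VolumeSeries, condition_value

# ---------------------------------------------------------------------------
# condition sets of the two sparse experiments

RATE_CONDITIONS: tuple[str, ...] = ("0.5", "2", "8", "32", "128", "512")
FREQ_CONDITIONS: tuple[str, ...] = ("500-1000", "2000-4000", "8000-16000")

#: auditory-field names carried by every parcellation
FIELD_NAMES: tuple[str, ...] = ("A1", "R", "RT", "CL", "ML", "AL", "CM")
OTHER = "other"


# ---------------------------------------------------------------------------
# surface + parcellation


@dataclass(frozen=True)
class SheetSpec:
    """Rectangular cortical sheet embedded in a 3D voxel grid.

    ``extent_mm`` is (u, v) size where u runs posterior->anterior and v
    medial->lateral; the sheet sits on the mid-plane of the grid's z axis.
    """

    extent_mm: tuple[float, float] = (30.0, 20.0)
    vertex_spacing_mm: float = 1.0
    hemisphere: str = "left"
    grid: GridSpec = field(
        default_factory=lambda: GridSpec(shape=(34, 24, 8), origin_mm=(-2.0, -2.0, 0.0))
    )

    def __post_init__(self) -> None:
        if self.hemisphere not in ("left", "right"):
            raise ValueError(f"hemisphere must be 'left' or 'right', got {self.hemisphere!r}")
        if self.vertex_spacing_mm <= 0 or any(e <= 0 for e in self.extent_mm):
            raise ValueError("sheet extent and spacing must be positive")
        for e in self.extent_mm:
            n = e / self.vertex_spacing_mm
            if abs(n - round(n)) > 1e-9:
                raise ValueError("vertex spacing must divide the sheet extent")
            if round(n) + 1 < 3:
                raise ValueError("sheet must have at least 3 vertices per side")

    @property
    def n_vertices_per_side(self) -> tuple[int, int]:
        return (
            int(round(self.extent_mm[0] / self.vertex_spacing_mm)) + 1,
            int(round(self.extent_mm[1] / self.vertex_spacing_mm)) + 1,
        )


def default_sheet_spec(hemisphere: str = "left") -> SheetSpec:
    """Default sheet; the right-hemisphere grid is the mirror of the left."""
    if hemisphere == "left":
        return SheetSpec()
    return SheetSpec(
        hemisphere="right",
        grid=GridSpec(shape=(34, 24, 8), origin_mm=(-2.0, -22.0, 0.0)),
    )


@dataclass
class SurfaceMesh:
    """Triangulated surface in mm world coordinates."""

    vertices: np.ndarray  # (n, 3)
    triangles: np.ndarray  # (m, 3) int
    hemisphere: str = "left"

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.triangles = np.asarray(self.triangles, dtype=int)
        n = len(self.vertices)
        if n < 4:
            raise ValueError("mesh needs at least 4 vertices")
        if self.triangles.min(initial=0) < 0 or self.triangles.max(initial=-1) >= n:
            raise ValueError("triangle indices out of range")
        a, b, c = (self.vertices[self.triangles[:, i]] for i in range(3))
        areas = 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1)
        if np.any(areas <= 1e-12):
            raise ValueError("mesh contains degenerate (zero-area) triangles")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)


@dataclass
class FieldParcellation:
    """Per-vertex auditory-field labels."""

    labels: np.ndarray  # (n,) unicode
    field_names: tuple[str, ...] = FIELD_NAMES

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype="U8")

    def vertices_of(self, field_id: str) -> np.ndarray:
        return np.flatnonzero(self.labels == field_id)


def sheet_uv(mesh: SurfaceMesh) -> np.ndarray:
    """(n, 2) sheet coordinates (u anterior, v lateral) of mesh vertices."""
    u = mesh.vertices[:, 0]
    v = mesh.vertices[:, 1] if mesh.hemisphere == "left" else -mesh.vertices[:, 1]
    return np.column_stack([u, v])


# field rectangles as fractions of the sheet extent: (u_lo, u_hi, v_lo, v_hi).
# A1 central, R/RT anterior, CL/ML/AL a lateral belt strip, CM caudo-medial.
_FIELD_LAYOUT: dict[str, tuple[float, float, float, float]] = {
    "A1": (0.10, 0.3667, 0.30, 0.70),
    "R": (0.3667, 0.60, 0.30, 0.70),
    "RT": (0.60, 0.80, 0.30, 0.70),
    "CM": (0.00, 0.10, 0.00, 0.70),
    "CL": (0.00, 0.3667, 0.70, 1.001),
    "ML": (0.3667, 0.60, 0.70, 1.001),
    "AL": (0.60, 0.80, 0.70, 1.001),
}


def field_rect_mm(field_id: str, extent_mm: tuple[float, float]) -> tuple[float, float, float, float]:
    fu0, fu1, fv0, fv1 = _FIELD_LAYOUT[field_id]
    return fu0 * extent_mm[0], fu1 * extent_mm[0], fv0 * extent_mm[1], fv1 * extent_mm[1]


def make_surface(spec: SheetSpec) -> tuple[SurfaceMesh, FieldParcellation]:
    """Triangulate the sheet and lay the idealised field parcellation on it.

    A ``w x h`` mm sheet at spacing ``s`` yields ``(w/s+1) x (h/s+1)``
    vertices and ``2 * (w/s) * (h/s)`` triangles. The parcellation assigns
    vertices by containment in per-field rectangles; on very coarse meshes a
    rectangle may catch no vertex, in which case the field claims the free
    vertex nearest its rectangle centre so every named field is non-empty.
    """
    nu, nv = spec.n_vertices_per_side
    s = spec.vertex_spacing_mm
    uu, vv = np.meshgrid(np.arange(nu) * s, np.arange(nv) * s, indexing="ij")
    u = uu.ravel()
    v = vv.ravel()
    z = spec.grid.origin_mm[2] + 0.5 * spec.grid.shape[2] * spec.grid.voxel_size_mm[2]
    y = v if spec.hemisphere == "left" else -v
    vertices = np.column_stack([u, y, np.full_like(u, z)])

    tris = []
    for i in range(nu - 1):
        for j in range(nv - 1):
            a = i * nv + j
            b = (i + 1) * nv + j
            tris.append((a, b, a + 1))
            tris.append((b, b + 1, a + 1))
    mesh = SurfaceMesh(vertices=vertices, triangles=np.asarray(tris), hemisphere=spec.hemisphere)

    labels = np.full(len(vertices), OTHER, dtype="U8")
    for name in FIELD_NAMES:
        u0, u1, v0, v1 = field_rect_mm(name, spec.extent_mm)
        inside = (u >= u0) & (u < u1) & (v >= v0) & (v < v1)
        labels[inside] = name
    # coarse-mesh fallback: every named field must be non-empty
    for name in FIELD_NAMES:
        if np.any(labels == name):
            continue
        u0, u1, v0, v1 = field_rect_mm(name, spec.extent_mm)
        centre = np.array([(u0 + u1) / 2, (v0 + v1) / 2])
        d = np.hypot(u - centre[0], v - centre[1])
        # only steal from 'other' or from fields that keep >= 2 vertices
        order = np.argsort(d, kind="stable")
        for cand in order:
            donor = labels[cand]
            if donor == OTHER or np.sum(labels == donor) >= 2:
                labels[cand] = name
                break
    return mesh, FieldParcellation(labels=labels)


# ---------------------------------------------------------------------------
# ground truth topographies


@dataclass(frozen=True)
class TopoParams:
    """Parameters of the planted rate/frequency organisation.

    ``field_axes_deg`` gives the tonotopic axis of each core band (A1, R,
    RT): the direction (0 deg = anterior, 90 deg = lateral) along which
    log2 preferred frequency increases. The defaults reverse the axis
    across the A1/R and R/RT borders and are chosen so the fitted A1 truth
    frequency/rate gradient axes sit at 165/53 deg (mod 180) with a
    relative angle of 112 deg.
    """

    centre_uv: tuple[float, float] = (0.0, 0.0)
    rate_decay_mm: float = 4.0
    rate_max_hz: float = 128.0
    rate_min_hz: float = 0.5
    freq_mid_hz: float = 2828.427
    freq_slope_oct_per_mm: float = 0.4
    freq_range_hz: tuple[float, float] = (500.0, 16000.0)
    field_axes_deg: dict[str, float] = field(
        default_factory=lambda: {"A1": 345.0, "R": 165.0, "RT": 345.0}
    )
    amplitude_pct: float = 1.0
    tuning_width_oct: float = 1.5

    def __post_init__(self) -> None:
        if self.rate_decay_mm <= 0:
            raise ValueError("rate decay length must be positive")
        if self.tuning_width_oct <= 0 or self.amplitude_pct < 0:
            raise ValueError("invalid tuning parameters")


@dataclass
class GroundTruthMaps:
    """Per-vertex planted tuning."""

    pref_rate_hz: np.ndarray
    pref_freq_hz: np.ndarray
    amplitude_pct: np.ndarray
    tuning_width_oct: np.ndarray


def make_ground_truth(
    mesh: SurfaceMesh,
    parcellation: FieldParcellation,
    topo_params: TopoParams | None = None,
    extent_mm: tuple[float, float] = (30.0, 20.0),
) -> GroundTruthMaps:
    """Plant concentric iso-rate bands and per-field tonotopic gradients.

    Preferred rate: ``r(d) = rate_max * 2**(-d / lambda)`` clipped to
    ``[rate_min, rate_max]``, ``d`` = distance from the concentric centre
    (postero-medial corner by default). The 512 Hz condition is deliberately
    outside the planted range: the highest rate band is barely represented.

    Preferred frequency: log2 f is affine within each core band along the
    band's configured axis, continuous along the anterior axis across the
    band borders (where the gradient sign reverses) and extended
    medio-laterally across the belt, then clipped to the stated range.
    """
    p = topo_params or TopoParams()
    uv = sheet_uv(mesh)
    d = np.linalg.norm(uv - np.asarray(p.centre_uv), axis=1)
    rate = np.clip(p.rate_max_hz * 2.0 ** (-d / p.rate_decay_mm), p.rate_min_hz, p.rate_max_hz)

    # Tonotopy: continuous piecewise-affine map built from the three core
    # bands (A1, R, RT) extended medio-laterally across the whole sheet, so
    # iso-frequency contours run from the medial edge through the core into
    # the lateral belt and the map has no jumps at field borders; the
    # gradient sign along u reverses at the A1/R and R/RT borders.
    bands = []
    for name in ("A1", "R", "RT"):
        u0, u1, _v0, _v1 = field_rect_mm(name, extent_mm)
        bands.append((name, u0, u1, math.radians(p.field_axes_deg[name])))
    v0, v1 = _FIELD_LAYOUT["A1"][2] * extent_mm[1], _FIELD_LAYOUT["A1"][3] * extent_mm[1]
    v_mid = 0.5 * (v0 + v1)
    # midline profile g(u), anchored at the A1 band centre = mid frequency
    anchor_u = 0.5 * (bands[0][1] + bands[0][2])
    edges = [bands[0][1], bands[1][1], bands[2][1], bands[2][2]]

    def slope_u(ax_rad: float) -> float:
        return p.freq_slope_oct_per_mm * math.cos(ax_rad)

    g_at = {edges[0]: math.log2(p.freq_mid_hz) - slope_u(bands[0][3]) * (anchor_u - edges[0])}
    for (name, u0, u1, ax), e0, e1 in zip(bands, edges[:-1], edges[1:]):
        g_at[e1] = g_at[e0] + slope_u(ax) * (e1 - e0)

    u = uv[:, 0]
    v = uv[:, 1]
    band_idx = np.clip(np.searchsorted(edges[1:3], u, side="right"), 0, 2)
    log2f = np.empty(mesh.n_vertices)
    for bi, ((name, u0, u1, ax), e0) in enumerate(zip(bands, edges[:-1])):
        sel = band_idx == bi
        log2f[sel] = (
            g_at[e0]
            + slope_u(ax) * (u[sel] - e0)
            + p.freq_slope_oct_per_mm * math.sin(ax) * (v[sel] - v_mid)
        )
    freq = np.clip(2.0 ** log2f, *p.freq_range_hz)

    n = mesh.n_vertices
    return GroundTruthMaps(
        pref_rate_hz=rate,
        pref_freq_hz=freq,
        amplitude_pct=np.full(n, p.amplitude_pct),
        tuning_width_oct=np.full(n, p.tuning_width_oct),
    )


def log_gaussian_tuning(stimulus_hz, preferred_hz, width_oct):
    """Gaussian tuning in log2(stimulus), peak 1 at the preferred value."""
    dx = np.log2(np.asarray(stimulus_hz, dtype=float)) - np.log2(preferred_hz)
    return np.exp(-(dx**2) / (2.0 * np.asarray(width_oct, dtype=float) ** 2))


# ---------------------------------------------------------------------------
# schedules and sparse simulation


@dataclass(frozen=True)
class NoiseParams:
    """Additive noise of the simulated scanner signal."""

    baseline: float = 100.0
    sd: float = 6.7
    ar1: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("noise SD must be non-negative")
        if not (0.0 <= self.ar1 < 1.0):
            raise ValueError("AR(1) coefficient must be in [0, 1)")


def make_schedule(
    n_volumes: int,
    condition_labels=RATE_CONDITIONS,
    seed: int = 0,
    tr_s: float = 10.0,
    ta_s: float = 1.0,
) -> StimulusSchedule:
    """Alternating baseline/stimulus schedule, conditions balanced.

    Even volume indices (0, 2, ...) are silent baseline — stimuli are
    omitted before every other acquisition — and the ``n_volumes / 2``
    stimulus slots carry each condition equally often in a seeded
    pseudo-random order.
    """
    conditions = tuple(condition_labels)
    if n_volumes % 2 != 0:
        raise ValueError("n_volumes must be even (alternating baseline)")
    n_stim = n_volumes // 2
    if n_stim % len(conditions) != 0:
        raise ValueError(
            f"{n_stim} stimulus volumes cannot be balanced over {len(conditions)} conditions"
        )
    per = n_stim // len(conditions)
    rng = np.random.default_rng(seed)
    stim = np.repeat(np.arange(len(conditions)), per)
    rng.shuffle(stim)
    labels = []
    k = 0
    for i in range(n_volumes):
        if i % 2 == 0:
            labels.append(BASELINE)
        else:
            labels.append(conditions[stim[k]])
            k += 1
    return StimulusSchedule(labels=tuple(labels), condition_order=conditions, tr_s=tr_s, ta_s=ta_s)


def _voxel_tuning(
    truth: GroundTruthMaps, mesh: SurfaceMesh, grid: GridSpec, radius_mm: float = 2.0
):
    """Nearest-vertex tuning inheritance for voxels within ``radius_mm``.

    Returns (has_signal, pref_rate, pref_freq, amplitude, width) flat arrays
    over voxels; voxels beyond the radius carry baseline only.
    """
    centres = grid.voxel_centres()
    tree = cKDTree(mesh.vertices)
    dist, idx = tree.query(centres, k=1, distance_upper_bound=radius_mm)
    has = np.isfinite(dist)
    idx = np.where(has, idx, 0)
    return (
        has,
        truth.pref_rate_hz[idx],
        truth.pref_freq_hz[idx],
        np.where(has, truth.amplitude_pct[idx], 0.0),
        truth.tuning_width_oct[idx],
    )


def _add_noise(data: np.ndarray, noise: NoiseParams, rng: np.random.Generator) -> np.ndarray:
    if noise.sd == 0:
        return data
    eps = rng.normal(0.0, noise.sd, size=data.shape)
    if noise.ar1 > 0:
        for t in range(1, data.shape[-1]):
            eps[..., t] += noise.ar1 * eps[..., t - 1]
        eps *= math.sqrt(1.0 - noise.ar1**2)  # keep marginal SD
    return data + eps


def simulate_sparse_experiment(
    truth: GroundTruthMaps,
    mesh: SurfaceMesh,
    schedule: StimulusSchedule,
    conditions=None,
    noise: NoiseParams = NoiseParams(),
    grid: GridSpec | None = None,
    experiment: str = "rate",
    inherit_radius_mm: float = 2.0,
) -> VolumeSeries:
    """Simulate a sparse-design session on the sheet's enclosing grid.

    At a stimulus volume the voxel value is
    ``baseline * (1 + a * G(condition) / 100)`` where ``G`` is the voxel's
    log2-Gaussian tuning curve evaluated at the condition's stimulus value;
    baseline volumes carry the baseline alone. Gaussian noise (optionally
    AR(1)) is added on top. Identical seeds give identical series.
    """
    if grid is None:
        grid = default_sheet_spec(mesh.hemisphere).grid
    if conditions is None:
        conditions = {c: condition_value(c) for c in schedule.conditions}
    if experiment not in ("rate", "frequency"):
        raise ValueError("experiment must be 'rate' or 'frequency'")
    has, rate, freq, amp, width = _voxel_tuning(truth, mesh, grid, inherit_radius_mm)
    pref = rate if experiment == "rate" else freq

    # per-condition response (percent) per voxel
    resp = {}
    for label, value in conditions.items():
        if value <= 0:
            warnings.warn(f"condition {label!r} outside tuning domain; zero response")
            resp[label] = np.zeros(grid.n_voxels)
        else:
            resp[label] = amp * log_gaussian_tuning(value, pref, width)

    data = np.empty(grid.shape + (schedule.n_volumes,))
    flat = data.reshape(-1, schedule.n_volumes)
    for t, lab in enumerate(schedule.labels):
        if lab == BASELINE:
            flat[:, t] = noise.baseline
        else:
            flat[:, t] = noise.baseline * (1.0 + resp[lab] / 100.0)
    rng = np.random.default_rng(noise.seed)
    data = _add_noise(data, noise, rng)
    return VolumeSeries(data=data, grid=grid, tr_s=schedule.tr_s, ta_s=schedule.ta_s)


# ---------------------------------------------------------------------------
# phase-encoded simulation


@dataclass(frozen=True)
class PhaseTiming:
    """Timing of the continuous phase-encoded runs."""

    tr_s: float = 1.4
    tone_block_s: float = 2.0
    n_frequencies: int = 9
    silence_s: float = 12.0
    n_cycles: int = 15
    n_volumes: int = 343
    hemodynamic_delay_s: float = 4.0
    base_frequency_hz: float = 500.0

    def __post_init__(self) -> None:
        if min(self.tr_s, self.tone_block_s, self.silence_s) <= 0:
            raise ValueError("timing values must be positive")
        if self.n_volumes * self.tr_s < self.n_cycles * self.cycle_s:
            raise ValueError("acquisition shorter than the stimulus cycles")
        if self.hemodynamic_delay_s < 0:
            raise ValueError("hemodynamic delay must be non-negative")

    @property
    def progression_s(self) -> float:
        return self.n_frequencies * self.tone_block_s

    @property
    def cycle_s(self) -> float:
        return self.progression_s + self.silence_s

    @property
    def frequency_ladder_hz(self) -> np.ndarray:
        """Half-octave ladder, 500 ... 8000 Hz by default."""
        return self.base_frequency_hz * 2.0 ** (np.arange(self.n_frequencies) / 2.0)

    def nearest_index(self, freq_hz) -> np.ndarray:
        steps = 2.0 * (np.log2(np.asarray(freq_hz, dtype=float) / self.base_frequency_hz))
        return np.clip(np.round(steps).astype(int), 0, self.n_frequencies - 1)


def gamma_hrf(t: np.ndarray, peak_delay_s: float, shape: float = 3.0) -> np.ndarray:
    """Gamma-shaped hemodynamic kernel with unit peak at ``peak_delay_s``.

    ``peak_delay_s == 0`` degenerates to an identity (delta) response.
    """
    t = np.asarray(t, dtype=float)
    if peak_delay_s == 0:
        h = np.zeros_like(t)
        h[np.argmin(np.abs(t))] = 1.0
        return h
    tau = peak_delay_s / shape
    x = np.maximum(t, 0.0) / tau
    with np.errstate(invalid="ignore"):
        h = x**shape * np.exp(shape - x)
    h[t < 0] = 0.0
    return h


def simulate_phase_runs(
    truth: GroundTruthMaps,
    mesh: SurfaceMesh,
    timing: PhaseTiming = PhaseTiming(),
    direction: str = "low_to_high",
    noise: NoiseParams = NoiseParams(),
    grid: GridSpec | None = None,
    inherit_radius_mm: float = 2.0,
    dt_s: float = 0.1,
) -> VolumeSeries:
    """Simulate one continuous phase-encoded run.

    Each tuned voxel is neurally active during the 2 s block of its
    preferred frequency in every cycle (cycle 1 starts at t = 0; the
    trailing part of the acquisition is silence); the boxcar is convolved
    with a gamma hemodynamic kernel peaking at ``hemodynamic_delay_s`` and
    sampled at the TR. The high-to-low run reverses the within-progression
    block order only.
    """
    if direction not in ("low_to_high", "high_to_low"):
        raise ValueError(f"unknown direction {direction!r}")
    if grid is None:
        grid = default_sheet_spec(mesh.hemisphere).grid
    has, _rate, freq, amp, _width = _voxel_tuning(truth, mesh, grid, inherit_radius_mm)
    k = np.asarray(timing.nearest_index(freq))

    t_hi = np.arange(0.0, timing.n_volumes * timing.tr_s + timing.cycle_s, dt_s)
    kernel = gamma_hrf(np.arange(0.0, 6.0 * max(timing.hemodynamic_delay_s, dt_s), dt_s),
                       timing.hemodynamic_delay_s)
    t_vol = np.arange(timing.n_volumes) * timing.tr_s

    # one response time course per distinct frequency index
    responses = np.zeros((timing.n_frequencies, timing.n_volumes))
    for ki in range(timing.n_frequencies):
        onset_in_prog = (
            ki * timing.tone_block_s
            if direction == "low_to_high"
            else (timing.n_frequencies - 1 - ki) * timing.tone_block_s
        )
        neural = np.zeros_like(t_hi)
        for c in range(timing.n_cycles):
            on = c * timing.cycle_s + onset_in_prog
            neural[(t_hi >= on) & (t_hi < on + timing.tone_block_s)] = 1.0
        conv = np.convolve(neural, kernel)[: len(t_hi)]
        peak = conv.max()
        if peak > 0:
            conv = conv / peak
        responses[ki] = np.interp(t_vol, t_hi, conv)

    data = np.empty(grid.shape + (timing.n_volumes,))
    flat = data.reshape(-1, timing.n_volumes)
    flat[:] = noise.baseline
    tuned = np.flatnonzero(has)
    flat[tuned] += noise.baseline * (amp[tuned, None] / 100.0) * responses[k[tuned]]
    rng = np.random.default_rng(noise.seed)
    data = _add_noise(data, noise, rng)
    return VolumeSeries(data=data, grid=grid, tr_s=timing.tr_s, ta_s=timing.tr_s)
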