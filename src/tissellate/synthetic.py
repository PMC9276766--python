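"""Synthetic collision experiments with known ground truth.

Real collision assays are terabyte-scale time-lapse stacks; every analysis
operation in this package is therefore exercised against synthetic
experiments whose ground truth is known by construction: label movies,
PIV-style velocity fields on ~88 um windows, density fields, and nuclei
point patterns.

The generator is a one-dimensional kinematic model of a two-rectangle
collision along x (uniform in y):

* free edges advance at v_n with an edge-localized velocity profile that
  decays into the bulk;
* cell density is advected conservatively by the velocity field (upwind
  finite volume) and grows logistically, so larger/older tissue regions end
  up denser and edges are diluted by spreading, as in experiments;
* after fusion, the boundary moves with ``v_b = -(P'/xi) * d(rho)/dx`` (the
  gradient measured over 300-um boxes either side, with the generator's own
  bookkeeping, independent of the analysis code), and the velocity field is
  a piecewise-linear divergent profile about a center of expansion that
  relaxes from the denser tissue's centroid to the fused-tissue centroid;
* Gaussian noise is added to the emitted fields; nuclei are an
  inhomogeneous Poisson pattern matching the density field.

All randomness flows through one ``numpy.random.default_rng(seed)``
(PCG64); a fixed seed gives bit-reproducible output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

from .mechanics import (DEFAULT_WINDOW_UM, DEFAULT_XI, FieldMovie,
                        pressure_velocity)
from .scenes import DEFAULT_SPEED, Grid, Rectangle, Scene, TissueSeed
from .simulate import LabelMovie

__all__ = [
    "SynthSpec",
    "GroundTruth",
    "SynthResult",
    "two_rectangle_scene",
    "synth_collision",
    "synth_velocity_density_pairs",
    "synth_nuclei",
]


def two_rectangle_scene(
    rho_a: float = 2600.0,
    rho_b: float = 1800.0,
    width_a: float = 1000.0,
    width_b: float = 1000.0,
    gap: float = 500.0,
    height: float = 3000.0,
    margin: float = 2000.0,
    speed: float = DEFAULT_SPEED,
) -> Scene:
    """Two vertical rectangle strips separated by a gap along x.

    Defaults reproduce the density-mismatch assay: equal 1000-um-wide
    strips seeded at ~2600 and ~1800 cells/mm^2, 500 um apart.
    """
    world_w = margin + width_a + gap + width_b + margin
    world_h = height + 2 * 100.0
    y_mid = world_h / 2
    xa = margin + width_a / 2
    xb = margin + width_a + gap + width_b / 2
    return Scene(
        tissues=[
            TissueSeed(1, Rectangle((xa, y_mid), width_a, height), speed=speed,
                       density=rho_a),
            TissueSeed(2, Rectangle((xb, y_mid), width_b, height), speed=speed,
                       density=rho_b),
        ],
        world_extent=(world_w, world_h),
        default_speed=speed,
    )


@dataclass
class SynthSpec:
    """Parameters of one synthetic collision assay.

    Defaults are the study conditions of the density-mismatch assay: equal
    1000-um rectangles, 2600 vs 1800 cells/mm^2, v_n = 29.5 um/h, frames
    every 20 min, 88-um analysis windows, P' = 0.5 Pa mm^2 and xi = 100
    Pa s/um^2.
    """

    scene: Scene = field(default_factory=two_rectangle_scene)
    growth_rate: float = 0.04        # 1/h logistic rate (~18 h doubling)
    rho_max: float = 6000.0          # cells/mm^2 carrying capacity
    p_prime: float = 0.5             # Pa mm^2
    xi: float = DEFAULT_XI           # Pa s/um^2
    noise_v: float = 1.0             # um/h additive Gaussian, per window
    noise_rho: float = 0.05          # fractional Gaussian, per window
    seed: int = 0
    dt: float = 1.0 / 3.0            # h between frames
    t_end: float = 60.0              # h
    window_um: float = DEFAULT_WINDOW_UM
    label_spacing: float = 20.0      # um, label-movie grid
    edge_decay: float = 300.0        # um, velocity penetration from free edges
    tau_center: float = 10.0         # h, center-of-expansion relaxation
    gradient_width: float = 300.0    # um, boundary gradient boxes
    dx: float = 20.0                 # um, internal 1-D grid
    nuclei_every_h: float = 8.0      # cadence of nuclei snapshots

    @classmethod
    def control(cls, rho: float = 2200.0, **kw) -> "SynthSpec":
        """Symmetric control: equal widths and equal densities."""
        return cls(scene=two_rectangle_scene(rho_a=rho, rho_b=rho), **kw)

    @classmethod
    def density_mismatch(cls, rho_a: float = 2600.0, rho_b: float = 1800.0,
                         **kw) -> "SynthSpec":
        return cls(scene=two_rectangle_scene(rho_a=rho_a, rho_b=rho_b), **kw)

    @classmethod
    def size_mismatch(cls, width_a: float = 1000.0, width_b: float = 500.0,
                      rho: float = 2200.0, **kw) -> "SynthSpec":
        return cls(scene=two_rectangle_scene(rho_a=rho, rho_b=rho,
                                             width_a=width_a, width_b=width_b),
                   **kw)


@dataclass
class GroundTruth:
    """Programmed truth of a synthetic collision, consistent by construction."""

    t_h: np.ndarray
    boundary_x: np.ndarray       # NaN before fusion
    center_x: np.ndarray         # programmed center of expansion, NaN pre-fusion
    v_boundary: np.ndarray       # um/h, NaN before fusion
    edges: np.ndarray            # (nt, 2) outer edge positions [L, R]
    x_fine: np.ndarray
    rho_profiles: np.ndarray     # (nt, nx_fine) cells/mm^2
    v_profiles: np.ndarray       # (nt, nx_fine) um/h, NaN outside tissue
    p_prime: float
    xi: float
    v_n: float
    t_collision: float
    x_fuse: float
    seed: int


class SynthResult(NamedTuple):
    movie: LabelMovie
    vx: FieldMovie
    density: FieldMovie
    nuclei: pd.DataFrame
    truth: GroundTruth


def _rect_intervals(scene: Scene) -> tuple[list[tuple[float, float, float]], float, float]:
    """Validate the two-rectangle scene; return x-intervals, y-span."""
    if len(scene.tissues) != 2:
        raise ValueError("synthetic collisions need exactly two tissues")
    spans = []
    ys = []
    for t in scene.tissues:
        if not isinstance(t.shape, Rectangle) or t.shape.angle_deg % 360 != 0:
            raise ValueError(
                "synthetic collisions support axis-aligned rectangle seeds only"
            )
        cx, cy = t.shape.center
        spans.append((cx - t.shape.width / 2, cx + t.shape.width / 2, t.id))
        ys.append((cy - t.shape.height / 2, cy + t.shape.height / 2))
    if abs(ys[0][0] - ys[1][0]) > 1e-6 or abs(ys[0][1] - ys[1][1]) > 1e-6:
        raise ValueError("the two rectangles must share the same y extent")
    spans.sort()
    if spans[0][1] >= spans[1][0]:
        raise ValueError("rectangles must be separated by a gap along x")
    v1 = scene.speed_of(spans[0][2])
    v2 = scene.speed_of(spans[1][2])
    if abs(v1 - v2) > 1e-9:
        raise ValueError("synthetic collisions assume equal expansion speeds")
    return spans, ys[0][0], ys[0][1]


def synth_collision(spec: SynthSpec) -> SynthResult:
    """Generate one synthetic two-rectangle collision assay.

    Returns the label movie, the v_x and density window fields, the nuclei
    table and the :class:`GroundTruth`.  See the module docstring for the
    generative model.
    """
    if spec.noise_v < 0 or spec.noise_rho < 0:
        raise ValueError("noise levels must be >= 0")
    spans, y0, y1 = _rect_intervals(spec.scene)
    (l1, r1, id_a), (l2, r2, id_b) = spans
    rho0 = {t.id: t.density for t in spec.scene.tissues}
    if any(v is None for v in rho0.values()):
        raise ValueError("every tissue needs an initial density")
    v_n = spec.scene.speed_of(id_a)
    world_w, world_h = spec.scene.world_extent
    rng = np.random.default_rng(spec.seed)

    dx = spec.dx
    x_f = np.arange(dx / 2, world_w, dx)
    faces = np.arange(0.0, world_w + dx / 2, dx)
    nxf = x_f.size
    nt = int(round(spec.t_end / spec.dt)) + 1
    times = np.arange(nt) * spec.dt

    t_c = (l2 - r1) / (2 * v_n)
    x_fuse = 0.5 * (r1 + l2)
    rho = np.zeros(nxf)
    rho[(x_f >= l1) & (x_f <= r1)] = rho0[id_a]
    rho[(x_f >= l2) & (x_f <= r2)] = rho0[id_b]
    if abs(rho0[id_a] - rho0[id_b]) <= 1e-9 * max(rho0[id_a], rho0[id_b]):
        dense_id = None  # symmetric control: no denser side
    else:
        dense_id = id_a if rho0[id_a] > rho0[id_b] else id_b

    edge_l, edge_r = l1, r2
    inner_r1, inner_l2 = r1, l2
    x_b = np.nan

    boundary_x = np.full(nt, np.nan)
    center_x = np.full(nt, np.nan)
    v_bound = np.full(nt, np.nan)
    edges_t = np.zeros((nt, 2))
    rho_t = np.zeros((nt, nxf))
    v_t = np.full((nt, nxf), np.nan)

    def gradient_at(xb: float) -> float:
        w = spec.gradient_width
        left = (x_f >= xb - w) & (x_f < xb)
        right = (x_f > xb) & (x_f <= xb + w)
        return (rho[right].mean() - rho[left].mean()) / w

    for n, t in enumerate(times):
        fused = t >= t_c - 1e-12
        if fused and np.isnan(x_b):
            x_b = x_fuse
        # --- velocity profile at time t (um/h), NaN outside tissue
        v_face = np.zeros(faces.size)
        v_prof = np.full(nxf, np.nan)
        if not fused:
            for (lo, hi) in ((edge_l, inner_r1), (inner_l2, edge_r)):
                for arr, pos in ((v_face, faces), (v_prof, x_f)):
                    sel = (pos >= lo) & (pos <= hi)
                    arr[sel] = v_n * (
                        np.exp(-(hi - pos[sel]) / spec.edge_decay)
                        - np.exp(-(pos[sel] - lo) / spec.edge_decay)
                    )
            v_b = np.nan
            x_e = np.nan
        else:
            grad = gradient_at(x_b)
            v_b = float(pressure_velocity(grad, spec.p_prime, spec.xi))
            cent_fused = 0.5 * (edge_l + edge_r)
            if dense_id is None:
                cent_dense = cent_fused
            elif dense_id == id_a:
                cent_dense = 0.5 * (edge_l + x_fuse)
            else:
                cent_dense = 0.5 * (x_fuse + edge_r)
            x_e = cent_fused + (cent_dense - cent_fused) * np.exp(
                -(t - t_c) / spec.tau_center)
            nodes_x = np.array([edge_l, x_e, x_b, edge_r])
            nodes_v = np.array([-v_n, 0.0, v_b, v_n])
            order = np.argsort(nodes_x)
            nodes_x, nodes_v = nodes_x[order], nodes_v[order]
            for arr, pos in ((v_face, faces), (v_prof, x_f)):
                sel = (pos >= edge_l) & (pos <= edge_r)
                arr[sel] = np.interp(pos[sel], nodes_x, nodes_v)
        # --- record state
        edges_t[n] = (edge_l, edge_r)
        rho_t[n] = rho
        v_t[n] = v_prof
        boundary_x[n] = x_b
        center_x[n] = x_e if fused else np.nan
        v_bound[n] = v_b
        if n == nt - 1:
            break
        # --- advance one step: conservative upwind advection + growth
        n_sub = max(1, int(np.ceil(np.nanmax(np.abs(v_face)) * spec.dt
                                   / (0.9 * dx))))
        sub_dt = spec.dt / n_sub
        for _ in range(n_sub):
            upwind = np.where(v_face[1:-1] > 0, rho[:-1], rho[1:])
            flux = np.zeros(faces.size)
            flux[1:-1] = v_face[1:-1] * upwind
            rho = rho - sub_dt / dx * np.diff(flux)
        if spec.growth_rate > 0:
            occupied = rho > 1e-9
            rho[occupied] += (spec.dt * spec.growth_rate * rho[occupied]
                              * (1 - rho[occupied] / spec.rho_max))
        edge_l = max(edge_l - v_n * spec.dt, dx / 2)
        edge_r = min(edge_r + v_n * spec.dt, world_w - dx / 2)
        if not fused:
            inner_r1 = min(inner_r1 + v_n * spec.dt, x_fuse)
            inner_l2 = max(inner_l2 - v_n * spec.dt, x_fuse)
        else:
            x_b = x_b + v_b * spec.dt

    truth = GroundTruth(
        t_h=times, boundary_x=boundary_x, center_x=center_x,
        v_boundary=v_bound, edges=edges_t, x_fine=x_f, rho_profiles=rho_t,
        v_profiles=v_t, p_prime=spec.p_prime, xi=spec.xi, v_n=v_n,
        t_collision=t_c, x_fuse=x_fuse, seed=spec.seed,
    )
    movie = _label_movie(spec, truth, id_a, id_b, y0, y1)
    vx_movie, rho_movie = _window_fields(spec, truth, rng, y0, y1)
    nuclei = _nuclei_table(spec, rho_movie, rng)
    return SynthResult(movie, vx_movie, rho_movie, nuclei, truth)


def _occupied_spans(spec: SynthSpec, truth: GroundTruth, n: int):
    """Occupied x-intervals [(lo, hi, tissue), ...] at frame n."""
    el, er = truth.edges[n]
    t = truth.t_h[n]
    spans, _, _ = _rect_intervals(spec.scene)
    (l1, r1, id1), (l2, r2, id2) = spans
    if t >= truth.t_collision - 1e-12:
        xb = truth.boundary_x[n]
        return [(el, xb, id1), (xb, er, id2)]
    adv = truth.v_n * t
    return [(el, min(r1 + adv, truth.x_fuse), id1),
            (max(l2 - adv, truth.x_fuse), er, id2)]


def _label_movie(spec, truth, id_a, id_b, y0, y1) -> LabelMovie:
    world_w, world_h = spec.scene.world_extent
    grid = Grid.from_extent(world_w, world_h, spec.label_spacing)
    xs, ys = grid.x_centers, grid.y_centers
    in_y = (ys >= y0) & (ys <= y1)
    nt = truth.t_h.size
    frames = np.zeros((nt, grid.ny, grid.nx), dtype=np.int16)
    for n in range(nt):
        row = np.zeros(grid.nx, dtype=np.int16)
        for lo, hi, tid in _occupied_spans(spec, truth, n):
            row[(xs >= lo) & (xs < hi)] = tid
        frames[n][np.ix_(in_y, row > 0)] = row[row > 0]
    speeds = dict(spec.scene.speeds)
    return LabelMovie(frames, truth.t_h.copy(), grid, speeds)


def _window_fields(spec, truth, rng, y0, y1):
    world_w, _ = spec.scene.world_extent
    w = spec.window_um
    xw = np.arange(w / 2, world_w, w)
    yw = np.arange(y0 + w / 2, y1, w)
    nt = truth.t_h.size
    vx = np.full((nt, yw.size, xw.size), np.nan)
    rho = np.full((nt, yw.size, xw.size), np.nan)
    for n in range(nt):
        occ = np.zeros(xw.size, dtype=bool)
        for lo, hi, _tid in _occupied_spans(spec, truth, n):
            occ |= (xw >= lo) & (xw <= hi)
        v_row = np.interp(xw, truth.x_fine,
                          np.nan_to_num(truth.v_profiles[n], nan=0.0))
        r_row = np.interp(xw, truth.x_fine, truth.rho_profiles[n])
        vx[n][:, occ] = v_row[None, occ]
        rho[n][:, occ] = r_row[None, occ]
    if spec.noise_v > 0:
        vx = vx + spec.noise_v * rng.standard_normal(vx.shape)
    if spec.noise_rho > 0:
        rho = rho * (1 + spec.noise_rho * rng.standard_normal(rho.shape))
    return (
        FieldMovie(vx, xw, yw, truth.t_h.copy(), kind="v_x", window_um=w),
        FieldMovie(rho, xw, yw, truth.t_h.copy(), kind="density", window_um=w),
    )


def _nuclei_table(spec, rho_movie, rng) -> pd.DataFrame:
    """Poisson nuclei snapshots at a coarser cadence than the field movies."""
    every = max(1, int(round(spec.nuclei_every_h / spec.dt)))
    idx = np.arange(0, rho_movie.t_h.size, every)
    sub = FieldMovie(rho_movie.values[idx], rho_movie.x_um, rho_movie.y_um,
                     rho_movie.t_h[idx], kind="density",
                     window_um=rho_movie.window_um)
    return synth_nuclei(sub, rng)


def synth_nuclei(density: FieldMovie, seed_or_rng=0) -> pd.DataFrame:
    """Sample an inhomogeneous Poisson nuclei pattern from a density field.

    Expected count per window is ``density * window_area``; points are
    uniform within their window.  Columns: x_um, y_um, t_h.
    """
    rng = (seed_or_rng if isinstance(seed_or_rng, np.random.Generator)
           else np.random.default_rng(seed_or_rng))
    vals = np.nan_to_num(density.values, nan=0.0)
    if (vals < 0).any():
        raise ValueError("density must be non-negative")
    w = density.window_um
    area_mm2 = (w * 1e-3) ** 2
    counts = rng.poisson(vals * area_mm2)
    frames = []
    for i, t in enumerate(density.t_h):
        total = int(counts[i].sum())
        if total == 0:
            continue
        rows, cols = np.nonzero(counts[i])
        reps = counts[i][rows, cols]
        cy = np.repeat(density.y_um[rows], reps)
        cx = np.repeat(density.x_um[cols], reps)
        jitter = rng.uniform(-w / 2, w / 2, size=(total, 2))
        frames.append(pd.DataFrame({
            "x_um": cx + jitter[:, 0],
            "y_um": cy + jitter[:, 1],
            "t_h": t,
        }))
    if not frames:
        return pd.DataFrame(columns=["x_um", "y_um", "t_h"])
    return pd.concat(frames, ignore_index=True)


def synth_velocity_density_pairs(
    p_prime: float = 0.5,
    xi: float = DEFAULT_XI,
    n: int = 25,
    noise_frac: float = 0.1,
    seed: int = 0,
    gradient_range: tuple[float, float] = (-3.0, 0.0),
) -> pd.DataFrame:
    """Synthetic (density gradient, boundary velocity) pairs on the model line.

    Gradients are uniform over ``gradient_range`` (cells/(mm^2 um));
    velocities follow the pressure-driven relation with multiplicative
    Gaussian noise of fractional amplitude ``noise_frac``.  Emulates the
    per-assay scatter used to fit the pressure-density slope.
    """
    if n < 2:
        raise ValueError("need at least two pairs")
    if noise_frac < 0:
        raise ValueError("noise fraction must be >= 0")
    rng = np.random.default_rng(seed)
    g = rng.uniform(*gradient_range, size=n)
    v = pressure_velocity(g, p_prime, xi)
    if noise_frac > 0:
        v = v * (1 + noise_frac * rng.standard_normal(n))
    return pd.DataFrame({"drho_dx": g, "v_boundary": v})
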