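"""Colliding-front tissue expansion engine.

Each tissue edge advances into free space with a uniform outward normal
speed v_n; where two fronts meet, the boundary pins in place and never moves
again.  This purely geometric rule — no mechanics, no cell-scale detail —
predicts the shapes of tissue tessellations at the 100+ um scale, and with
per-tissue speeds it reproduces engulfment of slow tissues by fast ones.

Numerics
--------
The engine tracks, for every claimed pixel, the continuous travel distance
``f`` of the front from the tissue's initial footprint.  At each time step
the distance field is relaxed over a Euclidean "chord" window (radius 5
pixels by default): a free pixel's tentative distance is the minimum of
``f(neighbour) + |offset|`` over all claimed pixels in the window, computed
with a single grey-scale erosion.  A pixel is claimed once its tentative
distance falls below the front's cumulative advance ``v_n * t``.  Because
distances accumulate along chords of real Euclidean length, long-run edge
speed is exact and fronts stay isotropic (worst-case direction error is a
fraction of a percent), unlike repeated single-pixel dilation whose limit
shape is a diamond.  Chords are short enough that fronts cannot jump across
other tissues at tissue scales.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.stats import linregress

from .scenes import Grid, LabelField, MaskShape, Scene, rasterize

__all__ = [
    "ArrivalField",
    "LabelMovie",
    "FrontEngine",
    "step_fronts",
    "simulate",
    "arrival_partition",
    "free_edge_speed",
]


@dataclass
class ArrivalField:
    """Front arrival time of one tissue at every pixel (hours; inf = never)."""

    tissue_id: int
    times_h: np.ndarray
    grid: Grid


@dataclass
class LabelMovie:
    """Stack of label fields at increasing times, with the speeds that made it."""

    frames: np.ndarray  # (nt, ny, nx) integer labels
    times: np.ndarray   # (nt,) hours
    grid: Grid
    speeds: dict[int, float] = field(default_factory=dict)

    def __post_init__(self):
        self.frames = np.asarray(self.frames)
        self.times = np.asarray(self.times, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[0] != self.times.size:
            raise ValueError("frames must be (nt, ny, nx) matching times")

    def __len__(self) -> int:
        return self.frames.shape[0]

    def field(self, index: int) -> LabelField:
        return LabelField(self.frames[index], self.grid, time=float(self.times[index]))

    @property
    def final(self) -> LabelField:
        return self.field(len(self) - 1)

    @property
    def dt(self) -> float:
        return float(np.median(np.diff(self.times))) if len(self) > 1 else 0.0


def _chord_kernel(radius_px: int, spacing: float):
    r = int(radius_px)
    dy, dx = np.mgrid[-r:r + 1, -r:r + 1]
    dist = np.hypot(dy, dx) * spacing
    footprint = dist <= r * spacing + 1e-9
    return footprint, dist


class FrontEngine:
    """Stateful multi-tissue front propagator with pinning on contact.

    Carries per-pixel continuous front distances between steps so that the
    long-run edge speed of every tissue equals its nominal v_n regardless of
    the time step (subject to the CFL condition ``v * dt <= spacing``).
    """

    def __init__(self, initial: LabelField, speeds: dict[int, float],
                 chord_radius_px: int = 5):
        self.grid = initial.grid
        self.spacing = initial.grid.spacing
        self.labels = np.asarray(initial.labels).copy()
        self.time = float(initial.time)
        present = set(initial.ids())
        unknown = present - set(speeds)
        if unknown:
            raise ValueError(f"no speed given for tissue ids {sorted(unknown)}")
        self.speeds = {int(k): float(v) for k, v in speeds.items()}
        for k, v in self.speeds.items():
            if v < 0:
                raise ValueError(f"tissue {k}: speed must be >= 0")
        self.ids = sorted(self.speeds)
        # continuous travel distance from the initial footprint boundary,
        # per tissue; seed pixels carry the (negative) signed distance so
        # fronts start from the footprint edge, not from pixel centers
        self._dist = {}
        for k in self.ids:
            inside = self.labels == k
            d_in = ndimage.distance_transform_edt(inside) * self.spacing
            self._dist[k] = np.where(
                inside, -np.maximum(d_in - self.spacing / 2.0, 0.0), np.inf
            )
        self._footprint, kernel_dist = _chord_kernel(chord_radius_px, self.spacing)
        # grey_erosion computes min(input(x+y) - structure(y)); with
        # structure = -distance this is min over the window of f + |offset|
        self._structure = -kernel_dist

    def check_cfl(self, dt: float) -> None:
        for k in self.ids:
            if self.speeds[k] * dt > self.spacing * (1 + 1e-9):
                raise ValueError(
                    f"CFL violation: tissue {k} advances "
                    f"{self.speeds[k] * dt:.2f} um per step but the grid "
                    f"spacing is {self.spacing:.2f} um; reduce dt to at most "
                    f"{self.spacing / self.speeds[k]:.4f} h"
                )

    def step(self, dt: float) -> LabelField:
        """Advance all fronts by ``dt`` hours and return the new label field."""
        if dt <= 0:
            raise ValueError("dt must be positive")
        self.check_cfl(dt)
        t_new = self.time + dt
        free = self.labels == 0
        best_arrival = np.full(self.labels.shape, np.inf)
        best_id = np.zeros(self.labels.shape, dtype=self.labels.dtype)
        tentative = {}
        for k in self.ids:
            v = self.speeds[k]
            if v <= 0 or not np.isfinite(self._dist[k]).any():
                continue
            g = ndimage.grey_erosion(
                self._dist[k], footprint=self._footprint,
                structure=self._structure, mode="constant", cval=np.inf,
            )
            tentative[k] = g
            arrival = g / v
            eligible = free & (g <= v * t_new)
            # ascending id order + strict '<' makes exact ties go to lower id
            better = eligible & (arrival < best_arrival)
            best_arrival[better] = arrival[better]
            best_id[better] = k
        for k in tentative:
            claimed = best_id == k
            if claimed.any():
                self.labels[claimed] = k
                self._dist[k][claimed] = tentative[k][claimed]
        self.time = t_new
        return LabelField(self.labels.copy(), self.grid, time=self.time)


@dataclass
class FrontState:
    """Opaque carry-over state for the functional :func:`step_fronts` API."""

    engine: FrontEngine


def step_fronts(
    current: LabelField,
    speeds: dict[int, float],
    dt: float,
    state: FrontState | None = None,
) -> tuple[LabelField, FrontState]:
    """Advance every tissue front by one time step of ``dt`` hours.

    Pass the returned :class:`FrontState` back in on subsequent calls so the
    sub-pixel advance of each front is carried between steps; without it,
    each call starts the advance budget from zero and slow fronts may never
    claim a pixel.  :func:`simulate` does this bookkeeping for you.
    """
    if state is None:
        state = FrontState(FrontEngine(current, speeds))
    new = state.engine.step(dt)
    return new, state


def simulate(
    scene: Scene,
    grid: Grid | None = None,
    t_end: float = 60.0,
    dt: float = 1.0 / 3.0,
    spacing: float = 10.0,
    chord_radius_px: int = 5,
) -> LabelMovie:
    """Run the colliding-front model from a scene's initial condition.

    Defaults follow the standard experimental setup: 10 um grid, one frame
    every 20 min, v_n from the scene (29.5 um/h unless overridden).
    Deterministic for fixed inputs.
    """
    if grid is None:
        grid = Grid.from_extent(*scene.world_extent, spacing=spacing)
    initial = rasterize(scene, grid)
    engine = FrontEngine(initial, scene.speeds, chord_radius_px=chord_radius_px)
    engine.check_cfl(dt)
    n_steps = int(round(t_end / dt))
    frames = [initial.labels.copy()]
    times = [0.0]
    for i in range(n_steps):
        fld = engine.step(dt)
        frames.append(fld.labels.copy())
        times.append(fld.time)
        if not (fld.labels == 0).any() and i < n_steps - 1:
            # world full: remaining frames are identical
            remaining = n_steps - 1 - i
            frames.extend([fld.labels.copy()] * remaining)
            times.extend((np.arange(1, remaining + 1) * dt + fld.time).tolist())
            break
    return LabelMovie(np.stack(frames), np.asarray(times), grid, dict(scene.speeds))


def arrival_partition(scene: Scene, grid: Grid | None = None,
                      spacing: float = 10.0) -> tuple[LabelField, dict[int, ArrivalField]]:
    """Closed-form tessellation oracle for unobstructed front growth.

    Assigns each pixel to the tissue with the smallest straight-line arrival
    time ``T_k = d(x, seed_k) / v_k`` (an additively/multiplicatively
    weighted-distance partition).  Exact for convex seeds at equal speeds as
    long as no front has to wrap around another tissue; used as an
    independent check of :func:`simulate`.
    """
    if grid is None:
        grid = Grid.from_extent(*scene.world_extent, spacing=spacing)
    for t in scene.tissues:
        if isinstance(t.shape, MaskShape):
            continue
        geom = t.shape.to_shapely()
        if geom.convex_hull.area > geom.area * (1 + 1e-6) + 1e-9:
            warnings.warn(
                f"tissue {t.id} seed is non-convex; the arrival-time oracle "
                "may disagree with the stepped simulation",
                stacklevel=2,
            )
    X, Y = grid.meshgrid()
    ids = sorted(t.id for t in scene.tissues)
    by_id = {t.id: t for t in scene.tissues}
    arrivals = {}
    stack = np.full((len(ids),) + grid.shape, np.inf)
    for idx, tid in enumerate(ids):
        seed = by_id[tid].shape.contains_points(X, Y)
        v = scene.speed_of(tid)
        dist = ndimage.distance_transform_edt(~seed) * grid.spacing
        with np.errstate(divide="ignore", invalid="ignore"):
            times = np.where(seed, 0.0, dist / v if v > 0 else np.inf)
        arrivals[tid] = ArrivalField(tid, times, grid)
        stack[idx] = times
    winner = np.argmin(stack, axis=0)  # ties -> first index -> lowest id
    labels = np.asarray(ids, dtype=np.int32)[winner]
    labels[~np.isfinite(np.min(stack, axis=0))] = 0
    return LabelField(labels, grid, time=np.inf), arrivals


def _free_edge_mask(labels: np.ndarray, tissue_id: int) -> np.ndarray:
    tissue = labels == tissue_id
    free = labels == 0
    plus = ndimage.generate_binary_structure(2, 1)
    near_free = ndimage.binary_dilation(free, structure=plus)
    return tissue & near_free


def free_edge_speed(movie: LabelMovie, tissue_id: int,
                    method: str = "radius") -> float:
    """Outward speed of a tissue's free (non-contact) edge in um/h.

    ``method="radius"`` regresses the effective radius ``sqrt(A / pi)`` on
    time — exact for freely expanding circles.  ``method="edge"`` regresses
    the mean distance of free-edge pixels from the initial footprint, which
    is shape-independent for convex seeds (uniform normal growth advances
    every edge point by v_n * t).
    """
    has_free_edge = [
        _free_edge_mask(movie.frames[i], tissue_id).any() for i in range(len(movie))
    ]
    if not any(has_free_edge):
        raise ValueError(
            f"tissue {tissue_id} has no free edge over the movie; "
            "free-edge speed is undefined"
        )
    t = movie.times
    if method == "radius":
        areas = (movie.frames == tissue_id).sum(axis=(1, 2)) * movie.grid.spacing ** 2
        values = np.sqrt(areas / np.pi)
    elif method == "edge":
        initial = movie.frames[0] == tissue_id
        dist0 = ndimage.distance_transform_edt(~initial) * movie.grid.spacing
        values = np.full(len(movie), np.nan)
        for i in range(len(movie)):
            edge = _free_edge_mask(movie.frames[i], tissue_id)
            if edge.any():
                values[i] = dist0[edge].mean()
    else:
        raise ValueError("method must be 'radius' or 'edge'")
    ok = np.isfinite(values)
    if ok.sum() < 2:
        raise ValueError("need at least two frames with a free edge")
    if np.allclose(values[ok], values[ok][0]):
        return 0.0
    return float(linregress(t[ok], values[ok]).slope)
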