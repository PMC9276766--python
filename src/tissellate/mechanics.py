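"""Collision mechanics: kymographs, center of expansion, boundary motion,
density gradients, and the pressure-density model.

Model
-----
After two monolayers collide, active traction at the fused boundary (which
is ~1 mm from the outer edges) is negligible, and boundary motion is driven
by tissue pressure gradients balanced by cell-substrate friction::

    -grad P = xi * v                       (force balance)
    v = -(P'(rho) / xi) * grad rho         (with P = P(rho), P' > 0)

so the boundary moves from high to low cell density with speed proportional
to the density gradient.  Fitting boundary velocity against the density
gradient across assays yields the pressure-density slope P'(rho); with a
logarithmic equation of state ``P = K ln(rho / rho_e)`` this gives the
monolayer bulk modulus ``K = rho * P'(rho)``.

Units: velocities um/h, densities cells/mm^2, gradients cells/(mm^2 um),
friction xi in Pa s/um^2, P' in Pa mm^2, pressures Pa.  The h <-> s
conversion is handled internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import linregress, pearsonr

__all__ = [
    "FieldMovie",
    "Kymograph",
    "BoundaryTrace",
    "MechFit",
    "build_kymograph",
    "average_kymographs",
    "center_of_expansion",
    "boundary_trace_from_labels",
    "boundary_velocity",
    "density_from_nuclei",
    "density_gradient_at_boundary",
    "density_gradient_series",
    "pressure_velocity",
    "fit_pressure_slope",
    "bulk_modulus",
    "eos_pressure",
    "stiffness_from_tension",
]

SECONDS_PER_HOUR = 3600.0


def _nanmean_axis(values: np.ndarray, axis: int) -> np.ndarray:
    """nanmean that returns NaN (without warning) for all-NaN slices."""
    finite = np.isfinite(values)
    counts = finite.sum(axis=axis)
    sums = np.where(finite, values, 0.0).sum(axis=axis)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = sums / counts
    return np.where(counts > 0, out, np.nan)

#: Cell-substrate friction coefficient, Pa s/um^2 (literature value).
DEFAULT_XI = 100.0

#: PIV analysis window edge length, um.
DEFAULT_WINDOW_UM = 88.0


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class FieldMovie:
    """Gridded scalar field sampled on square windows over time.

    ``values`` has shape (nt, ny, nx); NaN marks windows with no tissue.
    ``kind`` is ``"v_x"`` (um/h) or ``"density"`` (cells/mm^2).
    """

    values: np.ndarray
    x_um: np.ndarray
    y_um: np.ndarray
    t_h: np.ndarray
    kind: str = "v_x"
    window_um: float = DEFAULT_WINDOW_UM

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.x_um = np.asarray(self.x_um, dtype=float)
        self.y_um = np.asarray(self.y_um, dtype=float)
        self.t_h = np.asarray(self.t_h, dtype=float)
        if self.values.shape != (self.t_h.size, self.y_um.size, self.x_um.size):
            raise ValueError("values must have shape (nt, ny, nx)")
        if self.t_h.size > 1 and not np.all(np.diff(self.t_h) > 0):
            raise ValueError("timepoints must be strictly increasing")


@dataclass
class Kymograph:
    """Space x time matrix of a band-averaged field.

    ``values[i, j]`` is the average of the field in x-bin ``i`` at time
    ``t_h[j]``; NaN marks bins with no tissue.
    """

    values: np.ndarray  # (nx, nt)
    x_um: np.ndarray    # bin centers
    t_h: np.ndarray
    kind: str = "v_x"
    bin_um: float = DEFAULT_WINDOW_UM
    band: tuple[float, float] | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.x_um), len(self.t_h)):
            raise ValueError("kymograph must be (n_x_bins, n_timepoints)")


@dataclass
class BoundaryTrace:
    """Tissue-boundary x-position versus time; NaN before fusion."""

    t_h: np.ndarray
    x_um: np.ndarray
    x0: float
    t_fuse: float
    x_fuse: float

    def __post_init__(self):
        self.t_h = np.asarray(self.t_h, dtype=float)
        self.x_um = np.asarray(self.x_um, dtype=float)
        if self.t_h.shape != self.x_um.shape:
            raise ValueError("t_h and x_um must have the same shape")


@dataclass
class MechFit:
    """Linear fit of boundary velocity vs density gradient and derived moduli."""

    slope: float            # (um/h) per (cells/(mm^2 um))
    intercept: float        # um/h
    r: float                # Pearson r over individual pairs
    xi: float               # Pa s/um^2
    p_prime: float          # Pa mm^2
    rho_mean: float | None = None   # cells/mm^2
    bulk_modulus_pa: float | None = None
    n_pairs: int = 0
    n_assays: int = 0

    def as_dict(self) -> dict:
        return {
            "slope_um_per_h_per_gradient": self.slope,
            "intercept_um_per_h": self.intercept,
            "r_individual": self.r,
            "xi_pa_s_per_um2": self.xi,
            "p_prime_pa_mm2": self.p_prime,
            "rho_mean_per_mm2": self.rho_mean,
            "bulk_modulus_pa": self.bulk_modulus_pa,
            "n_pairs": self.n_pairs,
            "n_assays": self.n_assays,
        }


# ---------------------------------------------------------------------------
# kymographs
# ---------------------------------------------------------------------------

def _moving_average_time(values: np.ndarray, width: int) -> np.ndarray:
    """NaN-aware centered moving average along the last (time) axis."""
    if width <= 1:
        return values
    kernel = np.ones(width)
    filled = np.where(np.isfinite(values), values, 0.0)
    counts = np.isfinite(values).astype(float)
    num = np.apply_along_axis(lambda m: np.convolve(m, kernel, "same"), -1, filled)
    den = np.apply_along_axis(lambda m: np.convolve(m, kernel, "same"), -1, counts)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / den
    out[den == 0] = np.nan
    return out


def build_kymograph(movie: FieldMovie, band_margin: float = 1000.0,
                    bin_um: float | None = None,
                    time_smooth: int = 3) -> Kymograph:
    """Collapse a field movie to a space x time kymograph.

    Each column is the average of the field over the vertical (y) direction,
    ignoring ``band_margin`` um at the top and bottom of the data (1 mm by
    default, where edge effects of the strip dominate), followed by a
    centered moving average over ``time_smooth`` timepoints (3 by default,
    matching the measurement cadence; pass 1 to disable).  Bins with no
    tissue stay NaN, never zero.
    """
    y0, y1 = movie.y_um.min() + band_margin, movie.y_um.max() - band_margin
    rows = (movie.y_um >= y0 - 1e-9) & (movie.y_um <= y1 + 1e-9)
    if not rows.any():
        raise ValueError(
            f"band_margin {band_margin} um leaves no rows in a field of "
            f"height {movie.y_um.max() - movie.y_um.min():.0f} um"
        )
    band = movie.values[:, rows, :]
    cols = _nanmean_axis(band, axis=1)  # (nt, nx)
    values = cols.T  # (nx, nt)
    x = movie.x_um.copy()
    out_bin = movie.window_um
    if bin_um is not None and bin_um > movie.window_um * (1 + 1e-9):
        factor = max(1, int(round(bin_um / movie.window_um)))
        n = (values.shape[0] // factor) * factor
        values = _nanmean_axis(
            values[:n].reshape(-1, factor, values.shape[1]), axis=1)
        x = x[:n].reshape(-1, factor).mean(axis=1)
        out_bin = movie.window_um * factor
    values = _moving_average_time(values, time_smooth)
    return Kymograph(values, x, movie.t_h.copy(), kind=movie.kind,
                     bin_um=out_bin, band=(float(y0), float(y1)))


def average_kymographs(kymos: list[Kymograph],
                       offsets_um: list[float] | None = None) -> Kymograph:
    """Element-wise mean of kymographs aligned by initial configuration.

    ``offsets_um[i]`` shifts kymograph ``i`` left by that amount (rounded to
    whole bins) before averaging, so assays with different absolute
    positions align on their initial tissue configuration.  The output
    extent is the median extent of the aligned inputs.
    """
    if not kymos:
        raise ValueError("need at least one kymograph")
    k0 = kymos[0]
    for k in kymos[1:]:
        if abs(k.bin_um - k0.bin_um) > 1e-6:
            raise ValueError("kymographs have incompatible x binning")
        if k.t_h.size != k0.t_h.size or not np.allclose(k.t_h, k0.t_h):
            raise ValueError("kymographs have incompatible time sampling")
    if offsets_um is None:
        offsets_um = [0.0] * len(kymos)
    if len(offsets_um) != len(kymos):
        raise ValueError("one offset per kymograph required")
    bin_um = k0.bin_um
    # integer bin index of each kymograph's first bin after alignment
    starts = []
    for k, off in zip(kymos, offsets_um):
        starts.append(int(round((k.x_um[0] - off) / bin_um)))
    lo = min(starts)
    hi = max(s + k.values.shape[0] for s, k in zip(starts, kymos))
    acc = np.zeros((hi - lo, k0.t_h.size))
    cnt = np.zeros_like(acc)
    for k, s in zip(kymos, starts):
        sl = slice(s - lo, s - lo + k.values.shape[0])
        finite = np.isfinite(k.values)
        acc[sl][finite] += k.values[finite]
        cnt[sl][finite] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = acc / cnt
    mean[cnt == 0] = np.nan
    # crop to the median extent of the aligned individual kymographs
    med_lo = int(round(float(np.median(starts))))
    med_hi = int(round(float(np.median(
        [s + k.values.shape[0] for s, k in zip(starts, kymos)]))))
    sl = slice(med_lo - lo, med_hi - lo)
    x = (np.arange(lo, hi) * bin_um)[sl]
    return Kymograph(mean[sl], x, k0.t_h.copy(), kind=k0.kind, bin_um=bin_um,
                     band=k0.band)


def center_of_expansion(vx_kymo: Kymograph, threshold: float = 3.0) -> np.ndarray:
    """Per-timepoint position from which tissue flow diverges, um.

    Bins with ``|v_x| < threshold`` (default 3 um/h) are marked, the largest
    contiguous run is kept, and its midpoint returned.  NaN when no bin
    passes at a timepoint.
    """
    x = vx_kymo.x_um
    out = np.full(vx_kymo.t_h.size, np.nan)
    for j in range(vx_kymo.t_h.size):
        col = vx_kymo.values[:, j]
        ok = np.isfinite(col) & (np.abs(col) < threshold)
        if not ok.any():
            continue
        padded = np.concatenate([[False], ok, [False]])
        starts = np.flatnonzero(padded[1:] & ~padded[:-1])
        ends = np.flatnonzero(~padded[1:] & padded[:-1])
        i = int(np.argmax(ends - starts))
        out[j] = 0.5 * (x[starts[i]] + x[ends[i] - 1])
    return out


# ---------------------------------------------------------------------------
# boundary motion
# ---------------------------------------------------------------------------

def boundary_trace_from_labels(movie, id_a: int, id_b: int) -> BoundaryTrace:
    """Boundary x-position per frame of a label movie (mean over interface).

    Fusion is the first frame at which the two labels are 4-adjacent; the
    trace is NaN before fusion.  The initial midline ``x0`` is the midpoint
    of the gap between the tissues in the first frame.
    """
    from scipy import ndimage as ndi

    frames = movie.frames
    grid = movie.grid
    xs = grid.x_centers
    plus = ndi.generate_binary_structure(2, 1)
    trace = np.full(len(movie), np.nan)
    t_fuse = np.nan
    x_fuse = np.nan
    for i in range(len(movie)):
        a = frames[i] == id_a
        b = frames[i] == id_b
        touch = ndi.binary_dilation(a, plus) & b
        if not touch.any():
            continue
        # midpoints of 4-adjacent A-B pixel pairs, x coordinate
        vals = []
        for shift in (1, -1):
            pair = a & np.roll(b, shift, axis=1)
            if shift == 1:
                pair[:, 0] = False  # wrap-around guard
            else:
                pair[:, -1] = False
            if pair.any():
                cols = np.nonzero(pair)[1]
                vals.append(xs[cols] - shift * grid.spacing / 2.0)
        down = np.roll(b, 1, axis=0)
        down[0, :] = False
        up = np.roll(b, -1, axis=0)
        up[-1, :] = False
        pair_v = a & (down | up)
        if pair_v.any():
            vals.append(xs[np.nonzero(pair_v)[1]])
        trace[i] = float(np.concatenate(vals).mean())
        if np.isnan(t_fuse):
            t_fuse = float(movie.times[i])
            x_fuse = trace[i]
    a0 = np.nonzero((frames[0] == id_a).any(axis=0))[0]
    b0 = np.nonzero((frames[0] == id_b).any(axis=0))[0]
    if a0.size and b0.size and a0.max() < b0.min():
        x0 = 0.5 * (xs[a0.max()] + xs[b0.min()])
    elif a0.size and b0.size and b0.max() < a0.min():
        x0 = 0.5 * (xs[b0.max()] + xs[a0.min()])
    else:
        x0 = x_fuse
    return BoundaryTrace(movie.times.copy(), trace, x0=float(x0),
                         t_fuse=t_fuse, x_fuse=float(x_fuse))


def boundary_velocity(trace: BoundaryTrace,
                      window: tuple[float, float] = (20.0, 36.0)) -> float:
    """Least-squares boundary speed (um/h) over a time window (default
    20-36 h, after collision and before the boundary stalls)."""
    t0, t1 = window
    sel = (trace.t_h >= t0) & (trace.t_h <= t1) & np.isfinite(trace.x_um)
    if sel.sum() < 3:
        raise ValueError(
            f"boundary trace has only {int(sel.sum())} points in "
            f"[{t0}, {t1}] h; need at least 3"
        )
    x = trace.x_um[sel]
    if np.allclose(x, x[0]):
        return 0.0
    return float(linregress(trace.t_h[sel], x).slope)


# ---------------------------------------------------------------------------
# density
# ---------------------------------------------------------------------------

def density_from_nuclei(nuclei: pd.DataFrame, extent: tuple[float, float],
                        window_um: float = DEFAULT_WINDOW_UM) -> FieldMovie:
    """Cell density field from nucleus centroids, cells/mm^2 per window.

    ``nuclei`` needs columns ``x_um``, ``y_um`` and optionally ``t_h``
    (missing means a single timepoint at 0 h).  Each window's density is
    its centroid count divided by the window area; empty windows are 0.
    """
    width, height = extent
    x_edges = np.arange(0.0, width + window_um / 2, window_um)
    y_edges = np.arange(0.0, height + window_um / 2, window_um)
    if "t_h" not in nuclei.columns:
        nuclei = nuclei.assign(t_h=0.0)
    times = np.sort(nuclei["t_h"].unique()) if len(nuclei) else np.array([0.0])
    area_mm2 = (window_um * 1e-3) ** 2
    stack = np.zeros((times.size, y_edges.size - 1, x_edges.size - 1))
    for i, t in enumerate(times):
        sub = nuclei[nuclei["t_h"] == t]
        counts, _, _ = np.histogram2d(
            sub["y_um"], sub["x_um"], bins=[y_edges, x_edges])
        stack[i] = counts / area_mm2
    return FieldMovie(
        stack,
        x_um=(x_edges[:-1] + x_edges[1:]) / 2,
        y_um=(y_edges[:-1] + y_edges[1:]) / 2,
        t_h=times,
        kind="density",
        window_um=window_um,
    )


def _banded_profile(density: FieldMovie, t_index: int) -> np.ndarray:
    return _nanmean_axis(density.values[t_index], axis=0)


def density_gradient_at_boundary(density: FieldMovie, boundary_x: float,
                                 width: float = 300.0,
                                 t_h: float | None = None) -> float:
    """Density gradient across the boundary, cells/(mm^2 um).

    Computed as ``(rho_R - rho_L) / width`` where ``rho_L`` and ``rho_R``
    are mean densities in ``width``-um regions (default 300 um) immediately
    left and right of ``boundary_x``.  Exact for linear density profiles.
    """
    if t_h is None:
        t_idx = range(density.t_h.size)
    else:
        t_idx = [int(np.argmin(np.abs(density.t_h - t_h)))]
    x = density.x_um
    half = density.window_um / 2
    if boundary_x - width < x.min() - half or boundary_x + width > x.max() + half:
        raise ValueError(
            f"side regions of width {width} um around x={boundary_x:.0f} um "
            "extend outside the data"
        )
    left = (x >= boundary_x - width) & (x < boundary_x)
    right = (x > boundary_x) & (x <= boundary_x + width)
    if not left.any() or not right.any():
        raise ValueError("side regions contain no windows; widen them")
    grads = []
    for i in t_idx:
        profile = _banded_profile(density, i)
        rho_l = _nanmean_axis(profile[left], axis=0)
        rho_r = _nanmean_axis(profile[right], axis=0)
        if not (np.isfinite(rho_l) and np.isfinite(rho_r)):
            raise ValueError("side region lies outside the tissue")
        grads.append((rho_r - rho_l) / width)
    return float(np.mean(grads))


def density_gradient_series(density: FieldMovie, trace: BoundaryTrace,
                            width: float = 300.0) -> np.ndarray:
    """Per-timepoint density gradient at the (moving) boundary position.

    NaN where the trace is undefined.  Time bases of the density movie and
    the trace are matched by nearest neighbour.
    """
    out = np.full(density.t_h.size, np.nan)
    for i, t in enumerate(density.t_h):
        j = int(np.argmin(np.abs(trace.t_h - t)))
        xb = trace.x_um[j]
        if not np.isfinite(xb):
            continue
        try:
            out[i] = density_gradient_at_boundary(density, float(xb),
                                                  width=width, t_h=float(t))
        except ValueError:
            continue
    return out


# ---------------------------------------------------------------------------
# pressure-density model
# ---------------------------------------------------------------------------

def pressure_velocity(drho_dx: float | np.ndarray, p_prime: float = 0.5,
                      xi: float = DEFAULT_XI):
    """Boundary velocity (um/h) driven by a density gradient.

    Implements ``v = -(P'(rho)/xi) * d(rho)/dx`` with the h <-> s
    conversion: P' in Pa mm^2, gradient in cells/(mm^2 um), xi in
    Pa s/um^2 gives v in um/s, multiplied by 3600 to um/h.  A positive
    gradient drives negative (down-gradient) velocity.
    """
    if xi <= 0:
        raise ValueError("friction coefficient xi must be positive")
    return -(p_prime / xi) * np.asarray(drho_dx, dtype=float) * SECONDS_PER_HOUR


def fit_pressure_slope(gradients, velocities, xi: float = DEFAULT_XI,
                       assay=None, rho_mean: float | None = None,
                       through_origin: bool = False) -> MechFit:
    """Fit the boundary-velocity vs density-gradient line and invert for P'.

    The line is fit through assay-average points (pass ``assay`` labels to
    group pairs; by default every pair is its own assay), while the Pearson
    correlation ``r`` is reported over the individual pairs.  ``P' =
    -slope * xi`` with unit conversion; if ``rho_mean`` is given the bulk
    modulus ``K = P' * rho_mean`` is attached.
    """
    if xi <= 0:
        raise ValueError("friction coefficient xi must be positive")
    g = np.asarray(gradients, dtype=float)
    v = np.asarray(velocities, dtype=float)
    if g.shape != v.shape or g.size < 2:
        raise ValueError("need at least two (gradient, velocity) pairs")
    if assay is not None:
        df = pd.DataFrame({"g": g, "v": v, "assay": list(assay)})
        means = df.groupby("assay", sort=True).mean()
        gx, vy = means["g"].to_numpy(), means["v"].to_numpy()
    else:
        gx, vy = g, v
    if gx.size < 2 or np.ptp(gx) < 1e-12:
        raise ValueError("degenerate fit: gradients have no spread")
    if through_origin:
        slope = float(np.dot(gx, vy) / np.dot(gx, gx))
        intercept = 0.0
    else:
        res = linregress(gx, vy)
        slope, intercept = float(res.slope), float(res.intercept)
    if g.size >= 2 and np.ptp(g) > 1e-12 and np.ptp(v) > 1e-12:
        r = float(pearsonr(g, v)[0])
    else:
        r = np.nan
    p_prime = -slope * xi / SECONDS_PER_HOUR
    k = p_prime * rho_mean if rho_mean is not None else None
    return MechFit(slope=slope, intercept=intercept, r=r, xi=xi,
                   p_prime=p_prime, rho_mean=rho_mean, bulk_modulus_pa=k,
                   n_pairs=int(g.size),
                   n_assays=int(gx.size))


def bulk_modulus(p_prime: float, rho: float) -> float:
    """Bulk modulus K = P'(rho) * rho in Pa (logarithmic equation of state)."""
    if rho <= 0:
        raise ValueError("density must be positive")
    return float(p_prime * rho)


def eos_pressure(rho, K: float, rho_e: float):
    """Logarithmic equation of state ``P = K ln(rho / rho_e)`` in Pa."""
    rho = np.asarray(rho, dtype=float)
    if np.any(rho <= 0) or rho_e <= 0:
        raise ValueError("densities must be positive")
    if K <= 0:
        raise ValueError("bulk modulus must be positive")
    out = K * np.log(rho / rho_e)
    return float(out) if out.ndim == 0 else out


def stiffness_from_tension(gamma_mn_per_m: float, height_um: float) -> float:
    """Convert a monolayer tensile modulus to a 3D stiffness, kPa.

    ``E = Gamma / h``: Gamma in mN/m over a monolayer height in um;
    1 (mN/m)/um = 1 kPa.
    """
    if height_um <= 0:
        raise ValueError("monolayer height must be positive")
    return float(gamma_mn_per_m / height_um)
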