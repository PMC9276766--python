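"""File I/O: label TIFFs, field tables, boundary and nuclei CSVs.

Label fields and movies are stored as 16-bit label-valued TIFF (one page
per timepoint, time and grid metadata as JSON in the page description).
Field movies (velocity, density) travel as long-format delimited text with
columns ``x_um, y_um, t_h, value``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .boundaries import BoundaryCurve
from .mechanics import FieldMovie, Kymograph
from .scenes import Grid, LabelField
from .simulate import LabelMovie


# ---------------------------------------------------------------------------
# label TIFFs
# ---------------------------------------------------------------------------

def _page_meta(time: float, grid: Grid, speeds=None) -> str:
    meta = {
        "t_h": float(time),
        "spacing_um": grid.spacing,
        "origin_um": list(grid.origin),
    }
    if speeds:
        meta["speeds_um_per_h"] = {str(k): float(v) for k, v in speeds.items()}
    return json.dumps(meta)


def write_label_tiff(path: str | Path, data: LabelField | LabelMovie) -> None:
    """Write a label field or movie as 16-bit multi-page TIFF."""
    path = Path(path)
    if isinstance(data, LabelField):
        frames = [data.labels]
        times = [data.time]
        grid, speeds = data.grid, None
    else:
        frames = list(data.frames)
        times = list(data.times)
        grid, speeds = data.grid, data.speeds
    with tifffile.TiffWriter(path) as tif:
        for labels, t in zip(frames, times):
            tif.write(
                labels.astype(np.uint16),
                description=_page_meta(t, grid, speeds),
                contiguous=False,
            )


def read_label_movie(path: str | Path) -> LabelMovie:
    """Read a (multi-page) label TIFF written by :func:`write_label_tiff`."""
    frames = []
    times = []
    grid = None
    speeds: dict[int, float] = {}
    with tifffile.TiffFile(path) as tif:
        for i, page in enumerate(tif.pages):
            frames.append(page.asarray().astype(np.int32))
            try:
                meta = json.loads(page.description)
            except (json.JSONDecodeError, TypeError):
                meta = {}
            times.append(float(meta.get("t_h", i)))
            if grid is None:
                spacing = float(meta.get("spacing_um", 1.0))
                origin = tuple(meta.get("origin_um", (spacing / 2, spacing / 2)))
                ny, nx = frames[0].shape
                grid = Grid(spacing=spacing, nx=nx, ny=ny, origin=origin)
            for k, v in (meta.get("speeds_um_per_h") or {}).items():
                speeds[int(k)] = float(v)
    return LabelMovie(np.stack(frames), np.asarray(times), grid, speeds)


# ---------------------------------------------------------------------------
# field tables
# ---------------------------------------------------------------------------

def write_field_csv(path: str | Path, movie: FieldMovie) -> None:
    """Long-format table: x_um, y_um, t_h, value (NaN rows kept empty)."""
    T, Y, X = np.meshgrid(movie.t_h, movie.y_um, movie.x_um, indexing="ij")
    pd.DataFrame({
        "x_um": X.ravel(),
        "y_um": Y.ravel(),
        "t_h": T.ravel(),
        "value": movie.values.ravel(),
    }).to_csv(path, index=False)


def read_field_csv(path: str | Path, kind: str = "v_x",
                   window_um: float | None = None) -> FieldMovie:
    df = pd.read_csv(path)
    x = np.sort(df["x_um"].unique())
    y = np.sort(df["y_um"].unique())
    t = np.sort(df["t_h"].unique())
    values = np.full((t.size, y.size, x.size), np.nan)
    xi = np.searchsorted(x, df["x_um"].to_numpy())
    yi = np.searchsorted(y, df["y_um"].to_numpy())
    ti = np.searchsorted(t, df["t_h"].to_numpy())
    values[ti, yi, xi] = df["value"].to_numpy()
    if window_um is None:
        window_um = float(np.median(np.diff(x))) if x.size > 1 else 1.0
    return FieldMovie(values, x, y, t, kind=kind, window_um=window_um)


def write_kymograph_csv(path: str | Path, kymo: Kymograph) -> None:
    """Matrix layout: header row of times, first column of x bin centers."""
    df = pd.DataFrame(kymo.values, index=kymo.x_um, columns=kymo.t_h)
    df.index.name = "x_um"
    df.to_csv(path)


def read_kymograph_csv(path: str | Path, kind: str = "v_x") -> Kymograph:
    df = pd.read_csv(path, index_col=0)
    x = df.index.to_numpy(dtype=float)
    t = np.asarray([float(c) for c in df.columns])
    bin_um = float(np.median(np.diff(x))) if x.size > 1 else 1.0
    return Kymograph(df.to_numpy(dtype=float), x, t, kind=kind, bin_um=bin_um)


# ---------------------------------------------------------------------------
# boundary polylines
# ---------------------------------------------------------------------------

def write_boundaries_csv(path: str | Path, curves: list[BoundaryCurve]) -> None:
    """Columns: pair_a, pair_b, t_h, order, x_um, y_um."""
    rows = []
    for curve in curves:
        for i, (x, y) in enumerate(curve.vertices):
            rows.append((curve.pair[0], curve.pair[1], curve.time, i, x, y))
    pd.DataFrame(
        rows, columns=["pair_a", "pair_b", "t_h", "order", "x_um", "y_um"]
    ).to_csv(path, index=False)


def read_boundaries_csv(path: str | Path) -> list[BoundaryCurve]:
    df = pd.read_csv(path)
    curves = []
    for (a, b, t), sub in df.groupby(["pair_a", "pair_b", "t_h"], sort=True):
        sub = sub.sort_values("order")
        curves.append(BoundaryCurve(
            sub[["x_um", "y_um"]].to_numpy(), (int(a), int(b)), float(t)))
    return curves
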