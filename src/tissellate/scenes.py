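"""Scene descriptions of initial tissue footprints and their rasterization.

A :class:`Scene` is a declarative description of the initial condition of a
multi-tissue experiment: a list of tissue seeds (rectangles, circles,
ellipses, polygons, or raster masks), each with an outward normal expansion
speed and optionally an initial cell density.  All public geometry is in
physical micrometres; the world origin sits at the top-left corner and y
increases downward, matching image conventions.

Scenes are serialized as a small YAML schema (see ``docs/scene_format.md``)
so that initial conditions are diffable and reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
import numpy as np
import shapely
import shapely.affinity
import yaml
from scipy import ndimage
from shapely.geometry import Point, Polygon as ShapelyPolygon

#: Default outward normal edge speed of a freely expanding MDCK monolayer,
#: in micrometres per hour.
DEFAULT_SPEED = 29.5


# ---------------------------------------------------------------------------
# grid and label containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Grid:
    """Uniform pixel grid over the physical world.

    Pixel ``(i, j)`` (row, column) has its center at
    ``origin + (j * spacing, i * spacing)`` in micrometres.
    """

    spacing: float
    nx: int
    ny: int
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ValueError("grid spacing must be positive")
        if self.nx < 1 or self.ny < 1:
            raise ValueError("grid must have at least one pixel per axis")

    @classmethod
    def from_extent(cls, width: float, height: float, spacing: float) -> "Grid":
        """Grid of pixel centers covering ``[0, width] x [0, height]`` um."""
        nx = max(1, int(round(width / spacing)))
        ny = max(1, int(round(height / spacing)))
        return cls(spacing=spacing, nx=nx, ny=ny,
                   origin=(spacing / 2.0, spacing / 2.0))

    @property
    def shape(self) -> tuple[int, int]:
        return (self.ny, self.nx)

    @property
    def x_centers(self) -> np.ndarray:
        return self.origin[0] + self.spacing * np.arange(self.nx)

    @property
    def y_centers(self) -> np.ndarray:
        return self.origin[1] + self.spacing * np.arange(self.ny)

    @property
    def extent(self) -> tuple[float, float]:
        """Physical (width, height) covered by the pixel footprint, um."""
        return (self.nx * self.spacing, self.ny * self.spacing)

    def meshgrid(self) -> tuple[np.ndarray, np.ndarray]:
        return np.meshgrid(self.x_centers, self.y_centers)


@dataclass
class LabelField:
    """Integer-labeled occupancy grid: 0 is free space, ``k`` is tissue k."""

    labels: np.ndarray
    grid: Grid
    time: float = 0.0

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.shape != self.grid.shape:
            raise ValueError(
                f"label array shape {self.labels.shape} does not match grid "
                f"shape {self.grid.shape}"
            )
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be an integer array")

    def area(self, tissue_id: int) -> float:
        """Occupied area of one tissue in um^2."""
        return float(np.count_nonzero(self.labels == tissue_id)) * self.grid.spacing ** 2

    def ids(self) -> list[int]:
        present = np.unique(self.labels)
        return [int(k) for k in present if k != 0]


# ---------------------------------------------------------------------------
# seed shapes
# ---------------------------------------------------------------------------

class Shape:
    """Base class for tissue seed footprints (all coordinates in um)."""

    def to_shapely(self):
        raise NotImplementedError

    def contains_points(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        raise NotImplementedError


@dataclass(frozen=True)
class Rectangle(Shape):
    center: tuple[float, float]
    width: float
    height: float
    angle_deg: float = 0.0

    def to_shapely(self):
        hw, hh = self.width / 2.0, self.height / 2.0
        box = ShapelyPolygon([(-hw, -hh), (hw, -hh), (hw, hh), (-hw, hh)])
        box = shapely.affinity.rotate(box, self.angle_deg, origin=(0, 0))
        return shapely.affinity.translate(box, *self.center)

    def contains_points(self, x, y):
        c, s = math.cos(math.radians(self.angle_deg)), math.sin(math.radians(self.angle_deg))
        dx, dy = x - self.center[0], y - self.center[1]
        u = c * dx + s * dy
        v = -s * dx + c * dy
        return (np.abs(u) <= self.width / 2.0) & (np.abs(v) <= self.height / 2.0)


@dataclass(frozen=True)
class Circle(Shape):
    center: tuple[float, float]
    radius: float

    def to_shapely(self):
        return Point(*self.center).buffer(self.radius, quad_segs=64)

    def contains_points(self, x, y):
        return (x - self.center[0]) ** 2 + (y - self.center[1]) ** 2 <= self.radius ** 2


@dataclass(frozen=True)
class Ellipse(Shape):
    """Axis lengths ``a`` and ``b`` are semi-axes along x and y before rotation."""

    center: tuple[float, float]
    a: float
    b: float
    angle_deg: float = 0.0

    def to_shapely(self):
        circ = Point(0, 0).buffer(1.0, quad_segs=64)
        ell = shapely.affinity.scale(circ, self.a, self.b)
        ell = shapely.affinity.rotate(ell, self.angle_deg, origin=(0, 0))
        return shapely.affinity.translate(ell, *self.center)

    def contains_points(self, x, y):
        c, s = math.cos(math.radians(self.angle_deg)), math.sin(math.radians(self.angle_deg))
        dx, dy = x - self.center[0], y - self.center[1]
        u = c * dx + s * dy
        v = -s * dx + c * dy
        return (u / self.a) ** 2 + (v / self.b) ** 2 <= 1.0


@dataclass(frozen=True)
class PolygonShape(Shape):
    vertices: tuple[tuple[float, float], ...]

    def __post_init__(self):
        object.__setattr__(self, "vertices", tuple(tuple(map(float, v)) for v in self.vertices))
        poly = ShapelyPolygon(self.vertices)
        if not poly.is_valid:
            raise ValueError("polygon seed must be simple (non-self-intersecting)")

    def to_shapely(self):
        return ShapelyPolygon(self.vertices)

    def contains_points(self, x, y):
        return shapely.intersects_xy(self.to_shapely(), x, y)


@dataclass(frozen=True)
class MaskShape(Shape):
    """Raster seed: a boolean mask on its own grid, sampled at pixel centers."""

    mask: np.ndarray
    spacing: float
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self):
        object.__setattr__(self, "mask", np.asarray(self.mask).astype(bool))

    def to_shapely(self):
        raise TypeError("mask seeds have no vector geometry")

    def contains_points(self, x, y):
        col = (np.asarray(x, dtype=float) - self.origin[0]) / self.spacing
        row = (np.asarray(y, dtype=float) - self.origin[1]) / self.spacing
        out = ndimage.map_coordinates(
            self.mask.astype(np.uint8), [row, col], order=0, mode="constant", cval=0
        )
        return out.astype(bool)


# ---------------------------------------------------------------------------
# seeds and scenes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TissueSeed:
    """One tissue's initial footprint, expansion speed, and optional density.

    ``speed`` is the outward normal edge speed v_n in um/h (``None`` falls
    back to the scene default); ``density`` is the initial cell density in
    cells/mm^2 and is used only by the mechanics/synthetic layers.
    """

    id: int
    shape: Shape
    speed: float | None = None
    density: float | None = None
    color: str | None = None

    def __post_init__(self):
        if int(self.id) != self.id or self.id <= 0:
            raise ValueError("tissue id must be a positive integer")
        if self.speed is not None and self.speed < 0:
            raise ValueError(f"tissue {self.id}: speed must be >= 0")
        if self.density is not None and self.density <= 0:
            raise ValueError(f"tissue {self.id}: density must be positive")


@dataclass
class Scene:
    """Validated initial condition: disjoint tissue seeds in a finite world."""

    tissues: list[TissueSeed]
    world_extent: tuple[float, float]
    default_speed: float = DEFAULT_SPEED

    def __post_init__(self) -> None:
        w, h = self.world_extent
        if w <= 0 or h <= 0:
            raise ValueError("world_extent must be strictly positive")
        ids = [t.id for t in self.tissues]
        if len(set(ids)) != len(ids):
            raise ValueError("tissue ids must be unique")
        # pairwise disjointness of vector seeds; raster seeds are checked
        # against everything at rasterization time
        geoms = {
            t.id: t.shape.to_shapely()
            for t in self.tissues
            if not isinstance(t.shape, MaskShape)
        }
        keys = sorted(geoms)
        for i, ka in enumerate(keys):
            for kb in keys[i + 1:]:
                inter = geoms[ka].intersection(geoms[kb])
                if inter.area > 1e-6:
                    raise ValueError(
                        f"initial footprints of tissues {ka} and {kb} overlap"
                    )

    def speed_of(self, tissue_id: int) -> float:
        for t in self.tissues:
            if t.id == tissue_id:
                return t.speed if t.speed is not None else self.default_speed
        raise KeyError(f"no tissue with id {tissue_id}")

    @property
    def speeds(self) -> dict[int, float]:
        return {t.id: self.speed_of(t.id) for t in self.tissues}

    @property
    def densities(self) -> dict[int, float | None]:
        return {t.id: t.density for t in self.tissues}


# ---------------------------------------------------------------------------
# scene (de)serialization
# ---------------------------------------------------------------------------

_SHAPE_KINDS = ("rectangle", "circle", "ellipse", "polygon", "mask")


def _parse_shape(spec: dict, base_dir: Path) -> Shape:
    kind = spec.get("kind")
    if kind == "rectangle":
        return Rectangle(
            center=tuple(spec["center"]),
            width=float(spec["width"]),
            height=float(spec["height"]),
            angle_deg=float(spec.get("angle", 0.0)),
        )
    if kind == "circle":
        return Circle(center=tuple(spec["center"]), radius=float(spec["radius"]))
    if kind == "ellipse":
        return Ellipse(
            center=tuple(spec["center"]),
            a=float(spec["a"]),
            b=float(spec["b"]),
            angle_deg=float(spec.get("angle", 0.0)),
        )
    if kind == "polygon":
        return PolygonShape(vertices=tuple(tuple(v) for v in spec["vertices"]))
    if kind == "mask":
        import tifffile

        path = base_dir / spec["path"]
        mask = tifffile.imread(path) > 0
        return MaskShape(
            mask=mask,
            spacing=float(spec["spacing"]),
            origin=tuple(spec.get("origin", (0.0, 0.0))),
        )
    raise ValueError(f"unknown shape kind: {kind!r} (expected one of {_SHAPE_KINDS})")


def load_scene(config_text: str, base_dir: str | Path = ".") -> Scene:
    """Parse a YAML scene description into a validated :class:`Scene`.

    Schema (documented in ``docs/scene_format.md``)::

        world: {width: <um>, height: <um>}
        default_speed: <um/h>          # optional, default 29.5
        tissues:
          - id: 1
            shape: {kind: circle, center: [x, y], radius: R}
            speed: <um/h>              # optional
            density: <cells/mm^2>      # optional
            color: <tag>               # optional
    """
    data = yaml.safe_load(config_text)
    if data is None:
        raise ValueError("empty scene configuration")
    try:
        world = data["world"]
        extent = (float(world["width"]), float(world["height"]))
    except (KeyError, TypeError) as exc:
        raise ValueError("scene configuration must define world.width/height") from exc
    base = Path(base_dir)
    seeds = []
    for entry in data.get("tissues", []) or []:
        seeds.append(
            TissueSeed(
                id=int(entry["id"]),
                shape=_parse_shape(entry["shape"], base),
                speed=None if entry.get("speed") is None else float(entry["speed"]),
                density=None if entry.get("density") is None else float(entry["density"]),
                color=entry.get("color"),
            )
        )
    return Scene(
        tissues=seeds,
        world_extent=extent,
        default_speed=float(data.get("default_speed", DEFAULT_SPEED)),
    )


def load_scene_file(path: str | Path) -> Scene:
    path = Path(path)
    return load_scene(path.read_text(), base_dir=path.parent)


def scene_to_yaml(scene: Scene) -> str:
    """Serialize a scene built from vector shapes back to the YAML schema."""
    def shape_dict(shape: Shape) -> dict:
        if isinstance(shape, Rectangle):
            return {"kind": "rectangle", "center": list(shape.center),
                    "width": shape.width, "height": shape.height,
                    "angle": shape.angle_deg}
        if isinstance(shape, Circle):
            return {"kind": "circle", "center": list(shape.center),
                    "radius": shape.radius}
        if isinstance(shape, Ellipse):
            return {"kind": "ellipse", "center": list(shape.center),
                    "a": shape.a, "b": shape.b, "angle": shape.angle_deg}
        if isinstance(shape, PolygonShape):
            return {"kind": "polygon", "vertices": [list(v) for v in shape.vertices]}
        raise TypeError(f"cannot serialize shape {type(shape).__name__}")

    data = {
        "world": {"width": scene.world_extent[0], "height": scene.world_extent[1]},
        "default_speed": scene.default_speed,
        "tissues": [
            {
                "id": t.id,
                "shape": shape_dict(t.shape),
                **({"speed": t.speed} if t.speed is not None else {}),
                **({"density": t.density} if t.density is not None else {}),
                **({"color": t.color} if t.color is not None else {}),
            }
            for t in scene.tissues
        ],
    }
    return yaml.safe_dump(data, sort_keys=False)


# ---------------------------------------------------------------------------
# rasterization
# ---------------------------------------------------------------------------

def rasterize(scene: Scene, grid: Grid) -> LabelField:
    """Rasterize a scene: a pixel is labeled ``k`` iff its center lies inside
    tissue k's footprint.

    Seeds are painted in ascending id order.  Vector seeds were validated
    disjoint when the scene was built, so any residual pixel conflict between
    them can only come from shared boundaries and is resolved in favour of
    the lower id; overlap involving a raster (mask) seed is an error.
    """
    gw, gh = grid.extent
    w, h = scene.world_extent
    if gw < w - 1e-9 or gh < h - 1e-9:
        raise ValueError(
            f"grid extent {gw:.0f}x{gh:.0f} um is smaller than the world "
            f"extent {w:.0f}x{h:.0f} um"
        )
    X, Y = grid.meshgrid()
    labels = np.zeros(grid.shape, dtype=np.int32)
    by_id = {t.id: t for t in scene.tissues}
    for tid in sorted(by_id):
        seed = by_id[tid]
        inside = seed.shape.contains_points(X, Y)
        conflict = inside & (labels != 0)
        if conflict.any():
            other = int(np.unique(labels[conflict])[0])
            if isinstance(seed.shape, MaskShape) or isinstance(by_id[other].shape, MaskShape):
                raise ValueError(
                    f"initial footprints of tissues {other} and {tid} overlap"
                )
            inside &= labels == 0
        labels[inside] = tid
    return LabelField(labels=labels, grid=grid, time=0.0)
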