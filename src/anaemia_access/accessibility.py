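"""Travel-time modelling: friction surface and least-cost-path travel time.

The cost-distance model is the standard one used in health-accessibility
work: each landscape class carries a travel speed (and mode — walking,
motorcycle or vehicle), the reciprocal speed gives a friction in seconds per
metre, and the minimum cumulative cost from every pixel to the hospital is
computed on the 8-connected pixel graph.  The cost of moving between
adjacent pixels a and b is

    d(a, b) * (friction(a) + friction(b)) / 2

with d equal to the pixel size for rook moves and pixel_size * sqrt(2) for
diagonal moves.  The model is isotropic: no slope or direction penalty.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra
from shapely import contains_xy

from .raster import RasterGrid
from .region import LAND_COVER_CLASSES, ROAD_CLASSES, EnumerationArea, LandscapeLayers

__all__ = [
    "AccessibilityError",
    "SpeedEntry",
    "SpeedTable",
    "FrictionSurface",
    "TravelTimeRaster",
    "build_friction_surface",
    "least_cost_travel_time",
    "zonal_mean_travel_time",
    "bin_travel_time",
    "TT30_LABELS",
    "TT15_LABELS",
]

TT30_LABELS = ["<30", "30-59", "60-89", ">=90"]
TT15_LABELS = ["<15", "15-29", "30-44", "45-59", "60-74", "75-89", ">=90"]


class AccessibilityError(ValueError):
    """Raised for invalid accessibility inputs (unmapped class, bad origin)."""


@dataclass(frozen=True)
class SpeedEntry:
    speed_kmh: float
    mode: str  # walk | motorcycle | vehicle

    def __post_init__(self) -> None:
        if not self.speed_kmh > 0:
            raise AccessibilityError("speeds must be positive")

    @property
    def friction_s_per_m(self) -> float:
        # v [km/h] = v/3.6 m/s  ->  friction = 3.6/v s/m
        return 3.6 / self.speed_kmh


@dataclass
class SpeedTable:
    """Mapping from surface-class name to travel speed and mode.

    Classes in ``impassable`` (water bodies, protected areas) carry no finite
    friction.  Every class present in the landscape must either have an entry
    or be declared impassable.
    """

    entries: dict[str, SpeedEntry]
    impassable: frozenset[str] = frozenset({"water", "protected"})

    @classmethod
    def default(cls) -> "SpeedTable":
        """Hybrid walking/motorised scenario typical of rural East-African
        accessibility studies: motorised travel on the road network, walking
        across land cover."""
        return cls(
            entries={
                "tarmac": SpeedEntry(80.0, "vehicle"),
                "gravel": SpeedEntry(40.0, "motorcycle"),
                "earth": SpeedEntry(20.0, "motorcycle"),
                "builtup": SpeedEntry(5.0, "walk"),
                "cultivated": SpeedEntry(4.0, "walk"),
                "grassland": SpeedEntry(4.0, "walk"),
                "bushland": SpeedEntry(4.0, "walk"),
                "forest": SpeedEntry(2.0, "walk"),
            }
        )

    def friction_for(self, class_name: str) -> float:
        if class_name in self.impassable:
            return np.inf
        try:
            return self.entries[class_name].friction_s_per_m
        except KeyError:
            raise AccessibilityError(
                f"surface class {class_name!r} has no speed entry and is not "
                "declared impassable"
            ) from None


@dataclass
class FrictionSurface:
    """Per-pixel traversal cost in seconds per metre; NaN where impassable."""

    grid: RasterGrid
    impassable: np.ndarray  # boolean, True = cannot be traversed

    @property
    def pixel_size(self) -> float:
        return self.grid.pixel_size


@dataclass
class TravelTimeRaster:
    """Minutes of least-cost travel to the hospital; NaN where unreachable."""

    grid: RasterGrid
    reachable: np.ndarray
    origin_rowcol: tuple[int, int]


def build_friction_surface(layers: LandscapeLayers, speeds: SpeedTable) -> FrictionSurface:
    """Merge road, land-cover and barrier layers into a friction surface.

    A road pixel takes the road-class friction regardless of the underlying
    land cover (the road overrides); barrier pixels are impassable.  Raises
    :class:`AccessibilityError` naming any class without a speed entry.
    """
    road = np.asarray(layers.road_class.data, dtype=int)
    cover = np.asarray(layers.land_cover.data, dtype=int)
    barrier = np.asarray(layers.barrier_mask.data, dtype=bool)

    friction = np.empty(road.shape, dtype=float)
    for code in np.unique(cover):
        name = LAND_COVER_CLASSES.get(int(code))
        if name is None:
            raise AccessibilityError(f"unknown land-cover code {int(code)}")
        friction[cover == code] = speeds.friction_for(name)
    for code in np.unique(road):
        if code == 0:
            continue
        name = ROAD_CLASSES.get(int(code))
        if name is None:
            raise AccessibilityError(f"unknown road-class code {int(code)}")
        friction[road == code] = speeds.friction_for(name)

    impassable = barrier | ~np.isfinite(friction)
    friction = np.where(impassable, np.nan, friction)
    if np.any(friction[~impassable] <= 0):
        raise AccessibilityError("friction must be positive on passable pixels")
    grid = RasterGrid(friction, layers.pixel_size, layers.road_class.origin)
    return FrictionSurface(grid=grid, impassable=impassable)


# The four forward neighbour offsets; together with their reverses they give
# the full 8-connected stencil.
_OFFSETS = ((0, 1, 1.0), (1, 0, 1.0), (1, 1, np.sqrt(2.0)), (1, -1, np.sqrt(2.0)))


def least_cost_travel_time(
    friction: FrictionSurface, origin_rowcol: tuple[int, int]
) -> TravelTimeRaster:
    """Single-source least-cost travel time to ``origin_rowcol`` in minutes.

    Dijkstra on the 8-connected pixel graph with the symmetric mean-friction
    edge cost.  Unreachable passable pixels are flagged (NaN), not an error;
    an impassable origin is an error.
    """
    f = np.asarray(friction.grid.data, dtype=float)
    nrow, ncol = f.shape
    r0, c0 = origin_rowcol
    if not (0 <= r0 < nrow and 0 <= c0 < ncol):
        raise AccessibilityError("origin outside the raster")
    if friction.impassable[r0, c0]:
        raise AccessibilityError("origin pixel is impassable")

    passable = ~friction.impassable
    node = -np.ones(f.shape, dtype=np.int64)
    node[passable] = np.arange(int(passable.sum()))
    n_nodes = int(passable.sum())

    rows_i: list[np.ndarray] = []
    cols_j: list[np.ndarray] = []
    wts: list[np.ndarray] = []
    px = friction.pixel_size
    for dr, dc, mult in _OFFSETS:
        r_a, r_b = max(0, -dr), min(nrow, nrow - dr)
        c_a, c_b = max(0, -dc), min(ncol, ncol - dc)
        a = np.s_[r_a:r_b, c_a:c_b]
        b = np.s_[r_a + dr : r_b + dr, c_a + dc : c_b + dc]
        ok = passable[a] & passable[b]
        if not ok.any():
            continue
        w = px * mult * 0.5 * (f[a][ok] + f[b][ok])
        rows_i.append(node[a][ok])
        cols_j.append(node[b][ok])
        wts.append(w)

    if rows_i:
        graph = coo_matrix(
            (np.concatenate(wts), (np.concatenate(rows_i), np.concatenate(cols_j))),
            shape=(n_nodes, n_nodes),
        ).tocsr()
    else:
        graph = coo_matrix((n_nodes, n_nodes)).tocsr()

    seconds = dijkstra(graph, directed=False, indices=node[r0, c0])

    minutes = np.full(f.shape, np.nan)
    minutes[passable] = seconds / 60.0
    reachable = passable & np.isfinite(minutes)
    minutes[~reachable] = np.nan
    grid = RasterGrid(minutes, px, friction.grid.origin)
    return TravelTimeRaster(grid=grid, reachable=reachable, origin_rowcol=(r0, c0))


def zonal_mean_travel_time(
    tt: TravelTimeRaster, eas: list[EnumerationArea]
) -> pd.DataFrame:
    """Mean travel time per EA over reachable pixels (centre-in-polygon).

    Fills ``mean_travel_min`` on each EA in place and returns a table with
    the 30-min class and 15-min band.  EAs with no reachable pixel are
    flagged (NaN mean) with a warning, to be excluded downstream.
    """
    xs, ys = tt.grid.cell_centers()
    minutes = tt.grid.data
    rows = []
    for ea in eas:
        minx, miny, maxx, maxy = ea.polygon.bounds
        box = (xs >= minx) & (xs <= maxx) & (ys >= miny) & (ys <= maxy)
        inside = np.zeros_like(box)
        if box.any():
            inside[box] = contains_xy(ea.polygon, xs[box], ys[box])
        vals = minutes[inside & tt.reachable]
        if vals.size == 0:
            warnings.warn(
                f"EA {ea.ea_id} has no reachable pixel; excluded from analysis",
                stacklevel=2,
            )
            mean_tt = np.nan
        else:
            mean_tt = float(vals.mean())
        ea.mean_travel_min = None if np.isnan(mean_tt) else mean_tt
        rows.append(
            {
                "ea_id": ea.ea_id,
                "mean_travel_min": mean_tt,
                "n_pixels": int(inside.sum()),
                "n_reachable": int(vals.size),
            }
        )
    out = pd.DataFrame(rows)
    ok = out["mean_travel_min"].notna()
    out["class30"] = pd.array([None] * len(out), dtype="object")
    out["band15"] = pd.array([None] * len(out), dtype="object")
    out.loc[ok, "class30"] = bin_travel_time(out.loc[ok, "mean_travel_min"].to_numpy())
    out.loc[ok, "band15"] = bin_travel_time(
        out.loc[ok, "mean_travel_min"].to_numpy(), scheme="15min"
    )
    return out


def bin_travel_time(minutes, scheme: str = "30min"):
    """Classify travel time into half-open 30-min classes or 15-min bands.

    30-min scheme: [0,30) -> "<30", [30,60) -> "30-59", [60,90) -> "60-89",
    [90,inf) -> ">=90"; the 15-min scheme is analogous with ">=90" terminal.
    Scalars in, scalar out; arrays in, object array out.
    """
    arr = np.asarray(minutes, dtype=float)
    scalar = arr.ndim == 0
    arr = np.atleast_1d(arr)
    if np.any(arr < 0) or np.any(~np.isfinite(arr)):
        raise AccessibilityError("travel times must be finite and non-negative")
    if scheme == "30min":
        edges, labels = [30.0, 60.0, 90.0], TT30_LABELS
    elif scheme == "15min":
        edges, labels = [15.0, 30.0, 45.0, 60.0, 75.0, 90.0], TT15_LABELS
    else:
        raise AccessibilityError(f"unknown binning scheme {scheme!r}")
    idx = np.searchsorted(edges, arr, side="right")
    out = np.array(labels, dtype=object)[idx]
    return out[0] if scalar else out
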