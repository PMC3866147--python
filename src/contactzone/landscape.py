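"""Synthetic ridge-partitioned landscapes and site placement.

The study region this emulates is a long, narrow montane transect
(~100 km north-south by ~20 km east-west) subdivided by roughly east-west
ridgelines into a stack of catchments. Ridgelines are monotone-in-easting
polylines with bounded vertical jitter, so they span the extent and can
never cross; n ridgelines define n+1 catchments ordered south to north.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import LineString, Polygon

DEFAULT_EXTENT = (0.0, 0.0, 20_000.0, 100_000.0)  # xmin, ymin, xmax, ymax (m)


class PlacementError(RuntimeError):
    """Site placement could not satisfy the separation constraint."""


@dataclass
class Landscape:
    """A rectangular extent partitioned into catchments by ridgelines.

    ``ridgelines`` are (k, 2) coordinate arrays ordered south to north and
    labelled CB-1 ... CB-n; catchment i lies between ridge i-1 and ridge i.
    """

    extent: tuple[float, float, float, float]
    ridgelines: list[np.ndarray]
    ridge_labels: list[str] = field(default=None)
    catchment_labels: list[str] = field(default=None)

    def __post_init__(self) -> None:
        xmin, ymin, xmax, ymax = self.extent
        if not (xmax > xmin and ymax > ymin):
            raise ValueError("extent must have positive area")
        self.ridgelines = [np.asarray(r, dtype=float) for r in self.ridgelines]
        for r in self.ridgelines:
            if r[:, 0].min() > xmin or r[:, 0].max() < xmax:
                raise ValueError("ridgeline does not span the extent east-west")
            if r[:, 1].min() < ymin or r[:, 1].max() > ymax:
                raise ValueError("ridgeline leaves the extent")
        if self.ridge_labels is None:
            self.ridge_labels = [f"CB-{i + 1}" for i in range(len(self.ridgelines))]
        if self.catchment_labels is None:
            self.catchment_labels = [f"C{i + 1}" for i in range(self.n_catchments)]
        for a, b in zip(self.ridgelines[:-1], self.ridgelines[1:]):
            if LineString(a).crosses(LineString(b)):
                raise ValueError("ridgelines cross")

    @property
    def n_catchments(self) -> int:
        return len(self.ridgelines) + 1

    def ridge_y(self, x: np.ndarray, ridge: int) -> np.ndarray:
        """Northing of ridge ``ridge`` at easting(s) ``x`` (linear interpolation)."""
        r = self.ridgelines[ridge]
        return np.interp(np.asarray(x, dtype=float), r[:, 0], r[:, 1])

    def catchment_index(self, x, y) -> np.ndarray:
        """0-based catchment index (south to north) for points; vectorised."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        y = np.atleast_1d(np.asarray(y, dtype=float))
        xmin, ymin, xmax, ymax = self.extent
        if np.any((x < xmin) | (x > xmax) | (y < ymin) | (y > ymax)):
            raise ValueError("point outside extent")
        idx = np.zeros(len(x), dtype=int)
        for r in range(len(self.ridgelines)):
            idx += (y > self.ridge_y(x, r)).astype(int)
        return idx

    def catchment_of(self, x, y) -> np.ndarray:
        """Catchment labels for points; scalar in, scalar out."""
        idx = self.catchment_index(x, y)
        labels = np.asarray(self.catchment_labels, dtype=object)[idx]
        return labels if np.ndim(x) else labels[0]

    def catchment_polygons(self) -> list[Polygon]:
        """Catchment regions as shapely polygons partitioning the extent."""
        xmin, ymin, xmax, ymax = self.extent
        floors = [np.array([[xmin, ymin], [xmax, ymin]])] + self.ridgelines
        ceils = self.ridgelines + [np.array([[xmin, ymax], [xmax, ymax]])]
        polys = []
        for lo, hi in zip(floors, ceils):
            ring = np.vstack([lo, hi[::-1]])
            polys.append(Polygon(ring))
        return polys

    def distance_to_ridges(self, x, y) -> np.ndarray:
        """(n_points, n_ridges) matrix of distances to each ridgeline."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        y = np.atleast_1d(np.asarray(y, dtype=float))
        lines = [LineString(r) for r in self.ridgelines]
        from shapely.geometry import Point

        return np.array([[ln.distance(Point(px, py)) for ln in lines]
                         for px, py in zip(x, y)])


def generate_landscape(
    n_catchments: int,
    extent: tuple[float, float, float, float] = DEFAULT_EXTENT,
    seed: int = 0,
    n_vertices: int = 21,
    jitter_frac: float = 0.25,
) -> Landscape:
    """Generate a landscape of ``n_catchments`` stacked catchments.

    Ridgelines are placed at evenly spaced base northings and given uniform
    vertical jitter bounded by ``jitter_frac`` of the inter-ridge spacing
    (< 0.5, so vertical ordering — hence non-crossing — is guaranteed).
    Deterministic for a fixed seed.
    """
    if n_catchments < 2:
        raise ValueError("need at least 2 catchments")
    xmin, ymin, xmax, ymax = extent
    if not (xmax > xmin and ymax > ymin):
        raise ValueError("extent must have positive area")
    if not 0 <= jitter_frac < 0.5:
        raise ValueError("jitter_frac must lie in [0, 0.5)")
    rng = np.random.default_rng(seed)
    spacing = (ymax - ymin) / n_catchments
    xs = np.linspace(xmin, xmax, n_vertices)
    ridges = []
    for i in range(1, n_catchments):
        base = ymin + i * spacing
        ys = base + rng.uniform(-jitter_frac * spacing, jitter_frac * spacing,
                                size=n_vertices)
        ridges.append(np.column_stack([xs, ys]))
    return Landscape(extent=extent, ridgelines=ridges)


def place_sites(
    landscape: Landscape,
    n_sites: int,
    min_separation: float = 100.0,
    seed: int = 0,
    max_attempts: int | None = None,
) -> pd.DataFrame:
    """Place sampling sites uniformly with a hard minimum separation.

    Rejection sampling: candidate points uniform over the extent are kept
    only if farther than ``min_separation`` from every accepted site. Fails
    explicitly once the attempt budget (default ``500 * n_sites``) is spent,
    which catches infeasible packings.

    Returns a DataFrame with columns ``site``, ``easting``, ``northing``,
    ``catchment`` (the containing catchment, ignoring any ridge buffer).
    """
    if n_sites < 3:
        raise ValueError("need at least 3 sites")
    if min_separation <= 0:
        raise ValueError("min_separation must be positive")
    if max_attempts is None:
        max_attempts = 500 * n_sites
    xmin, ymin, xmax, ymax = landscape.extent
    rng = np.random.default_rng(seed)
    accepted: list[tuple[float, float]] = []
    attempts = 0
    while len(accepted) < n_sites:
        if attempts >= max_attempts:
            raise PlacementError(
                f"placed {len(accepted)}/{n_sites} sites after {attempts} "
                f"attempts with separation {min_separation} m; "
                "packing appears infeasible"
            )
        x = rng.uniform(xmin, xmax)
        y = rng.uniform(ymin, ymax)
        attempts += 1
        if all((x - ax) ** 2 + (y - ay) ** 2 > min_separation**2
               for ax, ay in accepted):
            accepted.append((x, y))
    pts = np.array(accepted)
    catchments = landscape.catchment_of(pts[:, 0], pts[:, 1])
    return pd.DataFrame({
        "site": [f"S{i + 1:03d}" for i in range(n_sites)],
        "easting": pts[:, 0],
        "northing": pts[:, 1],
        "catchment": catchments,
    })
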