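"""Categorical wombling on a Delaunay network of sites.

Step 1 of boundary overlap analysis: connect adjacent sites by Delaunay
triangulation, score each edge with a Boundary Likelihood Value (BLV; for
categorical variables the mean mismatch indicator between the two connected
sites), threshold BLVs at a natural break to pick Boundary Elements (BEs;
the dual Voronoi edges, perpendicular to the Delaunay connection and
equidistant from the two sites), and link vertex-sharing BEs into
spatially contiguous subboundaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial import Voronoi
from scipy.spatial.distance import pdist
from shapely.geometry import LineString, MultiPoint

VERTEX_TOL = 1e-6  # metres: BE endpoints closer than this share a vertex


@dataclass
class DelaunayNetwork:
    """Sites, Delaunay edges, and each edge's clipped dual Voronoi segment."""

    sites: pd.DataFrame                  # site, easting, northing
    edges: np.ndarray                    # (m, 2) indices into sites
    dual_segments: list[np.ndarray]      # (2, 2) endpoint arrays, metres

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def edge_sites(self, e: int) -> tuple[str, str]:
        i, j = self.edges[e]
        s = self.sites["site"].to_numpy()
        return s[i], s[j]


@dataclass
class BoundarySet:
    """Boundary elements grouped into subboundaries.

    ``elements`` columns: be, edge, x1, y1, x2, y2, mx, my, subboundary.
    """

    elements: pd.DataFrame
    variable: str = ""

    def __post_init__(self) -> None:
        if "subboundary" not in self.elements.columns:
            self.elements = self.elements.assign(subboundary=pd.NA)

    @property
    def n_elements(self) -> int:
        return len(self.elements)

    def midpoints(self) -> np.ndarray:
        return self.elements[["mx", "my"]].to_numpy(dtype=float)

    def segments(self) -> list[np.ndarray]:
        return [np.array([[r.x1, r.y1], [r.x2, r.y2]])
                for r in self.elements.itertuples()]


def build_delaunay(sites: pd.DataFrame,
                   clip_margin: float | None = None) -> DelaunayNetwork:
    """Delaunay network with clipped dual Voronoi segments.

    Unbounded Voronoi rays are extended far along their known direction and
    every dual segment is clipped to the convex hull of the sites expanded
    by ``clip_margin`` (default: the median Delaunay edge length), keeping
    all boundary-element distances finite. Endpoints of each clipped segment
    stay on the perpendicular bisector of their generator pair, so they
    remain equidistant from the two sites.
    """
    pts = sites[["easting", "northing"]].to_numpy(dtype=float)
    if len(pts) < 3:
        raise ValueError("need >= 3 sites")
    spread = pts - pts.mean(axis=0)
    if np.linalg.matrix_rank(spread, tol=1e-9 * max(1, np.abs(spread).max())) < 2:
        raise ValueError("sites are collinear")
    vor = Voronoi(pts)
    edges = np.array([sorted(rp) for rp in vor.ridge_points], dtype=int)
    edge_len = np.linalg.norm(pts[edges[:, 0]] - pts[edges[:, 1]], axis=1)
    if clip_margin is None:
        clip_margin = float(np.median(edge_len))
    hull = MultiPoint([tuple(p) for p in pts]).convex_hull.buffer(clip_margin)
    span = float(np.max(pdist(pts))) + 2 * clip_margin
    center = pts.mean(axis=0)

    segments = []
    for (p1, p2), (v1, v2) in zip(vor.ridge_points, vor.ridge_vertices):
        a, b = pts[p1], pts[p2]
        mid = (a + b) / 2
        t = b - a
        normal = np.array([-t[1], t[0]])
        normal = normal / np.linalg.norm(normal)
        if v1 == -1 or v2 == -1:
            vfin = vor.vertices[v2 if v1 == -1 else v1]
            direction = normal if np.dot(mid - center, normal) > 0 else -normal
            far = vfin + direction * 2 * span
            seg = LineString([tuple(vfin), tuple(far)])
        else:
            seg = LineString([tuple(vor.vertices[v1]), tuple(vor.vertices[v2])])
        clipped = seg.intersection(hull)
        if clipped.is_empty or clipped.geom_type != "LineString":
            clipped = seg  # degenerate clip: keep the raw segment
        coords = np.asarray(clipped.coords)
        segments.append(np.array([coords[0], coords[-1]], dtype=float))
    return DelaunayNetwork(sites=sites.reset_index(drop=True), edges=edges,
                           dual_segments=segments)


def compute_blv(network: DelaunayNetwork, surface: pd.DataFrame,
                variables: list[str] | str) -> pd.DataFrame:
    """Boundary Likelihood Value per edge.

    ``surface`` is a site-indexed frame (one category column per variable,
    with optional ``<var>_excluded`` flags). A single variable gives the
    binary mismatch indicator; several give the mean of the per-variable
    indicators. Edges with an excluded (or missing) endpoint are dropped.
    """
    if isinstance(variables, str):
        variables = [variables]
    for var in variables:
        if var not in surface.columns:
            raise ValueError(f"variable {var!r} absent from surface")
    site_names = network.sites["site"].to_numpy()
    rows = []
    for e in range(network.n_edges):
        i, j = network.edges[e]
        s1, s2 = site_names[i], site_names[j]
        if s1 not in surface.index or s2 not in surface.index:
            continue
        vals = []
        usable = True
        for var in variables:
            flag = f"{var}_excluded"
            c1, c2 = surface.at[s1, var], surface.at[s2, var]
            if (flag in surface.columns and
                    (surface.at[s1, flag] or surface.at[s2, flag])) \
                    or pd.isna(c1) or pd.isna(c2):
                usable = False
                break
            vals.append(float(c1 != c2))
        if usable:
            rows.append(dict(edge=e, blv=float(np.mean(vals))))
    return pd.DataFrame(rows)


def natural_break_threshold(values: np.ndarray) -> float | None:
    """Two-class minimal-within-variance (Jenks) break.

    Returns the smallest value of the upper class, or None when all values
    are identical (no boundary detectable). For binary BLVs this degenerates
    to selecting exactly the mismatch edges.
    """
    v = np.sort(np.asarray(values, dtype=float))
    if v[0] == v[-1]:
        return None
    best, best_cut = np.inf, None
    for cut in range(1, len(v)):
        if v[cut] == v[cut - 1]:
            continue
        lo, hi = v[:cut], v[cut:]
        ssd = ((lo - lo.mean()) ** 2).sum() + ((hi - hi.mean()) ** 2).sum()
        if ssd < best - 1e-15:
            best, best_cut = ssd, cut
    return float(v[best_cut])


def detect_boundary_elements(scores: pd.DataFrame, network: DelaunayNetwork,
                             method: str = "natural_breaks",
                             variable: str = "") -> BoundarySet:
    """Threshold BLVs into boundary elements carrying dual Voronoi segments."""
    if method != "natural_breaks":
        raise ValueError("only the natural-breaks method is implemented")
    if scores.empty:
        raise ValueError("no scored edges")
    thr = natural_break_threshold(scores["blv"].to_numpy())
    if thr is None:
        warnings.warn("all BLVs identical; no boundary detectable")
        cols = ["be", "edge", "x1", "y1", "x2", "y2", "mx", "my"]
        return BoundarySet(elements=pd.DataFrame(columns=cols),
                           variable=variable)
    sel = scores[scores["blv"] >= thr]
    rows = []
    for k, r in enumerate(sel.itertuples()):
        seg = network.dual_segments[int(r.edge)]
        mid = seg.mean(axis=0)
        rows.append(dict(be=k, edge=int(r.edge), blv=float(r.blv),
                         x1=seg[0, 0], y1=seg[0, 1],
                         x2=seg[1, 0], y2=seg[1, 1],
                         mx=mid[0], my=mid[1]))
    return BoundarySet(elements=pd.DataFrame(rows), variable=variable)


def link_subboundaries(b: BoundarySet, tol: float = VERTEX_TOL) -> BoundarySet:
    """Group BEs into subboundaries: connected components of the graph whose
    edges join BEs sharing a Voronoi vertex (endpoints within ``tol``)."""
    if b.n_elements == 0:
        return b
    ends = np.array([[[r.x1, r.y1], [r.x2, r.y2]]
                     for r in b.elements.itertuples()])
    g = nx.Graph()
    g.add_nodes_from(range(b.n_elements))
    flat = ends.reshape(-1, 2)   # endpoint k of BE i at row 2i+k
    from scipy.spatial import cKDTree

    tree = cKDTree(flat)
    for i, j in tree.query_pairs(tol):
        g.add_edge(i // 2, j // 2)
    labels = np.empty(b.n_elements, dtype=int)
    for cid, comp in enumerate(sorted(nx.connected_components(g),
                                      key=lambda c: min(c))):
        for node in comp:
            labels[node] = cid
    elems = b.elements.copy()
    elems["subboundary"] = labels
    return BoundarySet(elements=elems, variable=b.variable)


def womble(sites: pd.DataFrame, surface: pd.DataFrame,
           variables: list[str] | str, variable_name: str = "",
           clip_margin: float | None = None) -> BoundarySet:
    """Convenience: full Step-1 wombling from sites and a category surface."""
    net = build_delaunay(sites, clip_margin=clip_margin)
    scores = compute_blv(net, surface, variables)
    bset = detect_boundary_elements(scores, net, variable=variable_name)
    return link_subboundaries(bset)


def boundary_geojson(b: BoundarySet) -> dict:
    feats = []
    for r in b.elements.itertuples():
        feats.append({
            "type": "Feature",
            "properties": {"be": int(r.be), "edge": int(r.edge),
                           "subboundary": (None if pd.isna(r.subboundary)
                                           else int(r.subboundary)),
                           "variable": b.variable},
            "geometry": {"type": "LineString",
                         "coordinates": [[float(r.x1), float(r.y1)],
                                         [float(r.x2), float(r.y2)]]},
        })
    return {"type": "FeatureCollection", "features": feats}


def subboundary_nearest_line(b: BoundarySet, polyline: np.ndarray,
                             min_size: int = 3) -> np.ndarray | None:
    """Midpoints of the contiguous subboundary nearest a reference polyline.

    Single-boundary overlap analyses test a named contact zone — a linked
    subboundary — against one landscape feature; this picks the candidate
    zone for that feature: among subboundaries with at least ``min_size``
    BEs, the one minimising mean midpoint distance to the polyline. Returns
    None when no subboundary qualifies.
    """
    from shapely.geometry import LineString, Point

    if b.n_elements == 0 or b.elements["subboundary"].isna().all():
        return None
    line = LineString(np.asarray(polyline, dtype=float))
    best, best_d = None, np.inf
    for _, grp in b.elements.groupby("subboundary"):
        if len(grp) < min_size:
            continue
        mids = grp[["mx", "my"]].to_numpy(dtype=float)
        d = float(np.mean([line.distance(Point(*m)) for m in mids]))
        if d < best_d:
            best_d, best = d, mids
    return best
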