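"""Delaunay network construction, BLV scoring, natural-breaks thresholding
and subboundary linking, each against an independent oracle."""

import itertools
import warnings

import numpy as np
import pandas as pd
import pytest

import contactzone as cz
from contactzone import womble


def _sites(points):
    pts = np.asarray(points, dtype=float)
    return pd.DataFrame({"site": [f"s{i}" for i in range(len(pts))],
                         "easting": pts[:, 0], "northing": pts[:, 1]})


def test_triangle_network():
    net = womble.build_delaunay(_sites([(0, 0), (10, 0), (5, 8)]))
    assert net.n_edges == 3


def test_dual_segments_equidistant_from_generators(sites):
    net = womble.build_delaunay(sites)
    pts = sites[["easting", "northing"]].to_numpy()
    for e in range(net.n_edges):
        i, j = net.edges[e]
        for end in net.dual_segments[e]:
            di = np.hypot(*(end - pts[i]))
            dj = np.hypot(*(end - pts[j]))
            assert di == pytest.approx(dj, abs=1e-6)


def test_edges_match_empty_circumcircle_oracle():
    """<= 8 random sites: the Delaunay edge set equals the set of pairs
    admitting an empty circumcircle (brute-force check)."""
    rng = np.random.default_rng(23)
    pts = rng.uniform(0, 100, size=(8, 2))
    net = womble.build_delaunay(_sites(pts))
    got = {tuple(sorted(e)) for e in net.edges}

    def circumcircle(a, b, c):
        ax, ay = a
        bx, by = b
        cx, cy = c
        d = 2 * (ax * (by - cy) + bx * (cy - ay) + cx * (ay - by))
        if abs(d) < 1e-12:
            return None
        ux = ((ax**2 + ay**2) * (by - cy) + (bx**2 + by**2) * (cy - ay)
              + (cx**2 + cy**2) * (ay - by)) / d
        uy = ((ax**2 + ay**2) * (cx - bx) + (bx**2 + by**2) * (ax - cx)
              + (cx**2 + cy**2) * (bx - ax)) / d
        ctr = np.array([ux, uy])
        return ctr, np.hypot(*(a - ctr))

    oracle = set()
    n = len(pts)
    for i, j in itertools.combinations(range(n), 2):
        # an edge is Delaunay iff some circumcircle through i, j (with any
        # third point, or the diametral circle) is empty of other sites
        candidates = []
        mid = (pts[i] + pts[j]) / 2
        candidates.append((mid, np.hypot(*(pts[i] - mid))))
        for k in range(n):
            if k in (i, j):
                continue
            cc = circumcircle(pts[i], pts[j], pts[k])
            if cc:
                candidates.append(cc)
        for ctr, rad in candidates:
            empty = all(np.hypot(*(pts[m] - ctr)) >= rad - 1e-9
                        for m in range(n) if m not in (i, j))
            if empty:
                oracle.add((i, j))
                break
    assert got == oracle


def test_too_few_or_collinear_sites():
    with pytest.raises(ValueError):
        womble.build_delaunay(_sites([(0, 0), (1, 1)]))
    with pytest.raises(ValueError):
        womble.build_delaunay(_sites([(0, 0), (1, 1), (2, 2), (3, 3)]))


def test_blv_values():
    net = womble.build_delaunay(_sites([(0, 0), (10, 0), (5, 8)]))
    surface = pd.DataFrame({
        "v1": ["A", "A", "B"],
        "v2": ["X", "Y", "Y"],
    }, index=["s0", "s1", "s2"])
    one = womble.compute_blv(net, surface, "v1").set_index("edge")["blv"]
    edges = {tuple(net.edges[e]): e for e in range(net.n_edges)}
    assert one[edges[(0, 1)]] == 0.0      # same category
    assert one[edges[(0, 2)]] == 1.0      # different
    both = womble.compute_blv(net, surface, ["v1", "v2"]).set_index("edge")
    assert both.loc[edges[(0, 1)], "blv"] == 0.5  # one of two mismatches
    with pytest.raises(ValueError):
        womble.compute_blv(net, surface, "nope")


def test_natural_break_toy_matches_exhaustive_split():
    vals = np.array([0.1, 0.15, 0.2, 0.8, 0.9])
    thr = womble.natural_break_threshold(vals)
    # exhaustive split search oracle
    best = (np.inf, None)
    sv = np.sort(vals)
    for cut in range(1, len(sv)):
        lo, hi = sv[:cut], sv[cut:]
        ssd = ((lo - lo.mean()) ** 2).sum() + ((hi - hi.mean()) ** 2).sum()
        if ssd < best[0]:
            best = (ssd, sv[cut])
    assert thr == best[1] == 0.8


def test_binary_blvs_select_mismatch_edges(sites, surface):
    net = womble.build_delaunay(sites)
    scores = womble.compute_blv(net, surface, "cluster")
    bset = womble.detect_boundary_elements(scores, net)
    mismatch = set(scores.loc[scores["blv"] == 1.0, "edge"])
    assert set(bset.elements["edge"]) == mismatch


def test_all_identical_blvs_warn_empty():
    net = womble.build_delaunay(_sites([(0, 0), (10, 0), (5, 8)]))
    scores = pd.DataFrame({"edge": [0, 1, 2], "blv": [0.0, 0.0, 0.0]})
    with warnings.catch_warnings(record=True) as w:
        warnings.simplefilter("always")
        bset = womble.detect_boundary_elements(scores, net)
    assert bset.n_elements == 0
    assert any("no boundary" in str(x.message) for x in w)


def _bset(segs):
    rows = []
    for k, s in enumerate(segs):
        s = np.asarray(s, dtype=float)
        rows.append(dict(be=k, edge=k, x1=s[0, 0], y1=s[0, 1],
                         x2=s[1, 0], y2=s[1, 1],
                         mx=s[:, 0].mean(), my=s[:, 1].mean()))
    return womble.BoundarySet(elements=pd.DataFrame(rows))


def test_subboundary_linking_chain_and_islands():
    chain = _bset([[(0, 0), (1, 0)], [(1, 0), (2, 1)], [(2, 1), (3, 1)]])
    linked = womble.link_subboundaries(chain)
    assert linked.elements["subboundary"].nunique() == 1
    islands = _bset([[(0, 0), (1, 0)], [(5, 5), (6, 5)]])
    linked = womble.link_subboundaries(islands)
    assert linked.elements["subboundary"].nunique() == 2


def test_subboundary_labels_match_union_find_oracle(sites, surface):
    bset = womble.womble(sites, surface, "cluster")
    segs = bset.segments()

    # independent union-find over shared endpoints
    parent = list(range(len(segs)))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    def union(a, b):
        parent[find(a)] = find(b)

    for i, j in itertools.combinations(range(len(segs)), 2):
        for pi in segs[i]:
            for pj in segs[j]:
                if np.hypot(*(pi - pj)) < 1e-6:
                    union(i, j)
    roots = [find(i) for i in range(len(segs))]
    ours = bset.elements["subboundary"].tolist()
    # same partition: label pairs agree on togetherness
    for i, j in itertools.combinations(range(len(segs)), 2):
        assert (roots[i] == roots[j]) == (ours[i] == ours[j])


def test_catchment_wombling_reconstructs_ridge(two_catchment):
    """BE midpoints of the wombled catchment boundary track the true
    ridgeline to within the median inter-site spacing on a dense grid."""
    xs = np.linspace(500, 19_500, 12)
    ys = np.linspace(2_000, 98_000, 24)
    pts = np.array([(x, y) for y in ys for x in xs])
    sites = _sites(pts)
    sites["catchment"] = two_catchment.catchment_of(pts[:, 0], pts[:, 1])
    surface = sites.set_index("site")[["catchment"]]
    bset = womble.womble(sites, surface, "catchment")
    assert bset.n_elements > 0
    from shapely.geometry import LineString, Point

    ridge = LineString(two_catchment.ridgelines[0])
    dists = [ridge.distance(Point(mx, my))
             for mx, my in bset.midpoints()]
    net = womble.build_delaunay(sites)
    ptsarr = sites[["easting", "northing"]].to_numpy()
    med = np.median(np.linalg.norm(ptsarr[net.edges[:, 0]]
                                   - ptsarr[net.edges[:, 1]], axis=1))
    assert np.mean(dists) < med
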