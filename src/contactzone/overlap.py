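"""Step 2 of boundary overlap analysis: the directional overlap statistic
O1 and its Monte Carlo test.

O1(B1, B2) is the mean geographic distance from each boundary element (BE)
of the response boundary B1 to the nearest BE of the predictor boundary B2;
small values indicate spatial coincidence. The null re-locates only the
response boundary — the predictor (a fixed landscape feature such as a
catchment ridgeline) is never randomized — either under complete spatial
randomness (uniform points in the site convex hull) or by re-selecting BEs
among all candidate Voronoi edges of the network. Significance is assessed
in the lower tail: p = (1 + #{O1_sim <= O1_obs}) / (1 + n_sim).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from shapely.geometry import MultiPoint

from .womble import BoundarySet, DelaunayNetwork


@dataclass
class OverlapResult:
    response: str
    predictor: str
    o1: float              # metres
    n_sim: int
    null_mean: float
    null_sd: float
    p: float               # lower tail, +1 corrected
    seed: int

    @property
    def significant(self) -> bool:
        return self.p <= 0.05


def _midpoints(b) -> np.ndarray:
    if isinstance(b, BoundarySet):
        if b.n_elements == 0:
            raise ValueError("empty boundary set")
        return b.midpoints()
    arr = np.asarray(b, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or len(arr) == 0:
        raise ValueError("boundary must be a non-empty (n, 2) point array "
                         "or BoundarySet")
    return arr


def o1_statistic(b1, b2) -> float:
    """Mean distance from each BE midpoint of ``b1`` to the nearest BE
    midpoint of ``b2``; asymmetric by construction."""
    p1, p2 = _midpoints(b1), _midpoints(b2)
    d, _ = cKDTree(p2).query(p1)
    return float(np.mean(d))


def sample_csr(domain, n: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform points in a shapely polygon by vectorised rejection sampling."""
    import shapely

    minx, miny, maxx, maxy = domain.bounds
    out = np.empty((0, 2))
    # oversample by the bbox/polygon area ratio so one batch usually suffices
    factor = (maxx - minx) * (maxy - miny) / max(domain.area, 1e-12)
    while len(out) < n:
        m = max(16, int(1.5 * factor * (n - len(out))))
        xs = rng.uniform(minx, maxx, size=m)
        ys = rng.uniform(miny, maxy, size=m)
        keep = shapely.contains_xy(domain, xs, ys)
        out = np.vstack([out, np.column_stack([xs[keep], ys[keep]])])
    return out[:n]


def site_hull(sites: pd.DataFrame):
    pts = sites[["easting", "northing"]].to_numpy(dtype=float)
    return MultiPoint([tuple(p) for p in pts]).convex_hull


def overlap_randomization_test(
    response,
    predictor,
    domain=None,
    sites: pd.DataFrame | None = None,
    n_sim: int = 10_000,
    seed: int = 0,
    null_model: str = "csr",
    network: DelaunayNetwork | None = None,
    response_label: str = "",
    predictor_label: str = "",
) -> OverlapResult:
    """Monte Carlo test of directional overlap between boundaries.

    Parameters
    ----------
    response, predictor : BoundarySet or (n, 2) midpoint arrays
        Only the response is randomized.
    domain : shapely polygon, optional
        CSR domain; built as the convex hull of ``sites`` when omitted.
    null_model : "csr" or "network"
        ``csr`` drops |response| uniform points in the domain per replicate;
        ``network`` re-selects |response| BEs among all candidate Voronoi
        edges of ``network``.
    """
    if n_sim < 1:
        raise ValueError("n_sim must be >= 1")
    resp = _midpoints(response)
    pred = _midpoints(predictor)
    tree = cKDTree(pred)
    o1_obs = float(np.mean(tree.query(resp)[0]))
    rng = np.random.default_rng(seed)
    m = len(resp)
    null = np.empty(n_sim)
    if null_model == "csr":
        if domain is None:
            if sites is None:
                raise ValueError("csr null needs a domain or sites")
            domain = site_hull(sites)
        if domain.area <= 0:
            raise ValueError("domain must have positive area")
        for b in range(n_sim):
            pts = sample_csr(domain, m, rng)
            null[b] = np.mean(tree.query(pts)[0])
    elif null_model == "network":
        if network is None:
            raise ValueError("network null needs the Delaunay network")
        mids = np.array([seg.mean(axis=0) for seg in network.dual_segments])
        if m > len(mids):
            raise ValueError("more response BEs than candidate edges")
        for b in range(n_sim):
            pick = rng.choice(len(mids), size=m, replace=False)
            null[b] = np.mean(tree.query(mids[pick])[0])
    else:
        raise ValueError("null_model must be 'csr' or 'network'")
    p = (1 + int(np.sum(null <= o1_obs + 1e-12))) / (1 + n_sim)
    return OverlapResult(
        response=response_label, predictor=predictor_label, o1=o1_obs,
        n_sim=n_sim, null_mean=float(null.mean()), null_sd=float(null.std()),
        p=p, seed=seed,
    )


def pooled_boundaries(boundaries: list) -> np.ndarray:
    """Pool BE midpoints over several boundary sets (the "-all" analyses,
    e.g. all contact zones against all catchment boundaries jointly)."""
    return np.vstack([_midpoints(b) for b in boundaries])
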