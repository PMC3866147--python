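"""Post-processing of external clustering output: Q-threshold assignment,
the Evanno second-difference (delta-K) table, majority-rule site categories,
and buffered catchment assignment of sites.

The clustering MCMC itself (e.g. STRUCTURE) is out of scope; its membership
coefficients (Q) and log-likelihoods Ln P(X|K) are inputs here.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .landscape import Landscape

UNASSIGNED = "U"


def validate_q(q: pd.DataFrame, tol: float = 1e-6) -> None:
    arr = q.to_numpy(dtype=float)
    if np.any(arr < -tol) or np.any(arr > 1 + tol):
        raise ValueError("Q values must lie in [0, 1]")
    if np.any(np.abs(arr.sum(axis=1) - 1) > tol):
        bad = q.index[np.abs(arr.sum(axis=1) - 1) > tol][0]
        raise ValueError(f"Q rows must sum to 1 (individual {bad!r})")


def assign_individuals(q: pd.DataFrame, threshold: float = 0.8) -> pd.Series:
    """Assign each individual to its argmax cluster if that membership
    coefficient strictly exceeds ``threshold``, else label it "U".

    ``q`` is individuals x clusters; column names are the cluster labels.
    """
    validate_q(q)
    arr = q.to_numpy(dtype=float)
    best = arr.argmax(axis=1)
    labels = np.array([str(c) for c in q.columns], dtype=object)[best]
    labels[arr.max(axis=1) <= threshold] = UNASSIGNED
    return pd.Series(labels, index=q.index, name="cluster")


def best_run(lnp_by_run: pd.Series, rule: str = "highest") -> object:
    """Pick the most likely run for a K: the run with the highest Ln P(X|K)
    (``rule='lowest'`` provided for strict replication of descriptions that
    phrase it the other way)."""
    if rule == "highest":
        return lnp_by_run.idxmax()
    if rule == "lowest":
        return lnp_by_run.idxmin()
    raise ValueError("rule must be 'highest' or 'lowest'")


def delta_k(lnp: pd.DataFrame) -> pd.DataFrame:
    """Evanno delta-K from replicate log-likelihoods.

    ``lnp`` is replicates x K (columns are consecutive integer K values).
    delta-K(K) = mean over replicates of |L(K+1) - 2 L(K) + L(K-1)| divided
    by the across-replicate sd of L(K); undefined at the grid ends and where
    sd = 0 (flagged, not zero).
    """
    ks = [int(k) for k in lnp.columns]
    if ks != list(range(ks[0], ks[0] + len(ks))):
        raise ValueError("K grid must be contiguous integers")
    if len(ks) < 3:
        raise ValueError("need a K grid of length >= 3")
    if len(lnp) < 2:
        raise ValueError("need >= 2 replicate runs per K")
    arr = lnp.to_numpy(dtype=float)
    mean = arr.mean(axis=0)
    sd = arr.std(axis=0, ddof=1)
    rows = []
    for i, k in enumerate(ks):
        if i == 0 or i == len(ks) - 1:
            rows.append(dict(K=k, mean_lnp=mean[i], sd_lnp=sd[i],
                             delta_k=np.nan, defined=False))
            continue
        second = np.abs(arr[:, i + 1] - 2 * arr[:, i] + arr[:, i - 1]).mean()
        if sd[i] == 0:
            rows.append(dict(K=k, mean_lnp=mean[i], sd_lnp=0.0,
                             delta_k=np.nan, defined=False))
        else:
            rows.append(dict(K=k, mean_lnp=mean[i], sd_lnp=sd[i],
                             delta_k=second / sd[i], defined=True))
    return pd.DataFrame(rows)


def majority_site_category(categories) -> tuple[str | None, bool, bool]:
    """Majority-rule site category from individual categories.

    Drops "U" labels first; ties break to the lexicographically smallest
    label and raise a tie flag; all-"U" (or empty after dropping) sites are
    flagged excluded. Returns (category, tie, excluded).
    """
    cats = [c for c in categories if c is not None]
    if not cats:
        raise ValueError("no individuals at site")
    cats = [c for c in cats if c != UNASSIGNED]
    if not cats:
        return None, False, True
    counts = pd.Series(cats).value_counts()
    top = counts.max()
    winners = sorted(counts.index[counts == top])
    return winners[0], len(winners) > 1, False


def site_category_surface(individuals: pd.DataFrame,
                          variables: list[str]) -> pd.DataFrame:
    """Per-site single category per variable by majority rule.

    ``individuals`` needs a ``site`` column plus one column per variable.
    Output columns: ``<var>`` plus ``<var>_tie`` and ``<var>_excluded``.
    """
    rows = []
    for site, grp in individuals.groupby("site", sort=True):
        row: dict = {"site": site}
        for var in variables:
            cat, tie, excluded = majority_site_category(grp[var].dropna())
            row[var] = cat
            row[f"{var}_tie"] = tie
            row[f"{var}_excluded"] = excluded
        rows.append(row)
    return pd.DataFrame(rows).set_index("site")


def assign_sites_to_catchments(sites: pd.DataFrame, landscape: Landscape,
                               buffer: float = 100.0,
                               seed: int = 0) -> pd.Series:
    """Catchment label per site, with a ridge buffer.

    Sites farther than ``buffer`` from every ridgeline take their containing
    catchment; sites within the buffer of the nearest ridgeline are assigned
    uniformly at random (seeded) to one of that ridgeline's two adjacent
    catchments, mirroring field protocols where a site sits on a ridge top.
    """
    rng = np.random.default_rng(seed)
    x = sites["easting"].to_numpy(dtype=float)
    y = sites["northing"].to_numpy(dtype=float)
    contained = landscape.catchment_index(x, y)  # raises if outside extent
    dist = landscape.distance_to_ridges(x, y)
    labels = []
    for i in range(len(sites)):
        nearest = int(np.argmin(dist[i]))
        if dist[i, nearest] <= buffer:
            side = int(rng.integers(2))  # catchments nearest and nearest+1
            labels.append(landscape.catchment_labels[nearest + side])
        else:
            labels.append(landscape.catchment_labels[contained[i]])
    return pd.Series(labels, index=sites["site"].to_numpy(), name="catchment")


def hierarchical_subset(assignments: pd.Series, parent: str) -> pd.Index:
    """Individuals eligible for re-clustering within ``parent``: exactly
    those assigned (not "U") to that group at the parent level."""
    return assignments.index[assignments == parent]
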