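"""Microsatellite statistics: locus summaries, Weir-Cockerham theta, exact
Hardy-Weinberg tests, linkage-disequilibrium G-tests, the allele-size
permutation (pRST - RST) test, and Mantel tests for isolation by distance.

All permutation p-values use the +1 correction
p = (1 + #{null >= observed}) / (1 + n), so p is never exactly zero.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import GenotypeTable

# ---------------------------------------------------------------------------
# Locus summaries and Weir-Cockerham theta
# ---------------------------------------------------------------------------


@dataclass
class LocusSummary:
    locus: str
    n_alleles: int
    size_range: tuple[int, int]
    ho: float
    he: float
    theta: float  # NaN when undefined (monomorphic)


def _locus_groups(gt: GenotypeTable, locus: int, groups: pd.Series):
    """Yield (group, (n_i, 2) allele array) for non-missing genotypes."""
    slab = gt.alleles[:, locus, :]
    ok = slab[:, 0] != gt.missing
    g = groups.loc[gt.individuals.index].to_numpy()
    for lab in pd.unique(g[ok]):
        yield lab, slab[ok & (g == lab)]


def _wc_components(pop_alleles: list[np.ndarray]):
    """Weir-Cockerham (1984) variance components for one locus.

    ``pop_alleles`` holds one (n_i, 2) diploid allele array per population.
    Returns (a, b, c) summed over alleles; theta = a / (a + b + c).
    """
    pops = [p for p in pop_alleles if len(p)]
    r = len(pops)
    if r < 2:
        raise ValueError("need >= 2 populations with data")
    alleles = np.unique(np.concatenate([p.ravel() for p in pops]))
    if len(alleles) < 2:
        return np.nan, np.nan, np.nan
    n = np.array([len(p) for p in pops], dtype=float)
    nbar = n.mean()
    nc = (r * nbar - (n**2).sum() / (r * nbar)) / (r - 1)
    A = B = C = 0.0
    for u in alleles:
        p_i = np.array([(p == u).mean() for p in pops])
        h_i = np.array([np.mean((p == u).sum(axis=1) == 1) for p in pops])
        pbar = (n * p_i).sum() / (r * nbar)
        s2 = (n * (p_i - pbar) ** 2).sum() / ((r - 1) * nbar)
        hbar = (n * h_i).sum() / (r * nbar)
        a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4)
                           / (nbar - 1))
        b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2
                                   - (2 * nbar - 1) / (4 * nbar) * hbar)
        c = hbar / 2
        A, B, C = A + a, B + b, C + c
    return A, B, C


def wc_theta(gt: GenotypeTable, groups: pd.Series,
             locus: int | None = None) -> float:
    """Weir-Cockerham theta (FST); per locus, or global (components summed
    over loci) when ``locus`` is None."""
    loci = range(gt.n_loci) if locus is None else [locus]
    A = B = C = 0.0
    for l in loci:
        pops = [arr for _, arr in _locus_groups(gt, l, groups)]
        a, b, c = _wc_components(pops)
        if not math.isnan(a):
            A, B, C = A + a, B + b, C + c
    denom = A + B + C
    return np.nan if denom == 0 else A / denom


def locus_summary(gt: GenotypeTable, groups: pd.Series) -> pd.DataFrame:
    """Per-locus allele counts, size range, Ho, He and Weir-Cockerham theta,
    plus a ``global`` row with the multi-locus theta."""
    rows = []
    for l, name in enumerate(gt.loci):
        slab = gt.alleles[:, l, :]
        obs = slab[slab[:, 0] != gt.missing]
        vals = obs.ravel()
        freqs = pd.Series(vals).value_counts(normalize=True)
        he = 1 - (freqs**2).sum()
        ho = np.mean(obs[:, 0] != obs[:, 1]) if len(obs) else np.nan
        theta = wc_theta(gt, groups, locus=l) if freqs.size >= 2 else np.nan
        rows.append(dict(locus=name, n_alleles=int(freqs.size),
                         size_min=int(vals.min()), size_max=int(vals.max()),
                         ho=float(ho), he=float(he), theta=theta))
    rows.append(dict(locus="global", n_alleles=np.nan, size_min=np.nan,
                     size_max=np.nan, ho=np.nan, he=np.nan,
                     theta=wc_theta(gt, groups)))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Exact Hardy-Weinberg tests (Guo & Thompson style)
# ---------------------------------------------------------------------------


def _genotype_counts(obs: np.ndarray) -> dict[tuple[int, int], int]:
    counts: dict[tuple[int, int], int] = {}
    for a, b in np.sort(obs, axis=1):
        counts[(a, b)] = counts.get((a, b), 0) + 1
    return counts


def _log_table_prob(counts: dict[tuple[int, int], int],
                    allele_counts: dict[int, int], n: int) -> float:
    """Log conditional probability of a genotype table given allele counts
    under Hardy-Weinberg (Levene's distribution)."""
    h = sum(c for (a, b), c in counts.items() if a != b)
    lp = math.lgamma(n + 1) + h * math.log(2)
    lp += sum(math.lgamma(c + 1) for c in allele_counts.values())
    lp -= math.lgamma(2 * n + 1)
    lp -= sum(math.lgamma(c + 1) for c in counts.values())
    return lp


def _enumerate_tables(alleles: list[int], allele_counts: dict[int, int], n: int):
    """Recursively enumerate genotype-count tables with fixed allele counts."""
    cells = [(alleles[i], alleles[j]) for i in range(len(alleles))
             for j in range(i, len(alleles))]

    def rec(idx: int, remaining: dict[int, int], left: int, current: dict):
        if idx == len(cells):
            if left == 0 and all(v == 0 for v in remaining.values()):
                yield dict(current)
            return
        a, b = cells[idx]
        if a == b:
            cap = min(remaining[a] // 2, left)
        else:
            cap = min(remaining[a], remaining[b], left)
        for k in range(cap + 1):
            rem = dict(remaining)
            if a == b:
                rem[a] -= 2 * k
            else:
                rem[a] -= k
                rem[b] -= k
            if rem[a] < 0 or rem[b] < 0:
                continue
            if k:
                current[(a, b)] = k
            yield from rec(idx + 1, rem, left - k, current)
            current.pop((a, b), None)

    yield from rec(0, dict(allele_counts), n, {})


def hwe_exact_locus(obs: np.ndarray, n_mc: int = 10_000, seed: int = 0,
                    max_enumeration: int = 100_000) -> float:
    """Exact conditional Hardy-Weinberg test for one locus-site sample.

    ``obs`` is an (n, 2) diploid allele array with no missing entries. Full
    enumeration over genotype tables with the observed allele counts when
    that space is small; otherwise Monte Carlo by random pairing of the
    allele pool (which samples the conditional null exactly). Returns NaN
    for monomorphic samples. Two-sided in the conditional-probability
    ordering: p = Pr(P(table) <= P(observed)).
    """
    n = len(obs)
    vals, cnts = np.unique(obs.ravel(), return_counts=True)
    if len(vals) < 2:
        return np.nan
    allele_counts = dict(zip(vals.tolist(), cnts.tolist()))
    counts_obs = _genotype_counts(obs)
    lp_obs = _log_table_prob(counts_obs, allele_counts, n)

    # enumeration only attempted when the table space is plausibly small
    budget_ok = len(vals) <= 4 and n <= 30
    tables = []
    if budget_ok:
        for t in _enumerate_tables(list(vals), allele_counts, n):
            tables.append(t)
            if len(tables) > max_enumeration:
                budget_ok = False
                break
    if budget_ok:
        num = 0.0
        for t in tables:
            lp = _log_table_prob(t, allele_counts, n)
            if lp <= lp_obs + 1e-9:
                num += math.exp(lp)
        return min(num, 1.0)

    rng = np.random.default_rng(seed)
    pool = obs.ravel().copy()
    hits = 0
    for _ in range(n_mc):
        rng.shuffle(pool)
        sim = _genotype_counts(pool.reshape(-1, 2))
        if _log_table_prob(sim, allele_counts, n) <= lp_obs + 1e-9:
            hits += 1
    return (1 + hits) / (1 + n_mc)


def hwe_exact(gt: GenotypeTable, unit: str = "site", n_mc: int = 10_000,
              seed: int = 0) -> pd.DataFrame:
    """Hardy-Weinberg exact test per locus x grouping unit."""
    groups = gt.individuals[unit]
    rows = []
    rng = np.random.default_rng(seed)
    for l, name in enumerate(gt.loci):
        for lab, obs in _locus_groups(gt, l, groups):
            p = hwe_exact_locus(obs, n_mc=n_mc,
                                seed=int(rng.integers(2**31)))
            rows.append(dict(locus=name, unit=lab, n=len(obs), p=p))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Linkage disequilibrium G-test
# ---------------------------------------------------------------------------


def _g_statistic(table: np.ndarray) -> float:
    table = np.asarray(table, dtype=float)
    total = table.sum()
    exp = np.outer(table.sum(axis=1), table.sum(axis=0)) / total
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(table > 0, table * np.log(table / exp), 0.0)
    return 2 * terms.sum()


def _genotype_codes(slab: np.ndarray) -> np.ndarray:
    srt = np.sort(slab, axis=1)
    _, codes = np.unique(srt, axis=0, return_inverse=True)
    return codes


def ld_gtest(gt: GenotypeTable, unit: str = "site", n_perm: int = 1000,
             seed: int = 0) -> pd.DataFrame:
    """Genotypic linkage-disequilibrium permutation G-test per locus pair and
    site: the G statistic on the two-locus genotype contingency table, with
    the null built by permuting one locus's genotypes among individuals
    within the unit."""
    groups = gt.individuals[unit]
    rng = np.random.default_rng(seed)
    rows = []
    for lab in pd.unique(groups):
        mask = (groups == lab).to_numpy()
        for l1, l2 in itertools.combinations(range(gt.n_loci), 2):
            s1 = gt.alleles[mask, l1, :]
            s2 = gt.alleles[mask, l2, :]
            ok = (s1[:, 0] != gt.missing) & (s2[:, 0] != gt.missing)
            if ok.sum() < 2:
                rows.append(dict(unit=lab, locus1=gt.loci[l1],
                                 locus2=gt.loci[l2], g=np.nan, p=np.nan))
                continue
            c1, c2 = _genotype_codes(s1[ok]), _genotype_codes(s2[ok])
            if c1.max() == 0 or c2.max() == 0:  # a locus monomorphic here
                rows.append(dict(unit=lab, locus1=gt.loci[l1],
                                 locus2=gt.loci[l2], g=np.nan, p=np.nan))
                continue
            k1, k2 = c1.max() + 1, c2.max() + 1
            obs_tab = np.zeros((k1, k2))
            np.add.at(obs_tab, (c1, c2), 1)
            g_obs = _g_statistic(obs_tab)
            hits = 0
            perm = c2.copy()
            for _ in range(n_perm):
                rng.shuffle(perm)
                tab = np.zeros((k1, k2))
                np.add.at(tab, (c1, perm), 1)
                if _g_statistic(tab) >= g_obs - 1e-12:
                    hits += 1
            rows.append(dict(unit=lab, locus1=gt.loci[l1], locus2=gt.loci[l2],
                             g=g_obs, p=(1 + hits) / (1 + n_perm)))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# RST and the allele-size permutation (pRST) test
# ---------------------------------------------------------------------------


@dataclass
class RstTestResult:
    group_pair: tuple
    rst: float
    prst_mean: float
    n_perm: int
    p: float


def _rst_components(values_by_pop: list[np.ndarray]) -> tuple[float, float]:
    """One-way random-effects ANOVA on allele sizes -> (sigma2_among,
    sigma2_within); unequal group sizes via the n0 correction."""
    pops = [np.asarray(v, dtype=float) for v in values_by_pop if len(v)]
    r = len(pops)
    n = np.array([len(p) for p in pops], dtype=float)
    N = n.sum()
    grand = np.concatenate(pops).mean()
    ss_within = sum(((p - p.mean()) ** 2).sum() for p in pops)
    ss_among = sum(len(p) * (p.mean() - grand) ** 2 for p in pops)
    ms_within = ss_within / (N - r)
    ms_among = ss_among / (r - 1)
    n0 = (N - (n**2).sum() / N) / (r - 1)
    s2_within = ms_within
    s2_among = (ms_among - ms_within) / n0
    return s2_among, s2_within


def rst(gt: GenotypeTable, groups: pd.Series,
        size_maps: list[dict[int, int]] | None = None) -> float:
    """Multi-locus RST: allele-size variance components summed over loci.

    ``size_maps`` optionally remaps observed allele sizes per locus (used by
    the permutation test to shuffle sizes among allelic states).
    """
    Sa = Sw = 0.0
    for l in range(gt.n_loci):
        per_pop = []
        for _, arr in _locus_groups(gt, l, groups):
            vals = arr.ravel().astype(float)
            if size_maps is not None:
                vals = np.array([size_maps[l][int(v)] for v in vals], float)
            per_pop.append(vals)
        if len(per_pop) < 2 or len(np.unique(np.concatenate(per_pop))) < 2:
            continue
        sa, sw = _rst_components(per_pop)
        Sa, Sw = Sa + sa, Sw + sw
    denom = Sa + Sw
    return np.nan if denom == 0 else Sa / denom


def _locus_sizes(gt: GenotypeTable, groups: pd.Series) -> list[np.ndarray]:
    sizes = []
    for l in range(gt.n_loci):
        obs = np.concatenate([arr.ravel() for _, arr in
                              _locus_groups(gt, l, groups)])
        sizes.append(np.unique(obs))
    return sizes


def rst_prst_test(gt: GenotypeTable, groups: pd.Series, n_perm: int = 10_000,
                  seed: int = 0, exhaustive: bool = False) -> pd.DataFrame:
    """Pairwise pRST - RST tests between groups.

    The null shuffles allele *sizes* among allelic states (allele identities
    and frequencies are kept; only the size attached to each state moves),
    recomputing RST each time; the one-sided p-value is
    Pr(RST_perm >= RST_obs) with the +1 correction. A significant result
    means the stepwise-size information exceeds the drift-only expectation,
    i.e. divergence long enough for stepwise mutations to accumulate.

    With ``exhaustive`` the null enumerates every joint assignment of sizes
    to states across loci (feasible only for tiny allele ladders).
    """
    labels = pd.unique(groups.dropna())
    rng = np.random.default_rng(seed)
    rows = []
    for ga, gb in itertools.combinations(labels, 2):
        sub = groups[groups.isin([ga, gb])]
        keep = gt.individuals.index.isin(sub.index)
        if (groups.loc[gt.individuals.index][keep] == ga).sum() < 2 or \
           (groups.loc[gt.individuals.index][keep] == gb).sum() < 2:
            raise ValueError(f"group pair ({ga}, {gb}): need >= 2 "
                             "individuals per group")
        pair_gt = GenotypeTable(individuals=gt.individuals[keep].copy(),
                                alleles=gt.alleles[keep], loci=gt.loci,
                                missing=gt.missing)
        obs = rst(pair_gt, sub)
        sizes = _locus_sizes(pair_gt, sub)
        if exhaustive:
            perms_per_locus = [list(itertools.permutations(s)) for s in sizes]
            null = []
            for combo in itertools.product(*perms_per_locus):
                maps = [dict(zip(s.tolist(), list(p)))
                        for s, p in zip(sizes, combo)]
                null.append(rst(pair_gt, sub, size_maps=maps))
            null = np.asarray(null)
            n_used = len(null)
            hits = int((null >= obs - 1e-12).sum())
            # exhaustive null includes the identity, giving exact p without
            # an extra +1
            p = hits / n_used
        else:
            null = np.empty(n_perm)
            for b in range(n_perm):
                maps = [dict(zip(s.tolist(),
                                 rng.permutation(s).tolist()))
                        for s in sizes]
                null[b] = rst(pair_gt, sub, size_maps=maps)
            n_used = n_perm
            hits = int((null >= obs - 1e-12).sum())
            p = (1 + hits) / (1 + n_perm)
        rows.append(dict(group1=ga, group2=gb, rst=obs,
                         prst_mean=float(np.nanmean(null)),
                         n_perm=n_used, p=p))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Mantel test for isolation by distance
# ---------------------------------------------------------------------------


def mantel_ibd(genetic: np.ndarray, geographic: np.ndarray,
               n_perm: int = 10_000, seed: int = 0,
               transform: bool = True) -> tuple[float, float]:
    """Mantel test of isolation by distance across sites.

    Correlates linearised differentiation theta/(1 - theta) against
    ln(geographic distance) over off-diagonal pairs, with the null built by
    permuting site labels of one matrix; upper one-sided p with the +1
    correction. Returns (r, p); (nan, nan) when a matrix has no variance.
    """
    g = np.asarray(genetic, dtype=float)
    d = np.asarray(geographic, dtype=float)
    if g.shape != d.shape or g.shape[0] != g.shape[1]:
        raise ValueError("matrices must be square and matching")
    if g.shape[0] < 4:
        raise ValueError("need >= 4 sites")
    if not (np.allclose(g, g.T, equal_nan=True) and np.allclose(d, d.T)):
        raise ValueError("matrices must be symmetric")
    if transform:
        g = g / (1 - g)
        d = np.log(d, out=np.full_like(d, np.nan), where=d > 0)
    iu = np.triu_indices_from(g, k=1)
    x, y = g[iu], d[iu]
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.std() == 0 or y.std() == 0:
        return np.nan, np.nan
    r_obs = float(np.corrcoef(x, y)[0, 1])
    rng = np.random.default_rng(seed)
    n = g.shape[0]
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        gp = g[np.ix_(perm, perm)][iu]
        ok = np.isfinite(gp) & np.isfinite(d[iu])
        rp = np.corrcoef(gp[ok], d[iu][ok])[0, 1]
        if rp >= r_obs - 1e-12:
            hits += 1
    return r_obs, (1 + hits) / (1 + n_perm)


def pairwise_theta_matrix(gt: GenotypeTable, unit: str = "site") -> np.ndarray:
    """Pairwise Weir-Cockerham theta between grouping units (for Mantel)."""
    groups = gt.individuals[unit]
    labs = pd.unique(groups)
    k = len(labs)
    out = np.zeros((k, k))
    for i, j in itertools.combinations(range(k), 2):
        keep = groups.isin([labs[i], labs[j]]).to_numpy()
        sub = GenotypeTable(individuals=gt.individuals[keep].copy(),
                            alleles=gt.alleles[keep], loci=gt.loci,
                            missing=gt.missing)
        out[i, j] = out[j, i] = wc_theta(sub, groups[keep])
    return out
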