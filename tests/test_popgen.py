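"""Microsatellite statistics against independent oracles."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest

import contactzone as cz
from contactzone import popgen


def _make_gt(group_alleles, loci=1):
    """Build a GenotypeTable from {group: [(a, b), ...]} genotype lists."""
    rows, alleles = [], []
    k = 0
    for grp, genos in group_alleles.items():
        for g in genos:
            rows.append(dict(ind=f"i{k}", site=grp, easting=float(k),
                             northing=0.0))
            alleles.append(np.array(g).reshape(loci, 2))
            k += 1
    inds = pd.DataFrame(rows).set_index("ind")
    return cz.GenotypeTable(individuals=inds, alleles=np.stack(alleles),
                            loci=[f"L{j}" for j in range(loci)])


# ---------------------------------------------------------------------------
# Weir-Cockerham theta
# ---------------------------------------------------------------------------


def test_theta_fixed_groups_is_one(toy_genotypes):
    theta = popgen.wc_theta(toy_genotypes, toy_genotypes.sites)
    assert theta == pytest.approx(1.0, abs=1e-12)


def test_theta_identical_frequencies_near_zero():
    rng = np.random.default_rng(5)
    genos = {grp: [tuple(rng.choice([100, 102], 2, p=[0.5, 0.5]))
                   for _ in range(200)] for grp in ("a", "b", "c")}
    gt = _make_gt(genos)
    assert abs(popgen.wc_theta(gt, gt.sites)) < 0.05


def test_theta_matches_independent_variance_components():
    """3 groups, 2 alleles: compare with a from-scratch WC-84 calculation."""
    genos = {
        "a": [(100, 100), (100, 102), (100, 100), (100, 102), (102, 102)],
        "b": [(100, 102), (102, 102), (102, 102), (100, 102)],
        "c": [(100, 100), (100, 100), (100, 102), (102, 102), (102, 102),
              (100, 102)],
    }
    gt = _make_gt(genos)
    theta = popgen.wc_theta(gt, gt.sites)

    # independent oracle, scalar arithmetic for allele 100 and 102
    n = np.array([5.0, 4.0, 6.0])
    r = 3
    nbar = n.mean()
    nc = (r * nbar - (n**2).sum() / (r * nbar)) / (r - 1)
    A = B = C = 0.0
    for target in (100, 102):
        p_i, h_i = [], []
        for grp in ("a", "b", "c"):
            arr = np.array(genos[grp])
            p_i.append((arr == target).mean())
            h_i.append(np.mean((arr == target).sum(axis=1) == 1))
        p_i, h_i = np.array(p_i), np.array(h_i)
        pbar = (n * p_i).sum() / (r * nbar)
        s2 = (n * (p_i - pbar) ** 2).sum() / ((r - 1) * nbar)
        hbar = (n * h_i).sum() / (r * nbar)
        a = nbar / nc * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2
                               - hbar / 4) / (nbar - 1))
        b = nbar / (nbar - 1) * (pbar * (1 - pbar) - (r - 1) / r * s2
                                 - (2 * nbar - 1) / (4 * nbar) * hbar)
        A, B, C = A + a, B + b, C + hbar / 2
    assert theta == pytest.approx(A / (A + B + C), abs=1e-10)


def test_monomorphic_locus_theta_undefined(toy_genotypes):
    gt = toy_genotypes
    gt.alleles[:] = 100
    summary = popgen.locus_summary(gt, gt.sites)
    assert math.isnan(summary.loc[0, "theta"])
    assert summary.loc[0, "n_alleles"] == 1


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------


def test_hwe_monomorphic_is_na():
    assert math.isnan(popgen.hwe_exact_locus(np.full((6, 2), 100)))


def test_hwe_enumeration_matches_hand_enumeration():
    """6 heterozygotes, 2 alleles: enumerate tables with allele counts 6/6."""
    obs = np.array([[100, 102]] * 6)
    p = popgen.hwe_exact_locus(obs)

    def table_prob(h):  # h heterozygotes, (6-h)/2 of each homozygote
        n11 = n22 = (6 - h) // 2
        lp = (math.lgamma(7) + h * math.log(2) + 2 * math.lgamma(7)
              - math.lgamma(13) - math.lgamma(n11 + 1)
              - math.lgamma(n22 + 1) - math.lgamma(h + 1))
        return math.exp(lp)

    probs = {h: table_prob(h) for h in (0, 2, 4, 6)}
    assert sum(probs.values()) == pytest.approx(1.0, abs=1e-9)
    obs_p = probs[6]
    oracle = sum(v for v in probs.values() if v <= obs_p + 1e-12)
    assert p == pytest.approx(oracle, abs=1e-9)


def test_hwe_mc_agrees_with_enumeration():
    rng = np.random.default_rng(1)
    pool = np.repeat([100, 102], [14, 10])
    rng.shuffle(pool)
    obs = pool.reshape(-1, 2)
    p_enum = popgen.hwe_exact_locus(obs)
    n_mc = 4000
    p_mc = popgen.hwe_exact_locus(obs, n_mc=n_mc, seed=2,
                                  max_enumeration=0)
    se = math.sqrt(p_enum * (1 - p_enum) / n_mc)
    assert abs(p_mc - p_enum) < 3 * se + 1 / n_mc


# ---------------------------------------------------------------------------
# Linkage disequilibrium
# ---------------------------------------------------------------------------


def test_ld_pair_count(simulated):
    gt, _, inds, _ = simulated
    res = popgen.ld_gtest(gt, n_perm=20, seed=1)
    per_site = res.groupby("unit").size()
    assert (per_site == 28).all()  # C(8, 2)


def test_ld_co_inherited_minimal_p():
    rng = np.random.default_rng(3)
    genos = []
    for _ in range(30):
        a = rng.choice([100, 102], 2).tolist()
        genos.append(a + a)  # locus 2 duplicates locus 1
    gt = _make_gt({"s": [tuple(g) for g in genos]}, loci=2)
    res = popgen.ld_gtest(gt, n_perm=99, seed=4)
    assert res.loc[0, "p"] == pytest.approx(1 / 100)


def test_ld_null_p_uniform():
    """Independently simulated loci give uniform p over replicate sites."""
    rng = np.random.default_rng(6)
    ps = []
    for rep in range(200):
        genos = [tuple(rng.choice([100, 102, 104], 2).tolist()
                       + rng.choice([200, 202, 204], 2).tolist())
                 for _ in range(25)]
        gt = _make_gt({"s": genos}, loci=2)
        res = popgen.ld_gtest(gt, n_perm=99, seed=int(rng.integers(2**31)))
        ps.append(res.loc[0, "p"])
    assert kstest(ps, "uniform").pvalue > 0.01


# ---------------------------------------------------------------------------
# RST / pRST
# ---------------------------------------------------------------------------


def test_rst_two_sizes_invariant_p_one():
    rng = np.random.default_rng(7)
    genos = {g: [tuple(rng.choice([100, 104], 2, p=p))
                 for _ in range(15)]
             for g, p in (("a", [0.8, 0.2]), ("b", [0.2, 0.8]))}
    gt = _make_gt(genos)
    res = popgen.rst_prst_test(gt, gt.sites, n_perm=60, seed=8)
    assert res.loc[0, "p"] == 1.0


def test_rst_identical_distributions_near_zero():
    rng = np.random.default_rng(9)
    genos = {g: [tuple(rng.choice([100, 102, 104], 2))
                 for _ in range(60)] for g in ("a", "b")}
    gt = _make_gt(genos)
    res = popgen.rst_prst_test(gt, gt.sites, n_perm=200, seed=10)
    assert abs(res.loc[0, "rst"]) < 0.05
    assert res.loc[0, "p"] > 0.2


def test_rst_exhaustive_three_sizes_matches_enumeration():
    rng = np.random.default_rng(11)
    sizes = np.array([100, 103, 109])
    genos = {"a": [tuple(rng.choice(sizes, 2, p=[0.7, 0.2, 0.1]))
                   for _ in range(12)],
             "b": [tuple(rng.choice(sizes, 2, p=[0.1, 0.2, 0.7]))
                   for _ in range(12)]}
    gt = _make_gt(genos)
    res = popgen.rst_prst_test(gt, gt.sites, exhaustive=True, seed=0)
    assert res.loc[0, "n_perm"] == 6  # all 3! size assignments

    # independent enumeration with a from-scratch RST
    def rst_oracle(mapping):
        pops = []
        for grp in ("a", "b"):
            vals = np.array([mapping[v] for g in genos[grp] for v in g],
                            dtype=float)
            pops.append(vals)
        allv = np.concatenate(pops)
        N, r = len(allv), 2
        nvec = np.array([len(p) for p in pops], dtype=float)
        ssw = sum(((p - p.mean()) ** 2).sum() for p in pops)
        ssa = sum(len(p) * (p.mean() - allv.mean()) ** 2 for p in pops)
        msw, msa = ssw / (N - r), ssa / (r - 1)
        n0 = (N - (nvec**2).sum() / N) / (r - 1)
        s2a = (msa - msw) / n0
        return s2a / (s2a + msw)

    obs = rst_oracle(dict(zip(sizes, sizes)))
    null = [rst_oracle(dict(zip(sizes, perm)))
            for perm in itertools.permutations(sizes)]
    p_oracle = np.mean([v >= obs - 1e-12 for v in null])
    assert res.loc[0, "rst"] == pytest.approx(obs, abs=1e-10)
    assert res.loc[0, "p"] == pytest.approx(p_oracle, abs=1e-12)


def test_rst_empty_group_errors(toy_genotypes):
    groups = toy_genotypes.sites.copy()
    groups.iloc[4:] = "a"  # group b left with no members
    with pytest.raises(ValueError):
        popgen.rst_prst_test(toy_genotypes,
                             pd.Series(["a"] * 7 + ["b"],
                                       index=groups.index),
                             n_perm=10, seed=0)


# ---------------------------------------------------------------------------
# Mantel IBD
# ---------------------------------------------------------------------------


def _sym(rng, n):
    d = np.abs(rng.normal(size=(n, n))) + 0.5
    d = (d + d.T) / 2
    np.fill_diagonal(d, 0)
    return d


def test_mantel_monotone_transform_minimal_p():
    rng = np.random.default_rng(12)
    d = _sym(rng, 8)
    g = 0.2 * np.log(d + 1)
    np.fill_diagonal(g, 0)
    r, p = popgen.mantel_ibd(g, d, n_perm=999, seed=13)
    assert r > 0.9
    assert p < 0.01


def test_mantel_constant_matrix_na():
    rng = np.random.default_rng(14)
    d = _sym(rng, 6)
    g = np.full((6, 6), 0.2)
    np.fill_diagonal(g, 0)
    g = g * 0  # exactly constant off-diagonal after transform: use zeros
    r, p = popgen.mantel_ibd(g, d, n_perm=99, seed=0)
    assert math.isnan(r) and math.isnan(p)


def test_mantel_small_n_matches_exhaustive():
    """5 sites: Monte Carlo p within 3 binomial SE of the exhaustive 5!
    label-permutation p."""
    rng = np.random.default_rng(15)
    d = _sym(rng, 5)
    g = 0.1 * d + 0.05 * _sym(rng, 5)
    r_obs, p_mc = popgen.mantel_ibd(g, d, n_perm=10_000, seed=16)

    gt = g / (1 - g)
    dt = np.log(d, out=np.full_like(d, np.nan), where=d > 0)
    iu = np.triu_indices(5, 1)
    hits = total = 0
    for perm in itertools.permutations(range(5)):
        gp = gt[np.ix_(perm, perm)][iu]
        rp = np.corrcoef(gp, dt[iu])[0, 1]
        total += 1
        if rp >= r_obs - 1e-12:
            hits += 1
    p_ex = hits / total
    se = math.sqrt(p_ex * (1 - p_ex) / 10_000)
    assert abs(p_mc - p_ex) < 3 * se + 2e-4
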