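"""Simulate hierarchically structured genetic and phenotypic data with truth.

Genetic groups occupy bands of the landscape delimited by contact zones:
each contact zone is a copy of a catchment ridgeline displaced northwards by
a configurable offset delta (metres), so the truth of "boundary coincides
with ridge" (delta = 0) versus "boundary displaced from ridge" (delta > 0)
is known exactly. Within groups:

* microsatellite genotypes are drawn from per-group allele-frequency
  vectors sampled from a Dirichlet centred on shared ancestral frequencies
  with concentration (1 - F)/F per allele class, giving expected
  among-group FST close to the divergence parameter F without a coalescent;
  allele states are integer sizes on a stepwise ladder so size-based
  statistics (RST) are meaningful;
* mitochondrial haplotypes are drawn from group-specific frequency vectors
  concentrated on a group-diagnostic haplotype; the haplotype pool is built
  by planting substitutions at known positions on a fixed 448-base
  reference, so sequence site statistics have analytic truth;
* each individual shows its group-diagnostic three-trait colour phenotype
  with probability c (concordance), otherwise a uniformly random phenotype.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import GenotypeTable, HaplotypeAlignment
from .landscape import Landscape

BASES = np.array(list("ACGT"))

DEFAULT_GENETICS = dict(
    n_loci=8,
    n_alleles=8,
    divergence=0.3,
    repeat_motif=2,
    base_size=180,
    n_haplotypes=8,
    hap_substitutions=3,
    hap_diag_freq=0.7,
    phenotype_concordance=0.9,
    reference_length=448,
)

# Common phenotypes: triples of (segmental-spot colour, additional-spot
# colour, additional-spot pattern) state codes.
PHENOTYPE_POOL = ["111", "112", "114", "214", "234", "334", "312", "224"]
# Per-trait state alphabets (colour x colour x pattern); non-concordant
# individuals draw each trait independently from these.
TRAIT_STATES = ("123", "123", "1234")


@dataclass
class TruthModel:
    """Ground truth exported with every simulation.

    Sufficient to recompute each site's and individual's true category
    without re-running the simulation.
    """

    site_cluster: pd.Series          # site id -> hierarchical group label
    site_haplogroup: pd.Series       # site id -> haplotype-region label
    site_phenogroup: pd.Series       # site id -> phenotype distribution id
    boundaries: list[np.ndarray]     # true contact-zone polylines (metres)
    deltas: list[float]              # displacement of each boundary from its ridge
    cluster_labels: list[str]
    allele_freqs: dict = field(default_factory=dict)   # (cluster, locus) -> freq vector
    hap_freqs: dict = field(default_factory=dict)      # cluster -> freq vector
    diagnostic_phenotype: dict = field(default_factory=dict)
    planted_positions: dict = field(default_factory=dict)  # hap id -> variable positions


_STOPS = {"TAA", "TAG"}  # invertebrate mitochondrial code


def _reference_sequence(length: int) -> str:
    """Fixed pseudo-random coding reference, stop-free in frame 0;
    independent of the simulation seed."""
    rng = np.random.default_rng(448)
    codons = []
    while 3 * len(codons) < length:
        c = "".join(rng.choice(BASES, size=3))
        if c not in _STOPS:
            codons.append(c)
    return "".join(codons)[:length]


def build_haplotype_pool(
    n_haplotypes: int,
    length: int = 448,
    substitutions_per_hap: int = 3,
    seed: int = 0,
) -> tuple[list[str], dict[str, list[int]]]:
    """Plant substitutions at known, disjoint positions on the reference.

    Haplotype ``hap01`` is the reference itself; haplotype j carries
    ``substitutions_per_hap`` substitutions at positions unique to it.
    Returns (sequences, {hap id: planted 0-based positions}).
    """
    ref = _reference_sequence(length)
    rng = np.random.default_rng(seed)
    needed = (n_haplotypes - 1) * substitutions_per_hap
    if needed > length:
        raise ValueError("not enough sites to plant disjoint substitutions")
    positions = rng.choice(length, size=needed, replace=False)
    seqs, planted = [ref], {"hap01": []}
    for j in range(1, n_haplotypes):
        pos = sorted(positions[(j - 1) * substitutions_per_hap: j * substitutions_per_hap])
        s = list(ref)
        for p in pos:
            alts = [b for b in "ACGT" if b != ref[p]]
            rng.shuffle(alts)
            start = p - p % 3
            for alt in alts:  # keep the mutated codon stop-free in frame 0
                codon = s[start:start + 3]
                codon[p % 3] = alt
                if "".join(codon) not in _STOPS:
                    s[p] = alt
                    break
        seqs.append("".join(s))
        planted[f"hap{j + 1:02d}"] = [int(p) for p in pos]
    return seqs, planted


def _cluster_bands(landscape: Landscape, deltas: list[float]) -> list[np.ndarray]:
    """Contact-zone polylines: ridgelines shifted north by their deltas."""
    if len(deltas) != len(landscape.ridgelines):
        raise ValueError("one delta per ridgeline required")
    bounds = []
    for ridge, d in zip(landscape.ridgelines, deltas):
        if d < 0:
            raise ValueError("delta must be >= 0")
        b = ridge.copy()
        b[:, 1] = b[:, 1] + d
        bounds.append(b)
    return bounds


def _band_index(boundaries: list[np.ndarray], x: np.ndarray, y: np.ndarray) -> np.ndarray:
    idx = np.zeros(len(x), dtype=int)
    for b in boundaries:
        idx += (y > np.interp(x, b[:, 0], b[:, 1])).astype(int)
    return idx


def simulate_markers(
    landscape: Landscape,
    sites: pd.DataFrame,
    truth_config: dict | None = None,
    genetics_config: dict | None = None,
    n_per_site: int = 8,
    seed: int = 0,
):
    """Simulate genotypes, haplotypes and phenotypes over placed sites.

    Parameters
    ----------
    truth_config : dict
        ``deltas`` — northward displacement (m) of each genetic contact zone
        from its ridgeline (default all 0); ``cluster_labels`` — hierarchical
        labels for the bands, south to north (default "1", "2", ...).
    genetics_config : dict
        Overrides of :data:`DEFAULT_GENETICS`.

    Returns
    -------
    (GenotypeTable, HaplotypeAlignment, individuals DataFrame, TruthModel)
        The individuals frame has one row per simulated individual with its
        site, coordinates, haplotype id and phenotype triple.
    """
    cfg = dict(DEFAULT_GENETICS)
    if genetics_config:
        unknown = set(genetics_config) - set(cfg)
        if unknown:
            raise ValueError(f"unknown genetics_config keys: {sorted(unknown)}")
        cfg.update(genetics_config)
    F = cfg["divergence"]
    if not 0 <= F < 1:
        raise ValueError("divergence F must lie in [0, 1)")
    c = cfg["phenotype_concordance"]
    if not 0 <= c <= 1:
        raise ValueError("phenotype concordance must lie in [0, 1]")
    if n_per_site < 1:
        raise ValueError("n_per_site must be >= 1")

    truth_config = dict(truth_config or {})
    deltas = list(truth_config.get("deltas", [0.0] * len(landscape.ridgelines)))
    boundaries = _cluster_bands(landscape, deltas)
    n_clusters = len(boundaries) + 1
    labels = list(truth_config.get("cluster_labels",
                                   [str(i + 1) for i in range(n_clusters)]))
    if len(labels) != n_clusters:
        raise ValueError("need one cluster label per band")

    rng = np.random.default_rng(seed)
    site_band = _band_index(boundaries, sites["easting"].to_numpy(),
                            sites["northing"].to_numpy())
    site_cluster = pd.Series([labels[b] for b in site_band],
                             index=sites["site"], name="cluster")

    # --- microsatellites -------------------------------------------------
    L, A = cfg["n_loci"], cfg["n_alleles"]
    ladder = cfg["base_size"] + cfg["repeat_motif"] * np.arange(A)
    ancestral = rng.dirichlet(np.ones(A), size=L)  # one frequency vector per locus
    allele_freqs = {}
    for k, lab in enumerate(labels):
        for l in range(L):
            if F == 0:
                freqs = ancestral[l].copy()
            else:
                conc = ancestral[l] * (1 - F) / F
                freqs = rng.dirichlet(np.maximum(conc, 1e-9))
            allele_freqs[(lab, l)] = freqs

    # --- haplotype pool and per-cluster frequencies ----------------------
    H = cfg["n_haplotypes"]
    hap_seqs, planted = build_haplotype_pool(
        H, cfg["reference_length"], cfg["hap_substitutions"], seed=seed)
    hap_ids = list(planted.keys())
    hap_freqs = {}
    for k, lab in enumerate(labels):
        f = np.full(H, (1 - cfg["hap_diag_freq"]) / (H - 1))
        f[k % H] = cfg["hap_diag_freq"]
        hap_freqs[lab] = f

    diag_pheno = {lab: PHENOTYPE_POOL[k % len(PHENOTYPE_POOL)]
                  for k, lab in enumerate(labels)}

    # --- individuals ------------------------------------------------------
    rows, geno = [], []
    for _, srow in sites.iterrows():
        lab = site_cluster[srow["site"]]
        for j in range(n_per_site):
            ind = f"{srow['site']}_i{j + 1:02d}"
            hap = hap_ids[rng.choice(H, p=hap_freqs[lab])]
            if rng.random() < c:
                pheno = diag_pheno[lab]
            else:
                pheno = "".join(states[rng.integers(len(states))]
                                for states in TRAIT_STATES)
            rows.append(dict(individual=ind, site=srow["site"],
                             easting=srow["easting"], northing=srow["northing"],
                             cluster=lab, haplotype=hap, phenotype=pheno))
            g = np.empty((L, 2), dtype=int)
            for l in range(L):
                g[l] = ladder[rng.choice(A, size=2, p=allele_freqs[(lab, l)])]
            geno.append(g)
    inds = pd.DataFrame(rows).set_index("individual")
    gt = GenotypeTable(
        individuals=inds[["site", "easting", "northing"]].copy(),
        alleles=np.stack(geno),
        loci=[f"L{l + 1}" for l in range(L)],
    )

    counts = inds["haplotype"].value_counts()
    observed = [h for h in hap_ids if h in counts.index]
    aln = HaplotypeAlignment(
        ids=observed,
        seqs=[hap_seqs[hap_ids.index(h)] for h in observed],
        counts=np.array([counts[h] for h in observed]),
    )

    truth = TruthModel(
        site_cluster=site_cluster,
        site_haplogroup=pd.Series(
            [hap_ids[labels.index(site_cluster[s]) % H] for s in sites["site"]],
            index=sites["site"], name="haplogroup"),
        site_phenogroup=pd.Series(
            [diag_pheno[site_cluster[s]] for s in sites["site"]],
            index=sites["site"], name="phenogroup"),
        boundaries=boundaries,
        deltas=deltas,
        cluster_labels=labels,
        allele_freqs=allele_freqs,
        hap_freqs=hap_freqs,
        diagnostic_phenotype=diag_pheno,
        planted_positions=planted,
    )
    return gt, aln, inds, truth
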