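"""End-to-end pipeline: simulate -> popgen -> womble -> overlap -> associate.

Drives the library from a flat sectioned config (INI-style), writes every
report as TSV (locus summary, pairwise allele-size test matrix, hierarchical
association report, boundary-overlap report), boundaries as GeoJSON, and a
plain-text log carrying the config hash and every stage seed for
provenance. Each stage is callable on its own.
"""

from __future__ import annotations

import configparser
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import assoc, clusterpost, io, overlap, popgen, womble
from .landscape import generate_landscape, place_sites
from .simulate import simulate_markers

log = logging.getLogger("contactzone")

DEFAULT_CONFIG = {
    "landscape": {"n_catchments": "4", "extent": "0,0,20000,100000",
                  "seed": "1"},
    "sites": {"n_sites": "73", "min_separation": "100", "seed": "2"},
    "truth": {"deltas": "0,0,0"},
    "genetics": {"n_loci": "8", "divergence": "0.3",
                 "phenotype_concordance": "0.9", "n_per_site": "8",
                 "seed": "3"},
    "popgen": {"n_perm": "200", "hwe_mc": "2000", "seed": "4"},
    "overlap": {"n_sim": "999", "ridge_buffer": "100", "seed": "5"},
    "assoc": {"n_mc": "20000", "alpha": "0.05", "seed": "6"},
}


def load_config(path=None) -> dict:
    """Read an INI config, filling unset keys from the defaults."""
    cfg = {s: dict(d) for s, d in DEFAULT_CONFIG.items()}
    if path is not None:
        parser = configparser.ConfigParser()
        read = parser.read(str(path))
        if not read:
            raise FileNotFoundError(path)
        for section in parser.sections():
            cfg.setdefault(section, {}).update(dict(parser[section]))
    return cfg


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True).encode()).hexdigest()[:12]


def _floats(s: str) -> list[float]:
    return [float(v) for v in str(s).split(",") if str(v).strip() != ""]


def run_simulate(cfg: dict, outdir: Path):
    lc = cfg["landscape"]
    land = generate_landscape(int(lc["n_catchments"]),
                              tuple(_floats(lc["extent"])),
                              seed=int(lc["seed"]))
    sc = cfg["sites"]
    sites = place_sites(land, int(sc["n_sites"]),
                        float(sc["min_separation"]), seed=int(sc["seed"]))
    gc = dict(cfg["genetics"])
    n_per_site = int(gc.pop("n_per_site", 8))
    seed = int(gc.pop("seed", 3))
    genetics = {k: (int(v) if k in ("n_loci", "n_alleles", "repeat_motif",
                                    "base_size", "n_haplotypes",
                                    "hap_substitutions", "reference_length")
                    else float(v))
                for k, v in gc.items()}
    deltas = _floats(cfg["truth"].get("deltas", ""))
    if len(deltas) != len(land.ridgelines):
        raise ValueError("truth.deltas must list one value per ridgeline")
    gt, aln, inds, truth = simulate_markers(
        land, sites, truth_config={"deltas": deltas},
        genetics_config=genetics, n_per_site=n_per_site, seed=seed)
    io.write_structure_genotypes(gt, outdir / "genotypes.str")
    io.write_fasta(aln, outdir / "haplotypes.fasta")
    io.write_results_tsv(sites, outdir / "sites.tsv")
    io.write_landscape_geojson(land, outdir / "landscape.geojson")
    io.write_results_tsv(inds.reset_index(), outdir / "individuals.tsv")
    truth_df = pd.DataFrame({
        "site": truth.site_cluster.index,
        "cluster": truth.site_cluster.to_numpy(),
        "haplogroup": truth.site_haplogroup.to_numpy(),
        "phenogroup": truth.site_phenogroup.to_numpy(),
    })
    io.write_results_tsv(truth_df, outdir / "truth.tsv")
    log.info("simulated %d individuals at %d sites (%d clusters)",
             gt.n_individuals, len(sites), len(truth.cluster_labels))
    return land, sites, gt, aln, inds, truth


def run_popgen(cfg: dict, outdir: Path, gt, inds):
    pc = cfg["popgen"]
    seed = int(pc["seed"])
    clusters = inds["cluster"]
    summary = popgen.locus_summary(gt, clusters)
    io.write_results_tsv(summary, outdir / "locus_summary.tsv")
    rst_res = popgen.rst_prst_test(gt, clusters, n_perm=int(pc["n_perm"]),
                                   seed=seed)
    io.write_results_tsv(rst_res, outdir / "rst_prst_pairwise.tsv")
    hwe = popgen.hwe_exact(gt, unit="site", n_mc=int(pc["hwe_mc"]),
                           seed=seed + 1)
    io.write_results_tsv(hwe, outdir / "hwe.tsv")
    log.info("popgen: global theta=%.3f; %d pairwise allele-size tests",
             summary["theta"].iloc[-1], len(rst_res))
    return summary, rst_res, hwe


def build_surface(cfg: dict, land, sites, inds) -> pd.DataFrame:
    """Majority-rule site categories for every variable, plus buffered
    catchment assignment."""
    surface = clusterpost.site_category_surface(
        inds, ["cluster", "haplotype", "phenotype"])
    catch = clusterpost.assign_sites_to_catchments(
        sites, land, buffer=float(cfg["overlap"]["ridge_buffer"]),
        seed=int(cfg["overlap"]["seed"]) + 7)
    surface["catchment"] = catch.reindex(surface.index)
    surface["catchment_excluded"] = False
    return surface


def run_overlap(cfg: dict, outdir: Path, land, sites, surface):
    """Womble each response variable and the catchment predictor; test
    directional overlap of response BEs against each catchment boundary and
    against all of them pooled."""
    oc = cfg["overlap"]
    n_sim, seed = int(oc["n_sim"]), int(oc["seed"])
    net = womble.build_delaunay(sites)
    boundaries = {}
    for var in ("cluster", "haplotype", "phenotype", "catchment"):
        scores = womble.compute_blv(net, surface, var)
        bset = womble.detect_boundary_elements(scores, net, variable=var)
        boundaries[var] = womble.link_subboundaries(bset)
    with open(outdir / "boundaries.geojson", "w") as fh:
        json.dump({v: womble.boundary_geojson(b)
                   for v, b in boundaries.items()}, fh)

    # split the wombled catchment boundary into one predictor per ridgeline
    cb = boundaries["catchment"]
    predictors = {}
    if cb.n_elements:
        mids = cb.midpoints()
        d = land.distance_to_ridges(mids[:, 0], mids[:, 1])
        nearest = d.argmin(axis=1)
        for k, lab in enumerate(land.ridge_labels):
            pick = mids[nearest == k]
            if len(pick):
                predictors[lab] = pick
        predictors["CB-all"] = mids
    hull = overlap.site_hull(sites)
    rows = []
    rng = np.random.default_rng(seed)
    for var in ("cluster", "haplotype", "phenotype"):
        b = boundaries[var]
        if b.n_elements == 0:
            continue
        # single-boundary analyses pair each contact zone (the response BEs
        # nearest a given ridgeline) with that ridgeline's wombled boundary;
        # the "-all" analysis pools both sides
        rmids = b.midpoints()
        rd = land.distance_to_ridges(rmids[:, 0], rmids[:, 1])
        rnearest = rd.argmin(axis=1)
        for k, lab in enumerate(land.ridge_labels):
            if lab not in predictors:
                continue
            zone = rmids[rnearest == k]
            if not len(zone):
                continue
            res = overlap.overlap_randomization_test(
                zone, predictors[lab], domain=hull, n_sim=n_sim,
                seed=int(rng.integers(2**31)),
                response_label=f"{var} zone {k + 1}", predictor_label=lab)
            rows.append(dict(response=f"{var} zone {k + 1}", predictor=lab,
                             o1=res.o1, null_mean=res.null_mean, p=res.p,
                             n_sim=res.n_sim))
        if "CB-all" in predictors:
            res = overlap.overlap_randomization_test(
                b, predictors["CB-all"], domain=hull, n_sim=n_sim,
                seed=int(rng.integers(2**31)),
                response_label=f"{var}-all", predictor_label="CB-all")
            rows.append(dict(response=f"{var}-all", predictor="CB-all",
                             o1=res.o1, null_mean=res.null_mean, p=res.p,
                             n_sim=res.n_sim))
    report = pd.DataFrame(rows)
    io.write_results_tsv(report, outdir / "overlap_report.tsv")
    n_sig = int((report["p"] <= 0.05).sum()) if len(report) else 0
    log.info("overlap: %d tests, %d significant at the lower 0.05 tail",
             len(report), n_sig)
    return boundaries, report


def run_assoc(cfg: dict, outdir: Path, inds):
    ac = cfg["assoc"]
    seed, n_mc = int(ac["seed"]), int(ac["n_mc"])
    rep_hap = assoc.hierarchical_association(
        inds, "cluster", "haplotype", alpha=float(ac["alpha"]),
        n_mc=n_mc, seed=seed)
    rep_phe = assoc.hierarchical_association(
        inds, "cluster", "phenotype", alpha=float(ac["alpha"]),
        n_mc=n_mc, seed=seed + 1)
    out = pd.concat([rep_hap.rows.assign(pairing="haplotype-nuclear"),
                     rep_phe.rows.assign(pairing="phenotype-nuclear")])
    io.write_results_tsv(out, outdir / "association_report.tsv")

    # three-way colour-trait independence on the phenotype digit triples
    traits = inds["phenotype"].astype(str)
    t1 = sorted(traits.str[0].unique())
    t2 = sorted(traits.str[1].unique())
    t3 = sorted(traits.str[2].unique())
    counts = np.zeros((len(t1), len(t2), len(t3)))
    for p, n in traits.value_counts().items():
        counts[t1.index(p[0]), t2.index(p[1]), t3.index(p[2])] += n
    # trait combinations never observed are treated as structural zeros:
    # with them unmasked the homogeneous-association MLE sits on the
    # boundary and IPF stalls
    ll = assoc.loglinear_independence(counts, mask=counts > 0)
    io.write_results_tsv(ll.terms, outdir / "loglinear_report.tsv")
    log.info("association: %d cascade rows; three-way G2=%.3f",
             len(out), ll.term("three-way")["g2"])
    return out, ll


def run_pipeline(config=None, outdir="results/pipeline",
                 seed: int | None = None) -> dict:
    """Run every stage; returns the result bundle as a dict.

    ``config`` is a path to an INI file or a config dict; ``seed`` overrides
    every per-stage seed (stage seeds become seed, seed+1, ...).
    """
    cfg = config if isinstance(config, dict) else load_config(config)
    if seed is not None:
        for i, section in enumerate(
                ("landscape", "sites", "genetics", "popgen", "overlap",
                 "assoc")):
            cfg[section]["seed"] = str(seed + i)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    t0 = time.time()
    try:
        log.info("config hash %s", config_hash(cfg))
        with open(outdir / "config_used.json", "w") as fh:
            json.dump(cfg, fh, indent=1, sort_keys=True)
        land, sites, gt, aln, inds, truth = run_simulate(cfg, outdir)
        summary, rst_res, hwe = run_popgen(cfg, outdir, gt, inds)
        surface = build_surface(cfg, land, sites, inds)
        boundaries, overlap_report = run_overlap(cfg, outdir, land, sites,
                                                 surface)
        assoc_report, ll = run_assoc(cfg, outdir, inds)
        log.info("pipeline complete in %.1f s", time.time() - t0)
    finally:
        log.removeHandler(handler)
        handler.close()
    return dict(landscape=land, sites=sites, genotypes=gt, alignment=aln,
                individuals=inds, truth=truth, locus_summary=summary,
                rst=rst_res, hwe=hwe, surface=surface, boundaries=boundaries,
                overlap=overlap_report, association=assoc_report,
                loglinear=ll, config=cfg)


# ---------------------------------------------------------------------------
# Simulation-based operating characteristics
# ---------------------------------------------------------------------------


def boundary_coincidence_replicate(
    delta: float,
    divergence: float = 0.3,
    n_sites: int = 40,
    n_per_site: int = 6,
    n_sim: int = 199,
    seed: int = 0,
    extent=(0.0, 0.0, 20_000.0, 100_000.0),
) -> float:
    """One power-simulation replicate of the full downstream pipeline.

    Simulates a two-catchment landscape whose genetic contact zone is
    displaced ``delta`` metres north of the single ridgeline, wombles both
    the genetic clusters and the catchment membership, and returns the
    lower-tail p of the directional overlap test (genetic zone as response,
    wombled catchment boundary as predictor).
    """
    land = generate_landscape(2, extent, seed=seed)
    sites = place_sites(land, n_sites, 100.0, seed=seed + 1)
    _, _, inds, _ = simulate_markers(
        land, sites, truth_config={"deltas": [delta]},
        genetics_config={"divergence": divergence},
        n_per_site=n_per_site, seed=seed + 2)
    surface = clusterpost.site_category_surface(inds, ["cluster"])
    surface["catchment"] = clusterpost.assign_sites_to_catchments(
        sites, land, seed=seed + 3).reindex(surface.index)
    surface["catchment_excluded"] = False
    net = womble.build_delaunay(sites)
    bsets = {}
    for var in ("cluster", "catchment"):
        scores = womble.compute_blv(net, surface, var)
        bsets[var] = womble.detect_boundary_elements(scores, net, variable=var)
    if bsets["cluster"].n_elements == 0 or bsets["catchment"].n_elements == 0:
        return np.nan  # degenerate draw: a category was uniform
    res = overlap.overlap_randomization_test(
        bsets["cluster"], bsets["catchment"], sites=sites,
        n_sim=n_sim, seed=seed + 4)
    return res.p


def overlap_power(deltas, n_replicates: int = 100, alpha: float = 0.05,
                  seed: int = 0, **kwargs) -> pd.DataFrame:
    """Rejection rate of the overlap test at each boundary displacement."""
    rows = []
    for d in deltas:
        ps = [boundary_coincidence_replicate(d, seed=seed + 1000 * r, **kwargs)
              for r in range(n_replicates)]
        ps = [p for p in ps if np.isfinite(p)]
        rows.append(dict(delta=d, n=len(ps),
                         power=float(np.mean([p <= alpha for p in ps]))))
    return pd.DataFrame(rows)


def csr_type_i_error(n_tests: int = 500, n_response: int = 20,
                     n_predictor: int = 30, n_sim: int = 199,
                     alpha: float = 0.05, seed: int = 0) -> dict:
    """Empirical size of the CSR overlap test when the response really is
    completely spatially random over the domain."""
    rng = np.random.default_rng(seed)
    land = generate_landscape(2, seed=seed)
    sites = place_sites(land, 40, 100.0, seed=seed + 1)
    hull = overlap.site_hull(sites)
    pred = overlap.sample_csr(hull, n_predictor, rng)
    rejections = 0
    ps = []
    for t in range(n_tests):
        resp = overlap.sample_csr(hull, n_response, rng)
        res = overlap.overlap_randomization_test(
            resp, pred, domain=hull, n_sim=n_sim,
            seed=int(rng.integers(2**31)))
        ps.append(res.p)
        rejections += res.p <= alpha
    return dict(n_tests=n_tests, alpha=alpha, rate=rejections / n_tests,
                p_values=np.array(ps))
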