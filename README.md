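# contactzone

Detection of genetic and phenotypic contact zones across a sampled
landscape, and Monte Carlo tests of whether those zones coincide with
hypothesised landscape barriers.

## The problem

In topographically complex terrain, low-dispersal organisms — here modelled
on a saproxylic velvet worm (*Euperipatoides rowelli*) sampled along a
~100 km montane forest transect subdivided by east–west catchment
ridgelines — often form spatially localised genetic groups. Two questions
follow. First, where do the groups meet (the *contact zones*)? Second, do
those zones sit on the landscape features thought to limit gene flow
(high-elevation ridgelines between catchments, CB-1…CB-n), or are they
displaced, implying a historical rather than contemporary role for the
barrier?

`contactzone` implements the full analysis as a reusable, tested pipeline:

1. **Categorical wombling (boundary detection).** Sites are reduced to one
   category per variable (nuclear cluster, mtDNA clade or common haplotype,
   colour-pattern phenotype, catchment) by majority rule, connected by
   Delaunay triangulation, and each edge is scored with a Boundary
   Likelihood Value — for categorical data the (mean) mismatch indicator
   BLV ∈ [0, 1] between the two connected sites. Edges above a natural
   break (two-class Jenks) in the BLV distribution contribute Boundary
   Elements (BEs): the dual Voronoi edges, perpendicular to the connection
   and equidistant from the two sites. Vertex-sharing BEs are linked into
   contiguous subboundaries (candidate contact zones).
2. **Directional overlap test.** For a response boundary B₁ and predictor
   boundary B₂, the statistic *O*₁ = mean distance from each BE of B₁ to
   the nearest BE of B₂. Small *O*₁ means spatial coincidence. Only the
   response is randomized: 10,000 Monte Carlo replicates place |B₁| points
   under complete spatial randomness in the site convex hull (a
   network-constrained null is also provided), and significance is read in
   the lower tail, *p* = (1 + #{*O*₁ˢⁱᵐ ≤ *O*₁ᵒᵇˢ}) / (1 + n).
3. **Supporting statistics.** Per-locus summaries and global Weir–Cockerham
   θ (F_ST); exact Hardy–Weinberg tests (full enumeration or conditional
   Monte Carlo); genotypic linkage-disequilibrium permutation G-tests;
   pairwise pR_ST–R_ST allele-size permutation tests (is divergence old
   enough for stepwise mutations to matter?); Mantel tests of isolation by
   distance on θ/(1−θ) vs ln(distance); Tajima's D and Fu's Fs; variable /
   parsimony-informative site censuses with codon-position and
   synonymous/non-synonymous tallies under the invertebrate mitochondrial
   code; Fisher-exact association cascades over the nuclear group hierarchy
   with per-level Bonferroni correction; and a log-linear (IPF) test of
   three-trait independence.
4. **Synthetic data with exported truth.** A generator builds
   ridge-partitioned landscapes, places sites with a hard 100 m separation,
   and simulates diploid stepwise-ladder microsatellites (per-cluster
   allele frequencies Dirichlet-distributed about shared ancestral
   frequencies with concentration (1−F)/F, so expected among-cluster
   F_ST ≈ F), haplotypes from a 448-base pool with substitutions planted at
   known positions, and partially concordant phenotypes. Contact zones are
   ridgelines displaced north by a known offset Δ, so "boundary coincides
   with ridge" is a controllable truth.

## Worked example

```python
import contactzone as cz

land  = cz.generate_landscape(3, seed=41)          # 2 ridgelines, 3 catchments
sites = cz.place_sites(land, 60, 100.0, seed=42)   # >100 m apart
gt, aln, inds, truth = cz.simulate_markers(
    land, sites,
    truth_config={"deltas": [15_000.0, 0.0]},      # zone 1 displaced 15 km,
    genetics_config={"divergence": 0.3},           # zone 2 dead on CB-2
    n_per_site=8, seed=43)

surf = cz.clusterpost.site_category_surface(inds, ["haplotype"])
surf["catchment"] = cz.clusterpost.assign_sites_to_catchments(
    sites, land, seed=44).reindex(surf.index)
surf["catchment_excluded"] = False

net  = cz.womble.build_delaunay(sites)
resp = cz.womble.link_subboundaries(cz.womble.detect_boundary_elements(
    cz.womble.compute_blv(net, surf, "haplotype"), net))
pred = cz.womble.detect_boundary_elements(
    cz.womble.compute_blv(net, surf, "catchment"), net)

zone2 = cz.womble.subboundary_nearest_line(resp, land.ridgelines[1])
res = cz.overlap.overlap_randomization_test(
    zone2, pred.midpoints(), sites=sites, n_sim=9999, seed=45)
print(f"O1 = {res.o1/1000:.2f} km, p = {res.p:.4f}")
```

prints

```
O1 = 0.00 km, p = 0.0001
```

— the common-haplotype contact zone generated on the second ridgeline
falls on exactly the same Voronoi edges as the wombled catchment boundary
(*O*₁ = 0), and under the CSR null that coincidence is as extreme as it can
be at 9,999 randomizations (*p* = 1/10,000, lower tail). The displaced
zone 1 tested the same way gives `O1 = 14.61 km, p = 0.9253`: far from its
ridgeline and entirely unremarkable under the null.

The numbered drivers under `analysis/` run the same machinery end to end
(`python analysis/01_simulate.py`, … `05_operating_characteristics.py`),
writing TSV/GeoJSON reports under `results/`: locus summaries, pairwise
pR_ST–R_ST matrices, the hierarchical association report, the Table-shaped
overlap report, and the size/power study of the overlap test. The `contactzone`
console script exposes the same stages (`contactzone all --seed 1 --out out/`).

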