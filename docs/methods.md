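# Methods

This note documents the models and procedures implemented in `contactzone`,
the defaults and why they were chosen, what the synthetic-data generator
does and does not emulate, and the numerical decisions that affect results.

## Boundary detection (categorical wombling)

Sites carry one category per variable. Each variable's site surface is
built by majority rule over the individuals sampled there: "U"
(unassigned) labels are dropped first, ties break to the lexicographically
smallest label and are flagged, and sites left with nothing are flagged
excluded and drop their network edges. Adjacent sites are connected by
Delaunay triangulation (via the Voronoi dual; `scipy.spatial`). The
Boundary Likelihood Value of an edge is the mismatch indicator of its two
site categories, or the mean of the per-variable indicators when several
variables are wombled together; both conventions are supported because
either reading is defensible and with a single categorical variable the
distinction disappears.

Boundary Elements are the dual Voronoi edges of high-BLV connections. The
threshold is the two-class minimal-within-variance (Jenks) break in the
BLV distribution; with binary BLVs this degenerates to selecting exactly
the mismatch edges, which is the operative case for single categorical
variables. When every BLV is identical no break exists and the result is
an empty boundary set with a warning rather than an arbitrary cut.

Unbounded Voronoi rays are clipped to the convex hull of the sites
expanded by one median Delaunay edge length (configurable). Clipping keeps
every BE segment, midpoint and hence every O1 distance finite, while
leaving endpoints on the perpendicular bisector of their generator pair,
so the defining equidistance property survives clipping. Vertex-sharing
BEs (endpoints within 1e-6 m) form subboundaries via connected components.

## Directional overlap and its null

O1(B1, B2) is the mean distance from each BE of the response boundary to
the nearest BE of the predictor; BE location is the dual-segment midpoint
(segment-to-segment distance is available as an option, but midpoints are
the default because candidate segments have comparable lengths on
reasonably even site networks, and midpoints make the CSR null concrete).
The predictor — a fixed landscape feature — is never randomized. The CSR
null drops |B1| uniform points in the site convex hull per replicate; a
network-constrained null that re-selects |B1| BEs among all candidate
Voronoi edges is provided for sensitivity analysis, since commercial
implementations do not document their scheme. p-values are lower-tail
with the +1 correction, so p = 0 is impossible and p = 1/(n+1) is the
floor. Single-boundary analyses pair a named contact zone — the linked
subboundary nearest the feature in question (`subboundary_nearest_line`,
minimum 3 BEs) — with that feature; pooled ("-all") analyses concatenate
BE midpoints across zones and across features.

One caveat the simulations make visible: any coherent east–west contact
zone is more linearly concentrated than a CSR point set, so even a zone
displaced kilometres from its ridge can earn mild significance against the
CSR null. Conclusions should rest on the coincident-vs-displaced contrast
(O1 magnitude and p together), which is how the acceptance checks read it.

## Population-genetic statistics

* **θ (F_ST)** is the Weir–Cockerham (1984) variance-components estimator,
  summed over alleles within loci and over loci for the global value.
  Monomorphic loci yield an undefined (NaN) θ, never zero.
* **Hardy–Weinberg**: exact conditional test given allele counts, with the
  conditional (Levene) probability as the ordering statistic. Genotype tables are fully
  enumerated when the space is small (≤ 4 alleles, n ≤ 30, ≤ 1e5 tables);
  otherwise Monte Carlo by random pairing of the pooled alleles, which
  samples the conditional null exactly.
* **Linkage disequilibrium**: G-statistic on the two-locus genotype
  contingency table per site, null by permuting one locus's genotypes among
  individuals within the site.
* **R_ST / pR_ST**: allele-size variance components (one-way random-effects
  ANOVA with the unequal-size n0 correction), summed over loci. The null
  permutes allele sizes among allelic states — frequencies and identities
  stay put, only the sizes attached to states move — so a significant
  upper-tail p means stepwise-size information beyond drift. The exhaustive
  option enumerates all joint size assignments when the ladder is tiny.
  Note that the synthetic generator diverges clusters by drift on allele
  frequencies only; it plants no stepwise-mutation signal, so on simulated
  data this test is expected to be non-significant — which is itself a
  useful negative control.
* **Mantel IBD**: Pearson correlation of θ/(1−θ) against ln(distance)
  (the convention of the standard population-genetics software for
  isolation by distance), permuting site labels of one matrix; upper
  one-sided p.
* **Tajima's D** uses the standard a1, a2, b1, b2, c1, c2, e1, e2
  coefficients with π the mean pairwise difference. **Fu's Fs** is
  ln(S′/(1−S′)) with S′ = Pr(K ≥ k_obs | θ̂_π) under the Ewens sampling
  formula; Pr(K = k) is computed from unsigned Stirling numbers of the
  first kind by a log-scale recursion, stable to n in the hundreds. Both
  are flagged undefined when S = 0. Both a unique-haplotype mode and an
  individual-expanded mode are provided, because published values do not
  always say which sample was used.
* **Site statistics**: variable sites are columns with ≥ 2 unambiguous
  states; parsimony-informative sites additionally need ≥ 2 states each in
  ≥ 2 sequences; codon positions are relative to the first stop-free
  reading frame under the invertebrate mitochondrial code (error listing
  stop positions per frame when none exists). Synonymous/non-synonymous
  counts classify each observed variant against the majority-rule
  consensus codon — a deliberate, documented choice among the several
  defensible counting schemes. p-distances use pairwise deletion.
  Haplotypes carried by more than 9 individuals are "common".

## Clustering post-processing

The clustering MCMC itself is out of scope; its membership coefficients
(Q) and log-likelihoods are inputs. An individual is assigned to its
argmax cluster only when Q strictly exceeds 0.8, else labelled "U";
assignment is monotone in the threshold. The "most likely run" for a K is
taken as the run with the *highest* Ln P(X|K) (configurable; descriptions
sometimes phrase this as "lowest", which reads as a slip). Δ K is the
Evanno second-difference statistic: mean over replicates of
|L(K+1) − 2L(K) + L(K−1)| divided by the across-replicate sd of L(K),
undefined at grid ends and where sd = 0 (flagged, not zero). Hierarchical
re-clustering bookkeeping only ever admits individuals assigned (Q > 0.8)
at the parent level. Sites within 100 m of a ridgeline are assigned
uniformly at random (seeded) to one of that ridgeline's two adjacent
catchments; farther sites take their containing catchment.

## Association tests

Fisher's exact test on r×c tables uses conditional-probability ordering:
full enumeration of fixed-margin tables when a conservative bound says the
space is ≤ 1e6 tables, otherwise Monte Carlo by permuting column labels of
the individual-level representation (again exactly the conditional null),
with the +1 correction. The hierarchical cascade tests the top-level
grouping first and descends only into branches significant after
per-level Bonferroni correction (corrected p = min(1, raw p × tests at
that level)); branches without two testable categories are flagged
"unable to test".

The log-linear analysis fits hierarchical models by iterative proportional
fitting (tolerance 1e-10, 1e4 iterations by default). The three-way term
is saturated vs homogeneous association; each two-way term is dropped from
the homogeneous model. Structural zeros are excluded by a mask with the
three-way df reduced by the number of masked cells. Two numerical facts
matter: (i) when sampling zeros put the MLE on the boundary, plain IPF
converges only as 1/iteration, so cells collapsing towards zero are frozen
periodically to restore geometric convergence; (ii) in the pipeline's
trait analysis, trait combinations never observed are treated as
structural and masked — the phenotype state space is sparse by
construction and an unmasked fit stalls on its boundary.

## The synthetic-data generator

The generator emulates the study conditions: a 20 km × 100 km transect
(easting × northing) split into n catchments by east–west ridgelines —
monotone-in-easting polylines with vertical jitter bounded at 25% of the
inter-ridge spacing, which guarantees non-crossing by vertical ordering —
and sites placed uniformly with a hard >100 m separation (default 73
sites, matching the study's sampling intensity; rejection sampling with an
explicit failure after 500·n attempts). Genetic contact zones are the
ridgelines displaced north by Δ ≥ 0 m, so coincidence truth is exact and
exported.

Genotypes: 8 loci, 8-allele stepwise ladders (2 bp motif), per-cluster
allele frequencies drawn from Dirichlet(ancestral × (1−F)/F). This yields
a tunable expected among-cluster F_ST ≈ F without coalescent machinery;
the default F = 0.3 produces the strong, drift-dominated structuring the
method needs to detect (the source system reports no effect size usable to
calibrate F, so this default is a documented choice, not an estimate of
the real system). Haplotypes: a pool of 8 sequences built by planting 3
substitutions per haplotype at disjoint, recorded positions on a fixed
448-base stop-free coding reference, giving analytic truth for variable
sites and distances; each cluster draws its diagnostic haplotype with
probability 0.7 and the rest uniformly. Phenotypes: three colour traits
(3 × 3 × 4 states); with probability c = 0.9 an individual shows its
cluster's diagnostic triple, otherwise the traits are drawn independently.
Note the mixture "diagnostic triple + independent noise" deliberately
creates genuine three-way trait interaction; checks of the log-linear
three-way term therefore sample from an explicit homogeneous-association
law instead.

What the generator does **not** emulate: mutation processes on a real
timescale (no stepwise-mutation history, hence no pR_ST–R_ST signal),
isolation by distance within clusters, admixed individuals at zone edges,
missing genotypes, or rare-haplotype geography. Passing tests therefore
demonstrate correctness of the statistics and the operating
characteristics of the boundary machinery on known truth — not that any
particular biological conclusion transfers.

## Problem sizes and reproducibility

Simulation studies use sizes chosen to make the suite quick while keeping
Monte Carlo error in hand: the CSR size check runs 500 replicate tests at
199 randomizations each (the discrete null p-grid makes the nominal 0.05
exact); the power study uses a two-catchment landscape, 40 sites × 6
individuals, 199 randomizations, and 40–60 replicates per displacement
Δ ∈ {0, 5, 20} km. Every stochastic routine takes an explicit seed;
identical seeds give byte-identical outputs, and the pipeline writes its
config hash and seeds into the run log.

## Known limitations

* The overlap test's CSR null ignores the network geometry of candidate
  BEs; the network null is provided but not the default, and the two can
  disagree for strongly anisotropic site layouts.
* Enumeration feasibility bounds for the exact tests are conservative and
  switch to Monte Carlo early; MC p-values carry the +1 correction and a
  floor of 1/(n+1).
* The wombling operates on sites only (no lattice/continuous surface
  wombling) and boundary membership is crisp, not fuzzy.
* Catchment polygons and ridge distances assume planar coordinates in
  metres; no geodesy.
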