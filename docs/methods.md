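# Methods

## The problem

Dozens of published hydrophobicity scales assign each of the 20 amino acids
a real number, but they disagree substantially, and it is not obvious which
scale — or which window statistic computed from it — best distinguishes
peptides of different secondary structure and topology (soluble vs
transmembrane helices, sheets and coil).  This package measures that
discriminative power as a *separation capacity*: how little the
multi-dimensional parameter clouds of two peptide pools overlap.

## Peptide pools

Two construction strategies are applied to annotated proteins (per-residue
secondary structure H/E/C and topology M/S):

* **Structure dissection.** Maximal single-SSE runs become peptides.
  Soluble runs map to `s-helix`, `s-sheet`, `random` and are discarded below
  10 residues; runs containing membrane residues map to `tm-helix` /
  `tm-sheet` and, when shorter than 10, are padded with flanking parent
  residues (alternating right then left; at a sequence end the open side
  absorbs the deficit).  Membrane-annotated coil runs have no defined pool
  and are dropped.
* **In-silico tryptic digest.** Cleavage after every K and R; each fragment
  of ≥ 10 residues receives exactly one label.  Membrane content wins
  (`krtm-helix`/`krtm-sheet` by majority SSE among membrane residues; an
  H/E tie, including fragments whose membrane residues are all coil,
  resolves to helix — an arbitrary but fixed tie-break).  Otherwise an SSE
  occupying strictly more than 70 % of residues dominates: `dc-*` when its
  occurrences form one contiguous block, `dd-*` otherwise.  Otherwise
  exactly two SSE letters present give the `no-*` label of the absent one,
  and all three without dominance give `all`.

Pools are deduplicated on exact sequence.  The 70 % threshold is strict
(a fragment at exactly 70 % is not dominated).  Coordinates are 0-based
half-open throughout.

## Window parameters

Five statistics are computed in every length-10 sliding window (step 1),
all normalised by the window length L so values are comparable:

* average hydrophobicity `(1/L) Σ h_i`;
* hydrophobic moment `(1/L) √[(Σ h_i sin iδ)² + (Σ h_i cos iδ)²]` at
  δ = 100° (helical periodicity) and δ = 180° (strand alternation);
* alternating hydrophobicity `(1/L) |Σ (−1)^i h_i|` — analytically
  identical to the 180° moment; it is kept as a separately named parameter
  because the two are conceptually distinct probes, but any combination
  mask that selects the *same* extremum of both duplicates a coordinate
  and collapses the 5-D cloud onto a hyperplane (see below);
* EBSS, a strand-face score: the better of the two alternation phases of
  `(1/L) Σ log p_face(i)(a_i)`, where even-parity positions read from an
  outward (lipid-facing) propensity table and odd-parity from an inward
  (pore-facing) one, or vice versa.

The per-peptide maximum and minimum of each parameter over all windows form
a 10-component extrema vector; a 5-bit mask picks max or min per parameter
as one coordinate of a 5-D point, giving 32 scenarios per scale and pool
pair.

**EBSS propensities.**  The bundled table is a synthetic stand-in with the
qualitative behaviour of published β-barrel face propensities (apolar
residues favoured on the lipid face, polar on the pore face); real tables
load via `EbssPropensities.from_table`.  The stand-in is deliberately *not*
an antisymmetric transform `exp(±βh)` of a bundled scale: that construction
makes the phase-maximised score exactly proportional to the alternating
hydrophobicity of the same scale, which silently removes one cloud
dimension.  An all-ones (neutral) table is available for tests but makes
EBSS identically zero and is likewise unusable for 5-D scoring.

## Separation capacity

For a scenario, each pool's 5-D points form a convex cloud (Qhull).  The
points on the convex envelope are removed once and the hull rebuilt —
outliers otherwise inflate volumes drastically; the stripping bookkeeping
(fraction of points vs fraction of volume removed) is reported.  The score
of two clouds is

    S = Sv · Sp,  Sv = 1 − 2 Vov/(V1+V2),  Sp = 1 − Pov/(P1+P2),

with V the hull volumes, Vov their intersection volume, P the point counts
and Pov the number of points of either cloud inside the other (membership
is boundary-inclusive).  S is 0 for coincident clouds and 1 for clouds with
no mutual points.  When both volumes vanish (collapsed clouds) Sv is
defined as 1 if no point lies in the mutual overlap and 0 otherwise.

**Overlap volume.**  Default is Monte-Carlo: the smaller-volume cloud is
sampled exactly uniformly via its Delaunay simplex decomposition (simplex
chosen proportional to volume, flat-Dirichlet barycentric coordinates) and
Vov = V_small × (fraction of samples inside the other hull), with the
binomial standard error recorded.  Sampling the smaller cloud keeps the
estimate within [0, min(V1, V2)] up to noise.  An exact half-space
intersection (Chebyshev-centre LP + `HalfspaceIntersection`) is provided
for low dimensions and serves as the oracle in tests.  Degenerate
(affinely dependent) point sets never crash: the cloud falls back to a
recursive affine-subspace representation with volume 0.

**Aggregation.**  The per-scale overall score is configurable because no
single collapse of 32 masks × many pool pairs is canonical:
`best-combo-mean` (default; per pair the best mask, then the mean over
pairs), `mean-mean`, or `fixed-combo`.  The parameter-influence statistic
takes the best-separated fraction (default 5 %) of all scenarios and
reports |observed − expected| frequency for each of the 10 (parameter,
max/min) choices.

## Scale comparison and clustering

Scales are compared by the Pearson correlation r of their 20 paired values
in fixed alphabetical residue order; the dissimilarity is √(1 − r²), so a
scale and its sign inversion are identical (r = −1 ⇒ 0) — inverted scales
always cluster with their originals.  UPGMA (average linkage) on this
dissimilarity gives an ultrametric tree (join height = half the linkage
distance); equidistant merge candidates are resolved toward the pair with
lexicographically smallest member ids, so trees are reproducible.  Clusters
are maximal subtrees with root height at or below the threshold (default
0.05; 0.07 is a documented alternative), labelled a, b, c … in left-to-right
leaf order.  Constant scales are rejected outright rather than patched.

The amino-acid distance analysis min-max normalises a scale to [0, 1] and
flags residue pairs with |Δ| < 0.1 (interchangeable) or > 0.9 (maximally
spread).

## Pattern statistics

Overlapping k-mers (k = 2–5) are counted per pool and normalised to
frequencies of occurrence (FO).  Enrichment of a pattern in a focal pool is
measured against (i) the union of all remaining pools and (ii) the
remaining pools generated by the same strategy (GBSS); the focal pool is
excluded from the reference by default (a flag includes it).  A zero-count
reference FO is floored at 1/(reference total + 1) so a pattern absent
elsewhere yields a large finite fold.  Flags mark ≥ 50× and ≥ 500×
enrichment on the larger of the two folds.  Significance is a one-sided
Fisher exact test on the 2×2 k-mer table (computed via the equivalent
hypergeometric upper tail, vectorised), BH-adjusted within each (pool, k)
family.  An add-one-smoothed Markov chain (order configurable) supplies
background pattern probabilities; pattern coverage reports, per k, the
fraction of observed patterns present in every pool.

## Evolutionary scale optimisation

Random scales draw each residue value uniformly from the corpus-wide
[min, max] interval (200 by default).  Evolution is a single-parent hill
climb with elitism: each child perturbs exactly one amino acid of the
current best by a uniform draw from a signed interval; the best of
children ∪ parent survives.  The default six-round schedule: two broad
rounds over all 20 amino acids (positive then negative, 50 children each
per residue), three focused rounds (E, Y up / A, H, F, L down at ±10; E up
/ A, H down at ±20; E alone at +40) and a final mixed round of 25 + 25
children per residue — 4600 children in total.  Perturbed values may leave
the original interval by design.  After the broad rounds the top-100
children are summarised per amino acid (mean fitness gain and perturbation
sign).  The focused rounds' residue sets are schedule parameters, not
constants.

Fitness is the mean S over all unordered pairs of five evaluation pools at
one fixed mask (best-of-32 available by config).  The default mask is 8
(min of the 180° moment, max of the other four): the all-maxima mask
duplicates the alternating coordinate (see above) and cannot support
volume scoring.  Inside fitness, envelope stripping is off by default and
the Monte-Carlo budget reduced (4000 samples): at desk-scale pool sizes
(tens of peptides) most points of a 5-D cloud are hull vertices, so one
strip collapses the cloud; dense-cloud pipelines can re-enable both.

## Synthetic data

The generator replaces structure-database-derived pools with seeded
synthetic ones whose compositions carry the features the analysis assumes:
TM helices sample a strongly hydrophobic profile (mass on L, I, V, F, A,
M); TM sheets alternate a lipid-facing hydrophobic and a pore-facing polar
profile position by position; soluble helix/sheet segments use *mildly*
distinct soluble profiles (they share most of their composition — soluble
pools are intended to separate worse than membrane pools, matching the
biology the pipeline probes); coil is uniform.  K/R spacers between
segments (probability per joint) make the digest recover segment
boundaries; k-mer motifs can be planted at controlled per-segment rates
with a ground-truth ledger.  One seed drives everything; per-protein
streams are spawned with `SeedSequence` so output is byte-identical and
inserting a protein does not shift later draws.

Pool pairs for separation experiments interpolate position-wise profiles
symmetrically: at strength 0 both pools draw from the common midpoint
distribution (exchangeable), at 1 from their full kind profiles.  The
five-pool evaluation set for the optimiser maps the digest labels
(dd-helix, dd-sheet, dd-random, krtm-helix, krtm-sheet) onto generator
kinds the same way.

**What synthetic data does not show.**  Real pools are larger by orders of
magnitude, contain homology structure, length heterogeneity and
composition gradients the generator does not model.  Passing tests
demonstrate the pipeline's correctness and the qualitative orderings
(TM > soluble separability, coverage decay with k, motif recovery), not
the absolute S values of database-derived pools.  In particular, with tens
to hundreds of points per pool in five dimensions the hull-overlap score
of two *identical* distributions is biased well above zero (finite-sample
hulls disagree near their boundaries); measured null values are ≈ 0.1–0.2
at 200 points per pool, shrinking with sample size.  Absolute S values at
desk scale are therefore comparable only within a fixed sample size, which
is how all bundled analyses use them.

## Problem sizes and numerical choices

Bundled analyses use 200 peptides per pool for pairwise separation runs,
20–40 per pool inside the optimiser, 100 000 Monte-Carlo samples for
headline scores (4000 inside fitness), and a 20-random/50-children-per-round
schedule for desk-scale evolution demonstrations.  Membership tolerance is
1e-9 relative to the coordinate scale (boundary-inclusive, conservative
for Pov).  Scenario ranking ties break on (scale id, mask, pair order);
UPGMA merge ties on smallest member id.  Degenerate inputs (constant
scales, affinely dependent clouds, empty pools) raise informative errors
or produce flagged zero-volume results rather than crashing.
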