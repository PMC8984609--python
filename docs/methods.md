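# Methods

## Genome quality

The quality score is `Q = completeness − 5 × contamination`, both in
percent from single-copy-marker estimators upstream; `Q` may be negative.
Two gates are applied in pipeline order, so a genome failing refinement
never reaches the tree set:

1. *Refinement*: `completeness > 50` **and** `contamination < 10`, both
   strict — the conventional MetaWRAP-style refinement bounds read
   literally.
2. *Tree inclusion*: genomes with `Q < 40` are removed. The boundary is
   deliberately inclusive: `Q = 40` passes, because the rule is phrased as
   a removal of scores *below* 40. Scores are kept at full float precision
   internally; rounding (2 decimals, half away from zero) happens only when
   reports are written.

## Module catalog and assignment

A module is an ordered tuple of steps; a step is a set of alternatives; an
alternative is a set of identifiers that must all be present (a complex).
Key-enzyme clauses reuse the same shape; every clause must have one
alternative fully present. The file grammar is a documented subset of
KEGG's DEFINITION syntax without optional (`-`) terms or nested
parentheses — none of the shipped gene sets need them. Identifiers are
K-numbers or gene symbols; matching is exact string after optional alias
resolution (a small symbol → K-number table ships for the carbon-fixation
key enzymes).

Completeness is `satisfied steps / total steps` as an exact
`fractions.Fraction` — a 3-of-5 module compares as `3/5 ≥ 3/5`, never as
`59.999… ≥ 60`. Steps are binary: a complex missing one subunit
contributes nothing, which keeps "percent complete" well defined. The
assignment rule is `completeness ≥ 0.6 (inclusive) AND all key clauses
met`. Step-based counting was chosen over raw-KO-fraction scoring because
the 60 % rule speaks of module completeness, which KEGG defines over
steps; the raw fraction is available behind `raw_ko_fraction=True` for
comparison with tools that score that way.

The shipped catalog encodes the trait gene sets a phycosphere study
reports: six prokaryotic carbon-fixation modules with representative KO
step structure (keys: `aclA+aclB` for rTCA, `mcr` for 3-HP, `abfD` for the
hydroxybutyrate cycles, `acsB` for Wood–Ljungdahl, RuBisCO/PRK for CBB),
nitrate reduction (ANRA `nasA|narB → nirA`; DNRA
`narGHI|napAB → nirBD|nrfAH` keyed on the nitrate reductase),
denitrification (keyed on `nirK|nirS`), nitrification (keyed on `amoABC`),
taurine uptake/dioxygenation (keyed on `tauD`), SOX, `dsrAB`, sulfite
oxidation, assimilatory sulfate reduction (M00176), alkaline phosphatase,
cobalamin synthesis (aerobic keyed on the `cobNST` chelatase, anaerobic on
`cbiK|cbiX`), remodeling (keys `cbiZ` and `cbiB`), `btuB` transport,
`metE`/`metH`, the four bacterial auxin routes (IAM keyed on both steps,
IPyA on `ipdC`, TAM on `tdc`, IAN on the `CYP71A13|myrosinase` clause) and
ACC deaminase. The custom entries are a versioned curated reconstruction,
not an export of any database; users can swap in their own file in the
same grammar.

Taxon aggregation counts assigned genomes per taxon at a chosen GTDB rank;
genomes with a missing or malformed rank are grouped as `unclassified`
with a per-record warning.

## Phylogenetic distance and gain

Faith's PD of a taxon set is computed with the *rooted* convention: the sum
of branch lengths on the union of paths from each selected leaf to the
root. This makes `PD(all leaves)` exactly the total tree length and makes
phylogenetic gain additive by construction:
`PG(S) = PD(all) − PD(all \ S)`, so `PG(S) + PD(complement) = PD(full)`
holds exactly, and `PG(S) ≤ PD(S)` on every tree. The unrooted
minimal-spanning-subtree variant is available behind `rooted=False` for
comparison with tools that use it; which convention a given published
table used is often undocumented, and the rooted one was chosen for its
exactness properties. Implementation is a single post-order pass counting
selected leaves under each edge; tests check it against a brute-force
union-of-root-paths enumerator on all subsets of small random trees.

Percent PD is `100 × pd / pd(full)` computed from unrounded internals and
rounded (half away from zero, 2 decimals) only at serialization. When the
four-row summary is instead rebuilt from already-rounded printed PD values,
small discrepancies with a printed percent column are expected (the
ingroup-PD percent can shift by 0.01); the gain row is recomputed as
`full − outgroup` from the given inputs.

Trees are parsed with dendropy; duplicate leaf labels, negative branch
lengths and single-leaf trees are rejected, and missing branch lengths
default to zero with a warning. Zero-length branches are allowed (a
zero-length pendant contributes no gain).

## Abundance and rarefaction

Relative abundance normalizes each sample column of a coverage table to
100 %. An explicit `unbinned` remainder row may be carried through
normalization, in which case the binned fraction per sample is
`100 − unbinned`; this coverage-ratio proxy stands in for marker-based
community-recovery estimates and is reported as such. The heatmap filter
keeps genomes whose *cumulative* abundance — the sum across samples, not
the mean — strictly exceeds the threshold (default 1 %), so exactly 1.0
is dropped.

Trait-weighted site abundance: a genome is a carrier if assigned at least
one module of the requested set; carrier abundances are summed per sample
and averaged (unweighted mean) over the site's samples. The aggregation
across a site's replicates is our documented choice; a published single
percentage per site does not pin down the statistic.

Rarefaction is analytic: `E[S_n] = Σ_i [1 − C(N−N_i, n)/C(N, n)]`
evaluated with `scipy.special.gammaln`, at sizes `step, 2·step, …` plus a
final point at `n = N` where the expectation equals observed richness
exactly. Default `step = 2000` matches the vegan `rarecurve` convention.
Tests check the expectation against Monte-Carlo subsampling (10⁴ draws,
3-SE band).

## Synthetic community generator

The generator emulates a two-site seaweed-surface study design: defaults
are 202 genomes, six samples named `RZ-A…ND-C` (two sites × three pooled
replicates), completeness ~ U(50, 100) (mean 75 %) and contamination
~ U(0, 10) (mean 5 %), matching the scale of a real MAG cohort. No claim
is made that its noise model matches real metagenomes; the choices are the
simplest with testable signatures:

* genomes are distributed cyclically over trait groups (by default one per
  catalog category plus a trait-free background group); a genome's true KO
  set is the union of all identifiers of its carried modules, so every
  carried module is 100 % complete with keys before noise;
* dropout is i.i.d. Bernoulli per KO with retention probability
  `completeness/100` — the expected retained fraction equals the
  completeness, tested at 3 standard errors;
* contamination adds `round(contamination/100 × |true set|)` KOs sampled
  without replacement from a background pool disjoint from the catalog, so
  zero contamination means zero foreign KOs;
* taxonomy strings are GTDB-style 7-rank with invented lineage names keyed
  to the trait group, letting taxon aggregation be checked against truth;
* trees are random binary joins with Exponential(1) branch lengths
  (configurable rate), all strictly positive; coverages are lognormal
  (μ = 0, σ = 1.5 — heavy-tailed, as community coverage distributions
  are; σ = 0 degenerates to equal coverage for testing).

The random stream is split per artifact (genomes / tree / coverage) from
one seed, so adding samples never perturbs genome simulation, and a fixed
seed fixes every output bit-for-bit.

Because the generator's dropout is unstructured, passing recovery tests
show that the *decision rule* behaves correctly under random gene loss;
they do not show robustness to the correlated, assembly-driven gene loss
of real MAGs (co-located operons vanish together), nor to annotation
error, which the generator does not model.

## Problem sizes and numerical choices

Test and acceptance runs use desk-scale sizes chosen for tight feedback:
200-genome communities for recovery, 120 genomes per point of the
completeness grid {100, 80, 60, 40} %, 50 random trees of ≤ 8 leaves with
exhaustive subset enumeration for the PD oracle, 1 000 random
(module, KO-set) pairs for monotonicity, and 10⁴ Monte-Carlo draws for the
rarefaction check. Thresholds are compared exactly (rationals for
completeness, floats with strict inequalities for the abundance and
quality gates); no tolerance is applied to boundary semantics.

## Known limitations

* The custom module definitions are a reconstruction from reported gene
  lists; step decompositions of the original supplementary definitions may
  differ.
* The binned-community fraction is a coverage ratio, not a marker-gene
  census.
* Completeness/contamination are consumed as inputs; the package does not
  estimate them from sequence.
* The KEGG M-number modules carry representative, not exhaustive, KO
  alternatives.
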