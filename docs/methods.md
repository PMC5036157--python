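# Methods

This note documents the models, statistics and numerical choices behind
`algevo`, what the synthetic-data generators do and do not emulate, and
the known limitations. It states no empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## Trees and time

Phylogenies are rooted Newick trees (dendropy-backed) with unique leaf
labels and non-negative branch lengths; bootstrap supports are read from
internal-node labels (RAxML dialect) with a flag for the bracket-comment
dialect. A *dated* tree assigns each node the time equal to its
root-to-node path length, with the root at 0 and all tips
contemporaneous within a relative tolerance (default 10⁻⁶ of tree
height — relative-timed trees carry rounding noise from upstream tools).
After validation, leaf times are snapped to the common tip time so that
10-significant-digit serialisation round trips cannot make a terminal
branch appear to end before the present. Patristic distances are path
sums computed via root depths and MRCAs; on additive trees they satisfy
the four-point condition, which the tests check on simulated trees.

## Domain screening

Domain hits come from hmmsearch `--domtblout` tables (parsed with
Biopython) or equivalent CSVs. Filtering keeps hits with e-value
strictly below 10⁻²³ and model coverage strictly above 0.8; coverage is
aligned-HMM-positions over model length (the dbCAN convention — the
alternative query-relative definition is not implemented because every
input this package targets is a dbCAN-style HMM hit table). Copy numbers
count *distinct ORFs* with at least one retained hit per family — an ORF
carrying two domains of the same family counts once — and populations
report the maximum over member genomes, with zeros reported rather than
dropped. Marker selection for the reference phylogeny excludes hits with
e-value strictly greater than 10⁻¹⁰ (equality is kept), drops any marker
with more than one retained copy in any genome, and keeps markers present
in at least half of all genomes (boundary inclusive).

The read-based validation statistic is the percentage of sequenced bases
on reads with at least one domain hit, counting a hit read's *full*
length; the companion routine reports the Pearson correlation of this
statistic with assembled copy number across strains.

## Subfamily delineation

A gene subfamily is a set of focal-clade leaves inferred to descend from
one acquisition. Delineation applies three criteria in order:

1. **Bootstrap.** Maximal focal-only clades (every clade whose parent
   subtree contains an outgroup leaf) with support ≥ 70 stand on their
   own. The threshold is a community convention, configurable.
2. **AU test.** For explicitly named groups of weakly supported
   neighbouring clades, the conservative alternative — "these clades are
   one monophyletic subfamily" — is built by minimal rearrangement
   (prune the clades, join them pectinately, reattach at the nearest
   remaining relative of the first clade, preserving the anchor's
   original edge length so as few path lengths as possible change) and
   compared against the supplied topology with the approximately
   unbiased test: per-site log-likelihoods are RELL-resampled at scales
   0.5–1.4 (10,000 replicates by default, exact ties shared equally),
   the winning frequencies are fit by weighted least squares (binomial
   weights) to 1 − Φ(d√r + c/√r), and p = 1 − Φ(d − c). A topology that
   wins or ties in every replicate at every scale is degenerate with
   p = 1; one that never wins has p = 0. Failure to reject the
   alternative (p ≥ 0.05) merges the group — the conservative reading.
3. **Distance cutoff.** Remaining low-support clades are re-partitioned
   by UPGMA (average linkage, lexicographic tie-breaking for exact
   reproducibility) on leaf–leaf patristic distances, cut at the first
   merge height exceeding the cutoff. The cutoff derives from the oldest
   well-supported reference subfamily as its maximum root-to-leaf path
   length (0.66 substitutions/site for the published reference family);
   leaf–leaf patristic distance was chosen over root-to-leaf depth
   because clustering operates on leaf pairs.

Which clade groups get AU-tested is analyst-driven (the biologically
motivated alternatives cannot be guessed), so `delineate` takes an
explicit merge-candidate list rather than enumerating alternatives.

Per-site log-likelihoods can come from any external source (CSV) or from
the internal JC69 Felsenstein-pruning engine (uniform root prior, gaps
as missing data). JC69 suffices because the AU test consumes per-site
log-likelihoods from richer models transparently; the engine exists so
the whole chain runs without external ML software. Branch lengths of
constrained alternatives are reused, not re-optimized — a documented
approximation that makes the test slightly anti-conservative toward
rejection, i.e. toward *keeping* subfamilies separate.

## DTL reconciliation

The species tree is cut into contemporaneity slices at every node time
plus uniform subdivisions (default 4 per interval; costs are
slice-independent, so parsimony needs only enough resolution for
transfer endpoints — refining slices can only lower, never raise, the
minimum cost). A degenerate slice holds the root stem so a birth can
precede the first speciation. Slice boundaries closer than 10⁻⁹ of tree
height are merged to absorb serialisation rounding.

The DP runs over (gene node × species branch × slice), bottom-up in
time and postorder in the gene tree. Within a slice an internal gene
node may duplicate (cost 2, both children on the same branch) or
transfer (cost 3, one child jumps to a contemporaneous other branch;
the donor lineage continues — replacing transfers are not modelled). At
a slice boundary a lineage passes through, speciates (cost 0), or
passes into one daughter with a loss (cost 1) charged to the other.
Gene leaves must reach their species' terminal branch at the present.
The single gene birth is free and chosen over all (branch, slice)
placements; `cooptimal_births` returns every placement achieving the
minimum, and ties in the reported reconciliation are broken
deterministically (earliest slice, then pre-order branch index; event
order: descent, speciation, speciation-with-loss, duplication,
transfer). Gene-tree branch lengths are ignored: topology-only
parsimony. Transfer–loss composites are not in the event grammar; a
lineage changes branches only by transfer at an internal gene node.

Every emitted reconciliation is self-checked: the event costs must sum
to the DP total and every transfer's donor and recipient must be alive
in the event's slice. A brute-force enumerator implementing the same
event grammar as naive recursion (no memoisation, no candidate pruning)
serves as the exactness reference on instances with ≤ 4 species and ≤ 4
gene leaves.

**Loss-count semantics.** For loss-only simulations the parsimony loss
count equals the number of *maximal pruned species clades inside the
subtree of the survivors' MRCA* — not the number of simulated loss
events: sibling-lineage losses collapse into one ancestral loss, and
absences above the survivors' MRCA are absorbed by the free birth.

**Summaries.** An acquisition for a clade of interest is a birth on a
branch inside it or a transfer whose recipient is inside while the donor
is outside; transfers with both endpoints inside are within-clade
transfers. A population-collapse switch drops transfers and duplications
confined to a single population's subtree, matching the convention of
not depicting within-population events.

## Genomic context

Coordinates are 0-based half-open internally; GFF3 (1-based inclusive)
is converted on read, BED is exported natively. Lyase regions are
single-linkage chains: two lyases join one region iff the distance
between their nearest interval ends is ≤ 5,000 bp (inclusive — 5,000
chains, 5,001 splits); regions never span replicons. A gene is "in a
region" iff its interval overlaps a region span by ≥ 1 bp.

Mobile-element enrichment is the exact upper-tail hypergeometric
P(X ≥ k) with population = all genes of the genome, successes = genes
annotated mobile element/integrase/transposase, sample = genes in
regions. GC depletion treats bases the same way: population = host
replicon length, successes = its G+C count, sample = region span,
observed = region G+C, reporting the lower tail and its natural
logarithm (computed in log space; extreme tails like 10⁻³⁰⁰ stay
finite). The base-level hypergeometric reading of the GC comparison is
an interpretation; it is isolated in one operation so it can be swapped.

**Calibration caveat.** Lyase-anchored regions are *conditionally
non-exchangeable*: the region-defining lyase genes can never carry a
mobile-element annotation, which depresses the observed count by about
one standard deviation and makes the enrichment p conservative. This
bias works against false positives and is inherent to anchoring regions
on a gene category, not a software artifact. Null-calibration checks
therefore use regions placed at category-independent random coordinates
(`synthetic_data.random_regions`), for which the sampled genes are
exchangeable and the test exactly calibrated; planted-signal checks use
the real lyase-chained regions.

Because exact tests are discrete, their plain p-values are
super-uniform (conservative) under the null even when computed
correctly — a Kolmogorov–Smirnov test against U(0,1) rejects the
two-sided Fisher p for most random seeds at any realistic sample size.
Calibration is therefore verified on the randomized
probability-integral transforms (`hypergeom_upper_pit`, `fisher_pit`),
which are uniform if and only if the tail computation is exact, with a
one-sided KS guard that the plain p-values are never anti-conservative.

## Ecophysiology

**Growth.** Each replicate's OD trajectory is fit to the logistic
N(t) = K / (1 + ((K − N0)/N0) e^(−rt)) by multi-start nonlinear least
squares (starts seeded from the maximum log-slope, bounds r ∈ [10⁻⁶,
20] h⁻¹). A trajectory that peaks and then declines — detected as the
maximum occurring at least two points before the end with a ≥ 10%
subsequent drop — is refit as a pure exponential restricted to the
ascending window, because clumping or lysis makes the logistic
parameters meaningless there. Non-convergence returns a flagged fit,
never an exception. Lag time uses the classic tangent construction on
log-density: the tangent at the point of maximum log-slope of the
fitted curve is intersected with the horizontal baseline at the initial
*observed* log-density, and the crossing time, floored at 0, is the lag
(a delayed logistic is exactly a logistic with a smaller effective N0,
so the three-parameter fit captures planted lags without an explicit
lag parameter). A flat curve is a no-growth call with lag reported as
missing. Replicates are fit independently and parameters averaged — the
technical-replicate convention. Growth calls require r ≥ 0.05 h⁻¹ *and*
ΔOD = K − N0 ≥ 0.05 (the rate alone is spurious on flat data); both
thresholds are logged with every run.

**Association.** Genotype→phenotype tables (has ≥ 1 Aly family, has ≥ 1
Oal family, grows on each substrate class) are tested with the
two-sided Fisher exact test (sum of point hypergeometric probabilities
≤ the observed table's); the odds ratio is the sample OR with a Haldane
0.5 correction when a cell is zero.

**Enzyme activity.** The activity slope is the steepest, earliest,
longest contiguous A235 window (≥ 5 points) whose linear fit reaches
R² ≥ 0.99, divided by culture OD600. Only positive-slope windows
qualify: product absorbance cannot genuinely decline, and a flat
saturated tail is linear under any R² rule yet is not the activity
phase. A constant series reports slope 0; if no window qualifies the
global fit is returned with a low-quality flag. The statistic is
invariant to constant baseline shifts.

**Expression.** qPCR ratios follow the efficiency-corrected form
E_target^ΔCt / geomean over references of E_ref^ΔCt with ΔCt = mean
Ct(control) − mean Ct(treated) and rpoD/gyrB as default references. The
p-value reallocates replicate samples between conditions at random and
counts permutations whose |log ratio| *strictly* exceeds the observed
one: counting ties would include the identity and mirror relabellings
and floor the p-value at ~0.1 with triplicates, making a 4-fold
induction undetectable by construction.

## Synthetic data

Generators are bit-reproducible under an explicit seed (one
`numpy.random.Generator` per call; sub-streams by fixed offsets).

* **Species trees** are constant-rate birth–death trees conditioned on
  the number of extant tips (dendropy), with the stem removed, tips
  extended by the waiting time to the next event (the conditioning
  otherwise leaves the last speciation at the present), and height
  normalised to 1 so per-unit-time rates are comparable.
* **Gene families** evolve by Gillespie simulation down the dated tree:
  per-copy duplication, loss, and transfer to a uniformly chosen
  contemporaneous other branch; external acquisitions as a Poisson
  process seeding new copies on a uniform alive branch; vertical
  inheritance through every speciation. The emitted forest (one rooted
  tree per origin with surviving descendants — multiple origins cannot
  honestly be one rooted tree) carries branch lengths in time units, and
  the event log is replayable: an independent replay of the log
  reproduces the final per-species copy numbers exactly, asserted
  throughout the test suite. Mean event counts match the Poisson
  expectation λ × alive lineage-time (equal, for surviving pure-birth
  families, to total tree length).
* **Two-origin families** pair two congruent copies of the species tree,
  each with a divergent outgroup lineage, stems scaled to
  substitutions/site and clade supports set low — the planted truth for
  subfamily-recovery checks, which must resolve them via the AU path.
* **Alignments** are column-independent JC69 draws with uniform root
  states; the pairwise mismatch fraction matches the closed form
  (3/4)(1 − e^(−4t/3)) within binomial error.
* **Genomes** tile fixed-length genes along a replicon; islands carry
  lyase genes spaced below the chaining gap, an elevated mobile-element
  odds ratio (background 10%, odds ratio 10 by default), and depressed
  GC (0.35 vs 0.45) realised as binomial per-window counts. Island
  coordinates are returned as truth.
* **Growth curves** are delayed logistics on the plate-reader grid
  (hourly to 24 h, 2-hourly to 48 h, then 56 h and 76 h) with
  multiplicative lognormal noise (σ = 1% default — OD error scales with
  signal); non-growers are flat at N0.

What the generators do *not* emulate: sequence-level gain/loss (families
are simulated at the event level, alignments separately), rate
heterogeneity across sites or lineages, genome rearrangement,
compositional sequence evolution, biological (as opposed to technical)
replicate variance, and diauxie or death phases beyond the single
peak-decline pattern. Passing tests therefore demonstrate correctness of
the algorithms under their stated models, not robustness to every
real-data pathology.

## Problem sizes

The bundled verification runs use the sizes at which each property is
informative and exact oracles are tractable: brute-force reconciliation
comparisons on ≤ 4 × 4-leaf instances (200 random draws), loss-only and
congruent event recovery on 6–7-leaf species trees (100 and 50 draws),
subfamily recovery on 100 planted two-origin families with 1,000-site
alignments and 2,000 RELL replicates, growth recovery on 100 noisy
curves, and null calibrations with 200 replicates each. Null 2×2 tables
use 200 strains and qPCR nulls 8v8 replicates so the discrete test
statistics are near-continuous and a calibration failure would be
attributable to the implementation rather than to discreteness.

## Known limitations

* Constrained alternative topologies are scored with reused branch
  lengths (no re-optimization) — acceptable for the conservative merge
  logic, not for publication-grade AU p-values near the threshold.
* The reconciliation model excludes transfer–loss composites and
  replacing transfers; costs are slice-independent.
* Unrooted gene trees are not searched for roots; outgroup rerooting is
  provided only as a convenience on a named leaf set.
* The GC test's base-level hypergeometric treats bases as exchangeable
  draws, ignoring autocorrelation along the sequence; its extreme
  p-values should be read as ranks, not literal probabilities.
* `run-all` executes stages sequentially on one core; there is no
  workflow-engine integration.
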