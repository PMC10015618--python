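# Methods

## Demographic model

Two species, A and B, descend from an ancestral population that split
`T` generations ago.  Histories are parameterized by diploid effective
sizes (`ne_a`, `ne_b`, `ne_anc`), the split time in generations, and —
for isolation-with-migration (IM) models — a constant effective
migration rate `me`: the per-generation, per-lineage probability that a
lineage migrates, net of selection against introgressed material.
Migration is unidirectional and stated forwards in time
(donor → recipient); backwards in time this is implemented as lineages
currently in the *recipient* deme moving into the donor deme at rate
`me`.  DIV is the `me = 0` special case, so DIV is nested in both IM
directions and lnCL(IM) ≥ lnCL(DIV) at the respective optima.

Defaults bound to the study system: mutation rate `mu = 2.9e-9` per
site per generation, one-year generations, blocks of 64 callable bases
with a maximum genomic span of 128, `kmax = (2,2,2,2)`, per-base
recombination rate `8.5e-9` for linked-block simulation.  The
reference IM parameter card (`TABLE_IM_INTO_A`) is Ne = 0.171/0.880/
1.116 ×10⁶, T = 2.202×10⁶, me = 1.811×10⁻⁷ (into A); the DIV card is
0.252/0.683/1.433 ×10⁶ with T = 1.183×10⁶.

## Exact block probabilities

For one diploid sampled per species (2+2 haplotypes) each biallelic
site is one of four unpolarized types — hetA, hetB, hetAB, fixed — and
a block is summarized by its joint type counts truncated at `kmax`
(overflow pooled per type).  The probability of every truncated count
vector is computed exactly, not by Monte Carlo:

1. Every ancestral lineage is labelled by the number of sampled A and B
   haplotypes it subtends; the label determines the type of mutations
   on that lineage ((1,0)→hetA, (0,1)→hetB, (1,1)→hetAB,
   (2,0)/(0,2)→fixed, and the unpolarized complements (2,1)→hetB,
   (1,2)→hetA).  Mutations above the MRCA are unobservable and never
   counted.
2. The state of the process is (multiset of labelled lineages with deme
   locations) × (four mutation counters, each truncated at `kmax+1`
   with the overflow level absorbing).  Mutations of type t arrive at
   rate `mu·block_span` per lineage of that type; coalescence occurs at
   rate `1/(2·Ne_deme)` per same-deme pair; migration moves recipient-
   deme lineages at rate `me`.
3. Epoch 1 (0 → T) is solved by uniformization of the augmented
   generator (series of sparse matrix–vector products; time is split
   into sub-steps whenever the uniformization rate × duration exceeds
   250 to keep term counts and floating-point conditioning bounded).
4. At T all lineages are pooled into the ancestral deme.  Epoch 2 is
   solved to absorption in closed form by a single sweep: coalescence
   only reduces the lineage count and counters only increase, so the
   augmented chain is acyclic and the integrated occupancy of every
   transient state follows from states earlier in (lineage count ↓,
   counter total ↑) order.  The absorbed mass per counter vector is the
   block probability.

Tables sum to one to ~1e-12 and are validated on every call.  The
computation is ~15 ms per parameter point, which makes multi-start
Nelder–Mead fits (bounded, sizes/times searched on a log scale, `me`
linear so zero is reachable; convergence at 1e-3 lnCL) and small grids
practical.  Tiny negative entries from roundoff (|x| ≲ 1e-16) are
clipped to zero.

Some bins are *structural zeros*: hetAB- and fixed-type mutations
cannot co-occur in any single genealogy, because a (1,1) lineage and a
(2,0)/(0,2) lineage cannot both exist in one tree.  Data simulated (or
observed) with recombination *within* blocks can occupy such bins.  The
composite likelihood clamps occupied sub-floor bins to 1e-300 for the
log and reports the occurrence with a RuntimeWarning, rather than
returning −∞; this keeps the parametric bootstrap (which deliberately
simulates with recombination to probe exactly this model violation)
well defined while penalizing such blocks maximally.

Composite lnCL treats blocks as independent, which real data violate;
point estimates remain consistent but naive likelihood-ratio calibration
does not hold — hence the parametric bootstrap for the DIV-vs-IM
comparison.

## Windows, grids and barrier classification

Blocks in genome order are tiled into non-overlapping windows of a
fixed count (30,000 in the genome-scale configuration; scans in the
test suite and drivers use smaller windows, a size choice only).
Windows never span chromosomes; remainders are dropped and logged.
`scale_window_block_count` keeps window *span* comparable when fewer
pairs contribute blocks (e.g. 42 → 6 pairs gives 4,286 blocks).

The scan grid is the Cartesian product of per-parameter value lists
with the split time fixed to the genome-wide estimate; the bundled
`scan_grid_spec` uses 15 linear values each for the three Ne parameters
(2e4–7.2e5, 5e4–2.85e6, 5e4–2.01e6) and 20 linear `me` values from 0 to
6.65e-7 — 67,500 points, with 1.75e-7 the grid value nearest the
genome-wide `me` estimate and therefore the background value for
barrier classification.  Per window the MCL point is the grid argmax
(exact ties break toward smaller `me`, then smaller `ne_a`) and the
conditional profile records the max lnCL at each `me` value.  A window
is a **barrier window** iff lnCL(me=0) > lnCL(me=background), strictly;
equality is not a barrier.  Chromosome summaries use the
grid-discretized window MCL `me` (arithmetic mean per chromosome),
barrier fractions, and Spearman's rank correlation of chromosome length
with mean `me` (reported as undefined when either variable has zero
variance).  Window→chromosome assignment onto the aligned genome uses
majority aligned-base overlap, ties to the longer alignment.

## Rearrangements

Alignment filtering keeps records strictly longer than 50 kb (query
span) with mapping quality ≥ 60.  Internal junctions are emitted
between adjacent same-query alignments whose targets differ, at the
midpoint of the inter-alignment gap (the data constrain the point only
topologically); chromosome ends are emitted for each query chromosome
sharing a target with another query chromosome, at the end nearest its
alignments to that target.  Duplicate coordinates are collapsed.

Parsimony polarization collapses markers present in all three taxa into
maximal co-occurrence sets (same chromosome in every taxon).  The
ancestral partition of these sets minimizes the fission+fusion count on
the two ingroup branches, with ties broken toward partitions closer to
the outgroup.  The transformation cost between partitions R and P is
`(c − |R|)` fissions plus `(c − |P|)` fusions, where `c` counts
non-empty pairwise intersections.  The search enumerates all set
partitions exactly for ≤ 8 co-occurrence sets; above that it seeds from
the majority-rule linkage graph (pairs co-chromosomal in ≥ 2 of the
three taxa) and hill-climbs with merge and boundary-split moves.  Every
returned event list is replay-checked against the leaf partitions.
Histories in which both ingroup branches independently fuse the same
ancestral pair are not identifiable by parsimony (the fused ancestor
scores strictly better); with a 16-chromosome root and ≤ 6 events per
branch this affects ≲ 5% of random histories.  Reciprocal
translocations decompose into fission+fusion pairs rather than being
forced into a separate category.

Window distances to points are gap distances (0 when the point falls in
the window); windows within 1 Mb are "near", windows on chromosomes
without points are "not applicable".

## Permutation tests

Both tests are one-tailed with add-one p-values `(b+1)/(n+1)`.

*Label switching*: whole chromosomes are relabelled
rearranged/non-rearranged with the rearranged group size fixed (six in
the study configuration); statistics are the mean-`me` deficit of the
rearranged group and its barrier-fraction excess.  10,000 permutations
by default (the count is configurable; only the adjacent-window test
has a prescribed 100,000).

*Adjacent windows*: points are drawn uniformly from
rearranged-chromosome window positions; around each point the matched
number of adjacent windows (taken from the real annotation) is sampled,
centered, rolling over circularly across rearranged chromosomes
concatenated in karyotype-name order (the roll-over order is a
convention of this package).  Permutations sampling any window twice
are discarded and reported.  The statistic is the mean-`me` deficit of
sampled windows relative to the remaining rearranged-chromosome
windows.

Diversity summaries: per-individual heterozygosity, dxy (mean
interspecific individual-pair difference per callable site) and
Hudson-style FST = 1 − H<sub>w</sub>/H<sub>b</sub> with H<sub>w</sub>
averaged over the two species (the estimator choice is isolated in one
function).  The denominator is the total length of the
all-individuals-callable intergenic mask; variant sites with any
missing genotype are excluded from numerators.

## Variant filtering conventions

SNPs within 2 bases of an indel's reference footprint are removed
(distance ≤ 2 removes, matching SnpGap semantics); QUAL ≥ 10 is kept;
per-genotype depth must lie in `[8, floor(3 × sample mean coverage)]`
(bounds inclusive; the rounding of the cap is unstated upstream, floor
is this package's convention), otherwise the genotype is set missing.
Indel records are excluded from the SNP output; multiallelic SNPs pass
the filter and are resolved at block tallying, where any site with more
than two alleles *within the sampled pair* (or a missing genotype)
voids the block — a conservative convention, counted in the discard
log.  Callable masks are kept per sample; pairwise intersection happens
at block construction, and absence of a record inside callable span
means an invariant site.

## Synthetic data: what it does and does not emulate

The generators reproduce the *structure* of the study inputs: DIV/IM
coalescent blocks (unlinked by default — the configuration under which
the likelihood is exact — or linked with inter-block recombination,
reproducing the bootstrap setting), diploid VCF v4.2 + callable BED
with missing genotypes, and three-taxon marker tables under known
fission/fusion histories.  They do **not** emulate: selection or actual
barrier loci (`me` is the effective summary being tested downstream),
read-level error or depth-driven missingness (missingness is uniform at
random; depths are Poisson and independent of genotype quality),
reference bias, gene conversion, or intra-chromosomal rearrangements
(inversions/translocations are outside the event model).  Passing tests
therefore validate the estimators under the model's own assumptions —
they do not certify robustness to the full messiness of real
sequencing data.

Simulation sizes in tests and drivers (e.g. 10⁵-block recovery
replicates, 2×10⁵-genealogy oracle points, 3,000-block windows) are the
package's own choices balancing Monte-Carlo error against runtime; all
seeds are explicit arguments and no global random state is used.

## Known limitations

* Two populations, one epoch of migration; no migration in the
  ancestral epoch, no secondary-contact or size-change histories.
* The kernel assumes one genealogy per block; intra-block recombination
  is a model violation (quantified via the bootstrap, not corrected).
* Grid scans inherit the grid's discretization: window `me` estimates
  snap to grid values (resolution 3.5e-8 on the bundled grid).
* The parsimony search is exact only up to 8 co-occurrence sets;
  beyond that hill-climbing is used (no misses observed in 100-scenario
  recovery runs, but optimality is not guaranteed), and co-fusion
  homoplasy is inherently unidentifiable.
* The unpolarized bSFS cannot separate ancestral from derived states;
  no phasing is used anywhere.
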