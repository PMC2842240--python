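# Methods

`phyloprogress` measures how fast phylogenetic knowledge accumulates in a
public sequence archive.  It rebuilds, at desk scale and against a fully
synthetic archive, the classic automated-supermatrix design: slice the
archive by deposition year, assemble one supermatrix per clade per year,
bootstrap trees, prune rogue taxa, count well-supported nodes, and fit
trends to the resulting resolution series.  This note records the models,
the parameters that matter, and the design decisions taken where the
procedure was genuinely open.

## The resolution metric

For a clade with `N` described species (from checklists, not from the
archive), a fully bifurcating unrooted tree has `N − 2` internal nodes.
Resolution in year `y` is

    R(y) = (number of resolved nodes in the bootstrap consensus) / (N − 2)

computed at two support levels: splits retained in the 50% majority-rule
consensus (strictly more than half of the replicates) and in the 95%
consensus (at least 95% of replicates).  "Resolved nodes" are counted as
nontrivial unrooted bipartitions, the only support-bearing objects in a
bootstrap consensus; there are at most `n − 3` of them for `n` sampled
taxa, so a perfectly resolved, fully sampled clade scores `(N − 3)/(N − 2)`,
just under 1.  The `N − 2` denominator is the field's printed convention
and is kept verbatim; the one-node shortfall is noted here rather than
hidden by changing the denominator.  Pooling across clades is the
`(N − 2)`-weighted mean: `Σ resolved / Σ (N − 2)`.  Single-gene trees use
the sampled-taxa denominator `n_taxa − 2` instead, because no checklist
target exists for one gene.

## Synthetic archive

The generator (`synthetic.py`) emulates a GenBank-like nucleotide archive
with a known truth channel:

* **Taxonomy** — root → groups → clades → species, with described counts
  drawn uniformly per clade (default 8–24).
* **True trees** — one pure-birth (Yule) tree per clade, unit birth rate,
  rescaled to a root-to-tip depth of 0.15 substitutions/site by default.
  Pure birth is the simplest process with controllable divergence; nothing
  downstream depends on the branching model.
* **Sequences** — evolved along the true tree under an HKY model
  (transition/transversion ratio κ = 4, base frequencies
  (0.30, 0.20, 0.20, 0.30)), one locus at a time, with per-locus rate
  multipliers spread geometrically (2.0 × 0.6^i) to create the familiar
  fast-mitochondrial / slow-nuclear contrast.  No indels are simulated;
  alignment is still exercised because records may be end-truncated
  fragments (25% of deposits keep 40–100% of the locus from either end).
* **Deposition** — a (species, locus) pair is sequenced with probability
  `locus_popularity × clade_intensity × species_effort`, where locus
  popularity falls geometrically (0.95 × 0.8^i), clade intensity spans
  0.95 down to 0.45 across clades by default, and species effort is
  lognormal (σ = 0.75, median 1).  The effort term is essential: it
  correlates sampling across loci within a species, which is what makes
  gene clusters overlap by four or more species, as in a real archive
  where well-studied species are sequenced for many markers.  Deposition
  years are drawn in proportion to a clade-by-year intensity matrix,
  linear-in-year by default over 1993–2008 (the archive gives no
  quantitative description of the real skew; this is a free parameter).
  15% of deposits gain a duplicate record.
* **Contaminants** — hybrid binomials ("Genus spA x Genus spB", 2%),
  misspelled names (3%, adjacent-letter swaps recorded in an alias table;
  a swap that collides with a real binomial is suppressed because it would
  not be a resolvable misspelling), unsuitable sequence classes
  (microsatellite/repetitive flags, 3%), and optionally one model
  organism per clade buried under a configurable pile of records.

What the generator does **not** emulate: indels, alignment ambiguity,
paralogy, chimeric records, rate variation among sites, taxonomy revisions
through time.  Passing tests therefore certify the pipeline's contracts —
filtering, clustering, assembly, consensus arithmetic, trend recovery —
not alignment or inference quality on hard real data.

## Record filtering and clade selection

Records of 100–5000 bp (inclusive) are kept; microsatellite/repetitive/
otherwise-unsuitable classes, hybrids, and species with more than 10,000
records in the raw pool (model organisms; threshold configurable for
desk-scale tests) are excluded.  Each rejection carries exactly one
reason, assigned in the fixed order length → class → hybrid →
model-organism, so rejection reports are deterministic.  Misspellings are
standardized through the alias table; names resolving to more than one
species are dropped as ambiguous.

Analysis clades are chosen by the random-species walk: draw a sampled
species uniformly, walk rootward to the largest ancestor with fewer than
500 sampled species, accept if disjoint from all previously accepted
clades.  How non-overlap was enforced in the original design is not
documented; rejection sampling (discard a draw that lands inside or above
an accepted clade) is used here.  Pipeline runs may instead analyse the
taxonomy's clade level directly (`clade_selection: leaves`), which is the
natural choice when the synthetic taxonomy's clades are the units of
interest and an exact clade count is wanted.

## Clustering

All-against-all similarity with single-linkage (connected-component)
merging, mirroring BLAST-clustering semantics: an edge requires ≥ 75%
identity and ≥ 0.25 coverage of **both** sequences.  Identity is computed
from a free-end-gap global alignment (match +1, mismatch −0.25, gap open
−4, extend −2): mismatches are mild and gaps costly, so unrelated
sequences align end-to-end near the 25% background instead of gapping up
to spurious similarity — the simulated null for random 300 bp pairs sits
at 34–47% identity, far below the 75% threshold, while 10%-diverged
homologs score ~90%.  Coverage is the aligned-region fraction of each
sequence's own length.  A shared-11-mer prefilter skips pairs that cannot
match.  E-value machinery is deliberately not reproduced; the clustering
contract, not the scoring engine, is what the pipeline depends on.

Year slices keep members deposited by Dec 31 of the slice year; slices
are nested by construction.  Deduplication keeps the longest sequence per
species, ties to the smallest accession.

## Alignment and supermatrix assembly

Clusters are aligned by a deterministic progressive scheme: guide order by
decreasing length then accession, each new sequence merged into the
profile by Needleman–Wunsch with unit costs (column match −1, mismatch
+1, gap +1, free end gaps).  Columns are only inserted, never edited, so
ungapping any row returns its input exactly.  The aligner sits behind
`align_cluster` and can be swapped for a heavier tool; alignment quality
is not this package's contribution.

A cluster set is informative when each retained cluster has ≥ 4 species
and shares ≥ 4 species with another retained cluster, iterated to a fixed
point (dropping a cluster can orphan its only partner).  If the survivors
form several connected components, the component with the most species is
kept (ties: more clusters, then smallest cluster id) — the one-sentence
overlap rule does not say whether global connectivity was required, and a
single connected analysis mirrors supermatrix practice.  Concatenation
fills absent partitions with `?`; density and characters-per-species count
nucleotide cells only (gaps excluded), and partitions are recorded 0-based
half-open internally, 1-based inclusive in NEXUS `CHARSET` output.

## Tree inference, consensus, rogue pruning

Bootstrap replicates resample whole columns with replacement.  The default
engine is neighbor-joining on p-distances over shared non-missing sites;
pairs sharing fewer than 20 sites get a placeholder of 1.25 × the largest
finite distance so sparse overlap pushes taxa apart rather than spuriously
together.  An infinitesimal (1e-9) symmetric jitter is added per replicate
so exact ties — duplicate sequences, zero-variation matrices — break
randomly instead of letting the agglomeration order manufacture support
for one arbitrary topology.  A parsimony engine (random-addition start,
NNI hill climb on Fitch length) is selectable through the same interface;
it is a desk-scale search, not an exhaustive one.

Consensus retention is strict (> 1/2) at the 50% level — two incompatible
splits can tie at exactly half, and a strict rule keeps the retained set
compatible by construction — and inclusive (≥) at 95%.  Supports are exact
replicate counts over `n`.

The taxon instability score is the nodal-distance form: for tree pair
(x, y) and third taxon j, taxon t accrues
`|D(t,j;x) − D(t,j;y)| / (D(t,j;x) + D(t,j;y))²` with D the edge-count
path distance, averaged over all valid (pair, j) terms; taxa in fewer than
two trees have no score (and rank most unstable if pruning is asked to
order them).  The original instability index used for this kind of
screening is not printed anywhere accessible, so this definition is the
module's own, documented contract.  Pruning removes the
`⌊fraction × n⌋` most unstable species (5% default, 10% selectable), ties
broken by higher raw score then name, never below 4 species.

## Statistics

Trends are OLS polynomials in (year − first year): linear, quadratic
(with the nested-F p-value for the quadratic gain,
`F = (RSS₁ − RSS₂) / (RSS₂ / (n − 3))` on (1, n−3) df), or exponential via
log-linear OLS for positive series.  Projections scan integer years for
the first fitted value (capped at 1.0) reaching the target, returning
"not reached" for non-increasing fits or beyond the 2100 horizon.

The dataset-feature regression puts clade resolution on four features —
proportion of species sampled, clade size, characters per species,
dataset density — with all variables z-scored, so coefficients are
standardized betas comparable across units ("partial regression
coefficients" only support magnitude comparisons across differently
scaled predictors when standardized, which is why standardization was
chosen).  Collinear predictor pairs (condition number > 1e8) are rejected
by name.

Gene rankings take clades with ≥ 20 informative gene clusters (threshold
configurable; desk-scale worlds carry fewer loci), list the top five genes
by taxa sampled and by single-gene resolution, report each gene's top-five
frequency across clades, and check the sampling/resolution relationship by
a pooled OLS of per-gene resolution on taxa sampled.  In the pipeline,
clusters are labelled by their members' annotated locus (the synthetic
metadata's locus field stands in for a real archive's defline annotation)
so genes are comparable across clades.

## Orchestration and determinism

`run_pipeline` enumerates every (clade, year) slot — 16 × 100 = 1600 in
the full-grid configuration — and logs each as built, skipped (no
informative cluster set, the expected outcome for early years), or failed
(error captured, run continues; only a fully failed run raises).  One
global seed fans out to per-slot seeds by SHA-256 hashing of
(seed, clade, year), so reruns are byte-identical and partial reruns
reproducible.  Alignments are cached by (cluster, member set), which makes
later year slices cheap once membership stabilizes.

## Problem sizes

Tests and the acceptance script run scaled-down configurations chosen to
exercise every code path with comfortable margins: grid runs use 100
clades of 6–9 species with 3 short loci and 6 bootstrap replicates;
study runs use 10 clades of 10–22 species, 5 loci and 20 replicates over
16 years; the sampling-signature experiment uses ten runs of 10 clades ×
8 years at 16 replicates with clade intensities spread geometrically from
1.2 to 0.08, emulating the 6%–100% sampled-fraction spread seen across
real vertebrate clades.  The bootstrap default remains 100 replicates for
ordinary use.

## Known limitations

* NJ bootstrap support is not parsimony bootstrap support; absolute
  resolution values are engine-dependent even though the pipeline
  contracts are not.
* The progressive unit-cost aligner will misalign genuinely indel-rich
  loci; the generator does not produce them.
* The instability index is this module's definition (see above), not a
  reimplementation of any published tool's internal formula.
* Trend projections inherit every caveat of polynomial extrapolation;
  saturating (sigmoidal) models are out of scope.
* With only 4–6 loci per world, gene rankings rest on few genes per clade
  and should be read qualitatively.
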