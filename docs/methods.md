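# Methods

## Graph construction and canonicalization

K-mers are stored canonically (lexicographic minimum of the k-mer and its
reverse complement).  k must be odd — an even-length k-mer can equal its own
reverse complement, which would make canonical identity ambiguous — and at
most 63.  Sequences are uppercased and split at any character outside
{A,C,G,T} before k-mer extraction; splitting avoids fabricating k-mers that
span ambiguity codes.  How soft-masked (lowercase) bases should be treated
is genuinely open; we uppercase them, which treats masking as annotation
rather than content.

Only presence/absence per color is stored, never multiplicity.  Edges are
implicit in (k−1)-overlap under the bidirected convention (a k-mer can be
traversed in either orientation), which is what makes the graph invariant
under reverse-complementing any input file.

## Compaction and contig extraction

Unitigs are maximal non-branching paths in the **union** (color-blind)
graph; color changes do not break unitigs.  Two conventions are worth
stating because they are tie-breaks the definition leaves open:

* **Self-loops do not branch.** An extension whose canonical k-mer equals
  the current vertex (e.g. `AAA` → `AAA`) is ignored when counting
  in/out-degree.  Without this, any homopolymer end would split a unitig
  that is unambiguous to spell.
* Extraction starts from the lexicographically smallest unvisited k-mer and
  contig sequences are reported in canonical orientation and sorted, so
  output is deterministic.

Contigs are maximal runs of k-mers *within a unitig* sharing one color
profile.  "Same color profile" is exact set equality; the query layer adds
superset ("at least these colors") semantics behind an `exact` flag, since
queries like "contigs found in any two colors" are inherently non-exact.
Runs live within unitigs: a same-profile run is not continued across a
branch point.  The length filter is exact equality because the SNP rule
selects contigs of exactly 2k−1 bp; with isolated substitutions (≥ k
matching flanking bases each side) this length is guaranteed, and longer or
shorter unique contigs indicate indels, clustered variants, or boundary
effects rather than clean SNPs.

## Shades

A shade s is an auxiliary color with exactly one parent π(s) ∈ [n].  The
insertion rule examines the **pre-shade** graph: a k-mer already carrying
its parent color is reference sequence and is left untouched; a k-mer
present without the parent, or absent entirely, gains {π(s), s} together.
This makes insertion idempotent and maintains parent inclusion (no k-mer
ever carries a shade without its parent), which the test suite asserts
after every operation.

Mapping a contig to targets uses a smaller inner order `k_map` (default 29
under k = 31 contigs): a 61-bp SNP contig's outermost 29-mers avoid the
variant base and match the reference allele's flanks.  One shared canonical
`k_map`-mer suffices for a mapping — SNP contigs share ~30 flanking k-mers
with their parent, so a stricter threshold buys nothing and would need its
own justification.  A contig mapping to several targets is shaded once per
target sequence (not per gene); `max_targets` can cap pathological repeats
but is unlimited by default.  The graph order k and the mapping order
`k_map` are independent parameters.

## Pseudoalignment and counting

The EC rule intersects parent colors over the read's k-mers and unions
shades whose parent survives the intersection.  Read literally, the
intersection runs over *all* k-mers, so a single novel k-mer (one
sequencing error) unmaps the read.  The default here intersects only over
graph-present k-mers — standard pseudoalignment practice — and unmaps when
no k-mer is present; `literal=True` preserves the strict behaviour and is
what the oracle tests exercise.

Counting deduplicates (barcode, UMI, EC) triples: each distinct triple is
one molecule.  No barcode whitelisting/correction and no EC-level UMI
arbitration is performed — both are orthogonal to the method and belong to
dedicated preprocessing tools.  EC ids are assigned in first-seen order and
persisted (`ec.tsv`) so matrices are joinable across runs; the counts
matrix itself is order-invariant.  Demultiplexing sums UMIs of ECs that
resolve to a single strain's targets and takes the argmax, with exact ties
and zero totals reported as "ambiguous".

## Cluster-specificity testing

Presence means count ≥ 1; all four table cells count cells, not UMIs.  The
background row (c, d) uses only regular (shade-free) single-gene ECs of the
same gene.  Testable ECs must contain a shade, be present in at least
`min_cells` cells (default 10, evaluated on the full matrix before any
cluster subsetting), and resolve to exactly one annotated, non-pseudogene
gene.

`fisher_exact` is two-sided by the minimum-likelihood rule (both
enrichment and depletion are of interest) and is computed by exact integer
enumeration of the hypergeometric weights, cached per margin triple —
ties between equally probable tables are decided exactly rather than
within a float tolerance.  Odds ratios at the boundary use sentinels
(+inf when bc = 0 < ad, NaN when ad = bc = 0); a Haldane–Anscombe +0.5
smoothed variant exists for plotting only and is never used in tests.  BH
adjustment spans all (EC, cluster) tests of a run by default
(`per_cluster_family=True` switches to per-cluster families).  Results are
sorted by adjusted p, then odds ratio descending.

## Synthetic data

The generators draw from one seeded `numpy` Generator consumed in a fixed
order, so equal seeds give byte-identical files.  Conditions they emulate:

* **Genome pairs**: equal-length sequences differing at isolated
  substitutions, pairwise ≥ `min_snp_spacing` ≥ 2k apart and ≥ k from the
  ends, so each SNP yields exactly one 2k−1 bp unique contig per strain.
* **Transcriptome**: one random transcript per gene (default 8 genes ×
  400 bp); planted variants are single substitutions at the transcript
  midpoint, giving full k-mer flanks.
* **Single-cell reads**: 16-bp barcode + 10-bp UMI; 300 cells in three
  clusters of 100, 32 reads of 100 bp per cell drawn uniformly across genes
  and positions, strand-randomized, substitution errors at 0.5%.  A planted
  (gene, cluster, fraction) effect makes that fraction of in-cluster cells
  draw the gene's reads from the variant haplotype (default 30%, and 0%
  outside the cluster).
* **Strain mix**: 6-kb genome pair with 40 SNPs ≥ 120 bp apart; 150 cells,
  30 reads per cell centred (with jitter) on randomly chosen SNPs of the
  cell's own strain, 1% substitution error.
* **Null**: generated at the matrix level — 200 genes, each with one shade
  EC and one regular EC whose presence is drawn independently of the
  2-cluster labels — because the type-I property being checked is purely
  statistical.

What these simulations do *not* model: transcript-abundance variation, PCR
duplication, quality scores, barcode errors, intronic/antisense reads, and
repeat-induced k-mer sharing between genes (transcripts are i.i.d. random,
so cross-gene ECs are vanishingly rare).  Passing tests therefore show the
machinery is correct under clean conditions, not that real-data noise modes
are handled; on real data the EC filters (single annotated gene, ≥ 10
cells) do the corresponding work.

## Problem sizes and numerics

The test suite and the examples run on deliberately small instances (200-bp
to 6-kb references, ≤ 10⁴ reads), chosen so every expected output is
predictable from ground truth and exhaustive oracles (naive k-mer
enumeration, all 2×2 tables with total ≤ 40) stay cheap.  The in-memory
graph is a Python dict of sets: transparent and adequate at these scales;
succinct representations, minimizers, and multi-threaded construction are
explicit non-goals.  Planted-variant recovery is measured over 50
replicates at 300 cells each; recovery is defined as the planted EC being
the top hit by adjusted p with OR > 1.

## Known limitations

* Monochromatic extraction near repeat structure can yield unique contigs
  longer than 2k−1; only the isolated-SNP case has a length guarantee.
* A variant landing within k−1 bases of a transcript end has truncated
  flanks and may fail to map at `k_map`.
* The Fisher test conditions on both margins; with very small clusters it
  is conservative, and the BH threshold inherits that conservatism.
* Serialization is line-oriented JSON/TSV for transparency, not a compact
  index format; large references would need a different backend.
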