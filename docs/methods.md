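# Methods

`genomepair` re-implements, as a tested pipeline, the comparative analysis
of two intraspecific genome assemblies: calling genome-specific insertions
and inversions from whole-genome alignment blocks, summarising repeat
landscapes, estimating repeat-family copy numbers from shotgun read depth
calibrated on single-copy genes, building repeat phylogenies, and
converting flow-cytometry G1 peaks into genome sizes.  This note documents
the models, the defaults, and the choices made where the procedure was
genuinely open.

## Coordinates and formats

All internal intervals are 0-based half-open; conversion to the 1-based
inclusive coordinates of GFF3 and show-coords tables happens only at file
boundaries.  Free-text repeat annotations are mapped onto a controlled
vocabulary (`LTR_gypsy`, `LTR_copia`, `LINE`, `ClassI_other`, `ClassII`,
`rDNA_45S`, `rDNA_5S`, `gene`, `other`) by substring rules; unmapped types
fall into `other`.  Softmasking is discarded on read (no stage uses it).

## Anchor alignment

`anchor_align` is a desk-scale whole-genome comparison standing in for a
MUMmer-style aligner.  k-mers (default k = 21) occurring exactly once in a
reference and once in a query chromosome are matched on both strands and
chained along exact diagonals (anti-diagonals for reverse matches) while
consecutive anchors lie within `max_gap` (default 2 kb) on the reference.
Chains spanning at least `min_block` (default 4 kb) become blocks; percent
identity is computed by ungapped column comparison over the chained span.
Because chaining is diagonal-exact the aligner is substitution-only: it is
matched to the simulator (which plants SNPs but no small indels) and to the
≥ 95%-identity filter regime.  Real MUMmer `show-coords` tables can be
loaded instead through `read_alignment_blocks`.

Block filtering keeps identity ≥ 95% and reference span ≥ 4,000 bp by
default, mirroring the `-id 95 -l 4000` regime of chromosome-scale
comparisons of assemblies a few percent diverged.

## Genome-specific regions

A region of the reference is *specific* when no comparator genome covers it
with any filtered block: per chromosome, the complement of the
block-coverage union is computed for each comparator, the complements are
intersected across comparators, intervals separated by covered stretches
shorter than `merge_gap` are merged, and merged intervals of at least
`min_region` bp are reported.  Defaults (`min_region` = 1 Mb, `merge_gap` =
50 kb) target multi-megabase events on real chromosomes; the synthetic
benchmarks use 20 kb / 10 kb because their planted insertions are
0.05–0.2 Mb.  The implementation is property-tested against brute-force
per-base coverage arrays.

## Inversions

Reverse-orientation blocks on the same (reference, query) chromosome pair
are sorted by reference start and chained while consecutive blocks lie
within `chain_gap` (default 100 kb) on both genomes and query coordinates
decrease as reference coordinates increase.  Isolated reverse blocks are
reported as single-block calls, since real inversions down to tens of kb
appear as one block.

## Region summaries and table statistics

Per-region composition reports count a feature if it overlaps the region by
at least 1 bp and sum overlap lengths clipped to the region.  GC% uses an
all-bases denominator (N bases included), consistent with published tables
where an N-rich region shows proportionally depressed GC.  Column
statistics follow fixed reporting conventions: bp-valued means and medians
are truncated toward zero to integer bp, count columns are reported to two
decimals, percent columns rounded to two decimals.

## Repeat landscape

Windowed density tracks report the covered fraction of each window per
feature class, with overlapping same-class features merged first (repeat
annotations frequently overlap); cross-class overlaps are counted in both
classes so each class's fraction remains interpretable on its own.
The chi-square homogeneity test is the Pearson statistic with margins-based
expected counts and an upper-tail p-value from the regularized incomplete
gamma function; it is applied to cumulative-bp tables scaled to a
user-chosen unit (kb by default) because raw bp counts inflate the
statistic.  Genome-fraction arithmetic is exact inverse proportionality:
`pct_new = pct_old * size_old / size_new`.

## Copy-number estimation

Candidate repeat copies are clustered by single linkage with an edge
wherever global-alignment identity (unit costs, edlib) strictly exceeds
90%.  Each cluster is collapsed to a majority-rule consensus by center-star
alignment (center = member with highest mean identity to the rest;
insertions relative to the center are discarded; columns over 50% gaps
dropped; residue ties break alphabetically).  Reads are assigned by exact
k-mer seeding (k = 21, stride k/3 on both strands) followed by ungapped
extension clipped to reference bounds; a read counts toward the
reference(s) with the fewest mismatches provided the mismatch fraction is
at most 0.1, with ties split 1/n.  The dense seed stride matters: with
sparse seeds a read a few percent diverged from its consensus misses all
seeds a few percent of the time, biasing family depths low.

Mean depth is total aligned bp over reference length.  The calibration
depth is the **median** of per-gene mean depths over the single-copy gene
set (robust to occasional mis-annotated multi-copy genes), and copy number
is the depth ratio.  With an odd number of calibration genes the
self-applied estimator returns exactly 1.0, which the suite asserts.

## Phylogenies

Alignment is upstream (e.g. MAFFT); the module consumes gapped FASTA.
Trimming first strips leading/trailing columns while residue presence is
strictly below 25% (a column at exactly 25% is kept), then removes internal
columns whose gap fraction strictly exceeds 25%.  Jukes–Cantor distances
d = −(3/4)·ln(1 − (4/3)·p) use pairwise deletion, because repeat
alignments are gappy enough that complete deletion can empty the matrix;
saturated pairs (p ≥ 0.75) are set to a configurable cap (5.0) with a
warning rather than failing.  Neighbor joining uses the standard
Q-criterion with ties broken toward the lowest-index pair; a negative
branch length is clamped to zero with the deficit moved to its sister so
path lengths are preserved.  Bootstrap supports resample columns with
replacement (seeded), rebuild JC + NJ per replicate, and report the
percentage of replicates containing each internal bipartition of the
original tree.  Long-branch removal deletes leaves whose terminal branch
exceeds 10× the median terminal branch length and rebuilds, iterating at
most twice; the threshold is this package's choice, as no standard value
exists.  Protein-space analysis of translated repeats is out of scope; the
module operates on nucleotide (or pre-aligned arbitrary-character) rows.

## Genome size

1C content is `(sample G1 peak / standard G1 peak) × standard 1C`, with
*Pisum sativum* (4.45 pg) as the default internal standard — the standard
value is a required parameter, since published comparisons rarely print
it.  The pg→Mbp constant is fixed at 978 Mbp/pg, which reconciles printed
pg/Mb pairs such as 0.590 pg ↔ 577 Mb.  One-way ANOVA is the classical
decomposition with an F upper-tail p-value.  The Tukey-style post hoc is
implemented by seeded permutation: pairwise studentized ranges are compared
with the permutation distribution of the maximum studentized range over all
pairs (family-wise, as in the analytic HSD), and a compact letter display
is assigned greedily over groups sorted by mean.  This is an approximation
to the analytic studentized-range distribution; with 10,000 permutations
(default) its resolution is ample for letter grouping.  Shapiro–Wilk
normality testing delegates to the standard scipy implementation with the
3 ≤ n ≤ 5000 validity range enforced and constant input rejected.

## Synthetic data

The generator emulates the study design: an ancestral haploid genome A
(default GC 0.36) carrying single-copy genes, TE-family copies (each copy
independently diverged 2% from its family consensus, so that 90%-identity
clustering groups them) and a tandem 45S rDNA array (9 kb unit, 0.5%
inter-unit divergence); and a derived genome B built by applying a uniform
SNP overlay (default 2%) followed by planted inversions and then planted
insertions.  Applying SNPs before the structural events keeps alignment
identity uniform across planted segments.  Insertions are composed by
weight from tandem rDNA units, surplus TE copies (`copies_b − copies_a`
from the family library) and random filler, padded to the exact configured
length; an rDNA array excess in B is planted automatically as a tandem
extension at the array locus.  Features are written into (not spliced into)
the ancestral background, so genome A's length equals the configured
chromosome length and B grows only by insertions.  Reads are single-end,
fixed-length, uniform-start, strand-symmetric, with substitution errors
only — matched to the ungapped mini-mapper.  Everything is driven by one
seed; identical config + seed gives byte-identical genomes, annotations and
reads.

What the simulator does **not** model: small indels, heterozygosity,
sequencing-quality variation, GC-coverage bias, nested/fragmented repeats,
and segmental duplications.  Passing the planted-truth benchmarks therefore
demonstrates the correctness of the detectors' logic under the stated
divergence regime, not their performance on real long-read assemblies.

## Benchmark problem sizes

The planted-truth benchmarks (shared by the test suite and
`scripts/acceptance.py`) use: a 2 × 1 Mb genome pair at 2% SNP divergence
with three insertions (0.05/0.12/0.2 Mb) and two inversions (60/150 kb),
detected with `min_region` 20 kb, `merge_gap` 10 kb, `chain_gap` 50 kb; a
300 kb single-chromosome genome with family copy numbers {1, 5, 20, 50} at
20× coverage and 1% read error; 100 random additive matrices of up to 12
taxa; 50 fuzzed coverage instances up to 100 kb; and 5,000 homogeneous
5 × 4 multinomial tables (row totals 200) for chi-square type-I
calibration.  These sizes were fixed once as representative desk-scale
conditions.

## Known limitations

- The anchor aligner is substitution-only and will fragment across real
  indels; supply MUMmer coords files for real assemblies.
- Copy numbers are reported per consensus; whether that corresponds to a
  biological unit (e.g. a full rDNA unit) depends on how the input
  sequences were delimited.
- The permutation Tukey post hoc approximates the analytic HSD; exact
  agreement with R's `TukeyHSD` p-values is not expected, letter groupings
  on well-separated data are.
- Reciprocal inversion spans are reported on both genomes; any asymmetric
  aggregation over them is left to the user.
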