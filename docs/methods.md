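# Methods

## Overview

phamlin implements the comparative stage of a phage genomics study: given
annotated genome records, it builds protein phamilies, measures pairwise
nucleotide relatedness, partitions the genomes into clusters and
singletons, and summarizes how much gene content the clusters share with
each other and with an external reference set. A synthetic pangenome
generator with full ground truth drives the test suite, so every stage is
validated against planted answers rather than against fixtures that would
have to be downloaded.

## Pham construction

Proteins are compared all-vs-all with Biopython's local pairwise aligner
(BLOSUM62, gap open 11, extend 1). An edge requires three things of the
best local alignment:

* percent identity ≥ 32.5, counted as identical residue pairs over all
  alignment columns, gap columns included;
* coverage ≥ 0.5, i.e. the alignment spans at least half of the shorter
  protein;
* raw alignment score ≥ 100.

Phams are the connected components of the edge graph (single linkage), so
two proteins in one pham need not be directly similar — transitive chains
through intermediate relatives link them, which is the behaviour the
mosaic structure of phage genomes calls for. Pham ids are assigned by
decreasing size with lexicographic tie-breaking, making the table
deterministic for a given input.

The identity and coverage thresholds follow the conventions of
actinobacteriophage pham building. The score floor deserves a note: pairs
of entirely unrelated proteins routinely produce local alignments in the
twilight zone — 30–40% identity over 40–60 columns — and such alignments
score below ~60 in BLOSUM62 raw units, while genuinely homologous pairs
that satisfy the identity and coverage rules score in the hundreds. The
floor plays the significance-guard role that an E-value cutoff plays in
BLAST-based pham assembly, without introducing E-value statistics. With
identity and coverage alone, chance edges appear at a rate of roughly one
per few thousand unrelated pairs, which is enough to corrupt single-member
phams (orphams) in any collection of realistic size.

An all-vs-all prefilter skips alignment for pairs sharing no 4-mer; this
is a cost optimization whose neutrality is asserted by a test comparing
filtered and unfiltered runs on the same corpus.

External reference proteins (with host-genus tags) are mapped onto the
finished phams with the same edge criterion; they never alter the internal
partition, only the per-pham external membership counts used by the
diversity statistics.

## Fragment ANI

The query genome is cut into consecutive 1,020-bp fragments (a trailing
fragment is kept when at least half length). For each fragment the subject
genome is searched on both strands for shared 13-mers; a strand with fewer
than 3 distinct shared words yields no hit, mirroring how BLAST-based ANI
simply finds no alignment for unrelated fragments. When seeds exist, the
fragment is aligned with edlib (infix mode) against a window around the
densest seed cluster, and the alignment is rescored column-by-column
(match +1, mismatch −1, gap open −2, extend −0.5); the maximum-scoring
contiguous stretch gives the local identity and the fraction of the
fragment it covers. Fragments with identity ≥ 30% over ≥ 70% of their
length are retained; ANI is the mean retained identity and the aligned
fraction is the retained share of fragments. The symmetrized result is the
mean of the two directions.

Two numerical choices matter. First, restricting the subject to a
seed-supported window discards only placements the retention rule would
reject anyway, and makes all-vs-all comparisons fast enough for routine
use. Second, rescoring the edit-distance alignment and keeping its best
local stretch is essential: forcing the entire fragment into the identity
denominator lets gappy alignments of unrelated sequence masquerade as
~55% identity, and a partially homologous (chimeric) fragment would
otherwise report a diluted identity instead of failing the coverage rule.

Self-comparison returns ANI exactly 1.0 with aligned fraction 1.0. A
genome versus a copy mutated at an i.i.d. 5% per-site rate returns ANI
within 0.94–0.96, the calibration the test suite asserts over ten seeds.

## Cluster assignment

Genomes are linked when symmetrized ANI ≥ 0.6 **and** aligned fraction
≥ 0.5; components of size ≥ 2 are clusters, the rest singletons. ANI is
the primary evidence deliberately: phage cluster pairs can share a quarter
of their genes at the amino-acid level while remaining well separated in
nucleotide identity, and the aligned-fraction guard is what keeps such
pairs apart — their few shared genes align at high identity, but the
retained fraction stays far below 0.5. A shared-gene-fraction OR-criterion
exists behind a disabled-by-default threshold for corroboration studies.

An intra-cluster ANI summary flags (report-only) clusters whose minimum
pairwise ANI falls below a configurable floor (default 0.70), the signal
one would inspect before considering subdivision.

## Gene content and phylogeny export

The presence/absence matrix has one 0/1 column per pham. The default
distance is Jaccard on pham sets (1 − |∩|/|∪|, a metric); an alternative
"shared-fraction" distance (1 − mean directional shared fraction) is
selectable. The raw binary CHARACTERS block is exported as NEXUS alongside
a DISTANCES block so external split-network software can apply its own
transform; the neighbor-joining tree uses dendropy's canonical NJ with
negative branch lengths clamped to zero.

## Diversity statistics

All percentages are over a cluster's *pham universe* — the distinct phams
across its members. Cluster-identifier phams must occur in every member
and in no other study genome, so identifier and inter-cluster-shared sets
are disjoint by construction, and each metric is also recomputable by an
exhaustive scan over (phage, pham) membership — the form the tests use as
an oracle. Orpham percentages depend on the attached external set; without
one, an orpham is simply an internal single-member pham and the report
carries that definition.

## The synthetic pangenome generator

The generator emulates the statistical structure the analysis assumes:

* K clusters, each with a planted ancestral gene cassette: a core pham set
  carried by all members, accessory phams carried by ≥ 2 members, and
  per-genome orphams carried by exactly one;
* cluster-specific G+C targets (defaults 0.45–0.64, emulating the broad
  range real phage collections show, with singletons drawn from the same
  range);
* inter-cluster pham sharing at a configurable rate, planted as *diverged*
  homologs (default 20% nucleotide divergence) — shared phams between real
  clusters are old amino-acid-level relatives with weak nucleotide
  similarity, and planting verbatim copies would create spurious ANI
  links;
* singleton genomes whose genes are all unique.

Proteins are drawn at natural background amino-acid composition (uniform
composition over-represents rare high-scoring residues and inflates chance
alignment identity) with a mild dipeptide repeat tendency, then
reverse-translated with codon weights solved by bisection so each gene's
expected G+C matches the cluster target; intergenic gaps are drawn at the
same target. The configured intra-cluster mutation rate is the target
*pairwise* divergence: half the rate is applied per lineage from the
ancestor, so two members differ at approximately the configured rate and
realized intra-cluster ANI ≈ 1 − rate. Substitutions that would create an
internal stop codon are reverted (a ~4% correction at these rates), so
every CDS stays translatable. Core-region intergenic gaps are inherited
from the ancestor and mutated at the same rate, keeping cluster members
positionally homologous across the core region — as real intra-cluster
genome alignments are.

Every stochastic draw flows through one numpy generator seeded from the
config; emitted GenBank/FASTA/truth files are byte-identical across runs
with the same seed.

What the generator does **not** emulate: real gene synteny (terminase →
… → tape measure ordering), recombination breakpoints within genes,
insertion/deletion variation, tRNA genes, and genome-end architecture.
Passing tests therefore demonstrate correct recovery of planted cluster,
pham and sharing structure under substitution-only divergence — they do
not certify behaviour on genomes with large indels or rearrangements,
where the fragment scheme's aligned fraction (not its identity) absorbs
the difference.

## Default problem sizes

The default simulation (K = 4 clusters of 3–6 members plus 2 singletons,
15–25 genes per genome, 80–300 aa per gene) produces genomes of roughly
10–15 kb — deliberately at the small-genome end of real phage collections,
where the smallest cluster members sit near 15 kb with ~25 genes. Tests
and the acceptance script use these sizes so the complete suite runs on a
single CPU in a few minutes; every statistic scales to full-size genomes
with the same code paths, only slower.

## Known limitations

* ANI identity is derived from edit-distance alignments rescored locally,
  not from an affine-gap Smith–Waterman; on highly indel-rich pairs the
  identity can differ from BLAST-style values by a point or two, which is
  why cluster thresholds operate at the 0.6 level rather than near the
  retention boundary.
* The pham edge criterion is alignment-based only; remote homologs that
  profile methods would link (and that curated databases report) stay
  separate, so orpham percentages are upper bounds relative to a
  profile-aware database.
* `read_genbank` collapses compound (`join(...)`) CDS locations to their
  envelope with a flag — correct for unspliced phage genes, lossy
  elsewhere.
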