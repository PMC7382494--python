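# Methods

This note documents the models, conventions and design choices behind each
stage of the toolkit, what the synthetic generator does and does not emulate,
and the known limitations.

## Coordinates and formats

GFF3 is 1-based inclusive at every interface; internally all interval
arithmetic is 0-based half-open, with the conversion centralized in
`pantx.coords` and tested there. Hit tables use the 12-column tabular search
dialect (qid, sid, pident, length, mismatch, gapopen, qstart, qend, sstart,
send, evalue, bitscore). Genome-mapping evidence is accepted as BED6, PAF or
GFF3-like rows, auto-detected per line.

## Annotation merging

Two gene sets over one genome are compared "by exact chromosomal location
and orientation", operationalized as: two genes interact when they share
chromosome and strand and their spans overlap by at least 1 bp. Components
of this relation are computed by a plane sweep (equivalent to union-find
over all pairwise overlaps, which the tests verify). The decision tree:

| topology (A:B)        | outcome                                   |
|-----------------------|-------------------------------------------|
| single gene           | keep as-is (`keep_singleton`)             |
| 1:1                   | keep the policy-preferred source (default B) |
| 1:2 or 2:1            | keep the spanning gene if its CDS union covers ≥ `spanning_rule` (default 0.5) of *each* covered gene's CDS union, else keep the split genes |
| anything else         | manual curation queue                      |

The 1:1 preference and the spanning rule are policy, not biology: the
upstream projects resolved these programmatically without publishing the
rule, so both are explicit `MergePolicy` fields, logged in the output.
Size-3 components whose topology is not 1:2/2:1 (e.g. 3:0) and all size-≥4
components go to curation. Curation is file-driven: an override TSV maps
cluster ids to retained gene ids and is applied on re-run; strict mode
refuses to write output while unresolved clusters remain. The accounting
table maps every input gene to exactly one of retained / superseded_by:X /
curation:C, making the partition invariant checkable.

## ORF calling

The longest open reading frame is searched in all six frames by default
(pooled assemblies mix stranded and unstranded protocols; a flag restricts
to forward). Within each frame, stop codons split the sequence into runs; a
candidate ORF starts at the first ATG of a run, or at the run start when the
run touches the 5' edge of the frame (edge-truncated, `has_start=False`),
and ends at the terminating stop (included in the span) or at the 3' edge
(`has_stop=False`). The longest span wins; ties prefer the + strand, then
the 5'-most start. Codons containing any ambiguity translate to X, and
proteins containing X never participate in silent-variant grouping — an N
should not create spurious locus merges.

## Redundancy reduction

Steps run in order on the called records:

1. **Perfect duplicates** — byte-identical sequences keep one survivor: the
   longest CDS, ties by ascending transcript id. The ascending-name
   tie-break reproduces the observed behaviour of the upstream tooling
   (e.g. a CLC-assembled name surviving over a PacBio name for an identical
   sequence).
2. **Perfect fragments** — processed longest-first, a sequence contained
   exactly in a surviving longer sequence (either strand by default) is
   dropped, so no two survivors are in a containment relation.
3. **Silent variants** — identical translations group; the representative is
   the longest transcript. This also captures UTR-only variants (identical
   CDS, different ends).
4. **Isoform linking** — an edge joins two survivors when a local alignment
   window of length ≥ `min_segment_len` (default 120 nt) reaches identity ≥
   `min_segment_identity` (default 0.98). The numbers are this package's
   defaults — "exon-sized, high-identity" is the contract, the thresholds
   are configurable and recorded. Implementation: a shared exact block of
   the full window length is accepted immediately (the common case for
   alleles and splice variants); otherwise the optimal Smith-Waterman local
   path is scanned with a sliding window. Scanning only the optimal path is
   a heuristic for the existential criterion; adversarial cases could hide a
   qualifying segment off the optimal path, but the planted structures the
   recovery tests use are exact for it. Scoring is symmetric, which
   satisfies the both-directions requirement of a reciprocal search.

Connected components over (3) ∪ (4) each elect one **main** (longest CDS,
ascending-id ties); other members are **alt** with a pointer to their main;
steps (1)–(2) contribute the tagged **drop** set. Conservation
(|main|+|alt|+|drop| = input) and idempotence on the main ∪ alt set are
tested invariants.

A consequence of the component semantics worth knowing: a chimeric
misassembly that shares exon-sized segments with two distinct loci bridges
them into one component, which then elects a single main. This is faithful
to the component contract; the synthetic recovery rates account for it.

## Evidence filtering

A transcript survives iff it has ≥1 genome-mapping record, OR ≥1 domain
annotation, OR ≥1 protein hit with E ≤ `max_e_value` AND query coverage ≥
`min_query_cov` AND target coverage ≥ `min_target_cov` (defaults 1e-5, 0.5,
0.5 — the coverage thresholds apply to both sides of the alignment).
Genome mapping needs no identity threshold: presence of an alignment record
counts. Coverages are computed from aligned spans and sequence lengths when
length tables are supplied, otherwise a hit is taken at face value.
Vector-screen results are annotated (strongest call + span fraction per
transcript, per-strength summary counts) but never remove sequences unless
explicitly requested — borderline calls and meta-transcripts are worth
keeping for inspection. After filtering, components are rebuilt from the
prior alt→main edges restricted to survivors; a surviving main keeps its
role, otherwise the longest-CDS survivor is promoted and the rest re-pointed.

## Pan clustering

Clustering runs on CDS (the lowest common denominator between annotation
projects that define only coding sequences) with reverse-complement matching
off — inputs are oriented. Stage 1 processes entries longest-first
(ascending-id ties) and joins each to the *first* existing cluster whose
representative it matches; stage 2 seeds clusters from the reference
leftovers and joins tetraploid leftovers the same way. Identity conventions
mirror the cited clustering tools:

* global (stage 1, defaults 0.90 identity / 0.75 shorter-coverage, band 51,
  word 9): identity = matching columns / shorter-sequence length, computed
  from an infix (semi-global) alignment in which the shorter sequence aligns
  end-to-end — shorter-sequence coverage is therefore 1.0 by construction;
* local (stage 2, defaults 0.90 / 0.45, band 45, word 5): identity =
  matching columns / alignment length, coverage = aligned span on the
  shorter sequence / its length, from a Smith-Waterman alignment.

Band and word parameters are carried as provenance and treated as alignment
search hints; the contract is the identity/coverage criterion, and the
greedy order is fixed for reproducibility. Pan ids are assigned in
cluster-founding order as `stPanTr_` + zero-padded 6 digits. Categories from
the member genotype set: all genotypes → core; exactly one → genotype
specific; reference + a proper subset → reference-shared; ≥2 tetraploids
without the reference → tetraploid-shared. "Partial" members lack a start
or stop codon; each cluster reports its partial fraction.

## QC metrics

N50/N90 use the definition "the largest contig length L such that contigs of
length ≥ L contain ≥50%/90% of all assembled bases" (equivalently, the
cumulative-sum walk from the longest contig). Reference coverage bins use a
reciprocal-best-hit simplification of conditional reciprocal-best schemes:
"best" is highest bit-score (ties: lowest e-value, then subject id); a pair
is reciprocal when each is the other's best; covered reference bases are the
union of the pair's aligned reference intervals. Because the pre- vs
post-reciprocity query count is ambiguous in the field's tables, both are
emitted (`n_query_with_hit`, `n_query_reciprocal`).

## Synthetic data: what it emulates, and what it does not

The generator draws, from one numpy generator per seed, a study of
`n_loci` loci (default 200) shared among three tetraploid genotypes and one
reference clone: 50% core, 30% genotype-specific (round-robin across all
four genotypes), the rest random reference-shared or tetraploid-shared
subsets. Loci are independent random codon sequences (110–300 codons), which
keeps inter-locus divergence far above the 15% floor the 90% clustering
threshold needs for sharp recovery. Each genotype carries 1–4 haplotypes per
locus (SNPs at rate 0.01/nt, never creating stops) and a splice variant with
probability 0.2 (an in-frame 90 nt deletion leaving ≥150 nt on each flank so
isoform linking must find it). Tetraploid transcripts get 30–120 nt UTRs;
the reference contributes bare CDS, standing in for merged gene-model coding
sequences.

Two constructions guarantee that the planted CDS is each transcript's unique
longest ORF, so main-set recovery is well-defined: UTRs abut the CDS through
`TTAATTAATTAA` — a G-free, reverse-complement-palindromic motif containing a
stop in all six frames — and candidate CDS are rejected while any non-coding
frame holds a stop-free run long enough to rival the coding frame.

Artifacts are planted in exact study-wide counts (defaults: 20 duplicates,
20 fragments, 20 UTR variants, 10 frameshifts, 5 chimeras, 20 contaminants),
dealt round-robin across genotypes, each ledgered with its source. Artifact
ids sort after truth ids so the ascending-name duplicate tie-break retains
the original. Chimeras fuse the first half of one transcript with the second
half of another (whole-transcript concatenation would make a parent a
perfect fragment of its own chimera). Contaminants are dinucleotide-chain
resamples of real transcripts — realistic composition, zero planted
evidence. Evidence tables (BED mapping, 12-column protein hits at E=1e-50
and 90% coverage, domain TSV for half the loci, mostly-weak vector rows for
2% of ids) are consistent with the ledger: everything except contaminants
must pass the default filter.

The generator does **not** emulate: sequencing reads or base errors,
expression levels, real UTR structure or polyadenylation, paralogy gradients
between the 15%-divergence floor and the SNP rate, genotype-specific
presence/absence within a locus's haplotypes, or annotation errors beyond
the planted topologies. Passing recovery tests therefore demonstrates the
pipeline's bookkeeping and threshold logic under clean separations, not
robustness to borderline paralogues or noisy assemblies.

Default problem sizes (200 loci, ~1,200 over-assembly sequences, ~550 pooled
CDS) were chosen so a full end-to-end run completes in well under a minute
on one CPU while every planted phenomenon still occurs in double digits.

## Numerical and degenerate-input choices

* Greedy stage-1 candidate pruning caps the edlib search at edit distance
  |long| − (2t−1)|short| + 1, the worst case consistent with identity ≥ t
  under the matches/shorter convention (large internal gaps inflate edit
  distance without lowering that identity).
* Empty FASTA → all-zero contig metrics with a warning; empty GFF3 → empty
  gene set; absent evidence files → empty bundles (the filter then drops
  everything, as specified).
* Tie-breaks are everywhere (longest, then ascending id), making every
  output byte-deterministic for fixed inputs; the pipeline asserts exact
  byte identity across re-runs in its tests.

## Known limitations

* The isoform-linking existence check inspects only the optimal local path
  (see above).
* The reciprocal-coverage implementation is a plain RBH scheme, not the full
  conditional (e-value-threshold-learning) variant; bins are comparable but
  not identical to tools implementing the latter.
* The annotation merger resolves 1:1 and 1:2/2:1 by policy; real projects
  resolved some of these with RNA-seq evidence unavailable here. The
  curation queue plus override file is the escape hatch.
* cd-hit's own heuristics (word filtering, banding) are not reproduced
  bit-for-bit; an external-tool adapter would be needed to replicate a
  deposited clustering exactly.
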