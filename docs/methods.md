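# Methods

## Overview

`splicefrag` quantifies RNA-seq reads over the elementary units of splicing.
The pipeline is: (1) partition each gene into subexons; (2) enumerate
admissible novel junctions between annotated splice sites, implicitly
defining a virtual transcriptome; (3) enumerate the signatures a read of
length *l* can realize and emit a minimal fragment library; (4) pseudoalign
reads to fragments by k-mer offset voting and count signatures; (5) convert
the counts to coarser schemes and classify the novel introns they imply;
(6) optionally incorporate genuinely novel splice sites found by an external
spliced aligner on the reads left unmapped.

All internal coordinates are 0-based half-open; GTF I/O converts from/to the
1-based inclusive convention. Subexons are numbered by genomic coordinate
regardless of strand; donor/acceptor roles are strand-aware (the left
boundary of an intron is the donor on `+`, the acceptor on `-`).

## Gene models and subexons

Cut points are the union of all exon starts and ends of a gene's transcripts
(plus discovered sites after the refine phase). Every maximal run of exonic
positions, subdivided at internal cut points, is one subexon. Exons of one
transcript that abut (gap 0) are merged at parse time; abutting exons of
*different* transcripts are not merged, so the touching point remains a
subexon boundary. Transcripts with identical intron chains but different
start/end sites are kept distinct — they change the partition. Genes whose
transcripts span multiple chromosomes are rejected; unstranded records are
treated as `+` with a warning. Intronless genes have no splice sites and
therefore no guessable junctions.

## Virtual transcriptomes

Candidate novel junctions are all pairs (left boundary of an annotated
intron, right boundary of an annotated intron) that are not themselves
annotated and whose length is at least `min_intron` (default 20 nt —
shorter micro-introns are biologically implausible and would inflate the
graph; the number of guesses per gene is capped at 50 000 with a warning).

* **Mode `as`** (alternative splicing of a reference transcript): a
  candidate is admitted iff the event classifier types it ES, AD, AA or AP
  with respect to at least one annotated transcript whose TSS–TES span
  contains the junction. This local test operationalizes "skip exons and
  move remaining boundaries to annotated sites, keeping the anchor's start
  and end"; it is an approximation of the global membership test over whole
  virtual transcripts, which is intentionally never materialized. The
  remaining global constraint — a signature may not extend beyond the span
  of every possible anchor — is enforced at signature level during fragment
  construction.
* **Mode `ap`** (general alternative processing, including alternative 5'
  capping and 3' cleavage): every candidate is admitted; only the gene span
  bounds signatures. By construction annotated ⊆ as ⊆ ap.

The per-gene splice graph has subexons as nodes, spliced edges for the
junction catalog, and unspliced (read-through) edges between genomically
adjacent subexons whose shared boundary lies in the interior of at least one
annotated exon — the rule that prevents merging touching exons across
transcripts. In `annotated` mode the path language is exactly the set of
contiguous windows of annotated transcript signatures; in `as`/`ap` it is
the set of edge walks satisfying the mode's span rule.

## Feasible signatures and fragments

A signature ı=(i1..im) is feasible for read length l iff it is in the path
language (f1), Σ|s_i| ≥ l (f2), and for m ≥ 3 the internal lengths sum to at
most l−2 (f3). Enumeration is a bounded forward walk: once the running
internal length exceeds l−2 no extension can recover, so signatures are
local and enumeration is linear in practice.

The fragment of a feasible signature includes the boundary subexons up to
b = l − L_int − 1 nt (L_int = total internal length): a read covering all
internal subexons must keep at least one base for the opposite boundary, so
b is the largest usable boundary overlap. This boundary formula is derived
from that covering requirement and verified against an exhaustive
substring-coverage oracle in the tests. For m = 1 the fragment is the whole
subexon.

Fragment sets:

* `F11`: one minimally-trimmed fragment per feasible signature.
* `Fmax`: only maximal signatures (not contiguously contained in another
  feasible signature; ties between equal maximal signatures are broken
  lexicographically), boundary subexons included in full so that contained
  signatures remain readable by positional scan.
* `F` (default): `Fmax` with boundary contributions trimmed to
  min(|s|, l−1) nt, plus every subexon with |s| ≥ l as a singleton fragment.
  The singleton threshold is |s| ≥ l because a read can lie entirely within
  s iff that holds; trimming the rest to l−1 guarantees that any mapping
  overlapping a fragment's boundary subexon also overlaps its neighbour, so
  boundary mappings never conflict with singleton mappings.

`Fmax` and `F` contain fewer fragments than `F11`, and `F` carries less
sequence than `Fmax`; note `Fmax` routinely carries *more* sequence than
`F11` (its boundary subexons are untrimmed) — the three sets trade fragment
count against sequence redundancy, and `F` is the best compromise. All
three produce identical signature-count tables, which the tests assert.

Fragment names encode the inverse mapping (`gene|i1,i2,...|a,b` with a/b the
included boundary lengths) so a fragment file is self-describing. The
sequence is always genomic-forward regardless of gene strand; strandedness
is recovered at mapping time.

Correctness and completeness of `F` (every fragment derives from a virtual
transcript; every length-l window of every virtual transcript occurs in a
fragment with its true signature recoverable by scan) are verified
exhaustively on every test fixture by sliding-window enumeration over the
explicit maximal paths of the graph.

## Pseudoalignment

The index maps canonical k-mers (default k = 31, clamped to ≤ l−1) of every
fragment to (fragment, offset) postings. A read's k-mers vote for implied
(fragment, read-start offset, orientation) placements; k-mers absent from
the index — typically mismatch-affected or spanning an unindexed splice
site — are skipped. Because one substitution can affect at most k votes,
every placement within k votes of the leader is kept as a candidate; each
candidate is then verified by Hamming distance at its placement with a
default cap of 5% of the read length (`--verify-hamming` overrides). The
verification step is essential, not cosmetic: without it, reads spanning a
*novel* (undiscovered) splice site are majority-voted onto one-sided
placements and can never reach the refine phase. Among verified candidates
the winner is chosen by (k-mer support, exact-match length); remaining exact
ties that imply different signatures are counted as `ambiguous` and excluded
(ties with equal signatures are counted once; the deterministic primary is
the lowest fragment name). The read's signature is the set of subexon
segments its placement interval intersects.

Consequences of this design: a junction read maps with an overhang as small
as 1 nt when its sequence is unambiguous (the junction-crossing k-mers are
in the index); a single substitution at least k nt from both read ends never
changes the mapping; reads with more mismatches than the cap (about 1.6% of
reads at a 2% per-base error rate and l=100) and reads across unindexed
splice sites go to the unmapped pool. Reads shorter than l map if they
contain at least one k-mer; longer reads are rejected with instructions to
rebuild the index, since feasibility is l-specific. Reads with more than
50% ambiguous bases are unmapped. Paired-end mates are mapped independently
and summed (the ordered signature-pair table is available with
`--pair-signatures`). `--threads` is accepted for interface parity: per-read
mapping is pure and results merge in deterministic order, so output is
byte-identical for any value.

## Count conversions

Transcript-compatibility counts use the set expression
∩_{i∈ı} t(s_i) ∖ ∪_{i∈ı̄} t(s_i). Signatures whose set is empty (novel
patterns) accumulate under a reserved NOVEL key rather than being dropped,
so the total is conserved and assertable. Merged bins join signatures whose
genomic spans overlap (span = first subexon start to last subexon end — the
overlap notion is a documented choice) and whose compatibility sets are
equal, by union-find closure. Subexon (exon-bin) counts and splicing-graph
node/edge counts are plain summations; graph edges distinguish read-through
adjacencies from spliced junctions. All conversions are pure functions of
the count table (idempotent, many-to-one).

## Event classification

Each novel intron J observed in the counts is classified against every
annotated transcript t overlapping it, with precedence IE → ES → AD/AA → AP
→ UNK:

* IE if J lies strictly inside one exon of t;
* ES if ≥ 1 complete exon of t lies inside J (the count of skipped exons is
  reported); *classical* iff J's endpoints equal the boundaries of the
  t-introns immediately flanking the skipped run;
* AD if J's acceptor matches an intron of t but its donor does not (AA
  mirrored), provided no complete exon is skipped;
* AP if J overlaps an intron of t matching neither endpoint;
* UNK otherwise (reads from novel exons, or introns overlapping at most one
  exon of any transcript, would need assembly to classify).

Classification is strand-aware and mirror-symmetric (verified by
reverse-complement fixtures). Intron retention is called conservatively:
an intron is IR only if it overlaps no exon of any transcript of the gene,
at least one read maps contiguously across its boundary or inside it, and
no junction with an endpoint strictly inside it has nonzero count. The
interior-splicing veto is defensive: given the no-novel-exon policy, counted
junction endpoints always fall on subexon boundaries, which a fully
intronic interval contains none of. Intron-overlapping reads are observed
without a genomic aligner by `--with-introns` fragments (flank ≤ l−1 nt +
intron + flank), whose intron stretch is a pseudo-segment outside signature
index space and is tallied separately.

## Refine phase

Genuinely novel splice sites come from a spliced aligner run on the unmapped
pool; the contract is the standard 9-column junction file (chromosome,
1-based inclusive intron, strand code, motif, annotated flag, unique/multi
read counts, max overhang). Records passing the filters (defaults: ≥ 3
unique reads, overhang ≥ 10 — conventional values, configurable) whose
endpoints fall on exonic territory of a gene split the containing subexons;
sites in intronic or intergenic territory would require novel-exon assembly
and are written to a skipped-sites file. Existing counts are rewritten
through the old→new index remap: an index whose subexon was split expands to
all successor pieces when internal (the read covered the subexon fully), to
the rightmost piece when first, the leftmost when last, and to all pieces
for singletons — per-read offsets are no longer available, so the chosen
pieces are the ones guaranteed overlapped. Totals are conserved exactly.
Fragments are rebuilt only for affected genes; the unmapped reads are then
requantified and merged additively, so phase-one counts never decrease and
a second pass with the same junction file is a no-op.

## Synthetic data generator

The generator emulates a small multi-gene annotation with isoform structure
(a master exon chain per gene; isoforms by internal exon skipping and
alternative internal boundaries), a uniform-random genome, and
position-uniform read sampling over transcripts with uniform substitution
errors. Defaults: 5 genes of 3–8 exons (60–200 nt) with introns of 60–300
nt, 2–3 transcripts per gene, l = 100, 10 000 single-end reads, 0% error.
In hold-out mode, exon-skipping isoforms are removed from the emitted
annotation — their junctions become novel but remain guessable — while
reads are still drawn from them (10% of reads by default). Every read
carries a truth record (source transcript, genomic blocks, true signature,
error positions); all randomness flows through one seeded generator and all
outputs are byte-stable per seed.

Two named genes reproduce the documentation's reference structures: `FIXG1`
(five subexons from two isoforms, with an implied skip isoform and an
implied novel-TSS isoform) and `FIG3G` (eight subexons from three isoforms
exercising every event class including a fully intronic intron for IR).

One deliberate constraint: spliced reads are sampled with a minimum junction
anchor of 10 nt. A read overhanging a junction by only a few bases can be
*sequence-identical* between two fragments whose acceptor sides begin with
the same bases; its true signature is then unrecoverable in principle, and
exact-truth comparisons are only well-defined over identifiable reads. The
mapper itself resolves overhangs down to 1 nt whenever the sequence is
unambiguous and reports genuine ties as ambiguous.

What the generator does **not** emulate — and what passing tests therefore
do not show about real data: empirical error profiles and indels (the
engine has no gapped model), positional/fragment-GC bias, expression
dispersion (per-transcript weights default to uniform), overlapping genes
on one locus, repetitive genomic sequence (uniform-random genomes make
k-mer collisions vanishingly rare at k = 31; real repeats would raise the
ambiguous fraction), and intron-retention transcripts as such.

## Problem sizes and numerical choices

Test and acceptance workloads are sized for interactive iteration: the
exhaustive fragment verification runs 50 random single-gene fixtures at four
read lengths (8, 10, 15, 50); mapping checks use 10k-read libraries at
l = 100, k = 31; conversion oracles run 20 fixtures of 400 reads. These
sizes exercise every code path exhaustively at gene scale — correctness
claims are per-gene properties, so larger genomes add load, not coverage.
Determinism is enforced structurally (sorted iteration everywhere, one
seeded generator, no hash-order dependence) and asserted byte-for-byte.

## Known limitations

Pairing information is not used during mapping (mates are independent);
multi-gene exact ties are dropped as ambiguous rather than fractionally
assigned; the `as` admissibility test is local (junction-level) rather than
the global whole-transcript membership test; `ap` mode implements the
in-text description of general alternative processing (all annotated-site
combinations, gene-span bounded) without a formal grammar; no transcript
abundance estimation is performed (signature counts are the product, EM
quantification is out of scope); and the refine phase never assembles novel
exons.
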