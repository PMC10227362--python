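# Methods

## The unified event model

All modules share one event representation: `(event_id, gene_name, chrom,
strand, event_type, blocks, source_tool)` with the eight core AS types ES,
MES, MEE, IR, A5, A3, AFE, ALE. The *blocks* are the event-defining
coordinates (see `docs/format.md`). Comparison between tools and against
truth always goes through the canonical key `(chrom, strand, effective
type, blocks)` — gene names and IDs are deliberately excluded because
tools disagree on identifiers, and by default MES/MEE map onto ES
("skipping collapse") because most detectors cannot label multi-exon or
mutually exclusive skipping as such. A5/A3 are strand-relative labels: the
same genomic geometry is an A5 on `+` and an A3 on `-`.

Coordinates are 1-based inclusive throughout (the GTF/SAM convention);
half-open coordinates never enter the data model.

## Synthetic ground truth

The simulator emulates what a read simulator with event injection provides:
an annotation whose genes carry a *main* isoform (all exons) plus
alternative isoforms realising known events, truth tables for events and
reads, and perfectly aligned reads.

Gene geometry (defaults, chosen to keep desk-scale runs in seconds while
admitting every event type): exon count ~ U[4, 12], exon length ~
U[50, 300] bp, intron length ~ U[100, 1000] bp, 5000 bp intergenic gaps,
alternating strands, one synthetic chromosome `simchr1`. Realisation rules
against the main isoform:

* **ES** removes one internal exon; **MES** removes 2–3 consecutive
  internal exons (blocks = the removed exons).
* **IR** merges two adjacent exons across their intron (block = intron).
* **A5/A3** move a donor/acceptor 10–60 bp into the intron, leaving ≥ 20
  intronic bases (block = the exonic bases present in only one variant).
* **AFE/ALE** replace the first/last transcribed exon with a novel exon in
  the flanking intergenic space (block = the novel exon).
* **MEE** emits a *pair* of isoforms, each retaining exactly one of two
  adjacent internal exons; it therefore requires `events_per_transcript
  = 1` and appears in no stock design.

Within one isoform, co-occurring events claim disjoint exons and introns —
otherwise one event would erase the evidence for the other (e.g. a splice
site shift on a skipped exon is unobservable). The *events per exon* knob
therefore acts across isoforms: with 1, all events of a gene involve
disjoint exons; with ≥ 2, events in different isoforms may share an exon.
Event types are drawn independently from the configured proportions; a
draw that cannot be placed is resampled, and because greedy placement can
dead-end on small genes even when a feasible assignment exists, the whole
gene is retried (finally with a larger exon count) before the
configuration is declared infeasible. On the simplest design every type is
always placeable, so realised counts are exactly multinomial — the basis
of the χ² acceptance check.

Stock designs: S0 = {ES, IR, A5, A3} in equal proportions, 1 alternative
isoform, 1 event per transcript, 1 event per exon, error 0; S1 adds MES,
ALE, AFE; S2 = S1 with error 0.1 %; S3 = 2 events per transcript on
disjoint exons; S4 allows exon sharing; S5 = {ES, IR, A5, A3} with
caller-supplied proportions (they emulate proportions estimated from real
cohort data; without them, equal proportions). Designs with two events per
transcript use two alternative isoforms per gene, since exon sharing needs
at least two. Default scale is 200 genes — large enough for stable
proportions, small enough for CI.

Reads are single-end, length 76 by default, sampled uniformly over genes
with isoforms equiprobable within a gene and positions uniform along the
mature transcript; transcripts shorter than the read length are excluded.
Sequences come from a seeded synthetic base string; the per-base
substitution rate is the only error process (no indels, no quality model,
no expression model) and sequences are reported in the forward genomic
frame, so at error 0 the FASTQ equals the reference projection exactly.
What passing tests on this material shows is that the *pipeline logic* is
correct under known truth; it says nothing about tool behaviour on real
libraries with coverage biases, paralogy or annotation errors.

`corrupt_alignments` exists to give the mapping metrics analytically known
expectations: exact fractions (largest-remainder rounding, ties by
category order) of reads become unmapped or are shifted +1000 bp, so
u = 0.2, m = 0.1 on 100 reads must yield fraction_unmapped 0.200 and
precision 70/80 = 0.875 exactly.

## Normalisation rules

The gene is resolved by span containment (smallest span, then smallest
gene_id, on ties); junction records are classified against the *main*
isoform's splice sites — the same reference available in the truncated-
annotation setting:

* both junction ends annotated and ≥ 1 annotated exon strictly inside →
  ES/MES with those exons as blocks;
* exactly one end on an annotated intron boundary → A5/A3 (strand decides
  which), block = the interval between the competing splice sites,
  rejected if it leaves the gene span;
* retained flag with the anchor covering exactly one annotated intron →
  IR with that intron as block;
* neither end annotated → novel-junction rejection.

One additional gate is a deliberate design choice: the record's anchor
exon must itself match an annotated exon of the resolved gene (any
isoform). A junction-convention record whose anchor the annotation does
not contain is indistinguishable from a novel junction and is rejected as
one. With a full annotation the anchor of an IR or A5/A3 record is the
alternative exon, which is annotated, and the rules above apply verbatim;
with a main-isoform-only annotation those anchors are unknown, so IR and
alternative splice sites degrade while exon skipping (anchored on main
exons) survives — reproducing, in controlled form, the de-novo-detection
degradation observed for real tools. In this package's renderings the
degradation is complete (recall 0 for A5/A3/IR under the truncated
annotation) because every such record carries an alternative-exon anchor.

The A5/A3 "alternative part of an exon" is computed as the exonic
set-difference of the two splice-site variants, expressed as one closed
interval; this is the unique strand-symmetric choice and makes the mirror
test (reflecting gene and records through a pivot with strand flip) exact.
MEE cannot be expressed in the junction or flanking conventions without a
pairing protocol no tool agrees on; it enters only through the
direct-coordinate dialect with a claimed type.

## Matching

Candidates require equal chromosome and strand, equal effective types
(unless disabled), and block-wise agreement within the tolerance; partial
MES credit admits a reported single-block skip against one block of a
truth MES/MEE, consuming it. The assignment is a maximum bipartite
matching computed deterministically: a greedy pass over candidates sorted
by (exactness, deviation, chrom, start, truth id, reported id) is
completed with augmenting paths. Plain greedy in that order is *not*
always maximal once partial credit creates overlapping candidate sets
(duplicate reports of a block that also sits in a truth MES), and the
augmenting pass restores optimality without sacrificing reproducibility —
the result never depends on input file order. Truth events count once
regardless of block count; duplicate reports of a consumed truth event are
false positives. Undefined ratios (zero denominators) are reported as NA,
never as 0 or 1.

## Numerical and degenerate-input conventions

* Default tolerance is 0 bases: simulation and truth share one coordinate
  system, so exact comparison is meaningful.
* Reads absent from a SAM count as unmapped (some mappers drop reads
  rather than emit flag-4 records); only primary alignments vote.
* Mapping precision is reported junction-strict per read
  (`precision_read`, the headline number) and separately per junction
  (`precision_junction`), since "reads and junctions correct" can be
  pooled in more than one way.
* Single-block MES/MEE records are accepted (degenerate but real tool
  output); they collapse to ES under the default key.
* Empty event collections serialise to header-only files and read back as
  empty; single-exon transcripts have zero introns, not an error.
* All randomness flows through seeded generators (separate streams for
  annotation, reference sequence and reads), so equal configs give
  byte-identical GTF/TSV/SAM/FASTQ outputs.

## Validation strategy

An independent validator re-derives every truth event by diffing each
alternative isoform against the main isoform (missing internal runs → ES/
MES; an exact two-exon merge → IR; a one-boundary shift → A5/A3; a
disjoint terminal exon → AFE/ALE) and compares (transcript, type, blocks)
multisets with the truth table. It shares no code with event placement, so
agreement on every design is a genuine structural cross-check. MEE
re-derivation needs pairing across isoforms and is opt-in: with other
event types present, a pair of genuine adjacent exon skips in sibling
isoforms would be indistinguishable from MEE.

## Known limitations

* Paired-end reads, indel/quality error models, expression levels and
  fragment-length distributions are out of scope; all implemented metrics
  are coordinate-level.
* Native output parsers for specific tools are not included; the three
  dialect TSVs are this package's own exchange schemas.
* The truncated-annotation degradation is all-or-nothing per event type,
  sharper than the partial degradation real tools show.
* Consensus representatives inherit the record of the lexicographically
  smallest supporting tool label; no coordinate averaging is attempted.
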