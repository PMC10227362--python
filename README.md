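# splicebench

A benchmarking toolkit for alternative-splicing (AS) analysis of short-read
RNA-seq data. It addresses a practical obstacle in evaluating AS *event
detection* tools: every tool reports the same biological event in a
different coordinate convention, so results cannot be compared — to each
other or to a simulated ground truth — without a common format.

`splicebench` provides:

* a **unified event format** — one TSV row per event carrying the
  event-defining coordinates (skipped exon(s) for ES/MES/MEE, the retained
  intron for IR, the alternative part of an exon for A5/A3, the alternative
  first/last exon for AFE/ALE) plus gene name, chromosome, strand and a
  unique ID;
* **adapters** that normalise the three reporting conventions found in the
  wild (the event coordinates themselves; the flanking exons around a
  skipped exon; an anchor exon plus its splice junctions) into that format,
  using a gene model as the coordinate authority;
* a **synthetic ground-truth simulator** with six stock designs (S0–S5)
  that vary the event-type spectrum, events per transcript, events per
  exon and sequencing error rate, emitting GTF annotation, truth event and
  truth read tables, perfectly aligned SAM and FASTQ;
* **benchmark metrics**: for splice-aware mappers, the *fraction of
  unmapped reads* (unmapped / all simulated reads) and *precision*
  (correctly placed reads and junctions / mapped reads); for event
  detectors, *precision* and *recall* of unified calls against the truth,
  overall and per event type, with MES/MEE collapsible onto ES;
* **cross-tool analysis**: UpSet-style exclusive intersection counts and
  consensus calls (events supported by ≥ k of n tools).

Intended users are tool developers who want a reproducible desk-scale
harness and analysts who need to reconcile event calls from several tools.

## Core definitions

For a reported set R and truth set T, events are paired one-to-one by a
deterministic maximum matching over candidates with equal chromosome,
strand and (effective) type whose blocks agree within a tolerance
(default 0). Then

    recall    = |matched| / |T|
    precision = |matched| / |R|

A reported single-exon skip may consume one block of a truth multi-exon
skip ("partial MES credit"), which then counts as found once. For mapping,
a read is correct iff chromosome, every aligned block (from the CIGAR:
M/=/X/D extend a block, each N opens a junction) and every junction match
the truth.

## Worked example

Simulate the simplest design (S0: ES, IR, A5, A3 in equal proportions, one
event per transcript, no sequencing errors), express the truth the way two
tool families would report it, normalise, and benchmark:

```
$ splicebench simulate --preset S0 --genes 200 --reads 2000 --seed 1 --out sim
wrote 6 files across 1 replicate(s) to sim

$ splicebench normalize --annotation sim/rep1/annotation.gtf \
    --tool exoncalls=skipped_exon=skipped_exon.tsv \
    --tool junccalls=junction=junction.tsv --out out
normalised 2 tool file(s); 0 rejection(s)

$ splicebench bench-map --sam perfect=sim/rep1/reads.sam \
    --truth-reads sim/rep1/truth_reads.tsv --out map.tsv
  label  n_simulated  n_mapped  fraction_unmapped  precision_read  precision_junction
perfect         2000      2000                0.0             1.0                 1.0

$ splicebench bench-events --truth truth_unified.tsv \
    --tool exoncalls=out/unified_exoncalls.tsv \
    --tool junccalls=out/unified_junccalls.tsv --out metrics.tsv
    label  replicate event_type  n_truth  n_reported  n_correct  precision  recall
exoncalls          1        ALL      200         200        200        1.0     1.0
exoncalls          1         A3       56          56         56        1.0     1.0
exoncalls          1         A5       47          47         47        1.0     1.0
exoncalls          1         ES       45          45         45        1.0     1.0
exoncalls          1         IR       52          52         52        1.0     1.0
...
```

Reading the numbers: the simulated S0 truth holds 200 events (45 ES, 52 IR,
47 A5, 56 A3 for this seed); a perfectly aligned SAM maps every read to its
true blocks (fraction unmapped 0.0, precision 1.0); both dialect renderings
normalise back to exactly the truth coordinates, so event-level precision
and recall are 1.0 overall and per type. Repeating the benchmark on the
annotation truncated to main isoforms (`splicebench truncate`) makes the
annotation-dependent conversions fail in a characteristic way: exon
skipping survives, while IR and alternative splice sites are rejected as
novel junctions and their recall collapses — the behaviour real detectors
show when asked to find events de novo.

The first truth rows for this run look like:

```
event_id      gene_name  chrom    strand  event_type  blocks       source_tool  gene_id    transcript_id
SIMG00001.e1  SIMG00001  simchr1  +       A5          7730-7772    truth        SIMG00001  SIMG00001.t2
SIMG00002.e1  SIMG00002  simchr1  -       A3          17902-17947  truth        SIMG00002  SIMG00002.t2
```

See `docs/format.md` for the byte-exact file formats and `docs/methods.md`
for the simulation model, matching rules and their caveats.

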