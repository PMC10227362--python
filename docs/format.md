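# File formats

All files are plain TSV with a fixed header, `\n` line endings, no quoting
and no trailing whitespace. Coordinates are 1-based and inclusive on both
ends. Equal in-memory inputs always serialise to identical bytes.

## Unified event TSV (the flagship format)

Header (tab-separated, exactly):

```
event_id	gene_name	chrom	strand	event_type	blocks	source_tool
```

* `event_id` — unique within one file.
* `gene_name` — display name; `NA` when the producing record could not be
  assigned to a gene in lenient mode.
* `strand` — `+` or `-`.
* `event_type` — one of `ES`, `MES`, `MEE`, `IR`, `A5`, `A3`, `AFE`, `ALE`.
* `blocks` — the event-defining coordinates as `start-end` joined by `;`
  (e.g. `301-400;501-600`), sorted by start, pairwise disjoint:
  skipped exon(s) for ES/MES/MEE, the retained intron for IR, the
  alternative part of an exon for A5/A3, the alternative first/last exon
  for AFE/ALE. `ES`, `IR`, `A5`, `A3`, `AFE`, `ALE` carry exactly one
  block; `MES`/`MEE` carry one or more (normally ≥ 2).
* `source_tool` — free-text label of the producer.

Rows are sorted by (chrom, first block start, event_type, event_id).

Example:

```
event_id	gene_name	chrom	strand	event_type	blocks	source_tool
T1	G1	chr1	+	ES	301-400	truth
T2	G1	chr1	+	MES	301-400;501-600	truth
```

## Dialect input TSVs

One file per tool, one schema per reporting convention.

`skipped_exon` — the tool reports event-defining coordinates directly:

```
chrom	strand	blocks	claimed_type	gene
```

`blocks` uses the unified syntax above; `claimed_type` may be empty (then
one block ⇒ ES, several ⇒ MES) or any event type (the only way MEE enters);
`gene` is an optional hint.

`flanking_exons` — the tool reports the two annotated exons around a skip:

```
chrom	strand	up_start	up_end	down_start	down_end
```

`junction` — the tool reports an anchoring exon and junction(s):

```
chrom	strand	anchor_start	anchor_end	junctions	retained
```

`junctions` is `donor_end:acceptor_start` pairs joined by `;` (genomic
left < right; may be empty for retained records); `retained` is `0`/`1` —
`1` flags an intron-retention record whose anchor exon covers the intron.

## Truth tables

`truth_events.tsv` — unified columns plus two provenance columns
`gene_id` and `transcript_id` (the alternative isoform realising the
event).

`truth_reads.tsv`:

```
read_id	transcript_id	chrom	blocks	junctions
```

`blocks` as `start-end;...` (the read's true aligned segments, sorted);
`junctions` as `donor_end:acceptor_start;...`, exactly the gaps between
consecutive blocks (empty for single-block reads).

## Other outputs

* Annotation: Ensembl-dialect GTF; the main isoform carries a
  `main_transcript "true"` attribute so annotations round-trip.
* Alignments: plain SAM with an `@SQ` line for the synthetic chromosome;
  CIGARs of simulated reads use only `M` and `N`.
* Reads: FASTQ with constant `I` quality.
* Reports: mapping metrics TSV (label, n_simulated, n_mapped,
  fraction_unmapped, precision_read, precision_junction), event metrics
  TSV (label, replicate, event_type, n_truth, n_reported, n_correct,
  precision, recall) plus a `_summary` TSV with mean/std over replicates,
  intersection TSV (subset, n_tools, count), consensus TSV (unified
  columns + support + tools), rejection report TSV (row, dialect, reason,
  detail). Undefined ratios are written as `NA`.
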