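# Methods

## Data model

The unit of work is a `Genome`: an ordered list of sequences, each
carrying its gene models, plus an edit ledger. Gene models follow the
GFF3 hierarchy — `gene → transcript (mRNA, tRNA, …) → exon + CDS
segment` — with all coordinates 1-based inclusive. BED input is converted
at the boundary (`chromStart+1, chromEnd`); a BED region covering an
entire sequence is interpreted as whole-scaffold removal.

Structural invariants are enforced by `validate()` after every public
operation: unique IDs, features within sequence bounds, gene spans equal
to the union of child transcript spans, exons sorted and non-overlapping,
every CDS segment contained in an exon. An intron is the gap strictly
between consecutive exons (`next.start − prev.end − 1`); abutting exons
(gap 0) are reported as a warning, not an error, since a zero-length
intron is a representational oddity rather than an impossibility. Gene
spans are always re-derived from children after an edit and never trusted
to stay correct on their own.

Non-coding transcript types (tRNA, rRNA, ncRNA, …) are carried through as
transcripts with no CDS segments; CDS- and intron-length filters skip
them, exon and gene filters apply. Feature types outside the hierarchy
(e.g. `repeat_region`) pass through unmodified apart from coordinate
remapping.

## Filters

A filter is kind × bound × threshold × mode. Matching units: CDS rules
compare the **total spliced CDS length** of a transcript (the relevant
quantity for NCBI's ~150 bp coding-region floor), exon and intron rules
match any single element, gene rules the genomic span. Bounds use strict
inequality — "shorter than 10" spares an exact 10 — because that is what
the option names say; the boundary choice is otherwise arbitrary and is
frozen here.

An exon or intron match removes (or flags) the whole owning transcript:
excising one exon would leave a model that needs re-prediction, which is
out of scope. Gene rules act on the gene with all children. Flag mode
never changes structure; it appends a machine-readable token
(`intron_shorter_than_10`) to the feature's `gag_flag` attribute, and
tokens are deduplicated so re-applying a rule is a no-op. Only the
matched feature is flagged (a gene rule flags the gene, not its mRNAs);
the set of transcripts a flag rule marks is by construction the set the
corresponding remove rule would delete.

Removals funnel through two cascade helpers so that a gene emptied of
transcripts departs in the same ledger entry as its last transcript —
every removed ID appears in exactly one entry, and the removed-features
GFF (`genome.removed.gff`, original coordinates) plus the output GFF3
exactly partition the input IDs. Parsing the removed file back is
supported via an orphan-tolerant GFF3 mode (`orphan_parents="detach"`)
because a removed mRNA's parent gene may survive in the main output;
synthesized shell parents are tracked separately and never counted as
features of the file.

## Sequence edits

`fix_terminal_ns` strips maximal terminal runs of N/n (internal runs are
scaffold gaps and stay). `trim` excises merged BED intervals or deletes
whole scaffolds. Both rewrite coordinates through a per-sequence removed-
interval map (`new = old − bases removed before old`). The master
invariant, checked property-style in the tests, is base fidelity: the
substring at a surviving feature's new coordinates in the new FASTA
equals the substring at its old coordinates in the old FASTA.

Overlap policy differs deliberately between the two edits. A feature
overlapping a terminal-N run is truncated to the surviving region (the
overhang is all Ns, so nothing real is lost); a feature overlapping a
trim interval is removed whole and ledgered — a model truncated by a
contamination cut needs re-prediction, and the removed log tells the user
which ones. Features wholly inside a removed region are removed in both
cases. A sequence that is entirely N is dropped with a warning.

`fix_start_stop` reads the spliced CDS in transcript orientation
(reverse-complement on `-`), accepts `ATG` as the only start codon and
the stop set of the configured NCBI translation table (default table 1:
TAA/TAG/TGA; `--transl_table`), discards any pre-existing codon features,
then emits `start_codon`/`stop_codon` features over the terminal three
coding bases — split into two intervals when a codon straddles an intron.
An N in a terminal codon or a CDS shorter than one codon yields a warning
and no call. The booleans drive the feature table's partial markers. The
operation never changes sequence or exon/CDS coordinates.

## Statistics

`compute_stats` counts sequences, bases, genes, mRNAs (coding
transcripts), exons, CDS segments and introns, and summarizes min/mean/
max lengths per category (means to 1 decimal; empty categories print
`N/A`). `diff_stats` renders the fixed 19-row, two-column
original-vs-modified table written as `genome.stats`. The field list and
layout are this package's own frozen format.

## Feature table

Per sequence, a `>Feature <seq_id>` header; per gene a gene block with
`locus_tag` (`<prefix>_` + 6-digit ordinal in sequence order — required
by tbl2asn though absent from GFF3) and optional `gene` name; per
transcript an mRNA (or tRNA/…) block listing exon intervals and, for
coding transcripts, a CDS block listing segment intervals. The feature
key appears only on a block's first line. Minus-strand blocks are written
5'→3', high coordinate first on every line. Partial markers are placed on
the CDS block: `<` on the first coordinate iff no start codon, `>` on the
terminal coordinate iff no stop. `codon_start = phase+1` is emitted when
the 5'-most segment's phase is nonzero, `transl_table` when ≠ 1.
`product` qualifiers mirror between mRNA and CDS blocks; `Dbxref` and
`Ontology_term` values become `db_xref` qualifiers on the CDS, the
conventional tbl2asn representation for ontology terms. A structural
parser (`parse_tbl`) exists purely as the round-trip oracle for tests.

## Pipeline order

The CLI applies: harvest GFF3 annotations → `-a` table → terminal-N fix →
trim → length filters in command-line order → start/stop fix → outputs.
Trimming precedes filtering so filters judge final coordinates; codon
fixing runs last so codon features reflect the surviving models. The
order is a documented convention, not forced by the operations. Re-running
the pipeline with the same options on its own output is a fixed point for
the genome content (FASTA, GFF3, .tbl byte-identical; nothing newly
removed); the stats and removed-log outputs naturally reflect the second
run's empty edit set, and the session log is excluded from the
comparison.

## Synthetic genomes

The fixture generator builds scaffolds gene by gene: 1–3 exons (90–300 bp)
separated by 30–120 bp introns, 60–200 bp intergenic spacers, strands
mixed 50/50, CDS covering the exons with correct per-segment phases, a
designed coding sequence written into random background (ATG start,
in-frame body free of premature stops, stop-codon end). Configurable
fractions plant defects: one intron shortened below 10 bp, single-exon
genes with CDS total below 150 bp, GTG starts, non-stop ends, terminal-N
runs (5–30 bp), 10% extra isoforms (sharing the 5' structure, dropping
the 3' exon — their inherited/derived defect status is recorded too), 5%
tRNA genes. A planted-truth record lists exactly which models violate
which thresholds, and a generator test asserts the bookkeeping equals a
brute-force rescan. One integer seed drives all randomness; output is
byte-identical across runs. Default ranges were chosen as a compact
caricature of an insect-scale draft annotation.

What the generator does **not** emulate: overlapping or nested genes,
UTRs (CDS spans whole exons), alternative splicing beyond the one isoform
pattern, repeats, GC/codon-usage structure, assembly errors other than
terminal Ns. Passing tests therefore demonstrate the editing semantics
and format fidelity, not robustness to every pathology of real
annotations — though the readers reject structurally inconsistent input
loudly rather than guessing.

## Numerical / degenerate-input choices

- Thresholds are positive integers; filters use strict `<` / `>`.
- Means rounded half-even to 1 decimal in stats.
- Overlapping trim regions are merged (union) before application; a trim
  interval reaching the full sequence equals whole-scaffold removal.
- Empty genome → zero counts, `N/A` lengths, a `.tbl` with no headers,
  header-only GFF3 outputs.
- Duplicate FASTA IDs, features out of bounds, children with missing
  parents, malformed BED or annotation rows: hard errors naming the
  offender (exit 1 from the CLI).
- The whole session is deterministic: no timestamps in any output,
  locus tags ordinal in sequence order.

## Problem sizes in tests

The suite runs at desk scale: property tests use dozens of generated
genomes of 2 scaffolds × 6–10 genes; the end-to-end guarantees use a
5-scaffold × 100-gene genome (≥ 500 transcripts) and ~1100 base-fidelity
checks across 40 random trim scenarios. These sizes were picked as the
smallest that exercise every cascade and both strands while keeping the
whole suite around two seconds.

## Known limitations

- No ORF re-prediction: "correcting" a start/stop never extends a CDS to
  the next in-frame codon; models that fail detection are marked partial.
- Partial-overlap trim policy removes rather than truncates models.
- GTG/TTG alternative starts are not accepted even for tables where NCBI
  allows them.
- GFF2/GTF, embedded FASTA in GFF3, and compressed I/O are unsupported.
- tbl2asn itself (and the `.sqn` it produces) is outside scope; the
  `.tbl` is the hand-off point.
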