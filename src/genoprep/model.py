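"""In-memory genome + annotation hierarchy.

The object model mirrors the GFF3 gene -> mRNA -> exon/CDS hierarchy:
a :class:`Genome` holds ordered :class:`Sequence` records, each sequence
holds :class:`GeneModel` records, each gene holds :class:`Transcript`
records, and each transcript holds exon :class:`Interval` s and
:class:`CdsSegment` s.  All coordinates are 1-based inclusive (the GFF3
convention); BED input is converted at the I/O boundary.

Every editing operation in the package funnels removals through
:func:`remove_transcripts` / :func:`remove_genes` so that the
:class:`EditLedger` — the audit trail backing ``genome.removed.gff`` —
records each removed feature exactly once.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Iterator


# Canonical functional-annotation qualifier keys (GFF3 column-9 spelling).
ANNOTATION_KEYS = ("Name", "Dbxref", "Ontology_term", "product")

# Transcript types treated as coding-capable; everything else (tRNA, rRNA,
# ncRNA, ...) is carried through with empty cds_segments and skipped by
# CDS/intron length filters.
MRNA_TYPES = frozenset({"mRNA"})

TRANSCRIPT_TYPES = frozenset(
    {"mRNA", "tRNA", "rRNA", "ncRNA", "snRNA", "snoRNA", "miRNA", "transcript",
     "lnc_RNA", "pseudogenic_transcript"}
)


@dataclass(frozen=True)
class Interval:
    """Closed 1-based interval; all coordinate arithmetic lives here."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"interval start {self.start} > end {self.end}")
        if self.start < 1:
            raise ValueError(f"interval start {self.start} < 1")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def contains(self, other: "Interval") -> bool:
        return self.start <= other.start and other.end <= self.end

    def overlaps(self, other: "Interval") -> bool:
        return self.start <= other.end and other.start <= self.end

    def shifted(self, offset: int) -> "Interval":
        return Interval(self.start + offset, self.end + offset)


@dataclass
class CdsSegment:
    interval: Interval
    phase: int = 0

    def __post_init__(self) -> None:
        if self.phase not in (0, 1, 2):
            raise ValueError(f"CDS phase must be 0/1/2, got {self.phase}")


@dataclass
class Transcript:
    """One transcript (mRNA or non-coding) with its exon/CDS children.

    ``attributes`` holds functional qualifiers (Name, Dbxref, Ontology_term,
    product, plus any pass-through keys) as key -> list of values; ``flags``
    holds review-flag tokens serialized to the ``gag_flag`` GFF3 attribute.
    """

    mrna_id: str
    gene_id: str
    ttype: str = "mRNA"
    source: str = "."
    exons: list[Interval] = field(default_factory=list)
    cds_segments: list[CdsSegment] = field(default_factory=list)
    has_start_codon: bool = False
    has_stop_codon: bool = False
    start_codon_intervals: list[Interval] = field(default_factory=list)
    stop_codon_intervals: list[Interval] = field(default_factory=list)
    attributes: dict[str, list[str]] = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)

    @property
    def start(self) -> int:
        return min(e.start for e in self.exons)

    @property
    def end(self) -> int:
        return max(e.end for e in self.exons)

    @property
    def is_coding(self) -> bool:
        return bool(self.cds_segments)

    def cds_length(self) -> int:
        return sum(seg.interval.length for seg in self.cds_segments)

    def exon_lengths(self) -> list[int]:
        return [e.length for e in self.exons]

    def intron_lengths(self) -> list[int]:
        exons = sorted(self.exons, key=lambda e: e.start)
        return [
            exons[i + 1].start - exons[i].end - 1
            for i in range(len(exons) - 1)
        ]

    def add_flag(self, flag: str) -> None:
        if flag not in self.flags:
            self.flags.append(flag)

    def five_prime_phase(self, strand: str) -> int:
        """Phase of the 5'-most CDS segment given the gene's strand."""
        if not self.cds_segments:
            return 0
        segs = sorted(self.cds_segments, key=lambda s: s.interval.start)
        return segs[0].phase if strand == "+" else segs[-1].phase


@dataclass
class GeneModel:
    gene_id: str
    seq_id: str
    strand: str
    start: int
    end: int
    source: str = "."
    transcripts: list[Transcript] = field(default_factory=list)
    attributes: dict[str, list[str]] = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def add_flag(self, flag: str) -> None:
        if flag not in self.flags:
            self.flags.append(flag)

    def recompute_span(self) -> None:
        if self.transcripts:
            self.start = min(t.start for t in self.transcripts)
            self.end = max(t.end for t in self.transcripts)


@dataclass
class PassThroughRecord:
    """A GFF3 record of a feature type outside the gene-model hierarchy,
    preserved verbatim (minus coordinates, which follow sequence edits)."""

    seq_id: str
    source: str
    ftype: str
    interval: Interval
    score: str
    strand: str
    phase: str
    attributes: dict[str, list[str]] = field(default_factory=dict)


@dataclass
class Sequence:
    seq_id: str
    bases: str
    genes: list[GeneModel] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.bases) < 1:
            raise ValueError(f"sequence {self.seq_id} is empty")

    @property
    def length(self) -> int:
        return len(self.bases)

    def subseq(self, interval: Interval) -> str:
        return self.bases[interval.start - 1 : interval.end]


@dataclass
class RemovedFeature:
    """A fully detached removed gene or transcript, with original coordinates
    and enough parent context to round-trip to GFF3."""

    kind: str  # "gene" | "transcript"
    seq_id: str
    strand: str
    gene: GeneModel | None = None
    transcript: Transcript | None = None

    @property
    def feature_ids(self) -> list[str]:
        if self.kind == "gene":
            ids = [self.gene.gene_id]
            ids.extend(t.mrna_id for t in self.gene.transcripts)
            return ids
        return [self.transcript.mrna_id]


@dataclass
class LedgerEntry:
    operation: str
    params: dict
    feature_ids: list[str]


@dataclass
class EditLedger:
    """Ordered audit trail of the editing session."""

    entries: list[LedgerEntry] = field(default_factory=list)
    removed_features: list[RemovedFeature] = field(default_factory=list)

    def record(self, operation: str, params: dict, feature_ids: list[str],
               removed: list[RemovedFeature] | None = None) -> None:
        self.entries.append(LedgerEntry(operation, dict(params), list(feature_ids)))
        if removed:
            self.removed_features.extend(removed)

    def removed_ids(self) -> set[str]:
        out: set[str] = set()
        for rf in self.removed_features:
            out.update(rf.feature_ids)
        return out


@dataclass
class Genome:
    sequences: list[Sequence] = field(default_factory=list)
    edit_ledger: EditLedger = field(default_factory=EditLedger)
    pass_through: list[PassThroughRecord] = field(default_factory=list)
    # gene ids synthesized while parsing orphan transcripts (see
    # io.read_gff3 orphan_parents="detach"); not real features of the file
    shell_gene_ids: set[str] = field(default_factory=set)

    def sequence(self, seq_id: str) -> Sequence:
        for s in self.sequences:
            if s.seq_id == seq_id:
                return s
        raise KeyError(f"no sequence {seq_id!r} in genome")

    def seq_ids(self) -> list[str]:
        return [s.seq_id for s in self.sequences]

    def genes(self) -> Iterator[GeneModel]:
        for s in self.sequences:
            yield from s.genes

    def transcripts(self) -> Iterator[tuple[GeneModel, Transcript]]:
        for g in self.genes():
            for t in g.transcripts:
                yield g, t

    def feature_ids(self) -> set[str]:
        ids: set[str] = set()
        for g in self.genes():
            ids.add(g.gene_id)
            ids.update(t.mrna_id for t in g.transcripts)
        return ids


# ---------------------------------------------------------------------------
# Validation


def validate(genome: Genome) -> list[str]:
    """Check every structural invariant; return human-readable violations.

    An empty list means the genome is well formed.  Abutting exons (zero-gap
    "introns") are reported as warnings prefixed ``warning:`` and do not, on
    their own, make the genome invalid.
    """
    violations: list[str] = []
    seen_seq: set[str] = set()
    seen_gene: set[str] = set()
    seen_mrna: set[str] = set()
    for seq in genome.sequences:
        if seq.seq_id in seen_seq:
            violations.append(f"duplicate sequence id {seq.seq_id}")
        seen_seq.add(seq.seq_id)
        if len(seq.bases) < 1:
            violations.append(f"sequence {seq.seq_id} is empty")
        for gene in seq.genes:
            if gene.gene_id in seen_gene:
                violations.append(f"duplicate gene id {gene.gene_id}")
            seen_gene.add(gene.gene_id)
            if gene.seq_id != seq.seq_id:
                violations.append(
                    f"gene {gene.gene_id} claims seq {gene.seq_id} "
                    f"but lives on {seq.seq_id}")
            if gene.start > gene.end:
                violations.append(f"gene {gene.gene_id}: end < start")
                continue
            if gene.start < 1 or gene.end > seq.length:
                violations.append(
                    f"gene {gene.gene_id} interval ({gene.start},{gene.end}) "
                    f"outside [1,{seq.length}] of {seq.seq_id}")
            if gene.strand not in ("+", "-"):
                violations.append(f"gene {gene.gene_id}: bad strand {gene.strand!r}")
            if not gene.transcripts:
                violations.append(f"gene {gene.gene_id} has no transcripts")
                continue
            child_start = min(t.start for t in gene.transcripts)
            child_end = max(t.end for t in gene.transcripts)
            if (gene.start, gene.end) != (child_start, child_end):
                violations.append(
                    f"gene {gene.gene_id} span ({gene.start},{gene.end}) != "
                    f"union of transcript spans ({child_start},{child_end})")
            for t in gene.transcripts:
                if t.mrna_id in seen_mrna:
                    violations.append(f"duplicate transcript id {t.mrna_id}")
                seen_mrna.add(t.mrna_id)
                violations.extend(_validate_transcript(t))
    return violations


def _validate_transcript(t: Transcript) -> list[str]:
    out: list[str] = []
    if not t.exons:
        out.append(f"transcript {t.mrna_id} has no exons")
        return out
    exons = sorted(t.exons, key=lambda e: e.start)
    for a, b in zip(exons, exons[1:]):
        gap = b.start - a.end - 1
        if gap < 0:
            out.append(f"transcript {t.mrna_id}: overlapping exons "
                       f"({a.start},{a.end}) and ({b.start},{b.end})")
        elif gap == 0:
            out.append(f"warning: transcript {t.mrna_id}: abutting exons at "
                       f"{a.end}/{b.start} (zero-length intron)")
    for seg in t.cds_segments:
        if not any(e.contains(seg.interval) for e in t.exons):
            out.append(
                f"transcript {t.mrna_id}: CDS segment "
                f"({seg.interval.start},{seg.interval.end}) not contained "
                f"in any exon")
    return out


def is_valid(genome: Genome) -> bool:
    """True when :func:`validate` reports nothing worse than warnings."""
    return all(v.startswith("warning:") for v in validate(genome))


# ---------------------------------------------------------------------------
# Length queries


def feature_lengths(t: Transcript) -> tuple[int, list[int], list[int]]:
    """Return ``(cds_length, exon_lengths, intron_lengths)`` for a transcript.

    The intron between consecutive exons ``i`` and ``i+1`` has length
    ``exons[i+1].start - exons[i].end - 1``; a single-exon transcript has an
    empty intron list.
    """
    return t.cds_length(), t.exon_lengths(), t.intron_lengths()


# ---------------------------------------------------------------------------
# Cascade maintenance


def rebuild_spans(genome: Genome, operation: str = "rebuild_spans",
                  params: dict | None = None) -> Genome:
    """Re-derive every gene span from its surviving transcripts.

    Genes left with zero transcripts are removed and logged to the ledger
    (parent/child consistency: removing a gene's last mRNA removes the gene).
    Idempotent.
    """
    emptied: list[RemovedFeature] = []
    for seq in genome.sequences:
        kept: list[GeneModel] = []
        for gene in seq.genes:
            if gene.transcripts:
                gene.recompute_span()
                kept.append(gene)
            else:
                emptied.append(RemovedFeature(
                    kind="gene", seq_id=seq.seq_id, strand=gene.strand,
                    gene=gene))
        seq.genes = kept
    if emptied:
        genome.edit_ledger.record(
            operation, params or {},
            [fid for rf in emptied for fid in rf.feature_ids],
            removed=emptied)
    return genome


def remove_transcripts(genome: Genome, doomed: set[str], operation: str,
                       params: dict | None = None) -> list[str]:
    """Remove transcripts by mRNA id, cascading: a gene whose last transcript
    is removed goes with it.  Each removed feature id is ledgered exactly once
    (the emptied gene joins the same ledger entry as its last transcript).
    Returns the removed feature ids."""
    if not doomed:
        return []
    removed: list[RemovedFeature] = []
    for seq in genome.sequences:
        kept_genes: list[GeneModel] = []
        for gene in seq.genes:
            hit = [t for t in gene.transcripts if t.mrna_id in doomed]
            if not hit:
                kept_genes.append(gene)
                continue
            gene.transcripts = [t for t in gene.transcripts
                                if t.mrna_id not in doomed]
            if gene.transcripts:
                gene.recompute_span()
                kept_genes.append(gene)
                for t in hit:
                    removed.append(RemovedFeature(
                        kind="transcript", seq_id=seq.seq_id,
                        strand=gene.strand, transcript=t))
            else:
                # cascade: detach the whole gene, original span preserved
                shell = copy.copy(gene)
                shell.transcripts = hit
                removed.append(RemovedFeature(
                    kind="gene", seq_id=seq.seq_id, strand=gene.strand,
                    gene=shell))
        seq.genes = kept_genes
    ids = [fid for rf in removed for fid in rf.feature_ids]
    if removed:
        genome.edit_ledger.record(operation, params or {}, ids, removed=removed)
    return ids


def remove_genes(genome: Genome, doomed: set[str], operation: str,
                 params: dict | None = None) -> list[str]:
    """Remove genes by id with all their children; ledger each once."""
    if not doomed:
        return []
    removed: list[RemovedFeature] = []
    for seq in genome.sequences:
        kept: list[GeneModel] = []
        for gene in seq.genes:
            if gene.gene_id in doomed:
                removed.append(RemovedFeature(
                    kind="gene", seq_id=seq.seq_id, strand=gene.strand,
                    gene=gene))
            else:
                kept.append(gene)
        seq.genes = kept
    ids = [fid for rf in removed for fid in rf.feature_ids]
    if removed:
        genome.edit_ledger.record(operation, params or {}, ids, removed=removed)
    return ids
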