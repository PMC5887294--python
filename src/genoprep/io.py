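"""Readers and writers: FASTA, GFF3, BED3, and the tab-delimited
functional-annotation table.

GFF3 line parsing (column split, attribute decoding, multi-value commas)
is delegated to :func:`gffutils.feature.feature_from_line`; hierarchy
assembly is a two-pass build over Parent/ID links so child-before-parent
line order is accepted.  Writing percent-encodes the GFF3 reserved
characters in attribute values.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

from Bio import SeqIO
from Bio.SeqIO.FastaIO import FastaWriter
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from gffutils.feature import feature_from_line

from .model import (
    TRANSCRIPT_TYPES,
    CdsSegment,
    GeneModel,
    Genome,
    Interval,
    PassThroughRecord,
    RemovedFeature,
    Sequence,
    Transcript,
)
from .edits import TrimRegion

FLAG_ATTRIBUTE = "gag_flag"
GFF_VERSION_PRAGMA = "##gff-version 3"

_CHILD_TYPES = frozenset({"exon", "CDS", "start_codon", "stop_codon"})


class FormatError(ValueError):
    """Malformed or inconsistent input file."""


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | os.PathLike) -> list[Sequence]:
    """Load a FASTA file into :class:`Sequence` records, order preserved.

    The sequence id is the header token up to the first whitespace; case of
    the bases is preserved.  Duplicate ids and empty sequences are hard
    errors.
    """
    with open(path) as fh:
        first = fh.read(1)
        while first and first.isspace():
            first = fh.read(1)
        if first != ">":
            raise FormatError(f"{path}: not a FASTA file (no '>' header)")
    sequences: list[Sequence] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        bases = str(rec.seq)
        if not bases:
            raise FormatError(f"{path}: sequence {rec.id!r} is empty")
        sequences.append(Sequence(seq_id=rec.id, bases=bases))
    return sequences


def write_fasta(sequences: list[Sequence], path: str | os.PathLike,
                line_width: int = 80) -> None:
    """Write sequences as wrapped FASTA (default 80 columns)."""
    records = [SeqRecord(Seq(s.bases), id=s.seq_id, description="")
               for s in sequences]
    with open(path, "w") as fh:
        FastaWriter(fh, wrap=line_width).write_file(records)


# ---------------------------------------------------------------------------
# GFF3


def _encode_value(value: str) -> str:
    """Percent-encode GFF3 reserved characters inside an attribute value."""
    out = value.replace("%", "%25")
    for ch, code in (("\t", "%09"), ("\n", "%0A"), (";", "%3B"),
                     ("=", "%3D"), ("&", "%26"), (",", "%2C")):
        out = out.replace(ch, code)
    return out


def _format_attributes(pairs: list[tuple[str, list[str]]]) -> str:
    parts = []
    for key, values in pairs:
        if not values:
            continue
        parts.append(f"{key}=" + ",".join(_encode_value(v) for v in values))
    return ";".join(parts) if parts else "."


def read_gff3(path: str | os.PathLike, sequences: list[Sequence],
              orphan_parents: str = "error") -> Genome:
    """Assemble a :class:`Genome` from a GFF3 file.

    Two-pass parse: features are first indexed by ID, then linked through
    Parent attributes, so line order (children before parents) is irrelevant.
    Multiple CDS lines sharing a Parent merge into that transcript's
    ``cds_segments``.  Feature types outside the gene/transcript/exon/CDS
    hierarchy are preserved verbatim for pass-through.

    ``orphan_parents`` controls transcripts whose Parent gene is absent:
    ``"error"`` (default) raises; ``"detach"`` synthesizes a shell gene
    carrying the Parent's id and records it in ``genome.shell_gene_ids`` —
    needed to parse back ``genome.removed.gff``, where a removed mRNA's
    parent gene may itself survive in the main annotation.
    """
    if orphan_parents not in ("error", "detach"):
        raise ValueError(f"bad orphan_parents {orphan_parents!r}")
    genome = Genome(sequences=sequences)
    seq_len = {s.seq_id: s.length for s in sequences}

    genes: dict[str, GeneModel] = {}
    transcripts: dict[str, Transcript] = {}
    children: list = []  # (feature, parents) for exon/CDS/codon rows
    orphan_transcripts: list = []

    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            try:
                feat = feature_from_line(line)
            except Exception as exc:
                raise FormatError(f"{path}:{lineno}: bad GFF3 line: {exc}") from exc
            if feat.seqid not in seq_len:
                raise FormatError(
                    f"{path}:{lineno}: feature on unknown sequence "
                    f"{feat.seqid!r}")
            if feat.start < 1 or feat.end > seq_len[feat.seqid]:
                raise FormatError(
                    f"{path}:{lineno}: feature ({feat.start},{feat.end}) out "
                    f"of bounds [1,{seq_len[feat.seqid]}] on {feat.seqid}")
            attrs = {k: list(v) for k, v in feat.attributes.items()}
            fid = attrs.pop("ID", [None])[0]
            parents = attrs.pop("Parent", [])
            flags = attrs.pop(FLAG_ATTRIBUTE, [])

            if feat.featuretype == "gene":
                if fid is None:
                    raise FormatError(f"{path}:{lineno}: gene without ID")
                genes[fid] = GeneModel(
                    gene_id=fid, seq_id=feat.seqid, strand=feat.strand,
                    start=feat.start, end=feat.end, source=feat.source,
                    attributes=attrs, flags=list(flags))
            elif feat.featuretype in TRANSCRIPT_TYPES:
                if fid is None:
                    raise FormatError(
                        f"{path}:{lineno}: {feat.featuretype} without ID")
                t = Transcript(
                    mrna_id=fid, gene_id=parents[0] if parents else "",
                    ttype=feat.featuretype, source=feat.source,
                    attributes=attrs, flags=list(flags))
                transcripts[fid] = t
                orphan_transcripts.append(
                    (t, parents, lineno, feat.seqid, feat.strand,
                     feat.start, feat.end))
            elif feat.featuretype in _CHILD_TYPES:
                if not parents:
                    raise FormatError(
                        f"{path}:{lineno}: {feat.featuretype} without Parent")
                children.append((feat, parents, lineno))
            else:
                genome.pass_through.append(PassThroughRecord(
                    seq_id=feat.seqid, source=feat.source,
                    ftype=feat.featuretype,
                    interval=Interval(feat.start, feat.end),
                    score=feat.score, strand=feat.strand, phase=feat.frame,
                    attributes={**({"ID": [fid]} if fid else {}),
                                **({"Parent": parents} if parents else {}),
                                **attrs}))

    # link transcripts to genes
    for t, parents, lineno, seqid, strand, start, end in orphan_transcripts:
        if not parents:
            raise FormatError(
                f"{path}: transcript {t.mrna_id} (line {lineno}) has no Parent")
        pid = parents[0]
        if pid not in genes:
            if orphan_parents == "error":
                raise FormatError(
                    f"{path}: transcript {t.mrna_id} (line {lineno}) "
                    f"references missing Parent {pid!r}")
            genes[pid] = GeneModel(
                gene_id=pid, seq_id=seqid, strand=strand, start=start,
                end=end, source=t.source)
            genome.shell_gene_ids.add(pid)
        t.gene_id = pid
        genes[pid].transcripts.append(t)

    # attach exon/CDS/codon rows
    for feat, parents, lineno in children:
        for pid in parents:
            if pid not in transcripts:
                raise FormatError(
                    f"{path}: {feat.featuretype} at line {lineno} references "
                    f"missing Parent {pid!r}")
            t = transcripts[pid]
            iv = Interval(feat.start, feat.end)
            if feat.featuretype == "exon":
                t.exons.append(iv)
            elif feat.featuretype == "CDS":
                phase = int(feat.frame) if feat.frame in ("0", "1", "2") else 0
                t.cds_segments.append(CdsSegment(interval=iv, phase=phase))
            elif feat.featuretype == "start_codon":
                t.start_codon_intervals.append(iv)
                t.has_start_codon = True
            else:
                t.stop_codon_intervals.append(iv)
                t.has_stop_codon = True

    for t in transcripts.values():
        t.exons.sort(key=lambda e: e.start)
        t.cds_segments.sort(key=lambda s: s.interval.start)
        t.start_codon_intervals.sort(key=lambda i: i.start)
        t.stop_codon_intervals.sort(key=lambda i: i.start)

    for pid in genome.shell_gene_ids:
        genes[pid].recompute_span()

    by_seq: dict[str, list[GeneModel]] = {s.seq_id: [] for s in sequences}
    for g in genes.values():
        by_seq[g.seq_id].append(g)
    for s in sequences:
        s.genes = sorted(by_seq[s.seq_id], key=lambda g: (g.start, g.gene_id))
    return genome


def _gff_line(seq_id: str, source: str, ftype: str, start: int, end: int,
              score: str, strand: str, phase: str,
              attr_pairs: list[tuple[str, list[str]]]) -> str:
    return "\t".join([seq_id, source, ftype, str(start), str(end), score,
                      strand, phase, _format_attributes(attr_pairs)])


def _transcript_lines(seq_id: str, strand: str, t: Transcript) -> list[str]:
    lines = []
    pairs = [("ID", [t.mrna_id]), ("Parent", [t.gene_id])]
    pairs += [(k, v) for k, v in t.attributes.items()]
    if t.flags:
        pairs.append((FLAG_ATTRIBUTE, t.flags))
    lines.append(_gff_line(seq_id, t.source, t.ttype, t.start, t.end, ".",
                           strand, ".", pairs))
    for exon in t.exons:
        lines.append(_gff_line(seq_id, t.source, "exon", exon.start, exon.end,
                               ".", strand, ".", [("Parent", [t.mrna_id])]))
    for seg in t.cds_segments:
        lines.append(_gff_line(
            seq_id, t.source, "CDS", seg.interval.start, seg.interval.end,
            ".", strand, str(seg.phase),
            [("ID", [f"cds-{t.mrna_id}"]), ("Parent", [t.mrna_id])]))
    for iv in t.start_codon_intervals:
        lines.append(_gff_line(seq_id, t.source, "start_codon", iv.start,
                               iv.end, ".", strand, "0",
                               [("Parent", [t.mrna_id])]))
    for iv in t.stop_codon_intervals:
        lines.append(_gff_line(seq_id, t.source, "stop_codon", iv.start,
                               iv.end, ".", strand, "0",
                               [("Parent", [t.mrna_id])]))
    return lines


def _gene_lines(gene: GeneModel) -> list[str]:
    pairs = [("ID", [gene.gene_id])]
    pairs += [(k, v) for k, v in gene.attributes.items()]
    if gene.flags:
        pairs.append((FLAG_ATTRIBUTE, gene.flags))
    lines = [_gff_line(gene.seq_id, gene.source, "gene", gene.start, gene.end,
                       ".", gene.strand, ".", pairs)]
    for t in gene.transcripts:
        lines.extend(_transcript_lines(gene.seq_id, gene.strand, t))
    return lines


def write_gff3(genome: Genome, path: str | os.PathLike) -> None:
    """Serialize the genome's annotation to GFF3 (round-trips the model)."""
    with open(path, "w") as fh:
        fh.write(GFF_VERSION_PRAGMA + "\n")
        for seq in genome.sequences:
            for gene in seq.genes:
                for line in _gene_lines(gene):
                    fh.write(line + "\n")
            for rec in genome.pass_through:
                if rec.seq_id != seq.seq_id:
                    continue
                pairs = [(k, v) for k, v in rec.attributes.items()]
                fh.write(_gff_line(
                    rec.seq_id, rec.source, rec.ftype, rec.interval.start,
                    rec.interval.end, rec.score, rec.strand, rec.phase,
                    pairs) + "\n")


def write_removed_gff3(removed: list[RemovedFeature],
                       path: str | os.PathLike) -> None:
    """Write the removed-features log as GFF3 with ORIGINAL coordinates."""
    with open(path, "w") as fh:
        fh.write(GFF_VERSION_PRAGMA + "\n")
        for rf in removed:
            if rf.kind == "gene":
                for line in _gene_lines(rf.gene):
                    fh.write(line + "\n")
            else:
                for line in _transcript_lines(rf.seq_id, rf.strand,
                                              rf.transcript):
                    fh.write(line + "\n")


# ---------------------------------------------------------------------------
# BED


def read_bed(path: str | os.PathLike,
             sequences: list[Sequence]) -> list[TrimRegion]:
    """Read BED3 trim regions, converting 0-based half-open to 1-based
    inclusive.  A region spanning an entire sequence marks whole-sequence
    removal."""
    seq_len = {s.seq_id: s.length for s in sequences}
    regions: list[TrimRegion] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise FormatError(
                    f"{path}:{lineno}: BED line needs >= 3 columns")
            chrom, s_raw, e_raw = cols[0], cols[1], cols[2]
            if chrom not in seq_len:
                raise FormatError(
                    f"{path}:{lineno}: unknown sequence {chrom!r}")
            try:
                chrom_start, chrom_end = int(s_raw), int(e_raw)
            except ValueError as exc:
                raise FormatError(
                    f"{path}:{lineno}: non-integer coordinates") from exc
            if chrom_end <= chrom_start or chrom_start < 0:
                raise FormatError(
                    f"{path}:{lineno}: empty or negative interval "
                    f"[{chrom_start},{chrom_end})")
            if chrom_end > seq_len[chrom]:
                raise FormatError(
                    f"{path}:{lineno}: interval end {chrom_end} exceeds "
                    f"length {seq_len[chrom]} of {chrom}")
            interval = Interval(chrom_start + 1, chrom_end)
            regions.append(TrimRegion(
                seq_id=chrom, interval=interval,
                whole_sequence=(interval.start == 1
                                and interval.end == seq_len[chrom])))
    return regions


# ---------------------------------------------------------------------------
# Functional-annotation table


_CANONICAL_KEYS = {"name": "Name", "dbxref": "Dbxref",
                   "ontology_term": "Ontology_term", "product": "product"}


@dataclass
class AnnotationRow:
    feature_id: str
    key: str  # canonical: Name | Dbxref | Ontology_term | product
    value: str


def read_annotation_table(path: str | os.PathLike) -> list[AnnotationRow]:
    """Read the 3-column tab-delimited annotation file.

    Columns: feature id, key, value.  Keys are matched case-insensitively
    against the supported set (Name, Dbxref, Ontology_term, product) and
    normalized to canonical GFF3 spelling; anything else is an error naming
    the key and line.  Repeated rows for one feature/key accumulate.
    """
    rows: list[AnnotationRow] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) != 3:
                raise FormatError(
                    f"{path}:{lineno}: expected 3 tab-separated columns, "
                    f"got {len(cols)}")
            fid, key, value = cols
            canonical = _CANONICAL_KEYS.get(key.lower())
            if canonical is None:
                raise FormatError(
                    f"{path}:{lineno}: unsupported annotation key {key!r}")
            rows.append(AnnotationRow(feature_id=fid, key=canonical,
                                      value=value))
    return rows
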