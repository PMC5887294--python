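"""NCBI feature-table (.tbl) writer, plus a structural parser used as a
round-trip oracle in tests.

Format: one ``>Feature <seq_id>`` header per sequence; each feature is a
block of tab-separated coordinate lines (the feature key only on the
first line) followed by qualifier lines (three empty fields, qualifier,
value).  Minus-strand intervals are written 5'->3', i.e. high coordinate
first on every line.  A CDS lacking its start codon gets ``<`` on the
first coordinate (5'-partial); one lacking its stop codon gets ``>`` on
the terminal coordinate (3'-partial).  ``codon_start`` is emitted when
the 5'-most segment's phase is nonzero.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

from .model import GeneModel, Genome, Interval, Transcript


def _oriented(intervals: list[Interval], strand: str) -> list[tuple[int, int]]:
    """Interval endpoints in transcript orientation: ascending (start,end)
    pairs on '+', descending (end,start) pairs on '-'."""
    ordered = sorted(intervals, key=lambda i: i.start)
    if strand == "-":
        return [(i.end, i.start) for i in reversed(ordered)]
    return [(i.start, i.end) for i in ordered]


def _block(pairs: list[tuple[int, int]], key: str,
           partial5: bool = False, partial3: bool = False) -> list[str]:
    lines = []
    for idx, (a, b) in enumerate(pairs):
        first = f"{'<' if partial5 and idx == 0 else ''}{a}"
        last = f"{'>' if partial3 and idx == len(pairs) - 1 else ''}{b}"
        lines.append(f"{first}\t{last}\t{key}" if idx == 0
                     else f"{first}\t{last}")
    return lines


def _qual(key: str, value: str) -> str:
    return f"\t\t\t{key}\t{value}"


def _gene_block(gene: GeneModel, locus_tag: str) -> list[str]:
    a, b = ((gene.end, gene.start) if gene.strand == "-"
            else (gene.start, gene.end))
    lines = [f"{a}\t{b}\tgene"]
    for name in gene.attributes.get("Name", []):
        lines.append(_qual("gene", name))
    lines.append(_qual("locus_tag", locus_tag))
    return lines


def _transcript_blocks(gene: GeneModel, t: Transcript, locus_tag: str,
                       transl_table: int) -> list[str]:
    lines: list[str] = []
    products = t.attributes.get("product", [])
    xrefs = (t.attributes.get("Dbxref", [])
             + t.attributes.get("Ontology_term", []))

    lines.extend(_block(_oriented(t.exons, gene.strand), t.ttype))
    for p in products:
        lines.append(_qual("product", p))

    if t.cds_segments:
        pairs = _oriented([s.interval for s in t.cds_segments], gene.strand)
        lines.extend(_block(pairs, "CDS",
                            partial5=not t.has_start_codon,
                            partial3=not t.has_stop_codon))
        for p in products:
            lines.append(_qual("product", p))
        phase = t.five_prime_phase(gene.strand)
        if phase != 0:
            lines.append(_qual("codon_start", str(phase + 1)))
        if transl_table != 1:
            lines.append(_qual("transl_table", str(transl_table)))
        for x in xrefs:
            lines.append(_qual("db_xref", x))
    else:
        for x in xrefs:
            lines.append(_qual("db_xref", x))
    return lines


def write_tbl(genome: Genome, path: str | os.PathLike,
              locus_tag_prefix: str = "GP", transl_table: int = 1) -> str:
    """Write the genome as an NCBI feature table.

    Locus tags are ``<prefix>_`` plus a 6-digit ordinal assigned in
    sequence order.  Every gene yields a gene block; every transcript an
    mRNA (or tRNA/...) block and, when coding, a CDS block.
    """
    ordinal = 0
    with open(path, "w") as fh:
        for seq in genome.sequences:
            fh.write(f">Feature {seq.seq_id}\n")
            for gene in seq.genes:
                ordinal += 1
                tag = f"{locus_tag_prefix}_{ordinal:06d}"
                for line in _gene_block(gene, tag):
                    fh.write(line + "\n")
                for t in gene.transcripts:
                    for line in _transcript_blocks(gene, t, tag, transl_table):
                        fh.write(line + "\n")
    return str(path)


# ---------------------------------------------------------------------------
# Structural parser (round-trip oracle)


@dataclass
class TblFeature:
    key: str
    coords: list[tuple[str, str]] = field(default_factory=list)
    qualifiers: list[tuple[str, str]] = field(default_factory=list)

    def coord_ints(self) -> list[tuple[int, int]]:
        return [(int(a.lstrip("<>")), int(b.lstrip("<>")))
                for a, b in self.coords]

    @property
    def partial5(self) -> bool:
        return bool(self.coords) and self.coords[0][0].startswith("<")

    @property
    def partial3(self) -> bool:
        return bool(self.coords) and self.coords[-1][1].startswith(">")


def parse_tbl(path: str | os.PathLike) -> dict[str, list[TblFeature]]:
    """Parse a feature table back into per-sequence feature blocks.

    Returns ``{seq_id: [TblFeature, ...]}`` with coordinate strings kept
    verbatim (so partial markers are inspectable) and qualifier lines
    re-associated with the preceding block.  Raises on malformed lines.
    """
    result: dict[str, list[TblFeature]] = {}
    current_seq: str | None = None
    current: TblFeature | None = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line:
                continue
            if line.startswith(">Feature"):
                parts = line.split(None, 1)
                if len(parts) != 2:
                    raise ValueError(f"{path}:{lineno}: bad Feature header")
                current_seq = parts[1].strip()
                result[current_seq] = []
                current = None
                continue
            if current_seq is None:
                raise ValueError(f"{path}:{lineno}: data before >Feature")
            cols = line.split("\t")
            if len(cols) == 5 and cols[0] == cols[1] == cols[2] == "":
                if current is None:
                    raise ValueError(
                        f"{path}:{lineno}: qualifier with no feature")
                current.qualifiers.append((cols[3], cols[4]))
            elif len(cols) == 3:
                current = TblFeature(key=cols[2], coords=[(cols[0], cols[1])])
                result[current_seq].append(current)
            elif len(cols) == 2:
                if current is None:
                    raise ValueError(
                        f"{path}:{lineno}: continuation with no feature")
                current.coords.append((cols[0], cols[1]))
            else:
                raise ValueError(f"{path}:{lineno}: malformed line {line!r}")
    return result
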