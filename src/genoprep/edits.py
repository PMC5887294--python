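"""Edits that change sequence and annotation together.

Three operations: ``fix_start_stop`` (detect/emit start and stop codon
features from the actual CDS sequence), ``fix_terminal_ns`` (strip runs of
ambiguous bases from contig ends), and ``trim`` (excise BED-specified
regions or whole scaffolds).  The latter two rewrite coordinates through a
:class:`CoordinateMap` so the FASTA and GFF3 outputs stay synchronized:
the master invariant is that the bases under any surviving feature are
identical before and after the edit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from Bio.Data import CodonTable
from Bio.Seq import Seq

from .model import (
    GeneModel,
    Genome,
    Interval,
    RemovedFeature,
    Transcript,
    rebuild_spans,
)

log = logging.getLogger(__name__)

START_CODONS = frozenset({"ATG"})


def stop_codons(transl_table: int = 1) -> frozenset[str]:
    """Stop codons of an NCBI translation table (default: standard code)."""
    table = CodonTable.unambiguous_dna_by_id[transl_table]
    return frozenset(table.stop_codons)


@dataclass
class TrimRegion:
    """A region to excise, already in model coordinates (1-based inclusive)."""

    seq_id: str
    interval: Interval
    whole_sequence: bool = False


@dataclass
class CoordinateMap:
    """Old -> new coordinates after removing intervals from sequences.

    For a surviving position, new = old − (bases removed before old);
    positions inside a removed interval map to ``None``.
    """

    removed: dict[str, list[Interval]] = field(default_factory=dict)

    def add(self, seq_id: str, intervals: list[Interval]) -> None:
        merged = merge_intervals(self.removed.get(seq_id, []) + intervals)
        self.removed[seq_id] = merged

    def removed_before(self, seq_id: str, pos: int) -> int:
        total = 0
        for iv in self.removed.get(seq_id, []):
            if iv.end < pos:
                total += iv.length
            elif iv.start <= pos:
                return -1  # inside a removed interval: sentinel
            else:
                break
        return total

    def map_position(self, seq_id: str, pos: int) -> int | None:
        before = self.removed_before(seq_id, pos)
        return None if before < 0 else pos - before

    def map_interval(self, seq_id: str, iv: Interval) -> Interval | None:
        """Map an interval that does not overlap any removed region; returns
        None when it does (callers decide removal/truncation policy)."""
        for rm in self.removed.get(seq_id, []):
            if rm.overlaps(iv):
                return None
        shift = self.removed_before(seq_id, iv.start)
        return iv.shifted(-shift)


def merge_intervals(intervals: list[Interval]) -> list[Interval]:
    """Union of closed intervals: sorted, overlapping/abutting ones merged."""
    if not intervals:
        return []
    ordered = sorted(intervals, key=lambda i: (i.start, i.end))
    merged = [ordered[0]]
    for iv in ordered[1:]:
        last = merged[-1]
        if iv.start <= last.end + 1:
            merged[-1] = Interval(last.start, max(last.end, iv.end))
        else:
            merged.append(iv)
    return merged


# ---------------------------------------------------------------------------
# fix_start_stop


def _edge_positions(segments: list[Interval], strand: str, n: int,
                    from_five_prime: bool) -> list[int]:
    """Genomic positions of the first (or last) *n* coding bases, walking the
    CDS segments in transcript orientation."""
    pieces = sorted(segments, key=lambda s: s.start)
    ascending = (strand == "+") == from_five_prime
    if not ascending:
        pieces = pieces[::-1]
    out: list[int] = []
    for piece in pieces:
        rng = (range(piece.start, piece.end + 1) if ascending
               else range(piece.end, piece.start - 1, -1))
        for pos in rng:
            out.append(pos)
            if len(out) == n:
                return out
    return out


def _positions_to_intervals(positions: list[int]) -> list[Interval]:
    pts = sorted(positions)
    intervals: list[Interval] = []
    run_start = prev = pts[0]
    for p in pts[1:]:
        if p == prev + 1:
            prev = p
            continue
        intervals.append(Interval(run_start, prev))
        run_start = prev = p
    intervals.append(Interval(run_start, prev))
    return intervals


def spliced_cds(seq_bases: str, t: Transcript, strand: str) -> str:
    """Spliced CDS in transcript orientation (reverse-complemented on '-')."""
    segs = sorted(t.cds_segments, key=lambda s: s.interval.start)
    raw = "".join(seq_bases[s.interval.start - 1:s.interval.end] for s in segs)
    return str(Seq(raw).reverse_complement()) if strand == "-" else raw


def fix_start_stop(genome: Genome, transl_table: int = 1) -> Genome:
    """Detect start/stop codons on every coding transcript and (re)emit
    start_codon/stop_codon features over the terminal coding bases.

    The first codon must be ATG; the last must be a stop of the configured
    translation table.  Existing codon features are discarded first
    ("corrects").  Sequences and exon/CDS coordinates are never changed.
    """
    stops = stop_codons(transl_table)
    touched: list[str] = []
    for seq in genome.sequences:
        for gene in seq.genes:
            for t in gene.transcripts:
                if not t.cds_segments:
                    continue
                t.start_codon_intervals = []
                t.stop_codon_intervals = []
                t.has_start_codon = False
                t.has_stop_codon = False
                if t.cds_length() < 3:
                    log.warning("transcript %s: CDS shorter than one codon; "
                                "start/stop not assessed", t.mrna_id)
                    continue
                cds = spliced_cds(seq.bases, t, gene.strand).upper()
                first, last = cds[:3], cds[-3:]
                segs = [s.interval for s in t.cds_segments]
                if "N" in first:
                    log.warning("transcript %s: N in first codon", t.mrna_id)
                elif first in START_CODONS:
                    t.has_start_codon = True
                    t.start_codon_intervals = _positions_to_intervals(
                        _edge_positions(segs, gene.strand, 3, True))
                if "N" in last:
                    log.warning("transcript %s: N in last codon", t.mrna_id)
                elif last in stops:
                    t.has_stop_codon = True
                    t.stop_codon_intervals = _positions_to_intervals(
                        _edge_positions(segs, gene.strand, 3, False))
                touched.append(t.mrna_id)
    genome.edit_ledger.record("fix_start_stop",
                              {"transl_table": transl_table}, touched)
    return genome


# ---------------------------------------------------------------------------
# coordinate-changing edits


def _remap_transcript(t: Transcript, seq_id: str, cmap: CoordinateMap,
                      surviving: Interval) -> bool:
    """Clip a transcript's intervals to the surviving region and shift them.
    Returns False when nothing of the transcript survives."""

    def clip_shift(iv: Interval) -> Interval | None:
        s, e = max(iv.start, surviving.start), min(iv.end, surviving.end)
        if s > e:
            return None
        shift = cmap.removed_before(seq_id, s)
        return Interval(s - shift, e - shift)

    t.exons = [x for x in (clip_shift(e) for e in t.exons) if x]
    if not t.exons:
        return False
    kept_segments = []
    for seg in t.cds_segments:
        new = clip_shift(seg.interval)
        if new is not None:
            seg.interval = new
            kept_segments.append(seg)
    t.cds_segments = kept_segments
    t.start_codon_intervals = [x for x in
                               (clip_shift(i) for i in t.start_codon_intervals)
                               if x]
    t.stop_codon_intervals = [x for x in
                              (clip_shift(i) for i in t.stop_codon_intervals)
                              if x]
    return True


def fix_terminal_ns(genome: Genome) -> Genome:
    """Strip leading/trailing runs of N (or n) from every sequence and remap
    all feature coordinates.

    Features wholly inside a removed run are removed and ledgered; features
    overlapping a run are truncated to the surviving region.  A sequence that
    is entirely N is removed outright (with all its features).
    """
    removed: list[RemovedFeature] = []
    kept_seqs = []
    for seq in genome.sequences:
        n = seq.length
        lead = n - len(seq.bases.lstrip("Nn"))
        trail = n - len(seq.bases.rstrip("Nn"))
        if lead == n:  # entirely ambiguous
            log.warning("sequence %s is entirely N; removed", seq.seq_id)
            for gene in seq.genes:
                removed.append(RemovedFeature(kind="gene", seq_id=seq.seq_id,
                                              strand=gene.strand, gene=gene))
            genome.pass_through = [r for r in genome.pass_through
                                   if r.seq_id != seq.seq_id]
            continue
        kept_seqs.append(seq)
        if lead == 0 and trail == 0:
            continue
        surviving = Interval(lead + 1, n - trail)
        cmap = CoordinateMap()
        cut = []
        if lead:
            cut.append(Interval(1, lead))
        if trail:
            cut.append(Interval(n - trail + 1, n))
        cmap.add(seq.seq_id, cut)
        seq.bases = seq.bases[lead:n - trail]

        kept_genes = []
        for gene in seq.genes:
            survivors = []
            for t in gene.transcripts:
                if _remap_transcript(t, seq.seq_id, cmap, surviving):
                    survivors.append(t)
                else:
                    removed.append(RemovedFeature(
                        kind="transcript", seq_id=seq.seq_id,
                        strand=gene.strand, transcript=t))
            gene.transcripts = survivors
            if survivors:
                gene.recompute_span()
                kept_genes.append(gene)
            else:
                removed.append(RemovedFeature(kind="gene", seq_id=seq.seq_id,
                                              strand=gene.strand, gene=gene))
        seq.genes = kept_genes

        remapped_pt = []
        for rec in genome.pass_through:
            if rec.seq_id != seq.seq_id:
                remapped_pt.append(rec)
                continue
            s = max(rec.interval.start, surviving.start)
            e = min(rec.interval.end, surviving.end)
            if s > e:
                continue  # wholly inside a removed run
            rec.interval = Interval(s - lead, e - lead)
            remapped_pt.append(rec)
        genome.pass_through = remapped_pt
    genome.sequences = kept_seqs
    if removed:
        genome.edit_ledger.record(
            "fix_terminal_ns", {},
            [fid for rf in removed for fid in rf.feature_ids],
            removed=removed)
    else:
        genome.edit_ledger.record("fix_terminal_ns", {}, [])
    return genome


def trim(genome: Genome, regions: list[TrimRegion]) -> Genome:
    """Excise BED-derived regions from sequence and annotation together.

    Whole-sequence regions delete the sequence with all its features.  For
    interval regions the bases are cut out; gene models overlapping a cut —
    even partially — are removed and ledgered (a truncated model would need
    re-prediction), and surviving models are shifted so that the bases under
    them are unchanged.  Overlapping regions on one sequence are merged
    before application.
    """
    removed: list[RemovedFeature] = []
    whole = {r.seq_id for r in regions if r.whole_sequence}
    by_seq: dict[str, list[Interval]] = {}
    for r in regions:
        if not r.whole_sequence:
            by_seq.setdefault(r.seq_id, []).append(r.interval)

    kept_seqs = []
    for seq in genome.sequences:
        cuts = merge_intervals(by_seq.get(seq.seq_id, []))
        if seq.seq_id in whole or (
                len(cuts) == 1 and cuts[0].start == 1
                and cuts[0].end == seq.length):
            for gene in seq.genes:
                removed.append(RemovedFeature(kind="gene", seq_id=seq.seq_id,
                                              strand=gene.strand, gene=gene))
            genome.pass_through = [r for r in genome.pass_through
                                   if r.seq_id != seq.seq_id]
            continue
        kept_seqs.append(seq)
        if not cuts:
            continue
        for iv in cuts:
            if iv.end > seq.length:
                raise ValueError(
                    f"trim region ({iv.start},{iv.end}) exceeds length "
                    f"{seq.length} of {seq.seq_id}")
        cmap = CoordinateMap()
        cmap.add(seq.seq_id, cuts)
        pieces, prev = [], 1
        for iv in cuts:
            pieces.append(seq.bases[prev - 1:iv.start - 1])
            prev = iv.end + 1
        pieces.append(seq.bases[prev - 1:])
        seq.bases = "".join(pieces)

        kept_genes = []
        for gene in seq.genes:
            span = Interval(gene.start, gene.end)
            if any(iv.overlaps(span) for iv in cuts):
                removed.append(RemovedFeature(kind="gene", seq_id=seq.seq_id,
                                              strand=gene.strand, gene=gene))
                continue
            shift = cmap.removed_before(seq.seq_id, gene.start)
            gene.start -= shift
            gene.end -= shift
            for t in gene.transcripts:
                t.exons = [e.shifted(-shift) for e in t.exons]
                for s in t.cds_segments:
                    s.interval = s.interval.shifted(-shift)
                t.start_codon_intervals = [i.shifted(-shift)
                                           for i in t.start_codon_intervals]
                t.stop_codon_intervals = [i.shifted(-shift)
                                          for i in t.stop_codon_intervals]
            kept_genes.append(gene)
        seq.genes = kept_genes

        remapped_pt = []
        for rec in genome.pass_through:
            if rec.seq_id != seq.seq_id:
                remapped_pt.append(rec)
                continue
            new = cmap.map_interval(rec.seq_id, rec.interval)
            if new is None:
                continue
            rec.interval = new
            remapped_pt.append(rec)
        genome.pass_through = remapped_pt
    genome.sequences = kept_seqs
    genome.edit_ledger.record(
        "trim",
        {"regions": [(r.seq_id, r.interval.start, r.interval.end,
                      r.whole_sequence) for r in regions]},
        [fid for rf in removed for fid in rf.feature_ids],
        removed=removed)
    return rebuild_spans(genome)
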