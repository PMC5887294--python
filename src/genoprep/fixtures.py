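"""Deterministic synthetic genomes with known gene models.

The generator builds small multi-scaffold genomes gene by gene, writing a
designed coding sequence (controlled start codon, in-frame body free of
premature stops, controlled terminal codon) into a random background, on
either strand.  It plants defects on a configurable fraction of models —
short introns, sub-threshold CDS totals, non-ATG starts, missing stops,
terminal-N runs — and records which model carries which defect, so every
filter and fix operation can be checked against exact planted truth.

A single integer seed drives all randomness; the same seed yields a
byte-identical genome.  Generated genes never overlap.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from .model import (
    CdsSegment,
    GeneModel,
    Genome,
    Interval,
    Sequence,
    Transcript,
    validate,
)

_NON_STOP_CODONS = [a + b + c
                    for a in "ACGT" for b in "ACGT" for c in "ACGT"
                    if a + b + c not in ("TAA", "TAG", "TGA")]


@dataclass
class FixtureParams:
    """Knobs for the generator; defaults give a clean, realistic mix."""

    max_exons: int = 3
    exon_range: tuple[int, int] = (90, 300)
    intron_range: tuple[int, int] = (30, 120)
    intergenic_range: tuple[int, int] = (60, 200)
    frac_minus_strand: float = 0.5
    frac_two_mrna: float = 0.1
    frac_trna: float = 0.05
    # planted defects
    frac_short_intron: float = 0.0
    short_intron_below: int = 10
    frac_short_cds: float = 0.0
    short_cds_below: int = 150
    frac_non_atg_start: float = 0.0
    frac_no_stop: float = 0.0
    frac_lead_ns: float = 0.0
    frac_trail_ns: float = 0.0
    n_run_range: tuple[int, int] = (5, 30)

    def check(self) -> None:
        for lo, hi in (self.exon_range, self.intron_range,
                       self.intergenic_range, self.n_run_range):
            if lo < 1 or hi < lo:
                raise ValueError(f"infeasible range ({lo},{hi})")
        if self.short_intron_below >= self.intron_range[0]:
            raise ValueError(
                "intron_range must start above short_intron_below, or "
                "un-planted models would violate the planted threshold")
        if 3 * self.max_exons * self.exon_range[1] < self.short_cds_below:
            raise ValueError("exon_range cannot reach short_cds_below")
        for frac in (self.frac_minus_strand, self.frac_two_mrna,
                     self.frac_trna, self.frac_short_intron,
                     self.frac_short_cds, self.frac_non_atg_start,
                     self.frac_no_stop, self.frac_lead_ns,
                     self.frac_trail_ns):
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"fraction {frac} outside [0,1]")


@dataclass
class Truth:
    """Planted-defect bookkeeping plus per-model derived values."""

    short_intron: set[str] = field(default_factory=set)
    short_cds: set[str] = field(default_factory=set)
    non_atg_start: set[str] = field(default_factory=set)
    no_stop: set[str] = field(default_factory=set)
    intron_min: dict[str, int] = field(default_factory=dict)  # coding only
    cds_total: dict[str, int] = field(default_factory=dict)
    lead_ns: dict[str, int] = field(default_factory=dict)
    trail_ns: dict[str, int] = field(default_factory=dict)


def _designed_cds(rng: random.Random, n_codons: int, atg: bool,
                  stop: bool) -> str:
    first = "ATG" if atg else "GTG"
    last = rng.choice(["TAA", "TAG", "TGA"]) if stop else "AAA"
    body = "".join(rng.choice(_NON_STOP_CODONS)
                   for _ in range(n_codons - 2))
    return first + body + last


def _revcomp(s: str) -> str:
    return s.translate(str.maketrans("ACGTacgtNn", "TGCAtgcaNn"))[::-1]


def _phases(lengths: list[int]) -> list[int]:
    out, done = [], 0
    for n in lengths:
        out.append((3 - done % 3) % 3)
        done += n
    return out


def make_genome(seed: int, n_seqs: int = 2, genes_per_seq: int = 10,
                params: FixtureParams | None = None) -> tuple[Genome, Truth]:
    """Generate a genome plus the planted truth about its gene models."""
    p = params or FixtureParams()
    p.check()
    rng = random.Random(seed)
    truth = Truth()
    genome = Genome()
    ordinal = 0

    for si in range(n_seqs):
        seq_id = f"scaffold{si + 1}"
        lead = (rng.randint(*p.n_run_range)
                if rng.random() < p.frac_lead_ns else 0)
        trail = (rng.randint(*p.n_run_range)
                 if rng.random() < p.frac_trail_ns else 0)
        truth.lead_ns[seq_id] = lead
        truth.trail_ns[seq_id] = trail

        chars: list[str] = ["N"] * lead
        genes: list[GeneModel] = []
        cursor = lead  # 0-based length so far

        def pad(n: int) -> None:
            nonlocal cursor
            chars.extend(rng.choice("ACGT") for _ in range(n))
            cursor += n

        for _ in range(genes_per_seq):
            pad(rng.randint(*p.intergenic_range))
            ordinal += 1
            gid, mid = f"gene{ordinal}", f"mrna{ordinal}"
            strand = "-" if rng.random() < p.frac_minus_strand else "+"

            if rng.random() < p.frac_trna:
                length = 72
                start = cursor + 1
                pad(length)
                t = Transcript(mrna_id=mid, gene_id=gid, ttype="tRNA",
                               source="fixture",
                               exons=[Interval(start, start + length - 1)])
                genes.append(GeneModel(
                    gene_id=gid, seq_id=seq_id, strand=strand, start=start,
                    end=start + length - 1, source="fixture",
                    transcripts=[t]))
                continue

            plant_short_cds = rng.random() < p.frac_short_cds
            plant_short_intron = (not plant_short_cds
                                  and rng.random() < p.frac_short_intron)
            atg = rng.random() >= p.frac_non_atg_start
            has_stop = rng.random() >= p.frac_no_stop

            if plant_short_cds:
                exon_lens = [3 * rng.randint(20, (p.short_cds_below - 1) // 3)]
            else:
                k = rng.randint(2 if plant_short_intron else 1, p.max_exons)
                while True:
                    exon_lens = [rng.randint(*p.exon_range) for _ in range(k)]
                    excess = sum(exon_lens) % 3
                    exon_lens[-1] -= excess  # total a codon multiple
                    if (sum(exon_lens) >= p.short_cds_below
                            and exon_lens[-1] >= 3):
                        break
            introns = [rng.randint(*p.intron_range)
                       for _ in range(len(exon_lens) - 1)]
            if plant_short_intron:
                introns[rng.randrange(len(introns))] = rng.randint(
                    1, p.short_intron_below - 1)

            gene_start = cursor + 1
            exons: list[Interval] = []
            for i, elen in enumerate(exon_lens):
                if i:
                    pad(introns[i - 1])
                s = cursor + 1
                pad(elen)
                exons.append(Interval(s, cursor))
            gene_end = cursor

            cds = _designed_cds(rng, sum(exon_lens) // 3, atg, has_stop)
            genomic = cds if strand == "+" else _revcomp(cds)
            offset = 0
            for iv in exons:
                chars[iv.start - 1:iv.end] = genomic[offset:offset + iv.length]
                offset += iv.length

            order = exons if strand == "+" else exons[::-1]
            phases = _phases([iv.length for iv in order])
            phase_of = {iv: ph for iv, ph in zip(order, phases)}
            segments = [CdsSegment(interval=iv, phase=phase_of[iv])
                        for iv in exons]
            transcripts = [Transcript(
                mrna_id=mid, gene_id=gid, source="fixture", exons=list(exons),
                cds_segments=segments)]

            if len(exons) >= 2 and rng.random() < p.frac_two_mrna:
                # isoform sharing the 5' structure but dropping the 3' exon;
                # it inherits the primary's start codon and any planted short
                # intron it retains, so its truth is recorded here too
                sub = exons[:-1] if strand == "+" else exons[1:]
                sub_order = sub if strand == "+" else sub[::-1]
                sub_phases = _phases([iv.length for iv in sub_order])
                sub_phase = {iv: ph for iv, ph in zip(sub_order, sub_phases)}
                iso_id = f"{mid}b"
                transcripts.append(Transcript(
                    mrna_id=iso_id, gene_id=gid, source="fixture",
                    exons=list(sub),
                    cds_segments=[CdsSegment(interval=iv, phase=sub_phase[iv])
                                  for iv in sub]))
                iso_gaps = [sub[i + 1].start - sub[i].end - 1
                            for i in range(len(sub) - 1)]
                if any(gap < p.short_intron_below for gap in iso_gaps):
                    truth.short_intron.add(iso_id)
                if sum(iv.length for iv in sub) < p.short_cds_below:
                    truth.short_cds.add(iso_id)
                if not atg:
                    truth.non_atg_start.add(iso_id)

            genes.append(GeneModel(
                gene_id=gid, seq_id=seq_id, strand=strand,
                start=min(t.start for t in transcripts),
                end=max(t.end for t in transcripts),
                source="fixture", transcripts=transcripts))

            for t in transcripts:
                if t.mrna_id == mid:
                    if plant_short_cds:
                        truth.short_cds.add(mid)
                    if plant_short_intron:
                        truth.short_intron.add(mid)
                    if not atg:
                        truth.non_atg_start.add(mid)
                    if not has_stop:
                        truth.no_stop.add(mid)

        pad(rng.randint(*p.intergenic_range))
        chars.extend("N" * trail)
        genome.sequences.append(Sequence(seq_id=seq_id, bases="".join(chars),
                                         genes=genes))

    from .edits import spliced_cds

    for gene, t in genome.transcripts():
        if not t.is_coding:
            continue
        truth.cds_total[t.mrna_id] = t.cds_length()
        introns = t.intron_lengths()
        if introns:
            truth.intron_min[t.mrna_id] = min(introns)
        if t.mrna_id.endswith("b"):
            # isoform 3' ends fall at arbitrary frame: derive stop status
            seq = genome.sequence(gene.seq_id)
            last = spliced_cds(seq.bases, t, gene.strand)[-3:].upper()
            if last not in ("TAA", "TAG", "TGA"):
                truth.no_stop.add(t.mrna_id)

    problems = [v for v in validate(genome) if not v.startswith("warning:")]
    if problems:  # generator bug guard; should be unreachable
        raise AssertionError(f"generated invalid genome: {problems}")
    return genome, truth


def write_genome(genome: Genome, directory: str,
                 stem: str = "fixture") -> tuple[str, str]:
    """Write the genome as FASTA + GFF3 into *directory*; return the paths."""
    import os

    from .io import write_fasta, write_gff3

    fasta = os.path.join(directory, f"{stem}.fasta")
    gff = os.path.join(directory, f"{stem}.gff3")
    write_fasta(genome.sequences, fasta)
    write_gff3(genome, gff)
    return fasta, gff
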