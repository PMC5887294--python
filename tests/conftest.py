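import pytest

from genoprep.model import (
    CdsSegment,
    GeneModel,
    Genome,
    Interval,
    Sequence,
    Transcript,
)


def build_transcript(mrna_id, gene_id, exons, cds=None, ttype="mRNA",
                     phases=None):
    """Assemble a Transcript from (start, end) tuples; CDS phases default 0."""
    cds = cds or []
    phases = phases or [0] * len(cds)
    return Transcript(
        mrna_id=mrna_id, gene_id=gene_id, ttype=ttype,
        exons=[Interval(*e) for e in exons],
        cds_segments=[CdsSegment(interval=Interval(*c), phase=p)
                      for c, p in zip(cds, phases)])


def build_genome(layout):
    """Build a Genome from {seq_id: (bases, [(gene_id, strand, [transcript
    tuples])])} where each transcript tuple is (mrna_id, exons, cds)."""
    genome = Genome()
    for seq_id, (bases, gene_specs) in layout.items():
        seq = Sequence(seq_id=seq_id, bases=bases)
        for gene_id, strand, t_specs in gene_specs:
            transcripts = [build_transcript(mid, gene_id, exons, cds)
                           for mid, exons, cds in t_specs]
            gene = GeneModel(
                gene_id=gene_id, seq_id=seq_id, strand=strand,
                start=min(t.start for t in transcripts),
                end=max(t.end for t in transcripts),
                transcripts=transcripts)
            seq.genes.append(gene)
        genome.sequences.append(seq)
    return genome


def transcript_signature(t):
    return (
        t.mrna_id, t.ttype,
        tuple((e.start, e.end) for e in t.exons),
        tuple((s.interval.start, s.interval.end, s.phase)
              for s in t.cds_segments),
        t.has_start_codon, t.has_stop_codon,
        tuple((i.start, i.end) for i in t.start_codon_intervals),
        tuple((i.start, i.end) for i in t.stop_codon_intervals),
        tuple(sorted((k, tuple(v)) for k, v in t.attributes.items())),
        tuple(sorted(t.flags)),
    )


def genome_signature(genome):
    """Canonical structural digest of a genome, for equality assertions."""
    out = []
    for seq in genome.sequences:
        genes = []
        for g in sorted(seq.genes, key=lambda g: g.gene_id):
            genes.append((
                g.gene_id, g.strand, g.start, g.end,
                tuple(sorted((k, tuple(v)) for k, v in g.attributes.items())),
                tuple(sorted(g.flags)),
                tuple(transcript_signature(t)
                      for t in sorted(g.transcripts, key=lambda t: t.mrna_id)),
            ))
        out.append((seq.seq_id, seq.bases, tuple(genes)))
    return tuple(out)


@pytest.fixture
def two_gene_genome():
    """1000-bp sequence: a 2-exon plus-strand gene and a 1-exon minus-strand
    gene, CDS covering the exons."""
    bases = ("ACGT" * 250)
    return build_genome({
        "s1": (bases, [
            ("gene1", "+", [
                ("mrna1", [(11, 100), (201, 400)], [(11, 100), (201, 400)]),
            ]),
            ("gene2", "-", [
                ("mrna2", [(501, 700)], [(501, 700)]),
            ]),
        ]),
    })
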