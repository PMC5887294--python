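"""Per-genome summary statistics and the original-vs-modified report.

The ``genome.stats`` file has one row per field and two value columns so a
filtering session can be reviewed at a glance: the left column is the
genome as loaded, the right column the genome after edits.
"""

from __future__ import annotations

from dataclasses import dataclass

from .model import Genome

# (field key, pretty label); order fixed -> frozen report layout
FIELDS = [
    ("seq_count", "Number of sequences"),
    ("total_bases", "Total sequence length"),
    ("gene_count", "Number of genes"),
    ("mrna_count", "Number of mRNAs"),
    ("exon_count", "Number of exons"),
    ("cds_count", "Number of CDS segments"),
    ("intron_count", "Number of introns"),
    ("gene_length_min", "Shortest gene"),
    ("gene_length_mean", "Mean gene length"),
    ("gene_length_max", "Longest gene"),
    ("cds_length_min", "Shortest CDS"),
    ("cds_length_mean", "Mean CDS length"),
    ("cds_length_max", "Longest CDS"),
    ("exon_length_min", "Shortest exon"),
    ("exon_length_mean", "Mean exon length"),
    ("exon_length_max", "Longest exon"),
    ("intron_length_min", "Shortest intron"),
    ("intron_length_mean", "Mean intron length"),
    ("intron_length_max", "Longest intron"),
]

NA = "N/A"


@dataclass
class StatsReport:
    values: dict[str, float | int | str]

    def __getitem__(self, key: str):
        return self.values[key]


def _summary(prefix: str, lengths: list[int]) -> dict:
    if not lengths:
        return {f"{prefix}_min": NA, f"{prefix}_mean": NA, f"{prefix}_max": NA}
    return {
        f"{prefix}_min": min(lengths),
        f"{prefix}_mean": round(sum(lengths) / len(lengths), 1),
        f"{prefix}_max": max(lengths),
    }


def compute_stats(genome: Genome) -> StatsReport:
    """Count features and summarize lengths over the whole genome.

    mRNA counts cover coding transcripts only; exon/intron summaries cover
    all transcript types.  Empty categories report ``N/A`` lengths.
    """
    gene_lengths: list[int] = []
    cds_lengths: list[int] = []
    exon_lengths: list[int] = []
    intron_lengths: list[int] = []
    mrna_count = cds_count = exon_count = 0
    for gene in genome.genes():
        gene_lengths.append(gene.length)
        for t in gene.transcripts:
            if t.is_coding:
                mrna_count += 1
                cds_lengths.append(t.cds_length())
                cds_count += len(t.cds_segments)
            exon_count += len(t.exons)
            exon_lengths.extend(t.exon_lengths())
            intron_lengths.extend(t.intron_lengths())
    values: dict = {
        "seq_count": len(genome.sequences),
        "total_bases": sum(s.length for s in genome.sequences),
        "gene_count": len(gene_lengths),
        "mrna_count": mrna_count,
        "exon_count": exon_count,
        "cds_count": cds_count,
        "intron_count": len(intron_lengths),
    }
    values.update(_summary("gene_length", gene_lengths))
    values.update(_summary("cds_length", cds_lengths))
    values.update(_summary("exon_length", exon_lengths))
    values.update(_summary("intron_length", intron_lengths))
    return StatsReport(values)


def diff_stats(before: StatsReport, after: StatsReport) -> str:
    """Render the two-column original/modified report as fixed-width text."""
    label_w = max(len(label) for _, label in FIELDS)
    col_w = 12
    lines = [f"{'':<{label_w}}  {'original':>{col_w}}  {'modified':>{col_w}}"]
    for key, label in FIELDS:
        b, a = before[key], after[key]
        lines.append(f"{label:<{label_w}}  {b!s:>{col_w}}  {a!s:>{col_w}}")
    return "\n".join(lines) + "\n"
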