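"""Length-based remove/flag rules and removal by explicit ID list.

A :class:`FilterSpec` is one rule: feature kind (cds/exon/intron/gene) ×
bound direction (shorter_than/longer_than) × threshold × mode
(remove/flag).  Matching uses strict inequality, so boundary values
survive.  CDS rules compare the transcript's total spliced CDS length;
exon and intron rules match per element but act on (remove or flag) the
whole owning transcript, since a transcript missing one exon is not a
valid gene model.  Gene rules act on the gene span.

Removals cascade through :func:`genoprep.model.remove_transcripts` /
``remove_genes`` so parents are updated and everything lands in the
removed-features log exactly once.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

from .model import Genome, remove_genes, remove_transcripts
from .io import write_removed_gff3

KINDS = ("cds", "exon", "intron", "gene")
BOUNDS = ("shorter_than", "longer_than")
MODES = ("remove", "flag")


@dataclass(frozen=True)
class FilterSpec:
    feature_kind: str
    bound: str
    threshold: int
    mode: str

    def __post_init__(self) -> None:
        if self.feature_kind not in KINDS:
            raise ValueError(f"unknown feature kind {self.feature_kind!r}")
        if self.bound not in BOUNDS:
            raise ValueError(f"unknown bound {self.bound!r}")
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.threshold < 1:
            raise ValueError("threshold must be a positive integer")

    @property
    def flag_string(self) -> str:
        return f"{self.feature_kind}_{self.bound}_{self.threshold}"


def _matches(spec: FilterSpec, lengths: list[int]) -> bool:
    if spec.bound == "shorter_than":
        return any(n < spec.threshold for n in lengths)
    return any(n > spec.threshold for n in lengths)


def _transcript_lengths(spec: FilterSpec, t) -> list[int]:
    """Length values the rule is tested against for one transcript.

    Non-coding transcripts are exempt from cds and intron rules.
    """
    if spec.feature_kind == "cds":
        return [t.cds_length()] if t.is_coding else []
    if spec.feature_kind == "exon":
        return t.exon_lengths()
    if t.is_coding:
        return t.intron_lengths()
    return []


def apply_filter(genome: Genome, spec: FilterSpec) -> Genome:
    """Apply one remove/flag rule to the whole genome.

    mode=remove detaches matching transcripts (or genes with all children)
    into the ledger and rebuilds parent spans; mode=flag attaches the rule's
    token to the matching transcript/gene and changes nothing else.  No
    matches leaves the genome unchanged.
    """
    op = f"{spec.mode}_{spec.feature_kind}_{spec.bound}"
    params = {"threshold": spec.threshold}
    if spec.feature_kind == "gene":
        hits = [g for g in genome.genes() if _matches(spec, [g.length])]
        if spec.mode == "flag":
            for g in hits:
                g.add_flag(spec.flag_string)
            if hits:
                genome.edit_ledger.record(
                    op, params, [g.gene_id for g in hits])
        else:
            remove_genes(genome, {g.gene_id for g in hits}, op, params)
        return genome

    hits = [t for _, t in genome.transcripts()
            if _matches(spec, _transcript_lengths(spec, t))]
    if spec.mode == "flag":
        for t in hits:
            t.add_flag(spec.flag_string)
        if hits:
            genome.edit_ledger.record(op, params, [t.mrna_id for t in hits])
    else:
        remove_transcripts(genome, {t.mrna_id for t in hits}, op, params)
    return genome


def remove_by_id(genome: Genome, ids: list[str]) -> tuple[Genome, list[str]]:
    """Remove genes and/or transcripts named in *ids*, with cascade.

    Unknown ids are returned as warnings rather than raised: the typical
    input is a reviewer-supplied list of rejected features which may name
    models already gone.
    """
    wanted = set(ids)
    gene_ids = {g.gene_id for g in genome.genes()}
    mrna_ids = {t.mrna_id for _, t in genome.transcripts()}
    unknown = sorted(wanted - gene_ids - mrna_ids)
    remove_genes(genome, wanted & gene_ids, "remove_by_id", {"ids": ids})
    remove_transcripts(genome, wanted & mrna_ids, "remove_by_id",
                       {"ids": ids})
    warnings = [f"id {u!r} not found in genome" for u in unknown]
    return genome, warnings


def write_removed(genome: Genome, path: str | os.PathLike) -> None:
    """Serialize every removed feature (original coordinates) as GFF3."""
    write_removed_gff3(genome.edit_ledger.removed_features, path)
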