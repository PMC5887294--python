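"""Merge functional annotations into the model.

Two sources feed the same qualifier maps: a tab-delimited table
(feature id, key, value) and qualifiers already present in the input
GFF3 attribute column.  Supported keys are Name (genes), product
(mRNAs), and Dbxref / Ontology_term (either level).  Once in the model
they flow to both the output GFF3 and the NCBI feature table.
"""

from __future__ import annotations

import logging

from .io import AnnotationRow
from .model import Genome

log = logging.getLogger(__name__)

_CANONICAL = {"name": "Name", "dbxref": "Dbxref",
              "ontology_term": "Ontology_term", "product": "product"}


def _attach(attributes: dict[str, list[str]], key: str, value: str) -> None:
    values = attributes.setdefault(key, [])
    if value not in values:
        values.append(value)


def annotate(genome: Genome,
             rows: list[AnnotationRow]) -> tuple[Genome, list[str]]:
    """Attach annotation rows to their features; values accumulate.

    Name targets genes; product targets mRNAs (a product addressed to a
    gene is attached to all its mRNAs, with a warning); Dbxref and
    Ontology_term attach to whichever feature the id names.  Unmatched ids
    are reported as warnings, never fatal.  Structure is untouched.
    """
    genes = {g.gene_id: g for g in genome.genes()}
    mrnas = {t.mrna_id: t for _, t in genome.transcripts()}
    warnings: list[str] = []
    unmatched = 0
    for row in rows:
        gene = genes.get(row.feature_id)
        mrna = mrnas.get(row.feature_id)
        if gene is None and mrna is None:
            unmatched += 1
            warnings.append(
                f"annotation for unknown feature {row.feature_id!r} "
                f"({row.key}={row.value}) skipped")
            continue
        if row.key == "Name":
            _attach((gene or mrna).attributes, "Name", row.value)
        elif row.key == "product":
            if mrna is not None:
                _attach(mrna.attributes, "product", row.value)
            else:
                warnings.append(
                    f"product addressed to gene {row.feature_id!r}; "
                    f"attached to its mRNAs")
                for t in gene.transcripts:
                    _attach(t.attributes, "product", row.value)
        else:  # Dbxref / Ontology_term
            _attach((mrna or gene).attributes, row.key, row.value)
    if unmatched:
        warnings.append(f"{unmatched} annotation row(s) named features "
                        f"absent from the genome")
    for w in warnings:
        log.warning("%s", w)
    genome.edit_ledger.record("annotate", {"rows": len(rows)},
                              sorted({r.feature_id for r in rows}))
    return genome, warnings


def harvest_gff3_annotations(genome: Genome) -> Genome:
    """Normalize qualifier keys already present in the attribute maps.

    Input GFF3 may spell keys in any case (``name=``, ``Product=``); this
    promotes them to canonical capitalization so downstream writers see one
    spelling.  Idempotent; values already canonical pass through.
    """
    def normalize(attributes: dict[str, list[str]]) -> None:
        for key in list(attributes):
            canonical = _CANONICAL.get(key.lower())
            if canonical and canonical != key:
                values = attributes.pop(key)
                merged = attributes.setdefault(canonical, [])
                for v in values:
                    if v not in merged:
                        merged.append(v)

    for gene in genome.genes():
        normalize(gene.attributes)
        for t in gene.transcripts:
            normalize(t.attributes)
    return genome
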