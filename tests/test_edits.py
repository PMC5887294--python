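"""Sequence+annotation co-edits: codon fixing, terminal-N stripping, trim.

The master oracle for every coordinate remap: the bases under a surviving
feature, extracted at its new coordinates from the edited FASTA, must equal
the bases at its old coordinates from the original FASTA.
"""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from genoprep.edits import (
    TrimRegion,
    fix_start_stop,
    fix_terminal_ns,
    merge_intervals,
    spliced_cds,
    trim,
)
from genoprep.fixtures import FixtureParams, make_genome
from genoprep.model import Interval, validate

from conftest import build_genome


def snapshot_feature_bases(genome):
    """Map transcript id -> exon base strings (the remap fidelity oracle)."""
    out = {}
    for seq in genome.sequences:
        for gene in seq.genes:
            for t in gene.transcripts:
                out[t.mrna_id] = [seq.subseq(e) for e in t.exons]
    return out


class TestFixStartStop:
    def test_plus_strand_atg_taa_gets_both_codon_features(self):
        #       v ATG                v TAA
        bases = "ATGAAACCCGGGTTTACGTAA" + "A" * 20
        g = build_genome({"s1": (bases, [
            ("g1", "+", [("m1", [(1, 21)], [(1, 21)])])])})
        fix_start_stop(g)
        t = next(g.transcripts())[1]
        assert t.has_start_codon and t.has_stop_codon
        assert [(i.start, i.end) for i in t.start_codon_intervals] == [(1, 3)]
        assert [(i.start, i.end) for i in t.stop_codon_intervals] == [(19, 21)]

    def test_minus_strand_start_at_high_coordinate_end(self):
        # reverse complement of CAT is ATG; revcomp of TTA is TAA
        bases = "TTA" + "G" * 15 + "CAT" + "A" * 10
        g = build_genome({"s1": (bases, [
            ("g1", "-", [("m1", [(1, 21)], [(1, 21)])])])})
        fix_start_stop(g)
        t = next(g.transcripts())[1]
        assert t.has_start_codon and t.has_stop_codon
        assert [(i.start, i.end) for i in t.start_codon_intervals] == \
            [(19, 21)]
        assert [(i.start, i.end) for i in t.stop_codon_intervals] == [(1, 3)]

    def test_gtg_start_is_not_a_start(self):
        bases = "GTG" + "A" * 12 + "TAA" + "C" * 10
        g = build_genome({"s1": (bases, [
            ("g1", "+", [("m1", [(1, 18)], [(1, 18)])])])})
        fix_start_stop(g)
        t = next(g.transcripts())[1]
        assert not t.has_start_codon and t.has_stop_codon
        assert t.start_codon_intervals == []

    def test_codon_split_across_exons(self):
        # CDS = AT|G...TA|A split over three exons at awkward boundaries
        bases = "AT" + "C" * 5 + "GAAATTTA" + "C" * 5 + "A" + "G" * 5
        #        exon1 (1,2)     exon2 (8,15)           exon3 (21,21)
        g = build_genome({"s1": (bases, [
            ("g1", "+", [("m1", [(1, 2), (8, 15), (21, 21)],
                          [(1, 2), (8, 15), (21, 21)])])])})
        fix_start_stop(g)
        t = next(g.transcripts())[1]
        assert spliced_cds(g.sequences[0].bases, t, "+") == "ATGAAATTTAA"
        assert t.has_start_codon and t.has_stop_codon
        assert [(i.start, i.end) for i in t.start_codon_intervals] == \
            [(1, 2), (8, 8)]
        assert [(i.start, i.end) for i in t.stop_codon_intervals] == \
            [(14, 15), (21, 21)]

    def test_n_in_terminal_codon_is_not_a_match(self):
        bases = "NTG" + "A" * 12 + "TAN" + "C" * 4
        g = build_genome({"s1": (bases, [
            ("g1", "+", [("m1", [(1, 18)], [(1, 18)])])])})
        fix_start_stop(g)
        t = next(g.transcripts())[1]
        assert not t.has_start_codon and not t.has_stop_codon

    def test_sub_codon_cds_skipped_with_no_codons(self):
        g = build_genome({"s1": ("ATGAAA", [
            ("g1", "+", [("m1", [(1, 6)], [(1, 2)])])])})
        fix_start_stop(g)
        t = next(g.transcripts())[1]
        assert not t.has_start_codon and not t.has_stop_codon

    def test_matches_translate_the_ends_oracle_on_both_strands(self):
        params = FixtureParams(frac_non_atg_start=0.3, frac_no_stop=0.3,
                               frac_two_mrna=0.3)
        genome, _ = make_genome(31, n_seqs=3, genes_per_seq=15, params=params)
        snapshot = snapshot_feature_bases(genome)
        fix_start_stop(genome)
        stops = {"TAA", "TAG", "TGA"}
        for gene, t in genome.transcripts():
            if not t.is_coding:
                continue
            seq = genome.sequence(gene.seq_id)
            cds = spliced_cds(seq.bases, t, gene.strand).upper()
            assert t.has_start_codon == (cds[:3] == "ATG"), t.mrna_id
            assert t.has_stop_codon == (cds[-3:] in stops), t.mrna_id
        # never touches sequence or exon/CDS coordinates
        assert snapshot_feature_bases(genome) == snapshot

    def test_corrects_existing_codon_features(self):
        bases = "GTG" + "A" * 12 + "TAA" + "C" * 10
        g = build_genome({"s1": (bases, [
            ("g1", "+", [("m1", [(1, 18)], [(1, 18)])])])})
        t = next(g.transcripts())[1]
        t.has_start_codon = True  # wrong: claims a start that is not there
        t.start_codon_intervals = [Interval(1, 3)]
        fix_start_stop(g)
        assert not t.has_start_codon and t.start_codon_intervals == []


class TestFixTerminalNs:
    def test_both_runs_stripped_and_features_shifted(self):
        g = build_genome({"s1": ("NNNACGTNN", [
            ("g1", "+", [("m1", [(4, 7)], [(4, 7)])])])})
        fix_terminal_ns(g)
        seq = g.sequences[0]
        assert seq.bases == "ACGT"
        gene = seq.genes[0]
        assert (gene.start, gene.end) == (1, 4)
        assert validate(g) == []

    def test_internal_ns_untouched(self):
        g = build_genome({"s1": ("ACGNNNGT", [
            ("g1", "+", [("m1", [(1, 2)], [])])])})
        fix_terminal_ns(g)
        assert g.sequences[0].bases == "ACGNNNGT"

    def test_feature_inside_leading_run_removed_and_logged(self):
        g = build_genome({"s1": ("NNNNNACGT", [
            ("g1", "+", [("m1", [(1, 3)], [])]),
            ("g2", "+", [("m2", [(6, 9)], [])])])})
        fix_terminal_ns(g)
        assert {x.gene_id for x in g.genes()} == {"g2"}
        assert g.edit_ledger.removed_ids() == {"g1", "m1"}

    def test_feature_overlapping_leading_run_truncated(self):
        g = build_genome({"s1": ("NNNACGTACGT", [
            ("g1", "+", [("m1", [(2, 7)], [])])])})
        fix_terminal_ns(g)
        gene = g.sequences[0].genes[0]
        assert (gene.start, gene.end) == (1, 4)  # old (4,7) region survives

    def test_all_n_sequence_removed_entirely(self):
        g = build_genome({
            "s1": ("NNNNN", [("g1", "+", [("m1", [(2, 4)], [])])]),
            "s2": ("ACGT", [])})
        fix_terminal_ns(g)
        assert [s.seq_id for s in g.sequences] == ["s2"]
        assert g.edit_ledger.removed_ids() == {"g1", "m1"}

    def test_case_insensitive_n_stripping(self):
        g = build_genome({"s1": ("nNnACGTn", [])})
        fix_terminal_ns(g)
        assert g.sequences[0].bases == "ACGT"

    def test_planted_lead_run_shifts_by_its_length(self):
        params = FixtureParams(frac_lead_ns=1.0)
        genome, truth = make_genome(32, n_seqs=2, genes_per_seq=4,
                                    params=params)
        old_starts = {g.gene_id: g.start for g in genome.genes()}
        fix_terminal_ns(genome)
        for g in genome.genes():
            shift = truth.lead_ns[g.seq_id]
            assert g.start == old_starts[g.gene_id] - shift


class TestTrim:
    def test_excision_shifts_downstream_gene(self):
        g = build_genome({"s1": ("A" * 1000, [
            ("g1", "+", [("m1", [(201, 300)], [(201, 300)])])])})
        trim(g, [TrimRegion("s1", Interval(1, 100))])
        gene = g.sequences[0].genes[0]
        assert (gene.start, gene.end) == (101, 200)
        assert g.sequences[0].length == 900

    def test_gene_fully_inside_cut_removed(self):
        g = build_genome({"s1": ("A" * 1000, [
            ("g1", "+", [("m1", [(120, 180)], [])])])})
        trim(g, [TrimRegion("s1", Interval(100, 200))])
        assert g.feature_ids() == set()
        assert g.edit_ledger.removed_ids() == {"g1", "m1"}

    def test_partial_overlap_removes_whole_gene(self):
        g = build_genome({"s1": ("A" * 1000, [
            ("g1", "+", [("m1", [(90, 150)], [])])])})
        trim(g, [TrimRegion("s1", Interval(1, 100))])
        assert g.feature_ids() == set()
        assert "g1" in g.edit_ledger.removed_ids()

    def test_whole_scaffold_trim_drops_sequence_and_features(self):
        g = build_genome({
            "s1": ("A" * 100, [("g1", "+", [("m1", [(1, 50)], [])])]),
            "s2": ("C" * 100, [("g2", "+", [("m2", [(1, 50)], [])])])})
        trim(g, [TrimRegion("s2", Interval(1, 100), whole_sequence=True)])
        assert [s.seq_id for s in g.sequences] == ["s1"]
        assert g.edit_ledger.removed_ids() == {"g2", "m2"}

    def test_overlapping_regions_merge_before_application(self):
        g = build_genome({"s1": ("A" * 1000, [
            ("g1", "+", [("m1", [(501, 600)], [])])])})
        trim(g, [TrimRegion("s1", Interval(1, 60)),
                 TrimRegion("s1", Interval(50, 100))])
        gene = g.sequences[0].genes[0]
        assert (gene.start, gene.end) == (401, 500)
        assert g.sequences[0].length == 900

    def test_disjoint_trims_compose_like_their_union(self):
        def fresh():
            gnm, _ = make_genome(33, n_seqs=1, genes_per_seq=6)
            return gnm

        r1 = [TrimRegion("scaffold1", Interval(1, 40))]
        r2 = [TrimRegion("scaffold1", Interval(101, 140))]
        g_two_step, g_union = fresh(), fresh()
        trim(g_two_step, r1)
        # second trim addresses coordinates in the once-trimmed system
        trim(g_two_step, [TrimRegion("scaffold1", Interval(61, 100))])
        trim(g_union, r1 + r2)
        assert g_two_step.sequences[0].bases == g_union.sequences[0].bases
        assert {(x.gene_id, x.start, x.end) for x in g_two_step.genes()} == \
            {(x.gene_id, x.start, x.end) for x in g_union.genes()}


def test_merge_intervals_unions_overlaps_and_abutments():
    merged = merge_intervals([Interval(5, 10), Interval(11, 20),
                              Interval(1, 3), Interval(8, 15)])
    assert [(m.start, m.end) for m in merged] == [(1, 3), (5, 20)]


@settings(derandomize=True, max_examples=25, deadline=None)
@given(seed=st.integers(0, 10**6))
def test_remap_master_oracle_random_edits(seed):
    """Substring fidelity under random trims + terminal-N stripping."""
    rng = random.Random(seed)
    params = FixtureParams(frac_lead_ns=0.5, frac_trail_ns=0.5,
                           frac_two_mrna=0.2)
    genome, _ = make_genome(seed, n_seqs=2, genes_per_seq=6, params=params)
    old_bases = {s.seq_id: s.bases for s in genome.sequences}
    old_exons = {t.mrna_id: (g.seq_id, [(e.start, e.end) for e in t.exons])
                 for g, t in genome.transcripts()}
    fix_terminal_ns(genome)
    regions = []
    for s in genome.sequences:
        for _ in range(rng.randint(0, 2)):
            a = rng.randint(1, max(1, s.length - 50))
            b = min(s.length, a + rng.randint(0, 400))
            regions.append(TrimRegion(
                s.seq_id, Interval(a, b),
                whole_sequence=(a == 1 and b == s.length)))
    trim(genome, regions)
    assert not [v for v in validate(genome) if not v.startswith("warning:")]
    for gene, t in genome.transcripts():
        seq = genome.sequence(gene.seq_id)
        seq_id, old = old_exons[t.mrna_id]
        assert len(old) >= len(t.exons)
        # compare per-exon bases; terminal truncation may shorten edge exons
        for new_iv in t.exons:
            new_sub = seq.subseq(new_iv)
            assert any(new_sub in old_bases[seq_id][a - 1:b]
                       for a, b in old), t.mrna_id


def test_trim_rejects_region_past_sequence_end():
    g = build_genome({"s1": ("A" * 100, [])})
    with pytest.raises(ValueError, match="exceeds length"):
        trim(g, [TrimRegion("s1", Interval(50, 200))])
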