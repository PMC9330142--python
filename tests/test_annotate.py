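"""Gene joins, OXPHOS flags and coding effects under the mito code."""

import pytest
from Bio.Seq import Seq

from mtoop import annotate_variant, attach_scores, flag_known_pathogenic, \
    load_disease_table
from mtoop.annotate import (NON_SYNONYMOUS, NONCODING, OTHER_EFFECT,
                            SYNONYMOUS, GeneRecord)
from mtoop.errors import ValidationError
from mtoop.profiles import ObservedCall, call_from_label


def translate_gene(seq, gene):
    """Whole-gene protein under the vertebrate mitochondrial code."""
    sub = seq[gene.start - 1: gene.end]
    if gene.strand == "light":
        sub = str(Seq(sub).reverse_complement())
    n = len(sub) // 3
    return str(Seq(sub[: 3 * n]).translate(table=2))


def oracle_effect(seq, gene, call):
    """Brute-force oracle: mutate the genome, retranslate, compare."""
    mutated = seq[: call.position - 1] + call.alt_allele + seq[call.position:]
    before, after = translate_gene(seq, gene), translate_gene(mutated, gene)
    if before == after:
        # distinguish the untranslated incomplete-stop tail from a true
        # synonymous change by checking codon coverage
        n = gene.length // 3
        offset = (call.position - gene.start if gene.strand == "heavy"
                  else gene.end - call.position)
        return SYNONYMOUS if offset < 3 * n else OTHER_EFFECT
    return NON_SYNONYMOUS


def sub_at(seq, pos, alt=None):
    ref = seq[pos - 1]
    if alt is None:
        alt = "ACGT"[("ACGT".index(ref) + 1) % 4]
    return ObservedCall(pos, ref, alt, "substitution", 0.99)


class TestGeneJoin:
    def test_nd4_lhon_position_on_rcrs_map(self, rcrs_gene_map):
        call = ObservedCall(12132, "C", "G", "substitution", 0.99)
        ann = annotate_variant(rcrs_gene_map, None, call)
        assert ann.gene == "MT-ND4" and ann.is_oxphos

    @pytest.mark.parametrize("pos, gene, oxphos", [
        (11778, "MT-ND4", True),     # complex I
        (14484, "MT-ND6", True),     # complex I, light strand
        (1555, "MT-RNR1", False),    # rRNA
        (16100, "MT-CR1", False),    # control region
    ])
    def test_known_positions(self, rcrs_gene_map, pos, gene, oxphos):
        ref = "G" if pos != 1555 else "A"
        alt = "A" if pos != 1555 else "G"
        ann = annotate_variant(rcrs_gene_map, None,
                               ObservedCall(pos, ref, alt, "substitution", 1.0))
        assert (ann.gene, ann.is_oxphos) == (gene, oxphos)

    def test_overlap_is_annotated_against_both(self, toy_genome):
        seq, gene_map = toy_genome
        ann = annotate_variant(gene_map, seq, sub_at(seq, 65))
        assert set(ann.per_gene_effects) == {"geneA", "geneC"}

    def test_out_of_range_position(self, toy_genome):
        seq, gene_map = toy_genome
        with pytest.raises(Exception):
            annotate_variant(gene_map, seq,
                             ObservedCall(500, "A", "G", "substitution", 1.0))

    def test_reference_mismatch_reports_both_alleles(self, toy_genome):
        seq, gene_map = toy_genome
        pos = 20
        wrong = "ACGT"[("ACGT".index(seq[pos - 1]) + 1) % 4]
        call = ObservedCall(pos, wrong, seq[pos - 1], "substitution", 1.0)
        with pytest.raises(ValidationError, match="mismatch"):
            annotate_variant(gene_map, seq, call)


class TestCodingEffect:
    def test_heavy_strand_third_position_leucine(self, toy_genome):
        _, gene_map = toy_genome
        # codon 1 of geneA spans 10-12: make it CTA -> CTG (Leu -> Leu)
        seq = list("A" * 200)
        seq[9:12] = "CTA"
        seq = "".join(seq)
        call = ObservedCall(12, "A", "G", "substitution", 1.0)
        ann = annotate_variant(gene_map, seq, call)
        assert ann.per_gene_effects["geneA"] == SYNONYMOUS

    def test_light_strand_tga_is_tryptophan(self, toy_genome):
        _, gene_map = toy_genome
        # geneB is light strand, first codon at 159-161 (read downward);
        # heavy-strand CCA reads TGG; CCA->TCA reads TGA = Trp in the
        # mitochondrial code, hence synonymous
        seq = list("A" * 200)
        seq[158:161] = "CCA"
        seq = "".join(seq)
        call = ObservedCall(159, "C", "T", "substitution", 1.0)
        ann = annotate_variant(gene_map, seq, call)
        assert ann.per_gene_effects["geneB"] == SYNONYMOUS

    def test_incomplete_stop_tail_is_other(self, toy_genome):
        seq, gene_map = toy_genome
        # geneB tail = low-coordinate positions 100-101 (2 bases past the
        # last whole codon when reading from 161 downwards)
        ann = annotate_variant(gene_map, seq, sub_at(seq, 100))
        assert ann.per_gene_effects["geneB"] == OTHER_EFFECT

    def test_indels_and_noncoding(self, toy_genome):
        seq, gene_map = toy_genome
        ins = call_from_label("m.15insACG")
        assert annotate_variant(gene_map, seq, ins).effect == OTHER_EFFECT
        outside = sub_at(seq, 190)
        assert annotate_variant(gene_map, seq, outside).effect == NONCODING
        trna = sub_at(seq, 175)
        ann = annotate_variant(gene_map, seq, trna)
        assert ann.effect == NONCODING and ann.gene == "trnX"

    def test_agrees_with_whole_gene_translation_oracle(self, toy_genome):
        seq, gene_map = toy_genome
        proteins = [g for g in gene_map if g.category == "protein"]
        checked = 0
        for pos in range(1, 201):
            covering = [g for g in proteins if g.covers(pos)]
            if not covering:
                continue
            for alt in "ACGT":
                if alt == seq[pos - 1]:
                    continue
                call = ObservedCall(pos, seq[pos - 1], alt, "substitution", 1.0)
                ann = annotate_variant(gene_map, seq, call)
                for g in covering:
                    assert ann.per_gene_effects[g.name] == \
                        oracle_effect(seq, g, call), (pos, alt, g.name)
                checked += 1
        assert checked > 300

    def test_single_residue_changes_for_non_synonymous(self, toy_genome):
        seq, gene_map = toy_genome
        gene = gene_map[0]
        for pos in range(gene.start, gene.end + 1):
            for alt in "ACGT":
                if alt == seq[pos - 1]:
                    continue
                call = ObservedCall(pos, seq[pos - 1], alt, "substitution", 1.0)
                ann = annotate_variant(gene_map, seq, call)
                mutated = seq[: pos - 1] + alt + seq[pos:]
                diff = sum(x != y for x, y in zip(
                    translate_gene(seq, gene), translate_gene(mutated, gene)))
                expected = {SYNONYMOUS: 0, NON_SYNONYMOUS: 1}[
                    ann.per_gene_effects[gene.name]] \
                    if ann.per_gene_effects[gene.name] != OTHER_EFFECT else 0
                assert diff == expected


class TestLookups:
    def test_scores_attach_only_to_non_synonymous(self, toy_genome):
        seq, gene_map = toy_genome
        table = {}
        syn = non = None
        for pos in range(10, 70):
            for alt in "ACGT":
                if alt == seq[pos - 1]:
                    continue
                call = ObservedCall(pos, seq[pos - 1], alt, "substitution", 1.0)
                ann = annotate_variant(gene_map, seq, call)
                table[ann.label] = {"APOGEE": 0.3}
                if ann.effect == SYNONYMOUS and syn is None:
                    syn = ann
                if ann.effect == NON_SYNONYMOUS and non is None:
                    non = ann
        assert attach_scores(non, table).scores == {"APOGEE": 0.3}
        assert attach_scores(syn, table).scores == {}
        assert attach_scores(non, {}).scores == {}

    def test_known_disease_flags(self, rcrs_gene_map):
        table = load_disease_table()
        lhon = annotate_variant(rcrs_gene_map, None,
                                ObservedCall(11778, "G", "A",
                                             "substitution", 1.0))
        assert flag_known_pathogenic(lhon, table).known_disease == "LHON"
        deaf = annotate_variant(rcrs_gene_map, None,
                                ObservedCall(1555, "A", "G",
                                             "substitution", 1.0))
        assert flag_known_pathogenic(deaf, table).known_disease == "Deafness"
        other = annotate_variant(rcrs_gene_map, None,
                                 ObservedCall(100, "G", "A",
                                              "substitution", 1.0))
        assert flag_known_pathogenic(other, table).known_disease is None

    def test_oxphos_counts_sum_over_complexes(self, rcrs_gene_map):
        import collections
        calls = [ObservedCall(p, "A", "G", "substitution", 1.0)
                 for p in (3400, 5000, 6000, 8000, 8500, 9500, 10100,
                           11000, 13000, 14300, 15000)]
        anns = [annotate_variant(rcrs_gene_map, None, c) for c in calls]
        per_complex = collections.Counter()
        for ann, call in zip(anns, calls):
            for g in rcrs_gene_map:
                if g.covers(call.position) and g.complex_:
                    per_complex[g.complex_] += 1
                    break
        assert sum(per_complex.values()) == sum(a.is_oxphos for a in anns)
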