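"""EMS transition filtering, panel exclusion, and effect annotation."""

from itertools import permutations

import numpy as np
import pytest
from Bio.Seq import Seq

from muwalk import datasets
from muwalk.ems import (
    PanelGenotypes,
    SnpRecord,
    allele_report,
    annotate_effect,
    exclude_panel_variants,
    is_ems_transition,
)
from muwalk.models import GeneModel
from muwalk.simulate import SimConfig, simulate_reference

from conftest import toy_gene


class TestIsEmsTransition:
    def test_accepts_exactly_the_two_ems_substitutions(self):
        accepted = {
            (ref, alt)
            for ref, alt in permutations("ACGT", 2)
            if is_ems_transition(SnpRecord("c", 1, ref, alt))
        }
        assert accepted == {("G", "A"), ("C", "T")}

    @pytest.mark.parametrize("ref,alt", [("AC", "-"), ("A", "del:A"), ("C", "")])
    def test_indels_are_never_ems_typical(self, ref, alt):
        assert not is_ems_transition(SnpRecord("c", 1, ref, alt))


class TestPanelExclusion:
    def snp(self, pos=100, alt="A"):
        return SnpRecord("chr3", pos, "G", alt)

    def test_alt_in_one_founder_excludes(self):
        panel = PanelGenotypes()
        panel.add_call("chr3", 100, "B97", "A", support=4)
        assert exclude_panel_variants([self.snp()], panel) == []

    def test_missing_data_does_not_exclude(self):
        panel = PanelGenotypes()
        for f in [f"F{i}" for i in range(10)]:
            panel.add_call("chr3", 100, f, "--")  # all missing
        panel.add_call("chr3", 100, "F11", "G", support=9)  # reference call
        snps = [self.snp()]
        assert exclude_panel_variants(snps, panel) == snps

    def test_empty_panel_retains_all(self):
        snps = [self.snp(p) for p in (10, 20, 30)]
        assert exclude_panel_variants(snps, PanelGenotypes()) == snps

    def test_min_support_threshold(self):
        panel = PanelGenotypes()
        panel.add_call("chr3", 100, "B97", "A", support=1)
        assert exclude_panel_variants([self.snp()], panel, min_support=2) == [self.snp()]

    def test_adding_founders_is_monotone(self):
        rng = np.random.default_rng(8)
        snps = [self.snp(int(p)) for p in rng.choice(10_000, 50, replace=False)]
        panel = PanelGenotypes()
        previous = set(s.pos for s in exclude_panel_variants(snps, panel))
        for i in range(20):
            pos = int(rng.choice([s.pos for s in snps]))
            panel.add_call("chr3", pos, f"F{i}", "A", support=int(rng.integers(1, 5)))
            kept = set(s.pos for s in exclude_panel_variants(snps, panel))
            assert kept <= previous
            previous = kept


class TestAnnotateEffect:
    """Toy gene with CDS ATG CAG CAG TGA (M Q Q *)."""

    def test_ptc_at_codon_two(self):
        genome, model = toy_gene("+")
        pos = model.genomic_pos_of_cds_index(4)  # codon 2 base 1: CAG -> TAG
        eff = annotate_effect(SnpRecord("chrT", pos, "C", "T"), model, genome)
        assert eff.category == "PTC"
        assert eff.aa_position == 2 and eff.aa_change == ("Q", "*")
        assert eff.notation == "2AA(Q/PTC)"

    def test_synonymous_at_codon_three_wobble(self):
        genome, model = toy_gene("+")
        pos = model.genomic_pos_of_cds_index(9)  # codon 3 base 3: CAG -> CAA
        eff = annotate_effect(SnpRecord("chrT", pos, "G", "A"), model, genome)
        assert eff.category == "synonymous" and eff.aa_position == 3

    def test_minus_strand_gene_gives_identical_annotation(self):
        genome, model = toy_gene("-")
        pos = model.genomic_pos_of_cds_index(4)
        # CDS C->T is genomic G->A on the minus strand
        eff = annotate_effect(SnpRecord("chrT", pos, "G", "A"), model, genome)
        assert eff.category == "PTC"
        assert eff.aa_position == 2 and eff.aa_change == ("Q", "*")

    def test_upstream_distance_to_start_codon(self):
        genome, model = toy_gene("+")
        pos = model.cds_start_codon_pos() - 28
        eff = annotate_effect(SnpRecord("chrT", pos, genome["chrT"][pos - 1], "N"), model, genome)
        assert eff.category == "upstream" and eff.distance_bp == 28

    def test_downstream_distance_to_stop_codon(self):
        genome, model = toy_gene("+")
        pos = model.cds_stop_codon_end() + 47
        eff = annotate_effect(SnpRecord("chrT", pos, genome["chrT"][pos - 1], "N"), model, genome)
        assert eff.category == "downstream" and eff.distance_bp == 47

    def test_minus_strand_upstream_is_right_of_gene(self):
        genome, model = toy_gene("-")
        pos = model.cds_start_codon_pos() + 28  # 5' of a minus-strand gene
        eff = annotate_effect(SnpRecord("chrT", pos, genome["chrT"][pos - 1], "N"), model, genome)
        assert eff.category == "upstream" and eff.distance_bp == 28

    def test_utr_exon_position(self):
        genome, model = toy_gene("+", utr=10)
        pos = model.cds_start_codon_pos() - 6
        eff = annotate_effect(SnpRecord("chrT", pos, genome["chrT"][pos - 1], "N"), model, genome)
        assert eff.category == "UTR" and eff.distance_bp == 6

    def test_intron_position(self):
        genome, model = toy_gene("+")
        # split the single exon into two with an intron gap in the middle
        s, e = model.cds[0]
        split = GeneModel("TOY2", "chrT", "+", s, e + 50,
                          exons=[(s, s + 5), (s + 56, e + 50)],
                          cds=[(s, s + 5), (s + 56, e + 50)])
        eff = annotate_effect(SnpRecord("chrT", s + 20, "N", "A"), split, genome)
        assert eff.category == "intron"

    def test_cds_indel_is_frameshift(self):
        genome, model = toy_gene("+")
        pos = model.genomic_pos_of_cds_index(5)
        eff = annotate_effect(SnpRecord("chrT", pos, "AG", "-"), model, genome)
        assert eff.category == "frameshift"

    def test_invalid_cds_length_sets_error_flag(self):
        genome, model = toy_gene("+")
        s, e = model.cds[0]
        broken = GeneModel("TOY3", "chrT", "+", s, e - 1, exons=[(s, e - 1)], cds=[(s, e - 1)])
        eff = annotate_effect(SnpRecord("chrT", s + 3, "N", "A"), broken, genome)
        assert eff.error is not None

    def test_matches_full_cds_retranslation_oracle(self):
        """Codon-local annotation equals an oracle that rebuilds the mutant
        genome, re-splices the CDS and translates the whole protein, over
        >= 200 random variants on random multi-exon genes of both strands."""
        config = SimConfig(seed=13, genome_length_bp=100_000, n_genes=10,
                           n_sites_mutant=5, n_sites_wildtype=5, n_shared=2)
        rng = np.random.default_rng(13)
        genome, models = simulate_reference(config, rng)
        assert {m.strand for m in models} == {"+", "-"}
        chrom_seq = genome["chr1"]
        checked = 0
        while checked < 220:
            model = models[int(rng.integers(0, len(models)))]
            cds_idx = int(rng.integers(1, model.cds_length + 1))
            pos = model.genomic_pos_of_cds_index(cds_idx)
            ref = chrom_seq[pos - 1]
            alt = str(rng.choice([b for b in "ACGT" if b != ref]))
            eff = annotate_effect(SnpRecord("chr1", pos, ref, alt), model, genome)

            mutant_seq = chrom_seq[: pos - 1] + alt + chrom_seq[pos:]
            ref_prot = str(Seq(model.cds_sequence(chrom_seq)).translate())
            alt_prot = str(Seq(model.cds_sequence(mutant_seq)).translate())
            if ref_prot == alt_prot:
                expected = ("synonymous", None)
            else:
                i = next(k for k, (a, b) in enumerate(zip(ref_prot, alt_prot)) if a != b)
                if alt_prot[i] == "*":
                    expected = ("PTC", i + 1)
                else:
                    expected = ("non_synonymous", i + 1)
            assert eff.category == expected[0]
            if expected[1] is not None:
                assert eff.aa_position == expected[1]
            assert eff.error is None
            checked += 1


class TestAlleleReport:
    def test_printed_allele_table_counts(self):
        """The eight printed EMS alleles triage to six coding lesions
        (PTC or non-synonymous), four of them PTC."""
        alleles = datasets.gl13_allele_records(mutagen="EMS")
        assert len(alleles) == 8
        table, summary = allele_report(alleles)
        assert summary["n_coding"] == 6
        assert summary["n_ptc"] == 4
        ptc_rows = table[table["category"] == "PTC"]
        assert set(ptc_rows["ems_typical"]) == {True}

    def test_synonymous_only_allele_is_not_causal_candidate(self):
        alleles = datasets.gl13_allele_records()
        table, _ = allele_report({"gl13-Nec8495": alleles["gl13-Nec8495"]})
        row = table.iloc[0]
        assert row["category"] == "synonymous"
        assert not row["causal_candidate"]
        assert not row["ems_typical"]  # C->A transversion

    def test_allele_with_no_surviving_snps(self):
        table, summary = allele_report({"empty-allele": []})
        assert table.iloc[0]["category"] == "no candidate"
        assert summary["n_no_candidate"] == 1

    def test_report_with_genome_and_panel(self):
        genome, model = toy_gene("+")
        pos_ptc = model.genomic_pos_of_cds_index(4)  # CAG -> TAG
        pos_syn = model.genomic_pos_of_cds_index(9)  # CAG -> CAA
        causal = SnpRecord("chrT", pos_ptc, "C", "T", allele_name="a1")
        standing = SnpRecord("chrT", pos_syn, "G", "A", allele_name="a2")
        panel = PanelGenotypes()
        table, summary = allele_report(
            {"a1": [causal], "a2": [standing]}, models=[model], genome=genome, panel=panel
        )
        assert summary["n_ptc"] == 1
        assert table.set_index("allele").loc["a2", "category"] == "synonymous"
        # a2's variant is standing variation present in a founder -> excluded
        panel.add_call("chrT", pos_syn, "F01", "A", support=3)
        table, summary = allele_report(
            {"a1": [causal], "a2": [standing]}, models=[model], genome=genome, panel=panel
        )
        assert table.set_index("allele").loc["a2", "category"] == "no candidate"
        assert int(table.set_index("allele").loc["a2", "n_panel_excluded"]) == 1
        assert summary["n_ptc"] == 1
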