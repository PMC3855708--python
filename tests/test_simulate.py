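"""The synthetic-data generator: determinism, construction invariants, and
recovery of planted features by the analysis modules."""

import hashlib
from collections import Counter
from pathlib import Path

import numpy as np
import pytest
from Bio.Seq import Seq

from muwalk.ems import annotate_effect, exclude_panel_variants, is_ems_transition
from muwalk.pool_classify import classify_sites
from muwalk.readprep import decode_barcodes, length_filter, trim_mu_tir
from muwalk.simulate import (
    SimConfig,
    plant_ems_variants,
    plant_insertions,
    simulate_catalogs,
    simulate_reference,
    write_dataset,
)


def tiny_config(**overrides):
    base = dict(
        seed=5,
        genome_length_bp=150_000,
        n_genes=8,
        n_sites_mutant=25,
        n_sites_wildtype=12,
        n_shared=4,
        somatic_rate=3,
        interval_halfwidth_bp=30_000,
    )
    base.update(overrides)
    return SimConfig(**base)


class TestConfigValidation:
    def test_shared_exceeding_pool_rejected(self):
        with pytest.raises(ValueError):
            tiny_config(n_shared=13).validate()

    def test_genome_too_short_for_genes_rejected(self):
        with pytest.raises(ValueError, match="pack"):
            tiny_config(genome_length_bp=50_000).validate()


class TestSimulateReference:
    def test_gene_models_are_valid_and_non_overlapping(self):
        config = tiny_config()
        genome, models = simulate_reference(config)
        assert len(models) == config.n_genes
        seq = genome[config.chrom]
        spans = sorted((m.start, m.end) for m in models)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert e1 < s2
        for m in models:
            cds = m.cds_sequence(seq)
            assert len(cds) % 3 == 0
            protein = str(Seq(cds).translate())
            assert cds.startswith("ATG")
            assert protein.endswith("*") and "*" not in protein[:-1]

    def test_both_strands_represented(self):
        _, models = simulate_reference(tiny_config())
        assert {m.strand for m in models} == {"+", "-"}


class TestPlantInsertions:
    def test_zero_somatic_rate_means_no_count_one_sites(self):
        config = tiny_config(somatic_rate=0)
        mutant, wildtype, truth = simulate_catalogs(config)
        assert all(i.kind == "germinal" for i in truth.insertions)

    def test_all_shared_degenerate_case(self):
        config = tiny_config(n_sites_mutant=10, n_sites_wildtype=10, n_shared=10,
                             causal=False)
        mutant, wildtype, truth = simulate_catalogs(config)
        classified = classify_sites(mutant, wildtype)
        assert all(s.classification == "shared" for s in classified)

    def test_every_planted_feature_appears_exactly_once(self):
        truth = plant_insertions(tiny_config())
        keys = [(i.chrom, i.tsd_start) for i in truth.insertions]
        assert len(keys) == len(set(keys))

    def test_published_pool_structure_classifies_exactly(self):
        config = SimConfig(seed=3)  # defaults: 471 mutant / 251 wild-type / 82 shared
        mutant, wildtype, _ = simulate_catalogs(config)
        counts = Counter(s.classification for s in classify_sites(mutant, wildtype))
        assert counts == {"mutant_specific": 389, "wildtype_specific": 169, "shared": 82}


class TestSynthesizeReads:
    def test_reads_survive_prep_with_nothing_lost_to_length(self, small_config, sim_dataset):
        """Every synthesized read decodes, trims, and passes the >= 91 bp
        filter: pool sizes match the generator's output exactly."""
        _, _, _, sim = sim_dataset
        mixed = sim.reads["mutant"] + sim.reads["wildtype"]
        pools, undecoded = decode_barcodes(mixed, small_config.barcodes)
        assert not undecoded
        for pool in ("mutant", "wildtype"):
            trimmed = [t for r in pools[pool] if (t := trim_mu_tir(r, pool_label=pool))]
            assert len(trimmed) == len(sim.reads[pool])
            kept = list(length_filter(trimmed, small_config.min_flank))
            assert len(kept) == len(trimmed)

    def test_site_counts_reproduce_drawn_counts(self, sim_dataset):
        """Pipeline self-consistency: a germinal site's catalog count equals
        the count the generator drew for it (splitting across flanks and
        anchor pairing conserve reads)."""
        _, _, truth, sim = sim_dataset
        from muwalk.pipeline import catalog_from_alignments

        catalog = catalog_from_alignments(sim.alignments["mutant"], "mutant")
        by_key = {s.key: s for s in catalog.sites}
        for i, ins in enumerate(truth.insertions):
            if "mutant" not in ins.pools or ins.kind != "germinal":
                continue
            if sim.counts[(i, "mutant")] < 10:
                continue
            assert by_key[(ins.chrom, ins.tsd_start, ins.tsd_end)].read_count_mutant == \
                sim.counts[(i, "mutant")]


class TestPlantEmsVariants:
    def test_planted_categories_recovered_by_annotation(self):
        config = tiny_config()
        rng = np.random.default_rng(config.seed)
        genome, models = simulate_reference(config, rng)
        snps, panel, planted = plant_ems_variants(config, genome, models, rng)
        by_name = {v.allele_name: v for v in planted}
        model_of = {m.gene_id: m for m in models}
        for snp in snps:
            v = by_name[snp.allele_name]
            if v.decoy is not None:
                continue
            eff = annotate_effect(snp, model_of[v.gene_id], genome)
            assert eff.category == v.expected_category
            assert is_ems_transition(snp)

    def test_decoys_are_rejected_by_their_filters(self):
        config = tiny_config()
        rng = np.random.default_rng(config.seed)
        genome, models = simulate_reference(config, rng)
        snps, panel, planted = plant_ems_variants(config, genome, models, rng)
        by_name = {v.allele_name: v for v in planted}
        kept = {s.allele_name for s in exclude_panel_variants(snps, panel)}
        for v in planted:
            if v.decoy == "panel":
                assert v.allele_name not in kept
            else:
                assert v.allele_name in kept
        for snp in snps:
            if by_name[snp.allele_name].decoy == "transversion":
                assert not is_ems_transition(snp)


class TestDeterminism:
    def test_written_dataset_is_byte_identical_across_runs(self, tmp_path):
        config = tiny_config()
        d1, d2 = tmp_path / "a", tmp_path / "b"
        write_dataset(config, d1)
        write_dataset(config, d2)
        files = sorted(p.name for p in d1.iterdir())
        assert files == sorted(p.name for p in d2.iterdir())
        for name in files:
            h1 = hashlib.sha256((d1 / name).read_bytes()).hexdigest()
            h2 = hashlib.sha256((d2 / name).read_bytes()).hexdigest()
            assert h1 == h2, f"{name} differs between identically seeded runs"

    def test_different_seed_changes_positions(self):
        t1 = plant_insertions(tiny_config(seed=5))
        t2 = plant_insertions(tiny_config(seed=6))
        assert [i.tsd_start for i in t1.insertions] != [i.tsd_start for i in t2.insertions]
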