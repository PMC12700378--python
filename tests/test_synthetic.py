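"""Synthetic methylome generator: determinism, planting rules, recovery."""

import numpy as np
import pytest

import methylscan as m


GTNNAC = m.Motif("GTNNAC", 4)
CTAAG = m.Motif("CTAAG", 3)
CTNAG = m.Motif("CTNAG", 3)


class TestGenerateGenome:
    def test_deterministic(self):
        spec = m.MethylomeSpec(genome_length=10_000, n_genes=5)
        a = m.generate_genome(spec, 1)
        b = m.generate_genome(spec, 1)
        assert a[0].sequence == b[0].sequence
        assert a[1] == b[1]

    def test_gc_fraction_within_binomial_error(self):
        spec = m.MethylomeSpec(genome_length=100_000, gc=0.30)
        genome, _ = m.generate_genome(spec, 3)
        gc = sum(genome.sequence.count(b) for b in "GC") / len(genome)
        assert gc == pytest.approx(0.30, abs=0.02)

    def test_no_genes_valid(self):
        genome, genes = m.generate_genome(m.MethylomeSpec(genome_length=2000), 1)
        assert genes == [] and len(genome) == 2000

    def test_genes_non_overlapping_both_strands(self):
        spec = m.MethylomeSpec(genome_length=50_000, n_genes=30)
        _, genes = m.generate_genome(spec, 5)
        assert len(genes) == 30
        ordered = sorted(genes, key=lambda g: g.start)
        for a, b in zip(ordered, ordered[1:]):
            assert a.end <= b.start
        assert {g.strand for g in genes} == {"+", "-"}

    def test_infeasible_packing_errors(self):
        spec = m.MethylomeSpec(genome_length=5000, n_genes=10, gene_length=(900, 1000))
        with pytest.raises(ValueError):
            m.generate_genome(spec, 1)


class TestPlantMethylome:
    def test_specific_overrides_leaky_parent(self):
        spec = m.MethylomeSpec(
            genome_length=50_000,
            motifs=(m.PlantedMotif(CTAAG, 0.9, leak_parent=CTNAG, leak_p=0.4),),
        )
        genome, _ = m.generate_genome(spec, 2)
        planted = m.plant_methylome(genome, spec, seed=2)
        specific = {(s.mod_position, s.strand) for s in m.scan_motif(genome, CTAAG)}
        parent = {(s.mod_position, s.strand) for s in m.scan_motif(genome, CTNAG)}
        for pos, strand in specific:
            assert planted.p_native[strand][pos] == pytest.approx(0.9)
        leak_only = parent - specific
        assert leak_only
        for pos, strand in leak_only:
            assert planted.p_native[strand][pos] == pytest.approx(0.4)

    def test_no_motifs_all_background(self):
        spec = m.MethylomeSpec(genome_length=5000)
        genome, _ = m.generate_genome(spec, 4)
        planted = m.plant_methylome(genome, spec, seed=4)
        values = planted.p_native["+"]
        adenines = np.array([c == "A" for c in genome.sequence])
        assert np.all(values[adenines] == spec.p_background)
        assert np.all(np.isnan(values[~adenines]))

    def test_artifacts_present_in_both_truths(self):
        spec = m.MethylomeSpec(genome_length=20_000, artifacts=(10, 0.3))
        genome, _ = m.generate_genome(spec, 6)
        planted = m.plant_methylome(genome, spec, seed=6)
        assert len(planted.artifact_positions) == 10
        for pos, strand in planted.artifact_positions:
            assert planted.p_native[strand][pos] == pytest.approx(0.3)
            assert planted.p_wga[strand][pos] == pytest.approx(0.3)
        # elsewhere the WGA truth is the error floor
        other = np.flatnonzero(~np.isnan(planted.p_wga["+"]))
        floor = [p for p in other if (int(p), "+") not in planted.artifact_positions]
        assert np.allclose(planted.p_wga["+"][floor], spec.wga_error)

    def test_promoter_dip_on_coding_strand_only(self):
        spec = m.MethylomeSpec(
            genome_length=30_000, n_genes=10, promoter_dip=(50, 0.001)
        )
        genome, genes = m.generate_genome(spec, 7)
        planted = m.plant_methylome(genome, spec, genes, seed=7)
        def upstream_clear(g):
            return not any(
                o is not g and o.start < g.start and o.end > g.start - 50
                for o in genes
            )

        gene = next(
            g for g in genes if g.strand == "+" and g.start > 60 and upstream_clear(g)
        )
        window = slice(gene.start - 50, gene.start)
        coding = planted.p_native["+"][window]
        template = planted.p_native["-"][window]
        assert np.nanmax(coding) == pytest.approx(0.001)
        assert np.nanmax(template) == pytest.approx(spec.p_background)


class TestSimulate:
    def test_p_one_always_methylated(self):
        spec = m.MethylomeSpec(
            genome_length=5000, motifs=(m.PlantedMotif(GTNNAC, 1.0),),
            replicate_jitter_sd=0.0,
        )
        ds = m.simulate_methylome(spec, 9)
        motif_keys = {
            (s.mod_position, s.strand) for s in m.scan_motif(ds.genome, GTNNAC)
        }
        for records in ds.replicates:
            for rec in records:
                if (rec.position, rec.strand) in motif_keys:
                    assert rec.n_mod == rec.valid_coverage

    def test_pooled_mean_within_binomial_bound(self):
        spec = m.MethylomeSpec(
            genome_length=120_000, motifs=(m.PlantedMotif(GTNNAC, 0.75),)
        )
        ds = m.simulate_methylome(spec, 10)
        idx = m.index_summaries(m.aggregate_replicates(ds.replicates))
        sites = m.scan_motif(ds.genome, GTNNAC)
        result = m.summarize_motif(GTNNAC, sites, idx)
        assert result.n_sites >= 500
        assert result.mean_freq == pytest.approx(0.75, abs=0.02)

    def test_same_seed_byte_identical_files(self, tmp_path):
        spec = m.MethylomeSpec(genome_length=5000, n_genes=3)
        for d in ("a", "b"):
            m.simulate_methylome(spec, 11, tmp_path / d)
        for name in ("genome.fasta", "genes.gff3", "replicate_1.bedmethyl.tsv", "wga.bedmethyl.tsv"):
            assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()

    def test_depth_always_positive(self):
        spec = m.MethylomeSpec(genome_length=3000, coverage_mean=2.0)
        ds = m.simulate_methylome(spec, 12)
        assert min(r.valid_coverage for r in ds.replicates[0]) >= 1

    def test_full_coupling_suppresses_hemi_calls(self):
        spec = m.MethylomeSpec(
            genome_length=150_000,
            motifs=(m.PlantedMotif(GTNNAC, 0.5, correlation=1.0),),
        )
        ds = m.simulate_methylome(spec, 13)
        idx = m.index_summaries(m.aggregate_replicates(ds.replicates))
        pairs, _ = m.pair_palindrome_sites(GTNNAC, m.scan_motif(ds.genome, GTNNAC))
        coupled = m.palindrome_proportions(pairs, idx, threshold=0.5)

        spec_free = m.MethylomeSpec(
            genome_length=150_000,
            motifs=(m.PlantedMotif(GTNNAC, 0.5, correlation=0.0),),
        )
        ds_free = m.simulate_methylome(spec_free, 13)
        idx_free = m.index_summaries(m.aggregate_replicates(ds_free.replicates))
        pairs_free, _ = m.pair_palindrome_sites(
            GTNNAC, m.scan_motif(ds_free.genome, GTNNAC)
        )
        free = m.palindrome_proportions(pairs_free, idx_free, threshold=0.5)
        assert coupled.proportions["hemi"] < free.proportions["hemi"] / 2

    def test_palindrome_mix_truth_table(self):
        spec = m.MethylomeSpec(
            genome_length=80_000,
            motifs=(m.PlantedMotif(GTNNAC, 0.9, palindrome_mix=(0.5, 0.3, 0.2)),),
        )
        ds = m.simulate_methylome(spec, 14)
        truth = ds.planted.pair_classes
        assert set(truth["true_call"]) <= {"full", "hemi", "unmethylated"}
        observed = truth["true_call"].value_counts(normalize=True)
        assert observed["full"] == pytest.approx(0.5, abs=0.08)
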