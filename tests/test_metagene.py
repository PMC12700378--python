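"""Metagene profiles: region geometry, orientation, statistics."""

import numpy as np
import pandas as pd
import pytest

import methylscan as m
from methylscan.formats import reverse_complement
from methylscan.metagene import _gene_region_intervals, region_names
from methylscan.site_stats import SiteSummary


def summary(pos, mean, strand="+", contig="g"):
    return SiteSummary(contig, pos, strand, "6mA", mean, 0.0, 1, (mean,))


def gene(start, end, strand="+", gene_id="gene_1", contig="g"):
    return m.GeneFeature(contig, start, end, strand, gene_id)


def everywhere(length, freq, contig="g"):
    out = []
    for pos in range(length):
        out.append(summary(pos, freq, "+", contig))
        out.append(summary(pos, freq, "-", contig))
    return out


class TestRegionGeometry:
    def test_regions_partition_the_gene_and_flanks(self):
        for strand in "+-":
            intervals = _gene_region_intervals(gene(2000, 3005, strand), 1000, 50, 10)
            assert len(intervals) == 50
            covered = sorted((a, b) for _, a, b in intervals)
            assert covered[0][0] == 1000 and covered[-1][1] == 4005
            for (_, b1), (a2, _) in zip(covered, covered[1:]):
                assert b1 == a2  # contiguous, non-overlapping

    def test_bin_boundaries_floor_rule(self):
        intervals = dict(
            (r, (a, b)) for r, a, b in _gene_region_intervals(gene(0, 1003, "+"), 1000, 50, 10)
        )
        assert intervals["B1"] == (0, 100)
        assert intervals["B10"] == (902, 1003)  # floor(9*1003/10) = 902

    def test_upstream_orientation(self):
        plus = dict((r, (a, b)) for r, a, b in _gene_region_intervals(gene(2000, 3000, "+"), 1000, 50, 10))
        minus = dict((r, (a, b)) for r, a, b in _gene_region_intervals(gene(2000, 3000, "-"), 1000, 50, 10))
        assert plus["U20"] == (1950, 2000)  # immediately 5' of the start
        assert minus["U20"] == (3000, 3050)  # minus gene: upstream at higher coords
        assert minus["U1"] == (3950, 4000)


class TestBuildProfile:
    def test_uniform_input_flat_profile(self):
        genes = [gene(2000, 3000, "+")]
        profile = m.build_profile(genes, everywhere(5000, 0.3), {"g": 5000}, n_bootstrap=50)
        assert len(profile.table) == 100  # 50 regions x 2 relative strands
        assert np.allclose(profile.table["median"], 0.3)
        assert np.allclose(profile.table["mean"], 0.3)

    def test_short_gene_excluded(self):
        genes = [gene(100, 105), gene(2000, 3000)]
        profile = m.build_profile(genes, everywhere(5000, 0.3), {"g": 5000}, n_bootstrap=10)
        assert profile.n_genes_excluded == 1
        assert profile.n_genes_used == 1

    def test_flank_truncated_at_contig_end(self):
        genes = [gene(100, 1200)]  # upstream flank reaches past the origin
        profile = m.build_profile(genes, everywhere(3000, 0.5), {"g": 3000}, n_bootstrap=10)
        u1 = profile.table.query("region == 'U1' and rel_strand == 'sense'")
        assert np.isnan(u1["median"].item())  # window entirely off-contig

    def test_sense_antisense_separation(self):
        # methylation only on the coding strand of a plus gene
        sites = [summary(pos, 0.9, "+") for pos in range(2000, 3000)] + [
            summary(pos, 0.1, "-") for pos in range(2000, 3000)
        ]
        profile = m.build_profile([gene(2000, 3000, "+")], sites, {"g": 5000}, n_bootstrap=10)
        body = profile.table[profile.table.region.str.startswith("B")]
        assert np.allclose(body.query("rel_strand == 'sense'")["median"], 0.9)
        assert np.allclose(body.query("rel_strand == 'antisense'")["median"], 0.1)

    def test_orientation_invariance(self, planted_dataset):
        genome = planted_dataset.genome
        genes = planted_dataset.genes
        summaries = m.aggregate_replicates(planted_dataset.replicates)
        length = len(genome)
        flipped_sites = [
            SiteSummary(
                s.contig, length - 1 - s.position,
                "-" if s.strand == "+" else "+",
                s.mod_code, s.mean_freq, s.sd_freq, s.n_replicates,
                s.per_replicate_freq,
            )
            for s in summaries
        ]
        flipped_genes = [
            m.GeneFeature(
                g.contig, length - g.end, length - g.start,
                "-" if g.strand == "+" else "+", g.gene_id, g.annotation,
            )
            for g in genes
        ]
        a = m.build_profile(
            genes, summaries, {genome.contig_id: length}, n_bootstrap=2, seed=9
        )
        b = m.build_profile(
            flipped_genes, flipped_sites,
            {genome.contig_id: length}, n_bootstrap=2, seed=9,
        )
        pd.testing.assert_frame_equal(
            a.table.drop(columns=["ci_lo", "ci_hi"]),
            b.table.drop(columns=["ci_lo", "ci_hi"]),
        )

    def test_promoter_dip_minimum_at_nearest_window(self, planted_dataset):
        summaries = m.aggregate_replicates(planted_dataset.replicates)
        profile = m.build_profile(
            planted_dataset.genes, summaries,
            {planted_dataset.genome.contig_id: len(planted_dataset.genome)},
            n_bootstrap=50,
        )
        upstream = profile.table.query("rel_strand == 'sense'").set_index("region")
        medians = upstream.loc[[f"U{i}" for i in range(1, 21)], "median"]
        assert medians.idxmin() == "U20"


class TestUpstreamWindowTest:
    def make_matrix(self, shift=0.0, n_genes=80, seed=0):
        rng = np.random.default_rng(seed)
        data = {f"U{i}": rng.beta(2, 20, size=n_genes) for i in range(1, 21)}
        frame = pd.DataFrame(data)
        if shift:
            frame["U20"] = np.clip(frame["U20"] - shift, 0.0005, 1)
        return frame

    def test_identical_distributions_share_one_letter(self):
        letters, _ = m.upstream_window_test(self.make_matrix())
        assert set(letters["letters"]) == {"a"}

    def test_shifted_window_gets_distinct_letter(self):
        letters, pairs = m.upstream_window_test(self.make_matrix(shift=0.09, n_genes=150))
        by_window = dict(zip(letters["window"], letters["letters"]))
        u20 = set(by_window["U20"])
        others = set("".join(v for k, v in by_window.items() if k != "U20"))
        assert u20 and not (u20 & others)

    def test_deterministic(self):
        frame = self.make_matrix(shift=0.05, n_genes=100, seed=3)
        first, _ = m.upstream_window_test(frame)
        second, _ = m.upstream_window_test(frame)
        pd.testing.assert_frame_equal(first, second)


class TestBodyBinContrast:
    def make_bins(self, bump=0.0, n_genes=200, seed=0):
        rng = np.random.default_rng(seed)
        cols = {}
        for i in range(1, 11):
            for rel in ("sense", "antisense"):
                values = rng.normal(0.08, 0.02, size=n_genes)
                if bump and i == 1 and rel == "sense":
                    values = values + bump
                cols[(f"B{i}", rel)] = values
        return pd.DataFrame(cols)

    def test_uniform_no_significant_bins(self):
        frame = m.body_bin_contrast(self.make_bins())
        assert len(frame) == 20
        assert not frame["significant"].any()
        assert np.allclose(frame["difference"].abs(), 0.0, atol=0.01)

    def test_planted_bump_detected(self):
        frame = m.body_bin_contrast(self.make_bins(bump=0.05))
        hit = frame[(frame["bin"] == "B1") & (frame["rel_strand"] == "sense")]
        assert hit["significant"].item()
        assert hit["difference"].item() > 0.03
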