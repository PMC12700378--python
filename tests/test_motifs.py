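"""Motif model: scanning, palindromes, summaries, labelling, digestion."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import methylscan as m
from methylscan.motifs import IUPAC
from methylscan.scenarios import brute_force_scan
from methylscan.site_stats import SiteSummary

iupac_strings = st.text(alphabet=sorted(IUPAC), min_size=1, max_size=8)


def summary(pos, mean, strand="+", reps=None, contig="g"):
    reps = tuple(reps) if reps is not None else (mean,)
    return SiteSummary(contig, pos, strand, "6mA", mean, 0.0, len(reps), reps)


class TestIupac:
    @given(iupac_strings)
    def test_reverse_complement_is_an_involution(self, s):
        assert m.reverse_complement_iupac(m.reverse_complement_iupac(s)) == s

    def test_palindromes_of_the_catalogue(self):
        palindromic = {mo.iupac for mo in m.MOTIF_CATALOGUE if mo.is_palindromic}
        assert palindromic == {"CTAG", "CTNAG", "CTNNAG", "GTNNAC", "TGNNCA"}

    def test_mod_base_compatibility_enforced(self):
        with pytest.raises(ValueError):
            m.Motif("CTAG", 1)  # T cannot carry 6mA
        with pytest.raises(ValueError):
            m.Motif("CTAG", 2, mod_code="5mC")

    def test_canonical_prefers_smaller_string_when_valid(self):
        assert m.Motif("GTNNAC", 4).canonical() == m.Motif("GTNNAC", 4)
        # TACGTA's reverse complement is itself; a non-palindromic motif whose
        # swap would lose the adenine stays as written
        assert m.Motif("CTAAG", 3).canonical() == m.Motif("CTAAG", 3)


class TestScanMotif:
    def test_palindrome_reports_both_strands(self):
        genome = m.GenomeSequence("g", "ACTAGT")
        sites = m.scan_motif(genome, m.Motif("CTAG", 2))
        assert {(s.strand, s.mod_position) for s in sites} == {("+", 3), ("-", 2)}
        assert all(s.match_start == 1 for s in sites)

    def test_degenerate_palindrome_coordinates(self):
        genome = m.GenomeSequence("g", "GTCAAC")
        sites = m.scan_motif(genome, m.Motif("GTNNAC", 4))
        assert {(s.strand, s.mod_position) for s in sites} == {("+", 4), ("-", 1)}

    def test_no_match(self):
        assert m.scan_motif(m.GenomeSequence("g", "AAAAAA"), m.Motif("CTAG", 2)) == []

    def test_n_in_genome_never_matches(self):
        genome = m.GenomeSequence("g", "CTNAG")
        assert m.scan_motif(genome, m.Motif("CTNAG", 3)) == []

    def test_overlapping_matches_all_reported(self):
        genome = m.GenomeSequence("g", "CTAGCTAG")
        sites = m.scan_motif(genome, m.Motif("CTAG", 2))
        assert {s.match_start for s in sites} == {0, 4}

    @given(st.integers(0, 2**31 - 1))
    def test_matches_brute_force_on_random_sequence(self, seed):
        rng = np.random.default_rng(seed)
        seq = "".join(rng.choice(list("ACGTN"), size=300, p=[0.24] * 4 + [0.04]))
        genome = m.GenomeSequence("g", seq)
        for motif in (m.Motif("CTAG", 2), m.Motif("GTNNAC", 4), m.Motif("CYTAGC", 3)):
            got = {
                (s.match_start, s.strand, s.mod_position)
                for s in m.scan_motif(genome, motif)
            }
            assert got == brute_force_scan(seq, motif)

    def test_specified_motifs_are_subsets(self, planted_dataset):
        genome = planted_dataset.genome
        child = {s.mod_position for s in m.scan_motif(genome, m.Motif("CTAAG", 3)) if s.strand == "+"}
        parent = {s.mod_position for s in m.scan_motif(genome, m.Motif("CTNAG", 3)) if s.strand == "+"}
        assert child <= parent


class TestPalindromePairs:
    def test_pairing_coordinates(self):
        genome = m.GenomeSequence("g", "AAAAAAAAAACTAGAA")
        motif = m.Motif("CTAG", 2)
        pairs, unpaired = m.pair_palindrome_sites(motif, m.scan_motif(genome, motif))
        assert unpaired == []
        (pair,) = pairs
        assert (pair.plus_site.mod_position, pair.minus_site.mod_position) == (12, 11)

    def test_degenerate_pairing(self):
        genome = m.GenomeSequence("g", "GTCAAC")
        motif = m.Motif("GTNNAC", 4)
        ((pair,), _) = m.pair_palindrome_sites(motif, m.scan_motif(genome, motif))
        assert (pair.plus_site.mod_position, pair.minus_site.mod_position) == (4, 1)

    def test_non_palindromic_motif_rejected(self):
        with pytest.raises(ValueError):
            m.pair_palindrome_sites(m.Motif("TTCTNAG", 5), [])

    def test_pairing_total_on_planted_genome(self, planted_dataset):
        motif = m.Motif("GTNNAC", 4)
        sites = m.scan_motif(planted_dataset.genome, motif)
        pairs, unpaired = m.pair_palindrome_sites(motif, sites)
        assert unpaired == []
        assert len(pairs) * 2 == len(sites)


class TestClassifyPalindrome:
    def make_pair(self, plus_freq, minus_freq):
        genome = m.GenomeSequence("g", "AAAAAAAAAACTAGAA")
        motif = m.Motif("CTAG", 2)
        (pair,), _ = m.pair_palindrome_sites(motif, m.scan_motif(genome, motif))
        idx = {}
        if plus_freq is not None:
            idx[("g", 12, "+", "6mA")] = summary(12, plus_freq)
        if minus_freq is not None:
            idx[("g", 11, "-", "6mA")] = summary(11, minus_freq, strand="-")
        return pair, idx

    @pytest.mark.parametrize(
        "freqs, call",
        [
            ((0.90, 0.75), "full"),
            ((0.90, 0.30), "hemi"),
            ((0.30, 0.90), "hemi"),
            ((0.20, 0.10), "unmethylated"),
            ((0.70, 0.70), "full"),  # inclusive threshold
        ],
    )
    def test_threshold_rule(self, freqs, call):
        pair, idx = self.make_pair(*freqs)
        assert m.classify_palindrome(pair, idx, 0.70) == call

    def test_missing_summary_excluded(self):
        pair, idx = self.make_pair(0.9, None)
        assert m.classify_palindrome(pair, idx, 0.70) is None

    def test_proportions_of_known_calls(self):
        genome = m.GenomeSequence("g", "CTAGACTAGACTAGACTAGA")
        motif = m.Motif("CTAG", 2)
        pairs, _ = m.pair_palindrome_sites(motif, m.scan_motif(genome, motif))
        freqs = {0: (0.9, 0.9), 5: (0.9, 0.1), 10: (0.8, 0.2), 15: (0.1, 0.1)}
        idx = {}
        for start, (pf, mf) in freqs.items():
            idx[("g", start + 2, "+", "6mA")] = summary(start + 2, pf, reps=(pf, pf))
            idx[("g", start + 1, "-", "6mA")] = summary(
                start + 1, mf, strand="-", reps=(mf, mf)
            )
        calls = m.palindrome_proportions(pairs, idx, 0.70)
        assert calls.proportions == {"full": 0.25, "hemi": 0.50, "unmethylated": 0.25}
        assert calls.replicate_sd == {"full": 0.0, "hemi": 0.0, "unmethylated": 0.0}

    def test_empty_after_exclusions_errors(self):
        pair, _ = self.make_pair(None, None)
        with pytest.raises(ValueError):
            m.palindrome_proportions([pair], {}, 0.70)


class TestSummarizeMotif:
    def test_mean_and_fraction(self):
        motif = m.Motif("CTAG", 2)
        sites = [
            m.MotifSite("CTAG", "g", p - 2, "+", p) for p in (10, 20, 30)
        ]
        idx = {("g", p, "+", "6mA"): summary(p, f) for p, f in zip((10, 20, 30), (0.8, 0.7, 0.6))}
        result = m.summarize_motif(motif, sites, idx, 0.70)
        assert result.mean_freq == pytest.approx(0.70)
        assert result.genomic_methylation_fraction == pytest.approx(2 / 3)
        assert (result.n_sites, result.n_unjoined) == (3, 0)

    def test_unjoined_counted_zero_joined_errors(self):
        motif = m.Motif("CTAG", 2)
        sites = [m.MotifSite("CTAG", "g", 8, "+", 10)]
        with pytest.raises(ValueError):
            m.summarize_motif(motif, sites, {}, 0.70)

    def test_planted_recovery_within_sampling_error(self, planted_dataset, planted_index):
        motif = m.Motif("GTNNAC", 4)
        sites = m.scan_motif(planted_dataset.genome, motif)
        result = m.summarize_motif(motif, sites, planted_index)
        assert result.n_sites >= 200
        assert result.mean_freq == pytest.approx(0.80, abs=0.02)

    def test_ambiguous_parent_less_methylated_than_specific(
        self, planted_dataset, planted_index
    ):
        # data planted only at CTAG: the looser CTNAG inherits diluted signal
        genome = planted_dataset.genome
        specific = m.summarize_motif(
            m.Motif("CTAG", 2), m.scan_motif(genome, m.Motif("CTAG", 2)), planted_index
        )
        ambiguous = m.summarize_motif(
            m.Motif("CTNAG", 3), m.scan_motif(genome, m.Motif("CTNAG", 3)), planted_index
        )
        assert specific.mean_freq >= ambiguous.mean_freq


class TestAssignSites:
    def test_multi_label_and_non_motif(self):
        genome = m.GenomeSequence("g", "ACTAGTA")
        motifs = [m.Motif("CTAG", 2), m.Motif("CTAGY", 2)]
        sites = [summary(3, 0.9), summary(6, 0.2)]
        table = m.assign_sites(sites, motifs, genome)
        by_pos = table.set_index("position")
        assert by_pos.loc[3, "motifs"] == "CTAG;CTAGY"
        assert by_pos.loc[6, "motifs"] == "non-motif"

    def test_planted_high_sites_mostly_captured(self, planted_dataset, planted_summaries):
        motifs = [m.Motif("GTNNAC", 4), m.Motif("CTAG", 2)]
        six_ma = [s for s in planted_summaries if s.mod_code == "6mA"]
        assigned = m.assign_sites(six_ma, motifs, planted_dataset.genome)
        stats = m.motifs.capture_stats(assigned, thresholds=(0.70,))
        # artifacts are the only planted non-motif high sites
        assert stats["captured_fraction"].item() >= 0.9


class TestDigest:
    def build(self, freq):
        genome = m.GenomeSequence("g", "AAAAGATCAAAA")
        idx = {
            ("g", 5, "+", "6mA"): summary(5, freq),
            ("g", 6, "-", "6mA"): summary(6, freq, strand="-"),
        }
        return genome, idx

    def test_unmethylated_site_cut_by_dpnii_only(self):
        genome, idx = self.build(0.05)
        dpnii = m.in_silico_digest(genome, idx, m.ENZYMES["DpnII"])
        dpni = m.in_silico_digest(genome, idx, m.ENZYMES["DpnI"])
        assert len(dpnii.fragments) == 2 and len(dpni.fragments) == 1

    def test_methylated_site_cut_by_dpni_only(self):
        genome, idx = self.build(0.95)
        dpnii = m.in_silico_digest(genome, idx, m.ENZYMES["DpnII"])
        dpni = m.in_silico_digest(genome, idx, m.ENZYMES["DpnI"])
        assert len(dpni.fragments) == 2 and len(dpnii.fragments) == 1
        assert sorted(dpni.fragments) == [4, 8]

    def test_insensitive_always_cuts(self):
        genome = m.GenomeSequence("g", "AAGTCAACAA")
        result = m.in_silico_digest(genome, {}, m.ENZYMES["Hpy166II"])
        assert len(result.fragments) == 2

    def test_fragments_conserve_length_and_controls_partition(
        self, planted_dataset, planted_index
    ):
        genome = planted_dataset.genome
        dpni = m.in_silico_digest(genome, planted_index, m.ENZYMES["DpnI"])
        dpnii = m.in_silico_digest(genome, planted_index, m.ENZYMES["DpnII"])
        assert sum(dpni.fragments) == len(genome) == sum(dpnii.fragments)
        cuts_i, cuts_ii = set(dpni.cut_positions), set(dpnii.cut_positions)
        assert not (cuts_i & cuts_ii)
        all_gatc = {
            s.match_start
            for s in m.scan_motif(genome, m.Motif("GATC", 1))
            if s.strand == "+"
        }
        assert (cuts_i | cuts_ii) == all_gatc
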