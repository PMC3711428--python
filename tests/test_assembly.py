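"""In-silico cloning: sites, digestion, ligation, UTR assembly."""

import pytest
from Bio.Restriction import Restriction
from Bio.Seq import Seq

from utrtune.assembly import (CONTROL_TAIL, DISTANCE_CLASSES, ENZYMES, LEADER,
                              DNASequence, MotifCassette, all_motif_offsets,
                              assemble_utr, concatenate_motifs, digest,
                              find_sites, klenow_fill, ligate, motif_cassette,
                              motif_offset, pcr_amplify, read_fasta, revcomp,
                              self_ligate, write_fasta)

MOTIFS = ("Kl", "Kl2", "MS2SL", "Fr15")


class TestSequencePrimitives:
    def test_revcomp(self):
        assert revcomp("GGATCC") == "GGATCC"  # palindrome
        assert revcomp("AACGT") == "ACGTT"

    def test_invalid_bases_rejected(self):
        with pytest.raises(ValueError, match="invalid bases"):
            DNASequence("ACGU")

    def test_circular_cannot_carry_overhangs(self):
        with pytest.raises(ValueError, match="circular"):
            DNASequence("GATCAA", "circular", five_prime_overhang="GATC")

    def test_overhang_must_prefix_top_strand(self):
        with pytest.raises(ValueError, match="prefix"):
            DNASequence("AAAA", five_prime_overhang="GATC")

    def test_enzyme_overhangs(self):
        assert ENZYMES["BamHI"].overhang == "GATC"
        assert ENZYMES["BglII"].overhang == "GATC"
        assert ENZYMES["NheI"].overhang == "CTAG"
        assert ENZYMES["NotI"].overhang == "GGCC"


class TestFindSites:
    def test_hand_picked_positions(self):
        assert find_sites(DNASequence("AAGGATCCTT"), "BamHI") == [3]
        assert find_sites(DNASequence("GGATCCGGATCC"), "BamHI") == [1, 7]
        assert find_sites(DNASequence("AAAA"), "BamHI") == []

    def test_circular_site_across_origin(self):
        # site GGATCC split as ...TCC | GGA... across the origin
        seq = DNASequence("TCCAAAAAGGA", "circular")
        assert find_sites(seq, "BamHI") == [9]
        assert find_sites(DNASequence(seq.bases), "BamHI") == []

    def test_unknown_enzyme_rejected(self):
        with pytest.raises(ValueError, match="enzyme"):
            find_sites(DNASequence("GGATCC"), "EcoRI")

    @pytest.mark.parametrize("enzyme", ["BamHI", "BglII", "NheI", "NotI",
                                        "NcoI", "SpeI", "AgeI", "HindIII"])
    def test_against_reference_implementation(self, enzyme):
        """Site positions agree with Bio.Restriction on assembled UTRs.

        The reference reports 1-based top-strand cut positions, i.e. site
        start + the enzyme's cut offset.
        """
        enz = ENZYMES[enzyme]
        ref = getattr(Restriction, enzyme)
        for motif in MOTIFS:
            for k in (1, 3):
                cassette = motif_cassette(motif, k)
                _spec, utr = assemble_utr(120, cassette, seed=5)
                ours = [p + enz.cut_offset for p in find_sites(utr, enzyme)]
                theirs = ref.search(Seq(utr.bases))
                assert ours == theirs


class TestDigest:
    def test_single_cut_overhang_bookkeeping(self):
        frags = digest(DNASequence("AAGGATCCTT"), "BamHI")
        assert [f.bases for f in frags] == ["AAG", "GATCCTT"]
        assert frags[0].three_prime_overhang == "GATC"
        assert frags[1].five_prime_overhang == "GATC"
        assert frags[0].five_prime_overhang == ""
        assert frags[1].three_prime_overhang == ""

    def test_base_conservation_linear(self):
        seq = DNASequence("AAGGATCCTTAGATCTAAGGATCCAA")
        frags = digest(seq, ["BamHI", "BglII"])
        assert "".join(f.bases for f in frags) == seq.bases

    def test_no_sites_returns_input(self):
        seq = DNASequence("AAAA")
        assert digest(seq, "BamHI") == [seq]

    def test_circular_double_digest(self):
        """A circular molecule cut at two sites gives two linear fragments
        whose bases are a rotation of the original."""
        seq = DNASequence("GGATCCAAAAAGATCTTTTT", "circular")
        frags = digest(seq, ["BamHI", "BglII"])
        assert len(frags) == 2
        joined = "".join(f.bases for f in frags)
        assert len(joined) == len(seq.bases)
        assert joined in seq.bases + seq.bases  # rotation
        assert all(f.five_prime_overhang == "GATC" for f in frags)

    def test_digest_then_religate_round_trip(self):
        seq = DNASequence("AAGGATCCTTAAGGATCCAA")
        frags = digest(seq, "BamHI")
        out = frags[0]
        for frag in frags[1:]:
            out = ligate(out, frag)
        assert out.bases == seq.bases


class TestLigation:
    def test_sticky_requires_matching_ends(self):
        a = DNASequence("AAG", three_prime_overhang="GATC")
        b = DNASequence("CTAGAA", five_prime_overhang="CTAG")
        with pytest.raises(ValueError, match="incompatible"):
            ligate(a, b)

    def test_bamhi_bglii_scar_cut_by_neither(self):
        """BamHI/BglII GATC ends ligate into the AGATCC scar, which neither
        enzyme recognizes."""
        left = digest(DNASequence("AAGGATCCTT"), "BamHI")[0]  # ...G + GATC
        right = digest(DNASequence("TTAGATCTAA"), "BglII")[1]  # GATC + TC...
        product = ligate(left, right)
        assert "AGATCC" not in (ENZYMES["BamHI"].site,
                                ENZYMES["BglII"].site)
        assert find_sites(product, "BamHI") == []
        assert find_sites(product, "BglII") == []

    def test_blunt_fill_adds_four_bases(self):
        a = DNASequence("AAG", three_prime_overhang="GATC")
        b = DNASequence("CTAGAA", five_prime_overhang="CTAG")
        filled = klenow_fill(a)
        assert filled.bases == "AAGGATC"
        assert filled.is_blunt
        blunt = ligate(a, b, mode="blunt_after_fill")
        assert len(blunt) == len(a) + len(b) + 4

    def test_self_ligation_circularizes(self):
        frag = DNASequence("GATCAAAGATC", five_prime_overhang="GATC",
                           three_prime_overhang="GATC")
        circ = self_ligate(frag)
        assert circ.topology == "circular"
        assert len(circ) == len(frag)

    def test_circular_fragments_cannot_ligate(self):
        circ = DNASequence("AAAA", "circular")
        with pytest.raises(ValueError, match="linear"):
            ligate(circ, circ)


class TestCassettes:
    @pytest.mark.parametrize("motif", MOTIFS)
    @pytest.mark.parametrize("k", [1, 2, 3, 4])
    def test_outer_sites_unique_for_any_copy_number(self, motif, k):
        cassette = concatenate_motifs(motif_cassette(motif), k)
        seq = DNASequence(cassette.sequence)
        assert find_sites(seq, "BamHI") == [1]
        assert find_sites(seq, "BglII") == [len(seq) - 5]

    @pytest.mark.parametrize("motif", MOTIFS)
    def test_core_count_matches_copies(self, motif):
        for k in (1, 2, 3, 4):
            cassette = concatenate_motifs(motif_cassette(motif), k)
            assert cassette.sequence.count(cassette.core) == k

    def test_copy_number_out_of_range(self):
        cassette = motif_cassette("Kl")
        with pytest.raises(ValueError, match="1..4"):
            concatenate_motifs(cassette, 5)
        with pytest.raises(ValueError, match="1..4"):
            concatenate_motifs(cassette, 0)

    def test_unknown_motif_rejected(self):
        with pytest.raises(ValueError, match="motif"):
            motif_cassette("Kt7")

    def test_pcr_builds_fr15_core(self):
        cassette = motif_cassette("Fr15")
        assert cassette.core.startswith("TCGGTCGAAAGACTTGAGGG")
        assert "ATG" not in cassette.core

    def test_pcr_rejects_nonannealing_primers(self):
        with pytest.raises(ValueError, match="anneal"):
            pcr_amplify("A" * 60, "C" * 20, "G" * 20)


class TestAssembleUTR:
    @pytest.mark.parametrize("motif", MOTIFS)
    @pytest.mark.parametrize("d", DISTANCE_CLASSES)
    @pytest.mark.parametrize("k", [1, 2, 4])
    def test_first_motif_base_at_requested_distance(self, motif, d, k):
        cassette = motif_cassette(motif, k)
        spec, utr = assemble_utr(d, cassette, seed=3)
        assert motif_offset(utr, cassette) == d
        assert len(all_motif_offsets(utr, cassette)) == k
        assert spec.distance_nt == d and spec.copies == k

    def test_control_utr_is_32_nt(self):
        spec, utr = assemble_utr(None, None)
        assert len(utr) == 32
        assert utr.bases == LEADER + CONTROL_TAIL
        assert "ATG" not in utr.bases
        assert spec.copies == 0

    def test_spacers_are_atg_free_outside_cores(self):
        for seed in range(10):
            cassette = motif_cassette("Kl", 2)
            _spec, utr = assemble_utr(320, cassette, seed=seed)
            masked = utr.bases.replace(cassette.core, "N" * len(cassette.core))
            assert "ATG" not in masked

    def test_distance_below_minimum_rejected(self):
        with pytest.raises(ValueError, match="unachievable"):
            assemble_utr(17, motif_cassette("Kl"))

    def test_assembly_is_deterministic(self):
        cassette = motif_cassette("MS2SL", 3)
        _s1, u1 = assemble_utr(164, cassette, seed=9)
        _s2, u2 = assemble_utr(164, cassette, seed=9)
        assert u1.bases == u2.bases

    def test_fasta_round_trip(self, tmp_path):
        cassette = motif_cassette("Kl", 1)
        spec, utr = assemble_utr(67, cassette, seed=0)
        path = tmp_path / "utr.fasta"
        write_fasta([(spec.name, utr)], path)
        back = read_fasta(path)
        assert len(back) == 1
        assert back[0][1].bases == utr.bases
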