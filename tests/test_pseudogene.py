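"""Translation frames, identity, lesion detection and the degrade round-trip."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import ant4evo as a
from ant4evo.pseudogene import ScanError


class TestTranslateFrames:
    def test_standard_code_forward(self):
        frames = a.translate_frames("ATGAAATAA")
        assert frames[0] == "MK*"

    def test_frame_one_manual_walk(self):
        assert a.translate_frames("ATGAAAT")[1] == "*N"  # "TGAAAT" -> TGA AAT

    def test_reverse_frames_match_revcomp(self):
        from Bio.Seq import Seq

        seq = "ATGAAACCCGGGTTT"
        rc = str(Seq(seq).reverse_complement())
        assert a.translate_frames(seq)[3:] == a.translate_frames(rc)[:3]

    def test_frame_lengths(self):
        seq = "ATGAAACCCGG"  # 11 nt
        for offset in range(3):
            assert len(a.translate_frames(seq)[offset]) == (11 - offset) // 3

    def test_non_iupac_rejected(self):
        with pytest.raises(ScanError):
            a.translate_frames("ATG!!!")


class TestPercentIdentity:
    @pytest.mark.parametrize(
        "x,y,expected",
        [("MKV", "MKV", 100.0), ("MKVL", "MRVL", 75.0), ("M-KV", "MAKV", 100.0)],
    )
    def test_examples(self, x, y, expected):
        assert a.percent_identity(x, y) == pytest.approx(expected)

    @given(st.text(alphabet="MKVLR-", min_size=1, max_size=30))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_symmetric(self, s):
        other = s[::-1]
        try:
            forward = a.percent_identity(s, other)
        except ScanError:
            return
        assert forward == a.percent_identity(other, s)
        if forward == 100.0:
            assert all(x == y for x, y in zip(s, other) if x != "-" and y != "-")

    def test_no_comparable_columns_rejected(self):
        with pytest.raises(ScanError):
            a.percent_identity("--", "AA")


class TestDetectLesions:
    def test_identical_candidate_is_intact(self):
        cds = "ATGAAACCCGGGTTT"
        report = a.detect_lesions(cds, cds, (cds, cds))
        assert report.intact

    def test_nonsense_plus_2bp_insertion(self):
        """One premature stop and one 2-nt frameshift insertion, the lesion
        pair seen in a degenerate avian gene fragment."""
        ref = "ATGAAACCCGGGTTTCAT"
        #      codon1 -> TAA; 2-nt insertion after codon 3 (nt 9)
        cand = "ATGTAACCCTTGGGTTTCAT"
        cand_aln = "ATGTAACCCTTGGGTTTCAT"
        ref_aln = "ATGAAACCC--GGGTTTCAT"
        report = a.detect_lesions(cand, ref, (cand_aln, ref_aln))
        assert report.premature_stops == [(1, "TAA")]
        assert len(report.frameshifts) == 1
        fs = report.frameshifts[0]
        assert (fs.position, fs.indel_length, fs.type) == (9, 2, "insertion")
        assert not report.intact

    def test_in_frame_indel_is_not_a_frameshift(self):
        ref = "ATGAAACCCGGG"
        cand = "ATGAAATTTCCCGGG"
        report = a.detect_lesions(cand, ref, ("ATGAAATTTCCCGGG", "ATGAAA---CCCGGG"))
        assert report.frameshifts == []
        assert report.intact

    def test_deletion_frameshift_position(self):
        ref = "ATGAAACCCGGG"
        cand = "ATGAACCCGGG"  # 1-nt deletion at nt 5
        report = a.detect_lesions(cand, ref, ("ATGAA-CCCGGG", "ATGAAACCCGGG"))
        fs = report.frameshifts[0]
        assert (fs.position, fs.indel_length, fs.type) == (5, 1, "deletion")

    def test_reference_with_internal_stop_rejected(self):
        bad_ref = "ATGTAACCCGGG"
        with pytest.raises(ScanError, match="stop"):
            a.detect_lesions(bad_ref, bad_ref, (bad_ref, bad_ref))


class TestSpliceSites:
    def test_canonical_intron(self):
        genomic = "AAA" + "GTAAGTTTCAG" + "CCC"
        assert a.check_splice_sites(genomic, (3, 14)) == (True, True)

    def test_degenerate_donor_at(self):
        # GT -> AT donor degeneration, as in galliform pseudogene introns
        genomic = "AAA" + "ATAAGTTTCAG" + "CCC"
        assert a.check_splice_sites(genomic, (3, 14)) == (False, True)

    def test_minimal_span(self):
        assert a.check_splice_sites("GTAG", (0, 4)) == (True, True)

    def test_short_span_rejected(self):
        with pytest.raises(ScanError):
            a.check_splice_sites("GTAGAA", (0, 3))


class TestDegradeRoundTrip:
    def test_empty_spec_is_identity(self):
        rng = np.random.default_rng(0)
        cds = a.random_cds(30, rng)
        seq, report, pair = a.degrade_to_pseudogene(cds, a.DegradeSpec())
        assert seq == cds
        assert report.intact
        assert a.detect_lesions(seq, cds, pair).intact

    def test_constructed_lesion_pair(self):
        rng = np.random.default_rng(1)
        cds = a.random_cds(40, rng)
        spec = a.DegradeSpec(stop_codon_indices=[10], frameshifts=[(45, 2, "insertion")])
        seq, truth, pair = a.degrade_to_pseudogene(cds, spec)
        found = a.detect_lesions(seq, cds, pair)
        assert found.premature_stops == truth.premature_stops == [(10, "TAA")]
        assert [(f.position, f.indel_length, f.type) for f in found.frameshifts] == [
            (45, 2, "insertion")
        ]

    def test_splice_donor_degradation_detected(self):
        rng = np.random.default_rng(2)
        exon1, exon2 = a.random_cds(10, rng), a.random_cds(10, rng)[3:]
        intron = "GTAAGTATCTTTTTCAG"
        genomic = exon1 + intron + exon2
        spec = a.DegradeSpec(
            splice_mutations=[("donor", "AT")],
            intron_span=(len(exon1), len(exon1) + len(intron)),
        )
        seq, truth, _ = a.degrade_to_pseudogene(genomic, spec)
        donor_ok, acceptor_ok = a.check_splice_sites(
            seq, (len(exon1), len(exon1) + len(intron))
        )
        assert not donor_ok and acceptor_ok
        assert [(d.role, d.observed) for d in truth.splice_defects] == [("donor", "AT")]

    def test_overlapping_lesions_rejected(self):
        rng = np.random.default_rng(3)
        cds = a.random_cds(20, rng)
        spec = a.DegradeSpec(stop_codon_indices=[5], frameshifts=[(16, 2, "deletion")])
        with pytest.raises(ValueError, match="overlap"):
            a.degrade_to_pseudogene(cds, spec)

    def test_hundred_random_degradations_recovered_exactly(self):
        """detect_lesions inverts degrade_to_pseudogene on the lesion set."""
        rng = np.random.default_rng(2024)
        for _ in range(100):
            n = int(rng.integers(20, 60))
            cds = a.random_cds(n, rng)
            spec = a.random_degrade_spec(n, rng)
            seq, truth, pair = a.degrade_to_pseudogene(cds, spec)
            found = a.detect_lesions(seq, cds, pair)
            assert found.premature_stops == truth.premature_stops
            assert [(f.position, f.indel_length, f.type) for f in found.frameshifts] == [
                (f.position, f.indel_length, f.type) for f in truth.frameshifts
            ]


class TestFragmentMatching:
    def test_degenerate_fragment_found_in_genomic_context(self):
        rng = np.random.default_rng(7)
        cds = a.random_cds(40, rng)
        protein = a.translate_frames(cds)[0]
        flank = "".join(rng.choice(list("ACGT"), size=30))
        genomic = flank + cds + flank
        matches = a.find_fragment_matches(genomic, protein, min_length=15)
        assert matches
        best = matches[0]
        assert best.percent_identity == pytest.approx(100.0)
        start, end = best.query_span
        assert genomic[start:end] in genomic and (end - start) % 3 == 0
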