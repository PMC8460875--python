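"""Variant application and site loss/gain/retention calling."""

import numpy as np
import pytest

from seedbreak.reference_model import Utr3Record
from seedbreak.seed_sites import MiRNA, SeedMatchSite, site_pattern
from seedbreak.disruption import (
    apply_variant,
    call_disruption,
    sense_edit,
    variant_overlaps_site,
)
from seedbreak.variant_ingest import Variant

from conftest import oracle_apply_edit, oracle_find_all, oracle_revcomp

MIR_214_3P = MiRNA("miR-214-3p", "ACAGCAGGCACAGACAGGCAGU")   # pattern CCTGCTG
MIR_145A_5P = MiRNA("miR-145a-5p", "GUCCAGUUUUCCCAGGAAUCCCU")  # pattern AACTGGA


def _utr(seq: str, strand: str = "+", tid: str = "T1") -> Utr3Record:
    if strand == "+":
        positions = tuple(range(101, 101 + len(seq)))
    else:
        positions = tuple(range(100 + len(seq), 100, -1))
    return Utr3Record(
        transcript_id=tid, gene_symbol="G", chrom="chr1", strand=strand,
        utr_sequence=seq, genomic_positions=positions,
    )


class TestApplyVariant:
    def test_substitution_matches_string_oracle(self):
        seq = "AACCTGCTGAA"
        assert apply_variant(seq, 4, "T", "A") == oracle_apply_edit(seq, 4, "T", "A")
        assert apply_variant(seq, 4, "T", "A") == "AACCAGCTGAA"

    def test_snv_conserves_length(self):
        seq = "ACGTACGT"
        assert len(apply_variant(seq, 3, "T", "G")) == len(seq)

    def test_insertion_grows_by_one(self):
        seq = "ACGTACGT"
        assert len(apply_variant(seq, 3, "T", "TC")) == len(seq) + 1

    def test_ref_mismatch_guard(self):
        with pytest.raises(ValueError, match="mismatch"):
            apply_variant("ACGT", 1, "A", "G")


class TestOverlap:
    SITE = SeedMatchSite("T1", "m", 10, "CCTGCTG")

    @pytest.mark.parametrize(
        "offset, ref_len, expected",
        [(10, 1, True), (16, 1, True), (17, 1, False), (9, 1, False), (8, 3, True)],
    )
    def test_substitution_footprint(self, offset, ref_len, expected):
        assert variant_overlaps_site(offset, ref_len, self.SITE) is expected

    @pytest.mark.parametrize(
        "j, expected",
        # insertion lands between offsets j-1 and j; only strictly-inside breaks the 7-mer
        [(11, True), (12, True), (16, True), (10, False), (17, False)],
    )
    def test_insertion_strictly_inside(self, j, expected):
        assert variant_overlaps_site(j, 0, self.SITE, insertion=True) is expected


class TestCallDisruption:
    def test_snv_in_site_is_lost(self):
        utr = _utr("AAAA" + "CCTGCTG" + "AAAA")
        v = Variant("chr1", 101 + 6, "T", "A")  # third site base
        call = call_disruption(utr, v, MIR_214_3P)
        assert call.status == "LOST"
        assert [s.start_offset for s in call.ref_sites] == [4]
        assert call.alt_sites == ()
        assert call.overlapped_ref_site.start_offset == 4

    def test_snv_creating_site_is_gained(self):
        utr = _utr("GGGG" + "AACTGGT" + "GGGG")  # near-miss of AACTGGA
        v = Variant("chr1", 101 + 10, "T", "A")
        call = call_disruption(utr, v, MIR_145A_5P)
        assert call.status == "GAINED"
        assert [s.start_offset for s in call.alt_sites] == [4]

    def test_variant_far_from_site_is_none_site_persists(self):
        utr = _utr("CCTGCTG" + "A" * 50)
        v = Variant("chr1", 101 + 40, "A", "G")
        call = call_disruption(utr, v, MIR_214_3P)
        assert call.status == "NONE"
        assert [s.start_offset for s in call.alt_sites] == [0]

    def test_deletion_in_homopolymer_run_is_retained(self):
        # 8 A's hold two overlapping polyA sites; deleting one A keeps a site,
        # shifted — biologically the site survives, so the verdict is RETAINED
        poly_u = MiRNA("polyU", "CUUUUUUUCCCCCCCCCCCCCC")  # pattern AAAAAAA
        utr = _utr("GGG" + "A" * 8 + "GGG")
        v = Variant("chr1", 101 + 4, "AA", "A")
        call = call_disruption(utr, v, poly_u)
        assert {s.start_offset for s in call.ref_sites} == {3, 4}
        assert {s.start_offset for s in call.alt_sites} == {3}
        assert call.status == "RETAINED"

    def test_insertion_before_site_shifts_site_retained_not_lost(self):
        utr = _utr("AACCTGCTGAA")
        # insertion between offsets 1 and 2 (just 5' of the site at offset 2)
        v = Variant("chr1", 101 + 1, "A", "AG")
        call = call_disruption(utr, v, MIR_214_3P)
        assert call.status == "NONE"  # does not touch the site window
        assert [s.start_offset for s in call.alt_sites] == [3]

    def test_insertion_inside_site_is_lost(self):
        utr = _utr("AACCTGCTGAA")
        v = Variant("chr1", 101 + 2, "C", "CT")  # between site bases 1 and 2
        call = call_disruption(utr, v, MIR_214_3P)
        assert call.status == "LOST"

    def test_minus_strand_snv_lost(self):
        sense = "AAAA" + "CCTGCTG" + "AAAA"
        utr = _utr(sense, strand="-")
        # sense offset 6 (third site base, 'T'); genomic base is its complement
        g = utr.genomic_at(6)
        v = Variant("chr1", g, "A", "C")  # sense T -> G
        call = call_disruption(utr, v, MIR_214_3P)
        assert call.status == "LOST"

    def test_deletion_spanning_site_is_lost(self):
        utr = _utr("AACCTGCTGAA")
        v = Variant("chr1", 101 + 3, "CT", "C")  # anchor offset 3, deletes offset 4 ('T')
        call = call_disruption(utr, v, MIR_214_3P)
        assert call.status == "LOST"

    def test_rescan_oracle_on_random_edits(self):
        rng = np.random.default_rng(17)
        pattern = site_pattern(MIR_214_3P)
        for _ in range(150):
            bg = list(rng.choice(list("ACGT"), size=60))
            o = int(rng.integers(5, 45))
            bg[o : o + 7] = list(pattern)
            seq = "".join(bg)
            strand = "+" if rng.random() < 0.5 else "-"
            utr = _utr(seq, strand=strand)
            k = int(rng.integers(0, len(seq)))
            sense_ref = seq[k]
            sense_alt = "ACGT"[("ACGT".index(sense_ref) + 1 + int(rng.integers(0, 3))) % 4]
            g = utr.genomic_at(k)
            if strand == "+":
                v = Variant("chr1", g, sense_ref, sense_alt)
            else:
                v = Variant("chr1", g, oracle_revcomp(sense_ref), oracle_revcomp(sense_alt))
            call = call_disruption(utr, v, MIR_214_3P)
            mutated = seq[:k] + sense_alt + seq[k + 1 :]
            assert [s.start_offset for s in call.ref_sites] == oracle_find_all(seq, pattern)
            assert [s.start_offset for s in call.alt_sites] == oracle_find_all(mutated, pattern)
            # status is a pure function of the two scans plus the footprint
            overlapped = [s for s in oracle_find_all(seq, pattern) if s <= k <= s + 6]
            if overlapped and k not in [
                x for s in oracle_find_all(mutated, pattern) for x in range(s, s + 7)
            ]:
                if all(s not in oracle_find_all(mutated, pattern) for s in overlapped):
                    assert call.status == "LOST"
            if not overlapped and call.status == "LOST":
                raise AssertionError("LOST without a ref-site overlap")


class TestSenseEdit:
    def test_plus_strand_round_trip(self):
        utr = _utr("AACCTGCTGAA")
        edit = sense_edit(utr, Variant("chr1", 106, "G", "C"))
        assert (edit.start, edit.ref, edit.alt) == (5, "G", "C")

    def test_minus_strand_alleles_complemented(self):
        utr = _utr("AACCTGCTGAA", strand="-")
        g = utr.genomic_at(4)  # sense base 'T'
        edit = sense_edit(utr, Variant("chr1", g, "A", "G"))
        assert (edit.start, edit.ref, edit.alt) == (4, "T", "C")

    def test_footprint_outside_utr_rejected(self):
        utr = _utr("AACCTGCTGAA")
        with pytest.raises(ValueError, match="not fully inside"):
            sense_edit(utr, Variant("chr1", 99, "A", "G"))
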