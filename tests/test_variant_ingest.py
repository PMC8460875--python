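"""VCF reading, normalization, region annotation, rarity, carriage."""

import numpy as np
import pytest

from seedbreak.reference_model import GenomeSequence, TranscriptModel
from seedbreak.variant_ingest import (
    Variant,
    annotate_region,
    case_control_distribution,
    classify_rarity,
    normalize_variant,
    rare_fraction_percent,
    read_vcf,
)

from conftest import oracle_leftmost_deletion

VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    "##contig=<ID=chr1,length=1000>\n"
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
)


def _write_vcf(tmp_path, body, samples=()):
    p = tmp_path / "v.vcf"
    cols = "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO"
    header = VCF_HEADER
    if samples:
        cols += "\tFORMAT\t" + "\t".join(samples)
    else:
        header = header.replace('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n', "")
    p.write_text(header + cols + "\n" + body)
    return p


class TestReadVcf:
    def test_biallelic_genotype_counts(self, tmp_path):
        p = _write_vcf(
            tmp_path,
            "chr1\t41\t.\tC\tT\t.\tPASS\t.\tGT\t0/1\t0/0\t0/0\n",
            samples=("s1", "s2", "s3"),
        )
        variants, counts = read_vcf(p, sample_groups={"s1": "case", "s2": "case", "s3": "control"})
        (v,) = variants
        assert counts.n_alleles(v.key, "case") == 1
        assert counts.n_carriers(v.key, "case") == 1
        assert counts.n_carriers(v.key, "control") == 0
        assert v.maf == pytest.approx(1 / 6)

    def test_multiallelic_split(self, tmp_path):
        p = _write_vcf(tmp_path, "chr1\t41\t.\tA\tG,T\t.\tPASS\t.\n")
        variants, _ = read_vcf(p)
        assert [(v.ref, v.alt) for v in variants] == [("A", "G"), ("A", "T")]

    def test_af_info_passthrough(self, tmp_path):
        p = tmp_path / "v.vcf"
        p.write_text(
            "##fileformat=VCFv4.2\n##contig=<ID=chr1,length=1000>\n"
            '##INFO=<ID=AF,Number=A,Type=Float,Description="AF">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
            "chr1\t41\t.\tC\tT\t.\tPASS\tAF=0.004\n"
        )
        (v,), _ = read_vcf(p)
        assert v.maf == pytest.approx(0.004, abs=1e-6)

    def test_unknown_group_sample_rejected(self, tmp_path):
        p = _write_vcf(tmp_path, "chr1\t41\t.\tC\tT\t.\tPASS\t.\tGT\t0/1\n", samples=("s1",))
        with pytest.raises(ValueError, match="not in VCF header"):
            read_vcf(p, sample_groups={"ghost": "case"})


class TestNormalize:
    def _genome(self, seq="A" * 40 + "CATTTGC" + "A" * 53):
        return GenomeSequence({"chr1": seq})

    def test_snv_passthrough_both_modes(self):
        g = self._genome()
        v = Variant("chr1", 41, "C", "T")
        for mode in ("left_align", "paper_1bp"):
            assert normalize_variant(v, g, mode) == [v]

    def test_paper_1bp_single_insertion(self):
        g = self._genome()
        v = Variant("chr1", 42, "A", "AT")
        (out,) = normalize_variant(v, g, "paper_1bp")
        assert (out.pos, out.ref, out.alt) == (42, "A", "AT")

    def test_paper_1bp_decomposes_multibase_insertion(self):
        g = self._genome()
        v = Variant("chr1", 41, "C", "CTGG")
        out = normalize_variant(v, g, "paper_1bp")
        assert [o.alt[1:] for o in out] == ["T", "G", "G"]  # conserves inserted sequence
        assert all(o.pos == 41 and len(o.alt) == 2 for o in out)

    def test_paper_1bp_decomposes_multibase_deletion(self):
        g = self._genome()  # chr1[41:48] == CATTTGC
        v = Variant("chr1", 42, "ATT", "A")
        out = normalize_variant(v, g, "paper_1bp")
        assert all(len(o.ref) == 2 and len(o.alt) == 1 for o in out)
        assert "".join(o.ref[1] for o in out) == "TT"

    def test_left_align_matches_bruteforce_oracle(self):
        g = self._genome()
        seq = g["chr1"]
        # delete "TT" from the TTT run, specified at its rightmost position
        v = Variant("chr1", 43, "TTT", "T")
        (out,) = normalize_variant(v, g, "left_align")
        exp_pos, exp_ref, exp_alt = oracle_leftmost_deletion(seq, v.pos, v.ref, v.alt)
        assert (out.pos, out.ref, out.alt) == (exp_pos, exp_ref, exp_alt)

    def test_left_align_random_deletions_match_oracle(self):
        rng = np.random.default_rng(3)
        seq = "".join(rng.choice(list("ACGT"), size=300, p=[0.4, 0.1, 0.1, 0.4]))
        g = GenomeSequence({"chr1": seq})
        checked = 0
        for _ in range(60):
            pos = int(rng.integers(5, 290))
            d = int(rng.integers(1, 4))
            ref = seq[pos - 1 : pos + d]
            v = Variant("chr1", pos, ref, ref[0])
            (out,) = normalize_variant(v, g, "left_align")
            exp = oracle_leftmost_deletion(seq, v.pos, v.ref, v.alt)
            assert (out.pos, out.ref, out.alt) == exp
            checked += 1
        assert checked == 60

    def test_idempotent(self):
        rng = np.random.default_rng(5)
        seq = "".join(rng.choice(list("ACGT"), size=200, p=[0.4, 0.1, 0.1, 0.4]))
        g = GenomeSequence({"chr1": seq})
        for _ in range(40):
            pos = int(rng.integers(5, 180))
            kind = rng.integers(0, 3)
            if kind == 0:
                ref = seq[pos - 1]
                alt = "ACGT"[(("ACGT".index(ref)) + 1) % 4]
                v = Variant("chr1", pos, ref, alt)
            elif kind == 1:
                v = Variant("chr1", pos, seq[pos - 1], seq[pos - 1] + "TG")
            else:
                v = Variant("chr1", pos, seq[pos - 1 : pos + 2], seq[pos - 1])
            for mode in ("left_align", "paper_1bp"):
                once = normalize_variant(v, g, mode)
                twice = [w for o in once for w in normalize_variant(o, g, mode)]
                assert once == twice

    def test_ref_mismatch_rejected(self):
        g = self._genome()
        with pytest.raises(ValueError, match="does not match genome"):
            normalize_variant(Variant("chr1", 41, "G", "T"), g)


class TestRarity:
    @pytest.mark.parametrize(
        "maf, expected", [(0.005, "rare"), (0.01, "common"), (0.0, "rare"), (0.5, "common")]
    )
    def test_threshold_strict(self, maf, expected):
        assert classify_rarity(maf) == expected

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            classify_rarity(1.5)

    def test_planted_fraction_recovered_exactly(self):
        rng = np.random.default_rng(9)
        mafs = list(rng.uniform(0.001, 0.009, size=30)) + list(rng.uniform(0.05, 0.4, size=70))
        frac_rare = sum(classify_rarity(m) == "rare" for m in mafs) / len(mafs)
        assert frac_rare == 0.30

    def test_rare_fraction_percent(self):
        assert rare_fraction_percent(1, 4) == 25.0
        with pytest.raises(ValueError):
            rare_fraction_percent(5, 4)


class TestAnnotateRegion:
    def test_first_utr_base(self, toy_plus_transcript):
        av = annotate_region(Variant("chr1", 41, "C", "T", maf=0.004), [toy_plus_transcript])
        assert av.region == "UTR3"
        assert av.utr3_offset == 0
        assert av.cstar_label == "c.*1C>T"
        assert av.rarity == "rare"

    def test_upstream(self, toy_plus_transcript):
        tx = TranscriptModel("U", "U", "chr1", "+", ((600, 700),), 650)
        av = annotate_region(Variant("chr1", 100, "A", "G"), [tx])
        assert av.region == "upstream2kb"

    def test_cds_precedence_over_utr3_with_detail_retained(self, toy_plus_transcript):
        # overlapping transcript whose CDS covers position 41
        other = TranscriptModel("OV", "OVG", "chr1", "+", ((1, 100),), 90)
        av = annotate_region(Variant("chr1", 41, "C", "T"), [toy_plus_transcript, other])
        assert av.region == "CDS"
        assert [h.region for h in av.utr3_hits()] == ["UTR3"]
        assert av.utr3_hits()[0].utr3_offset == 0

    def test_minus_strand_label_uses_sense_alleles(self, toy_minus_transcript):
        # genomic position 60 is the first UTR base in transcription order
        av = annotate_region(Variant("chr1", 60, "A", "G"), [toy_minus_transcript])
        assert av.region == "UTR3"
        assert av.utr3_offset == 0
        assert av.cstar_label == "c.*1T>C"

    def test_utr3_always_has_offset(self, default_bundle):
        from seedbreak.reference_model import load_genome, load_transcripts

        g = load_genome(default_bundle.paths["genome"])
        txs = load_transcripts(default_bundle.paths["transcripts"])
        variants, _ = read_vcf(default_bundle.paths["vcf"], genome=g)
        for v in variants:
            av = annotate_region(v, txs)
            if av.region == "UTR3":
                assert av.utr3_offset is not None and av.cstar_label


class TestCaseControl:
    def _annotated(self, toy_plus_transcript, pos=41, ref="C", alt="T"):
        return annotate_region(Variant("chr1", pos, ref, alt), [toy_plus_transcript])

    def test_distribution_rows(self, tmp_path, toy_plus_transcript):
        samples = ("p1", "p2", "p3", "c1", "c2")
        body = (
            "chr1\t41\t.\tC\tT\t.\tPASS\t.\tGT\t0/1\t0/0\t0/0\t0/0\t0/0\n"
            "chr1\t50\t.\tA\tG\t.\tPASS\t.\tGT\t0/0\t0/0\t0/0\t0/0\t0/0\n"
            "chr1\t60\t.\tA\tG\t.\tPASS\t.\tGT\t0/1\t0/1\t0/0\t0/0\t0/0\n"
        )
        p = _write_vcf(tmp_path, body, samples=samples)
        groups = {"p1": "case", "p2": "case", "p3": "case", "c1": "control", "c2": "control"}
        variants, counts = read_vcf(p, sample_groups=groups)
        annotated = [annotate_region(v, [toy_plus_transcript]) for v in variants]
        table = case_control_distribution(annotated, counts)
        assert list(table["n_control"]) == [0, 0, 0]
        assert list(table["n_case"]) == [1, 0, 2]
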