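"""The fixture generator: determinism, self-consistency, planted truth."""

import filecmp

import pytest

from seedbreak.disruption import call_disruption
from seedbreak.expression_filter import classify_differential, differential_summary
from seedbreak.reference_model import extract_utr3, load_genome, load_transcripts
from seedbreak.seed_sites import MiRNA, load_mirnas, load_pairs, localize_pair_sites, site_pattern
from seedbreak.synthetic_data import (
    BundleError,
    FixtureSpec,
    generate_bundle,
    generate_expression,
    generate_reference,
    load_truth,
    spec_from_json,
)
from seedbreak.variant_ingest import Variant, read_vcf

from conftest import oracle_revcomp


class TestDeterminism:
    def test_same_seed_byte_identical(self, tmp_path):
        a = generate_bundle(FixtureSpec(), 5, tmp_path / "a")
        b = generate_bundle(FixtureSpec(), 5, tmp_path / "b")
        for name, pa in a.paths.items():
            assert filecmp.cmp(pa, b.paths[name], shallow=False), name

    def test_spec_json_round_trip_regenerates(self, tmp_path, default_bundle):
        spec, seed = spec_from_json(default_bundle.paths["spec"])
        again = generate_bundle(spec, seed, tmp_path / "again")
        for name, p in default_bundle.paths.items():
            assert filecmp.cmp(p, again.paths[name], shallow=False), name

    def test_different_seed_differs(self, tmp_path):
        a = generate_bundle(FixtureSpec(), 5, tmp_path / "a")
        c = generate_bundle(FixtureSpec(), 6, tmp_path / "c")
        assert not filecmp.cmp(a.paths["genome"], c.paths["genome"], shallow=False)


class TestSpecValidation:
    def test_zero_utr_length_rejected(self):
        with pytest.raises(BundleError):
            FixtureSpec(utr_length=(0, 0)).validate()

    def test_expression_roles_exceeding_mirnas_rejected(self):
        with pytest.raises(BundleError, match="expression design"):
            FixtureSpec(n_mirnas=5).validate()

    def test_more_disrupting_than_sites_rejected(self):
        with pytest.raises(BundleError, match="more disrupting"):
            FixtureSpec(n_transcripts=2, n_planted_sites=1, n_disrupting_snv=9).validate()


class TestSelfConsistency:
    def test_vcf_ref_matches_genome(self, default_bundle):
        genome = load_genome(default_bundle.paths["genome"])
        variants, _ = read_vcf(default_bundle.paths["vcf"], genome=genome)  # raises on mismatch
        assert len(variants) == len(default_bundle.truth)

    def test_minus_strand_transcript_present_and_revcomp_consistent(self, default_bundle):
        genome = load_genome(default_bundle.paths["genome"])
        transcripts = load_transcripts(default_bundle.paths["transcripts"])
        minus = [t for t in transcripts if t.strand == "-"]
        assert minus
        for tx in minus:
            rec = extract_utr3(tx, genome)
            ascending = sorted(rec.genomic_positions)
            plus_slice = "".join(genome.base(tx.chrom, p) for p in ascending)
            assert rec.utr_sequence == oracle_revcomp(plus_slice)

    def test_all_pair_ids_join(self, default_bundle):
        genome = load_genome(default_bundle.paths["genome"])
        transcripts = load_transcripts(default_bundle.paths["transcripts"])
        mirnas = load_mirnas(default_bundle.paths["mirnas"])
        utrs = {t.transcript_id: extract_utr3(t, genome) for t in transcripts}
        result = localize_pair_sites(load_pairs(default_bundle.paths["pairs"]), utrs, mirnas)
        assert result.unresolved == []
        # decoy pairs exist and are exactly the flagged zero-site ones
        assert len(result.zero_site_pairs) == FixtureSpec().n_decoy_pairs

    def test_truth_table_round_trips(self, default_bundle):
        records = load_truth(default_bundle.paths["truth"])
        assert records == default_bundle.truth


class TestPlantedTruth:
    def test_lost_variants_called_lost(self, default_bundle):
        genome = load_genome(default_bundle.paths["genome"])
        transcripts = {
            t.transcript_id: t
            for t in load_transcripts(default_bundle.paths["transcripts"], strip_versions=False)
        }
        mirnas = load_mirnas(default_bundle.paths["mirnas"])
        for t in default_bundle.truth:
            if t.label != "LOST":
                continue
            rec = extract_utr3(transcripts[t.transcript], genome)
            call = call_disruption(rec, Variant(t.chrom, t.pos, t.ref, t.alt), mirnas[t.mirna])
            assert call.status == "LOST", t

    def test_gained_variants_called_gained(self, default_bundle):
        genome = load_genome(default_bundle.paths["genome"])
        transcripts = {
            t.transcript_id: t
            for t in load_transcripts(default_bundle.paths["transcripts"], strip_versions=False)
        }
        mirnas = load_mirnas(default_bundle.paths["mirnas"])
        gained = [t for t in default_bundle.truth if t.label == "GAINED"]
        assert gained
        for t in gained:
            rec = extract_utr3(transcripts[t.transcript], genome)
            call = call_disruption(rec, Variant(t.chrom, t.pos, t.ref, t.alt), mirnas[t.mirna])
            assert call.status == "GAINED", t
            assert t.site_offset in {s.start_offset for s in call.alt_sites}

    def test_rarity_and_carriage_planted_correctly(self, default_bundle):
        genome = load_genome(default_bundle.paths["genome"])
        groups = {}
        with open(default_bundle.paths["groups"]) as fh:
            next(fh)
            for line in fh:
                s, g = line.split()
                groups[s] = g
        variants, counts = read_vcf(
            default_bundle.paths["vcf"], sample_groups=groups, genome=genome
        )
        by_key = {v.key: v for v in variants}
        for t in default_bundle.truth:
            v = by_key[t.key]
            assert (v.maf < 0.01) == (t.rarity == "rare"), t
            if t.carriage == "case_only":
                assert counts.n_carriers(t.key, "case") >= 1
                assert counts.n_carriers(t.key, "control") == 0
            elif t.carriage == "control_only":
                assert counts.n_carriers(t.key, "control") >= 1
                assert counts.n_carriers(t.key, "case") == 0
            else:
                assert counts.n_carriers(t.key, "case") >= 1
                assert counts.n_carriers(t.key, "control") >= 1


class TestExpressionGeneration:
    def test_planted_differential_counts_recovered(self):
        spec = FixtureSpec()
        table, expected = generate_expression(spec, seed=2)
        summary = differential_summary(classify_differential(table, cutoff=spec.fc_cutoff))
        for key, value in expected.items():
            assert summary[key] == value, key

    def test_all_pop2_missing_means_all_pop1_only(self):
        spec = FixtureSpec(
            n_mirnas=6, n_pop1_only=6, n_enriched=0, n_depleted=0, n_pop2_only=0,
            n_nonexpressed_lost=0,
        )
        table, _ = generate_expression(spec, seed=3)
        calls = classify_differential(table)
        assert all(c.klass == "POP1_ONLY" for c in calls) and len(calls) == 6

    def test_zero_noise_zero_delta_all_unchanged(self):
        spec = FixtureSpec(
            n_pop1_only=0, n_enriched=0, n_depleted=0, n_pop2_only=0,
            n_nonexpressed_lost=0, unchanged_delta=0.0,
        )
        table, _ = generate_expression(spec, seed=4)
        calls = classify_differential(table)
        assert len(calls) == spec.n_mirnas
        assert all(c.klass == "UNCHANGED" and c.log2fc == 0 for c in calls)


class TestReference:
    def test_spliced_utr_transcripts_present(self):
        ref = generate_reference(FixtureSpec(), seed=1)
        spliced = [t for t in ref.transcripts if len(t.exons) > 1]
        assert spliced
        for t in ref.transcripts:
            t.validate()
            lo, hi = FixtureSpec().utr_length
            assert lo <= len(t.utr3_genomic_positions()) <= hi

    def test_planted_sites_scannable_after_extraction(self, default_bundle):
        genome = load_genome(default_bundle.paths["genome"])
        transcripts = {
            t.transcript_id: t
            for t in load_transcripts(default_bundle.paths["transcripts"], strip_versions=False)
        }
        mirnas = load_mirnas(default_bundle.paths["mirnas"])
        for t in default_bundle.truth:
            if t.label != "LOST":
                continue
            rec = extract_utr3(transcripts[t.transcript], genome)
            pattern = site_pattern(mirnas[t.mirna])
            assert rec.utr_sequence[t.site_offset : t.site_offset + 7] == pattern
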