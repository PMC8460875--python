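"""Truth-labeled synthetic fixture bundles for the whole pipeline.

Generates a small random genome with plus- and minus-strand transcripts
(spliced and unspliced 3'UTRs), plants exact 7mer seed-match sites through
the genomic coordinate map, and derives a cohort VCF whose variants have
known disrupt/create/neutral status, planted rarity, and planted
case/control carriage — together with a miRNA set, a pair-hypothesis list,
a two-population log2-scale expression table with N.D. entries, and a truth
table.  Everything is a deterministic function of a single integer seed.

The site model is exact matching, so planted truth is noiseless; difficulty
comes from decoys: near-miss 7-mers, pairs without sites, non-expressed
miRNAs, and variants outside 3'UTRs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .reference_model import (
    GenomeSequence,
    TranscriptModel,
    Utr3Record,
    complement_base,
    extract_utr3,
)
from .seed_sites import MiRNA, PairHypothesis, find_pattern, site_pattern
from .variant_ingest import Variant, _left_align, _utr3_hit
from .disruption import UtrEdit, sense_edit, variant_overlaps_site

logger = logging.getLogger(__name__)

DNA = "ACGT"
ROLES = ("pop1_only", "enriched", "depleted", "unchanged", "pop2_only")


class BundleError(RuntimeError):
    """Raised when a fixture spec cannot be satisfied."""


@dataclass
class FixtureSpec:
    """Parameters of one synthetic study.

    Cohort sizes default to the emulated study design (412 cases, 213
    controls); the expression design targets 9 enriched-total and 7 depleted
    miRNAs at a log2 fold-change cutoff of 1, mirroring the reference
    differential table; rare variants draw MAF ~ U(0.001, 0.009) and common
    ones ~ U(0.05, 0.4).
    """

    n_transcripts: int = 8
    utr_length: tuple[int, int] = (300, 600)
    n_mirnas: int = 24
    n_planted_sites: int = 2
    n_disrupting_snv: int = 4
    n_disrupting_ins: int = 1
    n_disrupting_del: int = 1
    n_site_creating: int = 2
    n_neutral: int = 6
    n_nonexpressed_lost: int = 1
    n_decoy_pairs: int = 4
    rare_maf: tuple[float, float] = (0.001, 0.009)
    common_maf: tuple[float, float] = (0.05, 0.4)
    n_case: int = 412
    n_control: int = 213
    n_pop1_only: int = 4
    n_enriched: int = 5
    n_depleted: int = 7
    n_pop2_only: int = 3
    expr_mean: float = 8.0
    expr_sd: float = 1.5
    delta_range: tuple[float, float] = (1.3, 3.0)
    unchanged_delta: float = 0.6
    fc_cutoff: float = 1.0

    def validate(self) -> None:
        lo, hi = self.utr_length
        if lo < 80 or hi < lo:
            raise BundleError(f"utr_length {self.utr_length} too short to place sites")
        if self.n_transcripts < 2:
            raise BundleError("need at least 2 transcripts (one per strand)")
        if self.n_planted_sites * 22 > lo:
            raise BundleError("cannot place that many non-overlapping sites per UTR")
        roles_needed = self.n_pop1_only + self.n_enriched + self.n_depleted + self.n_pop2_only
        if roles_needed > self.n_mirnas:
            raise BundleError(
                f"expression design needs {roles_needed} miRNAs, spec has {self.n_mirnas}"
            )
        n_disrupt = (
            self.n_disrupting_snv
            + self.n_disrupting_ins
            + self.n_disrupting_del
            + self.n_nonexpressed_lost
        )
        if n_disrupt > self.n_transcripts * self.n_planted_sites:
            raise BundleError("more disrupting variants than planted sites")
        if self.n_nonexpressed_lost and not self.n_pop2_only:
            raise BundleError("n_nonexpressed_lost requires n_pop2_only >= 1")


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one planted variant."""

    variant_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    label: str  # LOST | GAINED | NONE
    mirna: str
    transcript: str
    site_offset: int  # -1 when not applicable
    rarity: str
    carriage: str  # case_only | control_only | both
    mirna_expressed: bool

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass
class ReferenceBundle:
    chrom_seqs: dict[str, list[str]]
    transcripts: list[TranscriptModel]

    def finalize(self) -> GenomeSequence:
        return GenomeSequence({c: "".join(s) for c, s in self.chrom_seqs.items()})


@dataclass
class PlannedVariant:
    variant: Variant
    truth: TruthRecord
    genotypes: dict[str, str] = field(default_factory=dict)


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), stream])


def mirna_names(spec: FixtureSpec) -> list[str]:
    return [f"syn-miR-{i + 1:02d}" for i in range(spec.n_mirnas)]


def mirna_roles(spec: FixtureSpec, seed: int) -> dict[str, str]:
    """Deterministic assignment of expression roles to miRNA names."""
    spec.validate()
    rng = _rng(seed, 7)
    names = mirna_names(spec)
    order = [names[i] for i in rng.permutation(len(names))]
    roles: dict[str, str] = {}
    cursor = 0
    for role, count in (
        ("pop1_only", spec.n_pop1_only),
        ("enriched", spec.n_enriched),
        ("depleted", spec.n_depleted),
        ("pop2_only", spec.n_pop2_only),
    ):
        for name in order[cursor : cursor + count]:
            roles[name] = role
        cursor += count
    for name in order[cursor:]:
        roles[name] = "unchanged"
    return {name: roles[name] for name in names}


def generate_mirnas(spec: FixtureSpec, seed: int) -> dict[str, MiRNA]:
    """Random 22-nt miRNAs with mutually distinct seed-match patterns."""
    rng = _rng(seed, 13)
    out: dict[str, MiRNA] = {}
    patterns: set[str] = set()
    for name in mirna_names(spec):
        for _ in range(200):
            seq = "".join(rng.choice(list("ACGU"), size=22))
            m = MiRNA(name=name, sequence=seq)
            if site_pattern(m) not in patterns:
                patterns.add(site_pattern(m))
                out[name] = m
                break
        else:  # pragma: no cover - astronomically unlikely
            raise BundleError("could not draw miRNAs with distinct seed patterns")
    return out


# ---------------------------------------------------------------------------
# reference generation


def _layout(index: int, cursor: int, utr_len: int):
    """Exon/CDS layout for transcript ``index`` starting at genomic ``cursor``.

    Cycles through four shapes: plus/minus strand x unspliced/spliced 3'UTR.
    Returns (strand, exons, cds_start, cds_end, consumed_span).
    """
    s = cursor
    shape = index % 4
    if shape == 0:  # plus strand, single-exon UTR
        exon_end = s + 99 + utr_len
        return "+", ((s, exon_end),), s + 10, s + 99, exon_end - s + 1
    if shape == 1:  # minus strand, single-exon UTR (UTR at low coordinates)
        exon_end = s + utr_len + 99
        return "-", ((s, exon_end),), exon_end - 10, s + utr_len, exon_end - s + 1
    if shape == 2:  # plus strand, UTR spliced across two exons (20 + rest)
        u2 = utr_len - 20
        exon2 = (s + 200, s + 200 + u2 - 1)
        return "+", ((s, s + 119), exon2), s + 10, s + 99, exon2[1] - s + 1
    # minus strand, UTR spliced (rest + 20, transcription right-to-left)
    u1 = utr_len - 20
    g2 = s + u1 + 80
    exon2 = (g2, g2 + 119)
    return "-", ((s, s + u1 - 1), exon2), g2 + 110, g2 + 20, exon2[1] - s + 1


def generate_reference(spec: FixtureSpec, seed: int) -> ReferenceBundle:
    """Random genome plus transcript models satisfying the spec.

    Transcripts alternate strand and splicing shape, so at least one
    minus-strand and one spliced-UTR transcript are always present.
    """
    spec.validate()
    rng = _rng(seed, 3)
    cursors = {"chr1": 201, "chr2": 201}
    lengths = {"chr1": 0, "chr2": 0}
    transcripts: list[TranscriptModel] = []
    for i in range(spec.n_transcripts):
        chrom = "chr1" if i % 2 == 0 else "chr2"
        utr_len = int(rng.integers(spec.utr_length[0], spec.utr_length[1] + 1))
        strand, exons, cds_start, cds_end, span = _layout(i, cursors[chrom], utr_len)
        transcripts.append(
            TranscriptModel(
                transcript_id=f"TX{i:03d}.1",
                gene_symbol=f"GENE{i}",
                chrom=chrom,
                strand=strand,
                exons=exons,
                cds_end_genomic=cds_end,
                cds_start_genomic=cds_start,
            )
        )
        cursors[chrom] += span + 300
        lengths[chrom] = cursors[chrom] + 200
    chrom_seqs = {
        chrom: list("".join(rng.choice(list(DNA), size=length)))
        for chrom, length in lengths.items()
    }
    return ReferenceBundle(chrom_seqs=chrom_seqs, transcripts=transcripts)


# ---------------------------------------------------------------------------
# site planting and variant construction


@dataclass
class PlantResult:
    genome: GenomeSequence
    utr_records: dict[str, Utr3Record]
    pairs: list[PairHypothesis]
    planted_sites: list[tuple[str, str, int]]  # (transcript_id, mirna, offset)
    variants: list[PlannedVariant]
    sample_names: list[str]
    groups: dict[str, str]


def _write_sense_window(
    chrom_seq: list[str], tx: TranscriptModel, positions: tuple[int, ...], offset: int, text: str
) -> None:
    """Write ``text`` (sense orientation) into the genome through the offset map."""
    for i, base in enumerate(text):
        g = positions[offset + i]
        chrom_seq[g - 1] = base if tx.strand == "+" else complement_base(base)


def _contiguous(positions: tuple[int, ...], offset: int, length: int) -> bool:
    window = positions[offset : offset + length]
    return len(window) == length and abs(window[-1] - window[0]) == length - 1


def _pick_offsets(
    rng: np.random.Generator, utr_len: int, positions: tuple[int, ...], k: int, spacing: int = 22
) -> list[int]:
    candidates = [
        o for o in range(8, utr_len - 15) if _contiguous(positions, o, 8)
    ]
    chosen: list[int] = []
    for _ in range(3000):
        if len(chosen) == k:
            break
        o = int(rng.choice(candidates))
        if all(abs(o - c) >= spacing for c in chosen):
            chosen.append(o)
    if len(chosen) < k:
        raise BundleError(
            f"cannot place {k} non-overlapping sites in a {utr_len} nt UTR; "
            "increase utr_length or lower n_planted_sites"
        )
    return sorted(chosen)


def _sense_snv(rec: Utr3Record, offset: int, alt_sense: str, genome: GenomeSequence) -> Variant:
    g = rec.genomic_at(offset)
    ref = genome.base(rec.chrom, g)
    alt = alt_sense if rec.strand == "+" else complement_base(alt_sense)
    return Variant(chrom=rec.chrom, pos=g, ref=ref, alt=alt)


def _genomic_insertion(rec: Utr3Record, j: int, base_sense: str, genome: GenomeSequence) -> Variant:
    """1-bp insertion landing between sense offsets j-1 and j."""
    if rec.strand == "+":
        g = rec.genomic_at(j - 1)
        ins = base_sense
    else:
        g = rec.genomic_at(j)
        ins = complement_base(base_sense)
    anchor = genome.base(rec.chrom, g)
    return Variant(chrom=rec.chrom, pos=g, ref=anchor, alt=anchor + ins)


def _genomic_deletion(rec: Utr3Record, offset: int, genome: GenomeSequence) -> Variant:
    """1-bp deletion of the sense base at ``offset``."""
    g = rec.genomic_at(offset)
    anchor = genome.base(rec.chrom, g - 1)
    return Variant(chrom=rec.chrom, pos=g - 1, ref=anchor + genome.base(rec.chrom, g), alt=anchor)


def _normalized_edit(
    variant: Variant, genome: GenomeSequence, rec: Utr3Record
) -> Optional[UtrEdit]:
    """Sense-space edit of the left-aligned variant, or None if it leaves the UTR."""
    try:
        nv = _left_align(variant, genome)
        return sense_edit(rec, nv)
    except (ValueError, IndexError):
        return None


def _patterns_for(tx_id: str, pair_mirnas: dict[str, list[MiRNA]]) -> list[MiRNA]:
    return pair_mirnas.get(tx_id, [])


def plant_sites_and_variants(
    spec: FixtureSpec, seed: int, reference: ReferenceBundle, mirnas: dict[str, MiRNA]
) -> PlantResult:
    """Plant seed sites and near-miss windows, then derive the variant set.

    All planted truth is re-verified by naive substring scanning on the
    reference and mutated UTR strings before a variant is accepted.
    """
    spec.validate()
    rng = _rng(seed, 17)
    roles = mirna_roles(spec, seed)
    expressed = [n for n, r in roles.items() if r != "pop2_only"]
    nonexpressed = [n for n, r in roles.items() if r == "pop2_only"]

    transcripts = reference.transcripts
    tx_positions = {t.transcript_id: t.utr3_genomic_positions() for t in transcripts}

    # --- phase A: choose site slots and write site patterns into the genome
    planted: list[tuple[str, str, int]] = []  # (tx, mirna, offset)
    site_offsets: dict[str, list[int]] = {}
    expr_cycle = list(rng.permutation(expressed))
    cycle_i = 0
    n_sites_total = spec.n_transcripts * spec.n_planted_sites
    for ti, tx in enumerate(transcripts):
        positions = tx_positions[tx.transcript_id]
        offsets = _pick_offsets(rng, len(positions), positions, spec.n_planted_sites)
        site_offsets[tx.transcript_id] = offsets
        for si, o in enumerate(offsets):
            slot = ti * spec.n_planted_sites + si
            if spec.n_nonexpressed_lost and slot == n_sites_total - 1:
                name = nonexpressed[0]
            else:
                name = expr_cycle[cycle_i % len(expr_cycle)]
                cycle_i += 1
            pattern = site_pattern(mirnas[name])
            _write_sense_window(
                reference.chrom_seqs[tx.chrom], tx, positions, o, pattern
            )
            planted.append((tx.transcript_id, name, o))

    # --- phase A': near-miss windows for site-creating variants
    creation_plans: list[tuple[str, str, int, int]] = []  # (tx, mirna, offset, mut_index)
    for ci in range(spec.n_site_creating):
        tx = transcripts[ci % len(transcripts)]
        tid = tx.transcript_id
        positions = tx_positions[tid]
        pair_name = next(m for t, m, _ in planted if t == tid)
        pattern = site_pattern(mirnas[pair_name])
        placed = False
        for _ in range(500):
            o = int(rng.integers(8, len(positions) - 15))
            if not _contiguous(positions, o, 8):
                continue
            if any(abs(o - po) < 22 for po in site_offsets[tid]):
                continue
            mi = int(rng.integers(0, 7))
            near = [b for b in DNA if b != pattern[mi]]
            nb = near[int(rng.integers(0, 3))]
            miss = pattern[:mi] + nb + pattern[mi + 1 :]
            # simulate on the current sense sequence before committing
            chrom_seq = reference.chrom_seqs[tx.chrom]
            sense_now = _current_sense(chrom_seq, tx, positions)
            trial = sense_now[:o] + miss + sense_now[o + 7 :]
            restored = trial[:o] + pattern + trial[o + 7 :]
            if _overlapping_hits(trial, pattern, o - 7, o + 13):
                continue
            if find_pattern(restored, pattern) != sorted(
                set(find_pattern(trial, pattern)) | {o}
            ):
                continue
            _write_sense_window(chrom_seq, tx, positions, o, miss)
            creation_plans.append((tid, pair_name, o, mi))
            site_offsets[tid].append(o)  # reserve the window
            placed = True
            break
        if not placed:
            raise BundleError("could not place a near-miss window for a site-creating variant")

    # --- phase B: freeze the genome and re-extract UTRs
    genome = reference.finalize()
    utr_records = {
        t.transcript_id: extract_utr3(t, genome) for t in transcripts
    }
    for tid, name, o in planted:
        pattern = site_pattern(mirnas[name])
        seq = utr_records[tid].utr_sequence
        if seq[o : o + 7] != pattern:
            raise BundleError(f"planted site verification failed for {tid}@{o}")

    # --- pair hypotheses: every planted pair, plus siteless decoys
    pair_keys = sorted({(m, t) for t, m, _ in planted} | {(m, t) for t, m, _, _ in creation_plans})
    pairs = [PairHypothesis(mirna_name=m, transcript_id=t, source="synthetic") for m, t in pair_keys]
    all_names = list(mirnas)
    decoys_added = 0
    for _ in range(1000):
        if decoys_added >= spec.n_decoy_pairs:
            break
        name = all_names[int(rng.integers(0, len(all_names)))]
        tx = transcripts[int(rng.integers(0, len(transcripts)))]
        key = (name, tx.transcript_id)
        if key in pair_keys:
            continue
        if find_pattern(utr_records[tx.transcript_id].utr_sequence, site_pattern(mirnas[name])):
            continue
        pair_keys.append(key)
        pairs.append(
            PairHypothesis(mirna_name=name, transcript_id=tx.transcript_id, source="decoy")
        )
        decoys_added += 1
    if decoys_added < spec.n_decoy_pairs:
        raise BundleError("could not place siteless decoy pairs")

    # actual site footprints of every hypothesized pair (accidental hits included)
    paired_mirnas: dict[str, list[MiRNA]] = {}
    for m, t in pair_keys:
        paired_mirnas.setdefault(t, []).append(mirnas[m])
    occupied: dict[str, set[int]] = {t.transcript_id: set() for t in transcripts}
    for tid, rec in utr_records.items():
        for m in paired_mirnas.get(tid, []):
            for h in find_pattern(rec.utr_sequence, site_pattern(m)):
                occupied[tid].update(range(h - 1, h + 8))
    for tid, _, o in [(t, m, o) for t, m, o in planted] + [
        (t, m, o) for t, m, o, _ in creation_plans
    ]:
        occupied[tid].update(range(o - 1, o + 8))

    # --- phase C: variants
    variants: list[PlannedVariant] = []
    used_positions: set[tuple[str, int]] = set()
    vid_counter = [0]
    samples, groups = _sample_names(spec)

    def _vid() -> str:
        vid_counter[0] += 1
        return f"v{vid_counter[0]:03d}"

    def _commit(
        variant: Variant,
        label: str,
        mirna: str,
        tid: str,
        site_offset: int,
        rarity_kind: str,
        carriage: str,
        expressed_flag: bool,
    ) -> None:
        footprint = {(variant.chrom, p) for p in range(variant.pos, variant.pos + len(variant.ref))}
        if footprint & used_positions:
            raise BundleError("variant placement collision")
        used_positions.update(footprint)
        genotypes, maf = _assign_genotypes(rng, spec, rarity_kind, carriage, samples, groups)
        truth = TruthRecord(
            variant_id=_vid(),
            chrom=variant.chrom,
            pos=variant.pos,
            ref=variant.ref,
            alt=variant.alt,
            label=label,
            mirna=mirna,
            transcript=tid,
            site_offset=site_offset,
            rarity="rare" if maf < 0.01 else "common",
            carriage=carriage,
            mirna_expressed=expressed_flag,
        )
        variants.append(PlannedVariant(variant=variant, truth=truth, genotypes=genotypes))

    expressed_sites = [
        (t, m, o) for t, m, o in planted if roles[m] != "pop2_only"
    ]
    nonexpr_sites = [(t, m, o) for t, m, o in planted if roles[m] == "pop2_only"]
    order = [expressed_sites[i] for i in rng.permutation(len(expressed_sites))]
    site_iter = iter(order)

    for _ in range(spec.n_disrupting_snv):
        tid, mname, o = next(site_iter)
        _plant_disrupting_snv(
            rng, genome, utr_records[tid], mirnas[mname], o, paired_mirnas[tid], _commit,
            mname, tid, expressed_flag=True,
        )
    for _ in range(spec.n_disrupting_ins):
        tid, mname, o = next(site_iter)
        _plant_disrupting_indel(
            rng, genome, utr_records[tid], mirnas[mname], o, _commit, mname, tid,
            kind="ins", expressed_flag=True,
        )
    for _ in range(spec.n_disrupting_del):
        tid, mname, o = next(site_iter)
        _plant_disrupting_indel(
            rng, genome, utr_records[tid], mirnas[mname], o, _commit, mname, tid,
            kind="del", expressed_flag=True,
        )
    for tid, mname, o in nonexpr_sites[: spec.n_nonexpressed_lost]:
        _plant_disrupting_snv(
            rng, genome, utr_records[tid], mirnas[mname], o, paired_mirnas[tid], _commit,
            mname, tid, expressed_flag=False,
        )

    for tid, mname, o, mi in creation_plans:
        rec = utr_records[tid]
        pattern = site_pattern(mirnas[mname])
        v = _sense_snv(rec, o + mi, pattern[mi], genome)
        mutated = rec.utr_sequence[: o + mi] + pattern[mi] + rec.utr_sequence[o + mi + 1 :]
        if _overlapping_hits(rec.utr_sequence, pattern, o, o + 6):
            raise BundleError("near-miss window already matches on the reference")
        if o not in find_pattern(mutated, pattern):
            raise BundleError("site-creating variant failed to restore the site")
        _commit(v, "GAINED", mname, tid, o, "rare", "case_only", True)

    _plant_neutral_variants(
        rng, spec, genome, reference.transcripts, utr_records, occupied, paired_mirnas,
        used_positions, _commit,
    )

    return PlantResult(
        genome=genome,
        utr_records=utr_records,
        pairs=pairs,
        planted_sites=planted,
        variants=variants,
        sample_names=samples,
        groups=groups,
    )


def _current_sense(chrom_seq: list[str], tx: TranscriptModel, positions: tuple[int, ...]) -> str:
    bases = [chrom_seq[g - 1] for g in positions]
    if tx.strand == "-":
        bases = [complement_base(b) for b in bases]
    return "".join(bases)


def _overlapping_hits(seq: str, pattern: str, lo: int, hi: int) -> list[int]:
    """Pattern hits whose 7-base window intersects offsets [lo, hi]."""
    return [h for h in find_pattern(seq, pattern) if h <= hi and h + 6 >= lo]


def _plant_disrupting_snv(
    rng, genome, rec, mirna, o, tx_mirnas, commit, mname, tid, expressed_flag
) -> None:
    pattern = site_pattern(mirna)
    for _ in range(100):
        bi = int(rng.integers(0, 7))
        alts = [b for b in DNA if b != pattern[bi]]
        alt_sense = alts[int(rng.integers(0, 3))]
        mutated = rec.utr_sequence[: o + bi] + alt_sense + rec.utr_sequence[o + bi + 1 :]
        if _overlapping_hits(mutated, pattern, o + bi - 6, o + bi + 6):
            continue  # still (or again) a site: not a clean loss
        if any(
            _overlapping_hits(mutated, site_pattern(m), o + bi - 6, o + bi + 6)
            != _overlapping_hits(rec.utr_sequence, site_pattern(m), o + bi - 6, o + bi + 6)
            for m in tx_mirnas
            if m.name != mirna.name
        ):
            continue  # would touch another hypothesized pair's site landscape
        v = _sense_snv(rec, o + bi, alt_sense, genome)
        commit(v, "LOST", mname, tid, o, "rare", "case_only", expressed_flag)
        return
    raise BundleError("could not construct a clean site-disrupting SNV")


def _plant_disrupting_indel(
    rng, genome, rec, mirna, o, commit, mname, tid, kind, expressed_flag
) -> None:
    pattern = site_pattern(mirna)
    seq = rec.utr_sequence
    for _ in range(200):
        if kind == "ins":
            j = o + int(rng.integers(1, 7))  # strictly inside the site
            base = DNA[int(rng.integers(0, 4))]
            v = _genomic_insertion(rec, j, base, genome)
            mutated = seq[:j] + base + seq[j:]
        else:
            bi = int(rng.integers(0, 7))
            v = _genomic_deletion(rec, o + bi, genome)
            mutated = seq[: o + bi] + seq[o + bi + 1 :]
        edit = _normalized_edit(v, genome, rec)
        if edit is None:
            continue
        # the left-aligned representation must still touch the planted site
        ok = (
            variant_overlaps_site_offsets(edit, o)
            and not _overlapping_hits(mutated, pattern, o - 7, o + 13)
        )
        if not ok:
            continue
        commit(v, "LOST", mname, tid, o, "rare", "case_only", expressed_flag)
        return
    raise BundleError(f"could not construct a clean site-disrupting {kind}")


def variant_overlaps_site_offsets(edit: UtrEdit, site_start: int) -> bool:
    """Overlap of a sense edit with a site window given only its start offset."""
    from .seed_sites import SeedMatchSite

    probe = SeedMatchSite("", "", site_start, "N" * 7)
    if edit.insertion:
        return variant_overlaps_site(edit.start, 0, probe, insertion=True)
    return variant_overlaps_site(edit.start, max(len(edit.ref), 1), probe)


def _plant_neutral_variants(
    rng, spec, genome, transcripts, utr_records, occupied, paired_mirnas, used_positions, commit
) -> None:
    kinds = ["utr"] * max(0, spec.n_neutral - 4) + ["cds", "cds", "intron", "upstream"][
        : min(4, spec.n_neutral)
    ]
    rarity_cycle = ["rare", "common"]
    spliced = [t for t in transcripts if len(t.exons) > 1]
    for ni, kind in enumerate(kinds):
        rarity_kind = rarity_cycle[ni % 2]
        carriage = "both" if rarity_kind == "common" else ("case_only" if ni % 4 else "control_only")
        placed = False
        for _ in range(500):
            tx = transcripts[int(rng.integers(0, len(transcripts)))]
            if kind == "intron":
                if not spliced:
                    kind = "cds"
                    continue
                tx = spliced[int(rng.integers(0, len(spliced)))]
                g = int(rng.integers(tx.exons[0][1] + 5, tx.exons[1][0] - 5))
            elif kind == "upstream":
                g = tx.tx_start - 100 if tx.strand == "+" else tx.tx_end + 100
            elif kind == "cds":
                lo = min(tx.cds_start_genomic, tx.cds_end_genomic)
                hi = max(tx.cds_start_genomic, tx.cds_end_genomic)
                if hi - lo < 10 or not tx._in_exon(lo + 5):
                    continue
                g = int(rng.integers(lo + 2, lo + min(80, hi - lo - 2)))
                if tx.region_of(g) != "CDS":
                    continue
            else:  # utr, away from every hypothesized site footprint
                rec = utr_records[tx.transcript_id]
                k = int(rng.integers(0, len(rec)))
                if k in occupied[tx.transcript_id]:
                    continue
                mutated_ok = True
                ref_sense = rec.utr_sequence[k]
                alt_sense = DNA[int(rng.integers(0, 4))]
                if alt_sense == ref_sense:
                    continue
                mutated = rec.utr_sequence[:k] + alt_sense + rec.utr_sequence[k + 1 :]
                for m in paired_mirnas.get(tx.transcript_id, []):
                    if find_pattern(mutated, site_pattern(m)) != find_pattern(
                        rec.utr_sequence, site_pattern(m)
                    ):
                        mutated_ok = False
                        break
                if not mutated_ok:
                    continue
                g = rec.genomic_at(k)
                ref = genome.base(rec.chrom, g)
                alt = alt_sense if rec.strand == "+" else complement_base(alt_sense)
                if (rec.chrom, g) in used_positions:
                    continue
                commit(
                    Variant(chrom=rec.chrom, pos=g, ref=ref, alt=alt),
                    "NONE", "", tx.transcript_id, -1, rarity_kind, carriage, True,
                )
                placed = True
                break
            if (tx.chrom, g) in used_positions:
                continue
            ref = genome.base(tx.chrom, g)
            alt = DNA[(DNA.index(ref) + 1 + int(rng.integers(0, 3))) % 4]
            if alt == ref:
                continue
            commit(
                Variant(chrom=tx.chrom, pos=g, ref=ref, alt=alt),
                "NONE", "", tx.transcript_id, -1, rarity_kind, carriage, True,
            )
            placed = True
            break
        if not placed:
            raise BundleError(f"could not place a neutral {kind} variant")


# ---------------------------------------------------------------------------
# cohort genotypes


def _sample_names(spec: FixtureSpec) -> tuple[list[str], dict[str, str]]:
    cases = [f"case{i:03d}" for i in range(spec.n_case)]
    controls = [f"ctrl{i:03d}" for i in range(spec.n_control)]
    groups = {s: "case" for s in cases} | {s: "control" for s in controls}
    return cases + controls, groups


def _assign_genotypes(
    rng: np.random.Generator,
    spec: FixtureSpec,
    rarity_kind: str,
    carriage: str,
    samples: list[str],
    groups: dict[str, str],
) -> tuple[dict[str, str], float]:
    """Heterozygous carriers consistent with the planted rarity and carriage."""
    n_total = len(samples)
    if rarity_kind == "rare":
        if carriage in {"case_only", "control_only"}:
            n_carriers = int(rng.integers(1, 3))
        else:
            target = rng.uniform(*spec.rare_maf)
            n_carriers = max(1, round(target * 2 * n_total))
    else:
        target = rng.uniform(*spec.common_maf)
        n_carriers = min(n_total, max(1, round(target * 2 * n_total)))
    pool_by_carriage = {
        "case_only": [s for s in samples if groups[s] == "case"],
        "control_only": [s for s in samples if groups[s] == "control"],
        "both": samples,
    }
    pool = pool_by_carriage[carriage]
    n_carriers = min(n_carriers, len(pool))
    idx = rng.choice(len(pool), size=n_carriers, replace=False)
    carriers = sorted(pool[i] for i in idx)
    if carriage == "both" and n_carriers >= 2:
        # force at least one carrier per group so 'both' is literal
        case_pool = pool_by_carriage["case_only"]
        ctrl_pool = pool_by_carriage["control_only"]
        if not set(carriers) & set(case_pool):
            carriers[0] = case_pool[int(rng.integers(0, len(case_pool)))]
        if not set(carriers) & set(ctrl_pool):
            carriers[-1] = ctrl_pool[int(rng.integers(0, len(ctrl_pool)))]
        carriers = sorted(set(carriers))
    genotypes = {s: "0/1" for s in carriers}
    maf = len(carriers) / (2 * n_total)
    if rarity_kind == "rare" and maf >= 0.01:
        raise BundleError("rare variant drew too many carriers")
    return genotypes, maf


# ---------------------------------------------------------------------------
# expression


def generate_expression(spec: FixtureSpec, seed: int):
    """Two-population log2-scale expression table with planted differentials.

    Returns ``(ExpressionTable, expected_counts)`` where the expected counts
    state exactly how many miRNAs exceed the fold-change cutoff by
    construction.
    """
    import pandas as pd

    from .expression_filter import ExpressionTable

    spec.validate()
    rng = _rng(seed, 11)
    roles = mirna_roles(spec, seed)
    rows = {}
    for name in mirna_names(spec):
        role = roles[name]
        base = float(rng.normal(spec.expr_mean, spec.expr_sd))
        base = max(base, 3.0)
        if role == "pop1_only":
            v1, v2 = base, float("nan")
        elif role == "pop2_only":
            v1, v2 = float("nan"), base
        elif role == "enriched":
            v1, v2 = base + float(rng.uniform(*spec.delta_range)), base
        elif role == "depleted":
            v1, v2 = base - float(rng.uniform(*spec.delta_range)), base
        else:
            v1, v2 = base + float(rng.uniform(-spec.unchanged_delta, spec.unchanged_delta)), base
        rows[name] = (round(v1, 3), round(v2, 3))
    data = pd.DataFrame(rows, index=["pop1_ncc", "pop2_nonncc"]).T
    data.index.name = "mirna"
    table = ExpressionTable(data=data, populations=("pop1_ncc", "pop2_nonncc"))
    expected = {
        "POP1_ONLY": spec.n_pop1_only,
        "POP2_ONLY": spec.n_pop2_only,
        "ENRICHED": spec.n_enriched,
        "DEPLETED": spec.n_depleted,
        "UNCHANGED": spec.n_mirnas
        - spec.n_pop1_only
        - spec.n_pop2_only
        - spec.n_enriched
        - spec.n_depleted,
        "enriched_total": spec.n_enriched + spec.n_pop1_only,
        "depleted_total": spec.n_depleted + spec.n_pop2_only,
    }
    return table, expected


# ---------------------------------------------------------------------------
# bundle assembly


@dataclass
class Bundle:
    """Paths and ground truth of one generated fixture directory."""

    directory: Path
    paths: dict[str, Path]
    truth: list[TruthRecord]
    expected_expression: dict[str, int]
    spec: FixtureSpec
    seed: int


def generate_bundle(spec: FixtureSpec, seed: int, outdir: str | Path) -> Bundle:
    """Write a complete, self-consistent fixture bundle to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spec.validate()

    reference = generate_reference(spec, seed)
    mirnas = generate_mirnas(spec, seed)
    plant = plant_sites_and_variants(spec, seed, reference, mirnas)
    table, expected = generate_expression(spec, seed)

    paths = {name: outdir / fname for name, fname in {
        "genome": "genome.fa",
        "transcripts": "transcripts.tsv",
        "vcf": "variants.vcf",
        "mirnas": "mirnas.tsv",
        "pairs": "pairs.tsv",
        "expression": "expression.tsv",
        "groups": "groups.tsv",
        "truth": "truth.tsv",
        "spec": "spec.json",
    }.items()}

    _write_fasta(paths["genome"], plant.genome)
    _write_transcript_table(paths["transcripts"], reference.transcripts)
    _write_vcf(paths["vcf"], plant, reference)
    with open(paths["mirnas"], "w") as fh:
        fh.write("mirna\tsequence\n")
        for name, m in mirnas.items():
            fh.write(f"{name}\t{m.sequence}\n")
    with open(paths["pairs"], "w") as fh:
        fh.write("mirna\ttranscript\n")
        for p in plant.pairs:
            fh.write(f"{p.mirna_name}\t{p.transcript_id}\n")
    with open(paths["expression"], "w") as fh:
        fh.write("mirna\tpop1_ncc\tpop2_nonncc\n")
        for name, row in table.data.iterrows():
            v1 = "N.D." if np.isnan(row["pop1_ncc"]) else f"{row['pop1_ncc']:.3f}"
            v2 = "N.D." if np.isnan(row["pop2_nonncc"]) else f"{row['pop2_nonncc']:.3f}"
            fh.write(f"{name}\t{v1}\t{v2}\n")
    with open(paths["groups"], "w") as fh:
        fh.write("sample\tgroup\n")
        for s in plant.sample_names:
            fh.write(f"{s}\t{plant.groups[s]}\n")
    _write_truth(paths["truth"], plant.variants)
    with open(paths["spec"], "w") as fh:
        json.dump({"seed": seed, "spec": dataclasses.asdict(spec)}, fh, indent=2, sort_keys=True)
        fh.write("\n")

    return Bundle(
        directory=outdir,
        paths=paths,
        truth=[pv.truth for pv in plant.variants],
        expected_expression=expected,
        spec=spec,
        seed=seed,
    )


def spec_from_json(path: str | Path) -> tuple[FixtureSpec, int]:
    """Re-read a bundle's spec.json into (FixtureSpec, seed)."""
    with open(path) as fh:
        payload = json.load(fh)
    raw = payload["spec"]
    for key in ("utr_length", "rare_maf", "common_maf", "delta_range"):
        raw[key] = tuple(raw[key])
    return FixtureSpec(**raw), int(payload["seed"])


def load_truth(path: str | Path) -> list[TruthRecord]:
    records = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for line in fh:
            f = dict(zip(header, line.rstrip("\n").split("\t")))
            records.append(
                TruthRecord(
                    variant_id=f["variant_id"],
                    chrom=f["chrom"],
                    pos=int(f["pos"]),
                    ref=f["ref"],
                    alt=f["alt"],
                    label=f["label"],
                    mirna=f["mirna"],
                    transcript=f["transcript"],
                    site_offset=int(f["site_offset"]),
                    rarity=f["rarity"],
                    carriage=f["carriage"],
                    mirna_expressed=f["mirna_expressed"] == "True",
                )
            )
    return records


def bundle_config(bundle_dir: str | Path, **overrides):
    """A ready-to-run :class:`~seedbreak.pipeline.PipelineConfig` for a bundle."""
    from .pipeline import PipelineConfig

    d = Path(bundle_dir)
    defaults = dict(
        genome=d / "genome.fa",
        transcripts=d / "transcripts.tsv",
        vcf=d / "variants.vcf",
        mirnas=d / "mirnas.tsv",
        pairs=d / "pairs.tsv",
        expression=d / "expression.tsv",
        groups=d / "groups.tsv",
        expressed_population="pop1_ncc",
    )
    defaults.update(overrides)
    return PipelineConfig(**defaults)


def _write_fasta(path: Path, genome: GenomeSequence, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name in genome.names:
            fh.write(f">{name}\n")
            seq = genome[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def _write_truth(path: Path, variants: list[PlannedVariant]) -> None:
    columns = (
        "variant_id", "chrom", "pos", "ref", "alt", "label", "mirna", "transcript",
        "site_offset", "rarity", "carriage", "mirna_expressed",
    )
    with open(path, "w") as fh:
        fh.write("\t".join(columns) + "\n")
        for pv in variants:
            t = pv.truth
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        t.variant_id, t.chrom, t.pos, t.ref, t.alt, t.label, t.mirna,
                        t.transcript, t.site_offset, t.rarity, t.carriage, t.mirna_expressed,
                    )
                )
                + "\n"
            )


def _write_transcript_table(path: Path, transcripts: list[TranscriptModel]) -> None:
    with open(path, "w") as fh:
        fh.write(
            "transcript_id\tgene\tchrom\tstrand\texon_starts\texon_ends\tcds_end\tcds_start\n"
        )
        for t in transcripts:
            starts = ",".join(str(s) for s, _ in t.exons)
            ends = ",".join(str(e) for _, e in t.exons)
            fh.write(
                f"{t.transcript_id}\t{t.gene_symbol}\t{t.chrom}\t{t.strand}\t"
                f"{starts}\t{ends}\t{t.cds_end_genomic}\t{t.cds_start_genomic}\n"
            )


def _write_vcf(path: Path, plant: PlantResult, reference: ReferenceBundle) -> None:
    genome = plant.genome
    records = sorted(plant.variants, key=lambda pv: (pv.variant.chrom, pv.variant.pos))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for name in genome.names:
            fh.write(f"##contig=<ID={name},length={genome.length(name)}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(plant.sample_names)
            + "\n"
        )
        for pv in records:
            v = pv.variant
            expected = genome.slice(v.chrom, v.pos, v.pos + len(v.ref) - 1)
            if expected != v.ref:
                raise BundleError(f"{v}: REF does not match generated genome")
            gts = "\t".join(pv.genotypes.get(s, "0/0") for s in plant.sample_names)
            fh.write(
                f"{v.chrom}\t{v.pos}\t{pv.truth.variant_id}\t{v.ref}\t{v.alt}\t.\tPASS\t.\tGT\t{gts}\n"
            )
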