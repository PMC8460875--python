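"""Cohort variant ingestion, normalization, region annotation, and rarity.

Reads VCF 4.x cohorts (optionally with per-sample genotypes and case/control
labels), normalizes indels (left-aligned minimal representation, plus a
compatibility mode that decomposes multi-base indels into consecutive 1-bp
events), classifies each variant's gene region, computes minor-allele
frequency, and tabulates case/control carriage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pysam

from .reference_model import (
    GenomeSequence,
    TranscriptModel,
    complement_base,
    reverse_complement,
    utr3_label,
)

logger = logging.getLogger(__name__)

REGION_PRECEDENCE = ("CDS", "UTR3", "UTR5", "intron", "upstream2kb", "intergenic")


@dataclass(frozen=True)
class Variant:
    """A genomic substitution, insertion, or deletion (VCF-style, 1-based).

    Indels carry one anchor base: an insertion has ``alt = ref + inserted``,
    a deletion has ``ref = alt + deleted``.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    id: Optional[str] = None
    maf: Optional[float] = None

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError(f"{self.chrom}:{self.pos}: ref equals alt ({self.ref})")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    @property
    def is_insertion(self) -> bool:
        return len(self.alt) > len(self.ref) == 1 and self.alt[0] == self.ref

    @property
    def is_deletion(self) -> bool:
        return len(self.ref) > len(self.alt) == 1 and self.ref[0] == self.alt

    def __str__(self) -> str:
        return f"{self.chrom}:{self.pos}{self.ref}>{self.alt}"


@dataclass
class CohortCounts:
    """Per-variant allele/carrier counts split by sample group (diploid)."""

    n_samples: dict[str, int] = field(default_factory=dict)
    carriers: dict[tuple, dict[str, int]] = field(default_factory=dict)
    alleles: dict[tuple, dict[str, int]] = field(default_factory=dict)

    def record(self, key: tuple, group: str, n_alt_alleles: int) -> None:
        if n_alt_alleles < 0:
            raise ValueError("negative allele count")
        self.carriers.setdefault(key, {})
        self.alleles.setdefault(key, {})
        if n_alt_alleles > 0:
            self.carriers[key][group] = self.carriers[key].get(group, 0) + 1
            self.alleles[key][group] = self.alleles[key].get(group, 0) + n_alt_alleles

    def n_carriers(self, key: tuple, group: str) -> int:
        return self.carriers.get(key, {}).get(group, 0)

    def n_alleles(self, key: tuple, group: str) -> int:
        return self.alleles.get(key, {}).get(group, 0)

    def validate(self) -> None:
        for key, by_group in self.alleles.items():
            for group, n in by_group.items():
                n_samp = self.n_samples.get(group, 0)
                if n > 2 * n_samp:
                    raise ValueError(f"{key}: {n} alleles in {group} exceeds 2x{n_samp} samples")


def read_vcf(
    path: str | Path,
    sample_groups: Optional[Mapping[str, str]] = None,
    genome: Optional[GenomeSequence] = None,
) -> tuple[list[Variant], CohortCounts]:
    """Read a VCF into per-ALT :class:`Variant` records plus cohort counts.

    Multi-allelic records are split, one Variant per ALT allele.  MAF source
    precedence: an explicit ``AF`` INFO annotation wins; otherwise the
    frequency is computed from genotypes over all samples (case + control
    combined); variants with neither keep ``maf=None``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    vf = pysam.VariantFile(str(path))
    samples = list(vf.header.samples)
    groups: dict[str, str] = dict(sample_groups or {})
    missing = set(groups) - set(samples)
    if missing:
        raise ValueError(f"samples in groups but not in VCF header: {sorted(missing)}")

    counts = CohortCounts()
    for sample in samples:
        group = groups.get(sample, "ungrouped")
        counts.n_samples[group] = counts.n_samples.get(group, 0) + 1

    variants: list[Variant] = []
    for rec in vf:
        if rec.ref is None or not rec.alts:
            continue
        ref = rec.ref.upper()
        if genome is not None:
            expected = genome.slice(rec.chrom, rec.pos, rec.pos + len(ref) - 1)
            if expected != ref:
                raise ValueError(
                    f"{rec.chrom}:{rec.pos}: VCF REF {ref} does not match genome {expected}"
                )
        af_info = rec.info.get("AF") if "AF" in rec.info else None
        if af_info is not None and not isinstance(af_info, (tuple, list)):
            af_info = (af_info,)
        for alt_index, alt in enumerate(rec.alts, start=1):
            alt = alt.upper()
            v = Variant(chrom=rec.chrom, pos=rec.pos, ref=ref, alt=alt, id=rec.id)
            n_alt_total = 0
            n_called = 0
            if samples:
                for sample in samples:
                    gt = rec.samples[sample].get("GT")
                    if gt is None:
                        continue
                    called = [a for a in gt if a is not None]
                    n_called += len(called)
                    n_alt = sum(1 for a in called if a == alt_index)
                    counts.record(v.key, groups.get(sample, "ungrouped"), n_alt)
                    n_alt_total += n_alt
            maf: Optional[float] = None
            if af_info is not None:
                maf = float(af_info[alt_index - 1])
            elif n_called > 0:
                maf = n_alt_total / n_called
            variants.append(replace(v, maf=maf))
    counts.validate()
    return variants, counts


# ---------------------------------------------------------------------------
# normalization


def normalize_variant(
    variant: Variant, genome: GenomeSequence, mode: str = "left_align"
) -> list[Variant]:
    """Normalize a variant; returns the list of normalized events.

    ``left_align`` (default) produces the minimal, left-aligned VCF
    representation (one event).  ``paper_1bp`` additionally decomposes any
    multi-base insertion/deletion into consecutive 1-bp events anchored
    immediately after the variant position, conserving the total
    inserted/deleted sequence — the convention used to make indels digestible
    by annotators that only accept single-base events.  SNVs pass through
    unchanged in both modes, and both modes are idempotent.
    """
    if mode not in {"left_align", "paper_1bp"}:
        raise ValueError(f"unknown normalization mode {mode!r}")
    if mode == "paper_1bp" and (
        variant.is_snv
        or (variant.is_insertion and len(variant.alt) == 2)
        or (variant.is_deletion and len(variant.ref) == 2)
    ):
        # already a 1-bp event: the compatibility mode repositions nothing
        observed = genome.slice(variant.chrom, variant.pos, variant.pos + len(variant.ref) - 1)
        if observed != variant.ref:
            raise ValueError(
                f"{variant.chrom}:{variant.pos}: REF {variant.ref} does not match genome {observed}"
            )
        return [variant]
    v = _left_align(variant, genome)
    if mode == "left_align" or (len(v.ref) == 1 and len(v.alt) == 1):
        return [v]
    if v.is_insertion:
        inserted = v.alt[1:]
        if len(inserted) == 1:
            return [v]
        return [
            Variant(chrom=v.chrom, pos=v.pos, ref=v.ref, alt=v.ref + base, id=v.id, maf=v.maf)
            for base in inserted
        ]
    if v.is_deletion:
        deleted = v.ref[1:]
        if len(deleted) == 1:
            return [v]
        out = []
        for i in range(len(deleted)):
            pos = v.pos + i
            anchor = genome.base(v.chrom, pos)
            out.append(
                Variant(
                    chrom=v.chrom,
                    pos=pos,
                    ref=anchor + genome.base(v.chrom, pos + 1),
                    alt=anchor,
                    id=v.id,
                    maf=v.maf,
                )
            )
        return out
    # balanced multi-base substitution: left as-is after minimal trimming
    return [v]


def _left_align(variant: Variant, genome: GenomeSequence) -> Variant:
    """Left-aligned minimal representation (vt-style) of one variant."""
    chrom, pos, ref, alt = variant.chrom, variant.pos, variant.ref, variant.alt
    observed = genome.slice(chrom, pos, pos + len(ref) - 1)
    if observed != ref:
        raise ValueError(f"{chrom}:{pos}: REF {ref} does not match genome {observed}")
    # shrink/extend right end while trailing bases agree
    while len(ref) > 0 and len(alt) > 0 and ref[-1] == alt[-1] and (len(ref) > 1 or len(alt) > 1):
        ref, alt = ref[:-1], alt[:-1]
        if not ref or not alt:
            if pos == 1:
                base = "N"  # cannot extend further left; degenerate at contig start
                ref, alt = base + ref, base + alt
                break
            pos -= 1
            base = genome.base(chrom, pos)
            ref, alt = base + ref, base + alt
    # trim leading common bases
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return Variant(chrom=chrom, pos=pos, ref=ref, alt=alt, id=variant.id, maf=variant.maf)


# ---------------------------------------------------------------------------
# region annotation


@dataclass(frozen=True)
class RegionHit:
    """One (transcript, region) assignment for a variant."""

    transcript_id: str
    gene_symbol: str
    region: str
    utr3_offset: Optional[int] = None
    cstar_label: Optional[str] = None


@dataclass(frozen=True)
class AnnotatedVariant:
    """A variant plus its region class, 3'UTR coordinates, and rarity."""

    variant: Variant
    region: str
    hits: tuple[RegionHit, ...]
    transcript_id: Optional[str] = None
    gene_symbol: Optional[str] = None
    utr3_offset: Optional[int] = None
    cstar_label: Optional[str] = None
    maf: Optional[float] = None
    rarity: Optional[str] = None

    @property
    def label(self) -> str:
        """Human-readable name: 'GENE c.*...' in the UTR, chrom:pos elsewhere."""
        if self.cstar_label and self.gene_symbol:
            return f"{self.gene_symbol} {self.cstar_label}"
        return str(self.variant)

    def utr3_hits(self) -> list[RegionHit]:
        return [h for h in self.hits if h.region == "UTR3"]


def classify_rarity(maf: float, rare_threshold: float = 0.01) -> str:
    """'rare' iff MAF is strictly below the threshold (MAF < 1% by default)."""
    if not 0.0 <= maf <= 1.0:
        raise ValueError(f"MAF {maf} outside [0, 1]")
    return "rare" if maf < rare_threshold else "common"


def rare_fraction_percent(n_rare: int, n_total: int) -> float:
    """Percentage of variants that are rare, as printed in rarity summaries."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 <= n_rare <= n_total:
        raise ValueError("n_rare outside [0, n_total]")
    return 100.0 * n_rare / n_total


def _utr3_hit(transcript: TranscriptModel, variant: Variant) -> Optional[RegionHit]:
    """UTR3 offset and c.* label of a variant on one transcript, if computable.

    Works structurally (no genome needed): the offset map is derived from the
    transcript's exon layout, and ref/alt are complemented into mRNA sense on
    minus-strand transcripts.
    """
    positions = transcript.utr3_genomic_positions()
    offset_of = {g: i for i, g in enumerate(positions)}
    minus = transcript.strand == "-"
    v = variant
    if v.is_snv:
        k = offset_of.get(v.pos)
        if k is None:
            return None
        ref_s = complement_base(v.ref) if minus else v.ref
        alt_s = complement_base(v.alt) if minus else v.alt
        return RegionHit(
            transcript.transcript_id,
            transcript.gene_symbol,
            "UTR3",
            utr3_offset=k,
            cstar_label=utr3_label(k, ref_s, alt_s),
        )
    if v.is_insertion:
        inserted = v.alt[1:]
        k_anchor = offset_of.get(v.pos)
        k_next = offset_of.get(v.pos + 1)
        if minus:
            ins_sense = reverse_complement(inserted)
            j = k_anchor if k_anchor is not None else (None if k_next is None else k_next + 1)
        else:
            ins_sense = inserted
            j = (k_anchor + 1) if k_anchor is not None else k_next
        if j is None or j < 1:
            return None
        return RegionHit(
            transcript.transcript_id,
            transcript.gene_symbol,
            "UTR3",
            utr3_offset=j - 1,
            cstar_label=f"c.*{j}_*{j + 1}ins{ins_sense}",
        )
    if v.is_deletion:
        deleted = v.ref[1:]
        offs = [offset_of.get(p) for p in range(v.pos + 1, v.pos + 1 + len(deleted))]
        if any(o is None for o in offs):
            return None
        omin, omax = min(offs), max(offs)
        if omax - omin + 1 != len(deleted):
            return None  # deletion spans a splice junction
        deleted_sense = reverse_complement(deleted) if minus else deleted
        if len(deleted) == 1:
            label = f"c.*{omin + 1}del{deleted_sense}"
        else:
            label = f"c.*{omin + 1}_*{omax + 1}del{deleted_sense}"
        return RegionHit(
            transcript.transcript_id,
            transcript.gene_symbol,
            "UTR3",
            utr3_offset=omin,
            cstar_label=label,
        )
    return None


def _representative_positions(variant: Variant) -> list[int]:
    """Genomic positions that place a variant in a feature class.

    SNVs are classified at their own position; deletions at the first deleted
    base; insertions at the anchor base, falling back to the next base.
    """
    if variant.is_deletion:
        return [variant.pos + 1]
    if variant.is_insertion:
        return [variant.pos, variant.pos + 1]
    return [variant.pos]


def annotate_region(
    variant: Variant,
    transcripts: Sequence[TranscriptModel],
    upstream_bp: int = 2000,
    rare_threshold: float = 0.01,
) -> AnnotatedVariant:
    """Assign a region class (and UTR3 coordinates) to one variant.

    Every (transcript, region) hit is retained; the variant-level ``region``
    is the highest-precedence class across transcripts
    (CDS > UTR3 > UTR5 > intron > upstream2kb > intergenic).  UTR3 hits carry
    a 0-based UTR offset and a ``c.*`` label.
    """
    if not transcripts:
        raise ValueError("transcripts must be nonempty")
    hits: list[RegionHit] = []
    for tx in transcripts:
        if tx.chrom != variant.chrom:
            continue
        region = None
        for pos in _representative_positions(variant):
            region = tx.region_of(pos, upstream_bp=upstream_bp)
            if region is not None:
                break
        if region is None:
            continue
        if region == "UTR3":
            hit = _utr3_hit(tx, variant)
            if hit is None:  # footprint leaves the UTR; report the class only
                hit = RegionHit(tx.transcript_id, tx.gene_symbol, "UTR3")
            hits.append(hit)
        else:
            hits.append(RegionHit(tx.transcript_id, tx.gene_symbol, region))

    hits.sort(key=lambda h: (REGION_PRECEDENCE.index(h.region), h.transcript_id))
    region = hits[0].region if hits else "intergenic"
    primary = next((h for h in hits if h.region == "UTR3" and h.utr3_offset is not None), None)
    maf = variant.maf
    rarity = classify_rarity(maf, rare_threshold) if maf is not None else None
    return AnnotatedVariant(
        variant=variant,
        region=region,
        hits=tuple(hits),
        transcript_id=primary.transcript_id if primary else None,
        gene_symbol=(primary or (hits[0] if hits else None)).gene_symbol if hits else None,
        utr3_offset=primary.utr3_offset if primary else None,
        cstar_label=primary.cstar_label if primary else None,
        maf=maf,
        rarity=rarity,
    )


def case_control_distribution(
    annotated_variants: Iterable[AnnotatedVariant],
    cohort_counts: CohortCounts,
    case_group: str = "case",
    control_group: str = "control",
):
    """Carrier counts by group, one row per variant (Table-4-style layout)."""
    import pandas as pd

    rows = []
    for av in annotated_variants:
        key = av.variant.key
        rows.append(
            {
                "variant": av.label,
                "gene": av.gene_symbol or "",
                "n_control": cohort_counts.n_carriers(key, control_group),
                "n_case": cohort_counts.n_carriers(key, case_group),
            }
        )
    return pd.DataFrame(rows, columns=["variant", "gene", "n_control", "n_case"])
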