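"""Seed-site gain/loss calling for 3'UTR variants.

A variant applied to a 3'UTR is classified, per miRNA, as:

* ``LOST``     — a reference site overlapping the variant has no surviving
                 counterpart in the mutated UTR;
* ``GAINED``   — a site appears in the mutated UTR over the edited region
                 with no reference counterpart;
* ``RETAINED`` — the variant overlaps a reference site that still matches
                 after the edit (possibly shifted by an indel);
* ``NONE``     — the variant touches no site of this miRNA on either allele.

Site correspondence across an indel uses offset identity adjusted by the
length shift: sites strictly 5' of the edit keep their offsets, sites 3' of
it shift by ``len(alt) - len(ref)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .reference_model import Utr3Record, reverse_complement
from .seed_sites import SITE_LENGTH, MiRNA, SeedMatchSite, scan_sites, site_pattern, find_pattern
from .variant_ingest import Variant

STATUSES = ("LOST", "GAINED", "RETAINED", "NONE")


def apply_variant(utr_sequence: str, utr_offset: int, ref: str, alt: str) -> str:
    """Apply an anchored UTR-space edit to a UTR sequence.

    ``utr_sequence[utr_offset : utr_offset + len(ref)]`` must equal ``ref``
    (for insertions ``ref`` is the single anchor base); a mismatch raises, as
    a guard against coordinate bugs.  Output length changes by
    ``len(alt) - len(ref)``.
    """
    if not ref:
        raise ValueError("ref must be nonempty (anchored convention)")
    observed = utr_sequence[utr_offset : utr_offset + len(ref)]
    if observed != ref:
        raise ValueError(
            f"UTR ref mismatch at offset {utr_offset}: expected {ref!r}, found {observed!r}"
        )
    return utr_sequence[:utr_offset] + alt + utr_sequence[utr_offset + len(ref) :]


@dataclass(frozen=True)
class UtrEdit:
    """A variant expressed in sense-strand UTR space.

    For substitutions/deletions, ``start`` is the first affected offset and
    ``ref``/``alt`` are the replaced/replacement sense bases (``alt`` empty
    for a pure deletion).  For insertions, ``start`` is the sense insertion
    index ``j`` (the inserted bases land between offsets ``j-1`` and ``j``)
    and ``ref`` is empty.
    """

    start: int
    ref: str
    alt: str
    insertion: bool = False

    @property
    def shift(self) -> int:
        return len(self.alt) - len(self.ref)


def sense_edit(utr3_record: Utr3Record, variant: Variant) -> UtrEdit:
    """Translate a genomic variant into sense-strand UTR space.

    Handles strand: on minus-strand transcripts alleles are (reverse)
    complemented and insertion points are mirrored.  Raises when the
    variant's footprint is not fully inside the UTR or spans a splice
    junction.
    """
    utr = utr3_record
    minus = utr.strand == "-"
    v = variant
    if len(v.ref) == len(v.alt):  # substitution (SNV or MNV)
        offs = [utr.offset_of(p) for p in range(v.pos, v.pos + len(v.ref))]
        if any(o is None for o in offs):
            raise ValueError(f"{v}: substitution footprint not fully inside 3'UTR")
        omin, omax = min(offs), max(offs)
        if omax - omin + 1 != len(v.ref):
            raise ValueError(f"{v}: substitution spans a splice junction")
        ref_s = reverse_complement(v.ref) if minus else v.ref
        alt_s = reverse_complement(v.alt) if minus else v.alt
        _check(utr, omin, ref_s)
        return UtrEdit(start=omin, ref=ref_s, alt=alt_s)
    if v.is_insertion:
        inserted = v.alt[1:]
        k_anchor = utr.offset_of(v.pos)
        k_next = utr.offset_of(v.pos + 1)
        if minus:
            ins_sense = reverse_complement(inserted)
            j = k_anchor if k_anchor is not None else (None if k_next is None else k_next + 1)
        else:
            ins_sense = inserted
            j = (k_anchor + 1) if k_anchor is not None else k_next
        if j is None:
            raise ValueError(f"{v}: insertion point not inside 3'UTR")
        return UtrEdit(start=j, ref="", alt=ins_sense, insertion=True)
    if v.is_deletion:
        deleted = v.ref[1:]
        offs = [utr.offset_of(p) for p in range(v.pos + 1, v.pos + 1 + len(deleted))]
        if any(o is None for o in offs):
            raise ValueError(f"{v}: deletion footprint not fully inside 3'UTR")
        omin, omax = min(offs), max(offs)
        if omax - omin + 1 != len(deleted):
            raise ValueError(f"{v}: deletion spans a splice junction")
        del_sense = reverse_complement(deleted) if minus else deleted
        _check(utr, omin, del_sense)
        return UtrEdit(start=omin, ref=del_sense, alt="")
    raise ValueError(f"{v}: unsupported allele combination")


def _check(utr: Utr3Record, offset: int, ref_sense: str) -> None:
    observed = utr.utr_sequence[offset : offset + len(ref_sense)]
    if observed != ref_sense:
        raise ValueError(
            f"{utr.transcript_id}: sense ref mismatch at offset {offset}: "
            f"expected {ref_sense!r}, found {observed!r}"
        )


def apply_edit(utr_sequence: str, edit: UtrEdit) -> str:
    """Apply a :class:`UtrEdit` to a sense UTR sequence."""
    if edit.insertion:
        return utr_sequence[: edit.start] + edit.alt + utr_sequence[edit.start :]
    observed = utr_sequence[edit.start : edit.start + len(edit.ref)]
    if observed != edit.ref:
        raise ValueError(
            f"ref mismatch at offset {edit.start}: expected {edit.ref!r}, found {observed!r}"
        )
    return utr_sequence[: edit.start] + edit.alt + utr_sequence[edit.start + len(edit.ref) :]


def variant_overlaps_site(
    utr_offset: int, ref_len: int, site: SeedMatchSite, insertion: bool = False
) -> bool:
    """Does the edit footprint intersect a site's 7-base window?

    For substitutions/deletions, ``utr_offset`` is the first affected offset
    and ``ref_len`` the number of affected reference bases; overlap is closed
    intersection with ``[site.start, site.start + 6]``.  For insertions,
    ``utr_offset`` is the insertion index ``j`` and the test is whether the
    insertion point lies strictly inside the site (so an insertion just 5' or
    just 3' of the window leaves the contiguous site intact).
    """
    s0, s1 = site.start_offset, site.end_offset
    if insertion:
        return s0 + 1 <= utr_offset <= s1
    if ref_len < 1:
        raise ValueError("ref_len must be >= 1 for non-insertion edits")
    return utr_offset <= s1 and utr_offset + ref_len - 1 >= s0


@dataclass(frozen=True)
class DisruptionCall:
    """Verdict for one variant x miRNA x transcript."""

    variant: Variant
    mirna_name: str
    transcript_id: str
    status: str
    ref_sites: tuple[SeedMatchSite, ...]
    alt_sites: tuple[SeedMatchSite, ...]
    overlapped_ref_site: Optional[SeedMatchSite] = None


def _edit_overlaps(edit: UtrEdit, site: SeedMatchSite) -> bool:
    if edit.insertion:
        return variant_overlaps_site(edit.start, 0, site, insertion=True)
    return variant_overlaps_site(edit.start, len(edit.ref), site)


def call_disruption(utr3_record: Utr3Record, variant: Variant, mirna: MiRNA) -> DisruptionCall:
    """Classify one variant x miRNA on one transcript's 3'UTR.

    Both the reference and the mutated UTR are rescanned from scratch, so the
    reported site lists are exactly what :func:`scan_sites` would return on
    either allele.
    """
    edit = sense_edit(utr3_record, variant)
    ref_seq = utr3_record.utr_sequence
    alt_seq = apply_edit(ref_seq, edit)
    pattern = site_pattern(mirna)
    ref_sites = tuple(scan_sites(utr3_record, mirna))
    alt_offsets = find_pattern(alt_seq, pattern)
    alt_sites = tuple(
        SeedMatchSite(utr3_record.transcript_id, mirna.name, i, pattern) for i in alt_offsets
    )
    alt_offset_set = set(alt_offsets)
    ref_offset_set = {s.start_offset for s in ref_sites}
    shift = edit.shift

    # edited interval in reference coordinates ([e0, e1] inclusive; insertions
    # are the zero-width point before offset e0)
    if edit.insertion:
        e0 = e1 = edit.start
    else:
        e0, e1 = edit.start, edit.start + len(edit.ref) - 1

    def ref_site_survives(s: int) -> bool:
        site_end = s + SITE_LENGTH - 1
        if edit.insertion:
            if site_end < edit.start:
                candidates = {s}
            elif s >= edit.start:
                candidates = {s + shift}
            else:
                candidates = {s, s + shift}
        else:
            if site_end < e0:
                candidates = {s}
            elif s > e1:
                candidates = {s + shift}
            else:
                candidates = {s, s + shift}
        return bool(candidates & alt_offset_set)

    def alt_site_has_counterpart(a: int) -> bool:
        site_end = a + SITE_LENGTH - 1
        if edit.insertion:
            if site_end < edit.start:
                candidates = {a}
            elif a >= edit.start + len(edit.alt):
                candidates = {a - shift}
            else:
                candidates = {a, a - shift}
        else:
            alt_e1 = edit.start + max(len(edit.alt), 1) - 1
            if site_end < e0:
                candidates = {a}
            elif a > alt_e1:
                candidates = {a - shift}
            else:
                candidates = {a, a - shift}
        return bool(candidates & ref_offset_set)

    overlapped_ref = [s for s in ref_sites if _edit_overlaps(edit, s)]
    lost = [s for s in overlapped_ref if not ref_site_survives(s.start_offset)]

    # alt sites overlapping the edited region in alt coordinates
    if edit.insertion:
        a0, a1 = edit.start, edit.start + len(edit.alt) - 1
        overlapped_alt = [a for a in alt_sites if a.start_offset <= a1 and a.end_offset >= a0]
    elif not edit.alt:  # pure deletion: sites spanning the junction
        j = edit.start
        overlapped_alt = [a for a in alt_sites if a.start_offset + 1 <= j <= a.end_offset]
    else:
        a0, a1 = edit.start, edit.start + len(edit.alt) - 1
        overlapped_alt = [a for a in alt_sites if a.start_offset <= a1 and a.end_offset >= a0]
    gained = [a for a in overlapped_alt if not alt_site_has_counterpart(a.start_offset)]

    if lost:
        status = "LOST"
    elif gained:
        status = "GAINED"
    elif overlapped_ref:
        status = "RETAINED"
    else:
        status = "NONE"
    return DisruptionCall(
        variant=variant,
        mirna_name=mirna.name,
        transcript_id=utr3_record.transcript_id,
        status=status,
        ref_sites=ref_sites,
        alt_sites=alt_sites,
        overlapped_ref_site=overlapped_ref[0] if overlapped_ref else None,
    )
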