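"""Shared fixtures and independent oracles.

The oracles here are deliberately written from first principles (dict-based
complementation, all-windows substring scanning, exhaustive representation
enumeration) so they stay independent of the implementation paths they
check.
"""

from __future__ import annotations

import pytest

from seedbreak.reference_model import GenomeSequence, TranscriptModel
from seedbreak.synthetic_data import FixtureSpec, generate_bundle

# --- independent oracles ---------------------------------------------------

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def oracle_revcomp(seq: str) -> str:
    """Reverse complement computed base-by-base from a lookup table."""
    return "".join(_COMP[b] for b in reversed(seq))


def oracle_find_all(sequence: str, pattern: str) -> list[int]:
    """Every window of len(pattern) compared literally."""
    k = len(pattern)
    return [i for i in range(len(sequence) - k + 1) if sequence[i : i + k] == pattern]


def oracle_apply_edit(seq: str, offset: int, ref: str, alt: str) -> str:
    """Plain string surgery, no shared code with the implementation."""
    assert seq[offset : offset + len(ref)] == ref
    return seq[:offset] + alt + seq[offset + len(ref) :]


def oracle_leftmost_deletion(genome_seq: str, pos: int, ref: str, alt: str):
    """Leftmost anchored representation of a deletion, by brute force.

    Applies the deletion to the whole sequence, then enumerates every
    anchored 1-anchor deletion of the same length and keeps the smallest
    position that reproduces the mutated sequence.
    """
    assert len(ref) > len(alt) == 1 and ref[0] == alt
    mutated = genome_seq[: pos - 1] + alt + genome_seq[pos - 1 + len(ref) :]
    d = len(ref) - 1
    for p in range(1, len(genome_seq) - d):
        cand_ref = genome_seq[p - 1 : p + d]
        cand = genome_seq[: p - 1] + cand_ref[0] + genome_seq[p + d :]
        if cand == mutated:
            return p, cand_ref, cand_ref[0]
    raise AssertionError("no equivalent representation found")


# --- toy reference fixtures ------------------------------------------------


@pytest.fixture
def toy_plus_genome() -> GenomeSequence:
    """chr1: 40 As, then CCTGCTG (a miR-214-3p site), then filler to 100 nt."""
    seq = "A" * 40 + "CCTGCTG" + "ACGT" * 13 + "A"
    assert len(seq) == 100
    return GenomeSequence({"chr1": seq})


@pytest.fixture
def toy_plus_transcript() -> TranscriptModel:
    """Single exon 1-100 on '+', stop codon ends at 40 -> UTR = 41..100."""
    return TranscriptModel(
        transcript_id="TOYP",
        gene_symbol="TOYPLUS",
        chrom="chr1",
        strand="+",
        exons=((1, 100),),
        cds_end_genomic=40,
        cds_start_genomic=5,
    )


@pytest.fixture
def toy_minus_transcript() -> TranscriptModel:
    """Single exon 1-100 on '-', stop codon's last base at 61 -> UTR = 1..60."""
    return TranscriptModel(
        transcript_id="TOYM",
        gene_symbol="TOYMINUS",
        chrom="chr1",
        strand="-",
        exons=((1, 100),),
        cds_end_genomic=61,
        cds_start_genomic=95,
    )


@pytest.fixture(scope="session")
def default_bundle(tmp_path_factory):
    """One default-spec synthetic bundle, shared across tests."""
    outdir = tmp_path_factory.mktemp("bundle")
    return generate_bundle(FixtureSpec(), seed=1, outdir=outdir)
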