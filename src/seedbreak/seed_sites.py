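"""miRNA seeds and canonical seed-match site scanning.

The canonical binding-site rule: a 7-nt stretch of 3'UTR is a site for a
miRNA when it is exactly reverse-complementary to the miRNA's seed,
nucleotides 2-8 of the mature sequence (the 7mer-m8 site class).  Matching
is exact Watson-Crick — no G:U wobble, no mismatches — and performed in DNA
space (the UTR is DNA; the seed is converted U->T when the site pattern is
built).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional

from .reference_model import Utr3Record, reverse_complement, strip_version

logger = logging.getLogger(__name__)

RNA_ALPHABET = frozenset("ACGU")

SEED_START = 1  # 0-based start of seed (nt 2 of the mature miRNA)
SEED_END = 8    # 0-based exclusive end (nt 8)
SITE_LENGTH = SEED_END - SEED_START


@dataclass(frozen=True)
class MiRNA:
    """A mature miRNA: name plus 5'->3' RNA sequence (>= 8 nt, uppercase)."""

    name: str
    sequence: str

    def __post_init__(self) -> None:
        seq = self.sequence
        if seq != seq.upper():
            object.__setattr__(self, "sequence", seq.upper())
            seq = self.sequence
        bad = set(seq) - RNA_ALPHABET
        if bad:
            raise ValueError(f"miRNA {self.name}: non-RNA characters {sorted(bad)}")
        if len(seq) < SEED_END:
            raise ValueError(f"miRNA {self.name}: sequence shorter than 8 nt")


@dataclass(frozen=True)
class SeedMatchSite:
    """One occurrence of a miRNA's seed-match pattern in a 3'UTR."""

    transcript_id: str
    mirna_name: str
    start_offset: int
    site_sequence: str

    @property
    def length(self) -> int:
        return SITE_LENGTH

    @property
    def end_offset(self) -> int:
        """0-based offset of the last site base (start + 6)."""
        return self.start_offset + SITE_LENGTH - 1


@dataclass(frozen=True)
class PairHypothesis:
    """An externally predicted miRNA-transcript pairing (e.g. a miRDB-style list)."""

    mirna_name: str
    transcript_id: str
    source: str = "pairs"


def seed_sequence(mirna: MiRNA) -> str:
    """Seed of a miRNA: nucleotides 2-8 (1-based) of the mature sequence."""
    return mirna.sequence[SEED_START:SEED_END]


def site_pattern(mirna: MiRNA) -> str:
    """DNA 7-mer a canonical site must equal: revcomp of the seed, U->T."""
    return reverse_complement(seed_sequence(mirna).replace("U", "T"))


def find_pattern(sequence: str, pattern: str) -> list[int]:
    """All (possibly overlapping) start indices of ``pattern`` in ``sequence``."""
    hits: list[int] = []
    start = sequence.find(pattern)
    while start != -1:
        hits.append(start)
        start = sequence.find(pattern, start + 1)
    return hits


def scan_sites(utr3_record: Utr3Record, mirna: MiRNA) -> list[SeedMatchSite]:
    """All canonical seed-match sites of a miRNA in a 3'UTR, 5'->3'.

    Overlapping occurrences are all reported, in ascending start offset.
    """
    pattern = site_pattern(mirna)
    return [
        SeedMatchSite(
            transcript_id=utr3_record.transcript_id,
            mirna_name=mirna.name,
            start_offset=i,
            site_sequence=pattern,
        )
        for i in find_pattern(utr3_record.utr_sequence, pattern)
    ]


@dataclass
class PairSiteMap:
    """Result of localizing sites for a list of pair hypotheses."""

    sites: dict[tuple[str, str], list[SeedMatchSite]]
    unresolved: list[PairHypothesis]
    zero_site_pairs: list[tuple[str, str]]

    def __getitem__(self, key: tuple[str, str]) -> list[SeedMatchSite]:
        return self.sites[key]


def localize_pair_sites(
    pairs: Iterable[PairHypothesis],
    utr3_records: Mapping[str, Utr3Record],
    mirnas: Mapping[str, MiRNA],
) -> PairSiteMap:
    """Map each resolvable (miRNA, transcript) pair to its canonical sites.

    Pairs whose miRNA or transcript cannot be resolved are logged and listed
    as unresolved; resolvable pairs with zero canonical sites are retained in
    the map (empty list) and flagged — external predictors also emit
    non-canonical sites, which this scanner deliberately does not model.
    Transcript IDs are joined exactly first, then with version suffixes
    stripped.
    """
    versionless = {strip_version(tid): rec for tid, rec in utr3_records.items()}
    sites: dict[tuple[str, str], list[SeedMatchSite]] = {}
    unresolved: list[PairHypothesis] = []
    zero: list[tuple[str, str]] = []
    for pair in pairs:
        mirna = mirnas.get(pair.mirna_name)
        rec = utr3_records.get(pair.transcript_id) or versionless.get(
            strip_version(pair.transcript_id)
        )
        if mirna is None or rec is None:
            logger.warning(
                "unresolvable pair (%s, %s): %s unknown",
                pair.mirna_name,
                pair.transcript_id,
                "miRNA" if mirna is None else "transcript",
            )
            unresolved.append(pair)
            continue
        key = (pair.mirna_name, rec.transcript_id)
        hits = scan_sites(rec, mirna)
        sites[key] = hits
        if not hits:
            zero.append(key)
    if zero:
        logger.info("%d pair(s) have no canonical 7mer site; retained and flagged", len(zero))
    return PairSiteMap(sites=sites, unresolved=unresolved, zero_site_pairs=zero)


# ---------------------------------------------------------------------------
# loading


def load_mirnas(path: str | Path) -> dict[str, MiRNA]:
    """Load miRNAs from FASTA or a two-column (name, sequence) TSV.

    Sequences are uppercased and DNA-style T is converted to U so either
    alphabet is accepted on input.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    out: dict[str, MiRNA] = {}

    def _add(name: str, seq: str) -> None:
        if name in out:
            raise ValueError(f"duplicate miRNA name {name!r}")
        out[name] = MiRNA(name=name, sequence=seq.upper().replace("T", "U"))

    with open(path) as fh:
        first = fh.read(1)
    if first == ">":
        from Bio import SeqIO

        for rec in SeqIO.parse(str(path), "fasta"):
            _add(rec.id, str(rec.seq))
        return out
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}: line {lineno}: expected 2 columns")
            if lineno == 1 and fields[0].lower() in {"mirna", "mirna_name", "name", "microrna"}:
                continue
            _add(fields[0], fields[1])
    return out


def load_pairs(path: str | Path, source: Optional[str] = None) -> list[PairHypothesis]:
    """Load (mirna_name, transcript_id) pair hypotheses from a 2-column TSV."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    tag = source or path.name
    pairs: list[PairHypothesis] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}: line {lineno}: expected 2 columns")
            if lineno == 1 and fields[0].lower() in {"mirna", "mirna_name", "name", "microrna"}:
                continue
            pairs.append(PairHypothesis(mirna_name=fields[0], transcript_id=fields[1], source=tag))
    return pairs
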