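"""Reference sequence and transcript models.

Loads a genome FASTA and transcript structures (GTF or a simple tab-delimited
transcript table), extracts sense-strand 3'UTR sequences, and converts between
genomic coordinates, 0-based 3'UTR offsets, and HGVS-style ``c.*`` labels.

Coordinate conventions
----------------------
* Genomic coordinates are 1-based inclusive (VCF/GTF convention).
* 3'UTR offsets are 0-based positions within the spliced, sense-oriented UTR.
* ``c.*`` labels are 1-based: the first base after the stop codon is ``c.*1``.

The 3'UTR is defined as all exonic sequence strictly 3' of the last base of
the stop codon, spliced across exons.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

from Bio import SeqIO
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

#: IUPAC nucleotide codes accepted in reference sequences.
IUPAC_DNA = frozenset("ACGTNRYSWKMBDHV")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (delegates to Bio.Seq)."""
    return str(Seq(seq).reverse_complement())


def complement_base(base: str) -> str:
    return base.translate(_COMPLEMENT)


class GenomeSequence:
    """In-memory genome: a name -> uppercase DNA sequence map.

    Lookups are case-insensitive on sequence content at load time (stored
    uppercase); slicing is bounds-checked.
    """

    def __init__(self, sequences: dict[str, str]):
        self._seqs: dict[str, str] = {}
        for name, seq in sequences.items():
            seq = seq.upper()
            bad = set(seq) - IUPAC_DNA
            if bad:
                raise ValueError(
                    f"sequence {name!r} contains non-IUPAC characters: {sorted(bad)}"
                )
            if name in self._seqs:
                raise ValueError(f"duplicate sequence name {name!r}")
            self._seqs[name] = seq

    @property
    def names(self) -> list[str]:
        return list(self._seqs)

    def __contains__(self, name: str) -> bool:
        return name in self._seqs

    def __getitem__(self, name: str) -> str:
        return self._seqs[name]

    def length(self, name: str) -> int:
        return len(self._seqs[name])

    def base(self, name: str, pos: int) -> str:
        """Base at 1-based position ``pos``."""
        seq = self._seqs[name]
        if not 1 <= pos <= len(seq):
            raise IndexError(f"position {name}:{pos} outside sequence (len {len(seq)})")
        return seq[pos - 1]

    def slice(self, name: str, start: int, end: int) -> str:
        """Sequence of the 1-based inclusive interval [start, end]."""
        seq = self._seqs[name]
        if not (1 <= start <= end <= len(seq)):
            raise IndexError(f"interval {name}:{start}-{end} outside sequence (len {len(seq)})")
        return seq[start - 1 : end]


def load_genome(fasta_path: str | Path) -> GenomeSequence:
    """Read a (multi-)FASTA into a :class:`GenomeSequence`.

    Raises on missing files, duplicate record names, and non-IUPAC characters.
    """
    fasta_path = Path(fasta_path)
    if not fasta_path.exists():
        raise FileNotFoundError(fasta_path)
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id in seqs:
            raise ValueError(f"duplicate FASTA record name {rec.id!r} in {fasta_path}")
        seqs[rec.id] = str(rec.seq)
    return GenomeSequence(seqs)


def strip_version(identifier: str) -> str:
    """Drop a trailing ``.N`` version suffix from a transcript identifier."""
    head, dot, tail = identifier.rpartition(".")
    if dot and tail.isdigit():
        return head
    return identifier


@dataclass(frozen=True)
class TranscriptModel:
    """One transcript: exon structure plus strand-aware stop-codon anchor.

    ``cds_end_genomic`` is the genomic position of the last base of the stop
    codon in transcription order (the highest CDS position on '+', the lowest
    on '-').  ``cds_start_genomic`` (first base of the start codon) is
    optional and only used to tell CDS from 5'UTR during region annotation.
    """

    transcript_id: str
    gene_symbol: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds_end_genomic: int
    cds_start_genomic: Optional[int] = None

    def validate(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"{self.transcript_id}: bad strand {self.strand!r}")
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: no exons")
        prev_end = 0
        for start, end in self.exons:
            if start > end:
                raise ValueError(f"{self.transcript_id}: exon {start}-{end} inverted")
            if start <= prev_end:
                raise ValueError(f"{self.transcript_id}: exons overlap or are unsorted")
            prev_end = end
        if not self._in_exon(self.cds_end_genomic):
            raise ValueError(f"{self.transcript_id}: cds_end {self.cds_end_genomic} not exonic")
        if not self.utr3_genomic_positions():
            raise ValueError(f"{self.transcript_id}: zero-length 3'UTR")

    def _in_exon(self, pos: int) -> bool:
        return any(s <= pos <= e for s, e in self.exons)

    @property
    def tx_start(self) -> int:
        return self.exons[0][0]

    @property
    def tx_end(self) -> int:
        return self.exons[-1][1]

    def exonic_positions(self) -> list[int]:
        out: list[int] = []
        for s, e in self.exons:
            out.extend(range(s, e + 1))
        return out

    def utr3_genomic_positions(self) -> tuple[int, ...]:
        """Genomic positions of the 3'UTR in transcription order.

        Exonic positions strictly 3' of the stop codon's last base: above it
        on the plus strand, below it (and returned descending) on minus.
        """
        pos = self.exonic_positions()
        if self.strand == "+":
            return tuple(p for p in pos if p > self.cds_end_genomic)
        return tuple(p for p in reversed(pos) if p < self.cds_end_genomic)

    def region_of(self, pos: int, upstream_bp: int = 2000) -> Optional[str]:
        """Region class of a genomic position relative to this transcript.

        Returns one of ``UTR3, UTR5, CDS, intron, upstream2kb`` or ``None``
        (the position does not touch this transcript's annotation footprint).
        """
        if self._in_exon(pos):
            if self.strand == "+":
                if pos > self.cds_end_genomic:
                    return "UTR3"
                if self.cds_start_genomic is not None and pos < self.cds_start_genomic:
                    return "UTR5"
                return "CDS"
            if pos < self.cds_end_genomic:
                return "UTR3"
            if self.cds_start_genomic is not None and pos > self.cds_start_genomic:
                return "UTR5"
            return "CDS"
        if self.tx_start <= pos <= self.tx_end:
            return "intron"
        if self.strand == "+" and self.tx_start - upstream_bp <= pos < self.tx_start:
            return "upstream2kb"
        if self.strand == "-" and self.tx_end < pos <= self.tx_end + upstream_bp:
            return "upstream2kb"
        return None


@dataclass
class Utr3Record:
    """Spliced, sense-oriented 3'UTR of one transcript.

    ``genomic_positions[i]`` is the genomic coordinate of ``utr_sequence[i]``;
    the pair forms a bijection between UTR offsets and genomic positions.
    """

    transcript_id: str
    gene_symbol: str
    chrom: str
    strand: str
    utr_sequence: str
    genomic_positions: tuple[int, ...]
    _offset_of: dict[int, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if len(self.utr_sequence) != len(self.genomic_positions):
            raise ValueError("utr_sequence and genomic_positions lengths differ")
        self._offset_of = {g: i for i, g in enumerate(self.genomic_positions)}
        if len(self._offset_of) != len(self.genomic_positions):
            raise ValueError("genomic_positions are not unique")

    def __len__(self) -> int:
        return len(self.utr_sequence)

    def offset_of(self, genomic_pos: int) -> Optional[int]:
        return self._offset_of.get(genomic_pos)

    def genomic_at(self, offset: int) -> int:
        return self.genomic_positions[offset]


def extract_utr3(transcript: TranscriptModel, genome: GenomeSequence) -> Utr3Record:
    """Build the :class:`Utr3Record` of a transcript from the genome.

    For minus-strand transcripts the sense sequence is the reverse complement
    of the concatenated genomic exon slices 3' of the stop codon.
    """
    positions = transcript.utr3_genomic_positions()
    if not positions:
        raise ValueError(f"{transcript.transcript_id}: empty 3'UTR")
    if transcript.chrom not in genome:
        raise KeyError(f"chromosome {transcript.chrom!r} not in genome")
    chrom_len = genome.length(transcript.chrom)
    if max(positions) > chrom_len or min(positions) < 1:
        raise IndexError(
            f"{transcript.transcript_id}: 3'UTR extends past chromosome end "
            f"({transcript.chrom} len {chrom_len})"
        )
    ascending = sorted(positions)
    plus_seq = "".join(genome.base(transcript.chrom, p) for p in ascending)
    sense = plus_seq if transcript.strand == "+" else reverse_complement(plus_seq)
    return Utr3Record(
        transcript_id=transcript.transcript_id,
        gene_symbol=transcript.gene_symbol,
        chrom=transcript.chrom,
        strand=transcript.strand,
        utr_sequence=sense,
        genomic_positions=positions,
    )


def genomic_to_utr3_offset(utr3_record: Utr3Record, genomic_pos: int) -> Optional[int]:
    """0-based UTR offset of a 1-based genomic position, or ``None``."""
    return utr3_record.offset_of(genomic_pos)


def utr3_label(offset: int, ref: str, alt: str) -> str:
    """HGVS-style ``c.*`` name for a UTR-space edit at a 0-based offset.

    * substitution: ``c.*{k+1}{REF}>{ALT}``
    * insertion (anchored: ``alt = ref + inserted``): ``c.*{k+1}_*{k+2}ins...``
    * deletion (anchored: ``ref = alt + deleted``): ``c.*{k+2}del...`` or a
      ``c.*a_*b del`` range for multi-base deletions
    """
    if offset < 0:
        raise ValueError(f"negative UTR offset {offset}")
    if not ref or not alt:
        raise ValueError("ref and alt must be nonempty (use anchored indel form)")
    ref, alt = ref.upper(), alt.upper()
    if len(ref) == len(alt) == 1:
        return f"c.*{offset + 1}{ref}>{alt}"
    if len(ref) == len(alt):
        end = offset + len(ref)
        return f"c.*{offset + 1}_*{end}delins{alt}"
    if len(alt) > len(ref) == 1 and alt[0] == ref:
        return f"c.*{offset + 1}_*{offset + 2}ins{alt[1:]}"
    if len(ref) > len(alt) == 1 and ref[0] == alt:
        deleted = ref[1:]
        if len(deleted) == 1:
            return f"c.*{offset + 2}del{deleted}"
        return f"c.*{offset + 2}_*{offset + len(ref)}del{deleted}"
    raise ValueError(f"cannot label edit ref={ref!r} alt={alt!r} (not anchored minimal form)")


# ---------------------------------------------------------------------------
# transcript loading


TABLE_COLUMNS = ("transcript_id", "gene", "chrom", "strand", "exon_starts", "exon_ends", "cds_end")


def load_transcripts(
    annotation_path: str | Path,
    dialect: str = "transcript_table",
    strip_versions: bool = True,
) -> list[TranscriptModel]:
    """Load transcript models from a GTF or transcript-table TSV.

    Transcripts violating structural invariants (including a zero-length
    3'UTR) are skipped with a logged warning; unparseable lines raise with
    their line number.
    """
    annotation_path = Path(annotation_path)
    if not annotation_path.exists():
        raise FileNotFoundError(annotation_path)
    if dialect == "transcript_table":
        raw = _parse_transcript_table(annotation_path)
    elif dialect == "gtf":
        raw = _parse_gtf(annotation_path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    out: list[TranscriptModel] = []
    for tx in raw:
        if strip_versions:
            tx = TranscriptModel(
                transcript_id=strip_version(tx.transcript_id),
                gene_symbol=tx.gene_symbol,
                chrom=tx.chrom,
                strand=tx.strand,
                exons=tx.exons,
                cds_end_genomic=tx.cds_end_genomic,
                cds_start_genomic=tx.cds_start_genomic,
            )
        try:
            tx.validate()
        except ValueError as exc:
            logger.warning("skipping transcript %s: %s", tx.transcript_id, exc)
            continue
        out.append(tx)
    return out


def _parse_transcript_table(path: Path) -> list[TranscriptModel]:
    """TSV dialect: transcript_id, gene, chrom, strand, exon_starts, exon_ends,
    cds_end and an optional trailing cds_start column (comma-separated exon
    coordinate lists, 1-based inclusive)."""
    records: list[TranscriptModel] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header[:7]) != TABLE_COLUMNS:
            raise ValueError(
                f"{path}: line 1: expected header {TABLE_COLUMNS}, got {tuple(header[:7])}"
            )
        has_cds_start = len(header) > 7 and header[7] == "cds_start"
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            try:
                starts = [int(x) for x in fields[4].split(",") if x]
                ends = [int(x) for x in fields[5].split(",") if x]
                if len(starts) != len(ends):
                    raise ValueError("exon_starts/exon_ends length mismatch")
                exons = tuple(sorted(zip(starts, ends)))
                cds_start = None
                if has_cds_start and len(fields) > 7 and fields[7]:
                    cds_start = int(fields[7])
                records.append(
                    TranscriptModel(
                        transcript_id=fields[0],
                        gene_symbol=fields[1],
                        chrom=fields[2],
                        strand=fields[3],
                        exons=exons,
                        cds_end_genomic=int(fields[6]),
                        cds_start_genomic=cds_start,
                    )
                )
            except (IndexError, ValueError) as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from exc
    return records


def _parse_gtf(path: Path) -> list[TranscriptModel]:
    """GTF dialect (features: exon, CDS, stop_codon), via gffutils."""
    import gffutils

    db = gffutils.create_db(
        str(path),
        ":memory:",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
        keep_order=True,
    )
    exons: dict[str, list[tuple[int, int]]] = {}
    cds: dict[str, list[tuple[int, int]]] = {}
    stops: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, tuple[str, str, str]] = {}
    for feat in db.all_features():
        tids = feat.attributes.get("transcript_id")
        if not tids:
            continue
        tid = tids[0]
        gene = (feat.attributes.get("gene_name") or feat.attributes.get("gene_id") or [""])[0]
        meta.setdefault(tid, (gene, feat.seqid, feat.strand))
        if feat.featuretype == "exon":
            exons.setdefault(tid, []).append((feat.start, feat.end))
        elif feat.featuretype == "CDS":
            cds.setdefault(tid, []).append((feat.start, feat.end))
        elif feat.featuretype == "stop_codon":
            stops.setdefault(tid, []).append((feat.start, feat.end))

    records: list[TranscriptModel] = []
    for tid, (gene, chrom, strand) in meta.items():
        if tid not in exons:
            logger.warning("transcript %s has no exon features; skipped", tid)
            continue
        tx_exons = tuple(sorted(exons[tid]))
        stop_iv = stops.get(tid)
        cds_iv = cds.get(tid)
        if strand == "+":
            if stop_iv:
                cds_end = max(e for _, e in stop_iv)
            elif cds_iv:
                cds_end = max(e for _, e in cds_iv)
            else:
                logger.warning("transcript %s has no CDS/stop_codon; skipped", tid)
                continue
            cds_start = min(s for s, _ in cds_iv) if cds_iv else None
        else:
            if stop_iv:
                cds_end = min(s for s, _ in stop_iv)
            elif cds_iv:
                cds_end = min(s for s, _ in cds_iv)
            else:
                logger.warning("transcript %s has no CDS/stop_codon; skipped", tid)
                continue
            cds_start = max(e for _, e in cds_iv) if cds_iv else None
        records.append(
            TranscriptModel(
                transcript_id=tid,
                gene_symbol=gene,
                chrom=chrom,
                strand=strand,
                exons=tx_exons,
                cds_end_genomic=cds_end,
                cds_start_genomic=cds_start,
            )
        )
    return records


def transcripts_by_id(transcripts: Iterable[TranscriptModel]) -> dict[str, TranscriptModel]:
    return {t.transcript_id: t for t in transcripts}
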