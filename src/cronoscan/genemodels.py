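"""Gene-model and sequence backbone.

Parses genome FASTA and GFF3/GTF annotation into strand-aware transcript
models, and derives everything downstream analyses need from them: spliced
coding sequence, in-silico translation, exon codon phases, genomic <->
amino-acid coordinate projection, and cross-species amino-acid projection
through a supplied exon-level interval map.

Internally every interval is 0-based half-open on the plus strand of the
genome; 1-based inclusive file conventions (GFF, VCF) are converted at the
I/O boundary and nowhere else.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import gffutils
from Bio import SeqIO
from Bio.Data.CodonTable import standard_dna_table

from .errors import (
    GeneModelError,
    OutOfCdsError,
    ParseError,
    UnmappedPositionError,
)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: codon -> amino acid, standard genetic code (stop codons excluded)
CODON_TABLE = dict(standard_dna_table.forward_table)
STOP_CODONS = frozenset(standard_dna_table.stop_codons)


def reverse_complement(seq: str) -> str:
    """Reverse complement of a nucleotide string (N-safe)."""
    return seq.translate(_COMPLEMENT)[::-1]


class GenomeSequence:
    """In-memory genome: mapping of contig name to uppercase sequence.

    Suitable for the region-scale references this toolkit operates on
    (single genes plus flanks); whole vertebrate genomes should be sliced
    before loading.
    """

    def __init__(self, sequences: dict[str, str]):
        if len(set(sequences)) != len(sequences):
            raise GeneModelError("duplicate contig names")
        self.sequences = {name: seq.upper() for name, seq in sequences.items()}

    def __contains__(self, contig: str) -> bool:
        return contig in self.sequences

    def contig_length(self, contig: str) -> int:
        return len(self.sequences[contig])

    def fetch(self, contig: str, start: int, end: int, strand: str = "+") -> str:
        """Return the sequence of ``[start, end)``; minus strand is
        reverse-complemented."""
        if contig not in self.sequences:
            raise KeyError(f"unknown contig {contig!r}")
        if not (0 <= start <= end <= len(self.sequences[contig])):
            raise IndexError(f"interval ({start}, {end}) out of bounds on {contig}")
        seq = self.sequences[contig][start:end]
        return reverse_complement(seq) if strand == "-" else seq


def read_genome_fasta(path: str | Path) -> GenomeSequence:
    """Load a FASTA file into a :class:`GenomeSequence` (sequences uppercased)."""
    path = Path(path)
    records = {}
    try:
        for rec in SeqIO.parse(str(path), "fasta"):
            records[rec.id] = str(rec.seq).upper()
    except (ValueError, FileNotFoundError) as exc:  # malformed records
        raise ParseError(f"{path}: {exc}") from exc
    if not records:
        raise ParseError(f"{path}: no FASTA records found (empty or malformed header)")
    return GenomeSequence(records)


@dataclass(frozen=True)
class ExonRecord:
    """One exon; ``index`` is the 1-based rank in transcript 5'->3' order."""

    contig: str
    start: int  # 0-based inclusive
    end: int    # 0-based exclusive
    index: int

    def __post_init__(self):
        if self.start >= self.end:
            raise GeneModelError(f"exon {self.index}: start >= end ({self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class TranscriptModel:
    """Strand-aware exon/CDS structure of one transcript.

    ``exons`` are ordered in transcript (5'->3') orientation, so on the
    minus strand exon 1 has the highest genomic coordinates. ``cds_start``
    and ``cds_end`` bound the coding region in genomic plus-strand
    coordinates (0-based half-open) and include the stop codon.
    """

    id: str
    strand: str
    exons: list[ExonRecord]
    cds_start: Optional[int] = None
    cds_end: Optional[int] = None

    def __post_init__(self):
        if self.strand not in {"+", "-"}:
            raise GeneModelError(f"{self.id}: strand must be '+' or '-'")
        if not self.exons:
            raise GeneModelError(f"{self.id}: transcript has zero exons")
        idx = [e.index for e in self.exons]
        if idx != list(range(1, len(self.exons) + 1)):
            raise GeneModelError(f"{self.id}: exon indices must be 1..n in order")
        genomic = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(genomic, genomic[1:]):
            if a.end > b.start:
                raise GeneModelError(f"{self.id}: overlapping exons {a.index} and {b.index}")
        expected = genomic if self.strand == "+" else genomic[::-1]
        if [e.index for e in expected] != idx:
            raise GeneModelError(f"{self.id}: exon index order does not match strand")
        if (self.cds_start is None) != (self.cds_end is None):
            raise GeneModelError(f"{self.id}: cds_start/cds_end must be set together")
        if self.cds_start is not None:
            if not any(e.start <= self.cds_start < e.end for e in self.exons):
                raise GeneModelError(f"{self.id}: cds_start outside exons")
            if not any(e.start < self.cds_end <= e.end for e in self.exons):
                raise GeneModelError(f"{self.id}: cds_end outside exons")

    # -- derived structure ------------------------------------------------

    @property
    def contig(self) -> str:
        return self.exons[0].contig

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    def exon(self, index: int) -> ExonRecord:
        if not 1 <= index <= self.n_exons:
            raise GeneModelError(f"{self.id}: no exon {index}")
        return self.exons[index - 1]

    def introns(self) -> list[tuple[int, int, int]]:
        """Introns as ``(intron_index, start, end)`` genomic half-open
        intervals; intron k separates exon k from exon k+1 (transcript
        order)."""
        out = []
        for k in range(1, self.n_exons):
            up, down = self.exon(k), self.exon(k + 1)
            if self.strand == "+":
                out.append((k, up.end, down.start))
            else:
                out.append((k, down.end, up.start))
        return out

    def coding_interval(self, exon_index: int) -> Optional[tuple[int, int]]:
        """Genomic interval of the coding part of an exon, or None if the
        exon is fully non-coding."""
        if self.cds_start is None:
            return None
        e = self.exon(exon_index)
        lo, hi = max(e.start, self.cds_start), min(e.end, self.cds_end)
        return (lo, hi) if lo < hi else None

    def coding_length(self, exon_index: int) -> int:
        iv = self.coding_interval(exon_index)
        return 0 if iv is None else iv[1] - iv[0]

    def cds_length(self) -> int:
        return sum(self.coding_length(i) for i in range(1, self.n_exons + 1))


def spliced_cds(transcript: TranscriptModel, genome: GenomeSequence) -> str:
    """Concatenated coding sequence in transcript orientation (includes the
    stop codon; minus-strand models are reverse-complemented)."""
    if transcript.cds_start is None:
        raise GeneModelError(f"{transcript.id}: no CDS boundaries set")
    segments = []
    for e in sorted(transcript.exons, key=lambda e: e.start):
        iv = transcript.coding_interval(e.index)
        if iv is not None:
            segments.append(genome.fetch(transcript.contig, iv[0], iv[1]))
    seq = "".join(segments)
    return reverse_complement(seq) if transcript.strand == "-" else seq


def translate_cds(seq: str) -> tuple[str, bool, Optional[int]]:
    """Translate with the standard genetic code, halting at the first stop.

    Returns ``(protein, stopped, stop_codon_index)`` where
    ``stop_codon_index`` is the 1-based codon rank of the stop (None when no
    stop is reached). A trailing partial codon is ignored.
    """
    if not seq:
        raise ParseError("cannot translate an empty sequence")
    if len(seq) < 3:
        raise ParseError("sequence shorter than one codon")
    seq = seq.upper()
    protein = []
    for i in range(0, len(seq) - 2, 3):
        codon = seq[i : i + 3]
        if codon in STOP_CODONS:
            return "".join(protein), True, i // 3 + 1
        protein.append(CODON_TABLE.get(codon, "X"))
    return "".join(protein), False, None


def exon_phase(transcript: TranscriptModel, exon_index: int) -> int:
    """Codon phase of an exon: (coding bases 5' of the exon) mod 3."""
    if transcript.coding_length(exon_index) == 0:
        raise OutOfCdsError(f"{transcript.id}: exon {exon_index} is non-coding")
    upstream = sum(transcript.coding_length(i) for i in range(1, exon_index))
    return upstream % 3


def genomic_to_cds_offset(transcript: TranscriptModel, pos: int) -> int:
    """0-based offset of a genomic position within the spliced CDS."""
    offset = 0
    for e in transcript.exons:  # transcript order
        iv = transcript.coding_interval(e.index)
        if iv is None:
            continue
        lo, hi = iv
        if lo <= pos < hi:
            within = (pos - lo) if transcript.strand == "+" else (hi - 1 - pos)
            return offset + within
        offset += hi - lo
    raise OutOfCdsError(f"{transcript.id}: position {pos} not in coding exons")


def cds_offset_to_genomic(transcript: TranscriptModel, offset: int) -> int:
    """Inverse of :func:`genomic_to_cds_offset`."""
    if offset < 0:
        raise OutOfCdsError(f"negative CDS offset {offset}")
    remaining = offset
    for e in transcript.exons:
        iv = transcript.coding_interval(e.index)
        if iv is None:
            continue
        lo, hi = iv
        if remaining < hi - lo:
            return (lo + remaining) if transcript.strand == "+" else (hi - 1 - remaining)
        remaining -= hi - lo
    raise OutOfCdsError(f"{transcript.id}: CDS offset {offset} beyond CDS end")


def genomic_to_protein(transcript: TranscriptModel, pos: int) -> int:
    """1-based amino-acid index of the codon containing a genomic position."""
    return genomic_to_cds_offset(transcript, pos) // 3 + 1


@dataclass(frozen=True)
class OrthologyRow:
    source_exon: int
    src_aa_start: int
    src_aa_end: int
    tgt_aa_start: int
    tgt_aa_end: int


class OrthologyMap:
    """Exon-level amino-acid interval map between two species' proteins.

    Intervals are 1-based inclusive in both coordinate systems and must be
    non-overlapping and monotone increasing; positions are projected by
    linear interpolation within the containing interval.
    """

    def __init__(self, rows: Iterable[OrthologyRow]):
        self.rows = sorted(rows, key=lambda r: r.src_aa_start)
        prev = None
        for r in self.rows:
            if r.src_aa_start > r.src_aa_end or r.tgt_aa_start > r.tgt_aa_end:
                raise GeneModelError(f"orthology row for exon {r.source_exon}: inverted interval")
            if prev is not None and (r.src_aa_start <= prev.src_aa_end or r.tgt_aa_start <= prev.tgt_aa_end):
                raise GeneModelError("orthology intervals overlap or are non-monotone")
            prev = r
        self._starts = [r.src_aa_start for r in self.rows]

    @classmethod
    def from_tsv(cls, path: str | Path) -> "OrthologyMap":
        rows = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) != 5:
                    raise ParseError(f"{path}:{lineno}: expected 5 columns, got {len(parts)}")
                try:
                    rows.append(OrthologyRow(*(int(p) for p in parts)))
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: non-integer field") from exc
        return cls(rows)

    def project(self, aa: int) -> int:
        i = bisect.bisect_right(self._starts, aa) - 1
        if i < 0 or aa > self.rows[i].src_aa_end:
            raise UnmappedPositionError(f"amino acid {aa} not covered by orthology map")
        r = self.rows[i]
        if r.src_aa_end == r.src_aa_start:
            return r.tgt_aa_start
        frac = (aa - r.src_aa_start) / (r.src_aa_end - r.src_aa_start)
        return round(r.tgt_aa_start + frac * (r.tgt_aa_end - r.tgt_aa_start))


def project_orthologous_aa(orthology: OrthologyMap, aa: int) -> int:
    """Project an amino-acid position onto the orthologous protein."""
    return orthology.project(aa)


# -- annotation I/O -------------------------------------------------------


def _transcript_ids(feature) -> list[str]:
    attrs = feature.attributes
    if "Parent" in attrs:
        return list(attrs["Parent"])
    if "transcript_id" in attrs:
        return list(attrs["transcript_id"])
    return []


def read_gene_models_gff(path: str | Path) -> list[TranscriptModel]:
    """Read transcripts (exon + CDS features) from a GFF3 or GTF file.

    File coordinates (1-based inclusive) are converted to the internal
    0-based half-open convention here and only here.
    """
    try:
        db = gffutils.create_db(
            str(path),
            ":memory:",
            merge_strategy="create_unique",
            keep_order=True,
            disable_infer_genes=True,
            disable_infer_transcripts=True,
        )
    except Exception as exc:
        raise ParseError(f"{path}: {exc}") from exc

    exons: dict[str, list] = {}
    cds: dict[str, list] = {}
    strands: dict[str, str] = {}
    for f in db.features_of_type("exon"):
        for tid in _transcript_ids(f):
            exons.setdefault(tid, []).append(f)
            strands[tid] = f.strand
    for f in db.features_of_type("CDS"):
        for tid in _transcript_ids(f):
            cds.setdefault(tid, []).append(f)

    models = []
    for tid in cds.keys() | exons.keys():
        if tid not in exons or not exons[tid]:
            raise GeneModelError(f"transcript {tid}: zero exons")
        strand = strands[tid]
        by_start = sorted(exons[tid], key=lambda f: f.start)
        ordered = by_start if strand == "+" else by_start[::-1]
        exon_records = [
            ExonRecord(contig=f.seqid, start=f.start - 1, end=f.end, index=i)
            for i, f in enumerate(ordered, 1)
        ]
        cds_start = cds_end = None
        if tid in cds:
            cds_start = min(f.start for f in cds[tid]) - 1
            cds_end = max(f.end for f in cds[tid])
            for f in cds[tid]:
                if not any(e.start <= f.start - 1 and f.end <= e.end for e in exon_records):
                    raise GeneModelError(f"transcript {tid}: CDS feature outside exons")
        models.append(TranscriptModel(tid, strand, exon_records, cds_start, cds_end))
    models.sort(key=lambda m: m.id)
    return models


def mirror_transcript(transcript: TranscriptModel, contig_length: int) -> TranscriptModel:
    """Coordinate-mirrored copy of a transcript on the opposite strand.

    Paired with a reverse-complemented genome this leaves every spliced
    sequence and phase unchanged; used for strand-symmetry checks.
    """
    flipped = [
        ExonRecord(e.contig, contig_length - e.end, contig_length - e.start, e.index)
        for e in transcript.exons
    ]
    cds_start = cds_end = None
    if transcript.cds_start is not None:
        cds_start = contig_length - transcript.cds_end
        cds_end = contig_length - transcript.cds_start
    return TranscriptModel(
        transcript.id,
        "-" if transcript.strand == "+" else "+",
        flipped,
        cds_start,
        cds_end,
    )


def mirror_genome(genome: GenomeSequence) -> GenomeSequence:
    """Reverse complement every contig (companion to :func:`mirror_transcript`)."""
    return GenomeSequence({name: reverse_complement(seq) for name, seq in genome.sequences.items()})
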