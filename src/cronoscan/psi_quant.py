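"""Percent-spliced-in (PSI) estimation from exon-exon junction reads.

For an internal exon with upstream-junction reads I5, downstream-junction
reads I3 and skipping-junction reads X, the inclusion level is

    psi = (I5 + I3) / (I5 + I3 + 2X)

The factor 2 on X reflects that one skipping event removes both inclusion
junctions, so inclusion and exclusion junction counts are on the same
per-event scale. Terminal exons carry a single inclusion junction I and use
psi = I / (I + 2X). Estimates with a junction-read denominator below a
configurable floor are reported as no-calls rather than unreliable numbers.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pysam

from .errors import GeneModelError, ParseError
from .genemodels import TranscriptModel

DEFAULT_MIN_DENOMINATOR = 15


@dataclass(frozen=True)
class JunctionRow:
    """Junction counts for one exon; None marks a junction that does not
    exist (terminal exons), as opposed to one observed zero times."""

    i5: Optional[int]
    i3: Optional[int]
    x: Optional[int]

    def __post_init__(self):
        for name, v in (("I5", self.i5), ("I3", self.i3), ("X", self.x)):
            if v is not None and (not isinstance(v, int) or v < 0):
                raise ParseError(f"{name} must be a non-negative integer or absent, got {v!r}")


class JunctionCountTable:
    """Ordered mapping of exon_id -> :class:`JunctionRow`."""

    def __init__(self, rows: dict[str, JunctionRow] | None = None):
        self.rows: dict[str, JunctionRow] = dict(rows or {})

    def __getitem__(self, exon_id: str) -> JunctionRow:
        return self.rows[exon_id]

    def __iter__(self):
        return iter(self.rows.items())

    def __len__(self) -> int:
        return len(self.rows)

    def add(self, exon_id: str, row: JunctionRow) -> None:
        if exon_id in self.rows:
            raise ParseError(f"duplicate exon_id {exon_id!r}")
        self.rows[exon_id] = row


def _parse_count(token: str, column: str, lineno: int) -> Optional[int]:
    token = token.strip()
    if token == ".":
        return None
    try:
        value = int(token)
    except ValueError as exc:
        raise ParseError(f"row {lineno}: non-integer {column} count {token!r}") from exc
    if value < 0:
        raise ParseError(f"row {lineno}: negative {column} count {value}")
    return value


def read_junction_table(path: str | Path) -> JunctionCountTable:
    """Read a TSV with columns exon_id, I5, I3, X ('.' = junction absent)."""
    table = JunctionCountTable()
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = ["exon_id", "I5", "I3", "X"]
        if [h.strip() for h in header[:4]] != expected:
            raise ParseError(f"{path}: header must start with {expected}, got {header}")
        for lineno, line in enumerate(fh, 2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ParseError(f"{path}: row {lineno}: expected 4 columns")
            exon_id = parts[0].strip()
            row = JunctionRow(
                i5=_parse_count(parts[1], "I5", lineno),
                i3=_parse_count(parts[2], "I3", lineno),
                x=_parse_count(parts[3], "X", lineno),
            )
            try:
                table.add(exon_id, row)
            except ParseError as exc:
                raise ParseError(f"{path}: row {lineno}: {exc}") from exc
    return table


def write_junction_table(table: JunctionCountTable, path: str | Path) -> None:
    def fmt(v: Optional[int]) -> str:
        return "." if v is None else str(v)

    with open(path, "w") as fh:
        fh.write("exon_id\tI5\tI3\tX\n")
        for exon_id, row in table:
            fh.write(f"{exon_id}\t{fmt(row.i5)}\t{fmt(row.i3)}\t{fmt(row.x)}\n")


@dataclass(frozen=True)
class PsiEstimate:
    """Inclusion level of one exon; ``psi`` is defined iff ``passed``."""

    psi: Optional[float]
    denominator: int
    passed: bool

    def __post_init__(self):
        if self.passed and not (self.psi is not None and 0.0 <= self.psi <= 1.0):
            raise ValueError(f"called PSI must lie in [0,1], got {self.psi}")


def estimate_psi(
    i5: Optional[int],
    i3: Optional[int],
    x: Optional[int],
    min_denominator: int = DEFAULT_MIN_DENOMINATOR,
) -> PsiEstimate:
    """Junction-read PSI with a read-sufficiency no-call filter.

    Internal exon: psi = (I5+I3)/(I5+I3+2X). Terminal exon (one inclusion
    junction absent): psi = I/(I+2X). No-call when every count is absent or
    the denominator is below ``min_denominator``.
    """
    if i5 is None and i3 is None and x is None:
        return PsiEstimate(None, 0, False)
    inclusion = (i5 or 0) + (i3 or 0)
    exclusion = x or 0
    denominator = inclusion + 2 * exclusion
    if denominator < min_denominator or denominator == 0:
        return PsiEstimate(None, denominator, False)
    return PsiEstimate(inclusion / denominator, denominator, True)


def median_psi(estimates: Iterable[PsiEstimate]) -> Optional[float]:
    """Median PSI over the passing estimates only; None if none pass."""
    values = [e.psi for e in estimates if e.passed]
    if not values:
        return None
    return statistics.median(values)


@dataclass(frozen=True)
class ExonAaSpan:
    """Amino-acid span an exon contributes, with its median PSI.

    Spans are 1-based half-open ``[aa_start, aa_end)`` so adjacent exons
    tile the protein without overlap.
    """

    exon_id: str
    aa_start: int
    aa_end: int
    median_psi: Optional[float]

    @property
    def aa_length(self) -> int:
        return self.aa_end - self.aa_start


def count_constitutive_aa(
    spans: Sequence[ExonAaSpan],
    threshold: float = 0.9,
    boundary_aa: Optional[int] = None,
) -> int:
    """Total amino acids in exons with median PSI strictly above ``threshold``.

    When ``boundary_aa`` is given, only exons lying entirely N-terminal to
    it (aa_end <= boundary_aa) are counted.
    """
    ordered = sorted(spans, key=lambda s: s.aa_start)
    for a, b in zip(ordered, ordered[1:]):
        if a.aa_end > b.aa_start:
            raise GeneModelError(f"overlapping aa spans: {a.exon_id} and {b.exon_id}")
    total = 0
    for s in spans:
        if boundary_aa is not None and s.aa_end > boundary_aa:
            continue
        if s.median_psi is not None and s.median_psi > threshold:
            total += s.aa_length
    return total


# -- SAM adapter ----------------------------------------------------------


@dataclass
class JunctionCountResult:
    table: JunctionCountTable
    discarded_gaps: int = 0
    skipped_records: int = 0


def _alignment_gaps(read: pysam.AlignedSegment) -> list[tuple[int, int]]:
    """Reference-skip (intron) intervals of one alignment, genomic half-open."""
    gaps = []
    pos = read.reference_start
    for op, length in read.cigartuples or []:
        if op == 3:  # N: reference skip
            gaps.append((pos, pos + length))
        if op in (0, 2, 3, 7, 8):  # consume reference
            pos += length
    return gaps


def count_junctions_from_alignments(
    sam_path: str | Path, transcript: TranscriptModel
) -> JunctionCountResult:
    """Tally inclusion and skipping junctions from spliced alignments.

    A gap matching annotated intron k (transcript order) supports both
    inclusion junctions it spans: I3 of exon k and I5 of exon k+1. A gap
    running from the end of exon k-1 to the start of exon k+1 supports
    skipping of exon k (X). Gaps matching neither are tallied as discarded.
    Terminal exons keep their non-existent junction as absent (None).
    """
    n = transcript.n_exons
    introns = {(s, e): k for k, s, e in transcript.introns()}
    skips = {}
    for k in range(2, n):
        up, down = transcript.exon(k - 1), transcript.exon(k + 1)
        if transcript.strand == "+":
            skips[(up.end, down.start)] = k
        else:
            skips[(down.end, up.start)] = k

    i5 = {k: 0 for k in range(2, n + 1)}
    i3 = {k: 0 for k in range(1, n)}
    x = {k: 0 for k in range(1, n + 1)}
    discarded = skipped = 0

    with pysam.AlignmentFile(str(sam_path), "r", check_sq=False) as fh:
        for read in fh:
            if read.is_unmapped or read.cigartuples is None:
                skipped += 1
                continue
            for gap in _alignment_gaps(read):
                if gap in introns:
                    k = introns[gap]
                    i3[k] += 1
                    i5[k + 1] += 1
                elif gap in skips:
                    x[skips[gap]] += 1
                else:
                    discarded += 1

    table = JunctionCountTable()
    for k in range(1, n + 1):
        table.add(
            f"{transcript.id}:e{k}",
            JunctionRow(i5=i5.get(k), i3=i3.get(k), x=x[k]),
        )
    return JunctionCountResult(table, discarded_gaps=discarded, skipped_records=skipped)
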