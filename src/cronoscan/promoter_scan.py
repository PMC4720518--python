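"""Internal-promoter detection from intronic read accumulation.

Transcription from a promoter buried in an intron shows up in RNA-Seq
coverage as a block of reads in the intron immediately 5' (transcript
orientation) of the first exon of the internal isoform, against an
otherwise low intronic background. Each internal exon is scored by the
fold-enrichment of the mean depth in a fixed-width window at its acceptor
edge over the per-gene median intronic depth; candidates are annotated with
overlap against epigenomic peak sets (DNase hypersensitivity, H3K4me3) and
the in-frame upstream initiator ATG can be located between an experimentally
determined TSS and the exon.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from intervaltree import IntervalTree

from .errors import InputError, ParseError
from .genemodels import GenomeSequence, TranscriptModel, exon_phase

DEFAULT_WINDOW_SIZE = 500
DEFAULT_FOLD_THRESHOLD = 5.0
DEFAULT_PSEUDOCOUNT = 1.0


class CoverageTrack:
    """Run-length encoded per-base depth over one contig; gaps are depth 0."""

    def __init__(self, contig: str, intervals: Sequence[tuple[int, int, float]]):
        ivs = sorted(intervals)
        for (s1, e1, d1) in ivs:
            if s1 >= e1:
                raise ParseError(f"empty or inverted interval ({s1}, {e1})")
            if d1 < 0:
                raise ParseError(f"negative depth {d1} at ({s1}, {e1})")
        for (s1, e1, _), (s2, _, _) in zip(ivs, ivs[1:]):
            if e1 > s2:
                raise ParseError(f"overlapping coverage intervals at {s2}")
        self.contig = contig
        self.starts = np.array([iv[0] for iv in ivs], dtype=np.int64)
        self.ends = np.array([iv[1] for iv in ivs], dtype=np.int64)
        self.depths = np.array([iv[2] for iv in ivs], dtype=float)

    @classmethod
    def from_per_base(cls, contig: str, start: int, values: np.ndarray) -> "CoverageTrack":
        """RLE-compress a dense per-base depth vector starting at ``start``."""
        values = np.asarray(values, dtype=float)
        if values.size == 0:
            return cls(contig, [])
        change = np.flatnonzero(np.diff(values)) + 1
        run_starts = np.concatenate(([0], change))
        run_ends = np.concatenate((change, [values.size]))
        intervals = [
            (start + int(s), start + int(e), float(values[s]))
            for s, e in zip(run_starts, run_ends)
            if values[s] != 0.0
        ]
        return cls(contig, intervals)

    def values(self, start: int, end: int) -> np.ndarray:
        """Dense per-base depths over ``[start, end)`` (gaps expand to 0)."""
        if start >= end:
            return np.zeros(0)
        out = np.zeros(end - start)
        lo = np.searchsorted(self.ends, start, side="right")
        hi = np.searchsorted(self.starts, end, side="left")
        for i in range(lo, hi):
            s = max(int(self.starts[i]), start)
            e = min(int(self.ends[i]), end)
            if s < e:
                out[s - start : e - start] = self.depths[i]
        return out

    def mean_depth(self, start: int, end: int) -> float:
        vals = self.values(start, end)
        return float(vals.mean()) if vals.size else 0.0


def read_bedgraph(path: str | Path) -> CoverageTrack:
    """Read a 4-column bedGraph into a run-length coverage track.

    All intervals must belong to one contig; overlaps are a parse error.
    """
    intervals = []
    contig = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("track", "#", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ParseError(f"{path}:{lineno}: expected 4 columns")
            if contig is None:
                contig = parts[0]
            elif parts[0] != contig:
                raise ParseError(f"{path}:{lineno}: multiple contigs not supported in one track")
            try:
                s, e, d = int(parts[1]), int(parts[2]), float(parts[3])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric field") from exc
            intervals.append((s, e, d))
    try:
        return CoverageTrack(contig or "NA", intervals)
    except ParseError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_bedgraph(track: CoverageTrack, path: str | Path) -> None:
    with open(path, "w") as fh:
        for s, e, d in zip(track.starts, track.ends, track.depths):
            value = int(d) if float(d).is_integer() else d
            fh.write(f"{track.contig}\t{s}\t{e}\t{value}\n")


@dataclass
class PeakSet:
    """Sorted genomic intervals from a BED file (e.g. DNase or ChIP peaks)."""

    intervals: list[tuple[str, int, int]]

    @classmethod
    def from_bed(cls, path: str | Path) -> "PeakSet":
        out = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith(("track", "#", "browser")):
                    continue
                parts = line.split("\t")
                if len(parts) < 3:
                    raise ParseError(f"{path}:{lineno}: expected at least 3 columns")
                out.append((parts[0], int(parts[1]), int(parts[2])))
        out.sort()
        return cls(out)

    def tree(self, contig: str) -> IntervalTree:
        return IntervalTree.from_tuples(
            (s, e) for c, s, e in self.intervals if c == contig and s < e
        )


@dataclass
class PromoterCandidate:
    """Scored upstream-intron window of one internal exon."""

    exon_index: int
    contig: str
    window_start: int
    window_end: int
    window_mean_depth: float
    background_depth: float
    fold_score: float
    truncated_window: bool = False
    called: bool = False
    peak_overlap: dict[str, bool] = field(default_factory=dict)


def score_intronic_windows(
    track: CoverageTrack,
    transcript: TranscriptModel,
    window_size: int = DEFAULT_WINDOW_SIZE,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> list[PromoterCandidate]:
    """Score each internal exon's upstream-intron acceptor-edge window.

    The window is the ``window_size`` intronic bases adjacent to the exon's
    5' (acceptor) edge in transcript orientation - at higher genomic
    coordinates for minus-strand genes. Background is the median per-base
    depth over all introns of the gene; fold = window mean / (background +
    pseudocount). Windows truncated by short introns are flagged.
    """
    if window_size < 1:
        raise InputError("window_size must be >= 1")
    introns = transcript.introns()
    if not introns:
        return []
    intronic = np.concatenate([track.values(s, e) for _, s, e in introns])
    background = float(np.median(intronic)) if intronic.size else 0.0

    candidates = []
    for k, istart, iend in introns:
        exon = transcript.exon(k + 1)  # exon downstream of intron k
        if exon.index >= transcript.n_exons:
            # window upstream of the terminal exon is still a valid internal
            # signal only if the exon is internal; terminal exon excluded
            continue
        if transcript.strand == "+":
            wstart, wend = exon.start - window_size, exon.start
        else:
            wstart, wend = exon.end, exon.end + window_size
        truncated = False
        if wstart < istart:
            wstart, truncated = istart, True
        if wend > iend:
            wend, truncated = iend, True
        mean = track.mean_depth(wstart, wend)
        fold = mean / (background + pseudocount)
        candidates.append(
            PromoterCandidate(
                exon_index=exon.index,
                contig=track.contig,
                window_start=wstart,
                window_end=wend,
                window_mean_depth=mean,
                background_depth=background,
                fold_score=fold,
                truncated_window=truncated,
            )
        )
    return candidates


def call_promoter_candidates(
    candidates: Sequence[PromoterCandidate],
    fold_threshold: float = DEFAULT_FOLD_THRESHOLD,
) -> list[PromoterCandidate]:
    """Subset with fold_score >= threshold, marked called, sorted descending."""
    if fold_threshold <= 1:
        raise InputError("fold_threshold must exceed 1")
    called = [c for c in candidates if c.fold_score >= fold_threshold]
    for c in called:
        c.called = True
    return sorted(called, key=lambda c: -c.fold_score)


def annotate_with_peaks(
    candidates: Sequence[PromoterCandidate], peaks: PeakSet, label: str
) -> list[PromoterCandidate]:
    """Flag each candidate window that intersects any peak (half-open)."""
    trees: dict[str, IntervalTree] = {}
    for c in candidates:
        if c.contig not in trees:
            trees[c.contig] = peaks.tree(c.contig)
        c.peak_overlap[label] = bool(trees[c.contig].overlap(c.window_start, c.window_end))
    return list(candidates)


@dataclass(frozen=True)
class InternalStart:
    atg_position: int  # genomic position of the codon's first base (plus strand)
    aa_offset: int     # codons from the ATG (inclusive) to the exon start (exclusive)
    in_frame: bool


def find_internal_start(
    genome: GenomeSequence,
    transcript: TranscriptModel,
    exon_index: int,
    tss_position: int,
) -> Optional[InternalStart]:
    """First in-frame ATG between an intronic TSS and the downstream exon.

    Scans in transcript orientation from the TSS toward the exon's acceptor
    edge and returns the first ATG whose frame matches the exon's codon
    phase, so translation from it runs in frame into the exon. Returns None
    when no in-frame ATG precedes the exon.
    """
    introns = {k: (s, e) for k, s, e in transcript.introns()}
    if exon_index - 1 not in introns:
        raise InputError(f"exon {exon_index} has no upstream intron")
    istart, iend = introns[exon_index - 1]
    exon = transcript.exon(exon_index)
    phase = exon_phase(transcript, exon_index)

    if transcript.strand == "+":
        if not (istart <= tss_position < exon.start):
            raise InputError("TSS must lie in the upstream intron, 5' of the exon")
        seq = genome.fetch(transcript.contig, tss_position, exon.start)
    else:
        if not (exon.end <= tss_position < iend):
            raise InputError("TSS must lie in the upstream intron, 5' of the exon")
        seq = genome.fetch(transcript.contig, exon.end, tss_position + 1, strand="-")

    n = len(seq)  # bases from TSS through the base adjacent to the exon
    for i in range(n - 2):
        if seq[i : i + 3] != "ATG":
            continue
        d = n - i  # nt from the ATG's A to the exon start
        if d % 3 != phase % 3:
            continue
        if transcript.strand == "+":
            atg_pos = tss_position + i
        else:
            atg_pos = tss_position - i - 2
        aa_offset = (d - phase) // 3 + (1 if phase else 0)
        return InternalStart(atg_position=atg_pos, aa_offset=aa_offset, in_frame=True)
    return None
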