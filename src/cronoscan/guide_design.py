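"""CRISPR/Cas9 guide design: NGG protospacer scanning and uniqueness.

A target site is a 23-mer whose final two bases are GG (20-nt protospacer +
NGG PAM). Both strands are scanned; protospacers beginning GG are
prioritized because T7 RNA polymerase initiates transcription efficiently
on GG. Genome uniqueness is exact 23-mer matching over both strands -
guides with a single genome match rank first.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .errors import InputError
from .genemodels import GenomeSequence, reverse_complement

SITE_LENGTH = 23
PROTOSPACER_LENGTH = 20


@dataclass(frozen=True)
class GuideCandidate:
    """One protospacer+PAM site; ``position`` is the 0-based genomic start
    of the full 23-mer on the plus strand of the source contig."""

    contig: str
    protospacer: str
    pam: str
    strand: str
    position: int
    gg_start: bool
    genome_matches: Optional[int] = None

    def __post_init__(self):
        if len(self.protospacer) != PROTOSPACER_LENGTH:
            raise InputError("protospacer must be 20 nt")
        if len(self.pam) != 3 or not self.pam.endswith("GG"):
            raise InputError(f"PAM must be NGG, got {self.pam!r}")

    @property
    def site(self) -> str:
        return self.protospacer + self.pam


def scan_protospacers(genome: GenomeSequence, contig: str, start: int, end: int) -> list[GuideCandidate]:
    """All 23-mer NGG sites on both strands of ``[start, end)``.

    Overlapping sites are all reported. Regions shorter than 23 nt yield an
    empty list. Minus-strand sites are reported at the plus-strand genomic
    start of their 23-mer footprint.
    """
    seq = genome.fetch(contig, start, end)
    n = len(seq)
    candidates = []
    for i in range(n - SITE_LENGTH + 1):
        window = seq[i : i + SITE_LENGTH]
        if window[-2:] == "GG":
            candidates.append(
                GuideCandidate(
                    contig=contig,
                    protospacer=window[:PROTOSPACER_LENGTH],
                    pam=window[PROTOSPACER_LENGTH:],
                    strand="+",
                    position=start + i,
                    gg_start=window.startswith("GG"),
                )
            )
        rc = reverse_complement(window)
        if rc[-2:] == "GG":
            candidates.append(
                GuideCandidate(
                    contig=contig,
                    protospacer=rc[:PROTOSPACER_LENGTH],
                    pam=rc[PROTOSPACER_LENGTH:],
                    strand="-",
                    position=start + i,
                    gg_start=rc.startswith("GG"),
                )
            )
    return candidates


def _count_overlapping(haystack: str, needle: str) -> int:
    count = 0
    i = haystack.find(needle)
    while i != -1:
        count += 1
        i = haystack.find(needle, i + 1)
    return count


def count_genome_matches(candidate: GuideCandidate, genome: GenomeSequence) -> int:
    """Exact occurrences of the full 23-mer over both strands of the genome."""
    site = candidate.site
    rc = reverse_complement(site)
    total = 0
    for seq in genome.sequences.values():
        total += _count_overlapping(seq, site)
        total += _count_overlapping(seq, rc)
    return total


def annotate_genome_matches(
    candidates: Sequence[GuideCandidate], genome: GenomeSequence
) -> list[GuideCandidate]:
    return [
        GuideCandidate(
            c.contig, c.protospacer, c.pam, c.strand, c.position, c.gg_start,
            genome_matches=count_genome_matches(c, genome),
        )
        for c in candidates
    ]


def rank_guides(candidates: Sequence[GuideCandidate]) -> list[GuideCandidate]:
    """Order: unique genome match first, then GG-start protospacers, then
    position ascending; ties broken + strand before -."""
    for c in candidates:
        if c.genome_matches is None:
            raise InputError("genome_matches must be populated before ranking")
    return sorted(
        candidates,
        key=lambda c: (c.genome_matches != 1, not c.gg_start, c.position, c.strand != "+"),
    )
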