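"""Nonsense-mediated decay estimation from allelic imbalance.

In a heterozygote, both alleles are transcribed at (assumed) equal rates,
so any deficit of mutant-allele reads in targeted RNA amplicon sequencing
measures degradation of the premature-termination-codon transcript. Reads
are assigned to alleles by exact match of a short discriminating window
(sequence context around the variant); the mutant:wild-type read ratio
estimates the surviving fraction, and percent degraded is (1 - ratio)x100.

Transcript-class abundance ratios (e.g. a C-terminal internal-promoter
isoform versus the full-length transcript) are estimated from read counts
over isoform-specific regions, normalized by region length.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from statsmodels.stats.proportion import proportion_confint

from .errors import ConfigError, InputError

DEFAULT_WINDOW_RADIUS = 10
DEFAULT_READ_FLOOR = 100


@dataclass(frozen=True)
class AllelicCounts:
    """Read tallies for one heterozygous site; ambiguous reads (matching
    neither or both windows) are excluded from ratios."""

    mutant_reads: int
    wildtype_reads: int
    ambiguous_reads: int = 0

    def __post_init__(self):
        for v in (self.mutant_reads, self.wildtype_reads, self.ambiguous_reads):
            if v < 0:
                raise InputError("read counts must be non-negative")

    @property
    def classified(self) -> int:
        return self.mutant_reads + self.wildtype_reads

    def __add__(self, other: "AllelicCounts") -> "AllelicCounts":
        return AllelicCounts(
            self.mutant_reads + other.mutant_reads,
            self.wildtype_reads + other.wildtype_reads,
            self.ambiguous_reads + other.ambiguous_reads,
        )


@dataclass(frozen=True)
class NmdEstimate:
    """Mutant:wild-type allelic ratio with a Wilson 95% interval.

    ``percent_degraded`` is the NMD efficiency under equal allelic
    transcription; it complements ``percent_of_wildtype`` to exactly 100.
    """

    ratio: float
    ci_low: float
    ci_high: float
    n_classified: int
    low_coverage: bool

    @property
    def percent_of_wildtype(self) -> float:
        return self.ratio * 100.0

    @property
    def percent_degraded(self) -> float:
        return 100.0 - self.percent_of_wildtype


def make_windows(context: str, radius: int = DEFAULT_WINDOW_RADIUS) -> str:
    """Discriminating window: the 2*radius+1 bases centred on a variant.

    ``context`` must already be centred on the variant base/allele.
    """
    mid = len(context) // 2
    lo, hi = mid - radius, mid + radius + 1
    if lo < 0 or hi > len(context):
        raise ConfigError("context shorter than the requested window")
    return context[lo:hi]


def assign_reads(reads: Iterable[str], ref_window: str, alt_window: str) -> AllelicCounts:
    """Assign each read to an allele by exact window containment.

    A read containing the reference window is wild-type, one containing the
    alternate window is mutant; reads matching neither or both are counted
    ambiguous and excluded downstream.
    """
    if ref_window == alt_window:
        raise ConfigError("ref and alt windows are identical; cannot discriminate alleles")
    ref_window, alt_window = ref_window.upper(), alt_window.upper()
    mut = wt = amb = 0
    for read in reads:
        read = read.upper()
        has_ref = ref_window in read
        has_alt = alt_window in read
        if has_ref and not has_alt:
            wt += 1
        elif has_alt and not has_ref:
            mut += 1
        else:
            amb += 1
    return AllelicCounts(mut, wt, amb)


def estimate_nmd(counts: AllelicCounts, read_floor: int = DEFAULT_READ_FLOOR) -> NmdEstimate:
    """Allelic-imbalance NMD estimate with a Wilson 95% CI on the ratio.

    The interval is computed on p = mutant/(mutant+wildtype) and mapped to
    the ratio scale via r = p/(1-p).
    """
    if counts.wildtype_reads == 0:
        raise InputError("wildtype read count is zero; ratio undefined")
    n = counts.classified
    ratio = counts.mutant_reads / counts.wildtype_reads
    p_low, p_high = proportion_confint(counts.mutant_reads, n, alpha=0.05, method="wilson")
    ci_low = p_low / (1.0 - p_low)
    ci_high = p_high / (1.0 - p_high) if p_high < 1.0 else float("inf")
    return NmdEstimate(
        ratio=ratio,
        ci_low=ci_low,
        ci_high=ci_high,
        n_classified=n,
        low_coverage=n < read_floor,
    )


def isoform_ratio(count_a: int, length_a: int, count_b: int, length_b: int) -> float:
    """Length-normalized abundance ratio (a vs b) from region-specific counts."""
    if length_a <= 0 or length_b <= 0:
        raise InputError("region lengths must be positive")
    if count_a < 0 or count_b < 0:
        raise InputError("counts must be non-negative")
    if count_b == 0:
        raise InputError("denominator count is zero; ratio undefined")
    return (count_a / length_a) / (count_b / length_b)


def read_reads_file(path: str | Path) -> list[str]:
    """Read sequences from FASTQ or plain one-read-per-line text."""
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
        fh.seek(0)
        if first.startswith("@"):
            reads = []
            while True:
                header = fh.readline()
                if not header:
                    break
                seq = fh.readline().strip()
                fh.readline()  # +
                fh.readline()  # qualities
                reads.append(seq)
            return reads
        return [line.strip() for line in fh if line.strip()]
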