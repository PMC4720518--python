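"""Splice-aware truncation-consequence calling.

Classification rules:

* coding SNVs that create a stop codon are NONSENSE (truncating);
* coding indels with net length not a multiple of 3 are FRAMESHIFT
  (truncating), with the protein change determined by re-translating the
  mutated coding sequence;
* variants at the canonical splice-acceptor dinucleotide (intronic -1/-2)
  are modelled as skipping of the downstream exon: truncating only if the
  skipped exon's coding length is not a multiple of 3, i.e. the downstream
  exon changes codon phase;
* variants at the canonical splice-donor dinucleotide (intronic +1/+2) are
  modelled as retention of the intron: the retained-intron transcript is
  translated in silico and the call is truncating only if a premature stop
  is actually observed (an in-frame, stop-free intron reads through).

Everything else is OTHER and non-truncating.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Optional

import pysam

from .errors import InputError
from .genemodels import (
    GenomeSequence,
    TranscriptModel,
    genomic_to_cds_offset,
    reverse_complement,
    spliced_cds,
    translate_cds,
)


class Category(str, Enum):
    NONSENSE = "NONSENSE"
    FRAMESHIFT = "FRAMESHIFT"
    ACCEPTOR_SKIP_FRAMESHIFT = "ACCEPTOR_SKIP_FRAMESHIFT"
    ACCEPTOR_SKIP_INFRAME = "ACCEPTOR_SKIP_INFRAME"
    DONOR_RETENTION_PTC = "DONOR_RETENTION_PTC"
    DONOR_RETENTION_READTHROUGH = "DONOR_RETENTION_READTHROUGH"
    OTHER = "OTHER"


TRUNCATING_CATEGORIES = {
    Category.NONSENSE,
    Category.FRAMESHIFT,
    Category.ACCEPTOR_SKIP_FRAMESHIFT,
    Category.DONOR_RETENTION_PTC,
}


@dataclass(frozen=True)
class VariantRecord:
    """One normalized variant; ``pos`` is 1-based (VCF convention)."""

    contig: str
    pos: int
    ref: str
    alt: str
    id: Optional[str] = None

    def __post_init__(self):
        if not self.ref or not self.alt:
            raise InputError("ref and alt alleles must be non-empty")


@dataclass(frozen=True)
class ConsequenceCall:
    category: Category
    truncating: bool
    aa_position: Optional[int]
    protein_change: Optional[str]
    detail: str = ""

    def __post_init__(self):
        if self.truncating != (self.category in TRUNCATING_CATEGORIES):
            raise ValueError(f"truncating flag inconsistent with category {self.category}")


def normalize_variant(variant: VariantRecord) -> tuple[int, str, str]:
    """Trim shared flanking bases; returns (0-based genomic start, ref, alt).

    Suffix then prefix trimming left-aligns VCF-style anchored indels to the
    minimal event. Either trimmed allele may be empty.
    """
    ref, alt = variant.ref.upper(), variant.alt.upper()
    pos0 = variant.pos - 1
    while len(ref) > 0 and len(alt) > 0 and ref[-1] == alt[-1] and (len(ref) > 1 or len(alt) > 1):
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 0 and len(alt) > 0 and ref[0] == alt[0] and (len(ref) > 1 or len(alt) > 1):
        ref, alt = ref[1:], alt[1:]
        pos0 += 1
    if ref == alt:
        ref = alt = ""
    return pos0, ref, alt


def hgvs_p_string(ref_protein: str, mut_protein: str, stopped: bool = True) -> str:
    """HGVS-like protein-change string in the single-letter "fsX" dialect.

    A mutant that is a shorter prefix of the reference ending in a stop is a
    nonsense change ("p.S7X"); otherwise the first divergent residue starts
    a frameshift ("p.E3GfsX2" - the stop is position k counted from the
    divergent residue, which itself is position 1). A frameshift whose new
    frame never reaches a stop renders "fsX?".
    """
    if mut_protein == ref_protein:
        raise InputError("proteins are identical; no change to describe")
    div = 0
    limit = min(len(ref_protein), len(mut_protein))
    while div < limit and ref_protein[div] == mut_protein[div]:
        div += 1
    pos = div + 1
    if div >= len(ref_protein):
        # mutant extends beyond reference: stop-loss style; report extension
        return f"p.X{len(ref_protein) + 1}ext"
    ref_aa = ref_protein[div]
    if div >= len(mut_protein):
        if stopped:
            if div == len(mut_protein) and mut_protein == ref_protein[:div]:
                return f"p.{ref_aa}{pos}X"
        return f"p.{ref_aa}{pos}fsX?"
    new_aa = mut_protein[div]
    if stopped:
        k = len(mut_protein) - div + 1
        return f"p.{ref_aa}{pos}{new_aa}fsX{k}"
    return f"p.{ref_aa}{pos}{new_aa}fsX?"


def acceptor_skip_consequence(transcript: TranscriptModel, exon_index: int) -> ConsequenceCall:
    """Consequence of skipping an internal exon (splice-acceptor variant).

    Truncating iff the exon's coding length is not a multiple of 3, which is
    exactly when the downstream exon's codon phase changes after the skip.
    """
    if exon_index <= 1 or exon_index >= transcript.n_exons:
        raise InputError(f"exon {exon_index} is terminal; no skip model applies")
    length = transcript.coding_length(exon_index)
    if length == 0:
        raise InputError(f"exon {exon_index} is non-coding")
    iv = transcript.coding_interval(exon_index)
    first_base = iv[0] if transcript.strand == "+" else iv[1] - 1
    aa = genomic_to_cds_offset(transcript, first_base) // 3 + 1
    if length % 3 == 0:
        return ConsequenceCall(
            Category.ACCEPTOR_SKIP_INFRAME,
            False,
            aa,
            None,
            detail=f"skipping exon {exon_index} ({length} coding nt) preserves frame; "
            "possible novel junction codons not assessed (phase rule only)",
        )
    return ConsequenceCall(
        Category.ACCEPTOR_SKIP_FRAMESHIFT,
        True,
        aa,
        None,
        detail=f"skipping exon {exon_index} ({length} coding nt) shifts frame by {length % 3}",
    )


def _retained_intron_cds(
    transcript: TranscriptModel, intron_index: int, genome: GenomeSequence
) -> tuple[str, int]:
    """Spliced CDS with intron ``intron_index`` retained; returns the
    sequence and the intron length."""
    introns = {k: (s, e) for k, s, e in transcript.introns()}
    if intron_index not in introns:
        raise InputError(f"intron {intron_index} out of range for {transcript.id}")
    up, down = transcript.exon(intron_index), transcript.exon(intron_index + 1)
    if transcript.coding_length(up.index) == 0 or transcript.coding_length(down.index) == 0:
        raise InputError(f"intron {intron_index} is not flanked by coding exons")
    s, e = introns[intron_index]
    pieces = []
    for exon in sorted(transcript.exons, key=lambda x: x.start):
        iv = transcript.coding_interval(exon.index)
        if iv is not None:
            pieces.append((iv[0], genome.fetch(transcript.contig, iv[0], iv[1])))
    pieces.append((s, genome.fetch(transcript.contig, s, e)))
    pieces.sort(key=lambda p: p[0])
    seq = "".join(p[1] for p in pieces)
    if transcript.strand == "-":
        seq = reverse_complement(seq)
    return seq, e - s


def donor_retention_consequence(
    transcript: TranscriptModel, intron_index: int, genome: GenomeSequence
) -> ConsequenceCall:
    """Consequence of retaining an intron (splice-donor variant).

    The retained-intron transcript is translated from the canonical start;
    a stop before the canonical stop position is a premature termination
    codon (truncating). An in-frame, stop-free intron reads through as an
    internal insertion (non-truncating).
    """
    ref_cds = spliced_cds(transcript, genome)
    ref_protein, ref_stopped, _ = translate_cds(ref_cds)
    mut_cds, intron_len = _retained_intron_cds(transcript, intron_index, genome)
    mut_protein, stopped, stop_idx = translate_cds(mut_cds)
    canonical_stop_codon = (len(ref_cds) + intron_len) // 3  # 1-based, if frame preserved
    if stopped and (intron_len % 3 != 0 or stop_idx < canonical_stop_codon):
        div = 0
        limit = min(len(ref_protein), len(mut_protein))
        while div < limit and ref_protein[div] == mut_protein[div]:
            div += 1
        change = hgvs_p_string(ref_protein, mut_protein, stopped=True)
        return ConsequenceCall(
            Category.DONOR_RETENTION_PTC,
            True,
            min(div + 1, len(ref_protein)),
            change,
            detail=f"retained intron {intron_index} ({intron_len} nt) yields a stop at codon {stop_idx}",
        )
    if intron_len % 3 == 0 and stopped and stop_idx == canonical_stop_codon:
        inserted = intron_len // 3
        up_iv = transcript.coding_interval(intron_index)
        last_base = up_iv[1] - 1 if transcript.strand == "+" else up_iv[0]
        aa = genomic_to_cds_offset(transcript, last_base) // 3 + 1
        return ConsequenceCall(
            Category.DONOR_RETENTION_READTHROUGH,
            False,
            aa,
            None,
            detail=f"in-frame stop-free intron {intron_index} inserts {inserted} residues",
        )
    return ConsequenceCall(
        Category.DONOR_RETENTION_READTHROUGH,
        False,
        None,
        None,
        detail=f"retained intron {intron_index} disrupts the frame but no premature stop "
        "is observed before the end of the transcript",
    )


def _coding_edit(
    transcript: TranscriptModel,
    genome: GenomeSequence,
    pos0: int,
    ref: str,
    alt: str,
) -> tuple[str, str]:
    """Apply a (trimmed) substitution of ref->alt at genomic pos0 to the
    spliced CDS; returns (reference CDS, mutant CDS)."""
    cds = spliced_cds(transcript, genome)
    if ref:
        if transcript.strand == "+":
            o_start = genomic_to_cds_offset(transcript, pos0)
            o_end = genomic_to_cds_offset(transcript, pos0 + len(ref) - 1) + 1
        else:
            o_start = genomic_to_cds_offset(transcript, pos0 + len(ref) - 1)
            o_end = genomic_to_cds_offset(transcript, pos0) + 1
        if o_end - o_start != len(ref):
            raise InputError("variant spans a splice junction; coding model not applicable")
        replacement = alt if transcript.strand == "+" else reverse_complement(alt)
        expected = ref if transcript.strand == "+" else ref
        if genome.fetch(transcript.contig, pos0, pos0 + len(ref)) != ref:
            raise InputError("ref allele does not match the genome")
    else:
        # pure insertion between pos0-1 and pos0
        if transcript.strand == "+":
            o_start = o_end = genomic_to_cds_offset(transcript, pos0)
        else:
            o_start = o_end = genomic_to_cds_offset(transcript, pos0 - 1)
        replacement = alt if transcript.strand == "+" else reverse_complement(alt)
    return cds, cds[:o_start] + replacement + cds[o_end:]


def classify_variant(
    variant: VariantRecord, transcript: TranscriptModel, genome: GenomeSequence
) -> ConsequenceCall:
    """Dispatch a variant to the nonsense / frameshift / splice rules.

    A variant touching the canonical splice dinucleotides is classified by
    the splice model even if it also overlaps coding bases (splice
    interpretation wins; the tie-break is recorded in ``detail``).
    """
    if variant.contig != transcript.contig:
        raise InputError(f"variant on {variant.contig}, transcript on {transcript.contig}")
    pos0_full = variant.pos - 1
    full_ref = variant.ref.upper()
    observed = genome.fetch(variant.contig, pos0_full, pos0_full + len(full_ref))
    if observed != full_ref:
        raise InputError(
            f"ref allele {full_ref!r} does not match genome {observed!r} at {variant.pos}"
        )
    span_lo = min(transcript.exon(i).start for i in range(1, transcript.n_exons + 1))
    span_hi = max(transcript.exon(i).end for i in range(1, transcript.n_exons + 1))
    if pos0_full + len(full_ref) <= span_lo or pos0_full >= span_hi:
        return ConsequenceCall(Category.OTHER, False, None, None, detail="outside transcript span")

    pos0, ref, alt = normalize_variant(variant)
    affected = set(range(pos0, pos0 + max(len(ref), 1)))

    # canonical splice dinucleotides, transcript orientation
    for k, s, e in transcript.introns():
        if transcript.strand == "+":
            donor, acceptor = {s, s + 1}, {e - 2, e - 1}
        else:
            donor, acceptor = {e - 1, e - 2}, {s, s + 1}
        if affected & donor:
            call = donor_retention_consequence(transcript, k, genome)
            return ConsequenceCall(
                call.category,
                call.truncating,
                call.aa_position,
                call.protein_change,
                detail=call.detail + "; splice-donor interpretation takes precedence",
            )
        if affected & acceptor:
            call = acceptor_skip_consequence(transcript, k + 1)
            return ConsequenceCall(
                call.category,
                call.truncating,
                call.aa_position,
                call.protein_change,
                detail=call.detail + "; splice-acceptor interpretation takes precedence",
            )

    try:
        ref_cds, mut_cds = _coding_edit(transcript, genome, pos0, ref, alt)
    except Exception:
        return ConsequenceCall(
            Category.OTHER, False, None, None, detail="non-coding or junction-spanning; no consequence model"
        )

    ref_protein, _, _ = translate_cds(ref_cds)
    mut_protein, mut_stopped, _ = translate_cds(mut_cds)
    if mut_protein == ref_protein:
        detail = (
            "synonymous"
            if mut_stopped
            else "edit confined to the stop codon; no premature truncation observed"
        )
        return ConsequenceCall(Category.OTHER, False, None, None, detail=detail)

    net = len(alt) - len(ref)
    div = 0
    limit = min(len(ref_protein), len(mut_protein))
    while div < limit and ref_protein[div] == mut_protein[div]:
        div += 1
    aa = min(div + 1, len(ref_protein))

    if div >= len(ref_protein):
        # mutant preserves the whole reference protein and extends it:
        # stop-loss, not a truncation
        return ConsequenceCall(
            Category.OTHER, False, len(ref_protein), None,
            detail="stop codon lost; protein extended, no premature truncation",
        )

    if net % 3 != 0:
        change = hgvs_p_string(ref_protein, mut_protein, stopped=mut_stopped)
        detail = "frameshift by re-translation"
        if not mut_stopped:
            detail += "; no stop reached in the shifted frame (undetermined extent)"
        return ConsequenceCall(Category.FRAMESHIFT, True, aa, change, detail=detail)

    premature_stop = mut_stopped and len(mut_protein) < len(ref_protein) and mut_protein == ref_protein[: len(mut_protein)]
    if premature_stop:
        change = hgvs_p_string(ref_protein, mut_protein, stopped=True)
        kind = "nonsense SNV" if net == 0 and len(ref) == 1 else "in-frame change creating a stop"
        return ConsequenceCall(Category.NONSENSE, True, aa, change, detail=kind)

    return ConsequenceCall(
        Category.OTHER, False, aa if div < len(ref_protein) else None, None,
        detail="in-frame non-truncating change",
    )


def read_vcf(path: str | Path) -> list[VariantRecord]:
    """Read variants from an (uncompressed) VCF; one record per alt allele."""
    out = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            for alt in rec.alts or ():
                out.append(
                    VariantRecord(
                        contig=rec.contig,
                        pos=rec.pos,
                        ref=rec.ref,
                        alt=alt,
                        id=rec.id,
                    )
                )
    return out
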