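"""Synthetic fixtures with the statistical structure the analyses assume.

The generator builds a miniature multi-exon "mini-titin" gene — valid CDS,
an intron hosting an internal promoter with an in-frame upstream initiator
ATG, and a Novex-3-style minor isoform ending in its own terminal exon —
and simulates the data types each pipeline stage consumes:

* junction counts: an included transcript exposes two inclusion junctions
  and a skipping transcript one exclusion junction, so with per-junction
  depth d and true inclusion level psi, I5, I3 ~ Poisson(d * psi) and
  X ~ Poisson(d * (1 - psi)); the psi = (I5+I3)/(I5+I3+2X) estimator is
  then consistent;
* heterozygote amplicon reads: each read is mutant with probability
  r/(1+r) for true mutant:wild-type ratio r, with flat per-base errors;
* coverage tracks: Poisson depth per base, elevated in exons and in the
  designated promoter window;
* cohort variant tables with configurable positional mixes.

All randomness comes from one numpy Generator seeded by the config; the
same config yields byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .cohort_positional import CohortVariantRow, CohortVariantTable
from .errors import ConfigError
from .genemodels import (
    ExonRecord,
    GenomeSequence,
    TranscriptModel,
    exon_phase,
    spliced_cds,
    translate_cds,
)
from .promoter_scan import CoverageTrack
from .psi_quant import JunctionCountTable, JunctionRow

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_STOPS = {"TAA", "TAG", "TGA"}
_NON_STOP_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOPS and a + b + c != "ATG"
]


@dataclass(frozen=True)
class CohortSpec:
    """One simulated cohort arm."""

    label: str
    n_subjects: int
    truncation_rate: float
    p_c_side: float
    p_novex3: float = 0.0


# Default cohort mix loosely mirrors the observed study arms: end-stage
# disease heavily C-terminal, population controls mixed, and a fit-elderly
# arm whose truncations sit exclusively in the Novex-3 terminal exon.
DEFAULT_COHORTS = (
    CohortSpec("end_stage_DCM", 124, 0.25, 30 / 31, 0.0),
    CohortSpec("unselected_DCM", 312, 0.154, 37 / 48, 0.0),
    CohortSpec("literature_controls", 1400, 0.012, 18 / 38, 0.13),
    CohortSpec("senior_athletes", 199, 0.015, 0.0, 1.0),
)


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    # toy gene geometry
    n_exons: int = 12
    n_aa: int = 400            # protein length (stop codon added on top)
    utr5_length: int = 60
    utr3_length: int = 60
    intron_length: int = 700
    flank: int = 200
    promoter_exon_index: Optional[int] = None  # default: two-thirds point
    tss_offset: int = 110      # TSS this many bp upstream of the promoter exon
    internal_atg_aa_offset: int = 7
    # junction simulation
    depth: int = 10_000
    psi_true: Optional[dict[int, float]] = None  # exon index -> psi (default 1.0)
    # heterozygote amplicon simulation
    nmd_ratio_true: float = 0.225
    base_error_rate: float = 0.001
    n_reads: int = 10_000
    amplicon_length: int = 101
    # coverage simulation
    promoter_fold: float = 10.0
    promoter_window: int = 500
    coverage_background: float = 10.0
    exon_depth_factor: float = 20.0
    # cohort simulation
    cohorts: tuple[CohortSpec, ...] = DEFAULT_COHORTS
    boundary_aa: int = 14_760
    total_aa: int = 34_350
    novex3_aa_range: tuple[int, int] = (5_000, 6_000)

    def __post_init__(self):
        for name in ("nmd_ratio_true", "base_error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0 and name == "base_error_rate":
                raise ConfigError(f"{name} must lie in [0,1], got {v}")
        if self.nmd_ratio_true < 0:
            raise ConfigError("nmd_ratio_true must be non-negative")
        for c in self.cohorts:
            for p in (c.truncation_rate, c.p_c_side, c.p_novex3):
                if not 0.0 <= p <= 1.0:
                    raise ConfigError(f"cohort {c.label}: probability {p} outside [0,1]")
        if self.psi_true is not None:
            for k, v in self.psi_true.items():
                if not 0.0 <= v <= 1.0:
                    raise ConfigError(f"psi_true[{k}] = {v} outside [0,1]")


def _random_seq(rng: np.random.Generator, n: int, alphabet: str = "ACGT") -> str:
    letters = np.frombuffer(alphabet.encode(), dtype="S1")
    return rng.choice(letters, size=n).tobytes().decode()


@dataclass
class ToyGene:
    genome: GenomeSequence
    transcript: TranscriptModel
    novex_transcript: TranscriptModel
    promoter_exon_index: int
    tss_position: int            # genomic (plus strand)
    internal_atg_position: int   # genomic start of the planted ATG
    internal_atg_aa_offset: int

    @property
    def contig(self) -> str:
        return self.transcript.contig


def make_toy_gene(config: SimulationConfig) -> ToyGene:
    """Build a miniature titin-like gene on the plus strand of one contig.

    Guarantees: the main transcript's spliced CDS starts ATG, ends in a
    stop, has length divisible by 3 and translates without internal stops;
    the intron upstream of the promoter exon carries an in-frame ATG at the
    configured codon offset, with no competing in-frame ATG between the TSS
    and the exon; the minor isoform shares the first two exons and ends in
    its own terminal exon inside intron 2.
    """
    cfg = config
    if cfg.n_exons < 6:
        raise ConfigError("need at least 6 exons for a toy titin")
    rng = np.random.default_rng(cfg.seed)

    # coding sequence: ATG + random non-stop codons + TAA
    codons = ["ATG"] + list(rng.choice(_NON_STOP_CODONS, size=cfg.n_aa - 1)) + ["TAA"]
    cds = "".join(codons)

    # split the CDS into n_exons chunks, each at least 9 nt
    min_chunk = 9
    if len(cds) < cfg.n_exons * min_chunk:
        raise ConfigError("CDS too short for the requested exon count")
    while True:
        cuts = np.sort(rng.choice(np.arange(1, len(cds)), size=cfg.n_exons - 1, replace=False))
        sizes = np.diff(np.concatenate(([0], cuts, [len(cds)])))
        if sizes.min() >= min_chunk:
            break
    chunks = []
    prev = 0
    for cut in list(cuts) + [len(cds)]:
        chunks.append(cds[prev:cut])
        prev = cut

    pe = cfg.promoter_exon_index or max(4, (2 * cfg.n_exons) // 3)
    if not 2 <= pe <= cfg.n_exons - 1:
        raise ConfigError(f"promoter exon {pe} must be internal")
    coding_before_pe = sum(len(chunks[i]) for i in range(pe - 1))
    phase = coding_before_pe % 3

    # planted initiator: d nt upstream of the exon with d == phase (mod 3)
    d = phase + 3 * (cfg.internal_atg_aa_offset - (1 if phase else 0))
    if d < 3 or d + 3 > cfg.tss_offset:
        raise ConfigError("internal ATG offset incompatible with TSS offset")

    def plain_intron() -> str:
        return "GT" + _random_seq(rng, cfg.intron_length - 4) + "AG"

    def promoter_intron() -> str:
        # last tss_offset bases: pyrimidine-only except the planted ATG and
        # the terminal 'CAG' (acceptor AG preceded by C) -> no competing
        # in-frame ATG and no stop codon between the ATG and the exon
        head = "GT" + _random_seq(rng, cfg.intron_length - 2 - cfg.tss_offset)
        pre_atg = _random_seq(rng, cfg.tss_offset - d, alphabet="CT")
        post_atg = _random_seq(rng, d - 3, alphabet="CT")
        tail = pre_atg + "ATG" + post_atg
        tail = tail[:-3] + "CAG"
        assert len(tail) == cfg.tss_offset
        return head + tail

    introns = []
    for k in range(1, cfg.n_exons):
        introns.append(promoter_intron() if k == pe - 1 else plain_intron())

    utr5 = _random_seq(rng, cfg.utr5_length, alphabet="CT")  # no spurious upstream ATG
    utr3 = _random_seq(rng, cfg.utr3_length)
    left_flank = _random_seq(rng, cfg.flank)
    right_flank = _random_seq(rng, cfg.flank)

    # assemble plus-strand genome and exon coordinates
    parts = [left_flank]
    pos = len(left_flank)
    exon_records = []
    cds_start = cds_end = None
    for k in range(1, cfg.n_exons + 1):
        exon_seq = chunks[k - 1]
        if k == 1:
            exon_seq = utr5 + exon_seq
        if k == cfg.n_exons:
            exon_seq = exon_seq + utr3
        start = pos
        end = pos + len(exon_seq)
        exon_records.append(ExonRecord("chrT", start, end, k))
        if k == 1:
            cds_start = start + len(utr5)
        if k == cfg.n_exons:
            cds_end = end - len(utr3)
        parts.append(exon_seq)
        pos = end
        if k < cfg.n_exons:
            parts.append(introns[k - 1])
            pos += len(introns[k - 1])

    # Novex-3-style terminal exon inside intron 2, continuing exon 2's frame
    phase2 = (len(chunks[0]) + len(chunks[1])) % 3
    pad = "C" * ((3 - phase2) % 3)
    novex_body = pad + "".join(rng.choice(_NON_STOP_CODONS, size=15)) + "TAA"
    novex_utr = _random_seq(rng, 40)
    novex_seq = novex_body + novex_utr
    intron2_start = exon_records[1].end
    novex_start = intron2_start + 100
    novex_end = novex_start + len(novex_seq)
    if novex_end + 50 > exon_records[2].start:
        raise ConfigError("intron 2 too short to host the minor-isoform exon")

    genome_seq = "".join(parts)
    genome_seq = (
        genome_seq[:novex_start] + novex_seq + genome_seq[novex_end:]
    )
    genome = GenomeSequence({"chrT": genome_seq})

    transcript = TranscriptModel("toygene-201", "+", exon_records, cds_start, cds_end)
    novex = TranscriptModel(
        "toygene-novex",
        "+",
        [
            ExonRecord("chrT", exon_records[0].start, exon_records[0].end, 1),
            ExonRecord("chrT", exon_records[1].start, exon_records[1].end, 2),
            ExonRecord("chrT", novex_start, novex_end, 3),
        ],
        cds_start,
        novex_start + len(novex_body),
    )

    # self-checks: both isoforms translate cleanly
    for model in (transcript, novex):
        protein, stopped, stop_idx = translate_cds(spliced_cds(model, genome))
        assert stopped and stop_idx == len(protein) + 1, f"{model.id}: invalid CDS"

    pe_exon = exon_records[pe - 1]
    tss_position = pe_exon.start - cfg.tss_offset
    atg_position = pe_exon.start - d
    assert genome_seq[atg_position : atg_position + 3] == "ATG"
    assert exon_phase(transcript, pe) == phase

    return ToyGene(
        genome=genome,
        transcript=transcript,
        novex_transcript=novex,
        promoter_exon_index=pe,
        tss_position=tss_position,
        internal_atg_position=atg_position,
        internal_atg_aa_offset=cfg.internal_atg_aa_offset,
    )


# -- junction counts ------------------------------------------------------


def simulate_junction_counts(
    config: SimulationConfig, transcript: TranscriptModel
) -> JunctionCountTable:
    """Poisson junction counts per exon under the paired generative model."""
    rng = np.random.default_rng(config.seed)
    psi = config.psi_true or {}
    table = JunctionCountTable()
    n = transcript.n_exons
    for k in range(1, n + 1):
        p = float(psi.get(k, 1.0))
        incl = config.depth * p
        excl = config.depth * (1.0 - p)
        i5 = int(rng.poisson(incl)) if k > 1 else None
        i3 = int(rng.poisson(incl)) if k < n else None
        x = int(rng.poisson(excl)) if 1 < k < n else 0
        table.add(f"{transcript.id}:e{k}", JunctionRow(i5=i5, i3=i3, x=x))
    return table


def simulate_spliced_read_alignments(
    config: SimulationConfig,
    transcript: TranscriptModel,
    genome: GenomeSequence,
    reads_per_junction: int = 30,
    anchor: int = 20,
) -> tuple[str, JunctionCountTable]:
    """SAM text of spliced reads plus the generator's own junction tallies.

    For each intron, ``reads_per_junction`` reads span the inclusion
    junction; for each internal exon, Poisson(reads_per_junction * (1 -
    psi)/psi-ish) skip reads are replaced by a simple fixed fraction here:
    skip reads are drawn per exon from psi_true. The returned table is the
    bookkeeping truth the SAM parser must reproduce.
    """
    rng = np.random.default_rng(config.seed)
    psi = config.psi_true or {}
    contig = transcript.contig
    n = transcript.n_exons
    lines = [
        "@HD\tVN:1.6\tSO:unsorted",
        f"@SQ\tSN:{contig}\tLN:{genome.contig_length(contig)}",
    ]
    i5 = {k: 0 for k in range(2, n + 1)}
    i3 = {k: 0 for k in range(1, n)}
    x = {k: 0 for k in range(1, n + 1)}
    serial = 0

    def emit(pos0: int, cigar: str) -> None:
        nonlocal serial
        serial += 1
        lines.append(
            f"read{serial}\t0\t{contig}\t{pos0 + 1}\t60\t{cigar}\t*\t0\t0\t*\t*"
        )

    for k, istart, iend in transcript.introns():
        n_incl = rng.poisson(reads_per_junction * float(psi.get(k + 1, 1.0)))
        gap = iend - istart
        up = transcript.exon(k)
        for _ in range(n_incl):
            emit(up.end - anchor, f"{anchor}M{gap}N{anchor}M")
            i3[k] += 1
            i5[k + 1] += 1
    for k in range(2, n):
        p = float(psi.get(k, 1.0))
        n_skip = rng.poisson(reads_per_junction * (1.0 - p))
        up, down = transcript.exon(k - 1), transcript.exon(k + 1)
        gap = down.start - up.end
        for _ in range(n_skip):
            emit(up.end - anchor, f"{anchor}M{gap}N{anchor}M")
            x[k] += 1

    table = JunctionCountTable()
    for k in range(1, n + 1):
        table.add(
            f"{transcript.id}:e{k}",
            JunctionRow(i5=i5.get(k), i3=i3.get(k), x=x[k]),
        )
    return "\n".join(lines) + "\n", table


# -- heterozygote amplicon ------------------------------------------------


@dataclass
class HetAmpliconSim:
    reads: list[str]
    labels: np.ndarray            # True where the read came from the mutant allele
    ref_window: str
    alt_window: str
    amplicon_ref: str
    amplicon_alt: str


def simulate_het_amplicon(
    config: SimulationConfig, window_radius: int = 10
) -> HetAmpliconSim:
    """Amplicon reads from a heterozygote with true mutant:wild-type ratio r.

    Each read covers the full amplicon; the two alleles differ by the SNV at
    the centre. Per-base substitution errors are applied at
    ``base_error_rate`` (uniform over the three other bases).
    """
    rng = np.random.default_rng(config.seed)
    L = config.amplicon_length
    mid = L // 2
    ref_idx = rng.integers(0, 4, size=L)
    alt_idx = ref_idx.copy()
    alt_idx[mid] = (ref_idx[mid] + 1 + rng.integers(0, 3)) % 4

    r = config.nmd_ratio_true
    p_mut = r / (1.0 + r)
    labels = rng.random(config.n_reads) < p_mut

    reads_idx = np.where(labels[:, None], alt_idx[None, :], ref_idx[None, :])
    err = rng.random((config.n_reads, L)) < config.base_error_rate
    shifts = rng.integers(1, 4, size=(config.n_reads, L))
    reads_idx = np.where(err, (reads_idx + shifts) % 4, reads_idx)

    to_str = lambda idx: _BASES[idx].tobytes().decode()
    reads = [to_str(row) for row in reads_idx]
    ref_seq, alt_seq = to_str(ref_idx), to_str(alt_idx)
    lo, hi = mid - window_radius, mid + window_radius + 1
    return HetAmpliconSim(
        reads=reads,
        labels=labels,
        ref_window=ref_seq[lo:hi],
        alt_window=alt_seq[lo:hi],
        amplicon_ref=ref_seq,
        amplicon_alt=alt_seq,
    )


# -- coverage -------------------------------------------------------------


def simulate_coverage_with_promoter(
    config: SimulationConfig, toy: ToyGene
) -> CoverageTrack:
    """Per-base Poisson coverage over the gene span with exonic enrichment
    and an elevated window upstream of the designated promoter exon."""
    rng = np.random.default_rng(config.seed)
    t = toy.transcript
    span_lo = min(e.start for e in t.exons)
    span_hi = max(e.end for e in t.exons)
    length = span_hi - span_lo
    lam = np.full(length, config.coverage_background)
    for e in t.exons:
        lam[e.start - span_lo : e.end - span_lo] = (
            config.coverage_background * config.exon_depth_factor
        )
    pe = t.exon(toy.promoter_exon_index)
    introns = {k: (s, e) for k, s, e in t.introns()}
    istart, iend = introns[toy.promoter_exon_index - 1]
    if t.strand == "+":
        wstart = max(istart, pe.start - config.promoter_window)
        wend = pe.start
    else:
        wstart = pe.end
        wend = min(iend, pe.end + config.promoter_window)
    lam[wstart - span_lo : wend - span_lo] = (
        config.coverage_background * config.promoter_fold
    )
    depths = rng.poisson(lam).astype(float)
    return CoverageTrack.from_per_base(t.contig, span_lo, depths)


# -- cohort tables --------------------------------------------------------


def simulate_cohort_variants(config: SimulationConfig) -> CohortVariantTable:
    """Cohort truncation tables with a configurable N/C positional mix."""
    rng = np.random.default_rng(config.seed)
    rows = []
    for spec in config.cohorts:
        carriers = rng.random(spec.n_subjects) < spec.truncation_rate
        for subject, carrier in enumerate(carriers, 1):
            if not carrier:
                continue
            subject_id = f"{spec.label}_{subject:04d}"
            if rng.random() < spec.p_novex3:
                aa = int(rng.integers(config.novex3_aa_range[0], config.novex3_aa_range[1] + 1))
                rows.append(CohortVariantRow(subject_id, spec.label, aa, True, True))
                continue
            if rng.random() < spec.p_c_side:
                aa = int(rng.integers(config.boundary_aa, config.total_aa + 1))
            else:
                aa = int(rng.integers(1, config.boundary_aa))
            rows.append(CohortVariantRow(subject_id, spec.label, aa, False, True))
    return CohortVariantTable(rows)


# -- fixture writers ------------------------------------------------------


def write_fasta(genome: GenomeSequence, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_gff3(transcripts: Sequence[TranscriptModel], path: str | Path) -> None:
    """Write transcripts as GFF3 (1-based inclusive on output)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for t in transcripts:
            lo = min(e.start for e in t.exons)
            hi = max(e.end for e in t.exons)
            fh.write(
                f"{t.contig}\tcronoscan\tmRNA\t{lo + 1}\t{hi}\t.\t{t.strand}\t.\tID={t.id}\n"
            )
            for e in t.exons:
                fh.write(
                    f"{t.contig}\tcronoscan\texon\t{e.start + 1}\t{e.end}\t.\t{t.strand}\t.\t"
                    f"ID={t.id}.exon{e.index};Parent={t.id}\n"
                )
                iv = t.coding_interval(e.index)
                if iv is not None:
                    fh.write(
                        f"{t.contig}\tcronoscan\tCDS\t{iv[0] + 1}\t{iv[1]}\t.\t{t.strand}\t.\t"
                        f"ID={t.id}.cds{e.index};Parent={t.id}\n"
                    )


def write_vcf(
    variants: Sequence, genome: GenomeSequence, path: str | Path
) -> None:
    """Write VariantRecords as a minimal uncompressed VCF."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for name, seq in genome.sequences.items():
            fh.write(f"##contig=<ID={name},length={len(seq)}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in variants:
            vid = v.id or "."
            fh.write(f"{v.contig}\t{v.pos}\t{vid}\t{v.ref}\t{v.alt}\t.\tPASS\t.\n")
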