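# Methods

## The analysis problem

Truncating variants in titin (nonsense, frameshift, canonical splice-site)
are a major cause of dilated cardiomyopathy, but their severity depends on
position: an internal promoter in the intron upstream of zebrafish *ttna*
exon 116 (human *TTN* exon 240) produces a C-terminal isoform that can
partially rescue truncations N-terminal to it. This package implements the
computational procedures such a study rests on — junction-read PSI
quantification, splice-aware consequence calling, allelic-imbalance NMD
estimation, coverage-based internal-promoter detection, positional cohort
comparison, and PAM-scanning guide design — as a tested pipeline exercised
end-to-end on synthetic data.

## Coordinates and gene models

All internal intervals are 0-based half-open on the genomic plus strand;
GFF/GTF and VCF conventions (1-based inclusive) are converted only at the
I/O boundary. A transcript is an ordered exon list in 5'→3' transcript
orientation (exon 1 has the highest genomic coordinates on the minus
strand) plus genomic CDS boundaries that include the stop codon. Spliced
CDS, codon phases (cumulative coding length mod 3), genomic↔amino-acid
projection, and translation (standard code only, halt at first stop,
trailing partial codon ignored) all derive from this structure.
Cross-species amino-acid positions are projected through a supplied
exon-level interval map by linear interpolation with rounding; no
alignment is performed and uncovered positions raise rather than
extrapolate.

## PSI from junction reads

An included transcript exposes two inclusion junctions (upstream and
downstream of the exon), a skipping transcript one exclusion junction.
With per-junction depth d and inclusion fraction ψ the paired generative
model is I5, I3 ~ Poisson(d·ψ), X ~ Poisson(d·(1−ψ)), under which

ψ̂ = (I5 + I3) / (I5 + I3 + 2X)

is consistent (the 2 puts exclusion counts on the per-event scale of the
two inclusion junctions). Terminal exons have a single inclusion junction
and use ψ̂ = I/(I + 2X); the missing junction is recorded as absent, not
zero. Estimates whose denominator falls below a configurable floor
(default 15 junction reads) are no-calls; per-exon medians are taken over
passing estimates only. At depth 10⁴ the estimator's sampling sd is
≈0.004 at ψ = 0.5 and ≈0.0004 at ψ = 0.996, so consistency checks bound
the mean error over seeds (0.01) rather than each draw. The SAM adapter
counts an alignment gap matching annotated intron k toward both I3(k) and
I5(k+1), a gap from exon k−1's end to exon k+1's start toward X(k), and
tallies unannotated gaps separately.

## Truncation-consequence rules

Coding SNVs creating a stop are NONSENSE; coding indels with net length
≢ 0 (mod 3) are FRAMESHIFT; both truncate. Protein changes are obtained
by re-translating the edited spliced CDS and reported in the single-letter
`fsX` dialect: `p.{ref}{pos}{new}fsX{k}` with k the stop's offset from the
first divergent residue (the divergent residue is position 1), `p.{ref}{pos}X`
for a clean nonsense change, `fsX?` when the shifted frame reaches the
transcript end without a stop. Variants are left-aligned (shared flanking
bases trimmed) before classification, and one record is processed per alt
allele.

Splice-site variants are classified structurally rather than by their base
change, and the splice interpretation wins when a variant also touches
coding bases (recorded in the call's detail text):

- acceptor (−1/−2): the downstream exon is skipped; truncating iff the
  exon's coding length ≢ 0 (mod 3), equivalently iff the downstream
  phase changes. In-frame skips that might create a novel stop at the new
  junction are still non-truncating — the rule is purely phase-based,
  and the caveat is noted in the detail string.
- donor (+1/+2): the intron is retained; the retained-intron transcript
  is translated from the canonical start and the call is truncating only
  if a stop appears before the canonical stop position. An in-frame,
  stop-free intron is a benign internal insertion; a frameshifting
  retained intron whose shifted frame never reaches a stop is likewise
  reported non-truncating, because no premature truncation is observed.

Edits confined to the stop codon (protein unchanged, or stop lost with the
protein extended) are OTHER and non-truncating for the same reason.

## NMD from allelic imbalance

Assuming equal transcription of both alleles in a heterozygote, the
mutant:wild-type read ratio r in targeted amplicon sequencing estimates
the surviving fraction of the premature-stop transcript; percent degraded
is (1 − r)·100. Reads are assigned by exact containment of a
discriminating window (default ±10 bp around the variant — amplicons of
~100 bp make realignment unnecessary); reads matching neither or both
windows are ambiguous and excluded. The 95% interval is Wilson on
p = mut/(mut+wt), mapped to the ratio via r = p/(1−p). Totals below a
read floor (default 100 classified reads; targeted experiments typically
yield 600–10,000) set a low-coverage flag rather than an error.
Isoform-class abundance ratios (internal-promoter vs full-length
transcript) are length-normalized count ratios over isoform-specific
regions.

## Internal-promoter detection

Transcription from an intronic promoter appears as read accumulation in
the window immediately 5' (transcript orientation) of the internal
isoform's first exon. Each internal exon is scored as

fold = mean depth in the acceptor-edge window / (median intronic depth + 1)

with window 500 bp, pseudocount 1 and call threshold 5 — the original
observation was visual, so these constants are this package's declared
formalization, all configurable. Background is the per-gene intronic
median (robust to exonic coverage and library depth); windows truncated
by short introns are flagged. Peak annotation is binary half-open
interval overlap, matching the qualitative use of DNase/H3K4me3 evidence.
The initiator search scans from a (supplied) TSS toward the exon in
transcript orientation and returns the first ATG whose distance d to the
exon start satisfies d ≡ phase (mod 3), so translation runs in frame into
the exon; the reported offset counts codons from the ATG to the exon
boundary. Kozak-context ranking is deliberately not applied.

## Cohort positional statistics

Truncating variants classify as C-terminal when their meta-transcript
position is ≥ 14,760 (the boundary residue itself is C), N-terminal below
it. Variants in the Novex-3-exclusive terminal exon are excluded from C:N
ratios (the isoform is minor and its truncations are not comparable) but
retained for prevalence and Novex-3-fraction comparisons. Cohorts are
compared with the pooled two-proportion z-test, two-sided normal p, no
continuity correction by default (a Yates-style correction is available
as a flag); degenerate pooled proportions return p = 1. z² equals the
uncorrected 1-df chi-square, which the tests verify against an
independent implementation.

## Guide design

A candidate is any 23-mer window on either strand ending in GG (20-nt
protospacer + NGG PAM); overlapping candidates are all reported.
Uniqueness is exact 23-mer matching over both genome strands — no
mismatch-tolerant off-target scoring, matching a "single genome match"
criterion. Ranking: unique sites first, then protospacers beginning GG
(efficient T7 initiation), then position, plus strand before minus.

## Synthetic data: what it emulates and what it does not

`make_toy_gene` builds a plus-strand 12-exon gene (~400-codon CDS split
at random exon boundaries, introns 700 bp, 60-bp UTRs) with (a) an
internal-promoter intron whose last 110 bp (the TSS region) are
constructed pyrimidine-rich so that exactly one in-frame ATG sits 7
codons upstream of the designated exon (two-thirds of the way through
the gene), and (b) a Novex-3-style minor isoform sharing exons 1–2 and
ending in its own terminal exon inside intron 2. Both isoforms are
verified at build time to translate cleanly. Mirror helpers produce the
coordinate-flipped minus-strand equivalent for strand-symmetry tests.

Generators draw from one `numpy` Generator seeded by the config, so equal
configs give byte-identical fixtures. Junction counts follow the paired
Poisson model above (depth 10,000 by default, ψ = 1 unless overridden —
titin exons are overwhelmingly constitutive). Amplicon reads are 101 bp,
mutant with probability r/(1+r) (default true ratio 0.225, the middle of
the 20–25%-of-wild-type band typical of NMD), with flat 0.1% substitution
errors. Coverage tracks are per-base Poisson: background 10, exons ×20,
promoter window ×10. Cohort arms default to an end-stage-disease-like mix
(C-heavy, rate 0.25), an unselected-disease arm, a population-control arm
(rate 0.012, mixed positions, 13% Novex-3) and a fit-elderly arm (rate
0.015, all Novex-3).

Not emulated: positional read-quality structure, indel sequencing errors,
PCR duplicates/UMIs, allelic transcription asymmetry, inter-library depth
normalization, and real splice-site sequence strength. Passing tests
therefore demonstrate correctness of the estimators and rules under the
stated generative assumptions, not robustness to those real-data
artifacts.

## Problem sizes and numerical choices

The shipped analyses and tests run at toy scale chosen to make every
stochastic check statistically decisive: junction depth 10⁴ (estimator sd
≤ 0.004), amplicon n = 10⁴ (ratio sd ≈ 0.006), 100-seed detector
operating-characteristic runs, 1,000-table z²/χ² agreement at 10⁻⁹, and
1,000-run Wilson coverage at n = 1,000 (expected ≈ 95%, required ≥ 93%).
Ties and degenerate inputs: identical proteins are a no-change signal,
not a call; empty coverage queries return 0; guide ranking is a stable
total order; orthology intervals of zero source width map to their target
start. Known limitations: consequence calling handles variants within a
single coding exon (junction-spanning edits return OTHER with an
explanatory detail), compound heterozygotes are processed per allele, and
the promoter detector assumes one dominant internal signal per gene.
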