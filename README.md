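# cronoscan

Splice-aware analysis of truncating variants in giant sarcomeric genes,
built around the observation that *TTN*/*ttna* truncations differ in
severity depending on whether they fall N- or C-terminal to a conserved
internal promoter (the *Cronos* promoter) in the intron upstream of
zebrafish exon 116 / human exon 240. The package is aimed at
transcriptomics and disease-genetics analysts who need to reproduce this
style of analysis end-to-end on their own data — or, as shipped here, on
synthetic data with the same statistical structure.

## What it computes

- **Exon inclusion (PSI)** from exon–exon junction reads. For an internal
  exon with upstream/downstream inclusion junction counts I5, I3 and
  skipping-junction counts X,

  ψ = (I5 + I3) / (I5 + I3 + 2X)

  (one skipping event removes both inclusion junctions, hence the 2).
  Estimates with denominator < 15 are no-calls; medians are taken across
  samples, and constitutive content (ψ > 0.9) is tallied in amino acids.
- **Truncation consequence calling.** Nonsense SNVs and frameshifting
  indels are truncating (protein change by re-translation, reported in
  the `p.E15193GfsX8` style). Canonical splice-acceptor variants (−1/−2)
  are modelled as skipping of the downstream exon and truncate only if
  the skipped exon's coding length ≢ 0 (mod 3); splice-donor variants
  (+1/+2) are modelled as intron retention and truncate only if in-silico
  translation of the retained intron actually reaches a premature stop.
- **NMD efficiency from allelic imbalance.** In a heterozygote, reads are
  assigned to alleles by exact match of a ±10-bp discriminating window;
  the mutant:wild-type ratio r estimates the surviving fraction of the
  premature-stop transcript (percent degraded = (1 − r) × 100), with a
  Wilson 95% interval on p = mut/(mut+wt) mapped to the ratio scale.
- **Internal-promoter detection.** Each internal exon's upstream-intron
  acceptor-edge window (500 bp) is scored as mean depth over the per-gene
  median intronic background (+1 pseudocount); fold ≥ 5 is called, and
  candidates are annotated with DNase/H3K4me3 peak overlap and the first
  in-frame upstream initiator ATG between a TSS and the exon.
- **Positional cohort statistics.** Truncating variants classify as N or
  C relative to meta-transcript residue 14,760 (inclusive on the C side);
  Novex-3-exon variants are excluded from C:N ratios; cohorts are
  compared with a pooled two-proportion z-test.
- **sgRNA design.** Both-strand scan for 23-bp protospacer+NGG sites,
  exact-match genome uniqueness, and ranking that prefers unique sites
  and 5′-GG protospacers (T7 transcription).
- **Synthetic data.** A miniature multi-exon "mini-titin" (valid CDS,
  internal-promoter intron with planted in-frame ATG, Novex-3-style minor
  isoform) plus generators for junction counts, heterozygote amplicon
  reads, coverage tracks and cohort tables, all seed-deterministic.

## Worked example

Run the numbered drivers (each writes tables under `results/`):

```sh
python analysis/01_build_toy_gene.py
python analysis/04_estimate_nmd.py
python analysis/05_scan_promoter.py
```

which prints, among other lines:

```
internal promoter: intron upstream of exon 8, TSS at 5487, in-frame ATG 7 codons upstream of the exon
mutant transcript at 20-25% of wild-type across lines (i.e. 75-80% degraded)
internal-promoter:full-length ratio 2.00 (N-terminal mutant) vs 0.26 (C-terminal mutant)
internal promoter called upstream of exon 8 (fold 9.1 over background 10.0; DNase overlap True, H3K4me3 overlap True)
```

Reading this: the generator planted a promoter in the intron upstream of
exon 8 with an initiator methionine 7 codons upstream of the exon; the
coverage detector recovers exactly that exon (window mean ≈ 100 over
background 10 gives fold 100/11 ≈ 9.1); heterozygote amplicon sequencing
puts the mutant transcript at 20–25% of wild-type (NMD degrading
75–80%); and length-normalized isoform-specific counts recover the ~2:1
internal-promoter:full-length transcript ratio expected when NMD removes
full-length but not internal-promoter transcripts in an N-terminal
mutant. `02_quantify_psi.py`, `03_call_truncations.py`,
`06_cohort_positions.py` and `07_design_guides.py` cover the remaining
stages (PSI tables, a six-line truncation panel, cohort C:N ratios with
the two-proportion tests, and ranked guides).

A `cronoscan` CLI exposes the same operations on files
(`cronoscan psi --junctions tbl.tsv`, `cronoscan classify --vcf v.vcf
--gff m.gff --fasta g.fa`, `cronoscan promoter-scan …`,
`cronoscan simulate …`; see `cronoscan --help`).

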