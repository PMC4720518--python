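#!/usr/bin/env python
"""Build the miniature titin-like gene every later stage analyses.

Writes the genome FASTA, the gene models (full-length transcript plus the
Novex-3-style minor isoform) and a synthetic zebrafish->human amino-acid
orthology map under results/toygene/, and prints the gene's anatomy.
"""

from pathlib import Path

from cronoscan.genemodels import spliced_cds, translate_cds
from cronoscan.synthetic_data import (
    SimulationConfig,
    make_toy_gene,
    write_fasta,
    write_gff3,
)

SEED = 1
OUT = Path(__file__).resolve().parent.parent / "results" / "toygene"

# synthetic orthology: the toy protein scaled onto a meta-transcript of
# 34,350 residues, so positions project the way Table-1-style coordinates do
META_TRANSCRIPT_AA = 34_350


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    config = SimulationConfig(seed=SEED)
    toy = make_toy_gene(config)
    t = toy.transcript

    write_fasta(toy.genome, OUT / "genome.fa")
    write_gff3([t, toy.novex_transcript], OUT / "models.gff3")

    protein, stopped, _ = translate_cds(spliced_cds(t, toy.genome))
    scale = META_TRANSCRIPT_AA / len(protein)
    with open(OUT / "orthology.tsv", "w") as fh:
        aa = 1
        for k in range(1, t.n_exons + 1):
            aa_len = max(1, t.coding_length(k) // 3)
            src_end = min(aa + aa_len - 1, len(protein))
            fh.write(
                f"{k}\t{aa}\t{src_end}\t{round(aa * scale)}\t{round(src_end * scale)}\n"
            )
            aa = src_end + 1

    print(f"toy gene: {t.n_exons} exons, CDS {t.cds_length()} nt, protein {len(protein)} aa")
    print(f"minor isoform: {toy.novex_transcript.n_exons} exons, own terminal exon")
    print(
        f"internal promoter: intron upstream of exon {toy.promoter_exon_index}, "
        f"TSS at {toy.tss_position}, in-frame ATG {toy.internal_atg_aa_offset} codons "
        f"upstream of the exon"
    )
    print(f"wrote genome.fa, models.gff3, orthology.tsv -> {OUT}")


if __name__ == "__main__":
    main()
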