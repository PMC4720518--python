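#!/usr/bin/env python
"""Design CRISPR sgRNAs against the exons targeted in 03.

Scans each target exon (plus 20 bp of flanking intron so PAMs at the exon
edge are usable) for 23-bp NGG sites on both strands, checks exact genome
uniqueness, and ranks guides (unique first, then 5'-GG protospacers for T7
transcription). Writes results/guides.tsv.
"""

from pathlib import Path

from cronoscan.guide_design import annotate_genome_matches, rank_guides, scan_protospacers
from cronoscan.synthetic_data import SimulationConfig, make_toy_gene

SEED = 1
OUT = Path(__file__).resolve().parent.parent / "results"
TARGET_EXONS = [2, 3, 5, 9, 10, 11]


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    toy = make_toy_gene(SimulationConfig(seed=SEED))
    t, g = toy.transcript, toy.genome

    with open(OUT / "guides.tsv", "w") as fh:
        fh.write("exon\trank\tprotospacer\tpam\tstrand\tposition\tgg_start\tgenome_matches\n")
        for exon_idx in TARGET_EXONS:
            e = t.exon(exon_idx)
            candidates = annotate_genome_matches(
                scan_protospacers(g, toy.contig, e.start - 20, e.end + 20), g
            )
            ranked = rank_guides(candidates)
            for rank, c in enumerate(ranked, 1):
                fh.write(
                    f"e{exon_idx}\t{rank}\t{c.protospacer}\t{c.pam}\t{c.strand}\t"
                    f"{c.position}\t{c.gg_start}\t{c.genome_matches}\n"
                )
            best = ranked[0] if ranked else None
            n_unique = sum(1 for c in candidates if c.genome_matches == 1)
            gg = sum(1 for c in candidates if c.gg_start and c.genome_matches == 1)
            print(
                f"e{exon_idx}: {len(candidates)} sites, {n_unique} unique, "
                f"{gg} unique with 5'-GG; top: {best.protospacer + best.pam if best else '-'} "
                f"({best.strand if best else '-'})"
            )
    print(f"wrote {OUT / 'guides.tsv'}")


if __name__ == "__main__":
    main()
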