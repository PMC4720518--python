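#!/usr/bin/env python
"""Engineer six frameshift lines in the toy gene and classify them.

Mimics the design of stable truncation lines: three N-terminal and three
C-terminal small indels, classified by re-translation, with amino-acid
positions projected onto the synthetic meta-transcript coordinate system
from 01. Writes results/truncations.tsv (a Table-1-style summary).
"""

import csv
from pathlib import Path

from cronoscan.genemodels import OrthologyMap
from cronoscan.synthetic_data import SimulationConfig, make_toy_gene, write_vcf
from cronoscan.truncation_caller import VariantRecord, classify_variant

SEED = 1
BASE = Path(__file__).resolve().parent.parent
OUT = BASE / "results"

# (line name, target exon, inserted/deleted bases) - net length mod 3 != 0
LINES = [
    ("n1", 2, +1),
    ("n2", 3, +2),
    ("n3", 5, -2),
    ("c1", 9, -1),
    ("c2", 10, +2),
    ("c3", 11, -2),
]


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    toy = make_toy_gene(SimulationConfig(seed=SEED))
    t, g = toy.transcript, toy.genome
    orth_path = OUT / "toygene" / "orthology.tsv"
    orthology = OrthologyMap.from_tsv(orth_path) if orth_path.exists() else None

    variants = []
    for name, exon, net in LINES:
        iv = t.coding_interval(exon)
        anchor = (iv[0] + iv[1]) // 2
        ref = g.fetch(toy.contig, anchor, anchor + 1)
        if net > 0:
            alt = ref + "AT"[:net]
        else:
            ref = g.fetch(toy.contig, anchor, anchor + 1 - net)
            alt = ref[0]
        variants.append((name, VariantRecord(toy.contig, anchor + 1, ref, alt, id=name)))

    write_vcf([v for _, v in variants], g, OUT / "toygene" / "variants.vcf")

    rows = []
    for name, v in variants:
        call = classify_variant(v, t, g)
        projected = ""
        if orthology is not None and call.aa_position is not None:
            projected = orthology.project(call.aa_position)
        rows.append(
            {
                "line": name,
                "category": call.category.value,
                "truncating": call.truncating,
                "aa_position": call.aa_position,
                "protein_change": call.protein_change,
                "meta_transcript_aa": projected,
            }
        )

    with open(OUT / "truncations.tsv", "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=rows[0].keys(), delimiter="\t")
        writer.writeheader()
        writer.writerows(rows)

    for r in rows:
        print(
            f"{r['line']}: {r['protein_change']} ({r['category']}, "
            f"meta-transcript aa {r['meta_transcript_aa']})"
        )
    assert all(r["truncating"] for r in rows), "all engineered lines should truncate"
    print(f"wrote {OUT / 'truncations.tsv'}")


if __name__ == "__main__":
    main()
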