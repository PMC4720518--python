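"""Truncation-consequence rules: nonsense, frameshift, splice-site models."""

import numpy as np
import pytest
from Bio.Seq import Seq

from cronoscan.errors import InputError
from cronoscan.genemodels import (
    ExonRecord,
    GenomeSequence,
    TranscriptModel,
    cds_offset_to_genomic,
    exon_phase,
    spliced_cds,
    translate_cds,
)
from cronoscan.synthetic_data import SimulationConfig, make_toy_gene
from cronoscan.truncation_caller import (
    Category,
    VariantRecord,
    acceptor_skip_consequence,
    classify_variant,
    donor_retention_consequence,
    hgvs_p_string,
    normalize_variant,
)


def _bio_translate_to_stop(seq: str) -> tuple[str, bool]:
    """Independent translation oracle: protein prefix up to the first stop."""
    aa = str(Seq(seq[: len(seq) - len(seq) % 3]).translate())
    star = aa.find("*")
    return (aa, False) if star == -1 else (aa[:star], True)


def _expected_hgvs(ref_protein: str, mut_protein: str, stopped: bool) -> str:
    """Re-derive the protein-change string by the stated counting rule."""
    i = 0
    while i < min(len(ref_protein), len(mut_protein)) and ref_protein[i] == mut_protein[i]:
        i += 1
    pos = i + 1
    if i >= len(mut_protein):
        return f"p.{ref_protein[i]}{pos}X" if stopped else f"p.{ref_protein[i]}{pos}fsX?"
    if not stopped:
        return f"p.{ref_protein[i]}{pos}{mut_protein[i]}fsX?"
    k = len(mut_protein) - i + 1
    return f"p.{ref_protein[i]}{pos}{mut_protein[i]}fsX{k}"


class TestHgvsString:
    def test_frameshift_counting_rule(self):
        # ref MKEF..., mutant MKG then stop at the next codon
        assert hgvs_p_string("MKEFLL", "MKG", stopped=True) == "p.E3GfsX2"

    def test_pure_nonsense(self):
        assert hgvs_p_string("MABCDESQR", "MABCDE", stopped=True) == "p.S7X"

    def test_undetermined_stop(self):
        assert hgvs_p_string("MKEFLL", "MKGAA", stopped=False).endswith("fsX?")

    def test_identical_rejected(self):
        with pytest.raises(InputError):
            hgvs_p_string("MKE", "MKE")


class TestNormalization:
    def test_anchor_insertion(self):
        pos, ref, alt = normalize_variant(VariantRecord("c", 10, "A", "AT"))
        assert (pos, ref, alt) == (10, "", "T")

    def test_anchor_deletion(self):
        pos, ref, alt = normalize_variant(VariantRecord("c", 10, "AT", "A"))
        assert (pos, ref, alt) == (10, "T", "")

    def test_snv_untouched(self):
        assert normalize_variant(VariantRecord("c", 5, "G", "T")) == (4, "G", "T")


class TestClassifyCoding:
    def _stop_making_snv(self, toy):
        cds = spliced_cds(toy.transcript, toy.genome)
        for aa_i in range(2, 60):
            off = (aa_i - 1) * 3
            codon = cds[off : off + 3]
            for j in range(3):
                for b in "ACGT":
                    if b == codon[j]:
                        continue
                    if codon[:j] + b + codon[j + 1 :] in ("TAA", "TAG", "TGA"):
                        return aa_i, off + j, b
        raise AssertionError("no stop-making SNV found in toy CDS")

    def test_nonsense_snv(self, toy):
        aa_i, cds_off, alt = self._stop_making_snv(toy)
        gpos = cds_offset_to_genomic(toy.transcript, cds_off)
        ref = toy.genome.fetch(toy.contig, gpos, gpos + 1)
        call = classify_variant(VariantRecord(toy.contig, gpos + 1, ref, alt), toy.transcript, toy.genome)
        assert call.category is Category.NONSENSE and call.truncating
        assert call.aa_position == aa_i
        assert call.protein_change == f"p.{translate_cds(spliced_cds(toy.transcript, toy.genome))[0][aa_i-1]}{aa_i}X"

    def test_one_base_insertion_matches_retranslation_oracle(self, toy):
        t, g = toy.transcript, toy.genome
        cds = spliced_cds(t, g)
        cds_off = 10  # inside codon 4
        gpos = cds_offset_to_genomic(t, cds_off)
        ref = g.fetch(toy.contig, gpos, gpos + 1)
        call = classify_variant(VariantRecord(toy.contig, gpos + 1, ref, ref + "T"), t, g)
        assert call.category is Category.FRAMESHIFT and call.truncating
        mutant_cds = cds[: cds_off + 1] + "T" + cds[cds_off + 1 :]
        ref_protein, _ = _bio_translate_to_stop(cds)
        mut_protein, stopped = _bio_translate_to_stop(mutant_cds)
        assert call.protein_change == _expected_hgvs(ref_protein, mut_protein, stopped)

    def test_inframe_deletion_is_other(self, toy):
        # anchor on the last base of codon 4, deleting codon 5 whole, so
        # the reading of every other codon is untouched
        t, g = toy.transcript, toy.genome
        gpos = cds_offset_to_genomic(t, 11)
        ref = g.fetch(toy.contig, gpos, gpos + 4)
        call = classify_variant(VariantRecord(toy.contig, gpos + 1, ref, ref[0]), t, g)
        assert call.category is Category.OTHER and not call.truncating

    def test_ref_mismatch_rejected(self, toy):
        t, g = toy.transcript, toy.genome
        gpos = cds_offset_to_genomic(t, 10)
        ref = g.fetch(toy.contig, gpos, gpos + 1)
        wrong = "A" if ref != "A" else "C"
        with pytest.raises(InputError):
            classify_variant(VariantRecord(toy.contig, gpos + 1, wrong, "T"), t, g)

    def test_random_indels_match_oracle(self, toy):
        """FRAMESHIFT verdict iff net length mod 3 != 0; protein change
        equals the independent re-translation oracle's description."""
        t, g = toy.transcript, toy.genome
        cds = spliced_cds(t, g)
        ref_protein, _ = _bio_translate_to_stop(cds)
        rng = np.random.default_rng(42)
        # keep edits inside single-exon coding stretches
        n_checked = 0
        while n_checked < 1000:
            exon_idx = int(rng.integers(1, t.n_exons + 1))
            iv = t.coding_interval(exon_idx)
            if iv is None or iv[1] - iv[0] < 24:
                continue
            if exon_idx == t.n_exons:
                iv = (iv[0], iv[1] - 12)  # keep edits clear of the stop codon
            is_insertion = bool(rng.random() < 0.5)
            if is_insertion:
                gpos = int(rng.integers(iv[0], iv[1] - 1))
                ins = "".join(rng.choice(list("ACGT"), size=int(rng.integers(1, 5))))
                ref = g.fetch(toy.contig, gpos, gpos + 1)
                alt = ref + ins
            else:
                del_len = int(rng.integers(1, 5))
                gpos = int(rng.integers(iv[0], iv[1] - del_len - 1))
                ref = g.fetch(toy.contig, gpos, gpos + 1 + del_len)
                alt = ref[0]
            variant = VariantRecord(toy.contig, gpos + 1, ref, alt)
            call = classify_variant(variant, t, g)
            net = len(alt) - len(ref)
            # oracle: edit the spliced CDS directly and re-translate
            o_start = None
            from cronoscan.genemodels import genomic_to_cds_offset
            o_anchor = genomic_to_cds_offset(t, gpos)
            if net > 0:
                mutant_cds = cds[: o_anchor + 1] + alt[1:] + cds[o_anchor + 1 :]
            else:
                mutant_cds = cds[: o_anchor + 1] + cds[o_anchor + 1 - net :]
            mut_protein, stopped = _bio_translate_to_stop(mutant_cds)
            if net % 3 != 0:
                assert call.category is Category.FRAMESHIFT, (variant, call)
                assert call.truncating
                assert call.protein_change == _expected_hgvs(ref_protein, mut_protein, stopped)
            else:
                assert call.category in (Category.OTHER, Category.NONSENSE)
                premature = stopped and len(mut_protein) < len(ref_protein) and \
                    mut_protein == ref_protein[: len(mut_protein)]
                assert call.truncating == premature
            n_checked += 1


class TestAcceptorRule:
    def test_inframe_exon_length(self):
        # 99 coding bases -> in-frame skip, non-truncating
        g = GenomeSequence({"c": "ATG" + "GCT" * 200})
        t = TranscriptModel(
            "t", "+",
            [ExonRecord("c", 0, 30, 1), ExonRecord("c", 60, 159, 2), ExonRecord("c", 200, 400, 3)],
            0, 399,
        )
        call = acceptor_skip_consequence(t, 2)
        assert call.category is Category.ACCEPTOR_SKIP_INFRAME and not call.truncating

    def test_frameshifting_exon_length(self):
        g = GenomeSequence({"c": "ATG" + "GCT" * 200})
        t = TranscriptModel(
            "t", "+",
            [ExonRecord("c", 0, 30, 1), ExonRecord("c", 60, 160, 2), ExonRecord("c", 200, 400, 3)],
            0, 399,
        )
        call = acceptor_skip_consequence(t, 2)  # 100 coding nt
        assert call.category is Category.ACCEPTOR_SKIP_FRAMESHIFT and call.truncating

    def test_terminal_exon_rejected(self, toy):
        with pytest.raises(InputError):
            acceptor_skip_consequence(toy.transcript, 1)
        with pytest.raises(InputError):
            acceptor_skip_consequence(toy.transcript, toy.transcript.n_exons)

    def test_verdict_equals_phase_recomputation_oracle(self):
        """Skipping changes the downstream exon's phase iff L mod 3 != 0."""
        for seed in range(30):
            toy = make_toy_gene(SimulationConfig(seed=seed))
            t = toy.transcript
            for k in range(2, t.n_exons):
                call = acceptor_skip_consequence(t, k)
                # oracle: rebuild the model without exon k, compare the
                # downstream exon's phase before and after the skip
                kept = [e for e in t.exons if e.index != k]
                rebuilt = TranscriptModel(
                    "skip", t.strand,
                    [ExonRecord(e.contig, e.start, e.end, i) for i, e in enumerate(kept, 1)],
                    t.cds_start, t.cds_end,
                )
                phase_before = exon_phase(t, k + 1)
                phase_after = exon_phase(rebuilt, k)  # same exon, re-indexed
                unchanged = phase_before == phase_after
                assert (call.category is Category.ACCEPTOR_SKIP_INFRAME) == unchanged


def _intron_model(intron_seq: str, exon2_cds: str = "GCCGAAGATTAA"):
    """Two-exon plus-strand model with a fully controlled intron."""
    exon1 = "ATGGCCAAG"  # 3 codons, phase 0 at the junction
    genome = GenomeSequence({"c": "CC" + exon1 + intron_seq + exon2_cds + "CC"})
    s1, e1 = 2, 2 + len(exon1)
    s2 = e1 + len(intron_seq)
    e2 = s2 + len(exon2_cds)
    t = TranscriptModel(
        "im", "+",
        [ExonRecord("c", s1, e1, 1), ExonRecord("c", s2, e2, 2)],
        s1, e2,
    )
    return genome, t


class TestDonorRule:
    def test_inframe_stop_in_intron_is_ptc(self):
        genome, t = _intron_model("GTTTAAAAG")  # TAA in frame 0 after GTT
        call = donor_retention_consequence(t, 1, genome)
        assert call.category is Category.DONOR_RETENTION_PTC and call.truncating

    def test_stopfree_inframe_intron_reads_through(self):
        genome, t = _intron_model("GTCCCCCAG")  # 9 nt, codons GTC CCC CAG
        call = donor_retention_consequence(t, 1, genome)
        assert call.category is Category.DONOR_RETENTION_READTHROUGH
        assert not call.truncating
        assert "3 residues" in call.detail

    def test_frameshifting_intron_hits_downstream_stop(self):
        # 10-nt stop-free intron shifts frame; the shifted frame reads
        # GCCGAAGATTAA as CGC CGA AGA TTA A... and must find a stop we plant
        genome, t = _intron_model("GTCCCCCCAG", exon2_cds="GCTAAGGATTGATTTTAA")
        seq = "ATGGCCAAG" + "GTCCCCCCAG" + "GCTAAGGATTGATTTTAA"
        aa = str(Seq(seq[: len(seq) - len(seq) % 3]).translate())
        assert "*" in aa  # construction check: shifted frame does stop
        call = donor_retention_consequence(t, 1, genome)
        assert call.category is Category.DONOR_RETENTION_PTC and call.truncating

    def test_readthrough_soundness_on_toy_models(self):
        """READTHROUGH implies full-length protein with an internal insertion."""
        for seed in range(5):
            toy = make_toy_gene(SimulationConfig(seed=seed))
            t, g = toy.transcript, toy.genome
            ref_protein, _, _ = translate_cds(spliced_cds(t, g))
            for k, istart, iend in t.introns():
                call = donor_retention_consequence(t, k, g)
                if call.category is not Category.DONOR_RETENTION_READTHROUGH:
                    continue
                intron = g.fetch(toy.contig, istart, iend)
                assert len(intron) % 3 == 0


class TestSpliceDispatch:
    def test_donor_site_variant_takes_precedence(self, toy):
        t, g = toy.transcript, toy.genome
        k, s, e = t.introns()[2]
        ref = g.fetch(toy.contig, s, s + 1)
        alt = "A" if ref != "A" else "C"
        call = classify_variant(VariantRecord(toy.contig, s + 1, ref, alt), t, g)
        assert call.category in (
            Category.DONOR_RETENTION_PTC,
            Category.DONOR_RETENTION_READTHROUGH,
        )
        assert "precedence" in call.detail

    def test_acceptor_site_variant_maps_to_downstream_exon_skip(self, toy):
        t, g = toy.transcript, toy.genome
        k, s, e = t.introns()[2]
        ref = g.fetch(toy.contig, e - 1, e)
        alt = "C" if ref != "C" else "T"
        call = classify_variant(VariantRecord(toy.contig, e, ref, alt), t, g)
        expected = acceptor_skip_consequence(t, k + 1)
        assert call.category is expected.category

    def test_deep_intronic_is_other(self, toy):
        t, g = toy.transcript, toy.genome
        _, s, e = t.introns()[0]
        mid = (s + e) // 2
        ref = g.fetch(toy.contig, mid, mid + 1)
        alt = "A" if ref != "A" else "C"
        call = classify_variant(VariantRecord(toy.contig, mid + 1, ref, alt), t, g)
        assert call.category is Category.OTHER and not call.truncating
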