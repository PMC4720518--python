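"""Internal-promoter detection: coverage tracks, fold scoring, peaks, ATG."""

import numpy as np
import pytest
from cronoscan.errors import InputError, ParseError
from cronoscan.genemodels import mirror_transcript
from cronoscan.promoter_scan import (
    CoverageTrack,
    PeakSet,
    annotate_with_peaks,
    call_promoter_candidates,
    find_internal_start,
    read_bedgraph,
    score_intronic_windows,
    write_bedgraph,
)
from cronoscan.synthetic_data import (
    SimulationConfig,
    make_toy_gene,
    simulate_coverage_with_promoter,
)


class TestBedgraphIO:
    def test_three_runs(self, tmp_path):
        p = tmp_path / "c.bedgraph"
        p.write_text("chr1\t0\t10\t5\nchr1\t10\t20\t7\nchr1\t30\t40\t2\n")
        track = read_bedgraph(p)
        assert len(track.starts) == 3
        assert track.mean_depth(0, 10) == 5.0

    def test_empty_file(self, tmp_path):
        p = tmp_path / "c.bedgraph"
        p.write_text("")
        track = read_bedgraph(p)
        assert track.mean_depth(0, 100) == 0.0

    def test_gap_query_includes_zeros(self, tmp_path):
        p = tmp_path / "c.bedgraph"
        p.write_text("chr1\t0\t10\t6\nchr1\t20\t30\t6\n")
        track = read_bedgraph(p)
        # per-base oracle over [0, 30): 20 bases at 6, 10 at 0
        dense = np.zeros(30)
        dense[0:10] = 6
        dense[20:30] = 6
        assert track.mean_depth(0, 30) == pytest.approx(dense.mean())
        assert np.array_equal(track.values(0, 30), dense)

    def test_overlap_rejected(self, tmp_path):
        p = tmp_path / "c.bedgraph"
        p.write_text("chr1\t0\t10\t5\nchr1\t5\t20\t7\n")
        with pytest.raises(ParseError):
            read_bedgraph(p)

    def test_roundtrip(self, tmp_path, toy, toy_config):
        track = simulate_coverage_with_promoter(toy_config, toy)
        p = tmp_path / "c.bedgraph"
        write_bedgraph(track, p)
        back = read_bedgraph(p)
        span = (int(track.starts[0]), int(track.ends[-1]))
        assert np.array_equal(back.values(*span), track.values(*span))


class TestWindowScoring:
    def test_flat_track_none_called(self, toy):
        t = toy.transcript
        lo = min(e.start for e in t.exons)
        hi = max(e.end for e in t.exons)
        track = CoverageTrack(toy.contig, [(lo, hi, 10.0)])
        candidates = score_intronic_windows(track, t)
        assert all(c.fold_score == pytest.approx(10 / 11) for c in candidates)
        assert call_promoter_candidates(candidates, 5.0) == []

    def test_constructed_signal_fold(self, toy):
        t = toy.transcript
        lo = min(e.start for e in t.exons)
        hi = max(e.end for e in t.exons)
        pe = t.exon(toy.promoter_exon_index)
        window = (pe.start - 500, pe.start)
        track = CoverageTrack(
            toy.contig,
            [(lo, window[0], 10.0), (window[0], window[1], 100.0), (window[1], hi, 10.0)],
        )
        candidates = score_intronic_windows(track, t)
        by_exon = {c.exon_index: c for c in candidates}
        assert by_exon[toy.promoter_exon_index].fold_score == pytest.approx(100 / 11)
        others = [c.fold_score for c in candidates if c.exon_index != toy.promoter_exon_index]
        assert max(others) < 2.0

    def test_strand_symmetry(self, toy, toy_config):
        track = simulate_coverage_with_promoter(toy_config, toy)
        called_plus = call_promoter_candidates(
            score_intronic_windows(track, toy.transcript)
        )
        n = toy.genome.contig_length(toy.contig)
        t2 = mirror_transcript(toy.transcript, n)
        dense = track.values(0, n)
        mirrored_track = CoverageTrack.from_per_base(toy.contig, 0, dense[::-1])
        called_minus = call_promoter_candidates(
            score_intronic_windows(mirrored_track, t2)
        )
        assert [c.exon_index for c in called_plus] == [c.exon_index for c in called_minus]

    def test_short_intron_truncates_window(self):
        from cronoscan.genemodels import ExonRecord, TranscriptModel

        t = TranscriptModel(
            "t", "+",
            [
                ExonRecord("c", 0, 100, 1),
                ExonRecord("c", 150, 250, 2),
                ExonRecord("c", 300, 400, 3),
            ],
            0, 399,
        )
        track = CoverageTrack("c", [(0, 400, 4.0)])
        candidates = score_intronic_windows(track, t, window_size=500)
        assert all(c.truncated_window for c in candidates)
        assert candidates[0].window_end - candidates[0].window_start == 50


class TestCalling:
    def test_empty_input(self):
        assert call_promoter_candidates([], 5.0) == []

    def test_single_candidate_called(self, toy):
        t = toy.transcript
        lo = min(e.start for e in t.exons)
        hi = max(e.end for e in t.exons)
        pe = t.exon(toy.promoter_exon_index)
        track = CoverageTrack(
            toy.contig,
            [(lo, pe.start - 500, 1.0), (pe.start - 500, pe.start, 100.0), (pe.start, hi, 1.0)],
        )
        called = call_promoter_candidates(score_intronic_windows(track, t), 5.0)
        assert [c.exon_index for c in called] == [toy.promoter_exon_index]
        assert called[0].called

    def test_threshold_sweep_monotone(self, toy, toy_config):
        track = simulate_coverage_with_promoter(toy_config, toy)
        candidates = score_intronic_windows(track, toy.transcript)
        previous = None
        for thr in (1.5, 2.0, 5.0, 8.0, 20.0):
            called = {c.exon_index for c in call_promoter_candidates(candidates, thr)}
            if previous is not None:
                assert called <= previous
            previous = called

    def test_threshold_must_exceed_one(self):
        with pytest.raises(InputError):
            call_promoter_candidates([], 1.0)


class TestPeakAnnotation:
    def _candidate(self, start, end):
        from cronoscan.promoter_scan import PromoterCandidate

        return PromoterCandidate(2, "c", start, end, 0.0, 0.0, 0.0)

    def test_window_inside_peak(self):
        peaks = PeakSet([("c", 0, 1000)])
        (c,) = annotate_with_peaks([self._candidate(100, 200)], peaks, "dnase")
        assert c.peak_overlap["dnase"]

    def test_adjacent_half_open_no_overlap(self):
        peaks = PeakSet([("c", 200, 300)])
        (c,) = annotate_with_peaks([self._candidate(100, 200)], peaks, "h3k4me3")
        assert not c.peak_overlap["h3k4me3"]

    def test_random_agrees_with_brute_force(self):
        rng = np.random.default_rng(8)
        peaks = []
        for _ in range(40):
            s = int(rng.integers(0, 5000))
            peaks.append(("c", s, s + int(rng.integers(1, 300))))
        ps = PeakSet(peaks)
        for _ in range(100):
            s = int(rng.integers(0, 5000))
            e = s + int(rng.integers(1, 400))
            (c,) = annotate_with_peaks([self._candidate(s, e)], ps, "p")
            brute = any(ps_s < e and s < ps_e for _, ps_s, ps_e in peaks)
            assert c.peak_overlap["p"] == brute

    def test_bed_parsing(self, tmp_path):
        p = tmp_path / "peaks.bed"
        p.write_text("track name=x\nc\t10\t50\npeakA\nc\t100\t200\tname\t5\n")
        with pytest.raises(ParseError):
            PeakSet.from_bed(p)
        p.write_text("c\t10\t50\nc\t100\t200\tname\t5\n")
        assert len(PeakSet.from_bed(p).intervals) == 2


class TestInternalStart:
    def test_planted_atg_found_at_expected_offset(self, toy):
        hit = find_internal_start(
            toy.genome, toy.transcript, toy.promoter_exon_index, toy.tss_position
        )
        assert hit is not None and hit.in_frame
        assert hit.atg_position == toy.internal_atg_position
        assert hit.aa_offset == toy.internal_atg_aa_offset == 7

    def test_out_of_frame_atg_skipped(self):
        from cronoscan.genemodels import ExonRecord, GenomeSequence, TranscriptModel

        # intron tail: out-of-frame ATG at d=20, in-frame ATG at d=9
        exon1 = "ATGGCC"   # phase 0 at exon 2
        tail = "CCCC" + "ATG" + "CCCCATGCCCCAG"  # len 20
        intron = "GT" + "C" * 10 + tail
        exon2 = "GAAGATTAA"
        seq = "CC" + exon1 + intron + exon2 + "CC"
        g = GenomeSequence({"c": seq})
        s1 = 2
        e1 = s1 + len(exon1)
        s2 = e1 + len(intron)
        t = TranscriptModel(
            "t", "+",
            [ExonRecord("c", s1, e1, 1), ExonRecord("c", s2, e2 := s2 + len(exon2), 2)],
            s1, e2,
        )
        tss = s2 - len(tail)
        hit = find_internal_start(g, t, 2, tss)
        assert hit is not None
        d = s2 - hit.atg_position
        assert d % 3 == 0  # phase-0 exon: in-frame hit only
        assert d == 9

    def test_no_inframe_atg_returns_none(self, toy):
        # scan a stretch guaranteed pyrimidine-only: just before the ATG
        hit = find_internal_start(
            toy.genome,
            toy.transcript,
            toy.promoter_exon_index,
            toy.internal_atg_position + 3,  # start scanning after the ATG
        )
        assert hit is None

    def test_tss_downstream_of_exon_rejected(self, toy):
        pe = toy.transcript.exon(toy.promoter_exon_index)
        with pytest.raises(InputError):
            find_internal_start(
                toy.genome, toy.transcript, toy.promoter_exon_index, pe.start + 5
            )


class TestDetectorOperatingCharacteristics:
    def test_sensitivity_fold_ten(self):
        """A fold-10 embedded signal is called at the target exon and only
        there, across 100 seeds."""
        hits = 0
        for seed in range(100):
            cfg = SimulationConfig(seed=seed, promoter_fold=10.0)
            toy = make_toy_gene(SimulationConfig(seed=1))  # fixed gene
            track = simulate_coverage_with_promoter(cfg, toy)
            called = call_promoter_candidates(
                score_intronic_windows(track, toy.transcript)
            )
            if [c.exon_index for c in called] == [toy.promoter_exon_index]:
                hits += 1
        assert hits == 100

    def test_specificity_flat_tracks(self, toy):
        t = toy.transcript
        lo = min(e.start for e in t.exons)
        hi = max(e.end for e in t.exons)
        for depth in (1.0, 10.0, 100.0):
            track = CoverageTrack(toy.contig, [(lo, hi, depth)])
            candidates = score_intronic_windows(track, t)
            for thr in (1.5, 2.0, 5.0):
                assert call_promoter_candidates(candidates, thr) == []

    def test_fold_one_rarely_called(self):
        false_calls = 0
        toy = make_toy_gene(SimulationConfig(seed=1))
        for seed in range(40):
            cfg = SimulationConfig(seed=seed, promoter_fold=1.0)
            track = simulate_coverage_with_promoter(cfg, toy)
            called = call_promoter_candidates(
                score_intronic_windows(track, toy.transcript)
            )
            false_calls += bool(called)
        assert false_calls <= 2  # >= 95% of seeds clean
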