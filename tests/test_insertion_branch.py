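"""SV branch: signature scanning, clustering, VCF ingestion, realignment, cascade."""

import numpy as np
import pytest
from Bio import Align

from numtcall.core import PipelineConfig, ScoringScheme, revcomp
from numtcall.insertion_branch import (
    AlignmentHit,
    InsertionCall,
    InsertionSignature,
    align_to_mt,
    call_from_insertions,
    cluster_signatures,
    filter_merge_hits,
    load_vcf_insertions,
    scan_insertion_signatures,
)

from conftest import random_dna


class TestScanSignatures:
    def test_insertion_position_from_cigar_prefix(self, record_factory, config):
        rec = record_factory("r1", "chr1", 10_001, "2000M500I2000M")
        sigs = scan_insertion_signatures([rec], config)
        assert len(sigs) == 1
        assert (sigs[0].chrom, sigs[0].pos, len(sigs[0].insert_seq)) == ("chr1", 12_000, 500)

    def test_insertions_below_min_sv_len_ignored(self, record_factory, config):
        rec = record_factory("r1", "chr1", 10_001, "2000M23I2000M")
        assert scan_insertion_signatures([rec], config) == []
        rec24 = record_factory("r1", "chr1", 10_001, "2000M24I2000M")
        assert len(scan_insertion_signatures([rec24], config)) == 1

    def test_low_mapq_and_non_primary_records_ignored(self, record_factory, config):
        low = record_factory("r1", "chr1", 10_001, "100M30I100M", mapq=0)
        supp = record_factory("r2", "chr1", 10_001, "100M30I100M", flag=2048)
        assert scan_insertion_signatures([low, supp], config) == []

    def test_deletions_shift_insertion_position(self, record_factory, config):
        rec = record_factory("r1", "chr1", 1_001, "100M5D100M30I50M")
        sigs = scan_insertion_signatures([rec], config)
        assert sigs[0].pos == 1_205  # 100M + 5D + 100M consumed


def _sig(name, pos, length, chrom="chr1"):
    return InsertionSignature(name, chrom, pos, "A" * length, 60)


class TestClusterSignatures:
    def test_four_supporting_reads_retained(self, config):
        sigs = [_sig(f"r{i}", 10_000 + d, 300) for i, d in enumerate((-20, -5, 3, 20))]
        calls = cluster_signatures(sigs, config)
        assert len(calls) == 1 and calls[0].support == 4

    def test_three_supporting_reads_discarded(self, config):
        sigs = [_sig(f"r{i}", 10_000 + i, 300) for i in range(3)]
        assert cluster_signatures(sigs, config) == []

    def test_duplicate_read_names_count_once(self, config):
        sigs = [_sig("r1", 10_000, 300), _sig("r1", 10_001, 300)] + [
            _sig(f"r{i}", 10_002 + i, 300) for i in range(2, 4)
        ]
        assert cluster_signatures(sigs, config) == []  # 3 distinct reads only

    def test_distant_groups_stay_separate(self, config):
        sigs = [_sig(f"a{i}", 10_000 + i, 300) for i in range(4)] + [
            _sig(f"b{i}", 15_000 + i, 200) for i in range(4)
        ]
        calls = cluster_signatures(sigs, config)
        assert len(calls) == 2

    def test_representative_is_median_length_tie_longer(self, config):
        lengths = [100, 200, 300, 400]
        sigs = [_sig(f"r{i}", 10_000 + i, ln) for i, ln in enumerate(lengths)]
        calls = cluster_signatures(sigs, config)
        assert len(calls[0].insert_seq) == 300  # upper median

    def test_breakpoint_is_median_position(self, config):
        sigs = [_sig(f"r{i}", p, 100) for i, p in enumerate((9_990, 10_000, 10_004, 10_030))]
        calls = cluster_signatures(sigs, config)
        assert calls[0].pos == 10_000


VCF_TEMPLATE = """##fileformat=VCFv4.2
##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">
##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="SV length">
##INFO=<ID=SUPPORT,Number=1,Type=Integer,Description="Supporting reads">
##FILTER=<ID=q5,Description="low qual">
##contig=<ID=chr1,length=1000000>
##contig=<ID=chr2,length=1000000>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
{rows}
"""


class TestLoadVcf:
    def _write(self, tmp_path, rows):
        path = tmp_path / "calls.vcf"
        path.write_text(VCF_TEMPLATE.format(rows="\n".join(rows)))
        return str(path)

    def test_passing_insertion_loaded(self, tmp_path, config):
        alt = "A" + "ACGT" * 75
        path = self._write(
            tmp_path,
            [f"chr2\t5000\tins1\tA\t{alt}\t60\tPASS\tSVTYPE=INS;SUPPORT=10"],
        )
        calls = load_vcf_insertions(path, config)
        assert len(calls) == 1
        assert (calls[0].chrom, calls[0].pos, calls[0].support) == ("chr2", 5_000, 10)
        assert calls[0].insert_seq == "ACGT" * 75  # anchor base stripped

    def test_low_support_and_failing_filter_excluded(self, tmp_path, config):
        alt = "A" + "ACGT" * 75
        path = self._write(
            tmp_path,
            [
                f"chr1\t1000\ta\tA\t{alt}\t60\tPASS\tSVTYPE=INS;SUPPORT=3",
                f"chr1\t2000\tb\tA\t{alt}\t60\tq5\tSVTYPE=INS;SUPPORT=10",
            ],
        )
        assert load_vcf_insertions(path, config) == []

    def test_non_insertion_and_symbolic_records_skipped(self, tmp_path, config):
        path = self._write(
            tmp_path,
            [
                "chr1\t1000\td\tACGTA\tA\t60\tPASS\tSVTYPE=DEL;SUPPORT=10",
                "chr1\t3000\ts\tA\t<INS>\t60\tPASS\tSVTYPE=INS;SUPPORT=10",
            ],
        )
        assert load_vcf_insertions(path, config) == []


def _oracle_score(q: str, t: str) -> float:
    """Best local alignment score by Biopython's exhaustive aligner, both strands."""
    al = Align.PairwiseAligner()
    al.mode = "local"
    al.match_score = 2
    al.mismatch_score = -3
    al.open_gap_score = -7
    al.extend_gap_score = -2
    return max(al.score(t, q), al.score(t, revcomp(q)))


def _oracle_spans(q: str, t: str):
    al = Align.PairwiseAligner()
    al.mode = "local"
    al.match_score = 2
    al.mismatch_score = -3
    al.open_gap_score = -7
    al.extend_gap_score = -2
    aln = al.align(t, q)[0]
    tgt, qry = aln.aligned
    return (
        aln.score,
        (qry[0][0] + 1, qry[-1][1]),
        (tgt[0][0] + 1, tgt[-1][1]),
    )


class TestAlignToMT:
    def test_exact_substring_is_top_hit(self, mito):
        ins = mito.sequence[100:200]
        hits = align_to_mt(ins, mito)
        assert len(hits) == 1
        h = hits[0]
        assert (h.q_start, h.q_end, h.s_start, h.s_end) == (1, 100, 101, 200)
        assert h.strand == "+" and h.pct_identity == 100.0 and h.evalue < 1e-3

    def test_reverse_complement_insert_found_on_minus_strand(self, mito):
        ins = revcomp(mito.sequence[1_000:1_100])
        hits = align_to_mt(ins, mito)
        assert len(hits) == 1
        h = hits[0]
        assert h.strand == "-" and (h.q_start, h.q_end) == (1, 100)
        assert (h.s_start, h.s_end) == (1_001, 1_100)

    def test_random_insert_has_no_significant_hit(self, mito):
        rnd = random_dna(100, 999)
        assert align_to_mt(rnd, mito) == []
        # independent check: the exhaustive optimum itself is not significant
        best = _oracle_score(rnd, mito.doubled_sequence)
        ev = ScoringScheme().evalue(best, 100, 2 * mito.length_bp)
        assert ev > 1e-3

    def test_control_region_insert_spans_the_origin_on_doubled_axis(self, mito):
        L = mito.length_bp
        ins = mito.sequence[L - 100 :] + mito.sequence[:100]
        hits = align_to_mt(ins, mito)
        assert len(hits) == 1
        assert (hits[0].s_start, hits[0].s_end) == (L - 99, L + 100)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_agrees_with_exhaustive_smith_waterman_oracle(self, small_mito, seed):
        rng = np.random.default_rng(seed)
        start = int(rng.integers(0, small_mito.length_bp - 160))
        ins = list(small_mito.sequence[start : start + 150])
        for p in rng.choice(150, 3, replace=False):  # ~2% substitutions
            ins[p] = "ACGT"[int(rng.integers(0, 4))]
        ins = "".join(ins)
        hits = align_to_mt(ins, small_mito)
        assert hits, "noisy substring must produce a hit"
        h = hits[0]
        score, (qs, qe), (ss, se) = _oracle_spans(ins, small_mito.doubled_sequence)
        assert h.score == score
        assert abs(h.q_start - qs) <= 2 and abs(h.q_end - qe) <= 2
        assert abs(h.s_start - ss) <= 2 and abs(h.s_end - se) <= 2

    def test_empty_insert_rejected(self, mito):
        with pytest.raises(ValueError):
            align_to_mt("", mito)


def _hit(qs, qe, ss, se, strand="+", evalue=1e-10):
    return AlignmentHit(qs, qe, ss, se, strand, 2 * (qe - qs + 1), evalue, 100.0)


class TestFilterMergeHits:
    def test_small_gaps_on_both_axes_merge(self, config):
        hits = [_hit(1, 50, 100, 149), _hit(55, 104, 154, 203)]
        segs, qcov = filter_merge_hits(hits, 104, config, 16_569)
        assert len(segs) == 1
        assert segs[0].q_span == (1, 104)
        assert (segs[0].interval.mt_start, segs[0].interval.mt_end) == (100, 203)
        # coverage counts the union of hit spans, not the merged segment span
        assert qcov == pytest.approx(100 * 100 / 104)

    def test_large_subject_gap_keeps_two_segments(self, config):
        # two fragments totalling 290 bp, 1,965 bp apart on the MT genome
        hits = [_hit(1, 145, 5_000, 5_144), _hit(146, 290, 7_110, 7_254)]
        segs, qcov = filter_merge_hits(hits, 290, config, 16_569)
        assert len(segs) == 2
        assert qcov == 100.0
        assert sum(s.length(16_569) for s in segs) == 290

    def test_query_coverage_boundary_at_exactly_70_percent(self, config):
        segs, qcov = filter_merge_hits([_hit(31, 100, 1_000, 1_069)], 100, config, 16_569)
        assert qcov == 70.0
        assert qcov >= config.min_query_cov_pct

    def test_evalue_filter_applied_before_merge(self, config):
        hits = [_hit(1, 50, 100, 149), _hit(55, 104, 154, 203, evalue=1.0)]
        segs, qcov = filter_merge_hits(hits, 104, config, 16_569)
        assert len(segs) == 1 and segs[0].q_span == (1, 50)
        assert qcov == pytest.approx(100 * 50 / 104)

    def test_opposite_strands_never_merge(self, config):
        hits = [_hit(1, 50, 100, 149, "+"), _hit(55, 104, 154, 203, "-")]
        segs, _ = filter_merge_hits(hits, 104, config, 16_569)
        assert len(segs) == 2

    def test_overlapping_query_spans_not_double_counted(self, config):
        hits = [_hit(1, 60, 100, 159), _hit(41, 100, 5_000, 5_059)]
        _, qcov = filter_merge_hits(hits, 100, config, 16_569)
        assert qcov == 100.0

    def test_looser_evalue_never_fewer_segments(self, config):
        hits = [_hit(1, 50, 100, 149), _hit(60, 104, 5_000, 5_044, evalue=5e-3)]
        strict, _ = filter_merge_hits(hits, 104, config, 16_569)
        loose, _ = filter_merge_hits(hits, 104, config.updated(evalue_max=1e-2), 16_569)
        assert len(loose) >= len(strict)


class TestCallFromInsertions:
    def test_mt_derived_insertion_called(self, mito, config):
        ins = InsertionCall("chr1", 10_000, mito.sequence[2_000:2_500], 8, set())
        calls = call_from_insertions([ins], mito, config)
        assert len(calls) == 1
        call = calls[0]
        assert call.branch == "sv" and call.total_mt_len == 500
        assert (call.segments[0].interval.mt_start, call.segments[0].interval.mt_end) == (
            2_001,
            2_500,
        )

    def test_random_insertion_not_called(self, mito, config):
        ins = InsertionCall("chr1", 10_000, random_dna(100, 999), 8, set())
        assert call_from_insertions([ins], mito, config) == []

    def test_control_region_insertion_called_as_wrapping_segment(self, mito, config):
        L = mito.length_bp
        seq = mito.sequence[L - 100 :] + mito.sequence[:100]
        ins = InsertionCall("chr1", 10_000, seq, 8, set())
        calls = call_from_insertions([ins], mito, config)
        assert len(calls) == 1
        seg = calls[0].segments[0].interval
        assert seg.wraps and calls[0].total_mt_len == 200
        assert (seg.mt_start, seg.mt_end) == (L - 99, 100)
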