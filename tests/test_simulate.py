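"""Synthetic genomes, truth events, reads and SAM fixtures."""

import numpy as np
import pysam
import pytest

from numtcall.core import CircularInterval, MitoReference, revcomp
from numtcall.simulate import (
    SimConfig,
    TruthEvent,
    emit_alignments,
    event_sequence,
    implant,
    make_genome,
    read_truth,
    sample_events,
    simulate_reads,
    write_truth,
)


@pytest.fixture(scope="module")
def tiny_cfg():
    return SimConfig(
        n_chroms=1, chrom_len_bp=350_000, n_events=4, seed=11,
        frac_wrapping=0.25, frac_complex=0.25,
    )


class TestMakeGenome:
    def test_contig_lengths_and_determinism(self, tiny_cfg):
        g1 = make_genome(tiny_cfg)
        g2 = make_genome(tiny_cfg)
        assert g1 == g2
        assert len(g1["chr1"]) == 350_000
        assert len(g1["chrM"]) == 16_569

    def test_different_seeds_differ(self, tiny_cfg):
        g1 = make_genome(tiny_cfg)
        g2 = make_genome(SimConfig(**{**tiny_cfg.__dict__, "seed": 12}))
        assert g1["chr1"] != g2["chr1"]


class TestSampleEvents:
    def test_sizes_fractions_and_spacing(self, tiny_cfg):
        mito = MitoReference("chrM", make_genome(tiny_cfg)["chrM"])
        events = sample_events(tiny_cfg, mito)
        assert len(events) == 4
        assert all(30 <= e.total_len <= 16_569 for e in events)
        assert sum(1 for e in events if any(s.wraps for s in e.segments)) >= 1
        assert sum(1 for e in events if len(e.segments) > 1) >= 1
        pos = sorted(e.nuc_pos for e in events)
        assert all(b - a >= 50_000 for a, b in zip(pos, pos[1:]))

    def test_insert_seq_matches_segments(self, tiny_cfg):
        mito = MitoReference("chrM", make_genome(tiny_cfg)["chrM"])
        for ev in sample_events(tiny_cfg, mito):
            parts = []
            for seg in ev.segments:
                if seg.wraps:
                    sub = mito.sequence[seg.mt_start - 1 :] + mito.sequence[: seg.mt_end]
                else:
                    sub = mito.sequence[seg.mt_start - 1 : seg.mt_end]
                parts.append(revcomp(sub) if seg.strand == "-" else sub)
            assert ev.insert_seq == "".join(parts)
            assert ev.total_len == len(ev.insert_seq)

    def test_zero_events(self, tiny_cfg):
        cfg = SimConfig(**{**tiny_cfg.__dict__, "n_events": 0})
        mito = MitoReference("chrM", make_genome(cfg)["chrM"])
        assert sample_events(cfg, mito) == []

    def test_placement_error_when_genome_too_small(self):
        cfg = SimConfig(n_chroms=1, chrom_len_bp=200_000, n_events=50, seed=1)
        mito = MitoReference("chrM", make_genome(cfg)["chrM"])
        with pytest.raises(ValueError):
            sample_events(cfg, mito)


class TestImplant:
    def _event(self, pos, seq, eid="e1"):
        return TruthEvent(
            eid, "chr1", pos, [CircularInterval(1, len(seq), "+", False)],
            len(seq), seq,
        )

    def test_length_conservation_and_extraction(self):
        genome = {"chr1": "A" * 10_000}
        ins = "C" * 500
        mod = implant(genome, [self._event(4_000, ins)])
        assert len(mod["chr1"]) == 10_500
        assert mod["chr1"][4_000 : 4_500] == ins  # [nuc_pos+1 .. nuc_pos+len] 1-based

    def test_descending_application_keeps_original_coordinates(self):
        genome = {"chr1": "A" * 10_000}
        evs = [self._event(2_000, "C" * 100, "e1"), self._event(8_000, "G" * 50, "e2")]
        mod = implant(genome, evs)
        assert mod["chr1"][2_000:2_100] == "C" * 100
        assert mod["chr1"][8_100:8_150] == "G" * 50

    def test_no_events_is_identity(self):
        genome = {"chr1": "ACGT" * 100}
        assert implant(genome, []) == genome

    def test_duplicate_positions_rejected(self):
        genome = {"chr1": "A" * 10_000}
        with pytest.raises(ValueError):
            implant(genome, [self._event(5_000, "C" * 10, "a"),
                             self._event(5_000, "G" * 10, "b")])


class TestSimulateReads:
    def test_coverage_contract_and_name_encoding(self, tiny_cfg):
        genome = {"chr1": make_genome(tiny_cfg)["chr1"]}
        reads = simulate_reads(genome, tiny_cfg)
        total = sum(len(r.seq_fwd) for r in reads)
        target = tiny_cfg.coverage * 350_000
        assert abs(total - target) / target < 0.05
        name = reads[0].name.split(";")
        assert name[1] == reads[0].chrom and int(name[2]) == reads[0].start0 + 1

    def test_zero_error_reads_are_exact_substrings(self, tiny_cfg):
        cfg = SimConfig(**{**tiny_cfg.__dict__, "sub_rate": 0.0, "ins_rate": 0.0,
                           "del_rate": 0.0, "coverage": 2.0})
        genome = {"chr1": make_genome(cfg)["chr1"]}
        for r in simulate_reads(genome, cfg):
            assert r.seq_fwd == genome[r.chrom][r.start0 : r.end0]

    def test_mean_read_length_near_configured(self, tiny_cfg):
        genome = {"chr1": make_genome(tiny_cfg)["chr1"]}
        reads = simulate_reads(genome, tiny_cfg)
        assert len(reads) >= 1_000
        mean = np.mean([r.end0 - r.start0 for r in reads])
        assert abs(mean - 10_000) / 10_000 < 0.10


@pytest.fixture(scope="module")
def fixture_sam(tmp_path_factory):
    cfg = SimConfig(
        n_chroms=1, chrom_len_bp=200_000, n_events=0, seed=5,
        sub_rate=0.0, ins_rate=0.0, del_rate=0.0, coverage=8.0,
    )
    genome = make_genome(cfg)
    mito = MitoReference("chrM", genome["chrM"])
    short = CircularInterval(2_001, 2_500, "+", False)  # 500 bp -> in-read I op
    long_ = CircularInterval(5_001, 10_000, "+", False)  # 5 kb -> split records
    events = [
        TruthEvent("e_short", "chr1", 50_000, [short], 500,
                   event_sequence([short], mito)),
        TruthEvent("e_long", "chr1", 150_000, [long_], 5_000,
                   event_sequence([long_], mito)),
    ]
    modified = implant({"chr1": genome["chr1"]}, events)
    modified["chrM"] = genome["chrM"]
    reads = simulate_reads(modified, cfg)
    path = tmp_path_factory.mktemp("sam") / "fixture.sam"
    emit_alignments(reads, genome, events, cfg, path)
    return str(path)


class TestEmitAlignments:
    def test_short_insert_becomes_cigar_I(self, fixture_sam):
        found = False
        with pysam.AlignmentFile(fixture_sam) as fh:
            for rec in fh:
                if rec.is_supplementary or rec.cigartuples is None:
                    continue
                for op, ln in rec.cigartuples:
                    if op == 1 and ln == 500:
                        found = True
                        assert rec.reference_name == "chr1"
        assert found

    def test_long_insert_becomes_split_records_with_SA(self, fixture_sam):
        n_anchor = n_supp_mt = 0
        with pysam.AlignmentFile(fixture_sam) as fh:
            for rec in fh:
                if rec.reference_name == "chr1" and not rec.is_supplementary and rec.has_tag("SA"):
                    if "chrM" in rec.get_tag("SA"):
                        n_anchor += 1
                        assert "S" in rec.cigarstring
                if rec.reference_name == "chrM" and rec.is_supplementary:
                    n_supp_mt += 1
        assert n_anchor >= 5 and n_supp_mt >= 5

    def test_untouched_reads_have_plain_match_cigar(self, fixture_sam):
        with pysam.AlignmentFile(fixture_sam) as fh:
            plain = [
                rec for rec in fh
                if not rec.has_tag("SA") and rec.cigartuples is not None
                and len(rec.cigartuples) == 1 and rec.cigartuples[0][0] == 0
            ]
        assert plain  # zero-error run: most reads are a single match run

    def test_sam_and_fastq_sequences_consistent(self, fixture_sam):
        # flag 16 records store the reverse complement of the sequenced read
        with pysam.AlignmentFile(fixture_sam) as fh:
            for rec in list(fh)[:50]:
                strand = rec.query_name.split(";")[3]
                if rec.reference_name == "chr1" and len(rec.cigartuples) == 1:
                    assert rec.is_reverse == (strand == "-")


def test_truth_tsv_roundtrip(tmp_path):
    events = [
        TruthEvent("e1", "chr1", 1_000,
                   [CircularInterval(16_500, 60, "+", True)], 130),
        TruthEvent("e2", "chr2", 2_000,
                   [CircularInterval(10, 59, "+", False),
                    CircularInterval(3_000, 3_099, "+", False)], 150),
    ]
    path = tmp_path / "truth.tsv"
    write_truth(events, path)
    back = read_truth(path)
    assert [(e.event_id, e.chrom, e.nuc_pos, e.total_len, len(e.segments)) for e in back] == [
        ("e1", "chr1", 1_000, 130, 1), ("e2", "chr2", 2_000, 150, 2)
    ]
    assert back[0].segments[0].wraps is True


def test_dataset_determinism(tmp_path):
    from numtcall.simulate import make_dataset

    cfg = SimConfig(n_chroms=1, chrom_len_bp=120_000, n_events=1, seed=3,
                    coverage=3.0, frac_wrapping=0.0, frac_complex=0.0)
    d1 = make_dataset(cfg, tmp_path / "a")
    d2 = make_dataset(cfg, tmp_path / "b")
    for key in ("reference", "modified", "reads", "truth", "alignments"):
        with open(d1.paths[key]) as f1, open(d2.paths[key]) as f2:
            assert f1.read() == f2.read()
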