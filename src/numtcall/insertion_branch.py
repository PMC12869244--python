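"""SV branch: insertion discovery, mitochondrial realignment and the filter cascade.

Long reads spanning a NuMT shorter than the read carry the whole insert as
a CIGAR ``I`` operation in their primary alignment.  This branch scans for
such insertion signatures (or ingests a Sniffles2-style VCF), clusters
them into supported insertion calls, realigns each representative insert
sequence against the doubled mitochondrial reference, and applies the
E-value (< 1e-3), 10 bp both-axis merge, and >= 70% query-coverage cascade
to decide which insertions are mitochondrial in origin.

The realignment is an iterated best-local-alignment search: the highest
scoring local alignment (either strand) is reported, its query span is
masked, and the search repeats until the best remaining score is no longer
significant under the Karlin-Altschul E-value E = K*m*n*exp(-lambda*S)
with n the doubled reference length.  Masking by query span is what lets a
two-fragment (complex) insert produce two separate hits.
"""

from __future__ import annotations

import logging
import math
import statistics
from dataclasses import dataclass

import numpy as np
import pysam

from . import localalign
from .core import (
    MitoReference,
    MTSegment,
    PipelineConfig,
    ScoringScheme,
    circularize_interval,
    revcomp,
    union_length,
)
from .report import NuMTCall

logger = logging.getLogger(__name__)

_REF_CONSUMING = set("MDN=X")
_QRY_CONSUMING = set("MIS=X")


@dataclass
class InsertionSignature:
    """One CIGAR `I` operation: ``pos`` is the reference base immediately
    left of the inserted sequence (1-based)."""

    read_name: str
    chrom: str
    pos: int
    insert_seq: str
    mapq: int


@dataclass
class InsertionCall:
    """A clustered insertion event with distinct-read support."""

    chrom: str
    pos: int
    insert_seq: str
    support: int
    read_names: set[str]


@dataclass
class AlignmentHit:
    """A local alignment of an insert against the doubled mitochondrial axis.

    Query coordinates are 1-based on the insert in its original orientation;
    subject coordinates are 1-based ascending on the doubled axis with the
    strand carried separately (BLAST convention).
    """

    q_start: int
    q_end: int
    s_start: int
    s_end: int
    strand: str
    score: float
    evalue: float
    pct_identity: float


# ---------------------------------------------------------------------------
# Signature discovery and clustering
# ---------------------------------------------------------------------------


def _iter_alignments(alignments) -> "iter":
    if isinstance(alignments, (str, bytes)):
        with pysam.AlignmentFile(str(alignments), check_sq=False) as fh:
            yield from fh
    elif isinstance(alignments, pysam.AlignmentFile):
        yield from alignments
    else:
        yield from alignments


def scan_insertion_signatures(
    alignments, config: PipelineConfig
) -> list[InsertionSignature]:
    """Emit one signature per in-read insertion of length >= min_sv_len on a
    primary alignment with MAPQ >= min_mapq (the Sniffles-parameter thresholds)."""
    out: list[InsertionSignature] = []
    for rec in _iter_alignments(alignments):
        if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
            continue
        if rec.mapping_quality < config.min_mapq:
            continue
        if rec.cigartuples is None or rec.query_sequence is None:
            logger.warning("skipping record %s without CIGAR/SEQ", rec.query_name)
            continue
        ref = rec.reference_start  # 0-based next reference base
        qry = 0
        for op, ln in rec.cigartuples:
            ch = "MIDNSHP=X"[op]
            if ch == "I" and ln >= config.min_sv_len:
                out.append(
                    InsertionSignature(
                        read_name=rec.query_name,
                        chrom=rec.reference_name,
                        pos=ref,  # 0-based next base == 1-based previous base
                        insert_seq=rec.query_sequence[qry : qry + ln],
                        mapq=rec.mapping_quality,
                    )
                )
            if ch in _REF_CONSUMING:
                ref += ln
            if ch in _QRY_CONSUMING:
                qry += ln
    return out


def cluster_signatures(
    signatures: list[InsertionSignature], config: PipelineConfig
) -> list[InsertionCall]:
    """Single-linkage clustering of signatures within sig_cluster_window_bp;
    clusters below min_sv_support (distinct reads) are discarded.

    Breakpoint is the median signature position; the representative insert
    is the member whose length is the cluster median (ties toward longer).
    """
    calls: list[InsertionCall] = []
    for group in _linkage_groups(signatures, config.sig_cluster_window_bp):
        names = {s.read_name for s in group}
        if len(names) < config.min_sv_support:
            continue
        pos = int(statistics.median_low(sorted(s.pos for s in group)))
        by_len = sorted(group, key=lambda s: (len(s.insert_seq), s.read_name))
        rep = by_len[len(by_len) // 2]  # upper median: ties resolve longer
        calls.append(
            InsertionCall(
                chrom=group[0].chrom,
                pos=pos,
                insert_seq=rep.insert_seq,
                support=len(names),
                read_names=names,
            )
        )
    calls.sort(key=lambda c: (c.chrom, c.pos))
    return calls


def _linkage_groups(signatures, window: int):
    by_chrom: dict[str, list[InsertionSignature]] = {}
    for s in signatures:
        by_chrom.setdefault(s.chrom, []).append(s)
    for chrom in sorted(by_chrom):
        sigs = sorted(by_chrom[chrom], key=lambda s: s.pos)
        group: list[InsertionSignature] = []
        span_max = None
        for s in sigs:
            if span_max is not None and s.pos - span_max > window:
                yield group
                group = []
            group.append(s)
            span_max = s.pos if span_max is None else max(span_max, s.pos)
        if group:
            yield group


def load_vcf_insertions(path: str, config: PipelineConfig) -> list[InsertionCall]:
    """Ingest SVTYPE=INS records from a Sniffles2-style VCF as insertion calls.

    Support is taken from the SUPPORT INFO field with DV/RE fallbacks;
    records failing FILTER, below min_sv_support, or with symbolic ALTs
    (no sequence) are excluded.
    """
    calls: list[InsertionCall] = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            try:
                if rec.info.get("SVTYPE") != "INS":
                    continue
                filters = list(rec.filter)
                if filters not in ([], ["PASS"]):
                    continue
                alt = rec.alts[0] if rec.alts else None
                if alt is None or alt.startswith("<"):
                    logger.warning("skipping symbolic INS at %s:%d", rec.chrom, rec.pos)
                    continue
                support = rec.info.get("SUPPORT")
                if support is None:
                    for key in ("DV", "RE"):
                        if key in rec.info:
                            support = rec.info[key]
                        else:
                            for sample in rec.samples.values():
                                if key in sample and sample[key] is not None:
                                    support = sample[key]
                                    break
                        if support is not None:
                            break
                if isinstance(support, tuple):
                    support = support[0]
                if support is None or support < config.min_sv_support:
                    continue
                seq = alt[1:] if rec.ref and alt[0].upper() == rec.ref[0].upper() else alt
                if not seq:
                    continue
                calls.append(
                    InsertionCall(
                        chrom=rec.chrom,
                        pos=rec.pos,
                        insert_seq=seq.upper(),
                        support=int(support),
                        read_names=set(),
                    )
                )
            except (KeyError, ValueError, IndexError) as exc:
                logger.warning("skipping unparseable VCF record: %s", exc)
    return calls


# ---------------------------------------------------------------------------
# Realignment against the doubled mitochondrial reference
# ---------------------------------------------------------------------------


def align_to_mt(
    insert_seq: str,
    mito: MitoReference,
    scoring: ScoringScheme | None = None,
    evalue_max: float = 1e-3,
    max_hits: int = 50,
) -> list[AlignmentHit]:
    """All significant local alignments of the insert against the doubled MT.

    Iterated best-local-alignment with masking of previously aligned query
    spans; both strands are searched each round; iteration stops when the
    best remaining score is not significant at ``evalue_max``.
    """
    if not insert_seq:
        raise ValueError("empty insert sequence")
    scoring = scoring or ScoringScheme()
    m = len(insert_seq)
    L = mito.length_bp
    n = 2 * L
    q_fwd = localalign.encode(insert_seq)
    q_rev = localalign.encode(revcomp(insert_seq))
    t = localalign.encode(mito.doubled_sequence)
    mask = np.zeros(m, dtype=bool)
    # minimum raw score that can reach significance; used to stop early
    if scoring.ka_k * m * n <= evalue_max:
        s_min = 0.0
    else:
        s_min = math.log(scoring.ka_k * m * n / evalue_max) / scoring.ka_lambda

    hits: list[AlignmentHit] = []
    for _ in range(max_hits):
        unmasked = int(m - mask.sum())
        if unmasked * scoring.match < s_min:
            break
        best = None
        for strand, q, qm in (("+", q_fwd, mask), ("-", q_rev, mask[::-1])):
            hit = localalign.best_local_alignment(
                q,
                t,
                scoring.match,
                scoring.mismatch,
                scoring.gap_open,
                scoring.gap_extend,
                qm,
            )
            if hit is not None and (best is None or hit.score > best[1].score):
                best = (strand, hit)
        if best is None:
            break
        strand, hit = best
        ev = scoring.evalue(hit.score, m, n)
        if ev >= evalue_max:
            break
        if strand == "+":
            qs, qe = hit.q_start + 1, hit.q_end + 1
        else:
            qs, qe = m - hit.q_end, m - hit.q_start
        q_sub = insert_seq[qs - 1 : qe]
        if strand == "-":
            q_sub = revcomp(q_sub)
        t_sub = mito.doubled_sequence[hit.t_start : hit.t_end + 1]
        hits.append(
            AlignmentHit(
                q_start=qs,
                q_end=qe,
                s_start=hit.t_start + 1,
                s_end=hit.t_end + 1,
                strand=strand,
                score=hit.score,
                evalue=ev,
                pct_identity=_identity_pct(q_sub, t_sub),
            )
        )
        mask[qs - 1 : qe] = True
    hits.sort(key=lambda h: (h.evalue, h.q_start))
    return hits


def _identity_pct(a: str, b: str) -> float:
    import edlib

    res = edlib.align(a, b, task="path")
    cigar = res["cigar"] or ""
    matches = cols = 0
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            ln = int(num)
            num = ""
            cols += ln
            if ch == "=":
                matches += ln
    return 100.0 * matches / cols if cols else 0.0


# ---------------------------------------------------------------------------
# Filter cascade
# ---------------------------------------------------------------------------


def filter_merge_hits(
    hits: list[AlignmentHit],
    insert_len: int,
    config: PipelineConfig,
    L: int,
) -> tuple[list[MTSegment], float]:
    """E-value filter, both-axis 10 bp merge, circularisation and query coverage.

    Two retained hits merge when they share a strand, are collinear, and
    both the query-axis and doubled-subject-axis intervening gaps are
    < hit_merge_gap_bp (single-linkage closure).  Query coverage is the
    union of retained query spans over the insert length, in percent.
    """
    kept = [h for h in hits if h.evalue < config.evalue_max]
    if not kept:
        return [], 0.0
    gap = config.hit_merge_gap_bp
    order = sorted(range(len(kept)), key=lambda i: kept[i].q_start)
    parent = list(range(len(kept)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for ii in range(len(order)):
        for jj in range(ii + 1, len(order)):
            a, b = kept[order[ii]], kept[order[jj]]
            if a.strand != b.strand:
                continue
            q_gap = b.q_start - a.q_end - 1
            if a.strand == "+":
                collinear = b.s_start > a.s_start
                s_gap = b.s_start - a.s_end - 1
            else:
                collinear = b.s_end < a.s_end
                s_gap = a.s_start - b.s_end - 1
            if collinear and q_gap < gap and s_gap < gap:
                ra, rb = find(order[ii]), find(order[jj])
                if ra != rb:
                    parent[rb] = ra
    groups: dict[int, list[AlignmentHit]] = {}
    for i, h in enumerate(kept):
        groups.setdefault(find(i), []).append(h)
    segments = []
    for members in groups.values():
        q_lo = min(h.q_start for h in members)
        q_hi = max(h.q_end for h in members)
        s_lo = min(h.s_start for h in members)
        s_hi = max(h.s_end for h in members)
        interval = circularize_interval(s_lo, s_hi, members[0].strand, L)
        segments.append(
            MTSegment(
                interval=interval,
                q_span=(q_lo, q_hi),
                best_evalue=min(h.evalue for h in members),
            )
        )
    segments.sort(key=lambda s: s.q_span)
    qcov = 100.0 * union_length((h.q_start, h.q_end) for h in kept) / insert_len
    return segments, qcov


def call_from_insertions(
    insertion_calls: list[InsertionCall],
    mito: MitoReference,
    config: PipelineConfig,
    sample: str = "sample",
) -> list[NuMTCall]:
    """Run the realignment cascade over insertion calls; emit SV-branch NuMT calls."""
    out: list[NuMTCall] = []
    for call in insertion_calls:
        hits = align_to_mt(
            call.insert_seq, mito, config.scoring, evalue_max=config.evalue_max
        )
        segments, qcov = filter_merge_hits(hits, len(call.insert_seq), config, mito.length_bp)
        if not segments or qcov < config.min_query_cov_pct:
            continue
        out.append(
            NuMTCall(
                sample=sample,
                chrom=call.chrom,
                breakpoint=call.pos,
                segments=segments,
                total_mt_len=sum(s.length(mito.length_bp) for s in segments),
                branch="sv",
                support_sv=call.support,
                support_split=0,
                query_cov_pct=qcov,
                best_evalue=min(s.best_evalue for s in segments),
            )
        )
    return out
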