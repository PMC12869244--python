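"""Supplementary-alignment branch: split-read evidence for long NuMTs.

A NuMT longer than the reads that cover it never appears as an in-read
insertion; instead, reads crossing its boundaries align partly to the
nuclear genome and partly to the mitochondrial contig, linked through SA
tags.  This branch collects nuclear-anchored reads whose SA tags name the
mitochondrial contig (and the reciprocal orientation, deduplicated),
merges nearby anchors BEDtools-style (< 100 bp gap), and reports a
breakpoint wherever at least five distinct reads support the junction.
"""

from __future__ import annotations

import logging
import statistics
from dataclasses import dataclass

import pysam

from .core import CircularInterval, MTSegment, PipelineConfig
from .insertion_branch import _iter_alignments
from .report import NuMTCall

logger = logging.getLogger(__name__)

_REF_CONSUMING = set("MDN=X")


@dataclass
class SplitAnchor:
    """One read's nuclear anchor for a split alignment into the MT contig.

    ``clip_pos`` is the nuclear coordinate of the soft-clipped anchor end
    that adjoins the MT-mapped read portion (== anchor_start or anchor_end);
    ``mt_interval`` may wrap when the read's MT portion crosses the origin.
    """

    read_name: str
    chrom: str
    anchor_start: int
    anchor_end: int
    clip_pos: int
    side: str  # 'L' when the clip is at anchor_start, 'R' at anchor_end
    mt_interval: CircularInterval
    mapq: int


@dataclass
class AnchorCluster:
    chrom: str
    span: tuple[int, int]
    support: int
    anchors: list[SplitAnchor]


def _cigar_ref_len(cigar: str) -> int:
    n = 0
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            if ch in _REF_CONSUMING:
                n += int(num)
            num = ""
    return n


def _cigar_clips(cigar: str) -> tuple[int, int]:
    """(leading, trailing) clipped bases (S or H) of a CIGAR string."""
    import re

    ops = re.findall(r"(\d+)([MIDNSHP=X])", cigar)
    lead = int(ops[0][0]) if ops and ops[0][1] in "SH" else 0
    tail = int(ops[-1][0]) if ops and ops[-1][1] in "SH" else 0
    return lead, tail


def _read_start_offset(cigar: str, reverse: bool) -> int:
    """Offset of the aligned portion within the original read."""
    lead, tail = _cigar_clips(cigar)
    return tail if reverse else lead


def _parse_sa(tag: str) -> list[dict]:
    out = []
    for entry in tag.rstrip(";").split(";"):
        if not entry:
            continue
        f = entry.split(",")
        if len(f) != 6:
            raise ValueError(f"malformed SA entry {entry!r}")
        out.append(
            {
                "rname": f[0],
                "pos": int(f[1]),
                "strand": f[2],
                "cigar": f[3],
                "mapq": int(f[4]),
                "nm": f[5],
            }
        )
    return out


def _combine_mt_entries(entries: list[dict], L: int) -> CircularInterval:
    """Summarise a read's MT-mapped SA entries as one (possibly wrapping) interval.

    Two entries adjacent at the origin (one ending at L, one starting at 1)
    fold into a wrapping interval; otherwise the longest entry wins.
    """
    ivs = []
    for e in entries:
        ln = _cigar_ref_len(e["cigar"])
        if ln <= 0:
            continue
        ivs.append((e["pos"], e["pos"] + ln - 1, e["strand"]))
    if not ivs:
        raise ValueError("SA entries with no reference-consuming operations")
    for s1, e1, st1 in ivs:
        for s2, e2, st2 in ivs:
            if e1 == L and s2 == 1 and st1 == st2 and (s1, e1) != (s2, e2):
                return CircularInterval(s1, e2, st1, True)
    s, e, st = max(ivs, key=lambda t: t[1] - t[0])
    return CircularInterval(s, e, st, False)


def extract_split_anchors(
    alignments, mt_name: str, config: PipelineConfig, L: int | None = None
) -> list[SplitAnchor]:
    """Anchors from nuclear primaries with MT supplementaries, plus the
    reciprocal orientation (MT primary, nuclear supplementary), deduplicated
    by (read, chrom, clip side).  The MAPQ filter applies to the nuclear
    anchor only."""
    anchors: dict[tuple, SplitAnchor] = {}
    for rec in _iter_alignments(alignments):
        if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
            continue
        if not rec.has_tag("SA"):
            continue
        try:
            sa = _parse_sa(rec.get_tag("SA"))
        except (ValueError, IndexError) as exc:
            logger.warning("skipping malformed SA tag on %s: %s", rec.query_name, exc)
            continue
        if L is None:
            try:
                L = rec.header.get_reference_length(mt_name)
            except (KeyError, ValueError):
                L = None
        if rec.reference_name != mt_name:
            mt_entries = [e for e in sa if e["rname"] == mt_name]
            if not mt_entries or rec.mapping_quality < config.min_mapq:
                continue
            anchor = _anchor_from_primary(rec, mt_entries, L)
        else:
            # reciprocal orientation: MT primary, nuclear supplementary
            nuc_entries = [e for e in sa if e["rname"] != mt_name]
            if not nuc_entries:
                continue
            anchor = _anchor_from_mt_primary(rec, nuc_entries, config, L)
        if anchor is None:
            continue
        key = (anchor.read_name, anchor.chrom, anchor.side)
        if key not in anchors:
            anchors[key] = anchor
    out = sorted(anchors.values(), key=lambda a: (a.chrom, a.clip_pos, a.read_name))
    return out


def _anchor_from_primary(rec, mt_entries: list[dict], L: int | None) -> SplitAnchor:
    anchor_start = rec.reference_start + 1
    anchor_end = rec.reference_end  # pysam reference_end is exclusive 0-based == inclusive 1-based
    r0 = _read_start_offset(rec.cigarstring, rec.is_reverse)
    best = min(
        mt_entries,
        key=lambda e: _read_start_offset(e["cigar"], e["strand"] == "-"),
    )
    mt_read_start = _read_start_offset(best["cigar"], best["strand"] == "-")
    # is the MT portion before the anchor in the original read?
    mt_first = mt_read_start < r0
    left_in_ref = mt_first != rec.is_reverse
    clip_pos, side = (anchor_start, "L") if left_in_ref else (anchor_end, "R")
    interval = _combine_mt_entries(mt_entries, L or 10**9)
    return SplitAnchor(
        read_name=rec.query_name,
        chrom=rec.reference_name,
        anchor_start=anchor_start,
        anchor_end=anchor_end,
        clip_pos=clip_pos,
        side=side,
        mt_interval=interval,
        mapq=rec.mapping_quality,
    )


def _anchor_from_mt_primary(
    rec, nuc_entries: list[dict], config: PipelineConfig, L: int | None
) -> SplitAnchor | None:
    best = max(nuc_entries, key=lambda e: _cigar_ref_len(e["cigar"]))
    if best["mapq"] < config.min_mapq:
        return None
    anchor_start = best["pos"]
    anchor_end = best["pos"] + _cigar_ref_len(best["cigar"]) - 1
    nuc_read_start = _read_start_offset(best["cigar"], best["strand"] == "-")
    mt_read_start = _read_start_offset(rec.cigarstring, rec.is_reverse)
    mt_first = mt_read_start < nuc_read_start
    left_in_ref = mt_first != (best["strand"] == "-")
    clip_pos, side = (anchor_start, "L") if left_in_ref else (anchor_end, "R")
    mt_len = _cigar_ref_len(rec.cigarstring)
    interval = CircularInterval(
        rec.reference_start + 1,
        rec.reference_start + mt_len,
        "-" if rec.is_reverse else "+",
        False,
    )
    if L is not None and rec.reference_start + mt_len > L:  # defensive; not expected
        interval = CircularInterval(
            rec.reference_start + 1, rec.reference_start + mt_len - L, interval.strand, True
        )
    return SplitAnchor(
        read_name=rec.query_name,
        chrom=best["rname"],
        anchor_start=anchor_start,
        anchor_end=anchor_end,
        clip_pos=clip_pos,
        side=side,
        mt_interval=interval,
        mapq=best["mapq"],
    )


def cluster_anchors(
    anchors: list[SplitAnchor], config: PipelineConfig
) -> list[AnchorCluster]:
    """Single-linkage merge of nuclear anchor intervals with intervening gap
    < anchor_merge_gap_bp; support counts distinct read names."""
    gap = config.anchor_merge_gap_bp
    by_chrom: dict[str, list[SplitAnchor]] = {}
    for a in anchors:
        by_chrom.setdefault(a.chrom, []).append(a)
    clusters: list[AnchorCluster] = []
    for chrom in sorted(by_chrom):
        group: list[SplitAnchor] = []
        span_end = None
        for a in sorted(by_chrom[chrom], key=lambda a: (a.anchor_start, a.anchor_end)):
            if span_end is not None and a.anchor_start - span_end - 1 >= gap:
                clusters.append(_finish_cluster(chrom, group))
                group = []
                span_end = None
            group.append(a)
            span_end = a.anchor_end if span_end is None else max(span_end, a.anchor_end)
        if group:
            clusters.append(_finish_cluster(chrom, group))
    return clusters


def _finish_cluster(chrom: str, group: list[SplitAnchor]) -> AnchorCluster:
    return AnchorCluster(
        chrom=chrom,
        span=(min(a.anchor_start for a in group), max(a.anchor_end for a in group)),
        support=len({a.read_name for a in group}),
        anchors=group,
    )


def call_from_split(
    clusters: list[AnchorCluster],
    config: PipelineConfig,
    L: int,
    sample: str = "sample",
) -> list[NuMTCall]:
    """Report the breakpoints supported by >= min_split_support distinct reads.

    Within each merged anchor region, clip positions are grouped by
    single-linkage (gap < anchor_merge_gap_bp) so that one region holding
    two distinct junctions yields two breakpoints; each supported group
    becomes one call.  The breakpoint is the group's median clip position;
    the MT segment summarises the anchors' (unrolled) MT intervals by
    per-endpoint medians, wrapping when the combined span crosses the origin.
    """
    out: list[NuMTCall] = []
    for cl in clusters:
        if cl.support < config.min_split_support:
            continue
        for group in _clip_groups(cl.anchors, config.anchor_merge_gap_bp):
            call = _call_from_group(cl.chrom, group, config, L, sample)
            if call is not None:
                out.append(call)
    out.sort(key=lambda c: (c.chrom, c.breakpoint))
    return out


def _clip_groups(anchors: list[SplitAnchor], gap: int) -> list[list[SplitAnchor]]:
    groups: list[list[SplitAnchor]] = []
    last = None
    for a in sorted(anchors, key=lambda a: (a.clip_pos, a.read_name)):
        if last is not None and a.clip_pos - last < gap:
            groups[-1].append(a)
        else:
            groups.append([a])
        last = a.clip_pos
    return groups


def _call_from_group(
    chrom: str,
    anchors: list[SplitAnchor],
    config: PipelineConfig,
    L: int,
    sample: str,
) -> NuMTCall | None:
    support = len({a.read_name for a in anchors})
    if support < config.min_split_support:
        return None
    breakpoint_ = int(statistics.median_low(sorted(a.clip_pos for a in anchors)))
    starts, ends = [], []
    for a in anchors:
        iv = a.mt_interval
        starts.append(iv.mt_start)
        ends.append(iv.mt_start + iv.length(L) - 1)  # unrolled, may exceed L
    med_s = int(round(statistics.median(starts)))
    med_e = int(round(statistics.median(ends)))
    if med_e > L:
        interval = CircularInterval(med_s, med_e - L, "+", True)
    elif med_s <= med_e:
        interval = CircularInterval(med_s, med_e, "+", False)
    else:
        interval = CircularInterval(med_s, med_e, "+", True)
    return NuMTCall(
        sample=sample,
        chrom=chrom,
        breakpoint=breakpoint_,
        segments=[MTSegment(interval=interval)],
        total_mt_len=interval.length(L),
        branch="split",
        support_sv=0,
        support_split=support,
    )
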