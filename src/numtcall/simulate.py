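"""Synthetic NuMT datasets: genomes, implanted truth events, reads and SAM fixtures.

The generator emulates the study conditions the caller is benchmarked
under: a small nuclear genome plus a 16,569 bp mitochondrial contig, NuMT
insertions from 30 bp up to the full mitochondrial length (including
control-region-spanning and two-fragment complex events), 30X long-read
coverage with ~10 kb mean read length, and ~5% per-base sequencing error.

Two output paths exist.  ``simulate_reads`` writes plain FASTQ for use
with an external aligner.  ``emit_alignments`` writes a coordinate-sorted
SAM directly from the known read origins, so the whole caller is testable
without running an aligner: a read wholly containing an insert shorter
than ``split_threshold_bp`` gets a primary nuclear alignment with an ``I``
CIGAR operation, while reads touching longer inserts get soft-clipped
nuclear primaries plus supplementary alignments on the mitochondrial
contig with mutually consistent SA tags.  Partial overlaps of short
inserts at read edges are soft-clipped outright, which keeps the two
detection branches cleanly separated by insert size in fixture data.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pysam

from .core import (
    CircularInterval,
    MitoReference,
    revcomp,
    write_fasta,
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


# ---------------------------------------------------------------------------
# Configuration and truth events
# ---------------------------------------------------------------------------


@dataclass
class SimConfig:
    """Study conditions for one simulated sample.

    The seed fully determines every output (FASTA, FASTQ, SAM bytes).
    """

    n_chroms: int = 2
    chrom_len_bp: int = 1_000_000
    n_events: int = 30
    size_min: int = 30
    size_max: int = 16_569
    frac_wrapping: float = 0.15
    frac_complex: float = 0.15
    coverage: float = 30.0
    read_len_mean: float = 10_000.0
    read_len_cv: float = 0.55
    min_read_len: int = 200
    max_read_len: int = 30_000
    sub_rate: float = 0.03
    ins_rate: float = 0.01
    del_rate: float = 0.01
    split_threshold_bp: int = 2_500
    mt_len: int = 16_569
    mt_contig: str = "chrM"
    seed: int = 42

    def __post_init__(self) -> None:
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")
        for r in (self.sub_rate, self.ins_rate, self.del_rate):
            if not 0 <= r <= 0.2:
                raise ValueError("per-base error rates must be in [0, 0.2]")
        if self.n_chroms <= 0 or self.chrom_len_bp <= 0 or self.mt_len <= 0:
            raise ValueError("contig counts and lengths must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


@dataclass
class TruthEvent:
    """An implanted ground-truth NuMT.

    The insert sits between ``nuc_pos`` and ``nuc_pos + 1`` of the
    *original* (pre-insertion) contig; ``insert_seq`` is the concatenation
    of the mitochondrial subsequences of ``segments`` (reverse-complemented
    for minus-strand segments).
    """

    event_id: str
    chrom: str
    nuc_pos: int
    segments: list[CircularInterval]
    total_len: int
    insert_seq: str | None = None


# ---------------------------------------------------------------------------
# Genome and events
# ---------------------------------------------------------------------------


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, n)].tobytes().decode("ascii")


def make_genome(cfg: SimConfig) -> dict[str, str]:
    """Nuclear contigs plus one mitochondrial contig, i.i.d. base composition."""
    rng = np.random.default_rng(cfg.seed)
    genome = {
        f"chr{i + 1}": _random_seq(rng, cfg.chrom_len_bp) for i in range(cfg.n_chroms)
    }
    genome[cfg.mt_contig] = _random_seq(rng, cfg.mt_len)
    return genome


def segment_sequence(seg: CircularInterval, mito: MitoReference) -> str:
    """Mitochondrial subsequence of one (possibly wrapping) segment, strand applied."""
    s = mito.sequence
    if seg.wraps:
        sub = s[seg.mt_start - 1 :] + s[: seg.mt_end]
    else:
        sub = s[seg.mt_start - 1 : seg.mt_end]
    return revcomp(sub) if seg.strand == "-" else sub


def event_sequence(segments: list[CircularInterval], mito: MitoReference) -> str:
    return "".join(segment_sequence(seg, mito) for seg in segments)


def sample_events(cfg: SimConfig, mito: MitoReference) -> list[TruthEvent]:
    """Draw the truth set: sizes uniform in [size_min, size_max], nuclear
    positions >= ~50 kb apart, with the configured fractions of
    control-region-spanning (wrapping) and two-fragment (complex) events.

    Wrapping and complex events are generated on the plus strand; complex
    events are capped at 8 kb so both fragments plus a 0.1-3 kb
    mitochondrial gap fit without wrapping.
    """
    if cfg.n_events == 0:
        return []
    rng = np.random.default_rng(cfg.seed + 1)
    L = mito.length_bp
    if cfg.size_max > L:
        raise ValueError("size_max exceeds the mitochondrial genome length")

    # nuclear placement slots, >= 51 kb apart after jitter
    step, margin, jitter = 55_000, 55_000, 2_000
    slots = [
        (chrom, c)
        for chrom in (f"chr{i + 1}" for i in range(cfg.n_chroms))
        for c in range(margin, cfg.chrom_len_bp - margin + 1, step)
    ]
    if len(slots) < cfg.n_events:
        raise ValueError(
            f"cannot place {cfg.n_events} events >=50 kb apart on "
            f"{cfg.n_chroms} x {cfg.chrom_len_bp} bp contigs"
        )
    chosen = [slots[i] for i in rng.choice(len(slots), cfg.n_events, replace=False)]
    positions = sorted(
        (chrom, int(c + rng.integers(-jitter, jitter + 1))) for chrom, c in chosen
    )

    sizes = rng.integers(cfg.size_min, cfg.size_max + 1, cfg.n_events)
    n_wrap = round(cfg.frac_wrapping * cfg.n_events)
    n_complex = round(cfg.frac_complex * cfg.n_events)
    order = rng.permutation(cfg.n_events)
    complex_ids: set[int] = set()
    wrap_ids: set[int] = set()
    for i in order:
        if len(complex_ids) < n_complex and 200 <= sizes[i] <= 8_000:
            complex_ids.add(i)
        elif len(wrap_ids) < n_wrap and sizes[i] >= 40 and i not in complex_ids:
            wrap_ids.add(i)

    events = []
    for idx, (chrom, pos) in enumerate(positions):
        s = int(sizes[idx])
        if idx in complex_ids:
            s1 = s // 2
            s2 = s - s1
            gap = int(rng.integers(100, 3_001))
            start1 = int(rng.integers(1, L - (s1 + gap + s2) + 2))
            segments = [
                CircularInterval(start1, start1 + s1 - 1, "+", False),
                CircularInterval(start1 + s1 + gap, start1 + s1 + gap + s2 - 1, "+", False),
            ]
        elif idx in wrap_ids:
            head = int(rng.integers(1, s))  # bases taken from [1..head]
            segments = [CircularInterval(L - (s - head) + 1, head, "+", True)]
        else:
            strand = "-" if rng.random() < 0.3 else "+"
            start = int(rng.integers(1, L - s + 2))
            segments = [CircularInterval(start, start + s - 1, strand, False)]
        events.append(
            TruthEvent(
                event_id=f"numt_{idx + 1:04d}",
                chrom=chrom,
                nuc_pos=pos,
                segments=segments,
                total_len=s,
                insert_seq=event_sequence(segments, mito),
            )
        )
    return events


def implant(genome: dict[str, str], events: list[TruthEvent]) -> dict[str, str]:
    """Insert every event into its contig; stated nuc_pos values always refer
    to the original contig (insertions applied in descending coordinate order)."""
    modified = dict(genome)
    by_chrom: dict[str, list[TruthEvent]] = {}
    for ev in events:
        by_chrom.setdefault(ev.chrom, []).append(ev)
    for chrom, evs in by_chrom.items():
        if chrom not in modified:
            raise KeyError(f"event contig {chrom!r} not in genome")
        if len({e.nuc_pos for e in evs}) != len(evs):
            raise ValueError(f"overlapping events at one position on {chrom}")
        seq = modified[chrom]
        for ev in sorted(evs, key=lambda e: e.nuc_pos, reverse=True):
            if not 0 < ev.nuc_pos < len(seq):
                raise ValueError(f"event {ev.event_id} position outside {chrom}")
            if ev.insert_seq is None or len(ev.insert_seq) != ev.total_len:
                raise ValueError(f"event {ev.event_id} has inconsistent insert_seq")
            seq = seq[: ev.nuc_pos] + ev.insert_seq + seq[ev.nuc_pos :]
        modified[chrom] = seq
    return modified


TRUTH_COLUMNS = [
    "event_id",
    "chrom",
    "nuc_pos",
    "n_segments",
    "mt_start",
    "mt_end",
    "strand",
    "wraps",
    "total_len",
]


def write_truth(events: list[TruthEvent], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(TRUTH_COLUMNS) + "\n")
        for ev in events:
            for seg in ev.segments:
                fh.write(
                    "\t".join(
                        str(x)
                        for x in (
                            ev.event_id,
                            ev.chrom,
                            ev.nuc_pos,
                            len(ev.segments),
                            seg.mt_start,
                            seg.mt_end,
                            seg.strand,
                            str(seg.wraps).lower(),
                            ev.total_len,
                        )
                    )
                    + "\n"
                )


def read_truth(path: str | Path) -> list[TruthEvent]:
    events: dict[str, TruthEvent] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != TRUTH_COLUMNS:
            raise ValueError(f"unexpected truth TSV header: {header}")
        for line in fh:
            f = line.rstrip("\n").split("\t")
            seg = CircularInterval(int(f[4]), int(f[5]), f[6], f[7] == "true")
            ev = events.get(f[0])
            if ev is None:
                events[f[0]] = TruthEvent(f[0], f[1], int(f[2]), [seg], int(f[8]))
            else:
                ev.segments.append(seg)
    return list(events.values())


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------


@dataclass
class SimRead:
    """One simulated read with its true origin on the modified genome.

    ``seq_fwd`` is stored in genome-forward orientation regardless of
    sequencing strand; FASTQ output reverse-complements minus-strand reads.
    Error positions are absolute 0-based modified-contig coordinates:
    substitutions replace the base, insertions add one base *after* the
    position, deletions drop the base.
    """

    name: str
    chrom: str
    start0: int
    end0: int
    strand: str
    seq_fwd: str
    sub_pos: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    ins_pos: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    ins_base: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.uint8))
    del_pos: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))


def _read_length(cfg: SimConfig, rng: np.random.Generator, contig_len: int) -> int:
    sigma = math.sqrt(math.log(1.0 + cfg.read_len_cv**2))
    mu = math.log(cfg.read_len_mean) - sigma**2 / 2.0
    ln = int(rng.lognormal(mu, sigma))
    return max(cfg.min_read_len, min(ln, cfg.max_read_len, contig_len))


def _build_read_seq(
    contig_arr: np.ndarray,
    start: int,
    end: int,
    sub_pos: np.ndarray,
    sub_base: np.ndarray,
    ins_pos: np.ndarray,
    ins_base: np.ndarray,
    del_pos: np.ndarray,
) -> str:
    arr = contig_arr[start:end].copy()
    if sub_pos.size:
        arr[sub_pos - start] = sub_base
    if not ins_pos.size and not del_pos.size:
        return arr.tobytes().decode("ascii")
    marks = sorted(
        [(int(p), "D", 0) for p in del_pos] + [(int(p), "I", int(b)) for p, b in zip(ins_pos, ins_base)]
    )
    parts: list[bytes] = []
    last = start
    for pos, kind, payload in marks:
        if kind == "D":
            parts.append(arr[last - start : pos - start].tobytes())
            last = pos + 1
        else:
            parts.append(arr[last - start : pos - start + 1].tobytes())
            parts.append(bytes([payload]))
            last = pos + 1
    parts.append(arr[last - start :].tobytes())
    return b"".join(parts).decode("ascii")


def simulate_reads(genome: dict[str, str], cfg: SimConfig) -> list[SimRead]:
    """Sample reads to the configured coverage with i.i.d. per-base errors.

    Total sequenced bases land within a read length of coverage x genome
    size; read names encode the true origin (contig, 1-based start, strand).
    """
    rng = np.random.default_rng(cfg.seed + 2)
    names = list(genome)
    arrs = {c: np.frombuffer(genome[c].encode("ascii"), dtype=np.uint8) for c in names}
    lengths = np.array([len(genome[c]) for c in names], dtype=float)
    probs = lengths / lengths.sum()
    target = cfg.coverage * lengths.sum()
    reads: list[SimRead] = []
    total = 0
    i = 0
    while total < target:
        c = names[int(rng.choice(len(names), p=probs))]
        clen = len(genome[c])
        ln = _read_length(cfg, rng, clen)
        start = int(rng.integers(0, clen - ln + 1))
        end = start + ln
        strand = "+" if rng.random() < 0.5 else "-"

        n_sub = rng.binomial(ln, cfg.sub_rate)
        n_ins = rng.binomial(ln, cfg.ins_rate)
        n_del = rng.binomial(ln, cfg.del_rate)
        sub_pos = ins_pos = del_pos = np.empty(0, dtype=np.int64)
        sub_base = ins_base = np.empty(0, dtype=np.uint8)
        if n_sub or n_ins or n_del:
            picks = rng.choice(ln, size=min(n_sub + n_ins + n_del, ln), replace=False)
            sub_pos = np.sort(picks[:n_sub]) + start
            ins_pos = np.sort(picks[n_sub : n_sub + n_ins]) + start
            del_pos = np.sort(picks[n_sub + n_ins :]) + start
            if sub_pos.size:
                orig = arrs[c][sub_pos - start]
                codes = np.select(
                    [orig == b for b in _BASES], [0, 1, 2, 3], default=0
                )
                sub_base = _BASES[(codes + rng.integers(1, 4, sub_pos.size)) % 4]
            if ins_pos.size:
                ins_base = _BASES[rng.integers(0, 4, ins_pos.size)]
        seq = _build_read_seq(
            arrs[c], start, end, sub_pos, sub_base, ins_pos, ins_base, del_pos
        )
        reads.append(
            SimRead(
                name=f"read{i:06d};{c};{start + 1};{strand}",
                chrom=c,
                start0=start,
                end0=end,
                strand=strand,
                seq_fwd=seq,
                sub_pos=sub_pos,
                ins_pos=ins_pos,
                ins_base=ins_base,
                del_pos=del_pos,
            )
        )
        total += len(seq)
        i += 1
    return reads


def write_fastq(reads: list[SimRead], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            seq = r.seq_fwd if r.strand == "+" else revcomp(r.seq_fwd)
            fh.write(f"@{r.name}\n{seq}\n+\n{'I' * len(seq)}\n")


# ---------------------------------------------------------------------------
# Aligner-free SAM fixtures
# ---------------------------------------------------------------------------

_MIN_PIECE = 30  # alignment pieces below this become soft clips


def _contig_blocks(
    events: list[TruthEvent], orig_len: int
) -> list[tuple[int, int, str, object]]:
    """Partition a modified contig into ('nuc', orig_start0) and ('ins', event)
    blocks on modified 0-based coordinates."""
    blocks: list[tuple[int, int, str, object]] = []
    mod = 0
    orig = 0
    for ev in sorted(events, key=lambda e: e.nuc_pos):
        span = ev.nuc_pos - orig
        if span:
            blocks.append((mod, mod + span, "nuc", orig))
            mod += span
        blocks.append((mod, mod + ev.total_len, "ins", ev))
        mod += ev.total_len
        orig = ev.nuc_pos
    if orig < orig_len:
        blocks.append((mod, mod + (orig_len - orig), "nuc", orig))
    return blocks


def _mt_subpieces(
    ev: TruthEvent, off0: int, off1: int, L: int
) -> list[tuple[int, int, int, str]]:
    """Map insert-offset range [off0, off1) to mitochondrial target pieces.

    Returns (insert_off0, insert_off1, mt_pos1, target_strand) tuples with
    mt_pos1 the smallest 1-based target coordinate of the piece.
    """
    out = []
    seg_off = 0
    for seg in ev.segments:
        slen = seg.length(L)
        lo, hi = max(off0, seg_off), min(off1, seg_off + slen)
        if lo < hi:
            l0, l1 = lo - seg_off, hi - seg_off  # [l0, l1) within segment
            if seg.strand == "-":
                if seg.wraps:
                    raise NotImplementedError(
                        "fixture emitter does not support minus-strand wrapping segments"
                    )
                out.append((lo, hi, seg.mt_end - l1 + 1, "-"))
            else:
                u0, u1 = seg.mt_start + l0, seg.mt_start + l1 - 1  # unrolled inclusive
                if u1 <= L:
                    out.append((lo, hi, u0, "+"))
                elif u0 > L:
                    out.append((lo, hi, u0 - L, "+"))
                else:
                    cut = lo + (L - u0) + 1  # insert offset of the fold
                    out.append((lo, cut, u0, "+"))
                    out.append((cut, hi, 1, "+"))
        seg_off += slen
    return out


def _span_errors(read: SimRead, a: int, b: int):
    d = read.del_pos[(read.del_pos >= a) & (read.del_pos < b)]
    ii = (read.ins_pos >= a) & (read.ins_pos < b)
    return d, read.ins_pos[ii]


def _cigar_for_span(read: SimRead, a: int, b: int) -> tuple[list[list], int]:
    """M/I/D ops (read-forward order) for modified-reference span [a, b)."""
    dels, inss = _span_errors(read, a, b)
    dset, iset = set(int(p) for p in dels), set(int(p) for p in inss)
    ops: list[list] = []

    def push(op: str, ln: int) -> None:
        if ln <= 0:
            return
        if ops and ops[-1][0] == op:
            ops[-1][1] += ln
        else:
            ops.append([op, ln])

    last = a
    for pos in sorted(dset | iset):
        if pos in dset:
            push("M", pos - last)
            push("D", 1)
            if pos in iset:
                push("I", 1)
        else:
            push("M", pos - last + 1)
            push("I", 1)
        last = pos + 1
    push("M", b - last)
    rlen = sum(ln for op, ln in ops if op in "MI")
    return ops, rlen


def _read_pieces(read: SimRead, blocks, cfg: SimConfig, L: int):
    """Classify the read's span into nuc / iop / mt / clip pieces, read order."""
    raw = []
    for bs, be, kind, payload in blocks:
        a, b = max(read.start0, bs), min(read.end0, be)
        if a >= b:
            continue
        if kind == "nuc":
            raw.append(["nuc", a, b, payload + (a - bs), None])
        else:
            ev: TruthEvent = payload
            off0, off1 = a - bs, b - bs
            if ev.total_len < cfg.split_threshold_bp:
                if off0 == 0 and off1 == ev.total_len:
                    raw.append(["iop", a, b, ev, None])
                else:
                    raw.append(["clip", a, b, None, None])
            else:
                for po0, po1, mt_pos1, tstrand in _mt_subpieces(ev, off0, off1, L):
                    pa, pb = bs + po0, bs + po1
                    if pb - pa >= _MIN_PIECE:
                        raw.append(["mt", pa, pb, mt_pos1, tstrand])
                    else:
                        raw.append(["clip", pa, pb, None, None])
    # demote tiny edge anchors, then insertion ops without both flanks
    if raw and raw[0][0] == "nuc" and raw[0][2] - raw[0][1] < _MIN_PIECE:
        raw[0][0] = "clip"
    if raw and raw[-1][0] == "nuc" and raw[-1][2] - raw[-1][1] < _MIN_PIECE:
        raw[-1][0] = "clip"
    for k, piece in enumerate(raw):
        if piece[0] == "iop":
            if not (
                k > 0
                and raw[k - 1][0] == "nuc"
                and k + 1 < len(raw)
                and raw[k + 1][0] == "nuc"
            ):
                piece[0] = "clip"
    return raw


def _trim_record(rec: dict) -> None:
    ops = rec["ops"]
    while ops and ops[0][0] in "DI":
        op, ln = ops.pop(0)
        if op == "I":
            rec["q0"] += ln
        elif rec["tstrand"] == "+":
            rec["pos1"] += ln
    while ops and ops[-1][0] in "DI":
        op, ln = ops.pop()
        if op == "I":
            rec["q1"] -= ln
        elif rec["tstrand"] == "-":
            rec["pos1"] += ln


def _records_for_read(read: SimRead, blocks, cfg: SimConfig, L: int) -> list[dict]:
    pieces = _read_pieces(read, blocks, cfg, L)
    recs: list[dict] = []
    cur: dict | None = None

    def flush() -> None:
        nonlocal cur
        if cur is not None:
            recs.append(cur)
            cur = None

    qoff = 0
    for kind, a, b, p3, p4 in pieces:
        if kind == "clip":
            _, rlen = _cigar_for_span(read, a, b)
            flush()
        elif kind == "nuc":
            ops, rlen = _cigar_for_span(read, a, b)
            if cur is not None and cur["ref_next"] == p3:
                for op in ops:
                    if cur["ops"] and cur["ops"][-1][0] == op[0]:
                        cur["ops"][-1][1] += op[1]
                    else:
                        cur["ops"].append(op)
                cur["q1"] = qoff + rlen
                cur["ref_next"] = p3 + (b - a)
                cur["spans"].append((a, b))
            else:
                flush()
                cur = {
                    "rname": read.chrom,
                    "pos1": p3 + 1,
                    "ops": ops,
                    "q0": qoff,
                    "q1": qoff + rlen,
                    "tstrand": "+",
                    "ref_next": p3 + (b - a),
                    "spans": [(a, b)],
                }
        elif kind == "iop":
            _, rlen = _cigar_for_span(read, a, b)
            if cur is not None:
                if cur["ops"] and cur["ops"][-1][0] == "I":
                    cur["ops"][-1][1] += rlen
                else:
                    cur["ops"].append(["I", rlen])
                cur["q1"] = qoff + rlen
                cur["spans"].append((a, b))
            # else: unreachable after demotion; bases become clip
        else:  # mt
            flush()
            ops, rlen = _cigar_for_span(read, a, b)
            recs.append(
                {
                    "rname": None,  # filled with mt contig name by caller
                    "pos1": p3,
                    "ops": ops,
                    "q0": qoff,
                    "q1": qoff + rlen,
                    "tstrand": p4,
                    "ref_next": None,
                    "spans": [(a, b)],
                }
            )
        qoff += rlen
    flush()
    for rec in recs:
        _trim_record(rec)
    return [r for r in recs if any(op == "M" for op, _ in r["ops"])]


def _cigar_string(rec: dict, read_len: int) -> str:
    lead, tail = rec["q0"], read_len - rec["q1"]
    ops = rec["ops"] if rec["tstrand"] == "+" else rec["ops"][::-1]
    if rec["tstrand"] == "-":
        lead, tail = tail, lead
    parts = []
    if lead:
        parts.append(f"{lead}S")
    parts.extend(f"{ln}{op}" for op, ln in ops)
    if tail:
        parts.append(f"{tail}S")
    return "".join(parts)


def _nm(rec: dict, read: SimRead) -> int:
    nm = sum(ln for op, ln in rec["ops"] if op in "ID")
    for a, b in rec["spans"]:
        nm += int(np.count_nonzero((read.sub_pos >= a) & (read.sub_pos < b)))
    return nm


def emit_alignments(
    reads: list[SimRead],
    genome_orig: dict[str, str],
    events: list[TruthEvent],
    cfg: SimConfig,
    path: str | Path,
) -> str:
    """Write a coordinate-sorted SAM for the reads, derived from truth (no aligner).

    Reference coordinates are on the *original* genome (the one the caller
    sees); MAPQ is 60 for every emitted record.
    """
    L = cfg.mt_len
    mt_name = cfg.mt_contig
    by_chrom: dict[str, list[TruthEvent]] = {}
    for ev in events:
        by_chrom.setdefault(ev.chrom, []).append(ev)
    blocks = {
        c: _contig_blocks(by_chrom.get(c, []), len(genome_orig[c])) for c in genome_orig
    }
    names = [c for c in genome_orig if c != mt_name] + [mt_name]
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c, "LN": len(genome_orig[c])} for c in names],
    }
    out: list[pysam.AlignedSegment] = []
    with pysam.AlignmentFile(str(path), "wh", header=header) as sam:
        for read in reads:
            recs = _records_for_read(read, blocks[read.chrom], cfg, L)
            if not recs:
                continue
            for rec in recs:
                if rec["rname"] is None:
                    rec["rname"] = mt_name
            nuclear = [r for r in recs if r["rname"] != mt_name]
            pool = nuclear or recs
            primary = max(pool, key=lambda r: (r["q1"] - r["q0"], -r["q0"]))
            read_len = len(read.seq_fwd)
            rc_seq = revcomp(read.seq_fwd)
            rendered = []
            for rec in recs:
                flag = 0
                if rec["tstrand"] != read.strand:
                    flag |= 16
                if rec is not primary:
                    flag |= 2048
                rendered.append(
                    {
                        "rec": rec,
                        "flag": flag,
                        "cigar": _cigar_string(rec, read_len),
                        "nm": _nm(rec, read),
                    }
                )
            for rd in rendered:
                rec = rd["rec"]
                seg = pysam.AlignedSegment(sam.header)
                seg.query_name = read.name
                seg.flag = rd["flag"]
                seg.reference_name = rec["rname"]
                seg.reference_start = rec["pos1"] - 1
                seg.mapping_quality = 60
                seg.cigarstring = rd["cigar"]
                seg.query_sequence = (
                    read.seq_fwd if rec["tstrand"] == "+" else rc_seq
                )
                tags = [("NM", rd["nm"])]
                if len(rendered) > 1:
                    sa = "".join(
                        f"{o['rec']['rname']},{o['rec']['pos1']},"
                        f"{'-' if o['flag'] & 16 else '+'},{o['cigar']},60,{o['nm']};"
                        for o in rendered
                        if o is not rd
                    )
                    tags.append(("SA", sa))
                seg.set_tags(tags)
                out.append(seg)
        tid = {c: i for i, c in enumerate(names)}
        out.sort(key=lambda s: (tid[s.reference_name], s.reference_start))
        for seg in out:
            sam.write(seg)
    return str(path)


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------


@dataclass
class SimDataset:
    config: SimConfig
    genome: dict[str, str]  # original genome, mitochondrial contig included
    mito: MitoReference
    events: list[TruthEvent]
    modified: dict[str, str]
    reads: list[SimRead]
    paths: dict[str, str] = field(default_factory=dict)


def make_dataset(cfg: SimConfig, outdir: str | Path) -> SimDataset:
    """Run the whole generator and write ref/modified FASTA, FASTQ, SAM, truth TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome = make_genome(cfg)
    mito = MitoReference(cfg.mt_contig, genome[cfg.mt_contig])
    events = sample_events(cfg, mito)
    nuclear = {c: s for c, s in genome.items() if c != cfg.mt_contig}
    modified = implant(nuclear, events)
    modified[cfg.mt_contig] = genome[cfg.mt_contig]
    reads = simulate_reads(modified, cfg)
    paths = {
        "reference": str(outdir / "reference.fasta"),
        "modified": str(outdir / "modified.fasta"),
        "reads": str(outdir / "reads.fastq"),
        "alignments": str(outdir / "alignments.sam"),
        "truth": str(outdir / "truth.tsv"),
    }
    write_fasta(genome, paths["reference"])
    write_fasta(modified, paths["modified"])
    write_fastq(reads, paths["reads"])
    emit_alignments(reads, genome, events, cfg, paths["alignments"])
    write_truth(events, paths["truth"])
    return SimDataset(cfg, genome, mito, events, modified, reads, paths)
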