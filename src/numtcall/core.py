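"""Reference handling, circular-coordinate arithmetic, interval algebra and configuration.

The mitochondrial genome is circular; insertions derived from the control
region span the 16,569 -> 1 origin.  Linear aligners cannot report such a
match as one interval, so the caller searches against a *doubled* reference
(the mitochondrial sequence concatenated with itself, sectors ``Concat_1``
and ``Concat_2``).  Everything downstream then needs a small amount of
coordinate algebra to fold positions on the doubled axis back onto the
circle, to canonicalise hits that landed entirely in the second copy, and
to split origin-spanning intervals for reporting and plotting.  That
algebra, plus the shared BEDtools-style interval merge and the pipeline
configuration, lives here.

All coordinates in this package are 1-based inclusive (VCF/BLAST
convention) unless a name explicitly says otherwise.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import yaml

HUMAN_MT_LENGTH = 16_569

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (IUPAC letters beyond ACGTN pass as N-like)."""
    return seq.translate(_COMP)[::-1]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class MitoReference:
    """The mitochondrial contig and its self-concatenated (doubled) form."""

    name: str
    sequence: str

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise ValueError("mitochondrial sequence is empty")

    @property
    def length_bp(self) -> int:
        return len(self.sequence)

    @property
    def doubled_sequence(self) -> str:
        return self.sequence + self.sequence


@dataclass(frozen=True)
class CircularInterval:
    """A 1-based inclusive interval on the mitochondrial circle.

    ``wraps=True`` denotes the union [mt_start..L] + [1..mt_end], i.e. an
    interval crossing the origin (control region).
    """

    mt_start: int
    mt_end: int
    strand: str = "+"
    wraps: bool = False

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r}")
        if self.mt_start < 1 or self.mt_end < 1:
            raise ValueError("circular interval coordinates must be >= 1")
        if not self.wraps and self.mt_start > self.mt_end:
            raise ValueError("non-wrapping interval with mt_start > mt_end")

    def length(self, L: int | None = None) -> int:
        if not self.wraps:
            return self.mt_end - self.mt_start + 1
        if L is None:
            raise ValueError("length of a wrapping interval requires L")
        return (L - self.mt_start + 1) + self.mt_end


@dataclass
class MTSegment:
    """A filtered, merged, circularised mitochondrial interval backing one call.

    ``q_span`` is the 1-based span on the insertion query for SV-branch
    segments, ``None`` for split-branch summaries; likewise ``best_evalue``.
    """

    interval: CircularInterval
    q_span: tuple[int, int] | None = None
    best_evalue: float | None = None

    def length(self, L: int | None = None) -> int:
        return self.interval.length(L)


@dataclass
class ScoringScheme:
    """blastn-default local alignment scoring with Karlin-Altschul constants.

    A gap of length k costs ``gap_open + gap_extend * k`` (BLAST convention).
    The Karlin-Altschul pair (lambda, K) gives E = K * m * n * exp(-lambda*S);
    the defaults are the published gapped blastn values for +2/-3 with
    open 5 / extend 2.
    """

    match: int = 2
    mismatch: int = -3
    gap_open: int = 5
    gap_extend: int = 2
    ka_lambda: float = 0.625
    ka_k: float = 0.41

    def __post_init__(self) -> None:
        if self.ka_lambda <= 0 or self.ka_k <= 0:
            raise ValueError("Karlin-Altschul constants must be positive")

    def evalue(self, score: float, m: int, n: int) -> float:
        """Expected number of chance local alignments scoring >= score."""
        import math

        return self.ka_k * m * n * math.exp(-self.ka_lambda * score)


@dataclass
class PipelineConfig:
    """All caller thresholds; defaults reproduce the optimised set {4, 0.001, 70, 5}."""

    min_sv_support: int = 4
    min_sv_len: int = 24
    min_mapq: int = 1
    evalue_max: float = 1e-3
    min_query_cov_pct: float = 70.0
    hit_merge_gap_bp: int = 10
    anchor_merge_gap_bp: int = 100
    min_split_support: int = 5
    dedupe_window_bp: int = 100
    sig_cluster_window_bp: int = 100
    mt_contig: str = "chrM"
    scoring: ScoringScheme = field(default_factory=ScoringScheme)

    def __post_init__(self) -> None:
        for name in (
            "min_sv_support",
            "min_sv_len",
            "min_mapq",
            "evalue_max",
            "hit_merge_gap_bp",
            "anchor_merge_gap_bp",
            "min_split_support",
            "dedupe_window_bp",
            "sig_cluster_window_bp",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if not 0 < self.min_query_cov_pct <= 100:
            raise ValueError("min_query_cov_pct must be in (0, 100]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        scoring = ScoringScheme(**data.pop("scoring", {}))
        return cls(scoring=scoring, **data)

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    def updated(self, **kwargs) -> "PipelineConfig":
        return dataclasses.replace(self, **kwargs)


# ---------------------------------------------------------------------------
# Circular coordinate arithmetic
# ---------------------------------------------------------------------------


def to_circular(pos_concat: int, L: int) -> int:
    """Fold a 1-based position on the doubled axis [1, 2L] back onto [1, L]."""
    if not 1 <= pos_concat <= 2 * L:
        raise ValueError(f"position {pos_concat} outside doubled axis [1, {2 * L}]")
    return pos_concat if pos_concat <= L else pos_concat - L


def circularize_interval(
    concat_start: int, concat_end: int, strand: str, L: int
) -> CircularInterval:
    """Map an interval on the doubled axis onto the circle.

    Intervals fully inside either copy are canonicalised to first-copy
    coordinates; intervals crossing position L become wrapping intervals.
    Intervals longer than L cannot be represented on the circle.
    """
    if not 1 <= concat_start <= concat_end <= 2 * L:
        raise ValueError(
            f"bad doubled-axis interval [{concat_start}, {concat_end}] for L={L}"
        )
    if concat_end - concat_start + 1 > L:
        raise ValueError("interval longer than the mitochondrial genome")
    if concat_end <= L or concat_start > L:
        return CircularInterval(
            to_circular(concat_start, L), to_circular(concat_end, L), strand, False
        )
    return CircularInterval(concat_start, concat_end - L, strand, True)


def split_wrapped(interval: CircularInterval, L: int) -> list[CircularInterval]:
    """Split a wrapping interval into its Concat_1 tail and Concat_2 head pieces."""
    if not interval.wraps:
        return [interval]
    return [
        CircularInterval(interval.mt_start, L, interval.strand, False),
        CircularInterval(1, interval.mt_end, interval.strand, False),
    ]


def circular_overlap(a: CircularInterval, b: CircularInterval, L: int) -> bool:
    """Do two circular intervals share at least one base on the circle?"""
    for pa in split_wrapped(a, L):
        for pb in split_wrapped(b, L):
            if pa.mt_start <= pb.mt_end and pb.mt_start <= pa.mt_end:
                return True
    return False


# ---------------------------------------------------------------------------
# Interval algebra
# ---------------------------------------------------------------------------


def merge_intervals(
    intervals: Iterable[tuple[int, int]], max_gap: int
) -> list[tuple[int, int]]:
    """Union 1-based closed intervals whose intervening gap is < max_gap bases.

    BEDtools ``merge -d``-like semantics on closed intervals: two intervals
    [a, b], [c, d] with b < c are joined when c - b - 1 < max_gap.
    Idempotent and order-independent.
    """
    ivs = sorted(intervals)
    for s, e in ivs:
        if s > e:
            raise ValueError(f"interval start {s} > end {e}")
    merged: list[list[int]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1] + max_gap:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def union_length(intervals: Iterable[tuple[int, int]]) -> int:
    """Total bases covered by a set of 1-based closed intervals (no double counting)."""
    return sum(e - s + 1 for s, e in merge_intervals(intervals, 1))


# ---------------------------------------------------------------------------
# FASTA I/O
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(contigs: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in contigs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def load_mito(contigs: dict[str, str], mt_contig: str = "chrM") -> MitoReference:
    if mt_contig not in contigs:
        raise KeyError(f"mitochondrial contig {mt_contig!r} not found in reference")
    return MitoReference(mt_contig, contigs[mt_contig])
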