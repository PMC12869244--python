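"""Final call merging, TSV output and circos-style visualisation.

The two branches can detect the same biological event (an insertion short
enough for in-read evidence but long enough to clip some reads), so their
call sets are deduplicated by breakpoint proximity plus mitochondrial
overlap on the circle.  Reporting keeps one row per mitochondrial segment;
control-region (wrapping) segments carry mt_start > mt_end with
wraps=true.  The circos plot shows the doubled mitochondrial genome as two
sectors (Concat_1, Concat_2): a wrapping segment draws two chords, one
from the tail of Concat_1 and one from the head of Concat_2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from .core import (
    CircularInterval,
    MTSegment,
    PipelineConfig,
    circular_overlap,
    split_wrapped,
)


@dataclass
class NuMTCall:
    """A reported NuMT: nuclear breakpoint, MT segment(s) and branch evidence."""

    sample: str
    chrom: str
    breakpoint: int
    segments: list[MTSegment]
    total_mt_len: int
    branch: str  # 'sv' | 'split' | 'both'
    support_sv: int = 0
    support_split: int = 0
    query_cov_pct: float | None = None
    best_evalue: float | None = None


def merge_branches(
    calls_sv: list[NuMTCall],
    calls_split: list[NuMTCall],
    config: PipelineConfig,
    L: int,
) -> list[NuMTCall]:
    """Concatenate branch calls and retain unique events.

    Two calls are duplicates when they share a chromosome, their
    breakpoints differ by <= dedupe_window_bp, and their MT segment unions
    overlap on the circle.  Fusions keep the SV-branch segments (they
    derive from the full inserted sequence) with branch='both' and the
    maximum support from each branch.
    """
    used = [False] * len(calls_split)
    merged: list[NuMTCall] = []
    for sv in calls_sv:
        fused = None
        for j, sp in enumerate(calls_split):
            if used[j] or sp.chrom != sv.chrom:
                continue
            if abs(sp.breakpoint - sv.breakpoint) > config.dedupe_window_bp:
                continue
            if any(
                circular_overlap(a.interval, b.interval, L)
                for a in sv.segments
                for b in sp.segments
            ):
                used[j] = True
                fused = sp
                break
        if fused is None:
            merged.append(sv)
        else:
            merged.append(
                NuMTCall(
                    sample=sv.sample,
                    chrom=sv.chrom,
                    breakpoint=sv.breakpoint,
                    segments=sv.segments,
                    total_mt_len=sv.total_mt_len,
                    branch="both",
                    support_sv=max(sv.support_sv, fused.support_sv),
                    support_split=max(sv.support_split, fused.support_split),
                    query_cov_pct=sv.query_cov_pct,
                    best_evalue=sv.best_evalue,
                )
            )
    merged.extend(sp for j, sp in enumerate(calls_split) if not used[j])
    merged.sort(key=lambda c: (c.chrom, c.breakpoint))
    return merged


# ---------------------------------------------------------------------------
# TSV
# ---------------------------------------------------------------------------

TSV_COLUMNS = [
    "sample",
    "chrom",
    "breakpoint",
    "n_segments",
    "mt_start",
    "mt_end",
    "strand",
    "wraps",
    "segment_len",
    "total_mt_len",
    "branch",
    "support_sv",
    "support_split",
    "query_cov_pct",
    "best_evalue",
]


def _fmt(value, kind: str) -> str:
    if value is None:
        return "NA"
    if kind == "evalue":
        return f"{value:.2e}"
    if kind == "pct":
        return f"{value:.1f}"
    return str(value)


def write_tsv(calls: list[NuMTCall], path: str | Path, L: int | None = None) -> None:
    """One row per MT segment, shared (sample, chrom, breakpoint); deterministic order."""
    rows = []
    for call in sorted(calls, key=lambda c: (c.sample, c.chrom, c.breakpoint)):
        for seg in call.segments:
            iv = seg.interval
            rows.append(
                [
                    call.sample,
                    call.chrom,
                    str(call.breakpoint),
                    str(len(call.segments)),
                    str(iv.mt_start),
                    str(iv.mt_end),
                    iv.strand,
                    str(iv.wraps).lower(),
                    str(iv.length(L)),
                    str(call.total_mt_len),
                    call.branch,
                    str(call.support_sv),
                    str(call.support_split),
                    _fmt(call.query_cov_pct, "pct"),
                    _fmt(call.best_evalue, "evalue"),
                ]
            )
    with open(path, "w") as fh:
        fh.write("\t".join(TSV_COLUMNS) + "\n")
        for row in rows:
            fh.write("\t".join(row) + "\n")


def read_tsv(path: str | Path) -> list[NuMTCall]:
    calls: dict[tuple, NuMTCall] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != TSV_COLUMNS:
            raise ValueError(f"unexpected calls TSV header: {header}")
        for line in fh:
            f = line.rstrip("\n").split("\t")
            key = (f[0], f[1], int(f[2]))
            seg = MTSegment(
                interval=CircularInterval(int(f[4]), int(f[5]), f[6], f[7] == "true"),
                best_evalue=None if f[14] == "NA" else float(f[14]),
            )
            if key in calls:
                calls[key].segments.append(seg)
            else:
                calls[key] = NuMTCall(
                    sample=f[0],
                    chrom=f[1],
                    breakpoint=int(f[2]),
                    segments=[seg],
                    total_mt_len=int(f[9]),
                    branch=f[10],
                    support_sv=int(f[11]),
                    support_split=int(f[12]),
                    query_cov_pct=None if f[13] == "NA" else float(f[13]),
                    best_evalue=None if f[14] == "NA" else float(f[14]),
                )
    return list(calls.values())


# ---------------------------------------------------------------------------
# Circos-style plot
# ---------------------------------------------------------------------------


def plot_circos(
    calls: list[NuMTCall],
    contig_lengths: dict[str, int],
    mt_len: int,
    out_prefix: str | Path,
) -> int:
    """Draw a circos-style overview and write <prefix>.png and <prefix>.svg.

    The outer ring shows the nuclear contigs plus two mitochondrial sectors
    (Concat_1 and Concat_2, each of length mt_len).  Every non-wrapping MT
    segment draws one chord from its midpoint in Concat_1 to the nuclear
    breakpoint; every wrapping segment draws two chords (Concat_1 tail and
    Concat_2 head).  Returns the number of chords drawn.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.patches import PathPatch
    from matplotlib.path import Path as MplPath
    import math

    if not contig_lengths or sum(contig_lengths.values()) <= 0 or mt_len <= 0:
        raise ValueError("genome layout must have positive total length")

    sectors = list(contig_lengths.items()) + [("Concat_1", mt_len), ("Concat_2", mt_len)]
    total = sum(ln for _, ln in sectors)
    pad = 2.0  # degrees between sectors
    span = 360.0 - pad * len(sectors)
    angles: dict[str, tuple[float, float]] = {}
    a = 90.0
    for name, ln in sectors:
        width = span * ln / total
        angles[name] = (a, a - width)
        a -= width + pad

    def angle_at(sector: str, pos: int) -> float:
        a0, a1 = angles[sector]
        ln = dict(sectors)[sector]
        frac = min(max(pos / ln, 0.0), 1.0)
        return a0 + (a1 - a0) * frac

    fig, ax = plt.subplots(figsize=(7, 7), subplot_kw={"aspect": "equal"})
    ax.set_xlim(-1.3, 1.3)
    ax.set_ylim(-1.3, 1.3)
    ax.axis("off")
    cmap = plt.get_cmap("tab20")
    for k, (name, ln) in enumerate(sectors):
        a0, a1 = angles[name]
        theta = [math.radians(t) for t in _frange(a0, a1, 60)]
        for r in (1.0, 1.08):
            ax.plot(
                [r * math.cos(t) for t in theta],
                [r * math.sin(t) for t in theta],
                color=cmap(k % 20),
                lw=2.5 if r == 1.0 else 1.0,
            )
        mid = math.radians((a0 + a1) / 2)
        ax.text(
            1.18 * math.cos(mid),
            1.18 * math.sin(mid),
            name,
            ha="center",
            va="center",
            fontsize=8,
        )

    samples = sorted({c.sample for c in calls})
    sample_color = {s: cmap((2 * i + 1) % 20) for i, s in enumerate(samples)}
    n_links = 0
    for call in calls:
        t_nuc = math.radians(angle_at(call.chrom, call.breakpoint))
        for seg in call.segments:
            pieces = split_wrapped(seg.interval, mt_len)
            sectors_for = (
                ["Concat_1"]
                if len(pieces) == 1
                else ["Concat_1", "Concat_2"]
            )
            for piece, sector in zip(pieces, sectors_for):
                mid_pos = (piece.mt_start + piece.mt_end) / 2
                t_mt = math.radians(angle_at(sector, int(mid_pos)))
                p0 = (math.cos(t_mt), math.sin(t_mt))
                p1 = (math.cos(t_nuc), math.sin(t_nuc))
                path = MplPath(
                    [p0, (0, 0), p1],
                    [MplPath.MOVETO, MplPath.CURVE3, MplPath.CURVE3],
                )
                ax.add_patch(
                    PathPatch(
                        path,
                        fill=False,
                        lw=0.9,
                        color=sample_color[call.sample],
                        alpha=0.8,
                    )
                )
                n_links += 1
    if len(samples) > 1:
        for i, s in enumerate(samples):
            ax.plot([], [], color=sample_color[s], label=s)
        ax.legend(loc="lower left", fontsize=7, frameon=False)
    out_prefix = str(out_prefix)
    fig.savefig(out_prefix + ".png", dpi=150)
    fig.savefig(out_prefix + ".svg")
    plt.close(fig)
    return n_links


def _frange(a: float, b: float, n: int) -> list[float]:
    return [a + (b - a) * i / (n - 1) for i in range(n)]
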