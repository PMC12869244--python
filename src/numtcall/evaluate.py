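"""Benchmarking: call-vs-truth matching and precision/recall/F1 arithmetic.

A call matches a truth event when both lie on the same chromosome and
their breakpoints differ by at most the tolerance (default 100 bp);
matching is greedy one-to-one by increasing breakpoint distance, so a
truth event consumes at most one call and vice versa.  Matching is
breakpoint-level by default; ``strict_mt`` additionally requires the call
and truth mitochondrial segments to overlap on the circle.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

from .core import circular_overlap
from .report import NuMTCall
from .simulate import TruthEvent


@dataclass
class BenchmarkResult:
    tp: int
    fp: int
    fn: int
    precision: float | None
    recall: float | None
    f1: float | None

    def rounded(self, ndigits: int = 3) -> dict:
        """Counts plus metrics rounded half-up to ndigits (None stays None)."""

        def r(x):
            if x is None:
                return None
            return float(
                Decimal(repr(x)).quantize(
                    Decimal(1).scaleb(-ndigits), rounding=ROUND_HALF_UP
                )
            )

        return {
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
            "precision": r(self.precision),
            "recall": r(self.recall),
            "f1": r(self.f1),
        }


def match_calls(
    calls: list[NuMTCall],
    truth: list[TruthEvent],
    tolerance_bp: int = 100,
    strict_mt: bool = False,
    L: int | None = None,
) -> tuple[list[tuple[NuMTCall, TruthEvent]], list[NuMTCall], list[TruthEvent]]:
    """Greedy one-to-one matching; returns (matches, false positives, false negatives)."""
    pairs = []
    for i, call in enumerate(calls):
        for j, ev in enumerate(truth):
            if call.chrom != ev.chrom:
                continue
            dist = abs(call.breakpoint - ev.nuc_pos)
            if dist > tolerance_bp:
                continue
            if strict_mt:
                if L is None:
                    raise ValueError("strict_mt matching requires L")
                if not any(
                    circular_overlap(cs.interval, ts, L)
                    for cs in call.segments
                    for ts in ev.segments
                ):
                    continue
            pairs.append((dist, i, j))
    pairs.sort()
    used_call: set[int] = set()
    used_truth: set[int] = set()
    matches = []
    for _, i, j in pairs:
        if i in used_call or j in used_truth:
            continue
        used_call.add(i)
        used_truth.add(j)
        matches.append((calls[i], truth[j]))
    fps = [c for i, c in enumerate(calls) if i not in used_call]
    fns = [t for j, t in enumerate(truth) if j not in used_truth]
    return matches, fps, fns


def score(tp: int, fp: int, fn: int) -> BenchmarkResult:
    """Precision, recall and F1 from confusion counts; undefined ratios are None."""
    if min(tp, fp, fn) < 0:
        raise ValueError("confusion counts must be non-negative")
    precision = tp / (tp + fp) if tp + fp > 0 else None
    recall = tp / (tp + fn) if tp + fn > 0 else None
    if precision is not None and recall is not None and precision + recall > 0:
        f1 = 2 * precision * recall / (precision + recall)
    else:
        f1 = None
    return BenchmarkResult(tp, fp, fn, precision, recall, f1)


def benchmark(
    calls: list[NuMTCall],
    truth: list[TruthEvent],
    tolerance_bp: int = 100,
    strict_mt: bool = False,
    L: int | None = None,
) -> BenchmarkResult:
    matches, fps, fns = match_calls(calls, truth, tolerance_bp, strict_mt, L)
    return score(len(matches), len(fps), len(fns))
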