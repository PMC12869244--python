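"""Affine-gap Smith-Waterman search engine used to realign inserts to the doubled MT.

Vectorised per query row with numpy.  The within-row (target-axis) affine
gap recurrence is resolved exactly with a prefix-max scan: a horizontal gap
entering column j from an H-cell that itself ended in a horizontal gap
would pay the gap-open penalty twice, so the scan over the gap-free row
values dominates all chained cases.

Start coordinates are recovered by re-running the score-only pass on the
reversed prefixes (the standard linear-memory trick), so memory stays
O(target length) regardless of problem size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

_NEG = -1.0e18


def encode(seq: str) -> np.ndarray:
    """Encode A/C/G/T as 0..3, anything else as 4 (never matches)."""
    raw = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    out = np.full(raw.size, 4, dtype=np.int8)
    for code, base in enumerate(b"ACGT"):
        out[raw == base] = code
    return out


@dataclass(frozen=True)
class LocalHit:
    """Best local alignment: 0-based inclusive endpoints on query and target."""

    score: float
    q_start: int
    q_end: int
    t_start: int
    t_end: int


def _best_end(
    q: np.ndarray,
    t: np.ndarray,
    match: float,
    mismatch: float,
    gap_open: float,
    gap_ext: float,
    qmask: np.ndarray | None,
) -> tuple[float, int, int]:
    """Score-only pass; returns (best score, 0-based query end, 0-based target end)."""
    n = t.size
    h_prev = np.zeros(n + 1)
    e_prev = np.full(n + 1, _NEG)  # gap consuming query (vertical)
    idx = np.arange(n, dtype=float)
    best = 0.0
    bi = bj = -1
    open_ext = gap_open + gap_ext
    t_is_n = t == 4
    for i in range(q.size):
        if qmask is not None and qmask[i]:
            srow = np.full(n, -1.0e6)
        elif q[i] == 4:
            srow = np.full(n, mismatch)
        else:
            srow = np.where(t == q[i], match, mismatch)
            if t_is_n.any():
                srow[t_is_n] = mismatch
        e_cur = np.maximum(h_prev[1:] - open_ext, e_prev[1:] - gap_ext)
        tmp = np.maximum(h_prev[:-1] + srow, e_cur)
        np.maximum(tmp, 0.0, out=tmp)
        # horizontal (target-consuming) gaps via prefix-max scan
        cm = np.maximum.accumulate(tmp + gap_ext * idx)
        h = tmp.copy()
        if n > 1:
            f = cm[:-1] - gap_open - gap_ext * idx[1:]
            np.maximum(h[1:], f, out=h[1:])
        j = int(h.argmax())
        if h[j] > best:
            best = float(h[j])
            bi, bj = i, j
        h_prev[1:] = h
        e_prev[1:] = e_cur
    return best, bi, bj


def best_local_alignment(
    q: np.ndarray,
    t: np.ndarray,
    match: float,
    mismatch: float,
    gap_open: float,
    gap_ext: float,
    qmask: np.ndarray | None = None,
) -> LocalHit | None:
    """Best local alignment of encoded query vs encoded target.

    ``qmask`` marks query positions excluded from matching (already claimed
    by an earlier hit during iterated search).  Returns None when nothing
    scores above zero.
    """
    score, qe, te = _best_end(q, t, match, mismatch, gap_open, gap_ext, qmask)
    if score <= 0:
        return None
    rmask = None if qmask is None else qmask[: qe + 1][::-1]
    score2, ri, rj = _best_end(
        q[: qe + 1][::-1], t[: te + 1][::-1], match, mismatch, gap_open, gap_ext, rmask
    )
    qs = qe - ri
    ts = te - rj
    if abs(score2 - score) > 1e-6:  # pragma: no cover - internal consistency
        raise AssertionError("forward/reverse local alignment scores disagree")
    return LocalHit(score, qs, qe, ts, te)
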