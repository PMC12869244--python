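"""Call a control-region (origin-spanning) NuMT via the doubled reference.

An insert copied from the mitochondrial control region crosses the
16,569 -> 1 origin, so against a single-copy reference it would align as
two pieces.  Realignment against the doubled reference captures it as one
contiguous hit, which is then folded back onto the circle as a wrapping
interval (mt_start > mt_end, wraps=True); the circos plot would render it
as two chords, one leaving the tail of Concat_1 and one the head of
Concat_2.
"""

import numpy as np

from numtcall import MitoReference, PipelineConfig, split_wrapped
from numtcall.insertion_branch import InsertionCall, call_from_insertions

rng = np.random.default_rng(321)
mt = np.frombuffer(b"ACGT", dtype=np.uint8)[rng.integers(0, 4, 16_569)].tobytes().decode()
mito = MitoReference("chrM", mt)
L = mito.length_bp

insert = mito.sequence[L - 150 :] + mito.sequence[:80]  # spans the origin
call = InsertionCall("chr1", 250_000, insert, support=9, read_names=set())

[numt] = call_from_insertions([call], mito, PipelineConfig())
iv = numt.segments[0].interval
print(f"wrapping segment MT:{iv.mt_start}-{iv.mt_end} wraps={iv.wraps} "
      f"length={iv.length(L)} bp")
for part in split_wrapped(iv, L):
    print(f"  plot link piece: MT:{part.mt_start}-{part.mt_end}")
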