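"""Draw the circos-style overview for a simulated sample's calls.

Writes sample.circos.png and sample.circos.svg in the working directory.
The printed link count equals the number of chords: one per mitochondrial
segment, two for segments that span the origin.
"""

import tempfile

from numtcall import SimConfig, make_dataset, plot_circos, run_caller

cfg = SimConfig(n_chroms=2, chrom_len_bp=500_000, n_events=8, seed=21)
with tempfile.TemporaryDirectory() as tmp:
    ds = make_dataset(cfg, tmp)
    calls = run_caller(ds.paths["alignments"], ds.mito)

layout = {c: len(s) for c, s in ds.genome.items() if c != "chrM"}
n_links = plot_circos(calls, layout, ds.mito.length_bp, "sample.circos")
print(f"{len(calls)} calls drawn as {n_links} links -> sample.circos.png / .svg")
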