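# Methods

## Problem and model

A NuMT (nuclear mitochondrial DNA segment) is an insertion of mitochondrial
sequence into a nuclear chromosome. The caller treats detection as two
sub-problems keyed to insert size relative to read length:

- **In-read insertions.** A read that fully spans the insert aligns with a
  single CIGAR `I` operation whose bases are the insert. Detection reduces
  to (a) finding well-supported insertion calls and (b) deciding whether the
  inserted sequence is mitochondrial.
- **Split alignments.** When the insert is comparable to or longer than the
  reads, no read spans it; reads crossing a boundary align partly to the
  nucleus and partly to the mitochondrial contig (supplementary alignments
  linked by SA tags). Detection reduces to clustering nuclear anchors of
  such reads and counting distinct supporting reads per breakpoint.

Both branches share one coordinate convention (1-based inclusive) and one
circularity device: the mitochondrial genome is searched as two tandem
copies (`Concat_1` + `Concat_2`, total length 2L). A hit crossing position L
is folded back onto the circle as a *wrapping* interval `[mt_start..L] ∪
[1..mt_end]`; a hit landing entirely in the second copy is canonicalised to
first-copy coordinates so identical NuMTs never differ by L.

## Insertion-branch cascade

1. **Signature scan.** One signature per `I` operation of length ≥
   `min_sv_len` (24 bp) on a primary alignment with MAPQ ≥ `min_mapq` (1).
   The breakpoint is the reference base immediately left of the inserted
   bases, computed from the reference-consuming CIGAR prefix.
2. **Clustering.** Single-linkage within `sig_cluster_window_bp` (100 bp)
   per chromosome; clusters with fewer than `min_sv_support` (4) distinct
   read names are dropped. The breakpoint is the median signature position
   (lower median); the representative insert is the member of median length,
   ties resolved toward the longer member. A consensus is deliberately not
   built: at the simulated error rates a median-length raw insert aligns
   essentially as well, and it keeps the branch free of partial-order
   alignment machinery.
3. **Realignment.** Iterated best local alignment of the insert (both
   strands) against the doubled MT: report the best-scoring hit, mask its
   query span, repeat until the best remaining score is not significant.
   Masking is by query position only, which is what allows a two-fragment
   insert to yield two hits at distant subject positions. Significance is
   the Karlin–Altschul expectation E = K·m·n·exp(−λS) with m the insert
   length and n = 2L (the doubled reference is the actual search space).
4. **Filter cascade**, in the stated order: drop hits with E ≥ `evalue_max`
   (10⁻³); merge retained hits that share a strand, are collinear, and have
   intervening gaps < `hit_merge_gap_bp` (10 bp) on **both** the query axis
   and the doubled-subject axis (single-linkage closure); fold each merged
   group onto the circle; keep the insertion when the union of retained
   query spans covers ≥ `min_query_cov_pct` (70 %) of the insert. The
   both-axes reading of the 10 bp merge is the only one under which a
   two-fragment insert with adjacent query spans but a ~2 kb subject gap is
   reported as two segments.

## Split-branch procedure

Primary nuclear alignments (MAPQ ≥ `min_mapq`, applied to the nuclear anchor
only — supplementary MAPQ is unreliable by convention) whose SA tag names
the mitochondrial contig yield one anchor each; the reciprocal orientation
(MT primary, nuclear supplementary) is also accepted, since the aligner
picks the primary by score, and deduplicated by (read, chromosome, clip
side). The clip side is determined by comparing read-coordinate offsets of
the nuclear and mitochondrial portions. Anchor intervals merge
single-linkage at < `anchor_merge_gap_bp` (100 bp); within each merged
region, clip positions are sub-grouped by the same gap rule and every group
with ≥ `min_split_support` (5) distinct reads becomes one call. Sub-grouping
matters with long reads: anchors extend up to a read length from each
junction, so one merged region can legitimately contain two distinct
junctions. Each call's breakpoint is the group's median clip position. The
MT interval is summarised by per-endpoint medians of the anchors' unrolled
intervals (wrapping when the summary crosses the origin); it is a support
summary, not a base-precise reconstruction — unlike SV-branch segments,
which derive from the full inserted sequence and are kept in preference
when the two branches are fused.

## Merging, output, plotting

Two calls are duplicates when they share a chromosome, their breakpoints
are within `dedupe_window_bp` (100 bp), and their MT intervals overlap on
the circle; fusions are labelled `both` with the maximum support from each
branch. The TSV has one row per MT segment; E-values are printed with two
significant digits and coordinates as integers so outputs are bit-stable.
The circos overview draws one chord per non-wrapping segment and two per
wrapping segment (Concat_1 tail + Concat_2 head); multiple samples overlay
in one figure, coloured by sample.

## Benchmarking

A call matches a truth event when the chromosomes agree and the breakpoints
differ by ≤ 100 bp (configurable; a strict mode additionally requires MT
overlap on the circle). Matching is greedy one-to-one by increasing
distance, so tp + fn = |truth| and tp + fp = |calls| always hold. Precision,
recall and F1 use the standard formulas; undefined ratios are reported as
not-available rather than zero, and rounding for display is half-up to
three decimals.

## Simulator: what it emulates, what it does not

The generator reproduces the study conditions at desk scale: by default a
2 × 1 Mb nuclear genome (i.i.d. bases) plus a 16,569 bp mitochondrial
contig; 30 implanted NuMTs with sizes uniform on [30, 16,569] bp, 15 % of
events spanning the origin and 15 % composed of two fragments separated by
a 0.1–3 kb mitochondrial gap; nuclear positions ≥ ~51 kb apart; 30X
coverage; lognormal read lengths with mean 10 kb and CV 0.55 (clipped to
[200, 30,000] bp); i.i.d. per-base errors totalling 5 % (3 % substitution,
1 % insertion, 1 % deletion). Uniform sizes, the lognormal length model and
the i.i.d. error model are this package's own choices where only ranges and
means are externally fixed; real instrument error is bursty and
context-dependent, and real NuMT size distributions are heavily skewed
short, so passing tests demonstrate the *logic* of the caller — coordinate
arithmetic, thresholds, branch complementarity, deduplication — not its
error tolerance on a particular instrument profile.

The SAM fixture emitter replaces an aligner, not an alignment model: reads
wholly containing an insert shorter than `split_threshold_bp` (2,500 bp)
get a primary nuclear alignment with an `I` operation; reads touching
longer inserts get soft-clipped nuclear primaries plus MT supplementaries
with mutually consistent SA tags; partial overlaps of short inserts at read
edges are soft-clipped outright. The 2,500 bp default sits at the crossover
where in-read insertion evidence gives way to split-read evidence for 10 kb
reads, so fixture data exercises both branches. Alignment pieces shorter than 30 bp are
not emitted as records (a real aligner would not place them uniquely).
Consequences worth knowing: fixture branch assignment is deterministic by
insert size, MAPQ is always 60, and there are no mismapped or chimeric
reads — so the false-positive behaviour of the caller on repetitive real
genomes is out of scope here. Minus-strand *wrapping* segments are not
supported by the emitter (the generator never produces the combination);
the caller itself handles them through the doubled-reference search.

## Numerical choices

- **Scoring**: blastn defaults +2/−3 with gap cost 5 + 2k; Karlin–Altschul
  gapped constants for that scheme, λ = 0.625, K = 0.41. Raw lengths (not
  effective lengths) enter E = K·m·n·e^(−λS); at these search-space sizes
  the edge correction is far smaller than the 10⁻³ threshold margin.
- **Smith–Waterman engine**: numpy-vectorised per query row; the within-row
  affine-gap recurrence is solved exactly with a prefix-max scan (a
  horizontal gap chained through another horizontal-gap cell pays the open
  penalty twice and is dominated). Start coordinates come from a reverse
  pass over the prefixes, so memory is O(n). Iteration stops early when the
  remaining unmasked query bases cannot reach the minimum significant score.
- **Percent identity** is bookkeeping only (never used for filtering) and
  is computed from an edit-distance alignment of the hit subsequences.
- **Medians**: breakpoints use the lower median; ties in representative
  insert length resolve toward the longer insert.
- **Degenerate inputs**: empty insert sequences are an error; empty hit
  lists yield coverage 0; undefined benchmark ratios are None; intervals
  longer than L cannot be circularised and raise.

## Problem sizes

The test suite and the acceptance script run the full study at 2 × 1 Mb /
30 events / 30X (~6,800 reads, ~2 minutes end to end) and unit-level checks
on 150–400 kb genomes; these sizes were chosen so the entire evaluation
reproduces comfortably on a single CPU while still exercising every event
class (short, long, origin-spanning, two-fragment) with realistic read
support per event.

## Known limitations

- The split-branch MT interval is a median summary; its endpoints can be
  off by up to about a read length, and mixtures of left- and right-side
  anchors for origin-spanning events can blur the wrap. Breakpoints are
  unaffected.
- No genotyping, no deletion/duplication/inversion calling, no assembly of
  the inserted sequence from split reads.
- One mitochondrial contig only; the doubling trick is the full extent of
  circular-genome support.
- The VCF entry point requires insertion sequences in ALT; symbolic
  `<INS>` records are skipped with a warning.
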