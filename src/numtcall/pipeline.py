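"""End-to-end caller: run both branches over an alignment file and merge."""

from __future__ import annotations

from pathlib import Path

from . import insertion_branch, split_branch
from .core import MitoReference, PipelineConfig, load_mito, read_fasta
from .report import NuMTCall, merge_branches


def run_caller(
    alignments: str | Path,
    mito: MitoReference,
    config: PipelineConfig | None = None,
    vcf: str | Path | None = None,
    sample: str = "sample",
) -> list[NuMTCall]:
    """Call NuMTs from a coordinate-sorted SAM/BAM.

    The SV branch discovers insertions from in-read CIGAR `I` signatures,
    or ingests them from a Sniffles2-style VCF when ``vcf`` is given; the
    split branch always runs over the supplementary alignments.  Returns
    the merged, deduplicated call set sorted by (chrom, breakpoint).
    """
    config = config or PipelineConfig()
    if vcf is not None:
        insertions = insertion_branch.load_vcf_insertions(str(vcf), config)
    else:
        signatures = insertion_branch.scan_insertion_signatures(str(alignments), config)
        signatures = [s for s in signatures if s.chrom != mito.name]
        insertions = insertion_branch.cluster_signatures(signatures, config)
    calls_sv = insertion_branch.call_from_insertions(insertions, mito, config, sample)

    anchors = split_branch.extract_split_anchors(
        str(alignments), mito.name, config, L=mito.length_bp
    )
    clusters = split_branch.cluster_anchors(anchors, config)
    calls_split = split_branch.call_from_split(clusters, config, mito.length_bp, sample)

    return merge_branches(calls_sv, calls_split, config, mito.length_bp)


def run_caller_from_files(
    alignments: str | Path,
    reference: str | Path,
    config: PipelineConfig | None = None,
    vcf: str | Path | None = None,
    sample: str = "sample",
) -> tuple[list[NuMTCall], MitoReference, dict[str, str]]:
    """Convenience wrapper reading the reference FASTA from disk."""
    config = config or PipelineConfig()
    contigs = read_fasta(reference)
    mito = load_mito(contigs, config.mt_contig)
    calls = run_caller(alignments, mito, config, vcf=vcf, sample=sample)
    return calls, mito, contigs
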