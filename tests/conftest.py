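import numpy as np
import pysam
import pytest

from numtcall.core import MitoReference, PipelineConfig

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def random_dna(n: int, seed: int) -> str:
    rng = np.random.default_rng(seed)
    return _BASES[rng.integers(0, 4, n)].tobytes().decode("ascii")


@pytest.fixture(scope="session")
def mito() -> MitoReference:
    """Full-size (16,569 bp) random mitochondrial reference."""
    return MitoReference("chrM", random_dna(16_569, 123))


@pytest.fixture(scope="session")
def small_mito() -> MitoReference:
    """2 kb mitochondrial reference for exhaustive-oracle comparisons."""
    return MitoReference("chrM", random_dna(2_000, 321))


@pytest.fixture
def config() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture(scope="session")
def sam_header() -> pysam.AlignmentHeader:
    return pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6"},
            "SQ": [
                {"SN": "chr1", "LN": 1_000_000},
                {"SN": "chr2", "LN": 1_000_000},
                {"SN": "chrM", "LN": 16_569},
            ],
        }
    )


def _query_len(cigar: str) -> int:
    import re

    return sum(
        int(n) for n, op in re.findall(r"(\d+)([MIDNSHP=X])", cigar) if op in "MIS=X"
    )


@pytest.fixture(scope="session")
def record_factory(sam_header):
    """Build an in-memory pysam AlignedSegment from compact arguments."""

    def make(
        name: str,
        chrom: str,
        pos1: int,
        cigar: str,
        mapq: int = 60,
        seq: str | None = None,
        flag: int = 0,
        tags: list | None = None,
    ) -> pysam.AlignedSegment:
        rec = pysam.AlignedSegment(sam_header)
        rec.query_name = name
        rec.flag = flag
        rec.reference_name = chrom
        rec.reference_start = pos1 - 1
        rec.mapping_quality = mapq
        rec.cigarstring = cigar
        rec.query_sequence = seq if seq is not None else "A" * _query_len(cigar)
        if tags:
            rec.set_tags(tags)
        return rec

    return make
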