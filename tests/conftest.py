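"""Shared test fixtures: in-memory reference sequences and toy transcripts."""

from __future__ import annotations

import pytest

from haplase.model import HetLocus, TranscriptModel


class StringReference:
    """ReferenceSource over explicit chromosome strings (1-based fetch)."""

    def __init__(self, sequences: dict[str, str]) -> None:
        self.sequences = sequences

    def fetch(self, chrom: str, start: int, end: int) -> str:
        return self.sequences[chrom][start - 1 : end]


@pytest.fixture
def string_reference():
    return StringReference


def make_locus(chrom="chr1", pos=100, hap1="A", hap2="G", gene="g1",
               phase_set="1", ref=None):
    return HetLocus(chrom, pos, hap1, hap2, gene, phase_set, ref_base=ref)


@pytest.fixture
def coding_plus_transcript():
    """Single-exon + strand transcript: exon 1..30, CDS 10..18 (3 codons)."""
    return TranscriptModel(
        transcript_id="t1", gene_id="g1", chrom="chr1", strand="+",
        exons=((1, 30),), cds=((10, 18),),
    )
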