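"""Format readers/writers: VCF, mpileup grammar, BED, GTF, TSV round-trips."""

from __future__ import annotations

import math

import pytest
from hypothesis import given, settings, strategies as st

from haplase import formats_io
from haplase.errors import ParseError
from haplase.model import ASEEvent, LocusCounts, PeakSet
from haplase.synthetic_data import (
    SimulationConfig,
    generate_phased_transcriptome,
    generate_peak_track,
    simulate_counts,
    write_bed_peaks,
    write_mpileup,
    write_phased_vcf,
)

# ----------------------------------------------------------------- VCF -----

VCF_HEADER = """##fileformat=VCFv4.2
##INFO=<ID=GENE,Number=1,Type=String,Description="Gene identifier">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=PS,Number=1,Type=Integer,Description="Phase set">
##contig=<ID=chr1,length=1000000>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1
"""


def write_vcf(tmp_path, body):
    path = tmp_path / "test.vcf"
    path.write_text(VCF_HEADER + body)
    return path


def test_vcf_phased_het_conventions(tmp_path):
    path = write_vcf(
        tmp_path,
        "chr1\t100\t.\tA\tG\t.\tPASS\tGENE=g1\tGT:PS\t0|1:5\n"
        "chr1\t200\t.\tA\tG\t.\tPASS\tGENE=g2\tGT:PS\t1|0:6\n",
    )
    events = formats_io.read_phased_vcf(path)
    assert len(events) == 2
    first, second = events
    # 0|1: haplotype 1 carries REF
    assert (first.loci[0].hap1_base, first.loci[0].hap2_base) == ("A", "G")
    # 1|0 swaps the haplotype assignment
    assert (second.loci[0].hap1_base, second.loci[0].hap2_base) == ("G", "A")


def test_vcf_groups_by_phase_set(tmp_path):
    body = "".join(
        f"chr1\t{pos}\t.\tA\tG\t.\tPASS\tGENE=g1\tGT:PS\t0|1:9\n"
        for pos in (100, 200, 300)
    )
    events = formats_io.read_phased_vcf(write_vcf(tmp_path, body))
    assert len(events) == 1
    assert len(events[0].loci) == 3
    assert events[0].hap1_string == "AAA" and events[0].hap2_string == "GGG"


def test_vcf_skips_unphased_het_and_non_snps(tmp_path, caplog):
    body = (
        "chr1\t100\t.\tA\tG\t.\tPASS\tGENE=g1\tGT:PS\t0/1:1\n"  # unphased
        "chr1\t150\t.\tAT\tA\t.\tPASS\tGENE=g1\tGT:PS\t0|1:1\n"  # indel
        "chr1\t200\t.\tA\tG\t.\tPASS\tGENE=g1\tGT:PS\t1|1:1\n"  # hom
        "chr1\t300\t.\tA\tG\t.\tPASS\tGENE=g1\tGT:PS\t0|1:1\n"
    )
    with caplog.at_level("WARNING"):
        events = formats_io.read_phased_vcf(write_vcf(tmp_path, body))
    assert len(events) == 1 and len(events[0].loci) == 1
    assert events[0].loci[0].pos == 300
    assert "unphased" in caplog.text


def test_vcf_malformed_raises_parse_error(tmp_path):
    path = tmp_path / "bad.vcf"
    path.write_text("this is not a VCF\n")
    with pytest.raises(ParseError):
        formats_io.read_phased_vcf(path)


def test_vcf_round_trip_preserves_haplotypes(tmp_path):
    config = SimulationConfig(n_genes=40, seed=3)
    events, _ = generate_phased_transcriptome(config)
    path = tmp_path / "sim.vcf"
    write_phased_vcf(events, path)
    back = {e.gene_id: e for e in formats_io.read_phased_vcf(path)}
    assert len(back) == len(events)
    for event in events:
        got = back[event.gene_id]
        assert got.hap1_string == event.hap1_string
        assert got.hap2_string == event.hap2_string
        assert [l.pos for l in got.loci] == [l.pos for l in event.loci]


# ------------------------------------------------------------- mpileup -----

def test_pileup_simple_line(tmp_path):
    path = tmp_path / "a.pileup"
    path.write_text("chr1\t100\tA\t7\t.,.,G,.\tIIIIIII\n")
    (lc,) = formats_io.read_mpileup(path)
    assert lc.tallies == {"A": 6, "G": 1}
    assert lc.depth == 7


def test_pileup_markup_consumed(tmp_path):
    path = tmp_path / "b.pileup"
    path.write_text("chr1\t101\tC\t3\t^].$,.\tIII\n")
    (lc,) = formats_io.read_mpileup(path)
    assert lc.tallies == {"C": 3}


def test_pileup_indels_and_deletions():
    # +2AG insertion attached to a ref match; * consumes one quality char
    tallies = formats_io.decode_pileup_bases(".+2AG,t*", "IIII", "G", 13)
    assert tallies == {"G": 2, "T": 1}


def test_pileup_quality_filtering():
    # '!' is Phred 0, '+' is Phred 10: both below the default floor of 13
    tallies = formats_io.decode_pileup_bases(".,GT", "I!+I", "A", 13)
    assert tallies == {"A": 1, "T": 1}
    # floor of 0 keeps everything
    assert formats_io.decode_pileup_bases(".,GT", "I!+I", "A", 0) == {
        "A": 2, "G": 1, "T": 1,
    }


def test_pileup_zero_depth(tmp_path):
    path = tmp_path / "c.pileup"
    path.write_text("chr1\t100\tA\t0\t*\t*\n")
    (lc,) = formats_io.read_mpileup(path)
    assert lc.tallies == {} and lc.depth == 0


def test_pileup_length_mismatch_raises():
    with pytest.raises(ParseError):
        formats_io.decode_pileup_bases("..,", "II", "A", 13)


def test_pileup_round_trip(tmp_path):
    config = SimulationConfig(n_genes=60, seed=5, error_rate=0.02)
    events, truth = generate_phased_transcriptome(config)
    counts = simulate_counts(events, truth, config)
    path = tmp_path / "sim.pileup"
    write_mpileup(counts, path)
    back = {(c.chrom, c.pos): c for c in formats_io.read_mpileup(path)}
    for lc in counts:
        got = back[(lc.chrom, lc.pos)]
        assert got.tallies == {b: n for b, n in lc.tallies.items() if n > 0}


@given(
    st.dictionaries(
        st.sampled_from("ACGT"), st.integers(0, 50), min_size=1, max_size=4
    )
)
@settings(derandomize=True, max_examples=100)
def test_pileup_grammar_round_trip_random_tallies(tmp_path_factory, tallies):
    """Writer -> grammar decoder is the identity on arbitrary tallies."""
    lc = LocusCounts("chr1", 10, "A", dict(tallies), sum(tallies.values()))
    path = tmp_path_factory.mktemp("pileup") / "x.pileup"
    write_mpileup([lc], path)
    (back,) = formats_io.read_mpileup(path)
    assert back.tallies == {b: n for b, n in tallies.items() if n > 0}


# ----------------------------------------------------------------- BED -----

def test_bed_coordinate_convention(tmp_path):
    path = tmp_path / "p.bed"
    path.write_text("chr1\t99\t200\tH3K27ac\tliver\ts1\n")
    (ps,) = formats_io.read_bed_peaks(path)
    chrom, start1, end1 = formats_io.bed_to_one_based(ps.intervals[0])
    assert (chrom, start1, end1) == ("chr1", 100, 200)
    assert formats_io.one_based_to_bed((chrom, start1, end1)) == ("chr1", 99, 200)


def test_bed_rejects_bad_intervals(tmp_path):
    path = tmp_path / "bad.bed"
    path.write_text("chr1\t200\t100\tH3K27ac\tliver\ts1\n")
    with pytest.raises(ParseError):
        formats_io.read_bed_peaks(path)


def test_bed_round_trip(tmp_path):
    config = SimulationConfig(n_genes=50, seed=9)
    events, _ = generate_phased_transcriptome(config)
    tracks = [
        generate_peak_track(events, mark, "liver", 0.5, seed=9)
        for mark in ("H3K27ac", "H3K4me1")
    ]
    path = tmp_path / "peaks.bed"
    write_bed_peaks(tracks, path)
    back = {ps.mark: ps for ps in formats_io.read_bed_peaks(path)}
    for ps in tracks:
        assert back[ps.mark].intervals == ps.intervals
        assert back[ps.mark].tissue == ps.tissue


# ----------------------------------------------------------------- GTF -----

def test_gtf_one_based_inclusive(tmp_path):
    path = tmp_path / "t.gtf"
    attrs = 'gene_id "g1"; transcript_id "t1";'
    path.write_text(
        f"chr1\tsrc\texon\t100\t150\t.\t+\t.\t{attrs}\n"
        f"chr1\tsrc\tCDS\t110\t130\t.\t+\t0\t{attrs}\n"
    )
    (model,) = formats_io.read_gtf(path)
    assert model.exons == ((100, 150),)
    assert model.cds == ((110, 130),)
    (s, e) = model.exons[0]
    assert s <= 150 <= e          # 150 inside
    assert not (s <= 151 <= e)    # 151 outside


# ----------------------------------------------------------------- TSV -----

def test_ase_event_table_round_trip(tmp_path):
    events = [
        ASEEvent("g1", "liver", "s1", 95, 5, 4.2479, 1e-18, 2e-18, True, True,
                 "chr1", 100, 400),
        ASEEvent("g2", "liver", "s1", 20, 0, math.inf, 1.9e-6, 2e-6, True, True,
                 "chr2", 5, 5),
        ASEEvent("g3", "liver", "s1", 4, 3, 0.415, math.nan, 1.0, False, False,
                 "chr3", 9, 90),
    ]
    path = tmp_path / "events.tsv"
    formats_io.write_tsv(formats_io.events_to_frame(events), path)
    back = formats_io.frame_to_events(formats_io.read_tsv(path))
    for orig, got in zip(events, back):
        for attr in ("gene_id", "tissue", "sample", "allele1_exp", "allele2_exp",
                     "prefilter_pass", "significant", "chrom", "start", "end"):
            assert getattr(got, attr) == getattr(orig, attr)
        assert got.aefc == orig.aefc or (
            math.isnan(got.aefc) and math.isnan(orig.aefc)
        )
        assert got.p_value == pytest.approx(orig.p_value, nan_ok=True)
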