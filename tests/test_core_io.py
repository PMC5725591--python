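"""Format I/O: VCF round-trips, genotype-category derivation, BED coordinate
conventions, GFF3 gene-structure derivation."""

import textwrap

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clonotyper.core_io import (
    FormatError,
    GenotypeCall,
    GenotypeCategory,
    RegionMask,
    read_gff3_genes,
    read_region_mask,
    read_vcf_multisample,
    write_vcf,
)


def _brute_force_category(gt: tuple[int, int], n_alts: int) -> GenotypeCategory:
    # independent rule table: indices into (ref, alt1, alt2, ...)
    if any(i is None for i in gt):
        return GenotypeCategory.MISSING
    if any(i >= 2 for i in gt):
        return GenotypeCategory.MULTI
    if gt == (0, 0):
        return GenotypeCategory.HOM_REF
    if len(set(gt)) == 1:
        return GenotypeCategory.HOM_ALT
    return GenotypeCategory.HET


@pytest.mark.parametrize("a", [0, 1, 2, None])
@pytest.mark.parametrize("b", [0, 1, 2, None])
def test_genotype_category_all_diploid_gts(a, b):
    """Category derivation agrees with the brute-force GT table for every
    diploid genotype over two alt alleles."""
    site = ("A", ["T", "G"])
    alleles = tuple(None if i is None else ([site[0]] + site[1])[i] for i in (a, b))
    got = GenotypeCall.categorize(alleles, site[0], site[1])
    assert got is _brute_force_category((a, b), 2)


def test_vcf_parses_fields_and_missing(tmp_path):
    vcf = tmp_path / "mini.vcf"
    vcf.write_text(
        textwrap.dedent(
            """\
            ##fileformat=VCFv4.2
            ##contig=<ID=chr1,length=1000>
            ##INFO=<ID=FS,Number=1,Type=Float,Description="x">
            ##INFO=<ID=QD,Number=1,Type=Float,Description="x">
            ##FORMAT=<ID=GT,Number=1,Type=String,Description="x">
            ##FORMAT=<ID=AD,Number=R,Type=Integer,Description="x">
            ##FORMAT=<ID=DP,Number=1,Type=Integer,Description="x">
            #CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tc1\tc2\tc3
            chr1\t100\t.\tA\tT\t500\t.\tFS=2.5;QD=20\tGT:AD:DP\t0/1:12,11:23\t./.:.:0\t1|1:0,30:30
            chr1\t200\t.\tG\tT,C\t500\t.\tQD=20\tGT:AD:DP\t1/2:0,15,15:30\t0/0:30,0,0:30\t0/0:30,0,0:30
            """
        )
    )
    records = read_vcf_multisample(vcf, ["c1", "c2", "c3"])
    r = records[0]
    assert r.calls["c1"].category is GenotypeCategory.HET
    assert r.calls["c1"].allele_depths == {"A": 12, "T": 11}
    assert r.calls["c1"].depth == 23
    assert r.calls["c2"].category is GenotypeCategory.MISSING
    assert r.calls["c3"].category is GenotypeCategory.HOM_ALT  # phased == unphased
    assert r.ann.fs == 2.5 and r.ann.qd == 20 and r.ann.read_pos_rank_sum is None
    assert records[1].calls["c1"].category is GenotypeCategory.MULTI


def test_vcf_sample_mismatch_raises(tmp_path):
    vcf = tmp_path / "mini.vcf"
    vcf.write_text(
        "##fileformat=VCFv4.2\n##contig=<ID=chr1>\n"
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tc1\n"
    )
    with pytest.raises(FormatError, match="not in VCF header"):
        read_vcf_multisample(vcf, ["c1", "nope"])


def test_vcf_round_trip(cohort_on_disk, tmp_path):
    """write(read(x)) re-parses to field-identical records on the synthetic cohort."""
    clones = list(cohort_on_disk.config.clone_names)
    records = read_vcf_multisample(cohort_on_disk.paths["vcf"], clones)
    assert records == cohort_on_disk.records
    out = tmp_path / "again.vcf"
    write_vcf(records, out, clones, contigs=dict(cohort_on_disk.config.chrom_lengths))
    assert read_vcf_multisample(out, clones) == records


def test_bed_conventions(tmp_path):
    bed = tmp_path / "mask.bed"
    bed.write_text("chr1\t0\t10\nchr1\t5\t20\n")
    mask = read_region_mask(bed)
    assert mask.intervals["chr1"] == [(0, 20)]  # overlap merged
    assert mask.covers("chr1", 5)
    assert mask.covers("chr1", 20)
    assert not mask.covers("chr1", 21)  # half-open right edge
    assert not mask.covers("chr2", 5)


def test_bed_rejects_empty_interval(tmp_path):
    bed = tmp_path / "bad.bed"
    bed.write_text("chr1\t10\t10\n")
    with pytest.raises(FormatError):
        read_region_mask(bed)


@settings(max_examples=50, deadline=None)
@given(
    st.lists(
        st.tuples(st.integers(0, 500), st.integers(1, 50)).map(lambda t: (t[0], t[0] + t[1])),
        min_size=1,
        max_size=10,
    )
)
def test_mask_boundary_property(intervals):
    """For every merged interval (s, e): 1-based s+1..e covered, e+1 not."""
    mask = RegionMask({"c": intervals})
    for s, e in mask.intervals["c"]:
        assert mask.covers("c", s + 1)
        assert mask.covers("c", e)
        assert not mask.covers("c", e + 1)


GFF = textwrap.dedent(
    """\
    ##gff-version 3
    chr1\t.\tgene\t101\t400\t.\t{strand}\t.\tID=g1
    chr1\t.\tmRNA\t101\t400\t.\t{strand}\t.\tID=g1.1;Parent=g1
    {features}
    """
)


def test_gff3_single_exon_utrs(tmp_path):
    """Exon 101-400 with CDS 151-350 implies UTR5 101-150 and UTR3 351-400."""
    gff = tmp_path / "g.gff3"
    gff.write_text(
        GFF.format(
            strand="+",
            features="chr1\t.\texon\t101\t400\t.\t+\t.\tParent=g1.1\n"
            "chr1\t.\tCDS\t151\t350\t.\t+\t0\tParent=g1.1",
        )
    )
    (gene,) = read_gff3_genes(gff)
    tx = gene.transcripts[0]
    utr5, utr3 = tx.utr_intervals("+")
    assert utr5 == ((101, 150),) and utr3 == ((351, 400),)
    # minus strand: transcription starts at the highest coordinate, UTRs swap
    utr5m, utr3m = tx.utr_intervals("-")
    assert utr5m == ((351, 400),) and utr3m == ((101, 150),)


def test_gff3_introns(tmp_path):
    gff = tmp_path / "g.gff3"
    gff.write_text(
        GFF.format(
            strand="+",
            features="chr1\t.\texon\t101\t200\t.\t+\t.\tParent=g1.1\n"
            "chr1\t.\texon\t301\t400\t.\t+\t.\tParent=g1.1\n"
            "chr1\t.\tCDS\t101\t200\t.\t+\t0\tParent=g1.1\n"
            "chr1\t.\tCDS\t301\t400\t.\t+\t0\tParent=g1.1",
        )
    )
    (gene,) = read_gff3_genes(gff)
    assert gene.transcripts[0].introns == ((201, 300),)


def test_gff3_orphan_cds_raises(tmp_path):
    gff = tmp_path / "g.gff3"
    gff.write_text(
        "##gff-version 3\nchr1\t.\tgene\t1\t100\t.\t+\t.\tID=g1\n"
        "chr1\t.\tCDS\t10\t60\t.\t+\t0\tID=c1;Parent=ghost\n"
    )
    with pytest.raises(FormatError, match="no mRNA parent"):
        read_gff3_genes(gff)
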