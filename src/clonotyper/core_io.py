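"""Domain types and readers/writers for the standard formats the pipeline touches.

Conventions
-----------
* VCF and GFF3 coordinates are 1-based closed; BED is 0-based half-open.
  All internal positions are 1-based; conversion happens at the format
  boundary, never downstream.
* Genotype category is derived from the GT field only; allele depths are
  consumed exclusively by the filter rules.
* Multi-allelic VCF lines are kept as single records; a genotype using any
  allele outside {ref, first alt} is category MULTI.
* Phased (``|``) and unphased (``/``) separators are equivalent here: no
  downstream rule is phase-aware.
"""

from __future__ import annotations

import os
from bisect import bisect_right
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import gffutils
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


class FormatError(ValueError):
    """Malformed input file (the message names the offending line/field)."""


class DataError(ValueError):
    """Well-formed input that violates a pipeline precondition."""


class GenotypeCategory(str, Enum):
    HOM_REF = "HOM_REF"
    HET = "HET"
    HOM_ALT = "HOM_ALT"
    MULTI = "MULTI"
    MISSING = "MISSING"


@dataclass(frozen=True)
class GenotypeCall:
    """One sample's genotype at one site.

    ``alleles`` holds the called allele strings (ref/alt bases, not indices);
    ``allele_depths`` maps allele string -> supporting reads.
    """

    category: GenotypeCategory
    alleles: tuple[str, ...]
    depth: int
    allele_depths: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.depth < 0 or any(d < 0 for d in self.allele_depths.values()):
            raise DataError("negative read depth")
        # zero-depth entries carry no information and are dropped so that
        # write->read round-trips compare equal at the field level
        object.__setattr__(self, "allele_depths", {a: d for a, d in self.allele_depths.items() if d > 0})

    @staticmethod
    def categorize(gt_alleles: Sequence[str | None], ref: str, alts: Sequence[str]) -> GenotypeCategory:
        """Genotype category from called allele strings.

        Both equal ref -> HOM_REF; both equal the first alt -> HOM_ALT; two
        distinct alleles from {ref, first alt} -> HET; anything touching a
        further alt (or >2 distinct alleles) -> MULTI; any missing -> MISSING.
        """
        if any(a is None for a in gt_alleles) or not gt_alleles:
            return GenotypeCategory.MISSING
        allowed = {ref, alts[0] if alts else ref}
        distinct = set(gt_alleles)
        if len(distinct) > 2 or any(a not in allowed for a in distinct):
            return GenotypeCategory.MULTI
        if distinct == {ref}:
            return GenotypeCategory.HOM_REF
        if len(distinct) == 1:
            return GenotypeCategory.HOM_ALT
        return GenotypeCategory.HET

    @classmethod
    def from_gt(
        cls,
        gt_alleles: Sequence[str | None],
        ref: str,
        alts: Sequence[str],
        depth: int,
        allele_depths: Mapping[str, int],
    ) -> "GenotypeCall":
        category = cls.categorize(gt_alleles, ref, alts)
        alleles = tuple(a for a in gt_alleles if a is not None)
        return cls(category=category, alleles=alleles, depth=depth, allele_depths=dict(allele_depths))


@dataclass(frozen=True)
class QualityAnnotations:
    """Site-level quality annotations (GATK-style).

    ``read_pos_rank_sum``, ``sb`` and ``af`` may be absent (``None``): GATK
    omits rank-sum statistics at sites without heterozygous carriers.
    """

    qual: float
    fs: float | None = None
    qd: float | None = None
    read_pos_rank_sum: float | None = None
    sb: float | None = None
    af: float | None = None

    def __post_init__(self) -> None:
        if self.qual < 0 or (self.fs is not None and self.fs < 0) or (self.qd is not None and self.qd < 0):
            raise DataError("QUAL, FS and QD must be non-negative")


@dataclass(frozen=True)
class VariantRecord:
    chrom: str
    pos: int  # 1-based
    ref: str
    alts: tuple[str, ...]
    calls: Mapping[str, GenotypeCall]  # clone name -> call
    ann: QualityAnnotations

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise DataError(f"position must be >= 1, got {self.pos}")
        if any(alt == self.ref for alt in self.alts):
            raise DataError(f"{self.chrom}:{self.pos}: alt equals ref")
        if not self.calls:
            raise DataError(f"{self.chrom}:{self.pos}: no genotype calls")

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and all(len(a) == 1 for a in self.alts)


class RegionMask:
    """Per-chromosome sorted, merged half-open 0-based intervals."""

    def __init__(self, intervals: Mapping[str, Iterable[tuple[int, int]]] | None = None):
        self.intervals: dict[str, list[tuple[int, int]]] = {}
        for chrom, ivs in (intervals or {}).items():
            self.intervals[chrom] = self._merge(ivs)

    @staticmethod
    def _merge(ivs: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
        merged: list[tuple[int, int]] = []
        for s, e in sorted(ivs):
            if s >= e:
                raise FormatError(f"empty interval ({s}, {e})")
            if merged and s <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], e))
            else:
                merged.append((s, e))
        return merged

    def covers(self, chrom: str, pos: int) -> bool:
        """True if 1-based position ``pos`` falls in the mask."""
        ivs = self.intervals.get(chrom)
        if not ivs:
            return False
        zero = pos - 1
        i = bisect_right(ivs, (zero, float("inf"))) - 1
        return i >= 0 and ivs[i][0] <= zero < ivs[i][1]

    def total_length(self) -> int:
        return sum(e - s for ivs in self.intervals.values() for s, e in ivs)


@dataclass(frozen=True)
class Transcript:
    """Exon/CDS structure in genomic 1-based closed coordinates (sorted ascending)."""

    transcript_id: str
    exons: tuple[tuple[int, int], ...]
    cds: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        for ivs, what in ((self.exons, "exon"), (self.cds, "CDS")):
            for (s, e) in ivs:
                if s > e:
                    raise FormatError(f"{self.transcript_id}: inverted {what} interval {s}-{e}")
            if list(ivs) != sorted(ivs) or any(a[1] >= b[0] for a, b in zip(ivs, ivs[1:])):
                raise FormatError(f"{self.transcript_id}: {what}s not sorted/non-overlapping")

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        return tuple((a[1] + 1, b[0] - 1) for a, b in zip(self.exons, self.exons[1:]) if b[0] - a[1] > 1)

    @property
    def cds_span(self) -> tuple[int, int] | None:
        return (self.cds[0][0], self.cds[-1][1]) if self.cds else None

    def utr_intervals(self, strand: str) -> tuple[tuple[tuple[int, int], ...], tuple[tuple[int, int], ...]]:
        """(5'UTR, 3'UTR) genomic intervals, strand-aware."""
        if not self.cds:
            return self.exons, ()
        cs, ce = self.cds_span
        low, high = [], []
        for s, e in self.exons:
            if s < cs:
                low.append((s, min(e, cs - 1)))
            if e > ce:
                high.append((max(s, ce + 1), e))
        return (tuple(low), tuple(high)) if strand == "+" else (tuple(high), tuple(low))


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    chrom: str
    strand: str
    transcripts: tuple[Transcript, ...]

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise FormatError(f"{self.gene_id}: bad strand {self.strand!r}")

    def cds_length_ok(self) -> bool:
        """CDS length divisible by 3 for every transcript (real annotations may violate)."""
        return all(sum(e - s + 1 for s, e in t.cds) % 3 == 0 for t in self.transcripts if t.cds)


# ---------------------------------------------------------------------------
# VCF

_INFO_FIELDS = ("FS", "QD", "ReadPosRankSum", "SB", "AF")


def _round4(x: float | None) -> float | None:
    # htslib stores INFO floats as float32; rounding to 4 decimals makes
    # write->read round-trips exact for the precision this pipeline uses.
    return None if x is None else round(float(x), 4)


def read_vcf_multisample(path: str | os.PathLike, clone_names: Sequence[str]) -> list[VariantRecord]:
    """Read a multi-sample VCF into :class:`VariantRecord` objects.

    ``clone_names`` must match the VCF sample columns (order is taken from
    ``clone_names``, not the file).
    """
    verbosity = pysam.set_verbosity(0)  # htslib header-sanity chatter
    try:
        vf = pysam.VariantFile(os.fspath(path))
    except (OSError, ValueError) as exc:
        raise FormatError(f"{path}: cannot parse VCF header: {exc}") from exc
    finally:
        pysam.set_verbosity(verbosity)
    with vf:
        samples = list(vf.header.samples)
        missing = [c for c in clone_names if c not in samples]
        if missing:
            raise FormatError(f"{path}: samples {missing} not in VCF header (has {samples})")
        records = []
        for rec in vf:
            alts = tuple(rec.alts or ())
            info = {}
            for key in _INFO_FIELDS:
                try:
                    val = rec.info.get(key)
                except (KeyError, ValueError):  # key not declared in header
                    val = None
                if isinstance(val, tuple):
                    val = val[0] if val else None
                info[key] = _round4(val)
            ann = QualityAnnotations(
                qual=_round4(rec.qual) if rec.qual is not None else 0.0,
                fs=info["FS"],
                qd=info["QD"],
                read_pos_rank_sum=info["ReadPosRankSum"],
                sb=info["SB"],
                af=info["AF"],
            )
            site_alleles = (rec.ref,) + alts
            calls = {}
            for clone in clone_names:
                s = rec.samples[clone]
                gt = s.get("GT")
                gt_alleles = tuple(None if i is None else site_alleles[i] for i in (gt or (None,)))
                ad = s.get("AD")
                allele_depths = {}
                if ad is not None:
                    for allele, d in zip(site_alleles, ad):
                        if d is not None:
                            allele_depths[allele] = int(d)
                dp = s.get("DP")
                if dp is None:
                    dp = sum(allele_depths.values())
                calls[clone] = GenotypeCall.from_gt(gt_alleles, rec.ref, alts, int(dp), allele_depths)
            records.append(
                VariantRecord(chrom=rec.chrom, pos=rec.pos, ref=rec.ref, alts=alts, calls=calls, ann=ann)
            )
    return records


def write_vcf(
    records: Sequence[VariantRecord],
    path: str | os.PathLike,
    clone_names: Sequence[str],
    contigs: Mapping[str, int] | None = None,
) -> None:
    """Write records as uncompressed VCF 4.2 with GT:AD:DP per sample."""
    header = pysam.VariantHeader()
    header.add_line('##FILTER=<ID=PASS,Description="All filters passed">')
    if contigs is None:
        contigs = {}
        for r in records:
            contigs[r.chrom] = max(contigs.get(r.chrom, 0), r.pos + 1000)
    for chrom, length in contigs.items():
        header.contigs.add(chrom, length=length)
    header.add_line('##INFO=<ID=FS,Number=1,Type=Float,Description="Phred-scaled Fisher strand bias">')
    header.add_line('##INFO=<ID=QD,Number=1,Type=Float,Description="Quality by depth">')
    header.add_line('##INFO=<ID=ReadPosRankSum,Number=1,Type=Float,Description="Read position rank-sum">')
    header.add_line('##INFO=<ID=SB,Number=1,Type=Float,Description="Strand bias">')
    header.add_line('##INFO=<ID=AF,Number=1,Type=Float,Description="Alternate allele frequency">')
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header.add_line('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">')
    header.add_line('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">')
    for clone in clone_names:
        header.add_sample(clone)
    verbosity = pysam.set_verbosity(0)
    try:
        out = pysam.VariantFile(os.fspath(path), "w", header=header)
    finally:
        pysam.set_verbosity(verbosity)
    with out:
        for r in records:
            rec = out.new_record(contig=r.chrom, start=r.pos - 1, alleles=(r.ref,) + r.alts)
            rec.qual = r.ann.qual
            for key, val in (
                ("FS", r.ann.fs),
                ("QD", r.ann.qd),
                ("ReadPosRankSum", r.ann.read_pos_rank_sum),
                ("SB", r.ann.sb),
                ("AF", r.ann.af),
            ):
                if val is not None:
                    rec.info[key] = val
            site_alleles = (r.ref,) + r.alts
            index = {a: i for i, a in enumerate(site_alleles)}
            for clone in clone_names:
                call = r.calls[clone]
                sample = rec.samples[clone]
                if call.category is GenotypeCategory.MISSING:
                    sample["GT"] = (None, None)
                else:
                    sample["GT"] = tuple(index[a] for a in call.alleles)
                sample["AD"] = tuple(call.allele_depths.get(a, 0) for a in site_alleles)
                sample["DP"] = call.depth
            out.write(rec)


def merge_per_sample_vcfs(paths: Mapping[str, str | os.PathLike]) -> list[VariantRecord]:
    """Merge single-sample VCFs on (chrom, pos, ref); utility for per-clone callsets.

    Sites absent from a clone's file get a MISSING call. Conflicting alt sets
    are unioned (first file's alt order wins for shared alts).
    """
    merged: dict[tuple[str, int, str], dict] = {}
    for clone, path in paths.items():
        for rec in read_vcf_multisample(path, list(read_samples(path))):
            key = (rec.chrom, rec.pos, rec.ref)
            slot = merged.setdefault(key, {"alts": list(rec.alts), "ann": rec.ann, "calls": {}})
            for alt in rec.alts:
                if alt not in slot["alts"]:
                    slot["alts"].append(alt)
            slot["calls"][clone] = next(iter(rec.calls.values()))
    out = []
    for (chrom, pos, ref), slot in sorted(merged.items()):
        calls = {}
        for clone in paths:
            calls[clone] = slot["calls"].get(
                clone, GenotypeCall(GenotypeCategory.MISSING, (), 0, {})
            )
        out.append(VariantRecord(chrom, pos, ref, tuple(slot["alts"]), calls, slot["ann"]))
    return out


def read_samples(path: str | os.PathLike) -> list[str]:
    with pysam.VariantFile(os.fspath(path)) as vf:
        return list(vf.header.samples)


# ---------------------------------------------------------------------------
# BED

def read_region_mask(path: str | os.PathLike) -> RegionMask:
    """Read a BED3+ file (0-based half-open) into a normalized RegionMask."""
    intervals: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: expected >=3 BED columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer BED coordinates") from exc
            if start >= end:
                raise FormatError(f"{path}:{lineno}: start {start} >= end {end}")
            intervals.setdefault(fields[0], []).append((start, end))
    return RegionMask(intervals)


def write_region_mask(mask: RegionMask, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(mask.intervals):
            for s, e in mask.intervals[chrom]:
                fh.write(f"{chrom}\t{s}\t{e}\n")


# ---------------------------------------------------------------------------
# GFF3

def read_gff3_genes(path: str | os.PathLike) -> list[GeneModel]:
    """Parse gene/mRNA/exon/CDS features (1-based closed, preserved as-is)."""
    db = gffutils.create_db(
        os.fspath(path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
        force=True,
    )
    mrna_ids = {f.id for f in db.features_of_type("mRNA")}
    for cds in db.features_of_type("CDS"):
        parents = cds.attributes.get("Parent", [])
        if not parents or not any(p in mrna_ids for p in parents):
            raise FormatError(f"{path}: CDS at {cds.seqid}:{cds.start}-{cds.end} has no mRNA parent")
    genes = []
    for g in db.features_of_type("gene"):
        transcripts = []
        for m in db.children(g, featuretype="mRNA", order_by="start"):
            exons = tuple(sorted((f.start, f.end) for f in db.children(m, featuretype="exon")))
            cds = tuple(sorted((f.start, f.end) for f in db.children(m, featuretype="CDS")))
            if not exons:
                raise FormatError(f"{path}: mRNA {m.id} has no exons")
            transcripts.append(Transcript(m.id, exons, cds))
        genes.append(GeneModel(g.id, g.seqid, g.strand, tuple(transcripts)))
    return genes


def write_gff3_genes(genes: Sequence[GeneModel], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            span = (min(t.span[0] for t in g.transcripts), max(t.span[1] for t in g.transcripts))
            fh.write(f"{g.chrom}\t.\tgene\t{span[0]}\t{span[1]}\t.\t{g.strand}\t.\tID={g.gene_id}\n")
            for t in g.transcripts:
                s, e = t.span
                fh.write(
                    f"{g.chrom}\t.\tmRNA\t{s}\t{e}\t.\t{g.strand}\t.\t"
                    f"ID={t.transcript_id};Parent={g.gene_id}\n"
                )
                for (xs, xe) in t.exons:
                    fh.write(f"{g.chrom}\t.\texon\t{xs}\t{xe}\t.\t{g.strand}\t.\tParent={t.transcript_id}\n")
                for (cs, ce) in t.cds:
                    fh.write(f"{g.chrom}\t.\tCDS\t{cs}\t{ce}\t.\t{g.strand}\t0\tParent={t.transcript_id}\n")


# ---------------------------------------------------------------------------
# FASTA

def read_genome(path: str | os.PathLike) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(os.fspath(path), "fasta")}


def write_genome(genome: Mapping[str, str], path: str | os.PathLike) -> None:
    records = [SeqRecord(Seq(seq), id=chrom, description="") for chrom, seq in genome.items()]
    SeqIO.write(records, os.fspath(path), "fasta")
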