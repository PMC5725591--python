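"""Synthetic inputs with planted truth for every stage of the pipeline.

The cohort generator emulates a three-clone resequencing callset: a mini
diploid genome (2 chromosomes of ~250 kb, GC 0.35), multi-exon gene models
with valid coding sequences, a repeat mask covering ~10% of the genome, and
a multi-sample VCF whose sites are planted with the genotype-concordance
structure of the real callset — the varietal : clone-specific : discordant
proportions and per-category genotype mixes default to the published
three-clone tallies (524,899 hom-alt + 111,424 het varietal sites;
12,886 / 7,914 / 8,070 clone-specific sites with their per-clone category
mixes; 368 discordant among 665,561), scaled to ``n_sites`` by largest-
remainder rounding. Per-clone depth is negative binomial around the ~30x
filtered coverage of the study. Sites intended to pass are constructed to
satisfy every recalibrated filter threshold; each intended-FAIL site
violates exactly its named rule.

The marker-panel generator emits a 98-accession x 10-marker table whose
seven genotype classes encode the published constraints (two markers private
to class A; three chimeric-state markers unique to class E; one class
identified only by a marker pair; minimal discriminating subset of size 6).
The full 7x10 profile matrix is not published; the default here is a
synthetic reconstruction satisfying those constraints.

The chimera-assay generator draws tissue allele fractions from the linear
layer-mixture model plus truncated Gaussian noise.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import chimera as chimera_mod
from .core_io import (
    DataError,
    GeneModel,
    GenotypeCall,
    GenotypeCategory,
    QualityAnnotations,
    RegionMask,
    Transcript,
    VariantRecord,
    write_genome,
    write_gff3_genes,
    write_region_mask,
    write_vcf,
)
from .clonal_panel import MarkerPanel, write_panel_csv
from .filtering import FilterReason

DEFAULT_CLONES = ("CVT71", "CVT423", "CVT185")

# Published three-clone tallies (varietal / per-clone clone-specific cells).
VARIETAL_MIX = {GenotypeCategory.HOM_ALT: 524_899, GenotypeCategory.HET: 111_424}
CLONE_SPECIFIC_MIX = {
    "CVT71": {GenotypeCategory.HOM_REF: 784, GenotypeCategory.HOM_ALT: 3_606, GenotypeCategory.HET: 8_496},
    "CVT423": {GenotypeCategory.HOM_REF: 403, GenotypeCategory.HOM_ALT: 3_113, GenotypeCategory.HET: 4_398},
    "CVT185": {GenotypeCategory.HOM_REF: 400, GenotypeCategory.HOM_ALT: 3_245, GenotypeCategory.HET: 4_425},
}
DISCORDANT_COUNT = 368
GRAND_TOTAL = 665_561

_BASES = np.array(list("ACGT"))
_PLANTABLE_REASONS = (
    FilterReason.IN_REPEAT,
    FilterReason.SPURIOUS_ALLELE,
    FilterReason.LOW_COVERAGE,
    FilterReason.HIGH_FS,
    FilterReason.LOW_QD,
    FilterReason.BAD_READ_POS,
    FilterReason.DISCORDANT_HOM,
)


def _default_proportions() -> dict[str, float]:
    props = {"varietal": sum(VARIETAL_MIX.values()) / GRAND_TOTAL, "discordant": DISCORDANT_COUNT / GRAND_TOTAL}
    for clone, mix in CLONE_SPECIFIC_MIX.items():
        props[f"clone_specific:{clone}"] = sum(mix.values()) / GRAND_TOTAL
    return props


def allocate(n: int, weights: Mapping[str, float]) -> dict[str, int]:
    """Largest-remainder apportionment of n items to weighted categories."""
    total = sum(weights.values())
    raw = {k: n * w / total for k, w in weights.items()}
    counts = {k: int(raw[k]) for k in raw}
    short = n - sum(counts.values())
    for k in sorted(raw, key=lambda k: (-(raw[k] - counts[k]), k))[:short]:
        counts[k] += 1
    return counts


@dataclass(frozen=True)
class CohortSimConfig:
    n_sites: int = 6_656
    clone_names: tuple[str, ...] = DEFAULT_CLONES
    proportions: Mapping[str, float] = field(default_factory=_default_proportions)
    varietal_mix: Mapping[GenotypeCategory, float] = field(default_factory=lambda: dict(VARIETAL_MIX))
    clone_specific_mix: Mapping[str, Mapping[GenotypeCategory, float]] = field(
        default_factory=lambda: {c: dict(m) for c, m in CLONE_SPECIFIC_MIX.items()}
    )
    fail_rates: Mapping[str, float] = field(
        default_factory=lambda: {r.value: 0.01 for r in _PLANTABLE_REASONS}
    )
    depth_mean: float = 30.0
    depth_size: float = 10.0  # negative-binomial dispersion
    min_depth: int = 15
    chrom_lengths: Mapping[str, int] = field(default_factory=lambda: {"chr1": 250_000, "chr2": 250_000})
    gc_content: float = 0.35
    genes_per_chrom: int = 20
    repeat_fraction: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.proportions.values()) - 1.0) > 1e-9:
            raise DataError("partition-label proportions must sum to 1")
        for frac in list(self.proportions.values()) + list(self.fail_rates.values()):
            if not 0.0 <= frac <= 1.0:
                raise DataError("fractions must lie in [0, 1]")


@dataclass
class CohortData:
    config: CohortSimConfig
    genome: dict[str, str]
    genes: list[GeneModel]
    mask: RegionMask
    records: list[VariantRecord]
    truth: pd.DataFrame
    paths: dict[str, str] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# genome / genes / repeats

def _random_genome(rng: np.random.Generator, lengths: Mapping[str, int], gc: float) -> dict[str, list[str]]:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return {chrom: list(rng.choice(_BASES, size=n, p=p)) for chrom, n in lengths.items()}


_NON_STOP_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]
_COMP = str.maketrans("ACGT", "TGCA")


def _make_gene(
    rng: np.random.Generator,
    seq: list[str],
    chrom: str,
    gene_id: str,
    start: int,  # 1-based genomic start of the transcript
    strand: str,
) -> GeneModel:
    """Embed one multi-exon coding gene at ``start``; mutates ``seq``."""
    utr5 = int(rng.integers(60, 200))
    n_codons = int(rng.integers(60, 150))
    utr3 = int(rng.integers(60, 200))
    coding = "ATG" + "".join(rng.choice(_NON_STOP_CODONS, size=n_codons - 2)) + \
        str(rng.choice(["TAA", "TAG", "TGA"]))
    transcript = (
        "".join(rng.choice(_BASES, size=utr5)) + coding + "".join(rng.choice(_BASES, size=utr3))
    )
    n_exons = int(rng.integers(2, 5))
    # split transcript into n_exons chunks of >= 40 nt
    cuts = sorted(rng.choice(np.arange(40, len(transcript) - 40), size=n_exons - 1, replace=False))
    while any(b - a < 40 for a, b in zip([0] + list(cuts), list(cuts) + [len(transcript)])):
        cuts = sorted(rng.choice(np.arange(40, len(transcript) - 40), size=n_exons - 1, replace=False))
    bounds = [0] + list(cuts) + [len(transcript)]
    chunks = [(bounds[i], bounds[i + 1]) for i in range(n_exons)]
    introns = [int(rng.integers(80, 300)) for _ in range(n_exons - 1)]

    exons: list[tuple[int, int]] = []
    tx_to_genomic: list[tuple[int, int, int]] = []  # (tx_start, tx_end_excl, genomic_start)
    g = start
    for i, (a, b) in enumerate(chunks):
        exons.append((g, g + (b - a) - 1))
        tx_to_genomic.append((a, b, g))
        for k in range(b - a):
            seq[g - 1 + k] = transcript[a + k]
        g += (b - a)
        if i < n_exons - 1:
            g += introns[i]

    def to_genomic(tx_pos: int) -> int:
        for a, b, gs in tx_to_genomic:
            if a <= tx_pos < b:
                return gs + (tx_pos - a)
        raise AssertionError

    cds_tx = (utr5, utr5 + 3 * n_codons)  # [start, end)
    cds: list[tuple[int, int]] = []
    for a, b, gs in tx_to_genomic:
        lo, hi = max(a, cds_tx[0]), min(b, cds_tx[1])
        if lo < hi:
            cds.append((to_genomic(lo), to_genomic(hi - 1)))

    if strand == "-":
        g0, g1 = exons[0][0], exons[-1][1]
        region = "".join(seq[g0 - 1 : g1])
        flipped = region[::-1].translate(_COMP)
        seq[g0 - 1 : g1] = list(flipped)
        mirror = lambda iv: (g0 + g1 - iv[1], g0 + g1 - iv[0])
        exons = sorted(mirror(iv) for iv in exons)
        cds = sorted(mirror(iv) for iv in cds)

    tx = Transcript(f"{gene_id}.1", tuple(exons), tuple(cds))
    return GeneModel(gene_id, chrom, strand, (tx,))


def _place_genes(rng: np.random.Generator, genome: dict[str, list[str]], per_chrom: int) -> list[GeneModel]:
    genes = []
    for chrom, seq in genome.items():
        slot = len(seq) // per_chrom
        for i in range(per_chrom):
            start = i * slot + int(rng.integers(500, 1500))
            strand = "+" if rng.random() < 0.5 else "-"
            gene = _make_gene(rng, seq, chrom, f"{chrom}g{i + 1:03d}", start, strand)
            genes.append(gene)
    return genes


def _place_repeats(
    rng: np.random.Generator,
    genome: Mapping[str, list[str]],
    genes: Sequence[GeneModel],
    fraction: float,
) -> RegionMask:
    """Carve repeat intervals out of intergenic gaps until ~fraction covered."""
    intervals: dict[str, list[tuple[int, int]]] = {}
    for chrom, seq in genome.items():
        length = len(seq)
        spans = sorted(
            (min(t.span[0] for t in g.transcripts), max(t.span[1] for t in g.transcripts))
            for g in genes
            if g.chrom == chrom
        )
        gaps, prev = [], 1
        for s, e in spans:
            if s - prev > 2_000:
                gaps.append((prev, s - 1))
            prev = e + 1
        if length - prev > 2_000:
            gaps.append((prev, length))
        target = int(fraction * length)
        covered = 0
        out = []
        for gs, ge in gaps:
            if covered >= target:
                break
            width = min(int(rng.integers(2_000, 5_000)), ge - gs - 1_000, target - covered)
            if width < 500:
                continue
            s0 = gs + 500
            out.append((s0 - 1, s0 - 1 + width))  # BED half-open
            covered += width
        intervals[chrom] = out
    return RegionMask(intervals)


# ---------------------------------------------------------------------------
# cohort sites

def _mutate_base(rng: np.random.Generator, ref: str) -> str:
    choices = [b for b in "ACGT" if b != ref]
    return choices[int(rng.integers(0, 3))]


def _depth(rng: np.random.Generator, cfg: CohortSimConfig) -> int:
    size, mean = cfg.depth_size, cfg.depth_mean
    d = int(rng.negative_binomial(size, size / (size + mean)))
    return max(d, cfg.min_depth)  # intended-PASS sites must satisfy the depth rule


def _call(
    rng: np.random.Generator,
    cfg: CohortSimConfig,
    category: GenotypeCategory,
    ref: str,
    alt: str,
    depth: int | None = None,
    discordant: int | None = None,
) -> GenotypeCall:
    depth = depth if depth is not None else _depth(rng, cfg)
    if category is GenotypeCategory.HET:
        lo, hi = 3, depth - 3
        alt_reads = int(np.clip(rng.binomial(depth, 0.5), lo, hi))
        ad = {ref: depth - alt_reads, alt: alt_reads}
        alleles = (ref, alt)
    elif category is GenotypeCategory.HOM_ALT:
        bad = discordant if discordant is not None else int(rng.integers(0, 3))
        ad = {ref: bad, alt: depth - bad}
        alleles = (alt, alt)
    else:  # HOM_REF
        bad = discordant if discordant is not None else int(rng.integers(0, 3))
        ad = {ref: depth - bad, alt: bad}
        alleles = (ref, ref)
    return GenotypeCall(category=category, alleles=alleles, depth=depth, allele_depths=ad)


def _pass_annotations(rng: np.random.Generator, has_het: bool) -> QualityAnnotations:
    return QualityAnnotations(
        qual=round(float(rng.uniform(200, 1000)), 1),
        fs=round(float(rng.uniform(0, 8)), 2),
        qd=round(float(rng.uniform(12, 30)), 2),
        read_pos_rank_sum=round(float(rng.uniform(-1.8, 1.8)), 2) if has_het else None,
    )


def _site_genotypes(
    rng: np.random.Generator,
    cfg: CohortSimConfig,
    label: str,
) -> tuple[dict[str, GenotypeCategory], str | None]:
    """Per-clone genotype categories for one planted site."""
    clones = cfg.clone_names
    if label == "varietal":
        cats = list(cfg.varietal_mix)
        w = np.array([cfg.varietal_mix[c] for c in cats], dtype=float)
        category = cats[int(rng.choice(len(cats), p=w / w.sum()))]
        return {c: category for c in clones}, None
    if label == "discordant":
        trio = [GenotypeCategory.HOM_REF, GenotypeCategory.HET, GenotypeCategory.HOM_ALT]
        order = rng.permutation(3)
        return {c: trio[order[i]] for i, c in enumerate(clones)}, None
    clone = label.split(":", 1)[1]
    mix = cfg.clone_specific_mix[clone]
    cats = list(mix)
    w = np.array([mix[c] for c in cats], dtype=float)
    outlier_cat = cats[int(rng.choice(len(cats), p=w / w.sum()))]
    if outlier_cat is GenotypeCategory.HOM_REF:
        w_var = np.array([VARIETAL_MIX[GenotypeCategory.HOM_ALT], VARIETAL_MIX[GenotypeCategory.HET]], float)
        shared = [GenotypeCategory.HOM_ALT, GenotypeCategory.HET][int(rng.choice(2, p=w_var / w_var.sum()))]
    else:
        shared = GenotypeCategory.HOM_REF
    return {c: (outlier_cat if c == clone else shared) for c in clones}, clone


def generate_cohort(config: CohortSimConfig | None = None, out_dir: str | os.PathLike | None = None) -> CohortData:
    """Generate the full cohort bundle (genome, annotation, mask, VCF, truth)."""
    cfg = config or CohortSimConfig()
    rng = np.random.default_rng(cfg.seed)
    genome_lists = _random_genome(rng, cfg.chrom_lengths, cfg.gc_content)
    genes = _place_genes(rng, genome_lists, cfg.genes_per_chrom)
    mask = _place_repeats(rng, genome_lists, genes, cfg.repeat_fraction)
    genome = {chrom: "".join(seq) for chrom, seq in genome_lists.items()}

    # eligible (non-repeat) positions, 1-based
    eligible: list[tuple[str, int]] = []
    repeat_pos: list[tuple[str, int]] = []
    for chrom, length in cfg.chrom_lengths.items():
        in_repeat = np.zeros(length, dtype=bool)
        for s, e in mask.intervals.get(chrom, []):
            in_repeat[s:e] = True
        pos = np.arange(1, length + 1)
        eligible.extend((chrom, int(p)) for p in pos[~in_repeat])
        repeat_pos.extend((chrom, int(p)) for p in pos[in_repeat])

    n_fail = {reason: int(round(rate * cfg.n_sites)) for reason, rate in cfg.fail_rates.items()}
    n_fail_in_repeat = n_fail.get(FilterReason.IN_REPEAT.value, 0)
    n_fail_clean = sum(v for k, v in n_fail.items() if k != FilterReason.IN_REPEAT.value)

    idx = rng.choice(len(eligible), size=cfg.n_sites + n_fail_clean, replace=False)
    clean_positions = [eligible[i] for i in idx]
    ridx = rng.choice(len(repeat_pos), size=n_fail_in_repeat, replace=False) if n_fail_in_repeat else []
    repeat_positions = [repeat_pos[i] for i in ridx]

    label_counts = allocate(cfg.n_sites, cfg.proportions)
    labels = [lab for lab, n in sorted(label_counts.items()) for _ in range(n)]
    rng.shuffle(labels)

    fail_labels = [
        reason for reason, n in sorted(n_fail.items()) if reason != FilterReason.IN_REPEAT.value
        for _ in range(n)
    ]

    rows = []
    records = []

    def build_site(chrom: str, pos: int, label: str, fate: str) -> None:
        ref = genome[chrom][pos - 1]
        alt = _mutate_base(rng, ref)
        cats, outlier = _site_genotypes(rng, cfg, label)
        has_het = any(c is GenotypeCategory.HET for c in cats.values())
        ann = _pass_annotations(rng, has_het)
        calls = {clone: _call(rng, cfg, cats[clone], ref, alt) for clone in cfg.clone_names}
        alts: tuple[str, ...] = (alt,)

        if fate == FilterReason.SPURIOUS_ALLELE.value:
            # a third allele must be read-supported alongside both called
            # alleles, so plant it on a het call (>=3 reads on each of ref,
            # alt and the extra allele; no homozygous-discordance side effect)
            third = next(b for b in "ACGT" if b not in (ref, alt))
            alts = (alt, third)
            clone = cfg.clone_names[int(rng.integers(len(cfg.clone_names)))]
            het = _call(rng, cfg, GenotypeCategory.HET, ref, alt)
            extra = int(rng.integers(3, 8))
            ad = dict(het.allele_depths)
            ad[third] = extra
            calls[clone] = GenotypeCall(GenotypeCategory.HET, het.alleles, het.depth + extra, ad)
            cats[clone] = GenotypeCategory.HET
        elif fate == FilterReason.LOW_COVERAGE.value:
            clone = cfg.clone_names[int(rng.integers(len(cfg.clone_names)))]
            depth = int(rng.integers(5, cfg.min_depth))
            calls[clone] = _call(rng, cfg, GenotypeCategory.HOM_ALT, ref, alt, depth=depth)
            cats[clone] = GenotypeCategory.HOM_ALT
        elif fate == FilterReason.HIGH_FS.value:
            ann = QualityAnnotations(ann.qual, round(float(rng.uniform(10.5, 60)), 2),
                                     ann.qd, ann.read_pos_rank_sum)
        elif fate == FilterReason.LOW_QD.value:
            ann = QualityAnnotations(ann.qual, ann.fs, round(float(rng.uniform(0, 9.5)), 2),
                                     ann.read_pos_rank_sum)
        elif fate == FilterReason.BAD_READ_POS.value:
            sign = 1 if rng.random() < 0.5 else -1
            ann = QualityAnnotations(ann.qual, ann.fs, ann.qd,
                                     sign * round(float(rng.uniform(2.2, 5.0)), 2))
        elif fate == FilterReason.DISCORDANT_HOM.value:
            clone = cfg.clone_names[int(rng.integers(len(cfg.clone_names)))]
            calls[clone] = _call(rng, cfg, GenotypeCategory.HOM_ALT, ref, alt,
                                 discordant=int(rng.integers(3, 7)))
            cats[clone] = GenotypeCategory.HOM_ALT

        records.append(VariantRecord(chrom, pos, ref, alts, calls, ann))
        rows.append(
            {
                "chrom": chrom,
                "pos": pos,
                "ref": ref,
                "alt": alt,
                "label": label,
                "outlier": outlier or "",
                **{f"category_{c}": cats[c].value for c in cfg.clone_names},
                "fate": fate,
            }
        )

    for (chrom, pos), label in zip(clean_positions[: cfg.n_sites], labels):
        build_site(chrom, pos, label, "PASS")
    for (chrom, pos), fate in zip(clean_positions[cfg.n_sites :], fail_labels):
        build_site(chrom, pos, "varietal", fate)
    for chrom, pos in repeat_positions:
        build_site(chrom, pos, "varietal", FilterReason.IN_REPEAT.value)

    order = sorted(range(len(records)), key=lambda i: (records[i].chrom, records[i].pos))
    records = [records[i] for i in order]
    truth = pd.DataFrame([rows[i] for i in order])

    data = CohortData(cfg, genome, genes, mask, records, truth)
    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        paths = {
            "genome": os.path.join(out_dir, "genome.fa"),
            "genes": os.path.join(out_dir, "genes.gff3"),
            "repeats": os.path.join(out_dir, "repeats.bed"),
            "vcf": os.path.join(out_dir, "cohort.vcf"),
            "truth": os.path.join(out_dir, "truth.csv"),
        }
        write_genome(genome, paths["genome"])
        write_gff3_genes(genes, paths["genes"])
        write_region_mask(mask, paths["repeats"])
        write_vcf(records, paths["vcf"], cfg.clone_names,
                  contigs=dict(cfg.chrom_lengths))
        truth.to_csv(paths["truth"], index=False)
        data.paths = paths
    return data


# ---------------------------------------------------------------------------
# marker panel

PANEL_MARKERS = (
    "Ne_SNV1", "Ne_SNV2", "Ne_SNV7", "Ne_SNV10", "Ne_SNV12",
    "Ne_SNV14", "Ne_SNV31", "Ne_SNV33", "Ne_SNV62", "Ne_SNV70",
)

_BASE_TOKENS = ("CC", "AA", "TT", "GG", "CC", "TT", "CC", "GG", "TT", "AA")
_VARIANT_TOKENS = ("CT", "AG", "CT", "AG", "CT", "GT", "CC~CT", "GG~GA", "TT~TC", "AT")

# rows: which markers carry the variant state in each genotype class
_CLASS_STATES = {
    "A": (1, 1, 1, 1, 0, 1, 0, 0, 0, 1),
    "B": (0, 1, 1, 1, 0, 0, 0, 0, 0, 1),
    "C": (0, 1, 0, 0, 1, 0, 0, 0, 0, 0),
    "D": (0, 1, 0, 0, 0, 0, 0, 0, 0, 0),
    "E": (0, 1, 0, 0, 0, 0, 1, 1, 1, 0),
    "F": (0, 0, 0, 0, 1, 0, 0, 0, 0, 0),
    "G": (0, 1, 1, 1, 0, 0, 0, 0, 0, 0),
}


def default_class_profiles() -> dict[str, tuple[str, ...]]:
    return {
        label: tuple(
            _VARIANT_TOKENS[i] if state else _BASE_TOKENS[i] for i, state in enumerate(states)
        )
        for label, states in _CLASS_STATES.items()
    }


def reference_panel_profile() -> tuple[str, ...]:
    """Reference-genome-like profile: homozygous base state at every marker."""
    return _BASE_TOKENS


DEFAULT_CLASS_COUNTS = {"A": 1, "B": 31, "C": 2, "D": 31, "E": 2, "F": 21, "G": 10}
# A=1, B=31, C=2, D=31, E=2 are published; the F/G split (21/10) is a
# generator default constrained only by F+G=31.


@dataclass(frozen=True)
class PanelSimConfig:
    n_accessions: int = 98
    class_profiles: Mapping[str, tuple[str, ...]] = field(default_factory=default_class_profiles)
    class_counts: Mapping[str, int] = field(default_factory=lambda: dict(DEFAULT_CLASS_COUNTS))
    markers: tuple[str, ...] = PANEL_MARKERS
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(self.class_counts.values()) != self.n_accessions:
            raise DataError("class counts must sum to n_accessions")
        profiles = list(self.class_profiles.values())
        if len(set(profiles)) != len(profiles):
            raise DataError("class profiles must be pairwise distinct")
        if set(self.class_counts) != set(self.class_profiles):
            raise DataError("class_counts and class_profiles must cover the same classes")


@dataclass
class PanelData:
    config: PanelSimConfig
    panel: MarkerPanel
    truth: pd.DataFrame  # accession -> class
    paths: dict[str, str] = field(default_factory=dict)


def generate_panel(config: PanelSimConfig | None = None, out_dir: str | os.PathLike | None = None) -> PanelData:
    """Emit the accession x marker table, rows grouped by class in letter order
    so that first-appearance labelling reproduces the class letters."""
    cfg = config or PanelSimConfig()
    rows: dict[str, tuple[str, ...]] = {}
    truth_rows = []
    i = 0
    for label in sorted(cfg.class_counts):
        profile = tuple(cfg.class_profiles[label])
        for _ in range(cfg.class_counts[label]):
            i += 1
            accession = f"NB{i:03d}"
            rows[accession] = profile
            truth_rows.append({"accession": accession, "genotype_class": label})
    panel = MarkerPanel(cfg.markers, rows)
    truth = pd.DataFrame(truth_rows)
    data = PanelData(cfg, panel, truth)
    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        paths = {
            "panel": os.path.join(out_dir, "panel.csv"),
            "truth": os.path.join(out_dir, "panel_truth.csv"),
        }
        write_panel_csv(panel, paths["panel"])
        truth.to_csv(paths["truth"], index=False)
        data.paths = paths
    return data


# ---------------------------------------------------------------------------
# chimera assays

@dataclass(frozen=True)
class ChimeraSimConfig:
    # locus -> (L1 alt-allele dosage, L2 alt-allele dosage), dosage in {0,1,2}
    layer_genotypes: Mapping[str, tuple[int, int]] = field(
        default_factory=lambda: {"Ne_SNV31": (1, 0), "Ne_SNV33": (1, 0), "Ne_SNV62": (1, 0)}
    )
    tissue_weights: Mapping[str, float] = field(
        default_factory=lambda: dict(chimera_mod.DEFAULT_TISSUE_WEIGHTS)
    )
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise DataError("noise_sd must be >= 0")
        for locus, (d1, d2) in self.layer_genotypes.items():
            if d1 not in (0, 1, 2) or d2 not in (0, 1, 2):
                raise DataError(f"{locus}: layer dosages must be 0, 1 or 2")
        if any(not 0 <= a <= 1 for a in self.tissue_weights.values()):
            raise DataError("tissue weights must lie in [0, 1]")


@dataclass
class ChimeraData:
    config: ChimeraSimConfig
    assays: list[chimera_mod.LayerAssay]
    truth: pd.DataFrame
    paths: dict[str, str] = field(default_factory=dict)


def generate_chimera_assays(
    config: ChimeraSimConfig | None = None, out_dir: str | os.PathLike | None = None
) -> ChimeraData:
    """Tissue alt-allele fractions from the layer-mixture model plus noise."""
    cfg = config or ChimeraSimConfig()
    rng = np.random.default_rng(cfg.seed)
    assays = []
    truth_rows = []
    for locus in cfg.layer_genotypes:
        d1, d2 = cfg.layer_genotypes[locus]
        s1, s2 = d1 / 2.0, d2 / 2.0
        for tissue, alpha in cfg.tissue_weights.items():
            f = chimera_mod.expected_fraction(s1, s2, alpha)
            if cfg.noise_sd > 0:
                f += float(rng.normal(0.0, cfg.noise_sd))
            f = float(np.clip(round(f, 6), 0.0, 1.0))
            assays.append(chimera_mod.LayerAssay(locus=locus, tissue=tissue, alt_fraction=f))
        truth_rows.append({"locus": locus, "l1_state": s1, "l2_state": s2, "is_chimera": s1 != s2})
    truth = pd.DataFrame(truth_rows)
    data = ChimeraData(cfg, assays, truth)
    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        paths = {
            "assays": os.path.join(out_dir, "chimera_assays.csv"),
            "truth": os.path.join(out_dir, "chimera_truth.csv"),
        }
        pd.DataFrame(
            [{"locus": a.locus, "tissue": a.tissue, "alt_fraction": a.alt_fraction} for a in assays]
        ).to_csv(paths["assays"], index=False)
        truth.to_csv(paths["truth"], index=False)
        data.paths = paths
    return data


def chimera_recovery_config(n_loci_per_pair: int, noise_sd: float, seed: int) -> ChimeraSimConfig:
    """All 9 (L1, L2) diploid state pairs, replicated, for recovery studies."""
    layer_genotypes = {
        f"locus_L1d{d1}_L2d{d2}_r{k}": (d1, d2)
        for d1 in (0, 1, 2)
        for d2 in (0, 1, 2)
        for k in range(n_loci_per_pair)
    }
    return ChimeraSimConfig(layer_genotypes=layer_genotypes, noise_sd=noise_sd, seed=seed)
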