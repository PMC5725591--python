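"""SnpEff-style effect classification of SNVs against gene models.

Each (variant, transcript) pair receives exactly one category:

* UPSTREAM / DOWNSTREAM — within 5,000 nt of the transcription start /
  transcript end, strand-aware, outside the transcript span;
* SPLICE_SITE_DONOR / SPLICE_SITE_ACCEPTOR — the first / last 2 intronic
  bases (GT–AG convention), otherwise INTRON;
* UTR_5_PRIME / UTR_3_PRIME, with START_GAINED when a 5'UTR change creates
  a new ATG on the coding strand;
* coding changes translated on the coding strand with the standard code:
  START_LOST (or NON_SYNONYMOUS_START when the alternative codon belongs to
  a configured alternative-start set, empty by default), STOP_LOST,
  SYNONYMOUS_STOP, STOP_GAINED, SYNONYMOUS_CODING, NON_SYNONYMOUS_CODING.

Impact (HIGH/MODERATE/LOW/MODIFIER) is a fixed function of the category.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping

from Bio.Seq import Seq

from .core_io import DataError, GeneModel, GenotypeCategory, Transcript, VariantRecord

STOP_CODONS = {"TAA", "TAG", "TGA"}
START_CODON = "ATG"


class EffectCategory(str, Enum):
    START_LOST = "START_LOST"
    STOP_GAINED = "STOP_GAINED"
    STOP_LOST = "STOP_LOST"
    SPLICE_SITE_ACCEPTOR = "SPLICE_SITE_ACCEPTOR"
    SPLICE_SITE_DONOR = "SPLICE_SITE_DONOR"
    NON_SYNONYMOUS_START = "NON_SYNONYMOUS_START"
    SYNONYMOUS_CODING = "SYNONYMOUS_CODING"
    SYNONYMOUS_STOP = "SYNONYMOUS_STOP"
    START_GAINED = "START_GAINED"
    NON_SYNONYMOUS_CODING = "NON_SYNONYMOUS_CODING"
    DOWNSTREAM = "DOWNSTREAM"
    INTRON = "INTRON"
    UPSTREAM = "UPSTREAM"
    UTR_3_PRIME = "UTR_3_PRIME"
    UTR_5_PRIME = "UTR_5_PRIME"


class Impact(str, Enum):
    HIGH = "HIGH"
    MODERATE = "MODERATE"
    LOW = "LOW"
    MODIFIER = "MODIFIER"


IMPACT_BY_CATEGORY: dict[EffectCategory, Impact] = {
    EffectCategory.START_LOST: Impact.HIGH,
    EffectCategory.STOP_GAINED: Impact.HIGH,
    EffectCategory.STOP_LOST: Impact.HIGH,
    EffectCategory.SPLICE_SITE_ACCEPTOR: Impact.HIGH,
    EffectCategory.SPLICE_SITE_DONOR: Impact.HIGH,
    EffectCategory.NON_SYNONYMOUS_START: Impact.LOW,
    EffectCategory.SYNONYMOUS_CODING: Impact.LOW,
    EffectCategory.SYNONYMOUS_STOP: Impact.LOW,
    EffectCategory.START_GAINED: Impact.LOW,
    EffectCategory.NON_SYNONYMOUS_CODING: Impact.MODERATE,
    EffectCategory.DOWNSTREAM: Impact.MODIFIER,
    EffectCategory.INTRON: Impact.MODIFIER,
    EffectCategory.UPSTREAM: Impact.MODIFIER,
    EffectCategory.UTR_3_PRIME: Impact.MODIFIER,
    EffectCategory.UTR_5_PRIME: Impact.MODIFIER,
}


@dataclass(frozen=True)
class EffectConfig:
    upstream_window: int = 5000
    downstream_window: int = 5000
    splice_window: int = 2
    alternative_starts: frozenset[str] = frozenset()


@dataclass(frozen=True)
class EffectCall:
    site: tuple[str, int]
    gene_id: str
    transcript_id: str
    category: EffectCategory
    impact: Impact
    codon_change: tuple[str, str] | None = None


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def _cds_sequence(tx: Transcript, chrom_seq: str, strand: str) -> str:
    parts = [chrom_seq[s - 1 : e] for s, e in tx.cds]
    seq = "".join(parts)
    return seq if strand == "+" else _revcomp(seq)


def _cds_index(tx: Transcript, pos: int, strand: str) -> int | None:
    """0-based index of genomic ``pos`` within the coding sequence, or None."""
    offset = 0
    for s, e in tx.cds:
        if s <= pos <= e:
            fwd = offset + (pos - s)
            total = sum(ce - cs + 1 for cs, ce in tx.cds)
            return fwd if strand == "+" else total - 1 - fwd
        offset += e - s + 1
    return None


def _utr5_sequence(tx: Transcript, strand: str, chrom_seq: str, substitute: tuple[int, str] | None = None) -> str:
    """5'UTR in transcription order on the coding strand; optionally with one
    genomic base substituted."""
    utr5, _ = tx.utr_intervals(strand)
    chunks = []
    for s, e in sorted(utr5):
        chunk = chrom_seq[s - 1 : e]
        if substitute and s <= substitute[0] <= e:
            i = substitute[0] - s
            chunk = chunk[:i] + substitute[1] + chunk[i + 1 :]
        chunks.append(chunk)
    seq = "".join(chunks)
    return seq if strand == "+" else _revcomp(seq)


def _classify_one(
    tx: Transcript,
    strand: str,
    pos: int,
    ref: str,
    alt: str,
    chrom_seq: str,
    config: EffectConfig,
) -> tuple[EffectCategory, tuple[str, str] | None] | None:
    start, end = tx.span
    if pos < start or pos > end:
        if strand == "+":
            before, after = start - pos, pos - end
        else:
            before, after = pos - end, start - pos
        if 0 < before <= config.upstream_window:
            return EffectCategory.UPSTREAM, None
        if 0 < after <= config.downstream_window:
            return EffectCategory.DOWNSTREAM, None
        return None

    for gs, ge in tx.introns:
        if gs <= pos <= ge:
            w = config.splice_window
            if strand == "+":
                donor = gs <= pos <= min(ge, gs + w - 1)
                acceptor = max(gs, ge - w + 1) <= pos <= ge
            else:
                donor = max(gs, ge - w + 1) <= pos <= ge
                acceptor = gs <= pos <= min(ge, gs + w - 1)
            if donor:
                return EffectCategory.SPLICE_SITE_DONOR, None
            if acceptor:
                return EffectCategory.SPLICE_SITE_ACCEPTOR, None
            return EffectCategory.INTRON, None

    cds_idx = _cds_index(tx, pos, strand) if tx.cds else None
    if cds_idx is not None:
        cds = _cds_sequence(tx, chrom_seq, strand)
        base = alt if strand == "+" else _revcomp(alt)
        alt_cds = cds[:cds_idx] + base + cds[cds_idx + 1 :]
        codon_i = cds_idx // 3
        ref_codon = cds[3 * codon_i : 3 * codon_i + 3]
        alt_codon = alt_cds[3 * codon_i : 3 * codon_i + 3]
        change = (ref_codon, alt_codon)
        n_codons = len(cds) // 3
        if codon_i == 0:
            if alt_codon == START_CODON:
                return EffectCategory.SYNONYMOUS_CODING, change
            if alt_codon in config.alternative_starts:
                return EffectCategory.NON_SYNONYMOUS_START, change
            return EffectCategory.START_LOST, change
        if codon_i == n_codons - 1 and ref_codon in STOP_CODONS:
            if alt_codon in STOP_CODONS:
                return EffectCategory.SYNONYMOUS_STOP, change
            return EffectCategory.STOP_LOST, change
        if alt_codon in STOP_CODONS:
            return EffectCategory.STOP_GAINED, change
        if str(Seq(ref_codon).translate()) == str(Seq(alt_codon).translate()):
            return EffectCategory.SYNONYMOUS_CODING, change
        return EffectCategory.NON_SYNONYMOUS_CODING, change

    # exonic, non-coding: decide which UTR by strand-aware comparison to CDS
    if not tx.cds:
        return EffectCategory.UTR_5_PRIME, None  # non-coding model: treat as UTR
    cs, ce = tx.cds_span
    five_prime = pos < cs if strand == "+" else pos > ce
    if five_prime:
        ref_utr = _utr5_sequence(tx, strand, chrom_seq)
        alt_utr = _utr5_sequence(tx, strand, chrom_seq, substitute=(pos, alt))
        ref_starts = {i for i in range(len(ref_utr) - 2) if ref_utr[i : i + 3] == START_CODON}
        alt_starts = {i for i in range(len(alt_utr) - 2) if alt_utr[i : i + 3] == START_CODON}
        if alt_starts - ref_starts:
            return EffectCategory.START_GAINED, None
        return EffectCategory.UTR_5_PRIME, None
    return EffectCategory.UTR_3_PRIME, None


def classify_effects(
    variant: VariantRecord,
    gene: GeneModel,
    genome: Mapping[str, str],
    config: EffectConfig | None = None,
) -> list[EffectCall]:
    """Classify one biallelic SNV against every transcript of one gene."""
    config = config or EffectConfig()
    if not variant.is_snv or len(variant.alts) != 1:
        raise DataError(f"{variant.chrom}:{variant.pos}: effect annotation requires a biallelic SNV")
    if gene.chrom != variant.chrom:
        return []
    chrom_seq = genome[gene.chrom]
    calls = []
    for tx in gene.transcripts:
        result = _classify_one(tx, gene.strand, variant.pos, variant.ref, variant.alts[0], chrom_seq, config)
        if result is None:
            continue
        category, change = result
        calls.append(
            EffectCall(
                site=(variant.chrom, variant.pos),
                gene_id=gene.gene_id,
                transcript_id=tx.transcript_id,
                category=category,
                impact=IMPACT_BY_CATEGORY[category],
                codon_change=change,
            )
        )
    return calls


def annotate_cohort(
    records: Iterable[VariantRecord],
    genes: Iterable[GeneModel],
    genome: Mapping[str, str],
    config: EffectConfig | None = None,
) -> list[EffectCall]:
    genes = list(genes)
    calls: list[EffectCall] = []
    for record in records:
        for gene in genes:
            if gene.chrom == record.chrom:
                calls.extend(classify_effects(record, gene, genome, config))
    return calls


@dataclass
class EffectSummary:
    """Table-2-shaped counts: category -> (het, hom-alt, total)."""

    counts: dict[EffectCategory, tuple[int, int]]

    def row(self, category: EffectCategory) -> tuple[int, int, int]:
        het, hom = self.counts.get(category, (0, 0))
        return het, hom, het + hom

    def impact_total(self, impact: Impact) -> int:
        return sum(
            h + a for cat, (h, a) in self.counts.items() if IMPACT_BY_CATEGORY[cat] is impact
        )

    def as_dict(self) -> dict:
        return {
            cat.value: {
                "impact": IMPACT_BY_CATEGORY[cat].value,
                "het": self.row(cat)[0],
                "hom_alt": self.row(cat)[1],
                "total": self.row(cat)[2],
            }
            for cat in EffectCategory
        }


def summarize_effects(
    effects: Iterable[EffectCall],
    labels: Mapping[tuple[str, int], GenotypeCategory],
) -> EffectSummary:
    """Tally effects by category and site genotype (HET / HOM_ALT).

    A site contributes one count per distinct (site, category) pair, however
    many transcripts it hits.
    """
    seen: set[tuple[tuple[str, int], EffectCategory]] = set()
    counts: dict[EffectCategory, list[int]] = {}
    for eff in effects:
        if eff.site not in labels:
            raise DataError(f"site {eff.site} has no genotype label")
        category_label = labels[eff.site]
        if category_label not in (GenotypeCategory.HET, GenotypeCategory.HOM_ALT):
            raise DataError(f"site {eff.site}: summary is defined for HET/HOM_ALT sites, got {category_label}")
        key = (eff.site, eff.category)
        if key in seen:
            continue
        seen.add(key)
        slot = counts.setdefault(eff.category, [0, 0])
        slot[0 if category_label is GenotypeCategory.HET else 1] += 1
    return EffectSummary({cat: (h, a) for cat, (h, a) in counts.items()})


def high_impact_genes(effects: Iterable[EffectCall]) -> set[str]:
    """Distinct genes carrying at least one HIGH-impact effect."""
    return {e.gene_id for e in effects if e.impact is Impact.HIGH}
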