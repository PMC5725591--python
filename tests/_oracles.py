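"""Independent brute-force oracles used by the test suite.

The effect oracle classifies a variant by physically rebuilding the spliced
mRNA, the coding sequence and the translated protein for both the reference
and the alternate genome, then diffing them — no codon-index arithmetic is
shared with the implementation under test.
"""

from __future__ import annotations

import numpy as np
from Bio.Seq import Seq

from clonotyper.core_io import GeneModel, Transcript
from clonotyper.effects import EffectCategory, EffectConfig

STOPS = {"TAA", "TAG", "TGA"}


def _splice(intervals, chrom_seq: str, strand: str, substitute=None) -> str:
    chunks = []
    for s, e in sorted(intervals):
        chunk = chrom_seq[s - 1 : e]
        if substitute is not None and s <= substitute[0] <= e:
            i = substitute[0] - s
            chunk = chunk[:i] + substitute[1] + chunk[i + 1 :]
        chunks.append(chunk)
    seq = "".join(chunks)
    return seq if strand == "+" else str(Seq(seq).reverse_complement())


def _transcription_order_positions(intervals, strand: str) -> list[int]:
    positions = [p for s, e in sorted(intervals) for p in range(s, e + 1)]
    return positions if strand == "+" else positions[::-1]


def oracle_classify(
    gene: GeneModel,
    tx: Transcript,
    genome: dict[str, str],
    pos: int,
    alt: str,
    config: EffectConfig | None = None,
) -> EffectCategory | None:
    config = config or EffectConfig()
    chrom_seq = genome[gene.chrom]
    strand = gene.strand
    start, end = tx.span

    if pos < start or pos > end:
        tss = start if strand == "+" else end
        tes = end if strand == "+" else start
        d_up = tss - pos if strand == "+" else pos - tss
        d_down = pos - tes if strand == "+" else tes - pos
        if 0 < d_up <= config.upstream_window:
            return EffectCategory.UPSTREAM
        if 0 < d_down <= config.downstream_window:
            return EffectCategory.DOWNSTREAM
        return None

    exonic = any(s <= pos <= e for s, e in tx.exons)
    if not exonic:
        for gs, ge in tx.introns:
            if gs <= pos <= ge:
                intron_positions = _transcription_order_positions([(gs, ge)], strand)
                if pos in intron_positions[: config.splice_window]:
                    return EffectCategory.SPLICE_SITE_DONOR
                if pos in intron_positions[-config.splice_window :]:
                    return EffectCategory.SPLICE_SITE_ACCEPTOR
                return EffectCategory.INTRON
        raise AssertionError("inside span but neither exonic nor intronic")

    cds_ref = _splice(tx.cds, chrom_seq, strand)
    cds_alt = _splice(tx.cds, chrom_seq, strand, substitute=(pos, alt))
    if cds_ref != cds_alt:
        i = next(k for k in range(len(cds_ref)) if cds_ref[k] != cds_alt[k])
        codon = i // 3
        ref_codon = cds_ref[3 * codon : 3 * codon + 3]
        alt_codon = cds_alt[3 * codon : 3 * codon + 3]
        if codon == 0:
            if alt_codon == "ATG":
                return EffectCategory.SYNONYMOUS_CODING
            if alt_codon in config.alternative_starts:
                return EffectCategory.NON_SYNONYMOUS_START
            return EffectCategory.START_LOST
        if codon == len(cds_ref) // 3 - 1 and ref_codon in STOPS:
            return EffectCategory.SYNONYMOUS_STOP if alt_codon in STOPS else EffectCategory.STOP_LOST
        if alt_codon in STOPS:
            return EffectCategory.STOP_GAINED
        prot_ref = str(Seq(cds_ref).translate())
        prot_alt = str(Seq(cds_alt).translate())
        return EffectCategory.SYNONYMOUS_CODING if prot_ref == prot_alt else EffectCategory.NON_SYNONYMOUS_CODING

    # exonic but outside the CDS: locate by transcript index
    tx_positions = _transcription_order_positions(tx.exons, strand)
    tx_idx = tx_positions.index(pos)
    cds_positions = set(p for s, e in tx.cds for p in range(s, e + 1))
    cds_tx_indices = [i for i, p in enumerate(tx_positions) if p in cds_positions]
    utr5_len = cds_tx_indices[0]
    if tx_idx < utr5_len:
        mrna_ref = _splice(tx.exons, chrom_seq, strand)
        mrna_alt = _splice(tx.exons, chrom_seq, strand, substitute=(pos, alt))
        utr_ref, utr_alt = mrna_ref[:utr5_len], mrna_alt[:utr5_len]
        ref_starts = {i for i in range(len(utr_ref) - 2) if utr_ref[i : i + 3] == "ATG"}
        alt_starts = {i for i in range(len(utr_alt) - 2) if utr_alt[i : i + 3] == "ATG"}
        return EffectCategory.START_GAINED if alt_starts - ref_starts else EffectCategory.UTR_5_PRIME
    return EffectCategory.UTR_3_PRIME


# ---------------------------------------------------------------------------
# random (gene, SNV) case generation for oracle-equivalence studies

def random_gene(rng: np.random.Generator, chrom: str = "chrT"):
    """One random multi-exon coding gene embedded in a fresh ~14 kb sequence."""
    from clonotyper.synthetic_data import _make_gene

    seq = list(rng.choice(list("ACGT"), size=14_000))
    strand = "+" if rng.random() < 0.5 else "-"
    gene = _make_gene(rng, seq, chrom, f"{chrom}_gene", 6_001, strand)
    return gene, {chrom: "".join(seq)}


def _positions_in(intervals):
    return [p for s, e in intervals for p in range(s, e + 1)]


def sample_variant_positions(rng: np.random.Generator, gene: GeneModel, genome_len: int, n: int) -> list[int]:
    """Stratified positions hitting every structural region of the gene."""
    tx = gene.transcripts[0]
    strand = gene.strand
    start, end = tx.span
    tss = start if strand == "+" else end
    tes = end if strand == "+" else start
    sign = 1 if strand == "+" else -1
    utr5, utr3 = tx.utr_intervals(strand)
    cds_pos = _positions_in(tx.cds)
    cds_first = cds_pos[:3] if strand == "+" else cds_pos[-3:]
    cds_last = cds_pos[-3:] if strand == "+" else cds_pos[:3]
    pools = [
        [max(1, min(genome_len, tss - sign * int(rng.integers(1, 5001)))) for _ in range(4)],
        [max(1, min(genome_len, tes + sign * int(rng.integers(1, 5001)))) for _ in range(4)],
        _positions_in(tx.introns),
        [p for gs, ge in tx.introns for p in (gs, gs + 1, ge - 1, ge)],
        _positions_in(utr5),
        _positions_in(utr3),
        cds_first,
        cds_last,
        cds_pos,
    ]
    pools = [p for p in pools if p]
    out = []
    for _ in range(n):
        pool = pools[int(rng.integers(len(pools)))]
        out.append(int(pool[int(rng.integers(len(pool)))]))
    return out
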