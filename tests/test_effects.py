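"""Effect classification: worked examples, oracle equivalence on random
genes/SNVs, strand symmetry, impact mapping, summarization."""

import numpy as np
import pytest
from Bio.Seq import Seq

from clonotyper.core_io import (
    DataError,
    GeneModel,
    GenotypeCall,
    GenotypeCategory,
    QualityAnnotations,
    Transcript,
    VariantRecord,
)
from clonotyper.effects import (
    IMPACT_BY_CATEGORY,
    EffectCall,
    EffectCategory,
    EffectConfig,
    Impact,
    classify_effects,
    high_impact_genes,
    summarize_effects,
)

from _oracles import oracle_classify, random_gene, sample_variant_positions


def build_gene(seq_len=10_000, exon=(101, 400), cds=(151, 351), strand="+"):
    rng = np.random.default_rng(5)
    seq = list(rng.choice(list("ACGT"), size=seq_len))
    s, e = cds
    seq[s - 1 : s + 2] = list("ATG")
    seq[e - 3 : e] = list("TAA")
    for i in range(s + 2, e - 3, 3):
        while "".join(seq[i : i + 3]) in ("TAA", "TAG", "TGA"):
            seq[i + 2] = "C"
    genome = {"chr1": "".join(seq)}
    gene = GeneModel("g1", "chr1", strand, (Transcript("g1.1", (exon,), (cds,)),))
    return gene, genome


def variant(genome, pos, alt, chrom="chr1"):
    ref = genome[chrom][pos - 1]
    assert ref != alt
    gt = GenotypeCall(GenotypeCategory.HET, (ref, alt), 30, {ref: 15, alt: 15})
    return VariantRecord(chrom, pos, ref, (alt,), {"c": gt}, QualityAnnotations(500, 1.0, 20.0, 0.0))


def one_category(gene, genome, pos, alt, config=None):
    calls = classify_effects(variant(genome, pos, alt), gene, genome, config)
    assert len(calls) == 1
    return calls[0].category


def test_start_lost_is_high_impact():
    gene, genome = build_gene()
    calls = classify_effects(variant(genome, 152, "C"), gene, genome)  # ATG -> ACG
    assert calls[0].category is EffectCategory.START_LOST
    assert calls[0].impact is Impact.HIGH
    assert calls[0].codon_change == ("ATG", "ACG")


def test_alternative_start_set():
    gene, genome = build_gene()
    config = EffectConfig(alternative_starts=frozenset({"GTG", "TTG"}))
    assert one_category(gene, genome, 151, "G", config) is EffectCategory.NON_SYNONYMOUS_START
    assert one_category(gene, genome, 151, "G") is EffectCategory.START_LOST


def test_upstream_window_5000():
    gene, genome = build_gene(seq_len=18_000, exon=(6_001, 6_300), cds=(6_051, 6_251))
    pos = 6_001 - 4_000  # 4,000 nt 5' of the transcription start
    assert one_category(gene, genome, pos, "A" if genome["chr1"][pos - 1] != "A" else "T") \
        is EffectCategory.UPSTREAM
    far = 6_300 + 5_200  # outside the downstream window: no call
    v = variant(genome, far, "A" if genome["chr1"][far - 1] != "A" else "T")
    assert classify_effects(v, gene, genome) == []


def test_stop_codon_rules():
    gene, genome = build_gene()
    assert one_category(gene, genome, 350, "G") is EffectCategory.SYNONYMOUS_STOP  # TAA->TGA
    assert one_category(gene, genome, 350, "C") is EffectCategory.STOP_LOST  # TAA->TCA


def test_splice_sites_two_intronic_bases():
    rng = np.random.default_rng(6)
    seq = list(rng.choice(list("ACGT"), size=2000))
    genome = {"chr1": "".join(seq)}
    tx = Transcript("t", ((101, 200), (301, 400)), ((101, 200), (301, 400)))
    plus = GeneModel("g", "chr1", "+", (tx,))
    minus = GeneModel("g", "chr1", "-", (tx,))

    def cat(gene, pos):
        alt = "A" if genome["chr1"][pos - 1] != "A" else "T"
        res = classify_effects(variant(genome, pos, alt), gene, genome)
        return res[0].category

    assert cat(plus, 201) is EffectCategory.SPLICE_SITE_DONOR
    assert cat(plus, 202) is EffectCategory.SPLICE_SITE_DONOR
    assert cat(plus, 299) is EffectCategory.SPLICE_SITE_ACCEPTOR
    assert cat(plus, 300) is EffectCategory.SPLICE_SITE_ACCEPTOR
    assert cat(plus, 250) is EffectCategory.INTRON
    # strand flip swaps donor and acceptor
    assert cat(minus, 201) is EffectCategory.SPLICE_SITE_ACCEPTOR
    assert cat(minus, 300) is EffectCategory.SPLICE_SITE_DONOR


def test_impact_mapping_is_total():
    assert set(IMPACT_BY_CATEGORY) == set(EffectCategory)
    high = {c for c, i in IMPACT_BY_CATEGORY.items() if i is Impact.HIGH}
    assert high == {
        EffectCategory.START_LOST, EffectCategory.STOP_GAINED, EffectCategory.STOP_LOST,
        EffectCategory.SPLICE_SITE_ACCEPTOR, EffectCategory.SPLICE_SITE_DONOR,
    }
    assert IMPACT_BY_CATEGORY[EffectCategory.NON_SYNONYMOUS_CODING] is Impact.MODERATE
    assert IMPACT_BY_CATEGORY[EffectCategory.NON_SYNONYMOUS_START] is Impact.LOW


def test_non_snv_rejected():
    gene, genome = build_gene()
    ref = genome["chr1"][199]
    gt = GenotypeCall(GenotypeCategory.HET, (ref, ref + "A"), 30, {ref: 15, ref + "A": 15})
    rec = VariantRecord("chr1", 200, ref, (ref + "A",), {"c": gt}, QualityAnnotations(500))
    with pytest.raises(DataError):
        classify_effects(rec, gene, genome)


def test_oracle_equivalence_random_sample():
    """Implementation agrees with the mRNA/protein-rebuild oracle on random
    genes of both strands (a larger replicate of the same study runs in the
    acceptance suite)."""
    rng = np.random.default_rng(42)
    config = EffectConfig(alternative_starts=frozenset({"GTG", "TTG"}))
    checked = 0
    for _ in range(40):
        gene, genome = random_gene(rng)
        for pos in sample_variant_positions(rng, gene, len(genome[gene.chrom]), 8):
            ref = genome[gene.chrom][pos - 1]
            alt = "ACGT"[int(rng.integers(4))]
            if alt == ref:
                continue
            got = classify_effects(variant(genome, pos, alt, gene.chrom), gene, genome, config)
            want = oracle_classify(gene, gene.transcripts[0], genome, pos, alt, config)
            if want is None:
                assert got == []
            else:
                assert got[0].category is want, (gene.strand, pos, ref, alt)
            checked += 1
    assert checked > 200


def test_strand_symmetry():
    """Reverse-complementing the genome and flipping the gene leaves every
    category unchanged."""
    rng = np.random.default_rng(99)
    for _ in range(10):
        gene, genome = random_gene(rng)
        chrom_seq = genome[gene.chrom]
        L = len(chrom_seq)
        flipped_seq = str(Seq(chrom_seq).reverse_complement())
        mirror = lambda iv: (L + 1 - iv[1], L + 1 - iv[0])
        tx = gene.transcripts[0]
        flipped_tx = Transcript(tx.transcript_id,
                                tuple(sorted(mirror(iv) for iv in tx.exons)),
                                tuple(sorted(mirror(iv) for iv in tx.cds)))
        flipped_gene = GeneModel(gene.gene_id, gene.chrom, "-" if gene.strand == "+" else "+", (flipped_tx,))
        flipped_genome = {gene.chrom: flipped_seq}
        for pos in sample_variant_positions(rng, gene, L, 6):
            ref = chrom_seq[pos - 1]
            alt = "ACGT"[int(rng.integers(4))]
            if alt == ref:
                continue
            a = classify_effects(variant(genome, pos, alt, gene.chrom), gene, genome)
            fpos = L + 1 - pos
            falt = str(Seq(alt).reverse_complement())
            b = classify_effects(variant(flipped_genome, fpos, falt, gene.chrom), flipped_gene, flipped_genome)
            assert [c.category for c in a] == [c.category for c in b]


def test_summarize_dedupes_site_category_pairs():
    site = ("chr1", 100)
    effs = [
        EffectCall(site, "g1", "g1.1", EffectCategory.INTRON, Impact.MODIFIER),
        EffectCall(site, "g1", "g1.2", EffectCategory.INTRON, Impact.MODIFIER),
        EffectCall(site, "g2", "g2.1", EffectCategory.UPSTREAM, Impact.MODIFIER),
    ]
    summary = summarize_effects(effs, {site: GenotypeCategory.HET})
    assert summary.row(EffectCategory.INTRON) == (1, 0, 1)
    assert summary.row(EffectCategory.UPSTREAM) == (1, 0, 1)


def test_summarize_requires_labels():
    eff = EffectCall(("chr1", 5), "g", "t", EffectCategory.INTRON, Impact.MODIFIER)
    with pytest.raises(DataError):
        summarize_effects([eff], {})
    with pytest.raises(DataError):
        summarize_effects([eff], {("chr1", 5): GenotypeCategory.HOM_REF})


def test_high_impact_genes_dedup():
    mk = lambda gene, cat: EffectCall(("c", 1), gene, gene + ".1", cat, IMPACT_BY_CATEGORY[cat])
    assert high_impact_genes(
        [mk("g1", EffectCategory.STOP_GAINED), mk("g1", EffectCategory.START_LOST),
         mk("g2", EffectCategory.INTRON)]
    ) == {"g1"}
    assert high_impact_genes([]) == set()
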