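# clonotyper

Clonal SNV genotyping toolkit for vegetatively propagated crops.

Clones of a grapevine cultivar (or any clonally propagated plant) are
near-identical genetically; telling them apart requires somatic single
nucleotide variants (SNVs) that arose after the clones diverged, separated
from the vastly larger set of variants the whole cultivar shares relative
to the reference genome. `clonotyper` implements that analysis end to end
at desk scale, for geneticists working on cultivar/clone identification:

* **Filter cascade** — retain high-confidence SNVs from a multi-clone
  callset: repeat-region mask, spurious-allele rule (a third allele at ≥3
  reads in any clone), per-clone coverage ≥ 15×, FS ≤ 10, QD ≥ 10,
  |ReadPosRankSum| ≤ 2, and rejection of homozygous calls carrying > 2
  reads of the opposite allele.
* **Concordance partition** — classify each passing site across the clones:
  *varietal* (same genotype, category and allele pair, in every clone),
  *clone-specific* (exactly one clone deviates; the site is attributed to
  that clone with its genotype), or *discordant* (no single outlier;
  excluded). Tabulated as a genotype-by-clone matrix with the varietal
  percentage.
* **Effect annotation** — SnpEff-style categories (START_LOST …
  UTR_5_PRIME) with HIGH/MODERATE/LOW/MODIFIER impacts, using a 5,000-nt
  upstream/downstream window and 2-base splice sites.
* **Periclinal-chimera inference** — meristem layers L1 and L2 can carry
  different genotypes; tissues mix the layers (berry flesh is pure L2,
  skin and leaf carry both), so the observed alt-allele fraction in tissue
  *t* is `f_t = α_t·s1 + (1−α_t)·s2` with `s1, s2 ∈ {0, ½, 1}` the layer
  states. An exhaustive least-squares fit over the nine state pairs calls
  the layered genotype, flagging hom/hemizygous ambiguity.
* **Marker panels** — group accessions into multilocus genotype classes
  (chimeric states such as `CC~CT` are first-class tokens) and search
  exhaustively for the smallest marker subsets that keep all classes
  distinct.
* **Relationships** — allele-sharing distance `D = 1 − (proportion of
  shared alleles)`, bootstrapped UPGMA dendrogram (Newick; NJ available as
  an alternative), and a median-joining network over the class profiles.
* **Synthetic data** — generators for every input (mini genome, gene
  models, repeat mask, three-clone VCF with planted truth, 98-accession
  panel, tissue assays), used by the test suite to verify exact truth
  recovery.

## Worked example

Tabulating a three-clone partition from per-cell counts (here the counts of
the published 'Nebbiolo' three-clone callset) and rendering the report:

```python
from clonotyper.core_io import GenotypeCategory as G
from clonotyper.partition import labels_from_counts, tabulate_partition
from clonotyper.reporting import render_partition_report

labels = labels_from_counts(
    {G.HOM_ALT: 524_899, G.HET: 111_424},
    {"CVT71":  {G.HOM_REF: 784, G.HOM_ALT: 3_606, G.HET: 8_496},
     "CVT423": {G.HOM_REF: 403, G.HOM_ALT: 3_113, G.HET: 4_398},
     "CVT185": {G.HOM_REF: 400, G.HOM_ALT: 3_245, G.HET: 4_425}},
    excluded=368)
text, payload = render_partition_report(
    tabulate_partition(labels, ("CVT71", "CVT423", "CVT185")))
print(text)
```

prints

```
Genotype    clone-specific CVT71  clone-specific CVT423  clone-specific CVT185  varietal  total
HOM_REF     784                   403                    400                    0         1,587
HOM_ALT     3,606                 3,113                  3,245                  524,899   534,863
HET         8,496                 4,398                  4,425                  111,424   128,743
Excluded    -                     -                      -                      -         368
TOTAL       12,886                7,914                  8,070                  636,323   665,561
Varietal fraction: 95.6%
```

i.e. 665,561 SNVs in total, of which 636,323 (95.6%) are shared by all
three clones and 28,870 are specific to one clone — the varietal versus
clone-specific split that drives marker selection.

Inferring a layered genotype from tissue assays (heterozygous L1 over a
homozygous L2 — the signature of a periclinal chimera, seen as an
"intermediate" cluster in allelic-discrimination plots):

```python
from clonotyper.chimera import LayerAssay, infer_layer_genotypes
inf = infer_layer_genotypes([LayerAssay("Ne_SNV31", "leaf", 0.25),
                             LayerAssay("Ne_SNV31", "skin", 0.25),
                             LayerAssay("Ne_SNV31", "flesh", 0.0)])
print(inf.l1_state, inf.l2_state, inf.is_chimera, inf.note)
# 0.5 0.0 True hom/hemizygous indistinguishable
```

The same operations are available from the shell via the `clonotyper`
console script (`simulate`, `filter`, `partition`, `annotate`, `chimera`,
`classify`, `tree`, `network`, `run`); `clonotyper run --out DIR --seed N`
executes the whole synthetic pipeline and writes a checksummed manifest.

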