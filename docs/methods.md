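# Methods

## Scope and data model

The package operates on a multi-sample VCF (one sample per clone of a
cultivar), a repeat-region BED mask, a GFF3 gene annotation with its FASTA
genome, an accession × marker genotype table, and a tissue-level
allelic-fraction assay table. Coordinates are 1-based closed internally;
BED input is converted at the boundary. Genotype category (hom-ref / het /
hom-alt / multi-allelic / missing) is derived from the GT field alone;
allele depths feed only the filter rules. Phased and unphased separators
are equivalent because no downstream rule is phase-aware. Multi-allelic
lines are kept as single records: a genotype touching any allele beyond the
first alternate is category MULTI and is removed by the spurious-allele
filter rather than split into pseudo-biallelic records.

INFO floats and QUAL are rounded to 4 decimals on read, because htslib
stores them as 32-bit floats; with that normalization a write→read
round-trip reproduces field-identical records.

## Filter cascade

The default ("recalibrated") cascade discards a site when any of the
following holds, and reports *all* violated rules rather than
short-circuiting:

| rule | threshold | note |
|---|---|---|
| repeat region | position in mask | half-open BED vs 1-based position |
| spurious allele | ≥ 3 alleles each ≥ 3 reads in any clone, or a MULTI genotype | |
| coverage | any clone depth < 15 reads | also reported as "inadequate coverage in a clone" |
| Fisher strand | FS > 10 (phred) | strict: FS = 10 passes |
| quality by depth | QD < 10 | absent QD never fails |
| read-position rank sum | \|RPRS\| > 2 | one-sided `> 2` available by switch |
| discordant homozygote | hom call with > 2 reads of the opposite allele | |

Design points: the per-clone depth rule realizes both the printed coverage
cut and the "not adequately covered in at least one clone" exclusion with
the single stated threshold; both reason labels are emitted for
traceability. The rank-sum rule defaults to two-sided because a one-sided
cut discards only one tail of a symmetric statistic — the literal one-sided
form is available by configuration. Absent annotations never fail their
rule, since rank-sum statistics are legitimately absent at sites without
heterozygous carriers; failing on absence would discard essentially all
hom-alt varietal sites. An earlier-generation hard-filter preset
(QUAL < 100, depth outside [0.5×, 3×] of the ~30× mean, SB > 0, FS < 1,
RPRS outside [−2, 2.5], AF < 0.2) is wired and individually testable but
not default.

## Concordance partition

"Same genotype" means identical allele content, not merely the same
category: an A/T heterozygote and an A/G heterozygote are different
genotypes. With three clones the classification is exactly: all equal →
varietal (all hom-ref → not a variant), exactly one outlier →
clone-specific, attributed to the outlier with the *outlier's* genotype
(so one hom-ref clone against two shared variant clones populates the
hom-ref clone-specific cells), otherwise discordant-excluded. For N > 3
clones the same trichotomy (all-equal / one-outlier / other) applies. The
tabulation is a genotype-category × (per-clone, varietal, total) matrix;
the varietal percentage is display-rounded to one decimal while the JSON
twin keeps exact integers.

## Effect annotation

Each (SNV, transcript) pair receives one category. Regions: upstream and
downstream windows of 5,000 nt from the transcription start/end
(strand-aware; the stated convention gives 5,000 nt upstream, and the same
window is applied downstream, matching the SnpEff 3.0 default); splice
donor/acceptor are the first/last two intronic bases (GT–AG convention;
the wider 3–8 nt "splice region" is deliberately not modelled); remaining
intronic, 5'/3' UTR and coding positions follow the annotation. Coding
changes are translated on the coding strand with the standard code:
start-codon disruption is START_LOST unless the alternate codon belongs to
a configurable alternative-start set (empty by default, in which case
NON_SYNONYMOUS_START is unreachable); a stop codon that mutates to another
stop is SYNONYMOUS_STOP, to a non-stop STOP_LOST; an internal codon
becoming a stop is STOP_GAINED; otherwise synonymous/non-synonymous by
amino-acid identity. A 5'UTR change that creates a new ATG on the coding
strand is START_GAINED. Impact is a fixed total function of category
(HIGH: start/stop/splice disruptions; MODERATE: missense; LOW: silent,
start-gained, alternative-start; MODIFIER: positional categories).

Correctness is established against an independent oracle that physically
rebuilds the spliced mRNA, CDS and protein for reference and alternate
genomes and diffs them; the suite requires 100% category agreement over
thousands of random gene/SNV pairs on both strands covering all 15
categories, plus a strand-symmetry property (reverse-complementing the
genome and flipping the gene leaves every call unchanged).

## Periclinal-chimera inference

Model: a tissue with L1 cell fraction α observes alt-allele fraction
`f = α·s1 + (1−α)·s2 + ε`, with layer states s ∈ {0, ½, 1} (diploid
hom-ref / het / hom-alt) and ε zero-mean noise. Defaults α(leaf) = 0.5,
α(skin) = 0.5, α(flesh) = 0 encode the developmental origin of the tissues
(flesh pure L2, skin and leaf mixed); the true leaf/skin layer proportions
are not quantified anywhere we know of, so these are explicit, configurable
assumptions — the qualitative signature (an "intermediate" cluster between
het and hom) appears for any α in (0, 1). Inference minimizes the summed
squared error over the nine (s1, s2) pairs; a chimeric solution is called
only when it beats the best non-chimeric one by the decision margin
τ = 0.01 (ties and sub-margin improvements resolve to non-chimeric —
conservative calling). States 0 and 1 always carry an explicit
"hom/hemizygous indistinguishable" note: an allele-fraction assay cannot
resolve copy number, and a hemizygous deletion would produce the same
fractions. Identifiability requires at least two tissues with different α.
Banded single-fraction calls (hom-ref ≤ 0.15, het 0.35–0.65, hom-alt
≥ 0.85, otherwise "intermediate") are provided for descriptive use.

With noise sd 0.03 (typical of normalized dual-probe fluorescence ratios)
the nine state pairs are separated by ≥ 0.25 in fraction space and recovery
is essentially perfect; the suite verifies exact zero-noise recovery, ≥ 99%
recovery at sd 0.03 with 50 loci per pair, and monotone degradation over a
noise grid.

## Marker panel and minimal subsets

Genotype classes are equivalence classes of exact profile equality;
composite chimeric tokens (`"CC~CT"`, layer-2 genotype ~ layer-1 genotype)
are states of their own, since chimeric states are precisely what
distinguishes some clonal genotypes. Rows with missing tokens are excluded
and reported, never imputed. Class letters follow first appearance in the
input; a canonical mode (descending member count, ties by profile order)
is available for order-independent reports. The minimal-subset search is
exhaustive over subsets of increasing size (practical to ~20 markers) and
returns *all* witnesses of the minimal size; a greedy heuristic is provided
for larger panels.

## Distances, trees, networks

The allele-sharing distance treats each locus as a diploid allele multiset
(chimeric tokens contribute the union of their layer alleles as a het
pair): per locus, shared = |multiset intersection| / 2; D = 1 − mean over
loci. D is a bounded symmetric premetric; the triangle inequality is not
asserted.

UPGMA is implemented directly (average linkage, node height = merge
distance / 2, hence ultrametric by construction) so that ties are broken
deterministically by joining the pair of clusters whose smallest member
labels sort first; merge heights are cross-checked against SciPy's average
linkage in the suite. Methods-grade sources prescribe UPGMA for this
analysis even where figure captions say "neighbour-joining"; both are
offered (NJ via scikit-bio) and UPGMA is the default. Bootstrap supports
resample loci with replacement (default 1,000 replicates, seeded),
rebuilding distance and tree per replicate and counting leaf-set clade
recovery; supports are written as integer percentages on internal Newick
nodes. The analytic sanity check: a clade supported by exactly one locus
of ten recovers with probability 1 − (9/10)^10 ≈ 65.1%.

The median-joining network (ε = 0) iterates: build the relaxed minimum
spanning network under Hamming distance over state tokens (process
distances in increasing levels; within a level add every edge joining
components distinct before the level — this always contains a minimum
spanning tree); for every triangle add quasi-median profiles (per-locus
majority state; loci where all three states differ expand to each state,
capped); repeat to a fixed point; finally prune unobserved medians of
degree ≤ 2, which lie on paths their neighbours span directly. Observed
nodes carry class frequencies; medians carry frequency 0; edges are
labelled with their differing loci. Output is GML.

## Synthetic data: what it emulates, and what not

The cohort generator emits a 2 × 250 kb genome (GC 0.35), 20 multi-exon
genes per chromosome with valid coding sequences (ATG start, no internal
in-frame stop, stop-terminated, CDS length divisible by 3), ~10% of the
genome masked as repeats, and a three-clone VCF whose sites follow the
published varietal : clone-specific : discordant proportions
(636,323 : 12,886 : 7,914 : 8,070 : 368 out of 665,561) and per-category
genotype mixes, scaled by largest-remainder rounding. Depth is negative
binomial (mean 30, size 10) per clone, floored at the coverage threshold
for intended-PASS sites so that construction guarantees the pass fate;
allele depths are binomial around the genotype expectation with ≤ 2
discordant reads on homozygous calls. Intended-FAIL sites violate exactly
one named rule each (default planting rate 0.01 per rule). Every output is
byte-deterministic given (config, seed).

What the generator does **not** emulate: mapping bias, indels and
structural variants, linkage between neighbouring sites, depth
autocorrelation, genotyping-error correlation across clones, or a
realistic annotation-derived site spectrum. Truth-recovery results on this
cohort therefore demonstrate the correctness of the rule logic and
bookkeeping, not variant-calling performance on real reads.

The default panel encodes the published textual constraints — two markers
private to class A (either alone identifies it), three chimeric-state
markers unique to class E (each alone identifies it; E's profile is
otherwise class D's, and A's is otherwise class B's, mirroring the
described mutational adjacency), one class identified only by a marker
pair, counts A=1, B=31, C=2, D=31, E=2 — with the F/G split (21/10) a
generator default constrained only by F+G = 31, and one marker
intentionally redundant with another. The full published 7 × 10 profile
matrix is not printed anywhere accessible, so this matrix is a labelled
synthetic reconstruction; by construction its minimal discriminating
subset size is 6 (12 witnesses). Panel rows are emitted grouped by class
in letter order so that first-appearance labelling reproduces the class
letters.

## Problem sizes and numerical choices

The acceptance study uses a 50,000-site cohort (about 7.5% of the real
callset, enough that every planted rule and label occurs hundreds of
times), 2,000+ oracle comparisons for the effect annotator, 50 loci per
layer-state pair at noise sd 0.03 for chimera recovery, and 1,000
bootstrap replicates; these sizes keep a full run in well under a minute
per component on one core. All randomness flows from
`numpy.random.default_rng` seeded per generator call; derived sub-seeds
stay below 2^31. Thresholds are strict inequalities exactly as configured,
and boundary behaviour (FS = 10, QD = 10, depth = 15, 2 discordant reads
all passing) is pinned by tests.

## Known limitations

* The filter thresholds are taken as given; no recalibration against
  validated variants is performed (the printed post-hoc recalibration is a
  wet-lab procedure outside desk scope).
* Effect annotation handles biallelic SNVs only, one category per
  transcript; UTR-spanning and exon-boundary indel semantics are out of
  scope.
* Chimera inference assumes exactly two effective layers and linear
  mixing; it reports fraction-space solutions only and never claims copy
  number.
* The median-joining implementation targets small multistate panels
  (≲ 15 loci); it is not optimized for hundreds of haplotypes.
* Genome-scale counts from the real study (raw SNV totals, gene-set sizes)
  depend on the real reads and reference annotation and are intentionally
  not reproduced.
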