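import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("suite", derandomize=True, deadline=None)
settings.load_profile("suite")

from clonotyper.core_io import (
    GenotypeCall,
    GenotypeCategory,
    QualityAnnotations,
    VariantRecord,
)
from clonotyper.synthetic_data import CohortSimConfig, PanelSimConfig, generate_cohort, generate_panel


@pytest.fixture(scope="session")
def small_cohort():
    """800 planted sites with default fail plantings (in memory)."""
    return generate_cohort(CohortSimConfig(n_sites=800, seed=11))


@pytest.fixture(scope="session")
def cohort_on_disk(tmp_path_factory):
    out = tmp_path_factory.mktemp("cohort")
    return generate_cohort(CohortSimConfig(n_sites=300, seed=7), out_dir=out)


@pytest.fixture(scope="session")
def panel_data():
    return generate_panel(PanelSimConfig(seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(123)


def make_record(
    *,
    chrom="chr1",
    pos=100,
    ref="A",
    alts=("T",),
    categories=(GenotypeCategory.HET,) * 3,
    depths=(30, 30, 30),
    discordant=(0, 0, 0),
    qual=500.0,
    fs=1.0,
    qd=20.0,
    rprs=0.5,
    sb=None,
    af=None,
    clones=("CVT71", "CVT423", "CVT185"),
) -> VariantRecord:
    """Hand-built three-clone record with clean defaults (passes every rule)."""
    alt = alts[0]
    calls = {}
    for clone, category, depth, disc in zip(clones, categories, depths, discordant):
        if category is GenotypeCategory.HET:
            ad = {ref: depth // 2, alt: depth - depth // 2}
            alleles = (ref, alt)
        elif category is GenotypeCategory.HOM_ALT:
            ad = {ref: disc, alt: depth - disc}
            alleles = (alt, alt)
        elif category is GenotypeCategory.HOM_REF:
            ad = {ref: depth - disc, alt: disc}
            alleles = (ref, ref)
        elif category is GenotypeCategory.MULTI:
            ad = {ref: depth // 3, alts[0]: depth // 3, alts[1]: depth - 2 * (depth // 3)}
            alleles = (alts[0], alts[1])
        else:
            ad, alleles = {}, ()
        calls[clone] = GenotypeCall(category=category, alleles=alleles, depth=depth, allele_depths=ad)
    ann = QualityAnnotations(qual=qual, fs=fs, qd=qd, read_pos_rank_sum=rprs, sb=sb, af=af)
    return VariantRecord(chrom=chrom, pos=pos, ref=ref, alts=tuple(alts), calls=calls, ann=ann)
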