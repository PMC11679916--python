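import pytest

from trioscope.model import (
    Acmg,
    AnnotatedVariant,
    Consequence,
    Genotype,
    Sex,
    TrioSite,
)

AUTO_PAR = []  # no PARs needed for autosomal tests


def gt(*alleles, phased=False):
    return Genotype(tuple(alleles), phased=phased)


def make_site(
    child,
    mother,
    father,
    chrom="chr1",
    pos=1000,
    ref="A",
    alt="T",
    sex=Sex.MALE,
    qualities=None,
):
    return TrioSite(
        chrom=chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        child_gt=child if isinstance(child, Genotype) else gt(*child),
        mother_gt=mother if isinstance(mother, Genotype) else gt(*mother),
        father_gt=father if isinstance(father, Genotype) else gt(*father),
        child_sex=sex,
        qualities=qualities,
    )


def make_variant(
    site=None,
    gene="GENE1",
    consequence=Consequence.MISSENSE,
    gnomad_af=0.0,
    cadd_phred=30.0,
    acmg=Acmg.LP,
    **site_kwargs,
):
    if site is None:
        site = make_site((0, 1), (0, 0), (0, 0), **site_kwargs)
    return AnnotatedVariant(
        site=site,
        gene=gene,
        consequence=consequence,
        gnomad_af=gnomad_af,
        cadd_phred=cadd_phred,
        acmg=acmg,
    )


@pytest.fixture(scope="session")
def small_bundle():
    """A compact simulated cohort reused across tests."""
    from trioscope.simulate import SimConfig, simulate_cohort

    return simulate_cohort(SimConfig(n_families=10, n_background_variants=50, seed=42))
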