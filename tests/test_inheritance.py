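"""Inheritance-mode classification against an independent truth-table oracle,
and compound-het detection properties."""

import itertools
from collections import Counter

import pytest

from trioscope.inheritance import (
    Mode,
    classify_family,
    classify_site,
    detect_compound_hets,
)
from trioscope.model import Consequence, SampleQuality, Sex

from conftest import gt, make_site, make_variant

PAR = [("X", 1, 100_000), ("X", 9_900_001, 10_000_000)]
DIPLOID_GTS = [(0, 0), (0, 1), (1, 1)]
HEMI_GTS = [(0,), (1,)]


# --------------------------------------------------------------------------
# Independent oracle: enumerate transmissible allele pairs by brute force.

def oracle_diploid(child, mother, father):
    combos = [(m, f) for m in mother for f in father]
    feasible = [c for c in combos if Counter(c) == Counter(child)]
    n_alt = child.count(1)
    if not feasible:
        # a single novel allele is de novo; anything else (e.g. hom-alt child
        # of ref/ref parents, which would need two events) is a Mendelian error
        if n_alt == 1 and 1 not in mother and 1 not in father:
            return Mode.DE_NOVO
        return Mode.MENDELIAN_ERROR
    if n_alt == 2:
        return Mode.HOMOZYGOUS_RECESSIVE
    if n_alt == 0:
        return Mode.UNINFORMATIVE
    origins = {"m" if m == 1 else "p" for m, f in feasible}
    if origins == {"m"}:
        return Mode.INHERITED_HET_MATERNAL
    if origins == {"p"}:
        return Mode.INHERITED_HET_PATERNAL
    return Mode.INHERITED_HET_AMBIGUOUS


def oracle_male_x(child, mother):
    if child[0] == 1:
        return Mode.X_LINKED_HEMIZYGOUS if 1 in mother else Mode.DE_NOVO
    if mother == (1, 1):
        return Mode.MENDELIAN_ERROR
    return Mode.UNINFORMATIVE


class TestClassifySiteOracle:
    @pytest.mark.parametrize(
        "child,mother,father",
        list(itertools.product(DIPLOID_GTS, DIPLOID_GTS, DIPLOID_GTS)),
    )
    def test_autosomal_configurations(self, child, mother, father):
        site = make_site(child, mother, father, chrom="chr7")
        call = classify_site(site, par_regions=PAR)
        assert call.mode is oracle_diploid(child, mother, father)

    @pytest.mark.parametrize(
        "child,mother,father",
        list(itertools.product(HEMI_GTS, DIPLOID_GTS, HEMI_GTS)),
    )
    def test_male_x_nonpar_configurations(self, child, mother, father):
        site = make_site(
            gt(*child), gt(*mother), gt(*father),
            chrom="chrX", pos=5_000_000, sex=Sex.MALE,
        )
        call = classify_site(site, par_regions=PAR)
        assert call.mode is oracle_male_x(child, mother)

    @pytest.mark.parametrize(
        "child,mother,father",
        list(itertools.product(DIPLOID_GTS, DIPLOID_GTS, HEMI_GTS)),
    )
    def test_female_x_uses_diploid_rules_with_hemizygous_father(
        self, child, mother, father
    ):
        site = make_site(
            gt(*child), gt(*mother), gt(*father),
            chrom="chrX", pos=5_000_000, sex=Sex.FEMALE,
        )
        call = classify_site(site, par_regions=PAR)
        assert call.mode is oracle_diploid(child, mother, father)


class TestClassifySiteEdges:
    def test_de_novo_definitional(self):
        call = classify_site(make_site((0, 1), (0, 0), (0, 0)), par_regions=PAR)
        assert call.mode is Mode.DE_NOVO

    def test_homozygous_recessive_definitional(self):
        call = classify_site(make_site((1, 1), (0, 1), (0, 1)), par_regions=PAR)
        assert call.mode is Mode.HOMOZYGOUS_RECESSIVE

    def test_x_linked_hemizygous_carrier_mother(self):
        site = make_site(gt(1), gt(0, 1), gt(0), chrom="chrX", pos=5_000_000, sex=Sex.MALE)
        assert classify_site(site, par_regions=PAR).mode is Mode.X_LINKED_HEMIZYGOUS

    def test_mendelian_error_impossible_transmission(self):
        call = classify_site(make_site((1, 1), (0, 0), (0, 1)), par_regions=PAR)
        assert call.mode is Mode.MENDELIAN_ERROR

    def test_diploid_male_nonpar_x_raises(self):
        site = make_site((0, 1), (0, 1), (0,), chrom="chrX", pos=5_000_000, sex=Sex.MALE)
        with pytest.raises(ValueError, match="hemizygous"):
            classify_site(site, par_regions=PAR)

    def test_par_site_in_male_child_is_autosomal(self):
        site = make_site((0, 1), (0, 0), (0, 0), chrom="chrX", pos=50_000, sex=Sex.MALE)
        assert classify_site(site, par_regions=PAR).mode is Mode.DE_NOVO

    def test_default_par_regions_cover_grch38_par1(self):
        site = make_site((0, 1), (0, 1), (0, 0), chrom="chrX", pos=1_000_000, sex=Sex.MALE)
        assert classify_site(site).mode is Mode.INHERITED_HET_MATERNAL

    def test_missing_genotype_is_uninformative(self):
        call = classify_site(make_site(gt(None, None), gt(0, 1), gt(0, 0)), par_regions=PAR)
        assert call.mode is Mode.UNINFORMATIVE

    def test_quality_gate_flags_low_confidence_calls(self):
        quals = {
            "child": SampleQuality(gq=10, dp=30),
            "mother": SampleQuality(gq=60, dp=30),
            "father": SampleQuality(gq=60, dp=30),
        }
        call = classify_site(
            make_site((0, 1), (0, 0), (0, 0), qualities=quals), par_regions=PAR
        )
        assert call.mode is Mode.DE_NOVO and call.quality_ok is False

    def test_every_enumerated_site_gets_exactly_one_mode(self):
        # exhaustiveness: no configuration is dropped or double-assigned
        for child, mother, father in itertools.product(
            DIPLOID_GTS + [(None, None)], repeat=3
        ):
            call = classify_site(make_site(child, mother, father), par_regions=PAR)
            assert isinstance(call.mode, Mode)


# --------------------------------------------------------------------------
# compound heterozygotes

def het_variant(gene, pos, origin):
    mother = (0, 1) if origin == "m" else (0, 0)
    father = (0, 0) if origin == "m" else (0, 1)
    site = make_site((0, 1), mother, father, pos=pos)
    return make_variant(site=site, gene=gene)


def classified(variants):
    return [(v, classify_site(v.site, par_regions=PAR)) for v in variants]


class TestCompoundHets:
    def test_one_maternal_one_paternal_pairs(self):
        items = classified([het_variant("G", 100, "m"), het_variant("G", 200, "p")])
        pairs = detect_compound_hets(items)
        assert len(pairs) == 1
        assert pairs[0].maternal_variant.site.pos == 100
        assert pairs[0].paternal_variant.site.pos == 200

    def test_cis_configuration_yields_no_pair(self):
        items = classified([het_variant("G", 100, "m"), het_variant("G", 200, "m")])
        assert detect_compound_hets(items) == []

    def test_bipartite_product_matches_brute_force(self):
        mats = [het_variant("G", 100 + i, "m") for i in range(3)]
        pats = [het_variant("G", 500 + i, "p") for i in range(2)]
        items = classified(mats + pats)
        pairs = detect_compound_hets(items)
        brute = {
            (m.site.pos, p.site.pos) for m in mats for p in pats
        }
        assert {(p.maternal_variant.site.pos, p.paternal_variant.site.pos) for p in pairs} == brute
        assert len(pairs) == 6

    def test_different_genes_never_pair(self):
        items = classified([het_variant("G1", 100, "m"), het_variant("G2", 200, "p")])
        assert detect_compound_hets(items) == []

    def test_ambiguous_origin_excluded_under_strict_included_under_permissive(self):
        amb_site = make_site((0, 1), (0, 1), (0, 1), pos=300)
        amb = make_variant(site=amb_site, gene="G")
        items = classified([het_variant("G", 100, "m"), amb])
        assert detect_compound_hets(items, policy="strict") == []
        permissive = detect_compound_hets(items, policy="permissive")
        assert len(permissive) == 1
        # two ambiguous hets still never pair with each other
        amb2 = make_variant(site=make_site((0, 1), (0, 1), (0, 1), pos=400), gene="G")
        both_amb = classified([amb, amb2])
        assert detect_compound_hets(both_amb, policy="permissive") == []

    def test_parent_label_symmetry(self):
        variants = [
            het_variant("G", 100, "m"),
            het_variant("G", 200, "p"),
            het_variant("G", 300, "m"),
        ]
        pairs = detect_compound_hets(classified(variants))
        mirrored_variants = [
            het_variant("G", 100, "p"),
            het_variant("G", 200, "m"),
            het_variant("G", 300, "p"),
        ]
        mirrored = detect_compound_hets(classified(mirrored_variants))
        orig = {(p.maternal_variant.site.pos, p.paternal_variant.site.pos) for p in pairs}
        swapped = {(p.paternal_variant.site.pos, p.maternal_variant.site.pos) for p in mirrored}
        assert orig == swapped


class TestClassifyFamily:
    def test_composition_reports_exactly_injected_modes(self):
        dn = make_variant(site=make_site((0, 1), (0, 0), (0, 0), pos=100), gene="A")
        hom = make_variant(site=make_site((1, 1), (0, 1), (0, 1), pos=200), gene="B")
        result = classify_family([dn, hom], par_regions=PAR)
        modes = [call.mode for _, call in result.calls]
        assert modes == [Mode.DE_NOVO, Mode.HOMOZYGOUS_RECESSIVE]
        assert result.comp_het_pairs == []

    def test_fixture_like_homozygous_frameshift(self):
        # a UBE3C-style homozygous frameshift in a consanguineous child
        site = make_site((1, 1), (0, 1), (0, 1), chrom="chr7", pos=1000)
        v = make_variant(site=site, gene="UBE3C", consequence=Consequence.FRAMESHIFT)
        result = classify_family([v], par_regions=PAR)
        assert result.calls[0][1].mode is Mode.HOMOZYGOUS_RECESSIVE

    def test_empty_input(self):
        result = classify_family([], par_regions=PAR)
        assert result.calls == [] and result.comp_het_pairs == []
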