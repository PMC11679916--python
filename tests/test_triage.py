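"""Filter cascade, constraint triage, panel labeling and candidate selection."""

import warnings

import pytest
from hypothesis import given, settings, strategies as st

from trioscope.fixtures import load_fixture_table
from trioscope.model import Acmg, Consequence, GeneConstraint
from trioscope.triage import (
    TriageMode,
    TriagePolicy,
    annotate_panels,
    apply_filter_cascade,
    candidate_set_from_rows,
    constraint_triage,
    select_candidates,
)

from conftest import make_variant

POLICY = TriagePolicy()


class TestFilterCascade:
    def test_passing_de_novo_missense_is_candidate(self):
        # SLC6A1-style row: rare, deleterious, pathogenic, constrained gene
        v = make_variant(gnomad_af=0.0, cadd_phred=27.9, acmg=Acmg.P)
        d = apply_filter_cascade(
            v, TriageMode.DE_NOVO, POLICY, GeneConstraint("GENE1", mis_z=4.92, pli=1.0)
        )
        assert d.is_candidate and d.fail_reasons == []

    def test_common_homozygous_fails_af_only(self):
        # MYO7A-style row: AF 1.14% violates the 0.1% ceiling, all else passes
        v = make_variant(gnomad_af=0.0114, cadd_phred=32.0, acmg=Acmg.VUS)
        d = apply_filter_cascade(v, TriageMode.HOMOZYGOUS_RECESSIVE, POLICY)
        assert not d.is_candidate
        assert d.fail_reasons == ["af_fail"]

    def test_synonymous_fails_consequence_only(self):
        v = make_variant(consequence=Consequence.SYNONYMOUS)
        d = apply_filter_cascade(
            v, TriageMode.DE_NOVO, POLICY, GeneConstraint("GENE1", 4.0, 0.99)
        )
        assert d.fail_reasons == ["consequence_fail"]

    def test_benign_acmg_fails(self):
        v = make_variant(acmg=Acmg.B)
        d = apply_filter_cascade(v, TriageMode.HOMOZYGOUS_RECESSIVE, POLICY)
        assert "acmg_fail" in d.fail_reasons

    def test_acmg_na_treated_as_vus(self):
        v = make_variant(acmg=Acmg.NA)
        d = apply_filter_cascade(v, TriageMode.HOMOZYGOUS_RECESSIVE, POLICY)
        assert d.acmg_pass

    def test_missing_af_counts_as_rare(self):
        v = make_variant(gnomad_af=None)
        d = apply_filter_cascade(v, TriageMode.HOMOZYGOUS_RECESSIVE, POLICY)
        assert d.af_pass

    @pytest.mark.parametrize(
        "consequence,expected",
        [
            (Consequence.FRAMESHIFT, True),
            (Consequence.INFRAME_INSERTION, True),
            (Consequence.MISSENSE, False),
        ],
    )
    def test_missing_cadd_tolerated_only_for_untyped_indels(self, consequence, expected):
        v = make_variant(consequence=consequence, cadd_phred=None)
        d = apply_filter_cascade(v, TriageMode.HOMOZYGOUS_RECESSIVE, POLICY)
        assert d.cadd_pass is expected

    def test_fail_reasons_complete_and_reversible(self):
        # violates AF and CADD; both must be reported, and relaxing exactly
        # those two criteria must flip the decision to candidate
        v = make_variant(gnomad_af=0.05, cadd_phred=3.0)
        constraint = GeneConstraint("GENE1", 4.0, 0.99)
        d = apply_filter_cascade(v, TriageMode.DE_NOVO, POLICY, constraint)
        assert d.fail_reasons == ["af_fail", "cadd_fail"]
        relaxed = TriagePolicy(af_max=1.0, cadd_min=0.0)
        d2 = apply_filter_cascade(v, TriageMode.DE_NOVO, relaxed, constraint)
        assert d2.is_candidate

    def test_population_max_af_option(self):
        from trioscope.model import AnnotatedVariant

        base = make_variant()
        v = AnnotatedVariant(
            site=base.site, gene="G", consequence=Consequence.MISSENSE,
            gnomad_af=0.0, gnomad_af_by_pop={"eur": 0.02}, cadd_phred=30.0, acmg=Acmg.LP,
        )
        assert apply_filter_cascade(v, TriageMode.HOMOZYGOUS_RECESSIVE, POLICY).af_pass
        pop_policy = TriagePolicy(af_population_max=True)
        assert not apply_filter_cascade(v, TriageMode.HOMOZYGOUS_RECESSIVE, pop_policy).af_pass


class TestConstraintTriage:
    def test_de_novo_missense_dual_criterion_pass(self):
        ok, _ = constraint_triage(
            TriageMode.DE_NOVO, Consequence.MISSENSE, GeneConstraint("SCN2A", 8.71, 1.0), POLICY
        )
        assert ok

    def test_de_novo_missense_low_z_fails_despite_high_pli(self):
        # COP1-style values: Z = -0.36 with pLI 0.92 fails the dual criterion
        ok, reason = constraint_triage(
            TriageMode.DE_NOVO, Consequence.MISSENSE, GeneConstraint("COP1", -0.36, 0.92), POLICY
        )
        assert not ok and "dual criterion" in reason

    @pytest.mark.parametrize("consequence", [Consequence.NONSENSE, Consequence.FRAMESHIFT, Consequence.SPLICING])
    def test_de_novo_lof_requires_high_pli(self, consequence):
        assert constraint_triage(
            TriageMode.DE_NOVO, consequence, GeneConstraint("G", 0.0, 0.95), POLICY
        )[0]
        assert not constraint_triage(
            TriageMode.DE_NOVO, consequence, GeneConstraint("G", 5.0, 0.5), POLICY
        )[0]

    def test_recessive_exemption(self):
        for mode in (
            TriageMode.HOMOZYGOUS_RECESSIVE,
            TriageMode.X_LINKED_HEMIZYGOUS,
            TriageMode.COMP_HET,
        ):
            ok, reason = constraint_triage(
                mode, Consequence.MISSENSE, GeneConstraint("G", -5.0, 0.0), POLICY
            )
            assert ok and reason == "recessive exemption"

    def test_na_constraint_fails_by_default_configurable(self):
        ok, reason = constraint_triage(
            TriageMode.DE_NOVO, Consequence.MISSENSE, GeneConstraint("G", None, None), POLICY
        )
        assert not ok and "unavailable" in reason
        lenient = TriagePolicy(na_constraint_passes=True)
        assert constraint_triage(
            TriageMode.DE_NOVO, Consequence.MISSENSE, GeneConstraint("G", None, None), lenient
        )[0]


class TestPolicy:
    def test_yaml_round_trip_reproduces_decisions(self, tmp_path):
        policy = TriagePolicy(af_max=0.005, cadd_min=15.0, na_constraint_passes=True)
        path = tmp_path / "policy.yaml"
        policy.to_yaml(path)
        loaded = TriagePolicy.from_yaml(path)
        assert loaded == policy
        v = make_variant(gnomad_af=0.002, cadd_phred=18.0)
        c = GeneConstraint("G", 4.0, 0.99)
        d1 = apply_filter_cascade(v, TriageMode.DE_NOVO, policy, c)
        d2 = apply_filter_cascade(v, TriageMode.DE_NOVO, loaded, c)
        assert (d1.is_candidate, d1.fail_reasons) == (d2.is_candidate, d2.fail_reasons)

    def test_invalid_af_max_rejected(self):
        with pytest.raises(ValueError):
            TriagePolicy(af_max=0.0)

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(
        af=st.floats(0, 0.2),
        cadd=st.floats(0, 50),
        z=st.floats(-5, 10),
        pli=st.floats(0, 1),
        tighter=st.sampled_from(["af_max", "cadd_min", "denovo_mis_z_min", "denovo_mis_pli_min"]),
    )
    def test_tightening_any_threshold_never_adds_candidates(self, af, cadd, z, pli, tighter):
        v = make_variant(gnomad_af=af, cadd_phred=cadd)
        constraint = GeneConstraint("G", z, pli)
        loose = TriagePolicy()
        tight_kwargs = {
            "af_max": {"af_max": loose.af_max / 10},
            "cadd_min": {"cadd_min": loose.cadd_min + 10},
            "denovo_mis_z_min": {"denovo_mis_z_min": loose.denovo_mis_z_min + 2},
            "denovo_mis_pli_min": {"denovo_mis_pli_min": 0.99},
        }[tighter]
        tight = TriagePolicy(**tight_kwargs)
        d_loose = apply_filter_cascade(v, TriageMode.DE_NOVO, loose, constraint)
        d_tight = apply_filter_cascade(v, TriageMode.DE_NOVO, tight, constraint)
        assert d_tight.is_candidate <= d_loose.is_candidate


class TestPanels:
    def test_known_novel_and_case_insensitivity(self):
        labels = annotate_panels(
            ["SLC6A1", "NOVELGENE"],
            {"sfari": {"slc6a1", "SCN2A"}, "ndd": {"HTT"}},
        )
        assert labels["SLC6A1"]["status"] == "Known"
        assert labels["SLC6A1"]["panels"] == {"sfari": True, "ndd": False}
        assert labels["NOVELGENE"]["status"] == "Novel"

    def test_empty_panel_file_warns(self, tmp_path):
        from trioscope.io import read_panel

        p = tmp_path / "empty.txt"
        p.write_text("")
        with warnings.catch_warnings(record=True) as rec:
            warnings.simplefilter("always")
            assert read_panel(p) == set()
        assert rec

    def test_fixture_candidates_against_packaged_labels(self):
        cands = candidate_set_from_rows(load_fixture_table("cohort_snv"))
        counts = cands.known_novel_gene_counts()
        assert counts["Known"] == 35 and counts["Novel"] == 48


class TestSelectCandidates:
    def test_fixture_candidate_set_totals(self):
        cands = candidate_set_from_rows(load_fixture_table("cohort_snv"))
        assert cands.n_variants == 90
        assert len(cands.genes) == 83
        assert cands.by_mode == {
            "de_novo": 15, "homozygous": 55, "comp_het": 6, "x_linked": 14,
        }

    def test_comp_het_pair_counts_two_variants_one_gene_occurrence(self):
        cands = candidate_set_from_rows(load_fixture_table("cohort_snv"))
        fams = cands.gene_families()
        # the DNAH17 candidate pair: two variants, one family occurrence
        assert fams["DNAH17"] == ["31"]
        assert sum(1 for v in cands.variants if v.gene == "DNAH17") == 2

    def test_recurrent_candidate_genes_reported_with_families(self):
        cands = candidate_set_from_rows(load_fixture_table("cohort_snv"))
        rec = cands.recurrent_genes()
        assert rec["SPATA31A3"] == ["44", "58"]
        assert rec["FMR1"] == ["22", "91"]

    def test_empty_decision_set(self):
        assert select_candidates([]).n_variants == 0
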