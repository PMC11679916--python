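"""End-to-end drivers: classify -> triage -> select across a cohort.

Works either on an in-memory simulated :class:`~trioscope.simulate.CohortBundle`
or on files (per-family VCFs + PED + annotation sidecar + constraint table).
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .inheritance import Mode, classify_family, default_par_regions
from .io import annotate_sites, load_constraint_table, read_annotation_table, read_ped, read_trio_vcf
from .model import AnnotatedVariant, GeneConstraint, Pedigree
from .triage import (
    CandidateSet,
    TriageDecision,
    TriagePolicy,
    apply_filter_cascade,
    select_candidates,
    triage_mode_for,
)


def triage_family(
    variants: Sequence[AnnotatedVariant],
    family_id: str,
    constraints: dict[str, GeneConstraint],
    policy: TriagePolicy,
    par_regions=None,
    comp_het_policy: str = "strict",
) -> tuple[list[TriageDecision], dict]:
    """Classify one family's annotated variants and push them through the cascade.

    Returns the triage decisions for every causal-hypothesis variant plus a
    per-mode tally of the raw inheritance calls (including Mendelian errors
    and uninformative sites, which are reported but never triaged).
    """
    classification = classify_family(
        variants, par_regions=par_regions, comp_het_policy=comp_het_policy
    )
    pair_keys = classification.comp_het_keys
    call_tally: dict[str, int] = {}
    decisions = []
    for variant, call in classification.calls:
        call_tally[call.mode.value] = call_tally.get(call.mode.value, 0) + 1
        if call.mode in (Mode.UNINFORMATIVE, Mode.MENDELIAN_ERROR) or not call.quality_ok:
            continue
        tmode = triage_mode_for(call.mode, variant.site.key in pair_keys)
        if tmode is None:
            continue
        decisions.append(
            apply_filter_cascade(
                variant,
                tmode,
                policy,
                constraint=constraints.get(variant.gene),
                family_id=family_id,
            )
        )
    return decisions, call_tally


def analyze_bundle(
    bundle, policy: Optional[TriagePolicy] = None, par_regions=None
) -> tuple[list[TriageDecision], CandidateSet]:
    """Run the full pipeline on an in-memory simulated cohort."""
    from .simulate import SYNTH_PAR

    if policy is None:
        policy = TriagePolicy()
    if par_regions is None:
        par_regions = SYNTH_PAR
    decisions: list[TriageDecision] = []
    for fs in bundle.families:
        variants = annotate_sites(fs.sorted_sites(), bundle.annotations)
        fam_decisions, _ = triage_family(
            variants, fs.family.family_id, bundle.constraints, policy, par_regions
        )
        decisions.extend(fam_decisions)
    return decisions, select_candidates(decisions)


def analyze_files(
    vcf_dir,
    ped_path,
    annotations_path,
    constraints_path,
    policy: Optional[TriagePolicy] = None,
    par_regions=None,
) -> tuple[list[TriageDecision], CandidateSet, Pedigree]:
    """Run the full pipeline from files (one VCF per family under vcf_dir)."""
    if policy is None:
        policy = TriagePolicy()
    pedigree = read_ped(ped_path)
    annotations = read_annotation_table(annotations_path)
    constraints = load_constraint_table(constraints_path)
    decisions: list[TriageDecision] = []
    for fam in pedigree:
        vcf = Path(vcf_dir) / f"{fam.family_id}.vcf"
        sites = read_trio_vcf(vcf, pedigree, fam.family_id)
        variants = annotate_sites(sites, annotations)
        fam_decisions, _ = triage_family(
            variants, fam.family_id, constraints, policy, par_regions
        )
        decisions.extend(fam_decisions)
    return decisions, select_candidates(decisions), pedigree


def decisions_table(decisions: Sequence[TriageDecision]) -> pd.DataFrame:
    rows = []
    for d in decisions:
        s = d.variant.site
        rows.append(
            {
                "family": d.family_id,
                "chrom": s.chrom,
                "pos": s.pos,
                "ref": s.ref,
                "alt": s.alt,
                "gene": d.variant.gene,
                "consequence": d.variant.consequence.value,
                "mode": d.mode.value,
                "final_status": d.final_status,
                "fail_reasons": ";".join(d.fail_reasons),
            }
        )
    return pd.DataFrame(rows)
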