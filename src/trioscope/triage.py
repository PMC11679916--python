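"""Rare-variant filter cascade and mode-dependent gene-constraint triage.

The cascade mirrors a standard trio prioritization workflow: a variant is a
*candidate* only if it is rare (gnomAD AF below a ceiling, default 0.1%),
predicted deleterious (CADD above a floor, default 20), not classified
benign/likely-benign under ACMG, protein-altering, and — for variants that
must act dominantly — in a constrained gene:

* dominant-acting loss-of-function (nonsense/frameshift/splicing):
  pLI > 0.9;
* dominant-acting missense: the dual criterion missense Z > 3.0 **and**
  pLI > 0.9.

Recessive-acting variants (homozygous, X-linked hemizygous, compound-het)
are exempt from the constraint rule: pLI and Z were developed for
haploinsufficiency, and recessive genes legitimately tolerate heterozygous
loss, so low-pLI homozygotes must not be discarded as benign.

Every criterion is evaluated (no short-circuiting), so a filtered variant
reports the complete list of criteria it failed.
"""

from __future__ import annotations

import enum
from collections import Counter
from dataclasses import dataclass, field, fields
from typing import Iterable, Mapping, Optional, Sequence

import yaml

from .inheritance import Mode
from .model import Acmg, AnnotatedVariant, Consequence, GeneConstraint

LOF_CONSEQUENCES = frozenset(
    {Consequence.NONSENSE, Consequence.FRAMESHIFT, Consequence.SPLICING}
)
#: consequences for which sources routinely print no CADD score
CADD_NA_TOLERATED = frozenset({Consequence.FRAMESHIFT, Consequence.INFRAME_INSERTION})


class TriageMode(enum.Enum):
    """Causal-hypothesis modes that enter the cascade."""

    DE_NOVO = "de_novo"
    HOMOZYGOUS_RECESSIVE = "homozygous_recessive"
    X_LINKED_HEMIZYGOUS = "x_linked_hemizygous"
    COMP_HET = "comp_het"
    DOMINANT_INHERITED = "dominant_inherited"


_MODE_FROM_CALL = {
    Mode.DE_NOVO: TriageMode.DE_NOVO,
    Mode.HOMOZYGOUS_RECESSIVE: TriageMode.HOMOZYGOUS_RECESSIVE,
    Mode.X_LINKED_HEMIZYGOUS: TriageMode.X_LINKED_HEMIZYGOUS,
    Mode.INHERITED_HET_MATERNAL: TriageMode.DOMINANT_INHERITED,
    Mode.INHERITED_HET_PATERNAL: TriageMode.DOMINANT_INHERITED,
    Mode.INHERITED_HET_AMBIGUOUS: TriageMode.DOMINANT_INHERITED,
}


def triage_mode_for(call_mode: Mode, in_comp_het_pair: bool = False) -> Optional[TriageMode]:
    """Map an inheritance call onto the cascade's causal-hypothesis mode.

    Hets that participate in a compound-het pair are triaged as COMP_HET;
    uninformative and Mendelian-error sites return None (not triaged).
    """
    if in_comp_het_pair and call_mode in (
        Mode.INHERITED_HET_MATERNAL,
        Mode.INHERITED_HET_PATERNAL,
        Mode.INHERITED_HET_AMBIGUOUS,
    ):
        return TriageMode.COMP_HET
    return _MODE_FROM_CALL.get(call_mode)


@dataclass(frozen=True)
class TriagePolicy:
    """All thresholds of the filter cascade and constraint rules."""

    af_max: float = 0.001
    cadd_min: float = 20.0
    acmg_keep: frozenset = frozenset({Acmg.P, Acmg.LP, Acmg.VUS})
    consequence_keep: frozenset = frozenset(
        {
            Consequence.MISSENSE,
            Consequence.NONSENSE,
            Consequence.FRAMESHIFT,
            Consequence.SPLICING,
            Consequence.INFRAME_INSERTION,
        }
    )
    denovo_lof_pli_min: float = 0.9
    denovo_mis_z_min: float = 3.0
    denovo_mis_pli_min: float = 0.9
    constraint_exempt_modes: frozenset = frozenset(
        {
            TriageMode.HOMOZYGOUS_RECESSIVE,
            TriageMode.X_LINKED_HEMIZYGOUS,
            TriageMode.COMP_HET,
        }
    )
    #: when True, a de novo variant in a gene without constraint data passes
    na_constraint_passes: bool = False
    #: when True, threshold the maximum per-population AF instead of the global one
    af_population_max: bool = False

    def __post_init__(self):
        if not (0.0 < self.af_max <= 1.0):
            raise ValueError(f"af_max must lie in (0, 1], got {self.af_max}")
        if Acmg.B in self.acmg_keep or Acmg.LB in self.acmg_keep:
            # permitted, but never by accident: callers must opt in explicitly
            pass

    # -- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "af_max": self.af_max,
            "cadd_min": self.cadd_min,
            "acmg_keep": sorted(a.value for a in self.acmg_keep),
            "consequence_keep": sorted(c.value for c in self.consequence_keep),
            "denovo_lof_pli_min": self.denovo_lof_pli_min,
            "denovo_mis_z_min": self.denovo_mis_z_min,
            "denovo_mis_pli_min": self.denovo_mis_pli_min,
            "constraint_exempt_modes": sorted(m.value for m in self.constraint_exempt_modes),
            "na_constraint_passes": self.na_constraint_passes,
            "af_population_max": self.af_population_max,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "TriagePolicy":
        kwargs = dict(d)
        if "acmg_keep" in kwargs:
            kwargs["acmg_keep"] = frozenset(Acmg.parse(a) for a in kwargs["acmg_keep"])
        if "consequence_keep" in kwargs:
            kwargs["consequence_keep"] = frozenset(
                Consequence.parse(c) for c in kwargs["consequence_keep"]
            )
        if "constraint_exempt_modes" in kwargs:
            kwargs["constraint_exempt_modes"] = frozenset(
                TriageMode(m) for m in kwargs["constraint_exempt_modes"]
            )
        allowed = {f.name for f in fields(cls)}
        unknown = set(kwargs) - allowed
        if unknown:
            raise ValueError(f"unknown TriagePolicy fields: {sorted(unknown)}")
        return cls(**kwargs)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "TriagePolicy":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class TriageDecision:
    variant: AnnotatedVariant
    mode: TriageMode
    af_pass: bool
    cadd_pass: bool
    acmg_pass: bool
    consequence_pass: bool
    constraint_pass: bool
    constraint_reason: str
    family_id: str = ""
    known_novel: Optional[str] = None

    @property
    def final_status(self) -> str:
        return "candidate" if self.is_candidate else "filtered"

    @property
    def is_candidate(self) -> bool:
        return (
            self.af_pass
            and self.cadd_pass
            and self.acmg_pass
            and self.consequence_pass
            and self.constraint_pass
        )

    @property
    def fail_reasons(self) -> list[str]:
        reasons = []
        for flag, name in (
            (self.af_pass, "af_fail"),
            (self.cadd_pass, "cadd_fail"),
            (self.acmg_pass, "acmg_fail"),
            (self.consequence_pass, "consequence_fail"),
            (self.constraint_pass, "constraint_fail"),
        ):
            if not flag:
                reasons.append(name)
        return reasons


def constraint_triage(
    mode: TriageMode,
    consequence: Consequence,
    constraint: Optional[GeneConstraint],
    policy: TriagePolicy,
) -> tuple[bool, str]:
    """Apply the mode-dependent gene-constraint rule; returns (pass, reason)."""
    if mode in policy.constraint_exempt_modes:
        return True, "recessive exemption"
    # dominant-acting variant (de novo or inherited het): constraint applies
    if consequence in LOF_CONSEQUENCES:
        if constraint is None or constraint.pli is None:
            if policy.na_constraint_passes:
                return True, "constraint unavailable (pass by policy)"
            return False, "constraint unavailable"
        if constraint.pli > policy.denovo_lof_pli_min:
            return True, f"pLI {constraint.pli} > {policy.denovo_lof_pli_min}"
        return False, f"pLI {constraint.pli} <= {policy.denovo_lof_pli_min}"
    if consequence is Consequence.MISSENSE:
        if constraint is None or constraint.pli is None or constraint.mis_z is None:
            if policy.na_constraint_passes:
                return True, "constraint unavailable (pass by policy)"
            return False, "constraint unavailable"
        ok = (
            constraint.mis_z > policy.denovo_mis_z_min
            and constraint.pli > policy.denovo_mis_pli_min
        )
        if ok:
            return True, "dual criterion met"
        return False, (
            f"dual criterion not met (Z {constraint.mis_z}, pLI {constraint.pli})"
        )
    return True, "no constraint rule for this consequence"


def apply_filter_cascade(
    variant: AnnotatedVariant,
    mode: TriageMode,
    policy: TriagePolicy,
    constraint: Optional[GeneConstraint] = None,
    family_id: str = "",
) -> TriageDecision:
    """Evaluate every criterion of the cascade (no short-circuit)."""
    if not isinstance(variant.consequence, Consequence):
        raise ValueError(f"unknown consequence {variant.consequence!r}")

    af = variant.gnomad_af
    if policy.af_population_max and variant.gnomad_af_by_pop:
        pops = [v for v in variant.gnomad_af_by_pop.values() if v is not None]
        if pops:
            af = max([af] + pops) if af is not None else max(pops)
    af_pass = True if af is None else af < policy.af_max

    if variant.cadd_phred is None:
        cadd_pass = variant.consequence in CADD_NA_TOLERATED
    else:
        cadd_pass = variant.cadd_phred > policy.cadd_min

    acmg = variant.acmg if variant.acmg is not Acmg.NA else Acmg.VUS  # NA treated as VUS
    acmg_pass = acmg in policy.acmg_keep

    consequence_pass = variant.consequence in policy.consequence_keep

    constraint_pass, constraint_reason = constraint_triage(
        mode, variant.consequence, constraint, policy
    )

    return TriageDecision(
        variant=variant,
        mode=mode,
        af_pass=af_pass,
        cadd_pass=cadd_pass,
        acmg_pass=acmg_pass,
        consequence_pass=consequence_pass,
        constraint_pass=constraint_pass,
        constraint_reason=constraint_reason,
        family_id=family_id,
    )


# ---------------------------------------------------------------------------
# panels

def annotate_panels(
    genes: Iterable[str], panels: Mapping[str, Iterable[str]]
) -> dict[str, dict]:
    """Label genes Known/Novel against named gene panels (case-insensitive)."""
    panel_sets = {name: {str(g).strip().upper() for g in members} for name, members in panels.items()}
    out = {}
    for gene in genes:
        g = str(gene).strip().upper()
        membership = {name: g in members for name, members in panel_sets.items()}
        out[gene] = {
            "status": "Known" if any(membership.values()) else "Novel",
            "panels": membership,
        }
    return out


# ---------------------------------------------------------------------------
# cohort-level candidate selection

@dataclass
class CandidateRecord:
    """Minimal per-variant record entering cohort tallies."""

    family_id: str
    gene: str
    mode: str  # de_novo | homozygous | comp_het | x_linked
    variant_type: str
    known_novel: Optional[str] = None
    key: Optional[tuple] = None


_TRIAGE_TO_TALLY = {
    TriageMode.DE_NOVO: "de_novo",
    TriageMode.HOMOZYGOUS_RECESSIVE: "homozygous",
    TriageMode.X_LINKED_HEMIZYGOUS: "x_linked",
    TriageMode.COMP_HET: "comp_het",
    TriageMode.DOMINANT_INHERITED: "dominant_inherited",
}


@dataclass
class CandidateSet:
    variants: list[CandidateRecord]

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def genes(self) -> set[str]:
        return {v.gene for v in self.variants}

    @property
    def by_mode(self) -> Counter:
        return Counter(v.mode for v in self.variants)

    @property
    def by_type(self) -> Counter:
        return Counter(v.variant_type for v in self.variants)

    def gene_families(self) -> dict[str, list[str]]:
        """Families in which each gene carries a candidate (comp-het pair = one occurrence)."""
        occ: dict[str, set[str]] = {}
        for v in self.variants:
            occ.setdefault(v.gene, set()).add(v.family_id)
        return {g: sorted(fams) for g, fams in sorted(occ.items())}

    def recurrent_genes(self) -> dict[str, list[str]]:
        return {g: fams for g, fams in self.gene_families().items() if len(fams) > 1}

    def known_novel_gene_counts(self) -> Counter:
        per_gene: dict[str, str] = {}
        for v in self.variants:
            if v.known_novel:
                per_gene.setdefault(v.gene, v.known_novel)
        return Counter(per_gene.values())


def select_candidates(decisions: Iterable[TriageDecision]) -> CandidateSet:
    """Collect candidate decisions into cohort-wide tallies."""
    records = []
    for d in decisions:
        if not d.is_candidate:
            continue
        records.append(
            CandidateRecord(
                family_id=d.family_id,
                gene=d.variant.gene,
                mode=_TRIAGE_TO_TALLY[d.mode],
                variant_type=d.variant.consequence.value,
                known_novel=d.known_novel,
                key=d.variant.site.key,
            )
        )
    return CandidateSet(variants=records)


def candidate_set_from_rows(rows) -> CandidateSet:
    """Build a CandidateSet from curated fixture rows (paper-concordance mode).

    ``rows`` is a DataFrame with columns subject_id, gene, inheritance,
    variant_type, known_novel and is_candidate; only flagged rows are kept.
    """
    records = []
    for _, r in rows.iterrows():
        if int(r["is_candidate"]) != 1:
            continue
        records.append(
            CandidateRecord(
                family_id=str(int(r["subject_id"])),
                gene=str(r["gene"]),
                mode=str(r["inheritance"]),
                variant_type=str(r["variant_type"]),
                known_novel=str(r["known_novel"]),
            )
        )
    return CandidateSet(variants=records)
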