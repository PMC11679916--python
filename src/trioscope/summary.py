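"""Cohort-level tallies: demographics, per-mode/per-type candidate counts,
and consanguinity stratification.

Percentages are rounded half away from zero to integers and always carry
their denominator.  The "recessive fraction" of a stratum is reported under
two explicit definitions — homozygous/total and (homozygous+X-linked)/total
— because published figures of this kind are frequently ambiguous about
whether hemizygous variants count as recessive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional

from .model import Pedigree, Sex
from .triage import CandidateSet


def pct_round(numerator: float, denominator: float) -> Optional[int]:
    """Integer percentage, rounding half away from zero; None for a zero denominator."""
    if denominator == 0:
        return None
    x = 100.0 * numerator / denominator
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass
class Percentage:
    value: Optional[int]
    numerator: float
    denominator: float


@dataclass
class CohortSummary:
    n_families: int
    n_male: int
    n_female: int
    pct_male: Percentage
    pct_female: Percentage
    n_consanguineous: int
    n_consanguinity_unknown: int
    n_candidate_variants: int
    n_candidate_genes: int
    candidates_by_mode: dict = field(default_factory=dict)
    candidates_by_type: dict = field(default_factory=dict)
    pct_homozygous: Optional[Percentage] = None
    known_count: Optional[int] = None
    novel_count: Optional[int] = None


def summarize(candidates: CandidateSet, pedigree: Pedigree) -> CohortSummary:
    n_male = sum(1 for f in pedigree if f.child_sex is Sex.MALE)
    n_female = sum(1 for f in pedigree if f.child_sex is Sex.FEMALE)
    n_children = n_male + n_female
    n_consang = sum(1 for f in pedigree if f.consanguineous is True)
    n_unknown = sum(1 for f in pedigree if f.consanguineous is None)
    by_mode = dict(candidates.by_mode)
    kn = candidates.known_novel_gene_counts()
    n_var = candidates.n_variants
    return CohortSummary(
        n_families=len(pedigree),
        n_male=n_male,
        n_female=n_female,
        pct_male=Percentage(pct_round(n_male, n_children), n_male, n_children),
        pct_female=Percentage(pct_round(n_female, n_children), n_female, n_children),
        n_consanguineous=n_consang,
        n_consanguinity_unknown=n_unknown,
        n_candidate_variants=n_var,
        n_candidate_genes=len(candidates.genes),
        candidates_by_mode=by_mode,
        candidates_by_type=dict(candidates.by_type),
        pct_homozygous=Percentage(
            pct_round(by_mode.get("homozygous", 0), n_var), by_mode.get("homozygous", 0), n_var
        ),
        known_count=kn.get("Known"),
        novel_count=kn.get("Novel"),
    )


@dataclass
class StratumSummary:
    n_variants: int
    by_mode: dict
    #: homozygous / total candidate variants in the stratum
    recessive_fraction_homozygous: Optional[float]
    #: (homozygous + x_linked) / total candidate variants in the stratum
    recessive_fraction_homozygous_plus_x: Optional[float]


def _stratum(by_mode: Mapping[str, int]) -> StratumSummary:
    total = sum(by_mode.values())
    if total == 0:
        return StratumSummary(0, dict(by_mode), None, None)
    hom = by_mode.get("homozygous", 0)
    hx = hom + by_mode.get("x_linked", 0)
    return StratumSummary(total, dict(by_mode), hom / total, hx / total)


def stratify_by_consanguinity(
    candidates: CandidateSet, consanguinity: Mapping[str, Optional[bool]]
) -> dict[str, StratumSummary]:
    """Split candidate tallies by family consanguinity status.

    ``consanguinity`` maps family_id -> True/False/None; families with an
    unknown flag are excluded from both strata and counted separately.
    """
    buckets: dict[str, dict[str, int]] = {
        "consanguineous": {}, "non_consanguineous": {}, "unknown": {},
    }
    for v in candidates.variants:
        flag = consanguinity.get(v.family_id)
        name = "consanguineous" if flag is True else "non_consanguineous" if flag is False else "unknown"
        buckets[name][v.mode] = buckets[name].get(v.mode, 0) + 1
    return {name: _stratum(modes) for name, modes in buckets.items()}
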