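"""Mendelian inheritance-mode classification and compound-het detection.

Each biallelic trio site is assigned exactly one mode by comparing the
child's genotype with both parental genotypes:

* **de novo** — the child carries the alternate allele while neither
  parent does;
* **homozygous recessive** — the child is alt/alt and each parent carries
  at least one alt (the classic consanguineous pattern, where both copies
  typically descend from a shared ancestor);
* **X-linked hemizygous** — a male child is hemizygous alt outside the
  pseudoautosomal regions and the mother carries the allele;
* **inherited heterozygous (maternal/paternal/ambiguous)** — the child is
  het and the allele's parental origin is resolved by transmission logic
  alone: the origin is "ambiguous" exactly when both a maternal and a
  paternal transmission are consistent with all three genotypes (no
  read-backed phasing is attempted);
* **Mendelian error** — no transmission is consistent (e.g. child alt/alt
  with a ref/ref parent); such sites are reported and excluded from
  candidacy rather than raised.

Compound heterozygotes are then detected per gene: every (maternal-only
het, paternal-only het) pair of distinct sites in the same gene is a
candidate in-trans pair.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Optional, Sequence

import pandas as pd

from .model import AnnotatedVariant, Genotype, Sex, TrioSite, is_x, normalize_chrom


class Mode(enum.Enum):
    DE_NOVO = "de_novo"
    HOMOZYGOUS_RECESSIVE = "homozygous_recessive"
    X_LINKED_HEMIZYGOUS = "x_linked_hemizygous"
    INHERITED_HET_MATERNAL = "inherited_het_maternal"
    INHERITED_HET_PATERNAL = "inherited_het_paternal"
    INHERITED_HET_AMBIGUOUS = "inherited_het_ambiguous"
    UNINFORMATIVE = "uninformative"
    MENDELIAN_ERROR = "mendelian_error"


@dataclass(frozen=True)
class InheritanceCall:
    mode: Mode
    evidence: dict = field(default_factory=dict, hash=False, compare=False)
    quality_ok: bool = True


@dataclass(frozen=True)
class CompHetPair:
    gene: str
    maternal_variant: AnnotatedVariant
    paternal_variant: AnnotatedVariant


def default_par_regions() -> list[tuple[str, int, int]]:
    """GRCh38 PAR1/PAR2 intervals shipped with the package (1-based inclusive)."""
    ref = resources.files("trioscope.data").joinpath("par_grch38.tsv")
    with ref.open("rb") as fh:
        df = pd.read_csv(fh, sep="\t", comment="#", dtype={"chrom": str})
    return [(str(r.chrom), int(r.start), int(r.end)) for r in df.itertuples()]


def in_par(chrom: str, pos: int, par_regions: Sequence[tuple[str, int, int]]) -> bool:
    c = normalize_chrom(chrom)
    return any(normalize_chrom(pc) == c and s <= pos <= e for pc, s, e in par_regions)


def _quality_ok(site: TrioSite, gq_min: int, dp_min: int) -> bool:
    if not site.qualities:
        return True
    for q in site.qualities.values():
        if q.gq is not None and q.gq < gq_min:
            return False
        if q.dp is not None and q.dp < dp_min:
            return False
    return True


def _consistent_transmissions(child: Genotype, mother: Genotype, father: Genotype):
    """All (maternal allele, paternal allele) assignments consistent with the trio.

    Handles a hemizygous parent naturally (its single allele is the only
    transmissible one).
    """
    a, b = child.alleles
    options = {(a, b), (b, a)}
    return [
        (m, f)
        for m, f in options
        if m in mother.alleles and f in father.alleles
    ]


def classify_site(
    site: TrioSite,
    par_regions: Optional[Sequence[tuple[str, int, int]]] = None,
    gq_min: int = 20,
    dp_min: int = 10,
) -> InheritanceCall:
    """Assign exactly one inheritance mode to a biallelic trio site."""
    if par_regions is None:
        par_regions = default_par_regions()
    quality_ok = _quality_ok(site, gq_min, dp_min)
    child, mother, father = site.child_gt, site.mother_gt, site.father_gt

    hemizygous_child = (
        is_x(site.chrom)
        and site.child_sex is Sex.MALE
        and not in_par(site.chrom, site.pos, par_regions)
    )
    if hemizygous_child:
        if child.ploidy != 1:
            raise ValueError(
                f"male child genotype at non-PAR X site {site.chrom}:{site.pos} "
                f"must be hemizygous (ploidy 1), got ploidy {child.ploidy}"
            )
        return _classify_hemizygous(site, quality_ok)

    if child.is_missing or mother.is_missing or father.is_missing:
        return InheritanceCall(Mode.UNINFORMATIVE, {"reason": "missing genotype"}, quality_ok)
    if child.ploidy != 2:
        return InheritanceCall(Mode.UNINFORMATIVE, {"reason": "non-diploid child"}, quality_ok)

    alt_n = child.alt_count
    if alt_n == 0:
        # child carries no target alt; still impossible if a parent is an
        # obligate transmitter (hom-alt, or hemizygous-alt on X for a daughter)
        if not _consistent_transmissions(child, mother, father):
            return InheritanceCall(
                Mode.MENDELIAN_ERROR, {"reason": "obligate allele not transmitted"}, quality_ok
            )
        return InheritanceCall(Mode.UNINFORMATIVE, {"reason": "no alt in child"}, quality_ok)

    if alt_n == 2:
        if mother.has_alt and father.has_alt:
            return InheritanceCall(
                Mode.HOMOZYGOUS_RECESSIVE,
                {"maternal": "alt", "paternal": "alt"},
                quality_ok,
            )
        return InheritanceCall(
            Mode.MENDELIAN_ERROR,
            {"reason": "homozygous child with non-carrier parent"},
            quality_ok,
        )

    # child heterozygous for the target alt
    assignments = _consistent_transmissions(child, mother, father)
    if not assignments:
        if not mother.has_alt and not father.has_alt:
            return InheritanceCall(
                Mode.DE_NOVO, {"maternal": "absent", "paternal": "absent"}, quality_ok
            )
        return InheritanceCall(
            Mode.MENDELIAN_ERROR, {"reason": "no consistent transmission"}, quality_ok
        )
    origins = {("maternal" if m == 1 else "paternal") for m, f in assignments}
    if origins == {"maternal"}:
        return InheritanceCall(Mode.INHERITED_HET_MATERNAL, {"origin": "maternal"}, quality_ok)
    if origins == {"paternal"}:
        return InheritanceCall(Mode.INHERITED_HET_PATERNAL, {"origin": "paternal"}, quality_ok)
    return InheritanceCall(Mode.INHERITED_HET_AMBIGUOUS, {"origin": "ambiguous"}, quality_ok)


def _classify_hemizygous(site: TrioSite, quality_ok: bool) -> InheritanceCall:
    child, mother = site.child_gt, site.mother_gt
    if child.is_missing or mother.is_missing:
        return InheritanceCall(Mode.UNINFORMATIVE, {"reason": "missing genotype"}, quality_ok)
    allele = child.alleles[0]
    if allele == 1:
        if mother.has_alt:
            return InheritanceCall(
                Mode.X_LINKED_HEMIZYGOUS, {"maternal": "carrier"}, quality_ok
            )
        return InheritanceCall(
            Mode.DE_NOVO, {"maternal": "absent", "paternal": "not transmitted (X)"}, quality_ok
        )
    # child does not carry the target alt
    if mother.ploidy == 2 and mother.alt_count == 2 and allele == 0:
        return InheritanceCall(
            Mode.MENDELIAN_ERROR, {"reason": "homozygous carrier mother, ref son"}, quality_ok
        )
    return InheritanceCall(Mode.UNINFORMATIVE, {"reason": "no alt in child"}, quality_ok)


# ---------------------------------------------------------------------------
# compound heterozygotes

def detect_compound_hets(
    items: Iterable[tuple[AnnotatedVariant, InheritanceCall]],
    policy: str = "strict",
) -> list[CompHetPair]:
    """Pair maternal-only and paternal-only hets within each gene.

    Under the default ``strict`` policy, hets of ambiguous parental origin
    participate in no pair.  Under ``permissive`` an ambiguous het may pair
    with a partner of determined origin (taking the opposite role), but two
    ambiguous hets never pair with each other.
    """
    if policy not in ("strict", "permissive"):
        raise ValueError(f"unknown comp-het policy {policy!r}")
    by_gene: dict[str, dict[str, list[AnnotatedVariant]]] = {}
    for variant, call in items:
        bucket = by_gene.setdefault(variant.gene, {"m": [], "p": [], "a": []})
        if call.mode is Mode.INHERITED_HET_MATERNAL:
            bucket["m"].append(variant)
        elif call.mode is Mode.INHERITED_HET_PATERNAL:
            bucket["p"].append(variant)
        elif call.mode is Mode.INHERITED_HET_AMBIGUOUS:
            bucket["a"].append(variant)

    pairs: list[CompHetPair] = []
    seen: set[tuple] = set()

    def emit(gene: str, mat: AnnotatedVariant, pat: AnnotatedVariant) -> None:
        if mat.site.key == pat.site.key:
            return
        sig = (gene, tuple(sorted((mat.site.key, pat.site.key))))
        if sig in seen:
            return
        seen.add(sig)
        pairs.append(CompHetPair(gene=gene, maternal_variant=mat, paternal_variant=pat))

    for gene, bucket in by_gene.items():
        for mat in bucket["m"]:
            for pat in bucket["p"]:
                emit(gene, mat, pat)
        if policy == "permissive":
            for amb in bucket["a"]:
                for mat in bucket["m"]:
                    emit(gene, mat, amb)
                for pat in bucket["p"]:
                    emit(gene, amb, pat)
    pairs.sort(
        key=lambda p: (
            p.gene,
            min(p.maternal_variant.site.key, p.paternal_variant.site.key),
            max(p.maternal_variant.site.key, p.paternal_variant.site.key),
        )
    )
    return pairs


@dataclass
class FamilyClassification:
    calls: list[tuple[AnnotatedVariant, InheritanceCall]]
    comp_het_pairs: list[CompHetPair]

    @property
    def comp_het_keys(self) -> set[tuple]:
        keys = set()
        for pair in self.comp_het_pairs:
            keys.add(pair.maternal_variant.site.key)
            keys.add(pair.paternal_variant.site.key)
        return keys


def classify_family(
    variants: Sequence[AnnotatedVariant],
    par_regions: Optional[Sequence[tuple[str, int, int]]] = None,
    gq_min: int = 20,
    dp_min: int = 10,
    comp_het_policy: str = "strict",
) -> FamilyClassification:
    """Classify every annotated site of one family and detect comp-het pairs.

    Output preserves input order; every site receives exactly one call.
    """
    if par_regions is None:
        par_regions = default_par_regions()
    calls = [
        (v, classify_site(v.site, par_regions=par_regions, gq_min=gq_min, dp_min=dp_min))
        for v in variants
    ]
    pairs = detect_compound_hets(calls, policy=comp_het_policy)
    return FamilyClassification(calls=calls, comp_het_pairs=pairs)
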