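"""Core domain types for trio-genome variant prioritization.

A *trio* is an affected child plus both biological parents sequenced
together.  Every downstream operation in this package works on small,
explicit value objects: a :class:`Genotype` per sample, a
:class:`TrioSite` per biallelic variant site, and an
:class:`AnnotatedVariant` once gene/consequence/frequency/pathogenicity
annotations have been attached.  Annotations are *inputs* here — the
package never computes CADD, gnomAD frequencies or ACMG classes itself.

Allele coding
-------------
After multiallelic splitting each site is biallelic with respect to one
*target* alternate allele.  Allele indices are coded as

* ``0``   — reference allele,
* ``1``   — the target alternate allele of this (split) site,
* ``2``   — some *other* non-reference allele of the original record
  (``OTHER_ALT``), retained so that allele counts are conserved across
  the split,
* ``None`` — missing.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional

#: allele code for "a non-reference allele other than this site's target alt"
OTHER_ALT = 2


class Sex(enum.Enum):
    MALE = "male"
    FEMALE = "female"

    @classmethod
    def from_ped_code(cls, code: str) -> "Sex":
        if str(code) == "1":
            return cls.MALE
        if str(code) == "2":
            return cls.FEMALE
        raise ValueError(f"unknown PED sex code {code!r} (expected 1 or 2)")


class Consequence(enum.Enum):
    MISSENSE = "missense"
    NONSENSE = "nonsense"
    FRAMESHIFT = "frameshift"
    SPLICING = "splicing"
    INFRAME_INSERTION = "inframe_insertion"
    INTRONIC = "intronic"
    SYNONYMOUS = "synonymous"
    OTHER = "other"

    @classmethod
    def parse(cls, value: str) -> "Consequence":
        try:
            return cls(str(value).strip().lower())
        except ValueError:
            raise ValueError(f"unknown consequence {value!r}") from None


class Acmg(enum.Enum):
    """ACMG variant interpretation tiers."""

    P = "P"
    LP = "LP"
    VUS = "VUS"
    LB = "LB"
    B = "B"
    NA = "NA"

    @classmethod
    def parse(cls, value) -> "Acmg":
        if value is None:
            return cls.NA
        v = str(value).strip().upper()
        if v in ("", "NA", "NAN", "."):
            return cls.NA
        try:
            return cls(v)
        except ValueError:
            raise ValueError(f"unknown ACMG class {value!r}") from None


@dataclass(frozen=True)
class Genotype:
    """A called genotype: an ordered tuple of allele indices.

    ``ploidy`` is implied by ``len(alleles)``; ploidy 1 is permitted only
    on sex chromosomes / mitochondria (enforced at the site level, not
    here, since the genotype itself does not know its chromosome).
    """

    alleles: tuple[Optional[int], ...]
    phased: bool = False

    def __post_init__(self):
        if len(self.alleles) not in (1, 2):
            raise ValueError(f"ploidy must be 1 or 2, got {len(self.alleles)}")
        for a in self.alleles:
            if a is not None and a < 0:
                raise ValueError(f"allele indices must be non-negative, got {a}")

    @property
    def ploidy(self) -> int:
        return len(self.alleles)

    @property
    def is_missing(self) -> bool:
        return any(a is None for a in self.alleles)

    @property
    def alt_count(self) -> int:
        """Number of target-alt (allele index 1) calls."""
        return sum(1 for a in self.alleles if a == 1)

    @property
    def has_alt(self) -> bool:
        return self.alt_count > 0

    def __str__(self) -> str:
        sep = "|" if self.phased else "/"
        return sep.join("." if a is None else str(a) for a in self.alleles)


#: convenience constructors used throughout tests and the simulator
def GT(*alleles: Optional[int], phased: bool = False) -> Genotype:
    return Genotype(tuple(alleles), phased=phased)


MISSING_DIPLOID = Genotype((None, None))


@dataclass(frozen=True)
class SampleQuality:
    gq: Optional[int] = None
    dp: Optional[int] = None


@dataclass(frozen=True)
class TrioSite:
    """One biallelic variant site with child/mother/father genotypes."""

    chrom: str
    pos: int  # 1-based, VCF convention
    ref: str
    alt: str
    child_gt: Genotype
    mother_gt: Genotype
    father_gt: Genotype
    child_sex: Sex
    qualities: Optional[dict[str, SampleQuality]] = None  # keys: child/mother/father

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref!r}) at {self.chrom}:{self.pos}")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class AnnotatedVariant:
    """A trio site plus externally supplied functional annotations."""

    site: TrioSite
    gene: str
    consequence: Consequence
    accession: str = ""
    hgvs_c: str = ""
    hgvs_p: str = ""
    gnomad_af: Optional[float] = None
    gnomad_af_by_pop: Optional[dict[str, float]] = None
    cohort_ref_af: Optional[float] = None
    cadd_phred: Optional[float] = None
    acmg: Acmg = Acmg.NA

    def __post_init__(self):
        for name, af in (("gnomad_af", self.gnomad_af), ("cohort_ref_af", self.cohort_ref_af)):
            if af is not None and not (0.0 <= af <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {af}")
        if self.cadd_phred is not None and self.cadd_phred < 0:
            raise ValueError(f"cadd_phred must be non-negative, got {self.cadd_phred}")


@dataclass(frozen=True)
class GeneConstraint:
    """Gene-level constraint metrics: missense depletion Z and pLI.

    pLI approximates the probability the gene is intolerant of
    loss-of-function variation; both fields may be NA (``None``), as is
    typical for X-linked genes in constraint releases.
    """

    gene: str
    mis_z: Optional[float] = None
    pli: Optional[float] = None

    def __post_init__(self):
        if self.pli is not None and not (0.0 <= self.pli <= 1.0):
            raise ValueError(f"pli must lie in [0, 1], got {self.pli} for {self.gene}")


@dataclass(frozen=True)
class Family:
    family_id: str
    child_id: str
    mother_id: str
    father_id: str
    child_sex: Sex
    consanguineous: Optional[bool] = None

    def __post_init__(self):
        ids = {self.child_id, self.mother_id, self.father_id}
        if len(ids) != 3:
            raise ValueError(
                f"family {self.family_id}: child/mother/father IDs must be distinct"
            )


@dataclass
class Pedigree:
    families: list[Family] = field(default_factory=list)

    def family(self, family_id: str) -> Family:
        for fam in self.families:
            if fam.family_id == family_id:
                return fam
        raise KeyError(f"family {family_id!r} not in pedigree")

    def __iter__(self):
        return iter(self.families)

    def __len__(self):
        return len(self.families)


def normalize_chrom(chrom: str) -> str:
    """Strip an optional 'chr' prefix so 'chrX' and 'X' compare equal."""
    c = str(chrom)
    return c[3:] if c.lower().startswith("chr") else c


def is_x(chrom: str) -> bool:
    return normalize_chrom(chrom).upper() == "X"
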