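"""Readers and writers for the standard file formats the pipeline consumes.

VCF access goes through :mod:`pysam`; everything tabular goes through
:mod:`pandas`.  Multiallelic VCF records are split here, once, so the rest
of the package only ever sees biallelic :class:`~trioscope.model.TrioSite`
objects.
"""

from __future__ import annotations

import math
import warnings
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
import pysam

from .model import (
    OTHER_ALT,
    Acmg,
    AnnotatedVariant,
    Consequence,
    Family,
    GeneConstraint,
    Genotype,
    Pedigree,
    SampleQuality,
    Sex,
    TrioSite,
)

# ---------------------------------------------------------------------------
# PED

def read_ped(path) -> Pedigree:
    """Read a 6-column PLINK pedigree, with an optional 7th consanguinity column.

    Columns: family, individual, father, mother, sex (1=male/2=female),
    phenotype.  The optional 7th column is parsed as 1/+/yes -> True,
    0/-/no -> False, anything else -> unknown.  One trio per family is
    derived from the row whose father and mother IDs are both non-zero.
    """
    fams: dict[str, dict] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 6:
                raise ValueError(f"{path}:{lineno}: expected >= 6 PED columns, got {len(parts)}")
            fam_id, iid, pat, mat, sex = parts[0], parts[1], parts[2], parts[3], parts[4]
            consang = None
            if len(parts) >= 7:
                token = parts[6].strip().lower()
                if token in ("1", "+", "yes", "true"):
                    consang = True
                elif token in ("0", "-", "no", "false"):
                    consang = False
            rec = fams.setdefault(fam_id, {"rows": []})
            rec["rows"].append((iid, pat, mat, sex, consang))

    families = []
    for fam_id, rec in fams.items():
        children = [r for r in rec["rows"] if r[1] not in ("0", "") and r[2] not in ("0", "")]
        if len(children) != 1:
            raise ValueError(
                f"family {fam_id}: expected exactly one individual with both parents set, "
                f"found {len(children)}"
            )
        iid, pat, mat, sex, consang = children[0]
        families.append(
            Family(
                family_id=fam_id,
                child_id=iid,
                mother_id=mat,
                father_id=pat,
                child_sex=Sex.from_ped_code(sex),
                consanguineous=consang,
            )
        )
    return Pedigree(families=families)


def write_ped(pedigree: Pedigree, path) -> None:
    with open(path, "w") as fh:
        for fam in pedigree:
            consang = "NA" if fam.consanguineous is None else ("1" if fam.consanguineous else "0")
            sex = "1" if fam.child_sex is Sex.MALE else "2"
            fh.write(f"{fam.family_id}\t{fam.father_id}\t0\t0\t1\t1\tNA\n")
            fh.write(f"{fam.family_id}\t{fam.mother_id}\t0\t0\t2\t1\tNA\n")
            fh.write(
                f"{fam.family_id}\t{fam.child_id}\t{fam.father_id}\t{fam.mother_id}\t{sex}\t2\t{consang}\n"
            )


# ---------------------------------------------------------------------------
# VCF

def _split_genotype(raw: tuple, alt_index: int, phased: bool) -> Genotype:
    """Remap a (possibly multiallelic) genotype onto one target alt."""
    mapped = []
    for a in raw:
        if a is None:
            mapped.append(None)
        elif a == 0:
            mapped.append(0)
        elif a == alt_index:
            mapped.append(1)
        else:
            mapped.append(OTHER_ALT)
    return Genotype(tuple(mapped), phased=phased)


def read_trio_vcf(vcf_path, pedigree: Pedigree, family_id: str) -> list[TrioSite]:
    """Read one family's sites from a multi-sample VCF.

    Multiallelic records are split into one :class:`TrioSite` per alternate
    allele, with genotype indices remapped to the split allele (other alt
    alleles are coded ``OTHER_ALT``).  Sites are returned sorted by
    (chrom, pos, alt).
    """
    fam = pedigree.family(family_id)
    sites: list[TrioSite] = []
    with pysam.VariantFile(str(vcf_path)) as vf:
        samples = list(vf.header.samples)
        for role, sid in (("child", fam.child_id), ("mother", fam.mother_id), ("father", fam.father_id)):
            if sid not in samples:
                raise ValueError(f"sample {sid!r} ({role}) not found in {vcf_path}")
        for rec in vf:
            alts = rec.alts or ()
            for k, alt in enumerate(alts, start=1):
                gts = {}
                quals = {}
                for role, sid in (
                    ("child", fam.child_id),
                    ("mother", fam.mother_id),
                    ("father", fam.father_id),
                ):
                    sample = rec.samples[sid]
                    raw = sample.get("GT")
                    if raw is None or len(raw) == 0:
                        raise ValueError(
                            f"malformed or absent genotype for {sid} at {rec.chrom}:{rec.pos}"
                        )
                    phased = bool(getattr(sample, "phased", False))
                    gts[role] = _split_genotype(tuple(raw), k, phased)
                    quals[role] = SampleQuality(gq=sample.get("GQ"), dp=sample.get("DP"))
                sites.append(
                    TrioSite(
                        chrom=rec.chrom,
                        pos=rec.pos,
                        ref=rec.ref,
                        alt=alt,
                        child_gt=gts["child"],
                        mother_gt=gts["mother"],
                        father_gt=gts["father"],
                        child_sex=fam.child_sex,
                        qualities=quals,
                    )
                )
    sites.sort(key=lambda s: (s.chrom, s.pos, s.alt))
    return sites


def write_trio_vcf(
    sites: Sequence[TrioSite],
    path,
    sample_ids: tuple[str, str, str],
    contigs: Optional[dict[str, int]] = None,
) -> None:
    """Write biallelic trio sites to a VCF 4.2 file.

    ``sample_ids`` is (child, mother, father).  Round-tripping through
    :func:`read_trio_vcf` preserves positions, alleles and genotypes.
    """
    if contigs is None:
        contigs = {}
        for s in sites:
            contigs[s.chrom] = max(contigs.get(s.chrom, 0), s.pos + 1000)
    header = pysam.VariantHeader()
    for chrom, length in contigs.items():
        header.contigs.add(chrom, length=length)
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("GQ", 1, "Integer", "Genotype quality")
    header.formats.add("DP", 1, "Integer", "Read depth")
    child_id, mother_id, father_id = sample_ids
    for sid in sample_ids:
        header.add_sample(sid)
    ordered = sorted(sites, key=lambda s: (s.chrom, s.pos, s.alt))
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for s in ordered:
            rec = out.new_record(
                contig=s.chrom, start=s.pos - 1, alleles=(s.ref, s.alt), qual=100.0
            )
            for sid, gt, role in (
                (child_id, s.child_gt, "child"),
                (mother_id, s.mother_gt, "mother"),
                (father_id, s.father_gt, "father"),
            ):
                rec.samples[sid]["GT"] = tuple(gt.alleles)
                rec.samples[sid].phased = gt.phased
                if s.qualities and role in s.qualities:
                    q = s.qualities[role]
                    if q.gq is not None:
                        rec.samples[sid]["GQ"] = q.gq
                    if q.dp is not None:
                        rec.samples[sid]["DP"] = q.dp
            out.write(rec)


# ---------------------------------------------------------------------------
# tabular inputs

def _parse_optional_float(value) -> Optional[float]:
    if value is None:
        return None
    s = str(value).strip()
    if s == "" or s.upper() in ("NA", "NAN", "."):
        return None
    x = float(s)
    return None if math.isnan(x) else x


def load_constraint_table(path) -> dict[str, GeneConstraint]:
    """Load a TSV of gene-level constraint metrics (gene, mis_z, pli)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    required = {"gene", "mis_z", "pli"}
    if not required.issubset(df.columns):
        raise ValueError(f"constraint table {path} must have columns {sorted(required)}")
    out: dict[str, GeneConstraint] = {}
    for _, row in df.iterrows():
        gene = str(row["gene"]).strip()
        if gene in out:
            raise ValueError(f"duplicate gene {gene!r} in constraint table {path}")
        out[gene] = GeneConstraint(
            gene=gene,
            mis_z=_parse_optional_float(row["mis_z"]),
            pli=_parse_optional_float(row["pli"]),
        )
    return out


def write_constraint_table(constraints: dict[str, GeneConstraint], path) -> None:
    with open(path, "w") as fh:
        fh.write("gene\tmis_z\tpli\n")
        for gene in constraints:
            c = constraints[gene]
            z = "NA" if c.mis_z is None else f"{c.mis_z:g}"
            p = "NA" if c.pli is None else f"{c.pli:g}"
            fh.write(f"{gene}\t{z}\t{p}\n")


ANNOTATION_COLUMNS = [
    "chrom", "pos", "ref", "alt", "gene", "consequence",
    "gnomad_af", "qgp_af", "cadd", "acmg",
]


def read_annotation_table(path) -> dict[tuple[str, int, str, str], dict]:
    """Read a sidecar annotation TSV keyed by (chrom, pos, ref, alt)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = set(ANNOTATION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"annotation table {path} missing columns {sorted(missing)}")
    out = {}
    for _, row in df.iterrows():
        key = (str(row["chrom"]), int(row["pos"]), str(row["ref"]), str(row["alt"]))
        out[key] = {
            "gene": str(row["gene"]),
            "consequence": Consequence.parse(row["consequence"]),
            "gnomad_af": _parse_optional_float(row["gnomad_af"]),
            "cohort_ref_af": _parse_optional_float(row["qgp_af"]),
            "cadd_phred": _parse_optional_float(row["cadd"]),
            "acmg": Acmg.parse(row["acmg"]),
        }
    return out


def parse_annotation(raw: dict) -> dict:
    """Normalize a raw annotation mapping onto AnnotatedVariant field names."""
    return {
        "gene": str(raw["gene"]),
        "consequence": (
            raw["consequence"]
            if isinstance(raw["consequence"], Consequence)
            else Consequence.parse(raw["consequence"])
        ),
        "gnomad_af": _parse_optional_float(raw.get("gnomad_af")),
        "cohort_ref_af": _parse_optional_float(raw.get("cohort_ref_af", raw.get("qgp_af"))),
        "cadd_phred": _parse_optional_float(raw.get("cadd_phred", raw.get("cadd"))),
        "acmg": raw["acmg"] if isinstance(raw.get("acmg"), Acmg) else Acmg.parse(raw.get("acmg")),
    }


def annotate_sites(
    sites: Iterable[TrioSite],
    annotations: dict[tuple[str, int, str, str], dict],
    info_annotations: Optional[dict[tuple[str, int, str, str], dict]] = None,
) -> list[AnnotatedVariant]:
    """Attach annotations to sites; the sidecar table wins over INFO-derived ones."""
    out = []
    for s in sites:
        ann = {}
        if info_annotations and s.key in info_annotations:
            ann.update(info_annotations[s.key])
        if s.key in annotations:
            ann.update(annotations[s.key])
        if not ann:
            continue
        out.append(AnnotatedVariant(site=s, **parse_annotation(ann)))
    return out


# ---------------------------------------------------------------------------
# CNV segments (BED-like) and gene panels

def read_segments(path) -> pd.DataFrame:
    """Read a BED-like segment file: chrom, start, end, type [, sample]."""
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None,
        names=["chrom", "start", "end", "cnv_type", "sample_id"],
        dtype={"chrom": str, "cnv_type": str, "sample_id": str},
    )
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    bad = ~df["cnv_type"].isin(["DEL", "DUP"])
    if bad.any():
        raise ValueError(f"{path}: segment type must be DEL or DUP, got {df.loc[bad, 'cnv_type'].unique()}")
    return df


def write_segments(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", header=False, index=False)


def read_panel(path) -> set[str]:
    """Read a plain-text gene list (one symbol per line), case-insensitively."""
    genes = set()
    with open(path) as fh:
        for line in fh:
            g = line.strip()
            if g and not g.startswith("#"):
                genes.add(g.upper())
    if not genes:
        warnings.warn(f"panel file {path} is empty; treated as an empty set")
    return genes
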