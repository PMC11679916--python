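"""Synthetic consanguineous trio-cohort generator with a ground-truth manifest.

The generator emulates the statistical structure a trio prioritization
pipeline relies on, on a small synthetic genome (two 10 Mb autosomes plus a
10 Mb X with pseudoautosomal stubs) so whole-cohort runs take seconds:

* parental haplotypes are simulated explicitly, so the parental origin of
  every transmitted allele is exact ground truth;
* consanguineous children carry *autozygous blocks* — contiguous runs where
  the maternally and paternally transmitted haplotypes descend from one
  shared ancestor — covering on average ``autozygous_genome_fraction`` of
  the autosomes (default 0.0625, the first-cousin expectation);
* background variation emulates common polymorphism (population AF drawn
  uniformly from [0.01, 0.5], benign-leaning annotations), which the filter
  cascade must remove on frequency grounds;
* injected variants realize each causal inheritance mode with annotations
  drawn to satisfy the default triage policy; decoys each violate exactly
  one policy criterion;
* optional parental genotype error (allele dropout to hom-ref) creates
  false de novo calls at a rate that grows with the error probability.

Every output is a deterministic function of (config, seed): rerunning with
the same configuration yields byte-identical files.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .cnv import CNVSegment
from .io import write_constraint_table, write_ped, write_trio_vcf
from .model import (
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

BASES = ("A", "C", "G", "T")

#: synthetic genome: two autosomes and an X, 10 Mb each
CHROM_LENGTH = 10_000_000
AUTOSOMES = ("chr1", "chr2")
X_CHROM = "chrX"
#: pseudoautosomal stubs on the synthetic X (1-based inclusive)
SYNTH_PAR = [("X", 1, 100_000), ("X", 9_900_001, 10_000_000)]

GENE_SPACING = 100_000
GENE_LENGTH = 20_000
GENE_OFFSET = 10_000


def gene_at(chrom: str, index: int) -> tuple[str, int, int]:
    """Synthetic gene *index* on *chrom*: (name, start, end), 1-based inclusive."""
    start = index * GENE_SPACING + GENE_OFFSET
    return (f"G{chrom[3:].upper()}_{index:04d}", start, start + GENE_LENGTH)


def n_genes_per_chrom() -> int:
    return CHROM_LENGTH // GENE_SPACING


@dataclass(frozen=True)
class SimConfig:
    n_families: int = 104
    consanguineous_fraction: float = 59 / 104
    male_fraction: float = 69 / 104
    autozygous_genome_fraction: float = 0.0625
    n_background_variants: int = 120
    genotype_error_rate: float = 0.0
    injection_plan: dict = field(
        default_factory=lambda: {"de_novo": 15, "homozygous": 55, "comp_het": 6, "x_linked": 14}
    )
    decoy_plan: dict = field(
        default_factory=lambda: {"af": 1, "cadd": 1, "acmg": 1, "consequence": 1, "constraint": 1}
    )
    seed: int = 0

    def __post_init__(self):
        for name in ("consanguineous_fraction", "male_fraction",
                     "autozygous_genome_fraction", "genotype_error_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if any(v < 0 for v in self.injection_plan.values()):
            raise ValueError("injection counts must be >= 0")
        if self.injection_plan.get("comp_het", 0) % 2:
            raise ValueError("comp_het injection count must be even (variants come in pairs)")


@dataclass
class TruthRecord:
    family_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    category: str  # background | de_novo | homozygous | comp_het | x_linked | decoy
    intended_outcome: str  # candidate | filtered | none
    violated_criterion: str = ""


@dataclass
class FamilySim:
    family: Family
    sites: list[TrioSite]
    autozygous_blocks: list[tuple[str, int, int]]

    def sorted_sites(self) -> list[TrioSite]:
        return sorted(self.sites, key=lambda s: (s.chrom, s.pos, s.alt))


@dataclass
class CohortBundle:
    config: SimConfig
    pedigree: Pedigree
    families: list[FamilySim]
    annotations: dict[tuple, dict]
    constraints: dict[str, GeneConstraint]
    truth: list[TruthRecord]
    edges: pd.DataFrame

    def family_sim(self, family_id: str) -> FamilySim:
        for fs in self.families:
            if fs.family.family_id == family_id:
                return fs
        raise KeyError(family_id)


_QUAL = {  # constant high-confidence qualities for simulated calls
    "child": SampleQuality(gq=60, dp=30),
    "mother": SampleQuality(gq=60, dp=30),
    "father": SampleQuality(gq=60, dp=30),
}


def _draw_alleles(rng) -> tuple[str, str]:
    ref = BASES[rng.integers(4)]
    alt = BASES[rng.integers(4)]
    while alt == ref:
        alt = BASES[rng.integers(4)]
    return ref, alt


def _in_blocks(chrom: str, pos: int, blocks) -> bool:
    return any(c == chrom and s <= pos <= e for c, s, e in blocks)


def _in_synth_par(pos: int) -> bool:
    return any(s <= pos <= e for _, s, e in SYNTH_PAR)


def _autozygous_blocks(rng, fraction: float) -> list[tuple[str, int, int]]:
    """Autozygous runs on the autosomes totalling ~fraction of their length."""
    genome = len(AUTOSOMES) * CHROM_LENGTH
    target = rng.gamma(shape=25.0, scale=fraction * genome / 25.0)
    target = float(np.clip(target, 50_000, 0.5 * genome))
    n_blocks = 1 + int(rng.poisson(1.0))
    weights = rng.dirichlet(np.ones(n_blocks))
    blocks = []
    for w in weights:
        length = max(int(w * target), 10_000)
        chrom = AUTOSOMES[int(rng.integers(len(AUTOSOMES)))]
        start = int(rng.integers(1, CHROM_LENGTH - length))
        blocks.append((chrom, start, start + length))
    return blocks


class _PositionPool:
    """Globally unique (chrom, pos) draws, so annotation keys never collide."""

    def __init__(self, rng):
        self.rng = rng
        self.used: set[tuple[str, int]] = set()

    def draw(self, chrom: str, lo: int = 1, hi: int = CHROM_LENGTH) -> int:
        while True:
            pos = int(self.rng.integers(lo, hi))
            if (chrom, pos) not in self.used:
                self.used.add((chrom, pos))
                return pos


def simulate_cohort(config: SimConfig) -> CohortBundle:
    """Generate the in-memory cohort bundle; see :func:`write_bundle` for files."""
    rng = np.random.default_rng(config.seed)
    pool = _PositionPool(rng)

    # --- families ----------------------------------------------------------
    n = config.n_families
    sexes = [Sex.MALE if rng.random() < config.male_fraction else Sex.FEMALE for _ in range(n)]
    consang = [bool(rng.random() < config.consanguineous_fraction) for _ in range(n)]
    families = []
    for i in range(n):
        fid = f"F{i + 1:03d}"
        families.append(
            Family(
                family_id=fid,
                child_id=f"{fid}_C",
                mother_id=f"{fid}_M",
                father_id=f"{fid}_F",
                child_sex=sexes[i],
                consanguineous=consang[i],
            )
        )
    pedigree = Pedigree(families=families)

    # feasibility checks before anything is generated
    plan = dict(config.injection_plan)
    males = [f for f in families if f.child_sex is Sex.MALE]
    consang_fams = [f for f in families if f.consanguineous]
    if plan.get("x_linked", 0) > 0 and not males:
        raise ValueError("x_linked variants requested but the cohort has no male children")
    if plan.get("homozygous", 0) > 0 and not consang_fams:
        raise ValueError("homozygous variants requested but the cohort has no consanguineous families")

    sims = {
        f.family_id: FamilySim(
            family=f,
            sites=[],
            autozygous_blocks=(
                _autozygous_blocks(rng, config.autozygous_genome_fraction)
                if f.consanguineous
                else []
            ),
        )
        for f in families
    }

    annotations: dict[tuple, dict] = {}
    truth: list[TruthRecord] = []

    # --- gene constraint table ---------------------------------------------
    constraints: dict[str, GeneConstraint] = {}
    for chrom in AUTOSOMES:
        for i in range(n_genes_per_chrom()):
            name, _, _ = gene_at(chrom, i)
            constraints[name] = GeneConstraint(
                gene=name,
                mis_z=round(float(rng.normal(0.0, 1.5)), 2),
                pli=round(float(rng.beta(0.2, 0.8)), 3),
            )
    for i in range(n_genes_per_chrom()):
        name, _, _ = gene_at(X_CHROM, i)
        constraints[name] = GeneConstraint(gene=name, mis_z=None, pli=None)

    def gene_for(chrom: str, pos: int) -> str:
        index = min(max((pos - GENE_OFFSET) // GENE_SPACING, 0), n_genes_per_chrom() - 1)
        return gene_at(chrom, index)[0]

    def add_site(fs: FamilySim, chrom, pos, ref, alt, child, mother, father, ann, category,
                 outcome, violated=""):
        fs.sites.append(
            TrioSite(
                chrom=chrom, pos=pos, ref=ref, alt=alt,
                child_gt=child, mother_gt=mother, father_gt=father,
                child_sex=fs.family.child_sex, qualities=dict(_QUAL),
            )
        )
        annotations[(chrom, pos, ref, alt)] = ann
        truth.append(
            TruthRecord(
                family_id=fs.family.family_id, chrom=chrom, pos=pos, ref=ref, alt=alt,
                gene=ann["gene"], category=category, intended_outcome=outcome,
                violated_criterion=violated,
            )
        )

    # --- background common variation ---------------------------------------
    chrom_cycle = AUTOSOMES + (X_CHROM,)
    for f in families:
        fs = sims[f.family_id]
        for j in range(config.n_background_variants):
            chrom = chrom_cycle[int(rng.integers(len(chrom_cycle)))]
            pos = pool.draw(chrom)
            ref, alt = _draw_alleles(rng)
            p = float(rng.uniform(0.01, 0.5))
            hemi_x = chrom == X_CHROM and not _in_synth_par(pos)
            m_hap = rng.random(2) < p
            f_hap = rng.random(1 if hemi_x else 2) < p
            if not hemi_x and _in_blocks(chrom, pos, fs.autozygous_blocks):
                shared = rng.random() < p
                m_hap[0] = shared
                f_hap[0] = shared
                maternal, paternal = m_hap[0], f_hap[0]
            else:
                maternal = m_hap[int(rng.integers(2))]
                paternal = f_hap[int(rng.integers(len(f_hap)))]
            mother = Genotype((int(m_hap[0]), int(m_hap[1])))
            father = Genotype(tuple(int(a) for a in f_hap))
            if hemi_x and f.child_sex is Sex.MALE:
                child = Genotype((int(maternal),))
            else:
                child = Genotype((int(maternal), int(paternal)))
            if not (child.has_alt or mother.has_alt or father.has_alt):
                continue  # monomorphic in this family; a VCF would not print it
            # parental genotype error: allele dropout to hom-ref
            e = config.genotype_error_rate
            if e > 0:
                if rng.random() < e:
                    mother = Genotype((0, 0))
                if rng.random() < e:
                    father = Genotype((0,) * father.ploidy)
            ann = {
                "gene": gene_for(chrom, pos),
                "consequence": ("synonymous", "intronic", "missense")[int(rng.integers(3))],
                "gnomad_af": round(p, 6),
                "qgp_af": round(float(np.clip(p * rng.uniform(0.5, 1.5), 0, 1)), 6),
                "cadd": round(float(rng.uniform(0, 15)), 1),
                "acmg": ("B", "LB", "VUS")[int(rng.integers(3))],
            }
            add_site(fs, chrom, pos, ref, alt, child, mother, father, ann, "background", "filtered",
                     "af")

    # --- injected causal variants ------------------------------------------
    autosomal_gene_pool = [
        (chrom, i) for chrom in AUTOSOMES for i in range(n_genes_per_chrom())
    ]
    rng.shuffle(autosomal_gene_pool)
    # X genes overlapping the PAR stubs are excluded from the injectable pool
    x_gene_pool = [
        (X_CHROM, i)
        for i in range(n_genes_per_chrom())
        if gene_at(X_CHROM, i)[1] > SYNTH_PAR[0][2] and gene_at(X_CHROM, i)[2] < SYNTH_PAR[1][1]
    ]
    rng.shuffle(x_gene_pool)
    auto_iter = iter(autosomal_gene_pool)
    x_iter = iter(x_gene_pool)

    def next_gene(x: bool = False, mis_z=None, pli=None):
        chrom, idx = next(x_iter if x else auto_iter)
        name, start, end = gene_at(chrom, idx)
        if mis_z is not None or pli is not None:
            constraints[name] = GeneConstraint(gene=name, mis_z=mis_z, pli=pli)
        return name, chrom, start, end

    def passing_ann(gene: str, consequence: str):
        return {
            "gene": gene,
            "consequence": consequence,
            "gnomad_af": 0.0,
            "qgp_af": 0.0,
            "cadd": round(float(rng.uniform(25, 40)), 1),
            "acmg": ("P", "LP")[int(rng.integers(2))],
        }

    def cycler(items):
        order = list(items)
        rng.shuffle(order)
        k = 0
        while True:
            yield order[k % len(order)]
            k += 1

    any_family = cycler(families)
    consang_family = cycler(consang_fams) if consang_fams else None
    male_family = cycler(males) if males else None

    for _ in range(plan.get("de_novo", 0)):
        f = next(any_family)
        fs = sims[f.family_id]
        lof = rng.random() < 0.3
        gene, chrom, gs, ge = next_gene(mis_z=None if lof else 4.5, pli=0.99)
        pos = pool.draw(chrom, gs, ge)
        ref, alt = _draw_alleles(rng)
        add_site(
            fs, chrom, pos, ref, alt,
            Genotype((0, 1)), Genotype((0, 0)), Genotype((0, 0)),
            passing_ann(gene, "nonsense" if lof else "missense"),
            "de_novo", "candidate",
        )

    for _ in range(plan.get("homozygous", 0)):
        f = next(consang_family)
        fs = sims[f.family_id]
        block = fs.autozygous_blocks[0]
        gene = gene_for(block[0], (block[1] + block[2]) // 2)
        pos = pool.draw(block[0], block[1], block[2])
        ref, alt = _draw_alleles(rng)
        ann = passing_ann(gene, "missense")
        add_site(
            fs, block[0], pos, ref, alt,
            Genotype((1, 1)), Genotype((0, 1)), Genotype((0, 1)),
            ann, "homozygous", "candidate",
        )

    for _ in range(plan.get("comp_het", 0) // 2):
        f = next(any_family)
        fs = sims[f.family_id]
        gene, chrom, gs, ge = next_gene()
        for origin in ("maternal", "paternal"):
            pos = pool.draw(chrom, gs, ge)
            ref, alt = _draw_alleles(rng)
            mother = Genotype((0, 1)) if origin == "maternal" else Genotype((0, 0))
            father = Genotype((0, 0)) if origin == "maternal" else Genotype((0, 1))
            add_site(
                fs, chrom, pos, ref, alt,
                Genotype((0, 1)), mother, father,
                passing_ann(gene, "missense"), "comp_het", "candidate",
            )

    for _ in range(plan.get("x_linked", 0)):
        f = next(male_family)
        fs = sims[f.family_id]
        gene, chrom, gs, ge = next_gene(x=True)
        pos = pool.draw(chrom, gs, ge)
        ref, alt = _draw_alleles(rng)
        add_site(
            fs, chrom, pos, ref, alt,
            Genotype((1,)), Genotype((0, 1)), Genotype((0,)),
            passing_ann(gene, "missense"), "x_linked", "candidate",
        )

    # --- decoys: each violates exactly one criterion ------------------------
    decoy_builders = {
        "af": lambda ann: ann.update(gnomad_af=0.05),
        "cadd": lambda ann: ann.update(cadd=5.0),
        "acmg": lambda ann: ann.update(acmg="B"),
        "consequence": lambda ann: ann.update(consequence="synonymous"),
        "constraint": None,  # handled via the gene's constraint values
    }
    for criterion, count in config.decoy_plan.items():
        if criterion not in decoy_builders:
            raise ValueError(f"unknown decoy criterion {criterion!r}")
        for _ in range(count):
            f = next(any_family)
            fs = sims[f.family_id]
            if criterion == "constraint":
                gene, chrom, gs, ge = next_gene(mis_z=0.0, pli=0.1)
            else:
                gene, chrom, gs, ge = next_gene(mis_z=4.5, pli=0.99)
            pos = pool.draw(chrom, gs, ge)
            ref, alt = _draw_alleles(rng)
            ann = passing_ann(gene, "missense")
            if decoy_builders[criterion] is not None:
                decoy_builders[criterion](ann)
            add_site(
                fs, chrom, pos, ref, alt,
                Genotype((0, 1)), Genotype((0, 0)), Genotype((0, 0)),
                ann, "decoy", "filtered", criterion,
            )

    # --- interaction edge list among injected candidate genes ---------------
    truth_genes = sorted({t.gene for t in truth if t.intended_outcome == "candidate"})
    edge_rows = []
    for i in range(len(truth_genes) - 1):
        if rng.random() < 0.5:
            edge_rows.append(
                (truth_genes[i], truth_genes[i + 1], round(float(rng.uniform(0.45, 0.99)), 3))
            )
        else:  # sub-threshold noise edge
            edge_rows.append(
                (truth_genes[i], truth_genes[i + 1], round(float(rng.uniform(0.05, 0.4)), 3))
            )
    edges = pd.DataFrame(edge_rows, columns=["gene_a", "gene_b", "score"])

    return CohortBundle(
        config=config,
        pedigree=pedigree,
        families=list(sims.values()),
        annotations=annotations,
        constraints=constraints,
        truth=truth,
        edges=edges,
    )


# ---------------------------------------------------------------------------
# file emission

def write_bundle(bundle: CohortBundle, out_dir) -> Path:
    """Write the bundle as the same formats the pipeline consumes."""
    out = Path(out_dir)
    (out / "families").mkdir(parents=True, exist_ok=True)
    write_ped(bundle.pedigree, out / "cohort.ped")
    contigs = {c: CHROM_LENGTH + 1000 for c in AUTOSOMES + (X_CHROM,)}
    for fs in bundle.families:
        f = fs.family
        write_trio_vcf(
            fs.sorted_sites(),
            out / "families" / f"{f.family_id}.vcf",
            sample_ids=(f.child_id, f.mother_id, f.father_id),
            contigs=contigs,
        )
    ann_rows = []
    for (chrom, pos, ref, alt), a in sorted(bundle.annotations.items()):
        ann_rows.append(
            {
                "chrom": chrom, "pos": pos, "ref": ref, "alt": alt,
                "gene": a["gene"], "consequence": a["consequence"],
                "gnomad_af": a["gnomad_af"], "qgp_af": a["qgp_af"],
                "cadd": a["cadd"], "acmg": a["acmg"],
            }
        )
    pd.DataFrame(ann_rows).to_csv(out / "annotations.tsv", sep="\t", index=False)
    write_constraint_table(bundle.constraints, out / "constraints.tsv")
    pd.DataFrame([vars(t) for t in bundle.truth]).to_csv(
        out / "truth_manifest.tsv", sep="\t", index=False
    )
    bundle.edges.to_csv(out / "edges.tsv", sep="\t", index=False, header=False)
    return out


def simulate_bundle(config: SimConfig, out_dir=None) -> CohortBundle:
    bundle = simulate_cohort(config)
    if out_dir is not None:
        write_bundle(bundle, out_dir)
    return bundle


# ---------------------------------------------------------------------------
# CNV trio simulation

def simulate_cnv_trio(
    de_novo_segments: list[CNVSegment],
    seed: int = 0,
    n_inherited: int = 3,
) -> tuple[list[CNVSegment], list[CNVSegment], list[CNVSegment]]:
    """Build child/mother/father segment lists around given de novo segments.

    The child carries the given segments plus inherited segments that are
    present identically in exactly one parent; the given segments appear in
    neither parent.
    """
    rng = np.random.default_rng(seed)
    child = list(de_novo_segments)
    mother: list[CNVSegment] = []
    father: list[CNVSegment] = []
    for k in range(n_inherited):
        chrom = AUTOSOMES[int(rng.integers(len(AUTOSOMES)))]
        length = int(rng.integers(500, 20_000))
        start = int(rng.integers(1, CHROM_LENGTH - length))
        seg = CNVSegment(
            chrom=chrom, start=start, end=start + length,
            cnv_type=("DEL", "DUP")[int(rng.integers(2))],
        )
        child.append(seg)
        (mother if rng.random() < 0.5 else father).append(replace(seg, sample_id="parent"))
    key = lambda s: (s.chrom, s.start, s.end)
    return sorted(child, key=key), sorted(mother, key=key), sorted(father, key=key)
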