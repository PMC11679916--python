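"""De novo CNV calling from per-sample segment files.

Segments are half-open intervals [start, end) with length ``end - start``
(every printed size in the reference cohort's CNV table matches that
convention).  A child segment is called de novo when no same-type parental
segment reaches the reciprocal-overlap threshold with it — the standard
CNV matching criterion overlap / max(len_a, len_b).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

from .model import normalize_chrom


@dataclass(frozen=True)
class CNVSegment:
    chrom: str
    start: int
    end: int
    cnv_type: str  # DEL | DUP
    sample_id: str = ""

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError(
                f"segment end must exceed start, got {self.chrom}:{self.start}-{self.end}"
            )
        if self.cnv_type not in ("DEL", "DUP"):
            raise ValueError(f"cnv_type must be DEL or DUP, got {self.cnv_type!r}")


@dataclass(frozen=True)
class DeNovoCNVCall:
    segment: CNVSegment
    overlapped_genes: tuple[str, ...] = ()
    overlapped_features: tuple[str, ...] = ()
    cytoband: str = ""
    inheritance: str = "de_novo"


def cnv_length(seg: CNVSegment) -> int:
    """Segment length in bp under the half-open convention (end - start)."""
    return seg.end - seg.start


def reciprocal_overlap(a: CNVSegment, b: CNVSegment) -> float:
    """overlap / max(length a, length b); 0 for different chromosomes."""
    if normalize_chrom(a.chrom) != normalize_chrom(b.chrom):
        return 0.0
    overlap = min(a.end, b.end) - max(a.start, b.start)
    if overlap <= 0:
        return 0.0
    return overlap / max(cnv_length(a), cnv_length(b))


def call_de_novo_cnvs(
    child_segs: Sequence[CNVSegment],
    mother_segs: Sequence[CNVSegment],
    father_segs: Sequence[CNVSegment],
    min_size: int = 50,
    min_recip_overlap: float = 0.5,
) -> list[DeNovoCNVCall]:
    """Call child segments absent from both parents.

    A child segment longer than ``min_size`` is de novo iff no same-type
    parental segment is suppressing, where a parental segment suppresses
    when its reciprocal overlap is positive and >= ``min_recip_overlap``
    (so at threshold 0 any touching same-type segment suppresses, the most
    conservative setting).
    """
    parental = list(mother_segs) + list(father_segs)
    calls = []
    for seg in child_segs:
        if cnv_length(seg) <= min_size:
            continue
        suppressed = any(
            p.cnv_type == seg.cnv_type
            and (ro := reciprocal_overlap(seg, p)) > 0
            and ro >= min_recip_overlap
            for p in parental
        )
        if not suppressed:
            calls.append(DeNovoCNVCall(segment=seg))
    calls.sort(key=lambda c: (c.segment.chrom, c.segment.start, c.segment.end))
    return calls


# ---------------------------------------------------------------------------
# gene/feature annotation

@dataclass
class GeneModel:
    """Gene and exon intervals for feature-level CNV annotation.

    ``genes`` maps gene name -> (chrom, start, end, strand); ``exons`` maps
    gene name -> list of (start, end) half-open exon intervals.  Exons are
    numbered along the strand (exon 1 is 5'-most), introns between
    consecutive exons.
    """

    genes: dict[str, tuple[str, int, int, str]] = field(default_factory=dict)
    exons: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    @classmethod
    def from_records(cls, records) -> "GeneModel":
        """Build from (gene, chrom, start, end, strand, exon_list) tuples."""
        model = cls()
        for gene, chrom, start, end, strand, exon_list in records:
            model.genes[gene] = (chrom, start, end, strand)
            model.exons[gene] = sorted(exon_list)
        return model

    @classmethod
    def from_gff3(cls, path) -> "GeneModel":
        """Parse a GFF3 gene model (gene + exon features) via gffutils."""
        import gffutils

        db = gffutils.create_db(
            str(path), ":memory:", merge_strategy="create_unique", keep_order=True
        )
        model = cls()
        for gene in db.features_of_type("gene"):
            name = gene.attributes.get("Name", gene.attributes.get("ID", [gene.id]))[0]
            # GFF3 is 1-based inclusive; convert to half-open 0-based
            model.genes[name] = (gene.seqid, gene.start - 1, gene.end, gene.strand)
            exons = [
                (f.start - 1, f.end)
                for f in db.children(gene, featuretype="exon")
            ]
            model.exons[name] = sorted(exons)
        return model


def _intersects(a_start: int, a_end: int, b_start: int, b_end: int) -> bool:
    return min(a_end, b_end) > max(a_start, b_start)


def annotate_cnv_genes(
    call: DeNovoCNVCall,
    gene_model: GeneModel,
    cytobands: Optional[Sequence[tuple[str, int, int, str]]] = None,
) -> DeNovoCNVCall:
    """Attach intersected genes and exon/intron labels to a de novo call."""
    seg = call.segment
    chrom = normalize_chrom(seg.chrom)
    genes: list[str] = []
    features: list[str] = []
    model_chroms = {normalize_chrom(c) for c, *_ in gene_model.genes.values()}
    if gene_model.genes and chrom not in model_chroms:
        import warnings

        warnings.warn(
            f"segment chromosome {seg.chrom} absent from gene model; no annotation"
        )
    for gene, (g_chrom, g_start, g_end, strand) in gene_model.genes.items():
        if normalize_chrom(g_chrom) != chrom:
            continue
        if not _intersects(seg.start, seg.end, g_start, g_end):
            continue
        genes.append(gene)
        exon_list = gene_model.exons.get(gene, [])
        if not exon_list:
            continue
        # order features 5'->3' along the strand
        ordered = exon_list if strand != "-" else list(reversed(exon_list))
        for i, (e_start, e_end) in enumerate(ordered, start=1):
            if _intersects(seg.start, seg.end, e_start, e_end):
                features.append(f"{gene}:exon {i}")
        introns = []
        for j in range(len(exon_list) - 1):
            introns.append((exon_list[j][1], exon_list[j + 1][0]))
        ordered_introns = introns if strand != "-" else list(reversed(introns))
        for i, (i_start, i_end) in enumerate(ordered_introns, start=1):
            if _intersects(seg.start, seg.end, i_start, i_end):
                features.append(f"{gene}:intron {i}")
    band = ""
    if cytobands:
        for c_chrom, c_start, c_end, name in cytobands:
            if normalize_chrom(c_chrom) == chrom and _intersects(seg.start, seg.end, c_start, c_end):
                band = name
                break
    return replace(
        call,
        overlapped_genes=tuple(sorted(genes)),
        overlapped_features=tuple(features),
        cytoband=band,
    )
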