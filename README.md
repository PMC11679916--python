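# trioscope

Trio-genome variant prioritization for consanguineous cohorts.

`trioscope` implements the analysis pipeline used to find candidate disease
genes in parent–offspring trio sequencing studies of autism spectrum disorder
(ASD) in populations with high consanguinity, where recessive inheritance
carries far more weight than in outbred cohorts. Given per-family VCFs with
external annotations (gene, consequence, gnomAD/reference-cohort allele
frequencies, CADD, ACMG class), a pedigree, a gene-constraint table and gene
panels, it:

1. **classifies Mendelian inheritance** for every biallelic trio site —
   de novo (child het, both parents ref/ref), homozygous recessive (child
   alt/alt, each parent a carrier), X-linked hemizygous (male child hemizygous
   alt outside the pseudoautosomal regions, carrier mother), inherited
   heterozygous with maternal/paternal origin resolved by transmission, and
   Mendelian errors;
2. **detects compound heterozygotes** by pairing maternal-only and
   paternal-only hets within a gene (in trans);
3. **applies a rare-variant filter cascade**: gnomAD AF < 0.1 %, CADD > 20,
   ACMG ∈ {P, LP, VUS}, protein-altering consequence, and a mode-dependent
   gene-constraint rule — dominant-acting loss-of-function variants require
   pLI > 0.9, dominant-acting missense variants require the dual criterion
   missense Z > 3.0 **and** pLI > 0.9, while recessive-acting variants
   (homozygous, hemizygous, compound-het) are exempt because constraint
   metrics measure intolerance to *heterozygous* loss;
4. **calls de novo CNVs** from BED-like trio segment files using reciprocal
   overlap (overlap / max length, default threshold 0.5) against parental
   segments, with exon/intron-level gene annotation from a GFF3 model;
5. **labels candidate genes Known/Novel** against plain-text gene panels;
6. **summarizes cohorts** (per-mode/per-type tallies, integer percentages,
   consanguinity strata with both definitions of the recessive fraction); and
7. **computes interaction-network statistics** for candidate gene sets:
   average node degree 2·|E|/|V|, mean local clustering, and an edge-count
   enrichment p-value P(X ≥ e) with X ~ Binomial(k(k−1)/2, q) under a
   density-matched binomial null.

A packaged, digitized reference cohort (104 Omani ASD trios: the full SNV
table with a curated candidate flag, the ten de novo micro-CNVs, and the
clinical summary) plus a fully deterministic synthetic-cohort generator make
every stage testable without any external download.

## Worked example

```python
from trioscope import (
    SimConfig, simulate_cohort, analyze_bundle, candidate_set_from_rows,
    load_fixture_table,
)

# 1. the packaged reference cohort
snv = load_fixture_table("cohort_snv")
cands = candidate_set_from_rows(snv)
print(cands.n_variants, len(cands.genes), dict(cands.by_mode))
# 90 83 {'homozygous': 55, 'x_linked': 14, 'de_novo': 15, 'comp_het': 6}

# 2. a synthetic cohort with the same injection plan, recovered end to end
bundle = simulate_cohort(SimConfig(seed=1))
decisions, recovered = analyze_bundle(bundle)
print(recovered.n_variants, dict(recovered.by_mode))
# 90 {'comp_het': 6, 'homozygous': 55, 'x_linked': 14, 'de_novo': 15}
```

The first block tallies the digitized reference table: 90 candidate variants
in 83 unique genes, of which 55 (61 %) are homozygous — the signature of a
recessive architecture in a consanguineous cohort. The second block simulates
104 trios with those counts as the injection plan, classifies every site,
runs the cascade, and recovers exactly the injected candidates while
filtering all decoys.

A command-line interface wraps the same library calls:

```bash
trioscope simulate --n-families 104 --seed 1 --out cohort/
trioscope triage --vcf-dir cohort/families --ped cohort/cohort.ped \
    --annotations cohort/annotations.tsv --constraints cohort/constraints.tsv \
    --out-dir results/
trioscope cnv --child c.bed --mother m.bed --father f.bed --genes genes.gff3
trioscope net --edges edges.tsv --genes candidates.txt
```

## Layout

```
src/trioscope/
  model.py        domain types (Genotype, TrioSite, AnnotatedVariant, ...)
  io.py           VCF/PED/BED/TSV readers and writers (pysam, pandas)
  fixtures.py     packaged digitized reference-cohort tables (checksummed)
  inheritance.py  inheritance-mode classifier and compound-het detection
  triage.py       filter cascade, constraint triage, panels, candidate set
  cnv.py          de novo CNV calling and gene/feature annotation
  network.py      interaction-graph statistics
  summary.py      cohort tallies and consanguinity strata
  simulate.py     synthetic-cohort generator with truth manifest
  pipeline.py     classify -> triage -> select drivers
  cli.py          `trioscope` command group
docs/methods.md   model assumptions, parameter defaults, design notes
```
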