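# Methods

## Inheritance classification

Each biallelic trio site receives exactly one mode. Multiallelic VCF records
are split upstream (one site per alternate allele; other non-reference
alleles are retained under a dedicated allele code so per-sample allele
counts are conserved). Classification enumerates the transmissible
(maternal allele, paternal allele) assignments consistent with all three
genotypes:

* no consistent assignment and the child carries exactly one copy of a
  target allele absent from both parents → **de novo**;
* no consistent assignment otherwise → **Mendelian error** (this covers
  child alt/alt with a ref/ref parent, a hom-alt parent whose obligate
  allele was not transmitted, and a hemizygous-alt father with a ref/ref
  daughter). Mendelian-error sites are reported and excluded from
  candidacy, never raised;
* child alt/alt with both parents carrying the allele → **homozygous
  recessive**;
* child het → maternal/paternal origin if only one parent can have
  transmitted the allele, **ambiguous** if both transmissions are
  consistent. Read-backed phasing is deliberately out of scope; ambiguity
  is resolved only by transmission logic.

Male children at non-PAR X sites must be represented hemizygously
(ploidy 1; a diploid genotype there is an upstream representation error and
raises). A hemizygous alt child with a carrier mother is **X-linked
hemizygous**; with a non-carrier mother, **de novo**. Female X sites use the
diploid rules with the father's single transmissible allele. PAR1/PAR2
coordinates (GRCh38) ship with the package; sites inside them are treated as
autosomal. Genotype-quality gates default to GQ ≥ 20 and DP ≥ 10 across all
three samples — conventional trio-confidence values, configurable because
upstream callers differ; gate failures flag the call (`quality_ok=False`)
rather than suppress it.

Compound heterozygotes are all (maternal-only het, paternal-only het) pairs
of distinct sites within one gene. Under the default **strict** policy an
ambiguous-origin het joins no pair; **permissive** lets it pair with a
determined-origin partner (never with another ambiguous het). Pairs are
deduplicated and ordered by position.

## Filter cascade and constraint triage

Defaults: gnomAD AF < 0.001 (missing AF counts as rare), CADD > 20 (a
missing CADD is tolerated only for frameshifts and in-frame insertions,
which score engines routinely leave unscored), ACMG ∈ {P, LP, VUS} with NA
treated as VUS (classification is consumed, never computed), consequence ∈
{missense, nonsense, frameshift, splicing, in-frame insertion}. All
criteria are evaluated without short-circuiting so the failure list is
complete; a filtered variant re-run with exactly its failing criteria
relaxed becomes a candidate.

The constraint rule is mode-dependent. Variants that must act dominantly
(de novo, or inherited heterozygous under a dominant hypothesis) require
gene-level constraint: pLI > 0.9 for loss-of-function consequences, and the
dual criterion missense Z > 3.0 with pLI > 0.9 for missense. Recessive-acting
modes (homozygous, X-linked hemizygous, compound-het) are exempt: pLI and
missense Z quantify intolerance to heterozygous loss, so low-constraint
genes are fully compatible with recessive disease. A de novo variant in a
gene without constraint data fails with reason "constraint unavailable"
(configurable). AF thresholds use the global gnomAD value by default;
`af_population_max` switches to the maximum across per-population AFs when
those are supplied.

The cascade flags-and-reports rather than hard-drops: every triaged variant
keeps its per-criterion flags, because published candidate tables frequently
retain individual threshold-violating rows on curatorial grounds. For the
packaged reference cohort the curated `is_candidate` flag (the outcome of a
manual literature review that is not mechanically reproducible) is used for
cohort tallies — "paper-concordance mode" — while the mechanical policy is
available for any re-analysis; the two disagree on a handful of rows (e.g. a
de novo missense candidate with Z = −0.36) and both behaviours are exposed.

## De novo CNV calling

Segments are half-open, length = end − start; all ten reference-cohort CNV
sizes match this convention exactly, which fixed the choice. A child segment
longer than 50 bp is de novo when no same-type parental segment reaches the
reciprocal-overlap threshold (overlap / max length, default 0.5 — a field
convention). At threshold 0 any touching same-type parental segment
suppresses, the most conservative setting, so its call set is a subset of
any positive threshold's. Gene/feature annotation numbers exons along the
strand and labels intersected exons and introns; a cytoband label is taken
from an optional user-supplied band table (none is packaged) and left blank
otherwise.

## Network statistics

Interaction edges with confidence strictly above 0.4 between query genes
form the graph (0–1000-scaled scores are auto-detected and rescaled).
Average node degree is 2|E|/|V| rounded half away from zero to two decimals;
mean local clustering counts degree-<2 nodes as zero. The enrichment
p-value is the exact binomial tail P(X ≥ e), X ~ Binomial(k(k−1)/2, q), with
q the background network's edge density. This density-matched null is
intentionally simple and documented; it is **not** the degree-corrected null
used by online interaction databases, whose published p-values are therefore
not comparable and are not targets of this package. Module partitioning is
deterministic connected-component splitting.

## Cohort summaries

Percentages round half away from zero to integers (e.g. 69/104 → 66) and
always carry their denominators. Consanguinity strata report the recessive
fraction under two explicit definitions — homozygous/total and
(homozygous + X-linked)/total — because summary figures of this kind are
ambiguous about hemizygous variants; families with unknown consanguinity are
excluded from both strata and counted separately. A compound-het pair
contributes two variants but one gene occurrence per family to gene-level
tallies.

## Synthetic cohort generator

The generator emulates what the pipeline consumes, not a population-genetic
model. Genome: two 10 Mb autosomes and a 10 Mb X with 100 kb pseudoautosomal
stubs at both ends; a regular lattice of 20 kb genes every 100 kb keeps
coordinates↔gene assignment trivial and deterministic. Defaults mirror the
reference cohort's study conditions: 104 families, consanguineous fraction
59/104, male fraction 69/104, and the injection plan
{de novo 15, homozygous 55, comp-het 6, X-linked 14}.

* **Autozygosity.** Each consanguineous child carries 1 + Poisson(1)
  autozygous blocks whose total length is Gamma-distributed with mean
  `autozygous_genome_fraction` × autosomal genome (default 0.0625, the
  first-cousin expectation) and CV 0.2; inside a block the transmitted
  maternal and paternal haplotypes are identical by descent. Calibration is
  asserted over ≥ 50 simulated children.
* **Background variation** emulates common polymorphism: population AF
  uniform on [0.01, 0.5] (every background site therefore legitimately fails
  the 0.1 % rarity rule), CADD uniform on [0, 15], ACMG drawn from
  {B, LB, VUS}, consequences from {synonymous, intronic, missense}. Parental
  haplotypes are explicit, so background genotypes contain zero Mendelian
  errors by construction.
* **Injected variants** realize each mode with annotations satisfying the
  default policy (AF 0, CADD 25–40, ACMG P/LP; de novo genes get pLI 0.99
  and, for missense, Z 4.5). Homozygous injections are placed inside an
  autozygous block with both parents het; comp-het pairs are placed in trans
  in one gene; X-linked injections are hemizygous in male children with
  carrier mothers. Infeasible plans (X-linked without male children,
  homozygous without consanguineous families, odd comp-het counts) raise
  before any file is written.
* **Decoys** each violate exactly one criterion (AF 0.05, CADD 5, ACMG B,
  synonymous consequence, or an unconstrained gene for the constraint
  decoy), so the expected triage outcome is a single specific fail reason.
* **Genotype error** replaces a parental genotype with hom-ref with
  probability e per parent per background site (allele dropout), the error
  mode that manufactures false de novo calls; the false-positive count is
  asserted to grow monotonically with e over ≥ 20 seeds.

What the generator does **not** model: linkage disequilibrium,
recombination maps, demography, per-site depth/quality variation, mosaicism,
multi-nucleotide or structural variants within the SNV stream, and
annotation errors. Passing recovery tests therefore demonstrates the
correctness of the classification/triage logic under clean inputs, not
robustness to real-data artifacts beyond the explicit genotype-error model.

Determinism: all randomness flows from one `numpy.random.default_rng(seed)`;
identical (config, seed) produces byte-identical file bundles.

## Digitized reference fixtures

The packaged tables are bit-controlled (SHA-256 verified at load). The SNV
table stores every printed row (134 variants, 116 distinct genes) even
though the source text counts 126 variants; both totals are exposed
unreconciled. The curated `is_candidate` flag reproduces the published
candidate totals (90 variants, 83 genes, 15/55/6/14 by mode, 1/4/6/12/67 by
type, 35 Known / 48 Novel genes); under those totals the flag assignment is
forced almost everywhere — every X-linked row, every homozygous row except
the single intronic one, the three Known compound-het pairs, and all twelve
Known de novo genes must be included, leaving freedom only in one Novel
de novo missense row, where the row satisfying the stated dual constraint
criterion was chosen. A consequence worth knowing: under this candidate set
the recurrent compound-het gene DNAH17 is a candidate in one family; its
three-family recurrence is visible only across all printed rows. The CNV
fixture preserves one printed size with a sign typo ("−4198") alongside the
coordinate-derived 4198, and the clinical fixture stores all three
non-identical printed consanguinity figures (56 %, 59 families/57 %, 56
families) as printed.

## Problem sizes used in tests

Full-cohort checks run at the study scale (104 families, ~7.5 k sites,
seconds per run). Property tests use compact cohorts (4–10 families) and 20
seeds per error rate for the Monte-Carlo monotonicity check; graph
properties are exercised on random graphs up to 25 nodes against brute-force
triad enumeration.
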