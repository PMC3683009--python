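# Methods

## The filtering cascade

The pipeline assumes the input is a *called, annotated* single-sample variant
set: each record carries a gene symbol, a consequence class (one of
missense, nonsense, frameshift indel, in-frame indel, splice site,
synonymous, noncoding) and a zygosity call. Consequence classes are consumed
as annotations, not computed from transcripts; transcript-level effect
prediction is out of scope. Splice-site variants are a pre-assigned class
(by the generator's convention, the canonical ±2 intronic dinucleotide).

The five steps are pure set filters / per-gene predicates:

1. **Class filter.** Keeps the five non-silent classes. Configurable via
   `CascadeConfig.kept_classes`.
2. **Panel filter.** Keeps variants whose gene symbol is in the disease
   panel (default fixture: 160 genes).
3. **Frequency filter.** A variant is removed iff its site
   (chrom, pos, ref, alt) matches a frequency-catalog entry **and** that
   entry has a frequency **and** the frequency is strictly greater than the
   threshold (default 0.02). Consequences of this strict reading:
   a catalogued site *without* a frequency is retained (it cannot be shown
   common), and a variant at exactly the threshold is retained. An optional
   second catalog (`recheck_catalog`) may be attached for annotation but is
   never used to filter.
4. **Recessive-model filter.** Per gene: `AR_homozygous` when ≥ 1 homozygous
   variant; `AR_compound_het` when ≥ 2 distinct heterozygous variants —
   phase is unknowable in an index-only analysis, so two hets are *assumed*
   in trans and left to cosegregation to confirm; `XL_hemizygous` when the
   patient is male and the gene is on chrX with ≥ 1 variant of any zygosity.
   Callers typically emit hemizygous male chrX genotypes as `1/1`; the
   X-linked rule makes the call robust to either encoding. Genes with more
   than two qualifying variants yield one candidate listing all supporting
   variants. Candidates are reported sorted by gene symbol.
   Pseudo-autosomal regions are ignored (all chrX is treated as hemizygous
   in males); no PAR gene is in the panel.
5. **Known/novel annotation.** A supporting variant is flagged *known* iff
   (gene, hgvs_c) matches a mutation-catalog record whose status is `known`;
   catalog records with status `novel` mark mutations that were novel at
   publication and are deliberately not treated as prior knowledge. Variants
   without an hgvs_c string are flagged novel with a logged warning.

Steps 1–3 are pure predicates on independent fields, hence commute pairwise
and are idempotent; the per-step surviving counts (`CascadeTrace`) are
monotone non-increasing by construction. Both properties are enforced by
property tests.

## Exact cosegregation

Under the autosomal-recessive model the parents are obligate carriers with
known phase: the father carries candidate allele A, the mother allele B.
Each genotyped sibling receives one of 4 equiprobable parental-allele
combinations; under the X-linked model the mother is the obligate carrier
and each child has 2 equiprobable maternal-X transmissions. The test
enumerates all 4ⁿ (or 2ⁿ) transmission vectors and reports the fraction
consistent with every member's observed carrier genotype (when genotyped)
and affection status (affected ⇔ carries both alleles under AR; affected
male ⇔ carries the mutant X under XL; females are never affected under XL —
skewed X-inactivation is not modelled). Probabilities are exact rationals
(`fractions.Fraction`).

When every affected sibling is a compound heterozygote and every unaffected
sibling is merely non-compound-heterozygous, the enumeration collapses to
the closed form (1/4)^affected · (3/4)^unaffected, which is used as an
analytic cross-check.

Two conventions needed a decision:

* **Index inclusion.** The index patient is part of the sibship and included
  in the constraint set by default (`include_index=True`). For the bundled
  six-sibling pedigree this gives 27/4096 ≈ 0.0066; excluding the index
  gives 27/1024 ≈ 0.026. The flag exposes both readings.
* **Display truncation.** Reported probabilities carry full precision;
  `SegregationResult.truncated(3)` truncates (does not round) to three
  decimals, the convention used for the headline 0.006.

The enumeration supports single-sibship pedigrees whose parents are
founders; consanguineous loops and multi-generation transmission are out of
scope and rejected with an error.

## The synthetic cohort generator

The generator emulates a 12-family diagnostic WES study; its defaults are
the study conditions, not tuning knobs.

**Stratum sizes.** Per exome: total variants ~ Poisson(67,000); coding
non-silent ~ Poisson(12,000) (clipped to the total); panel-gene non-silent
count uniform on [108, 143]; rare count uniform on [18, 34]. Poisson is a
stand-in for the unreported per-patient variance of the two large strata;
the two small strata are drawn uniformly from their observed ranges.
The nested draws are clipped so containment (rare ⊆ panel ⊆ coding
non-silent ⊆ all) holds even for degenerate parameter choices.

**Background attributes.** Non-panel variants get uniform positions on a
synthetic gene map (chromosomes 1–22), random SNV alleles, and consequence
classes drawn with missense dominating (74%). Noncoding variants carry no
gene symbol. Panel-gene variants are placed in deterministic per-gene
100 kb windows so sites are attributable to genes.

**Rare vs common.** Common panel variants are registered in the generated
frequency catalog with AF drawn in (0.02, 0.5]; they are guaranteed removable
by step 3. Rare panel variants are either uncatalogued (~50%), catalogued at
AF ≤ 0.02, or occasionally catalogued without a frequency (~5%) — all three
retained by step 3. Catalog AFs are quantised to 6 decimals so the VCF
round trip (32-bit floats) is lossless.

**Background must not create candidates.** Rare background panel variants
are always heterozygous, at most one per gene, never in the scenario's
causal (or spurious) gene, and never in a chrX gene for a male patient.
Without these constraints, random background would occasionally produce
spurious compound-het or hemizygous candidates and the cohort's diagnostic
yield would not be a property of the planted scenarios. This is the main
respect in which the generator is cleaner than real data: in practice
occasional background genes do survive the cascade and are removed by
cosegregation or validation, so passing tests here demonstrate the cascade's
mechanics, not its real-world specificity.

**Planting.** Each solved scenario plants its causal variants (real HGVS
notations, consequence classes and known/novel statuses from the bundled
mutation table) with the correct zygosity; hemizygous genotypes are encoded
homozygous, as callers do. One scenario additionally plants two spurious
heterozygous missense variants in *USH2A* (synthetic hgvs_c values, marked
by their absence from the mutation table) to reproduce a dual-candidate
patient whose second candidate fails validation. Planted variants are
asserted at generation time to survive steps 1–3. The two unsolved
scenarios plant nothing in panel genes.

**Determinism.** All randomness flows from `numpy.random.default_rng`
seeded with `[master_seed, patient_index]`, so each patient's exome is a
function of the master seed and its scenario position only, and cohort
composition is order-independent. Identical parameters and seed give
byte-identical outputs.

**Panel fixture.** The true 160-gene panel membership is not public; the
fixture combines the six causal genes (with their real chromosomes), ~80
well-known RD genes, and `RDPnnn` placeholders up to 160. Placeholders are
autosomal.

**Pedigree fixtures.** Each family carries a small pedigree template:
nuclear (parents, affected index, one unaffected sibling) for most, the
six-sibling configuration (3 affected compound-het including the index, 3
unaffected ungenotyped) for the Usher-syndrome family, and a two-affected-
brother X-linked pedigree for the choroideremia family. Affected members
are genotyped as carrying both candidate alleles; unaffected siblings are
left ungenotyped, which makes the enumerated probability a pure
phenotype-consistency statistic.

**Gene dropping.** `drop_alleles` simulates independent Mendelian
transmissions through a pedigree template; `fraction_consistent` scores
replicates against genotype and phenotype constraints. At n = 10,000 the
Monte-Carlo fraction agrees with the exact enumeration within a 99%
binomial interval (property-tested).

## Problem sizes and numerical choices

* The full cohort (12 exomes, ~800k variant records) generates in a few
  seconds and the cascade runs in well under a second; the test suite
  generates one session-scoped cohort plus twenty scaled-down cohorts
  (total ≈ 6,700 variants each) for the calibration property.
* Cosegregation enumerates at most 4⁶ = 4096 vectors for the bundled
  pedigrees; complexity is 4ⁿ in the number of siblings, fine for the
  sibship sizes the test targets.
* Probabilities are exact rationals; equality tests are exact, Monte-Carlo
  checks use 99% binomial intervals.
* `CascadeTrace` validates monotonicity at construction; `VariantRecord`
  validates chromosome labels, positions and allele distinctness.

## Known limitations

* No copy-number variant detection: a family whose cause is a deletion is
  unsolvable by design, which is what the two unsolved scenarios emulate.
* No pathogenicity scoring (SIFT/PolyPhen-style), no dominant-model
  filtering, no ACMG classification.
* Compound heterozygotes are called without phase; two variants in cis are
  a false positive this pipeline cannot detect without family data.
* The cosegregation model treats parents as obligate carriers with known
  phase and does not handle consanguinity loops or multi-generation
  pedigrees.
* The generator does not model linkage disequilibrium, realistic site
  frequency spectra, sequencing error, or transcript structure.
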