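"""The five-step variant filtering cascade for recessive retinal dystrophies.

Starting from an index patient's full called variant set, the cascade

1. keeps coding non-silent variants (missense, nonsense, indels, splice-site),
2. restricts to a panel of known retinal-dystrophy genes,
3. removes common polymorphisms (catalog allele frequency strictly above a
   threshold, default 2%),
4. keeps genes compatible with recessive inheritance — two heterozygous hits
   (assumed in trans; an index-only analysis cannot phase), one homozygous
   hit, or any chrX hit in a male (hemizygous), and
5. annotates each surviving variant as known or novel against a catalog of
   published mutations.

Each step is a pure function of its input exome; steps compose in order via
:func:`run_cascade`, which also records the per-step surviving counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

from .types import (
    CandidateGene,
    CascadeTrace,
    ConsequenceClass,
    FrequencyCatalog,
    GenePanel,
    MutationCatalog,
    PatientExome,
    VariantRecord,
)
from .types import NON_SILENT_CLASSES

__all__ = [
    "CascadeConfig",
    "step1_coding_nonsilent",
    "step2_panel",
    "step3_frequency",
    "step4_recessive",
    "step5_annotate_known",
    "run_cascade",
]

logger = logging.getLogger(__name__)


@dataclass
class CascadeConfig:
    """Parameters and reference resources of the filtering cascade.

    ``af_threshold`` is the common-polymorphism cutoff: a catalogued variant
    is removed only when its frequency is present and STRICTLY above the
    threshold, so a variant at exactly the threshold is retained, as is a
    catalogued site without a frequency.  ``recheck_catalog`` is an optional
    second frequency catalog used for annotation only, never for filtering.
    """

    panel: GenePanel
    frequency_catalog: FrequencyCatalog
    mutation_catalog: MutationCatalog
    af_threshold: float = 0.02
    kept_classes: frozenset[ConsequenceClass] = NON_SILENT_CLASSES
    recheck_catalog: FrequencyCatalog | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.af_threshold <= 1.0):
            raise ValueError(f"af_threshold must be in [0, 1], got {self.af_threshold}")
        self.kept_classes = frozenset(
            ConsequenceClass(c) if isinstance(c, str) else c for c in self.kept_classes
        )


def _subset(exome: PatientExome, variants: list[VariantRecord]) -> PatientExome:
    return PatientExome(patient_id=exome.patient_id, sex=exome.sex, variants=variants)


def step1_coding_nonsilent(exome: PatientExome, config: CascadeConfig) -> PatientExome:
    """Keep variants whose consequence class can alter the protein or splicing."""
    kept = [v for v in exome.variants if v.consequence in config.kept_classes]
    logger.info("step1 coding/non-silent: %d -> %d", len(exome), len(kept))
    return _subset(exome, kept)


def step2_panel(exome: PatientExome, config: CascadeConfig) -> PatientExome:
    """Keep variants whose gene symbol belongs to the disease-gene panel."""
    panel_genes = config.panel.genes
    kept = [v for v in exome.variants if v.gene in panel_genes]
    logger.info("step2 panel: %d -> %d", len(exome), len(kept))
    return _subset(exome, kept)


def step3_frequency(exome: PatientExome, config: CascadeConfig) -> PatientExome:
    """Remove common polymorphisms.

    A variant is removed iff its site is in the frequency catalog AND the
    catalog records a frequency AND that frequency exceeds ``af_threshold``
    (strict inequality).  Uncatalogued sites and catalogued sites without a
    frequency are retained — they cannot be shown to be common.
    """
    cat = config.frequency_catalog
    thr = config.af_threshold
    kept = []
    for v in exome.variants:
        af = cat.get(v.key) if v.key in cat else None
        if af is not None and af > thr:
            continue
        kept.append(v)
    logger.info("step3 frequency: %d -> %d", len(exome), len(kept))
    return _subset(exome, kept)


def step4_recessive(
    exome: PatientExome, patient_sex: str | None, config: CascadeConfig
) -> list[CandidateGene]:
    """Call genes compatible with recessive (or X-linked) disease.

    Per gene: ``AR_homozygous`` if it carries at least one homozygous variant;
    ``AR_compound_het`` if it carries at least two distinct heterozygous
    variants; ``XL_hemizygous`` if the patient is male, the gene lies on chrX,
    and it carries any variant (a single mutant allele suffices on the male
    X).  Genes with more than two qualifying variants yield one candidate
    carrying all supporting variants.  Candidates are sorted by gene symbol.
    """
    if patient_sex is None:
        if any(v.chrom == "X" for v in exome.variants):
            raise ValueError(
                "patient sex is required to interpret chrX variants "
                "(hemizygous in males)"
            )
        patient_sex = "female"
    if patient_sex not in ("male", "female"):
        raise ValueError(f"invalid sex {patient_sex!r}")

    by_gene: dict[str, list[VariantRecord]] = {}
    for v in exome.variants:
        if v.gene:
            by_gene.setdefault(v.gene, []).append(v)

    candidates = []
    for gene in sorted(by_gene):
        variants = by_gene[gene]
        on_x = all(v.chrom == "X" for v in variants) and variants
        n_hom = sum(1 for v in variants if v.zygosity == "homozygous_alt")
        n_het = sum(1 for v in variants if v.zygosity == "heterozygous")
        if patient_sex == "male" and on_x:
            model = "XL_hemizygous"
        elif n_hom >= 1:
            model = "AR_homozygous"
        elif n_het >= 2:
            model = "AR_compound_het"
        else:
            continue
        candidates.append(CandidateGene(gene=gene, variants=variants, model=model))
    logger.info(
        "step4 recessive model: %d variants -> %d candidate gene(s)",
        len(exome),
        len(candidates),
    )
    return candidates


def step5_annotate_known(
    candidates: list[CandidateGene], config: CascadeConfig
) -> list[CandidateGene]:
    """Flag each supporting variant known/novel against the mutation catalog.

    A variant is flagged known iff (gene, hgvs_c) matches a catalog record
    whose status is ``known``.  Variants without a coding-change notation are
    flagged novel with a warning.
    """
    annotated = []
    for cand in candidates:
        flags = []
        for v in cand.variants:
            if v.hgvs_c is None:
                logger.warning(
                    "variant %s:%d %s>%s in %s lacks hgvs_c; flagged novel",
                    v.chrom,
                    v.pos,
                    v.ref,
                    v.alt,
                    cand.gene,
                )
                flags.append(False)
            else:
                flags.append(config.mutation_catalog.is_known(cand.gene, v.hgvs_c))
        annotated.append(replace(cand, known_flags=flags))
    return annotated


def run_cascade(
    exome: PatientExome, patient_sex: str | None, config: CascadeConfig
) -> tuple[CascadeTrace, list[CandidateGene]]:
    """Run the full five-step cascade and record per-step surviving counts."""
    s1 = step1_coding_nonsilent(exome, config)
    s2 = step2_panel(s1, config)
    s3 = step3_frequency(s2, config)
    candidates = step5_annotate_known(step4_recessive(s3, patient_sex, config), config)
    n_candidate_variants = sum(len(c.variants) for c in candidates)
    trace = CascadeTrace(
        n_total=len(exome),
        n_coding_nonsilent=len(s1),
        n_panel=len(s2),
        n_rare=len(s3),
        n_candidate_variants=n_candidate_variants,
        candidate_genes=tuple(c.gene for c in candidates),
    )
    return trace, candidates
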