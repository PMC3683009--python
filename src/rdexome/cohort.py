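"""Seeded synthetic exome cohort with the structure the cascade assumes.

The generator emulates the study design that motivates the pipeline: 12
index patients from families with apparently recessive retinal dystrophy,
each sequenced alone.  Every exome is built in four nested strata

* ~67,000 called variants in total (Poisson),
* of which ~12,000 are coding and non-silent (Poisson),
* of which 108-143 fall in the 160-gene disease panel (uniform integer),
* of which 18-34 are rare — uncatalogued, or catalogued at AF <= 2% (uniform
  integer); the rest are common panel polymorphisms catalogued above 2%.

Ten family scenarios plant causal genotypes (3x ABCA4, 2x RP1, 2x CNGB3,
1x CHM X-linked, 1x USH2A, 1x NMNAT1); two plant nothing, emulating families
whose cause lies outside the panel or in copy-number changes the pipeline
cannot see.  One scenario additionally plants two spurious heterozygous
USH2A calls, emulating a false-positive compound heterozygote that later
fails orthogonal validation.

Background rare panel variants are heterozygous, one per gene, never in the
causal gene, and never on chrX in males — so the recessive-model step's
output over the cohort is a property of the planted scenarios, not of
background noise.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .io import write_mutation_catalog
from .types import (
    ConsequenceClass,
    FrequencyCatalog,
    GenePanel,
    MutationCatalog,
    MutationRecord,
    PatientExome,
    Pedigree,
    PedigreeMember,
    VariantRecord,
)
from .types import NON_SILENT_CLASSES

__all__ = [
    "GeneratorParams",
    "CausalVariantSpec",
    "FamilyScenario",
    "default_panel",
    "default_scenarios",
    "build_table1_catalog",
    "write_fixture_table1",
    "generate_exome",
    "generate_cohort",
    "Cohort",
    "drop_alleles",
    "fraction_consistent",
]

_BASES = np.array(list("ACGT"))

# ---------------------------------------------------------------------------
# Disease-gene panel
# ---------------------------------------------------------------------------

# Chromosome of each causal gene used by the family scenarios.
CAUSAL_GENE_CHROM = {
    "ABCA4": "1",
    "USH2A": "1",
    "NMNAT1": "1",
    "RP1": "8",
    "CNGB3": "8",
    "CHM": "X",
}

# Additional retinal-dystrophy genes (symbol, chromosome) filling the panel;
# membership of the original 160-gene panel is not public, so the fixture
# combines the six causal genes, well-known RD genes, and placeholders.
_EXTRA_RD_GENES = [
    ("RHO", "3"), ("PDE6A", "5"), ("PDE6B", "4"), ("RPE65", "1"),
    ("CRB1", "1"), ("CEP290", "12"), ("GUCY2D", "17"), ("AIPL1", "17"),
    ("RPGR", "X"), ("RP2", "X"), ("RS1", "X"), ("CACNA1F", "X"),
    ("NYX", "X"), ("USH1C", "11"), ("MYO7A", "11"), ("CDH23", "10"),
    ("PCDH15", "10"), ("CLRN1", "3"), ("EYS", "6"), ("CERKL", "2"),
    ("CRX", "19"), ("NR2E3", "15"), ("NRL", "14"), ("PRPH2", "6"),
    ("ROM1", "11"), ("SAG", "2"), ("GRK1", "13"), ("CNGA1", "4"),
    ("CNGB1", "16"), ("CNGA3", "2"), ("GNAT1", "3"), ("GNAT2", "1"),
    ("PDE6C", "10"), ("RDH12", "14"), ("RDH5", "12"), ("LRAT", "4"),
    ("RLBP1", "15"), ("TULP1", "6"), ("MERTK", "2"), ("ADGRV1", "5"),
    ("WHRN", "9"), ("MAK", "6"), ("C8orf37", "8"), ("FAM161A", "2"),
    ("PRCD", "17"), ("BEST1", "11"), ("TIMP3", "22"), ("ELOVL4", "6"),
    ("PROM1", "4"), ("IMPDH1", "7"), ("KLHL7", "7"), ("TOPORS", "9"),
    ("SNRNP200", "2"), ("PRPF3", "1"), ("PRPF8", "17"), ("PRPF31", "19"),
    ("RP9", "7"), ("SPATA7", "14"), ("LCA5", "6"), ("RD3", "1"),
    ("IMPG2", "3"), ("IQCB1", "3"), ("CABP4", "11"), ("KCNV2", "9"),
    ("GRM6", "5"), ("TRPM1", "15"), ("SEMA4A", "1"), ("ZNF513", "2"),
    ("DHDDS", "1"), ("FLVCR1", "1"), ("IDH3B", "20"), ("TTC8", "14"),
    ("ARL6", "3"), ("BBS1", "11"), ("BBS2", "16"), ("CLN3", "16"),
]


def default_panel(size: int = 160) -> GenePanel:
    """The bundled 160-gene retinal-dystrophy panel fixture."""
    entries: list[tuple[str, str]] = [(g, c) for g, c in CAUSAL_GENE_CHROM.items()]
    entries += list(_EXTRA_RD_GENES)
    autosomes = [str(i) for i in range(1, 23)]
    i = 0
    while len(entries) < size:
        entries.append((f"RDP{i + 1:03d}", autosomes[i % 22]))
        i += 1
    return GenePanel(entries=tuple(entries[:size]), name="RD-160")


def _panel_gene_window(panel: GenePanel) -> dict[str, tuple[str, int]]:
    """Deterministic (chrom, base position) for each panel gene.

    Genes on one chromosome get disjoint 100 kb windows 200 kb apart.
    """
    per_chrom: dict[str, int] = {}
    windows = {}
    for gene, chrom in panel.entries:
        idx = per_chrom.get(chrom, 0)
        per_chrom[chrom] = idx + 1
        windows[gene] = (chrom, 1_000_000 + idx * 200_000)
    return windows


# ---------------------------------------------------------------------------
# Family scenarios
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CausalVariantSpec:
    """One planted causal (or spurious) variant."""

    hgvs_c: str
    protein: str
    consequence: ConsequenceClass
    status: str  # "known" | "novel"
    ref: str
    alt: str


@dataclass(frozen=True)
class FamilyScenario:
    """One family's design: causal gene, genotype configuration, pedigree.

    ``genotype_config`` is one of AR_compound_het / AR_homozygous /
    XL_hemizygous, or None for an unsolved family (and then ``causal_gene``
    is None too).  ``spurious`` lists extra heterozygous panel-gene variants
    planted on top of the causal genotype (false positive calls).
    ``pedigree_members`` are (member_id, sex, affected, father, mother,
    genotype) tuples; genotype is a set of carried candidate alleles or None.
    """

    family_id: str
    patient_id: str
    sex: str
    causal_gene: Optional[str]
    genotype_config: Optional[str]
    variants: tuple[CausalVariantSpec, ...] = ()
    spurious_gene: Optional[str] = None
    spurious: tuple[CausalVariantSpec, ...] = ()
    pedigree_members: tuple = ()

    def __post_init__(self) -> None:
        if (self.causal_gene is None) != (self.genotype_config is None):
            raise ValueError(
                f"{self.family_id}: causal_gene and genotype_config must be "
                "both set or both None"
            )
        if self.genotype_config == "XL_hemizygous":
            if self.sex != "male":
                raise ValueError(f"{self.family_id}: XL_hemizygous requires a male index")
            if CAUSAL_GENE_CHROM.get(self.causal_gene) != "X":
                raise ValueError(f"{self.family_id}: XL_hemizygous requires a chrX gene")

    def build_pedigree(self) -> Pedigree:
        model = "XL" if self.genotype_config == "XL_hemizygous" else "AR"
        members = [
            PedigreeMember(
                member_id=mid,
                sex=sex,
                affected=affected,
                father_id=father,
                mother_id=mother,
                genotype=frozenset(geno) if geno is not None else None,
            )
            for mid, sex, affected, father, mother, geno in self.pedigree_members
        ]
        return Pedigree(
            family_id=self.family_id, members=members, model=model, index_id=self.patient_id
        )


def _nuclear(family: str, index_id: str, index_sex: str, extra_children=()):
    """Parents + affected index + one unaffected sib + optional extras."""
    f, m = f"{family}-F", f"{family}-M"
    members = [
        (f, "male", False, None, None, None),
        (m, "female", False, None, None, None),
        (index_id, index_sex, True, f, m, {"A", "B"}),
        (f"{family}-S1", "female", False, f, m, None),
    ]
    members.extend(extra_children)
    return tuple(members)


def _table1_specs():
    C = ConsequenceClass
    return {
        "RP-0674": (
            CausalVariantSpec("c.287delA", "p.N96Tfs*19", C.FRAMESHIFT_INDEL, "novel", "TA", "T"),
            CausalVariantSpec("c.6148G>C", "p.V2050L", C.MISSENSE, "known", "G", "C"),
        ),
        "RP-0298": (
            CausalVariantSpec("c.4720G>T", "p.E1574*", C.NONSENSE, "known", "G", "T"),
            CausalVariantSpec("c.950delG", "p.G317Afs*57", C.FRAMESHIFT_INDEL, "novel", "AG", "A"),
        ),
        "RP-1102": (
            CausalVariantSpec("c.2285C>A", "p.A762E", C.MISSENSE, "known", "C", "A"),
        ),
        "RP-1164": (
            CausalVariantSpec("c.863dupA", "p.M289Y*18", C.FRAMESHIFT_INDEL, "novel", "C", "CA"),
        ),
        "RP-1263": (
            CausalVariantSpec(
                "c.920_923dupGCCA", "p.H308Qfs*16", C.FRAMESHIFT_INDEL, "known", "T", "TGCCA"
            ),
            CausalVariantSpec("c.12574C>T", "p.R4192C", C.MISSENSE, "novel", "C", "T"),
        ),
        "RP-1659": (
            CausalVariantSpec("c.1148delC", "p.T383Ifs*13", C.FRAMESHIFT_INDEL, "known", "GC", "G"),
            CausalVariantSpec("c.1666G>T", "p.E556*", C.NONSENSE, "novel", "G", "T"),
        ),
        "RP-1174": (
            CausalVariantSpec("c.1148delC", "p.T383Ifs*13", C.FRAMESHIFT_INDEL, "known", "GC", "G"),
        ),
        "RP-0137": (
            CausalVariantSpec("c.1625C>G", "p.S542*", C.NONSENSE, "novel", "C", "G"),
            CausalVariantSpec("c.4804C>T", "p.Q1602*", C.NONSENSE, "novel", "C", "T"),
        ),
        "RP-0235": (
            CausalVariantSpec("c.5173C>T", "p.Q1725*", C.NONSENSE, "novel", "C", "T"),
        ),
        "RP-1116": (
            CausalVariantSpec("c.507G>A", "p.W169*", C.NONSENSE, "known", "G", "A"),
            CausalVariantSpec("c.769G>A", "p.E257K", C.MISSENSE, "known", "G", "A"),
        ),
    }


def default_scenarios() -> tuple[FamilyScenario, ...]:
    """The 12 default family scenarios: 10 solved, 2 unsolved."""
    specs = _table1_specs()
    C = ConsequenceClass

    rp1263_children = (
        ("RP-1263-S2", "male", True, "RP-1263-F", "RP-1263-M", {"A", "B"}),
        ("RP-1263-S3", "female", True, "RP-1263-F", "RP-1263-M", {"A", "B"}),
        ("RP-1263-S4", "male", False, "RP-1263-F", "RP-1263-M", None),
        ("RP-1263-S5", "female", False, "RP-1263-F", "RP-1263-M", None),
    )
    rp1263_members = (
        ("RP-1263-F", "male", False, None, None, None),
        ("RP-1263-M", "female", False, None, None, None),
        ("08-0177", "female", True, "RP-1263-F", "RP-1263-M", {"A", "B"}),
        ("RP-1263-S1", "female", False, "RP-1263-F", "RP-1263-M", None),
    ) + rp1263_children

    rp1164_members = (
        ("RP-1164-F", "male", False, None, None, None),
        ("RP-1164-M", "female", False, None, None, None),
        ("07-0360", "male", True, "RP-1164-F", "RP-1164-M", {"A"}),
        ("RP-1164-B1", "male", True, "RP-1164-F", "RP-1164-M", {"A"}),
    )

    scenarios = [
        FamilyScenario(
            "RP-0674", "01-0570", "female", "ABCA4", "AR_compound_het",
            specs["RP-0674"], pedigree_members=_nuclear("RP-0674", "01-0570", "female"),
        ),
        FamilyScenario(
            "RP-0298", "95-0103", "male", "ABCA4", "AR_compound_het",
            specs["RP-0298"], pedigree_members=_nuclear("RP-0298", "95-0103", "male"),
        ),
        FamilyScenario(
            "RP-1102", "07-0366", "female", "ABCA4", "AR_homozygous",
            specs["RP-1102"], pedigree_members=_nuclear("RP-1102", "07-0366", "female"),
        ),
        FamilyScenario(
            "RP-1164", "07-0360", "male", "CHM", "XL_hemizygous",
            specs["RP-1164"], pedigree_members=rp1164_members,
        ),
        FamilyScenario(
            "RP-1263", "08-0177", "female", "USH2A", "AR_compound_het",
            specs["RP-1263"], pedigree_members=rp1263_members,
        ),
        FamilyScenario(
            "RP-1659", "10-1367", "male", "CNGB3", "AR_compound_het",
            specs["RP-1659"], pedigree_members=_nuclear("RP-1659", "10-1367", "male"),
        ),
        FamilyScenario(
            "RP-1174", "04-0834", "male", "CNGB3", "AR_homozygous",
            specs["RP-1174"],
            spurious_gene="USH2A",
            spurious=(
                CausalVariantSpec("c.4457A>G", "p.N1486S", C.MISSENSE, "novel", "A", "G"),
                CausalVariantSpec("c.9304C>G", "p.L3102V", C.MISSENSE, "novel", "C", "G"),
            ),
            pedigree_members=_nuclear("RP-1174", "04-0834", "male"),
        ),
        FamilyScenario(
            "RP-0137", "1601", "female", "RP1", "AR_compound_het",
            specs["RP-0137"], pedigree_members=_nuclear("RP-0137", "1601", "female"),
        ),
        FamilyScenario(
            "RP-0235", "2343", "male", "RP1", "AR_homozygous",
            specs["RP-0235"], pedigree_members=_nuclear("RP-0235", "2343", "male"),
        ),
        FamilyScenario(
            "RP-1116", "06-1075", "female", "NMNAT1", "AR_compound_het",
            specs["RP-1116"], pedigree_members=_nuclear("RP-1116", "06-1075", "female"),
        ),
        FamilyScenario(
            "RP-0886", "IX-0886", "male", None, None,
            pedigree_members=_nuclear("RP-0886", "IX-0886", "male"),
        ),
        FamilyScenario(
            "RP-0461", "IX-0461", "female", None, None,
            pedigree_members=_nuclear("RP-0461", "IX-0461", "female"),
        ),
    ]
    return tuple(scenarios)


def build_table1_catalog() -> MutationCatalog:
    """The published-mutation catalog fixture: 15 distinct mutations, 8 novel.

    One mutation (CNGB3 c.1148delC) was observed in two families but is a
    single catalog record.
    """
    refs = {
        ("ABCA4", "c.6148G>C"): "Allikmets-1997",
        ("ABCA4", "c.4720G>T"): "Maia-Lopes-2009",
        ("ABCA4", "c.2285C>A"): "Aguirre-Lamban-2011",
        ("USH2A", "c.920_923dupGCCA"): "Weston-2000",
        ("CNGB3", "c.1148delC"): "Sundin-2000",
        ("NMNAT1", "c.507G>A"): "Chiang-2012",
        ("NMNAT1", "c.769G>A"): "Chiang-2012",
    }
    catalog = MutationCatalog()
    seen = set()
    for family, specs in _table1_specs().items():
        gene = next(
            s.causal_gene for s in default_scenarios() if s.family_id == family
        )
        for spec in specs:
            key = (gene, spec.hgvs_c)
            if key in seen:
                continue
            seen.add(key)
            catalog.add(
                MutationRecord(
                    gene=gene,
                    hgvs_c=spec.hgvs_c,
                    protein=spec.protein,
                    status=spec.status,
                    reference=refs.get(key, ""),
                )
            )
    return catalog


def write_fixture_table1(path: str | os.PathLike) -> MutationCatalog:
    """Write the published-mutation catalog fixture as a TSV; return it."""
    catalog = build_table1_catalog()
    write_mutation_catalog(catalog, path)
    return catalog


# ---------------------------------------------------------------------------
# Generator
# ---------------------------------------------------------------------------


@dataclass
class GeneratorParams:
    """Cohort-generator calibration: the study conditions the exomes emulate.

    Defaults reproduce the four count strata of the emulated study: ~67,000
    variants per exome, ~12,000 coding non-silent, 108-143 in the 160-gene
    panel, 18-34 rare at the 2% frequency threshold.
    """

    mean_total_variants: float = 67_000
    mean_coding_nonsilent: float = 12_000
    panel_count_range: tuple[int, int] = (108, 143)
    rare_count_range: tuple[int, int] = (18, 34)
    af_threshold: float = 0.02
    seed: int = 0
    n_spurious_panel_variants: int = 0
    panel: GenePanel = field(default_factory=default_panel)

    def __post_init__(self) -> None:
        if self.mean_total_variants < self.mean_coding_nonsilent:
            raise ValueError("mean_coding_nonsilent cannot exceed mean_total_variants")
        for lo, hi in (self.panel_count_range, self.rare_count_range):
            if lo < 0 or hi < lo:
                raise ValueError("count ranges must be non-empty and non-negative")
        if self.rare_count_range[1] > self.panel_count_range[0]:
            raise ValueError(
                "rare_count_range upper bound must not exceed panel_count_range "
                "lower bound"
            )
        if not (0 <= self.af_threshold <= 1):
            raise ValueError("af_threshold must be in [0, 1]")


def _rng_for_patient(params: GeneratorParams, patient_index: int) -> np.random.Generator:
    # documented substream: per-patient streams depend only on (seed, index),
    # so cohort composition is order-independent
    return np.random.default_rng([params.seed, patient_index])


def _random_snv_alleles(rng: np.random.Generator, n: int) -> tuple[np.ndarray, np.ndarray]:
    ref_idx = rng.integers(0, 4, n)
    alt_idx = (ref_idx + rng.integers(1, 4, n)) % 4
    return _BASES[ref_idx], _BASES[alt_idx]


_BACKGROUND_CHROMS = [str(i) for i in range(1, 23)]


def generate_exome(
    params: GeneratorParams,
    scenario: Optional[FamilyScenario],
    patient_id: str,
    patient_index: int = 0,
    catalog: Optional[FrequencyCatalog] = None,
) -> PatientExome:
    """Generate one synthetic index-patient exome.

    Common panel polymorphisms are registered in ``catalog`` (when given)
    with frequencies above the threshold; a fraction of the rare background
    is registered at or below it, the rest is left uncatalogued.  Planted
    causal variants are always rare and uncatalogued, and are asserted to
    survive the class, panel, and frequency filters at generation time.
    """
    rng = _rng_for_patient(params, patient_index)
    panel = params.panel
    windows = _panel_gene_window(panel)
    sex = scenario.sex if scenario is not None else "female"

    planted: list[VariantRecord] = []
    if scenario is not None and scenario.causal_gene is not None:
        gene = scenario.causal_gene
        if gene not in panel:
            raise ValueError(f"scenario gene {gene} absent from panel")
        chrom, base = windows[gene]
        zyg = (
            "homozygous_alt"
            if scenario.genotype_config in ("AR_homozygous", "XL_hemizygous")
            else "heterozygous"
        )
        for i, spec in enumerate(scenario.variants):
            planted.append(
                VariantRecord(
                    chrom=chrom,
                    pos=base + 10_001 + 2 * i,
                    ref=spec.ref,
                    alt=spec.alt,
                    gene=gene,
                    consequence=spec.consequence,
                    zygosity=zyg,
                    hgvs_c=spec.hgvs_c,
                )
            )
    if scenario is not None and scenario.spurious:
        s_gene = scenario.spurious_gene
        if s_gene not in panel:
            raise ValueError(f"scenario spurious gene {s_gene} absent from panel")
        chrom, base = windows[s_gene]
        for i, spec in enumerate(scenario.spurious):
            planted.append(
                VariantRecord(
                    chrom=chrom,
                    pos=base + 20_001 + 2 * i,
                    ref=spec.ref,
                    alt=spec.alt,
                    gene=s_gene,
                    consequence=spec.consequence,
                    zygosity="heterozygous",
                    hgvs_c=spec.hgvs_c,
                )
            )

    # --- stratum sizes (clipped to containment) ---
    n_total = int(rng.poisson(params.mean_total_variants))
    n_cns = min(int(rng.poisson(params.mean_coding_nonsilent)), n_total)
    lo, hi = params.panel_count_range
    n_panel = min(int(rng.integers(lo, hi + 1)) if hi > 0 else 0, n_cns)
    lo, hi = params.rare_count_range
    n_rare = min(int(rng.integers(lo, hi + 1)) if hi > 0 else 0, n_panel)
    n_rare = max(n_rare, len(planted))

    n_common_panel = n_panel - n_rare
    n_rare_background = n_rare - len(planted)
    n_cns_background = n_cns - n_panel
    n_silent = n_total - n_cns

    variants: list[VariantRecord] = list(planted)

    # --- rare background panel variants: het, one per gene ---
    excluded = {scenario.causal_gene, scenario.spurious_gene} if scenario else set()
    eligible = [
        g
        for g, c in panel.entries
        if g not in excluded and not (sex == "male" and c == "X")
    ]
    genes = rng.choice(np.array(eligible), size=n_rare_background, replace=False)
    kept_classes = sorted(NON_SILENT_CLASSES, key=lambda c: c.value)
    class_p = _class_probs(kept_classes)
    for g in genes:
        chrom, base = windows[str(g)]
        pos = base + 1 + 2 * int(rng.integers(0, 50_000))  # odd offsets
        ref_arr, alt_arr = _random_snv_alleles(rng, 1)
        ref, alt = str(ref_arr[0]), str(alt_arr[0])
        csq = kept_classes[int(rng.choice(len(kept_classes), p=class_p))]
        rec = VariantRecord(
            chrom=chrom, pos=pos, ref=ref, alt=alt, gene=str(g),
            consequence=csq, zygosity="heterozygous",
        )
        # half the rare background is catalogued at or below the threshold
        if catalog is not None and rng.random() < 0.5:
            if rec.key not in catalog:
                if rng.random() < 0.1:
                    af = None  # registered site without a frequency
                else:
                    af = round(float(rng.uniform(1e-4, params.af_threshold)), 6)
                catalog.add(rec.key, af)
            rec.catalog_af = catalog.get(rec.key)
            rec.rs_id = f"rs9{rec.pos % 10_000_000:07d}"
        variants.append(rec)

    # --- common panel polymorphisms: catalogued above the threshold ---
    panel_genes = np.array([g for g, _ in panel.entries])
    common_gene_idx = rng.integers(0, len(panel_genes), n_common_panel)
    for gi in common_gene_idx:
        g = str(panel_genes[gi])
        chrom, base = windows[g]
        pos = base + 2 * int(rng.integers(0, 50_000))  # even offsets
        pos = max(pos, base)
        ref, alt = _random_snv_alleles(rng, 1)
        ref, alt = str(ref[0]), str(alt[0])
        key = (chrom, pos, ref, alt)
        if catalog is not None:
            if key not in catalog or catalog.get(key) is None or catalog.get(key) <= params.af_threshold:
                af = round(float(rng.uniform(params.af_threshold + 1e-3, 0.5)), 6)
                catalog.add(key, af)
            af = catalog.get(key)
        else:
            af = round(float(rng.uniform(params.af_threshold + 1e-3, 0.5)), 6)
        csq = kept_classes[int(rng.choice(len(kept_classes), p=class_p))]
        variants.append(
            VariantRecord(
                chrom=chrom, pos=pos, ref=ref, alt=alt, gene=g,
                consequence=csq,
                zygosity="homozygous_alt" if rng.random() < 0.35 else "heterozygous",
                rs_id=f"rs{pos % 10_000_000:07d}",
                catalog_af=af,
            )
        )

    # --- coding non-silent background outside the panel ---
    variants.extend(_background_block(rng, n_cns_background, silent=False))
    # --- silent / noncoding background ---
    variants.extend(_background_block(rng, n_silent, silent=True))

    exome = PatientExome(patient_id=patient_id, sex=sex, variants=variants)
    _assert_plants_survive(planted, params, catalog)
    return exome


def _class_probs(kept_classes) -> np.ndarray:
    weights = {
        ConsequenceClass.MISSENSE: 0.74,
        ConsequenceClass.NONSENSE: 0.05,
        ConsequenceClass.FRAMESHIFT_INDEL: 0.08,
        ConsequenceClass.INFRAME_INDEL: 0.04,
        ConsequenceClass.SPLICE_SITE: 0.09,
    }
    p = np.array([weights[c] for c in kept_classes])
    return p / p.sum()


def _background_block(
    rng: np.random.Generator, n: int, silent: bool
) -> list[VariantRecord]:
    """Non-panel background variants, vectorized for speed."""
    if n <= 0:
        return []
    chroms = rng.choice(np.array(_BACKGROUND_CHROMS), size=n)
    pos = rng.integers(1, 240_000_000, n)
    ref, alt = _random_snv_alleles(rng, n)
    hom = rng.random(n) < 0.35
    if silent:
        noncoding = rng.random(n) < 0.8
        gene_num = rng.integers(1, 2000, n)
        records = [
            VariantRecord(
                chrom=str(chroms[i]),
                pos=int(pos[i]),
                ref=str(ref[i]),
                alt=str(alt[i]),
                gene="" if noncoding[i] else f"BG{chroms[i]}_{gene_num[i]:04d}",
                consequence=ConsequenceClass.NONCODING
                if noncoding[i]
                else ConsequenceClass.SYNONYMOUS,
                zygosity="homozygous_alt" if hom[i] else "heterozygous",
            )
            for i in range(n)
        ]
    else:
        kept_classes = sorted(NON_SILENT_CLASSES, key=lambda c: c.value)
        csq_idx = rng.choice(len(kept_classes), size=n, p=_class_probs(kept_classes))
        gene_num = rng.integers(1, 2000, n)
        records = [
            VariantRecord(
                chrom=str(chroms[i]),
                pos=int(pos[i]),
                ref=str(ref[i]),
                alt=str(alt[i]),
                gene=f"BG{chroms[i]}_{gene_num[i]:04d}",
                consequence=kept_classes[csq_idx[i]],
                zygosity="homozygous_alt" if hom[i] else "heterozygous",
            )
            for i in range(n)
        ]
    return records


def _assert_plants_survive(
    planted: list[VariantRecord],
    params: GeneratorParams,
    catalog: Optional[FrequencyCatalog],
) -> None:
    for v in planted:
        assert v.consequence in NON_SILENT_CLASSES, v
        assert v.gene in params.panel, v
        if catalog is not None and v.key in catalog:
            af = catalog.get(v.key)
            assert af is None or af <= params.af_threshold, v


@dataclass
class Cohort:
    """A generated cohort: exomes plus the shared reference resources."""

    params: GeneratorParams
    scenarios: tuple[FamilyScenario, ...]
    exomes: dict[str, PatientExome]
    panel: GenePanel
    frequency_catalog: FrequencyCatalog
    mutation_catalog: MutationCatalog
    pedigrees: dict[str, Pedigree]

    @property
    def manifest(self) -> pd.DataFrame:
        rows = [
            {
                "family_id": s.family_id,
                "patient_id": s.patient_id,
                "sex": s.sex,
                "causal_gene": s.causal_gene or "",
                "genotype_config": s.genotype_config or "",
            }
            for s in self.scenarios
        ]
        return pd.DataFrame(rows)


def generate_cohort(
    params: Optional[GeneratorParams] = None,
    scenarios: Optional[tuple[FamilyScenario, ...]] = None,
) -> Cohort:
    """Generate the full synthetic cohort (12 families by default)."""
    params = params if params is not None else GeneratorParams()
    scenarios = scenarios if scenarios is not None else default_scenarios()
    fam_ids = [s.family_id for s in scenarios]
    if len(fam_ids) != len(set(fam_ids)):
        raise ValueError("duplicated family ids in scenarios")

    catalog = FrequencyCatalog()
    exomes: dict[str, PatientExome] = {}
    pedigrees: dict[str, Pedigree] = {}
    for idx, scenario in enumerate(scenarios):
        exomes[scenario.patient_id] = generate_exome(
            params, scenario, scenario.patient_id, patient_index=idx, catalog=catalog
        )
        if scenario.pedigree_members:
            pedigrees[scenario.family_id] = scenario.build_pedigree()
    return Cohort(
        params=params,
        scenarios=tuple(scenarios),
        exomes=exomes,
        panel=params.panel,
        frequency_catalog=catalog,
        mutation_catalog=build_table1_catalog(),
        pedigrees=pedigrees,
    )


# ---------------------------------------------------------------------------
# Allele-dropping simulation
# ---------------------------------------------------------------------------


def drop_alleles(
    pedigree: Pedigree, n_replicates: int, seed: int = 0
) -> pd.DataFrame:
    """Gene-dropping: simulate transmissions through the pedigree.

    Founders keep their fixed carrier genotypes (father {A}, mother {B} under
    AR; mother {A} under XL); every child independently receives each
    parental allele with probability 1/2.  Returns a long DataFrame with
    columns replicate, member_id, carries_A, carries_B.
    """
    model = pedigree.model
    rng = np.random.default_rng(seed)
    rows = {}
    for m in pedigree.founders:
        if model == "AR":
            carries_a = np.full(n_replicates, m.sex == "male")
            carries_b = np.full(n_replicates, m.sex == "female")
        else:
            carries_a = np.full(n_replicates, m.sex == "female")
            carries_b = np.zeros(n_replicates, bool)
        rows[m.member_id] = (carries_a, carries_b)
    for m in pedigree.non_founders:
        if model == "AR":
            carries_a = rng.random(n_replicates) < 0.5  # paternal allele A
            carries_b = rng.random(n_replicates) < 0.5  # maternal allele B
        else:
            carries_a = rng.random(n_replicates) < 0.5  # maternal X
            carries_b = np.zeros(n_replicates, bool)
        rows[m.member_id] = (carries_a, carries_b)

    frames = []
    for mid, (a, b) in rows.items():
        frames.append(
            pd.DataFrame(
                {
                    "replicate": np.arange(n_replicates),
                    "member_id": mid,
                    "carries_A": a,
                    "carries_B": b,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def fraction_consistent(pedigree: Pedigree, dropped: pd.DataFrame) -> float:
    """Fraction of replicates fully consistent with genotypes and phenotypes."""
    model = pedigree.model
    n_rep = int(dropped["replicate"].max()) + 1 if len(dropped) else 0
    ok = np.ones(n_rep, bool)
    for m in pedigree.non_founders:
        sub = dropped[dropped["member_id"] == m.member_id].sort_values("replicate")
        a = sub["carries_A"].to_numpy()
        b = sub["carries_B"].to_numpy()
        if model == "AR":
            affected_if = a & b
        else:
            affected_if = a if m.sex == "male" else np.zeros_like(a)
        ok &= affected_if == m.affected
        if m.genotype is not None:
            ok &= a == ("A" in m.genotype)
            if model == "AR":
                ok &= b == ("B" in m.genotype)
    return float(ok.mean()) if n_rep else 1.0
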