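"""Domain types for exome-based molecular diagnosis of recessive retinal dystrophies.

The pipeline operates on called, annotated variants of a single index patient
(proband): each variant carries a gene symbol, a functional consequence class,
and a zygosity call.  Panels, frequency catalogs and mutation catalogs are the
reference resources the filtering cascade consults; pedigrees feed the exact
cosegregation test.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Optional

__all__ = [
    "ConsequenceClass",
    "VariantRecord",
    "GenePanel",
    "FrequencyCatalog",
    "MutationRecord",
    "MutationCatalog",
    "PatientExome",
    "CandidateGene",
    "CascadeTrace",
    "PedigreeMember",
    "Pedigree",
    "SegregationResult",
    "VALID_CHROMOSOMES",
]

VALID_CHROMOSOMES = tuple(str(i) for i in range(1, 23)) + ("X", "Y")
_VALID_CHROM_SET = frozenset(VALID_CHROMOSOMES)


class ConsequenceClass(str, enum.Enum):
    """Functional consequence of a variant on its transcript.

    The first five classes can alter the protein or its splicing and are the
    classes retained by the coding/non-silent filter; ``synonymous`` and
    ``noncoding`` are discarded by it.
    """

    MISSENSE = "missense"
    NONSENSE = "nonsense"
    FRAMESHIFT_INDEL = "frameshift_indel"
    INFRAME_INDEL = "inframe_indel"
    SPLICE_SITE = "splice_site"
    SYNONYMOUS = "synonymous"
    NONCODING = "noncoding"


#: Consequence classes that can alter the protein product or splicing.
NON_SILENT_CLASSES = frozenset(
    {
        ConsequenceClass.MISSENSE,
        ConsequenceClass.NONSENSE,
        ConsequenceClass.FRAMESHIFT_INDEL,
        ConsequenceClass.INFRAME_INDEL,
        ConsequenceClass.SPLICE_SITE,
    }
)


@dataclass(slots=True)
class VariantRecord:
    """One called variant in one patient.

    Coordinates are 1-based VCF convention; indels are left-anchored.  A male
    patient's chrX calls are encoded as ``homozygous_alt`` by upstream callers
    and reinterpreted as hemizygous by the recessive-model step.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str = ""
    consequence: ConsequenceClass = ConsequenceClass.NONCODING
    zygosity: str = "heterozygous"  # "heterozygous" | "homozygous_alt"
    rs_id: Optional[str] = None
    catalog_af: Optional[float] = None
    hgvs_c: Optional[str] = None

    def __post_init__(self) -> None:
        if self.chrom not in _VALID_CHROM_SET:
            raise ValueError(f"invalid chromosome label {self.chrom!r}")
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref and alt alleles identical at {self.chrom}:{self.pos}")
        if self.zygosity not in ("heterozygous", "homozygous_alt"):
            raise ValueError(f"invalid zygosity {self.zygosity!r}")
        if isinstance(self.consequence, str):
            self.consequence = ConsequenceClass(self.consequence)
        if not self.gene and self.consequence is not ConsequenceClass.NONCODING:
            raise ValueError(
                f"variant {self.chrom}:{self.pos} has consequence "
                f"{self.consequence.value} but no gene symbol"
            )

    @property
    def key(self) -> tuple[str, int, str, str]:
        """Site key used to match this variant against a frequency catalog."""
        return (self.chrom, self.pos, self.ref, self.alt)

    def typed_fields(self) -> tuple:
        """All typed fields, for order-independent set comparisons."""
        return (
            self.chrom,
            self.pos,
            self.ref,
            self.alt,
            self.gene,
            self.consequence.value,
            self.zygosity,
            self.rs_id,
            self.catalog_af,
            self.hgvs_c,
        )


@dataclass(frozen=True)
class GenePanel:
    """A disease-gene panel: gene symbols with their chromosome labels."""

    entries: tuple[tuple[str, str], ...]
    name: str = "panel"

    def __post_init__(self) -> None:
        genes = [g for g, _ in self.entries]
        if len(genes) != len(set(genes)):
            dupes = sorted({g for g in genes if genes.count(g) > 1})
            raise ValueError(f"duplicate gene symbols in panel: {dupes}")
        for _, chrom in self.entries:
            if chrom not in VALID_CHROMOSOMES:
                raise ValueError(f"invalid chromosome label {chrom!r} in panel")

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(g for g, _ in self.entries)

    def chrom_of(self, gene: str) -> str:
        for g, chrom in self.entries:
            if g == gene:
                return chrom
        raise KeyError(gene)

    def __contains__(self, gene: str) -> bool:
        return gene in self.genes

    def __len__(self) -> int:
        return len(self.entries)


class FrequencyCatalog:
    """Catalog of known variant sites with optional allele frequencies.

    Emulates a dbSNP-style resource: a site may be registered with a
    population allele frequency, or registered with no frequency at all.
    """

    def __init__(
        self, entries: Optional[Iterable[tuple[tuple[str, int, str, str], Optional[float]]]] = None
    ) -> None:
        self._sites: dict[tuple[str, int, str, str], Optional[float]] = {}
        for key, af in entries or ():
            self.add(key, af)

    def add(self, key: tuple[str, int, str, str], af: Optional[float]) -> None:
        if af is not None and not (0.0 <= af <= 1.0):
            raise ValueError(f"allele frequency {af} outside [0, 1] for site {key}")
        self._sites[key] = af

    def __contains__(self, key: tuple[str, int, str, str]) -> bool:
        return key in self._sites

    def frequency(self, key: tuple[str, int, str, str]) -> Optional[float]:
        """AF for a registered site, None if registered without frequency.

        Raises KeyError for unregistered sites.
        """
        return self._sites[key]

    def get(self, key: tuple[str, int, str, str]) -> Optional[float]:
        return self._sites.get(key)

    def items(self):
        return self._sites.items()

    def __len__(self) -> int:
        return len(self._sites)


@dataclass(frozen=True)
class MutationRecord:
    """One published disease mutation: gene, coding change, protein change."""

    gene: str
    hgvs_c: str
    protein: str
    status: str  # "known" | "novel"  (novel = novel at publication)
    reference: str = ""

    def __post_init__(self) -> None:
        if self.status not in ("known", "novel"):
            raise ValueError(f"invalid mutation status {self.status!r}")


class MutationCatalog:
    """Catalog of disease mutations keyed on (gene, hgvs_c)."""

    def __init__(self, records: Optional[Iterable[MutationRecord]] = None) -> None:
        self._records: dict[tuple[str, str], MutationRecord] = {}
        for rec in records or ():
            self.add(rec)

    def add(self, rec: MutationRecord) -> None:
        key = (rec.gene, rec.hgvs_c)
        if key in self._records:
            raise ValueError(f"duplicate mutation catalog entry {key}")
        self._records[key] = rec

    def lookup(self, gene: str, hgvs_c: str) -> Optional[MutationRecord]:
        return self._records.get((gene, hgvs_c))

    def is_known(self, gene: str, hgvs_c: Optional[str]) -> bool:
        """True iff (gene, hgvs_c) matches a catalog record with status known."""
        if hgvs_c is None:
            return False
        rec = self._records.get((gene, hgvs_c))
        return rec is not None and rec.status == "known"

    @property
    def records(self) -> list[MutationRecord]:
        return list(self._records.values())

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self):
        return iter(self._records.values())


@dataclass
class PatientExome:
    """An index patient's sex and called variant set."""

    patient_id: str
    sex: str  # "male" | "female"
    variants: list[VariantRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.patient_id:
            raise ValueError("patient_id must be non-empty")
        if self.sex not in ("male", "female"):
            raise ValueError(f"invalid sex {self.sex!r}")

    def __len__(self) -> int:
        return len(self.variants)

    def variant_set(self) -> frozenset[tuple]:
        """Typed-field set for order-independent exome equality."""
        return frozenset(v.typed_fields() for v in self.variants)


@dataclass
class CandidateGene:
    """A gene surviving the recessive-model filter, with supporting variants.

    ``model`` records how the gene qualified: two heterozygous hits assumed in
    trans (AR_compound_het), one homozygous hit (AR_homozygous), or any chrX
    hit in a male (XL_hemizygous).  ``known_flags[i]`` is True when
    ``variants[i]`` matches a published mutation.
    """

    gene: str
    variants: list[VariantRecord]
    model: str  # "AR_compound_het" | "AR_homozygous" | "XL_hemizygous"
    known_flags: list[bool] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.model not in ("AR_compound_het", "AR_homozygous", "XL_hemizygous"):
            raise ValueError(f"invalid inheritance model {self.model!r}")
        if not self.variants:
            raise ValueError("candidate gene requires at least one supporting variant")
        if self.model == "AR_compound_het":
            n_het = sum(1 for v in self.variants if v.zygosity == "heterozygous")
            if n_het < 2:
                raise ValueError(
                    f"AR_compound_het candidate {self.gene} needs >=2 heterozygous variants"
                )
        if self.model == "AR_homozygous":
            if not any(v.zygosity == "homozygous_alt" for v in self.variants):
                raise ValueError(
                    f"AR_homozygous candidate {self.gene} needs a homozygous variant"
                )
        if self.model == "XL_hemizygous":
            if not all(v.chrom == "X" for v in self.variants):
                raise ValueError(f"XL_hemizygous candidate {self.gene} must be on chrX")


@dataclass(frozen=True)
class CascadeTrace:
    """Per-step surviving-variant counts of the five-step filtering cascade."""

    n_total: int
    n_coding_nonsilent: int
    n_panel: int
    n_rare: int
    n_candidate_variants: int
    candidate_genes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        counts = self.counts
        if any(c < 0 for c in counts):
            raise ValueError("trace counts must be non-negative")
        if any(a < b for a, b in zip(counts, counts[1:])):
            raise ValueError(f"trace counts must be non-increasing: {counts}")

    @property
    def counts(self) -> tuple[int, int, int, int, int]:
        return (
            self.n_total,
            self.n_coding_nonsilent,
            self.n_panel,
            self.n_rare,
            self.n_candidate_variants,
        )


@dataclass(frozen=True)
class PedigreeMember:
    """One pedigree member with carrier status for up to two candidate alleles.

    ``genotype`` is the subset of {"A", "B"} of candidate alleles the member
    carries, or None when ungenotyped.  In the X-linked model only allele "A"
    (the maternal mutant X) is used.
    """

    member_id: str
    sex: str  # "male" | "female"
    affected: bool
    father_id: Optional[str] = None
    mother_id: Optional[str] = None
    genotype: Optional[frozenset[str]] = None

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValueError(f"invalid sex {self.sex!r} for member {self.member_id}")
        if self.genotype is not None:
            if not self.genotype <= {"A", "B"}:
                raise ValueError(
                    f"genotype of {self.member_id} must be a subset of {{A, B}}"
                )


@dataclass
class Pedigree:
    """A nuclear or extended pedigree for cosegregation analysis."""

    family_id: str
    members: list[PedigreeMember]
    model: str = "AR"  # "AR" | "XL"
    index_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.model not in ("AR", "XL"):
            raise ValueError(f"invalid inheritance model {self.model!r}")
        ids = [m.member_id for m in self.members]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate member ids in pedigree")
        known = set(ids)
        for m in self.members:
            for pid in (m.father_id, m.mother_id):
                if pid is not None and pid not in known:
                    raise ValueError(
                        f"member {m.member_id} references unknown parent {pid!r}"
                    )
            if (m.father_id is None) != (m.mother_id is None):
                raise ValueError(
                    f"member {m.member_id} must have both parents or neither"
                )
        self._check_acyclic()
        if self.index_id is not None and self.index_id not in known:
            raise ValueError(f"index id {self.index_id!r} not in pedigree")

    def _check_acyclic(self) -> None:
        by_id = {m.member_id: m for m in self.members}
        state: dict[str, int] = {}

        def visit(mid: str) -> None:
            if state.get(mid) == 1:
                raise ValueError(f"pedigree relations contain a cycle at {mid}")
            if state.get(mid) == 2:
                return
            state[mid] = 1
            m = by_id[mid]
            for pid in (m.father_id, m.mother_id):
                if pid is not None:
                    visit(pid)
            state[mid] = 2

        for m in self.members:
            visit(m.member_id)

    def member(self, member_id: str) -> PedigreeMember:
        for m in self.members:
            if m.member_id == member_id:
                return m
        raise KeyError(member_id)

    @property
    def founders(self) -> list[PedigreeMember]:
        return [m for m in self.members if m.father_id is None]

    @property
    def non_founders(self) -> list[PedigreeMember]:
        return [m for m in self.members if m.father_id is not None]


@dataclass(frozen=True)
class SegregationResult:
    """Exact cosegregation probability from transmission-vector enumeration."""

    probability: Fraction
    n_transmission_vectors: int
    n_consistent: int
    model: str

    def __post_init__(self) -> None:
        if self.n_transmission_vectors <= 0:
            raise ValueError("n_transmission_vectors must be positive")
        expected = Fraction(self.n_consistent, self.n_transmission_vectors)
        if self.probability != expected:
            raise ValueError("probability must equal n_consistent / n_transmission_vectors")
        if not (0 <= self.probability <= 1):
            raise ValueError("probability must lie in [0, 1]")

    @property
    def value(self) -> float:
        return float(self.probability)

    def truncated(self, decimals: int = 3) -> float:
        """Probability truncated (not rounded) to the given decimals."""
        scale = 10**decimals
        return int(self.probability * scale) / scale
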