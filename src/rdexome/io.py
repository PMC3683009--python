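"""File I/O: single-sample annotated VCF, panel/catalog TSVs, PED pedigrees.

The VCF dialect carries the annotations the cascade needs as INFO keys:
``GENE`` (gene symbol), ``CSQ_CLASS`` (one of the seven consequence-class
labels), ``RS`` (optional catalog identifier) and ``CAT_AF`` (optional catalog
allele frequency).  Exactly one sample column with a GT field is expected.
"""

from __future__ import annotations

import math
import os
from typing import Optional

import pandas as pd
import pysam

from .types import (
    ConsequenceClass,
    FrequencyCatalog,
    GenePanel,
    MutationCatalog,
    MutationRecord,
    PatientExome,
    Pedigree,
    PedigreeMember,
    VALID_CHROMOSOMES,
    VariantRecord,
)

__all__ = [
    "read_vcf",
    "write_vcf",
    "read_panel",
    "write_panel",
    "read_frequency_catalog",
    "write_frequency_catalog",
    "read_mutation_catalog",
    "write_mutation_catalog",
    "read_pedigree",
    "write_pedigree",
]


class VcfParseError(ValueError):
    """Raised when a VCF line lacks a required annotation."""


def _norm_chrom(chrom: str) -> str:
    return chrom[3:] if chrom.startswith("chr") else chrom


def read_vcf(path: str | os.PathLike) -> PatientExome:
    """Read a single-sample annotated VCF into a PatientExome.

    Genotypes map 0/1 (or any single-ALT het) to ``heterozygous`` and 1/1 to
    ``homozygous_alt``; reference calls (0/0) and no-calls (./.) are dropped.
    Multiallelic lines yield one record per ALT allele carried.

    The patient's sex is read from a ``##patient_sex=`` header line (written
    by :func:`write_vcf`); it defaults to female when absent.
    """
    vf = pysam.VariantFile(os.fspath(path))
    samples = list(vf.header.samples)
    if len(samples) != 1:
        raise VcfParseError(
            f"expected exactly one sample column, found {len(samples)}: {samples}"
        )
    sample = samples[0]

    sex = "female"
    for rec in vf.header.records:
        text = str(rec)
        if text.startswith("##patient_sex="):
            sex = text.split("=", 1)[1].strip()

    variants: list[VariantRecord] = []
    for line_no, rec in enumerate(vf, start=1):
        gt = rec.samples[sample].get("GT")
        if gt is None or all(a is None for a in gt):
            continue  # no-call
        alleles = [a for a in gt if a is not None]
        for alt_index, alt in enumerate(rec.alts or (), start=1):
            n_alt = alleles.count(alt_index)
            if n_alt == 0:
                continue
            zygosity = "homozygous_alt" if n_alt >= 2 else "heterozygous"
            info = rec.info
            if "CSQ_CLASS" not in info:
                raise VcfParseError(
                    f"missing INFO key CSQ_CLASS at record {line_no} "
                    f"({rec.chrom}:{rec.pos})"
                )
            def _info(key):
                # .get raises for keys missing from the header; treat both
                # undeclared and absent keys as None
                if key not in info:
                    return None
                value = info[key]
                return value[0] if isinstance(value, tuple) else value

            gene = _info("GENE") or ""
            csq = _info("CSQ_CLASS")
            rs = _info("RS")
            cat_af = _info("CAT_AF")
            hgvs = _info("HGVS_C")
            variants.append(
                VariantRecord(
                    chrom=_norm_chrom(rec.chrom),
                    pos=rec.pos,
                    ref=rec.ref,
                    alt=alt,
                    gene=gene or "",
                    consequence=ConsequenceClass(csq),
                    zygosity=zygosity,
                    rs_id=rs,
                    # CAT_AF is stored as a 32-bit float in VCF; re-quantize
                    catalog_af=round(float(cat_af), 6) if cat_af is not None else None,
                    hgvs_c=hgvs,
                )
            )
    vf.close()
    return PatientExome(patient_id=sample, sex=sex, variants=variants)


def _vcf_header(sex: str) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for chrom in VALID_CHROMOSOMES:
        header.contigs.add(chrom)
    header.info.add("GENE", 1, "String", "Gene symbol")
    header.info.add("CSQ_CLASS", 1, "String", "Consequence class")
    header.info.add("RS", 1, "String", "Catalog identifier")
    header.info.add("CAT_AF", 1, "Float", "Catalog allele frequency")
    header.info.add("HGVS_C", 1, "String", "Coding-change notation")
    header.formats.add("GT", 1, "String", "Genotype")
    header.add_line(f"##patient_sex={sex}")
    return header


def write_vcf(exome: PatientExome, path: str | os.PathLike) -> None:
    """Write a PatientExome as an uncompressed single-sample VCF.

    Round trip: ``read_vcf(write_vcf(x))`` reproduces every typed field.
    """
    header = _vcf_header(exome.sex)
    header.add_sample(exome.patient_id)
    vf = pysam.VariantFile(os.fspath(path), "w", header=header)
    order = {c: i for i, c in enumerate(VALID_CHROMOSOMES)}
    for v in sorted(exome.variants, key=lambda v: (order[v.chrom], v.pos, v.ref, v.alt)):
        rec = vf.new_record(
            contig=v.chrom,
            start=v.pos - 1,
            stop=v.pos - 1 + len(v.ref),
            alleles=(v.ref, v.alt),
        )
        if v.gene:
            rec.info["GENE"] = v.gene
        rec.info["CSQ_CLASS"] = v.consequence.value
        if v.rs_id is not None:
            rec.info["RS"] = v.rs_id
        if v.catalog_af is not None:
            rec.info["CAT_AF"] = v.catalog_af
        if v.hgvs_c is not None:
            rec.info["HGVS_C"] = v.hgvs_c
        rec.samples[exome.patient_id]["GT"] = (
            (1, 1) if v.zygosity == "homozygous_alt" else (0, 1)
        )
        vf.write(rec)
    vf.close()


def read_panel(path: str | os.PathLike, name: str = "panel") -> GenePanel:
    """Read a gene panel TSV with columns ``gene`` and ``chrom``."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("gene", "chrom"):
        if col not in df.columns:
            raise ValueError(f"panel file missing column {col!r}")
    entries = tuple(zip(df["gene"], df["chrom"]))
    return GenePanel(entries=entries, name=name)


def write_panel(panel: GenePanel, path: str | os.PathLike) -> None:
    pd.DataFrame(panel.entries, columns=["gene", "chrom"]).to_csv(
        path, sep="\t", index=False
    )


def read_frequency_catalog(path: str | os.PathLike) -> FrequencyCatalog:
    """Read a frequency catalog TSV: chrom, pos, ref, alt, af (af may be empty)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "ref": str, "alt": str})
    catalog = FrequencyCatalog()
    for row in df.itertuples(index=False):
        af = None if (row.af is None or (isinstance(row.af, float) and math.isnan(row.af))) else float(row.af)
        catalog.add((str(row.chrom), int(row.pos), row.ref, row.alt), af)
    return catalog


def write_frequency_catalog(catalog: FrequencyCatalog, path: str | os.PathLike) -> None:
    rows = [
        {"chrom": k[0], "pos": k[1], "ref": k[2], "alt": k[3], "af": af}
        for k, af in sorted(catalog.items())
    ]
    pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "af"]).to_csv(
        path, sep="\t", index=False
    )


def read_mutation_catalog(path: str | os.PathLike) -> MutationCatalog:
    """Read a mutation catalog TSV: gene, hgvs_c, protein, status, reference."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    catalog = MutationCatalog()
    for row in df.itertuples(index=False):
        catalog.add(
            MutationRecord(
                gene=row.gene,
                hgvs_c=row.hgvs_c,
                protein=row.protein,
                status=row.status,
                reference=row.reference,
            )
        )
    return catalog


def write_mutation_catalog(catalog: MutationCatalog, path: str | os.PathLike) -> None:
    rows = [
        {
            "gene": r.gene,
            "hgvs_c": r.hgvs_c,
            "protein": r.protein,
            "status": r.status,
            "reference": r.reference,
        }
        for r in catalog
    ]
    pd.DataFrame(
        rows, columns=["gene", "hgvs_c", "protein", "status", "reference"]
    ).to_csv(path, sep="\t", index=False)


_PED_SEX = {"1": "male", "2": "female"}
_CARRY = {"yes": True, "no": False, "unknown": None}


def read_pedigree(
    ped_path: str | os.PathLike,
    genotype_path: Optional[str | os.PathLike] = None,
    model: str = "AR",
    index_id: Optional[str] = None,
) -> Pedigree:
    """Read a 6-column PED file plus an optional carrier-genotype TSV.

    PED columns: family, id, father, mother, sex (1=male, 2=female),
    phenotype (2=affected, 1=unaffected).  The genotype TSV has columns
    ``id``, ``carries_alleleA``, ``carries_alleleB`` with values
    yes/no/unknown; members absent from it (or with both columns unknown)
    are treated as ungenotyped.
    """
    ped = pd.read_csv(
        ped_path,
        sep=r"\s+",
        header=None,
        names=["family", "id", "father", "mother", "sex", "phenotype"],
        dtype=str,
    )
    genotypes: dict[str, Optional[frozenset[str]]] = {}
    if genotype_path is not None:
        gdf = pd.read_csv(genotype_path, sep="\t", dtype=str)
        for row in gdf.itertuples(index=False):
            a = _CARRY[row.carries_alleleA]
            b = _CARRY[row.carries_alleleB]
            if a is None and b is None:
                genotypes[str(row.id)] = None
            else:
                carried = set()
                if a:
                    carried.add("A")
                if b:
                    carried.add("B")
                # a single unknown with the other known is treated as
                # ungenotyped for that allele only; we require both known
                if a is None or b is None:
                    genotypes[str(row.id)] = None
                else:
                    genotypes[str(row.id)] = frozenset(carried)

    members = []
    family_id = str(ped["family"].iloc[0]) if len(ped) else "FAM"
    for row in ped.itertuples(index=False):
        father = None if row.father in ("0", None) else str(row.father)
        mother = None if row.mother in ("0", None) else str(row.mother)
        members.append(
            PedigreeMember(
                member_id=str(row.id),
                sex=_PED_SEX[str(row.sex)],
                affected=str(row.phenotype) == "2",
                father_id=father,
                mother_id=mother,
                genotype=genotypes.get(str(row.id)),
            )
        )
    return Pedigree(family_id=family_id, members=members, model=model, index_id=index_id)


def write_pedigree(
    pedigree: Pedigree,
    ped_path: str | os.PathLike,
    genotype_path: Optional[str | os.PathLike] = None,
) -> None:
    rows = []
    for m in pedigree.members:
        rows.append(
            {
                "family": pedigree.family_id,
                "id": m.member_id,
                "father": m.father_id or "0",
                "mother": m.mother_id or "0",
                "sex": "1" if m.sex == "male" else "2",
                "phenotype": "2" if m.affected else "1",
            }
        )
    pd.DataFrame(rows).to_csv(ped_path, sep="\t", index=False, header=False)
    if genotype_path is not None:
        grows = []
        for m in pedigree.members:
            if m.genotype is None:
                a = b = "unknown"
            else:
                a = "yes" if "A" in m.genotype else "no"
                b = "yes" if "B" in m.genotype else "no"
            grows.append({"id": m.member_id, "carries_alleleA": a, "carries_alleleB": b})
        pd.DataFrame(grows, columns=["id", "carries_alleleA", "carries_alleleB"]).to_csv(
            genotype_path, sep="\t", index=False
        )
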