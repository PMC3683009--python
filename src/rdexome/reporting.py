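"""Tabular reports: per-step filter traces, candidate tables, cohort summary."""

from __future__ import annotations

import os
from dataclasses import dataclass

import pandas as pd

from .types import CandidateGene, CascadeTrace, MutationCatalog

__all__ = ["CohortSummary", "summarize_cohort", "write_trace", "write_candidates", "report"]

_TRACE_STEPS = (
    "total",
    "coding_nonsilent",
    "panel",
    "rare",
    "candidate_variants",
)


@dataclass(frozen=True)
class CohortSummary:
    """Cohort-level diagnostic yield and mutation tallies.

    A patient counts as solved when the cascade returns at least one
    candidate gene.  Distinct mutations are deduplicated on (gene, hgvs_c);
    a mutation is novel when it does not match a catalog record of status
    known.
    """

    n_families: int
    n_solved: int
    per_gene_tally: tuple[tuple[str, int], ...]
    n_distinct_mutations: int
    n_novel_mutations: int

    def __post_init__(self) -> None:
        if not (0 <= self.n_solved <= self.n_families):
            raise ValueError("n_solved must lie in [0, n_families]")
        if self.n_novel_mutations > self.n_distinct_mutations:
            raise ValueError("novel mutations cannot exceed distinct mutations")

    @property
    def solved_fraction(self) -> float:
        return self.n_solved / self.n_families

    @property
    def solved_percent(self) -> int:
        """Diagnostic yield as a whole-number percentage."""
        return round(100 * self.solved_fraction)


def summarize_cohort(
    results: dict[str, tuple[CascadeTrace, list[CandidateGene]]],
    mutation_catalog: MutationCatalog,
) -> CohortSummary:
    """Summarize per-patient cascade results into cohort-level counts.

    ``results`` maps patient id to that patient's (trace, candidates); a
    duplicate patient id cannot occur in a dict, but an empty cohort is
    rejected.
    """
    if not results:
        raise ValueError("cannot summarize an empty cohort")
    n_families = len(results)
    n_solved = sum(1 for _, cands in results.values() if cands)

    tally: dict[str, int] = {}
    mutations: set[tuple[str, str, bool]] = set()
    for _, cands in results.values():
        for cand in cands:
            tally[cand.gene] = tally.get(cand.gene, 0) + 1
            for v, known in zip(cand.variants, cand.known_flags or [False] * len(cand.variants)):
                mutations.add((cand.gene, v.hgvs_c or f"{v.chrom}:{v.pos}{v.ref}>{v.alt}", known))
    n_distinct = len({(g, h) for g, h, _ in mutations})
    known_keys = {(g, h) for g, h, k in mutations if k}
    n_novel = len({(g, h) for g, h, _ in mutations} - known_keys)
    return CohortSummary(
        n_families=n_families,
        n_solved=n_solved,
        per_gene_tally=tuple(sorted(tally.items())),
        n_distinct_mutations=n_distinct,
        n_novel_mutations=n_novel,
    )


def write_trace(trace: CascadeTrace, path: str | os.PathLike) -> None:
    """Write the five per-step surviving counts as a two-column TSV."""
    pd.DataFrame({"step": _TRACE_STEPS, "count": trace.counts}).to_csv(
        path, sep="\t", index=False
    )


def read_trace(path: str | os.PathLike) -> CascadeTrace:
    df = pd.read_csv(path, sep="\t")
    counts = dict(zip(df["step"], df["count"]))
    return CascadeTrace(
        n_total=int(counts["total"]),
        n_coding_nonsilent=int(counts["coding_nonsilent"]),
        n_panel=int(counts["panel"]),
        n_rare=int(counts["rare"]),
        n_candidate_variants=int(counts["candidate_variants"]),
    )


def write_candidates(
    patient_id: str, candidates: list[CandidateGene], path: str | os.PathLike
) -> None:
    """Write one row per supporting variant of each candidate gene."""
    rows = []
    for cand in candidates:
        flags = cand.known_flags or [False] * len(cand.variants)
        for v, known in zip(cand.variants, flags):
            rows.append(
                {
                    "patient": patient_id,
                    "gene": cand.gene,
                    "model": cand.model,
                    "hgvs_c": v.hgvs_c or "",
                    "zygosity": v.zygosity,
                    "known_novel": "known" if known else "novel",
                }
            )
    pd.DataFrame(
        rows, columns=["patient", "gene", "model", "hgvs_c", "zygosity", "known_novel"]
    ).to_csv(path, sep="\t", index=False)


def report(
    patient_id: str,
    trace: CascadeTrace,
    candidates: list[CandidateGene],
    out_dir: str | os.PathLike,
) -> tuple[str, str]:
    """Write the trace and candidate TSVs for one patient; return their paths."""
    os.makedirs(out_dir, exist_ok=True)
    trace_path = os.path.join(os.fspath(out_dir), f"{patient_id}.trace.tsv")
    cand_path = os.path.join(os.fspath(out_dir), f"{patient_id}.candidates.tsv")
    write_trace(trace, trace_path)
    write_candidates(patient_id, candidates, cand_path)
    return trace_path, cand_path


def summary_frame(summary: CohortSummary) -> pd.DataFrame:
    rows = [
        ("n_families", summary.n_families),
        ("n_solved", summary.n_solved),
        ("solved_percent", summary.solved_percent),
        ("n_distinct_mutations", summary.n_distinct_mutations),
        ("n_novel_mutations", summary.n_novel_mutations),
    ]
    rows += [(f"candidates_in_{g}", n) for g, n in summary.per_gene_tally]
    return pd.DataFrame(rows, columns=["quantity", "value"])
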