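"""Exact Mendelian cosegregation probability by transmission-vector enumeration.

The test asks: under random Mendelian transmission from obligate-carrier
parents, what fraction of the equiprobable transmission vectors is consistent
with the observed genotypes and affection statuses of the children?  A small
probability means the observed perfect cosegregation of the candidate alleles
with disease is unlikely to be coincidental.

Autosomal recessive (AR) model: the father carries candidate allele "A" and
the mother allele "B" (phase known — the standard obligate-carrier assumption
for a family with an affected recessive child).  Each child independently
receives the mutant or the wild-type allele from each parent: 4 equiprobable
transmissions per child.  A child is affected iff it receives both mutant
alleles (compound heterozygote, or homozygote when A and B denote the same
allele).

X-linked (XL) model: the mother is an obligate carrier of mutant allele "A"
on one X; each child receives mutant or wild-type maternal X with equal
probability (2 transmissions per child).  A male is affected iff he receives
the mutant X; females are never affected (no skewed-inactivation modelling).
"""

from __future__ import annotations

import itertools
from fractions import Fraction

from .types import Pedigree, PedigreeMember, SegregationResult

__all__ = ["segregation_probability", "closed_form_ar"]


def _child_states(model: str) -> list[frozenset[str]]:
    """Possible transmitted-allele sets for one child, one per transmission."""
    if model == "AR":
        # paternal choice (A or wild) x maternal choice (B or wild)
        return [
            frozenset({"A", "B"}),
            frozenset({"A"}),
            frozenset({"B"}),
            frozenset(),
        ]
    # XL: maternal X choice only
    return [frozenset({"A"}), frozenset()]


def _consistent(member: PedigreeMember, carried: frozenset[str], model: str) -> bool:
    """Is one transmission consistent with a member's genotype and phenotype?"""
    if model == "AR":
        affected_if = carried == {"A", "B"}
    else:  # XL
        if member.sex == "male":
            affected_if = "A" in carried
        else:
            affected_if = False  # carrier females are unaffected
    if affected_if != member.affected:
        return False
    if member.genotype is not None and member.genotype != carried:
        return False
    return True


def segregation_probability(
    pedigree: Pedigree, model: str | None = None, include_index: bool = True
) -> SegregationResult:
    """Enumerate all transmission vectors and return the consistent fraction.

    Children (non-founders) are enumerated; founders are the obligate-carrier
    parents and are not random.  ``include_index`` controls whether the index
    patient (``pedigree.index_id``) contributes a consistency constraint; the
    index's transmission is always enumerated, so excluding it multiplies the
    count of consistent vectors rather than shrinking the vector space.

    Raises ValueError for pedigrees violating the model's preconditions,
    naming the offending member.
    """
    model = model or pedigree.model
    if model not in ("AR", "XL"):
        raise ValueError(f"invalid model {model!r}")

    children = pedigree.non_founders
    by_id = {m.member_id: m for m in pedigree.members}
    for child in children:
        for pid in (child.father_id, child.mother_id):
            if pid not in by_id:
                raise ValueError(f"member {child.member_id}: unknown parent {pid!r}")
            if by_id[pid].father_id is not None:
                raise ValueError(
                    f"member {child.member_id}: parent {pid} is not a founder; "
                    "the enumeration supports single-sibship pedigrees with "
                    "obligate-carrier founder parents"
                )
    if model == "XL":
        for child in children:
            if child.affected and child.sex == "female":
                raise ValueError(
                    f"member {child.member_id}: affected female is inconsistent "
                    "with the X-linked model"
                )

    states = _child_states(model)
    constrained = [
        c
        for c in children
        if include_index or c.member_id != pedigree.index_id
    ]

    n_children = len(children)
    n_vectors = len(states) ** n_children
    if n_children == 0:
        return SegregationResult(
            probability=Fraction(1), n_transmission_vectors=1, n_consistent=1, model=model
        )

    # Unconstrained children contribute a free factor; enumerate only the
    # constrained ones and scale.
    free = [c for c in children if c not in constrained]
    n_consistent = 0
    for combo in itertools.product(states, repeat=len(constrained)):
        if all(_consistent(m, carried, model) for m, carried in zip(constrained, combo)):
            n_consistent += 1
    n_consistent *= len(states) ** len(free)

    return SegregationResult(
        probability=Fraction(n_consistent, n_vectors),
        n_transmission_vectors=n_vectors,
        n_consistent=n_consistent,
        model=model,
    )


def closed_form_ar(n_affected: int, n_unaffected: int) -> Fraction:
    """Analytic AR cosegregation probability: (1/4)^affected * (3/4)^unaffected.

    Valid when every affected child is required to be compound heterozygous
    and every unaffected child merely non-compound-heterozygous (genotypes
    otherwise unconstrained).
    """
    if n_affected < 0 or n_unaffected < 0:
        raise ValueError("counts must be non-negative")
    return Fraction(1, 4) ** n_affected * Fraction(3, 4) ** n_unaffected
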