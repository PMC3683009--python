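"""Unit and property tests for the five-step filtering cascade."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rdexome import (
    CascadeConfig,
    ConsequenceClass,
    FrequencyCatalog,
    GenePanel,
    MutationCatalog,
    MutationRecord,
    PatientExome,
    VariantRecord,
    run_cascade,
    step1_coding_nonsilent,
    step2_panel,
    step3_frequency,
    step4_recessive,
    step5_annotate_known,
)

PANEL = GenePanel(
    entries=(("ABCA4", "1"), ("USH2A", "1"), ("CNGB3", "8"), ("CHM", "X"), ("RP1", "8"))
)


def make_config(catalog_entries=(), mutations=(), af_threshold=0.02):
    return CascadeConfig(
        panel=PANEL,
        frequency_catalog=FrequencyCatalog(catalog_entries),
        mutation_catalog=MutationCatalog(mutations),
        af_threshold=af_threshold,
    )


def var(chrom="1", pos=100, ref="A", alt="G", gene="ABCA4", csq="missense",
        zyg="heterozygous", **kw):
    return VariantRecord(chrom, pos, ref, alt, gene, csq, zyg, **kw)


def exome_of(variants, sex="female", pid="P1"):
    return PatientExome(pid, sex, list(variants))


class TestStep1:
    def test_one_variant_per_class_keeps_five_nonsilent(self):
        variants = [
            var(pos=i + 1, csq=c.value, gene="ABCA4")
            for i, c in enumerate(ConsequenceClass)
        ]
        out = step1_coding_nonsilent(exome_of(variants), make_config())
        kept = {v.consequence for v in out.variants}
        assert kept == {
            ConsequenceClass.MISSENSE,
            ConsequenceClass.NONSENSE,
            ConsequenceClass.FRAMESHIFT_INDEL,
            ConsequenceClass.INFRAME_INDEL,
            ConsequenceClass.SPLICE_SITE,
        }

    def test_empty_exome(self):
        assert len(step1_coding_nonsilent(exome_of([]), make_config())) == 0


class TestStep2:
    def test_set_membership(self):
        variants = [
            var(pos=1, gene="ABCA4"),
            var(pos=2, gene="FAKEGENE"),
            var(pos=3, gene="USH2A"),
        ]
        out = step2_panel(exome_of(variants), make_config())
        assert {v.gene for v in out.variants} == {"ABCA4", "USH2A"}

    def test_empty_panel(self):
        config = CascadeConfig(
            panel=GenePanel(entries=()),
            frequency_catalog=FrequencyCatalog(),
            mutation_catalog=MutationCatalog(),
        )
        assert len(step2_panel(exome_of([var()]), config)) == 0


class TestStep3:
    def test_strict_threshold(self):
        # catalogued at 0.5, exactly 0.02, 0.01, and uncatalogued:
        # only the 0.5 site is removable as a common polymorphism
        variants = [var(pos=p) for p in (10, 20, 30, 40)]
        config = make_config(
            catalog_entries=[
                (("1", 10, "A", "G"), 0.5),
                (("1", 20, "A", "G"), 0.02),
                (("1", 30, "A", "G"), 0.01),
            ]
        )
        out = step3_frequency(exome_of(variants), config)
        assert {v.pos for v in out.variants} == {20, 30, 40}

    def test_catalogued_site_without_frequency_retained(self):
        config = make_config(catalog_entries=[(("1", 10, "A", "G"), None)])
        out = step3_frequency(exome_of([var(pos=10)]), config)
        assert len(out) == 1

    def test_threshold_one_removes_nothing(self):
        variants = [var(pos=p) for p in (10, 20)]
        config = make_config(
            catalog_entries=[(("1", 10, "A", "G"), 0.99), (("1", 20, "A", "G"), 0.5)],
            af_threshold=1.0,
        )
        assert len(step3_frequency(exome_of(variants), config)) == 2


class TestStep4:
    def test_single_homozygous_autosomal(self):
        cands = step4_recessive(
            exome_of([var(zyg="homozygous_alt", hgvs_c="c.2285C>A")]),
            "female",
            make_config(),
        )
        assert [(c.gene, c.model) for c in cands] == [("ABCA4", "AR_homozygous")]

    def test_male_single_chrx_variant_is_hemizygous(self):
        cands = step4_recessive(
            exome_of([var(chrom="X", gene="CHM", zyg="homozygous_alt")], sex="male"),
            "male",
            make_config(),
        )
        assert [(c.gene, c.model) for c in cands] == [("CHM", "XL_hemizygous")]

    def test_female_single_chrx_het_not_candidate(self):
        cands = step4_recessive(
            exome_of([var(chrom="X", gene="CHM")]), "female", make_config()
        )
        assert cands == []

    def test_single_het_autosomal_not_candidate(self):
        assert step4_recessive(exome_of([var()]), "female", make_config()) == []

    def test_two_candidates_one_patient(self):
        variants = [
            var(chrom="8", pos=1, gene="CNGB3", zyg="homozygous_alt"),
            var(pos=2, gene="USH2A"),
            var(pos=3, gene="USH2A", ref="C", alt="T"),
        ]
        cands = step4_recessive(exome_of(variants), "male", make_config())
        assert [(c.gene, c.model) for c in cands] == [
            ("CNGB3", "AR_homozygous"),
            ("USH2A", "AR_compound_het"),
        ]

    def test_unknown_sex_with_chrx_raises(self):
        with pytest.raises(ValueError, match="sex"):
            step4_recessive(
                exome_of([var(chrom="X", gene="CHM")]), None, make_config()
            )

    def test_sorted_by_gene_symbol(self):
        variants = [
            var(chrom="8", pos=1, gene="RP1", zyg="homozygous_alt"),
            var(pos=2, gene="ABCA4", zyg="homozygous_alt"),
        ]
        cands = step4_recessive(exome_of(variants), "female", make_config())
        assert [c.gene for c in cands] == ["ABCA4", "RP1"]


class TestStep5:
    MUTATIONS = (
        MutationRecord("CNGB3", "c.1148delC", "p.T383Ifs*13", "known", "ref"),
        MutationRecord("CHM", "c.863dupA", "p.M289Y*18", "novel", ""),
    )

    def test_catalogued_known_mutation_flagged_known(self):
        cands = step4_recessive(
            exome_of(
                [var(chrom="8", gene="CNGB3", ref="GC", alt="G",
                     csq="frameshift_indel", zyg="homozygous_alt",
                     hgvs_c="c.1148delC")]
            ),
            "female",
            make_config(mutations=self.MUTATIONS),
        )
        annotated = step5_annotate_known(cands, make_config(mutations=self.MUTATIONS))
        assert annotated[0].known_flags == [True]

    def test_mutation_novel_at_publication_flagged_novel(self):
        cands = step4_recessive(
            exome_of([var(chrom="X", gene="CHM", ref="C", alt="CA",
                          csq="frameshift_indel", zyg="homozygous_alt",
                          hgvs_c="c.863dupA")], sex="male"),
            "male",
            make_config(mutations=self.MUTATIONS),
        )
        annotated = step5_annotate_known(cands, make_config(mutations=self.MUTATIONS))
        assert annotated[0].known_flags == [False]

    def test_missing_hgvs_flagged_novel(self, caplog):
        cands = step4_recessive(
            exome_of([var(zyg="homozygous_alt")]), "female",
            make_config(mutations=self.MUTATIONS),
        )
        annotated = step5_annotate_known(cands, make_config(mutations=self.MUTATIONS))
        assert annotated[0].known_flags == [False]

    def test_empty_candidates(self):
        assert step5_annotate_known([], make_config()) == []


class TestRunCascade:
    def test_empty_exome_trace_all_zero(self):
        trace, cands = run_cascade(exome_of([]), "female", make_config())
        assert trace.counts == (0, 0, 0, 0, 0)
        assert cands == []

    def test_hand_built_fixture_trace(self):
        """20 variants filtered by hand: 20 -> 12 -> 7 -> 5 -> 3."""
        config = make_config(
            catalog_entries=[
                (("1", 1, "A", "G"), 0.30),   # common ABCA4 -> removed at step 3
                (("1", 2, "A", "G"), 0.40),   # common USH2A -> removed at step 3
                (("8", 3, "A", "G"), 0.015),  # rare catalogued CNGB3 -> retained
            ],
            mutations=(MutationRecord("ABCA4", "c.2285C>A", "p.A762E", "known", ""),),
        )
        variants = (
            # 6 silent/noncoding: removed at step 1
            [var(pos=100 + i, csq="synonymous") for i in range(3)]
            + [var(pos=200 + i, gene="", csq="noncoding") for i in range(3)]
            # 2 silent in non-panel genes, also removed at step 1
            + [var(chrom="2", pos=300 + i, gene="OFFPANEL", csq="synonymous") for i in range(2)]
            # 5 non-silent but off panel: removed at step 2
            + [var(chrom="2", pos=400 + i, gene="OFFPANEL") for i in range(5)]
            # 2 common panel variants: removed at step 3
            + [var(pos=1), var(pos=2, gene="USH2A")]
            # 2 rare panel singles (one catalogued rare): survive step 3, not candidates
            + [var(chrom="8", pos=3, gene="CNGB3"), var(chrom="8", pos=4, gene="RP1")]
            # 1 homozygous ABCA4: candidate
            + [var(pos=5, zyg="homozygous_alt", hgvs_c="c.2285C>A")]
            # 2 het CHM variants in a female: compound het candidate
            + [var(chrom="X", pos=6, gene="CHM"), var(chrom="X", pos=7, gene="CHM")]
        )
        assert len(variants) == 20
        trace, cands = run_cascade(exome_of(variants), "female", config)
        assert trace.counts == (20, 12, 7, 5, 3)
        assert trace.candidate_genes == ("ABCA4", "CHM")
        assert [(c.gene, c.model) for c in cands] == [
            ("ABCA4", "AR_homozygous"),
            ("CHM", "AR_compound_het"),
        ]
        assert cands[0].known_flags == [True]
        assert cands[1].known_flags == [False, False]


# ---------------------------------------------------------------------------
# Property tests on random exomes
# ---------------------------------------------------------------------------

GENE_CHROM = {"ABCA4": "1", "USH2A": "1", "CNGB3": "8", "RP1": "8", "CHM": "X",
              "OFF1": "2", "OFF2": "3"}


@st.composite
def random_exomes(draw, max_size=30):
    n = draw(st.integers(0, max_size))
    variants = []
    used = set()
    for _ in range(n):
        gene = draw(st.sampled_from(sorted(GENE_CHROM)))
        pos = draw(st.integers(1, 500))
        if (gene, pos) in used:
            continue
        used.add((gene, pos))
        variants.append(
            VariantRecord(
                GENE_CHROM[gene], pos, "A", "G", gene,
                draw(st.sampled_from(list(ConsequenceClass))).value,
                draw(st.sampled_from(["heterozygous", "homozygous_alt"])),
            )
        )
    sex = draw(st.sampled_from(["male", "female"]))
    return PatientExome("PX", sex, variants)


CONFIG = make_config(
    catalog_entries=[(("1", p, "A", "G"), 0.5) for p in range(1, 250, 7)]
    + [(("8", p, "A", "G"), 0.01) for p in range(1, 250, 11)]
)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(random_exomes())
def test_steps_monotone_and_idempotent(exome):
    for step in (step1_coding_nonsilent, step2_panel, step3_frequency):
        out = step(exome, CONFIG)
        assert out.variant_set() <= exome.variant_set()
        assert step(out, CONFIG).variant_set() == out.variant_set()


@settings(max_examples=60, deadline=None, derandomize=True)
@given(random_exomes())
def test_steps_commute_pairwise(exome):
    steps = (step1_coding_nonsilent, step2_panel, step3_frequency)
    for a in steps:
        for b in steps:
            ab = b(a(exome, CONFIG), CONFIG).variant_set()
            ba = a(b(exome, CONFIG), CONFIG).variant_set()
            assert ab == ba


def brute_force_recessive(exome, sex):
    """Independent oracle: check each gene's variant group by definition."""
    genes = sorted({v.gene for v in exome.variants if v.gene})
    out = []
    for gene in genes:
        group = [v for v in exome.variants if v.gene == gene]
        homs = [v for v in group if v.zygosity == "homozygous_alt"]
        hets = [v for v in group if v.zygosity == "heterozygous"]
        if sex == "male" and all(v.chrom == "X" for v in group):
            out.append((gene, "XL_hemizygous"))
        elif homs:
            out.append((gene, "AR_homozygous"))
        elif len(hets) >= 2:
            out.append((gene, "AR_compound_het"))
    return out


@settings(max_examples=80, deadline=None, derandomize=True)
@given(random_exomes())
def test_step4_matches_brute_force_oracle(exome):
    result = step4_recessive(exome, exome.sex, CONFIG)
    assert [(c.gene, c.model) for c in result] == brute_force_recessive(exome, exome.sex)
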