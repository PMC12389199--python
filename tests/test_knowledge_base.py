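"""Guideline knowledge base: loading, validation, lookup, actionability."""

import textwrap

import pytest
import yaml

from pgxeval import (
    Gene,
    KBCoverageError,
    KBSchemaError,
    Phenotype,
    Recommendation,
    load_knowledge_base,
)
from pgxeval.alleles import call_phenotype, load_allele_definitions, parse_diplotype
from pgxeval.knowledge_base import NO_GUIDELINE, VALID_PHENOTYPES

DIPLO = {
    (Gene.CYP2C19, Phenotype.PM): "*2/*2",
    (Gene.CYP2C19, Phenotype.IM): "*1/*2",
    (Gene.CYP2C19, Phenotype.NM): "*1/*1",
    (Gene.CYP2C19, Phenotype.RM): "*1/*17",
    (Gene.CYP2C19, Phenotype.UM): "*17/*17",
    (Gene.CYP2C19, Phenotype.INDETERMINATE): "*1/*12",
    (Gene.CYP2D6, Phenotype.PM): "*4/*4",
    (Gene.CYP2D6, Phenotype.IM): "*1/*4",
    (Gene.CYP2D6, Phenotype.NM): "*1/*1",
    (Gene.CYP2D6, Phenotype.UM): "*1/*1x2",
    (Gene.CYP2D6, Phenotype.INDETERMINATE): "*1/*22",
}


@pytest.fixture(scope="module")
def calls_factory(defs):
    def make(c19=Phenotype.NM, d6=Phenotype.NM):
        return {
            gene: call_phenotype(
                parse_diplotype(DIPLO[(gene, pheno)], gene), defs
            )
            for gene, pheno in ((Gene.CYP2C19, c19), (Gene.CYP2D6, d6))
        }

    return make


class TestLoading:
    def test_shipped_kb_loads_with_full_coverage(self, kb):
        assert len(kb.medications()) == 12
        for med, genes in kb.gene_map.items():
            for gene in genes:
                for pheno in VALID_PHENOTYPES[gene]:
                    kb.rule_for(med, gene, pheno)  # must never raise

    def test_shipped_kb_gene_mapping(self, kb):
        assert set(kb.gene_map["sertraline"]) == {Gene.CYP2C19}
        assert set(kb.gene_map["risperidone"]) == {Gene.CYP2D6}
        assert set(kb.gene_map["amitriptyline"]) == {Gene.CYP2C19, Gene.CYP2D6}
        assert set(kb.gene_map["clomipramine"]) == {Gene.CYP2C19, Gene.CYP2D6}

    def test_missing_cell_raises_coverage_error(self, tmp_path):
        kb_file = tmp_path / "kb.yaml"
        kb_file.write_text(
            textwrap.dedent(
                """
                version: "test"
                medication_gene_map:
                  sertraline: {CYP2C19: primary}
                rules:
                  - {medication: sertraline, gene: CYP2C19, phenotype: NM,
                     recommendation: standard, source: CPIC}
                """
            )
        )
        with pytest.raises(KBCoverageError, match=r"sertraline, CYP2C19, PM"):
            load_knowledge_base(kb_file)

    def test_rm_for_cyp2d6_is_schema_error(self, tmp_path):
        kb_file = tmp_path / "kb.yaml"
        kb_file.write_text(
            textwrap.dedent(
                """
                version: "test"
                medication_gene_map:
                  risperidone: {CYP2D6: primary}
                rules:
                  - {medication: risperidone, gene: CYP2D6, phenotype: RM,
                     recommendation: standard, source: DPWG}
                """
            )
        )
        with pytest.raises(KBSchemaError):
            load_knowledge_base(kb_file)

    def test_standard_with_dose_adjust_is_schema_error(self, tmp_path):
        kb_file = tmp_path / "kb.yaml"
        kb_file.write_text(
            textwrap.dedent(
                """
                version: "test"
                medication_gene_map:
                  risperidone: {CYP2D6: primary}
                rules:
                  - {medication: risperidone, gene: CYP2D6, phenotype: default,
                     recommendation: standard, dose_adjust_percent: 50, source: DPWG}
                """
            )
        )
        with pytest.raises(KBSchemaError):
            load_knowledge_base(kb_file)

    def test_default_entry_provides_coverage(self, tmp_path):
        kb_file = tmp_path / "kb.yaml"
        kb_file.write_text(
            textwrap.dedent(
                """
                version: "test"
                medication_gene_map:
                  risperidone: {CYP2D6: primary}
                rules:
                  - {medication: risperidone, gene: CYP2D6, phenotype: default,
                     recommendation: standard, source: DPWG}
                """
            )
        )
        kb = load_knowledge_base(kb_file)
        assert (
            kb.rule_for("risperidone", Gene.CYP2D6, Phenotype.PM).recommendation
            is Recommendation.STANDARD
        )


class TestLookup:
    def test_risperidone_pm_dose_reduction(self, kb, calls_factory):
        result = kb.lookup("risperidone", calls_factory(d6=Phenotype.PM))
        (rule,) = result.rules
        assert rule.dose_adjust_percent == 67
        assert rule.adr_risk

    def test_sertraline_pm_rule(self, kb, calls_factory):
        result = kb.lookup("sertraline", calls_factory(c19=Phenotype.PM))
        (rule,) = result.rules
        assert rule.dose_adjust_percent == 50
        assert rule.recommendation is Recommendation.DOSE_ADJUST_OR_ALTERNATIVE

    def test_aripiprazole_pm_range(self, kb, calls_factory):
        result = kb.lookup("aripiprazole", calls_factory(d6=Phenotype.PM))
        (rule,) = result.rules
        assert rule.dose_adjust_percent == (25, 32)

    def test_no_guideline_medication(self, kb, calls_factory):
        result = kb.lookup("methylphenidate", calls_factory())
        assert result.no_guideline
        assert kb.actionable("methylphenidate", calls_factory()) == (False, NO_GUIDELINE)

    def test_brand_name_synonym_resolves(self, kb, calls_factory):
        result = kb.lookup("Zoloft", calls_factory(c19=Phenotype.PM))
        assert result.medication == "sertraline"
        assert result.rules[0].dose_adjust_percent == 50

    def test_indeterminate_phenotype_yields_sentinel(self, kb, calls_factory):
        result = kb.lookup(
            "sertraline", calls_factory(c19=Phenotype.INDETERMINATE)
        )
        assert not result.no_guideline
        assert result.hits[0].rule is None
        assert kb.actionable(
            "sertraline", calls_factory(c19=Phenotype.INDETERMINATE)
        ) == (False, "not_evaluable")

    def test_dual_gene_medication_returns_one_rule_per_gene(self, kb, calls_factory):
        result = kb.lookup("amitriptyline", calls_factory())
        assert {h.gene for h in result.hits} == {Gene.CYP2C19, Gene.CYP2D6}


class TestActionability:
    def test_aripiprazole_pm_actionable(self, kb, calls_factory):
        actionable, rec = kb.actionable("aripiprazole", calls_factory(d6=Phenotype.PM))
        assert actionable and rec == "dose_adjust"

    def test_fluvoxamine_nm_standard(self, kb, calls_factory):
        assert kb.actionable("fluvoxamine", calls_factory()) == (False, "standard")

    def test_all_normal_dual_gene_standard(self, kb, calls_factory):
        assert kb.actionable("amitriptyline", calls_factory()) == (False, "standard")

    def test_dual_gene_either_gene_triggers(self, kb, calls_factory):
        actionable, _ = kb.actionable(
            "amitriptyline", calls_factory(d6=Phenotype.PM)
        )
        assert actionable
        actionable, _ = kb.actionable(
            "amitriptyline", calls_factory(c19=Phenotype.UM)
        )
        assert actionable


class TestInvariants:
    def test_nm_neutrality(self, kb, calls_factory):
        """All-normal phenotypes get standard dosing and no risk flags for
        every medication in the shipped KB."""
        calls = calls_factory()
        for med in kb.medications():
            result = kb.lookup(med, calls)
            for hit in result.hits:
                assert hit.rule.recommendation is Recommendation.STANDARD
                assert not hit.rule.adr_risk
                assert not hit.rule.inefficacy_risk

    def test_risk_recommendation_coherence(self, kb):
        """Every risk-flagged cell in the shipped KB has a non-standard
        recommendation (no unexplained standard+risk combinations)."""
        assert kb.coherence_warnings() == []

    def test_lookup_total_over_all_phenotypes(self, kb, calls_factory):
        for med in kb.medications():
            genes = set(kb.gene_map[med])
            c19_options = (
                VALID_PHENOTYPES[Gene.CYP2C19] if Gene.CYP2C19 in genes else [Phenotype.NM]
            )
            d6_options = (
                VALID_PHENOTYPES[Gene.CYP2D6] if Gene.CYP2D6 in genes else [Phenotype.NM]
            )
            for c19 in c19_options:
                for d6 in d6_options:
                    kb.lookup(med, calls_factory(c19=c19, d6=d6))  # never raises
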