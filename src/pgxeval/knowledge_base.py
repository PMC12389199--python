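"""CPIC/DPWG guideline knowledge base: loading, validation and lookup.

The knowledge base is a versioned YAML data file (not code) mapping each
PGx-guided medication to the gene(s) that drive its dosing guidance and,
for every (medication, gene, phenotype) cell, a dosing recommendation plus
explicit ADR-risk and inefficacy-risk flags. Guideline content drifts, so
the file can be re-curated without touching the rule engine.

Validation is structural (pydantic models, exported as JSON Schema in
``data/kb.schema.json``) plus semantic: complete phenotype coverage for
every mapped gene, ``RM`` restricted to CYP2C19, and a coherence audit
requiring every risk-flagged cell to carry a non-standard recommendation
unless a note explains the exception.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Literal, Mapping, Optional, Sequence, Union

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from .alleles import Gene, Phenotype, PhenotypeCall

__all__ = [
    "Recommendation",
    "GuidelineRule",
    "GeneRuleHit",
    "LookupResult",
    "KnowledgeBase",
    "KBError",
    "KBSchemaError",
    "KBCoverageError",
    "load_knowledge_base",
    "default_kb_path",
    "NO_GUIDELINE",
]


class Recommendation(str, Enum):
    STANDARD = "standard"
    DOSE_ADJUST = "dose_adjust"
    DOSE_ADJUST_OR_ALTERNATIVE = "dose_adjust_or_alternative"
    ALTERNATIVE = "alternative"


#: Sentinel recommendation string returned for medications without a guideline.
NO_GUIDELINE = "no_guideline"

#: Sentinel for trials whose phenotype cannot be evaluated.
NOT_EVALUABLE = "not_evaluable"

VALID_PHENOTYPES: dict[Gene, tuple[Phenotype, ...]] = {
    Gene.CYP2C19: (Phenotype.PM, Phenotype.IM, Phenotype.NM, Phenotype.RM, Phenotype.UM),
    Gene.CYP2D6: (Phenotype.PM, Phenotype.IM, Phenotype.NM, Phenotype.UM),
}


class KBError(ValueError):
    """Base class for knowledge-base load/validation failures."""


class KBSchemaError(KBError):
    """The KB file violates the schema (shape, enum values, constraints)."""


class KBCoverageError(KBError):
    """A (medication, gene, phenotype) cell has no rule and no default."""

    def __init__(self, missing: Sequence[tuple[str, str, str]]):
        self.missing = list(missing)
        listing = ", ".join(f"({m}, {g}, {p})" for m, g, p in self.missing)
        super().__init__(f"knowledge base has coverage gaps: {listing}")


class GuidelineRule(BaseModel):
    """One guideline cell: medication x gene x phenotype."""

    model_config = ConfigDict(frozen=True, extra="forbid")

    medication: str
    gene: Gene
    phenotype: Union[Phenotype, Literal["default"]]
    recommendation: Recommendation
    dose_adjust_percent: Optional[Union[float, tuple[float, float]]] = None
    adr_risk: bool = False
    inefficacy_risk: bool = False
    source: Literal["CPIC", "DPWG"]
    note: Optional[str] = None

    @model_validator(mode="after")
    def _check(self) -> "GuidelineRule":
        if isinstance(self.phenotype, Phenotype):
            if self.phenotype is Phenotype.INDETERMINATE:
                raise ValueError("rules may not target Indeterminate phenotypes")
            if self.phenotype not in VALID_PHENOTYPES[self.gene]:
                raise ValueError(
                    f"phenotype {self.phenotype.value} is not defined for "
                    f"{self.gene.value} (RM exists for CYP2C19 only)"
                )
        if self.recommendation is Recommendation.STANDARD:
            if self.dose_adjust_percent is not None:
                raise ValueError(
                    "standard recommendation must not carry dose_adjust_percent"
                )
            if (self.adr_risk or self.inefficacy_risk) and not self.note:
                raise ValueError(
                    "risk flag with a standard recommendation requires an "
                    "explanatory note"
                )
        if isinstance(self.dose_adjust_percent, tuple):
            lo, hi = self.dose_adjust_percent
            if lo > hi:
                raise ValueError("dose_adjust_percent range must be [low, high]")
        return self


class _KBFile(BaseModel):
    """Top-level shape of the YAML knowledge-base file."""

    model_config = ConfigDict(extra="forbid")

    version: str
    sources: list[str] = Field(default_factory=list)
    medication_gene_map: dict[str, dict[Gene, Literal["primary", "dual"]]]
    synonyms: dict[str, str] = Field(default_factory=dict)
    rules: list[GuidelineRule]


@dataclass(frozen=True)
class GeneRuleHit:
    """Lookup result for one mapped gene of a medication.

    ``rule`` is ``None`` when the phenotype is Indeterminate (the sentinel
    not-evaluable case).
    """

    gene: Gene
    phenotype: Phenotype
    rule: Optional[GuidelineRule]


@dataclass(frozen=True)
class LookupResult:
    medication: str
    no_guideline: bool
    hits: tuple[GeneRuleHit, ...] = ()

    @property
    def rules(self) -> list[GuidelineRule]:
        return [h.rule for h in self.hits if h.rule is not None]


class KnowledgeBase:
    """Queryable guideline rule set for the PGx-guided medications."""

    def __init__(self, kb: _KBFile):
        self.version = kb.version
        self.sources = list(kb.sources)
        self.gene_map: dict[str, dict[Gene, str]] = {
            med: dict(genes) for med, genes in kb.medication_gene_map.items()
        }
        self.synonyms = {k.lower(): v.lower() for k, v in kb.synonyms.items()}
        self._rules: dict[tuple[str, Gene, str], GuidelineRule] = {}
        for rule in kb.rules:
            pheno_key = (
                rule.phenotype.value
                if isinstance(rule.phenotype, Phenotype)
                else rule.phenotype
            )
            key = (rule.medication.lower(), rule.gene, pheno_key)
            if key in self._rules:
                raise KBSchemaError(f"duplicate rule for {key}")
            self._rules[key] = rule
        self._validate()

    # -- validation -------------------------------------------------------

    def _validate(self) -> None:
        for med, _, _ in self._rules:
            if med not in self.gene_map:
                raise KBSchemaError(
                    f"rule for {med!r} but medication missing from medication_gene_map"
                )
        missing: list[tuple[str, str, str]] = []
        for med, genes in self.gene_map.items():
            for gene in genes:
                for pheno in VALID_PHENOTYPES[gene]:
                    if (med, gene, pheno.value) not in self._rules and (
                        med,
                        gene,
                        "default",
                    ) not in self._rules:
                        missing.append((med, gene.value, pheno.value))
        if missing:
            raise KBCoverageError(missing)

    def coherence_warnings(self) -> list[str]:
        """Audit: risk-flagged cells should have non-standard recommendations
        unless a note explains why (returns warnings; shipped KB has none
        without notes by schema)."""
        warnings = []
        for rule in self._rules.values():
            if (
                (rule.adr_risk or rule.inefficacy_risk)
                and rule.recommendation is Recommendation.STANDARD
            ):
                warnings.append(
                    f"{rule.medication}/{rule.gene.value}/{rule.phenotype}: risk flag "
                    f"with standard recommendation (note: {rule.note})"
                )
        return warnings

    # -- queries ----------------------------------------------------------

    def normalize_medication(self, name: str) -> str:
        name = name.strip().lower()
        return self.synonyms.get(name, name)

    def medications(self) -> list[str]:
        return sorted(self.gene_map)

    def has_guideline(self, medication: str) -> bool:
        return self.normalize_medication(medication) in self.gene_map

    def rule_for(
        self, medication: str, gene: Gene, phenotype: Phenotype
    ) -> GuidelineRule:
        med = self.normalize_medication(medication)
        rule = self._rules.get((med, gene, phenotype.value)) or self._rules.get(
            (med, gene, "default")
        )
        if rule is None:
            raise KeyError(f"no rule for ({med}, {gene.value}, {phenotype.value})")
        return rule

    def lookup(
        self, medication: str, phenotype_calls: Mapping[Gene, PhenotypeCall]
    ) -> LookupResult:
        """Return the matching rule for each gene mapped to the medication.

        Medications without a guideline yield ``no_guideline=True`` (a
        signal, not an exception); an Indeterminate phenotype yields a hit
        with ``rule=None``.
        """
        med = self.normalize_medication(medication)
        if med not in self.gene_map:
            return LookupResult(medication=med, no_guideline=True)
        hits = []
        for gene in sorted(self.gene_map[med], key=lambda g: g.value):
            if gene not in phenotype_calls:
                raise KeyError(
                    f"{med} requires a {gene.value} phenotype call, none provided"
                )
            call = phenotype_calls[gene]
            if call.phenotype is Phenotype.INDETERMINATE:
                hits.append(GeneRuleHit(gene=gene, phenotype=call.phenotype, rule=None))
            else:
                hits.append(
                    GeneRuleHit(
                        gene=gene,
                        phenotype=call.phenotype,
                        rule=self.rule_for(med, gene, call.phenotype),
                    )
                )
        return LookupResult(medication=med, no_guideline=False, hits=tuple(hits))

    def actionable(
        self, medication: str, phenotype_calls: Mapping[Gene, PhenotypeCall]
    ) -> tuple[bool, str]:
        """Whether guidelines recommend deviating from standard therapy.

        Returns ``(True, recommendation)`` if any mapped gene's rule is
        non-standard (either-gene logic for dual-gene medications);
        ``(False, "standard")`` otherwise. Medications without a guideline
        return ``(False, "no_guideline")`` and all-Indeterminate phenotypes
        ``(False, "not_evaluable")``.
        """
        result = self.lookup(medication, phenotype_calls)
        if result.no_guideline:
            return False, NO_GUIDELINE
        for hit in result.hits:
            if hit.rule is not None and hit.rule.recommendation is not Recommendation.STANDARD:
                return True, hit.rule.recommendation.value
        if all(h.rule is None for h in result.hits):
            return False, NOT_EVALUABLE
        return False, Recommendation.STANDARD.value


def default_kb_path() -> Path:
    return Path(str(resources.files("pgxeval.data").joinpath("guidelines.yaml")))


def load_knowledge_base(path: str | Path | None = None) -> KnowledgeBase:
    """Load and validate a knowledge-base YAML file.

    Raises :class:`KBSchemaError` on structural violations (with the
    pydantic error locations) and :class:`KBCoverageError` when a
    (medication, gene, phenotype) cell is unresolvable.
    """
    if path is None:
        raw = resources.files("pgxeval.data").joinpath("guidelines.yaml").read_text(
            encoding="utf-8"
        )
    else:
        raw = Path(path).read_text(encoding="utf-8")
    data = yaml.safe_load(raw)
    try:
        kb_file = _KBFile.model_validate(data)
    except ValidationError as exc:
        locations = "; ".join(
            "/" + "/".join(str(p) for p in err["loc"]) + ": " + err["msg"]
            for err in exc.errors()
        )
        raise KBSchemaError(f"knowledge base schema violation: {locations}") from exc
    return KnowledgeBase(kb_file)


def export_json_schema() -> dict:
    """JSON Schema for the KB file format (generated from the models)."""
    return _KBFile.model_json_schema()
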