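"""Medication trials and phenotype-consistency adjudication.

A :class:`MedicationTrial` records one participant's experience with one
medication (ADR, inefficacy, both, neither, or unknown). Each reported
event is adjudicated against the guideline knowledge base: an ADR is
*consistent* with the participant's metabolizer phenotypes exactly when a
mapped gene's rule carries an explicit ADR-risk flag for the assigned
phenotype, and likewise for inefficacy with the inefficacy-risk flag.
Medications without a guideline, or Indeterminate phenotypes, produce
*not_evaluable* verdicts: they stay in event denominators but can never be
counted as consistent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Optional

from .alleles import Gene, Phenotype, PhenotypeCall
from .knowledge_base import KnowledgeBase

__all__ = [
    "Response",
    "EventType",
    "Verdict",
    "MedicationTrial",
    "ConsistencyVerdict",
    "explode_events",
    "adjudicate",
    "adjudicate_trials",
]


class Response(str, Enum):
    NONE = "none"
    ADR = "adr"
    INEFFICACY = "inefficacy"
    ADR_AND_INEFFICACY = "adr_and_inefficacy"
    UNKNOWN = "unknown"


class EventType(str, Enum):
    ADR = "adr"
    INEFFICACY = "inefficacy"


class Verdict(str, Enum):
    CONSISTENT = "consistent"
    INCONSISTENT = "inconsistent"
    NOT_EVALUABLE = "not_evaluable"


@dataclass(frozen=True)
class MedicationTrial:
    """One participant's treatment course with one medication.

    ``adr_and_inefficacy`` means both outcomes occurred during the
    treatment course for that single medication.
    """

    participant_id: str
    medication: str
    response: Response = Response.NONE
    adr_description: Optional[str] = None
    dose_info: Optional[str] = None


@dataclass(frozen=True)
class ConsistencyVerdict:
    """Adjudicated relation between one reported event and the phenotypes.

    ``gene_basis`` names the gene/phenotype whose guideline risk flag fired
    (present exactly for consistent verdicts); ``reason`` distinguishes the
    two not-evaluable causes (``no_guideline`` vs ``indeterminate``).
    ``guideline_medication`` marks whether the medication is in the KB map,
    which downstream analytics use to form denominators.
    """

    participant_id: str
    medication: str
    event_type: EventType
    verdict: Verdict
    gene_basis: Optional[tuple[Gene, Phenotype]] = None
    rationale: str = ""
    reason: Optional[str] = None
    guideline_medication: bool = True

    def __post_init__(self) -> None:
        if (self.verdict is Verdict.CONSISTENT) != (self.gene_basis is not None):
            raise ValueError("gene_basis must be present iff verdict is consistent")


def explode_events(trial: MedicationTrial) -> list[EventType]:
    """Expand a trial's response into individual adjudicable events.

    ``adr_and_inefficacy`` yields one event of each type (a single
    medication course with both outcomes contributes to both denominators);
    ``none``/``unknown`` yield nothing.
    """
    return {
        Response.NONE: [],
        Response.UNKNOWN: [],
        Response.ADR: [EventType.ADR],
        Response.INEFFICACY: [EventType.INEFFICACY],
        Response.ADR_AND_INEFFICACY: [EventType.ADR, EventType.INEFFICACY],
    }[trial.response]


def adjudicate(
    trial: MedicationTrial,
    event_type: EventType,
    phenotype_calls: Mapping[Gene, PhenotypeCall],
    kb: KnowledgeBase,
) -> ConsistencyVerdict:
    """Adjudicate one event against the knowledge base.

    Either-gene logic applies for dual-gene medications: the event is
    consistent if any mapped gene's rule asserts the corresponding risk for
    the participant's phenotype. If no rule fires but a mapped gene's
    phenotype is Indeterminate, the verdict is not_evaluable (the risk
    cannot be excluded); otherwise inconsistent.
    """
    result = kb.lookup(trial.medication, phenotype_calls)
    if result.no_guideline:
        return ConsistencyVerdict(
            participant_id=trial.participant_id,
            medication=result.medication,
            event_type=event_type,
            verdict=Verdict.NOT_EVALUABLE,
            rationale="no CPIC/DPWG guideline for this medication",
            reason="no_guideline",
            guideline_medication=False,
        )
    for hit in result.hits:
        if hit.rule is None:
            continue
        flag = hit.rule.adr_risk if event_type is EventType.ADR else hit.rule.inefficacy_risk
        if flag:
            return ConsistencyVerdict(
                participant_id=trial.participant_id,
                medication=result.medication,
                event_type=event_type,
                verdict=Verdict.CONSISTENT,
                gene_basis=(hit.gene, hit.phenotype),
                rationale=(
                    f"{hit.rule.source} rule {result.medication}/{hit.gene.value}/"
                    f"{hit.phenotype.value}: {event_type.value} risk asserted"
                ),
            )
    if any(h.rule is None for h in result.hits):
        return ConsistencyVerdict(
            participant_id=trial.participant_id,
            medication=result.medication,
            event_type=event_type,
            verdict=Verdict.NOT_EVALUABLE,
            rationale="indeterminate metabolizer phenotype for a mapped gene",
            reason="indeterminate",
        )
    basis = "; ".join(
        f"{h.gene.value} {h.phenotype.value}" for h in result.hits if h.rule is not None
    )
    return ConsistencyVerdict(
        participant_id=trial.participant_id,
        medication=result.medication,
        event_type=event_type,
        verdict=Verdict.INCONSISTENT,
        rationale=f"no {event_type.value}-risk flag for {basis}",
    )


def adjudicate_trials(
    trials: Iterable[MedicationTrial],
    phenotypes: Mapping[str, Mapping[Gene, PhenotypeCall]],
    kb: KnowledgeBase,
) -> list[ConsistencyVerdict]:
    """Explode and adjudicate every event of every trial.

    ``phenotypes`` maps participant_id to per-gene phenotype calls.
    Deterministic and order-independent: verdicts depend only on each
    trial's own fields and the participant's phenotypes.
    """
    verdicts = []
    for trial in trials:
        calls = phenotypes[trial.participant_id]
        for event_type in explode_events(trial):
            verdicts.append(adjudicate(trial, event_type, calls, kb))
    return verdicts
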