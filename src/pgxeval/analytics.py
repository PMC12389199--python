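"""Cohort-level summary surfaces.

Four views over a translated, adjudicated cohort:

* phenotype distribution — per-gene metabolizer counts plus the joint
  CYP2C19 x CYP2D6 combination (UpSet-style) counts;
* actionability — the fraction of PGx-guided-medication users whose test
  result would have changed dosing or drug selection preemptively;
* medication-centered concordance — per-medication and overall fractions
  of ADR and inefficacy events consistent with phenotype;
* participant-centered utility — how many participants had at least one
  event explained, all guideline-medication events explained, and all
  psychotropic events (including medications without guidelines) explained.

Percentages are rounded half-up to one decimal so report output is
bit-reproducible.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Optional, Sequence

from .alleles import Gene, Phenotype, PhenotypeCall, altered
from .knowledge_base import KnowledgeBase
from .response import ConsistencyVerdict, EventType, MedicationTrial, Verdict

__all__ = [
    "round_half_up",
    "phenotype_distribution",
    "actionability_summary",
    "medication_centered_summary",
    "participant_centered_summary",
    "summarize_cohort",
]


def round_half_up(value: float, ndigits: int = 1) -> float:
    """Decimal round-half-up (0.05 at the cut always rounds away from zero)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def _percent(numerator: int, denominator: int) -> Optional[float]:
    """100*n/d rounded half-up to 1 decimal; None when the denominator is 0."""
    if denominator == 0:
        return None
    return round_half_up(100.0 * numerator / denominator)


def phenotype_distribution(
    phenotypes: Mapping[str, Mapping[Gene, PhenotypeCall]],
) -> dict:
    """Per-gene phenotype counts and joint combination counts.

    The combination counts are the cells of the CYP2C19 x CYP2D6 table
    (the UpSet intersections); their marginals equal the per-gene counts
    and they sum to the cohort size.
    """
    per_gene: dict[str, Counter] = {g.value: Counter() for g in Gene}
    combinations: Counter = Counter()
    n_altered_any = 0
    for calls in phenotypes.values():
        for gene in Gene:
            per_gene[gene.value][calls[gene].phenotype.value] += 1
        combinations[
            (calls[Gene.CYP2C19].phenotype.value, calls[Gene.CYP2D6].phenotype.value)
        ] += 1
        if any(altered(calls[g]) for g in Gene):
            n_altered_any += 1
    n = len(phenotypes)
    return {
        "n_participants": n,
        "per_gene": {g: dict(c) for g, c in per_gene.items()},
        "combinations": {f"{c19}|{d6}": k for (c19, d6), k in sorted(combinations.items())},
        "n_altered_any": n_altered_any,
        "percent_altered_any": _percent(n_altered_any, n),
    }


def actionability_summary(
    phenotypes: Mapping[str, Mapping[Gene, PhenotypeCall]],
    trials: Sequence[MedicationTrial],
    kb: KnowledgeBase,
) -> dict:
    """Fraction of PGx-guided-medication users with an actionable result.

    The denominator is participants with at least one trial of a medication
    that has a guideline; the numerator is those for whom at least one such
    trial resolves to a non-standard recommendation. Also returns the
    per-medication recommendation breakdown among that medication's users.
    """
    users: set[str] = set()
    actionable_participants: set[str] = set()
    per_medication: dict[str, Counter] = defaultdict(Counter)
    seen: set[tuple[str, str]] = set()
    for trial in trials:
        med = kb.normalize_medication(trial.medication)
        if not kb.has_guideline(med):
            continue
        key = (trial.participant_id, med)
        if key in seen:
            continue
        seen.add(key)
        users.add(trial.participant_id)
        is_actionable, recommendation = kb.actionable(med, phenotypes[trial.participant_id])
        per_medication[med][recommendation] += 1
        if is_actionable:
            actionable_participants.add(trial.participant_id)
    return {
        "n_pgx_med_users": len(users),
        "n_actionable_participants": len(actionable_participants),
        "percent_actionable": _percent(len(actionable_participants), len(users)),
        "per_medication": {m: dict(c) for m, c in sorted(per_medication.items())},
    }


def medication_centered_summary(verdicts: Sequence[ConsistencyVerdict]) -> dict:
    """Consistent-event fractions per medication and overall, by event type.

    Denominators cover events on guideline medications only (not-evaluable
    verdicts for guideline medications stay in denominators; events on
    medications without a guideline are excluded). Fractions are absent
    (None) when a denominator is zero.
    """
    out: dict = {}
    for event_type in EventType:
        evs = [
            v
            for v in verdicts
            if v.event_type is event_type and v.guideline_medication
        ]
        per_med: dict[str, dict] = {}
        for med in sorted({v.medication for v in evs}):
            med_evs = [v for v in evs if v.medication == med]
            n_cons = sum(v.verdict is Verdict.CONSISTENT for v in med_evs)
            per_med[med] = {
                "events": len(med_evs),
                "consistent": n_cons,
                "percent_consistent": _percent(n_cons, len(med_evs)),
            }
        n_cons = sum(v.verdict is Verdict.CONSISTENT for v in evs)
        out[event_type.value] = {
            "events": len(evs),
            "consistent": n_cons,
            "percent_consistent": _percent(n_cons, len(evs)),
            "per_medication": per_med,
        }
    return out


def participant_centered_summary(verdicts: Sequence[ConsistencyVerdict]) -> dict:
    """Per-participant explained-event tallies.

    The denominator is participants with at least one ADR/inefficacy event
    on a guideline medication. Three nested numerators: at least one event
    consistent; every guideline-medication event consistent; every event
    including those on medications without guidelines consistent (the last
    is the strictest view — non-guideline events can never be explained by
    metabolizer phenotypes).
    """
    guideline_events: dict[str, list[ConsistencyVerdict]] = defaultdict(list)
    all_events: dict[str, list[ConsistencyVerdict]] = defaultdict(list)
    for v in verdicts:
        all_events[v.participant_id].append(v)
        if v.guideline_medication:
            guideline_events[v.participant_id].append(v)
    denominator = sorted(guideline_events)
    at_least_one = [
        p
        for p in denominator
        if any(v.verdict is Verdict.CONSISTENT for v in guideline_events[p])
    ]
    fully_guideline = [
        p
        for p in denominator
        if all(v.verdict is Verdict.CONSISTENT for v in guideline_events[p])
    ]
    fully_all = [
        p
        for p in denominator
        if all(v.verdict is Verdict.CONSISTENT for v in all_events[p])
    ]
    n = len(denominator)
    per_participant = {
        p: {
            "events": len(all_events[p]),
            "guideline_events": len(guideline_events[p]),
            "consistent": sum(
                v.verdict is Verdict.CONSISTENT for v in guideline_events[p]
            ),
        }
        for p in denominator
    }
    return {
        "n_event_participants": n,
        "n_at_least_one_explained": len(at_least_one),
        "percent_at_least_one_explained": _percent(len(at_least_one), n),
        "n_fully_explained_guideline": len(fully_guideline),
        "n_fully_explained_all_medications": len(fully_all),
        "per_participant": per_participant,
    }


def summarize_cohort(
    phenotypes: Mapping[str, Mapping[Gene, PhenotypeCall]],
    trials: Sequence[MedicationTrial],
    verdicts: Sequence[ConsistencyVerdict],
    kb: KnowledgeBase,
) -> dict:
    """Machine-readable summary of all four analytic surfaces."""
    return {
        "phenotype_distribution": phenotype_distribution(phenotypes),
        "actionability": actionability_summary(phenotypes, trials, kb),
        "medication_centered": medication_centered_summary(verdicts),
        "participant_centered": participant_centered_summary(verdicts),
    }
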