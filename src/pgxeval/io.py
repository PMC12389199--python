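"""Cohort file I/O and end-to-end pipeline orchestration.

A cohort is two CSV tables: a participant table (one row per participant,
with the CYP2C19 and CYP2D6 diplotype strings) and a long-format trial
table (one row per participant-medication course). The pipeline translates
diplotypes, adjudicates every reported event against the knowledge base
and writes a verdict TSV plus a deterministic summary JSON.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd

from .alleles import (
    AlleleTable,
    DEFAULT_BINS,
    DiplotypeParseError,
    Gene,
    PhenotypeBinConfig,
    PhenotypeCall,
    call_phenotype,
    load_allele_definitions,
    parse_diplotype,
)
from .analytics import summarize_cohort
from .knowledge_base import KnowledgeBase
from .response import (
    ConsistencyVerdict,
    MedicationTrial,
    Response,
    adjudicate_trials,
)

__all__ = [
    "Cohort",
    "CohortSchemaError",
    "CohortIntegrityError",
    "read_cohort",
    "write_cohort",
    "translate_cohort",
    "run_pipeline",
    "PipelineResult",
    "write_verdicts",
    "write_summary_json",
]

logger = logging.getLogger("pgxeval")

PARTICIPANT_COLUMNS = [
    "participant_id",
    "age_years",
    "sex",
    "diagnoses",
    "cyp2c19_diplotype",
    "cyp2d6_diplotype",
]
TRIAL_COLUMNS = ["participant_id", "medication", "response", "adr_description", "dose_info"]


class CohortSchemaError(ValueError):
    """A required column is missing or a value is outside its enum."""


class CohortIntegrityError(ValueError):
    """Cross-table referential or uniqueness violation."""


@dataclass
class Cohort:
    """In-memory cohort: participant table plus long-format trials."""

    participants: pd.DataFrame
    trials: list[MedicationTrial] = field(default_factory=list)

    def __post_init__(self) -> None:
        missing = [c for c in PARTICIPANT_COLUMNS if c not in self.participants.columns]
        if missing:
            raise CohortSchemaError(f"participant table missing column(s): {missing}")
        ids = self.participants["participant_id"]
        dupes = ids[ids.duplicated()].tolist()
        if dupes:
            raise CohortIntegrityError(f"duplicate participant_id(s): {sorted(set(dupes))}")
        known = set(ids)
        orphans = sorted({t.participant_id for t in self.trials} - known)
        if orphans:
            raise CohortIntegrityError(
                f"trial rows reference unknown participant_id(s): {orphans}"
            )

    def __len__(self) -> int:
        return len(self.participants)

    def trials_for(self, participant_id: str) -> list[MedicationTrial]:
        return [t for t in self.trials if t.participant_id == participant_id]


def read_cohort(participants_path: str | Path, trials_path: str | Path) -> Cohort:
    """Load and validate a cohort from its two CSV files.

    Raises :class:`CohortSchemaError` for missing columns or bad enum
    values, :class:`CohortIntegrityError` for duplicate or orphan
    participant ids, and :class:`DiplotypeParseError` (annotated with the
    participant id) for unparseable diplotype strings.
    """
    participants = pd.read_csv(participants_path, dtype=str).fillna("")
    trials_df = pd.read_csv(trials_path, dtype=str).fillna("")
    missing = [c for c in TRIAL_COLUMNS if c not in trials_df.columns]
    if missing:
        raise CohortSchemaError(f"trial table missing column(s): {missing}")
    trials = []
    for row in trials_df.itertuples(index=False):
        try:
            response = Response(row.response)
        except ValueError as exc:
            raise CohortSchemaError(
                f"invalid response {row.response!r} for participant "
                f"{row.participant_id}"
            ) from exc
        trials.append(
            MedicationTrial(
                participant_id=row.participant_id,
                medication=row.medication,
                response=response,
                adr_description=row.adr_description or None,
                dose_info=row.dose_info or None,
            )
        )
    cohort = Cohort(participants=participants, trials=trials)
    # fail fast on malformed diplotypes, naming the offending row
    for row in participants.itertuples(index=False):
        for gene, column in (
            (Gene.CYP2C19, "cyp2c19_diplotype"),
            (Gene.CYP2D6, "cyp2d6_diplotype"),
        ):
            try:
                parse_diplotype(getattr(row, column), gene)
            except DiplotypeParseError as exc:
                raise DiplotypeParseError(
                    f"participant {row.participant_id}: {exc}"
                ) from exc
    return cohort


def write_cohort(
    cohort: Cohort, participants_path: str | Path, trials_path: str | Path
) -> None:
    """Write the two cohort CSVs (diplotypes in canonical form)."""
    df = cohort.participants.copy()
    for gene, column in (
        (Gene.CYP2C19, "cyp2c19_diplotype"),
        (Gene.CYP2D6, "cyp2d6_diplotype"),
    ):
        df[column] = [str(parse_diplotype(v, gene)) for v in df[column]]
    df.to_csv(participants_path, index=False, lineterminator="\n")
    pd.DataFrame(
        [
            {
                "participant_id": t.participant_id,
                "medication": t.medication,
                "response": t.response.value,
                "adr_description": t.adr_description or "",
                "dose_info": t.dose_info or "",
            }
            for t in cohort.trials
        ],
        columns=TRIAL_COLUMNS,
    ).to_csv(trials_path, index=False, lineterminator="\n")


def translate_cohort(
    cohort: Cohort,
    defs: AlleleTable | None = None,
    bins: PhenotypeBinConfig = DEFAULT_BINS,
) -> dict[str, dict[Gene, PhenotypeCall]]:
    """Translate every participant's diplotypes to phenotype calls."""
    defs = defs if defs is not None else load_allele_definitions()
    phenotypes: dict[str, dict[Gene, PhenotypeCall]] = {}
    for row in cohort.participants.itertuples(index=False):
        calls = {}
        for gene, column in (
            (Gene.CYP2C19, "cyp2c19_diplotype"),
            (Gene.CYP2D6, "cyp2d6_diplotype"),
        ):
            calls[gene] = call_phenotype(
                parse_diplotype(getattr(row, column), gene), defs, bins
            )
        phenotypes[row.participant_id] = calls
    return phenotypes


@dataclass
class PipelineResult:
    phenotypes: dict[str, dict[Gene, PhenotypeCall]]
    verdicts: list[ConsistencyVerdict]
    summary: dict


def verdicts_frame(verdicts: Sequence[ConsistencyVerdict]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "participant_id": v.participant_id,
                "medication": v.medication,
                "event_type": v.event_type.value,
                "verdict": v.verdict.value,
                "gene_basis": (
                    f"{v.gene_basis[0].value}:{v.gene_basis[1].value}"
                    if v.gene_basis
                    else ""
                ),
                "rationale": v.rationale,
            }
            for v in verdicts
        ],
        columns=[
            "participant_id",
            "medication",
            "event_type",
            "verdict",
            "gene_basis",
            "rationale",
        ],
    )


def write_verdicts(verdicts: Sequence[ConsistencyVerdict], path: str | Path) -> None:
    verdicts_frame(verdicts).to_csv(path, sep="\t", index=False, lineterminator="\n")


def write_summary_json(summary: dict, path: str | Path) -> None:
    """Deterministic JSON: sorted keys, stable float formatting."""
    Path(path).write_text(
        json.dumps(_stringify_keys(summary), indent=2, sort_keys=True) + "\n",
        encoding="utf-8",
    )


def _stringify_keys(obj):
    if isinstance(obj, dict):
        return {str(k): _stringify_keys(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_stringify_keys(v) for v in obj]
    return obj


def run_pipeline(
    cohort: Cohort,
    kb: KnowledgeBase,
    out_dir: str | Path | None = None,
    defs: AlleleTable | None = None,
    bins: PhenotypeBinConfig = DEFAULT_BINS,
) -> PipelineResult:
    """Translate, adjudicate and summarize a cohort.

    When ``out_dir`` is given, writes ``verdicts.tsv`` and ``summary.json``
    there; partially written outputs are removed if a stage fails.
    """
    stage = "translate"
    written: list[Path] = []
    try:
        phenotypes = translate_cohort(cohort, defs, bins)
        logger.info("translated %d participants", len(phenotypes))
        stage = "adjudicate"
        verdicts = adjudicate_trials(cohort.trials, phenotypes, kb)
        logger.info("adjudicated %d events from %d trials", len(verdicts), len(cohort.trials))
        stage = "summarize"
        summary = summarize_cohort(phenotypes, cohort.trials, verdicts, kb)
        if out_dir is not None:
            out = Path(out_dir)
            out.mkdir(parents=True, exist_ok=True)
            stage = "write"
            path = out / "verdicts.tsv"
            written.append(path)
            write_verdicts(verdicts, path)
            path = out / "summary.json"
            written.append(path)
            write_summary_json(summary, path)
        return PipelineResult(phenotypes=phenotypes, verdicts=verdicts, summary=summary)
    except Exception as exc:
        for path in written:
            path.unlink(missing_ok=True)
        raise RuntimeError(f"pipeline failed during {stage}: {exc}") from exc
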