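# Methods

## Phenotype translation model

A *diplotype* is the pair of star-allele haplotypes an individual carries
for one pharmacogene. The grammar accepted is
`allele[xN](+allele)* "/" allele[xN](+allele)*`: `xN` multiplies the copy
number of a haplotype (gene duplication), and `+` joins the components of
a hybrid tandem (e.g. CYP2D6 `*36+*10`), which is treated as a single
haplotype unit with its own entry in the allele table. Parsed diplotypes
are canonically ordered by the numeric part of the star label so `*2/*1`
and `*1/*2` compare equal.

**CYP2D6** is translated through the activity score
`AS = a₁·c₁ + a₂·c₂`, with per-copy activity values from the shipped
allele table (1.0 normal, 0.5 or 0.25 decreased, 0 no-function) and the
standard bins AS = 0 → PM, (0, 1] → IM, (1, 2.25] → NM, > 2.25 → UM. The
bin edges live in `PhenotypeBinConfig` so alternative binnings (e.g. the
older 2.0 NM upper edge) can be tested without code changes. A hybrid
tandem contributes the activity value of its dedicated table entry, which
defaults to the value of its functional component — detection platforms
report the tandem as a unit and no finer-grained scoring rule exists.

**CYP2C19** has no activity score; translation is a function-class pair
lookup: two no-function alleles → PM; exactly one no-function allele → IM
(including no-function/increased); normal/normal → NM; normal/increased →
RM; increased/increased → UM. Decreased-function CYP2C19 alleles (e.g.
`*9`) are mapped conservatively to IM whenever no no-function partner is
present. RM exists only for CYP2C19; increased function is only permitted
for CYP2C19 `*17`.

Any allele that is absent from the table or carries uncertain function
yields an **Indeterminate** call. Indeterminate is deliberately inert:
`altered()` is false, actionability is `not_evaluable`, and consistency
verdicts become `not_evaluable` — indeterminate results can appear in
denominators but never in numerators. The alternative (dropping them from
denominators) would silently shrink the cohort; keeping them visible was
judged the safer default for a clinical-evaluation tool.

## Guideline knowledge base

Rules are data, not code: a versioned YAML file maps each medication to
its metabolizing gene(s) (`primary`, or `dual` for the two TCAs
amitriptyline and clomipramine, which CYP2C19 and CYP2D6 both clear) and
gives, per (medication, gene, phenotype): a recommendation category
(`standard`, `dose_adjust`, `dose_adjust_or_alternative`, `alternative`),
an optional dose adjustment in percent reduction of standard dose
(positive = reduce; a `[low, high]` pair encodes a range such as
aripiprazole PM's 25–32%), and two explicit risk flags (`adr_risk`,
`inefficacy_risk`). Loading validates structure (pydantic; the JSON Schema
ships in `data/kb.schema.json`), full phenotype coverage for every mapped
gene (a `default` phenotype entry may stand in for unlisted cells), and
coherence: a risk flag with a standard recommendation requires an
explanatory note.

The risk flags follow the guidelines' explicit statements, including the
exceptions that make naive counting wrong: CYP2C19 IM/PM carry ADR risk
for sertraline/escitalopram/citalopram, but sertraline RM/UM carry **no**
inefficacy risk; CYP2D6 PM (not IM) carries ADR risk for aripiprazole;
risperidone UM carries inefficacy, not ADR, risk. Cells the published
guidelines leave without recommendation are encoded `standard` with a
provenance note; curated-judgement cells (e.g. atomoxetine IM,
brexpiprazole PM) are marked "Curated:" in their notes and can be
re-curated without code changes. Brand names resolve through a synonym
table at the I/O boundary.

## Adjudication semantics

Each trial's response (`adr`, `inefficacy`, `adr_and_inefficacy`, `none`,
`unknown`) explodes into zero, one or two events; a combined response
contributes one event to each denominator. An event is **consistent** iff
any mapped gene's rule asserts the corresponding risk flag for the
participant's phenotype (either-gene logic for dual-gene TCAs, since both
enzymes' guidance keys on exposure). If no flag fires and some mapped
gene is Indeterminate, the verdict is `not_evaluable` (risk cannot be
excluded); otherwise `inconsistent`. Medications without guidelines are
`not_evaluable` and are excluded from medication-centered denominators but
count as unexplained in the all-psychotropics participant view —
metabolizer genotypes cannot, by construction, explain them.

Percentages are rounded half-up to one decimal (`decimal.Decimal`), so
summary output is bit-reproducible.

## Synthetic cohort generator

The generator emulates the study design the analytics assume: per gene,
haplotypes are drawn i.i.d. from allele frequencies (Hardy–Weinberg;
duplications enter as haplotype classes like `*1x2`), medications are used
independently with per-medication probabilities mirroring the reported
cohort use rates (sertraline 0.46 … clomipramine 0.01, plus seven common
non-guideline psychotropics led by methylphenidate at 0.55, giving a
median of ~4 psychotropics per participant), and each trial draws ADR and
inefficacy independently with baseline probabilities 0.25 and 0.20
(mid-range of reported pediatric ADR/inefficacy discontinuation rates),
multiplied by a relative risk (default 2.0, capped at probability 1) when
the participant's phenotype is risk-flagged for that medication. Default
allele frequencies are an illustrative set tuned so that roughly half the
cohort is non-NM per gene and ~70% in at least one gene — the regime the
analysis targets; they are config-overridable and are not population
estimates. The generator records ground-truth phenotypes so tests can
verify the translator round-trips them, and identical config+seed yields
byte-identical cohort CSVs.

What the generator does **not** model: linkage or phasing, population
structure, medication co-occurrence and ADR/inefficacy correlation,
age/sex effects, phenoconversion by inhibiting co-medication, and
dose/duration. Passing calibration tests therefore show the pipeline's
internal statistical coherence (null behaviour, relative-risk recovery,
HWE), not fidelity to any real clinic population.

## The deterministic study fixture

`build_paper_fixture()` reconstructs, participant by participant, the
event structure of a published retrospective pediatric cohort: 69
event-bearing participants carrying 76 ADR and 61 inefficacy events on the
12 guideline medications. Eleven carriers hold the informative phenotypes
— eight whose guideline risk flag fires (citalopram IM; escitalopram IM;
two sertraline PM; aripiprazole PM; risperidone PM; two escitalopram RM
inefficacies) and three decoys whose guideline explicitly does not
(aripiprazole IM, risperidone UM, sertraline UM); all remaining events sit
on relevant-gene NM participants. Six of the consistent carriers carry one
additional inconsistent event keyed on their risk-neutral gene and the
other two a methylphenidate ADR, so the participant-centered view
reproduces the published structure: 8/69 with ≥1 event explained, 2 fully
explained over guideline medications, 0 over all psychotropics. Event
assignment to the NM participants is a grouped round-robin that also
fixes the marginals (51/69 with ≥1 ADR, 30/69 with ≥1 inefficacy, 28 ADRs
among 46 sertraline users). The split of the 12 small-medication ADRs and
the 52 non-escitalopram inefficacies across medications is not published;
the fixture's split is arbitrary and provably irrelevant to the pinned
totals because every such event sits on a relevant-gene NM phenotype.

## Numerical and design choices

- Ties at CYP2D6 bin edges go to the lower bin (`score <= edge`), matching
  the published bin definitions (1.0 → IM, 2.25 → NM).
- Copy numbers must be positive integers; `x0` is a parse error, not a
  deletion — deletions are the `*5` allele.
- Zero-event denominators report an absent (null) percentage rather than 0.
- Actionability deduplicates repeat trials of the same medication per
  participant; the denominator is participants, not trials.
- Calibration tests run at n = 10,000 with 3-Monte-Carlo-SE tolerances and
  fixed seeds; the whole suite completes in a few seconds on one CPU.

## Known limitations

Only CYP2C19 and CYP2D6 are covered (no CYP2B6 for sertraline, no CYP3A4
for quetiapine); there is no variant-level genotyping (the pipeline starts
from called diplotypes), no phenoconversion adjustment, no causality
scoring of ADRs, and no inferential statistics — the analytics are
deliberately descriptive, mirroring the evaluation design they implement.
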