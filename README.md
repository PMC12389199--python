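# pgxeval

Pharmacogenetic interpretation and cohort evaluation for **CYP2C19** and
**CYP2D6** in psychotropic prescribing.

Children and adolescents treated for mental health conditions frequently
discontinue antidepressants and antipsychotics because of adverse drug
reactions (ADRs) or lack of effect, and pharmacogenetic (PGx) testing of
the two major metabolism genes is often ordered *reactively* — after the
fact — to explain those events. `pgxeval` implements the full evaluation
chain needed to quantify what such testing can and cannot explain:

1. **Star-allele translation** — parse diplotype strings such as `*1/*2`,
   `*1/*1x2` (gene duplication) or `*4/*36+*10` (hybrid tandem) and
   translate them to metabolizer phenotypes. CYP2D6 uses the activity
   score AS = Σᵢ aᵢ·cᵢ (per-allele activity value × copy number), binned
   as AS = 0 → PM, 0 < AS ≤ 1 → IM, 1 < AS ≤ 2.25 → NM, AS > 2.25 → UM;
   CYP2C19 uses the allele function-pair lookup (PM/IM/NM/RM/UM).
2. **Guideline knowledge base** — a versioned YAML file encoding CPIC and
   DPWG dosing recommendations and explicit ADR-/inefficacy-risk flags for
   the 12 PGx-guided psychotropics (sertraline, escitalopram, citalopram,
   fluvoxamine, vortioxetine, venlafaxine, atomoxetine, risperidone,
   aripiprazole, brexpiprazole, amitriptyline, clomipramine), with
   schema + coverage validation.
3. **Actionability** — would the phenotype have changed dosing or drug
   choice preemptively (any non-standard recommendation)?
4. **Consistency adjudication** — an ADR (or inefficacy) event is
   *consistent* with the phenotype exactly when the guideline explicitly
   associates that phenotype with increased ADR (or therapeutic-failure)
   risk for that medication; dual-gene medications use either-gene logic;
   medications without guidelines are *not evaluable*.
5. **Cohort analytics** — phenotype distributions and combinations,
   actionability fractions, medication-centered concordance and
   participant-centered explained fractions.
6. **Synthetic cohorts** — a Hardy–Weinberg generator with
   phenotype-dependent event risks, plus a deterministic fixture
   reconstructing a published pediatric cohort's event structure.

## Worked example

```python
from pgxeval import build_paper_fixture, load_knowledge_base, run_pipeline

cohort = build_paper_fixture()          # 69 event-bearing participants
kb = load_knowledge_base()              # shipped CPIC/DPWG rules
result = run_pipeline(cohort, kb)
mc = result.summary["medication_centered"]
print(mc["adr"]["consistent"], mc["adr"]["events"], mc["adr"]["percent_consistent"])
```

Running `python examples/03_adjudicate_study_fixture.py` prints:

```
cohort: 69 event-bearing participants
adr        : 6/76 events consistent (7.9%)
inefficacy : 2/61 events consistent (3.3%)
participants with >=1 event explained: 8/69 (11.6%)
fully explained over guideline medications: 2
fully explained over all psychotropics:    0
```

Only 6 of 76 ADR events (7.9%) and 2 of 61 inefficacy events (3.3%) are
consistent with the metabolizer phenotypes, 8 of 69 participants (11.6%)
have at least one event explained, and nobody has every psychotropic
response explained — reactive testing of the two metabolism genes accounts
for only isolated events. Reaching these numbers requires honouring the
guidelines' exceptions (aripiprazole IM, risperidone UM and sertraline UM
carry **no** risk flag); naive "altered phenotype = explained" counting
over-counts.

The other example scripts demonstrate translation
(`01_translate_diplotypes.py`), knowledge-base queries
(`02_guideline_lookup.py`) and the stochastic generator with relative-risk
recovery (`04_simulate_cohort.py`).

## Command line

A thin CLI wraps the library:

```bash
pgxeval fixture --out-dir fx                 # emit the fixture cohort CSVs
pgxeval summarize fx/participants.csv fx/trials.csv
pgxeval simulate --n 500 --seed 7 --out-dir sim
pgxeval translate sim/participants.csv sim/trials.csv
pgxeval evaluate sim/participants.csv sim/trials.csv --out-dir out
pgxeval kb-validate                          # validate the shipped KB
```

## Layout

- `src/pgxeval/alleles.py` — diplotype grammar, activity score, phenotype calls
- `src/pgxeval/knowledge_base.py` — KB loading/validation/lookup
- `src/pgxeval/response.py` — trials, events, consistency verdicts
- `src/pgxeval/analytics.py` — cohort summary surfaces
- `src/pgxeval/simulate.py` — synthetic cohorts and the study fixture
- `src/pgxeval/io.py`, `src/pgxeval/cli.py` — CSV I/O, pipeline, CLI
- `src/pgxeval/data/` — allele table (TSV), guideline KB (YAML), KB JSON Schema
- `docs/methods.md` — model, assumptions, parameters and limitations
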