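"""Synthetic cohort generator: HWE sampling, event model, study fixture."""

import math

import numpy as np
import pandas as pd
import pytest

from pgxeval import (
    EventType,
    Gene,
    Phenotype,
    Response,
    SimulationConfig,
    Verdict,
    adjudicate_trials,
    build_paper_fixture,
    run_pipeline,
    sample_diplotypes,
    simulate_cohort,
    translate_cohort,
    write_cohort,
)
from pgxeval.alleles import call_phenotype, parse_diplotype
from pgxeval.simulate import DEFAULT_MED_USE_PROBS


def config(**overrides):
    defaults = dict(n_participants=200, seed=11)
    defaults.update(overrides)
    return SimulationConfig(**defaults)


class TestConfigValidation:
    def test_frequencies_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum"):
            SimulationConfig(
                allele_freqs={
                    Gene.CYP2C19: {"*1": 0.5, "*2": 0.4},
                    Gene.CYP2D6: {"*1": 1.0},
                }
            )

    def test_probabilities_in_unit_interval(self):
        with pytest.raises(ValueError):
            SimulationConfig(baseline_adr_prob=1.5)

    def test_negative_multiplier_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(risk_multiplier_adr=-1)


class TestDiplotypeSampling:
    def test_degenerate_frequency_gives_reference_homozygotes(self, defs):
        cfg = config(
            allele_freqs={
                Gene.CYP2C19: {"*1": 1.0},
                Gene.CYP2D6: {"*1": 1.0},
            }
        )
        rng = np.random.default_rng(0)
        frame = sample_diplotypes(cfg, Gene.CYP2C19, rng, defs)
        assert set(frame["diplotype"]) == {"*1/*1"}
        assert set(frame["phenotype"]) == {"NM"}

    def test_hwe_heterozygote_fraction(self, defs):
        """With two alleles at p = q = 0.5 the heterozygote fraction matches
        the Hardy-Weinberg closed form 2pq within 3 Monte-Carlo SE."""
        n = 10_000
        cfg = SimulationConfig(
            n_participants=n,
            seed=5,
            allele_freqs={
                Gene.CYP2C19: {"*1": 0.5, "*2": 0.5},
                Gene.CYP2D6: {"*1": 1.0},
            },
        )
        rng = np.random.default_rng(cfg.seed)
        frame = sample_diplotypes(cfg, Gene.CYP2C19, rng, defs)
        het = (frame["diplotype"] == "*1/*2").mean()
        se = math.sqrt(0.5 * 0.5 / n)
        assert abs(het - 0.5) <= 3 * se

    def test_truth_bookkeeping_matches_translator(self, kb, defs):
        sim = simulate_cohort(config(n_participants=150), kb, defs)
        phenotypes = translate_cohort(sim.cohort, defs)
        truth = sim.truth_phenotypes.set_index(["participant_id", "gene"])["phenotype"]
        for pid, calls in phenotypes.items():
            for gene, call in calls.items():
                assert truth.loc[(pid, gene.value)] == call.phenotype.value


class TestEventModel:
    def test_zero_baselines_give_no_events(self, kb):
        sim = simulate_cohort(
            config(baseline_adr_prob=0.0, baseline_ineff_prob=0.0), kb
        )
        assert all(t.response is Response.NONE for t in sim.cohort.trials)

    def test_zero_multiplier_forces_zero_consistent_adrs(self, kb):
        sim = simulate_cohort(
            config(n_participants=500, risk_multiplier_adr=0.0), kb
        )
        phenotypes = translate_cohort(sim.cohort)
        verdicts = adjudicate_trials(sim.cohort.trials, phenotypes, kb)
        consistent_adrs = [
            v
            for v in verdicts
            if v.event_type is EventType.ADR and v.verdict is Verdict.CONSISTENT
        ]
        assert consistent_adrs == []

    def test_seed_determinism_byte_identical_csv(self, kb, tmp_path):
        paths = []
        for run in ("a", "b"):
            sim = simulate_cohort(config(seed=42), kb)
            p_path = tmp_path / f"participants_{run}.csv"
            t_path = tmp_path / f"trials_{run}.csv"
            write_cohort(sim.cohort, p_path, t_path)
            paths.append((p_path.read_bytes(), t_path.read_bytes()))
        assert paths[0] == paths[1]

    def test_relative_risk_recovery(self, kb):
        """The injected ADR relative risk is recovered from the risk vs
        non-risk phenotype strata within 3 SE (delta method on log rates)."""
        R = 3.0
        sim = simulate_cohort(
            SimulationConfig(
                n_participants=10_000,
                seed=17,
                baseline_adr_prob=0.1,
                risk_multiplier_adr=R,
                risk_multiplier_ineff=1.0,
            ),
            kb,
        )
        phenotypes = translate_cohort(sim.cohort)
        from pgxeval.simulate import _risk_flags

        n = {True: 0, False: 0}
        events = {True: 0, False: 0}
        for t in sim.cohort.trials:
            if not kb.has_guideline(t.medication):
                continue
            flag, _ = _risk_flags(kb, t.medication, phenotypes[t.participant_id])
            had_adr = t.response in (Response.ADR, Response.ADR_AND_INEFFICACY)
            n[flag] += 1
            events[flag] += had_adr
        p1 = events[True] / n[True]
        p0 = events[False] / n[False]
        se_log = math.sqrt(
            (1 - p1) / (n[True] * p1) + (1 - p0) / (n[False] * p0)
        )
        assert abs(math.log(p1 / p0) - math.log(R)) <= 3 * se_log


class TestPaperFixture:
    def test_event_totals(self, fixture_cohort, fixture_result):
        mc = fixture_result.summary["medication_centered"]
        assert mc["adr"]["events"] == 76
        assert mc["inefficacy"]["events"] == 61
        assert len(fixture_cohort) == 69

    def test_per_medication_adr_composition(self, fixture_result):
        per_med = fixture_result.summary["medication_centered"]["adr"]["per_medication"]
        assert per_med["citalopram"]["events"] == 1
        assert per_med["escitalopram"]["events"] == 6
        assert per_med["sertraline"]["events"] == 28
        assert per_med["aripiprazole"]["events"] == 14
        assert per_med["risperidone"]["events"] == 15
        small = ["atomoxetine", "fluvoxamine", "vortioxetine"]
        assert sum(per_med[m]["events"] for m in small) == 12

    def test_escitalopram_inefficacy_composition(self, fixture_result):
        per_med = fixture_result.summary["medication_centered"]["inefficacy"][
            "per_medication"
        ]
        assert per_med["escitalopram"]["events"] == 8
        assert per_med["escitalopram"]["consistent"] == 2
        assert per_med["sertraline"]["consistent"] == 0

    def test_decoy_phenotypes_are_not_counted(self, fixture_cohort, fixture_result):
        """Naive altered-phenotype counting would over-count: the CYP2D6 IM
        aripiprazole ADR, CYP2D6 UM risperidone ADR and CYP2C19 UM
        sertraline inefficacy carriers must all be inconsistent."""
        phenotypes = translate_cohort(fixture_cohort)
        decoys = 0
        for v in fixture_result.verdicts:
            if v.verdict is not Verdict.INCONSISTENT:
                continue
            calls = phenotypes[v.participant_id]
            if (
                (v.medication == "aripiprazole" and calls[Gene.CYP2D6].phenotype is Phenotype.IM)
                or (v.medication == "risperidone" and calls[Gene.CYP2D6].phenotype is Phenotype.UM)
                or (
                    v.medication == "sertraline"
                    and v.event_type is EventType.INEFFICACY
                    and calls[Gene.CYP2C19].phenotype is Phenotype.UM
                )
            ):
                decoys += 1
        assert decoys == 3

    def test_participant_marginals(self, fixture_result):
        adr_havers = {
            v.participant_id
            for v in fixture_result.verdicts
            if v.event_type is EventType.ADR and v.guideline_medication
        }
        ineff_havers = {
            v.participant_id
            for v in fixture_result.verdicts
            if v.event_type is EventType.INEFFICACY
        }
        assert len(adr_havers) == 51  # 73.9% of 69
        assert len(ineff_havers) == 30  # 43.5% of 69

    def test_sertraline_users_and_adr_rate(self, fixture_cohort, fixture_result):
        users = {
            t.participant_id
            for t in fixture_cohort.trials
            if t.medication == "sertraline"
        }
        adr = fixture_result.summary["medication_centered"]["adr"]["per_medication"][
            "sertraline"
        ]
        assert len(users) == 46
        assert adr["events"] == 28  # 60.9% of users

    def test_fixture_is_deterministic(self):
        a, b = build_paper_fixture(), build_paper_fixture()
        pd.testing.assert_frame_equal(a.participants, b.participants)
        assert a.trials == b.trials

    def test_one_trial_per_participant_medication(self, fixture_cohort):
        keys = [(t.participant_id, t.medication) for t in fixture_cohort.trials]
        assert len(keys) == len(set(keys))
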