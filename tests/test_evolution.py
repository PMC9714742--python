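"""Mutation step, network classification, maintained networks, predecessors."""

import numpy as np
import pytest

from replinet.core import (
    HOST,
    PARASITE,
    CoefficientMatrix,
    Species,
    SpeciesRegistry,
)
from replinet.cycle import CycleConfig, PopulationState
from replinet.evolution import (
    EvolutionConfig,
    classify_network,
    composition_label,
    mutation_rate_from_error_rate,
    mutation_step,
    predecessor_analysis,
    run_evolution,
    _extract_maintained,
)


def _single_host_state(compartments=20, count=10):
    host = Species("H1", HOST)
    pop = PopulationState(
        np.full((compartments, 1), count, dtype=np.int64), [host]
    )
    matrix = CoefficientMatrix([host], coeffs={("H1", "H1"): 2.0})
    return pop, matrix


class TestMutationStep:
    def test_no_op_at_species_cap(self, table1_matrix, rng):
        pop = PopulationState(
            np.full((10, 3), 30, dtype=np.int64), table1_matrix.species
        )
        reps = {sid: np.full(10, 50) for sid in pop.ids}
        out, matrix, events = mutation_step(
            pop, table1_matrix, reps, EvolutionConfig(), rng
        )
        assert events == []
        assert out is pop and matrix is table1_matrix

    def test_no_op_without_replication(self, rng):
        pop, matrix = _single_host_state()
        out, _, events = mutation_step(
            pop, matrix, {"H1": np.zeros(20, dtype=np.int64)},
            EvolutionConfig(), rng,
        )
        assert events == []
        assert np.array_equal(out.counts, pop.counts)

    def test_round_one_has_no_mutation(self, rng):
        pop, matrix = _single_host_state()
        out, _, events = mutation_step(pop, matrix, None, EvolutionConfig(), rng)
        assert events == []

    def test_appearance_frequency_matches_rate(self):
        # replication count 10 in one compartment, rate 0.02 -> p ~ 0.2
        cfg = EvolutionConfig(
            parasite_from_host_rate=0.0  # isolate the host channel
        )
        reps_template = np.zeros(20, dtype=np.int64)
        reps_template[3] = 10
        n_trials = 4000
        fired = 0
        for seed in range(n_trials):
            pop, matrix = _single_host_state()
            _, _, events = mutation_step(
                pop, matrix, {"H1": reps_template}, cfg,
                np.random.default_rng(seed),
            )
            fired += bool(events)
        p_hat = fired / n_trials
        se = np.sqrt(0.2 * 0.8 / n_trials)
        assert abs(p_hat - 0.2) < 3 * se

    def test_new_species_enters_with_one_copy(self, rng):
        pop, matrix = _single_host_state()
        reps = {"H1": np.full(20, 60, dtype=np.int64)}  # p saturates at 1
        out, new_matrix, events = mutation_step(
            pop, matrix, reps, EvolutionConfig(), rng, round_index=5
        )
        assert {ev.role for ev in events} == {HOST, PARASITE}
        added = out.counts.sum() - pop.counts.sum()
        assert added == len(events)  # exactly one copy per new species
        for ev in events:
            assert len(ev.compartments) == 1

    def test_new_host_coefficients_cover_the_full_matrix(self, rng):
        pop, matrix = _single_host_state()
        reps = {"H1": np.full(20, 60, dtype=np.int64)}
        cfg = EvolutionConfig(parasite_from_host_rate=0.0)
        out, new_matrix, events = mutation_step(
            pop, matrix, reps, cfg, rng, round_index=2
        )
        (event,) = events
        new_id = event.species_id
        for rep_sp in new_matrix.species:
            if rep_sp.role != HOST:
                continue
            assert 1.0 <= new_matrix.get(rep_sp.id, new_id) <= 3.0
        assert 1.0 <= new_matrix.get(new_id, "H1") <= 3.0
        new_matrix.validate()

    def test_host_priority_when_one_slot_remains(self, rng):
        host = Species("H1", HOST)
        par = Species("P1", PARASITE)
        matrix = CoefficientMatrix(
            [host, par], coeffs={("H1", "H1"): 2.0, ("H1", "P1"): 5.0}
        )
        pop = PopulationState(
            np.full((20, 2), 30, dtype=np.int64), [host, par]
        )
        reps = {sid: np.full(20, 60, dtype=np.int64) for sid in pop.ids}
        cfg = EvolutionConfig(appearance_order="host_first")
        _, _, events = mutation_step(pop, matrix, reps, cfg, rng)
        assert [ev.role for ev in events] == [HOST]

    def test_both_policy_admits_host_and_parasite(self, rng):
        host = Species("H1", HOST)
        par = Species("P1", PARASITE)
        matrix = CoefficientMatrix(
            [host, par], coeffs={("H1", "H1"): 2.0, ("H1", "P1"): 5.0}
        )
        pop = PopulationState(
            np.full((20, 2), 30, dtype=np.int64), [host, par]
        )
        reps = {sid: np.full(20, 60, dtype=np.int64) for sid in pop.ids}
        out, _, events = mutation_step(
            pop, matrix, reps, EvolutionConfig(), rng
        )
        assert {ev.role for ev in events} == {HOST, PARASITE}
        assert len(out.species) == 4  # transient overshoot by one


class TestClassification:
    def test_threshold_is_strict(self, host1, parasite1):
        counts = np.zeros((3, 2), dtype=np.int64)
        counts[0] = [150_000, 1000]  # parasite exactly at threshold
        pop = PopulationState(counts, [host1, parasite1])
        members, label = classify_network(pop)
        assert members == frozenset({"H1"})
        assert label == "H"
        counts[0, 1] = 1001
        members, label = classify_network(PopulationState(counts, [host1, parasite1]))
        assert members == frozenset({"H1", "P1"})
        assert label == "HP"

    def test_empty_classification(self, host1):
        pop = PopulationState(np.zeros((3, 1), dtype=np.int64), [host1])
        assert classify_network(pop) == (frozenset(), "")

    def test_composition_labels_are_canonical(self):
        assert composition_label([HOST, PARASITE, HOST]) == "HHP"
        assert composition_label([PARASITE, PARASITE, HOST]) == "HPP"
        assert composition_label([]) == ""


class TestMaintainedNetworks:
    def _registry(self):
        return SpeciesRegistry([
            Species("H1", HOST), Species("H2", HOST), Species("P1", PARASITE),
        ])

    def test_extraction_requires_strictly_more_than_window(self):
        h = frozenset({"H1"})
        hp = frozenset({"H1", "P1"})
        timeline = [h] * 10 + [hp] * 5 + [h] * 4
        labels = ["H"] * 10 + ["HP"] * 5 + ["H"] * 4
        nets = _extract_maintained(timeline, labels, self._registry(), {}, 4)
        assert [(n.label, n.start, n.end) for n in nets] == [
            ("H", 0, 9), ("HP", 10, 14)
        ]
        # exactly window-long intervals are excluded (strict >)
        nets = _extract_maintained(timeline, labels, self._registry(), {}, 5)
        assert [n.label for n in nets] == ["H"]

    def test_predecessor_is_the_prior_classified_composition(self):
        h = frozenset({"H1"})
        hp = frozenset({"H1", "P1"})
        hhp = frozenset({"H1", "H2", "P1"})
        timeline = [h] * 6 + [hp] * 6 + [hhp] * 6
        labels = ["H"] * 6 + ["HP"] * 6 + ["HHP"] * 6
        nets = _extract_maintained(timeline, labels, self._registry(), {}, 3)
        by_label = {n.label: n for n in nets}
        assert by_label["HP"].predecessor_label == "H"
        assert by_label["HHP"].predecessor_label == "HP"
        assert by_label["H"].predecessor_label == ""

    def test_predecessor_analysis_aggregates_hhp(self):
        h = frozenset({"H1"})
        hh = frozenset({"H1", "H2"})
        hhp = frozenset({"H1", "H2", "P1"})

        class FakeLog:
            def __init__(self, nets):
                self.maintained = nets

        nets1 = _extract_maintained(
            [h] * 5 + [hhp] * 5, ["H"] * 5 + ["HHP"] * 5,
            self._registry(), {}, 3,
        )
        nets2 = _extract_maintained(
            [hh] * 5 + [hhp] * 5, ["HH"] * 5 + ["HHP"] * 5,
            self._registry(), {}, 3,
        )
        tally = predecessor_analysis([FakeLog(nets1), FakeLog(nets2)])
        assert tally == {"H": 1, "HH": 1}


class TestRunEvolution:
    SMALL = CycleConfig(compartments=250, fusion_frequency=400, rounds=1)

    def test_zero_rates_keep_a_pure_host_lineage(self):
        cfg = EvolutionConfig(
            host_from_host_rate=0.0,
            parasite_from_host_rate=0.0,
            parasite_from_parasite_rate=0.0,
            rounds=30,
        )
        log = run_evolution(cfg, self.SMALL, seed=3)
        assert len(log.registry) == 1
        assert log.appearances == []
        assert set(log.labels) <= {"H", ""}

    def test_identical_seeds_reproduce(self):
        cfg = EvolutionConfig(rounds=40)
        a = run_evolution(cfg, self.SMALL, seed=9)
        b = run_evolution(cfg, self.SMALL, seed=9)
        assert a.totals == b.totals
        assert a.labels == b.labels
        assert [e.species_id for e in a.appearances] == [
            e.species_id for e in b.appearances
        ]

    def test_established_species_respect_the_cap(self):
        cfg = EvolutionConfig(rounds=60)
        log = run_evolution(cfg, self.SMALL, seed=21)
        for comp in log.timeline:
            assert len(comp) <= cfg.species_cap

    def test_extinction_is_flagged_and_padded(self):
        # a lethal environment: tiny system, heavy parasite pressure
        cfg = EvolutionConfig(rounds=50)
        tiny = CycleConfig(compartments=60, fusion_frequency=100)
        extinct_logs = [
            run_evolution(cfg, tiny, seed=s) for s in range(6)
        ]
        assert any(log.extinct for log in extinct_logs)
        for log in extinct_logs:
            assert len(log.labels) == cfg.rounds
            if log.extinct:
                assert log.extinction_round is not None
                assert all(
                    lab == "" for lab in log.labels[log.extinction_round:]
                )

    def test_totals_frame_round_trip(self):
        cfg = EvolutionConfig(rounds=10)
        log = run_evolution(cfg, self.SMALL, seed=2)
        frame = log.totals_frame()
        assert set(frame.columns) == {
            "round", "species_id", "role", "global_total"
        }
        log.to_json()  # serializes without error


class TestRates:
    def test_host_rate_derives_from_error_rate_and_genome_size(self):
        expected = mutation_rate_from_error_rate(9.1e-6, 2000)
        assert expected == pytest.approx(0.02, rel=0.1)
        assert EvolutionConfig().host_from_host_rate == 0.02

    def test_config_validation(self):
        with pytest.raises(Exception):
            EvolutionConfig(host_from_host_rate=1.5)
        with pytest.raises(Exception):
            EvolutionConfig(appearance_order="alphabetical")
        with pytest.raises(Exception):
            EvolutionConfig(host_coeff_range=(3.0, 1.0))
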