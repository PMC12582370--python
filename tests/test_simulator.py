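"""Evolution simulator: mutation replay, boundary behavior, branching process."""

import numpy as np
import pytest

from ltrtrace.simulator import (
    SimConfig,
    apply_event,
    make_benchmark,
    replay,
    simulate,
)

QUIET = dict(p_sub=0.0, p_indel_te=0.0, p_sv=0.0, p_elim=0.0, founder_subs=0, founder_svs=0)


class TestEvents:
    def test_substitution(self):
        assert apply_event("ACGT", ("sub", 1, "G")) == "AGGT"

    def test_insertion_deletion(self):
        assert apply_event("ACGT", ("ins", 2, "TTT")) == "ACTTTGT"
        assert apply_event("ACGTAC", ("del", 1, 3)) == "AAC"

    def test_inversion_is_reverse_complement(self):
        assert apply_event("AACGTT", ("inv", 1, 4)) == "AACGTT"  # palindrome
        assert apply_event("AAAACC", ("inv", 2, 4)) == "AAGGTT"


class TestNoMutationLimit:
    def test_children_identical_and_counted(self):
        cfg = SimConfig(n_paths=2, n_generations=1, burst_copies_per_gen=2,
                        ancestor_len=500, seed=3, **QUIET)
        elements, truth = simulate(cfg)
        # 1 founder + 2 children per path
        per_path = {}
        for e in elements:
            per_path.setdefault(truth.path_of(e.element_id), []).append(e)
        assert all(len(v) == 3 for v in per_path.values())
        for path_elements in per_path.values():
            seqs = {e.seq for e in path_elements}
            assert len(seqs) == 1  # children identical to founder

    def test_full_elimination_boundary(self):
        cfg = SimConfig(n_paths=2, n_generations=2, burst_copies_per_gen=2,
                        ancestor_len=500, seed=3,
                        **{**QUIET, "p_elim": 1.0})
        elements, truth = simulate(cfg)
        assert elements == []  # every copy eliminated each generation
        assert all(not r.alive for r in truth.rows.values())


class TestGenealogyReplay:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_replay_reproduces_emitted_sequences_exactly(self, seed):
        cfg = SimConfig(n_paths=3, n_generations=3, ancestor_len=2000, seed=seed)
        elements, truth = simulate(cfg)
        assert len(elements) > 0
        memo = {}
        for e in elements:
            assert replay(truth, e.element_id, memo) == e.seq

    def test_truth_covers_fasta_exactly(self):
        cfg = SimConfig(n_paths=2, n_generations=2, ancestor_len=1000, seed=5)
        elements, truth = simulate(cfg)
        emitted = {e.element_id for e in elements}
        alive = set(truth.alive_ids())
        assert emitted == alive
        dead = {eid for eid, r in truth.rows.items() if not r.alive}
        assert dead.isdisjoint(emitted)


def test_small_indel_only_length_bound():
    cfg = SimConfig(n_paths=2, n_generations=2, ancestor_len=2000, seed=8,
                    p_sub=0.0, p_sv=0.0, p_elim=0.0, p_indel_te=0.005,
                    founder_subs=0, founder_svs=0)
    elements, truth = simulate(cfg)
    for e in elements:
        indel_net = 0
        eid = e.element_id
        while eid not in truth.ancestors:
            for ev in truth.rows[eid].events:
                if ev[0] == "ins":
                    indel_net += len(ev[2])
                elif ev[0] == "del":
                    indel_net += ev[2]
            eid = truth.rows[eid].parent_id
        assert abs(len(e.seq) - 2000) <= indel_net


def test_branching_process_expectation():
    # E[N_g] = ((1+b)(1-p_elim))^g surviving copies per founder
    b, pe, g = 2, 0.1, 3
    cfg0 = SimConfig(n_paths=2, n_generations=g, burst_copies_per_gen=b,
                     ancestor_len=60, min_seq_len=20, seed=0,
                     p_sub=0.0, p_indel_te=0.0, p_sv=0.0, p_elim=pe,
                     founder_subs=0, founder_svs=0)
    expected = ((1 + b) * (1 - pe)) ** g
    counts = []
    for seed in range(200):
        elements, _ = simulate(SimConfig(**{**cfg0.__dict__, "seed": seed}))
        counts.append(len(elements) / cfg0.n_paths)
    mean = np.mean(counts)
    se = np.std(counts, ddof=1) / np.sqrt(len(counts))
    assert abs(mean - expected) <= 3 * se + 1e-9


class TestBenchmark:
    def test_default_grid_is_nine_datasets(self):
        small = SimConfig(ancestor_len=300, n_generations=1, seed=0)
        datasets = make_benchmark(base_config=small, master_seed=7)
        assert len(datasets) == 9
        assert [cfg.n_paths for _, _, cfg in datasets] == [2, 3, 4] * 3

    def test_truth_has_n_paths_distinct_labels(self):
        small = SimConfig(ancestor_len=300, n_generations=1, p_elim=0.0, seed=0)
        for _, truth, cfg in make_benchmark(base_config=small, master_seed=7):
            assert len({r.path_id for r in truth.rows.values()}) == cfg.n_paths

    def test_deterministic_under_master_seed(self):
        small = SimConfig(ancestor_len=300, n_generations=1, seed=0)
        d1 = make_benchmark(base_config=small, master_seed=3)
        d2 = make_benchmark(base_config=small, master_seed=3)
        for (e1, t1, _), (e2, t2, _) in zip(d1, d2):
            assert [(e.element_id, e.seq) for e in e1] == [(e.element_id, e.seq) for e in e2]
            assert {k: (r.alive, r.events) for k, r in t1.rows.items()} == {
                k: (r.alive, r.events) for k, r in t2.rows.items()
            }


def test_simconfig_file_round_trip(tmp_path):
    cfg = SimConfig(n_paths=4, p_sub=0.01, sv_len_range=(50, 500), seed=9)
    p = tmp_path / "sim.config"
    cfg.write(p)
    back = SimConfig.from_file(p)
    assert back == cfg


def test_path_separability_non_decreasing_in_founder_dose():
    """More founder divergence never makes simulated paths harder to tell
    apart: clustering purity is non-decreasing over three dose levels."""
    from ltrtrace import RunConfig, evaluate_labels, iterate_layers, self_align

    purities = []
    for dose in (0, 3, 6):
        cfg = SimConfig(seed=11, n_paths=2, n_generations=2, ancestor_len=3000,
                        founder_svs=dose, founder_subs=100 * (dose > 0))
        elements, truth = simulate(cfg)
        hits = self_align(elements, seed=11)
        res = iterate_layers(elements, hits, RunConfig(seed=11, min_split_size=10))
        labels = res.labels_dict()
        paths = [truth.path_of(e.element_id) for e in elements]
        pairs = [(t, labels[e.element_id]) for t, e in zip(paths, elements)
                 if labels[e.element_id] != "unassigned"]
        purities.append(evaluate_labels([a for a, _ in pairs], [b for _, b in pairs])["purity"])
    assert purities[0] <= purities[1] + 1e-9
    assert purities[1] <= purities[2] + 1e-9
    assert purities[2] >= 0.9


def test_invalid_config_rejected():
    with pytest.raises(ValueError):
        SimConfig(p_sub=1.5)
    with pytest.raises(ValueError):
        SimConfig(n_paths=1)
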