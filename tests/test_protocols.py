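"""Stimulation schedules, template matrices, perturbations, capacity rules."""

import numpy as np
import pytest

from qifnet.params import NetworkParams
from qifnet.protocols import (
    ExperimentConfig,
    MatrixTemplate,
    build_modular_matrix,
    build_stimulus_schedule,
    feasible,
    find_hubs,
    make_assignment,
    max_feasible_memories,
    randomize_weight_subset,
)


class TestAssignment:
    def test_two_memory_split_covers_blocks(self, params100):
        a = make_assignment(params100, 2)
        assert a.M == 2
        assert len(a.exc[0]) == len(a.exc[1]) == 40
        assert len(a.hi[0]) == len(a.ai[0]) == 5
        all_ids = np.concatenate(a.exc + a.hi + a.ai)
        assert np.array_equal(np.sort(all_ids), np.arange(100))

    def test_overlap_shared_between_memories(self, params100):
        a = make_assignment(params100, 2, overlap=8)
        shared = np.intersect1d(a.exc[0], a.exc[1])
        assert shared.size == 8
        assert np.array_equal(np.sort(a.overlap), np.sort(shared))

    def test_inhibitory_sets_disjoint(self, params100):
        a = make_assignment(params100, 4)
        hi_all = np.concatenate(a.hi)
        ai_all = np.concatenate(a.ai)
        assert np.unique(hi_all).size == hi_all.size
        assert np.intersect1d(hi_all, ai_all).size == 0

    def test_empty_pool_rejected_unless_allowed(self, params100):
        with pytest.raises(ValueError):
            make_assignment(params100, 12)  # only 10 Hebbian-I neurons
        a = make_assignment(params100, 12, allow_empty=True)
        assert a.M == 12


class TestSchedule:
    def test_random_mode_presents_every_memory(self, params100):
        a = make_assignment(params100, 2)
        proto = build_stimulus_schedule(a, "random", 35, params=params100, seed=0)
        assert len(proto.epochs) == 35
        memories = {ep.memory for ep in proto.epochs}
        assert memories == {0, 1}

    def test_epoch_structure_exactly_one_second(self, params100):
        a = make_assignment(params100, 2)
        proto = build_stimulus_schedule(a, "random", 35, params=params100, seed=1)
        for k, ep in enumerate(proto.epochs):
            assert ep.stim_dur == pytest.approx(0.8)
            assert ep.relax == pytest.approx(0.2)
            assert ep.onset == pytest.approx(k * 1.0)
        assert proto.end == pytest.approx(35.0)

    def test_strict_mode_cycles_in_order(self, params100):
        a = make_assignment(params100, 2)
        proto = build_stimulus_schedule(a, "strict", 4, params=params100)
        assert [ep.memory for ep in proto.epochs] == [0, 1, 0, 1]

    def test_random_subset_option(self, params100):
        a = make_assignment(params100, 2)
        proto = build_stimulus_schedule(a, "random", 10, params=params100,
                                        subset_fraction=0.8, seed=3)
        sets = []
        for ep in proto.epochs:
            full = a.targets(ep.memory)
            assert ep.target_ids.size == round(0.8 * full.size)
            assert np.all(np.isin(ep.target_ids, full))
            sets.append(tuple(ep.target_ids))
        assert len(set(sets)) > 1  # fresh subsets per epoch

    def test_amplitude_jitter_option(self, params100):
        a = make_assignment(params100, 2)
        proto = build_stimulus_schedule(a, "random", 10, params=params100,
                                        amplitude_jitter=0.2, seed=3)
        amps = np.array([ep.amplitude for ep in proto.epochs])
        base = params100.stim_amplitude
        assert np.all((amps >= 0.8 * base) & (amps <= 1.2 * base))
        assert amps.std() > 0

    def test_fewer_epochs_than_memories_rejected(self, params100):
        a = make_assignment(params100, 4)
        with pytest.raises(ValueError):
            build_stimulus_schedule(a, "random", 3, params=params100)


class TestTemplates:
    def test_imperfect_template_intra_blocks_exact(self, params100):
        a = make_assignment(params100, 2)
        wm = build_modular_matrix(MatrixTemplate(), params100, a, seed=0)
        m0 = np.concatenate([a.exc[0], a.hi[0], a.ai[0]])
        sub = wm.w[np.ix_(m0, m0)]
        pre_exc = np.isin(m0, a.exc[0])
        off_diag = ~np.eye(m0.size, dtype=bool)
        assert np.all(sub[:, pre_exc][off_diag[:, pre_exc]] == 0.7)
        assert np.all(sub[:, ~pre_exc][off_diag[:, ~pre_exc]] == -0.7)

    def test_diagonal_zero_and_sign_truncation(self, params100):
        a = make_assignment(params100, 2)
        wm = build_modular_matrix(MatrixTemplate(), params100, a, seed=5)
        assert np.all(np.diagonal(wm.w) == 0.0)
        exc_col = wm.class_of == 0
        assert np.all(wm.w[:, exc_col] >= 0.0)
        assert np.all(wm.w[:, ~exc_col] <= 0.0)

    def test_idempotent_given_seed(self, params100):
        a = make_assignment(params100, 2)
        w1 = build_modular_matrix(MatrixTemplate(), params100, a, seed=9)
        w2 = build_modular_matrix(MatrixTemplate(), params100, a, seed=9)
        assert np.array_equal(w1.w, w2.w)

    def test_learned_style_anti_hebbian_is_lateral(self, params100):
        from qifnet.indicators import module_weight_stats

        a = make_assignment(params100, 2)
        wm = build_modular_matrix(MatrixTemplate(style="learned"),
                                  params100, a, seed=0)
        stats = module_weight_stats(wm.w, a)
        assert stats["A-E"]["inter"] == pytest.approx(-0.7)
        assert abs(stats["A-E"]["intra"]) < 0.3
        assert stats["H-E"]["intra"] == pytest.approx(-0.7)


class TestRandomization:
    def _learned(self, params100):
        a = make_assignment(params100, 2)
        return build_modular_matrix(MatrixTemplate.trained(), params100, a, seed=0)

    def test_e_out_redraws_only_excitatory_columns(self, params100):
        wm = self._learned(params100)
        out = randomize_weight_subset(wm, "E-out", np.random.default_rng(1))
        exc = wm.class_of == 0
        assert np.all(out.w[:, exc][wm.mask[:, exc]] >= 0.0)
        assert np.all(out.w[:, exc][wm.mask[:, exc]] <= 1.0)
        assert np.array_equal(out.w[:, ~exc], wm.w[:, ~exc])
        assert not np.array_equal(out.w[:, exc], wm.w[:, exc])

    def test_i_out_redraws_only_inhibitory_columns(self, params100):
        wm = self._learned(params100)
        out = randomize_weight_subset(wm, "I-out", np.random.default_rng(1))
        exc = wm.class_of == 0
        assert np.array_equal(out.w[:, exc], wm.w[:, exc])
        assert np.all(out.w[:, ~exc] <= 0.0)

    def test_none_is_identity(self, params100):
        wm = self._learned(params100)
        out = randomize_weight_subset(wm, "none", np.random.default_rng(1))
        assert np.array_equal(out.w, wm.w)

    def test_all_but_ee_preserves_ee_block(self, params100):
        wm = self._learned(params100)
        out = randomize_weight_subset(wm, "all-but-EE", np.random.default_rng(1))
        exc = wm.class_of == 0
        ee = np.ix_(exc, exc)
        assert np.array_equal(out.w[ee], wm.w[ee])

    def test_unknown_spec_rejected(self, params100):
        with pytest.raises(ValueError):
            randomize_weight_subset(self._learned(params100), "bogus",
                                    np.random.default_rng(0))


class TestCapacityRules:
    def test_feasibility_examples(self):
        assert feasible(100, 4, 8)        # 4 Hebbian + 4 anti-Hebbian
        assert not feasible(100, 4, 6)    # below the NI = 2M requirement
        assert not feasible(100, 34, 68)  # NE = 32 < 34 excitatory seeds

    def test_max_feasible_is_n_over_three(self):
        assert max_feasible_memories(100) == 33
        assert max_feasible_memories(1000) == 333
        assert feasible(100, 33, 66)

    def test_feasibility_matches_counting_rule_over_grid(self):
        N = 100
        for M in range(1, 50, 3):
            for NI in range(0, 101, 5):
                nhi = NI // 2
                expect = min(N - NI, nhi, NI - nhi) >= M
                assert feasible(N, M, NI) == expect


class TestHubs:
    def test_declared_overlap_becomes_hub_set(self, params100):
        a = make_assignment(params100, 2, overlap=8)
        # construct a matrix where exactly the shared neurons project
        # strongly to both modules
        w = np.zeros((100, 100))
        for m in range(2):
            excl = np.setdiff1d(a.exc[m], a.overlap)
            for j in np.concatenate([excl, a.overlap]):
                w[excl, j] = 0.9
        np.fill_diagonal(w, 0.0)
        hubs = find_hubs(w, a)
        assert np.array_equal(np.sort(hubs), np.sort(a.overlap))

    def test_zero_overlap_no_hubs(self, params100):
        a = make_assignment(params100, 2)
        wm = build_modular_matrix(MatrixTemplate.trained(), params100, a, seed=0)
        assert find_hubs(wm.w, a).size == 0


class TestRecoveryAndOverlap:
    def _damaged(self, subset, seed=3):
        from qifnet.protocols import randomize_weight_subset

        cfg = ExperimentConfig(M=2, seed=seed)
        p = cfg.resolved_params()
        a = make_assignment(p, 2)
        rng = np.random.default_rng(seed)
        learned = build_modular_matrix(MatrixTemplate.trained(), p, a, rng)
        return cfg, randomize_weight_subset(learned, subset, rng)

    def test_frozen_control_trajectory_flat(self):
        from qifnet.protocols import recovery_experiment

        cfg, damaged = self._damaged("I-out")
        _, _, stats = recovery_experiment(damaged, 5.0, cfg, snapshot_every=2.5,
                                          plasticity_on=False, noise_on=False)
        first, last = stats[0], stats[-1]
        for key in first:
            assert first[key] == last[key]

    def test_excitatory_recovery_from_preserved_inhibition(self):
        """Randomized excitatory weights recover modular contrast through
        spontaneous recalls when the inhibitory structure is intact."""
        from qifnet.protocols import recovery_experiment

        cfg, damaged = self._damaged("E-out")
        _, _, stats = recovery_experiment(damaged, 120.0, cfg,
                                          snapshot_every=60.0)
        c0 = stats[0]["E-E"]["intra"] - stats[0]["E-E"]["inter"]
        c1 = stats[-1]["E-E"]["intra"] - stats[-1]["E-E"]["inter"]
        assert c0 < 0.05          # randomization erased the contrast
        assert c1 > c0 + 0.1      # partial recovery within the scaled horizon

    def test_inhibitory_recovery_direction(self):
        """With inhibition randomized, Hebbian weights re-concentrate
        intra-module and anti-Hebbian weights laterally (slow drift)."""
        from qifnet.protocols import recovery_experiment

        cfg, damaged = self._damaged("I-out")
        _, _, stats = recovery_experiment(damaged, 120.0, cfg,
                                          snapshot_every=120.0)
        def h_contrast(s):
            return abs(s["H-E"]["intra"]) - abs(s["H-E"]["inter"])
        def a_contrast(s):
            return abs(s["A-E"]["inter"]) - abs(s["A-E"]["intra"])
        assert h_contrast(stats[-1]) > h_contrast(stats[0])
        assert a_contrast(stats[-1]) > a_contrast(stats[0])

    def test_overlap_training_declared_neurons_become_hubs(self):
        from qifnet.protocols import overlap_experiment

        exp = overlap_experiment(ExperimentConfig(M=2, overlap=8, seed=5))
        assert np.array_equal(np.sort(exp.hubs), np.sort(exp.assignment.overlap))

    def test_overlap_requires_shared_neurons(self):
        from qifnet.protocols import overlap_experiment

        with pytest.raises(ValueError):
            overlap_experiment(ExperimentConfig(M=2, overlap=0))


def test_capacity_scan_simulated_point_and_masks():
    """A comfortably feasible point simulates as stable; the counting rule
    partitions the rest into unstable and non-accessible regions."""
    from qifnet.protocols import capacity_scan

    grid = capacity_scan(100, [2], [20], ExperimentConfig(seed=1), horizon=60.0)
    assert grid[(2, 20)] == "stable"
    rule = capacity_scan(100, [40], [20, 99], simulate=False)
    assert rule[(40, 20)] == "unstable"         # needs 80 inhibitory
    assert rule[(40, 99)] == "non-accessible"   # NE = 1 < 40
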