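"""SFFO / MFFO optimizer mechanics."""

import numpy as np
import pytest

import lassofold as lf
from lassofold.optimize import (
    OptimizerConfig,
    OptimizerEntry,
    ema_update,
    initial_population,
    metropolis_accept,
    mffo_run,
    mutate_forcefield,
    rank_and_crossover,
    sffo_step,
)

CFG = OptimizerConfig()


class StubObjective:
    """Deterministic stand-in for folding tests: returns scripted values."""

    def __init__(self, mean_F_values, pi_values=None, n_beads=10):
        self.mean_F_values = list(mean_F_values)
        if pi_values is None:
            pi_values = [0.5] * len(self.mean_F_values)
        self.pi_values = list(pi_values)
        self.calls = 0

        class _N:
            pass

        self.native = _N()
        self.native.n_beads = n_beads

    def evaluate(self, ff, config, seed):
        i = min(self.calls, len(self.mean_F_values) - 1)
        self.calls += 1
        return self.mean_F_values[i], self.pi_values[i], None


class TestMutation:
    def test_exactly_one_group_changes(self):
        ff = lf.ForceField.homogeneous(12)
        mut = mutate_forcefield(ff, CFG, seed=1)
        diff = mut.coefficients != ff.coefficients
        changed = [g for g in ff.pairing if diff[g].any()]
        assert len(changed) == 1
        # both members of the group receive the same delta
        g = changed[0]
        deltas = mut.coefficients[g] - ff.coefficients[g]
        assert np.allclose(deltas, deltas[0])
        assert mut.satisfies_pairing()

    def test_mutation_sd(self):
        ff = lf.ForceField.homogeneous(12, 100.0, 100.0)  # far from the floor
        deltas = []
        for seed in range(10000):
            mut = mutate_forcefield(ff, CFG, seed=seed)
            d = mut.coefficients - ff.coefficients
            deltas.append(d[np.nonzero(d)][0])
        assert np.std(deltas) == pytest.approx(2.5, rel=0.03)

    def test_floor_clipping(self):
        ff = lf.ForceField.homogeneous(10, 1.05, 1.05)
        lows = []
        for seed in range(200):
            mut = mutate_forcefield(ff, CFG, seed=seed)
            lows.append(mut.coefficients.min())
        assert min(lows) >= CFG.k_floor

    def test_determinism(self):
        ff = lf.ForceField.homogeneous(10)
        a = mutate_forcefield(ff, CFG, seed=3)
        b = mutate_forcefield(ff, CFG, seed=3)
        np.testing.assert_array_equal(a.coefficients, b.coefficients)


class TestMetropolis:
    def test_improvement_always_accepted(self):
        for seed in range(50):
            assert metropolis_accept(1.0, 0.5, seed)

    def test_equal_always_accepted(self):
        for seed in range(50):
            assert metropolis_accept(1.0, 1.0, seed)

    def test_acceptance_frequency_at_unit_penalty(self):
        rng = np.random.default_rng(123)
        acc = sum(metropolis_accept(0.0, 1.0, rng) for _ in range(100000))
        assert acc / 100000 == pytest.approx(np.exp(-1.0), abs=0.005)


class TestEMA:
    def test_alpha_one_replaces(self):
        assert ema_update(0.2, 0.9, 1.0) == 0.9

    def test_fixed_point(self):
        x = 0.0
        for _ in range(1000):
            x = ema_update(x, 0.7, 0.1)
        assert x == pytest.approx(0.7, abs=1e-8)

    def test_e_folding_time_at_default_alpha(self):
        # weight decay (1 - alpha)^n: e-folding in 33 steps at alpha = 0.03
        assert round(-1.0 / np.log(1.0 - 0.03)) == 33
        x = 1.0
        for _ in range(33):
            x = ema_update(x, 0.0, 0.03)
        assert x == pytest.approx(np.exp(-1.0), rel=0.02)


class TestSFFOStep:
    def test_forced_accept_updates_coefficients(self):
        # mutant scores much better: always accepted
        obj = StubObjective([0.1], [0.9])
        entry = OptimizerEntry(lf.ForceField.homogeneous(10), mean_F=5.0, Pi_f=0.5)
        out = sffo_step(entry, obj, CFG, seed=0)
        assert out.mean_F == 0.1
        assert out.accepted == 1
        assert not np.array_equal(
            out.ff.coefficients, lf.ForceField.homogeneous(10).coefficients
        )

    def test_forced_reject_keeps_forcefield(self):
        # mutant scores hopelessly worse: essentially never accepted
        obj = StubObjective([500.0], [0.0])
        base = lf.ForceField.homogeneous(10)
        entry = OptimizerEntry(base.copy(), mean_F=0.1, Pi_f=0.5)
        out = sffo_step(entry, obj, CFG, seed=0)
        np.testing.assert_array_equal(out.ff.coefficients, base.coefficients)
        assert out.mean_F == 0.1
        assert out.accepted == 0

    def test_rejected_test_still_feeds_ema(self):
        obj = StubObjective([500.0], [0.8])
        entry = OptimizerEntry(
            lf.ForceField.homogeneous(10), mean_F=0.1, Pi_f=0.5
        )
        out = sffo_step(entry, obj, CFG, seed=0)
        assert out.Pi_f == pytest.approx(ema_update(0.5, 0.8, CFG.alpha))

    def test_descent_with_improving_evaluations(self):
        """With scripted strictly improving evaluations every mutation is
        accepted and the stored <F> sequence is strictly decreasing."""
        values = [5.0, 4.0, 3.0, 2.0, 1.0]
        obj = StubObjective(values)
        entry = OptimizerEntry(lf.ForceField.homogeneous(10), mean_F=5.5, Pi_f=0.5)
        stored = [entry.mean_F]
        for step in range(len(values)):
            entry = sffo_step(entry, obj, CFG, seed=step)
            stored.append(entry.mean_F)
        assert stored == [5.5] + values
        assert entry.accepted == len(values)


class TestCrossover:
    def _entries(self, n_k, n_beads=10, seed=0):
        rng = np.random.default_rng(seed)
        entries = []
        for i in range(n_k):
            ff = lf.ForceField.homogeneous(n_beads, 20.0 + i, 30.0 + i)
            entries.append(
                OptimizerEntry(ff, mean_F=1.0, Pi_f=float(rng.uniform(0, 1)))
            )
        return entries

    def test_degenerate_selection_is_identity(self):
        cfg = OptimizerConfig(N_K=4, N_win=4, N_low=2)
        entries = self._entries(4)
        out = rank_and_crossover(entries, cfg, seed=0)
        in_sets = {tuple(e.ff.coefficients) for e in entries}
        out_sets = {tuple(e.ff.coefficients) for e in out}
        assert in_sets == out_sets

    def test_hybrid_count_paper_sizes(self):
        cfg = OptimizerConfig(N_K=16, N_win=6, N_low=4)
        entries = self._entries(16)
        out = rank_and_crossover(entries, cfg, seed=0)
        assert len(out) == 16
        hybrids = [e for e in out if e.Pi_f is None]
        assert len(hybrids) == 10

    def test_hybrid_groups_come_from_parents(self):
        cfg = OptimizerConfig(N_K=6, N_win=3, N_low=0)  # parents = winners only
        entries = self._entries(6)
        out = rank_and_crossover(entries, cfg, seed=1)
        winners = sorted(entries, key=lambda e: -e.Pi_f)[:3]
        parent_coeffs = [w.ff.coefficients for w in winners]
        pairing = entries[0].ff.pairing
        for hybrid in out[3:]:
            for g in pairing:
                assert any(
                    np.allclose(hybrid.ff.coefficients[g], pc[g])
                    for pc in parent_coeffs
                )
            assert hybrid.ff.satisfies_pairing()

    def test_ranking_ties_broken_by_index(self):
        cfg = OptimizerConfig(N_K=4, N_win=2, N_low=0)
        entries = self._entries(4)
        for e in entries:
            e.Pi_f = 0.5
        out = rank_and_crossover(entries, cfg, seed=0)
        np.testing.assert_array_equal(
            out[0].ff.coefficients, entries[0].ff.coefficients
        )
        np.testing.assert_array_equal(
            out[1].ff.coefficients, entries[1].ff.coefficients
        )

    def test_pairing_preserved_across_many_operations(self):
        cfg = OptimizerConfig(N_K=6, N_win=2, N_low=2)
        ff = lf.ForceField.homogeneous(12)
        for seed in range(5000):
            ff = mutate_forcefield(ff, cfg, seed=seed)
            assert ff.satisfies_pairing()
        entries = self._entries(6, n_beads=12)
        for seed in range(200):
            entries = rank_and_crossover(entries, cfg, seed=seed)
            for e in entries:
                assert e.ff.satisfies_pairing()
                if e.Pi_f is None:
                    e.Pi_f = 0.5  # pretend evaluated for the next round


class TestMFFORun:
    def test_history_bookkeeping(self):
        cfg = OptimizerConfig(N_K=3, N_win=2, N_low=1, m_cycle=2, n_test=1)
        obj = StubObjective(
            mean_F_values=np.linspace(5, 1, 50), pi_values=np.linspace(0.1, 0.9, 50),
            n_beads=10,
        )
        best, history = mffo_run(obj, cfg, cycles=3, master_seed=0)
        assert len(history) == 3
        for h in history:
            assert all(a <= cfg.m_cycle for a in h["accepted"])
        assert best.satisfies_pairing()

    def test_checkpoint_round_trip(self, tmp_path):
        from lassofold.optimize import load_checkpoint, save_checkpoint

        cfg = OptimizerConfig(N_K=3, N_win=2, N_low=1, m_cycle=1, n_test=1)
        obj = StubObjective(
            mean_F_values=np.linspace(5, 1, 20), pi_values=np.linspace(0.1, 0.9, 20),
            n_beads=10,
        )
        mffo_run(obj, cfg, cycles=2, master_seed=0, checkpoint_dir=tmp_path)
        files = sorted(tmp_path.glob("cycle_*.json"))
        assert len(files) == 2
        entries, cycle, seed = load_checkpoint(files[-1])
        assert cycle == 1 and seed == 0
        assert len(entries) == 3
        for e in entries:
            assert e.ff.satisfies_pairing()
            assert e.Pi_f is not None

    def test_initial_population_spreads_grid(self):
        cfg = OptimizerConfig(N_K=16)
        pop = initial_population(10, cfg)
        combos = {
            (e.ff.k_bend[0], e.ff.k1_tor[0]) for e in pop
        }
        assert len(combos) == 16
        cfg4 = OptimizerConfig(N_K=4, N_win=2)
        pop4 = initial_population(10, cfg4)
        kbs = sorted({e.ff.k_bend[0] for e in pop4})
        assert kbs[0] == 20.0 and kbs[-1] == 80.0
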