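"""MSD, native contacts, success criterion, transition times, pathways."""

import numpy as np
import pytest

import lassofold as lf
from lassofold.analysis import (
    classify_pathway,
    folding_landscape,
    is_folded,
    kabsch_superpose,
    msd_from_native,
    native_contact_fraction,
    pathway_statistics,
    transition_times,
)
from lassofold.fixtures import make_trace

SB1 = 1.2 / 2 ** (1 / 6)  # bridge sigma of the mini-lasso fixture
B_THR = 1.5 * SB1
R_THR = 2.0 * SB1


class TestMSD:
    def test_identity(self, mini_lasso):
        conf, _ref, _spec = mini_lasso
        assert msd_from_native(conf, conf) == pytest.approx(0.0, abs=1e-20)

    def test_translation(self, mini_lasso):
        conf, _ref, _spec = mini_lasso
        shifted = conf.copy()
        shifted.positions = shifted.positions + np.array([5.0, 5.0, 5.0])
        assert msd_from_native(shifted, conf, superpose=True) == pytest.approx(
            0.0, abs=1e-18
        )
        assert msd_from_native(shifted, conf, superpose=False) == pytest.approx(75.0)

    def test_against_independent_superposition(self, mini_lasso):
        """Own Kabsch vs scipy's independent align_vectors implementation."""
        from scipy.spatial.transform import Rotation

        conf, _ref, _spec = mini_lasso
        rng = np.random.default_rng(0)
        other = conf.positions + rng.normal(0, 0.4, conf.positions.shape)
        R = Rotation.random(random_state=3).as_matrix()
        other = other @ R.T + [1.0, -2.0, 0.7]

        rot, _ = Rotation.align_vectors(
            conf.positions - conf.positions.mean(0), other - other.mean(0)
        )
        aligned = rot.apply(other - other.mean(0)) + conf.positions.mean(0)
        expected = np.mean(np.sum((aligned - conf.positions) ** 2, axis=1))
        assert msd_from_native(other, conf.positions) == pytest.approx(
            expected, abs=1e-10
        )

    def test_kabsch_no_reflection(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=(8, 3))
        b = a * np.array([-1.0, 1.0, 1.0])  # mirror image
        sup = kabsch_superpose(b, a)
        # a proper rotation cannot undo a reflection
        assert np.mean(np.sum((sup - a) ** 2, axis=1)) > 0.01

    def test_mismatched_sizes(self, mini_lasso):
        conf, _ref, _spec = mini_lasso
        with pytest.raises(ValueError):
            msd_from_native(conf.positions[:-1], conf.positions)


class TestNativeContacts:
    def test_native_is_one(self, mini_lasso):
        conf, _ref, _spec = mini_lasso
        goff = lf.build_go_forcefield(conf)
        assert native_contact_fraction(conf, goff.contact_list()) == 1.0

    def test_stretched_is_low(self, mini_lasso):
        conf, _ref, _spec = mini_lasso
        goff = lf.build_go_forcefield(conf)
        s = lf.generate_stretched_configuration(conf.n_beads, 5)
        assert native_contact_fraction(s, goff.contact_list()) < 0.05

    def test_infinite_factor_limit(self, mini_lasso):
        conf, _ref, _spec = mini_lasso
        goff = lf.build_go_forcefield(conf)
        s = lf.generate_stretched_configuration(conf.n_beads, 5)
        assert native_contact_fraction(s, goff.contact_list(), factor=1e9) == 1.0

    def test_empty_contacts(self, mini_lasso):
        conf, _ref, _spec = mini_lasso
        with pytest.raises(ValueError):
            native_contact_fraction(conf, [])


class TestIsFolded:
    @pytest.mark.parametrize(
        "F,L,expected",
        [(0.64, 0.95, True), (0.64, 0.5, False), (1.0, 0.95, False)],
    )
    def test_examples(self, F, L, expected):
        assert is_folded(F, L) is expected

    def test_monotone(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            F, L = rng.uniform(0, 2), rng.uniform(0, 1)
            if is_folded(F, L):
                assert is_folded(F * rng.uniform(0, 1), L)
                assert is_folded(F, L + (1 - L) * rng.uniform(0, 1))


class TestTransitionTimes:
    def test_transient_dip_is_ignored(self):
        """A 5-tau dip below threshold does not count; the later sustained
        closure at t = 100 does."""
        traj = make_trace(
            [
                (0, 50, {"d_b1": 5.0, "L": 0.0, "F": 50.0}),
                (50, 55, {"d_b1": 1.0, "L": 0.0, "F": 50.0}),
                (55, 100, {"d_b1": 5.0, "L": 0.0, "F": 50.0}),
                (100, 200, {"d_b1": 1.0, "L": 0.0, "F": 50.0}),
            ]
        )
        times = transition_times(traj, bridge_threshold=B_THR)
        assert times.t_b == 100.0
        assert times.t_k is None and times.t_f is None

    def test_never_below_threshold(self):
        traj = make_trace([(0, 100, {"d_b1": 5.0, "L": 0.0, "F": 50.0})])
        assert transition_times(traj, B_THR).t_b is None

    def test_instant_fold(self):
        traj = make_trace([(0, 100, {"d_b1": 5.0, "L": 1.0, "F": 0.25})])
        times = transition_times(traj, B_THR)
        assert times.t_k == 0.0 and times.t_f == 0.0

    def test_missing_trace_named(self):
        traj = make_trace([(0, 100, {"d_b1": 5.0, "L": 1.0})])
        with pytest.raises(KeyError, match="'F'"):
            transition_times(traj, B_THR)

    def test_tf_requires_tk(self):
        with pytest.raises(ValueError):
            lf.TransitionTimes(t_f=10.0)


def _pathway_trace(kind):
    """Hand-constructed traces realizing each folding mechanism."""
    open_d = 5.0
    closed = 1.0
    if kind == "open-loop":  # topology at 50, bridge at 80
        return make_trace(
            [
                (0, 50, {"d_b1": open_d, "L": 0.0, "F": 50.0}),
                (50, 80, {"d_b1": open_d, "L": 1.0, "F": 0.2}),
                (80, 200, {"d_b1": closed, "L": 1.0, "F": 0.2}),
            ]
        )
    if kind == "threading":  # bridge at 30, stays closed, topology at 90
        return make_trace(
            [
                (0, 30, {"d_b1": open_d, "L": 0.0, "F": 50.0}),
                (30, 90, {"d_b1": closed, "L": 0.0, "F": 10.0}),
                (90, 200, {"d_b1": closed, "L": 1.0, "F": 0.2}),
            ]
        )
    if kind == "reopening":  # bridge at 30, spike to 4.0 at 60, topology at 90
        return make_trace(
            [
                (0, 30, {"d_b1": open_d, "L": 0.0, "F": 50.0}),
                (30, 60, {"d_b1": closed, "L": 0.0, "F": 10.0}),
                (60, 65, {"d_b1": 4.0, "L": 0.0, "F": 10.0}),
                (65, 90, {"d_b1": closed, "L": 0.0, "F": 10.0}),
                (90, 200, {"d_b1": closed, "L": 1.0, "F": 0.2}),
            ]
        )
    raise ValueError(kind)


class TestClassifyPathway:
    @pytest.mark.parametrize("kind", ["open-loop", "threading", "reopening"])
    def test_constructed_traces(self, kind):
        traj = _pathway_trace(kind)
        times = transition_times(traj, B_THR)
        assert times.successful
        assert classify_pathway(traj, times, R_THR) == kind

    @pytest.mark.parametrize("kind", ["open-loop", "threading", "reopening"])
    def test_invariant_under_finer_sampling(self, kind):
        coarse = _pathway_trace(kind)
        fine_traj = make_trace(
            [
                (0, 30, {"d_b1": 5.0, "L": 0.0, "F": 50.0}),
            ]
        )
        # resample the same piecewise description at 5x finer interval
        segments = {
            "open-loop": [
                (0, 50, {"d_b1": 5.0, "L": 0.0, "F": 50.0}),
                (50, 80, {"d_b1": 5.0, "L": 1.0, "F": 0.2}),
                (80, 200, {"d_b1": 1.0, "L": 1.0, "F": 0.2}),
            ],
            "threading": [
                (0, 30, {"d_b1": 5.0, "L": 0.0, "F": 50.0}),
                (30, 90, {"d_b1": 1.0, "L": 0.0, "F": 10.0}),
                (90, 200, {"d_b1": 1.0, "L": 1.0, "F": 0.2}),
            ],
            "reopening": [
                (0, 30, {"d_b1": 5.0, "L": 0.0, "F": 50.0}),
                (30, 60, {"d_b1": 1.0, "L": 0.0, "F": 10.0}),
                (60, 65, {"d_b1": 4.0, "L": 0.0, "F": 10.0}),
                (65, 90, {"d_b1": 1.0, "L": 0.0, "F": 10.0}),
                (90, 200, {"d_b1": 1.0, "L": 1.0, "F": 0.2}),
            ],
        }[kind]
        fine = make_trace(segments, sample_interval=0.2)
        t_c = transition_times(coarse, B_THR)
        t_f = transition_times(fine, B_THR)
        assert classify_pathway(coarse, t_c, R_THR) == classify_pathway(
            fine, t_f, R_THR
        )

    def test_unsuccessful_raises(self):
        traj = make_trace([(0, 100, {"d_b1": 5.0, "L": 0.0, "F": 50.0})])
        times = transition_times(traj, B_THR)
        with pytest.raises(ValueError, match="not a successful"):
            classify_pathway(traj, times, R_THR)


class TestLandscape:
    def test_single_bin_mass(self):
        traj = make_trace([(0, 100, {"F": 0.5, "d_b1": 1.0, "L": 1.0})])
        ls = folding_landscape([traj], "F", "d_b1", bins=5)
        surf = ls.surface
        assert surf.count() == 1  # one defined bin
        assert surf.compressed()[0] == pytest.approx(0.0)  # -log(1)

    def test_two_equal_bins_symmetric(self):
        traj = make_trace(
            [
                (0, 49.5, {"F": 0.0, "d_b1": 0.0, "L": 0.0}),
                (49.5, 99, {"F": 1.0, "d_b1": 0.0, "L": 0.0}),
            ]
        )
        ls = folding_landscape(
            [traj], "F", "d_b1", bins=2, ranges=[[-0.5, 1.5], [-1, 1]]
        )
        vals = ls.surface.compressed()
        assert len(vals) == 2
        assert vals[0] == pytest.approx(vals[1])

    def test_counts_match_recount(self, mini_lasso):
        rng = np.random.default_rng(0)
        trajs = []
        for s in range(3):
            n = 50
            times = np.arange(n, dtype=float)
            trajs.append(
                lf.TrajectoryRecord(
                    times,
                    {
                        "F": rng.uniform(0, 2, n),
                        "d_b1": rng.uniform(0, 5, n),
                    },
                    run_length=float(n - 1),
                )
            )
        ls = folding_landscape(trajs, "F", "d_b1", bins=7)
        assert ls.counts.sum() == 150
        xs = np.concatenate([t.trace("F") for t in trajs])
        ys = np.concatenate([t.trace("d_b1") for t in trajs])
        expected, _, _ = np.histogram2d(xs, ys, bins=[ls.x_edges, ls.y_edges])
        np.testing.assert_array_equal(ls.counts, expected)

    def test_empty_selection(self):
        with pytest.raises(ValueError):
            folding_landscape([], "F", "d_b1")


class TestPathwayStatistics:
    def test_small_ensemble(self):
        trajs = [
            _pathway_trace("open-loop"),
            _pathway_trace("open-loop"),
            make_trace([(0, 200, {"d_b1": 5.0, "L": 0.0, "F": 50.0})]),
            make_trace([(0, 200, {"d_b1": 5.0, "L": 0.0, "F": 50.0})]),
        ]
        stats = pathway_statistics(trajs, B_THR, R_THR)
        assert stats["P_f"] == 0.5
        assert stats["P_open_loop"] == 0.5
        assert stats["P_threading"] == 0.0

    def test_no_successes(self):
        trajs = [make_trace([(0, 200, {"d_b1": 5.0, "L": 0.0, "F": 50.0})])] * 3
        stats = pathway_statistics(trajs, B_THR, R_THR)
        assert stats["P_f"] == 0.0
        assert stats["P_open_loop"] == 0.0

    def test_probabilities_sum_to_pf_exactly(self):
        trajs = [
            _pathway_trace("open-loop"),
            _pathway_trace("threading"),
            _pathway_trace("reopening"),
            make_trace([(0, 200, {"d_b1": 5.0, "L": 0.0, "F": 50.0})]),
        ]
        s = pathway_statistics(trajs, B_THR, R_THR)
        assert (
            s["P_threading"] + s["P_reopening"] + s["P_open_loop"] + s["P_unresolved"]
            == s["P_f"]
        )
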