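import numpy as np
import pytest

from warpelast.states import (
    StateDynamics,
    cluster_states,
    elbow_curve,
    group_compare,
    state_dynamics,
)


def make_blobs(rng, centers, n_per, spread=0.05):
    X = np.concatenate([c + spread * rng.standard_normal((n_per, len(c))) for c in centers])
    labels = np.repeat(np.arange(len(centers)), n_per)
    return X, labels


class TestClusterStates:
    def test_separable_blobs_recovered(self, rng):
        X, truth = make_blobs(rng, [(-5, -5), (5, 5)], 60)
        model = cluster_states(X, k=2, seed=0)
        # agreement up to label permutation
        agree = max(
            np.mean(model.labels == truth), np.mean(model.labels == 1 - truth)
        )
        assert agree == 1.0

    def test_k1_centroid_is_coordinatewise_median(self, rng):
        X = rng.standard_normal((50, 4))
        model = cluster_states(X, k=1, seed=0)
        np.testing.assert_allclose(model.centroids[0], np.median(X, axis=0))

    def test_duplicated_rows_leave_centroids_stable(self, rng):
        X, _ = make_blobs(rng, [(-3, 0), (3, 0)], 40)
        m1 = cluster_states(X, k=2, seed=1)
        m2 = cluster_states(np.vstack([X, X]), k=2, seed=1)
        c1 = np.sort(m1.centroids[:, 0])
        c2 = np.sort(m2.centroids[:, 0])
        np.testing.assert_allclose(c1, c2, atol=0.1)

    def test_deterministic_given_seed(self, rng):
        X = rng.standard_normal((80, 3))
        m1 = cluster_states(X, k=3, seed=42)
        m2 = cluster_states(X, k=3, seed=42)
        np.testing.assert_array_equal(m1.labels, m2.labels)

    def test_k_out_of_range_rejected(self, rng):
        with pytest.raises(ValueError):
            cluster_states(rng.standard_normal((5, 2)), k=6)


class TestElbowCurve:
    def test_knee_at_true_cluster_count(self, rng):
        X, _ = make_blobs(rng, [(-6, 0), (0, 6), (6, 0)], 50, spread=0.2)
        curve = elbow_curve(X, k_range=[2, 3, 4, 5], n_init=5, seed=0).set_index("k")
        drop_23 = curve.loc[2, "ratio"] - curve.loc[3, "ratio"]
        drop_34 = curve.loc[3, "ratio"] - curve.loc[4, "ratio"]
        assert drop_23 > 10 * max(drop_34, 1e-12)

    def test_wss_zero_when_k_equals_n(self, rng):
        X = rng.standard_normal((6, 2))
        curve = elbow_curve(X, k_range=[6], n_init=3, seed=0)
        assert curve["wss"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_wss_nonincreasing_in_k(self, rng):
        X = rng.standard_normal((60, 3))
        curve = elbow_curve(X, k_range=[1, 2, 3, 4], n_init=10, seed=0)
        assert np.all(np.diff(curve["wss"]) <= 1e-9)


class TestStateDynamics:
    def test_hand_example(self):
        dyn = state_dynamics(np.array([[0, 0, 1, 1]]), k=2, tr=2.0)
        np.testing.assert_allclose(dyn.fraction[0], [0.5, 0.5])
        assert dyn.mean_dwell[0, 0] == pytest.approx(4.0)  # 2 samples x 2 s
        assert dyn.mean_dwell[0, 1] == pytest.approx(4.0)

    def test_constant_sequence(self):
        dyn = state_dynamics(np.zeros((1, 10), dtype=int), k=2, tr=1.0)
        assert dyn.fraction[0, 0] == 1.0
        assert dyn.transition[0, 0, 0] == 1.0
        assert dyn.transition[0, 1, 1] == 1.0  # never-visited: self-prob 1
        assert np.isnan(dyn.mean_dwell[0, 1])

    def test_alternating_sequence_unit_dwell(self):
        seq = np.tile([0, 1], 10)[None, :]
        dyn = state_dynamics(seq, k=2, tr=0.72)
        np.testing.assert_allclose(dyn.mean_dwell[0], 0.72)

    def test_rows_normalize(self, rng):
        seq = rng.integers(0, 3, size=(5, 200))
        dyn = state_dynamics(seq, k=3)
        np.testing.assert_allclose(dyn.fraction.sum(axis=1), 1.0)
        np.testing.assert_allclose(dyn.transition.sum(axis=2), 1.0)

    def test_label_permutation_invariance(self, rng):
        seq = rng.integers(0, 3, size=(4, 150))
        perm = np.array([2, 0, 1])
        dyn = state_dynamics(seq, k=3, tr=1.5)
        dyn_p = state_dynamics(perm[seq], k=3, tr=1.5)
        # old state l becomes new state perm[l]
        np.testing.assert_allclose(dyn.fraction, dyn_p.fraction[:, perm])
        np.testing.assert_allclose(dyn.mean_dwell, dyn_p.mean_dwell[:, perm])


def synthetic_dynamics(rng, n_sub, k=3, dwell_shift=0.0, shift_state=1):
    dwell = 5 + rng.standard_normal((n_sub, k))
    dwell[:, shift_state] += dwell_shift
    frac = rng.dirichlet(np.ones(k), size=n_sub)
    trans = rng.dirichlet(np.ones(k), size=(n_sub, k))
    return StateDynamics(mean_dwell=dwell, fraction=frac, transition=trans, tr=1.0)


class TestGroupCompare:
    def test_identical_groups_no_flags(self, rng):
        dyn = synthetic_dynamics(rng, 40)
        comp = group_compare(dyn, dyn)
        assert not comp.table["significant"].any()

    def test_planted_dwell_shift_flagged(self, rng):
        a = synthetic_dynamics(rng, 40, dwell_shift=3.0)
        b = synthetic_dynamics(rng, 40)
        comp = group_compare(a, b)
        row = comp.table.query("metric == 'mean_dwell' and state == '2'")
        assert bool(row["significant"].iloc[0])

    def test_adjusted_p_not_below_raw(self, rng):
        a = synthetic_dynamics(rng, 20, dwell_shift=1.0)
        b = synthetic_dynamics(rng, 20)
        comp = group_compare(a, b)
        ok = comp.table.dropna(subset=["p", "p_adj"])
        assert np.all(ok["p_adj"] >= ok["p"] - 1e-12)

    def test_signed_logp_matrix_shape_and_sign(self, rng):
        a = synthetic_dynamics(rng, 25)
        b = synthetic_dynamics(rng, 25)
        comp = group_compare(a, b)
        assert comp.signed_logp_transition.shape == (3, 3)

    def test_degenerate_metric_skipped_with_notice(self, rng):
        a = synthetic_dynamics(rng, 10)
        b = synthetic_dynamics(rng, 10)
        a.mean_dwell[:, 0] = 5.0
        b.mean_dwell[:, 0] = 5.0
        comp = group_compare(a, b)
        row = comp.table.query("metric == 'mean_dwell' and state == '1'")
        assert "skipped" in row["note"].iloc[0]
        assert np.isnan(row["p"].iloc[0])

    def test_too_few_subjects_rejected(self, rng):
        a = synthetic_dynamics(rng, 1)
        with pytest.raises(ValueError):
            group_compare(a, a)
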