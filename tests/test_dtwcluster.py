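"""DTW distance (with brute-force oracle), DBA, temporal k-means, DB index."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cogtraj import dtwcluster as dc
from cogtraj.dtwcluster import Trajectory, _Packed


# ---------------------------------------------------------------------------
# independent oracle: exhaustive enumeration of monotone alignment paths


def brute_force_dtw(A, B):
    A = np.atleast_2d(np.asarray(A, dtype=float))
    B = np.atleast_2d(np.asarray(B, dtype=float))
    la, lb = A.shape[0], B.shape[0]
    best = [np.inf]

    def cost(i, j):
        d = A[i] - B[j]
        return float(d @ d)

    def walk(i, j, acc):
        if (i, j) == (la - 1, lb - 1):
            best[0] = min(best[0], acc)
            return
        for di, dj in ((1, 1), (1, 0), (0, 1)):
            ni, nj = i + di, j + dj
            if ni < la and nj < lb:
                walk(ni, nj, acc + cost(ni, nj))

    walk(0, 0, cost(0, 0))
    return np.sqrt(best[0])


def _traj(values, d=1):
    X = np.asarray(values, dtype=float).reshape(-1, d)
    ages = 57.0 + np.arange(X.shape[0])
    return Trajectory("p", ages, X)


class TestDTWDistance:
    def test_identical_sequences_zero(self):
        t = _traj([0.0, 1.0, 2.0])
        assert dc.dtw_distance(t, t) == 0.0

    def test_forced_alignment_length_one_vs_two(self):
        v, w1, w2 = 3.0, 1.0, 2.0
        expected = np.sqrt((v - w1) ** 2 + (v - w2) ** 2)
        assert dc.dtw_distance(_traj([v]), _traj([w1, w2])) == pytest.approx(expected)

    def test_matches_enumeration_on_1d_example(self):
        a, b = [0.0, 1.0, 2.0], [0.0, 2.0]
        assert dc.dtw_distance(_traj(a), _traj(b)) == pytest.approx(
            brute_force_dtw(np.array(a).reshape(-1, 1), np.array(b).reshape(-1, 1)))

    def test_symmetry_and_nonnegativity(self, rng):
        for _ in range(50):
            la, lb, d = rng.integers(1, 4), rng.integers(1, 4), rng.integers(1, 4)
            A = rng.normal(size=(la, d))
            B = rng.normal(size=(lb, d))
            dab = dc.dtw_distance(A, B)
            assert dab >= 0
            assert dab == pytest.approx(dc.dtw_distance(B, A))

    def test_dimension_mismatch_and_empty_rejected(self):
        with pytest.raises(ValueError, match="dimension"):
            dc.dtw_distance(np.zeros((2, 2)), np.zeros((2, 3)))
        with pytest.raises(ValueError, match="empty"):
            dc.dtw_distance(np.zeros((0, 1)), np.zeros((2, 1)))

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(
        a=st.lists(st.sampled_from([-2.0, -0.5, 0.0, 1.0, 3.0]), min_size=1, max_size=4),
        b=st.lists(st.sampled_from([-2.0, -0.5, 0.0, 1.0, 3.0]), min_size=1, max_size=4),
    )
    def test_property_matches_bruteforce_1d(self, a, b):
        A = np.array(a).reshape(-1, 1)
        B = np.array(b).reshape(-1, 1)
        assert dc.dtw_distance(A, B) == pytest.approx(brute_force_dtw(A, B), abs=1e-12)

    @settings(max_examples=80, deadline=None, derandomize=True)
    @given(
        a=st.lists(st.tuples(st.sampled_from([-1.0, 0.0, 2.0]),
                             st.sampled_from([-1.0, 0.0, 2.0])),
                   min_size=1, max_size=4),
        b=st.lists(st.tuples(st.sampled_from([-1.0, 0.0, 2.0]),
                             st.sampled_from([-1.0, 0.0, 2.0])),
                   min_size=1, max_size=4),
    )
    def test_property_matches_bruteforce_2d(self, a, b):
        A = np.array(a)
        B = np.array(b)
        assert dc.dtw_distance(A, B) == pytest.approx(brute_force_dtw(A, B), abs=1e-12)


class TestBatchEngine:
    def test_batch_distances_equal_scalar_dtw(self, rng):
        trajs = []
        for i in range(30):
            L = int(rng.integers(1, 4))
            trajs.append(Trajectory(f"P{i}", 57.0 + np.arange(L),
                                    rng.normal(size=(L, 3))))
        packed = _Packed(trajs)
        for Lc in (1, 2, 3):
            C = rng.normal(size=(Lc, 3))
            batch = np.sqrt(packed.sq_distances(C))
            scalar = np.array([dc.dtw_distance(t, C) for t in trajs])
            assert np.allclose(batch, scalar, atol=1e-10)

    def test_alignment_counts_cover_all_centroid_bins(self, rng):
        trajs = [Trajectory(f"P{i}", 57.0 + np.arange(2), rng.normal(size=(2, 2)))
                 for i in range(10)]
        packed = _Packed(trajs)
        C = rng.normal(size=(3, 2))
        sums, counts, final = packed.align_sums(C)
        # boundary + continuity: every member's path visits every centroid bin
        assert (counts >= len(trajs)).all()
        assert np.allclose(final, packed.sq_distances(C))


class TestDBA:
    def test_single_trajectory_is_its_own_centroid(self):
        t = _traj([1.0, 2.0, 3.0])
        C = dc.dba_centroid([t], L=3)
        assert np.allclose(C, t.X)

    def test_two_identical_trajectories(self):
        t1, t2 = _traj([0.0, 1.0, 0.5]), _traj([0.0, 1.0, 0.5])
        C = dc.dba_centroid([t1, t2], L=3)
        assert np.allclose(C, t1.X)
        assert dc.dtw_distance(C, t1) == pytest.approx(0.0, abs=1e-12)

    def test_constant_sequences_average_pointwise(self):
        C = dc.dba_centroid([_traj([0.0, 0.0, 0.0]), _traj([2.0, 2.0, 2.0])], L=3)
        assert np.allclose(C, np.ones((3, 1)))

    def test_objective_nonincreasing(self, rng):
        trajs = [Trajectory(f"P{i}", 57.0 + np.arange(3), rng.normal(size=(3, 2)))
                 for i in range(20)]
        packed = _Packed(trajs)
        C = rng.normal(size=(3, 2))
        objs = []
        for _ in range(8):
            sums, counts, final = packed.align_sums(C)
            objs.append(final.sum())
            C = np.where(counts[:, None] > 0, sums / np.maximum(counts[:, None], 1), C)
        assert all(objs[i + 1] <= objs[i] + 1e-9 for i in range(len(objs) - 1))


def _blob_trajectories(rng, centers, n_per, d=2, sd=0.05):
    trajs, truth = [], []
    i = 0
    for c_idx, center in enumerate(centers):
        for _ in range(n_per):
            L = int(rng.integers(1, 4))
            X = np.full((L, d), center) + rng.normal(0, sd, size=(L, d))
            trajs.append(Trajectory(f"P{i}", 57.0 + np.arange(L), X))
            truth.append(c_idx)
            i += 1
    return trajs, np.array(truth)


class TestTemporalKMeans:
    def test_k1_groups_everything(self, rng):
        trajs, _ = _blob_trajectories(rng, [0.0, 5.0], 5)
        model = dc.temporal_kmeans(trajs, 1, seed=0, n_init=2)
        assert set(model.labels) == {1}

    def test_two_blobs_recovered_exactly(self, rng):
        from sklearn.metrics import adjusted_rand_score
        trajs, truth = _blob_trajectories(rng, [0.0, 5.0], 20)
        model = dc.temporal_kmeans(trajs, 2, seed=0)
        ari = adjusted_rand_score(truth, model.labels_array(trajs))
        assert ari == 1.0

    def test_deterministic_given_seed(self, rng):
        trajs, _ = _blob_trajectories(rng, [0.0, 3.0, 6.0], 10)
        m1 = dc.temporal_kmeans(trajs, 3, seed=5)
        m2 = dc.temporal_kmeans(trajs, 3, seed=5)
        assert m1.inertia == m2.inertia
        assert (m1.labels == m2.labels).all()

    def test_objective_history_nonincreasing(self, rng):
        trajs, _ = _blob_trajectories(rng, [0.0, 2.0, 4.0], 15, sd=0.5)
        model = dc.temporal_kmeans(trajs, 3, seed=1, n_init=3)
        h = model.objective_history
        assert all(h[i + 1] <= h[i] + 1e-9 for i in range(len(h) - 1))

    def test_k_exceeding_n_rejected(self, rng):
        trajs, _ = _blob_trajectories(rng, [0.0], 3)
        with pytest.raises(ValueError, match="exceeds"):
            dc.temporal_kmeans(trajs, 10)

    def test_identical_data_warns(self):
        trajs = [_traj([1.0, 1.0]) for _ in range(6)]
        trajs = [Trajectory(f"P{i}", t.ages, t.X) for i, t in enumerate(trajs)]
        with pytest.warns(UserWarning, match="identical"):
            dc.temporal_kmeans(trajs, 2, seed=0, n_init=1)

    def test_no_empty_clusters_returned(self, rng):
        trajs, _ = _blob_trajectories(rng, [0.0, 0.1], 10, sd=1.0)
        model = dc.temporal_kmeans(trajs, 2, seed=2)
        assert set(model.labels.unique()) == {1, 2}


class TestDaviesBouldin:
    def test_zero_scatter_distinct_centroids_gives_zero(self):
        trajs = [_traj([0.0, 0.0, 0.0]), _traj([5.0, 5.0, 5.0])]
        trajs = [Trajectory(f"P{i}", t.ages, t.X) for i, t in enumerate(trajs)]
        model = dc.temporal_kmeans(trajs, 2, seed=0, n_init=1)
        assert dc.davies_bouldin(trajs, model) == pytest.approx(0.0, abs=1e-12)

    def test_direct_formula_two_clusters(self):
        # S1 = S2 = 1, M12 = 4 -> DB = 0.5; engineered via hand-built model
        t1 = [_traj([0.0 - 1.0]), _traj([0.0 + 1.0])]
        t2 = [_traj([4.0 - 1.0]), _traj([4.0 + 1.0])]
        trajs = [Trajectory(f"P{i}", t.ages, t.X) for i, t in enumerate(t1 + t2)]
        model = dc.ClusterModel(
            k=2,
            centroids=[np.array([[0.0]]), np.array([[4.0]])],
            labels=pd.Series([1, 1, 2, 2], index=[t.participant_id for t in trajs]),
            inertia=4.0, objective_history=[], iterations_run=1, seed=0,
        )
        assert dc.davies_bouldin(trajs, model) == pytest.approx(0.5)

    def test_matches_independent_reimplementation(self, rng):
        trajs, _ = _blob_trajectories(rng, [0.0, 2.0, 5.0], 8, sd=0.4)
        model = dc.temporal_kmeans(trajs, 3, seed=3)
        db = dc.davies_bouldin(trajs, model)
        # independent recomputation from pairwise distances
        labels = model.labels_array(trajs)
        S = []
        for c in range(3):
            members = [t for t, l in zip(trajs, labels) if l == c + 1]
            S.append(np.mean([dc.dtw_distance(t, model.centroids[c]) for t in members]))
        worst = []
        for i in range(3):
            ratios = [(S[i] + S[j]) / dc.dtw_distance(model.centroids[i],
                                                      model.centroids[j])
                      for j in range(3) if j != i]
            worst.append(max(ratios))
        assert db == pytest.approx(np.mean(worst), rel=1e-12)

    def test_k1_rejected(self, rng):
        trajs, _ = _blob_trajectories(rng, [0.0], 5)
        model = dc.temporal_kmeans(trajs, 1, seed=0, n_init=1)
        with pytest.raises(ValueError, match="k >= 2"):
            dc.davies_bouldin(trajs, model)


class TestSelectK:
    def test_two_blobs_select_two(self, rng):
        trajs, _ = _blob_trajectories(rng, [0.0, 5.0], 15)
        k, curve, models = dc.select_k(trajs, range(2, 6), seed=0, n_init=3)
        assert k == 2

    def test_singleton_range(self, rng):
        trajs, _ = _blob_trajectories(rng, [0.0, 5.0, 10.0], 5)
        k, curve, _ = dc.select_k(trajs, [3], seed=0, n_init=2)
        assert k == 3 and len(curve) == 1

    def test_empty_range_rejected(self, rng):
        trajs, _ = _blob_trajectories(rng, [0.0], 5)
        with pytest.raises(ValueError, match="empty"):
            dc.select_k(trajs, [], seed=0)


class TestLabelArchetypes:
    @staticmethod
    def _model_and_composite(rng):
        # four constant-level groups; one low and one high group decline
        spec = {"A": (-4.0, 0.0), "B": (-1.5, -0.25), "C": (1.5, -0.12), "D": (4.0, 0.0)}
        trajs, rows = [], []
        i = 0
        for _name, (level, slope) in spec.items():
            for _ in range(8):
                ages = np.array([57.0, 62.0, 67.0])
                vals = level + slope * (ages - 57) + rng.normal(0, 0.05, 3)
                trajs.append(Trajectory(f"P{i:02d}", ages, vals.reshape(-1, 1)))
                for a, v in zip(ages, vals):
                    rows.append((f"P{i:02d}", a, v))
                i += 1
        comp = pd.DataFrame(rows, columns=["participant_id", "age", "value"])
        model = dc.temporal_kmeans(trajs, 4, seed=0)
        return model, comp

    def test_mapping_matches_generated_structure(self, rng):
        model, comp = self._model_and_composite(rng)
        mapping = dc.label_archetypes(model, comp)
        named = comp.merge(model.labels.rename("cluster"), left_on="participant_id",
                           right_index=True)
        named["arch"] = named["cluster"].map(mapping)
        levels = named.groupby("arch")["value"].mean()
        assert levels["low_stable"] < levels["low_declining"] \
            < levels["high_lower"] < levels["high_upper"]

    def test_inverted_orientation_flips_low_high(self, rng):
        model, comp = self._model_and_composite(rng)
        normal = dc.label_archetypes(model, comp)
        flipped = dc.label_archetypes(model, comp.assign(value=-comp["value"]),
                                      higher_is_better=False)
        assert normal == flipped

    def test_non_four_k_gets_rank_names(self, rng):
        trajs, _ = _blob_trajectories(rng, [0.0, 3.0, 6.0], 6)
        model = dc.temporal_kmeans(trajs, 3, seed=0, n_init=2)
        rows = [(t.participant_id, 60.0, float(t.X.mean())) for t in trajs]
        comp = pd.DataFrame(rows, columns=["participant_id", "age", "value"])
        mapping = dc.label_archetypes(model, comp)
        assert sorted(mapping.values()) == [
            "level_rank_1_of_3", "level_rank_2_of_3", "level_rank_3_of_3"]
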