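import numpy as np
import pandas as pd
import pytest

import voltphys as vp
from voltphys import classify as vc


@pytest.fixture(scope="module")
def blob_model(two_blob_features):
    X, truth = two_blob_features
    Z, params = vc.standardize(X)
    link, labels, k, cut = vc.ward_cluster(Z)
    model = vc.build_model(Z, labels, params, cutoff=cut)
    return Z, params, labels, model, truth


def _hand_built_model(k=10, dim=29, seed=0):
    rng = np.random.default_rng(seed)
    C = rng.normal(0, 1, (k, dim))
    params = vc.StandardizeParams(
        columns=[f"f{j}" for j in range(dim)],
        mean=np.zeros(dim), sd=np.ones(dim), median=np.zeros(dim))
    centroids = pd.DataFrame(C, index=range(1, k + 1),
                             columns=params.columns)
    return vc.ClusterModel(centroids=centroids, params=params)


def _brute_force_consensus(v, model, top=3):
    """Independent oracle: rank by explicit loops, intersect, min rank sum."""
    C = model.centroids.to_numpy(float)
    ids = list(model.centroids.index)
    d = [float(np.sqrt(((c - v) ** 2).sum())) for c in C]
    r = [float(np.corrcoef(v, c)[0, 1]) for c in C]
    by_d = sorted(range(len(ids)), key=lambda i: d[i])
    by_r = sorted(range(len(ids)), key=lambda i: -r[i])
    rank_d = {i: by_d.index(i) + 1 for i in range(len(ids))}
    rank_r = {i: by_r.index(i) + 1 for i in range(len(ids))}
    inter = set(by_d[:top]) & set(by_r[:top])
    if not inter:
        return None
    best = min(inter, key=lambda i: (rank_d[i] + rank_r[i], rank_d[i]))
    return ids[best]


class TestStandardize:
    def test_z_scores(self):
        Z, params = vc.standardize(np.array([[1.0], [2.0], [3.0]]))
        assert np.allclose(Z[:, 0], [-1.2247, 0, 1.2247], atol=1e-3)

    def test_standardized_input_unchanged(self, two_blob_features):
        X, _ = two_blob_features
        Z, params = vc.standardize(X)
        Z2, _ = vc.standardize(Z)
        assert np.allclose(Z, Z2, atol=1e-10)

    def test_constant_column_dropped(self):
        X = np.column_stack([np.arange(5.0), np.full(5, 3.0)])
        with pytest.warns(UserWarning, match="zero-variance"):
            Z, params = vc.standardize(X)
        assert Z.shape[1] == 1 and params.dropped == ["f1"]

    def test_nan_median_imputation(self):
        X = np.array([[1.0, 1.0], [np.nan, 2.0], [3.0, 3.0]])
        Z, params = vc.standardize(X)
        assert np.isfinite(Z).all()
        assert params.median[0] == 2.0

    def test_params_apply_matches_training_transform(self, two_blob_features):
        X, _ = two_blob_features
        Z, params = vc.standardize(X)
        assert np.allclose(params.apply(X), Z)


class TestWardCluster:
    def test_two_blobs_auto_cutoff_gives_two(self, blob_model):
        _, _, labels, model, truth = blob_model
        assert model.k == 2
        # labels match generation up to relabeling
        a = labels[truth == 0]
        b = labels[truth == 1]
        assert len(set(a)) == 1 and len(set(b)) == 1 and a[0] != b[0]

    def test_single_blob_high_cutoff_gives_one(self):
        rng = np.random.default_rng(2)
        X = rng.normal(0, 0.1, (50, 5))
        _, labels, k, _ = vc.ward_cluster(X, cutoff=1e6)
        assert k == 1 and np.all(labels == 1)

    def test_row_permutation_permutes_labels(self, two_blob_features):
        X, _ = two_blob_features
        Z, _ = vc.standardize(X)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(Z))
        _, lab_a, _, _ = vc.ward_cluster(Z, cutoff=30.0)
        _, lab_b, _, _ = vc.ward_cluster(Z[perm], cutoff=30.0)
        # co-membership structure is invariant
        co_a = lab_a[perm][:, None] == lab_a[perm][None, :]
        co_b = lab_b[:, None] == lab_b[None, :]
        assert np.array_equal(co_a, co_b)

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError, match="rows"):
            vc.ward_cluster(np.zeros((1, 3)))


class TestClusterModel:
    def test_centroids_are_member_means(self, blob_model):
        Z, _, labels, model, _ = blob_model
        for cid in model.centroids.index:
            expect = Z[labels == cid].mean(axis=0)
            assert np.allclose(model.centroids.loc[cid], expect)

    def test_identical_vectors_centroid_is_that_vector(self):
        params = vc.StandardizeParams(columns=["a", "b"],
                                      mean=np.zeros(2), sd=np.ones(2),
                                      median=np.zeros(2))
        Z = np.tile([1.5, -2.0], (4, 1))
        model = vc.build_model(Z, np.ones(4, int), params)
        assert np.allclose(model.centroids.iloc[0], [1.5, -2.0])

    def test_round_trip_serialization(self, blob_model, tmp_path):
        Z, _, _, model, _ = blob_model
        model.to_json(tmp_path / "model.json")
        back = vp.ClusterModel.from_json(tmp_path / "model.json")
        for z in Z[:20]:
            assert vc.classify_consensus(z, model)[0] == \
                vc.classify_consensus(z, back)[0]

    def test_empty_cluster_rejected(self):
        params = vc.StandardizeParams(columns=["a"], mean=np.zeros(1),
                                      sd=np.ones(1), median=np.zeros(1))
        with pytest.raises(ValueError, match="empty"):
            vc.build_model(np.zeros((0, 1)), np.array([], int), params)


class TestConsensusClassifier:
    def test_centroid_classifies_to_itself(self):
        model = _hand_built_model()
        for cid in model.centroids.index:
            got, diag = vc.classify_consensus(
                model.centroids.loc[cid].to_numpy(), model)
            assert got == cid
            assert diag["top_distance"][0] == cid
            assert diag["top_correlation"][0] == cid

    def test_agrees_with_brute_force_on_hand_built_model(self):
        model = _hand_built_model(k=10)
        rng = np.random.default_rng(3)
        for _ in range(200):
            v = rng.normal(0, 1.5, 29)
            assert vc.classify_consensus(v, model)[0] == \
                _brute_force_consensus(v, model)

    def test_assignment_member_of_both_top3(self):
        model = _hand_built_model(k=10, seed=4)
        rng = np.random.default_rng(5)
        for _ in range(100):
            v = rng.normal(0, 2, 29)
            got, diag = vc.classify_consensus(v, model)
            if got is not None:
                assert got in diag["top_distance"]
                assert got in diag["top_correlation"]

    def test_disjoint_top3_unassigned(self):
        # centroids arranged so distance ranking and correlation ranking
        # favour disjoint sets: near-origin centroids win on distance,
        # far scaled copies of the query win on correlation
        rng = np.random.default_rng(6)
        base = rng.normal(0, 1, 29)
        C = np.vstack([rng.normal(0, 0.05, (3, 29)),     # close, uncorrelated
                       50 + 5 * base, 60 + 6 * base, 70 + 7 * base])
        params = vc.StandardizeParams(
            columns=[f"f{j}" for j in range(29)], mean=np.zeros(29),
            sd=np.ones(29), median=np.zeros(29))
        model = vc.ClusterModel(
            centroids=pd.DataFrame(C, index=range(1, 7),
                                   columns=params.columns), params=params)
        got, diag = vc.classify_consensus(base * 0.1, model)
        assert set(diag["top_distance"]).isdisjoint(diag["top_correlation"])
        assert got is None

    def test_correlation_ranking_affine_invariant(self):
        model = _hand_built_model(k=6, seed=7)
        rng = np.random.default_rng(8)
        v = rng.normal(0, 1, 29)
        _, d1 = vc.classify_consensus(v, model)
        _, d2 = vc.classify_consensus(3.0 * v + 10.0, model)
        assert d1["top_correlation"] == d2["top_correlation"]
        assert d1["top_distance"] != d2["top_distance"]


class TestClusterLoad:
    def test_rows_at_one_centroid_load_there(self):
        model = _hand_built_model(k=5)
        X = np.tile(model.centroids.loc[4].to_numpy(), (20, 1))
        load = vc.cluster_load(X, model)
        assert load[4] == 1.0 and load.drop(4).sum() == 0.0

    def test_loads_match_sampling_proportions(self, blob_model):
        _, params, _, model, _ = blob_model
        rng = np.random.default_rng(9)
        c1 = model.centroids.iloc[0].to_numpy()
        c2 = model.centroids.iloc[1].to_numpy()
        Z = np.vstack([c1 + rng.normal(0, 0.2, (70, len(c1))),
                       c2 + rng.normal(0, 0.2, (30, len(c2)))])
        X = Z * params.sd + params.mean       # back to raw scale
        load = vc.cluster_load(X, model)
        assert load[model.centroids.index[0]] == pytest.approx(0.7, abs=0.05)
        assert load[model.centroids.index[1]] == pytest.approx(0.3, abs=0.05)

    def test_proportions_sum_to_one(self, blob_model):
        _, params, _, model, _ = blob_model
        rng = np.random.default_rng(10)
        X = rng.normal(0, 5, (40, len(params.columns)))
        assert vc.cluster_load(X, model).sum() == pytest.approx(1.0)

    def test_empty_population_rejected(self, blob_model):
        _, _, _, model, _ = blob_model
        with pytest.raises(ValueError, match="empty"):
            vc.cluster_load(np.zeros((0, 29)), model)


def test_self_consistency_reports_majority(blob_model):
    Z, _, labels, model, _ = blob_model
    rate = vc.self_consistency(Z, labels, model)
    assert rate >= 0.9
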