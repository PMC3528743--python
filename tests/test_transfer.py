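"""HEGS transfer: clustering-based KL divergence, source-sample
selection, similarity-preserving output generation, and the full loop's
degenerate/deterministic behavior."""

import numpy as np
import pytest

from sitransfer.records import DomainDataset
from sitransfer.ridge import fit_ridge, predict
from sitransfer.transfer import (
    ClusterModel,
    TransferConfig,
    cluster_combined,
    generate_outputs,
    hegs_fit,
    kl_divergence,
    select_source_samples,
)


def _manual_cluster_model(assignments, n_target, n_features=2):
    assignments = np.asarray(assignments)
    X = np.zeros((len(assignments), n_features))
    k = int(assignments.max()) + 1
    return ClusterModel(
        k=k,
        assignments=assignments,
        centroids=np.zeros((k, n_features)),
        seed=0,
        X_combined=X,
        n_target=n_target,
    )


class TestKLDivergence:
    def test_identical_proportions_give_zero(self):
        # target: 2 in c0, 2 in c1; source: same proportions
        model = _manual_cluster_model([0, 0, 1, 1, 0, 0, 1, 1], n_target=4)
        rep = kl_divergence(model, 4, 4, use_centroid_weighting=False)
        assert rep.total == pytest.approx(0.0)
        assert not rep.has_infinite

    def test_two_cluster_hand_value(self):
        # P_S = (0.5, 0.5), P_T = (0.25, 0.75)
        # 0.5 ln 2 + 0.5 ln(2/3) = 0.143841...
        target = [0] * 1 + [1] * 3
        source = [0] * 2 + [1] * 2
        model = _manual_cluster_model(target + source, n_target=4)
        rep = kl_divergence(model, 4, 4, use_centroid_weighting=False)
        expected = 0.5 * np.log(2) + 0.5 * np.log(2 / 3)
        assert rep.total == pytest.approx(expected, abs=1e-6)

    def test_source_only_cluster_flagged_infinite(self):
        target = [0, 0, 1, 1]
        source = [0, 0, 2, 2]  # cluster 2 has no target members
        model = _manual_cluster_model(target + source, n_target=4)
        rep = kl_divergence(model, 4, 4, use_centroid_weighting=False)
        assert rep.has_infinite
        inf_terms = [t for t in rep.per_cluster if t.infinite]
        assert [t.cluster_id for t in inf_terms] == [2]
        assert np.isfinite(rep.total)

    def test_centroid_weighting_scales_terms(self, rng):
        Xt = rng.normal(0, 1, (20, 3))
        Xs = rng.normal(0.5, 1, (20, 3))
        model = cluster_combined(Xt, Xs, k=3, seed=0)
        plain = kl_divergence(model, 20, 20, use_centroid_weighting=False)
        weighted = kl_divergence(model, 20, 20, use_centroid_weighting=True)
        for a, b in zip(plain.per_cluster, weighted.per_cluster):
            if not a.infinite and a.term > 0:
                assert b.term >= a.term

    def test_empty_side_rejected(self):
        model = _manual_cluster_model([0, 0], n_target=2)
        with pytest.raises(ValueError):
            kl_divergence(model, 2, 0)


class TestClusterCombined:
    def test_separated_blobs_recovered(self, rng):
        a = rng.normal(0, 0.5, (30, 2))
        b = rng.normal(10, 0.5, (30, 2))
        model = cluster_combined(a, b, k=2, seed=0)
        first, second = model.assignments[:30], model.assignments[30:]
        assert len(set(first.tolist())) == 1
        assert len(set(second.tolist())) == 1
        assert first[0] != second[0]

    def test_k_equals_n(self, rng):
        X = rng.normal(size=(4, 2))
        model = cluster_combined(X[:2], X[2:], k=4, seed=0)
        assert len(set(model.assignments.tolist())) == 4

    def test_deterministic_given_seed(self, rng):
        Xt, Xs = rng.normal(size=(15, 3)), rng.normal(size=(25, 3))
        m1 = cluster_combined(Xt, Xs, k=4, seed=7)
        m2 = cluster_combined(Xt, Xs, k=4, seed=7)
        assert np.array_equal(m1.assignments, m2.assignments)


class TestSelection:
    def test_two_blob_purity(self):
        rng = np.random.default_rng(0)
        Xt = rng.normal(0, 1, (60, 5))
        Xs = np.vstack(
            [rng.normal(0, 1, (100, 5)), rng.normal(8, 1, (100, 5))]
        )
        target = DomainDataset("t", Xt, np.zeros(60), role="target")
        source = DomainDataset("s", Xs, np.zeros(200))
        idx, rep = select_source_samples(
            source, target, TransferConfig(seed=0, k_clusters=2)
        )
        assert len(idx) > 0
        assert np.mean(idx < 100) >= 0.9

    def test_disjoint_support_selects_nothing(self):
        rng = np.random.default_rng(1)
        Xt = rng.normal(0, 0.5, (30, 4))
        Xs = rng.normal(50, 0.5, (60, 4))
        target = DomainDataset("t", Xt, np.zeros(30), role="target")
        source = DomainDataset("s", Xs, np.zeros(60))
        idx, rep = select_source_samples(
            source, target, TransferConfig(seed=0, k_clusters=2)
        )
        # all source mass sits in target-empty clusters -> nothing selectable
        assert rep.has_infinite
        assert len(idx) == 0

    def test_cap_respected(self):
        rng = np.random.default_rng(2)
        Xt = rng.normal(0, 1, (10, 3))
        Xs = rng.normal(0, 1, (200, 3))
        target = DomainDataset("t", Xt, np.zeros(10), role="target")
        source = DomainDataset("s", Xs, np.zeros(200))
        cfg = TransferConfig(seed=0, max_augment_ratio=2.0)
        idx, _ = select_source_samples(source, target, cfg)
        assert len(idx) <= 20


class TestGenerateOutputs:
    @pytest.fixture()
    def setup(self, rng):
        X = rng.normal(size=(40, 3))
        y = rng.uniform(0.2, 0.8, 40)
        model = fit_ridge(X, y, 1.0)
        sel_X = rng.normal(size=(30, 3))
        src_y = rng.uniform(0, 1, 30)
        return model, sel_X, src_y

    def test_alpha_zero_returns_predictions(self, setup):
        model, sel_X, src_y = setup
        cfg = TransferConfig(seed=0, shrinkage=0.0)
        out = generate_outputs(sel_X, model, cfg, (-10, 10), source_outputs=src_y)
        assert np.allclose(out, predict(model, sel_X))

    def test_alpha_one_collapses_to_group_centers(self, setup):
        model, sel_X, src_y = setup
        cfg = TransferConfig(seed=0, shrinkage=1.0, n_output_groups=3)
        out = generate_outputs(sel_X, model, cfg, (-10, 10), source_outputs=src_y)
        assert len(np.unique(np.round(out, 12))) <= 3

    def test_order_preserved_within_groups(self, setup):
        model, sel_X, src_y = setup
        cfg = TransferConfig(seed=0, shrinkage=0.5, n_output_groups=3)
        out = generate_outputs(sel_X, model, cfg, (-10, 10), source_outputs=src_y)
        y_hat = predict(model, sel_X)
        # within a group the affine map preserves pairwise order
        cfg1 = TransferConfig(seed=0, shrinkage=1.0, n_output_groups=3)
        centers = generate_outputs(sel_X, model, cfg1, (-10, 10), source_outputs=src_y)
        for c in np.unique(centers):
            members = np.flatnonzero(centers == c)
            order_pred = np.argsort(y_hat[members], kind="stable")
            order_new = np.argsort(out[members], kind="stable")
            assert np.array_equal(order_pred, order_new)

    def test_outputs_clipped_to_target_range(self, setup):
        model, sel_X, src_y = setup
        cfg = TransferConfig(seed=0)
        out = generate_outputs(sel_X, model, cfg, (0.4, 0.6), source_outputs=src_y)
        assert out.min() >= 0.4 and out.max() <= 0.6

    def test_group_reduction_warns(self, setup):
        model, _, _ = setup
        cfg = TransferConfig(seed=0, n_output_groups=10)
        with pytest.warns(UserWarning, match="reducing output groups"):
            generate_outputs(
                np.zeros((2, 3)), model, cfg, (0, 1), source_outputs=np.array([0.1, 0.9])
            )


class TestHegsFit:
    def test_no_sources_equals_baseline_bitwise(self, benchmark0):
        tgt = benchmark0[1]
        train = tgt.subset(np.arange(20), role="target")
        hegs_model, results = hegs_fit(train, [], TransferConfig(seed=0), lam=1.0)
        base = fit_ridge(train.X, train.y, 1.0, feature_names=train.feature_names)
        assert np.array_equal(hegs_model.weights, base.weights)
        assert results == []

    def test_disjoint_sources_equal_baseline_bitwise(self, benchmark0):
        tgt = benchmark0[1]
        train = tgt.subset(np.arange(20), role="target")
        far = DomainDataset(
            "far", tgt.X[50:150] + 1000.0, tgt.y[50:150], role="source"
        )
        model, results = hegs_fit(train, [far], TransferConfig(seed=0), lam=1.0)
        base = fit_ridge(train.X, train.y, 1.0, feature_names=train.feature_names)
        assert len(results[0].selected_indices) == 0
        assert np.array_equal(model.weights, base.weights)

    def test_deterministic(self, benchmark0):
        tgt = benchmark0[1]
        train = tgt.subset(np.arange(30), role="target")
        sources = [benchmark0[0], benchmark0[2]]
        m1, r1 = hegs_fit(train, sources, TransferConfig(seed=5), lam=1.0)
        m2, r2 = hegs_fit(train, sources, TransferConfig(seed=5), lam=1.0)
        assert np.array_equal(m1.weights, m2.weights)
        for a, b in zip(r1, r2):
            assert np.array_equal(a.selected_indices, b.selected_indices)
            assert np.array_equal(a.generated_outputs, b.generated_outputs)

    def test_generated_outputs_within_target_range(self, benchmark0):
        tgt = benchmark0[1]
        train = tgt.subset(np.arange(25), role="target")
        sources = [d for i, d in enumerate(benchmark0) if i != 1]
        _, results = hegs_fit(train, sources, TransferConfig(seed=3), lam=1.0)
        lo, hi = train.y.min(), train.y.max()
        for res in results:
            if len(res.generated_outputs):
                assert res.generated_outputs.min() >= lo - 1e-12
                assert res.generated_outputs.max() <= hi + 1e-12

    def test_selection_capped_overall(self, benchmark0):
        tgt = benchmark0[1]
        train = tgt.subset(np.arange(20), role="target")
        sources = [d for i, d in enumerate(benchmark0) if i != 1]
        cfg = TransferConfig(seed=0, max_augment_ratio=2.0)
        _, results = hegs_fit(train, sources, cfg, lam=1.0)
        total = sum(len(r.selected_indices) for r in results)
        assert total <= 40
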