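import numpy as np
import pytest

from actitag import dmf
from actitag.tags import ActivityTag, TAG_ORDER


class TestStructure:
    def test_eight_nodes_ten_leaves(self):
        d = dmf.build_dichotomy()
        assert len(d.nodes) == 8
        leaves = d.leaves
        assert len(leaves) == 10
        assert set(leaves) == set(TAG_ORDER)

    def test_at_most_three_groups_per_node(self):
        d = dmf.build_dichotomy()
        assert max(len(n.groups) for n in d.nodes.values()) == 3

    def test_every_tag_has_unique_path(self):
        d = dmf.build_dichotomy()
        # a path is the node sequence plus the terminal group (tags sit/stand/
        # lie share the ternary leaf node but exit through different groups)
        paths = {
            t: (*d.path(t), d.nodes[d.path(t)[-1]].group_of(t)) for t in TAG_ORDER
        }
        assert len(set(paths.values())) == 10
        for t, p in paths.items():
            assert p[0] == "N1"
            assert 2 <= len(p) - 1 <= d.levels

    def test_node_groups_partition_subtree_tags(self):
        d = dmf.build_dichotomy()
        for node in d.nodes.values():
            for g, child in zip(node.groups, node.children):
                if child is not None:
                    assert d.nodes[child].tags == g  # no leakage across branches

    def test_one_vs_one_decomposition_size(self):
        assert dmf.one_vs_one_count(10) == 45


class TestLevelWeights:
    def test_single_level_carries_all_weight(self):
        assert dmf.level_weight(1, 1) == 1.0

    def test_four_levels_closed_form(self):
        got = [dmf.level_weight(4, k) for k in (1, 2, 3, 4)]
        np.testing.assert_allclose(got, [0.4, 0.3, 0.2, 0.1])

    @pytest.mark.parametrize("l", range(1, 11))
    def test_weights_sum_to_one_and_decrease(self, l):
        w = [dmf.level_weight(l, k) for k in range(1, l + 1)]
        assert sum(w) == pytest.approx(1.0)
        assert all(a > b for a, b in zip(w, w[1:]))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            dmf.level_weight(3, 4)
        with pytest.raises(ValueError):
            dmf.level_weight(3, 0)


class TestFusion:
    def test_unweighted_product(self):
        assert dmf.fuse_confidence_unweighted([0.9, 0.8]) == pytest.approx(0.72)
        assert dmf.fuse_confidence_unweighted([1.0, 1.0, 1.0]) == 1.0
        assert dmf.fuse_confidence_unweighted([0.9, 0.0, 0.8]) == 0.0

    def test_weighted_single_level(self):
        assert dmf.fuse_confidence_weighted([0.9], [1], l=1) == pytest.approx(0.9)

    def test_weighted_two_levels(self):
        got = dmf.fuse_confidence_weighted([1.0, 1.0], [1, 2], l=2)
        assert got == pytest.approx(2.0 / 9.0)  # (2/3)*(1/3)

    def test_weighted_not_exceeding_unweighted_for_deep_paths(self):
        confs, levels = [0.9, 0.8, 0.7], [1, 2, 3]
        w = dmf.fuse_confidence_weighted(confs, levels, l=5)
        assert w <= dmf.fuse_confidence_unweighted(confs)

    def test_monotone_in_path_confidence(self):
        lo = dmf.fuse_confidence_weighted([0.5, 0.8], [1, 2], l=5)
        hi = dmf.fuse_confidence_weighted([0.9, 0.8], [1, 2], l=5)
        assert hi >= lo

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            dmf.fuse_confidence_unweighted([])
        with pytest.raises(ValueError):
            dmf.fuse_confidence_unweighted([1.2])


@pytest.fixture(scope="module")
def trained(separable_clusters):
    X, y = separable_clusters
    cfg = dmf.DMFConfig(n_trees=30, sffs_max_features=3, sffs_prefilter=None)
    return X, y, dmf.train_dmf(X, y, config=cfg, rng_seed=0)


class TestTrainPredict:
    def test_resubstitution_perfect_on_separable_clusters(self, trained):
        X, y, model = trained
        preds = dmf.predict_dmf(X, model)
        assert all(p.tag is t for p, t in zip(preds, y))

    def test_path_confidences_valid_and_depth_bounded(self, trained):
        X, y, model = trained
        for p in dmf.predict_dmf(X[::25], model):
            assert all(0.0 <= c <= 1.0 for c in p.path_confidences)
            assert 2 <= len(p.path_nodes) <= 5
            assert 0.0 <= p.confidence <= 1.0

    def test_missing_tag_raises_with_node_and_tag_name(self, separable_clusters):
        X, y = separable_clusters
        keep = [i for i, t in enumerate(y) if t is not ActivityTag.WALK]
        with pytest.raises(ValueError, match="walk"):
            dmf.train_dmf(X[keep], [y[i] for i in keep], rng_seed=0)

    def test_same_seed_identical_predictions(self, separable_clusters):
        X, y = separable_clusters
        cfg = dmf.DMFConfig(n_trees=15, sffs_max_features=2, sffs_prefilter=None)
        a = dmf.train_dmf(X, y, config=cfg, rng_seed=3)
        b = dmf.train_dmf(X, y, config=cfg, rng_seed=3)
        pa = [p.tag for p in dmf.predict_dmf(X, a)]
        pb = [p.tag for p in dmf.predict_dmf(X, b)]
        assert pa == pb

    def test_dimension_mismatch_rejected(self, trained):
        X, y, model = trained
        with pytest.raises(ValueError, match="mismatch"):
            dmf.predict_dmf(X[:, :5], model)

    def test_save_load_roundtrip(self, trained, tmp_path):
        X, y, model = trained
        path = tmp_path / "model.joblib"
        dmf.save_model(model, path)
        loaded = dmf.load_model(path)
        pa = [p.tag for p in dmf.predict_dmf(X[::10], model)]
        pb = [p.tag for p in dmf.predict_dmf(X[::10], loaded)]
        assert pa == pb


def test_single_root_forest_equivalence(separable_clusters):
    """With an identity mapping and a single root node over all 10 tags,
    predict_dmf degenerates to a plain random forest."""
    from sklearn.ensemble import RandomForestClassifier

    from actitag.mapping import MetricMapping

    X, y = separable_clusters
    m = X.shape[1]
    yi = np.array([TAG_ORDER.index(t) for t in y])
    rf = RandomForestClassifier(n_estimators=30, random_state=7, n_jobs=1).fit(X, yi)

    # hand-build the degenerate structure (bypasses the 2-3 group contract
    # of the production tree on purpose)
    node = dmf.DichotomyNode.__new__(dmf.DichotomyNode)
    node.id, node.level = "ROOT", 1
    node.groups = [frozenset({t}) for t in TAG_ORDER]
    node.children = [None] * 10
    fitted = dmf._FittedNode(
        node=node, selected=list(range(m)), mu=np.zeros(m), sd=np.ones(m),
        mapping=MetricMapping(A=np.eye(m), objective=0.0, n_iter=0), forest=rf,
    )
    model = dmf.DMFModel(
        dichotomy=dmf.Dichotomy(nodes={"ROOT": node}, root="ROOT"),
        config=dmf.DMFConfig(), fitted={"ROOT": fitted}, n_features=m,
    )
    routed = [TAG_ORDER.index(p.tag) for p in dmf.predict_dmf(X, model)]
    np.testing.assert_array_equal(routed, rf.predict(X))
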