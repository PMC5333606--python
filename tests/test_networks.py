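"""Baseline fitting and deviation-network construction against brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from parenclitic import (
    BaselineModel,
    Relation,
    SyntheticConfig,
    binarize,
    compute_network,
    compute_networks,
    fit_baseline,
    generate_cohort,
)
from parenclitic.networks import InsufficientDataError, pair_indices

from oracles import network_weights_oracle, ols_pair_oracle


def frame_of(arrays: dict) -> pd.DataFrame:
    return pd.DataFrame(arrays)


class TestFitBaseline:
    def test_matches_closed_form_ols_on_four_points(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([1.1, 1.9, 3.2, 3.8])
        model = fit_baseline(frame_of({"f1": x, "f2": y}))
        alpha, beta, sigma = ols_pair_oracle(x, y)
        assert model.alpha[0] == pytest.approx(alpha, abs=1e-12)
        assert model.beta[0] == pytest.approx(beta, abs=1e-12)
        assert model.sigma[0] == pytest.approx(sigma, abs=1e-12)
        assert not model.degenerate[0]
        assert model.n_train == 4

    def test_perfect_collinearity_flagged_degenerate(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        model = fit_baseline(frame_of({"f1": x, "f2": 2 * x}))
        assert model.degenerate[0]
        assert model.sigma[0] == pytest.approx(0.0, abs=1e-12)

    def test_constant_predictor_flagged_degenerate(self):
        model = fit_baseline(frame_of({"f1": [1.0, 1.0, 1.0, 1.0],
                                       "f2": [0.1, 0.9, 0.4, 0.6]}))
        assert model.degenerate[0]

    def test_too_few_controls_raises(self):
        with pytest.raises(InsufficientDataError):
            fit_baseline(frame_of({"f1": [1.0, 2.0], "f2": [1.0, 2.0]}))

    def test_non_numeric_feature_raises_naming_it(self):
        frame = frame_of({"f1": [1.0, 2.0, 3.0]})
        frame["f2"] = ["a", "b", "c"]
        with pytest.raises(TypeError, match="f2"):
            fit_baseline(frame)

    def test_recovers_known_generating_parameters(self):
        rel = Relation("num_01", "num_02", intercept=-0.4, slope=2.0,
                       noise_sd=0.3)
        config = SyntheticConfig(n_controls=500, n_cases=0, n_numeric=2,
                                 n_binary=0, relation_pairs=(rel,), seed=17)
        cohort = generate_cohort(config)
        model = fit_baseline(cohort.survivors())
        n = config.n_controls
        x = cohort.frame["num_01"].to_numpy()
        se_beta = rel.noise_sd / np.sqrt(np.sum((x - x.mean()) ** 2))
        se_alpha = se_beta * np.sqrt(np.mean(x ** 2))
        assert abs(model.beta[0] - rel.slope) < 3 * se_beta
        assert abs(model.alpha[0] - rel.intercept) < 3 * se_alpha
        assert model.sigma[0] == pytest.approx(rel.noise_sd, rel=0.10)


class TestComputeNetwork:
    def test_direct_substitution_into_weight_equation(self):
        # alpha=0, beta=2, sigma=0.5 and subject (f_k, f_l) = (2, 10) -> w = 12
        model = BaselineModel(
            feature_names=["fk", "fl"], alpha=np.array([0.0]),
            beta=np.array([2.0]), sigma=np.array([0.5]),
            degenerate=np.array([False]), n_train=10)
        net = compute_network({"fk": 2.0, "fl": 10.0}, model)
        assert net.weights[0] == pytest.approx((10.0 - 4.0) / 0.5)

    def test_subject_on_every_fitted_line_has_zero_weights(self):
        x = np.linspace(0, 1, 20)
        cohort = frame_of({"f1": x, "f2": 2 * x + np.sin(10 * x) * 0.3,
                           "f3": x ** 2})
        model = fit_baseline(cohort)
        k, l = pair_indices(3)
        subj = {"f1": 0.5}
        # construct a subject lying exactly on each fitted line of pairs with f1;
        # simplest exact case: all features on all lines is only possible for
        # consistent models, so check the zero-residual property pairwise
        w = model.zscores(np.array([[0.5,
                                     model.alpha[0] + model.beta[0] * 0.5,
                                     model.alpha[1] + model.beta[1] * 0.5]]))[0]
        assert w[0] == pytest.approx(0.0, abs=1e-12)
        assert w[1] == pytest.approx(0.0, abs=1e-12)

    def test_missing_feature_value_gives_zero_weight_and_warning(self, caplog):
        model = fit_baseline(frame_of({"f1": [1, 2, 3, 4.0],
                                       "f2": [1.1, 1.9, 3.2, 3.8]}))
        with caplog.at_level("WARNING", logger="parenclitic.networks"):
            net = compute_network({"f1": np.nan, "f2": 1.0}, model)
        assert net.weights[0] == 0.0
        assert "missing" in caplog.text

    def test_feature_name_mismatch_raises(self):
        model = fit_baseline(frame_of({"f1": [1, 2, 3.0], "f2": [3, 1, 2.0]}))
        with pytest.raises(KeyError):
            compute_network({"f1": 1.0, "other": 2.0}, model)

    def test_fresh_control_weights_approximately_standard_normal(self):
        config = SyntheticConfig(
            n_controls=3000, n_cases=0, n_numeric=5, n_binary=0,
            relation_pairs=(Relation("num_01", "num_02", 0, 1.2, 0.5),
                            Relation("num_02", "num_04", 1.0, -0.7, 0.8)),
            seed=23)
        cohort = generate_cohort(config)
        train = cohort.subset(cohort.subject_ids[:2000])
        fresh = cohort.subset(cohort.subject_ids[2000:])
        model = fit_baseline(train)
        W = model.zscores(fresh.feature_matrix(model.feature_names))
        assert W.mean() == pytest.approx(0.0, abs=0.05)
        assert W.std() == pytest.approx(1.0, abs=0.05)


class TestOracleEquivalence:
    def test_micro_cohorts_match_brute_force(self):
        """fit_baseline + compute_network == explicit normal-equation oracle to 1e-10."""
        rng = np.random.default_rng(0)
        for _ in range(25):
            n = int(rng.integers(4, 7))
            p = int(rng.integers(2, 5))
            X = rng.normal(size=(n, p))
            if rng.random() < 0.2:
                X[:, 0] = 1.0  # constant predictor corner case
            subject = rng.normal(size=p)
            names = [f"f{j}" for j in range(p)]
            model = fit_baseline(pd.DataFrame(X, columns=names))
            net = compute_network(dict(zip(names, subject)), model)
            expected = network_weights_oracle(subject, X)
            k, l = pair_indices(p)
            for i in range(len(k)):
                assert net.weights[i] == pytest.approx(
                    expected[(k[i], l[i])], abs=1e-10)


class TestBinarize:
    def test_strict_threshold_boundary(self):
        net_weights = np.array([0.5, -0.5, 0.51, -0.7])
        model_names = [f"f{i}" for i in range(4)]
        from parenclitic import ParencliticNetwork
        # place the four values on some pairs of a 4-node graph (6 pairs)
        weights = np.array([0.5, -0.5, 0.51, -0.7, 0.0, 0.0])
        net = ParencliticNetwork("s", model_names, weights)
        b = binarize(net, 0.5)
        assert list(b.binary.astype(int)) == [0, 0, 1, 1, 0, 0]

    def test_threshold_zero_links_every_nonzero_pair(self):
        from parenclitic import ParencliticNetwork
        net = ParencliticNetwork("s", ["a", "b", "c"],
                                 np.array([0.1, 0.0, -0.2]))
        b = binarize(net, 0.0)
        assert list(b.binary.astype(int)) == [1, 0, 1]

    def test_all_zero_weights_give_empty_network(self):
        from parenclitic import ParencliticNetwork
        net = ParencliticNetwork("s", ["a", "b", "c"], np.zeros(3))
        assert binarize(net, 0.5).binary.sum() == 0

    def test_negative_threshold_rejected(self):
        from parenclitic import ParencliticNetwork
        net = ParencliticNetwork("s", ["a", "b"], np.array([1.0]))
        with pytest.raises(ValueError):
            binarize(net, -0.1)

    @given(st.lists(st.floats(-5, 5), min_size=3, max_size=15),
           st.floats(0, 2), st.floats(0, 2))
    @settings(max_examples=50, deadline=None)
    def test_raising_threshold_never_adds_links(self, ws, t1, t2):
        from parenclitic import ParencliticNetwork
        # condensed vector length must be a triangular number; pad
        m = len(ws)
        n = 3
        while n * (n - 1) // 2 < m:
            n += 1
        weights = np.zeros(n * (n - 1) // 2)
        weights[:m] = ws
        net = ParencliticNetwork("s", [f"f{i}" for i in range(n)], weights)
        lo, hi = sorted([t1, t2])
        assert binarize(net, hi).binary.sum() <= binarize(net, lo).binary.sum()


class TestSerialization:
    def test_baseline_csv_round_trip(self, tmp_path):
        rng = np.random.default_rng(5)
        model = fit_baseline(pd.DataFrame(rng.normal(size=(30, 4)),
                                          columns=list("abcd")))
        path = tmp_path / "baseline.csv"
        model.to_csv(path)
        back = BaselineModel.from_csv(path)
        assert back.feature_names == model.feature_names
        np.testing.assert_allclose(back.alpha, model.alpha)
        np.testing.assert_allclose(back.beta, model.beta)
        np.testing.assert_allclose(back.sigma, model.sigma)
        assert back.n_train == model.n_train

    def test_edge_list_and_graphml_export(self, tmp_path):
        import networkx as nx

        rng = np.random.default_rng(6)
        frame = pd.DataFrame(rng.normal(size=(40, 4)), columns=list("abcd"))
        model = fit_baseline(frame)
        cohort_frame = frame.copy()
        cohort_frame.insert(0, "DEATH", 0)
        from parenclitic import Cohort
        nets = compute_networks(Cohort(cohort_frame), model)
        net = binarize(nets[0], 0.5)
        edges = net.to_edge_list()
        assert set(edges.columns) == {"source", "target", "weight", "binary"}
        assert len(edges) == 6
        path = tmp_path / "net.graphml"
        net.write_graphml(path)
        g = nx.read_graphml(path)
        assert set(g.nodes) == set("abcd")

    def test_network_round_trips_through_edge_list_and_graphml(self, tmp_path):
        from parenclitic import Cohort, ParencliticNetwork

        rng = np.random.default_rng(7)
        frame = pd.DataFrame(rng.normal(size=(30, 4)), columns=list("abcd"))
        cf = frame.copy()
        cf.insert(0, "DEATH", 0)
        net = binarize(compute_networks(Cohort(cf), fit_baseline(frame))[0], 0.5)
        csv = tmp_path / "edges.csv"
        net.to_edge_list().to_csv(csv, index=False)
        back = ParencliticNetwork.from_edge_list(csv, net.subject_id)
        np.testing.assert_allclose(back.weights, net.weights)
        np.testing.assert_array_equal(back.binary, net.binary)
        gml = tmp_path / "net.graphml"
        net.write_graphml(gml)
        back2 = ParencliticNetwork.from_graphml(gml)
        assert back2.subject_id == net.subject_id
        assert set(back2.feature_names) == set(net.feature_names)


def test_case_density_exceeds_control_density_with_strong_deviations():
    """With delta >= 3 on >= 10% of pairs, mean case link density is higher."""
    from scipy import stats

    from parenclitic import default_benchmark_config, link_density
    from parenclitic.netfeatures import features_from_zscores

    config = default_benchmark_config(seed=31, n_controls=200, n_cases=200,
                                      effect_size_delta=3.0,
                                      marginal_shift=0.0)
    cohort = generate_cohort(config)
    model = fit_baseline(cohort.survivors())
    W = model.zscores(cohort.feature_matrix(model.feature_names))
    links = (np.abs(W) > 0.5) & ~model.degenerate
    density = links.mean(axis=1)
    y = cohort.labels
    res = stats.ttest_ind(density[y == 1], density[y == 0],
                          alternative="greater")
    assert density[y == 1].mean() > density[y == 0].mean()
    assert res.pvalue < 0.01
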