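"""Graphical-lasso network estimation: contracts, oracles, recovery."""

import numpy as np
import pytest

from dietmicrobe import (
    DietaryNetwork,
    SyntheticTruth,
    chain_precision,
    extract_networks,
    fit_ggm_path,
    fit_glasso,
    gen_intake,
    log_transform,
    make_lambda_path,
    node_strength,
    precision_to_parcor,
    select_lambda,
)
from dietmicrobe.errors import InvalidConfigError

from oracles import (
    connected_components_union_find,
    glasso_coordinate_descent,
    partial_correlations_by_regression,
)


class TestLogTransform:
    @pytest.mark.parametrize("g, expected", [(0.0, 0.0), (9.0, 1.0), (99.0, 2.0)])
    def test_round_decade_values(self, g, expected):
        assert log_transform(np.array([g]))[0] == pytest.approx(expected)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            log_transform(np.array([-1.0]))


class TestLambdaPath:
    def test_endpoints_and_monotone(self):
        path = make_lambda_path(0.96, 0.09, 10)
        assert path[0] == pytest.approx(0.96)
        assert path[-1] == pytest.approx(0.09)
        assert (np.diff(path) < 0).all()

    def test_closed_form_log_spacing(self):
        assert make_lambda_path(1.0, 0.01, 3) == pytest.approx([1.0, 0.1, 0.01])

    def test_bad_ordering_rejected(self):
        with pytest.raises(InvalidConfigError):
            make_lambda_path(0.09, 0.96, 10)


class TestFitGlasso:
    def test_saturation_gives_empty_graph(self):
        rng = np.random.default_rng(1)
        S = np.corrcoef(rng.standard_normal((40, 4)), rowvar=False)
        lam = np.abs(S - np.eye(4)).max() + 0.01
        omega = fit_glasso(S, lam)
        assert np.abs(omega - np.diag(np.diag(omega))).max() < 1e-8

    def test_zero_penalty_recovers_inverse(self):
        rng = np.random.default_rng(2)
        S = np.corrcoef(rng.standard_normal((200, 3)), rowvar=False)
        assert np.abs(fit_glasso(S, 0.0) - np.linalg.inv(S)).max() < 1e-6

    @pytest.mark.parametrize("p", [2, 3, 4, 5])
    def test_matches_independent_coordinate_descent(self, p):
        """Same minimizer as a from-scratch block coordinate-descent solver
        on small standardized problems, to 1e-6."""
        rng = np.random.default_rng(p)
        for _ in range(3):
            S = np.corrcoef(rng.standard_normal((60, p)), rowvar=False)
            for lam in (0.05, 0.2, 0.5):
                ours = fit_glasso(S, lam, max_iter=5000, tol=1e-10)
                oracle = glasso_coordinate_descent(S, lam)
                assert np.abs(ours - oracle).max() < 1e-6

    def test_two_variable_support(self):
        r = 0.6
        S = np.array([[1.0, r], [r, 1.0]])
        omega = fit_glasso(S, 0.3)
        assert omega[0, 1] != 0.0

    def test_edge_count_monotone_along_path(self):
        truth = SyntheticTruth(precision_matrix=chain_precision(10, 0.35), seed=77)
        intake = gen_intake(400, truth)
        fit = fit_ggm_path(log_transform(intake), make_lambda_path(0.9, 0.05, 12))
        counts = [int(np.count_nonzero(np.triu(prec, 1))) for prec in fit.precisions]
        assert all(a <= b for a, b in zip(counts, counts[1:]))


class TestSelectLambda:
    def test_fixed_returns_value(self):
        fit = _tiny_fit()
        assert select_lambda(fit, method="fixed", fixed_value=0.37).lambda_ == 0.37

    def test_single_element_path(self):
        fit = _tiny_fit()
        fit.lambda_path = np.array([0.5])
        fit.precisions = fit.precisions[:1]
        assert select_lambda(fit, method="ebic").lambda_ == 0.5

    def test_unknown_method_rejected(self):
        with pytest.raises(InvalidConfigError):
            select_lambda(_tiny_fit(), method="magic")

    def test_stability_selection_recovers_planted_chain(self):
        """StARS-style selection on a strong chain network keeps >=80% of
        planted edges with <=20% spurious ones."""
        p = 12
        truth = SyntheticTruth(precision_matrix=chain_precision(p, 0.35), seed=5)
        intake = gen_intake(400, truth)
        logx = log_transform(intake)
        fit = fit_ggm_path(logx, make_lambda_path(0.9, 0.05, 15))
        sel = select_lambda(fit, method="stability", data=logx, n_subsamples=12, seed=0)
        prec = fit.precision_at(sel.lambda_)
        est = {(i, j) for i in range(p) for j in range(i + 1, p) if abs(prec[i, j]) > 1e-10}
        tp = len(est & truth.planted_edges)
        assert tp / len(truth.planted_edges) >= 0.8
        assert (len(est) - tp) <= 0.2 * len(est)


class TestParcor:
    def test_identity_gives_zero_offdiagonals(self):
        rho = precision_to_parcor(np.eye(4))
        assert np.abs(rho - np.eye(4)).max() == 0.0

    def test_two_by_two_closed_form(self):
        rho = precision_to_parcor(np.array([[2.0, -1.0], [-1.0, 2.0]]))
        assert rho[0, 1] == pytest.approx(0.5)

    def test_matches_residual_regression_oracle(self):
        """Partial correlations from the precision matrix equal correlations
        of residuals after regressing out all other variables."""
        rng = np.random.default_rng(8)
        A = rng.standard_normal((6, 6))
        omega = A @ A.T + 6 * np.eye(6)
        cov = np.linalg.inv(omega)
        X = rng.multivariate_normal(np.zeros(6), cov, size=200000)
        rho = precision_to_parcor(np.linalg.inv(np.cov(X, rowvar=False)))
        oracle = partial_correlations_by_regression(X)
        assert np.abs(rho - oracle).max() < 1e-6

    def test_nonpositive_diagonal_rejected(self):
        with pytest.raises(ValueError):
            precision_to_parcor(np.array([[0.0, 0.1], [0.1, 1.0]]))


class TestNetworks:
    def test_two_components_from_edge_lists(self):
        rho = np.eye(5)
        lab = ["A", "B", "C", "D", "E"]
        for i, j, w in [(0, 1, 0.3), (1, 2, 0.2), (3, 4, -0.4)]:
            rho[i, j] = rho[j, i] = w
        nets = extract_networks(rho, labels=lab)
        assert [set(n.nodes) for n in nets] == [{"A", "B", "C"}, {"D", "E"}]
        assert nets[1].edges[("D", "E")] == pytest.approx(-0.4)

    def test_all_zero_offdiagonals_give_no_patterns(self):
        assert extract_networks(np.eye(6)) == []

    def test_components_match_union_find_oracle(self):
        rng = np.random.default_rng(123)
        p = 15
        rho = np.eye(p)
        edges = []
        for i in range(p):
            for j in range(i + 1, p):
                if rng.random() < 0.12:
                    rho[i, j] = rho[j, i] = rng.uniform(-0.5, 0.5) or 0.1
                    edges.append((i, j))
        nets = extract_networks(rho)
        ours = {frozenset(int(n[1:]) for n in net.nodes) for net in nets}
        oracle = {
            frozenset(c)
            for c in connected_components_union_find(p, edges)
            if len(c) >= 2
        }
        assert ours == oracle

    def test_node_strength_sums_published_weights(self):
        # the three condiment/seasoning partial correlations reported for
        # the total-population vegetable network: 0.23 + 0.19 + 0.25
        net = DietaryNetwork(
            pattern_id="veg",
            nodes=("condiments", "green_yellow_veg", "light_veg", "tubers"),
            edges={
                ("condiments", "green_yellow_veg"): 0.23,
                ("condiments", "light_veg"): 0.19,
                ("condiments", "tubers"): 0.25,
            },
        )
        assert node_strength(net, "condiments") == pytest.approx(0.67)

    def test_isolated_node_strength_zero(self):
        net = DietaryNetwork("p", ("A", "B", "C"), {("A", "B"): 0.4})
        assert node_strength(net, "C") == 0.0
        with pytest.raises(KeyError):
            node_strength(net, "Z")

    def test_strength_matches_double_loop(self):
        rng = np.random.default_rng(5)
        nodes = tuple("n%d" % i for i in range(8))
        edges = {}
        for i in range(8):
            for j in range(i + 1, 8):
                if rng.random() < 0.4:
                    edges[(nodes[i], nodes[j])] = rng.uniform(-1, 1)
        net = DietaryNetwork("x", nodes, edges)
        for node in nodes:
            brute = sum(abs(w) for (a, b), w in edges.items() if node in (a, b))
            assert node_strength(net, node) == pytest.approx(brute)


def _tiny_fit():
    rng = np.random.default_rng(0)
    X = rng.standard_normal((50, 3))
    return fit_ggm_path(X, make_lambda_path(0.8, 0.2, 4))
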