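"""Sparse Gaussian graphical models for dietary-pattern networks.

Food-group intakes (g/day) are transformed as log10(g + 1), standardized
to a correlation matrix, and a sparse precision matrix is estimated with
the graphical lasso along a decreasing regularization path. The precision
estimate is converted to partial correlations; connected components with
two or more nodes form the dietary-pattern networks, and each node's
strength (sum of |incident edge weights|) is the centrality used for
pattern scoring.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.covariance import graphical_lasso as _sk_graphical_lasso

from dietmicrobe.errors import ConvergenceError, InvalidConfigError

__all__ = [
    "DietaryNetwork",
    "GgmFit",
    "SelectionResult",
    "log_transform",
    "make_lambda_path",
    "fit_glasso",
    "fit_ggm_path",
    "select_lambda",
    "precision_to_parcor",
    "extract_networks",
    "node_strength",
]


def log_transform(intake) -> pd.DataFrame | np.ndarray:
    """Elementwise log10(g/day + 1); shape and labels preserved."""
    values = intake.to_numpy() if isinstance(intake, pd.DataFrame) else np.asarray(intake, dtype=float)
    if np.any(values < 0):
        raise ValueError("negative intake values are not allowed")
    out = np.log10(values + 1.0)
    if isinstance(intake, pd.DataFrame):
        return pd.DataFrame(out, index=intake.index, columns=intake.columns)
    return out


def make_lambda_path(lambda_max: float, lambda_min: float, n_lambda: int) -> np.ndarray:
    """Log-spaced decreasing regularization path from lambda_max to lambda_min."""
    if not lambda_max > lambda_min > 0:
        raise InvalidConfigError("require lambda_max > lambda_min > 0")
    if n_lambda < 2:
        raise InvalidConfigError("need at least 2 path values")
    return np.geomspace(lambda_max, lambda_min, n_lambda)


def fit_glasso(covariance: np.ndarray, lam: float, max_iter: int = 500, tol: float = 1e-4) -> np.ndarray:
    """L1-penalized precision estimate for one penalty value.

    Minimizes -log det(Theta) + tr(S Theta) + lam * sum_{i!=j} |theta_ij|.
    At lam = 0 the solution is the plain inverse of S (computed directly).
    A run that stops at the iteration cap with a dual gap still above
    sqrt(tol) raises :class:`ConvergenceError` with the gap in the message.
    """
    S = np.asarray(covariance, dtype=float)
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise InvalidConfigError("covariance must be square")
    if not np.allclose(S, S.T, atol=1e-8):
        raise InvalidConfigError("covariance must be symmetric")
    if lam < 0:
        raise InvalidConfigError("penalty must be >= 0")
    if lam == 0.0:
        return np.linalg.inv(S)
    try:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            _, precision = _sk_graphical_lasso(
                S, alpha=float(lam), max_iter=max_iter, tol=tol, enet_tol=min(tol, 1e-4)
            )
    except FloatingPointError as exc:
        raise ConvergenceError(f"graphical lasso failed at lambda={lam}: {exc}") from exc
    for w in caught:
        msg = str(w.message)
        gap = re.search(r"dual gap:\s*(-?[\d.eE+-]+)", msg)
        # a negative reported gap is roundoff noise at the optimum; only a
        # genuinely positive gap above sqrt(tol) means non-convergence
        if gap is None or float(gap.group(1)) > np.sqrt(tol):
            raise ConvergenceError(f"graphical lasso did not converge at lambda={lam}: {msg}")
    if np.any(~np.isfinite(precision)):
        raise ConvergenceError(f"graphical lasso produced non-finite entries at lambda={lam}")
    return 0.5 * (precision + precision.T)


@dataclass
class GgmFit:
    """A graphical-lasso path fit on one (standardized) covariance matrix."""

    lambda_path: np.ndarray
    covariance: np.ndarray
    precisions: list[np.ndarray]
    n_samples: int
    selected_lambda: float | None = None

    def precision_at(self, lam: float) -> np.ndarray:
        """Precision estimate for a penalty value (refit if not on the path)."""
        matches = np.flatnonzero(np.isclose(self.lambda_path, lam))
        if matches.size:
            return self.precisions[matches[0]]
        return fit_glasso(self.covariance, lam)


def fit_ggm_path(log_intake, lambda_path: np.ndarray) -> GgmFit:
    """Fit the graphical lasso at every value of a decreasing penalty path.

    ``log_intake`` is the participants x food-groups matrix of
    log10(g/d + 1) values; the working covariance is its correlation
    matrix (standardized scale, on which penalties around 0.1-1 are
    meaningful).
    """
    X = log_intake.to_numpy() if isinstance(log_intake, pd.DataFrame) else np.asarray(log_intake, float)
    path = np.asarray(lambda_path, dtype=float)
    if np.any(np.diff(path) >= 0):
        raise InvalidConfigError("lambda path must be strictly decreasing")
    S = np.corrcoef(X, rowvar=False)
    precisions = [fit_glasso(S, lam) for lam in path]
    return GgmFit(lambda_path=path, covariance=S, precisions=precisions, n_samples=X.shape[0])


@dataclass
class SelectionResult:
    lambda_: float
    method: str
    scores: dict[float, float] = field(default_factory=dict)


def _ebic_score(S: np.ndarray, precision: np.ndarray, n: int, gamma: float) -> float:
    sign, logdet = np.linalg.slogdet(precision)
    if sign <= 0:
        return np.inf
    loglik = 0.5 * n * (logdet - np.trace(S @ precision))
    p = S.shape[0]
    k = int(np.count_nonzero(np.triu(precision, 1)))
    return -2.0 * loglik + k * np.log(n) + 4.0 * gamma * k * np.log(p)


def _stars_instability(
    X: np.ndarray, path: np.ndarray, n_subsamples: int, frac: float, seed: int
) -> dict[float, float]:
    rng = np.random.default_rng(seed)
    n, p = X.shape
    b = max(int(frac * n), p + 1)
    edge_freq = np.zeros((len(path), p, p))
    for _ in range(n_subsamples):
        rows = rng.choice(n, size=b, replace=False)
        S = np.corrcoef(X[rows], rowvar=False)
        for k, lam in enumerate(path):
            # subsample fits only feed edge indicators; a loose tolerance is fine
            prec = fit_glasso(S, lam, tol=1e-4)
            edge_freq[k] += (np.abs(prec) > 1e-10).astype(float)
    edge_freq /= n_subsamples
    iu = np.triu_indices(p, 1)
    scores = {}
    for k, lam in enumerate(path):
        theta = edge_freq[k][iu]
        scores[float(lam)] = float(np.mean(2.0 * theta * (1.0 - theta)))
    return scores


def select_lambda(
    fit: GgmFit,
    method: str = "fixed",
    data=None,
    fixed_value: float | None = None,
    ebic_gamma: float = 0.5,
    n_subsamples: int = 20,
    subsample_frac: float = 0.75,
    instability_threshold: float = 0.05,
    seed: int = 0,
) -> SelectionResult:
    """Choose one penalty value from the path.

    Methods
    -------
    fixed
        Return ``fixed_value`` as-is (reproduces an externally chosen
        optimum, e.g. a published lambda* = 0.37).
    ebic
        Extended BIC with parameter ``ebic_gamma`` over the path.
    stability
        StARS-style subsample edge-instability: pick the smallest penalty
        whose monotonized instability stays below ``instability_threshold``.
        Requires ``data`` (the log-intake matrix).
    """
    path = np.asarray(fit.lambda_path, dtype=float)
    if path.size == 0:
        raise InvalidConfigError("empty lambda path")
    if path.size == 1 and method != "fixed":
        return SelectionResult(lambda_=float(path[0]), method=method)
    if method == "fixed":
        if fixed_value is None:
            raise InvalidConfigError("fixed selection requires fixed_value")
        return SelectionResult(lambda_=float(fixed_value), method="fixed")
    if method == "ebic":
        scores = {
            float(lam): _ebic_score(fit.covariance, prec, fit.n_samples, ebic_gamma)
            for lam, prec in zip(path, fit.precisions)
        }
        best = min(scores, key=scores.get)
        return SelectionResult(lambda_=best, method="ebic", scores=scores)
    if method == "stability":
        if data is None:
            raise InvalidConfigError("stability selection requires the data matrix")
        X = data.to_numpy() if isinstance(data, pd.DataFrame) else np.asarray(data, float)
        scores = _stars_instability(X, path, n_subsamples, subsample_frac, seed)
        # monotonize along decreasing lambda, then take the smallest stable lambda
        lams = sorted(scores, reverse=True)
        running, chosen = 0.0, lams[0]
        for lam in lams:
            running = max(running, scores[lam])
            if running <= instability_threshold:
                chosen = lam
        return SelectionResult(lambda_=chosen, method="stability", scores=scores)
    raise InvalidConfigError(f"unknown selection method {method!r}")


def precision_to_parcor(precision: np.ndarray) -> np.ndarray:
    """Partial correlations rho_ij = -omega_ij / sqrt(omega_ii * omega_jj)."""
    omega = np.asarray(precision, dtype=float)
    d = np.diag(omega)
    if np.any(d <= 0):
        raise ValueError("precision diagonal must be strictly positive")
    rho = -omega / np.sqrt(np.outer(d, d))
    np.fill_diagonal(rho, 1.0)
    return 0.5 * (rho + rho.T)


@dataclass
class DietaryNetwork:
    """One dietary-pattern network: a connected component of the partial-
    correlation graph with at least two nodes. Edge weights are signed
    partial correlations; node strength sums their magnitudes."""

    pattern_id: str
    nodes: tuple[str, ...]
    edges: dict[tuple[str, str], float]

    def strength(self, node: str) -> float:
        if node not in self.nodes:
            raise KeyError(f"node {node!r} not in network {self.pattern_id}")
        return float(sum(abs(w) for (a, b), w in self.edges.items() if node in (a, b)))

    @property
    def strengths(self) -> dict[str, float]:
        return {node: self.strength(node) for node in self.nodes}

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for (a, b), w in self.edges.items():
            g.add_edge(a, b, weight=w)
        return g


def extract_networks(
    parcor: np.ndarray,
    labels: list[str] | None = None,
    min_abs_weight: float = 0.0,
) -> list[DietaryNetwork]:
    """Pattern networks from a partial-correlation matrix.

    Edges are pairs with |rho_ij| > min_abs_weight (default: exact
    nonzeros of the sparse estimate); negative weights keep their sign.
    Patterns are connected components with >= 2 nodes, ordered by
    decreasing size then lexicographic first node.
    """
    rho = np.asarray(parcor, dtype=float)
    p = rho.shape[0]
    names = list(labels) if labels is not None else [f"v{i}" for i in range(p)]
    g = nx.Graph()
    g.add_nodes_from(names)
    for i in range(p):
        for j in range(i + 1, p):
            if abs(rho[i, j]) > min_abs_weight:
                g.add_edge(names[i], names[j], weight=float(rho[i, j]))
    comps = [sorted(c, key=names.index) for c in nx.connected_components(g) if len(c) >= 2]
    comps.sort(key=lambda c: (-len(c), names.index(c[0])))
    networks = []
    for k, comp in enumerate(comps):
        sub = g.subgraph(comp)
        edges = {
            (min(a, b, key=names.index), max(a, b, key=names.index)): d["weight"]
            for a, b, d in sub.edges(data=True)
        }
        networks.append(DietaryNetwork(pattern_id=f"pattern_{k + 1}", nodes=tuple(comp), edges=edges))
    return networks


def node_strength(network: DietaryNetwork, node: str) -> float:
    """Sum of |edge weights| incident to a node (strength centrality)."""
    return network.strength(node)
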