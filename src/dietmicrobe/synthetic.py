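"""Synthetic cohort generators with known ground truth.

Every downstream stage (network estimation, pattern scoring, co-occurrence
screening, dysbiosis index, association models) is exercised against data
drawn from generators whose estimands are planted explicitly:

* intake tables drawn from a zero-mean Gaussian with a known sparse
  precision matrix, mapped to a g/day scale so that ``log10(g/d + 1)``
  recovers the Gaussian coordinates;
* compositional genus abundance tables with per-genus case/control fold
  changes planted on the log scale;
* covariate/outcome tables drawn from a logistic model with planted main
  and interaction log odds ratios.

A single integer seed fans out to independent per-generator substreams so
that each stage is reproducible on its own.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from dietmicrobe.errors import InvalidConfigError, InvalidTruthError

# substream ids: one per generator, so stages can be re-drawn independently
_STREAM_INTAKE = 1
_STREAM_MICROBIOME = 2
_STREAM_COHORT = 3


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(stream,)))


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth for one synthetic study.

    Parameters
    ----------
    precision_matrix
        Symmetric positive-definite precision (inverse covariance) over the
        p food groups. Its off-diagonal support defines the planted dietary
        network.
    fold_changes
        Per-genus case/control abundance ratio (> 0); 1.0 means no shift.
    effect_log_ors
        Planted log odds ratios of the binary exposures in the cohort
        generator, in exposure order.
    interaction_log_or
        Log OR of the product of the first two exposures (0.0 = no
        interaction).
    seed
        Global integer seed; each generator derives its own substream.
    intercept
        Intercept of the outcome logistic model (controls baseline risk).
    """

    precision_matrix: np.ndarray
    fold_changes: np.ndarray = field(default_factory=lambda: np.ones(8))
    effect_log_ors: np.ndarray = field(default_factory=lambda: np.zeros(2))
    interaction_log_or: float = 0.0
    seed: int = 0
    intercept: float = -1.0

    def __post_init__(self) -> None:
        omega = np.asarray(self.precision_matrix, dtype=float)
        object.__setattr__(self, "precision_matrix", omega)
        object.__setattr__(self, "fold_changes", np.asarray(self.fold_changes, dtype=float))
        object.__setattr__(self, "effect_log_ors", np.asarray(self.effect_log_ors, dtype=float))
        if omega.ndim != 2 or omega.shape[0] != omega.shape[1]:
            raise InvalidTruthError("precision_matrix must be square")
        if not np.allclose(omega, omega.T, atol=1e-10):
            raise InvalidTruthError("precision_matrix must be symmetric")
        if np.linalg.eigvalsh(omega).min() <= 0:
            raise InvalidTruthError("precision_matrix must be positive-definite")
        if np.any(self.fold_changes <= 0):
            raise InvalidTruthError("all fold_changes must be > 0")

    @property
    def n_food_groups(self) -> int:
        return self.precision_matrix.shape[0]

    @property
    def planted_edges(self) -> frozenset[tuple[int, int]]:
        """Unordered index pairs on the nonzero off-diagonal support."""
        omega = self.precision_matrix
        p = omega.shape[0]
        return frozenset(
            (i, j) for i in range(p) for j in range(i + 1, p) if omega[i, j] != 0.0
        )

    @property
    def partial_correlations(self) -> np.ndarray:
        """True partial correlations implied by the precision matrix."""
        omega = self.precision_matrix
        d = np.sqrt(np.diag(omega))
        rho = -omega / np.outer(d, d)
        np.fill_diagonal(rho, 1.0)
        return rho


def chain_precision(p: int, partial_corr: float = 0.3, alternate_sign: bool = False) -> np.ndarray:
    """Tridiagonal precision whose chain edges all have partial correlation
    ``partial_corr`` (sign alternating if requested).

    Diagonally dominant for |partial_corr| < 0.5, hence positive-definite.
    """
    if not 0 < abs(partial_corr) < 0.5:
        raise InvalidConfigError("chain_precision needs 0 < |partial_corr| < 0.5")
    omega = np.eye(p)
    for i in range(p - 1):
        w = -partial_corr if not alternate_sign or i % 2 == 0 else partial_corr
        omega[i, i + 1] = omega[i + 1, i] = w
    return omega


def gen_intake(
    n_participants: int,
    truth: SyntheticTruth,
    loc: float | np.ndarray = 1.0,
    scale: float | np.ndarray = 0.4,
    food_group_names: list[str] | None = None,
) -> pd.DataFrame:
    """Draw a participants x food-groups intake table in g/day.

    Latent vectors z ~ N(0, Omega^-1); each coordinate maps through
    ``10**(z*scale + loc) - 1`` clipped at 0, so ``log10(g + 1)`` recovers
    the Gaussian scale (up to the rare clipped coordinates). With the
    default loc=1, scale=0.4 intakes land in realistic food-group
    magnitudes (tens to a few hundred g/day).
    """
    p = truth.n_food_groups
    if n_participants < p + 1:
        raise InvalidConfigError(f"need at least p+1={p + 1} participants, got {n_participants}")
    rng = _rng(truth.seed, _STREAM_INTAKE)
    cov = np.linalg.inv(truth.precision_matrix)
    z = rng.multivariate_normal(np.zeros(p), cov, size=n_participants, method="cholesky")
    intake = np.clip(10.0 ** (z * scale + loc) - 1.0, 0.0, None)
    names = food_group_names or [f"food_{i:02d}" for i in range(p)]
    if len(names) != p:
        raise InvalidConfigError("food_group_names length must match precision dimension")
    idx = pd.Index([f"P{i:05d}" for i in range(n_participants)], name="participant_id")
    return pd.DataFrame(intake, index=idx, columns=names)


def gen_microbiome(
    n_cases: int,
    n_controls: int,
    n_genera: int,
    truth: SyntheticTruth,
    sigma: float = 1.0,
    factor_loadings: np.ndarray | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Draw a samples x genera relative-abundance table plus group labels.

    Absolute abundances are log-normal: ``log A = mu_g + log(FC_g)*case +
    L_g . f + sigma*eps`` where ``f`` are optional standard-normal latent
    factors (``factor_loadings`` of shape (n_genera, k) plants genus
    co-variation / co-exclusion for the co-occurrence screen). Baseline
    means mu_g are spread over several orders of magnitude (heavy-tailed,
    as 16S genus abundances are). Each sample row is renormalized to sum
    exactly 1 (compositional closure).

    Returns
    -------
    (abundance, group) where ``group`` is a Series of "case"/"control".
    """
    if n_genera < 2:
        raise InvalidConfigError("need at least 2 genera")
    fc = np.asarray(truth.fold_changes, dtype=float)
    if fc.shape[0] != n_genera:
        raise InvalidConfigError(
            f"truth.fold_changes has length {fc.shape[0]}, expected n_genera={n_genera}"
        )
    rng = _rng(truth.seed, _STREAM_MICROBIOME)
    n = n_cases + n_controls
    # baseline log-means spread across ~3 decades, fixed by the seed
    mu = rng.uniform(-3.0, 0.0, size=n_genera) * np.log(10.0)
    is_case = np.concatenate([np.ones(n_cases, bool), np.zeros(n_controls, bool)])
    shift = np.where(is_case[:, None], np.log(fc)[None, :], 0.0)
    log_abs = mu[None, :] + shift + sigma * rng.standard_normal((n, n_genera))
    if factor_loadings is not None:
        L = np.atleast_2d(np.asarray(factor_loadings, dtype=float))
        if L.shape[0] != n_genera:
            raise InvalidConfigError("factor_loadings must have one row per genus")
        f = rng.standard_normal((n, L.shape[1]))
        log_abs = log_abs + f @ L.T
    abs_abund = np.exp(log_abs)
    rel = abs_abund / abs_abund.sum(axis=1, keepdims=True)
    ids = [f"GC{i:04d}" if c else f"CT{i:04d}" for i, c in enumerate(is_case)]
    idx = pd.Index(ids, name="sample_id")
    cols = [f"genus_{i:02d}" for i in range(n_genera)]
    abundance = pd.DataFrame(rel, index=idx, columns=cols)
    group = pd.Series(np.where(is_case, "case", "control"), index=idx, name="group")
    return abundance, group


def gen_cohort(
    n: int,
    truth: SyntheticTruth,
    confounding: float = 0.0,
    conf_log_or: float = 0.0,
) -> pd.DataFrame:
    """Draw a covariate/outcome table from a planted logistic model.

    Exposures x1..xk are Bernoulli(0.5). A continuous covariate ``conf``
    enters the linear predictor with coefficient ``conf_log_or`` and,
    when ``confounding`` > 0, has its mean shifted by that amount when
    x1 = 1; with both nonzero the crude and adjusted effects of x1
    differ. With the defaults (no covariate effect) the marginal 2x2
    odds ratio of each exposure equals its planted conditional OR, so
    crude-table recovery is exact in expectation. The outcome follows

        logit P(case) = intercept + sum_j beta_j x_j
                        + interaction_log_or * x1 * x2 + conf_log_or * conf
    """
    betas = np.asarray(truth.effect_log_ors, dtype=float)
    k = betas.shape[0]
    if k < 1:
        raise InvalidConfigError("need at least one exposure effect")
    rng = _rng(truth.seed, _STREAM_COHORT)
    x = rng.integers(0, 2, size=(n, k)).astype(float)
    conf = rng.standard_normal(n) + confounding * x[:, 0]
    eta = truth.intercept + x @ betas + conf_log_or * conf
    if k >= 2 and truth.interaction_log_or != 0.0:
        eta = eta + truth.interaction_log_or * x[:, 0] * x[:, 1]
    p_case = 1.0 / (1.0 + np.exp(-eta))
    case = (rng.random(n) < p_case).astype(int)
    idx = pd.Index([f"P{i:05d}" for i in range(n)], name="participant_id")
    data = {"case": case}
    for j in range(k):
        data[f"x{j + 1}"] = x[:, j].astype(int)
    data["conf"] = conf
    return pd.DataFrame(data, index=idx)
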