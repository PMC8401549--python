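"""Checkerboard co-occurrence screening on compositional abundances.

Genus pairs are scored with an N-level checkerboard score (NC-score):
abundances are quantile-binned into a few ordinal levels and, over all
pairs of samples, covariations (both genera move the same way) and
coexclusions (opposite ways) are counted; the score is their normalized
difference (C - D) / (C + D), a rank-concordance measure in [-1, 1].

Because relative abundances are compositional (rows sum to 1), naive
nulls are biased toward negative association. Significance is therefore
assessed with a permutation-renormalization null: every genus column is
permuted independently across samples, each sample row renormalized to
sum 1, and the score recomputed; the two-sided add-one permutation
p-value compares |observed| against this null. Pairs passing an FDR and
an |NC-score| threshold define the candidate genus set carried into the
dysbiosis index.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from dietmicrobe.errors import InvalidConfigError

__all__ = [
    "discretize",
    "nc_score",
    "nc_score_from_levels",
    "permutation_null",
    "screen_pairs",
    "fdr_bh",
    "select_candidates",
]


def discretize(values, n_bins: int = 4) -> np.ndarray:
    """Quantile-bin values into ordinal levels 1..n_bins (ties share a level).

    Cut points are linear-interpolation quantiles at j/n_bins; a value
    exactly on a cut goes to the lower level.
    """
    if n_bins < 1:
        raise InvalidConfigError("n_bins must be >= 1")
    v = np.asarray(values, dtype=float)
    if n_bins == 1:
        return np.ones(v.shape[0], dtype=np.int64)
    cuts = np.quantile(v, np.arange(1, n_bins) / n_bins)
    return np.searchsorted(cuts, v, side="left").astype(np.int64) + 1


def _concordance_counts(x: np.ndarray, y: np.ndarray) -> tuple[int, int]:
    """Concordant/discordant sample-pair counts from a level contingency table."""
    kx, ky = int(x.max()), int(y.max())
    table = np.zeros((kx, ky), dtype=np.int64)
    np.add.at(table, (x - 1, y - 1), 1)
    # suffix sums: cells strictly below-and-right / below-and-left of (i, j)
    concordant = discordant = 0
    for i in range(kx - 1):
        rows_below = table[i + 1 :]
        right = rows_below[:, 1:].sum(axis=0)[::-1].cumsum()[::-1]  # sum over l > j
        left = rows_below[:, :-1].sum(axis=0).cumsum()  # sum over l < j
        concordant += int((table[i, :-1] * right).sum())
        discordant += int((table[i, 1:] * left).sum())
    return concordant, discordant


def nc_score_from_levels(x, y) -> float:
    """NC-score (C - D)/(C + D) on pre-binned ordinal levels; 0 if C + D = 0."""
    x = np.asarray(x, dtype=np.int64)
    y = np.asarray(y, dtype=np.int64)
    if x.shape != y.shape:
        raise ValueError("level vectors must have equal length")
    if x.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    c, d = _concordance_counts(x, y)
    if c + d == 0:
        return 0.0
    return (c - d) / (c + d)


def nc_score(x, y, n_bins: int | None = None) -> float:
    """NC-score of two abundance (or level) vectors.

    With ``n_bins`` given, raw values are quantile-binned first; otherwise
    inputs are taken as ordinal levels already.
    """
    if n_bins is not None:
        x, y = discretize(x, n_bins), discretize(y, n_bins)
    return nc_score_from_levels(x, y)


def _permuted_renormalized(matrix: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    perm = rng.permuted(matrix, axis=0)  # each column gets its own permutation
    sums = perm.sum(axis=1, keepdims=True)
    sums[sums == 0] = 1.0
    return perm / sums


def permutation_null(
    table: pd.DataFrame,
    pair: tuple[str, str],
    n_permutations: int = 999,
    n_bins: int = 4,
    seed: int = 0,
) -> float:
    """Two-sided permutation-renormalization p-value for one genus pair.

    Each iteration permutes *every* genus column independently across
    samples, renormalizes each sample row to compositional closure, and
    recomputes the pair's NC-score; p = (1 + #{|null| >= |obs|}) /
    (n_permutations + 1). Constant (non-informative) columns give p = 1.
    """
    if n_permutations < 99:
        raise InvalidConfigError("need at least 99 permutations")
    a, b = pair
    mat = table.to_numpy(dtype=float)
    ia, ib = table.columns.get_loc(a), table.columns.get_loc(b)
    if np.ptp(mat[:, ia]) == 0 or np.ptp(mat[:, ib]) == 0:
        return 1.0
    obs = abs(nc_score(mat[:, ia], mat[:, ib], n_bins=n_bins))
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        null_tab = _permuted_renormalized(mat, rng)
        score = nc_score(null_tab[:, ia], null_tab[:, ib], n_bins=n_bins)
        if abs(score) >= obs:
            hits += 1
    return (1 + hits) / (n_permutations + 1)


def screen_pairs(
    table: pd.DataFrame,
    n_bins: int = 4,
    n_permutations: int = 999,
    seed: int = 0,
    max_absence_frac: float = 0.95,
) -> pd.DataFrame:
    """NC-score + permutation p + BH q for every informative genus pair.

    All pairs share the same permuted-renormalized tables per iteration
    (one full-table permutation per iteration), which keeps the null
    exchangeable across pairs while costing B table permutations total.
    Genera absent (zero) in more than ``max_absence_frac`` of samples are
    skipped as non-informative and reported with ``skipped=True``.
    """
    if n_permutations < 99:
        raise InvalidConfigError("need at least 99 permutations")
    genera = list(table.columns)
    mat = table.to_numpy(dtype=float)
    n = mat.shape[0]
    absent_frac = (mat == 0).mean(axis=0)
    informative = [g for g, f in zip(genera, absent_frac) if f <= max_absence_frac]
    skip = set(genera) - set(informative)
    idx = {g: table.columns.get_loc(g) for g in genera}

    levels = {g: discretize(mat[:, idx[g]], n_bins) for g in informative}
    pairs = [(a, b) for i, a in enumerate(informative) for b in informative[i + 1 :]]
    obs = np.array([nc_score_from_levels(levels[a], levels[b]) for a, b in pairs])

    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(pairs), dtype=np.int64)
    cols = [idx[g] for g in informative]
    for _ in range(n_permutations):
        null_tab = _permuted_renormalized(mat, rng)
        null_levels = [discretize(null_tab[:, c], n_bins) for c in cols]
        pos = {g: k for k, g in enumerate(informative)}
        for j, (a, b) in enumerate(pairs):
            s = nc_score_from_levels(null_levels[pos[a]], null_levels[pos[b]])
            if abs(s) >= abs(obs[j]):
                exceed[j] += 1
    p = (1 + exceed) / (n_permutations + 1)
    q = fdr_bh(p)
    out = pd.DataFrame(
        {
            "genus_a": [a for a, _ in pairs],
            "genus_b": [b for _, b in pairs],
            "nc_score": obs,
            "p_value": p,
            "q_value": q,
            "skipped": False,
        }
    )
    skipped_rows = [
        {"genus_a": g, "genus_b": g, "nc_score": np.nan, "p_value": np.nan, "q_value": np.nan, "skipped": True}
        for g in sorted(skip)
    ]
    if skipped_rows:
        out = pd.concat([out, pd.DataFrame(skipped_rows)], ignore_index=True)
    out.attrs["n_samples"] = n
    return out


def fdr_bh(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def select_candidates(
    associations: pd.DataFrame,
    q_threshold: float = 0.05,
    score_threshold: float = 0.30,
) -> set[str]:
    """Union of genera in pairs with q < q_threshold and |NC-score| > score_threshold.

    Both comparisons are strict: a pair sitting exactly on a threshold is
    excluded.
    """
    if not 0 < q_threshold < 1 or not 0 < score_threshold <= 1:
        raise InvalidConfigError("thresholds out of range")
    keep = associations[
        (~associations.get("skipped", False))
        & (associations["q_value"] < q_threshold)
        & (associations["nc_score"].abs() > score_threshold)
    ]
    return set(keep["genus_a"]) | set(keep["genus_b"])
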