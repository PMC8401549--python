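"""Network-specific pattern scores and control-based tertiles.

A participant's score for a pattern network is

    score = log10( sum over network foods of intake_g * strength_g )

with intakes in raw g/day and strengths from the network (sum of |edge
weights| at the node). Scores are cut into tertiles at the 33.33rd and
66.67th percentiles of the *control* score distribution; cases and
controls are then assigned by the same cuts (ties go to the lower
tertile).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from dietmicrobe.errors import DegenerateDistributionError
from dietmicrobe.ggm import DietaryNetwork

log = logging.getLogger(__name__)

__all__ = ["pattern_score", "pattern_scores", "tertile_assign", "TertileAssignment"]


def pattern_score(intake_row: pd.Series, network: DietaryNetwork) -> float:
    """Score one participant against one pattern network.

    Returns NaN (flagged missing) when the weighted intake sum is zero,
    since the log would be undefined; such participants are excluded from
    tertile assignment.
    """
    if not network.nodes:
        raise ValueError("network has no nodes")
    strengths = network.strengths
    total = 0.0
    for node, s in strengths.items():
        intake = float(intake_row[node])
        if intake < 0:
            raise ValueError(f"negative intake for {node!r}")
        total += intake * s
    if total <= 0.0:
        return float("nan")
    return float(np.log10(total))


def pattern_scores(intake: pd.DataFrame, network: DietaryNetwork) -> pd.Series:
    """Vectorized per-participant scores for one network."""
    strengths = network.strengths
    sub = intake[list(strengths)]
    if (sub.to_numpy() < 0).any():
        raise ValueError("negative intake values")
    weighted = sub.to_numpy() @ np.array([strengths[n] for n in strengths])
    with np.errstate(divide="ignore"):
        scores = np.where(weighted > 0, np.log10(np.where(weighted > 0, weighted, 1.0)), np.nan)
    n_missing = int(np.isnan(scores).sum())
    if n_missing:
        log.info("%d participants with zero weighted intake excluded from scoring", n_missing)
    return pd.Series(scores, index=intake.index, name=network.pattern_id)


@dataclass
class TertileAssignment:
    scores: pd.Series
    tertile: pd.Series  # 1|2|3, <NA> where score missing
    cuts: tuple[float, float]
    medians: dict[int, float]  # per-tertile median score (all assigned participants)


def tertile_assign(scores: pd.Series, control_mask: pd.Series) -> TertileAssignment:
    """Cut scores into tertiles of the control distribution.

    Cut points are the 33.33rd / 66.67th percentiles (linear-interpolation
    quantiles) of the non-missing control scores; every participant is
    assigned by the same cuts, ties going to the lower tertile.
    """
    ctrl = scores[control_mask.reindex(scores.index, fill_value=False)].dropna()
    if ctrl.nunique() < 3:
        raise DegenerateDistributionError("need at least 3 distinct control scores")
    c1, c2 = np.quantile(ctrl.to_numpy(), [1.0 / 3.0, 2.0 / 3.0])
    if not c1 < c2:
        raise DegenerateDistributionError("tertile cuts coincide; control distribution degenerate")
    vals = scores.to_numpy(dtype=float)
    tert = np.where(vals <= c1, 1, np.where(vals <= c2, 2, 3)).astype(float)
    tert[np.isnan(vals)] = np.nan
    tertile = pd.Series(tert, index=scores.index, name="tertile").astype("Int64")
    medians = {
        k: float(scores[tertile == k].median()) for k in (1, 2, 3) if (tertile == k).any()
    }
    return TertileAssignment(scores=scores, tertile=tertile, cuts=(float(c1), float(c2)), medians=medians)
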