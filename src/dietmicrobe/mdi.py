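"""Case/control fold changes and the microbial dysbiosis index (MDI).

Candidate genera are split by the ratio of their mean relative abundance
in cases to that in controls: fold change > 1 marks a genus "increased"
in cases, < 1 "decreased", exactly 1 excluded. A sample's MDI is the log
(base 10 by default) of the total abundance over the increased set
divided by the total over the decreased set, with a small pseudocount to
keep the index finite when one side sums to zero.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from dietmicrobe.errors import PartitionError

log = logging.getLogger(__name__)

__all__ = ["fold_change", "fold_changes", "partition", "default_pseudocount", "mdi", "mdi_scores"]


def fold_change(table: pd.DataFrame, is_case: pd.Series, genus: str) -> float:
    """Mean relative abundance among cases / mean among controls.

    Returns NaN (flagged undefined; genus excluded downstream) when the
    control mean is zero.
    """
    mask = is_case.reindex(table.index).astype(bool)
    case_mean = float(table.loc[mask, genus].mean())
    ctrl_mean = float(table.loc[~mask, genus].mean())
    if ctrl_mean == 0.0:
        log.warning("control mean abundance of %s is zero; fold change undefined", genus)
        return float("nan")
    return case_mean / ctrl_mean


def fold_changes(table: pd.DataFrame, is_case: pd.Series, genera=None) -> pd.Series:
    """Per-genus case/control fold changes (restricted to ``genera`` if given)."""
    cols = list(genera) if genera is not None else list(table.columns)
    mask = is_case.reindex(table.index).astype(bool)
    if mask.all() or (~mask).all():
        raise ValueError("both case and control groups must be non-empty")
    case_mean = table.loc[mask, cols].mean(axis=0)
    ctrl_mean = table.loc[~mask, cols].mean(axis=0)
    fc = case_mean / ctrl_mean.replace(0.0, np.nan)
    return fc.rename("fold_change")


def partition(fcs: pd.Series) -> pd.DataFrame:
    """Strict partition at fold change 1: >1 increased, <1 decreased,
    exactly 1 (or undefined) excluded."""
    membership = pd.Series("excluded", index=fcs.index, dtype=object)
    membership[fcs > 1.0] = "increased"
    membership[fcs < 1.0] = "decreased"
    return pd.DataFrame({"fold_change": fcs, "membership": membership})


def default_pseudocount(table: pd.DataFrame) -> float:
    """Half the smallest nonzero abundance in the table (zero-handling)."""
    vals = table.to_numpy(dtype=float)
    nz = vals[vals > 0]
    if nz.size == 0:
        raise ValueError("abundance table is all zeros")
    return float(nz.min()) / 2.0


def mdi(
    sample_abundances: pd.Series,
    part: pd.DataFrame,
    epsilon: float,
    log_base: float = 10.0,
) -> float:
    """Dysbiosis index of one sample:
    log_base( (sum over increased + eps) / (sum over decreased + eps) )."""
    inc = part.index[part["membership"] == "increased"]
    dec = part.index[part["membership"] == "decreased"]
    if len(inc) == 0 or len(dec) == 0:
        raise PartitionError("both increased and decreased sets must be non-empty")
    num = float(sample_abundances[inc].sum()) + epsilon
    den = float(sample_abundances[dec].sum()) + epsilon
    return float(np.log(num / den) / np.log(log_base))


def mdi_scores(
    table: pd.DataFrame,
    part: pd.DataFrame,
    epsilon: float | None = None,
    log_base: float = 10.0,
) -> pd.Series:
    """Vectorized per-sample MDI; epsilon defaults to half the smallest
    nonzero abundance in the table."""
    if epsilon is None:
        epsilon = default_pseudocount(table)
    inc = part.index[part["membership"] == "increased"]
    dec = part.index[part["membership"] == "decreased"]
    if len(inc) == 0 or len(dec) == 0:
        raise PartitionError("both increased and decreased sets must be non-empty")
    num = table[list(inc)].sum(axis=1) + epsilon
    den = table[list(dec)].sum(axis=1) + epsilon
    return pd.Series(np.log(num / den) / np.log(log_base), index=table.index, name="mdi")
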