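"""Table readers/writers and pipeline configuration.

All tabular artifacts are plain TSV (diffable, language-neutral);
networks additionally export to GraphML. The configuration is a flat
YAML file whose keys mirror :class:`PipelineConfig`.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from dietmicrobe.errors import InvalidConfigError
from dietmicrobe.ggm import DietaryNetwork

__all__ = [
    "PipelineConfig",
    "load_config",
    "read_intake_table",
    "read_abundance_table",
    "read_covariate_table",
    "write_tsv",
    "write_networks",
]


def read_intake_table(path) -> pd.DataFrame:
    """Participants x food-groups intake table (g/day) from TSV/CSV.

    The first column holds unique participant IDs; remaining columns are
    food-group names. Negative values and duplicate IDs are rejected.
    """
    df = _read_table(path).set_index("participant_id")
    if df.index.duplicated().any():
        dupes = df.index[df.index.duplicated()].tolist()
        raise ValueError(f"duplicate participant IDs: {dupes}")
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ValueError(f"malformed numeric cell in {path}: {exc}") from exc
    if (df.to_numpy() < 0).any():
        rows, cols = np.nonzero(df.to_numpy() < 0)
        cell = (df.index[rows[0]], df.columns[cols[0]])
        raise ValueError(f"negative intake at participant {cell[0]!r}, food group {cell[1]!r}")
    return df


def read_abundance_table(path, tol: float = 0.01) -> pd.DataFrame:
    """Samples x genera relative-abundance table from TSV/CSV.

    Rows whose sum is within ``tol`` (relative) of 1 are renormalized to
    sum exactly 1; rows further off are rejected as not compositional.
    """
    df = _read_table(path).set_index("sample_id").astype(float)
    sums = df.sum(axis=1)
    off = sums[(sums - 1.0).abs() > tol]
    if len(off):
        raise ValueError(f"rows not compositional (sum != 1 within {tol:.0%}): {off.index.tolist()}")
    if (df.to_numpy() < 0).any():
        raise ValueError("negative abundances")
    zero_genera = df.columns[(df == 0).all()].tolist()
    if zero_genera:
        df.attrs["zero_genera"] = zero_genera
    return df.div(sums, axis=0)


def read_covariate_table(path) -> pd.DataFrame:
    """Covariate/outcome table with a binary ``case`` column."""
    df = _read_table(path).set_index("participant_id")
    if "case" not in df.columns:
        raise ValueError("covariate table must contain a 'case' column")
    if not set(pd.unique(df["case"].dropna())) <= {0, 1}:
        raise ValueError("'case' must be binary 0/1")
    return df


def _read_table(path) -> pd.DataFrame:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    first = df.columns[0]
    rename = {first: "participant_id"} if "sample" not in first.lower() else {first: "sample_id"}
    if first.lower() in ("participant_id", "sample_id", "id", "sample", "participant", "sampleid"):
        df = df.rename(columns=rename if first not in ("participant_id", "sample_id") else {})
    return df


def write_tsv(df: pd.DataFrame, path, index: bool = True, float_format: str = "%.10g") -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index, float_format=float_format)


def write_networks(networks: list[DietaryNetwork], edge_path, graphml_path=None) -> None:
    """Edge-list TSV (node_a, node_b, weight, component_id) and optional GraphML."""
    rows = [
        {"node_a": a, "node_b": b, "weight": w, "component_id": net.pattern_id}
        for net in networks
        for (a, b), w in sorted(net.edges.items())
    ]
    write_tsv(pd.DataFrame(rows, columns=["node_a", "node_b", "weight", "component_id"]), edge_path, index=False)
    if graphml_path is not None:
        g = nx.Graph()
        for net in networks:
            for node in net.nodes:
                g.add_node(node, component_id=net.pattern_id, strength=net.strength(node))
            for (a, b), w in net.edges.items():
                g.add_edge(a, b, weight=float(w))
        nx.write_graphml(g, graphml_path)


@dataclass
class PipelineConfig:
    """End-to-end run configuration (flat YAML keys map 1:1 onto fields)."""

    outdir: str = "out"
    seed: int = 0
    # input tables (None => stage must be fed synthetic data via `simulate`)
    intake_path: str | None = None
    abundance_path: str | None = None
    covariate_path: str | None = None
    # graphical lasso
    lambda_max: float = 0.96
    lambda_min: float = 0.09
    n_lambda: int = 30
    lambda_selection: str = "stability"  # fixed | ebic | stability
    lambda_fixed: float | None = None
    min_abs_weight: float = 0.0
    # pattern scoring
    score_log_base: float = 10.0
    # co-occurrence screen
    n_bins: int = 4
    n_permutations: int = 999
    q_threshold: float = 0.05
    score_threshold: float = 0.30
    # dysbiosis index
    mdi_log_base: float = 10.0
    mdi_cut: float | None = None  # dichotomization cut; None => control median
    # association models
    model2_covariates: list[str] = field(default_factory=list)
    model3_covariates: list[str] = field(default_factory=list)
    stratum: str = "total"  # total | male | female

    def __post_init__(self) -> None:
        if not 0 < self.q_threshold < 1:
            raise InvalidConfigError("q_threshold must be in (0,1)")
        if not 0 < self.score_threshold <= 1:
            raise InvalidConfigError("score_threshold must be in (0,1]")
        if self.lambda_max <= self.lambda_min or self.lambda_min <= 0:
            raise InvalidConfigError("require lambda_max > lambda_min > 0")
        if self.lambda_selection not in ("fixed", "ebic", "stability"):
            raise InvalidConfigError(f"unknown lambda_selection {self.lambda_selection!r}")
        if self.lambda_selection == "fixed" and self.lambda_fixed is None:
            raise InvalidConfigError("fixed lambda selection requires lambda_fixed")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise InvalidConfigError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**raw)
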