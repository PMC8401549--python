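"""End-to-end orchestration: GGM -> scoring -> co-occurrence -> MDI -> ORs.

Each stage writes its artifact under the configured output directory and
appends to a JSON run manifest (seeds, selected penalty, exclusion
counts), so a run is reproducible byte-for-byte given the same config
and seed.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from dietmicrobe import association, ccrepe, ggm, scoring
from dietmicrobe.mdi import fold_changes, mdi_scores, partition
from dietmicrobe.errors import InvalidConfigError
from dietmicrobe.io import (
    PipelineConfig,
    read_abundance_table,
    read_covariate_table,
    read_intake_table,
    write_networks,
    write_tsv,
)

__all__ = ["run_pipeline"]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage for which inputs are configured; return the manifest."""
    if config.intake_path is None or config.covariate_path is None:
        raise InvalidConfigError("intake_path and covariate_path are required")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": json.loads(config.to_json()), "stages": {}}

    intake = read_intake_table(config.intake_path)
    covar = read_covariate_table(config.covariate_path)
    covar = covar.reindex(intake.index.intersection(covar.index))
    intake = intake.loc[covar.index]
    if config.stratum in ("male", "female") and "sex" in covar.columns:
        keep = covar["sex"].astype(str).str.lower() == config.stratum
        covar, intake = covar[keep], intake[keep]
    control_mask = covar["case"] == 0
    manifest["stages"]["input"] = {
        "n_participants": int(len(intake)),
        "n_cases": int(covar["case"].sum()),
        "n_controls": int(control_mask.sum()),
        "n_food_groups": int(intake.shape[1]),
    }

    # --- dietary networks -------------------------------------------------
    log_intake = ggm.log_transform(intake)
    path = ggm.make_lambda_path(config.lambda_max, config.lambda_min, config.n_lambda)
    fit = ggm.fit_ggm_path(log_intake, path)
    sel = ggm.select_lambda(
        fit,
        method=config.lambda_selection,
        data=log_intake,
        fixed_value=config.lambda_fixed,
        seed=config.seed,
    )
    fit.selected_lambda = sel.lambda_
    parcor = ggm.precision_to_parcor(fit.precision_at(sel.lambda_))
    networks = ggm.extract_networks(parcor, labels=list(intake.columns), min_abs_weight=config.min_abs_weight)
    write_networks(networks, outdir / "edges.tsv", outdir / "network.graphml")
    strengths = pd.DataFrame(
        [
            {"node": n, "component_id": net.pattern_id, "strength": net.strength(n)}
            for net in networks
            for n in net.nodes
        ]
    )
    write_tsv(strengths, outdir / "strengths.tsv", index=False)
    manifest["stages"]["ggm"] = {
        "selected_lambda": float(sel.lambda_),
        "selection_method": sel.method,
        "n_patterns": len(networks),
        "n_edges": int(sum(len(net.edges) for net in networks)),
    }

    # --- pattern scores and tertiles -------------------------------------
    score_rows = []
    tertiles: dict[str, pd.Series] = {}
    for net in networks:
        scores = scoring.pattern_scores(intake, net)
        assign = scoring.tertile_assign(scores, control_mask)
        tertiles[net.pattern_id] = assign.tertile
        score_rows.append(
            pd.DataFrame(
                {
                    "participant_id": scores.index,
                    "pattern_id": net.pattern_id,
                    "score": scores.to_numpy(),
                    "tertile": assign.tertile.to_numpy(),
                }
            )
        )
    if score_rows:
        write_tsv(pd.concat(score_rows, ignore_index=True), outdir / "scores.tsv", index=False)
    manifest["stages"]["scoring"] = {
        "n_patterns_scored": len(score_rows),
        "n_missing_scores": int(sum(t.isna().sum() for t in tertiles.values())),
    }

    # --- microbiome stages (optional) -------------------------------------
    or_frames = []
    if config.abundance_path is not None:
        abundance = read_abundance_table(config.abundance_path)
        shared = abundance.index.intersection(covar.index)
        abundance = abundance.loc[shared]
        is_case = covar.loc[shared, "case"] == 1
        assoc = ccrepe.screen_pairs(
            abundance,
            n_bins=config.n_bins,
            n_permutations=config.n_permutations,
            seed=config.seed,
        )
        write_tsv(assoc, outdir / "pair_associations.tsv", index=False)
        candidates = ccrepe.select_candidates(assoc, config.q_threshold, config.score_threshold)
        (outdir / "candidates.txt").write_text("\n".join(sorted(candidates)) + "\n")
        manifest["stages"]["ccrepe"] = {
            "n_genera": int(abundance.shape[1]),
            "n_candidates": len(candidates),
        }
        if len(candidates) >= 2:
            fcs = fold_changes(abundance, is_case, sorted(candidates))
            part = partition(fcs)
            write_tsv(part.rename_axis("genus"), outdir / "partition.tsv")
            mdi_vals = mdi_scores(abundance, part, log_base=config.mdi_log_base)
            ctrl_mdi = mdi_vals[~is_case]
            cut = config.mdi_cut if config.mdi_cut is not None else float(ctrl_mdi.median())
            mdi_assign = scoring.tertile_assign(mdi_vals, ~is_case)
            mdi_df = pd.DataFrame(
                {"mdi": mdi_vals, "tertile": mdi_assign.tertile, "high": (mdi_vals >= cut).astype(int)}
            ).rename_axis("sample_id")
            write_tsv(mdi_df, outdir / "mdi.tsv")
            manifest["stages"]["mdi"] = {
                "n_increased": int((part["membership"] == "increased").sum()),
                "n_decreased": int((part["membership"] == "decreased").sum()),
                "dichotomization_cut": cut,
            }
            # combined pattern x MDI analysis on the shared samples
            sub_cov = covar.loc[shared]
            mdi_high = mdi_df["high"]
            for net in networks:
                scores = scoring.pattern_scores(intake.loc[shared], net)
                pat_cut = float(scores[~is_case].median())
                pat_high = (scores >= pat_cut).astype(int)
                try:
                    cells = association.combined_or_table(sub_cov, pat_high, mdi_high, model="crude")
                    p_int = association.interaction_lrt(sub_cov, pat_high, mdi_high)
                except Exception:
                    continue
                or_frames.append(
                    pd.DataFrame(
                        {
                            "analysis": "combined",
                            "exposure": net.pattern_id,
                            "level": [c.exposure_level for c in cells],
                            "n_cases": [c.n_cases for c in cells],
                            "n_controls": [c.n_controls for c in cells],
                            "or": [c.or_point for c in cells],
                            "ci_low": [c.ci_low for c in cells],
                            "ci_high": [c.ci_high for c in cells],
                            "p_interaction": p_int,
                        }
                    )
                )

    # --- tertile odds ratios ----------------------------------------------
    for pattern_id, tert in tertiles.items():
        counts = {}
        for k in (1, 2, 3):
            in_k = tert == k
            counts[k] = (
                int(covar.loc[in_k.reindex(covar.index, fill_value=False), "case"].sum()),
                int((in_k.reindex(covar.index, fill_value=False) & control_mask).sum()),
            )
        if min(c for pair in counts.values() for c in pair) == 0:
            continue
        rows = [
            {
                "analysis": "tertile",
                "exposure": pattern_id,
                "level": "T1",
                "n_cases": counts[1][0],
                "n_controls": counts[1][1],
                "or": 1.0,
                "ci_low": 1.0,
                "ci_high": 1.0,
            }
        ]
        for k in (2, 3):
            est = association.crude_or_ci(counts[k][0], counts[k][1], counts[1][0], counts[1][1])
            rows.append(
                {
                    "analysis": "tertile",
                    "exposure": pattern_id,
                    "level": f"T{k}",
                    "n_cases": counts[k][0],
                    "n_controls": counts[k][1],
                    "or": est.or_point,
                    "ci_low": est.ci_low,
                    "ci_high": est.ci_high,
                }
            )
        or_frames.append(pd.DataFrame(rows))
    if or_frames:
        report = pd.concat(or_frames, ignore_index=True)
        write_tsv(report, outdir / "or_report.tsv", index=False)
        manifest["stages"]["association"] = {"n_rows": int(len(report))}

    (outdir / "run_manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
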