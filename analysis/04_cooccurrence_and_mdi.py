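"""Screen genus pairs with the NC-score + permutation-renormalization
null, select candidate genera (q < 0.05, |NC| > 0.30), partition them by
case/control fold change, and compute the per-sample dysbiosis index.

Writes pair associations, the candidate list, the fold-change partition
and the MDI table under results/microbiome/.
"""

import argparse
from pathlib import Path

import pandas as pd

from dietmicrobe import fold_changes, mdi_scores, partition, screen_pairs, select_candidates, tertile_assign
from dietmicrobe.io import read_abundance_table, read_covariate_table, write_tsv


def run(seed: int, outdir: Path) -> None:
    abundance = read_abundance_table(outdir / "synthetic" / "abundance.tsv")
    covar = read_covariate_table(outdir / "synthetic" / "covariates.tsv")
    shared = abundance.index.intersection(covar.index)
    abundance = abundance.loc[shared]
    is_case = covar.loc[shared, "case"] == 1
    mdir = outdir / "microbiome"

    assoc = screen_pairs(abundance, n_permutations=499, seed=seed)
    write_tsv(assoc, mdir / "pair_associations.tsv", index=False)
    candidates = select_candidates(assoc)
    (mdir / "candidates.txt").write_text("\n".join(sorted(candidates)) + "\n")
    print(f"{abundance.shape[1]} genera screened -> {len(candidates)} candidates "
          f"(q < 0.05 and |NC-score| > 0.30)")

    part = partition(fold_changes(abundance, is_case, sorted(candidates)))
    write_tsv(part.rename_axis("genus"), mdir / "partition.tsv")
    n_inc = int((part.membership == "increased").sum())
    n_dec = int((part.membership == "decreased").sum())
    print(f"fold-change partition: {n_inc} increased, {n_dec} decreased in cases")

    vals = mdi_scores(abundance, part)
    assign = tertile_assign(vals, ~is_case)
    out = pd.DataFrame({"mdi": vals, "tertile": assign.tertile}).rename_axis("sample_id")
    write_tsv(out, mdir / "mdi.tsv")
    print(f"MDI tertile cuts from controls: ({assign.cuts[0]:.3f}, {assign.cuts[1]:.3f}); "
          f"case mean {vals[is_case].mean():.3f} vs control mean {vals[~is_case].mean():.3f}")


if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()
    run(args.seed, args.outdir)
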