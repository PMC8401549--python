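"""Generate the synthetic case-control study used by the later steps.

Writes a participants x food-groups intake table (33 groups, g/day), a
samples x genera relative-abundance table (74 genera, with planted
case/control fold-change blocks and co-varying factors), and the
covariate/outcome table, under results/synthetic/.
"""

import argparse
from pathlib import Path

from click.testing import CliRunner

from dietmicrobe.cli import main as cli_main


def run(seed: int, outdir: Path) -> None:
    target = outdir / "synthetic"
    res = CliRunner().invoke(
        cli_main,
        ["simulate", "--outdir", str(target), "--seed", str(seed),
         "--n-participants", "556", "--n-cases", "268",
         "--n-food-groups", "33", "--n-genera", "74"],
    )
    if res.exit_code != 0:
        raise SystemExit(res.output)
    print(f"synthetic study written to {target}: 556 participants "
          f"(268 cases / 288 controls), 33 food groups, 74 genera")


if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()
    run(args.seed, args.outdir)
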