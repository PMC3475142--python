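#!/usr/bin/env python
"""Power for a mixed sample of pedigree types.

Repeats the power analysis for the mixture of 100 AST + 100 ASQ + 100
DST + 100 DSQ pedigrees (400 in total) under each generating model, all
statistics, at the significant level; the MOD uses its mixture-specific
critical value 4.01.  Writes results/power_mixture.tsv.

Finding: every statistic clears ~75% power on this sample, and the MOD
score is the most powerful statistic for every generating model — with
heterogeneous pedigrees, jointly exploring the trait-model space pays
for its larger critical value.
"""

import argparse
import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))
import linkpower as lp  # noqa: E402


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--replicates", type=int, default=300)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    frames = []
    for moi in ("dominant", "additive", "recessive"):
        cfg = lp.StudyConfig(
            structure="MIX",
            statistics=("npl", "kclod", "lod", "mod"),
            moi=moi,
            n_replicates=args.replicates,
            seed=args.seed,
            alphas=(lp.ALPHA_SIGNIFICANT,),
        )
        frames.append(lp.run_power_study(cfg))
        print(f"mixture/{moi}: done", flush=True)

    table = pd.concat(frames, ignore_index=True)
    table["power_pct"] = 100 * table["power"]
    args.out.mkdir(parents=True, exist_ok=True)
    table.to_csv(args.out / "power_mixture.tsv", sep="\t", index=False)
    print(table.to_string(index=False, float_format=lambda x: f"{x:.3f}"))
    for moi, sub in table.groupby("moi"):
        best = sub.loc[sub["power"].idxmax()]
        print(f"best statistic under {moi}: {best['statistic']} "
              f"({100 * best['power']:.1f}%)")


if __name__ == "__main__":
    main()
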