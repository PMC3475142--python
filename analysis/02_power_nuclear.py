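#!/usr/bin/env python
"""Power by pedigree structure and generating model, nuclear families.

For every structure (ASP, AST, ASQ, DST, DSQ) and every generating model
(dominant, additive, recessive), simulates replicates of 500 pedigrees
under complete linkage and estimates the power of NPL, KC-LOD, LOD (all
three analysis models) and — where a published critical value exists —
the MOD score, at the significant level (alpha = 0.000049).  Writes
results/power_nuclear.tsv.

Findings this table reproduces: power falls when unaffected sibs are
added (ASP -> DST -> DSQ) for every statistic; a third affected sib
(AST) lifts power to ~99%+; the recessive model is hardest for small
sibships; with a dominant generating model the additive analysis model
out-scores the dominant one (deliberate parameter misspecification).
"""

import argparse
import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))
import linkpower as lp  # noqa: E402

STRUCTURES = ("ASP", "AST", "ASQ", "DST", "DSQ")
MOIS = ("dominant", "additive", "recessive")


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--replicates", type=int, default=500)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    frames = []
    for code in STRUCTURES:
        stats = ["npl", "kclod", "lod"]
        if code in lp.MOD_SIGNIFICANT_THRESHOLDS:
            stats.append("mod")
        for moi in MOIS:
            cfg = lp.StudyConfig(
                structure=code,
                statistics=tuple(stats),
                moi=moi,
                n_replicates=args.replicates,
                seed=args.seed,
                alphas=(lp.ALPHA_SIGNIFICANT,),
            )
            frames.append(lp.run_power_study(cfg))
            print(f"{code}/{moi}: done", flush=True)

    table = pd.concat(frames, ignore_index=True)
    table["power_pct"] = 100 * table["power"]
    args.out.mkdir(parents=True, exist_ok=True)
    table.to_csv(args.out / "power_nuclear.tsv", sep="\t", index=False)
    wide = table.pivot_table(
        index=["statistic"], columns=["structure", "moi"], values="power_pct"
    )
    print(wide.to_string(float_format=lambda x: f"{x:5.1f}"))


if __name__ == "__main__":
    main()
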