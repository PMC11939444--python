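#!/usr/bin/env python
"""Relative expression and hormetic shape classification per gene.

Generates seeded Ct tables for each shipped effect profile (a biphasic
responder, a single-amplitude peak responder and a null gene), runs the
ddCt pipeline with ANOVA/Tukey significance, and classifies each gene's
amplitude ladder.  Writes ``results/qpcr_results.csv`` and
``results/dose_response_profiles.csv``.
"""

import argparse
from pathlib import Path

import pandas as pd

from rfdosim import qpcr
from rfdosim.synth import PROFILES, GeneratorConfig, gen_ct_table

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=42)
    args = ap.parse_args()
    OUT.mkdir(exist_ok=True)

    all_results, shapes = [], []
    for key, profile in sorted(PROFILES.items()):
        ct = gen_ct_table(profile, GeneratorConfig(seed=args.seed, replicates=3))
        res = qpcr.analyze(ct, "GAPDH", "sham")
        all_results.append(res)
        prof = qpcr.profile_from_results(res, profile.name, "sham")
        shape = qpcr.classify_dose_response(prof, alpha=0.05)
        shapes.append({"profile": key, "gene": profile.name, "shape": shape})
        print(f"{profile.name}: classified {shape}")
        for _, r in res.iterrows():
            print(f"  {r['condition']:>7}: fold {r['fold_change']:.2f} "
                  f"+/- {r['sem']:.2f} (n={r['n']}) {r['stars']}")

    pd.concat(all_results, ignore_index=True).to_csv(OUT / "qpcr_results.csv",
                                                     index=False)
    pd.DataFrame(shapes).to_csv(OUT / "dose_response_profiles.csv", index=False)
    print("\nthe biphasic gene responds at both amplitude extremes but not in "
          "between — the U-shaped signature of a hormetic dose response")


if __name__ == "__main__":
    main()
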