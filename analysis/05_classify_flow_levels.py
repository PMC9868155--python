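#!/usr/bin/env python
"""Segment each template's plane stack into the three flow levels
(attached jet formation / confined jet / separated-recirculating) and
summarize how the total-pressure loss distributes across them."""

import argparse
from pathlib import Path

import pandas as pd

from pharyngoflow.io import RunConfig
from pharyngoflow.pipeline import run_report
from pharyngoflow.synthetic import TEMPLATES


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", type=Path, default=Path("results/levels"))
    args = ap.parse_args()

    rows = []
    for name in sorted(TEMPLATES):
        cfg = RunConfig(
            template=name, seed=args.seed,
            output_dir=str(args.out / name), log_level="WARNING",
        )
        res = run_report(cfg)
        subs = res.subsegments
        by_level = subs.groupby("level")["dpt_pa"].sum()
        n_by_level = pd.Series(res.levels.labels).value_counts().sort_index()
        row = {"template": name}
        for lvl in (1, 2, 3):
            row[f"n_planes_l{lvl}"] = int(n_by_level.get(lvl, 0))
            row[f"dpt_l{lvl}_pa"] = float(by_level.get(lvl, 0.0))
        rows.append(row)

    summary = pd.DataFrame(rows)
    summary.to_csv(args.out / "summary.csv", index=False, float_format="%.6g")
    print(summary.to_string(index=False))
    l3 = summary[[f"dpt_l{k}_pa" for k in (1, 2, 3)]].sum()
    print(
        "\nsampled-field dPt by level across templates: "
        + ", ".join(f"level {k}: {l3[f'dpt_l{k}_pa']:.3g} Pa" for k in (1, 2, 3))
        + "\n(negative level-2 totals reflect kinetic-energy recovery in the "
        "mass-flow-averaged separated-jet samples; reported, not clamped)"
    )


if __name__ == "__main__":
    main()
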