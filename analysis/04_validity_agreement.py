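#!/usr/bin/env python
"""Validity of device ENMO against the shaker reference.

Reads the epoch table produced by 02_simulate_validity.py (rebuilding it
if absent) and computes, per brand and aggregation method: pooled mean and
SD, Pearson r, Lin's CCC with 95% CI, mean absolute error, and mean bias
with 95% limits of agreement; plus the same errors broken out by shaker
speed, and Bland-Altman point exports.
"""

import runpy
from pathlib import Path

import pandas as pd

from shakerval import bland_altman_points, per_speed_error_summary, summarize_validity
from shakerval.agreement import _AGG_COLUMN
from shakerval.io import read_epoch_table

ROOT = Path(__file__).resolve().parents[1]
EPOCHS = ROOT / "scratch" / "epoch_table.csv"


def main() -> None:
    if not EPOCHS.exists():
        runpy.run_path(str(ROOT / "analysis" / "02_simulate_validity.py"), run_name="__main__")
    table = read_epoch_table(EPOCHS)

    summary = pd.concat(
        [summarize_validity(table, a) for a in ("mean", "rms")], ignore_index=True
    )
    per_speed = pd.concat(
        [per_speed_error_summary(table, a) for a in ("mean", "rms")],
        ignore_index=True,
    )
    print(summary.round(3).to_string(index=False))

    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    summary.to_csv(results / "table2_validity.csv", index=False)
    per_speed.to_csv(results / "per_speed_errors.csv", index=False)

    ba_dir = ROOT / "scratch" / "bland_altman"
    ba_dir.mkdir(parents=True, exist_ok=True)
    for agg, col in _AGG_COLUMN.items():
        for brand, grp in table.df.groupby("brand"):
            bland_altman_points(
                grp[col].to_numpy(), grp["reference_mg"].to_numpy()
            ).to_csv(ba_dir / f"{brand}_{agg}.csv", index=False)
    print("summaries -> results/, Bland-Altman points -> scratch/bland_altman/")


if __name__ == "__main__":
    main()
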