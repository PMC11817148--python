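#!/usr/bin/env python
"""Summarize the contour maps extracted from the fitted synthetic model.

The pipeline run (03) already exported sd-weighted coefficient fields
as OpenDX grids with 90th/10th-percentile region labels.  This driver
reloads them and reports where the favorable/unfavorable regions sit —
for the electrostatic field, positive values mark regions where
positive potential raises predicted activity; for the steric field,
positive values mark regions where bulk raises it.

Reads:  results/synthetic/run/regions_{electrostatic,steric}.csv
Writes: results/contour_summary.csv
"""

from pathlib import Path

import pandas as pd

BASE = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    rows = []
    for kind in ("electrostatic", "steric"):
        df = pd.read_csv(BASE / "synthetic" / "run" / f"regions_{kind}.csv")
        for label in ("favorable_high", "favorable_low"):
            sel = df[df["label"] == label]
            rows.append({
                "field": kind,
                "label": label,
                "n_points": len(sel),
                "value_min": sel["value"].min() if len(sel) else float("nan"),
                "value_max": sel["value"].max() if len(sel) else float("nan"),
            })
            centroid = (
                f"({sel['x'].mean():.1f}, {sel['y'].mean():.1f}, "
                f"{sel['z'].mean():.1f})" if len(sel) else "n/a"
            )
            print(f"{kind:<14} {label:<15} {len(sel):4d} points, "
                  f"centroid {centroid}")
    summary = pd.DataFrame(rows)
    summary.to_csv(BASE / "contour_summary.csv", index=False)
    print(f"\nWrote {BASE / 'contour_summary.csv'}")


if __name__ == "__main__":
    main()
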