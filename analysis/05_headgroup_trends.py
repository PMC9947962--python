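#!/usr/bin/env python
"""Headgroup-position trends across cholesterol content and temperature.

Reads results/headgroup_fits.csv (written by 04_selfconsistent_refinement)
and computes, within each (environment, temperature), the signed percent
change of the recovered headgroup position between every ordered
cholesterol pair — positive means the bilayer thinned as cholesterol
increased.  Writes results/headgroup_changes.csv and reports the
room-temperature 20 -> 40 mol% spans per environment.
"""

from pathlib import Path

import pandas as pd

from lamedp import headgroup_percent_change

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"


def main() -> None:
    fits_path = RESULTS / "headgroup_fits.csv"
    if not fits_path.exists():
        raise SystemExit("run analysis/04_selfconsistent_refinement.py first")
    fits = pd.read_csv(fits_path)

    rows = []
    for (cond, temp), grp in fits.groupby(["condition", "temp_K"]):
        grp = grp.sort_values("chol_pct")
        recs = list(grp.itertuples())
        for i, a in enumerate(recs):
            for b in recs[i + 1:]:
                rows.append(
                    {
                        "condition": cond, "temp_K": temp,
                        "chol_from": a.chol_pct, "chol_to": b.chol_pct,
                        "percent_change": headgroup_percent_change(a.z_H, b.z_H),
                    }
                )
    changes = pd.DataFrame(rows)
    changes.to_csv(RESULTS / "headgroup_changes.csv", index=False)

    print(f"all percent changes positive (thinning with cholesterol): "
          f"{(changes.percent_change > 0).all()}")
    room = changes.query("temp_K == 294 and chol_from == 20 and chol_to == 40")
    for row in room.itertuples():
        print(f"  {row.condition:>5} 294 K, 20 -> 40 mol%: "
              f"headgroup position changes by {row.percent_change:.1f}%")


if __name__ == "__main__":
    main()
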