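#!/usr/bin/env python
"""Peak analysis of every simulated pattern: background subtraction, peak
detection and fitting, lamellar indexing, and wide-angle (chain-packing)
characterisation.

Writes results/peak_table.csv (every fitted peak with its lamellar order)
and results/waxs_table.csv (chain-packing peak center/width per condition),
and reports whether the indexing reproduces the generator repeat spacings
and whether any sharp crystalline-like reflection contaminates the
wide-angle window.
"""

import math
from pathlib import Path

import pandas as pd

from lamedp import characterize_waxs, detect_peaks, index_lamellar, simulate_pattern, study_conditions
from lamedp.peak_analysis import subtract_background

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    peak_rows, waxs_rows = [], []
    d_errors = []
    for (cond, chol, temp), spec in study_conditions().items():
        profile = simulate_pattern(spec)
        sub = subtract_background(profile, model="power_law").profile
        peaks = detect_peaks(sub, min_prominence=0.005)
        lattices = index_lamellar(peaks)
        true_d = spec.lattices[0][0].d
        d_errors.append(abs(lattices[0].d - true_d) / true_d)
        for pk in peaks:
            peak_rows.append(
                {
                    "condition": cond, "chol_pct": chol, "temp_K": temp,
                    "center_q": pk.center, "center_d": 2 * math.pi / pk.center,
                    "fwhm": pk.fwhm, "area": pk.area,
                    "label": pk.label, "lattice_id": pk.lattice_id, "h": pk.h,
                }
            )
        waxs = characterize_waxs(profile)
        waxs_rows.append(
            {
                "condition": cond, "chol_pct": chol, "temp_K": temp,
                "waxs_center_d": waxs.peak.center, "waxs_fwhm_d": waxs.peak.fwhm,
                "sharp_components": len(waxs.sharp_components),
            }
        )

    peaks_df = pd.DataFrame(peak_rows)
    waxs_df = pd.DataFrame(waxs_rows)
    peaks_df.to_csv(RESULTS / "peak_table.csv", index=False)
    waxs_df.to_csv(RESULTS / "waxs_table.csv", index=False)

    first = peaks_df.query("h == 1")
    print(f"indexed {len(waxs_df)} patterns; all first-order d-spacings in "
          f"[{first.center_d.min():.1f}, {first.center_d.max():.1f}] A")
    print(f"worst relative d error vs generator truth: {max(d_errors):.2e}")
    lo = waxs_df.query("temp_K < 314").waxs_center_d
    hi = waxs_df.query("temp_K == 314").waxs_center_d
    print(f"chain-packing peak: {lo.min():.2f}-{lo.max():.2f} A below 314 K, "
          f"{hi.min():.2f}-{hi.max():.2f} A at 314 K")
    print(f"sharp crystalline-like components flagged: {waxs_df.sharp_components.sum()}")


if __name__ == "__main__":
    main()
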