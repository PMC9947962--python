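#!/usr/bin/env python
"""Electron density profiles and form factors for one example series.

For the water environment at 30 mol% cholesterol, runs the pipeline at all
three temperatures and writes the final relative electron density profiles
(results/edp_examples.csv: z vs delta-rho per temperature) together with
the signed form factors entering each synthesis
(results/form_factors.csv).  The density profiles show the expected
bilayer anatomy: headgroup maxima at +/- z_H and the methyl trough at the
centre; the form-factor table records which reflection was extrapolated
from the fitted model rather than measured.
"""

from pathlib import Path

import pandas as pd

from lamedp import analyze_pattern, simulate_pattern, study_conditions

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"

CONDITION, CHOL = "water", 30


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    grid = study_conditions()
    edp_rows, ff_rows = [], []
    for temp in (294, 304, 314):
        spec = grid[(CONDITION, CHOL, temp)]
        res = analyze_pattern(simulate_pattern(spec))
        for z, rho in zip(res.edp.z[::10], res.edp.delta_rho[::10]):
            edp_rows.append({"temp_K": temp, "z": z, "delta_rho": rho})
        for e in res.trace.final_form_factors.entries:
            ff_rows.append(
                {
                    "temp_K": temp, "h": e.h, "q": e.q,
                    "amplitude": e.amplitude, "sign": e.sign, "source": e.source,
                }
            )
        print(
            f"T={temp} K: d={res.d:.2f} A, z_H={res.z_H:.2f} A "
            f"(truth {spec.lattices[0][0].z_H:.2f}), "
            f"{res.trace.n_iterations} iterations, signs "
            + "".join("+" if e.sign > 0 else "-" for e in res.trace.final_form_factors.entries)
        )
    pd.DataFrame(edp_rows).to_csv(RESULTS / "edp_examples.csv", index=False)
    pd.DataFrame(ff_rows).to_csv(RESULTS / "form_factors.csv", index=False)
    print(f"wrote {RESULTS / 'edp_examples.csv'} and {RESULTS / 'form_factors.csv'}")


if __name__ == "__main__":
    main()
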