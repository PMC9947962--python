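#!/usr/bin/env python
"""Self-consistent headgroup refinement of every condition in the study.

Runs the full pipeline on all 27 simulated patterns and writes
results/headgroup_fits.csv (recovered z_H, its uncertainty, iteration
count, convergence flag, recovery error vs generator truth) plus one
example convergence trace (results/convergence_trace.csv).  The refinement
should converge within a handful of iterations everywhere and recover the
generator headgroup position to well under 0.5 A.
"""

from pathlib import Path

import pandas as pd

from lamedp import analyze_pattern, simulate_pattern, study_conditions

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    rows = []
    example_trace = None
    for (cond, chol, temp), spec in study_conditions().items():
        res = analyze_pattern(simulate_pattern(spec))
        truth = spec.lattices[0][0]
        rows.append(
            {
                "condition": cond, "chol_pct": chol, "temp_K": temp,
                "z_H": res.z_H, "z_H_uncertainty": res.fit.z_H_uncertainty,
                "z_H_true": truth.z_H, "abs_error": abs(res.z_H - truth.z_H),
                "d": res.d, "n_iterations": res.trace.n_iterations,
                "converged": res.trace.converged,
            }
        )
        if example_trace is None:
            example_trace = res.trace.to_frame()

    fits = pd.DataFrame(rows).sort_values(["condition", "chol_pct", "temp_K"])
    fits.to_csv(RESULTS / "headgroup_fits.csv", index=False)
    example_trace.to_csv(RESULTS / "convergence_trace.csv", index=False)

    print(f"refined {len(fits)} conditions; all converged: {fits.converged.all()}")
    print(f"iterations: max {fits.n_iterations.max()}, "
          f"headgroup recovery error: max {fits.abs_error.max():.3f} A "
          f"(max fit-derived z_H s.d. {fits.z_H_uncertainty.max():.2e} A)")


if __name__ == "__main__":
    main()
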