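"""Self-consistent coupling of electron-density synthesis and form-factor
fitting, plus headgroup trend statistics.

Each iteration: (1) assign phase signs from the current model (the first
iteration uses the canonical initialisation pattern), (2) synthesise the
electron density profile from the signed amplitudes, (3) fit the Gaussian
bilayer model to the signed measured amplitudes, (4) extrapolate one order
beyond the highest measured reflection, (5) measure the relative change of
the model headgroup position z_H.  The loop stops when that change drops to
the tolerance (default 1 part in 1e4) or after ``max_iterations`` (default
10).  Convergence is judged on the model parameter z_H, not the density
argmax, which is only logged for cross-checking — the reconstruction is
truncated at 3-4 orders, so its argmax is resolution-limited.

Sign oscillation (the sign tuple cycling with period 2) is detected and
reported with both attractors instead of spinning until the cap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .edp_reconstruction import (
    ElectronDensityProfile,
    FormFactorSet,
    assign_signs,
    canonicalize_orientation,
    fourier_edp,
    headgroup_from_edp,
)
from .form_factor_fit import FitError, FitResult, extrapolate_form_factor, fit_gaussian_model
from .synthetic_data import GaussianBilayerModel

__all__ = [
    "IterationRecord",
    "IterationTrace",
    "LoopError",
    "run_selfconsistent",
    "headgroup_percent_change",
    "trend_table",
]


class LoopError(ValueError):
    """Raised for invalid loop inputs."""


@dataclass(frozen=True)
class IterationRecord:
    iteration: int
    z_H_model: float
    z_H_edp: float
    signs: tuple[int, ...]
    residual_rms: float
    rel_change: float | None  # None on the first iteration


@dataclass
class IterationTrace:
    records: list[IterationRecord] = field(default_factory=list)
    converged: bool = False
    stop_reason: str = "max_iterations"   # tolerance | max_iterations
    oscillating: bool = False
    attractors: tuple[tuple[int, ...], tuple[int, ...]] | None = None
    final_form_factors: FormFactorSet | None = None  # measured + extrapolated

    @property
    def n_iterations(self) -> int:
        return len(self.records)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "iteration": r.iteration,
                    "z_H_model": r.z_H_model,
                    "z_H_edp": r.z_H_edp,
                    "signs": "".join("+" if s > 0 else "-" for s in r.signs),
                    "residual_rms": r.residual_rms,
                    "rel_change": np.nan if r.rel_change is None else r.rel_change,
                }
                for r in self.records
            ]
        )


def run_selfconsistent(
    ff: FormFactorSet,
    init: GaussianBilayerModel,
    tolerance: float = 1e-4,
    max_iterations: int = 10,
    refit_signs: bool = True,
    n_grid: int = 1001,
    bounds: dict[str, tuple[float, float]] | None = None,
    fix: tuple[str, ...] = (),
) -> tuple[FitResult, ElectronDensityProfile, IterationTrace]:
    """Iterate EDP synthesis and form-factor fitting to convergence in z_H.

    ``ff`` needs at least two measured orders (three to leave the default
    shape parameters free).  ``refit_signs=False`` freezes the signs after
    the first iteration instead of re-deriving them from each fitted model.
    Returns the final fit, the final density profile (measured plus one
    extrapolated order, signed by the final model), and the full trace.
    The procedure is fully deterministic.
    """
    measured = ff.measured
    if len(measured) < 2:
        raise LoopError(f"need >= 2 measured orders, got {len(measured)}")
    ff_measured = FormFactorSet(ff.lattice_id, ff.d, tuple(measured))

    trace = IterationTrace()
    model = init
    fit: FitResult | None = None
    ff_ext: FormFactorSet | None = None
    prev_z = None
    try:
        for k in range(1, max_iterations + 1):
            if k == 1:
                ff_signed = assign_signs(ff_measured)  # canonical init pattern
            elif refit_signs:
                ff_signed = assign_signs(ff_measured, reference=model)
            # else: keep previous ff_signed

            # density synthesis includes last iteration's extrapolated order
            if ff_ext is not None:
                extrap = tuple(e for e in ff_ext.entries if e.source == "extrapolated")
                ff_for_edp = FormFactorSet(ff.lattice_id, ff.d, ff_signed.entries + extrap)
            else:
                ff_for_edp = ff_signed
            edp = canonicalize_orientation(fourier_edp(ff_for_edp, n_grid))
            z_edp = headgroup_from_edp(edp)

            fit = fit_gaussian_model(ff_signed, init=model, bounds=bounds, fix=fix)
            model = fit.model
            ff_ext = extrapolate_form_factor(fit, ff_signed)

            rel = None if prev_z is None else abs(model.z_H - prev_z) / prev_z
            prev_z = model.z_H
            trace.records.append(
                IterationRecord(k, model.z_H, z_edp, ff_signed.signs(), fit.residual_rms, rel)
            )

            if len(trace.records) >= 3:
                s = [r.signs for r in trace.records]
                if s[-1] == s[-3] and s[-1] != s[-2]:
                    trace.oscillating = True
                    trace.attractors = (s[-2], s[-1])

            # tolerance 0 disables early stopping (forces the iteration cap)
            if rel is not None and tolerance > 0 and rel <= tolerance:
                trace.converged = True
                trace.stop_reason = "tolerance"
                break
    except FitError as exc:
        err = LoopError(f"fit failed at iteration {len(trace.records) + 1}: {exc}")
        err.trace = trace  # partial trace up to the failure
        raise err from exc

    if not trace.converged:
        trace.stop_reason = "max_iterations"

    final_signed = assign_signs(ff_measured, reference=model) if refit_signs else ff_signed
    final_full = FormFactorSet(
        ff.lattice_id,
        ff.d,
        final_signed.entries
        + tuple(e for e in extrapolate_form_factor(fit, final_signed).entries
                if e.source == "extrapolated"),
    )
    final_edp = canonicalize_orientation(fourier_edp(final_full, n_grid))
    trace.final_form_factors = final_full
    return fit, final_edp, trace


def headgroup_percent_change(zH_a: float, zH_b: float) -> float:
    """Signed percent change 100*(zH_a - zH_b)/zH_a.

    Positive = the headgroup moved inward (bilayer thinned) from condition
    a to condition b.
    """
    if not zH_a > 0:
        raise LoopError(f"reference headgroup position must be > 0, got {zH_a}")
    return 100.0 * (zH_a - zH_b) / zH_a


def trend_table(
    results: Mapping[tuple[str, float, float], object]
    | Iterable[tuple[tuple[str, float, float], object]],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tabulate headgroup positions across conditions and their pairwise
    percent changes with cholesterol content.

    ``results`` maps (condition, chol mol %, temperature K) to either a
    :class:`FitResult` or a ``(FitResult, IterationTrace)`` pair.  Returns
    a long-format sample table and a change table holding, within each
    (condition, temperature), the percent change between every ordered
    cholesterol pair (low -> high).
    """
    items = list(results.items()) if isinstance(results, Mapping) else list(results)
    keys = [k for k, _ in items]
    if len(keys) != len(set(keys)):
        raise LoopError("duplicate condition keys in results")
    if not items:
        raise LoopError("no results supplied")

    rows = []
    for (cond, chol, temp), value in items:
        if isinstance(value, tuple):
            fit, trace = value
            n_iter, conv = trace.n_iterations, trace.converged
        else:
            fit, n_iter, conv = value, np.nan, value.converged
        rows.append(
            {
                "condition": cond,
                "chol_pct": chol,
                "temp_K": temp,
                "z_H": fit.model.z_H,
                "z_H_uncertainty": fit.z_H_uncertainty,
                "n_iterations": n_iter,
                "converged": conv,
            }
        )
    table = pd.DataFrame(rows).sort_values(["condition", "temp_K", "chol_pct"]).reset_index(drop=True)

    changes = []
    for (cond, temp), grp in table.groupby(["condition", "temp_K"], sort=True):
        grp = grp.sort_values("chol_pct")
        recs = list(grp.itertuples())
        for i, a in enumerate(recs):
            for b in recs[i + 1:]:
                changes.append(
                    {
                        "condition": cond,
                        "temp_K": temp,
                        "chol_from": a.chol_pct,
                        "chol_to": b.chol_pct,
                        "percent_change": headgroup_percent_change(a.z_H, b.z_H),
                    }
                )
    change_table = pd.DataFrame(
        changes, columns=["condition", "temp_K", "chol_from", "chol_to", "percent_change"]
    )
    return table, change_table
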