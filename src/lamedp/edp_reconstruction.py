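"""Electron density profile reconstruction by Fourier synthesis.

For a centrosymmetric bilayer the form factor is real, so each Bragg order
carries an amplitude |F_h| (from the Lorentz-corrected integrated intensity)
plus an unknown sign.  Once signs are assigned, the relative density across
the bilayer normal is the truncated cosine series

    drho(z) = sum_h  s_h * |F_h| * cos(2*pi*h*z/d),   z in [-d/2, d/2]

with the (constant) average density rho_AVG carried only as metadata — all
outputs here are on a relative scale, and the headgroup position z_H is read
off as the density maximum on [0, d/2].

Sign conventions: with no reference model, signs initialise to the canonical
gel/fluid PC pattern (-, -, +, -) — i.e. -1 for every order except h = 3 —
which serves purely as the seed of the self-consistent loop; with a
reference model, s_h = sign(F_model(q_h)) (exact zeros count as -1).  The
global sign ambiguity is resolved by the convention that headgroup maxima
are positive (density at z_H above density at the bilayer centre).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .peak_analysis import LamellarIndexing
from .synthetic_data import GaussianBilayerModel, model_form_factor

__all__ = [
    "FormFactorEntry",
    "FormFactorSet",
    "ElectronDensityProfile",
    "ReconstructionError",
    "amplitudes_from_peaks",
    "assign_signs",
    "exact_form_factors",
    "initial_sign",
    "fourier_edp",
    "headgroup_from_edp",
    "canonicalize_orientation",
]


class ReconstructionError(ValueError):
    """Raised for invalid form-factor sets or degenerate profiles."""


@dataclass(frozen=True)
class FormFactorEntry:
    h: int
    q: float                 # 1/Angstrom, = 2*pi*h/d
    amplitude: float         # >= 0, arbitrary units
    sign: int = 0            # -1, +1, or 0 = unassigned
    source: str = "measured"  # measured | extrapolated

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ReconstructionError(f"amplitude must be >= 0, got {self.amplitude}")
        if self.sign not in (-1, 0, 1):
            raise ReconstructionError(f"sign must be -1, 0 or +1, got {self.sign}")


@dataclass(frozen=True)
class FormFactorSet:
    """Per-order form factors of one lamellar lattice of repeat d."""

    lattice_id: int
    d: float
    entries: tuple[FormFactorEntry, ...]

    def __post_init__(self) -> None:
        hs = [e.h for e in self.entries]
        if len(hs) != len(set(hs)):
            raise ReconstructionError("duplicate diffraction orders")
        for e in self.entries:
            expected = 2.0 * math.pi * e.h / self.d
            if abs(e.q - expected) > 1e-9 * expected:
                raise ReconstructionError(
                    f"q_{e.h} = {e.q} inconsistent with 2*pi*h/d = {expected}"
                )

    @property
    def measured(self) -> tuple[FormFactorEntry, ...]:
        return tuple(e for e in self.entries if e.source == "measured")

    def signs(self) -> tuple[int, ...]:
        return tuple(e.sign for e in sorted(self.entries, key=lambda e: e.h))


def amplitudes_from_peaks(indexing: LamellarIndexing) -> FormFactorSet:
    """Convert indexed peak areas to structure-factor amplitudes.

    Inverts the powder Lorentz weighting: |F_h| = sqrt(area_h * h^2), then
    normalises so the lowest measured order has amplitude 1 (intensities are
    in arbitrary units; every downstream quantity is scale-free).  Signs are
    left unassigned.
    """
    entries = []
    for h, peak in sorted(indexing.orders, key=lambda e: e[0]):
        if not peak.area > 0:
            raise ReconstructionError(f"order {h} has non-positive area {peak.area}")
        amp = math.sqrt(peak.area * h * h)
        entries.append(FormFactorEntry(h, 2.0 * math.pi * h / indexing.d, amp))
    norm = entries[0].amplitude
    if norm == 0:
        raise ReconstructionError("lowest-order amplitude is zero; cannot normalise")
    entries = [replace(e, amplitude=e.amplitude / norm) for e in entries]
    return FormFactorSet(indexing.lattice_id, indexing.d, tuple(entries))


def exact_form_factors(
    model: GaussianBilayerModel,
    orders: tuple[int, ...] = (1, 2, 4),
    signed: bool = True,
    normalized: bool = True,
    lattice_id: int = 1,
) -> FormFactorSet:
    """Form factors evaluated exactly from a bilayer model at its Bragg
    positions — the noise-free input the rest of the pipeline would
    extract from a simulated pattern of that model.
    """
    entries = []
    norm = None
    for h in sorted(orders):
        q = 2.0 * math.pi * h / model.d
        f = float(model_form_factor(model, q))
        if norm is None:
            norm = abs(f) if (normalized and f != 0) else 1.0
        entries.append(
            FormFactorEntry(
                h=h, q=q, amplitude=abs(f) / norm,
                sign=(-1 if f < 0 else 1) if signed else 0,
            )
        )
    return FormFactorSet(lattice_id, model.d, tuple(entries))


def initial_sign(h: int) -> int:
    """Model-free initialisation: canonical PC-bilayer pattern (-,-,+,-)
    extended as -1 for every order except h = 3."""
    return 1 if h == 3 else -1


def assign_signs(
    ff: FormFactorSet,
    reference: GaussianBilayerModel | None = None,
    eps: float = 1e-12,
) -> FormFactorSet:
    """Assign phase signs, from a reference model if supplied.

    With a reference, s_h = sign(F_model(q_h)); |F_model| < eps counts as
    -1 (documented tie-break).  Without one, the canonical initialisation
    pattern is used.
    """
    entries = []
    for e in ff.entries:
        if reference is not None:
            f = float(model_form_factor(reference, e.q))
            s = -1 if f < eps else 1
        else:
            s = initial_sign(e.h)
        entries.append(replace(e, sign=s))
    return replace(ff, entries=tuple(entries))


@dataclass
class ElectronDensityProfile:
    """Relative electron density on a symmetric grid over [-d/2, d/2].

    ``rho_avg`` is metadata only; it is never added to ``delta_rho``.
    """

    z: np.ndarray
    delta_rho: np.ndarray
    d: float
    rho_avg: float = 0.0

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        self.delta_rho = np.asarray(self.delta_rho, dtype=float)
        if self.z.shape != self.delta_rho.shape:
            raise ReconstructionError("z and delta_rho must have the same shape")


def fourier_edp(ff: FormFactorSet, n_grid: int = 1001) -> ElectronDensityProfile:
    """Synthesise drho(z) = sum_h s_h |F_h| cos(2*pi*h*z/d).

    The grid is symmetric about 0 with ``n_grid`` points over [-d/2, d/2]
    (an even count is promoted to odd so z = 0 is on the grid).  Requires
    every sign to be assigned.  The cosine series is even and mean-zero
    over the unit cell by construction.
    """
    for e in ff.entries:
        if e.sign == 0:
            raise ReconstructionError(f"order {e.h} has no assigned sign")
    if n_grid % 2 == 0:
        n_grid += 1
    z = np.linspace(-ff.d / 2, ff.d / 2, n_grid)
    rho = np.zeros_like(z)
    for e in ff.entries:
        rho += e.sign * e.amplitude * np.cos(2.0 * math.pi * e.h * z / ff.d)
    return ElectronDensityProfile(z, rho, ff.d)


def canonicalize_orientation(edp: ElectronDensityProfile) -> ElectronDensityProfile:
    """Resolve the global sign ambiguity: headgroup maxima positive.

    If the bilayer centre is the global maximum (density peak at z = 0,
    the trough convention violated), all signs — hence the profile — are
    flipped.
    """
    centre = float(np.interp(0.0, edp.z, edp.delta_rho))
    if centre >= float(np.max(edp.delta_rho)) - 1e-12:
        return ElectronDensityProfile(edp.z, -edp.delta_rho, edp.d, edp.rho_avg)
    return edp


def headgroup_from_edp(edp: ElectronDensityProfile) -> float:
    """Headgroup position: z of the global density maximum on [0, d/2],
    refined by parabolic interpolation through the 3 grid points around
    the maximum.  Equal maxima resolve to the larger z (determinism rule).
    """
    mask = edp.z >= 0
    z, rho = edp.z[mask], edp.delta_rho[mask]
    if np.ptp(edp.delta_rho) < 1e-15:
        raise ReconstructionError("constant profile has no headgroup position")
    rho_max = float(np.max(rho))
    # ties resolve to the largest z among near-equal maxima
    i = int(np.max(np.flatnonzero(rho >= rho_max - 1e-12 * max(abs(rho_max), 1.0))))
    if i == 0 or i == z.size - 1:
        return float(z[i])
    y0, y1, y2 = rho[i - 1], rho[i], rho[i + 1]
    denom = y0 - 2 * y1 + y2
    if denom == 0:
        return float(z[i])
    offset = 0.5 * (y0 - y2) / denom
    return float(z[i] + offset * (z[1] - z[0]))
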