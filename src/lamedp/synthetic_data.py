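"""Forward simulation of lamellar SAXS/WAXS powder patterns.

A multilamellar vesicle suspension diffracts as a 1-D powder: a lamellar
lattice of repeat ``d`` produces Bragg reflections at ``q_h = 2*pi*h/d``
whose integrated areas are ``|F(q_h)|^2 / h^2`` — the form factor of one
bilayer sampled at the Bragg positions, weighted by the standard powder
Lorentz factor for unoriented stacks (``1/h^2``, equivalently ``1/q_h^2``
up to a constant).  The bilayer's electron-density contrast is modelled as
three Gaussians — a positive headgroup pair at ``+/- z_H`` of width
``sigma_H`` and a negative methyl trough at the bilayer centre of width
``sigma_C``:

    drho(z) = scale * [ exp(-(z - z_H)^2 / (2 sigma_H^2))
                      + exp(-(z + z_H)^2 / (2 sigma_H^2))
                      - rho_ratio * exp(-z^2 / (2 sigma_C^2)) ]

whose analytic cosine transform is

    F(q) = scale * sqrt(2*pi) * [ 2 sigma_H cos(q z_H) exp(-sigma_H^2 q^2 / 2)
                                - rho_ratio sigma_C exp(-sigma_C^2 q^2 / 2) ]

Because every pattern is generated from known parameters, every downstream
stage (background subtraction, peak fitting, indexing, reconstruction,
model fitting, the self-consistent loop) is testable by parameter recovery.

The simulator also emulates the phenomenology of real sub-Tm ternary
DPPC/sphingomyelin/cholesterol samples: coexisting lamellar lattices with
broad, overlapping first-order peaks; a broad wide-angle chain-packing peak
between ~4.1 and ~4.9 Angstrom; an optional sharp crystalline-cholesterol
reflection near 34 Angstrom; smooth background and counting noise.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field

import numpy as np

from .profile_io import AbscissaKind, DiffractionProfile

__all__ = [
    "GaussianBilayerModel",
    "SharpReflection",
    "WaxsComponent",
    "Background",
    "SyntheticSpec",
    "SimulationError",
    "model_edp",
    "model_form_factor",
    "pseudo_voigt",
    "simulate_pattern",
    "default_model",
    "default_spec",
    "study_conditions",
]

SQRT_2PI = math.sqrt(2.0 * math.pi)


class SimulationError(ValueError):
    """Raised for invalid simulation specifications."""


@dataclass(frozen=True)
class GaussianBilayerModel:
    """Three-Gaussian bilayer electron-density model.

    Parameters
    ----------
    z_H : float
        Headgroup position, Angstrom from the bilayer centre; 0 < z_H < d/2.
    sigma_H : float
        Width of the headgroup Gaussians, Angstrom.
    sigma_C : float
        Width of the central methyl-trough Gaussian, Angstrom.
    rho_ratio : float
        rho_C / rho_H, depth of the trough relative to the headgroup peaks.
    scale : float
        Overall amplitude (rho_H absorbed); arbitrary units.
    d : float
        Lamellar repeat spacing, Angstrom.
    """

    z_H: float
    sigma_H: float
    sigma_C: float
    rho_ratio: float
    scale: float
    d: float

    def __post_init__(self) -> None:
        if not 0 < self.z_H < self.d / 2:
            raise SimulationError(f"z_H must lie in (0, d/2): z_H={self.z_H}, d={self.d}")
        for name in ("sigma_H", "sigma_C", "scale"):
            if not getattr(self, name) > 0:
                raise SimulationError(f"{name} must be > 0, got {getattr(self, name)}")
        if not self.rho_ratio >= 0:
            raise SimulationError(f"rho_ratio must be >= 0, got {self.rho_ratio}")

    def bragg_q(self, h: int | np.ndarray) -> np.ndarray:
        """Bragg position(s) q_h = 2*pi*h/d."""
        return 2.0 * math.pi * np.asarray(h, dtype=float) / self.d


def model_edp(model: GaussianBilayerModel, z_grid: np.ndarray) -> np.ndarray:
    """Relative electron density drho(z) of the model on ``z_grid``.

    ``z_grid`` must lie within the unit cell [-d/2, d/2].  The profile is
    even in z by construction.
    """
    z = np.asarray(z_grid, dtype=float)
    half = model.d / 2 + 1e-9
    if np.any(z < -half) or np.any(z > half):
        raise SimulationError("z_grid extends outside the unit cell [-d/2, d/2]")
    head = np.exp(-((z - model.z_H) ** 2) / (2 * model.sigma_H**2))
    head = head + np.exp(-((z + model.z_H) ** 2) / (2 * model.sigma_H**2))
    trough = model.rho_ratio * np.exp(-(z**2) / (2 * model.sigma_C**2))
    return model.scale * (head - trough)


def model_form_factor(model: GaussianBilayerModel, q: np.ndarray | float) -> np.ndarray:
    """Analytic bilayer form factor F(q) (real; sign carries the phase)."""
    q = np.asarray(q, dtype=float)
    head = 2.0 * model.sigma_H * np.cos(q * model.z_H) * np.exp(-(model.sigma_H**2) * q**2 / 2)
    trough = model.rho_ratio * model.sigma_C * np.exp(-(model.sigma_C**2) * q**2 / 2)
    return model.scale * SQRT_2PI * (head - trough)


def pseudo_voigt(
    x: np.ndarray, center: float, fwhm: float, area: float, eta: float = 0.5
) -> np.ndarray:
    """Area-normalised pseudo-Voigt line: eta*Lorentzian + (1-eta)*Gaussian.

    Both components share the same FWHM, matching the common diffraction
    peak-fitting convention.
    """
    dx = np.asarray(x, dtype=float) - center
    gauss = (2.0 / fwhm) * math.sqrt(math.log(2) / math.pi) * np.exp(
        -4.0 * math.log(2) * dx**2 / fwhm**2
    )
    lorentz = (2.0 / (math.pi * fwhm)) / (1.0 + 4.0 * dx**2 / fwhm**2)
    return area * (eta * lorentz + (1.0 - eta) * gauss)


@dataclass(frozen=True)
class SharpReflection:
    """A sharp reflection given in real-space units (e.g. crystalline
    cholesterol near 34 Angstrom)."""

    center_d: float  # Angstrom
    fwhm_d: float    # Angstrom
    height: float    # arbitrary units


@dataclass(frozen=True)
class WaxsComponent:
    """Broad wide-angle chain-packing peak, real-space units."""

    center_d: float = 4.15  # Angstrom; 4.1-4.2 at low T, 4.6-4.9 near 314 K
    fwhm_d: float = 0.35
    height: float = 40.0


@dataclass(frozen=True)
class Background:
    """Smooth background c + a * q**(-p)."""

    constant: float = 50.0
    amplitude: float = 0.5
    exponent: float = 1.2

    def __call__(self, q: np.ndarray) -> np.ndarray:
        return self.constant + self.amplitude * np.power(q, -self.exponent)


@dataclass(frozen=True)
class SyntheticSpec:
    """Full description of one simulated pattern.

    ``lattices`` holds (model, weight) pairs with weights summing to 1;
    ``visible_orders`` suppresses Bragg orders outside the tuple (default
    (1, 2, 4): order 3 extinct, as in gel-phase PC patterns showing repeat
    spacings at 1/2 and 1/4); ``peak_fwhm`` is the Bragg peak FWHM in 1/A;
    ``noise_sd_fraction`` sets multiplicative Gaussian noise.
    """

    lattices: tuple[tuple[GaussianBilayerModel, float], ...]
    n_orders: int = 4
    visible_orders: tuple[int, ...] | None = (1, 2, 4)
    peak_fwhm: float = 0.005
    peak_eta: float = 0.5
    waxs: WaxsComponent | None = field(default_factory=WaxsComponent)
    chol_reflection: SharpReflection | None = None
    background: Background = field(default_factory=Background)
    noise_sd_fraction: float = 0.01
    seed: int = 0
    q_grid: tuple[float, float, int] = (0.03, 2.4, 12000)

    def __post_init__(self) -> None:
        if not self.lattices:
            raise SimulationError("at least one lattice is required")
        total = sum(w for _, w in self.lattices)
        if not math.isclose(total, 1.0, rel_tol=0, abs_tol=1e-9):
            raise SimulationError(f"lattice weights must sum to 1, got {total}")
        if self.n_orders < 2:
            raise SimulationError("n_orders must be >= 2")
        if self.noise_sd_fraction < 0:
            raise SimulationError("noise_sd_fraction must be >= 0")
        if self.q_grid[0] <= 0:
            raise SimulationError("q_grid minimum must be > 0")
        if self.peak_fwhm <= 0:
            raise SimulationError("peak_fwhm must be > 0")

    def orders(self) -> tuple[int, ...]:
        hs = range(1, self.n_orders + 1)
        if self.visible_orders is None:
            return tuple(hs)
        return tuple(h for h in hs if h in self.visible_orders)


def default_model(**overrides) -> GaussianBilayerModel:
    """Typical gel-phase PC-bilayer parameters (literature values):
    z_H = 22 A, sigma_H = 3 A, sigma_C = 5 A, rho_ratio = 1, d = 65 A."""
    params = dict(z_H=22.0, sigma_H=3.0, sigma_C=5.0, rho_ratio=1.0, scale=1.0, d=65.0)
    params.update(overrides)
    return GaussianBilayerModel(**params)


def default_spec(**overrides) -> SyntheticSpec:
    """Single default lattice, orders 1/2/4, WAXS peak at 4.15 A, 1% noise."""
    params: dict = dict(lattices=((default_model(), 1.0),))
    params.update(overrides)
    return SyntheticSpec(**params)


def simulate_pattern(spec: SyntheticSpec) -> DiffractionProfile:
    """Simulate one powder pattern on the spec's q grid.

    Each lamellar lattice contributes pseudo-Voigt Bragg peaks at
    ``q_h = 2*pi*h/d`` with integrated area ``weight * |F(q_h)|^2 / h^2``;
    optional WAXS and sharp reflections, background, and seeded
    multiplicative Gaussian noise are added on top.  Identical specs give
    identical output.
    """
    qmin, qmax, n = spec.q_grid
    q = np.linspace(qmin, qmax, int(n))
    dq = q[1] - q[0]

    narrowest = spec.peak_fwhm
    if spec.chol_reflection is not None:
        r = spec.chol_reflection
        narrowest = min(narrowest, 2 * math.pi * r.fwhm_d / r.center_d**2)
    if narrowest / dq < 4:
        raise SimulationError(
            f"q grid too coarse: {narrowest / dq:.2f} points per FWHM (need >= 4)"
        )

    intensity = spec.background(q)
    for model, weight in spec.lattices:
        for h in spec.orders():
            q_h = 2.0 * math.pi * h / model.d
            if not qmin <= q_h <= qmax:
                continue
            area = weight * float(model_form_factor(model, q_h)) ** 2 / h**2
            intensity = intensity + pseudo_voigt(q, q_h, spec.peak_fwhm, area, spec.peak_eta)

    for comp in (spec.waxs, spec.chol_reflection):
        if comp is None:
            continue
        q_c = 2.0 * math.pi / comp.center_d
        fwhm_q = 2.0 * math.pi * comp.fwhm_d / comp.center_d**2
        # height-parameterised: scale unit-height pseudo-Voigt
        shape = pseudo_voigt(q, q_c, fwhm_q, 1.0, spec.peak_eta)
        peak_max = pseudo_voigt(np.array([q_c]), q_c, fwhm_q, 1.0, spec.peak_eta)[0]
        intensity = intensity + comp.height * shape / peak_max

    if spec.noise_sd_fraction > 0:
        rng = np.random.default_rng(spec.seed)
        intensity = intensity * (1.0 + spec.noise_sd_fraction * rng.standard_normal(q.size))
        intensity = np.clip(intensity, 0.0, None)

    return DiffractionProfile(q, intensity, AbscissaKind.Q)


def study_conditions() -> dict[tuple[str, int, int], SyntheticSpec]:
    """Synthetic study grid emulating a sub-Tm ternary lipid XRD campaign.

    Conditions: sample environment (water, or trace vitamin-D binding
    protein DBP / vitamin-D receptor VDR) x cholesterol 20/30/40 mol% x
    temperature 294/304/314 K.  Generator truths encode the expected
    phenomenology: headgroup position (hence bilayer thickness) decreases
    with cholesterol content — spanning ~17% for the DBP series and ~8%
    for the VDR series at 294 K — d stays within 60-80 A, and the WAXS
    chain-packing peak sits at 4.15 A at low temperature, shifting to
    4.75 A at 314 K.  Conditions differ more at 20% Chol than at 40%.
    """
    z_h_by_chol = {
        "water": {20: 23.6, 30: 21.8, 40: 20.1},
        "DBP": {20: 23.0, 30: 21.2, 40: 19.09},   # 17% span 20->40
        "VDR": {20: 22.5, 30: 21.5, 40: 20.7},    # 8% span 20->40
    }
    d_by_chol = {20: 72.0, 30: 67.0, 40: 63.0}
    grid: dict[tuple[str, int, int], SyntheticSpec] = {}
    for cond, by_chol in z_h_by_chol.items():
        for chol, z_h in by_chol.items():
            for i_t, temp in enumerate((294, 304, 314)):
                model = default_model(
                    z_H=z_h - 0.15 * i_t,  # mild thinning with temperature
                    d=d_by_chol[chol],
                )
                waxs = WaxsComponent(center_d=4.15 if temp < 314 else 4.75)
                # deterministic across processes (str hash is randomised)
                seed = zlib.crc32(f"{cond}/{chol}/{temp}".encode()) % (2**31)
                grid[(cond, chol, temp)] = default_spec(
                    lattices=((model, 1.0),), waxs=waxs, seed=seed
                )
    return grid
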