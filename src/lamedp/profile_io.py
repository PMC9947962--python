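"""Read, write and convert 1-D powder diffraction profiles.

Profiles are azimuthally integrated scattering curves stored as two-column
ASCII text (abscissa, intensity), ``#`` comment lines allowed, whitespace or
comma delimited.  A JSON sidecar (``<file>.meta.json``) carries the abscissa
kind and wavelength so a profile round-trips without external bookkeeping.

Conventions used throughout the package:

    q = (4*pi/lambda) * sin(theta),  theta = (2theta)/2 in radians
    d = 2*pi / q
    lambda = hc / E,  hc = 12.398419 keV*Angstrom (fixed for reproducibility)

Intensities are detector counts in arbitrary units; conversions act on the
abscissa only and never apply a Jacobian reweighting, because all downstream
analysis extracts per-peak positions and integrated areas rather than
treating the curve as a density.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path

import numpy as np

__all__ = [
    "HC_KEV_ANGSTROM",
    "AbscissaKind",
    "DiffractionProfile",
    "ProfileError",
    "energy_to_wavelength",
    "convert_abscissa",
    "read_profile",
    "write_profile",
]

#: hc in keV*Angstrom (CODATA), fixed so conversions are bit-reproducible.
HC_KEV_ANGSTROM = 12.398419


class ProfileError(ValueError):
    """Raised for malformed profile data or invalid conversions."""


class AbscissaKind(str, Enum):
    """What the abscissa of a profile measures."""

    TWO_THETA = "two_theta"  # scattering angle 2theta, degrees
    Q = "q"                  # momentum transfer, 1/Angstrom
    D = "d"                  # Bragg spacing, Angstrom


@dataclass
class DiffractionProfile:
    """A sampled 1-D scattering curve.

    Parameters
    ----------
    abscissa : array
        Strictly increasing grid (degrees 2theta, 1/A, or A per ``kind``).
    intensity : array
        Intensities in arbitrary units, same length as ``abscissa``, finite.
        May be slightly negative after background subtraction.
    kind : AbscissaKind
    wavelength : float, optional
        X-ray wavelength in Angstrom; required when ``kind`` is two_theta
        and for any conversion involving two_theta.
    """

    abscissa: np.ndarray
    intensity: np.ndarray
    kind: AbscissaKind
    wavelength: float | None = field(default=None)

    def __post_init__(self) -> None:
        self.abscissa = np.asarray(self.abscissa, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.kind = AbscissaKind(self.kind)
        if self.abscissa.ndim != 1 or self.intensity.ndim != 1:
            raise ProfileError("abscissa and intensity must be 1-D arrays")
        if self.abscissa.size != self.intensity.size:
            raise ProfileError(
                f"length mismatch: {self.abscissa.size} abscissa values vs "
                f"{self.intensity.size} intensities"
            )
        if not np.all(np.isfinite(self.abscissa)):
            raise ProfileError("abscissa contains non-finite values")
        if not np.all(np.isfinite(self.intensity)):
            raise ProfileError("intensity contains non-finite values")
        diffs = np.diff(self.abscissa)
        if np.any(diffs <= 0):
            row = int(np.argmax(diffs <= 0)) + 1
            raise ProfileError(
                f"abscissa not strictly increasing at index {row} "
                f"(value {self.abscissa[row]!r})"
            )
        if self.wavelength is not None and self.wavelength <= 0:
            raise ProfileError(f"wavelength must be > 0, got {self.wavelength}")
        if self.kind is AbscissaKind.TWO_THETA and self.wavelength is None:
            raise ProfileError("wavelength is required when kind is two_theta")

    def __len__(self) -> int:
        return self.abscissa.size


def energy_to_wavelength(energy_kev: float) -> float:
    """Convert beam energy in keV to wavelength in Angstrom (lambda = hc/E)."""
    if not energy_kev > 0:
        raise ProfileError(f"energy must be positive, got {energy_kev}")
    return HC_KEV_ANGSTROM / energy_kev


def _to_q(values: np.ndarray, kind: AbscissaKind, wavelength: float | None) -> np.ndarray:
    if kind is AbscissaKind.Q:
        return values
    if kind is AbscissaKind.D:
        if np.any(values == 0):
            raise ProfileError("d-spacing of 0 cannot be converted")
        return 2.0 * math.pi / values
    if wavelength is None:
        raise ProfileError("conversion involving two_theta requires a wavelength")
    theta = np.radians(values / 2.0)
    return (4.0 * math.pi / wavelength) * np.sin(theta)


def _from_q(q: np.ndarray, kind: AbscissaKind, wavelength: float | None) -> np.ndarray:
    if kind is AbscissaKind.Q:
        return q
    if kind is AbscissaKind.D:
        if np.any(q == 0):
            raise ProfileError("q of 0 cannot be converted to d-spacing")
        return 2.0 * math.pi / q
    if wavelength is None:
        raise ProfileError("conversion involving two_theta requires a wavelength")
    arg = q * wavelength / (4.0 * math.pi)
    if np.any(np.abs(arg) > 1):
        raise ProfileError("q out of range for the given wavelength")
    return np.degrees(2.0 * np.arcsin(arg))


def convert_abscissa(profile: DiffractionProfile, target: AbscissaKind | str) -> DiffractionProfile:
    """Convert a profile between 2theta, q and d-spacing representations.

    The intensity vector is carried unchanged (no Jacobian reweighting).
    Conversions through d reverse the abscissa ordering; the result is
    re-sorted so the strictly-increasing invariant holds.
    """
    target = AbscissaKind(target)
    if target is profile.kind:
        return replace(profile)
    q = _to_q(profile.abscissa, profile.kind, profile.wavelength)
    new_x = _from_q(q, target, profile.wavelength)
    intensity = profile.intensity
    if new_x[0] > new_x[-1]:
        new_x = new_x[::-1]
        intensity = intensity[::-1]
    return DiffractionProfile(new_x, intensity.copy(), target, profile.wavelength)


def read_profile(
    path: str | Path,
    kind: AbscissaKind | str | None = None,
    wavelength: float | None = None,
) -> DiffractionProfile:
    """Read a two-column ASCII profile.

    ``kind``/``wavelength`` override whatever a JSON sidecar written by
    :func:`write_profile` declares; if neither is given, kind defaults to q.
    Non-numeric or short rows are rejected with their 1-based line number.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    meta_path = path.with_name(path.name + ".meta.json")
    own_output = meta_path.exists()
    if own_output:
        meta = json.loads(meta_path.read_text())
        if kind is None:
            kind = meta.get("kind")
        if wavelength is None:
            wavelength = meta.get("wavelength")
    if kind is None:
        kind = AbscissaKind.Q
    xs: list[float] = []
    ys: list[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            parts = stripped.replace(",", " ").split()
            if len(parts) < 2:
                raise ProfileError(f"{path}: line {lineno}: expected 2 columns, got {len(parts)}")
            try:
                xs.append(float(parts[0]))
                ys.append(float(parts[1]))
            except ValueError as exc:
                raise ProfileError(f"{path}: line {lineno}: non-numeric content: {stripped!r}") from exc
    # Raw detector data must be non-negative; our own sidecar-tagged files
    # may carry background-subtracted (slightly negative) intensities.
    if not own_output and np.any(np.asarray(ys) < 0):
        raise ProfileError(f"{path}: negative intensity in raw input")
    try:
        return DiffractionProfile(np.asarray(xs), np.asarray(ys), kind, wavelength)
    except ProfileError as exc:
        raise ProfileError(f"{path}: {exc}") from exc


def write_profile(path: str | Path, profile: DiffractionProfile) -> Path:
    """Write a profile as two-column text plus a JSON metadata sidecar.

    Values are written with 17 significant digits so a read-back is
    bitwise identical.
    """
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# lamedp profile: kind={profile.kind.value}\n")
        for x, y in zip(profile.abscissa, profile.intensity):
            fh.write(f"{x:.17g} {y:.17g}\n")
    meta = {"kind": profile.kind.value, "wavelength": profile.wavelength}
    path.with_name(path.name + ".meta.json").write_text(json.dumps(meta))
    return path
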