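"""Background subtraction, peak detection/fitting, lamellar indexing and
WAXS characterisation for 1-D powder profiles.

The lamellar indexer assigns Bragg peaks to harmonic series q_h = 2*pi*h/d.
Because gel-phase PC patterns commonly show orders 1, 2 and 4 with order 3
extinct, the indexer never requires consecutive orders.  Peaks that join no
series (e.g. a crystalline-cholesterol reflection near 34 Angstrom against a
60-80 Angstrom lattice) are labelled non-lamellar.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from lmfit.models import ConstantModel, LinearModel, PseudoVoigtModel
from scipy import signal
from scipy.optimize import least_squares

from .profile_io import AbscissaKind, DiffractionProfile, convert_abscissa

__all__ = [
    "Peak",
    "LamellarIndexing",
    "BackgroundResult",
    "WaxsResult",
    "PeakAnalysisError",
    "subtract_background",
    "detect_peaks",
    "deconvolve_first_order",
    "index_lamellar",
    "characterize_waxs",
]


class PeakAnalysisError(ValueError):
    """Raised when peak detection, fitting or indexing fails."""


@dataclass
class Peak:
    """One fitted diffraction peak (units follow the profile abscissa)."""

    center: float
    fwhm: float
    area: float
    shape: str = "pseudo_voigt"
    label: str = "unassigned"       # lamellar | non_lamellar | waxs | unassigned
    h: int | None = None            # diffraction order when lamellar
    lattice_id: int | None = None
    height: float = 0.0

    def __post_init__(self) -> None:
        if not self.fwhm > 0:
            raise PeakAnalysisError(f"fwhm must be > 0, got {self.fwhm}")
        if not self.area > 0:
            raise PeakAnalysisError(f"area must be > 0, got {self.area}")
        if self.label == "lamellar" and (self.h is None or self.h < 1):
            raise PeakAnalysisError("lamellar peak requires an order h >= 1")


@dataclass
class LamellarIndexing:
    """One indexed lamellar lattice.

    ``residual`` is max over assigned orders of |h*d_h - d| / d.
    """

    lattice_id: int
    d: float
    orders: list[tuple[int, Peak]]
    residual: float

    def __post_init__(self) -> None:
        if not self.d > 0:
            raise PeakAnalysisError("d must be > 0")
        if not self.orders:
            raise PeakAnalysisError("an indexed lattice needs at least one order")


@dataclass
class BackgroundResult:
    """Background-subtracted profile plus the fit diagnostics."""

    profile: DiffractionProfile
    background: np.ndarray
    noise_sd: float
    n_clipped: int          # points clipped at -3*noise_sd
    model: str


@dataclass
class WaxsResult:
    """Chain-packing peak characterisation in the wide-angle window."""

    peak: Peak                              # center/fwhm in Angstrom
    sharp_components: list[Peak] = field(default_factory=list)

    @property
    def has_crystalline_candidate(self) -> bool:
        return bool(self.sharp_components)


# ---------------------------------------------------------------- background

def _background_design(x: np.ndarray, model: str):
    if model == "constant":
        return lambda p, xx: np.full_like(xx, p[0]), [1.0]
    if model == "linear":
        return lambda p, xx: p[0] + p[1] * xx, [1.0, 0.0]
    if model == "power_law":
        return lambda p, xx: p[0] + abs(p[1]) * np.power(xx, -abs(p[2])), [1.0, 0.1, 1.0]
    raise PeakAnalysisError(f"unknown background model {model!r}")


def subtract_background(
    profile: DiffractionProfile,
    model: str = "power_law",
    anchor_mask: np.ndarray | None = None,
    anchor_quantile: float = 0.10,
) -> BackgroundResult:
    """Fit and subtract a smooth background.

    Anchor points are either supplied as a boolean mask over the grid or
    auto-chosen as the lowest-``anchor_quantile`` intensities within rolling
    windows, which lands them between peaks.  Residual intensities may be
    slightly negative; values below -3x the anchor noise are clipped there
    and counted in ``n_clipped``.
    """
    x, y = profile.abscissa, profile.intensity
    if x.size < 20:
        raise PeakAnalysisError(f"need >= 20 points for background fitting, got {x.size}")
    if anchor_mask is None:
        # local minima capture inter-peak valleys even on sloping background
        nwin = max(x.size // 50, 5)
        anchor_mask = np.zeros(x.size, dtype=bool)
        for start in range(0, x.size, nwin):
            block = slice(start, min(start + nwin, x.size))
            ys = y[block]
            cut = np.quantile(ys, anchor_quantile)
            anchor_mask[block] = ys <= cut
    anchor_mask = np.asarray(anchor_mask, dtype=bool)
    if anchor_mask.sum() < 5:
        raise PeakAnalysisError("fewer than 5 background anchor points")

    fn, p0 = _background_design(x, model)
    p0[0] = float(np.median(y[anchor_mask]))

    def _fit_on(mask):
        fit = least_squares(lambda p: fn(p, x[mask]) - y[mask], p0, method="lm")
        return fit.x

    params = _fit_on(anchor_mask)
    # second pass: drop anchors sitting on peak flanks, which bias the
    # first fit upward near strong reflections
    resid_all = y - fn(params, x)
    try:
        idx, _ = signal.find_peaks(resid_all, prominence=0.002 * float(np.max(resid_all)))
        widths, *_ = signal.peak_widths(resid_all, idx, rel_height=0.5)
        refined = anchor_mask.copy()
        for i, w in zip(idx, widths):
            lo = max(int(i - 4 * w), 0)
            hi = min(int(i + 4 * w) + 1, x.size)
            refined[lo:hi] = False
        if refined.sum() >= 5:
            params = _fit_on(refined)
            anchor_mask = refined
    except Exception:
        pass

    bg = fn(params, x)
    resid = y[anchor_mask] - fn(params, x[anchor_mask])
    noise_sd = float(np.std(resid)) or 1e-12
    sub = y - bg
    floor = -3.0 * noise_sd
    n_clipped = int(np.sum(sub < floor))
    sub = np.clip(sub, floor, None)
    out = DiffractionProfile(x.copy(), sub, profile.kind, profile.wavelength)
    return BackgroundResult(out, bg, noise_sd, n_clipped, model)


# ------------------------------------------------------------ peak detection

def _fit_single_peak(
    x: np.ndarray, y: np.ndarray, center0: float, fwhm0: float, with_offset: bool = False
) -> Peak:
    """Refine one peak by a pseudo-Voigt least-squares fit around center0."""
    lo, hi = center0 - 2 * fwhm0, center0 + 2 * fwhm0
    mask = (x >= lo) & (x <= hi)
    if mask.sum() < 6:
        # widen until enough points
        order = np.argsort(np.abs(x - center0))
        mask = np.zeros_like(mask)
        mask[order[:8]] = True
    xs, ys = x[mask], y[mask]
    pv = PseudoVoigtModel()
    params = pv.guess(ys, x=xs)
    params["center"].set(value=center0, min=xs.min(), max=xs.max())
    params["sigma"].set(value=max(fwhm0 / 2, 1e-6), min=1e-8)
    params["fraction"].set(value=0.5, min=0.0, max=1.0)
    mod = pv
    if with_offset:
        mod = pv + ConstantModel()
        params.update(ConstantModel().make_params(c=float(np.min(ys))))
    res = mod.fit(ys, params, x=xs)
    best = res.params
    return Peak(
        center=float(best["center"].value),
        fwhm=float(best["fwhm"].value),
        area=max(float(best["amplitude"].value), 1e-30),
        shape="pseudo_voigt",
        height=float(best["height"].value),
    )


def detect_peaks(profile: DiffractionProfile, min_prominence: float = 0.05) -> list[Peak]:
    """Detect local maxima above a prominence threshold and refine each by a
    pseudo-Voigt fit over +/-2 estimated FWHM.

    ``min_prominence`` is a fraction of the maximum intensity.  Raises when
    nothing clears the threshold (e.g. pure noise).
    """
    x, y = profile.abscissa, profile.intensity
    # detect on a lightly smoothed copy so single-point noise spikes on top
    # of strong peaks do not register; refinement runs on the raw data
    y_det = signal.savgol_filter(y, 11, 2) if y.size >= 25 else y
    prom = min_prominence * float(np.max(y_det))
    idx, props = signal.find_peaks(y_det, prominence=prom, width=3)
    if idx.size == 0:
        raise PeakAnalysisError(
            f"no peak with prominence >= {min_prominence:.3g} of max intensity"
        )
    widths, *_ = signal.peak_widths(y_det, idx, rel_height=0.5)
    dx = float(np.median(np.diff(x)))
    peaks = []
    for i, w in zip(idx, widths):
        fwhm0 = max(w * dx, 2 * dx)
        try:
            # the constant offset absorbs residual baseline (e.g. Lorentzian
            # tails of stronger orders) that survives background subtraction
            peaks.append(_fit_single_peak(x, y, float(x[i]), fwhm0, with_offset=True))
        except Exception as exc:  # fit blow-up on pathological shoulder
            raise PeakAnalysisError(f"peak refinement failed near x={x[i]:.4g}: {exc}") from exc
    peaks.sort(key=lambda p: p.center)
    return peaks


# --------------------------------------------------- first-order deconvolution

def _local_noise(y: np.ndarray, win: int = 25) -> np.ndarray:
    """Per-point noise SD from a rolling robust estimate of successive
    differences; tracks intensity-dependent (e.g. multiplicative) noise."""
    from scipy.ndimage import median_filter

    d = np.abs(np.diff(y))
    sigma = 1.4826 * median_filter(d, size=min(win, max(d.size, 1))) / math.sqrt(2)
    sigma = np.append(sigma, sigma[-1] if sigma.size else 1.0)
    floor = max(1e-12, 1e-9 * float(np.max(np.abs(y))))
    return np.maximum(sigma, floor)


def _multi_voigt_fit(x, y, centers, fwhm0, weights=None, n_tries=3):
    model = LinearModel()  # absorbs residual baseline in the window
    params = model.make_params(slope=0.0, intercept=float(np.min(y)))
    for i, c in enumerate(centers):
        pv = PseudoVoigtModel(prefix=f"p{i}_")
        p = pv.make_params()
        p[f"p{i}_center"].set(value=c, min=x.min(), max=x.max())
        p[f"p{i}_sigma"].set(value=fwhm0 / 2, min=1e-8, max=(x.max() - x.min()))
        p[f"p{i}_amplitude"].set(value=float(np.trapezoid(y, x)) / len(centers), min=0)
        p[f"p{i}_fraction"].set(value=0.5, min=0, max=1)
        model = model + pv
        params.update(p)
    best = None
    shifts = [0.0, 0.25 * fwhm0, -0.25 * fwhm0][:n_tries]
    for shift in shifts:
        trial = params.copy()
        for i in range(len(centers)):
            c = min(max(centers[i] + shift, x.min()), x.max())
            trial[f"p{i}_center"].set(value=c)
        res = model.fit(y, trial, x=x, weights=weights)
        if best is None or res.chisqr < best.chisqr:
            best = res
    return best


def deconvolve_first_order(
    profile: DiffractionProfile, window: tuple[float, float]
) -> list[Peak]:
    """Resolve the first-order feature into one or two pseudo-Voigt
    components, the count chosen by BIC.

    The fits are weighted by a per-point noise estimate from peak-free
    rolling statistics of the profile (tracking intensity-dependent
    counting noise), so the weighted chi^2 is correctly scaled and a
    marginal second component must beat the ln(n) parameter penalty.
    Components are returned sorted by center.
    """
    x, y = profile.abscissa, profile.intensity
    mask = (x >= window[0]) & (x <= window[1])
    if mask.sum() < 10:
        raise PeakAnalysisError("window too narrow for deconvolution")
    xs, ys = x[mask], y[mask]
    imax = int(np.argmax(ys))
    widths, *_ = signal.peak_widths(ys, np.array([imax]), rel_height=0.5)
    dx = float(np.median(np.diff(xs)))
    fwhm0 = max(float(widths[0]) * dx, 2 * dx)
    weights = 1.0 / _local_noise(y)[mask]

    c0 = float(xs[imax])
    fit1 = _multi_voigt_fit(xs, ys, [c0], fwhm0, weights)
    fit2 = _multi_voigt_fit(xs, ys, [c0 - fwhm0 / 2, c0 + fwhm0 / 2], fwhm0, weights)
    if fit1 is None and fit2 is None:
        raise PeakAnalysisError("first-order deconvolution failed to converge")

    n = xs.size

    def bic(res, k):
        return res.chisqr + k * math.log(n)

    use_two = (
        fit2 is not None
        and fit2.success
        and (fit1 is None or bic(fit2, 12) < bic(fit1, 7))
    )
    res = fit2 if use_two else fit1
    ncomp = 2 if use_two else 1
    peaks = []
    for i in range(ncomp):
        p = res.params
        peaks.append(
            Peak(
                center=float(p[f"p{i}_center"].value),
                fwhm=float(p[f"p{i}_fwhm"].value),
                area=max(float(p[f"p{i}_amplitude"].value), 1e-30),
                height=float(p[f"p{i}_height"].value),
            )
        )
    peaks.sort(key=lambda pk: pk.center)
    return peaks


# ------------------------------------------------------------------ indexing

def _peak_d(peak: Peak, kind: AbscissaKind) -> float:
    if kind is AbscissaKind.D:
        return peak.center
    if kind is AbscissaKind.Q:
        return 2.0 * math.pi / peak.center
    raise PeakAnalysisError("index_lamellar expects peaks on a q or d abscissa")


def index_lamellar(
    peaks: list[Peak],
    tolerance: float = 0.02,
    kind: AbscissaKind | str = AbscissaKind.Q,
    max_order: int = 6,
) -> list[LamellarIndexing]:
    """Greedy harmonic indexing of fitted peaks into lamellar lattices.

    Candidate first-order peaks are tried largest-d first; another peak of
    spacing d_h joins the lattice as order h (2..max_order, smallest
    relative residual wins) when |h*d_h - d| / d <= tolerance.  A lattice
    must collect at least two orders.  d is then refined by area-weighted
    least squares of q_h vs h through the origin, and peaks fitting two
    lattices go to the one with the smaller relative residual.  Leftover
    peaks are labelled non_lamellar.  Lattices are sorted by d descending.
    """
    kind = AbscissaKind(kind)
    if len(peaks) < 2:
        raise PeakAnalysisError("indexing needs at least 2 peaks")
    entries = sorted(peaks, key=lambda p: _peak_d(p, kind), reverse=True)
    assigned: dict[int, tuple[int, int]] = {}  # id(peak) -> (lattice idx, h)
    lattices: list[dict] = []

    for cand in entries:
        if id(cand) in assigned:
            continue
        d_hat = _peak_d(cand, kind)
        members = [(1, cand)]
        for other in entries:
            if other is cand or id(other) in assigned:
                continue
            d_o = _peak_d(other, kind)
            best = None
            for h in range(2, max_order + 1):
                rel = abs(h * d_o - d_hat) / d_hat
                if rel <= tolerance and (best is None or rel < best[1]):
                    best = (h, rel)
            if best is not None and all(h != best[0] for h, _ in members):
                members.append((best[0], other))
        if len(members) >= 2:
            li = len(lattices)
            lattices.append({"members": members})
            for h, pk in members:
                assigned[id(pk)] = (li, h)

    if not lattices:
        raise PeakAnalysisError("no self-consistent lamellar lattice found")

    def _refine(members: list[tuple[int, Peak]]) -> tuple[float, float]:
        hs = np.array([h for h, _ in members], dtype=float)
        qs = np.array(
            [
                pk.center if kind is AbscissaKind.Q else 2.0 * math.pi / pk.center
                for _, pk in members
            ]
        )
        w = np.array([pk.area for _, pk in members])
        slope = float(np.sum(w * hs * qs) / np.sum(w * hs**2))  # q = (2*pi/d) h
        d_ref = 2.0 * math.pi / slope
        resid = float(
            max(abs(h * (2.0 * math.pi / q) - d_ref) / d_ref for h, q in zip(hs, qs))
        )
        return d_ref, resid

    member_lists = [list(lat["members"]) for lat in lattices]
    d_refined = [_refine(m)[0] for m in member_lists]

    if len(member_lists) > 1:
        # tie-break: a peak fitting two lattices goes to the smaller residual
        for li, members in enumerate(member_lists):
            for entry in list(members):
                h_cur, pk = entry
                d_pk = _peak_d(pk, kind)
                rel_cur = abs(h_cur * d_pk - d_refined[li]) / d_refined[li]
                best = (li, h_cur, rel_cur)
                for lj, d_j in enumerate(d_refined):
                    if lj == li:
                        continue
                    taken = {h for h, _ in member_lists[lj]}
                    for h in range(1, max_order + 1):
                        if h in taken:
                            continue
                        rel = abs(h * d_pk - d_j) / d_j
                        if rel <= tolerance and rel < best[2]:
                            best = (lj, h, rel)
                if best[0] != li and len(members) > 2:
                    members.remove(entry)
                    member_lists[best[0]].append((best[1], pk))
        d_refined = [_refine(m)[0] for m in member_lists]

    results: list[LamellarIndexing] = []
    for members in member_lists:
        members.sort(key=lambda e: e[0])
        d_ref, resid = _refine(members)
        results.append(LamellarIndexing(0, d_ref, [(int(h), pk) for h, pk in members], resid))

    results.sort(key=lambda r: r.d, reverse=True)
    for i, r in enumerate(results, start=1):
        r.lattice_id = i
        for h, pk in r.orders:
            pk.label, pk.h, pk.lattice_id = "lamellar", h, i
    for pk in peaks:
        if id(pk) not in assigned:
            pk.label = "non_lamellar"
    return results


# ---------------------------------------------------------------------- WAXS

def characterize_waxs(
    profile: DiffractionProfile,
    window: tuple[float, float] = (2.65, 7.15),
    sharpness_threshold: float = 0.05,
    min_prominence: float = 0.05,
) -> WaxsResult:
    """Fit the broad acyl-chain packing peak in the wide-angle window.

    The profile is converted to d-spacing, a linear baseline plus single
    pseudo-Voigt is fitted inside ``window`` (Angstrom), and any detected
    component with FWHM below ``sharpness_threshold`` (Angstrom) is flagged
    as a possible crystalline reflection.
    """
    prof_d = profile if profile.kind is AbscissaKind.D else convert_abscissa(profile, AbscissaKind.D)
    x, y = prof_d.abscissa, prof_d.intensity
    mask = (x >= window[0]) & (x <= window[1])
    if mask.sum() < 10:
        raise PeakAnalysisError(f"profile does not cover the WAXS window {window}")
    xs, ys = x[mask], y[mask]
    # peakless check: require an interior local maximum that stands out of
    # both the noise and the linearly detrended span of the window
    coef = np.polyfit(xs, ys, 1)
    resid0 = ys - np.polyval(coef, xs)
    noise = float(np.std(np.diff(ys))) / math.sqrt(2)
    smooth = signal.savgol_filter(resid0, 11, 2) if resid0.size >= 25 else resid0
    prom_floor = max(5.0 * noise, 0.25 * float(np.ptp(smooth)), 1e-12)
    interior, _ = signal.find_peaks(smooth, prominence=prom_floor)
    if interior.size == 0:
        raise PeakAnalysisError("no peak found in the WAXS window")

    span = float(np.ptp(ys))
    imax = int(np.argmax(ys))
    widths, *_ = signal.peak_widths(ys, np.array([imax]), rel_height=0.5)
    dx = float(np.median(np.diff(xs)))
    fwhm0 = max(float(widths[0]) * dx, 2 * dx)
    pv = PseudoVoigtModel() + LinearModel()
    params = pv.make_params()
    params["center"].set(value=float(xs[imax]), min=xs.min(), max=xs.max())
    params["sigma"].set(value=fwhm0 / 2, min=1e-6, max=(xs.max() - xs.min()))
    params["amplitude"].set(value=span * fwhm0, min=0)
    params["fraction"].set(value=0.5, min=0, max=1)
    params["slope"].set(value=0.0)
    params["intercept"].set(value=float(np.min(ys)))
    res = pv.fit(ys, params, x=xs)
    if not res.success:
        raise PeakAnalysisError("WAXS peak fit did not converge")
    main = Peak(
        center=float(res.params["center"].value),
        fwhm=float(res.params["fwhm"].value),
        area=max(float(res.params["amplitude"].value), 1e-30),
        label="waxs",
        height=float(res.params["height"].value),
    )

    sharp: list[Peak] = []
    # search the smoothed, detrended window so single-point noise spikes
    # do not masquerade as crystalline reflections
    idx, _ = signal.find_peaks(
        smooth, prominence=max(min_prominence * span, 5.0 * noise)
    )
    w_all, *_ = signal.peak_widths(smooth, idx, rel_height=0.5)
    for i, w in zip(idx, w_all):
        fwhm_i = float(w) * dx
        if 3 * dx < fwhm_i < sharpness_threshold:
            sharp.append(
                Peak(center=float(xs[i]), fwhm=fwhm_i,
                     area=max(float(smooth[i]) * fwhm_i, 1e-30),
                     label="non_lamellar", height=float(smooth[i]))
            )
    if main.fwhm < sharpness_threshold:
        sharp.insert(0, replace(main, label="non_lamellar"))
    return WaxsResult(main, sharp)
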