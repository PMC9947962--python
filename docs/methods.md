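# Methods

## Scope and shape

`lamedp` is organised as an analysis project: the computation lives in the
library under `src/lamedp`, and the numbered scripts under `analysis/` are
thin narrative drivers over it. The library is the unit that is tested;
the drivers only orchestrate and tabulate. No separate command-line tool is
provided — the driver scripts and the library functions are the interface.

## Conventions

* Momentum transfer `q = (4π/λ) sin θ` with `θ = 2θ/2`; Bragg spacing
  `d = 2π/q`. Both are stated once in `profile_io` and used everywhere.
* `hc = 12.398419 keV·Å` (CODATA), fixed so energy→wavelength conversions
  are bit-reproducible.
* Conversions between 2θ, q and d act on the abscissa only. No Jacobian
  (dq/d2θ) intensity reweighting is applied: all downstream analysis
  extracts per-peak positions and integrated areas, for which the counts
  on whatever grid they arrived are the right raw material.
* Powder Lorentz factor `1/h²` (equivalently `1/q_h²` up to a constant),
  appropriate for unoriented multilamellar vesicles. The simulator applies
  it to peak areas and the reconstruction inverts exactly the same factor
  (`|F_h| = √(h² · area_h)`), so forward/inverse recovery tests are exact
  regardless of the convention's constant.
* Amplitudes are normalised to the lowest measured order
  (`|F| = 1` there). Intensities are in arbitrary units, so every reported
  quantity (z_H, percent changes, sign patterns) is scale-free.

## The bilayer model

Relative electron density contrast of one bilayer:

```
Δρ(z) = scale · [ e^(−(z−z_H)²/2σ_H²) + e^(−(z+z_H)²/2σ_H²) − (ρ_C/ρ_H) e^(−z²/2σ_C²) ]
```

with analytic cosine transform

```
F(q) = scale · √(2π) [ 2σ_H cos(q z_H) e^(−σ_H²q²/2) − (ρ_C/ρ_H) σ_C e^(−σ_C²q²/2) ]
```

Parameters (defaults are typical gel-phase PC-bilayer literature values,
used as the known-molecular-parameter prior, not as assertions about any
particular sample): `z_H = 22 Å` (headgroup position), `σ_H = 3 Å`,
`σ_C = 5 Å`, `ρ_C/ρ_H = 1`, `d = 65 Å`. The test suite verifies the
analytic transform against trapezoid quadrature of the real-space profile
(spectrally accurate for Gaussians; agreement ~1e−15 relative) over 100
random in-bounds models.

## Synthetic data generator

The simulator emulates sub-Tm ternary phospholipid/cholesterol powder
patterns: for each lamellar lattice `(model, weight)` it places
pseudo-Voigt peaks (Gaussian fraction 0.5; Gaussian and Lorentzian share
one FWHM, default 0.005 Å⁻¹) at `q_h = 2πh/d` with area
`weight·|F(q_h)|²/h²`; adds an optional broad wide-angle chain-packing
peak (default 4.15 Å, moving to 4.75 Å for the hottest study condition),
an optional sharp crystalline-cholesterol-like reflection near 34 Å, a
smooth background `c + a·q^(−p)`, and seeded multiplicative Gaussian noise
(default 1% — arbitrary-unit intensities carry no count scale for Poisson
noise). Default visible orders are 1, 2 and 4 with order 3 suppressed, the
repeat-spacing pattern these gel-phase systems show; note this extinction
is imposed on the synthetic pattern as phenomenology even though the
three-Gaussian model itself predicts a non-zero third order. The default
grid is 12 000 points over 0.03–2.4 Å⁻¹ (≈25 points per Bragg FWHM);
generation fails loudly below 4 points per FWHM.

What the generator does *not* emulate: Caillé/paracrystalline fluctuation
tails, instrumental resolution smearing, detector artefacts, absolute
intensities, and asymmetric WAXS line shapes. Passing recovery tests
therefore demonstrate the pipeline's correctness under idealised peak
shapes and noise, not its robustness to every real-beamline pathology.

The `study_conditions()` grid (3 environments × cholesterol 20/30/40 mol%
× 294/304/314 K) encodes the phenomenology the analysis drivers exercise:
headgroup position decreasing with cholesterol (spanning ~17% for the DBP
series and ~8% for the VDR series at 294 K, ~15% for water), d between 63
and 72 Å, mild thinning with temperature, WAXS peak shifting at 314 K.
These truths are emulation inputs chosen once; the drivers then show the
pipeline recovers them.

## Peak analysis

* **Background**: constant, linear or power-law (`c + a·q^(−p)`) fitted on
  anchor points auto-chosen as lowest-decile intensities within rolling
  windows, then refitted after masking ±4 widths around detected residual
  peaks (first-pass anchors on peak flanks otherwise bias the level near
  strong reflections). Subtracted intensities below −3× the anchor-residual
  noise are clipped there and counted.
* **Detection**: `scipy.signal.find_peaks` on a lightly smoothed copy
  (Savitzky–Golay, window 11) with a prominence threshold relative to the
  maximum intensity and a ≥3-sample width requirement, so single-point
  noise spikes on strong peaks do not register. Each detection is refined
  by an `lmfit` pseudo-Voigt least-squares fit over ±2 estimated FWHM with
  a constant offset that absorbs residual baseline (chiefly Lorentzian
  tails of stronger orders — without it, weak order-4 areas bias by >20%).
  The end-to-end pipeline uses a lower prominence default (0.005) than the
  standalone detector (0.05) because the 1/h² Lorentz decay leaves order 4
  near 1% of the first-order height.
* **First-order deconvolution**: one- versus two-component pseudo-Voigt
  (plus linear baseline) fits in a window, weighted by a per-point noise
  estimate from rolling robust statistics of successive differences (this
  tracks multiplicative noise; a homoscedastic estimate from quiet regions
  would understate on-peak variance ~400-fold and always favour two
  components). Model count chosen by BIC = weighted χ² + k·ln n; ties and
  degenerate (identical-lattice) mixtures resolve to one component.
* **Indexing**: greedy harmonic assignment, candidate first orders tried
  largest-d first; a peak of spacing `d_h` joins as order h (2–6, smallest
  relative residual) when `|h·d_h − d|/d ≤ 2%` — tight enough to reject a
  34 Å cholesterol reflection against a 60–80 Å lattice, loose enough for
  broad peaks. Consecutive orders are *not* required (order 3 may simply
  be absent). `d` is refined by area-weighted least squares of `q_h` vs
  `h` through the origin; with several lattices, a peak fitting more than
  one goes to the smaller relative residual; lattices sort by d
  descending. Indexing is scale-equivariant by construction.
* **WAXS**: single pseudo-Voigt plus linear baseline in the 2.65–7.15 Å
  window after conversion to d-spacing. A window is declared peakless
  unless its smoothed, detrended profile has an interior maximum standing
  above both 5× the point noise and a quarter of the detrended span. Any
  component narrower than 0.05 Å (and wider than 3 grid steps) is flagged
  as a possible crystalline reflection.

## Phase signs and Fourier synthesis

Signs initialise to the canonical gel/fluid PC pattern (−,−,+,−) — i.e.
−1 for every order except h = 3 — used purely as the seed of the loop;
thereafter `s_h = sign(F_model(q_h))` from the current fitted model, with
`|F| < ε` counting as −1 (deterministic tie-break). The global sign
ambiguity is fixed by requiring the headgroup maxima positive (density at
the bilayer centre must not be the global maximum). The synthesis is a
plain truncated cosine series on a symmetric grid (even counts promoted to
odd so z = 0 is on-grid); the average density ρ_AVG is carried as metadata
only, never added — all outputs are relative. The headgroup position reads
off as the density argmax on [0, d/2], refined by parabolic interpolation
through the three points around the grid maximum; exact ties resolve to
the larger z.

## Form-factor fitting

Bounded least squares of the signed amplitudes (not |F|², so the loop's
phase information is used) with `d` fixed from indexing. Default bounds
are tight literature-informed boxes — `z_H ∈ [15, 30] Å`,
`σ_H ∈ [2, 5] Å`, `σ_C ∈ [3, 8] Å`, `ρ_C/ρ_H ∈ [0.5, 2]` — standing in
for known molecular parameters; all are configuration-exposed, and any
parameter can be fixed at its initial value (the pipeline automatically
fixes both widths when only two orders were measured, e.g. when a
reflection is extinct). The overall scale is linear in the model and is
profiled out analytically, leaving a four-parameter nonlinear search run
from five deterministic starts (the unperturbed initial guess first, then
fixed fraction-of-box perturbations); no random state anywhere.

With 3–4 amplitudes the model retains one soft direction (shape/scale
trade-off), so statistically indistinguishable optima are common. The
multistart therefore prefers the start nearest the initial guess and lets
a later start win only when decisively better (0.1% lower cost): among
equivalent explanations of the data, the one closest to the molecular
prior is reported. Parameter uncertainties come from the Jacobian
covariance at the optimum; the extra reflection appended after each fit is
the model's own prediction at `q_{h_max+1}`, flagged `extrapolated` and
never overwriting measured entries.

## Self-consistent loop

Per iteration: signs from the current model → Fourier synthesis (including
the previous iteration's extrapolated order once one exists) → model fit
to the signed measured amplitudes → extrapolate one order → relative
change of the *model* z_H. Convergence is judged on the model parameter,
not the density argmax (which is truncation-limited and only logged for
cross-checking). Defaults: tolerance 1e−4 relative, at most 10 iterations;
tolerance 0 disables early stopping and forces the cap. Sign oscillation
(tuple at iteration k equal to k−2 but not k−1) is detected and reported
with both attractors. Whether signs are re-derived every cycle is
configurable (`refit_signs`, default on); the default matches feeding each
density-profile output back into form-factor analysis. The headgroup
percent change statistic is the signed `100·(z_a − z_b)/z_a`, positive
when the bilayer thins from condition a to b.

## Numerical choices and limitations

* Problem sizes: the default 12 000-point grid, 27-condition study grid,
  20-seed noise ensembles and 100-model property suites keep the full test
  and analysis runs in the tens of seconds on one core while leaving every
  statistic comfortably estimated.
* Noise-free self-fits reach residual RMS ≤ 1e−10; recovery of all four
  shape parameters is exact to well under 0.1% over 100 random in-bounds
  models.
* Under 1% multiplicative noise the end-to-end pipeline recovers the
  default generator's z_H to ≤ ~0.05 Å (worst over 20 seeds), an order of
  magnitude inside the 0.5 Å uncertainty relevant to such analyses.
* Known limitations: single dominant lattice is refined per pattern (the
  indexer reports all lattices, but the driver pipeline follows the
  largest-d one); no Caillé/fluctuation corrections; no absolute electron
  density calibration; the two-lattice deconvolution considers at most two
  components; extinct orders are treated as unmeasured rather than as
  zero-amplitude constraints.
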