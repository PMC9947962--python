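# lamedp

Self-consistent electron density profile analysis of lamellar lipid-phase
X-ray diffraction.

## The problem

Multilamellar vesicles of mixed phospholipids (e.g. DPPC / brain
sphingomyelin / cholesterol below the chain-melting transition) diffract as
a 1-D powder: a lamellar lattice of repeat `d` gives Bragg reflections at
`q_h = 2πh/d`, typically with only 2–3 orders visible (often 1, 2 and 4,
with order 3 extinct), broad and sometimes overlapping first-order peaks
from coexisting lattices, and a broad wide-angle chain-packing peak between
~4.1 and ~4.9 Å. From these few reflections one wants the bilayer's
relative electron density profile and, above all, the headgroup position
`z_H` — half the phosphate-to-phosphate bilayer thickness — and how it
shifts with composition and temperature.

For a centrosymmetric bilayer the form factor is real, so the density is
the truncated cosine series

```
Δρ(z) = Σ_h  s_h |F_h| cos(2πhz/d),        s_h ∈ {−1, +1}
```

with `|F_h| = √(h² I_h)` from Lorentz-corrected integrated intensities and
an unknown sign per order (the phase problem). The bilayer is modelled as
three Gaussians — headgroup peaks at ±z_H of width σ_H, a methyl trough of
width σ_C and relative depth ρ_C/ρ_H at the centre — whose analytic form
factor is

```
F(q) = scale · √(2π) · [ 2 σ_H cos(q z_H) e^(−σ_H²q²/2) − (ρ_C/ρ_H) σ_C e^(−σ_C²q²/2) ]
```

Because so few orders are measured, the package iterates to
self-consistency: assign signs (canonical (−,−,+,−) pattern to start, then
from the fitted model), synthesize Δρ(z), fit the Gaussian model to the
signed amplitudes under tight molecular-parameter bounds, extrapolate one
reflection beyond the last measured order (so 3–4 enter each synthesis),
and stop when the relative change of `z_H` falls below 1 part in 10⁴
(at most 10 iterations).

Raw beamline data for such systems are rarely deposited, so the package
includes a forward simulator (`lamedp.synthetic_data`) that generates
patterns from known Gaussian-bilayer parameters — coexisting lattices,
pseudo-Voigt peak shapes with the 1/h² powder Lorentz weighting, WAXS and
crystalline-cholesterol components, background, seeded noise — making every
stage testable by parameter recovery.

## Worked example

```python
from lamedp import analyze_pattern, default_spec, simulate_pattern

profile = simulate_pattern(default_spec(noise_sd_fraction=0.01, seed=1))
res = analyze_pattern(profile)
print(f"d = {res.d:.2f} A, z_H = {res.z_H:.3f} A, "
      f"{res.trace.n_iterations} iterations, converged: {res.trace.converged}")
for e in res.trace.final_form_factors.entries:
    print(f"  h={e.h}  |F|={e.amplitude:.3f}  sign={e.sign:+d}  ({e.source})")
```

prints

```
d = 65.00 A, z_H = 21.989 A, 2 iterations, converged: True
  h=1  |F|=1.000  sign=-1  (measured)
  h=2  |F|=0.722  sign=-1  (measured)
  h=4  |F|=0.352  sign=-1  (measured)
  h=5  |F|=0.138  sign=-1  (extrapolated)
```

The generator truth was `z_H = 22 Å`, `d = 65 Å`: the pipeline
(background subtraction → peak fitting → harmonic indexing →
Lorentz-corrected amplitudes → self-consistent refinement) recovers the
repeat to 0.01% and the headgroup position to 0.011 Å from a noisy pattern,
converging in two iterations. The loop's extra reflection (h = 5 here)
comes from the fitted model, mirroring the practice of estimating one form
factor beyond the measured orders.

The `analysis/` directory holds the numbered study drivers: simulate a
3 environments × 3 cholesterol levels × 3 temperatures grid
(`01_simulate_study.py`), characterise peaks and the WAXS chain-packing
region (`02`), reconstruct example density profiles (`03`), refine all
headgroup positions (`04`), and tabulate cholesterol/temperature trends
(`05`). Each writes its tables under `results/`.

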