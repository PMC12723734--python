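# tabsr — transient-binding super-resolution analysis

`tabsr` is an analysis pipeline for fluorescence movies in which a
fluorogenic dye binds transiently to amyloid fibrils (e.g. curli, the
CsgA-based extracellular fibrils of *E. coli* biofilms). The dye is dark in
solution and bright while bound, so a movie of a fibril field is a stream
of stochastic, localized fluorescence bursts. That one data type supports
four complementary analyses, all implemented here over a common movie
model and exercised end to end on simulated movies with known ground
truth:

* **PAINT (single-molecule localization)** — per frame: Laplacian-of-
  Gaussian filtering (σ = 1.5 px), candidate detection at 3× the filtered
  frame's standard deviation, 2-D Gaussian fitting for subpixel positions;
  reconstruction as a 5 nm histogram convolved with a σ = 25 nm kernel;
  apparent binding ("on") times from nearest-neighbor linking of
  consecutive-frame detections, fit with mono-/biexponential decays.
* **SOFI (second-order fluctuation imaging)** — per pixel, the lagged
  cumulant C2(τ) = ⟨δI(t)·δI(t+τ)⟩ summed over lags; independent emitters
  are uncorrelated, so each spot narrows from σ to σ/√2: a √2 ≈ 1.4-fold
  resolution gain.
* **iFCS (pixel-wise imaging FCS)** — per pixel, G(τ) = ⟨δI(t)δI(t+τ)⟩/⟨I⟩²
  averaged over six movie segments (SEM per lag), fit by weighted least
  squares with a two-component binding model
  G(τ) = G0 (1−f_f+f_f e^{−τ/τ_fast})(1−f_s+f_s e^{−τ/τ_slow}) + G∞,
  compared to its one-component reduction by reduced χ², and rendered as
  SNR-gated parameter maps (gate: ACF amplitude / tail scatter > 10).
* **FRC (resolution estimation)** — localizations split at random into two
  half-images; the ring-wise normalized cross-spectrum's 1/7 crossing
  gives the effective resolution.

The SOFI cumulant is, by construction, exactly the numerator of the iFCS
autocorrelation; the two stages share one computation and the test suite
asserts the identity to machine precision.

A ground-truth simulator generates fibril fields (worm-like chains with
Poisson binding sites), two-mode exponential binding kinetics
(τ = 23/482 ms by default), and camera movies via an integrated-Gaussian
PSF with Poisson noise — in both acquisition regimes (30 ms / 92 nm /
10,000 frames and 2.5 ms / 46 nm / 36,000 frames in six 15 s segments,
~690 photons per molecule per 30 ms frame).

## Worked example

Simulate a single blinking emitter and measure the SOFI resolution gain:

```python
from tabsr import simulate, sofi

movie, _ = simulate.simulate_blinking_emitter(n_frames=5000, seed=11)
print(sofi.measure_enhancement(movie))
```

```
{'sigma_average_nm': 122.66, 'sigma_sofi_nm': 86.81, 'enhancement': 1.413}
```

The diffraction-limited spot (fitted σ 122.7 nm) narrows to 86.8 nm in the
first-lag cumulant image — a 1.41-fold enhancement, matching the √2 theory
for second-order cumulants of a Gaussian PSF.

Run the full pipeline on a simulated fibril scenario from the shell:

```bash
tabsr run --out runs/demo --seed 11
tabsr validate runs/demo
```

which writes the movie, localization table, PAINT/SOFI images, per-pixel
ACF fits, parameter maps, FRC curve and a reproducibility manifest, then
re-checks the pipeline invariants on the artifacts.

The numbered scripts under `analysis/` are narrative drivers for the main
analyses (simulation scenarios, PAINT reconstruction + FRC, SOFI
enhancement, iFCS kinetics recovery, estimator bias); each prints its
findings and writes a table under `results/`. On the demo scenarios they
yield, e.g., an FRC resolution of ~21 nm from ~3,000 localizations, fibril
widths of 122 nm (temporal average) vs 102 nm (SOFI), and two-component
binding fits preferred over the one-component model by a ~4× reduced-χ²
ratio, with the fast relaxation time recovered to ~19% at demo scale (the
full-scale 36,000-frame scenario in the test suite recovers both the 23 ms
and 482 ms times with median errors below 25%).

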