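# Methods

`tabsr` analyzes fluorescence movies in which a fluorogenic dye binds
transiently to amyloid fibrils: the dye is essentially dark in solution and
bright while bound, so each binding event appears as a localized burst.
Four analyses share the same movie input: single-molecule localization
(PAINT), second-order fluctuation imaging (SOFI), pixel-wise imaging FCS
(iFCS), and Fourier-ring-correlation (FRC) resolution estimation. A
ground-truth simulator makes every stage testable end to end.

## Movie model and conventions

A movie is a `frames x rows x cols` stack of non-negative intensities with
pixel size (nm) and frame time (ms). Intensities are stored as floating
point even for photon-resolved data so cumulant arithmetic cannot overflow.
Pixel indices are 0-based; the physical center of pixel `(r, c)` is
`((r + 0.5) px, (c + 0.5) px)` nm, and all positions (localizations,
binding sites) are reported in nm in this frame. Standard-mode camera
counts are converted to photons as `max(0, (counts - offset) / gain)`;
conversion parameters are user-supplied. Temporal segmentation uses floor
division: a non-divisible frame count drops the trailing remainder so all
segments share identical statistics.

Two acquisition regimes are built in:

| regime | frame time | pixel | frames | emitter brightness |
|---|---|---|---|---|
| single-molecule (PAINT + SOFI) | 30 ms | 92 nm | 10,000 | 690 photons/frame |
| high-temporal-resolution (iFCS + SOFI) | 2.5 ms | 46 nm | 36,000 (six 15 s segments) | 57.5 photons/frame |

The 2.5 ms brightness keeps the per-millisecond emission rate of the 30 ms
regime (690 x 2.5/30). Defaults the analyses rely on: LoG sigma 1.5 px,
detection threshold 3x the filtered-frame standard deviation, histogram
bin 5 nm, rendering kernel sigma 25 nm, six segments, SNR gate 10, FRC
threshold 1/7.

## Simulator

**Geometry.** Fibril backbones are discrete worm-like chains (50 nm steps;
heading variance step/persistence, persistence 2 µm by default) started
inside an interior margin and truncated at the field edge. Binding sites
are Poisson-placed along arc length (default 0.05 sites/nm).

**Kinetics.** Each site receives Poisson arrivals (default 1.1 /s/site).
Each event draws its dwell from a two-mode exponential mixture:
tau_fast = 23 ms with event probability f = 0.95, tau_slow = 482 ms
otherwise. Because an autocorrelation weights a bound state by its
residence time, the ACF-visible fast fraction is
`f tau_f / (f tau_f + (1-f) tau_s)` = 0.49 at these defaults — both
components carry comparable correlation amplitude, which is what makes the
two-component fit well-posed FOV-wide. Events at one site may overlap
(no excluded volume), so site occupancy is Poisson (M/G/inf) and the
binding ACF amplitude scales as 1/occupancy. Fast photophysical blinking
and fast binding are indistinguishable in these data; the simulator
represents both as the single fast dwell mode.

**Image formation.** Each active emitter contributes an *integrated* 2-D
Gaussian PSF (error-function integral over each pixel area; point sampling
would be wrong at 46–92 nm pixels against a 120 nm PSF sigma), scaled by
its brightness and its fractional temporal overlap with each frame.
Per-event mean brightness is log-normal with CV 0.55, reflecting the broad
brightness spread of dye molecules in heterogeneous binding environments.
Poisson shot noise applies to signal plus uniform background (2 photons/px
per 30 ms by default); optional Gaussian read noise is added and the
result clamped at zero. Unbound dye contributes only to the uniform
background (fluorogenic contrast treated as complete). One master seed
spawns independent sub-streams for geometry, kinetics and optics.

**What the simulator does not model:** defocus/3-D PSF structure,
photobleaching, cell-body autofluorescence texture, drift, and any spatial
heterogeneity of kinetics. Passing recovery tests therefore demonstrate
estimator correctness under the stated model, not robustness to every
property of real movies.

## PAINT

Per frame: negated Laplacian-of-Gaussian filter (sigma 1.5 px; the frame
mean is subtracted first so a constant frame gives an exactly zero
response), threshold at 3x the standard deviation of the filtered frame
(computed including signal pixels, accepting mild threshold inflation in
dense frames), 8-connected local maxima, and suppression of maxima within
2 sigma_filter px of a brighter one (one emitter, one candidate).
Candidates get a 2-D Gaussian least-squares fit (amplitude, center, width,
offset) on a window of side `2 ceil(3 sigma_psf) + 1` px; windows clipped
by the frame edge are discarded and counted. Photons = 2 pi A sigma^2.
A fit is rejected when the optimizer fails, the center leaves the window,
or the width pins at its bounds (a flat sub-image lands here). Quality
filtering by width bounds, minimum photons and maximum residual follows;
thresholds are configuration, not inference.

Reconstruction: 5 nm 2-D histogram convolved with a sigma = 25 nm Gaussian
kernel; total mass equals the localization count up to kernel truncation
at the field edge.

On-times: greedy nearest-neighbor linking between consecutive frames
(default radius one 92 nm pixel), deliberately without gap closing — a
missed frame splits a run, reproducing how apparent on-times behave when
neighboring emitters interrupt linking. Run-length counts are fit with
one- or two-exponential decays `sum_i A_i exp(-k dt / tau_i)` by weighted
least squares with Poisson weights (`sigma_k = sqrt(max(counts, 1))`);
counts are fit directly, not normalized frequencies. The k = 1 bin mixes
sub-frame events and can be excluded by flag (default: included). Note the
discretization law: for exponential dwells with uniform phase the apparent
run-length tail decays exactly as `exp(-dt/tau)` per frame but the k = 1
bin is depleted relative to that geometric law, and the mean run length is
`mean dwell/dt + 1` frames — the tests' sampling oracles account for this.

Apparent structure widths are measured by averaging intensity profiles
perpendicular to a line and fitting a 1-D Gaussian plus offset; on
coarse-pixel images, sampling and linear interpolation broaden the profile
by roughly `px^2/12` in variance, so width oracles in the tests use fine
(20 nm) grids, matching the 5 nm reconstructions this operation is used on.

## SOFI

Second-order cumulant per pixel: `C2(tau) = sum_t dI(t) dI(t+tau) / (n - tau)`
with `dI = I - <I>_t`. Dividing by the number of summed products keeps this
exactly equal to the iFCS autocorrelation numerator, and that identity is
enforced structurally: the iFCS module computes its numerator by calling
the SOFI routines, and tests assert the identity to machine precision.
A batch FFT path (`lagged_covariance`) computes many lags at once and
agrees with direct summation to better than 1e-10 relative.

Two lag policies: `first_lag` uses C2(tau = 1) only (appropriate for 30 ms
frames, where binding decorrelates within about one frame);
`sum_to_half_decay` sums C2 over `0 < tau <= tau_max`, with tau_max the
first lag at which the mean ACF (over pixels passing a pre-fit SNR gate)
has decayed below 50% of its first-lag value — larger lags would mostly
add noise. Unit weights are used in the sum. The 50% reference is the
first lag *present in the supplied curve*; movie-driven callers pass lags
from 1 because lag 0 carries shot noise. Negative cumulant values are
estimator noise: they are retained in the raw output (clamping before
summation would bias the sum) and clamped to zero only for display.
Cross-correlation variants and cumulant orders above 2 are out of scope.

For an emitter with Gaussian PSF of width sigma, the cumulant image is the
PSF squared: width sigma/sqrt(2), a 1.4-fold resolution gain. The
single-blinking-emitter benchmark (telegraph blinking, on-probability 0.3,
mean on-time 3 frames, 1000 photons/frame, 5000 frames) reproduces this
ratio within +-0.02 across seeds.

## iFCS

Per segment and pixel, `G(tau) = <dI(t) dI(t+tau)>_t / <I>_t^2`; pixels
with zero mean are flagged invalid, never zero-filled. Full linear lags
are computed per segment by FFT and decimated onto a quasi-logarithmic
grid (every lag to 16, then ~16 points/decade, up to a quarter of the
segment length); segment curves are averaged and the SEM across the six
segments is the per-lag uncertainty. No detrending or bleach correction is
applied before averaging.

The SNR of an averaged curve is its amplitude divided by the standard
deviation of its last five lags. "Amplitude" here is the mean of the first
three nonzero lags — a pre-fit quantity, because gating must precede
fitting. The map gate is strict (`SNR > 10`); a pixel at exactly 10 is
excluded.

The two-component binding model is the product form

    G(tau) = G0 (1 - ff + ff e^{-tau/tau_f}) (1 - fs + fs e^{-tau/tau_s}) + Ginf

with the one-component model its `ff = 1, fs = 0` reduction. Weighted
least squares uses weights 1/SEM^2, with SEM floored at 1e-6 x max|G| to
avoid infinite weights; reduced chi2 = weighted residual sum / (n_lags -
n_params). Initialization: G0 from the amplitude, time constants from the
70%/30% amplitude crossings, ff = fs = 0.5; bounds tau in [frame time,
segment duration], fractions in [0, 1]; up to three jittered restarts on
failure. After fitting, components are relabeled so tau_fast <= tau_slow.
A relaxation time that pins at an optimizer bound marks the fit
non-converged: a boundary optimum means that component is unidentifiable
in that pixel. The mapped "fraction of molecules on the shorter relaxation
time" is `ff / (ff + fs)`; the product model does not force ff + fs = 1,
so this normalization is a declared convention. Bayesian or
maximum-likelihood ACF fitting is deliberately out of scope — the known
small-sample bias of weighted least squares is part of what the package
characterizes (see below).

The analytic reference curve used by recovery tests maps the simulator's
event-probability f to residence-time weights (above) and folds the
product's constant term `(1-ff)(1-fs)` into the offset so the curve obeys
G(0) = G0 + Ginf and G(inf) = Ginf and reduces exactly to a single
exponential when one fraction vanishes.

**Measured behavior** (computed by the test suite and analysis scripts, at
fixed seeds): on the full-scale scenario (64x64 px, 36,000 frames, 23/482
ms), the median absolute relative error of recovered times is ~15% (fast)
and ~22% (slow) over SNR > 10 pixels, with a mild downward bias of the
slow time; the two-component model's median reduced chi2 is ~0.3 versus
~1.7 for the one-component model (ratio ~5). Per-pixel tau_slow estimates
are heavy-tailed — a 90 s trace contains few slow events in weakly covered
pixels — so map homogeneity is judged by robust scatter (MAD-based CV
~0.32) rather than the raw CV (~0.47). In a photon-starved variant
(3 photons/frame), fitted relaxation times fall significantly below truth
(sign test p < 1e-3 for both), reproducing the known least-squares ACF
estimator bias in dim regions.

## FRC

Localizations are assigned independently to two half-sets with probability
1/2 (splitting by localization, not by frame, so repeated localizations of
one binding event can correlate across halves; no correction is applied).
Each half is rendered as a *raw* 5 nm histogram on a square grid — the
25 nm kernel is never applied here, since smoothing would multiply both
spectra by the kernel's transfer function and bias the correlation
normalization near the threshold. Rings are one discrete frequency step
wide (1/(N x 5 nm)); per ring, FRC = Re(sum F1 F2*) / sqrt(sum|F1|^2
sum|F2|^2), with rings lacking power flagged undefined. Only the r = 0
ring is excluded from crossing detection. The resolution is the inverse of
the frequency where the curve first drops below 1/7, located by linear
interpolation between the neighboring rings; a curve that never crosses
reports an undefined resolution rather than a number.

## Pipeline

`run_pipeline` executes simulate -> PAINT -> SOFI -> iFCS -> FRC per a
YAML-serializable config whose hash, seed and library versions go into a
run manifest; identical config + seed reproduce bit-identical artifacts.
`validate_run` re-checks the SOFI/iFCS numerator identity and
reconstruction mass conservation on a finished run directory and reports
pass/fail/skipped per check (a single-segment run reports its SEM check
"skipped", not failed). Per-stage timings and filter counts (candidates
discarded at edges, fits rejected, pixels gated) are logged to make the
pipeline auditable.

## Problem sizes

Tests and analysis scripts run the full-scale iFCS recovery scenario
(64x64 px, 36,000 frames) once and otherwise use scaled-down scenarios
(32-48 px fields, 2,000-18,000 frames) chosen so each stage still operates
in its intended statistical regime: sparse frames for PAINT, hundreds of
binding fluctuations per pixel for iFCS, tens of thousands of
localizations for FRC.

## Known limitations

* Single-emitter fitting only; overlapping emitters yield merged, wide
  fits that must be removed by the width filter, and dense regions are
  under-sampled exactly as in real transient-binding SMLM.
* The product-form two-component model is fit as stated; for a true
  mixture of independent binding modes the exact ACF is a weight sum of
  exponentials, and the product's cross term (rate 1/tau_f + 1/tau_s) is
  absorbed into the fast component. Recovered fractions are therefore
  model conventions, not physical bound fractions.
* tau_slow in individual pixels is limited by the number of slow events in
  the trace; per-pixel maps are accurate in the median but heavy-tailed.
* No drift correction, no 3-D localization, no multi-emitter or
  neural-network detection, no photobleaching model.
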