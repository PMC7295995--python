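# Methods

`octflow` quantifies blood flow from the *intensity* of OCT time-series
measurements.  Phase-based (Doppler) OCT measures only the axial flow
component and becomes unstable when the beam meets the vessel near 90°, which
is the common geometry in the retina.  Flow also modulates the OCT speckle
intensity, and the decay of that temporal modulation encodes the total speed
without the angular singularity — but inverting it analytically is hard at
the short record lengths eye motion permits.  The framework therefore trains
a classifier on simulated speckle records and surrounds it with the pre- and
post-processing needed to turn per-pixel classifications into vessel flow
rates, with a Doppler pipeline retained as the reference method on phantoms.

## Forward signal model

A point scatterer field translates transversely through a Gaussian beam.
The detected complex field of one record is

    a(t) = sum_k exp(i phi_k) g(x_k + v t),      g(x) = exp(-x^2 / w0^2),

with `w0 = 9 um` (half the 18 um e^-2 intensity diameter), sampled at the
100 kHz A-scan rate for 128 samples.  Scatterer positions are drawn uniformly
(Poisson count) over the beam support (±3 w0) extended by the travel
distance, with unit amplitudes and i.i.d. uniform phases; fully developed
Rayleigh speckle emerges from the summation.  Positions, counts and phases
are redrawn for every realization.  Defaults that the underlying description
leaves open, chosen once:

- linear scatterer density: 2 per e^-2 radius (2/9 um^-1), a hematocrit
  proxy only — the model makes no claim of optical realism for blood;
- beam support truncation at ±3 w0 (amplitude error < 1.3e-4);
- the model is purely transverse; axial Doppler phase is injected only by
  the phantom generator as a deterministic per-pixel phase ramp.

Shot noise is circular complex Gaussian noise on the field with variance
`sigma^2 = <I>_ens / 10^(SNR/10)`, referenced to the *ensemble*-mean signal
intensity `<I>_ens = rho w0 sqrt(pi/2)` (a fixed-brightness target), not the
per-record mean.  Monte-Carlo re-estimation of a requested SNR agrees within
0.2 dB.

## Classifier

Each record is self-normalized to unity mean over its own 128 samples and
classified by a 1D CNN: one convolutional layer (128 kernels, length 32,
unpadded — output length 97), ReLU, max-pooling (length 4, stride 4), then
fully connected layers of 1024, 256 and `n_classes` units with a softmax
output read as a velocity likelihood curve over a log-spaced grid
(reference configuration: 64 classes, 0.001–2000 mm/s; the consecutive-class
ratio is (2×10^6)^(1/63) ≈ 1.259).  The network is implemented directly on
NumPy (im2col convolution and BLAS matrix products) and trained with
mini-batch SGD (batch 128, learning rate 0.01, momentum 0.9) on the softmax
cross-entropy; unpadded convolution makes the parameter count well defined
(3,429,824 for the 64-class configuration).  Training details the source
description leaves open — loss, optimizer, padding, batch size — are set to
these era-standard defaults and exposed in `TrainingConfig`.

Because speckle statistics change with noise level, one network is trained
per SNR (reference: 5–35 dB in 1 dB steps, 49.6 million records in total).
At inference the per-pixel SNR selects the nearest trained network (ties
toward the lower SNR; out-of-range estimates clamped with a warning;
estimates below 4 dB evaluated at the lowest network but flagged
unreliable).

### Desk-scale configuration

The suite and the acceptance script train a reduced bank chosen once as the
study conditions: 12 classes from 5 to 400 mm/s (the range the 128-sample /
18 um / 10 us geometry actually resolves), SNR levels {10, 15, 20} dB, 1000
realizations per cell split 800/200 (mirroring the 22,000/3,000 ratio of the
full configuration), at most 30 epochs with early stopping on validation
accuracy (patience 4, best-epoch weights kept).  Typical held-out top-1
accuracy is 0.54–0.71 (chance 1/12), with ≥ 95% of mid-range records within
±1 class.

## B-scan pipeline

Stepped M-scans (128 repeated A-scans per lateral location) are processed
per pixel: SNR estimated against a designated noise region (default the
deepest 10% of the image) as `10 log10(<I>_t / floor)`; each pixel's record
self-normalized and classified with the SNR-matched network, strictly
without neighbor information.  Spatial regularization happens only in
likelihood space: the curves of each 3×3 neighborhood are multiplied
elementwise (in log space; edge pixels use available neighbors only) and the
argmax gives the velocity class.  Ties break toward the lower class and are
flagged.  The angiography mask thresholds the temporal variance of the
self-normalized intensity (default 5× the median statistic of
significant-SNR pixels), keeps the largest connected component (≥ 10 px),
and fills holes.

## Doppler reference

Within one record the flow is assumed constant, so phase differences at
delays of 1–40 A-scans all estimate the same per-A-scan phase step.  Per
delay, the complex lag products are averaged over the record (Kasai
estimator — an amplitude-weighted circular mean robust to wrapped samples)
and converted to a phase image; bulk motion is removed by subtracting the
per-A-scan circular mean phase of static pixels (static = significant SNR,
high lag coherence *at two long probe delays* and small accumulated phase
there — short delays cannot separate slow flow from static tissue); the
image is unwrapped in 2D (reliability-ordered algorithm) and re-anchored to
zero mean phase on the static pixels.  Corrupted per-delay images are
rejected by two criteria: residual discontinuity density above 1% of pixels,
and disagreement of the delay-scaled image with the shortest surviving delay
(median absolute deviation over flow pixels > 0.15 rad) — the second catches
smooth-but-wrong unwrappings of marginal delays that the discontinuity count
misses.  Survivors are scaled by 1/delay, averaged, and converted with

    v = (dphi * lambda0) / (4 pi n tau cos(alpha)),

lambda0 = 1040 nm, n = 1.36, tau = 10 us.  Angles in 88–92° are rejected.
The Doppler angle can be estimated from the depth shift of a vessel between
two locations 200 um apart: `alpha = 90° + atan(dz/dx)` on optical-path-
corrected depths.

### Accuracy floor of the Doppler closure

On noise-free phantoms the pipeline is unbiased, but each pixel's phase
still carries speckle-decorrelation noise (~0.02 rad per B-scan at the
lumen core): the lag products decorrelate as speckle transits the beam, and
this noise is almost perfectly correlated across delays within one scan, so
multi-delay averaging suppresses additive detection noise but not speckle
noise.  Averaging the protocol's 10 repeated B-scans gives the expected
sqrt(10); the residual per-pixel median velocity error at 50 uL/min and 85°
is ~0.6%, while vessel-level quantities (integrated rate, fitted peak
velocity) close within 0.2–0.5%.  The tests assert the vessel-level closure
and document the per-pixel floor.

## Flow-rate quantification

Per-pixel rate is `v * A_pix` with `A_pix` = lateral step × axial pixel size
/ 1.36 (refractive index of blood); vessel rates are reported in uL/min
(60e-6 uL/min per mm/s·um^2).  Intensity-based velocimetry overestimates at
the lumen edge, increasingly as |alpha - 90°| grows, so vessel rates use
spatial masking: pixels within an aperture radius Ra (default 67% of the
vessel radius, in physical um with the pixel anisotropy corrected) enter a
least-squares fit of the zero-at-wall paraboloid `v(r) = v_max (1 -
r^2/R^2)`, and the rate is its analytic lumen integral `v_max pi R^2 / 2`.
The vessel center and radius come from the mask centroid and equivalent-area
radius.  For noise-free paraboloid inputs the result is invariant to Ra;
smaller apertures trade angle robustness against higher measurement
variability (fewer pixels), quantified by the coefficient of variation
(sample SD / mean) over repeats.  An empirically derived scale factor
(reference value 3.18 between network and Doppler rates) is applied only at
reporting time, guarded against double application; it is a stored constant
here because deriving it requires physical measurements.

Conservation analysis sums daughter-segment rates against the parent
(|A − (B+C)|/A); the diameter dependence is an OLS fit of log10(rate) on
log10(diameter), arteries and veins pooled.

## Phantom generator

The generator emulates the validation phantom: a 125 um tube in a static
scattering slab, imaged with the stepped M-scan protocol (100 locations,
3 um lateral step, 4.5 um axial pixel in air, 0.13 s per B-scan, 10 repeats
= 1.3 s).  Lumen pixels carry forward-model speckle at the local speed of
the Poiseuille profile implied by the pump rate (peak = 2 × mean =
2Q/(pi R^2)) times the axial phase ramp `exp(i dphi(r) t)` with `dphi(r) =
4 pi n v(r) cos(alpha) tau / lambda0`; static pixels carry temporally
constant speckle; margins at top and bottom are pure noise floor.  Every
pixel's scatterer field is drawn independently (no shared speckle between
neighbors), all randomness flows from the spec seed, and ground truth
(velocity map, phase ramp, lumen mask, rates) is emitted alongside.
Optional features: per-A-scan bulk phase jitter, raised-cosine pulsatility
across repeats, a 2-pixel lumen-rim "edge artifact" velocity injector
(amplitude `3 v_peak ((alpha-90)/10)^2`, plus 5% multiplicative pixel noise
per repeat) used to reproduce the masking experiments, bifurcation triplets
(daughter diameters from a branching exponent, default Murray's k = 3; the
second location of each segment offset 200 um with the lumen depth shifted
accordingly), and diameter series following `Q = c D^k`.

What the generator does *not* emulate — and hence what passing tests do not
show: real blood scattering (multiple scattering, hematocrit-dependent
optics, non-Newtonian profiles), intravoxel velocity gradients, axial
displacement of scatterers within a record, shared speckle between
neighboring pixels, and eye motion beyond a per-A-scan phase offset.
Closure results are algorithmic, not physical, validations; in particular
the network-to-reference scale factor of real measurements (3.18) cannot
arise here because the classifier is trained on the same forward model the
phantom uses.

## Numerical choices and degenerate inputs

- Likelihood filtering uses log-space sums (argmax-invariant, no underflow);
  renormalization only for display.
- All-zero records raise a normalization error; all-zero pixels in a B-scan
  get uniform likelihood curves and are flagged unreliable.
- Self-normalization scales the complex field by sqrt(mean intensity) so
  intensity == |field|^2 stays true; the operation is idempotent.
- Aperture fits require ≥ 6 pixels; empty masks, zero inflow, single-point
  power-law fits and double calibration raise typed errors.
- CoV uses the sample standard deviation (ddof = 1).
- Determinism: every cell of the library, every phantom and every training
  run derives its generator from an explicit seed (per-cell spawn keys make
  the library independent of generation order); repeated runs are
  bit-identical.

## Known limitations

- The per-pixel Doppler closure floor (~0.6%) described above.
- The coarse 12-class desk grid quantizes continuous speeds at ±20%
  per pixel; profile fits average this out at vessel level (bifurcation
  imbalance ~3%), and the median velocity ratio for continuous probe speeds
  carries a ~-5% grid bias that a calibration constant would absorb.
- The SNR estimator assumes an available signal-free noise region and does
  not subtract the noise floor from the signal estimate (a +0.04 dB bias at
  20 dB).
- Training the full 64 × 31 × 25,000 configuration is supported by the API
  (sharded HDF5 library, per-SNR training) but is a cluster-scale job; all
  shipped results use the desk-scale configuration above.
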