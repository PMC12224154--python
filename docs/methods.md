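# Methods

## Measurement model

Transport efficiency is estimated as a ratio of two particle counts of the
same (or statistically equivalent) sample area,

    eta(%) = X_ICPMS / X_UCM * 100 ,

with upconversion microscopy (UCM) as the reference.  The model's
assumptions are those of the underlying measurement: particles are counted,
not weighed, so TE is insensitive to particle size as long as every intact
particle yields one countable event; UCM is background-free, so its only
uncertainty at fixed area is Poisson counting noise (RSD = 100/sqrt(N));
and a second ablation pass (reablation) over the same area converts
incomplete desorption and redeposition from a bias into a measurable,
correctable term, `TE_total - TE_first = 100 * X_re / X_UCM`.

Two protocols are implemented.  *random_area* counts UCM tiles (default
ten 0.667 mm fields, the microscope's field of view) and ablates separate,
statistically equivalent areas; both counts are rescaled to a common area,
so layer inhomogeneity enters the uncertainty (tile RSD above the Poisson
RSD measures it).  *grid_area* counts and ablates the identical bounded
square, removing the inhomogeneity term; co-registration of the UCM spot
set with the reconstructed count map then allows a per-pixel overlay.

## Synthetic ground truth

The generator emulates the three observables of the real experiment.

*Layers.*  Homogeneous Poisson point process at 7000 particles/mm²
(default), or a Neyman-Scott parent-offspring process for overdispersed
layers: offspring per parent ~ Poisson(D-1) gives count variance/mean ~ D,
reproducing super-Poisson tile RSDs (e.g. 3.9% instead of the 1.2% Poisson
floor at 7000 counts).  Per-particle brightness/mass factors are lognormal
with sigma 0.1 (a monodisperse batch).

*UCM images.*  Each particle is a Gaussian PSF (sigma 0.4 μm) carrying
`photon_scale x mass_scale` photons (default 2000) on a zero background,
with Poisson shot noise; pixels are 0.5 μm.

*Transients.*  The raster schedule sweeps the layer; the nominal ablation
time of a particle is when the spot centre crosses it (a top-hat beam
removes material centred on its axis).  The XY stage adds uniform ±2.5 μm
position jitter.  Each swept particle draws a fate:

| fate      | probability            | signal                                     |
|-----------|------------------------|--------------------------------------------|
| decayed   | `decay_prob`           | baseline smear (Gaussian, sigma 2.5 ms)    |
| desorbed  | `desorption_prob` (rest)| one peak, width U(200, 500) μs            |
| residual  | remainder              | none; kept for the reablation pass         |

Peak areas are lognormal with mode 220 counts (sigma 0.25); peaks are a
single-dwell rise with exponential decay truncated at the drawn width, and
arrive after an exponential washout delay (mean 10 ms).  The dwell is
100 μs, so peaks span 2–5 dwells.  The ion background is Poisson at 0.05
counts/dwell for every regime; the elevated baseline characteristic of
193-nm ablation *emerges* from the decay smears rather than being injected,
which is what makes the disintegration diagnostics meaningful.  Decayed
particles contribute only `decay_signal_fraction` (0.5) of their ion yield
to the smear; the remainder represents fragments below the detection limit
and evaporation, which by construction do not affect counting.

Regime defaults: `ir_2940` desorption 1.0, decay 0; `uv_213` desorption
0.94, decay 0.03, redeposition 0.5 (residual ≈ 6% of the first-pass
count); `uv_193` desorption 0.95, decay 0.55 (≈ 45% countable).  The
literature gives these fractions only qualitatively, so they are tunable
configuration, not canonical constants.

Coincidence is emergent: two particles ablated within one peak duration
simply add in the transient and merge into one detected event, so the
correction stage can be validated against the per-particle event log.
Every generator is bit-reproducible under a fixed seed, and the event log
conserves particles exactly (desorbed + decayed + residual + not swept =
layer count).

What the generator does *not* emulate: plasma ionization and aerosol
fluid dynamics (fluence enters only through the regime probabilities),
detector dead time, ionic dissolved background, sample topography, and
spatially correlated stage drift.  Passing tests therefore demonstrate
the correctness of the counting and correction chain under the stated
stochastic model, not instrument-level accuracy.

## Numerical choices

*Baseline estimation* is iterative sigma clipping (k = 3) with a two-count
discreteness guard: thresholds are `mu + k*sigma + 2` counts.  At the
near-zero integer baselines of this modality (0.05 counts/dwell) a pure
k-sigma rule clips every nonzero dwell and the baseline collapses to zero;
the guard keeps ordinary Poisson fluctuations while still rejecting
particle peaks, which carry tens of counts per dwell.  The same guard in
the detection threshold `mu + k_detect*max(sigma, sqrt(mu)) + 2`
(k_detect = 5) keeps the false-positive rate below 1 per 1e5 baseline
dwells; detection recall at default settings exceeds 99%.  The noise-free
conservation tests set the guard to zero explicitly.

*Spot detection* thresholds at `median + 5*robust_sd` with three floors on
the robust SD — sqrt(median) (Poisson), one count (quantization), and 1e-3
of the dynamic range (scale invariance) — plus an additive
`3 + 3*sqrt(median)` guard that controls the family-wise false-positive
rate over ~1e6 background pixels.  Non-maximum suppression is greedy and
Euclidean (keep the brighter spot), because a square suppression footprint
was measured to over-suppress resolvable pairs at 1–1.4 μm and bias counts
low by ~2%.

*Coincidence correction* treats the acquiring schedule as W independent
windows, each one mean-event-duration long: `corrected = -W ln(1 - n/W)`.
It is monotone, convex, at least the raw count, and tends to the raw count
as occupancy tends to zero.  W from the *observed* mean event width
slightly over-counts window length when events merge, which partially
compensates the residual clustering bias; simulations up to ~10% occupancy
show the corrected count strictly closer to truth than the raw count.

*Disintegration diagnostics*: the peri-event baseline elevation ratio is
the mean intensity in ±20-dwell guard bands flanking events divided by the
clipped baseline mu, and the wide-event fraction counts events longer than
1000 μs.  The flag trips at ratio > 1.5 or wide fraction > 0.10.  The
ratio threshold sits midway between the calibrated regime populations
(soft desorption 1.00–1.01, partial desorption ≤ 1.35, disintegration
≥ 1.75 on 1 mm² runs); a flagged run marks its TE as biased low (a lower
bound), which is exactly the 193-nm failure mode.

*Histogram* bins are 10 counts wide, anchored at zero; the mode bin centre
ties break toward the smaller area.  The mode near 220 counts, unchanged
between ablation and reablation, indicates particles survive both passes.

*Registration* restricts the transform to rigid rotation + shift (scale
fixed at 1) because both modalities are metrically calibrated and a free
scale invites degenerate optima on featureless point data.  The search is
exhaustive (default rotation ±5° step 0.5°, shift ±3 pixels step 1 pixel)
over the NCC between the map and the binned, transformed spots, followed
by step-halving 3x3x3 local refinement to 0.1 μm / 0.05°.  NCC is used
instead of mutual information because the count grids are low and sparse.
Flat (zero-variance) maps raise an error rather than returning an
undefined score.

*Mapping* assigns each event by its onset time (minus an optional
transport delay, default 0); events in non-acquiring intervals go to the
last pixel of the preceding line with a warning.  Assignment never changes
the total count, so mapping artefacts cannot bias TE.  Edge accumulation
from redeposition is reproduced by the simulator but deliberately not
corrected in the map.

## Problem sizes and design choices

The reference study conditions are 1 mm² rasters at 7000 particles/mm²
with a 100 μs dwell (~4.5 million dwells per pass); protocol-level tests
and the acceptance script run at these conditions or on quarter-scale
(0.5 mm or 0.25 mm) rasters where only per-event statistics matter, with
seed counts (20–50 replicates) chosen so Monte-Carlo means are a few
standard errors tighter than the asserted tolerances.  The grid protocol's
registration step is optional (`do_registration`): in closed-loop recovery
studies both modalities share one coordinate frame, so registration only
confirms the identity and is skipped inside large seed sweeps; its
recovery accuracy is validated separately against known applied
transforms.  The flyback return defaults to 0.5 s per line but carries no
physics; simulations shorten it, since only event ordering matters.

## Known limitations

* TE above 100% is possible (and reported with a warning) when the
  coincidence correction or UCM merge losses push the ratio over unity;
  the report layer never clips.
* At reference density ~1% of spot pairs fall below the optical merging
  scale, so UCM counts run ~1% low and TE correspondingly ~1% high; this
  is within the Poisson-level uncertainty the method claims.
* The dead-time coincidence model assumes temporally homogeneous arrivals;
  strongly clustered layers violate it and leave a residual undercount.
* The disintegration flag is calibrated on the synthetic regime
  populations; on real instruments its thresholds should be re-derived
  from blank and soft-ablation runs.
* Serpentine (bidirectionally acquiring) scans, stage acceleration, washout
  deconvolution and sub-pixel event localization are out of scope.
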