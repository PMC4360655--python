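# Methods

This note records the models, estimators and numerical choices behind each
stage of the pipeline, the defaults and why they were chosen, and what the
synthetic-data tests do and do not establish about real recordings.

## The coupled Markov chain model

A cluster of `n` identical two-state channels is modelled through its
*occupancy chain*: the number of simultaneously open channels, a Markov
chain on `0..n` sampled once per digitization interval. Two limiting
kernels are mixed linearly by the coupling coefficient κ:

* **Independent kernel** `T_indep`: each of the `k` open channels stays
  open with probability `1 − p_oc` and each of the `n − k` closed channels
  opens with probability `p_co`; the next occupancy is the sum of the two
  binomial counts (computed by convolving the binomial pmfs, built by the
  stable Pascal recurrence rather than factorials).
* **All-or-none kernel** `T_coup`: a representative channel — open with
  probability `k/n` in state `k` — makes one two-state transition and all
  channels copy it; the chain jumps to `n` with probability
  `(k/n)(1 − p_oc) + (1 − k/n)p_co`, else to `0`.

`T(κ) = (1 − κ)·T_indep + κ·T_coup` is row-stochastic for all parameters,
continuous in κ, and reproduces both conceptual endpoints exactly: κ = 0 is
purely independent gating and κ = 1 visits only the all-closed and all-open
states after the first step. The published description of the binary
coupled Markov chain method does not fix a unique parameterization; this
linear mixture is our concrete realization of it, chosen for exactly those
endpoint and continuity properties, and is stated as such.

Because the channels are exchangeable and elementary amplitudes are fixed,
inference runs directly on the observed idealized occupancy sequence — no
hidden-state machinery. The likelihood of a sequence is the product of
kernel entries over successive samples (the initial state is conditioned
on); it depends on the data only through the (n+1)² matrix of transition
counts, which makes evaluation O(n²) regardless of record length.

### Estimating κ

`estimate_kappa` maximizes the likelihood jointly over (κ, p_co, p_oc):

1. a moment-matching start for the rates (counting per-channel openings and
   closings under an independence approximation);
2. a coarse search alternating a **vectorized κ grid scan** (step 0.01 —
   `T(κ)` is linear in κ, so the entire grid is evaluated at once) with
   Nelder-Mead re-optimization of the rates at the current best κ;
3. a joint Nelder-Mead refinement from the best coarse point, clipped to
   the closed unit cube.

Ties on the κ grid break toward smaller κ, i.e. conservatively with respect
to declaring cooperativity. A record with no occupancy transitions is
returned with a `degenerate` flag and κ = NaN, never a silent 0. `n`
defaults to the maximum observed level. The classification threshold is a
strict κ > 0.1.

On synthetic 8-channel records (Po = 0.3, 20 kHz, 2 s) the mean estimate
over seeds is within 0.01 of the truth at κ = 0 and 1 and within 0.02 at
κ = 0.5 (the tests pin |mean κ̂ − κ| ≤ 0.1 at 50 seeds per level).

## Idealization and quantal analysis

* **All-points histogram**: every sample counted once; bin edges snapped to
  multiples of the bin width.
* **Quantal mixture**: Gaussian mixture with means constrained to
  `baseline + k·q` (k = 0..L) and one shared σ, fit by EM for
  L = 0..max_levels, with the winner chosen by BIC. L = 0 (a single
  Gaussian) flags `q` as unidentifiable rather than reporting a spacing.
  The (baseline, q) M-step is a 2×2 weighted least-squares solve. EM runs
  on a fine histogram (bin width σ/20) instead of raw samples, making the
  cost independent of record length; the binning error is far below the
  reported precision. The baseline initializer is the *leftmost* peak of
  the smoothed histogram — not the global mode, which in active records is
  an occupied level rather than the baseline.
* **Idealization**: nearest-level rounding, `round((v − baseline)/q)`,
  equivalent to half-amplitude thresholds midway between levels. An
  optional Schmitt-trigger mode (`hysteresis`, default off) changes level
  only when the signal moves more than `hysteresis·q` (default use: 0.75)
  from the current level's mean. At the default noise level (SD = 0.2 q)
  plain rounding misreads ~1 % of samples; those single-sample glitches
  mimic independent-channel transitions and bias κ̂ at the coupled end
  (κ = 1 records estimate at ~0.87 without hysteresis, ~1.00 with). The
  hysteresis band is wide enough to reject noise (0.75 q ≈ 3.75 noise SD)
  yet narrower than a genuine transition (≥ 1 q), so event timing is
  essentially unaffected. A median de-glitch utility for level sequences
  exists but is *not* used before coupling inference: under a mixed kernel
  genuine intermediate-state dwells last only 1–2 samples and the filter
  deletes them, biasing κ̂ downward mid-range.
* **Activity**: nPo (and sparklet nPs) is the time-average of the level
  sequence, which equals n·P̄ₒ for exchangeable channels. For sparklet
  sites, "number of quantal levels" is read as the per-site maximum level;
  the same time-average formula is used.

## Imaging

Coordinates are (row, col), 0-based, pixel centers on the integer grid.

* **F/F0**: each frame median-filtered (radius 1), divided by the
  (identically filtered) baseline image; non-positive baseline pixels are
  reported with coordinates.
* **Fmax equation**: `[Ca²⁺] = K_d (F/F_max − 1/R_f)/(1 − F/F_max)` with
  required indicator constants; the defaults (K_d = 570 nM, R_f = 100) are
  literature-typical for Rhod-2 in cells and must be overridden for
  quantitative use on real data. Saturation (F ≥ F_max) and below-range
  (F < F_max/R_f) inputs raise distinct errors.
* **Sparklet detection**: per-pixel quiescent statistics are the 20th
  percentile (robust to sites active most of the movie; for Gaussian noise
  it sits 0.8416 SD below the quiescent mean, which is added back) and a
  first-difference MAD noise SD. A pixel is a candidate if it exceeds
  baseline + 3 SD for ≥ 3 consecutive frames; candidates are grouped by
  greedy local-maximum selection within a 3-pixel radius. The site trace is
  the 3×3 average around the center. Because that spatial average
  attenuates the quantal amplitude by the PSF shape (~0.65× for a 1.2-pixel
  Gaussian), the per-site quantal unit is re-estimated from the trace by
  the constrained mixture fit (accepted within [0.3, 1.5]× nominal),
  falling back to the nominal 38 nM. The original detection software is
  unpublished; this mean + k·SD / minimum-duration design follows the
  sparklet literature and is a reimplementation choice. Measured on planted
  sites at SNR 5: recall 20/20 with exact nPs; false positives 0/40 flat
  movies.
* **Photobleaching extraction**: reference = mean of first 5 frames →
  rolling-ball background subtraction (radius 50 px — the stated chain
  names no radius; large relative to spots) → band-pass as a difference of
  Gaussians with 2- and 5-pixel sigmas (the named pixel cut-offs; the
  kernel itself was unspecified) → threshold at mean + 3 SD → 8-connected
  regions → 4×4 ROI at each region's peak pixel → ROI **sum** per frame.
* **Step counting** (automated, replacing manual counting): the trace is
  smoothed (width-3 median + 10-frame moving average), then a
  piecewise-constant model is grown by greedy change-point insertion
  (minimum segment 5 frames) while each insertion reduces the RSS by more
  than `penalty × σ²_sm`, where σ_sm is the smoothed-trace noise SD derived
  from the MAD of *raw* first differences (the median-filtered differences
  are biased low ~5× because adjacent filtered samples coincide).
  Breakpoints within twice the smoothing window are merged into one event;
  events must drop by more than max(5 σ_sm, 0.25 × median drop); and since
  bleaching steps share a unit amplitude, each merged event is counted as
  `round(drop/unit)` steps with unit = median event drop — recovering
  closely spaced bleach events that the smoothing fuses. Defaults
  (penalty 80) give exact counts on noiseless 1–12-step traces, zero counts
  on pure-noise traces, and a mean-count error of −2 to −5 % at SNR 6 over
  435 spots; the error is insensitive to the penalty over 32–250.
* **Cluster areas**: binary mask at a fractional-of-max (or absolute)
  threshold, 8-connected components, pixel counts × pixel_size² in nm²;
  border-touching components flagged.

## Kinetics

* **Multi-exponential fits** use variable projection: amplitudes and offset
  are solved linearly at each τ iterate; the τs (log-parameterized) are
  optimized by Nelder-Mead from 20 log-spaced, jittered multi-starts and
  polished by bounded joint least squares. τ is confined to
  [dt/2, 2 × duration]: beyond that an exponential is indistinguishable
  from the offset and the fit can wander without changing the residual.
  Noiseless round-trips recover 1–3 component taus to < 0.5 %. A caveat
  the tests document explicitly: with noise at just 1 % of peak, the
  *components* of a triple exponential with neighboring taus are not
  identifiable (the global optimum can place the slow tau far from the
  generating value at lower RSS than the truth); the fitted *curve* and
  T50 % remain stable, and those are what the noisy-data tests assert.
* **T50 %**: first crossing of half of (peak − final baseline) after the
  peak, linearly interpolated; the final baseline is the mean of the last
  5 % of samples. A trace with no decay returns NaN.
* **Boltzmann fits**: `floor + (ceiling − floor)/(1 + exp((V50 − x)/k))` by
  Levenberg-Marquardt from a half-range-crossing start; monotone-flat data
  and midpoints outside the sampled range are flagged degenerate. The
  noiseless 9-point perfusion series (0–5000 nM) returns V50 = 254.3 nM to
  < 0.1 nM.
* **Conductance**: `G = I/(V − V_rev)` normalized by max |G|; V = V_rev is
  rejected per point, all-zero currents flag the normalization.
* **FRET ratio**: `FRETr = (RFP − bg_R − b·GFPg)/GFPg` with donor
  bleed-through b = 0.16 by default; invariant under common gain.
* **Facilitation**: `I₂/I₁(t) = (1 − e^{−t/τ_rec})(1 + A e^{−t/τ_dec})`
  with τ_rec = 375 ms and τ_dec = 333 ms. The `+1` offset in the decoupling
  factor is forced by the long-interval limit I₂/I₁ → 1. The decoupling
  amplitude A is a scale factor fit to facilitation data when available;
  its default is 2.5. The choice matters: with these taus the product has
  an interior facilitation peak only for A ≳ 1.4 (below that it rises
  monotonically to 1); A = 2.5 gives a peak ratio ≈ 1.15 at ≈ 0.44 s,
  consistent with the modest paired-pulse enhancement such protocols
  report. `fit_facilitation_amplitude` recovers A from curve data by
  linear least squares. Note the 333 ms decoupling constant is a model
  input taken from the published simulation, not a quantity derived here
  from the FRET decay components — it matches none of the three FRETr taus
  exactly, and the two are deliberately not forced to agree.

## Synthetic data: what it does and does not emulate

The generators reproduce the statistical structure the estimators assume:
Markovian two-state gating at 20 kHz, additive i.i.d. Gaussian noise
(default SD = 0.2 × the elementary amplitude — the recordings themselves
never state a noise figure, so this is a documented choice), isotropic
Gaussian PSF, geometric (constant-rate) bleach times truncated to the
movie, and exact exponential/sigmoid functional forms. They do **not**
emulate 1/f or correlated amplifier noise, analog low-pass distortion (a
first-order filter is available but off by default so tests see the stated
noise model), flicker/blinking of fluorophores, drift, photobleaching of
the Ca²⁺ indicator, or non-stationary gating within a record. Passing
tests therefore demonstrate correctness of the estimators under their own
assumptions and calibrated robustness at realistic SNR — not performance
on any particular experimental recording.

Problem sizes in the tests and the acceptance script (e.g. 20–50 records
of 40 000 samples for κ recovery, 435 photobleaching spots, 20-seed
quantal batches) were chosen to keep the full suite fast while leaving the
Monte-Carlo error well inside every asserted tolerance.

## Reproducibility

All randomness flows from explicit integer seeds through
`numpy.random.default_rng`; identical parameters reproduce identical
records bit for bit. The pipeline derives per-stage streams from one
master seed via `SeedSequence` spawning, and a rerun with the same config
reproduces every table byte for byte.
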