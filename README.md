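# cavcoupling

Quantitative analysis of **cooperative gating of CaV1.2 channels** — the
L-type Ca²⁺ channel clusters of cardiac myocytes — for electrophysiologists
and cell-imaging labs who need the complete chain from raw traces and TIRF
movies to a per-record **coupling coefficient (κ)**, with every stage
exercisable on synthetic data with known ground truth.

The package implements, as a tested pipeline:

* **Coupled Markov chain model.** A cluster of *n* two-state channels is
  described by its occupancy chain on states 0…*n* with transition kernel

  ```
  T(κ) = (1 − κ)·T_indep + κ·T_coup
  ```

  where `T_indep` is the aggregate kernel of *n* exchangeable independent
  channels (binomial thinning with per-sample rates p_co, p_oc) and
  `T_coup` is the all-or-none kernel in which every channel copies a single
  representative channel. κ = 0 is purely independent gating, κ = 1 is
  exclusively cooperative gating; κ is estimated per record by maximum
  likelihood (κ grid at 0.01 plus joint refinement) and a record is
  classified cooperative when **κ > 0.1**.
* **Idealization and quantal analysis.** All-points histograms,
  equal-spacing shared-σ Gaussian-mixture fits (component means constrained
  to `baseline + k·q`, level count chosen by BIC), multi-level
  half-amplitude idealization (optionally with Schmitt-trigger hysteresis),
  and the activity statistic nPo / nPs = mean occupancy = n·P̄ₒ.
* **Imaging.** F/F0 calibration, the Fmax equation
  `[Ca²⁺] = K_d·(F/F_max − 1/R_f)/(1 − F/F_max)` for Rhod-2, Ca²⁺ sparklet
  site detection (mean + 3 SD for ≥ 3 frames, 38 nM quantal unit),
  the photobleaching chain (rolling-ball background, 2/5-pixel band-pass,
  4×4-pixel ROIs, change-point step counting), and binary-mask cluster
  areas in nm².
* **Kinetics.** Multi-exponential decay fits (variable projection,
  multi-start) with T50 %, Boltzmann sigmoids for dose-response and G-V
  curves (`G = I/(V − V_rev)`), FRET ratio `FRETr = RFPg/GFPg` with 16 %
  bleed-through correction, and the paired-pulse facilitation model
  `I₂/I₁(t) = (1 − e^{−t/τ_rec})·(1 + A·e^{−t/τ_dec})` with
  τ_rec = 375 ms, τ_dec = 333 ms.
* **Synthetic data.** Generators for every input above — κ-coupled gating
  records (20 kHz, 0.5 pA elementary current), 100-Hz sparklet movies
  (38 nM quanta, Gaussian PSF), 2000-frame photobleaching traces with
  geometric bleach times, multi-exponential decays and Boltzmann tables —
  all returning ground truth beside the data.

## Worked example

Simulate an 8-channel record at κ = 0.5, idealize it and estimate κ:

```python
from cavcoupling.synthetic import GatingParams, simulate_coupled_record
from cavcoupling.idealize import idealize_record, compute_activity
from cavcoupling.markov import estimate_kappa

params = GatingParams(n_channels=8, p_co=0.003, p_oc=0.007, kappa=0.5,
                      amplitude=0.5, fs=20_000, duration=2.0, seed=1)
rec, truth = simulate_coupled_record(params)
levels = idealize_record(rec, amplitude=0.5, baseline=0.0, n_max=8,
                         hysteresis=0.75)
res = estimate_kappa(levels, n=8)
act = compute_activity(levels, fs=rec.fs)
print(f"kappa_hat = {res.kappa_hat:.3f}  cooperative = {res.cooperative}")
print(f"nPo = {act.value:.3f}")
```

prints

```
kappa_hat = 0.489  cooperative = True
nPo = 2.394
```

`kappa_hat` is the maximum-likelihood coupling coefficient (true value 0.5;
above the 0.1 threshold, so the record is classified as cooperatively
gating), and `nPo` is the time-averaged activity — with 8 channels at
single-channel open probability 0.3 its expectation is 8 × 0.3 = 2.4.

The numbered drivers under `analysis/` run each study stage end to end and
write tables under `results/`:

```bash
python analysis/01_simulate_gating.py      # records at kappa = 0 … 1
python analysis/02_estimate_coupling.py    # kappa recovery table
python analysis/03_quantal_sparklets.py    # sparklet detection + 38 nM quanta
python analysis/04_photobleach_counting.py # 435 spots, step counting
python analysis/05_decay_kinetics.py       # decay taus, T50, Boltzmann V50
python analysis/06_facilitation_model.py   # I2/I1 facilitation curve
```

The same stages are available as a CLI (`cavcoupling all --seed 1 --out
results/`) driven by a YAML run config.

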