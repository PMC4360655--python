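"""Synthetic data generators with known ground truth.

Every generator returns the simulated data together with the ground truth
that produced it, so each downstream analysis stage has an oracle.  Defaults
mirror the experimental conditions the analyses assume: cell-attached
currents sampled at 20 kHz with a 0.5 pA elementary amplitude, Ca2+
sparklet movies at 100 Hz with a 38 nM quantal amplitude, photobleaching
stacks of 2000 frames, and triple-exponential fluorescence decays.

Noise is additive i.i.d. Gaussian.  The default noise SD is 0.2 x the
elementary amplitude (the recordings the pipeline emulates are low-pass
filtered; an optional first-order low-pass is provided but off by default
so that tests see exactly the stated noise model).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import ChannelRecord, MovieStack, ValidationError
from .markov import build_transition_matrix

__all__ = [
    "GatingParams",
    "SpotTruth",
    "DecaySpec",
    "simulate_coupled_record",
    "simulate_levels",
    "simulate_sparklet_movie",
    "simulate_photobleach_spots",
    "simulate_photobleach_traces",
    "simulate_decay_trace",
    "simulate_dose_response",
    "lowpass_first_order",
]


@dataclass
class GatingParams:
    """Parameters of a coupled multi-channel gating simulation.

    ``p_co`` / ``p_oc`` are per-sample closed->open / open->closed
    probabilities of a single channel; the single-channel open probability
    at stationarity is ``p_co / (p_co + p_oc)``.
    """

    n_channels: int = 8
    p_co: float = 0.003
    p_oc: float = 0.007
    kappa: float = 0.0
    amplitude: float = 0.5  # pA (use 38.0 for sparklets in nM)
    noise_sd: float | None = None  # default 0.2 * amplitude
    fs: float = 20_000.0
    duration: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_channels < 1 or int(self.n_channels) != self.n_channels:
            raise ValidationError("n_channels must be a positive integer")
        for name in ("p_co", "p_oc", "kappa"):
            v = getattr(self, name)
            if not np.isfinite(v) or not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1], got {v}")
        if not np.isfinite(self.amplitude) or self.amplitude <= 0:
            raise ValidationError("amplitude must be positive")
        if not np.isfinite(self.fs) or self.fs <= 0:
            raise ValidationError("fs must be positive")
        if not np.isfinite(self.duration) or self.duration <= 0:
            raise ValidationError("duration must be positive")
        if self.noise_sd is None:
            self.noise_sd = 0.2 * self.amplitude
        if not np.isfinite(self.noise_sd) or self.noise_sd < 0:
            raise ValidationError("noise_sd must be non-negative")

    @property
    def n_samples(self) -> int:
        return int(round(self.fs * self.duration))

    @property
    def p_open(self) -> float:
        """Stationary single-channel open probability."""
        if self.p_co + self.p_oc == 0:
            return 0.0
        return self.p_co / (self.p_co + self.p_oc)


@dataclass
class SpotTruth:
    """Ground truth for one photobleaching spot."""

    center: tuple[int, int]
    true_steps: int
    step_amplitude: float
    bleach_times: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.true_steps != len(self.bleach_times):
            raise ValidationError("true_steps must equal number of bleach times")
        if any(b <= a for a, b in zip(self.bleach_times, self.bleach_times[1:])):
            raise ValidationError("bleach times must be strictly increasing")


@dataclass
class DecaySpec:
    """A multi-exponential decay: offset + sum_i amplitudes[i] * exp(-t/taus[i])."""

    amplitudes: list[float]
    taus: list[float]
    offset: float = 0.0
    fs: float = 100.0
    duration: float = 20.0
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if len(self.amplitudes) != len(self.taus):
            raise ValidationError("amplitudes and taus must have equal length")
        if any(a < 0 for a in self.amplitudes):
            raise ValidationError("amplitudes must be non-negative")
        if any(t <= 0 for t in self.taus):
            raise ValidationError("taus must be positive")
        order = np.argsort(self.taus)
        self.taus = [float(self.taus[i]) for i in order]
        self.amplitudes = [float(self.amplitudes[i]) for i in order]


def simulate_levels(params: GatingParams, rng: np.random.Generator) -> np.ndarray:
    """Simulate the occupancy level sequence from the coupled kernel.

    The chain starts from level 0 (all channels closed, as at the start of
    a depolarizing step).
    """
    kernel = build_transition_matrix(
        params.n_channels, params.p_co, params.p_oc, params.kappa
    )
    cum = np.cumsum(kernel.T, axis=1)
    cum[:, -1] = 1.0  # guard against rounding
    n_samples = params.n_samples
    u = rng.random(n_samples - 1)
    levels = np.empty(n_samples, dtype=np.intp)
    levels[0] = 0
    state = 0
    for t in range(1, n_samples):
        state = int(np.searchsorted(cum[state], u[t - 1], side="right"))
        levels[t] = state
    return levels


def simulate_coupled_record(
    params: GatingParams, lowpass_hz: float | None = None
) -> tuple[ChannelRecord, np.ndarray]:
    """Simulate a noisy multi-channel record plus its true level sequence.

    value_t = level_t * amplitude + Gaussian noise.  Identical parameters
    (including ``seed``) reproduce identical output bit-for-bit.

    Parameters
    ----------
    lowpass_hz : float, optional
        If given, apply a first-order low-pass with this cut-off to the
        noisy trace (emulating analog filtering); off by default.
    """
    rng = np.random.default_rng(params.seed)
    levels = simulate_levels(params, rng)
    values = levels * params.amplitude
    if params.noise_sd > 0:
        values = values + rng.normal(0.0, params.noise_sd, size=values.size)
    if lowpass_hz is not None:
        values = lowpass_first_order(values, params.fs, lowpass_hz)
    units = "nM" if params.amplitude > 10 else "pA"
    rec = ChannelRecord(
        values=values, fs=params.fs, amplitude=params.amplitude, units=units
    )
    return rec, levels


def lowpass_first_order(x: np.ndarray, fs: float, cutoff_hz: float) -> np.ndarray:
    """Single-pole RC low-pass (forward pass only)."""
    if cutoff_hz <= 0:
        raise ValidationError("cutoff must be positive")
    alpha = 1.0 - np.exp(-2.0 * np.pi * cutoff_hz / fs)
    y = np.empty_like(np.asarray(x, dtype=float))
    acc = x[0]
    for i, xi in enumerate(x):
        acc += alpha * (xi - acc)
        y[i] = acc
    return y


def _gaussian_spot(shape: tuple[int, int], center: tuple[float, float], sigma: float) -> np.ndarray:
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    return np.exp(-(((rr - center[0]) ** 2 + (cc - center[1]) ** 2) / (2.0 * sigma**2)))


def simulate_sparklet_movie(
    sites: list[tuple[tuple[float, float], GatingParams]],
    frame_rate: float = 100.0,
    shape: tuple[int, int] = (40, 40),
    psf_sigma: float = 1.2,
    baseline: float = 100.0,
    noise_sd: float = 5.0,
    pixel_size: float = 200.0,
    n_frames: int | None = None,
    seed: int = 0,
) -> tuple[MovieStack, list[np.ndarray]]:
    """Simulate a calibrated ([Ca2+] in nM) sparklet movie.

    Each site contributes an isotropic 2-D Gaussian spot whose peak
    amplitude follows ``level_t * quantal amplitude`` with the level
    sequence drawn from that site's gating parameters.  Background is
    ``baseline`` plus i.i.d. Gaussian noise.

    Returns the movie and the list of ground-truth level sequences
    (one per site).
    """
    if psf_sigma <= 0:
        raise ValidationError("psf_sigma must be positive")
    for (r, c), _ in sites:
        if not (0 <= r < shape[0] and 0 <= c < shape[1]):
            raise ValidationError(f"site center {(r, c)} outside frame bounds {shape}")
    centers = [np.array(c) for c, _ in sites]
    for i in range(len(centers)):
        for j in range(i + 1, len(centers)):
            if np.linalg.norm(centers[i] - centers[j]) < 3.0 * psf_sigma:
                warnings.warn(
                    f"sites {i} and {j} closer than 3 x psf_sigma: "
                    "detection may be ambiguous",
                    stacklevel=2,
                )

    rng = np.random.default_rng(seed)
    if sites:
        durations = [p.n_samples for _, p in sites]
        nf = min(durations) if n_frames is None else n_frames
    else:
        nf = 200 if n_frames is None else n_frames

    truths: list[np.ndarray] = []
    frames = np.full((nf, *shape), baseline, dtype=float)
    for center, params in sites:
        site_rng = np.random.default_rng(params.seed)
        levels = simulate_levels(params, site_rng)[:nf]
        truths.append(levels)
        spot = _gaussian_spot(shape, center, psf_sigma)
        frames += levels[:, None, None] * params.amplitude * spot[None, :, :]
    if noise_sd > 0:
        frames += rng.normal(0.0, noise_sd, size=frames.shape)
    movie = MovieStack(
        frames=frames, frame_rate=frame_rate, pixel_size=pixel_size, units="nM"
    )
    return movie, truths


def simulate_photobleach_traces(
    n_spots: int,
    step_counts: np.ndarray | list[int] | None = None,
    step_count_mean: float = 8.0,
    step_amplitude: float = 100.0,
    bleach_rate: float = 0.002,
    n_frames: int = 2000,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, list[SpotTruth]]:
    """Simulate per-spot photobleaching intensity traces.

    Each spot starts at ``true_steps * step_amplitude`` and drops by one
    ``step_amplitude`` at each bleach time; per-fluorophore bleach times are
    geometric (constant per-frame bleach probability ``bleach_rate``),
    truncated to the movie so that every fluorophore bleaches within
    ``n_frames`` (noiseless traces end at 0).  Step counts are Poisson
    (shifted to >= 1) with mean ``step_count_mean`` unless given explicitly.

    Returns an (n_spots, n_frames) array of traces and the SpotTruth list.
    """
    if n_frames < 2:
        raise ValidationError("n_frames must be >= 2")
    if step_amplitude <= 0:
        raise ValidationError("step_amplitude must be positive")
    if not 0 < bleach_rate <= 1:
        raise ValidationError("bleach_rate must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    if step_counts is None:
        counts = 1 + rng.poisson(max(step_count_mean - 1.0, 0.0), size=n_spots)
    else:
        counts = np.asarray(step_counts, dtype=int)
        if counts.size != n_spots:
            raise ValidationError("step_counts length must equal n_spots")
        if np.any(counts < 0):
            raise ValidationError("step counts must be >= 0")

    traces = np.zeros((n_spots, n_frames))
    truths: list[SpotTruth] = []
    for s in range(n_spots):
        k = int(counts[s])
        times = rng.geometric(bleach_rate, size=k)
        times = np.minimum(times, n_frames - 1)
        # resolve collisions so bleach times are strictly increasing
        times = np.sort(times)
        for i in range(1, k):
            if times[i] <= times[i - 1]:
                times[i] = times[i - 1] + 1
        times = np.minimum(times, n_frames - 1)
        for i in range(k - 2, -1, -1):
            if times[i] >= times[i + 1]:
                times[i] = times[i + 1] - 1
        trace = np.full(n_frames, k * step_amplitude)
        for t in times:
            trace[t:] -= step_amplitude
        traces[s] = trace
        truths.append(
            SpotTruth(
                center=(0, 0),
                true_steps=k,
                step_amplitude=step_amplitude,
                bleach_times=[int(t) for t in times],
            )
        )
    if noise_sd > 0:
        traces = traces + rng.normal(0.0, noise_sd, size=traces.shape)
    return traces, truths


def simulate_photobleach_spots(
    n_spots: int = 9,
    shape: tuple[int, int] = (64, 64),
    psf_sigma: float = 1.2,
    step_count_mean: float = 8.0,
    step_amplitude: float = 100.0,
    bleach_rate: float = 0.002,
    n_frames: int = 2000,
    frame_rate: float = 30.0,
    noise_sd: float = 0.0,
    baseline: float = 10.0,
    pixel_size: float = 100.0,
    seed: int = 0,
) -> tuple[MovieStack, list[SpotTruth]]:
    """Simulate a photobleaching movie with spots on a margin-padded grid."""
    rng = np.random.default_rng(seed)
    margin = 8
    side = int(np.ceil(np.sqrt(n_spots)))
    rows = np.linspace(margin, shape[0] - margin - 1, side).round().astype(int)
    cols = np.linspace(margin, shape[1] - margin - 1, side).round().astype(int)
    centers = [(int(r), int(c)) for r in rows for c in cols][:n_spots]

    traces, truths = simulate_photobleach_traces(
        n_spots,
        step_count_mean=step_count_mean,
        step_amplitude=step_amplitude,
        bleach_rate=bleach_rate,
        n_frames=n_frames,
        noise_sd=0.0,
        seed=seed,
    )
    frames = np.full((n_frames, *shape), baseline, dtype=float)
    for (r, c), trace in zip(centers, traces):
        spot = _gaussian_spot(shape, (r, c), psf_sigma)
        frames += trace[:, None, None] * spot[None, :, :]
    if noise_sd > 0:
        frames += rng.normal(0.0, noise_sd, size=frames.shape)
    for truth, center in zip(truths, centers):
        truth.center = center
    movie = MovieStack(
        frames=frames, frame_rate=frame_rate, pixel_size=pixel_size, units="au"
    )
    return movie, truths


def simulate_decay_trace(spec: DecaySpec, seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Return (t, y) for a multi-exponential decay with optional noise."""
    n = int(round(spec.fs * spec.duration))
    t = np.arange(n) / spec.fs
    y = np.full(n, spec.offset, dtype=float)
    for a, tau in zip(spec.amplitudes, spec.taus):
        y += a * np.exp(-t / tau)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, spec.noise_sd, size=n)
    return t, y


def simulate_dose_response(
    v50: float,
    slope: float,
    floor: float = 0.0,
    ceiling: float = 100.0,
    levels: list[float] | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Boltzmann sigmoid dose-response table over a [Ca2+] perfusion series.

    response = floor + (ceiling - floor) / (1 + exp((v50 - x) / slope)).
    The default concentration series is the 9-step perfusion ladder
    (0 ... 5000 nM) used for the FRET [Ca2+] dependence.
    """
    if slope == 0:
        raise ValidationError("slope must be non-zero")
    if levels is None:
        levels = [0, 25, 50, 100, 200, 300, 400, 800, 5000]
    levels = list(levels)
    if not levels:
        raise ValidationError("levels must be non-empty")
    if any(x < 0 for x in levels):
        raise ValidationError("concentrations must be non-negative")
    x = np.asarray(levels, dtype=float)
    y = floor + (ceiling - floor) / (1.0 + np.exp((v50 - x) / slope))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, noise_sd, size=y.size)
    return pd.DataFrame({"ca_nM": x, "response": y})
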