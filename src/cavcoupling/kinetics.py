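"""Curve fitting and model computations for fluorescence/current kinetics.

Covers the decay-phase analyses of the pipeline: multi-exponential decays
(with T50%), Boltzmann sigmoids for dose-response and conductance-voltage
relationships, FRET ratios with spectral bleed-through correction, and the
paired-pulse facilitation model

    I2/I1(t) = R(t) * D(t),
    R(t) = 1 - exp(-t / tau_recovery)        (recovery from inactivation)
    D(t) = 1 + A * exp(-t / tau_decoupling)  (channel decoupling)

whose product peaks at an intermediate interpulse interval and tends to 1
as the interval grows (pure recovery, no residual coupling).  The ``+1``
offset in D is forced by the long-interval limit I2/I1 -> 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .core import ValidationError

__all__ = [
    "ExpFit",
    "BoltzmannFit",
    "FacilitationModel",
    "fit_multiexp",
    "t50",
    "fit_boltzmann",
    "conductance_curve",
    "fret_ratio",
    "fret_percent_change",
    "facilitation_curve",
    "fit_facilitation_amplitude",
]


@dataclass
class ExpFit:
    """Multi-exponential decay fit: offset + sum_i amp[i] * exp(-t/tau[i])."""

    amplitudes: np.ndarray
    taus: np.ndarray  # seconds, sorted ascending
    offset: float
    rss: float
    n_components: int
    converged: bool = True

    def __call__(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        y = np.full_like(t, self.offset)
        for a, tau in zip(self.amplitudes, self.taus):
            y += a * np.exp(-t / tau)
        return y


@dataclass
class BoltzmannFit:
    """Boltzmann sigmoid fit: floor + (ceiling-floor)/(1+exp((v50-x)/slope))."""

    v50: float
    slope: float
    floor: float
    ceiling: float
    rss: float
    degenerate: bool = False

    def __call__(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return self.floor + (self.ceiling - self.floor) / (
            1.0 + np.exp((self.v50 - x) / self.slope)
        )


@dataclass
class FacilitationModel:
    """Recovery x decoupling facilitation model parameters.

    Defaults are the time constants used in the facilitation simulation:
    recovery from inactivation 375 ms, channel decoupling 333 ms; the
    decoupling amplitude ``amp_decoupling`` is scaled to the facilitation
    data when fit.
    """

    tau_recovery: float = 0.375
    tau_decoupling: float = 0.333
    amp_decoupling: float = 2.5

    def __post_init__(self) -> None:
        if self.tau_recovery <= 0 or self.tau_decoupling <= 0:
            raise ValidationError("time constants must be positive")
        if self.amp_decoupling < 0:
            raise ValidationError("decoupling amplitude must be >= 0")


def _multiexp(t: np.ndarray, offset: float, amps: np.ndarray, taus: np.ndarray) -> np.ndarray:
    return offset + np.exp(-t[:, None] / taus[None, :]) @ amps


def _fit_amps_offset(
    t: np.ndarray, y: np.ndarray, taus: np.ndarray
) -> tuple[np.ndarray, float, float]:
    """Linear LS for amplitudes and offset at fixed taus (variable projection)."""
    X = np.column_stack([np.exp(-t[:, None] / taus[None, :]), np.ones_like(t)])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    amps, offset = coef[:-1], float(coef[-1])
    r = y - X @ coef
    return amps, offset, float(r @ r)


def fit_multiexp(
    t: np.ndarray,
    y: np.ndarray,
    n_components: int,
    n_starts: int = 20,
    seed: int = 0,
) -> ExpFit:
    """Fit a sum of decaying exponentials by multi-start nonlinear LS.

    tau starting points are log-spaced across the trace duration (from two
    sample intervals up to twice the duration), jittered across restarts;
    amplitudes and offset are profiled out linearly at each tau iterate
    (variable projection).  The best fit over all starts is returned, with
    taus sorted ascending.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if not 1 <= n_components <= 3:
        raise ValidationError("n_components must be 1, 2 or 3")
    if t.size != y.size:
        raise ValidationError("t and y must have equal length")
    if t.size < 5 * (2 * n_components + 1):
        raise ValidationError("trace too short for the requested component count")

    duration = float(t[-1] - t[0])
    dt = float(np.median(np.diff(t)))
    # taus are confined to what the trace can resolve: between half a sample
    # interval and twice the duration (beyond that an exponential is
    # indistinguishable from the offset)
    lo_b, hi_b = np.log(max(0.5 * dt, 1e-12)), np.log(2 * duration)
    lo, hi = np.log(max(2 * dt, 1e-9)), np.log(duration)
    rng = np.random.default_rng(seed)

    def nll_logtau(logtau: np.ndarray) -> float:
        taus = np.exp(np.clip(logtau, lo_b, hi_b))
        _, _, rss = _fit_amps_offset(t, y, taus)
        return rss

    best = None
    for s in range(n_starts):
        base = np.linspace(lo, hi, n_components + 2)[1:-1]
        jitter = rng.uniform(-0.5, 0.5, n_components) if s > 0 else 0.0
        x0 = base + jitter
        res = optimize.minimize(
            nll_logtau,
            x0=x0,
            method="Nelder-Mead",
            options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 2000},
        )
        if best is None or res.fun < best.fun:
            best = res
    logtau = np.clip(best.x, lo_b, hi_b)
    taus = np.exp(logtau)
    amps, offset, rss = _fit_amps_offset(t, y, taus)

    # joint bounded least-squares polish from the multi-start solution
    def resid(theta: np.ndarray) -> np.ndarray:
        a = theta[:n_components]
        lt = theta[n_components : 2 * n_components]
        off = theta[-1]
        return off + np.exp(-t[:, None] / np.exp(lt)[None, :]) @ a - y

    theta0 = np.concatenate([amps, logtau, [offset]])
    bounds = (
        np.concatenate([np.full(n_components, -np.inf), np.full(n_components, lo_b), [-np.inf]]),
        np.concatenate([np.full(n_components, np.inf), np.full(n_components, hi_b), [np.inf]]),
    )
    ls = optimize.least_squares(resid, theta0, bounds=bounds, xtol=1e-14, ftol=1e-14)
    if 2 * ls.cost < rss:
        amps = ls.x[:n_components]
        taus = np.exp(ls.x[n_components : 2 * n_components])
        offset = float(ls.x[-1])
        rss = float(2 * ls.cost)

    order = np.argsort(taus)
    return ExpFit(
        amplitudes=amps[order],
        taus=taus[order],
        offset=offset,
        rss=rss,
        n_components=n_components,
        converged=bool(best.success or rss <= best.fun * (1 + 1e-12)),
    )


def t50(t: np.ndarray, y: np.ndarray) -> float:
    """Time after the peak to decay to 50% of (peak - final baseline).

    The final baseline is the mean of the last 5% of samples; the crossing
    is located by linear interpolation between the bracketing samples.
    Returns NaN when the trace never crosses half-peak.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    i_peak = int(np.argmax(y))
    tail = y[max(y.size - max(y.size // 20, 1), i_peak + 1) :]
    baseline = float(np.mean(tail)) if tail.size else float(y[-1])
    span = y[i_peak] - baseline
    if span <= 0 or not np.isfinite(span):
        return float("nan")  # no decay to measure
    half = baseline + 0.5 * span
    yy = y[i_peak:]
    below = np.nonzero(yy <= half)[0]
    if below.size == 0:
        return float("nan")
    j = int(below[0])
    if j == 0:
        return 0.0
    t0, t1 = t[i_peak + j - 1], t[i_peak + j]
    y0, y1 = yy[j - 1], yy[j]
    frac = (y0 - half) / (y0 - y1)
    return float(t0 + frac * (t1 - t0) - t[i_peak])


def fit_boltzmann(x: np.ndarray, y: np.ndarray) -> BoltzmannFit:
    """Least-squares Boltzmann sigmoid fit.

    Flags (rather than fails on) degenerate monotone-flat data, where the
    midpoint is not identified within the sampled range.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 5:
        raise ValidationError("need at least 5 points spanning the transition")
    y_span = float(y.max() - y.min())
    if y_span <= 0:
        return BoltzmannFit(
            v50=float("nan"), slope=float("nan"), floor=float(y.min()),
            ceiling=float(y.max()), rss=0.0, degenerate=True,
        )

    def model(x, v50, slope, floor, ceiling):
        return floor + (ceiling - floor) / (1.0 + np.exp((v50 - x) / slope))

    # midpoint guess: x at the half-range crossing
    order = np.argsort(x)
    xs, ys = x[order], y[order]
    half = y.min() + 0.5 * y_span
    idx = int(np.argmin(np.abs(ys - half)))
    x_scale = float(xs[-1] - xs[0]) or 1.0
    p0 = [float(xs[idx]), 0.1 * x_scale, float(y.min()), float(y.max())]
    try:
        popt, _ = optimize.curve_fit(model, x, y, p0=p0, maxfev=20000)
    except RuntimeError:
        # retry with the opposite orientation (decreasing sigmoid)
        p0[1] = -p0[1]
        popt, _ = optimize.curve_fit(model, x, y, p0=p0, maxfev=20000)
    v50, slope, floor, ceiling = (float(v) for v in popt)
    if floor > ceiling:
        floor, ceiling, slope = ceiling, floor, -slope
    r = y - model(x, v50, slope, floor, ceiling)
    rss = float(r @ r)
    degenerate = not (xs[0] <= v50 <= xs[-1])
    return BoltzmannFit(
        v50=v50, slope=slope, floor=floor, ceiling=ceiling, rss=rss,
        degenerate=degenerate,
    )


def conductance_curve(
    iv: np.ndarray | list[tuple[float, float]],
    v_rev: float,
    normalize: bool = True,
) -> np.ndarray:
    """Convert an I-V relationship to (normalized) conductance.

    G(V) = I / (V - v_rev); when ``normalize`` the result is divided by
    max |G|.  Returns an array of shape (n, 2) with columns (V, G).
    Raises when any test potential equals the reversal potential; flags
    all-zero currents (normalization undefined) with a ValidationError.
    """
    iv = np.asarray(iv, dtype=float)
    if iv.ndim != 2 or iv.shape[1] != 2:
        raise ValidationError("iv must be an (n, 2) array of (V, I)")
    V, I = iv[:, 0], iv[:, 1]
    if np.any(V == v_rev):
        raise ValidationError("test potential equals reversal potential")
    G = I / (V - v_rev)
    if normalize:
        gmax = np.max(np.abs(G))
        if gmax == 0:
            raise ValidationError("all conductances are zero; cannot normalize")
        G = G / gmax
    return np.column_stack([V, G])


def fret_ratio(
    rfp_raw: np.ndarray,
    gfp_raw: np.ndarray,
    bleedthrough: float = 0.16,
    background_r: float = 0.0,
    background_g: float = 0.0,
) -> np.ndarray:
    """Bleed-through-corrected FRET ratio FRETr = RFPg / GFPg.

    RFPg = rfp_raw - background_r - bleedthrough * (gfp_raw - background_g);
    GFPg = gfp_raw - background_g.  The default donor->acceptor bleed-through
    is 16%.  Raises when GFPg is non-positive anywhere.
    """
    rfp = np.asarray(rfp_raw, dtype=float)
    gfp = np.asarray(gfp_raw, dtype=float)
    gfp_g = gfp - background_g
    if np.any(gfp_g <= 0):
        bad = int(np.nonzero(gfp_g <= 0)[0][0])
        raise ValidationError(
            f"non-positive donor signal after background subtraction at sample {bad}"
        )
    rfp_g = rfp - background_r - bleedthrough * gfp_g
    return rfp_g / gfp_g


def fret_percent_change(fretr: np.ndarray, n_baseline: int) -> np.ndarray:
    """Percent change of FRETr relative to the pre-stimulus mean."""
    fretr = np.asarray(fretr, dtype=float)
    if not 0 < n_baseline <= fretr.size:
        raise ValidationError("n_baseline must address a non-empty prefix")
    f0 = float(np.mean(fretr[:n_baseline]))
    if f0 == 0:
        raise ValidationError("pre-stimulus FRETr mean is zero")
    return 100.0 * (fretr - f0) / f0


def facilitation_curve(
    model: FacilitationModel, intervals: np.ndarray | list[float]
) -> np.ndarray:
    """Paired-pulse facilitation ratio I2/I1 at the given interpulse intervals.

    I2/I1(t) = (1 - exp(-t/tau_recovery)) * (1 + A * exp(-t/tau_decoupling)).
    Returns shape (n, 2) with columns (interval_s, ratio).
    """
    t = np.asarray(intervals, dtype=float)
    if np.any(t <= 0):
        raise ValidationError("intervals must be positive")
    R = 1.0 - np.exp(-t / model.tau_recovery)
    D = 1.0 + model.amp_decoupling * np.exp(-t / model.tau_decoupling)
    return np.column_stack([t, R * D])


def fit_facilitation_amplitude(
    intervals: np.ndarray,
    ratios: np.ndarray,
    tau_recovery: float = 0.375,
    tau_decoupling: float = 0.333,
) -> FacilitationModel:
    """Scale the decoupling amplitude to facilitation data at fixed taus.

    Linear least squares: with R and E = exp(-t/tau_decoupling) known,
    I2/I1 = R + A * R * E.
    """
    t = np.asarray(intervals, dtype=float)
    y = np.asarray(ratios, dtype=float)
    R = 1.0 - np.exp(-t / tau_recovery)
    E = np.exp(-t / tau_decoupling)
    denom = float(np.sum((R * E) ** 2))
    if denom == 0:
        raise ValidationError("degenerate design: cannot scale decoupling amplitude")
    A = float(np.sum((y - R) * R * E) / denom)
    return FacilitationModel(
        tau_recovery=tau_recovery,
        tau_decoupling=tau_decoupling,
        amp_decoupling=max(A, 0.0),
    )
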