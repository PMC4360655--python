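"""Trace idealization and quantal analysis.

Converts raw current/fluorescence traces into integer occupancy sequences
and activity statistics:

* all-points amplitude histograms, whose equally spaced peaks reveal
  simultaneous channel openings;
* constrained Gaussian-mixture fits of the quantal structure — component
  means are restricted to ``baseline + k * q`` with a shared component SD,
  making the quantal unit ``q`` (single-channel current or elementary
  sparklet amplitude) a single identifiable parameter; the number of levels
  is chosen by BIC;
* multi-level half-amplitude idealization (thresholds halfway between
  adjacent quantal levels);
* time-averaged activity, nPo / nPs = mean occupancy level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import ActivityStat, ChannelRecord, ValidationError

__all__ = [
    "QuantalFit",
    "all_points_histogram",
    "fit_quantal_mixture",
    "idealize_record",
    "compute_activity",
    "estimate_baseline",
]


@dataclass
class QuantalFit:
    """Equal-spacing Gaussian mixture fit of an amplitude distribution.

    Component means are ``baseline_mu + k * q`` for ``k = 0..n_levels``
    (``n_levels + 1`` components, shared SD ``sigma``).  ``n_levels = 0``
    means a single Gaussian fit the data best, in which case the quantal
    spacing is unidentifiable and ``q_identifiable`` is False (q is NaN).
    """

    baseline_mu: float
    q: float
    sigma: float
    weights: np.ndarray
    n_levels: int
    bic: float
    loglik: float
    converged: bool = True
    q_identifiable: bool = True

    @property
    def means(self) -> np.ndarray:
        if self.n_levels == 0:
            return np.array([self.baseline_mu])
        return self.baseline_mu + self.q * np.arange(self.n_levels + 1)


def all_points_histogram(
    record: ChannelRecord | np.ndarray, bin_width: float
) -> tuple[np.ndarray, np.ndarray]:
    """All-points histogram: every sample counted exactly once.

    Returns (bin_edges, counts) with ``counts.sum() == n_samples``.
    """
    values = record.values if isinstance(record, ChannelRecord) else np.asarray(record)
    if values.size == 0:
        raise ValidationError("empty record")
    if bin_width <= 0:
        raise ValidationError("bin_width must be positive")
    lo = np.floor(values.min() / bin_width) * bin_width
    hi = np.ceil(values.max() / bin_width) * bin_width
    if hi <= lo:
        hi = lo + bin_width
    n_bins = int(round((hi - lo) / bin_width))
    edges = lo + bin_width * np.arange(n_bins + 1)
    # make the top edge inclusive so the maximum sample is counted
    counts, _ = np.histogram(values, bins=edges)
    return edges, counts.astype(np.int64)


def estimate_baseline(values: np.ndarray, bin_width: float | None = None) -> float:
    """Baseline estimate: mode of the lowest (leftmost) histogram peak.

    The all-points histogram of a quantal record has a peak per occupancy
    level; the baseline is the leftmost one, which need not be the tallest
    (high-activity records spend more time above baseline).  Peaks are
    local maxima of the lightly smoothed histogram with prominence at
    least 5% of the tallest; falls back to the global mode when no peak
    qualifies.
    """
    from scipy.ndimage import gaussian_filter1d
    from scipy.signal import find_peaks

    values = np.asarray(values, dtype=float)
    if bin_width is None:
        spread = np.subtract(*np.percentile(values, [97.5, 2.5]))
        bin_width = max(spread / 100.0, 1e-12)
    edges, counts = all_points_histogram(values, bin_width)
    centers = 0.5 * (edges[:-1] + edges[1:])
    smooth = gaussian_filter1d(counts.astype(float), sigma=2.0)
    peaks, _ = find_peaks(smooth, prominence=0.05 * smooth.max())
    if peaks.size:
        return float(centers[peaks[0]])
    return float(centers[int(np.argmax(counts))])


def _em_fit(
    x: np.ndarray,
    n_levels: int,
    mu0: float,
    q0: float,
    sigma0: float,
    weights: np.ndarray | None = None,
    max_iter: int = 200,
    tol: float = 1e-8,
) -> tuple[float, float, float, np.ndarray, float, bool]:
    """EM for a shared-sigma mixture with means mu0 + k*q, k = 0..n_levels.

    ``weights`` lets the EM run on binned data (x = bin centers, weights =
    bin counts); sums become weighted sums and the total weight plays the
    role of the sample size.
    """
    ks = np.arange(n_levels + 1, dtype=float)
    wt = np.ones_like(x) if weights is None else np.asarray(weights, dtype=float)
    n = float(wt.sum())
    mu, q, sigma = mu0, q0, max(sigma0, 1e-12)
    w = np.full(n_levels + 1, 1.0 / (n_levels + 1))
    ll_old = -np.inf
    converged = False
    for _ in range(max_iter):
        means = mu + q * ks
        # E step
        z = -0.5 * ((x[:, None] - means[None, :]) / sigma) ** 2
        z += np.log(np.maximum(w, 1e-300)) - np.log(sigma) - 0.5 * np.log(2 * np.pi)
        zmax = z.max(axis=1, keepdims=True)
        p = np.exp(z - zmax)
        norm = p.sum(axis=1, keepdims=True)
        ll = float(np.sum(wt * (np.log(norm[:, 0]) + zmax[:, 0])))
        r = (p / norm) * wt[:, None]
        # M step
        rk = r.sum(axis=0)
        w = rk / n
        # weighted least squares for (mu, q): minimize sum r_ik (x_i - mu - k q)^2
        s_r = float(rk.sum())
        s_k = float(np.dot(rk, ks))
        s_kk = float(np.dot(rk, ks**2))
        s_x = float(np.sum(r * x[:, None]))
        s_kx = float(np.sum(r * (ks[None, :] * x[:, None])))
        det = s_r * s_kk - s_k**2
        if n_levels > 0 and det > 1e-12 * max(s_r * s_kk, 1.0):
            mu = (s_x * s_kk - s_kx * s_k) / det
            q = (s_r * s_kx - s_k * s_x) / det
        else:
            mu = s_x / s_r
            q = 0.0
        means = mu + q * ks
        var = float(np.sum(r * (x[:, None] - means[None, :]) ** 2) / n)
        sigma = max(np.sqrt(var), 1e-12)
        if abs(ll - ll_old) < tol * (1.0 + abs(ll)):
            converged = True
            ll_old = ll
            break
        ll_old = ll
    return mu, q, sigma, w, ll_old, converged


def fit_quantal_mixture(
    record: ChannelRecord | np.ndarray,
    max_levels: int = 5,
    q_init: float | None = None,
) -> QuantalFit:
    """Fit equal-spacing Gaussian mixtures and select the level count by BIC.

    Candidate models have ``n_levels + 1`` components at ``baseline + k*q``
    for ``n_levels = 0..max_levels``; each is fit by EM from several
    spacing initializations, and the minimum-BIC model is returned.

    Raises a ValidationError when no candidate converges.
    """
    if max_levels < 1:
        raise ValidationError("max_levels must be >= 1")
    x = record.values if isinstance(record, ChannelRecord) else np.asarray(record, float)
    if x.size < 20:
        raise ValidationError("need at least 20 samples for a quantal fit")

    mu0 = estimate_baseline(x)
    span = float(x.max() - mu0)
    sigma_glob = float(np.std(x))

    # bin the samples so EM cost is independent of record length; the bin
    # width is far below any resolvable quantal spacing
    bw = max(sigma_glob / 20.0, (x.max() - x.min()) / 2000.0, 1e-12)
    edges, counts = all_points_histogram(x, bw)
    centers = 0.5 * (edges[:-1] + edges[1:])
    nz = counts > 0
    xb, wb = centers[nz], counts[nz].astype(float)
    n_tot = float(wb.sum())

    best: QuantalFit | None = None
    any_converged = False
    for L in range(0, max_levels + 1):
        if L == 0:
            mu = float(np.mean(x))
            sigma = max(float(np.std(x)), 1e-12)
            ll = float(
                np.sum(wb * (-0.5 * ((xb - mu) / sigma) ** 2 - np.log(sigma) - 0.5 * np.log(2 * np.pi)))
            )
            k_params = 2  # mu, sigma
            bic = -2 * ll + k_params * np.log(n_tot)
            fit = QuantalFit(
                baseline_mu=mu,
                q=float("nan"),
                sigma=sigma,
                weights=np.array([1.0]),
                n_levels=0,
                bic=bic,
                loglik=ll,
                q_identifiable=False,
            )
            any_converged = True
        else:
            q_seeds = []
            if q_init is not None:
                q_seeds.append(q_init)
            if span > 0:
                q_seeds.extend([span / L, span / (L + 1), 0.5 * span / L])
            q_seeds = [q for q in q_seeds if q > 0] or [max(sigma_glob, 1e-6)]
            cand = None
            for q0 in q_seeds:
                mu, q, sigma, w, ll, conv = _em_fit(
                    xb, L, mu0, q0, sigma0=max(0.25 * q0, 1e-9), weights=wb
                )
                if cand is None or ll > cand[4]:
                    cand = (mu, q, sigma, w, ll, conv)
            mu, q, sigma, w, ll, conv = cand
            # free params: mu, q, sigma, L mixture weights
            k_params = 3 + L
            bic = -2 * ll + k_params * np.log(n_tot)
            identifiable = q > 3.0 * sigma / np.sqrt(n_tot) and q > 0
            fit = QuantalFit(
                baseline_mu=mu,
                q=float(q) if identifiable else float("nan"),
                sigma=sigma,
                weights=w,
                n_levels=L,
                bic=bic,
                loglik=ll,
                converged=conv,
                q_identifiable=bool(identifiable),
            )
            any_converged = any_converged or conv
        if best is None or fit.bic < best.bic:
            best = fit
    if not any_converged:
        raise ValidationError("quantal mixture fit failed to converge for all level counts")
    return best


def idealize_record(
    record: ChannelRecord | np.ndarray,
    amplitude: float | None = None,
    baseline: float = 0.0,
    n_max: int | None = None,
    hysteresis: float = 0.0,
) -> np.ndarray:
    """Half-amplitude idealization: nearest quantal level per sample.

    ``level_t = round((value_t - baseline) / amplitude)`` clipped to
    ``[0, n_max]`` — equivalent to thresholds at ``baseline + (k - 1/2) *
    amplitude``.

    With ``hysteresis > 0`` the idealization becomes a Schmitt trigger:
    the level changes only when the signal moves further than
    ``hysteresis * amplitude`` from the current level's mean, in which case
    it jumps to the nearest level.  A guard band wider than half an
    amplitude (0.75 works well at noise SD = 0.2 x amplitude) suppresses
    single-sample noise glitches without delaying genuine transitions,
    whose excursions are at least one full amplitude.  ``hysteresis = 0``
    is plain nearest-level rounding.
    """
    if isinstance(record, ChannelRecord):
        values = record.values
        if amplitude is None:
            amplitude = record.amplitude
    else:
        values = np.asarray(record, dtype=float)
    if amplitude is None or amplitude <= 0:
        raise ValidationError("amplitude must be positive")
    levels = np.rint((values - baseline) / amplitude).astype(np.intp)
    levels = np.clip(levels, 0, None)
    if n_max is not None:
        levels = np.clip(levels, 0, n_max)
    if hysteresis > 0:
        if hysteresis < 0.5:
            raise ValidationError("hysteresis below 0.5 cannot latch a level")
        guard = hysteresis * amplitude
        out = np.empty_like(levels)
        cur = int(levels[0])
        out[0] = cur
        centers = baseline + amplitude * np.arange(
            (n_max if n_max is not None else int(levels.max())) + 1
        )
        for i in range(1, levels.size):
            if abs(values[i] - centers[cur]) > guard:
                cur = int(levels[i])
            out[i] = cur
        return out
    return levels


def deglitch_levels(levels: np.ndarray, width: int = 3) -> np.ndarray:
    """Median-filter an idealized level sequence to remove 1-sample glitches.

    Noise on the raw trace occasionally flips a single sample across the
    half-amplitude threshold; such one-sample excursions are artifacts of
    idealization, not gating, and bias downstream transition statistics
    (they mimic independent-channel transitions).  A short median filter —
    the discrete counterpart of imposing a minimum event duration — removes
    them while leaving dwells longer than ``width // 2`` samples intact.
    """
    levels = np.asarray(levels)
    if width < 3 or width % 2 == 0:
        raise ValidationError("width must be an odd integer >= 3")
    from scipy.ndimage import median_filter

    return median_filter(levels, size=width, mode="nearest")


def compute_activity(levels: np.ndarray, fs: float | None = None) -> ActivityStat:
    """Time-averaged activity nPo (or nPs for sparklet sites).

    For exchangeable channels the mean occupancy equals n * Po; for sparklet
    sites the same time average over quantal levels gives nPs.
    """
    levels = np.asarray(levels)
    if levels.size == 0:
        raise ValidationError("empty level sequence")
    value = float(np.mean(levels))
    total_time = levels.size / fs if fs else float(levels.size)
    return ActivityStat(
        value=value,
        n_levels_observed=int(levels.max()),
        total_time=float(total_time),
    )
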