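"""Movie-domain analyses.

F/F0 calibration, indicator-fluorescence -> [Ca2+] conversion, sparklet site
detection, the photobleaching preprocessing / step-counting chain, and
binary-mask cluster areas.

Coordinate convention: arrays are (frame, row, col), 0-based, pixel centers
at integer coordinates.  Pixel sizes are in nm; cluster areas in nm^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import measure, morphology, restoration
from skimage.filters import difference_of_gaussians

from .core import ActivityStat, MovieStack, ValidationError
from .idealize import compute_activity, fit_quantal_mixture, idealize_record

__all__ = [
    "SparkletSite",
    "BleachSpot",
    "ClusterSet",
    "calibrate_ff0",
    "fluo_to_ca",
    "ca_to_fluo",
    "detect_sparklet_sites",
    "extract_bleach_spots",
    "count_bleach_steps",
    "smooth_bleach_trace",
    "cluster_areas",
]

#: Rhod-2 calibration constants used when converting fluorescence to [Ca2+]:
#: literature-typical in-cell dissociation constant (nM) and dynamic range
#: (Fmax/Fmin).  Required configuration for real data; override per run.
RHOD2_KD_NM = 570.0
RHOD2_RF = 100.0


@dataclass
class SparkletSite:
    """A detected Ca2+ sparklet site with its calibrated trace and activity."""

    center: tuple[int, int]
    trace: np.ndarray  # nM
    nps: ActivityStat
    n_quantal_levels: int


@dataclass
class BleachSpot:
    """A photobleaching spot: 4x4-pixel ROI and its intensity time course."""

    center: tuple[int, int]
    roi: tuple[slice, slice]
    raw_trace: np.ndarray
    smoothed_trace: np.ndarray | None = None
    counted_steps: int | None = None


@dataclass
class ClusterSet:
    """Connected-component cluster areas from a binary mask."""

    labels: np.ndarray
    areas: np.ndarray  # nm^2
    pixel_size: float  # nm
    touches_border: np.ndarray = field(default_factory=lambda: np.array([], bool))


# ---------------------------------------------------------------------------
# calibration


def calibrate_ff0(
    stack: MovieStack,
    baseline: np.ndarray | None = None,
    baseline_frames: int | None = None,
    median_radius: int = 1,
) -> MovieStack:
    """Median-filter each frame and divide by a baseline image (F/F0).

    The baseline is either an explicit image or the mean of the first
    ``baseline_frames`` frames; it receives the same median filter.  Zero or
    negative baseline pixels are reported with their coordinates.
    """
    if baseline is None:
        if baseline_frames is None or baseline_frames < 1:
            raise ValidationError("provide a baseline image or baseline_frames >= 1")
        baseline = stack.frames[:baseline_frames].mean(axis=0)
    baseline = np.asarray(baseline, dtype=float)
    footprint = morphology.disk(median_radius)
    base_f = ndimage.median_filter(baseline, footprint=footprint)
    bad = np.argwhere(base_f <= 0)
    if bad.size:
        coords = ", ".join(f"({r}, {c})" for r, c in bad[:5])
        raise ValidationError(
            f"{len(bad)} non-positive baseline pixels after filtering, e.g. {coords}"
        )
    out = np.empty_like(stack.frames, dtype=float)
    for i, frame in enumerate(stack.frames):
        out[i] = ndimage.median_filter(np.asarray(frame, float), footprint=footprint) / base_f
    return MovieStack(
        frames=out, frame_rate=stack.frame_rate, pixel_size=stack.pixel_size, units=""
    )


def fluo_to_ca(
    F: np.ndarray | float,
    f_max: float,
    k_d: float = RHOD2_KD_NM,
    r_f: float = RHOD2_RF,
) -> np.ndarray | float:
    """Convert single-wavelength indicator fluorescence to [Ca2+] (nM).

    The Fmax equation:  [Ca2+] = Kd * (F/Fmax - 1/Rf) / (1 - F/Fmax),
    where Rf is the indicator dynamic range (Fmax/Fmin).  Monotone
    increasing in F on its domain 1/Rf <= F/Fmax < 1.
    """
    ratio = np.asarray(F, dtype=float) / f_max
    if np.any(ratio >= 1.0):
        raise ValidationError("fluorescence at or above Fmax: indicator saturated")
    if np.any(ratio < 1.0 / r_f):
        raise ValidationError("fluorescence below Fmax/Rf: outside indicator range")
    ca = k_d * (ratio - 1.0 / r_f) / (1.0 - ratio)
    return float(ca) if np.isscalar(F) else ca


def ca_to_fluo(
    ca: np.ndarray | float,
    f_max: float,
    k_d: float = RHOD2_KD_NM,
    r_f: float = RHOD2_RF,
) -> np.ndarray | float:
    """Inverse of :func:`fluo_to_ca` (algebraic)."""
    ca_arr = np.asarray(ca, dtype=float)
    ratio = (ca_arr + k_d / r_f) / (ca_arr + k_d)
    out = ratio * f_max
    return float(out) if np.isscalar(ca) else out


# ---------------------------------------------------------------------------
# sparklet detection


def detect_sparklet_sites(
    ca_stack: MovieStack,
    detect_sd: float = 3.0,
    min_event_frames: int = 3,
    quantal_amplitude: float = 38.0,
    merge_radius: int = 3,
) -> list[SparkletSite]:
    """Detect sparklet sites in a [Ca2+]-calibrated movie.

    A pixel is a candidate when its signal exceeds (per-pixel baseline
    median + ``detect_sd`` robust SD) for at least ``min_event_frames``
    consecutive frames.  Candidates are grouped by greedy local-maximum
    selection within ``merge_radius`` pixels; each site's trace is the 3x3
    neighborhood average around the center, idealized at the quantal
    amplitude (default 38 nM, the elementary sparklet event) to produce nPs.
    """
    if ca_stack.units != "nM":
        raise ValidationError("stack must be calibrated to nM before detection")
    frames = np.asarray(ca_stack.frames, dtype=float)
    nf, nr, nc = frames.shape

    # quiescent statistics per pixel: the 20th percentile is robust to
    # sites active much of the movie, and for Gaussian noise sits 0.8416
    # SD below the quiescent mean; the noise SD comes from first
    # differences (robust to occupancy-level changes)
    p20 = np.percentile(frames, 20, axis=0)
    dmad = np.median(np.abs(np.diff(frames, axis=0)), axis=0)
    sd = np.maximum(1.4826 * dmad / np.sqrt(2.0), 1e-6)
    base = p20 + 0.8416 * sd
    above = frames > (base + detect_sd * sd)[None]

    # longest run of consecutive suprathreshold frames per pixel
    run = np.zeros((nr, nc), dtype=np.int32)
    best_run = np.zeros((nr, nc), dtype=np.int32)
    for t in range(nf):
        run = np.where(above[t], run + 1, 0)
        np.maximum(best_run, run, out=best_run)
    candidate = best_run >= min_event_frames
    if not candidate.any():
        return []

    # greedy local-maximum grouping: strongest candidate first, suppress
    # neighbors within merge_radius
    score = np.where(candidate, (frames - base[None]).max(axis=0), -np.inf)
    centers: list[tuple[int, int]] = []
    score_work = score.copy()
    while np.isfinite(score_work).any() and score_work.max() > -np.inf:
        r, c = np.unravel_index(int(np.argmax(score_work)), score_work.shape)
        if not np.isfinite(score_work[r, c]):
            break
        centers.append((int(r), int(c)))
        r0, r1 = max(r - merge_radius, 0), min(r + merge_radius + 1, nr)
        c0, c1 = max(c - merge_radius, 0), min(c + merge_radius + 1, nc)
        score_work[r0:r1, c0:c1] = -np.inf

    sites: list[SparkletSite] = []
    for r, c in centers:
        r0, r1 = max(r - 1, 0), min(r + 2, nr)
        c0, c1 = max(c - 1, 0), min(c + 2, nc)
        trace = frames[:, r0:r1, c0:c1].mean(axis=(1, 2))
        # the 3x3 spatial average attenuates the quantal amplitude by the
        # PSF shape, so re-estimate the effective per-site quantal spacing
        # from the trace itself; fall back to the nominal amplitude when
        # too few events make the spacing unidentifiable
        local_base = float(np.median(trace))
        q_eff = quantal_amplitude
        try:
            qfit = fit_quantal_mixture(trace, max_levels=5)
            if qfit.q_identifiable and 0.3 * quantal_amplitude <= qfit.q <= 1.5 * quantal_amplitude:
                q_eff = float(qfit.q)
                local_base = float(qfit.baseline_mu)
        except ValidationError:
            pass
        levels = idealize_record(trace, amplitude=q_eff, baseline=local_base)
        nps = compute_activity(levels, fs=ca_stack.frame_rate)
        sites.append(
            SparkletSite(
                center=(r, c),
                trace=trace,
                nps=nps,
                n_quantal_levels=int(levels.max()),
            )
        )
    return sites


# ---------------------------------------------------------------------------
# photobleaching


def extract_bleach_spots(
    stack: MovieStack,
    rolling_ball_radius: int = 50,
    low_sigma: float = 2.0,
    high_sigma: float = 5.0,
    threshold_sd: float = 3.0,
    min_area: int = 4,
) -> list[BleachSpot]:
    """Locate photobleaching spots and extract 4x4-pixel ROI traces.

    Reference image = mean of the first 5 frames -> rolling-ball background
    subtraction -> band-pass (difference of Gaussians with 2- and 5-pixel
    sigmas, realizing the stated low-/high-pass pixel cut-offs) -> threshold
    at mean + ``threshold_sd`` SD -> connected regions -> 4x4 ROI centered
    on each region's peak pixel.  Each ROI trace is the ROI *sum* per frame.

    An image with no suprathreshold regions yields an empty list.
    """
    if stack.n_frames < 5:
        raise ValidationError("need at least 5 frames for the reference image")
    ref = np.asarray(stack.frames[:5], dtype=float).mean(axis=0)
    background = restoration.rolling_ball(ref, radius=rolling_ball_radius)
    ref_bs = ref - background
    band = difference_of_gaussians(ref_bs, low_sigma, high_sigma)
    thr = band.mean() + threshold_sd * band.std()
    mask = band > thr
    labels = measure.label(mask, connectivity=2)
    spots: list[BleachSpot] = []
    nr, nc = ref.shape
    for region in measure.regionprops(labels, intensity_image=ref_bs):
        if region.area < min_area:
            continue
        rr, cc = region.coords[:, 0], region.coords[:, 1]
        peak = int(np.argmax(ref_bs[rr, cc]))
        r, c = int(rr[peak]), int(cc[peak])
        # 4x4 ROI centered on the peak pixel: rows r-1..r+2, cols c-1..c+2
        r0 = int(np.clip(r - 1, 0, nr - 4))
        c0 = int(np.clip(c - 1, 0, nc - 4))
        roi = (slice(r0, r0 + 4), slice(c0, c0 + 4))
        trace = np.asarray(stack.frames[:, roi[0], roi[1]], dtype=float).sum(axis=(1, 2))
        spots.append(BleachSpot(center=(r, c), roi=roi, raw_trace=trace))
    return spots


def smooth_bleach_trace(trace: np.ndarray, moving_average: int = 10) -> np.ndarray:
    """Step-preserving smoothing chain for a bleach-spot trace.

    Median filter (width 3, the 1-D counterpart of a 1-pixel-radius median)
    followed by a ``moving_average``-frame moving average.  (The rolling-ball
    background subtraction of the published chain acts on the image, where it
    is applied by :func:`extract_bleach_spots`; applied to a decreasing
    staircase trace it would remove the steps themselves.)
    """
    x = ndimage.median_filter(np.asarray(trace, dtype=float), size=3)
    kernel = np.ones(moving_average) / moving_average
    # reflective padding keeps the trace length and avoids edge ramps
    pad = moving_average
    xp = np.pad(x, pad, mode="edge")
    sm = np.convolve(xp, kernel, mode="same")[pad:-pad]
    return sm


def _greedy_steps(
    y: np.ndarray, min_seg: int, threshold: float
) -> list[int]:
    """Greedy change-point insertion on a piecewise-constant model.

    Repeatedly inserts the breakpoint giving the largest residual
    sum-of-squares reduction, while the best reduction exceeds
    ``threshold``; breakpoints keep every segment at least ``min_seg``
    samples long.
    """
    n = y.size
    cs = np.concatenate([[0.0], np.cumsum(y)])
    cs2 = np.concatenate([[0.0], np.cumsum(y * y)])

    def seg_rss(a: int, b: int) -> float:
        # RSS of samples a..b-1 around their mean
        s, s2, m = cs[b] - cs[a], cs2[b] - cs2[a], b - a
        return float(s2 - s * s / m)

    def best_split(a: int, b: int) -> tuple[float, int]:
        if b - a < 2 * min_seg:
            return 0.0, -1
        total = seg_rss(a, b)
        cuts = np.arange(a + min_seg, b - min_seg + 1)
        s_left = cs[cuts] - cs[a]
        s2_left = cs2[cuts] - cs2[a]
        m_left = cuts - a
        s_right = cs[b] - cs[cuts]
        s2_right = cs2[b] - cs2[cuts]
        m_right = b - cuts
        rss = (s2_left - s_left**2 / m_left) + (s2_right - s_right**2 / m_right)
        i = int(np.argmin(rss))
        return total - float(rss[i]), int(cuts[i])

    breakpoints: list[int] = []
    segments: dict[tuple[int, int], tuple[float, int]] = {(0, n): best_split(0, n)}
    while True:
        (a, b), (gain, cut) = max(segments.items(), key=lambda kv: kv[1][0])
        if cut < 0 or gain <= threshold:
            break
        del segments[(a, b)]
        segments[(a, cut)] = best_split(a, cut)
        segments[(cut, b)] = best_split(cut, b)
        breakpoints.append(cut)
    return sorted(breakpoints)


def count_bleach_steps(
    trace: np.ndarray,
    penalty: float = 80.0,
    moving_average: int = 10,
    min_seg: int = 5,
) -> int:
    """Count downward bleaching steps in a spot intensity trace.

    The trace is smoothed (median + moving average), then a
    piecewise-constant step function is grown by iterative change-point
    insertion; an insertion must reduce the residual sum of squares by more
    than ``penalty`` x the noise variance of the smoothed trace (estimated
    robustly from first differences of the median-filtered raw trace,
    scaled for the moving average).  Because smoothing turns each step into
    a short ramp, breakpoints closer than 2 x the moving-average window are
    merged into a single step event; the returned count is the number of
    merged events whose net level change is downward and larger than both
    the noise scale and a quarter of the median step size.
    """
    trace = np.asarray(trace, dtype=float)
    if trace.size <= 10:
        raise ValidationError("trace too short for step counting")
    sm = smooth_bleach_trace(trace, moving_average=moving_average)

    # robust noise scale from raw first differences (steps are sparse and
    # barely move the median of |diff|)
    diffs = np.diff(trace)
    sigma_raw = 1.4826 * float(np.median(np.abs(diffs - np.median(diffs)))) / np.sqrt(2.0)
    # variance after an m-point moving average
    sigma_sm2 = sigma_raw**2 / moving_average
    floor = 1e-10 * float(np.ptp(sm)) ** 2 + 1e-30
    threshold = max(penalty * sigma_sm2, floor)

    breakpoints = _greedy_steps(sm, min_seg=min_seg, threshold=threshold)
    if not breakpoints:
        return 0
    bounds = [0, *breakpoints, sm.size]
    levels = np.array(
        [sm[a:b].mean() for a, b in zip(bounds[:-1], bounds[1:])]
    )
    jumps = np.diff(levels)  # one per breakpoint

    # merge breakpoints within 2x the smoothing window into one step event
    merged: list[float] = []
    cur = jumps[0]
    for bp_prev, bp, j in zip(breakpoints[:-1], breakpoints[1:], jumps[1:]):
        if bp - bp_prev <= 2 * moving_average:
            cur += j
        else:
            merged.append(cur)
            cur = j
    merged.append(cur)

    down = np.array([-m for m in merged if m < 0])
    if down.size == 0:
        return 0
    typical = float(np.median(down))
    min_jump = max(5.0 * sigma_raw / np.sqrt(moving_average), 0.25 * typical)
    down = down[down > min_jump]
    if down.size == 0:
        return 0
    # bleaching steps share a unit amplitude, so a merged cluster of closely
    # spaced events carries a near-integer multiple of it; most clusters are
    # single steps, making the median a robust unit estimate
    unit = float(np.median(down))
    multiplicities = np.maximum(1, np.rint(down / unit).astype(int))
    return int(multiplicities.sum())


# ---------------------------------------------------------------------------
# cluster areas


def cluster_areas(
    image: np.ndarray,
    threshold: float = 0.5,
    pixel_size: float = 1.0,
    absolute: bool = False,
) -> ClusterSet:
    """Areas of connected suprathreshold regions in a binary mask.

    ``threshold`` is a fraction of the image maximum unless ``absolute``.
    Components are 8-connected; areas are pixel counts x pixel_size^2 (nm^2).
    Border-touching components are flagged.
    """
    if pixel_size <= 0:
        raise ValidationError("pixel_size must be positive")
    img = np.asarray(image, dtype=float)
    thr = threshold if absolute else threshold * float(img.max())
    mask = img > thr
    labels = measure.label(mask, connectivity=2)
    n = int(labels.max())
    if n == 0:
        return ClusterSet(
            labels=labels,
            areas=np.array([]),
            pixel_size=pixel_size,
            touches_border=np.array([], bool),
        )
    counts = np.bincount(labels.ravel())[1:]
    areas = counts * pixel_size**2
    border_labels = np.unique(
        np.concatenate([labels[0], labels[-1], labels[:, 0], labels[:, -1]])
    )
    touches = np.isin(np.arange(1, n + 1), border_labels[border_labels > 0])
    return ClusterSet(
        labels=labels, areas=areas, pixel_size=pixel_size, touches_border=touches
    )
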