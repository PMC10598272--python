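"""Two-channel ROI fluorescence -> one normalized single-axon trace.

Thin axonal segments are small enough that residual motion shows up as
shared fluctuations in both the green (activity, GCaMP6s-like) and red
(structural, mRuby-like) channels.  Because the artifact is common to both,
regressing the red channel out of the green removes its linear effect:
after Savitzky-Golay smoothing both channels, the demeaned red trace scaled
by Cov(G, R)/Cov(R, R) is subtracted from the demeaned green trace, which
leaves a corrected trace with exactly zero covariance with the red channel.

Segments of one highly branched axon are then identified by correlating
each corrected ROI against the others and comparing to a null built from
circularly time-shifted copies (99th-percentile criterion, plus an absolute
r^2 > 0.2 floor).  Passing ROIs are combined by PCA (first component), the
combined trace converted to dF/F against a rolling-percentile baseline, and
rescaled so its 99th percentile equals 1.  Peaks are detected on the dF/F
trace with a 0.1 height / 0.1 prominence / 0.5 s separation contract.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import percentile_filter
from scipy.signal import find_peaks, savgol_filter
from sklearn.decomposition import PCA

from .exceptions import AlignmentError, ConfigError, DegenerateTraceError
from .synthetic_data import RoiTraceSet

#: Minimum peak height and prominence, in dF/F units.
PEAK_MIN_HEIGHT = 0.1
PEAK_MIN_PROMINENCE = 0.1
#: Minimum separation between peaks, seconds.
PEAK_MIN_SEPARATION_S = 0.5


@dataclass
class AxonTrace:
    """Combined, normalized single-axon dF/F trace."""

    dff: np.ndarray
    norm: np.ndarray
    norm_constant: float
    frame_rate_hz: float
    contributing_roi_ids: list[str] = field(default_factory=list)


@dataclass
class PeakSet:
    """Detected transient peaks on a dF/F trace."""

    peak_frames: np.ndarray
    heights: np.ndarray
    prominences: np.ndarray

    def __len__(self) -> int:
        return len(self.peak_frames)


def _smooth(trace: np.ndarray, window: int, order: int) -> np.ndarray:
    n = len(trace)
    window = min(window, n if n % 2 == 1 else n - 1)
    if window <= order:
        return trace
    return savgol_filter(trace, window, order)


def orthogonalize_channels(
    green: np.ndarray,
    red: np.ndarray,
    smooth: bool = True,
    sg_window: int = 7,
    sg_order: int = 3,
) -> np.ndarray:
    """Remove the shared motion artifact by projecting out the red channel.

    Returns ``demeaned(G) - [Cov(G, R)/Cov(R, R)] * demeaned(R)`` (population
    covariances), which by construction has zero covariance with the red
    channel.  Both channels are Savitzky-Golay smoothed first unless
    ``smooth=False``.  The returned trace is demeaned.
    """
    green = np.asarray(green, dtype=float)
    red = np.asarray(red, dtype=float)
    if green.shape != red.shape:
        raise AlignmentError("green and red traces differ in length")
    if len(green) < 3:
        raise ConfigError("need at least 3 frames to orthogonalize")
    if smooth:
        green = _smooth(green, sg_window, sg_order)
        red = _smooth(red, sg_window, sg_order)
    g = green - green.mean()
    r = red - red.mean()
    var_r = np.mean(r * r)
    if var_r == 0:
        raise DegenerateTraceError("red channel is constant; cannot orthogonalize")
    beta = np.mean(g * r) / var_r
    return g - beta * r


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return 0.0
    return float(np.mean((a - a.mean()) * (b - b.mean())) / (sa * sb))


def roi_significance(
    traces: np.ndarray,
    frame_rate_hz: float,
    n_shuffles: int = 1000,
    percentile: float = 99.0,
    r2_min: float = 0.2,
    min_shift_s: float = 2.0,
    seed: int = 0,
) -> list[int]:
    """Indices of ROIs belonging to the common (same-axon) signal.

    Each ROI is correlated against the mean of the remaining ROIs; the null
    distribution is built from the same correlation after circularly
    time-shifting the ROI by uniform offsets of at least ``min_shift_s``.
    An ROI passes when its observed correlation exceeds the null's
    ``percentile`` AND its r^2 against the reference exceeds ``r2_min``
    (set ``r2_min=0`` to apply the shuffle criterion alone).  A single ROI
    is returned unchanged (no test possible).
    """
    traces = np.asarray(traces, dtype=float)
    k, n = traces.shape
    if k == 1:
        return [0]
    if n_shuffles < 100:
        warnings.warn("fewer than 100 shuffles gives a coarse null percentile", stacklevel=2)
    rng = np.random.default_rng(seed)
    min_shift = int(round(min_shift_s * frame_rate_hz))
    if 2 * min_shift >= n:
        raise ConfigError("trace too short for the configured minimum circular shift")

    passing = []
    for i in range(k):
        ref = traces[np.arange(k) != i].mean(axis=0)
        obs = _pearson(traces[i], ref)
        shifts = rng.integers(min_shift, n - min_shift, size=n_shuffles)
        # all shifted copies at once: row j is traces[i] rolled by shifts[j]
        idx = (np.arange(n)[None, :] - shifts[:, None]) % n
        shifted = traces[i][idx]
        sc = shifted - shifted.mean(axis=1, keepdims=True)
        rc = ref - ref.mean()
        denom = sc.std(axis=1) * rc.std()
        with np.errstate(invalid="ignore", divide="ignore"):
            null = np.where(denom > 0, (sc @ rc) / (n * denom), 0.0)
        if obs > np.percentile(null, percentile) and obs * obs > r2_min:
            passing.append(i)
    return passing


def combine_rois(traces: np.ndarray) -> np.ndarray:
    """First principal component of the passing ROI traces.

    The PC sign is fixed so its correlation with the across-ROI mean trace
    is positive, and its scale matched to that mean trace (PC standard
    deviation set equal to the mean trace's).  The result is demeaned; a
    single ROI comes back as its own demeaned trace.
    """
    traces = np.atleast_2d(np.asarray(traces, dtype=float))
    k, n = traces.shape
    mean_trace = traces.mean(axis=0)
    mean_trace = mean_trace - mean_trace.mean()
    if k == 1:
        return traces[0] - traces[0].mean()
    if np.allclose(traces.std(axis=1), 0):
        raise DegenerateTraceError("all ROI traces are constant")
    pca = PCA(n_components=1)
    scores = pca.fit_transform(traces.T)[:, 0]
    if _pearson(scores, mean_trace) < 0:
        scores = -scores
    s = scores.std()
    if s > 0 and mean_trace.std() > 0:
        scores = scores * (mean_trace.std() / s)
    return scores - scores.mean()


def normalize_trace(
    f: np.ndarray,
    frame_rate_hz: float,
    baseline_window_s: float = 30.0,
    baseline_percentile: float = 8.0,
    contributing_roi_ids: list[str] | None = None,
) -> AxonTrace:
    """Baseline-correct a fluorescence trace and rescale to near-max 1.

    Baseline is the rolling 8th percentile over a 30 s window; dF/F is
    (F - baseline)/baseline; the normalized trace divides dF/F by its own
    99th percentile (stored as ``norm_constant``), so each day's trace tops
    out near 1 regardless of absolute indicator brightness.
    """
    f = np.asarray(f, dtype=float)
    if f.std() == 0:
        raise DegenerateTraceError("constant trace cannot be normalized")
    window = max(3, int(round(baseline_window_s * frame_rate_hz)))
    baseline = percentile_filter(f, baseline_percentile, size=window, mode="nearest")
    if baseline.min() <= 0:
        raise DegenerateTraceError("non-positive baseline; supply a positively offset trace")
    dff = (f - baseline) / baseline
    norm_constant = float(np.percentile(dff, 99))
    if norm_constant <= 0:
        raise DegenerateTraceError("99th percentile of dF/F is non-positive")
    return AxonTrace(
        dff=dff,
        norm=dff / norm_constant,
        norm_constant=norm_constant,
        frame_rate_hz=frame_rate_hz,
        contributing_roi_ids=contributing_roi_ids or [],
    )


def detect_peaks(axon: AxonTrace) -> PeakSet:
    """Transient peaks on the dF/F trace.

    Local maxima with height >= 0.1 dF/F, prominence >= 0.1, and at least
    ceil(0.5 s x frame rate) frames (8 at 15.49 Hz) between kept peaks, the
    higher peak winning a conflict.
    """
    distance = math.ceil(PEAK_MIN_SEPARATION_S * axon.frame_rate_hz)
    peaks, props = find_peaks(
        axon.dff,
        height=PEAK_MIN_HEIGHT,
        distance=distance,
        prominence=PEAK_MIN_PROMINENCE,
    )
    return PeakSet(
        peak_frames=peaks,
        heights=axon.dff[peaks],
        prominences=props["prominences"],
    )


def qc_active(axon: AxonTrace, peaks: PeakSet) -> bool:
    """True iff the axon shows >= 2 peaks reaching 0.1 dF/F (usable day)."""
    return int(np.sum(peaks.heights >= PEAK_MIN_HEIGHT)) >= 2


def process_roi_set(
    rois: RoiTraceSet,
    n_shuffles: int = 1000,
    seed: int = 0,
) -> tuple[AxonTrace, PeakSet, list[str]]:
    """Full ROI -> axon pipeline for one session.

    Orthogonalizes each ROI's channels, keeps ROIs passing the shuffle
    significance test, combines them by PCA, re-offsets the combined trace
    to the mean raw green level, normalizes to dF/F, and detects peaks.
    """
    rois.validate()
    corrected = np.stack(
        [orthogonalize_channels(g, r) for g, r in zip(rois.green, rois.red)]
    )
    passing = roi_significance(corrected, rois.frame_rate_hz, n_shuffles=n_shuffles, seed=seed)
    if not passing:
        # fall back to the ROI best correlated with the others' mean
        best, best_r = 0, -np.inf
        for i in range(len(corrected)):
            ref = corrected[np.arange(len(corrected)) != i].mean(axis=0)
            r = _pearson(corrected[i], ref)
            if r > best_r:
                best, best_r = i, r
        passing = [best]
    combined = combine_rois(corrected[passing])
    offset = float(rois.green[passing].mean())
    roi_ids = [rois.roi_ids[i] for i in passing]
    axon = normalize_trace(
        combined + offset, rois.frame_rate_hz, contributing_roi_ids=roi_ids
    )
    peaks = detect_peaks(axon)
    return axon, peaks, roi_ids
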