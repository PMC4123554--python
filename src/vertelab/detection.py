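"""Disk detection: sinc pattern matching with a rescaled distance template.

The detector models a disk peak as ``sinc(space/width)**(2n)`` sampled at 11
points, finds the most rostral match (the C2-C3 disk) on the normalized spine
profile, then walks caudally: the next disk is first predicted from the
template's generic distance scaled by a subject-specific ratio, then refined
by local correlation within +/-20% of the predicted gap.  When the local
correlation is below 40% of the median of the previously accepted scores the
disk is placed at its predicted location instead (template fallback), which
makes the scan robust to artifacted or missing disks.

Correlation score
-----------------
The score at offset ``x`` is the least-squares amplitude of the mean-centered
pattern within the mean-centered profile window,
``<w_c, p_c> / <p_c, p_c>``.  On a peak-normalized profile a clean disk
scores close to 1 regardless of the underlying image intensity scale, pure
noise scores near 0, and an attenuated disk scores in proportion to its
remaining amplitude — which is what makes the 40%-of-median fallback rule
discriminative.  (A fully amplitude-normalized correlation coefficient would
score a tiny-but-clean bump as highly as a full-amplitude disk and could only
trigger the fallback through noise.)
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import find_peaks

from .profile import IntensityProfile
from .template import DiskTemplate

#: number of samples in the matching pattern
PATTERN_POINTS = 11
#: default FWHM of the sinc pattern (mm), approximately the disk width
DEFAULT_PATTERN_WIDTH_MM = 15.0
#: default sinc exponent parameter (pattern is raised to 2*n)
DEFAULT_PATTERN_N = 10
#: half-width of the refinement window as a fraction of the predicted gap
DEFAULT_SEARCH_FRACTION = 0.2
#: fallback when the score drops below this fraction of the history median
DEFAULT_FALLBACK_FRACTION = 0.4
#: bounds on the subject-morphology scale factor
DEFAULT_RATIO_CLAMP = (0.7, 1.3)
#: absolute score floor for first-disk detection on top of the relative gate
FIRST_DISK_MIN_SCORE = 0.5
#: minimum window-vs-pattern correlation coefficient for a first-disk
#: candidate; on an amplitude-normalized profile only shape separates a disk
#: from the largest noise excursion
FIRST_DISK_MIN_SHAPE = 0.9

MODE_CORRELATED = "correlated"
MODE_FALLBACK = "template_fallback"


@dataclass
class DiskPattern:
    """The 11-sample disk matching pattern ``sinc(x/width)**(2n)``."""

    samples: np.ndarray
    support_mm: np.ndarray
    width_mm: float
    n: int


def make_pattern(
    width_mm: float = DEFAULT_PATTERN_WIDTH_MM,
    n: int = DEFAULT_PATTERN_N,
    step_mm: float = 1.0,
) -> DiskPattern:
    """Build the disk pattern sampled at the profile step.

    ``width_mm`` is the FWHM of the normalized sinc; squaring to the power
    2n removes side lobes and negative values.  The 11 samples sit at
    offsets ``-5*step_mm .. +5*step_mm``, so the center sample is exactly 1.
    """
    if width_mm <= 0:
        raise ValueError(f"pattern width must be positive, got {width_mm}")
    if n < 1:
        raise ValueError(f"pattern exponent n must be >= 1, got {n}")
    half = PATTERN_POINTS // 2
    support = step_mm * np.arange(-half, half + 1, dtype=float)
    samples = np.sinc(support / width_mm) ** (2 * int(n))
    return DiskPattern(samples=samples, support_mm=support, width_mm=width_mm, n=int(n))


def correlation_curve(values: np.ndarray, pattern: DiskPattern) -> np.ndarray:
    """Pattern-match score at every profile sample (0 where the window clips).

    Score = projection amplitude of the mean-centered pattern onto the
    mean-centered 11-sample window centered at each position.
    """
    v = np.asarray(values, dtype=float)
    p = pattern.samples
    half = len(p) // 2
    p_c = p - p.mean()
    denom = float(p_c @ p_c)
    scores = np.zeros_like(v)
    if len(v) < len(p):
        return scores
    windows = np.lib.stride_tricks.sliding_window_view(v, len(p))
    w_c = windows - windows.mean(axis=1, keepdims=True)
    scores[half : half + len(windows)] = w_c @ p_c / denom
    return scores


def parabolic_offset(corr: np.ndarray, i: int) -> float:
    """Sub-sample offset of a correlation peak at index ``i`` (in samples).

    Fits a parabola through the three samples around the peak; returns 0 at
    the array edges or when the samples are not concave.  The offset is
    always within half a sample.
    """
    if i <= 0 or i >= len(corr) - 1:
        return 0.0
    denom = corr[i - 1] - 2.0 * corr[i] + corr[i + 1]
    if denom >= 0:
        return 0.0
    delta = 0.5 * (corr[i - 1] - corr[i + 1]) / denom
    return float(np.clip(delta, -0.5, 0.5))


def shape_correlation(values: np.ndarray, i: int, pattern: DiskPattern) -> float:
    """Correlation coefficient between the window at sample ``i`` and the
    pattern (both mean-centered and unit-scaled); 0 where the window clips
    or is constant."""
    v = np.asarray(values, dtype=float)
    half = len(pattern.samples) // 2
    if i < half or i >= len(v) - half:
        return 0.0
    w = v[i - half : i + half + 1]
    w_c = w - w.mean()
    p_c = pattern.samples - pattern.samples.mean()
    denom = np.linalg.norm(w_c) * np.linalg.norm(p_c)
    if denom == 0:
        return 0.0
    return float(w_c @ p_c / denom)


def detect_first_disk(
    p: IntensityProfile,
    pattern: DiskPattern | None = None,
    min_score: float = FIRST_DISK_MIN_SCORE,
    min_shape_corr: float = FIRST_DISK_MIN_SHAPE,
) -> tuple[float, float]:
    """Locate the most rostral disk (C2-C3) on the correlation curve.

    Returns the arc-length position and score of the most rostral local
    correlation maximum that passes the noise gate: score at least
    ``min_score`` and at least half the global correlation maximum, and
    window shape within ``min_shape_corr`` correlation of the pattern.  The
    global maximum is capped at 1 (the nominal score of a clean unit-height
    disk) before taking half, so a super-unity artifact response further
    down the spine cannot gate out the true first disk; the shape condition
    rejects profiles with no disk-like peak at all, whose largest noise
    excursion the amplitude normalization would otherwise promote to a
    unit-height pseudo-peak.
    """
    if pattern is None:
        pattern = make_pattern(step_mm=p.step_mm)
    corr = correlation_curve(p.values, pattern)
    peaks, _ = find_peaks(corr)
    gate = max(min_score, 0.5 * min(corr.max(), 1.0))
    peaks = [
        i
        for i in peaks
        if corr[i] >= gate and shape_correlation(p.values, i, pattern) >= min_shape_corr
    ]
    if len(peaks) == 0:
        raise ValueError(
            "no disk-like correlation peak found; if the C2 vertebra is not in "
            "the field of view, supply a starting level"
        )
    i = int(peaks[0])
    pos = p.positions_mm[i] + parabolic_offset(corr, i) * p.step_mm
    return float(pos), float(corr[i])


def normalize_peaks(
    p: IntensityProfile,
    min_prominence_frac: float = 0.1,
    min_separation_mm: float = 8.0,
    min_height_frac: float = 0.2,
) -> IntensityProfile:
    """Flatten peak heights by dividing by a cubic-spline peak envelope.

    A cubic spline is interpolated through the profile's rough local maxima
    (prominence-gated, minimum separation half the smallest template gap) and
    the profile is divided by it, so residual intensity inhomogeneity across
    disks — typically lower peaks in the lumbar spine — is equalized.  Maxima
    below ``min_height_frac`` of the profile maximum are not treated as disk
    peaks (an artifact-destroyed disk must not re-inflate), and the envelope
    is floored at that height.  With fewer than 3 usable maxima the spline is
    under-determined and the profile is returned unchanged with a warning.
    """
    v = p.values
    vmax = float(v.max())
    if vmax <= 0:
        raise ValueError("peak normalization requires a positive-peak profile")
    distance = max(1, int(round(min_separation_mm / p.step_mm)))
    peaks, _ = find_peaks(v, prominence=min_prominence_frac * vmax, distance=distance)
    peaks = peaks[v[peaks] >= min_height_frac * vmax]
    if len(peaks) < 3:
        warnings.warn(
            f"only {len(peaks)} usable profile maxima; peak normalization skipped",
            stacklevel=2,
        )
        return p.with_values(v.copy())
    spline = CubicSpline(p.positions_mm[peaks], v[peaks])
    env = np.asarray(spline(p.positions_mm), dtype=float)
    # hold the envelope flat beyond the outermost peaks and floor it
    env[: peaks[0]] = v[peaks[0]]
    env[peaks[-1] + 1 :] = v[peaks[-1]]
    env = np.maximum(env, min_height_frac * vmax)
    return p.with_values(v / env)


@dataclass
class DiskDetection:
    """One detected intervertebral disk.

    ``level`` is the upper vertebra of the disk pair (2 for C2-C3);
    ``max_corr`` is None for template-fallback detections.
    """

    level: int
    position_mm: float
    max_corr: float | None
    mode: str


@dataclass
class DetectionState:
    """Running state of the caudal scan."""

    first_peak_loc: float
    template: DiskTemplate
    detections: list[DiskDetection] = field(default_factory=list)
    ratio: float = 1.0
    corr_history: list[float] = field(default_factory=list)


def predict_location(state: DetectionState) -> float | None:
    """Template prediction of the next disk: last position + generic * ratio.

    Returns None when the template is exhausted (normal termination).
    """
    last = state.detections[-1]
    gap = state.template.gap_from(last.level)
    if gap is None:
        return None
    return last.position_mm + gap.mean_mm * state.ratio


def update_ratio(
    state: DetectionState,
    clamp: tuple[float, float] = DEFAULT_RATIO_CLAMP,
) -> float:
    """Update the subject-morphology scale factor.

    The ratio is the detected span from the first disk to the most recent
    correlation-confirmed disk divided by the template span over the same
    gaps, clamped to ``clamp``.  Template-fallback detections sit exactly
    where the current ratio predicted them, so they carry no information
    about the subject's scale and are excluded from the span.  The ratio
    stays at 1 until the span covers at least two gaps: a single inter-disk
    distance is too noisy an estimate to rescale the whole template by.
    """
    if len(state.detections) < 2:
        return 1.0
    first = state.detections[0]
    correlated = [d for d in state.detections if d.mode == MODE_CORRELATED]
    last = correlated[-1]
    if last.level - first.level < 2:
        return 1.0
    detected = last.position_mm - first.position_mm
    generic = state.template.span_mm(first.level, last.level)
    return float(np.clip(detected / generic, *clamp))


def refine_location(
    p: IntensityProfile,
    pattern: DiskPattern,
    prob_location_mm: float,
    search_halfwidth_mm: float,
    corr: np.ndarray | None = None,
) -> tuple[float, float] | None:
    """Refine a predicted disk position within +/- the search half-width.

    Returns the position of the highest correlation in the window and its
    score, or None when the window lies entirely outside the profile.  Ties
    are broken toward the position closest to the prediction, then toward
    the more rostral one.  The winning peak is refined to sub-sample
    precision by parabolic interpolation, clamped to the search window.
    """
    if corr is None:
        corr = correlation_curve(p.values, pattern)
    s = p.positions_mm
    in_window = np.abs(s - prob_location_mm) <= search_halfwidth_mm
    idx = np.flatnonzero(in_window)
    if len(idx) == 0:
        return None
    best = corr[idx].max()
    cand = idx[corr[idx] >= best - 1e-12]
    dist = np.abs(s[cand] - prob_location_mm)
    cand = cand[dist <= dist.min() + 1e-12]
    i = int(cand[0])  # more rostral on a residual tie
    pos = s[i]
    if len(cand) == 1:  # a unique maximum is a genuine peak worth refining
        pos = pos + parabolic_offset(corr, i) * p.step_mm
        pos = float(
            np.clip(
                pos,
                prob_location_mm - search_halfwidth_mm,
                prob_location_mm + search_halfwidth_mm,
            )
        )
    return float(pos), float(corr[i])


def accept_or_fallback(
    max_corr_i: float,
    history: list[float],
    fallback_fraction: float = DEFAULT_FALLBACK_FRACTION,
) -> str:
    """Decide correlation vs template fallback for one disk.

    The correlation result is rejected when its score is below
    ``fallback_fraction`` (40%) of the median of the previously accepted
    scores.  With an empty history the correlation is always accepted.
    """
    if history and max_corr_i < fallback_fraction * float(np.median(history)):
        return MODE_FALLBACK
    return MODE_CORRELATED


def detect_all_disks(
    p: IntensityProfile,
    template: DiskTemplate,
    pattern: DiskPattern | None = None,
    start: tuple[int, float] | str = "auto",
    search_fraction: float = DEFAULT_SEARCH_FRACTION,
    fallback_fraction: float = DEFAULT_FALLBACK_FRACTION,
    ratio_clamp: tuple[float, float] = DEFAULT_RATIO_CLAMP,
) -> list[DiskDetection]:
    """Detect every disk caudally from the first disk (or a user start).

    Parameters
    ----------
    p : IntensityProfile
        Detrended, normalized, peak-normalized profile.
    template : DiskTemplate
        Generic inter-disk distances covering the scanned levels.
    start : "auto" or (level, position_mm)
        ``"auto"`` detects the C2-C3 disk as the most rostral correlation
        peak; otherwise the caller supplies the first visible disk's level
        (upper vertebra index) and its arc-length position.

    The scan alternates predict -> refine -> accept-or-fallback -> ratio
    update until the template or the field of view is exhausted.  Trailing
    template-fallback detections whose search window was clipped by the
    caudal end of the profile are truncated (they cannot be confirmed).
    """
    if pattern is None:
        pattern = make_pattern(step_mm=p.step_mm)
    corr = correlation_curve(p.values, pattern)

    if start == "auto":
        pos0, score0 = detect_first_disk(p, pattern)
        level0 = template.first_disk_level
        history = [score0]
        first = DiskDetection(level0, pos0, score0, MODE_CORRELATED)
    else:
        level0, pos0 = int(start[0]), float(start[1])
        history = []
        first = DiskDetection(level0, pos0, None, MODE_CORRELATED)
    state = DetectionState(
        first_peak_loc=pos0, template=template,
        detections=[first], corr_history=history,
    )

    caudal_end = float(p.positions_mm[-1])
    trailing_clipped_fallbacks = 0
    while True:
        prob = predict_location(state)
        if prob is None or prob > caudal_end:
            break
        gap = template.gap_from(state.detections[-1].level)
        halfwidth = search_fraction * gap.mean_mm * state.ratio
        refined = refine_location(p, pattern, prob, halfwidth, corr=corr)
        if refined is None:
            break
        adjusted, score = refined
        mode = accept_or_fallback(score, state.corr_history, fallback_fraction)
        if mode == MODE_CORRELATED:
            det = DiskDetection(gap.lower_level, adjusted, score, mode)
            state.corr_history.append(score)
            trailing_clipped_fallbacks = 0
        else:
            det = DiskDetection(gap.lower_level, prob, None, mode)
            if prob + halfwidth > caudal_end:
                trailing_clipped_fallbacks += 1
            else:
                trailing_clipped_fallbacks = 0
        state.detections.append(det)
        if trailing_clipped_fallbacks >= 2:
            del state.detections[-trailing_clipped_fallbacks:]
            break
        state.ratio = update_ratio(state, clamp=ratio_clamp)

    positions = [d.position_mm for d in state.detections]
    if np.any(np.diff(positions) <= 0):
        raise RuntimeError("detected disk positions are not strictly increasing")
    return state.detections
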