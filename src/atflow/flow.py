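"""Capillary flow-front tracking on paper-chip video.

The measurement chain mirrors how a paper-microfluidic flow assay is read
out: a smartphone video of the chip is reduced, frame by frame, to the
position of the advancing wet/dry boundary along each channel, yielding a
distance-versus-frame profile per measurement line.  Obvious acquisition
errors (frames where the boundary collapses to zero or to the full channel
length mid-flow) are removed, the profile is shifted so that frame 0 is the
flow onset, and the capillary flow velocity is the ordinary-least-squares
slope of distance vs frame over an early window (default: the first 35
frames, i.e. 1.17 s at 30 fps) where antibody-antigen binding dominates the
flow response.

Distances are in pixels, time in frame indices; velocities are px/frame.
All coordinates are 0-based with origin at the top-left of the frame.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import (
    ConfigurationError,
    InvalidInputError,
    NoFlowError,
    QualityFailureError,
)

__all__ = [
    "FrameStack",
    "ChannelGeometry",
    "FlowProfile",
    "VelocityEstimate",
    "detect_front",
    "build_profile",
    "clean_profile",
    "detect_inflection",
    "estimate_velocity",
    "analyze_video",
]

#: width (px) of the centred moving average applied to the difference profile
SMOOTH_WIDTH = 5
#: minimum wet/dry contrast (intensity units) considered estimable; below this
#: the Otsu fallback is used
MIN_CONTRAST = 4.0


@dataclass
class FrameStack:
    """An ordered stack of video frames plus acquisition metadata.

    ``frames`` is an ``(n_frames, height, width)`` uint8 array (grayscale) or
    ``(n_frames, height, width, 3)`` for RGB; front detection operates on
    grayscale (RGB input is converted via the luminance mean).
    """

    frames: np.ndarray
    fps: float = 30.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim not in (3, 4):
            raise InvalidInputError(
                f"frames must be (n, h, w[, 3]); got shape {self.frames.shape}"
            )
        if self.fps <= 0:
            raise InvalidInputError(f"fps must be positive, got {self.fps}")

    def __len__(self) -> int:
        return self.frames.shape[0]

    def gray(self, index: int) -> np.ndarray:
        """Frame ``index`` as float64 grayscale."""
        frame = self.frames[index]
        if frame.ndim == 3:
            frame = frame.mean(axis=-1)
        return frame.astype(np.float64)


@dataclass(frozen=True)
class ChannelGeometry:
    """Where the channel sits in the frame and where distance is measured from.

    ``roi`` is ``(x, y, w, h)``: the main-channel rectangle, with flow running
    along +x.  ``entry_line`` is the x coordinate of the loading-zone/main-
    channel boundary; front distances are measured from it.  ``line_offsets``
    are the four fractional positions across the channel width at which the
    front is localized and later averaged.
    """

    roi: tuple[int, int, int, int]
    entry_line: int
    channel_length_px: int
    line_offsets: tuple[float, ...] = (0.2, 0.4, 0.6, 0.8)

    def __post_init__(self) -> None:
        x, y, w, h = self.roi
        if w <= 0 or h <= 0 or x < 0 or y < 0:
            raise ConfigurationError(f"invalid roi {self.roi}")
        if not (x <= self.entry_line < x + w):
            raise ConfigurationError(
                f"entry_line {self.entry_line} outside roi x-range [{x}, {x + w})"
            )
        if self.channel_length_px <= 0:
            raise ConfigurationError("channel_length_px must be positive")
        offs = tuple(self.line_offsets)
        if len(offs) != 4:
            raise ConfigurationError("exactly 4 line_offsets required")
        if not all(0.0 < o < 1.0 for o in offs):
            raise ConfigurationError("line_offsets must lie strictly in (0, 1)")
        if any(b <= a for a, b in zip(offs, offs[1:])):
            raise ConfigurationError("line_offsets must be strictly increasing")

    @property
    def line_rows(self) -> list[int]:
        """Absolute frame rows of the four measurement lines."""
        _, y, _, h = self.roi
        return [int(round(y + o * (h - 1))) for o in self.line_offsets]

    def validate_frame(self, shape: tuple[int, ...]) -> None:
        x, y, w, h = self.roi
        fh, fw = shape[:2]
        if y + h > fh or x + w > fw:
            raise ConfigurationError(
                f"roi {self.roi} exceeds frame shape {(fh, fw)}"
            )


@dataclass
class FlowProfile:
    """Per-line front distance (px from the entry line) vs frame index.

    ``distances`` is ``(4, n_frames)``; NaN marks frames removed by cleanup.
    ``f0`` is the detected flow-onset frame of the *original* indexing;
    after :func:`detect_inflection` the arrays are shifted so column 0 is f0.
    ``provenance`` lists frame indices (original indexing) removed by cleanup.
    """

    distances: np.ndarray
    fps: float
    channel_length_px: int
    f0: int = 0
    shifted: bool = False
    provenance: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.distances = np.asarray(self.distances, dtype=np.float64)
        if self.distances.ndim != 2:
            raise InvalidInputError("distances must be (n_lines, n_frames)")

    @property
    def n_frames(self) -> int:
        return self.distances.shape[1]

    @property
    def n_lines(self) -> int:
        return self.distances.shape[0]


@dataclass(frozen=True)
class VelocityEstimate:
    """Windowed flow-velocity estimate: mean of the four per-line OLS slopes."""

    velocity: float
    per_line: tuple[float, ...]
    se: float
    window: tuple[int, int]
    fps: float

    @property
    def window_seconds(self) -> float:
        """Duration of the fitting window in seconds (window_frames / fps)."""
        return (self.window[1] - self.window[0]) / self.fps


def _smooth(profile: np.ndarray, width: int = SMOOTH_WIDTH) -> np.ndarray:
    """Centred moving average; edges padded with the edge value.

    Edge padding (rather than window shrinking) keeps a clean step edge at
    exactly half-contrast one pixel past the last wet pixel, so pixel-exact
    front recovery holds arbitrarily close to the entry line and channel end.
    """
    half = width // 2
    padded = np.pad(profile, half, mode="edge")
    return np.convolve(padded, np.ones(width) / width, mode="valid")


def detect_front(
    frame: np.ndarray,
    geom: ChannelGeometry,
    reference: np.ndarray,
) -> np.ndarray:
    """Localize the wet front on each of the four measurement lines.

    For each line the absolute difference from the pre-wetting reference frame
    is taken along the flow axis, smoothed with a centred 5-px moving average,
    and the front is the farthest position past the entry line where the
    smoothed difference exceeds half the observed wet/dry contrast (the
    profile maximum).  If the contrast is too small to estimate, an Otsu
    threshold on the difference profile is used instead; if nothing exceeds
    the threshold the distance is 0.

    Returns an array of four distances (px from ``entry_line``), clipped to
    ``channel_length_px``.
    """
    frame = np.asarray(frame, dtype=np.float64)
    reference = np.asarray(reference, dtype=np.float64)
    if frame.shape != reference.shape:
        raise InvalidInputError(
            f"frame shape {frame.shape} != reference shape {reference.shape}"
        )
    geom.validate_frame(frame.shape)

    x, _, w, _ = geom.roi
    start = geom.entry_line
    stop = min(x + w, start + geom.channel_length_px)
    distances = np.empty(4, dtype=np.float64)
    for i, row in enumerate(geom.line_rows):
        diff = np.abs(frame[row, start:stop] - reference[row, start:stop])
        smoothed = _smooth(diff)
        # contrast from the raw step (the smoothed maximum underestimates it
        # when the wetted run is shorter than the smoothing window)
        contrast = float(diff.max()) if diff.size else 0.0
        if contrast >= MIN_CONTRAST:
            threshold = contrast / 2.0
        else:
            threshold = _otsu_or_none(diff)
            if threshold is None:
                distances[i] = 0.0
                continue
        above = np.nonzero(smoothed > threshold)[0]
        if above.size == 0:
            distances[i] = 0.0
        else:
            # farthest exceeding pixel; +1 converts index to wetted length
            distances[i] = min(float(above[-1] + 1), float(geom.channel_length_px))
    return distances


def _otsu_or_none(diff: np.ndarray) -> float | None:
    from skimage.filters import threshold_otsu

    if diff.size == 0 or float(diff.max()) == float(diff.min()):
        return None
    try:
        return float(threshold_otsu(diff))
    except ValueError:
        return None


def build_profile(
    stack: FrameStack,
    geom: ChannelGeometry,
    reference_index: int = 0,
) -> FlowProfile:
    """Compile the raw distance-versus-frame profile for one channel.

    Frame ``reference_index`` (default 0) serves as the dry reference; it must
    precede flow onset, which :func:`detect_inflection` will verify implicitly
    (a mid-flow reference produces an undetectable onset and a quality error
    downstream).
    """
    if len(stack) < 2:
        raise InvalidInputError("need at least 2 frames to build a profile")
    if not (0 <= reference_index < len(stack)):
        raise ConfigurationError(f"reference_index {reference_index} out of range")
    reference = stack.gray(reference_index)
    geom.validate_frame(reference.shape)
    distances = np.empty((4, len(stack)), dtype=np.float64)
    for f in range(len(stack)):
        distances[:, f] = detect_front(stack.gray(f), geom, reference)
    return FlowProfile(
        distances=distances,
        fps=stack.fps,
        channel_length_px=geom.channel_length_px,
    )


def clean_profile(
    profile: FlowProfile,
    isotonic: bool = False,
    max_removed_fraction: float = 0.5,
) -> FlowProfile:
    """Remove physically impossible frames from a raw profile.

    A frame is an acquisition error on a given line when its distance is 0 or
    ≥ channel length while neighbouring frames (within ±2) on both sides
    report interior values (0 < d < L): mid-flow the front cannot vanish or
    jump to the end.  Such frames are marked missing (NaN) and recorded in
    ``provenance``.  The optional isotonic pass additionally replaces any
    decrease with the running maximum (the wet front cannot recede).

    Raises :class:`QualityFailureError` if more than ``max_removed_fraction``
    of frames are removed on any line.
    """
    d = profile.distances.copy()
    L = float(profile.channel_length_px)
    n = profile.n_frames
    removed: set[int] = set()
    for line in range(profile.n_lines):
        row = d[line]
        bad: list[int] = []
        for f in range(n):
            v = row[f]
            if not np.isfinite(v) or (0.0 < v < L):
                continue
            left = row[max(0, f - 2) : f]
            right = row[f + 1 : f + 3]
            left_ok = np.any((left > 0) & (left < L))
            right_ok = np.any((right > 0) & (right < L))
            if left_ok and right_ok:
                bad.append(f)
        if len(bad) > max_removed_fraction * n:
            raise QualityFailureError(
                f"line {line}: {len(bad)}/{n} frames removed by cleanup"
            )
        row[bad] = np.nan
        removed.update(bad)
    if isotonic:
        for line in range(profile.n_lines):
            running = -np.inf
            row = d[line]
            for f in range(n):
                if np.isnan(row[f]):
                    continue
                running = max(running, row[f])
                row[f] = running
    return replace(
        profile,
        distances=d,
        provenance=sorted(set(profile.provenance) | removed),
    )


def detect_inflection(
    profile: FlowProfile,
    baseline_frames: int = 5,
    sd_floor: float = 0.5,
    n_sigma: float = 5.0,
    sustain: int = 3,
) -> FlowProfile:
    """Find the flow-onset frame f0 and shift the profile so f0 maps to 0.

    Departure from baseline is declared at the first frame whose
    median-across-lines distance exceeds ``baseline_mean + n_sigma * sd``
    (baseline = the first ``baseline_frames`` frames; sd floored at
    ``sd_floor`` px) and stays above for ``sustain`` consecutive frames.  The
    onset f0 is then located by backtracking along the monotone rise to the
    frame where the climb began, which recovers the exact first-motion frame
    even when flow starts so early that the baseline window is contaminated.

    Raises :class:`NoFlowError` when no sustained departure exists.
    """
    with np.errstate(all="ignore"):
        import warnings as _warnings

        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN frames
            med = np.nanmedian(profile.distances, axis=0)
    n = med.size
    nb = min(baseline_frames, n)
    base = med[:nb]
    base = base[np.isfinite(base)]
    if base.size == 0:
        raise NoFlowError("no finite baseline frames")
    threshold = float(base.mean()) + n_sigma * max(float(base.std()), sd_floor)

    finite = np.isfinite(med)
    above = finite & (med > threshold)
    f_star = None
    run = 0
    for f in range(n):
        if not finite[f]:
            continue  # missing frames do not break a run
        run = run + 1 if above[f] else 0
        if run == sustain:
            f_star = f - _nth_finite_back(finite, f, sustain - 1)
            break
    if f_star is None:
        raise NoFlowError(
            f"no frame exceeds onset threshold {threshold:.2f} px for "
            f"{sustain} consecutive frames"
        )

    # Backtrack step tolerance uses the sd *floor*, not the baseline sd: when
    # flow starts inside the baseline window the baseline sd is inflated by
    # the rise itself and would stop the backtrack mid-climb.
    rise_eps = sd_floor
    f0 = f_star
    while f0 > 0:
        prev = _prev_finite(med, finite, f0)
        if prev is None:
            break
        pf, pv = prev
        if pv < med[f0] - rise_eps:
            f0 = pf
        else:
            break

    return replace(
        profile,
        distances=profile.distances[:, f0:],
        f0=f0,
        shifted=True,
        provenance=[i for i in profile.provenance],
    )


def _nth_finite_back(finite: np.ndarray, f: int, nth: int) -> int:
    """Offset from f back to the nth previous finite frame (0 → f itself)."""
    count = 0
    for g in range(f, -1, -1):
        if finite[g]:
            if count == nth:
                return f - g
            count += 1
    return f


def _prev_finite(
    med: np.ndarray, finite: np.ndarray, f: int
) -> tuple[int, float] | None:
    for g in range(f - 1, -1, -1):
        if finite[g]:
            return g, float(med[g])
    return None


def _ols_slope(x: np.ndarray, y: np.ndarray) -> float:
    xm = x.mean()
    ym = y.mean()
    denom = float(np.sum((x - xm) ** 2))
    if denom == 0.0:
        raise QualityFailureError("degenerate frame support for slope fit")
    return float(np.sum((x - xm) * (y - ym)) / denom)


def estimate_velocity(
    profile: FlowProfile,
    window_frames: int = 35,
) -> VelocityEstimate:
    """Capillary flow velocity over the first ``window_frames`` frames.

    Fits the OLS slope of distance vs frame index over the half-open window
    [0, window_frames) independently on each of the four measurement lines
    (missing frames are skipped) and averages the slopes.  At the default 35
    frames and 30 fps this is the first 1.17 s of flow.  The standard error
    is the sd of the four per-line slopes over √4.
    """
    if not profile.shifted:
        raise InvalidInputError(
            "profile must be onset-shifted (run detect_inflection first)"
        )
    if window_frames < 2:
        raise InvalidInputError("window_frames must be ≥ 2")
    stop = min(window_frames, profile.n_frames)
    slopes = []
    for line in range(profile.n_lines):
        y = profile.distances[line, :stop]
        x = np.arange(stop, dtype=np.float64)
        ok = np.isfinite(y)
        if ok.sum() < 2:
            raise QualityFailureError(
                f"line {line}: only {int(ok.sum())} usable frames in window "
                f"[0, {window_frames})"
            )
        slopes.append(_ols_slope(x[ok], y[ok]))
    per_line = tuple(slopes)
    velocity = float(np.mean(per_line))
    se = float(np.std(per_line, ddof=1) / math.sqrt(len(per_line)))
    return VelocityEstimate(
        velocity=velocity,
        per_line=per_line,
        se=se,
        window=(0, window_frames),
        fps=profile.fps,
    )


def analyze_video(
    stack: FrameStack,
    geom: ChannelGeometry,
    window_frames: int = 35,
    isotonic: bool = False,
    reference_index: int = 0,
) -> tuple[VelocityEstimate, FlowProfile]:
    """Full chain: profile → cleanup → onset shift → windowed velocity."""
    profile = build_profile(stack, geom, reference_index=reference_index)
    profile = clean_profile(profile, isotonic=isotonic)
    profile = detect_inflection(profile)
    estimate = estimate_velocity(profile, window_frames=window_frames)
    return estimate, profile
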