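"""Random-dot stimulus generation for segmentation psychophysics.

Two stimulus families are produced:

* **Motion**: random-dot kinematograms within a square display window. The
  *test* stimulus is divided into horizontal bands; signal dots in adjacent
  bands drift in opposing horizontal directions (rightward / leftward) while
  noise dots drift in independently drawn random directions. The paired
  *comparison* stimulus contains the identical mixture of local motion cues
  (the same per-direction signal-dot counts) but spatially intermingled with
  no banding.

* **Form**: a short coherent or random-walk dot trajectory is computed and
  its frames superimposed into a single static image, so signal elements
  appear as oriented streaks and noise elements as compact random clusters.
  In the segmented test pattern streak orientations alternate
  (vertical / horizontal) across adjacent bands.

All geometry is in degrees of visual angle, origin at the lower-left corner
of the window, y increasing upward. Bands are half-open intervals
``[low, high)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "RIGHTWARD",
    "LEFTWARD",
    "VERTICAL_AXIS",
    "HORIZONTAL_AXIS",
    "MOTION_POLARITIES",
    "FORM_POLARITIES",
    "StimulusParameterError",
    "StimulusParams",
    "model_params",
    "form_params",
    "SegmentLayout",
    "build_segment_layout",
    "DotFrame",
    "MotionSequence",
    "sample_test_stimulus",
    "sample_comparison_stimulus",
    "advance_frame",
    "FormPattern",
    "render_form_pattern",
    "dump_frames",
    "frame_to_pgm",
]

RIGHTWARD = 0.0
LEFTWARD = float(np.pi)
#: Streak orientation axes for the form task (angle of the streak axis).
VERTICAL_AXIS = float(np.pi / 2)
HORIZONTAL_AXIS = 0.0

MOTION_POLARITIES = (RIGHTWARD, LEFTWARD)
FORM_POLARITIES = (VERTICAL_AXIS, HORIZONTAL_AXIS)


class StimulusParameterError(ValueError):
    """Raised for invalid stimulus parameters or constructor misuse."""


@dataclass(frozen=True)
class StimulusParams:
    """Geometry and timing of the random-dot display.

    Defaults are the psychophysical stimulus: a 7 x 7 deg window containing
    256 dots of diameter 0.07 deg, displaced 0.035 deg on each of 43 updates
    at 100 Hz (speed 3.5 deg/s, duration 0.43 s), with a limited dot
    lifetime of 22 frames.
    """

    window_width: float = 7.0
    window_height: float = 7.0
    n_dots: int = 256
    dot_diameter: float = 0.07
    displacement_per_update: float = 0.035
    update_rate: float = 100.0
    n_frames: int = 43
    dot_lifetime: int = 22

    def __post_init__(self) -> None:
        positive = (
            self.window_width,
            self.window_height,
            self.dot_diameter,
            self.displacement_per_update,
            self.update_rate,
        )
        if any(v <= 0 for v in positive):
            raise StimulusParameterError("all stimulus dimensions must be positive")
        if self.n_dots < 1:
            raise StimulusParameterError("n_dots must be >= 1")
        if self.n_frames < 2:
            raise StimulusParameterError("n_frames must be >= 2")
        if self.dot_lifetime < 1:
            raise StimulusParameterError("dot_lifetime must be >= 1")

    @property
    def speed(self) -> float:
        """Dot speed in deg/s (displacement per update x update rate)."""
        return self.displacement_per_update * self.update_rate

    @property
    def duration(self) -> float:
        """Stimulus duration in seconds (n_frames / update rate)."""
        return self.n_frames / self.update_rate


def model_params(**overrides) -> StimulusParams:
    """Parameters for model-observer trials: 2-frame sequences."""
    overrides.setdefault("n_frames", 2)
    return StimulusParams(**overrides)


def form_params(**overrides) -> StimulusParams:
    """Parameters for the form task: 4 superimposed frames."""
    overrides.setdefault("n_frames", 4)
    return StimulusParams(**overrides)


@dataclass(frozen=True)
class SegmentLayout:
    """Horizontal banding of the display window.

    ``band_edges`` is an ascending array starting at 0 and ending at the
    window height; band *i* spans ``[band_edges[i], band_edges[i+1])`` and
    carries polarity ``band_polarities[i]`` (a direction or orientation
    angle). Interior bands have height ``segment_size``; at most the first
    and last bands are partial. Adjacent bands always carry opposite
    polarity under the cyclic tiling.
    """

    segment_size: float
    jitter_offset: float
    band_edges: np.ndarray
    band_polarities: np.ndarray

    @property
    def n_bands(self) -> int:
        return len(self.band_edges) - 1

    @property
    def window_height(self) -> float:
        return float(self.band_edges[-1])

    def band_index(self, y) -> np.ndarray:
        """Band index for y-coordinates (half-open bands, top edge inclusive)."""
        idx = np.searchsorted(self.band_edges, np.asarray(y, dtype=float), side="right") - 1
        return np.clip(idx, 0, self.n_bands - 1)

    def band_bounds(self, i: int) -> tuple[float, float]:
        return float(self.band_edges[i]), float(self.band_edges[i + 1])

    def polarity_at(self, y) -> np.ndarray:
        return self.band_polarities[self.band_index(y)]


def build_segment_layout(
    window_height: float,
    segment_size: float,
    rng: Optional[np.random.Generator] = None,
    *,
    polarities: Sequence[float] = MOTION_POLARITIES,
    jitter_offset: Optional[float] = None,
    first_polarity: Optional[float] = None,
) -> SegmentLayout:
    """Tile the window into alternating-polarity horizontal bands.

    The vertical position of the band boundaries is jittered by a uniform
    offset in ``[0, segment_size)`` and the polarity of the band containing
    ``y = 0`` is drawn uniformly from the two possibilities, so neither edge
    position nor polarity assignment is a predictable cue. ``jitter_offset``
    and ``first_polarity`` can be forced for deterministic construction.
    """
    if not (0 < segment_size <= window_height):
        raise StimulusParameterError(
            f"segment_size must be in (0, {window_height}], got {segment_size}"
        )
    if jitter_offset is None:
        if rng is None:
            raise StimulusParameterError("rng required when jitter_offset is not forced")
        jitter_offset = float(rng.uniform(0.0, segment_size))
    if not (0.0 <= jitter_offset < segment_size):
        raise StimulusParameterError("jitter_offset must lie in [0, segment_size)")

    y0 = jitter_offset - segment_size  # low edge of tiling band 0 (may be < 0)
    n_tiles = int(math.ceil((window_height - y0) / segment_size)) + 1
    full_edges = y0 + segment_size * np.arange(n_tiles + 1)
    tol = 1e-9 * segment_size
    interior = full_edges[(full_edges > tol) & (full_edges < window_height - tol)]
    band_edges = np.concatenate(([0.0], interior, [window_height]))

    if first_polarity is None:
        if rng is None:
            raise StimulusParameterError("rng required when first_polarity is not forced")
        first_polarity = float(polarities[int(rng.integers(2))])
    if first_polarity == polarities[0]:
        pair = (polarities[0], polarities[1])
    elif first_polarity == polarities[1]:
        pair = (polarities[1], polarities[0])
    else:
        raise StimulusParameterError("first_polarity must be one of the polarity pair")

    # window bands are consecutive tiles of the cyclic tiling, so polarity
    # strictly alternates with band index, anchored at the band containing y=0
    n_bands = len(band_edges) - 1
    band_polarities = np.where(np.arange(n_bands) % 2 == 0, pair[0], pair[1])

    return SegmentLayout(
        segment_size=float(segment_size),
        jitter_offset=float(jitter_offset),
        band_edges=band_edges,
        band_polarities=band_polarities.astype(float),
    )


@dataclass
class DotFrame:
    """One frame of dot state, stored as parallel arrays.

    ``theta`` is each dot's direction of motion in radians; ``signal`` flags
    signal dots; ``age`` counts frames lived in [1, lifetime]; ``band`` is
    the dot's band index (-1 when the sequence has no layout).
    """

    x: np.ndarray
    y: np.ndarray
    theta: np.ndarray
    signal: np.ndarray
    age: np.ndarray
    band: np.ndarray

    @property
    def n_dots(self) -> int:
        return len(self.x)

    def copy(self) -> "DotFrame":
        return DotFrame(
            self.x.copy(), self.y.copy(), self.theta.copy(),
            self.signal.copy(), self.age.copy(), self.band.copy(),
        )


@dataclass
class MotionSequence:
    """A random-dot motion sequence (test or comparison stimulus)."""

    params: StimulusParams
    frames: list  # list[DotFrame]
    layout: Optional[SegmentLayout]
    coherence: float
    signal_counts: tuple  # (n_rightward, n_leftward)
    is_test: bool

    @property
    def n_signal(self) -> int:
        return int(self.signal_counts[0] + self.signal_counts[1])


def _uniform_positions(params: StimulusParams, n: int, rng: np.random.Generator):
    x = rng.uniform(0.0, params.window_width, n)
    y = rng.uniform(0.0, params.window_height, n)
    return x, y


def sample_test_stimulus(
    params: StimulusParams,
    layout: SegmentLayout,
    coherence: float,
    rng: np.random.Generator,
) -> MotionSequence:
    """Generate a segmented test stimulus at the given coherence.

    Exactly ``round(coherence * n_dots)`` dots are flagged as signal and
    take the polarity direction of the band they occupy; the remaining noise
    dots move in independently drawn directions uniform on [0, 2*pi), fixed
    for their lifetime. Initial positions are uniform over the window and
    initial ages uniform on [1, lifetime].
    """
    if layout is None:
        raise StimulusParameterError(
            "test stimulus requires a layout; use sample_comparison_stimulus"
        )
    if not (0.0 <= coherence <= 1.0):
        raise StimulusParameterError("coherence must lie in [0, 1]")
    n = params.n_dots
    x, y = _uniform_positions(params, n, rng)
    band = layout.band_index(y)
    n_signal = int(round(coherence * n))
    signal = np.zeros(n, dtype=bool)
    if n_signal > 0:
        signal[rng.choice(n, size=n_signal, replace=False)] = True
    theta = rng.uniform(0.0, 2.0 * np.pi, n)
    theta[signal] = layout.band_polarities[band[signal]]
    age = rng.integers(1, params.dot_lifetime + 1, size=n)

    frame = DotFrame(x, y, theta, signal, age.astype(int), band.astype(int))
    frames = [frame]
    for _ in range(params.n_frames - 1):
        frame = advance_frame(frame, params, layout, rng)
        frames.append(frame)

    theta0 = frames[0].theta
    n_right = int(np.sum(signal & (theta0 == RIGHTWARD)))
    n_left = int(np.sum(signal & (theta0 == LEFTWARD)))
    return MotionSequence(
        params=params,
        frames=frames,
        layout=layout,
        coherence=float(coherence),
        signal_counts=(n_right, n_left),
        is_test=True,
    )


def sample_comparison_stimulus(
    params: StimulusParams,
    signal_counts: tuple,
    n_noise: int,
    rng: np.random.Generator,
) -> MotionSequence:
    """Generate an intermingled comparison stimulus with matched motion cues.

    The per-direction signal counts are copied from the paired test
    stimulus, so test and comparison contain identical local motion cues;
    positions are uniform over the whole window with no banding.
    """
    n_right, n_left = int(signal_counts[0]), int(signal_counts[1])
    if n_right < 0 or n_left < 0 or n_noise < 0:
        raise StimulusParameterError("dot counts must be non-negative")
    n = params.n_dots
    if n_right + n_left + n_noise != n:
        raise StimulusParameterError(
            f"signal ({n_right}+{n_left}) + noise ({n_noise}) counts must sum to n_dots ({n})"
        )
    theta = np.concatenate(
        [
            np.full(n_right, RIGHTWARD),
            np.full(n_left, LEFTWARD),
            rng.uniform(0.0, 2.0 * np.pi, n_noise),
        ]
    )
    signal = np.concatenate([np.ones(n_right + n_left, dtype=bool), np.zeros(n_noise, dtype=bool)])
    perm = rng.permutation(n)
    theta, signal = theta[perm], signal[perm]
    x, y = _uniform_positions(params, n, rng)
    age = rng.integers(1, params.dot_lifetime + 1, size=n)
    frame = DotFrame(x, y, theta, signal, age.astype(int), np.full(n, -1))
    frames = [frame]
    for _ in range(params.n_frames - 1):
        frame = advance_frame(frame, params, None, rng)
        frames.append(frame)
    return MotionSequence(
        params=params,
        frames=frames,
        layout=None,
        coherence=(n_right + n_left) / n,
        signal_counts=(n_right, n_left),
        is_test=False,
    )


def advance_frame(
    frame: DotFrame,
    params: StimulusParams,
    layout: Optional[SegmentLayout],
    rng: np.random.Generator,
) -> DotFrame:
    """Advance every dot by one positional update.

    Dots translate by ``displacement_per_update`` along their direction;
    horizontal motion wraps around the window width, vertical excursions are
    clamped so dots never leave their band (or the window) between replots.
    Ages increment, and dots exceeding the lifetime are replotted uniformly
    within their own band (or the whole window when there is no layout) with
    age reset to 1; replotted noise dots draw a fresh random direction.
    """
    d = params.displacement_per_update
    new = frame.copy()
    new.x = np.mod(frame.x + d * np.cos(frame.theta), params.window_width)
    y = frame.y + d * np.sin(frame.theta)
    if layout is None:
        lo = np.zeros_like(y)
        hi = np.full_like(y, params.window_height)
    else:
        lo = layout.band_edges[frame.band]
        hi = layout.band_edges[frame.band + 1]
    new.y = np.clip(y, lo, np.nextafter(hi, -np.inf))
    new.age = frame.age + 1

    expired = new.age > params.dot_lifetime
    if np.any(expired):
        k = int(np.sum(expired))
        new.x[expired] = rng.uniform(0.0, params.window_width, k)
        new.y[expired] = rng.uniform(lo[expired], hi[expired])
        new.age[expired] = 1
        redraw = expired & ~frame.signal
        if np.any(redraw):
            new.theta[redraw] = rng.uniform(0.0, 2.0 * np.pi, int(np.sum(redraw)))
    return new


@dataclass
class FormPattern:
    """A static form pattern of superimposed dot trajectories.

    ``centres`` has shape ``(n_elements, n_frames, 2)``: the dot-centre
    positions whose superposition forms each element. Signal elements are
    straight streaks along ``axis`` (radians; vertical = pi/2, horizontal
    = 0); noise elements are random-walk clusters (``axis`` is NaN).
    """

    params: StimulusParams
    centres: np.ndarray
    signal: np.ndarray
    axis: np.ndarray
    layout: Optional[SegmentLayout]
    coherence: float

    @property
    def n_elements(self) -> int:
        return self.centres.shape[0]

    def element_extent(self, i: int) -> float:
        """Total spatial extent of element i (max centre spread + dot diameter)."""
        pts = self.centres[i]
        diff = pts[:, None, :] - pts[None, :, :]
        spread = float(np.sqrt((diff ** 2).sum(-1)).max())
        return spread + self.params.dot_diameter


def render_form_pattern(
    params: StimulusParams,
    layout: Optional[SegmentLayout],
    coherence: float,
    rng: np.random.Generator,
) -> FormPattern:
    """Render a form pattern by superimposing a short trajectory's frames.

    Signal elements follow a fixed direction along their band's orientation
    axis (sign drawn at random), producing collinear streaks of extent
    ``dot_diameter + (n_frames - 1) * displacement_per_update``. Noise
    elements take an independent uniform direction on every frame, producing
    compact random clusters. With ``layout=None`` (comparison pattern),
    signal orientations are drawn uniformly from the two axes.
    """
    if not (0.0 <= coherence <= 1.0):
        raise StimulusParameterError("coherence must lie in [0, 1]")
    n = params.n_dots
    f = params.n_frames
    d = params.displacement_per_update
    x, y = _uniform_positions(params, n, rng)
    start = np.column_stack([x, y])

    n_signal = int(round(coherence * n))
    signal = np.zeros(n, dtype=bool)
    if n_signal > 0:
        signal[rng.choice(n, size=n_signal, replace=False)] = True

    axis = np.full(n, np.nan)
    if layout is not None:
        axis[signal] = layout.polarity_at(y[signal])
    else:
        axis[signal] = rng.choice(FORM_POLARITIES, size=n_signal)

    centres = np.empty((n, f, 2))
    centres[:, 0] = start
    sign = rng.choice([-1.0, 1.0], size=n)
    step_sig = np.column_stack([np.cos(axis), np.sin(axis)]) * (sign * d)[:, None]
    for j in range(1, f):
        centres[signal, j] = centres[signal, j - 1] + step_sig[signal]
        noise = ~signal
        phi = rng.uniform(0.0, 2.0 * np.pi, int(noise.sum()))
        walk = np.column_stack([np.cos(phi), np.sin(phi)]) * d
        centres[noise, j] = centres[noise, j - 1] + walk
    return FormPattern(
        params=params,
        centres=centres,
        signal=signal,
        axis=axis,
        layout=layout,
        coherence=float(coherence),
    )


def dump_frames(sequence: MotionSequence, path) -> None:
    """Write a motion sequence as a delimited text table for inspection.

    Columns: frame, dot, x, y, theta, role, age.
    """
    with open(path, "w") as fh:
        fh.write("frame\tdot\tx\ty\ttheta\trole\tage\n")
        for fi, fr in enumerate(sequence.frames):
            for di in range(fr.n_dots):
                role = "signal" if fr.signal[di] else "noise"
                fh.write(
                    f"{fi}\t{di}\t{fr.x[di]:.6f}\t{fr.y[di]:.6f}\t"
                    f"{fr.theta[di]:.6f}\t{role}\t{int(fr.age[di])}\n"
                )


def frame_to_pgm(frame: DotFrame, params: StimulusParams, path, pixels_per_degree: int = 20) -> None:
    """Write one frame as a plain-text portable graymap (P2) image.

    Dots are rendered as single dark pixels on a mid-grey background; this
    is a quick visual sanity check, not a display-accurate rendering.
    """
    w = int(round(params.window_width * pixels_per_degree))
    h = int(round(params.window_height * pixels_per_degree))
    img = np.full((h, w), 180, dtype=int)
    px = np.clip((frame.x * pixels_per_degree).astype(int), 0, w - 1)
    py = np.clip((frame.y * pixels_per_degree).astype(int), 0, h - 1)
    img[h - 1 - py, px] = 0  # image row 0 at top
    with open(path, "w") as fh:
        fh.write(f"P2\n{w} {h}\n255\n")
        for row in img:
            fh.write(" ".join(str(v) for v in row) + "\n")
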