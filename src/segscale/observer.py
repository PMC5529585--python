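"""Motion-opponency model observer with selectable integration-field scale.

The observer pools local motion within circular integration fields tiling
the display. At each lattice location (i, j) the net opponent motion
(rightward minus leftward) is the sum of the horizontal direction
components of all dots whose centres fall inside the field:

    R_ij = sum_d cos(theta_d)

The directional variance of the opponent map across space,

    sigma^2 = (1/n) * sum_ij (R_mean - R_ij)^2,

is the decision variable: on each two-alternative trial the sequence with
the larger directional variance is chosen as the segmented test stimulus.
A segmented pattern produces strongly signed opponent responses that
alternate between bands — hence high spatial variance — provided the field
is no larger than a band; an intermingled pattern pools cancelling
directions everywhere.

Four field-size policies model how the scale of integration is selected:
``fixed`` (constant diameter), ``proportional`` (ratio x segment size),
``bounded_matched`` (segment size clamped to physiological bounds) and
``bounded_random`` (drawn uniformly within the bounds on every trial —
the sub-optimal selection hypothesised to underlie the dyslexic profile).
Optional Gaussian internal noise perturbs each dot's encoded direction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .stimuli import MotionSequence

__all__ = [
    "POLICIES",
    "ObserverConfig",
    "OpponentMap",
    "TrialOutcome",
    "ObserverParameterError",
    "TrialContractError",
    "Lattice",
    "make_lattice",
    "encode_directions",
    "net_opponent_motion_map",
    "directional_variance",
    "choose_field_diameter",
    "decide_trial",
]

POLICIES = ("fixed", "proportional", "bounded_matched", "bounded_random")

#: Default lattice spacing in degrees (~2 dot diameters).
DEFAULT_GRID_SPACING = 0.14
#: Default physiological bounds on the integration-field diameter (deg).
DEFAULT_LOWER_BOUND = 0.62
DEFAULT_UPPER_BOUND = 1.24


class ObserverParameterError(ValueError):
    """Invalid observer configuration."""


class TrialContractError(ValueError):
    """Test and comparison sequences do not form a matched pair."""


@dataclass(frozen=True)
class ObserverConfig:
    """Integration-field policy, internal noise, and spatial sampling.

    noise_sd is the SD of the Gaussian internal direction noise in
    *degrees* (0 disables it); grid_spacing is the lattice pitch in degrees.
    """

    policy: str = "bounded_matched"
    field_diameter: Optional[float] = None
    ratio: Optional[float] = None
    lower_bound: float = DEFAULT_LOWER_BOUND
    upper_bound: float = DEFAULT_UPPER_BOUND
    noise_sd: float = 0.0
    grid_spacing: float = DEFAULT_GRID_SPACING

    def __post_init__(self) -> None:
        if self.policy not in POLICIES:
            raise ObserverParameterError(f"unknown policy {self.policy!r}")
        if self.policy == "fixed" and (self.field_diameter is None or self.field_diameter <= 0):
            raise ObserverParameterError("fixed policy requires field_diameter > 0")
        if self.policy == "proportional" and (self.ratio is None or self.ratio <= 0):
            raise ObserverParameterError("proportional policy requires ratio > 0")
        if not (0 < self.lower_bound <= self.upper_bound):
            raise ObserverParameterError("require 0 < lower_bound <= upper_bound")
        if self.noise_sd < 0:
            raise ObserverParameterError("noise_sd must be >= 0")
        if self.grid_spacing <= 0:
            raise ObserverParameterError("grid_spacing must be > 0")


@dataclass
class OpponentMap:
    """Net opponent motion sampled on the spatial lattice."""

    values: np.ndarray
    n: int
    mean: float


@dataclass
class TrialOutcome:
    """Result of one two-alternative model trial."""

    sigma2_test: float
    sigma2_comparison: float
    chosen: str  # "test" | "comparison"
    correct: bool
    tie: bool
    field_diameter: float


@dataclass(frozen=True)
class Lattice:
    """Regular square lattice covering the window.

    Locations are ordered row-major over (y, x); ``points`` flattens them
    to an (m, 2) array in that order.
    """

    xs: np.ndarray
    ys: np.ndarray
    spacing: float

    @property
    def n(self) -> int:
        return len(self.xs) * len(self.ys)

    @property
    def points(self) -> np.ndarray:
        gx, gy = np.meshgrid(self.xs, self.ys)
        return np.column_stack([gx.ravel(), gy.ravel()])


def make_lattice(width: float, height: float, spacing: float) -> Lattice:
    """Regular square lattice covering the window at the given pitch."""
    xs = np.arange(0.0, width + spacing * 0.5, spacing)
    ys = np.arange(0.0, height + spacing * 0.5, spacing)
    return Lattice(xs=xs, ys=ys, spacing=spacing)


def _scatter_map(x, y, w, radius2, lattice: Lattice) -> np.ndarray:
    """Accumulate weights onto lattice cells within the field radius.

    Exact equivalent of the dense distance test, but each dot touches only
    the lattice cells inside its field, which is far cheaper on the default
    grid. Assumes the lattice origin is 0 with uniform spacing.
    """
    h = lattice.spacing
    nx, ny = len(lattice.xs), len(lattice.ys)
    reach = int(math.ceil(math.sqrt(radius2) / h)) + 1
    off = np.arange(-reach, reach + 1)
    di, dj = np.meshgrid(off, off)
    di, dj = di.ravel()[None, :], dj.ravel()[None, :]
    ix = np.round(np.asarray(x) / h).astype(int)[:, None]
    iy = np.round(np.asarray(y) / h).astype(int)[:, None]
    cx, cy = ix + di, iy + dj
    ok = ((cx * h - np.asarray(x)[:, None]) ** 2 + (cy * h - np.asarray(y)[:, None]) ** 2) <= radius2
    ok &= (cx >= 0) & (cx < nx) & (cy >= 0) & (cy < ny)
    flat = cy * nx + cx
    weights = np.broadcast_to(np.asarray(w)[:, None], flat.shape)
    return np.bincount(flat[ok], weights=weights[ok], minlength=nx * ny)


def encode_directions(
    theta: np.ndarray, noise_sd: float, rng: Optional[np.random.Generator]
) -> np.ndarray:
    """Perturb encoded dot directions with independent Gaussian noise.

    ``noise_sd`` is in degrees and applied in radians; each dot receives one
    independent deviate per trial. With ``noise_sd == 0`` this is the
    identity.
    """
    if noise_sd < 0:
        raise ObserverParameterError("noise_sd must be >= 0")
    if noise_sd == 0:
        return np.asarray(theta, dtype=float)
    if rng is None:
        raise ObserverParameterError("rng required when noise_sd > 0")
    sd_rad = np.deg2rad(noise_sd)
    return np.asarray(theta, dtype=float) + rng.normal(0.0, sd_rad, size=len(theta))


def net_opponent_motion_map(
    x: np.ndarray,
    y: np.ndarray,
    theta: np.ndarray,
    field_diameter: float,
    lattice: np.ndarray,
) -> OpponentMap:
    """Opponent response R_ij = sum of cos(theta) over dots within the field.

    Fields centred near the window edge are truncated by the window — dots
    simply cannot lie outside it; no padding or reflection is applied. An
    empty dot set yields a map of zeros. ``lattice`` is either a
    :class:`Lattice` (fast scatter path) or an arbitrary (m, 2) array of
    locations (dense path); both give identical values.
    """
    if field_diameter <= 0:
        raise ObserverParameterError("field_diameter must be > 0")
    r2 = (field_diameter / 2.0) ** 2
    m = lattice.n if isinstance(lattice, Lattice) else len(lattice)
    if len(x) == 0:
        return OpponentMap(values=np.zeros(m), n=m, mean=0.0)
    cos_theta = np.cos(np.asarray(theta, dtype=float))
    if isinstance(lattice, Lattice):
        values = _scatter_map(x, y, cos_theta, r2, lattice)
    else:
        pts = np.asarray(lattice, dtype=float)
        dx = pts[:, 0][:, None] - np.asarray(x)[None, :]
        dy = pts[:, 1][:, None] - np.asarray(y)[None, :]
        inside = (dx * dx + dy * dy) <= r2
        values = inside.astype(float) @ cos_theta
    return OpponentMap(values=values, n=m, mean=float(values.mean()))


def directional_variance(om: OpponentMap) -> float:
    """Population variance (divisor n) of the opponent map across space."""
    if om.n < 1:
        raise ObserverParameterError("opponent map must contain at least one location")
    return float(np.mean((om.mean - om.values) ** 2))


def choose_field_diameter(
    config: ObserverConfig,
    segment_size: Optional[float],
    rng: Optional[np.random.Generator] = None,
) -> float:
    """Select the integration-field diameter for one trial.

    fixed -> the configured diameter; proportional -> ratio x segment size;
    bounded_matched -> segment size clamped to [lower, upper];
    bounded_random -> uniform draw on [lower, upper], redrawn every trial.
    """
    if config.policy == "fixed":
        return float(config.field_diameter)
    if config.policy == "bounded_random":
        if rng is None:
            raise ObserverParameterError("bounded_random requires an rng")
        return float(rng.uniform(config.lower_bound, config.upper_bound))
    if segment_size is None or segment_size <= 0:
        raise ObserverParameterError(f"policy {config.policy!r} requires a segment size")
    if config.policy == "proportional":
        return float(config.ratio * segment_size)
    # bounded_matched
    return float(np.clip(segment_size, config.lower_bound, config.upper_bound))


def _sequence_variance(
    seq: MotionSequence,
    field_diameter: float,
    config: ObserverConfig,
    lattice: np.ndarray,
    rng: Optional[np.random.Generator],
) -> float:
    frame = seq.frames[0]
    theta = encode_directions(frame.theta, config.noise_sd, rng)
    om = net_opponent_motion_map(frame.x, frame.y, theta, field_diameter, lattice)
    return directional_variance(om)


def decide_trial(
    test: MotionSequence,
    comparison: MotionSequence,
    config: ObserverConfig,
    rng: np.random.Generator,
    lattice: Optional[np.ndarray] = None,
) -> TrialOutcome:
    """Run one two-alternative trial of the model observer.

    A single field diameter is selected per trial (from the test stimulus's
    segment size where the policy needs one) and applied to both sequences.
    The sequence with the strictly larger directional variance is chosen;
    an exact tie (floating-point equality) is resolved by a fair coin.
    """
    if test.params != comparison.params:
        raise TrialContractError("test and comparison must share stimulus parameters")
    if tuple(test.signal_counts) != tuple(comparison.signal_counts):
        raise TrialContractError("test and comparison must share per-direction signal counts")
    if test.layout is None:
        raise TrialContractError("test sequence must be segmented")
    if lattice is None:
        lattice = make_lattice(
            test.params.window_width, test.params.window_height, config.grid_spacing
        )
    diameter = choose_field_diameter(config, test.layout.segment_size, rng)
    s2_test = _sequence_variance(test, diameter, config, lattice, rng)
    s2_comp = _sequence_variance(comparison, diameter, config, lattice, rng)
    if s2_test == s2_comp:
        correct = bool(rng.integers(2))
        chosen = "test" if correct else "comparison"
        return TrialOutcome(s2_test, s2_comp, chosen, correct, True, diameter)
    correct = s2_test > s2_comp
    chosen = "test" if correct else "comparison"
    return TrialOutcome(s2_test, s2_comp, chosen, correct, False, diameter)
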