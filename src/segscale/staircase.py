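"""3-down/1-up adaptive staircases for acuity limits and coherence thresholds.

The stimulus level decreases (gets harder) after three consecutive correct
responses and increases after any error, tracking the 100 * 0.5**(1/3)
~ 79.4%-correct point. The step size halves at every reversal of movement
direction; a staircase terminates after 16 reversals and its threshold is
the arithmetic mean of the last six reversal levels. Reported thresholds
average at least five staircases.

Two measurement wrappers mirror the two psychophysical procedures: acuity
staircases vary segment size (degrees, initial step 3.5) at 100% coherence;
coherence staircases vary the number of signal dots (integer levels,
initial step equal to the total number of elements) at fixed segment size,
reporting the threshold as a percentage of the dots.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, List, Optional

import numpy as np

__all__ = [
    "StaircaseConfig",
    "StaircaseState",
    "StaircaseRun",
    "ThresholdEstimate",
    "StaircaseError",
    "update_staircase",
    "run_staircase",
    "measure_acuity",
    "measure_coherence_threshold",
    "acuity_staircase_config",
    "coherence_staircase_config",
    "dump_trace",
]

#: Default 7-point half-octave segment-size grid (degrees), 0.438-3.5.
SEGMENT_SIZE_GRID = tuple(float(v) for v in np.geomspace(0.438, 3.5, 7))


class StaircaseError(RuntimeError):
    """Raised when a staircase cannot terminate within its trial cap."""


@dataclass(frozen=True)
class StaircaseConfig:
    """Parameters of the adaptive rule.

    Steps are additive in the level's own units (degrees or dot counts) and
    halve at each reversal; with ``integer_levels`` the level is rounded and
    halved steps round up to at least one unit.
    """

    initial_level: float
    initial_step: float
    n_down: int = 3
    n_up: int = 1
    n_reversals: int = 16
    estimate_reversals: int = 6
    min_level: float = -math.inf
    max_level: float = math.inf
    integer_levels: bool = False
    max_trials: int = 2000

    def __post_init__(self) -> None:
        if self.initial_step <= 0:
            raise ValueError("initial_step must be > 0")
        if self.n_down < 1 or self.n_up < 1:
            raise ValueError("n_down and n_up must be >= 1")
        if self.n_reversals < self.estimate_reversals:
            raise ValueError("termination must cover the estimator window")
        if not (self.min_level <= self.initial_level <= self.max_level):
            raise ValueError("initial_level must lie within the clamps")

    @property
    def target_proportion(self) -> float:
        """Equilibrium percent-correct of the n-down/1-up rule (0.794 for 3-down)."""
        return 0.5 ** (1.0 / self.n_down)


@dataclass
class StaircaseState:
    """Mutable track state of one running staircase."""

    level: float
    step: float
    n_correct: int = 0
    n_incorrect: int = 0
    last_move: Optional[str] = None  # "up" | "down"
    reversal_levels: List[float] = field(default_factory=list)
    trial_count: int = 0


@dataclass
class StaircaseRun:
    """Completed staircase: estimate plus full trace."""

    estimate: float
    reversal_levels: List[float]
    n_trials: int
    trace: List[tuple]  # (trial, level, correct, reversal_flag)


def _halve_step(step: float, config: StaircaseConfig) -> float:
    step = step / 2.0
    if config.integer_levels:
        step = max(1.0, math.ceil(step))
    return step


def _clamp_level(level: float, config: StaircaseConfig) -> float:
    level = min(max(level, config.min_level), config.max_level)
    if config.integer_levels:
        level = float(round(level))
    return level


def update_staircase(
    state: StaircaseState, correct: bool, config: StaircaseConfig
) -> StaircaseState:
    """Apply one trial outcome to the staircase state (mutates and returns it).

    Three consecutive correct responses move the level down by the current
    step and reset the counter; any error moves it up. A change of movement
    direction records a reversal (the level at which it occurred) and halves
    the step *before* the move is applied. Levels are clamped; a clamp alone
    never records a reversal — only a true change of intended direction does.
    """
    state.trial_count += 1
    move = None
    if correct:
        state.n_correct += 1
        state.n_incorrect = 0
        if state.n_correct >= config.n_down:
            move = "down"
            state.n_correct = 0
    else:
        state.n_incorrect += 1
        state.n_correct = 0
        if state.n_incorrect >= config.n_up:
            move = "up"
            state.n_incorrect = 0
    if move is not None:
        if state.last_move is not None and move != state.last_move:
            state.reversal_levels.append(state.level)
            state.step = _halve_step(state.step, config)
        state.last_move = move
        delta = state.step if move == "up" else -state.step
        state.level = _clamp_level(state.level + delta, config)
    return state


def run_staircase(
    oracle: Callable[[float], bool], config: StaircaseConfig
) -> StaircaseRun:
    """Run a staircase against a trial oracle until 16 reversals.

    ``oracle(level)`` returns whether the simulated trial at that level was
    answered correctly. Returns the mean of the last ``estimate_reversals``
    reversal levels. Raises :class:`StaircaseError` if the trial cap is hit
    first (e.g. a non-terminating oracle).
    """
    state = StaircaseState(level=_clamp_level(config.initial_level, config), step=config.initial_step)
    trace: List[tuple] = []
    while len(state.reversal_levels) < config.n_reversals:
        if state.trial_count >= config.max_trials:
            raise StaircaseError(
                f"staircase did not terminate within {config.max_trials} trials "
                f"({len(state.reversal_levels)} reversals, level {state.level})"
            )
        level = state.level
        n_rev_before = len(state.reversal_levels)
        correct = bool(oracle(level))
        update_staircase(state, correct, config)
        trace.append((state.trial_count, level, correct, len(state.reversal_levels) > n_rev_before))
    estimate = float(np.mean(state.reversal_levels[-config.estimate_reversals:]))
    return StaircaseRun(
        estimate=estimate,
        reversal_levels=list(state.reversal_levels),
        n_trials=state.trial_count,
        trace=trace,
    )


@dataclass
class ThresholdEstimate:
    """Reversal-mean threshold averaged over repeated staircases."""

    value: float
    per_staircase_values: List[float]
    n_staircases: int

    def __post_init__(self) -> None:
        if self.n_staircases != len(self.per_staircase_values):
            raise ValueError("n_staircases must match the per-staircase list")


def acuity_staircase_config(
    *, initial_level: float = 3.5, initial_step: float = 3.5,
    min_level: float = 0.05, max_level: float = 3.5, max_trials: int = 2000,
) -> StaircaseConfig:
    """Acuity procedure: segment size varied at 100% coherence.

    Starts at the largest (easiest) segment size with a 3.5 deg initial
    step; the lower clamp keeps segment size strictly positive.
    """
    return StaircaseConfig(
        initial_level=initial_level, initial_step=initial_step,
        min_level=min_level, max_level=max_level, max_trials=max_trials,
    )


def coherence_staircase_config(
    *, n_dots: int = 256, max_trials: int = 2000
) -> StaircaseConfig:
    """Coherence procedure: signal-dot count varied at fixed segment size.

    Starts at 100% coherence with an initial step equal to the total number
    of elements; levels are integer dot counts clamped to [0, n_dots].
    """
    return StaircaseConfig(
        initial_level=float(n_dots), initial_step=float(n_dots),
        min_level=0.0, max_level=float(n_dots), integer_levels=True,
        max_trials=max_trials,
    )


def _run_repeated(
    make_oracle: Callable[[int], Callable[[float], bool]],
    config: StaircaseConfig,
    n_staircases: int,
) -> tuple:
    if n_staircases < 5:
        raise ValueError("thresholds average at least five staircases")
    runs = [run_staircase(make_oracle(i), config) for i in range(n_staircases)]
    return runs


def measure_acuity(
    trial_fn: Callable[[float, np.random.Generator], bool],
    rng: np.random.Generator,
    n_staircases: int = 5,
    config: Optional[StaircaseConfig] = None,
) -> ThresholdEstimate:
    """Acuity limit: mean of >= 5 segment-size staircases at 100% coherence.

    ``trial_fn(segment_size, rng)`` simulates one trial and reports
    correctness.
    """
    config = config or acuity_staircase_config()
    children = rng.spawn(n_staircases)

    def make_oracle(i: int):
        child = children[i]
        return lambda level: trial_fn(float(level), child)

    runs = _run_repeated(make_oracle, config, n_staircases)
    values = [r.estimate for r in runs]
    return ThresholdEstimate(float(np.mean(values)), values, n_staircases)


def measure_coherence_threshold(
    trial_fn: Callable[[int, np.random.Generator], bool],
    rng: np.random.Generator,
    n_dots: int = 256,
    n_staircases: int = 5,
    config: Optional[StaircaseConfig] = None,
) -> ThresholdEstimate:
    """Coherence threshold (percent): mean of >= 5 signal-dot staircases.

    ``trial_fn(n_signal, rng)`` simulates one trial at an integer signal-dot
    count; the estimate is converted to percent coherence (dots / n_dots
    x 100).
    """
    config = config or coherence_staircase_config(n_dots=n_dots)
    children = rng.spawn(n_staircases)

    def make_oracle(i: int):
        child = children[i]
        return lambda level: trial_fn(int(round(level)), child)

    runs = _run_repeated(make_oracle, config, n_staircases)
    values = [r.estimate / n_dots * 100.0 for r in runs]
    return ThresholdEstimate(float(np.mean(values)), values, n_staircases)


def dump_trace(run: StaircaseRun, path) -> None:
    """Write one staircase trace as delimited text (trial, level, outcome, reversal)."""
    with open(path, "w") as fh:
        fh.write("trial\tlevel\tcorrect\treversal\n")
        for trial, level, correct, reversal in run.trace:
            fh.write(f"{trial}\t{level:.6f}\t{int(correct)}\t{int(reversal)}\n")
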