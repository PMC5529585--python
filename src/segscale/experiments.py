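"""The four model-observer experiments on integration-field scale selection.

Each experiment measures, for every level of its manipulated variable, the
spatial acuity limit (segment-size staircases at 100% coherence) and a full
coherence-threshold-versus-segment-size curve (signal-dot staircases at
each of 7 half-octave segment sizes from 0.438 to 3.5 deg), then fits the
two-limbed function to the curve:

* **fixed** — the integration-field diameter is constant across trials;
  thresholds become asymptotic near the field size (the knee tracks the
  field diameter) and the acuity limit grows with it.
* **proportional** — field diameter = ratio x segment size; performance is
  best when the field matches the segment (ratio 1) and collapses when the
  field is larger than the segment.
* **bounded** — the field is limited to [0.62, 1.24] deg and either
  *matched* (segment size clamped to the bounds) or *random* (drawn
  uniformly within the bounds on every trial). Random, sub-optimal
  selection shallows the descending limb and pushes the knee outward
  without changing the acuity limit or asymptotic threshold — the pattern
  seen in the poorest readers.
* **noise** — matched bounded fields with Gaussian internal direction noise
  (SD 0-90 deg); heavy noise raises the acuity limit and the asymptotic
  threshold but leaves knee and slope unchanged — the opposite dissociation.

Model trials use 2-frame, 256-dot stimuli for speed; directions are read
from the assigned per-dot directions, which for 2 frames coincide with the
frame-to-frame displacements.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .curvefit import CurveFit, ThresholdCurve, fit_two_limb
from .observer import ObserverConfig, decide_trial, make_lattice
from .staircase import (
    SEGMENT_SIZE_GRID,
    ThresholdEstimate,
    acuity_staircase_config,
    coherence_staircase_config,
    measure_acuity,
    measure_coherence_threshold,
)
from .stimuli import (
    StimulusParams,
    build_segment_layout,
    model_params,
    sample_comparison_stimulus,
    sample_test_stimulus,
)

__all__ = [
    "CONDITIONS",
    "DEFAULT_FIXED_DIAMETERS",
    "DEFAULT_RATIOS",
    "DEFAULT_BOUNDED_MODES",
    "DEFAULT_NOISE_SDS",
    "ExperimentSpec",
    "LevelResult",
    "ExperimentResult",
    "ModelObserverTask",
    "run_experiment",
    "run_fixed_field",
    "run_proportional_field",
    "run_bounded_selection",
    "run_internal_noise",
]

CONDITIONS = ("fixed", "proportional", "bounded", "noise")

DEFAULT_FIXED_DIAMETERS = SEGMENT_SIZE_GRID
DEFAULT_RATIOS = (0.25, 0.5, 1.0, 2.0)
DEFAULT_BOUNDED_MODES = ("matched", "random")
DEFAULT_NOISE_SDS = (0.0, 30.0, 60.0, 90.0)


@dataclass(frozen=True)
class ExperimentSpec:
    """One experiment: a condition, its levels, and simulation sizes."""

    condition: str
    levels: tuple
    segment_sizes: tuple = SEGMENT_SIZE_GRID
    staircases_per_point: int = 5
    grid_spacing: float = 0.14
    n_frames: int = 2
    seed: int = 0
    max_trials_per_staircase: int = 2000
    lower_bound: float = 0.62
    upper_bound: float = 1.24

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        if not self.levels:
            raise ValueError("levels must be non-empty")
        if self.staircases_per_point < 5:
            raise ValueError("thresholds average at least five staircases")


@dataclass
class LevelResult:
    """Acuity, threshold curve and two-limbed fit at one condition level."""

    level: object
    acuity: ThresholdEstimate
    curve: ThresholdCurve
    threshold_estimates: list
    fit: CurveFit
    n_trials: int


@dataclass
class ExperimentResult:
    """All level results of one experiment plus run metadata."""

    spec: ExperimentSpec
    levels: list  # list[LevelResult]
    metadata: dict

    def fits_frame(self) -> pd.DataFrame:
        rows = []
        for lr in self.levels:
            rows.append(dict(
                condition=self.spec.condition, level=lr.level,
                acuity=lr.acuity.value, k=lr.fit.k, t=lr.fit.t, s=lr.fit.s,
                r2=lr.fit.r2, clamped=lr.fit.clamped, n_trials=lr.n_trials,
            ))
        return pd.DataFrame(rows)

    def curves_frame(self) -> pd.DataFrame:
        rows = []
        for lr in self.levels:
            for seg, thr in zip(lr.curve.x, lr.curve.y):
                rows.append(dict(condition=self.spec.condition, level=lr.level,
                                 segment_size=float(seg), threshold=float(thr)))
        return pd.DataFrame(rows)

    def save(self, outdir) -> None:
        import pathlib

        out = pathlib.Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.fits_frame().to_csv(out / "fits.csv", index=False)
        self.curves_frame().to_csv(out / "curves.csv", index=False)
        with open(out / "metadata.json", "w") as fh:
            json.dump(self.metadata, fh, indent=2)


def _observer_config(spec: ExperimentSpec, level) -> ObserverConfig:
    common = dict(grid_spacing=spec.grid_spacing,
                  lower_bound=spec.lower_bound, upper_bound=spec.upper_bound)
    if spec.condition == "fixed":
        return ObserverConfig(policy="fixed", field_diameter=float(level), **common)
    if spec.condition == "proportional":
        return ObserverConfig(policy="proportional", ratio=float(level), **common)
    if spec.condition == "bounded":
        if level not in DEFAULT_BOUNDED_MODES:
            raise ValueError("bounded levels are 'matched' or 'random'")
        policy = "bounded_matched" if level == "matched" else "bounded_random"
        return ObserverConfig(policy=policy, **common)
    # noise: matched bounded fields with internal direction noise
    return ObserverConfig(policy="bounded_matched", noise_sd=float(level), **common)


class ModelObserverTask:
    """Bundles stimulus parameters, observer config and lattice for trials."""

    def __init__(self, config: ObserverConfig, params: Optional[StimulusParams] = None):
        self.config = config
        self.params = params or model_params()
        self.lattice = make_lattice(
            self.params.window_width, self.params.window_height, config.grid_spacing
        )
        self.n_trials = 0

    def run_trial(self, segment_size: float, n_signal: int, rng: np.random.Generator) -> bool:
        """One two-alternative trial: fresh layout, matched stimulus pair."""
        self.n_trials += 1
        layout = build_segment_layout(self.params.window_height, segment_size, rng)
        coherence = n_signal / self.params.n_dots
        test = sample_test_stimulus(self.params, layout, coherence, rng)
        nr, nl = test.signal_counts
        comp = sample_comparison_stimulus(
            self.params, (nr, nl), self.params.n_dots - nr - nl, rng
        )
        return decide_trial(test, comp, self.config, rng, self.lattice).correct


def _measure_level(spec: ExperimentSpec, level, rng: np.random.Generator) -> LevelResult:
    task = ModelObserverTask(
        _observer_config(spec, level), params=StimulusParams(n_frames=spec.n_frames)
    )

    acuity = measure_acuity(
        lambda seg, r: task.run_trial(seg, task.params.n_dots, r),
        rng,
        n_staircases=spec.staircases_per_point,
        config=acuity_staircase_config(max_trials=spec.max_trials_per_staircase),
    )

    estimates = []
    for seg in spec.segment_sizes:
        est = measure_coherence_threshold(
            lambda dots, r, seg=seg: task.run_trial(seg, dots, r),
            rng,
            n_dots=task.params.n_dots,
            n_staircases=spec.staircases_per_point,
            config=coherence_staircase_config(
                n_dots=task.params.n_dots, max_trials=spec.max_trials_per_staircase
            ),
        )
        estimates.append(est)
    y = np.clip([e.value for e in estimates], 1e-6, 100.0)
    curve = ThresholdCurve(np.asarray(spec.segment_sizes, dtype=float), y)
    fit = fit_two_limb(curve)
    return LevelResult(level=level, acuity=acuity, curve=curve,
                       threshold_estimates=estimates, fit=fit, n_trials=task.n_trials)


def run_experiment(spec: ExperimentSpec) -> ExperimentResult:
    """Run one experiment across all its levels, reproducibly seeded."""
    root = np.random.default_rng(spec.seed)
    level_rngs = root.spawn(len(spec.levels))
    results = [_measure_level(spec, level, r) for level, r in zip(spec.levels, level_rngs)]
    metadata = dict(
        condition=spec.condition,
        levels=[str(l) for l in spec.levels],
        segment_sizes=[float(s) for s in spec.segment_sizes],
        staircases_per_point=spec.staircases_per_point,
        grid_spacing=spec.grid_spacing,
        n_frames=spec.n_frames,
        seed=spec.seed,
        total_trials=int(sum(lr.n_trials for lr in results)),
    )
    return ExperimentResult(spec=spec, levels=results, metadata=metadata)


def run_fixed_field(
    diameters: Sequence[float] = DEFAULT_FIXED_DIAMETERS, **kwargs
) -> ExperimentResult:
    """Fixed integration-field diameters (default: the 7-point grid)."""
    return run_experiment(ExperimentSpec("fixed", tuple(diameters), **kwargs))


def run_proportional_field(
    ratios: Sequence[float] = DEFAULT_RATIOS, **kwargs
) -> ExperimentResult:
    """Field diameter proportional to segment size; ratios must include 1.0."""
    ratios = tuple(ratios)
    if 1.0 not in ratios:
        raise ValueError("ratios must include the matched ratio 1.0")
    return run_experiment(ExperimentSpec("proportional", ratios, **kwargs))


def run_bounded_selection(
    modes: Sequence[str] = DEFAULT_BOUNDED_MODES, **kwargs
) -> ExperimentResult:
    """Bounded fields, matched (clamped) versus random per-trial selection."""
    return run_experiment(ExperimentSpec("bounded", tuple(modes), **kwargs))


def run_internal_noise(
    noise_sds: Sequence[float] = DEFAULT_NOISE_SDS, **kwargs
) -> ExperimentResult:
    """Matched bounded fields with Gaussian internal direction noise (deg SD)."""
    return run_experiment(ExperimentSpec("noise", tuple(noise_sds), **kwargs))
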