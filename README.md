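# segscale

Simulation and analysis of motion- and form-based visual segmentation
psychophysics, built around the question of how the visual system selects
a *spatial scale* for pooling local motion — and how sub-optimal scale
selection could limit object segmentation in poor readers.

The package is aimed at visual psychophysicists and computational
modellers. It provides, as a library with a thin CLI:

- **Stimuli** — random-dot kinematograms divided into horizontal bands of
  opposing motion (test) versus spatially intermingled patterns with
  identical motion cues (comparison), plus static form patterns of
  superimposed dot streaks.
- **Model observer** — opponent-motion pooling in circular integration
  fields on a spatial lattice, `R_ij = Σ_d cos θ_d`, with the spatial
  variance `σ² = (1/n) Σ (R_mean − R_ij)²` as the decision variable and
  four field-size policies (fixed, proportional to segment size, bounded
  matched, bounded random).
- **Adaptive staircases** — 3-down/1-up tracks (79.4% correct) with
  reversal-halved steps, 16-reversal termination and last-six-reversal
  estimates, for acuity limits and coherence thresholds.
- **Two-limbed fits** — `y = t·(x/k)^s` below the knee `k`, flat at the
  asymptote `t` beyond it, with a conservative clamp at the largest
  tested segment size.
- **Synthetic cohorts and statistics** — single-factor reading batteries
  with optional planted effects on the motion knee and slope, and the
  eight-test analysis: PCA reading composite, semi-partial Spearman
  correlations controlling gender and IQ, Benjamini–Hochberg FDR
  control, and Cohen's d = 2r/√(1−r²).

See `docs/methods.md` for the full model description, parameter defaults
and known limitations.

## Worked example

`examples/fixed_field_observer.py` runs the complete psychophysical
procedure on the model observer with a fixed 0.88-deg integration field
(coarsened lattice for speed):

```text
acuity limit      : 0.431 deg (100% coherence)
segment sizes     : [0.438 0.619 0.876 1.238 1.751 2.475 3.5  ]
thresholds (%)    : [82.5 31.2 29.7 22.5 22.2 19.6 17.4]
two-limbed fit    : knee k=0.70 deg, asymptote t=22.3%, slope s=-2.81, R^2=0.972
trials simulated  : 3008
```

Coherence thresholds fall steeply with segment size and flatten once the
segments exceed the pooling field: the fitted knee sits near the 0.88-deg
field diameter (averages over replicate runs land at ~0.85 deg), i.e. the
scale of motion pooling sets the scale of segmentation. The acuity limit
is the smallest segment size discriminable at full coherence.

`examples/cohort_to_stats.py` shows the statistics stage on a synthetic
cohort with planted reading effects: only the motion knee and slope rows
come out significant, with negative correlations (poorer readers — larger
knees, shallower slopes), e.g.

```text
  task outcome   r_s  p_adjusted     d  significant
motion       k -0.38      0.0000 -0.82         True
motion       s -0.28      0.0003 -0.58         True
```

Other examples cover stimulus generation, a single staircase run, and
curve fitting. The `segscale` CLI exposes the same stages
(`segscale cohort | stats | fit | experiment --help`).

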