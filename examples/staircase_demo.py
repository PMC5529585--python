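"""Run one 3-down/1-up staircase against a known psychometric observer.

The simulated observer answers a two-alternative task correctly with a
logistic probability that rises with stimulus level, so the staircase's
reversal-mean estimate should sit near the level where the observer is
~79.4% correct (the 0.5**(1/3) equilibrium of the 3-down/1-up rule). The
script prints the trial count, the reversal levels and the percent correct
at the recovered threshold.
"""

import numpy as np

from segscale import StaircaseConfig, run_staircase

rng = np.random.default_rng(3)


def p_correct(level):
    return 0.5 + 0.5 / (1.0 + np.exp(-(level - 2.0) / 0.35))


config = StaircaseConfig(initial_level=4.0, initial_step=1.0, min_level=0.0, max_level=4.0)
run = run_staircase(lambda level: bool(rng.uniform() < p_correct(level)), config)

print(f"trials to 16 reversals : {run.n_trials}")
print("reversal levels        :", np.round(run.reversal_levels, 3))
print(f"threshold (last six)   : {run.estimate:.3f}")
print(f"percent correct there  : {100 * p_correct(run.estimate):.1f}%"
      " (3-down/1-up tracks 79.4%)")
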