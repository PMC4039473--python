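"""Measure contrast thresholds with transformed up-down staircases.

A simulated observer with a known Weibull psychometric answers the
above/below-fixation task; two interleaved staircases per condition
(one-up one-down until the first error, then one-up two-down) drive the
contrast to the 70.71%-correct point, and the threshold is the mean of
each staircase's last 20 trials.
"""

import numpy as np

from cfskit.psychophysics import (CONVERGENCE_P, ObserverModel,
                                  estimate_session_thresholds,
                                  measure_convergence, plan_session,
                                  simulate_session)

observer = ObserverModel(alpha={"easy": 0.02, "hard": 0.08}, beta=3.5,
                         lapse=0.0)

conv = measure_convergence(observer, "hard", n_main_trials=3000, seed=1)
print(f"staircase converges at {conv['percent_correct']:.2f}% correct "
      f"(theory: {100 * CONVERGENCE_P:.2f}%)")

plan = plan_session(["easy", "hard"], n_per_staircase=65, seed=2)
print(f"session: {plan.n_trials} trials "
      f"({len(plan.start_levels)} interleaved staircases)")

trials, states = simulate_session(plan, observer, seed=3)
est = estimate_session_thresholds(plan, states)
print(est.table.to_string(index=False))
for cond in ("easy", "hard"):
    target = observer.alpha[cond] * (-np.log(1 - (CONVERGENCE_P - 0.5)
                                             / 0.5)) ** (1 / observer.beta)
    print(f"  {cond}: 70.71%-point of the true psychometric = {target:.4f}")
# Thresholds sit near each condition's true 70.71% contrast; the
# normalized column divides by the session mean (and itself averages to 1).
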