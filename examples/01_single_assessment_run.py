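"""Simulate one participant taking one adaptive assessment.

Builds a logistic observer whose true 79.4%-correct threshold is 8 items
on Scene Crasher (a change-detection task whose adaptive dimension is set
size), runs the 3-down-1-up staircase, and prints the trial count, exit
reason and threshold estimate.  The score should land near the planted
threshold: the staircase's stationary point is exactly the level where
the observer is 79.4% correct.
"""

import numpy as np

import cogbattery as cb

spec = cb.get_spec("Scene Crasher")
observer = cb.ObserverModel(theta80=8.0, slope=1.5, guess_rate=0.0, lapse_rate=0.02)
rng = np.random.default_rng(0)

run = cb.run_assessment(spec, observer, rng, participant_id="demo")
print(f"assessment:   {run.assessment}")
print(f"trials:       {run.n_trials} ({run.duration_min:.1f} min)")
print(f"reversals:    {run.n_reversals}")
print(f"exit reason:  {run.exit_reason}")
print(f"score:        {run.score:.2f}  (planted threshold {observer.theta80})")

scores = [cb.run_assessment(spec, observer, rng).score for _ in range(500)]
print(f"mean over 500 runs: {np.mean(scores):.2f} — converges onto the planted 79.4% point")
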