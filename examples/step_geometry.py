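"""Base-step parameters from base reference frames and back.

Builds an ideal helix from a repeated step, then recovers the parameters
of a jittered chain.
"""

import numpy as np

from oxidna.ensemble import StepParameters
from oxidna.geometry import BaseFrame, build_step, helix_fixture, step_parameters

# One ideal B-form-like step: 3.4 A rise, 36 deg twist.
p = StepParameters(1, 0.0, 0.0, 3.4, 0.0, 0.0, 36.0)
f = BaseFrame.identity()
for _ in range(10):
    f = build_step(f, p)
print(f"10 ideal steps advance to z = {f.origin[2]:.1f} A with a full 360-degree turn")
print(f"final triad deviates from identity by {np.abs(f.triad - np.eye(3)).max():.2e}")

# Jittered chain: recover the step parameters and their spread.
frames = helix_fixture(200, p, jitter=[0.3, 0.3, 0.2, 4.0, 4.0, 6.0], seed=1)
rec = np.array([step_parameters(a, b).as_tuple() for a, b in zip(frames, frames[1:])])
names = ("shift", "slide", "rise", "tilt", "roll", "twist")
for name, mean, sd in zip(names, rec.mean(axis=0), rec.std(axis=0, ddof=1)):
    print(f"  {name:>5}: {mean:7.2f} +/- {sd:.2f}")
print("means match the generating step and the spreads match the jitter sigmas")
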