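"""Two-stage learning: the tutor discovers its signal from reward.

The tutor starts with a flat firing-rate program and no knowledge of
the student-output map.  On every rendition it correlates its own rate
fluctuations with the (baseline-subtracted) instantaneous reward and
nudges its program toward rewarded fluctuations; the student
simultaneously consolidates the tutor signal through the
reward-independent heterosynaptic rule.  Much slower than tutoring
with known credit, but converges to a comparable final accuracy.
"""

import numpy as np

from songlearn import (
    PlasticityParams,
    TutorSpec,
    rate_preset,
    run_reinforcement,
)

cfg = rate_preset(
    seed=1,
    n_renditions=4000,
    plasticity=PlasticityParams(alpha=-1.0, beta=-2.0, eta=6e-4),
    tutor=TutorSpec(mode="reinforcement", tau_tutor=0.0, zeta=120.0, eta_tutor=0.02),
)
trace = run_reinforcement(cfg)

print("memory-less reinforcement tutor (tau_tutor = 0)")
for k in (0, 500, 1000, 2000, 3000, 3999):
    window = trace.losses[max(0, k - 50) : k + 50]
    print(f"rendition {k:4d}: loss {np.median(window):.4f}")
ratio = np.median(trace.losses[-100:]) / trace.losses[0]
print(f"final loss is {ratio:.1%} of initial (exploration noise sets the floor)")
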