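"""Tutor-student mismatch sweep (reduced grid).

Varies the plasticity rule (via alpha, with alpha - beta = 1 and
tau1 = 80 ms, tau2 = 40 ms fixed) so its implied matched timescale
tau* spans 40 ms - 1 s, and independently forces the tutor to
integrate the motor error on each of the same timescales.  Cells on
the diagonal are matched pairs.  The printed matrix holds final/initial
loss after 200 renditions: ~0 means learned, ~1 stalled, >1 the output
drifted away from the target (tutor much faster than matched).
"""

import numpy as np

from songlearn import rate_preset, run_mismatch_sweep

cfg = rate_preset(seed=3, n_renditions=200)
res = run_mismatch_sweep(cfg, n_seeds=1)

ratio = res.final_loss / res.initial_loss
header = "tau*\\tau_t " + " ".join(f"{t * 1e3:7.0f}ms" for t in res.tau_tutor)
print(header)
for i, ts in enumerate(res.tau_star):
    row = " ".join(f"{ratio[i, j]:9.3f}" for j in range(len(res.tau_tutor)))
    print(f"{ts * 1e3:7.0f}ms  {row}")
print("\ndiagonal = matched pairs; below-diagonal cells show disrupted learning")
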