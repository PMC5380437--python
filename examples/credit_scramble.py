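"""Robustness of learning to credit-assignment errors.

The tutor needs to know which output channel each student neuron
drives.  Here a fraction rho of the student neurons is attributed to
the wrong channel when the tutor computes the motor error, while the
true map still produces the output.  Learning tolerates sizeable
mis-assignment but collapses as rho approaches 50%, where the tutor's
credit carries no information.
"""

from songlearn import rate_preset, run_credit_scramble

cfg = rate_preset(seed=5, n_renditions=1000)
print("scrambled fraction -> final/initial loss after 1000 renditions")
for rho in (0.0, 0.1, 0.2, 0.3, 0.4, 0.5):
    trace = run_credit_scramble(cfg, rho)
    print(f"  rho = {rho:.1f}: {trace.losses[-1] / trace.losses[0]:6.1%}")
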