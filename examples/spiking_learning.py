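"""Matched learning in the spiking (LIF) student network.

A reduced songbird-like network (150 conductor neurons firing jittered
5-6-spike bursts, 40 LIF student neurons with AMPA/NMDA synapses and
global inhibition) learns a two-channel smooth target under a
saturating Poisson tutor matched to the timing-based plasticity rule
(alpha=1, beta=0, tau_tutor = tau* = 80 ms).  Prints the loss drop and
how the student's firing statistics change from the irregular, 'juvenile'
regime toward burstier trained activity.
"""

import numpy as np

from songlearn import spiking_preset, run_matched, spike_statistics

cfg = spiking_preset(seed=1, n_renditions=300)
trace = run_matched(cfg)

print(f"tutor timescale: {cfg.resolved_tau_tutor() * 1e3:.0f} ms (matched)")
print(f"initial loss: {np.median(trace.losses[:5]):.0f}")
print(f"final loss:   {np.median(trace.losses[-20:]):.0f}")
ratio = np.median(trace.losses[-20:]) / np.median(trace.losses[:5])
print(f"reduction to {ratio * 100:.0f}% of initial")

for cp in trace.checkpoints:
    if "raster" in cp:
        s = spike_statistics(cp["raster"], 0.010, grid=cfg.grid())
        tag = "untrained" if cp["rendition"] == 0 else "trained  "
        print(
            f"{tag} student: rate {s.mean_rate:5.1f} Hz, ISI CV {s.isi_cv:.2f}, "
            f"bursts/s {s.burst_frequency:.1f}"
        )
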