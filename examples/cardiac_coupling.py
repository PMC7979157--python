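"""Cardiac coupling of flow pulsatility: conditional averages and delays.

Simulates a scene whose flow pulses 0.05 s after each ECG R-wave, runs the
full pipeline, and shows that (i) the Vrms peak delay recovers the imposed
lag and (ii) conditionally averaging over the respiratory cycle shows no
spurious modulation when none was generated.
"""

import numpy as np

from pvsflow import SceneConfig, analyze_stack, simulate

cfg = SceneConfig(image_size=(224, 224), duration=15.0, centerline_speed=30.0,
                  cardiac_amplitude=0.02, cardiac_lag=0.05,
                  respiratory_amplitude=0.0, heart_rate=5.0, heart_jitter=0.02,
                  n_particles=60, stagnant_fraction=0.0, rng_seed=1)
stack, truth = simulate(cfg, seed=1)
result = analyze_stack(stack, truth.ecg, truth.respiration,
                       heart_rate_hint=cfg.heart_rate,
                       resp_rate_hint=cfg.resp_rate)

d = result.cardiac_delay
print(f"generated cardiac lag : {cfg.cardiac_lag:.3f} s")
print(f"recovered mean delta-t: {d.mean:.4f} +/- {d.sem:.4f} s "
      f"(n = {d.n} beats)")

cond = result.respiratory
dev = np.nanmax(np.abs(cond["mean"] - np.nanmean(cond["mean"])) / cond["sem"])
print(f"respiratory conditional average: max |deviation| = {dev:.2f} SEM "
      f"(flat; no respiratory drive was generated)")
# The delay-time distribution ties each ECG peak to the next Vrms peak; a
# mean near the generated lag shows the pulsatile flow component is locked
# to the cardiac cycle, while the flat respiratory curve shows the method
# does not invent coupling that is not there.
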