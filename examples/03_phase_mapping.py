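"""Traveling-wave phase mapping: encode a macaque subject's retinotopy in
wedge (8 cycles x 40 s) and ring (7 cycles x 40 s + 10 s blanks) time
series, decode it back by Fourier analysis, and cancel the hemodynamic
delay by combining opposite stimulus directions.
"""

import numpy as np

import sulcmap as sm

preset = sm.macaque_preset()
pial, white, truth = sm.generate_v1_patch(preset, seed=2)

spec_f = sm.StimulusSpec(kind="wedge", tr=2.0, direction=+1)
spec_r = sm.StimulusSpec(kind="wedge", tr=2.0, direction=-1)
ts_f = sm.generate_timeseries(truth, spec_f, noise_sd=0.5,
                              hemodynamic_delay=4.0, seed=2)
ts_r = sm.generate_timeseries(truth, spec_r, noise_sd=0.5,
                              hemodynamic_delay=4.0, seed=3)

pm = sm.combine_directions(sm.fourier_phase(ts_f, spec_f),
                           sm.fourier_phase(ts_r, spec_r))
decoded = sm.phase_to_visual(pm, spec_f)
err = np.abs(sm.wrap_angle_deg(decoded.values -
                               truth.true_map.polar_angle.values))
ok = decoded.valid_mask
print(f"wedge run: {spec_f.n_samples} samples, 4 s delay, noise sd 0.5")
print(f"decoded polar angle: median |error| = {np.median(err[ok]):.2f} deg "
      f"over {ok.sum()} coherent vertices "
      f"(median coherence {np.median(pm.coherence.values):.2f})")

# The common 4 s hemodynamic delay cancels in the direction combination,
# so the residual angular error reflects only the injected noise.
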