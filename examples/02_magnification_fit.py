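"""Fit the exponential cortical magnification function to a synthetic
subject: E = a(e^(b*d_hat) - 1), where d_hat is the geodesic distance of
each V1 vertex from the foveal confluence line.
"""

import sulcmap as sm

preset = sm.human_preset()
pial, white, truth = sm.generate_v1_patch(preset, seed=1)

for label, rmap in (("noiseless", truth.true_map),
                    ("default noise", sm.add_measurement_noise(truth, seed=1))):
    deli = sm.delineate_v1(rmap, pial, ecc_max=preset.stimulus_radius)
    samples = sm.collect_samples(rmap, deli, truth.labels)
    fit = sm.fit_cmf(samples["d_hat"], samples["ecc"])
    print(f"{label}: a = {fit.a:.4f} deg (truth {preset.cmf_a}), "
          f"b = {fit.b:.5f} /mm (truth {preset.cmf_b}), "
          f"r^2 = {fit.r_squared:.4f}, n = {fit.n_samples}")

# The noiseless fit recovers the generating parameters to well under 1%
# (the residual error is mesh discretization); with measurement noise the
# fit stays close and r^2 drops, as it does for real retinotopy data.
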