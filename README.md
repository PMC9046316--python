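# sulcmap

Sulcal–retinotopic coupling in primary visual cortex (V1), on triangulated
cortical surfaces.

The same occipital sulcus can map different parts of the visual field in
different primate species: the retrocalcarine sulcus (rCaS, the bifurcated
posterior end of the calcarine) represents ~2–5° of eccentricity in
humans but ~7–10° in macaques, while the external calcarine sulcus (eCaS)
holds central representations in both. `sulcmap` implements the analysis
chain needed to quantify this kind of structure–function coupling from
per-vertex retinotopic maps:

- **surface I/O** — FreeSurfer binary surfaces, curv overlays and label
  files; GIFTI surf/func/label; CSV overlays; JSON label sets;
- **mesh geometry** — triangle/vertex areas (one-third attribution, so
  partition areas are additive) and multi-source geodesic distances along
  the edge graph;
- **phase mapping** — Fourier analysis of traveling-wave (rotating wedge /
  expanding ring) time series: amplitude, phase, coherence, opposite-
  direction combination that cancels the hemodynamic delay, and decoding
  to polar angle / eccentricity;
- **V1 delineation** — vertical-meridian borders from polar-angle
  reversals, the foveal-confluence line, and geodesic
  distance-from-fovea for every V1 vertex;
- **cortical magnification** — the exponential fit

  ```
  E = a (e^{b·d̂} − 1)
  ```

  of eccentricity `E` (deg) against cortical distance from the foveal
  confluence `d̂` (mm), plus the 0.5° × 1 mm 2D histogram with per-sulcus
  isocontours at 99/75/50/25% of each sulcus' peak bin;
- **sulcal metrics** — pial/white areas, %V1, mean eccentricity and
  ranges per sulcus; visual-field coverage (pol→cart); group overlap maps;
- **statistics** — species × hemisphere two-way ANOVA (Type II when
  unbalanced) and group mean ± SEM tables;
- **synthetic data** — a folded-V1 generator (wedge-shaped sheet,
  calcarine-like trough, retrocalcarine/external-calcarine folds at
  species-specific eccentricity bands, measurement noise, traveling-wave
  time series) with human and macaque presets, used as ground truth
  throughout the test suite.

See `docs/methods.md` for the models, conventions (polar angle: 0° =
contralateral horizontal meridian, +90° = upper vertical meridian), and
limitations.

## Worked example

```python
import sulcmap as sm

preset = sm.human_preset()                      # a=1.0°, b=0.063/mm, 8° field
pial, white, truth = sm.generate_v1_patch(preset, seed=1)
rmap = sm.add_measurement_noise(truth, seed=1)  # 3° angle sd, 10% ecc noise

deli = sm.delineate_v1(rmap, pial, ecc_max=preset.stimulus_radius)
samples = sm.collect_samples(rmap, deli, truth.labels)
fit = sm.fit_cmf(samples["d_hat"], samples["ecc"])
print(f"a = {fit.a:.3f} deg, b = {fit.b:.4f} /mm, r^2 = {fit.r_squared:.3f}")

s = sm.summarize_sulcus(rmap, pial, white, truth.labels, deli, "rCaS")
print(f"rCaS: mean ecc {s.mean_ecc:.2f} deg, {s.pct_of_v1:.1f}% of V1")
```

prints (seed 1):

```
a = 1.180 deg, b = 0.0589 /mm, r^2 = 0.977
rCaS: mean ecc 3.33 deg, 30.2% of V1
```

The fitted magnification parameters sit near the generating values (the
offset reflects the injected measurement noise; the noiseless fit
recovers them to <1%), and the retrocalcarine's mean eccentricity falls
inside its 2–5° human band. Running the same analysis on a macaque
subject puts the rCaS near 8° — the species contrast at the heart of the
package. The `examples/` directory holds one short script per capability
(simulation, magnification fit, phase mapping, species comparison), and
the `sulcmap` CLI (`simulate`, `phasemap`, `delineate`, `magnify`,
`summarize`, `compare`, `run`) exposes the same stages on files.

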