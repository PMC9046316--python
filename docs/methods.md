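# Methods

`sulcmap` quantifies how occipital sulci — the retrocalcarine sulcus
(rCaS) and the external calcarine sulcus (eCaS) — couple to the
retinotopic map of primary visual cortex (V1), on triangulated cortical
surfaces. This note documents the models, the synthetic-data generator,
the numerical choices, and the limits of what the test suite shows.

## The analysis chain

Given a cortical hemisphere mesh, a per-vertex retinotopic map (polar
angle and eccentricity in degrees of visual angle, optional coherence),
and sulcal vertex labels, the pipeline computes:

1. **V1 delineation.** The V1/V2 border lies at vertical-meridian
   representations. Vertices within `tol_deg` (default 10°) of the lower
   (−90°) and upper (+90°) vertical meridians are banded; each band's
   largest connected component is thinned to a shortest path from its most
   foveal to its most peripheral vertex, with edge weights penalized by
   angular distance from the meridian so the path tracks the meridian
   representation. Banding-plus-thinning is a reproducible surrogate for
   the manual border drawing used with real data; no quantitative reversal
   criterion exists to replicate, so exact border placement on real data
   is out of reach by design.
2. **Foveal confluence.** A curved line through the most foveal
   measurements linking the foveal endpoints of the two borders: a
   shortest path with edge weights `length · (1 + E_mid/E_scale)`
   (`E_scale` = 1°), so the path prefers low-eccentricity cortex. If any
   measured path vertex exceeds the 5% quantile of V1 eccentricity
   (+0.5°), a warning is logged. The vertical-meridian border is hard to
   measure inside the fovea with fMRI, which is why a line (rather than a
   point) anchors the distance computation.
3. **Distance from the fovea.** Multi-source Dijkstra over the edge graph
   (edge weight = Euclidean edge length) from all confluence-line
   vertices; a `midpoint` mode treats the confluence as a single point at
   the line's middle vertex. Edge-graph geodesics overestimate true
   surface distance by at most ~8.2% in the worst direction on a grid
   with both diagonals (1/cos(π/8)); the package documents and tests a 9%
   bound. Exact polyhedral geodesics were deliberately not used:
   simplicity, determinism, and no heavy dependency, at a documented and
   tested fidelity.
4. **Cortical magnification.** Eccentricity vs. cortical distance for all
   valid V1 vertices is fit with the exponential

       E(d̂) = a · (e^{b·d̂} − 1),   a > 0 [deg], b > 0 [1/mm]

   by bounded trust-region least squares (`scipy.optimize.least_squares`,
   init (a₀, b₀) = (1.0, 0.05), bounds a ∈ (1e−6, 50], b ∈ (1e−6, 1]).
   The −1 term forces E(0) = 0 so the curve can accommodate foveal (<1°)
   measurements. r² = 1 − SSE/SST is reported per fitted sample set (per
   hemisphere). Degenerate inputs (<10 samples, or <5 mm distance span)
   return `converged=False` with diagnostics rather than a silent fit.
5. **2D histogram & isocontours.** Counts over 0.5° eccentricity × 1 mm
   distance bins, edges anchored at 0 (half-open). Per-sulcus isocontours
   are marching-squares level sets (scikit-image `find_contours` on the
   zero-padded sub-histogram) at 99/75/50/25% of that sulcus' maximum
   bin. The 99% (not 100%) level is kept even though it typically yields
   a tiny contour around the mode.
6. **Sulcal summaries.** Areas on the pial and white surfaces by
   one-third-per-vertex triangle attribution (which makes a partition's
   areas sum exactly to the total); %V1 normalizes the pial area of
   label ∩ V1 by V1's pial area (pial is the default normalization
   surface; configurable). Vertices of a sulcus outside V1 count toward
   its area but are excluded from eccentricity statistics — mirroring
   hemispheres whose external calcarine extends beyond V1. Mean
   eccentricity is unweighted by default, with a coherence-weighted
   option.
7. **Visual-field coverage.** x = E·cosθ, y = E·sinθ under the package
   convention (0° = contralateral horizontal meridian, +90° upper
   vertical, −90° lower vertical; contralateral sign from hemisphere
   metadata). Group overlap maps count, per template vertex, the subjects
   whose label contains it.
8. **Statistics.** Two-way fixed-effects ANOVA with species and
   hemisphere as factors; hemispheres enter as independent observations
   (a 24 + 6 subject cohort gives error df = 60 − 4 = 56). Balanced
   designs use classical sums of squares; unbalanced designs use Type II
   (via statsmodels OLS/anova_lm). No multiple-testing correction by
   default; Holm correction is available. Treating hemispheres as
   independent replicates the conventional analysis, not an endorsement —
   a mixed model with subject as a random effect would be the stricter
   choice.

## Phase-encoded (traveling-wave) mapping

Macaque-style maps come from periodic stimuli: rotating wedges (8 cycles
× 40 s) and expanding/contracting rings (7 cycles × 40 s with 10 s blanks
between cycles, inserted to separate foveal from peripheral responses).
Per vertex, the amplitude and phase at the stimulus frequency are
estimated by joint least-squares regression onto {cos, sin, constant,
linear trend} — equivalent to the DFT bin of the detrended series, but
exact for noiseless sinusoids even in the presence of the trend
regressors. Coherence is the stimulus-frequency amplitude over the
root-sum-square of all non-DC, non-trend spectral amplitudes; vertices
below 0.25 coherence (configurable) are marked invalid. Blank periods are
excluded from the analysis window by default (restoring exact periodicity
in the concatenated samples); an including option exists for sensitivity
checks.

Opposite sweep directions are combined by the circular half-difference of
phases, cancelling the common hemodynamic delay. The half-difference has
an intrinsic π ambiguity; the branch implying the smaller |delay| is
kept, which is correct for delays under a quarter cycle (10 s here —
comfortably above hemodynamic delays). Delay cancellation is exact for
wedge runs. For ring runs it is approximate: a delayed response leaks
into the blank-excluded window, which the analysis cannot know; ring
decoding is therefore validated at zero delay and real ring analyses
should rely on the combined-direction phase.

## The synthetic-data generator

No public dataset pairs per-vertex retinotopy with expert rCaS/eCaS
labels in both species, so the generator is the package's test substrate.
It emulates:

- **Geometry.** V1 as a wedge-shaped sheet (an annular sector): the
  foveal confluence is a short inner arc (radius 2 mm) and iso-
  eccentricity lines are arcs, so radial arc length equals the distance
  coordinate d exactly. The across-width is `v1_width_mm` at the
  peripheral edge (human 30 mm, macaque 20 mm).
- **Retinotopy.** Eccentricity E(d) = a(e^{bd} − 1) with ground-truth
  parameters human a = 1.0°, b = 0.063 /mm and macaque a = 0.8°,
  b = 0.12 /mm — generator defaults chosen so V1 spans the stimulated
  field (8° human, 10° macaque → extents ≈ 34.9 and 21.7 mm) over
  realistic cortical extents; they are configurable, not empirical
  claims. Polar angle is linear in the angular coordinate, ±90° at the
  sheet edges.
- **Folds.** A calcarine-like trough along the long axis whose depth
  tapers linearly from zero at the fovea (the sulcus shallows toward the
  occipital pole), plus transverse rCaS-like and eCaS-like corrugations
  spanning the distance interval whose eccentricities are the species'
  band (rCaS: human 2–5°, macaque 7–10°; eCaS: human 0–1°, macaque
  1–4°, the latter informed by reported species means of ≈0.4° and
  ≈2.45° but a generator choice). Transverse folds are built by
  tangent-angle (arc-length) parametrization — the cross-section is a
  curve whose tangent angle follows a sinusoid — so the grid coordinate
  remains true in-surface distance however deep the fold; grid sampling
  is adaptively densified where the tangent turns quickly (≤0.3 rad per
  edge), keeping chord-vs-arc error ≲ 0.4%. Fold depths (CaS 4 mm, rCaS
  2.5 mm, eCaS 1.5 mm) are capped by the achievable depth at 80° peak
  tilt for narrow folds.
- **Labels.** Sulcal labels are fold flanks: vertices whose fold tangent
  tilt exceeds 15°. Every labeled vertex's true eccentricity lies inside
  its fold's band by construction. V1 is the whole sheet. The white
  surface is the pial offset 2 mm inward along vertex normals.
- **Noise.** Wrapped-Gaussian polar-angle noise (default sd 3°),
  multiplicative log-normal eccentricity noise (default sd 0.10),
  Bernoulli vertex dropout (default 5%), and a coherence overlay that
  decreases with the injected per-vertex error. Defaults are plausible
  for fMRI retinotopy at the voxel sizes involved; all are parameters.
- **Time series.** Unit-amplitude cosine responses at the stimulus
  frequency whose phase encodes each vertex's sweep position, shifted by
  a hemodynamic delay, zero baseline during blanks, plus white noise.

**What passing tests do and do not show.** The generator's subjects
differ only by measurement noise — there is no inter-subject anatomical
variability (fold position, band extent, map idiosyncrasy), no spatially
correlated noise, no pRF-model structure, and no registration error.
Consequently between-species F statistics on synthetic cohorts are far
larger than any real cohort would give, and passing the pipeline on
synthetic data demonstrates correctness of the computations and the
qualitative species contrast, not performance on real maps. Border
placement on real data additionally depends on manual judgment the
banding surrogate cannot reproduce.

## Problem sizes and determinism

Default resolution is 1.2 vertices/mm (≥40×40 grid), giving ~2,000–2,500
vertices per hemisphere — small enough that a full two-species cohort
(24 + 6 subjects × 2 hemispheres) runs in seconds while leaving mesh
discretization error well under the 1% end-to-end recovery tolerance.
Every stochastic step takes an explicit seed; per-hemisphere seeds are
derived from the run seed by hashing (species, subject, hemisphere), so
identical configs produce byte-identical output bundles (verified by
manifest hash equality). Noiseless end-to-end recovery of (a, b) through
meshing, delineation, geodesics and fitting is within 1% for both species
presets; the residual is discretization, not the optimizer.

## Known limitations

- Edge-graph geodesics (≤9% directional overestimate) rather than exact
  polyhedral geodesics.
- Ring-run delay handling as described above.
- Hemispheres treated as independent observations in the ANOVA.
- The V1 region grown without an explicit hint is capped at the
  stimulated-field isoline; on real data a hint (atlas or manual label)
  is the safer route.
- GIFTI label files cannot express overlapping labels; the JSON label
  format is the lossless interchange for label sets with overlap.
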