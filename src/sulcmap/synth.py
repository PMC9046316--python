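"""Synthetic folded-V1 subjects with ground-truth retinotopy.

The generator lays out V1 as a parameter grid (d, phi): d is distance along
the cortical sheet from the foveal confluence (mm), phi is polar angle
(deg, -90..+90 spanning the contralateral hemifield).  Ground-truth
eccentricity follows the exponential magnification function

    E(d) = a * (exp(b * d) - 1)

and folds (a calcarine-like trough along the long axis, plus transverse
retrocalcarine-like and external-calcarine-like corrugations placed at
species-specific eccentricity bands) are embedded by *arc-length*
parametrization: the fold cross-section is a curve whose tangent angle
follows a sinusoidal profile, so the grid coordinate remains the true
in-surface distance.  The sheet itself is an annular sector (V1 is
wedge-shaped): the foveal confluence is a short inner arc and radial arc
length equals d, so the generated d coordinate is exactly what the
analysis pipeline later measures as geodesic distance from the confluence,
up to mesh discretization.

Species presets place the retrocalcarine fold at 2-5 deg eccentricity in
the human and 7-10 deg in the macaque, and the external calcarine fold at
0-1 deg (human) and 1-4 deg (macaque).  Sulcal labels are the fold flanks:
vertices whose fold tangent tilt exceeds a threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Callable

import numpy as np

from .errors import ParameterError
from .types import (LabelSet, RetinotopicMap, TriangleMesh, VertexOverlay,
                    wrap_angle_deg)


#: radius (mm) of the inner (foveal-confluence) arc of the synthetic sheet
FOVEA_RADIUS_MM = 2.0


def predict_ecc(d, a: float, b: float):
    """Eccentricity (deg) at cortical distance d (mm): ``a*(exp(b*d)-1)``."""
    return a * np.expm1(b * np.asarray(d, dtype=float))


def distance_of_ecc(ecc, a: float, b: float):
    """Inverse magnification function: ``d = ln(E/a + 1)/b`` (mm)."""
    return np.log1p(np.asarray(ecc, dtype=float) / a) / b


@dataclass
class SpeciesPreset:
    """Generator parameters for one species.

    ``rcas_band`` / ``ecas_band`` are the eccentricity intervals (deg) the
    retrocalcarine / external calcarine folds occupy; ``fold_amplitudes``
    are target fold depths in mm.  ``v1_extent_mm`` defaults to the
    cortical distance at which eccentricity reaches ``stimulus_radius``;
    ``v1_width_mm`` is the across-V1 arc width at the peripheral edge (the
    sheet is wedge-shaped, narrowing to a short arc at the fovea).
    """

    name: str
    cmf_a: float
    cmf_b: float
    stimulus_radius: float
    rcas_band: tuple[float, float]
    ecas_band: tuple[float, float]
    v1_extent_mm: float | None = None
    v1_width_mm: float = 30.0
    fold_amplitudes: dict = field(default_factory=lambda: {
        "CaS": 4.0, "rCaS": 2.5, "eCaS": 1.5})

    def __post_init__(self):
        if self.cmf_a <= 0 or self.cmf_b <= 0:
            raise ParameterError("cmf_a and cmf_b must be positive")
        if self.v1_extent_mm is None:
            self.v1_extent_mm = float(distance_of_ecc(self.stimulus_radius,
                                                      self.cmf_a, self.cmf_b))
        for band, nm in ((self.rcas_band, "rcas_band"), (self.ecas_band, "ecas_band")):
            lo, hi = band
            if not (0 <= lo < hi <= self.stimulus_radius):
                raise ParameterError(
                    f"{nm} {band} must lie within [0, stimulus_radius="
                    f"{self.stimulus_radius}] with lo < hi")
            if distance_of_ecc(hi, self.cmf_a, self.cmf_b) > self.v1_extent_mm + 1e-9:
                raise ParameterError(
                    f"{nm} upper edge {hi} deg lies beyond the simulated V1 extent")
        r_lo, r_hi = self.rcas_band
        e_lo, e_hi = self.ecas_band
        if max(r_lo, e_lo) < min(r_hi, e_hi):
            raise ParameterError("rcas_band and ecas_band must be disjoint")


def human_preset(**overrides) -> SpeciesPreset:
    """Human default: a=1.0 deg, b=0.063 /mm, 8 deg stimulus radius,
    retrocalcarine fold at 2-5 deg, external calcarine at 0-1 deg."""
    kw = dict(name="human", cmf_a=1.0, cmf_b=0.063, stimulus_radius=8.0,
              rcas_band=(2.0, 5.0), ecas_band=(0.0, 1.0), v1_width_mm=30.0)
    kw.update(overrides)
    return SpeciesPreset(**kw)


def macaque_preset(**overrides) -> SpeciesPreset:
    """Macaque default: a=0.8 deg, b=0.12 /mm, 10 deg stimulus radius,
    retrocalcarine fold at 7-10 deg, external calcarine at 1-4 deg."""
    kw = dict(name="macaque", cmf_a=0.8, cmf_b=0.12, stimulus_radius=10.0,
              rcas_band=(7.0, 10.0), ecas_band=(1.0, 4.0), v1_width_mm=20.0)
    kw.update(overrides)
    return SpeciesPreset(**kw)


PRESETS: dict[str, Callable[..., SpeciesPreset]] = {
    "human": human_preset, "macaque": macaque_preset}


@dataclass
class GroundTruth:
    """Noiseless retinotopy + labels + generator bookkeeping for one subject."""

    true_map: RetinotopicMap
    labels: LabelSet
    generator_params: dict
    d_coord: np.ndarray      # per-vertex generator distance coordinate (mm)
    phi_coord: np.ndarray    # per-vertex generator polar angle (deg)
    grid_shape: tuple[int, int]  # (n_d, n_phi)


@dataclass
class StimulusSpec:
    """Phase-encoded traveling-wave stimulus timing.

    Wedge runs: 8 cycles x 40 s, no blanks.  Ring runs: 7 cycles x 40 s
    with 10 s blanks between cycles (inserted to separate foveal from
    peripheral responses).  ``sweep_range`` is the polar-angle span (wedge)
    or eccentricity span (ring); ring spacing may be linear or log.
    """

    kind: str                      # "wedge" | "ring"
    tr: float = 2.0
    n_cycles: int | None = None
    cycle_duration: float = 40.0
    blank_duration: float | None = None
    direction: int = 1
    sweep_range: tuple[float, float] | None = None
    sweep_spacing: str = "linear"  # ring only: "linear" | "log"

    def __post_init__(self):
        if self.kind not in ("wedge", "ring"):
            raise ParameterError("stimulus kind must be 'wedge' or 'ring'")
        if self.n_cycles is None:
            self.n_cycles = 8 if self.kind == "wedge" else 7
        if self.blank_duration is None:
            self.blank_duration = 0.0 if self.kind == "wedge" else 10.0
        if self.direction not in (1, -1):
            raise ParameterError("direction must be +1 or -1")
        if self.sweep_range is None:
            self.sweep_range = (-180.0, 180.0) if self.kind == "wedge" else (0.0, 8.0)

    @property
    def period(self) -> float:
        return self.cycle_duration + self.blank_duration

    @property
    def run_duration(self) -> float:
        return self.n_cycles * self.period

    @property
    def n_samples(self) -> int:
        return int(round(self.run_duration / self.tr))

    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) * self.tr

    def stimulus_on(self, t: np.ndarray) -> np.ndarray:
        tau = np.mod(t, self.period)
        return tau < self.cycle_duration

    def sweep_position(self, truth_angle: np.ndarray, truth_ecc: np.ndarray) -> np.ndarray:
        """Normalized sweep position p in [0, 1) for each vertex."""
        lo, hi = self.sweep_range
        if self.kind == "wedge":
            p = np.mod(wrap_angle_deg(truth_angle) - lo, 360.0) / (hi - lo)
        else:
            if self.sweep_spacing == "log":
                if lo <= 0:
                    raise ParameterError("log ring sweep requires sweep_range[0] > 0")
                p = np.log(np.maximum(truth_ecc, lo) / lo) / np.log(hi / lo)
            else:
                p = (truth_ecc - lo) / (hi - lo)
        return np.clip(p, 0.0, 1.0 - 1e-12)


# ---------------------------------------------------------------------------
# fold construction (arc-length parametrized corrugations)

def _fold_theta_for_depth(depth: float, width: float) -> float:
    """Peak tangent angle (rad) giving the requested fold depth, capped at 80 deg."""
    cap = np.deg2rad(80.0)

    def depth_of(theta):
        u = np.linspace(0, width / 2, 201)
        dz = np.sin(theta * np.sin(2 * np.pi * u / width))
        return abs(np.trapezoid(dz, u))

    if depth <= 0:
        return 0.0
    if depth_of(cap) <= depth:
        return cap
    lo, hi = 0.0, cap
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if depth_of(mid) < depth:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


class _CorrugatedProfile:
    """1-D profile built from tangent-angle bumps; maps arc length s to
    (horizontal, depth) coordinates while preserving arc length exactly."""

    def __init__(self, s_max: float, folds: list[tuple[float, float, float]],
                 n_quad: int = 4001):
        # folds: (start_s, width, theta_max)
        self.folds = folds
        self.s_grid = np.linspace(0.0, s_max, n_quad)
        alpha = self.tangent_angle(self.s_grid)
        dx = np.cos(alpha)
        dz = np.sin(alpha)
        ds = self.s_grid[1] - self.s_grid[0] if n_quad > 1 else 1.0
        self.x_grid = np.concatenate([[0.0], np.cumsum((dx[1:] + dx[:-1]) / 2) * ds])
        self.z_grid = np.concatenate([[0.0], np.cumsum((dz[1:] + dz[:-1]) / 2) * ds])

    def tangent_angle(self, s) -> np.ndarray:
        s = np.asarray(s, dtype=float)
        alpha = np.zeros_like(s)
        for s0, width, theta in self.folds:
            inside = (s >= s0) & (s <= s0 + width)
            alpha[inside] += -theta * np.sin(2 * np.pi * (s[inside] - s0) / width)
        return alpha

    def embed(self, s) -> tuple[np.ndarray, np.ndarray]:
        x = np.interp(s, self.s_grid, self.x_grid)
        z = np.interp(s, self.s_grid, self.z_grid)
        return x, z

    def sample_points(self, max_spacing: float, min_points: int,
                      max_turn: float = 0.3) -> np.ndarray:
        """Arc-length sample positions adapted to fold curvature.

        Chooses points so consecutive samples are at most ``max_spacing``
        apart in arc length *and* the fold tangent rotates by at most
        ``max_turn`` radians between them; this keeps chord length close to
        arc length (relative deficit ~ max_turn^2/24) however steep a fold
        is, so mesh distances remain faithful to the arc-length coordinate.
        """
        alpha = self.tangent_angle(self.s_grid)
        tv = np.concatenate([[0.0], np.cumsum(np.abs(np.diff(alpha)))])
        measure = self.s_grid / max_spacing + tv / max_turn
        n = max(min_points, int(np.ceil(measure[-1])) + 1)
        targets = np.linspace(0.0, measure[-1], n)
        return np.interp(targets, measure, self.s_grid)


def generate_v1_patch(preset: SpeciesPreset, resolution: float = 1.2,
                      fold_spec: dict | None = None, seed: int = 0,
                      hemisphere: str = "left", subject_id: str = "",
                      flank_tilt_deg: float = 15.0,
                      ) -> tuple[TriangleMesh, TriangleMesh, GroundTruth]:
    """Generate a folded V1-like patch with ground-truth retinotopy.

    Parameters
    ----------
    resolution : vertices per mm along each grid axis (grid is at least
        40 x 40 regardless).
    fold_spec : optional override of ``preset.fold_amplitudes``.
    flank_tilt_deg : tangent-tilt threshold above which a fold vertex is
        assigned to that fold's sulcal label.

    Returns
    -------
    (pial, white, truth) : the pial mesh, the white mesh (2 mm inward
        offset along vertex normals), and the ground truth record.
    """
    amps = dict(preset.fold_amplitudes)
    if fold_spec:
        amps.update(fold_spec)
    a, b = preset.cmf_a, preset.cmf_b
    extent, width = preset.v1_extent_mm, preset.v1_width_mm

    # transverse folds along d at the species' eccentricity bands
    folds_d = []
    band_intervals = {}
    for fold_name, band in (("rCaS", preset.rcas_band), ("eCaS", preset.ecas_band)):
        d_lo, d_hi = (float(distance_of_ecc(e, a, b)) for e in band)
        d_hi = min(d_hi, extent)
        theta = _fold_theta_for_depth(amps.get(fold_name, 0.0), d_hi - d_lo)
        folds_d.append((d_lo, d_hi - d_lo, theta))
        band_intervals[fold_name] = (d_lo, d_hi, theta)
    prof_d = _CorrugatedProfile(extent, folds_d)

    # V1 is wedge-shaped: embed the sheet as an annular sector whose inner
    # arc (radius fovea_radius_mm) is the foveal confluence, so the polar
    # angle span is short at the fovea and ``width`` mm wide at the
    # peripheral edge, and radial arc length equals the d coordinate.
    r0 = FOVEA_RADIUS_MM
    span = width / (r0 + extent)          # angular extent (radians)

    # grid sampling adapted to fold curvature (at least 40 x 40)
    d = prof_d.sample_points(max_spacing=1.0 / resolution, min_points=40)
    n_theta = max(40, int(np.ceil(width * resolution)) + 1)
    theta_grid = np.linspace(-span / 2, span / 2, n_theta)
    phi = theta_grid / span * 180.0
    n_d, n_phi = d.size, phi.size

    # calcarine-like trough along the long axis; its depth tapers linearly
    # from zero at the fovea (the sulcus shallows toward the occipital
    # pole, which also keeps the foveal confluence arc short and flat)
    w_cas = 0.5 * span
    depth_cas = amps.get("CaS", 0.0)
    z_theta = np.where(
        np.abs(theta_grid) < w_cas / 2,
        -depth_cas * 0.5 * (1 + np.cos(2 * np.pi * theta_grid / w_cas)), 0.0)

    dd, pp = np.meshgrid(d, phi, indexing="ij")
    tt = np.meshgrid(d, theta_grid, indexing="ij")[1]
    rho, z_d = prof_d.embed(dd.ravel())
    radius = r0 + rho
    z_cas = (dd.ravel() / extent) * np.tile(z_theta, n_d)
    vertices = np.column_stack([
        radius * np.cos(tt.ravel()),
        radius * np.sin(tt.ravel()),
        z_d + z_cas,
    ])

    faces = _grid_faces(n_d, n_phi)
    pial = TriangleMesh(vertices, faces, surface_kind="pial")
    white = TriangleMesh(vertices - 2.0 * _vertex_normals(pial), faces,
                         surface_kind="white")

    ecc = np.minimum(predict_ecc(dd.ravel(), a, b), preset.stimulus_radius)
    ang = pp.ravel()
    true_map = RetinotopicMap(
        polar_angle=VertexOverlay(ang, units="deg"),
        eccentricity=VertexOverlay(ecc, units="deg"),
        coherence=VertexOverlay(np.ones(ang.size), units="unitless"),
    )

    labels = {"V1": np.arange(vertices.shape[0])}
    tilt = np.deg2rad(flank_tilt_deg)
    for fold_name, (d_lo, d_hi, theta) in band_intervals.items():
        wfold = d_hi - d_lo
        if wfold <= 0 or theta == 0:
            labels[fold_name] = np.array([], dtype=np.int64)
            continue
        alpha = np.zeros_like(dd.ravel())
        inside = (dd.ravel() >= d_lo) & (dd.ravel() <= d_hi)
        alpha[inside] = theta * np.sin(2 * np.pi * (dd.ravel()[inside] - d_lo) / wfold)
        labels[fold_name] = np.flatnonzero(np.abs(alpha) > tilt)

    label_set = LabelSet(labels=labels, species=preset.name, hemisphere=hemisphere,
                         subject_id=subject_id or f"{preset.name}-sim")
    params = asdict(preset)
    params.update(seed=seed, resolution=resolution, flank_tilt_deg=flank_tilt_deg,
                  grid_shape=(n_d, n_phi))
    truth = GroundTruth(true_map=true_map, labels=label_set, generator_params=params,
                        d_coord=dd.ravel(), phi_coord=pp.ravel(),
                        grid_shape=(n_d, n_phi))
    return pial, white, truth


def _grid_faces(n_d: int, n_phi: int) -> np.ndarray:
    """Triangulate an (n_d, n_phi) grid, two triangles per cell."""
    i, j = np.meshgrid(np.arange(n_d - 1), np.arange(n_phi - 1), indexing="ij")
    v00 = (i * n_phi + j).ravel()
    v01 = v00 + 1
    v10 = v00 + n_phi
    v11 = v10 + 1
    return np.concatenate([np.column_stack([v00, v10, v11]),
                           np.column_stack([v00, v11, v01])])


def _vertex_normals(mesh: TriangleMesh) -> np.ndarray:
    """Area-weighted vertex normals oriented toward +z."""
    tri = mesh.vertices[mesh.faces]
    fn = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    vn = np.zeros_like(mesh.vertices)
    for k in range(3):
        np.add.at(vn, mesh.faces[:, k], fn)
    norms = np.linalg.norm(vn, axis=1, keepdims=True)
    vn = vn / np.maximum(norms, 1e-12)
    flip = np.sign(vn[:, 2:3])
    flip[flip == 0] = 1.0
    return vn * flip


# ---------------------------------------------------------------------------
# measurement noise and traveling-wave time series

def add_measurement_noise(truth: GroundTruth, angle_sd: float = 3.0,
                          log_ecc_sd: float = 0.10, dropout_rate: float = 0.05,
                          seed: int = 0) -> RetinotopicMap:
    """Apply wrapped-Gaussian angle noise, log-normal eccentricity noise and
    vertex dropout to a ground-truth map.  Deterministic given ``seed``; with
    all noise parameters zero the truth is returned unchanged.
    """
    if angle_sd < 0 or log_ecc_sd < 0:
        raise ParameterError("noise standard deviations must be >= 0")
    if not (0 <= dropout_rate < 1):
        raise ParameterError("dropout_rate must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    n = truth.true_map.n_vertices
    d_ang = rng.normal(0.0, angle_sd, n) if angle_sd > 0 else np.zeros(n)
    d_log = rng.normal(0.0, log_ecc_sd, n) if log_ecc_sd > 0 else np.zeros(n)
    keep = rng.random(n) >= dropout_rate if dropout_rate > 0 else np.ones(n, bool)

    if angle_sd > 0:
        ang = wrap_angle_deg(truth.true_map.polar_angle.values + d_ang)
    else:  # bit-identical with zero noise
        ang = truth.true_map.polar_angle.values.copy()
    ecc = truth.true_map.eccentricity.values * np.exp(d_log)
    coh = np.clip(np.exp(-np.abs(d_ang) / 45.0 - np.abs(d_log)), 0.0, 1.0)
    return RetinotopicMap(
        polar_angle=VertexOverlay(ang, units="deg", valid_mask=keep),
        eccentricity=VertexOverlay(ecc, units="deg", valid_mask=keep),
        coherence=VertexOverlay(coh, units="unitless", valid_mask=keep),
    )


def generate_timeseries(truth: GroundTruth, spec: StimulusSpec,
                        noise_sd: float = 0.0, hemodynamic_delay: float = 0.0,
                        seed: int = 0) -> np.ndarray:
    """Per-vertex traveling-wave time series, shape (n_vertices, n_samples).

    Each vertex responds with a unit cosine at the stimulus frequency whose
    phase encodes its sweep position (polar angle for wedges, eccentricity
    for rings), delayed by ``hemodynamic_delay`` seconds; blank periods
    contribute baseline (zero) response.
    """
    p = spec.sweep_position(truth.true_map.polar_angle.values,
                            truth.true_map.eccentricity.values)
    t = spec.times()
    t_eff = t - hemodynamic_delay
    tau = np.mod(t_eff, spec.period)
    on = tau < spec.cycle_duration
    psi = 2 * np.pi * tau / spec.cycle_duration
    sig = np.cos(psi[None, :] - spec.direction * 2 * np.pi * p[:, None])
    sig = sig * on[None, :]
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        sig = sig + rng.normal(0.0, noise_sd, sig.shape)
    return sig
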