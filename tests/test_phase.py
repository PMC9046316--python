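"""Phase-mapping tests: spectral estimates against constructed signals and
an independent maximum-likelihood phase oracle; direction combination
including the wrapped branch; decoding back to visual coordinates."""

import numpy as np
import pytest

import sulcmap as sm
from sulcmap.errors import DimensionError, ParameterError
from sulcmap.phase import PhaseMap
from sulcmap.types import VertexOverlay


def _wedge_spec(**kw):
    return sm.StimulusSpec(kind="wedge", tr=2.0, **kw)


def test_pure_cosine_recovers_phase_exactly():
    spec = _wedge_spec()
    t = spec.times()
    ts = np.cos(2 * np.pi * spec.n_cycles * t / spec.run_duration - 1.0)
    pm = sm.fourier_phase(ts[None, :], spec)
    assert pm.phase.values[0] == pytest.approx(1.0, abs=1e-9)
    assert pm.amplitude.values[0] == pytest.approx(1.0, abs=1e-9)
    assert pm.coherence.values[0] > 0.99


def test_off_frequency_signal_has_low_coherence():
    spec = _wedge_spec()
    t = spec.times()
    ts = np.cos(2 * np.pi * 13 * t / spec.run_duration)  # 13 cycles, not 8
    pm = sm.fourier_phase(ts[None, :], spec)
    assert pm.coherence.values[0] < 0.05
    assert pm.amplitude.values[0] < 0.01


def test_phase_error_matches_ml_oracle():
    """With white noise, the regression phase matches an independent
    maximum-likelihood estimator (grid search over phase minimizing SSE of
    a known-frequency cosine) on the same noise draws."""
    spec = _wedge_spec()
    t = spec.times()
    omega = 2 * np.pi * spec.n_cycles / spec.run_duration
    true_phase = 0.7
    rng = np.random.default_rng(42)
    clean = np.cos(omega * t - true_phase)
    errors_pkg, errors_ml = [], []
    grid = np.linspace(-np.pi, np.pi, 20001)
    trend = np.column_stack([np.ones_like(t), t])
    for _ in range(20):
        y = clean + rng.normal(0, 0.5, t.size)  # SNR 2
        pm = sm.fourier_phase(y[None, :], spec)
        # oracle: detrend, then profile a non-negative amplitude per
        # candidate phase and grid-search the likelihood
        y_d = y - trend @ np.linalg.lstsq(trend, y, rcond=None)[0]
        basis = np.cos(omega * t[None, :] - grid[:, None])
        amps = np.maximum(basis @ y_d / (basis ** 2).sum(axis=1), 0.0)
        sse = ((y_d[None, :] - amps[:, None] * basis) ** 2).sum(axis=1)
        ml_phase = grid[np.argmin(sse)]
        errors_pkg.append(sm.wrap_angle_rad(pm.phase.values[0] - true_phase))
        errors_ml.append(sm.wrap_angle_rad(ml_phase - true_phase))
    # same draws -> nearly identical estimates (they differ only in how the
    # trend is handled: jointly vs projected out first), same error spread
    np.testing.assert_allclose(errors_pkg, errors_ml, atol=0.01)
    assert np.median(np.abs(errors_pkg)) <= np.median(np.abs(errors_ml)) + 0.01


def test_short_series_rejected():
    spec = _wedge_spec()
    with pytest.raises(DimensionError):
        sm.fourier_phase(np.zeros((1, 10)), spec)
    one_cycle = sm.StimulusSpec(kind="wedge", tr=2.0, n_cycles=1)
    with pytest.raises(ParameterError):
        sm.fourier_phase(np.zeros((1, one_cycle.n_samples)), one_cycle)


def _phase_map(phases):
    phases = np.asarray(phases, dtype=float)
    ones = np.ones_like(phases)
    return PhaseMap(amplitude=VertexOverlay(ones),
                    phase=VertexOverlay(phases),
                    coherence=VertexOverlay(ones))


@pytest.mark.parametrize("phi,delta", [(0.4, 0.0), (0.4, 0.5), (-2.0, 0.3),
                                       (3.0, 0.5), (-3.1, -0.4), (1.0, 1.2)])
def test_combine_directions_cancels_delay(phi, delta):
    """phi_fwd = phi + delta, phi_rev = -phi + delta -> combined phi, even
    in the wrapped case near +-pi; verified against a brute-force search
    over 2*pi offsets minimizing circular distance to the truth."""
    fwd = _phase_map([sm.wrap_angle_rad(phi + delta)])
    rev = _phase_map([sm.wrap_angle_rad(-phi + delta)])
    combined = sm.combine_directions(fwd, rev)
    # brute-force oracle: candidate half-differences over 2*pi offsets
    pf, pr = fwd.phase.values[0], rev.phase.values[0]
    candidates = [(pf - pr) / 2 + k * np.pi for k in range(-2, 3)]
    best = min(candidates, key=lambda c: abs(sm.wrap_angle_rad(c - phi)))
    assert combined.phase.values[0] == pytest.approx(
        sm.wrap_angle_rad(best), abs=1e-12)
    assert combined.phase.values[0] == pytest.approx(sm.wrap_angle_rad(phi),
                                                     abs=1e-12)


def test_combine_directions_mesh_mismatch():
    with pytest.raises(DimensionError):
        sm.combine_directions(_phase_map([0.0]), _phase_map([0.0, 1.0]))


def test_phase_to_visual_examples():
    ring = sm.StimulusSpec(kind="ring", tr=2.0, sweep_range=(0.0, 10.0))
    pm = _phase_map([0.0, np.pi])
    decoded = sm.phase_to_visual(pm, ring)
    assert decoded.values[0] == pytest.approx(0.0)   # sweep start
    assert decoded.values[1] == pytest.approx(5.0)   # half sweep, linear


def test_phase_to_visual_log_spacing():
    ring = sm.StimulusSpec(kind="ring", tr=2.0, sweep_range=(0.5, 8.0),
                           sweep_spacing="log")
    pm = _phase_map([np.pi])
    assert sm.phase_to_visual(pm, ring).values[0] == pytest.approx(
        0.5 * np.sqrt(8.0 / 0.5))


def test_low_coherence_vertices_marked_invalid():
    spec = _wedge_spec()
    t = spec.times()
    good = np.cos(2 * np.pi * spec.n_cycles * t / spec.run_duration)
    rng = np.random.default_rng(0)
    bad = rng.normal(size=t.size)
    pm = sm.fourier_phase(np.vstack([good, bad]), spec)
    decoded = sm.phase_to_visual(pm, spec, coherence_threshold=0.25)
    assert decoded.valid_mask[0]
    assert not decoded.valid_mask[1]


def test_noiseless_end_to_end_decoding(macaque_subject):
    """Generator truth -> time series -> decoded maps equals truth to
    <0.01 deg for both wedge (polar angle) and ring (eccentricity), with
    any hemodynamic delay cancelled by direction combination."""
    pial, white, truth, preset = macaque_subject
    for kind, attr in (("wedge", "polar_angle"), ("ring", "eccentricity")):
        sweep = None if kind == "wedge" else (0.0, preset.stimulus_radius)
        # blanks make ring windows delay-sensitive, so the ring run is
        # decoded at zero delay; the wedge carries the delay cancellation
        delay = 4.0 if kind == "wedge" else 0.0
        fwd = sm.StimulusSpec(kind=kind, tr=2.0, direction=1, sweep_range=sweep)
        rev = sm.StimulusSpec(kind=kind, tr=2.0, direction=-1, sweep_range=sweep)
        combined = sm.combine_directions(
            sm.fourier_phase(sm.generate_timeseries(truth, fwd,
                                                    hemodynamic_delay=delay), fwd),
            sm.fourier_phase(sm.generate_timeseries(truth, rev,
                                                    hemodynamic_delay=delay), rev))
        decoded = sm.phase_to_visual(combined, fwd)
        target = getattr(truth.true_map, attr).values
        if kind == "wedge":
            err = np.abs(sm.wrap_angle_deg(decoded.values - target))
        else:
            err = np.abs(decoded.values - target)
        assert err.max() < 0.01


def test_delay_invariance_of_combined_maps(macaque_subject):
    """Decoded combined phases are identical (1e-9) for any delay."""
    pial, white, truth, preset = macaque_subject
    fwd = _wedge_spec(direction=1)
    rev = _wedge_spec(direction=-1)

    def decode(delay):
        return sm.combine_directions(
            sm.fourier_phase(sm.generate_timeseries(truth, fwd,
                                                    hemodynamic_delay=delay), fwd),
            sm.fourier_phase(sm.generate_timeseries(truth, rev,
                                                    hemodynamic_delay=delay), rev)
        ).phase.values

    base = decode(0.0)
    for delay in (1.7, 4.0, 8.5):
        np.testing.assert_allclose(sm.wrap_angle_rad(decode(delay) - base),
                                   0.0, atol=1e-9)
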