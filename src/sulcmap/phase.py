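"""Traveling-wave (phase-encoded) retinotopic analysis.

``fourier_phase`` estimates, per vertex, the amplitude and phase of the
response at the stimulus frequency together with a coherence index
(amplitude at the stimulus frequency over the root-sum-square amplitude of
all non-DC, non-trend frequencies).  Blank periods of ring runs are
excluded from the analysis window by default, which restores exact
periodicity of the stimulus-locked response in the concatenated samples.

Opposite rotation/sweep directions are combined by the circular
half-difference of their phases, which cancels the common hemodynamic
delay; the intrinsic pi ambiguity of the half-difference is resolved by
choosing the branch whose implied delay is smallest in magnitude (valid for
delays under a quarter cycle).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DimensionError, ParameterError
from .synth import StimulusSpec
from .types import VertexOverlay, check_same_length, wrap_angle_rad


@dataclass
class PhaseMap:
    """Per-vertex amplitude, phase (radians, (-pi, pi]) and coherence."""

    amplitude: VertexOverlay
    phase: VertexOverlay
    coherence: VertexOverlay

    def __post_init__(self):
        check_same_length(self.amplitude, self.phase, self.coherence)

    @property
    def n_vertices(self) -> int:
        return len(self.phase)


def fourier_phase(timeseries: np.ndarray, spec: StimulusSpec,
                  include_blanks: bool = False) -> PhaseMap:
    """Estimate the stimulus-frequency component of each vertex's series.

    Amplitude and phase come from a joint least-squares regression of each
    series onto {cos, sin, constant, linear trend} at the stimulus
    frequency (phase convention: ``A*cos(omega*t - phase)``), which equals
    the detrended DFT bin but is exact for noiseless sinusoids.  Coherence
    uses the discrete spectrum of the detrended series with the DC and
    1-cycle/run bins excluded from the denominator.
    """
    ts = np.atleast_2d(np.asarray(timeseries, dtype=float))
    t = spec.times()
    if ts.shape[1] != t.size:
        raise DimensionError(
            f"series length {ts.shape[1]} does not match stimulus spec "
            f"({t.size} samples)")
    if spec.n_cycles < 2:
        raise ParameterError("need at least 2 stimulus cycles for phase analysis")
    if spec.blank_duration > 0 and not include_blanks:
        keep = spec.stimulus_on(t)
        ts = ts[:, keep]
    n = ts.shape[1]
    if n < 2 * spec.n_cycles:
        raise ParameterError("analysis window shorter than 2 samples per cycle")
    j = np.arange(n)
    w = 2 * np.pi * spec.n_cycles * j / n
    X = np.column_stack([np.cos(w), np.sin(w), np.ones(n), j - j.mean()])
    coef, *_ = np.linalg.lstsq(X, ts.T, rcond=None)
    c_cos, c_sin = coef[0], coef[1]
    amp = np.hypot(c_cos, c_sin)
    phase = np.arctan2(c_sin, c_cos)
    phase = wrap_angle_rad(np.where(amp > 0, phase, 0.0))

    detrended = ts - (X[:, 2:] @ coef[2:]).T
    spec_amp = np.abs(np.fft.rfft(detrended, axis=1))
    spec_amp[:, :2] = 0.0  # DC and 1-cycle/run trend bin
    denom = np.sqrt((spec_amp ** 2).sum(axis=1))
    numer = spec_amp[:, spec.n_cycles]
    coh = np.divide(numer, denom, out=np.zeros_like(numer), where=denom > 0)
    return PhaseMap(
        amplitude=VertexOverlay(amp, units="unitless"),
        phase=VertexOverlay(phase, units="unitless", valid_mask=amp > 0),
        coherence=VertexOverlay(np.clip(coh, 0.0, 1.0), units="unitless"),
    )


def combine_directions(map_fwd: PhaseMap, map_rev: PhaseMap) -> PhaseMap:
    """Cancel the common hemodynamic delay by combining opposite directions.

    With forward phase ``p + delta`` and reverse phase ``-p + delta``, the
    circular half-difference recovers ``p``; of the two pi-separated
    branches, the one implying the smaller |delta| is kept (assumes the
    delay is under a quarter cycle).  Amplitude and coherence are combined
    by geometric mean.
    """
    if map_fwd.n_vertices != map_rev.n_vertices:
        raise DimensionError("phase maps have different vertex counts")
    pf = map_fwd.phase.values
    pr = map_rev.phase.values
    half_diff = wrap_angle_rad((pf - pr) / 2.0)
    half_sum = wrap_angle_rad((pf + pr) / 2.0)
    # alternate branch: phase + pi, delay - pi
    alt_diff = wrap_angle_rad(half_diff + np.pi)
    alt_sum = wrap_angle_rad(half_sum - np.pi)
    use_alt = np.abs(alt_sum) < np.abs(half_sum)
    phase = np.where(use_alt, alt_diff, half_diff)
    amp = np.sqrt(map_fwd.amplitude.values * map_rev.amplitude.values)
    coh = np.sqrt(map_fwd.coherence.values * map_rev.coherence.values)
    valid = map_fwd.phase.valid_mask & map_rev.phase.valid_mask
    return PhaseMap(
        amplitude=VertexOverlay(amp, units="unitless"),
        phase=VertexOverlay(wrap_angle_rad(phase), units="unitless", valid_mask=valid),
        coherence=VertexOverlay(coh, units="unitless"),
    )


def phase_to_visual(pmap: PhaseMap, spec: StimulusSpec,
                    coherence_threshold: float = 0.25) -> VertexOverlay:
    """Decode delay-free phases into visual-field coordinates (degrees).

    Wedge phases map linearly onto the polar-angle sweep range; ring phases
    map linearly (or logarithmically, per ``spec.sweep_spacing``) onto the
    eccentricity sweep range.  Vertices below the coherence threshold are
    marked invalid.
    """
    p = np.mod(pmap.phase.values, 2 * np.pi) / (2 * np.pi)
    lo, hi = spec.sweep_range
    if spec.kind == "wedge":
        from .types import wrap_angle_deg
        values = wrap_angle_deg(lo + p * (hi - lo))
    else:
        if spec.sweep_spacing == "log":
            values = lo * (hi / lo) ** p
        else:
            values = lo + p * (hi - lo)
    valid = pmap.phase.valid_mask & (pmap.coherence.values >= coherence_threshold)
    return VertexOverlay(values, units="deg", valid_mask=valid)
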