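"""Cortical magnification: the exponential eccentricity-vs-distance fit and
the 2D histogram / isocontour characterization of sulci within V1.

Every valid V1 vertex contributes one sample (d_hat, E): its geodesic
distance from the foveal confluence and its measured eccentricity.  The
magnification function

    E(d_hat) = a * (exp(b * d_hat) - 1),   a > 0 [deg], b > 0 [1/mm]

is fit by bounded nonlinear least squares; the constant -1 term forces
E(0) = 0, which lets the curve accommodate foveal (< 1 deg) measurements.
The 2D histogram uses 0.5 deg eccentricity by 1 mm distance bins anchored
at zero, with per-sulcus isocontours traced at 99/75/50/25 % of that
sulcus' maximum bin.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from skimage import measure

from .delineate import V1Delineation
from .errors import ParameterError
from .synth import distance_of_ecc, predict_ecc
from .types import LabelSet, RetinotopicMap

log = logging.getLogger(__name__)

DEFAULT_FRACTIONS = (0.99, 0.75, 0.50, 0.25)


def collect_samples(rmap: RetinotopicMap, delineation: V1Delineation,
                    labels: LabelSet | None = None,
                    sulcus_names: tuple[str, ...] = ("rCaS", "eCaS"),
                    ) -> pd.DataFrame:
    """One (d_hat, E) sample per valid V1 vertex, tagged by sulcus membership.

    Returns a DataFrame with columns ``vertex, d_hat, ecc`` plus one boolean
    column per sulcus tag.  Vertices invalid in the map or in the distance
    field are skipped.
    """
    n = rmap.n_vertices
    v1 = delineation.v1_mask(n)
    if not v1.any():
        raise ParameterError("V1 vertex set is empty")
    ok = v1 & rmap.valid & delineation.distance_from_fovea.distance.valid_mask
    idx = np.flatnonzero(ok)
    df = pd.DataFrame({
        "vertex": idx,
        "d_hat": delineation.distance_from_fovea.distance.values[idx],
        "ecc": rmap.eccentricity.values[idx],
    })
    for name in sulcus_names:
        if labels is not None and name in labels:
            df[name] = labels.mask(name, n)[idx]
        else:
            df[name] = False
    return df


@dataclass
class CMFFit:
    """Fitted magnification parameters with diagnostics."""

    a: float
    b: float
    r_squared: float
    n_samples: int
    sse: float
    converged: bool
    init_used: tuple[float, float]
    message: str = ""

    def predict(self, d):
        return predict_ecc(d, self.a, self.b)

    def invert(self, ecc):
        return distance_of_ecc(ecc, self.a, self.b)


def fit_cmf(d_hat, ecc, init: tuple[float, float] = (1.0, 0.05),
            bounds: tuple[tuple[float, float], tuple[float, float]] = ((1e-6, 1e-6),
                                                                       (50.0, 1.0)),
            min_samples: int = 10, min_span_mm: float = 5.0) -> CMFFit:
    """Fit ``E = a*(exp(b*d)-1)`` by bounded trust-region least squares.

    Deterministic given the samples and init.  Degenerate inputs (too few
    samples or distance span under ``min_span_mm``) yield ``converged=False``
    with diagnostics rather than a silent bad fit.
    """
    d = np.asarray(d_hat, dtype=float)
    e = np.asarray(ecc, dtype=float)
    if d.shape != e.shape:
        raise ParameterError("d_hat and ecc must have the same length")
    keep = np.isfinite(d) & np.isfinite(e)
    d, e = d[keep], e[keep]
    n = d.size

    def degenerate(msg: str) -> CMFFit:
        log.warning("cmf fit degenerate: %s", msg)
        return CMFFit(a=float("nan"), b=float("nan"), r_squared=float("nan"),
                      n_samples=n, sse=float("nan"), converged=False,
                      init_used=init, message=msg)

    if n < min_samples:
        return degenerate(f"only {n} samples (need {min_samples})")
    if d.max() - d.min() < min_span_mm:
        return degenerate(f"distance span {d.max() - d.min():.2f} mm "
                          f"< {min_span_mm} mm")

    def resid(p):
        return predict_ecc(d, p[0], p[1]) - e

    x0 = np.clip(np.asarray(init, dtype=float), bounds[0], bounds[1])
    sol = least_squares(resid, x0, bounds=bounds, method="trf",
                        xtol=1e-14, ftol=1e-14, gtol=1e-14)
    sse = float(np.sum(sol.fun ** 2))
    sst = float(np.sum((e - e.mean()) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else float("nan")
    return CMFFit(a=float(sol.x[0]), b=float(sol.x[1]), r_squared=r2,
                  n_samples=n, sse=sse, converged=bool(sol.status > 0),
                  init_used=init, message=sol.message)


def predict_eccentricity(fit: CMFFit, d):
    """Predicted eccentricity (deg) at cortical distance d (mm)."""
    return fit.predict(d)


@dataclass
class EccDistHistogram:
    """2D histogram of (eccentricity, distance) samples with per-sulcus
    isocontours at fixed fractions of each sulcus' maximum bin."""

    counts: np.ndarray          # (n_ecc_bins, n_dist_bins)
    ecc_edges: np.ndarray       # 0.5 deg bins anchored at 0
    dist_edges: np.ndarray      # 1 mm bins anchored at 0
    isocontours: dict = field(default_factory=dict)
    # isocontours[tag][fraction] -> list of (k, 2) polylines in (ecc, dist) units

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def _histogram(ecc, dist, ecc_edges, dist_edges) -> np.ndarray:
    h, _, _ = np.histogram2d(ecc, dist, bins=[ecc_edges, dist_edges])
    return h


def _trace_isocontours(counts: np.ndarray, level: float, ecc_width: float,
                       dist_width: float) -> list[np.ndarray]:
    """Marching-squares level-set polylines in physical (ecc, dist) units.

    The grid is zero-padded so contours around boundary-touching peaks
    close; coordinates map bin centers to ``(index + 0.5) * width``.
    """
    padded = np.pad(counts, 1, mode="constant")
    polys = measure.find_contours(padded, level=level)
    out = []
    for poly in polys:
        ecc = (poly[:, 0] - 1.0 + 0.5) * ecc_width
        dist = (poly[:, 1] - 1.0 + 0.5) * dist_width
        out.append(np.column_stack([ecc, dist]))
    return out


def ecc_distance_histogram(samples: pd.DataFrame,
                           fractions: tuple[float, ...] = DEFAULT_FRACTIONS,
                           ecc_bin: float = 0.5, dist_bin: float = 1.0,
                           tags: tuple[str, ...] | None = None) -> EccDistHistogram:
    """2D histogram over all samples plus per-tag isocontours.

    Bin edges are anchored at 0 (first bins [0, 0.5) deg and [0, 1) mm);
    isocontours for each sulcus tag are traced on that tag's own
    sub-histogram at ``fraction * max_bin``.
    """
    if samples.empty:
        raise ParameterError("no samples to histogram")
    ecc = samples["ecc"].to_numpy()
    dist = samples["d_hat"].to_numpy()
    ecc_edges = np.arange(0.0, np.ceil(max(ecc.max(), ecc_bin) / ecc_bin) * ecc_bin
                          + ecc_bin * 0.5 + ecc_bin, ecc_bin)
    dist_edges = np.arange(0.0, np.ceil(max(dist.max(), dist_bin) / dist_bin) * dist_bin
                           + dist_bin * 0.5 + dist_bin, dist_bin)
    counts = _histogram(ecc, dist, ecc_edges, dist_edges)

    if tags is None:
        tags = tuple(c for c in samples.columns
                     if c not in ("vertex", "d_hat", "ecc")
                     and samples[c].dtype == bool)
    isocontours: dict = {}
    for tag in tags:
        sub = samples[samples[tag]]
        if sub.empty:
            isocontours[tag] = {f: [] for f in fractions}
            continue
        sub_counts = _histogram(sub["ecc"].to_numpy(), sub["d_hat"].to_numpy(),
                                ecc_edges, dist_edges)
        peak = sub_counts.max()
        isocontours[tag] = {
            f: _trace_isocontours(sub_counts, f * peak, ecc_bin, dist_bin)
            for f in fractions}
    return EccDistHistogram(counts=counts, ecc_edges=ecc_edges,
                            dist_edges=dist_edges, isocontours=isocontours)


def plot_magnification(samples: pd.DataFrame, fit: CMFFit,
                       hist: EccDistHistogram | None = None, ax=None):
    """Scatter of eccentricity vs cortical distance with the fitted curve
    and, when given, the per-sulcus isocontours (layout echoes the standard
    magnification figure)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    tags = [c for c in samples.columns
            if c not in ("vertex", "d_hat", "ecc") and samples[c].dtype == bool]
    rest = ~samples[tags].any(axis=1) if tags else np.ones(len(samples), bool)
    ax.plot(samples.loc[rest, "d_hat"], samples.loc[rest, "ecc"], ".",
            color="0.7", ms=2, label="V1")
    colors = {"rCaS": "tab:blue", "eCaS": "tab:red"}
    for tag in tags:
        sub = samples[samples[tag]]
        ax.plot(sub["d_hat"], sub["ecc"], ".", ms=2,
                color=colors.get(tag, None), label=tag)
    if np.isfinite(fit.a):
        dd = np.linspace(0, samples["d_hat"].max(), 200)
        ax.plot(dd, fit.predict(dd), "k-", lw=1.5,
                label=f"E=a(e^(bd)-1), r2={fit.r_squared:.2f}")
    if hist is not None:
        for tag, by_frac in hist.isocontours.items():
            for frac, polys in by_frac.items():
                for poly in polys:
                    ax.plot(poly[:, 1], poly[:, 0], "-", lw=0.8,
                            color=colors.get(tag, "k"), alpha=0.6)
    ax.set_xlabel("cortical distance from foveal confluence (mm)")
    ax.set_ylabel("eccentricity (deg)")
    ax.legend(fontsize=7)
    return ax
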