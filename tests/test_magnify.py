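"""Magnification tests: sample collection bookkeeping, the exponential fit
against noiseless identity / grid-search oracle, and histogram isocontours
against a flood-fill oracle."""

import numpy as np
import pandas as pd
import pytest
from matplotlib.path import Path as MplPath

import sulcmap as sm
from sulcmap.magnify import ecc_distance_histogram, fit_cmf


def _samples_from(d, e, **tags):
    df = pd.DataFrame({"vertex": np.arange(len(d)), "d_hat": d, "ecc": e})
    for k, v in tags.items():
        df[k] = v
    return df


# ---------------------------------------------------------------------------
# sample collection

def test_collect_samples_conservation(human_subject, human_delineation):
    pial, white, truth, preset = human_subject
    samples = sm.collect_samples(truth.true_map, human_delineation, truth.labels)
    assert len(samples) == len(human_delineation.v1_vertices)
    # rCaS-labeled V1 vertices carry the rCaS tag
    rcas = set(truth.labels["rCaS"].tolist())
    assert set(samples.loc[samples["rCaS"], "vertex"]) == rcas & set(
        samples["vertex"])


def test_collect_samples_respects_dropout(human_subject, human_delineation):
    pial, white, truth, preset = human_subject
    rmap = sm.add_measurement_noise(truth, angle_sd=0, log_ecc_sd=0,
                                    dropout_rate=0.2, seed=21)
    samples = sm.collect_samples(rmap, human_delineation, truth.labels)
    expected = int(rmap.valid[human_delineation.v1_vertices].sum())
    assert len(samples) == expected


# ---------------------------------------------------------------------------
# exponential fit

def test_noiseless_fit_identity():
    d = np.linspace(0, 35, 400)
    e = sm.predict_ecc(d, 1.0, 0.063)
    fit = fit_cmf(d, e)
    assert fit.converged
    assert fit.a == pytest.approx(1.0, rel=1e-6)
    assert fit.b == pytest.approx(0.063, rel=1e-6)
    assert fit.r_squared == pytest.approx(1.0, abs=1e-12)
    assert fit.predict(0.0) == 0.0


def test_degenerate_fit_flagged_not_crashed():
    d = np.zeros(30)
    e = np.zeros(30)
    e[-1] = 5.0
    fit = fit_cmf(d, e)
    assert not fit.converged
    assert fit.message != ""


def test_noisy_fit_median_error_and_grid_oracle():
    """10% multiplicative noise, n=5000: median parameter error < 5% over
    seeds; on a subset of seeds the optimizer beats (or ties) an
    independent (a, b) grid-search minimizer."""
    rng_d = np.random.default_rng(100)
    d = rng_d.uniform(0, 35, 5000)
    clean = sm.predict_ecc(d, 1.0, 0.063)
    a_err, b_err = [], []
    for seed in range(30):
        rng = np.random.default_rng(1000 + seed)
        e = clean * np.exp(rng.normal(0, 0.1, d.size))
        fit = fit_cmf(d, e)
        a_err.append(abs(fit.a - 1.0))
        b_err.append(abs(fit.b - 0.063) / 0.063)
        if seed < 5:
            a_grid = np.linspace(0.7, 1.4, 71)
            b_grid = np.linspace(0.04, 0.09, 101)
            sse = np.empty((a_grid.size, b_grid.size))
            for i, a in enumerate(a_grid):
                pred = a * np.expm1(b_grid[:, None] * d[None, :])
                sse[i] = ((pred - e[None, :]) ** 2).sum(axis=1)
            i, j = np.unravel_index(np.argmin(sse), sse.shape)
            assert fit.sse <= sse[i, j] + 1e-9
            assert fit.a == pytest.approx(a_grid[i], rel=0.05)
            assert fit.b == pytest.approx(b_grid[j], rel=0.05)
    assert np.median(a_err) < 0.05
    assert np.median(b_err) < 0.05


def test_fit_is_local_minimum():
    """Perturbing a converged fit by +-1% never decreases the SSE."""
    rng = np.random.default_rng(7)
    d = rng.uniform(0, 30, 800)
    e = sm.predict_ecc(d, 1.2, 0.07) * np.exp(rng.normal(0, 0.05, d.size))
    fit = fit_cmf(d, e)

    def sse(a, b):
        return float(((sm.predict_ecc(d, a, b) - e) ** 2).sum())

    for fa in (0.99, 1.0, 1.01):
        for fb in (0.99, 1.0, 1.01):
            assert sse(fit.a * fa, fit.b * fb) >= fit.sse - 1e-9


def test_predict_and_invert():
    fit = sm.CMFFit(a=1.0, b=0.1, r_squared=1.0, n_samples=0, sse=0.0,
                    converged=True, init_used=(1, 0.05))
    assert sm.predict_eccentricity(fit, 10.0) == pytest.approx(np.e - 1, rel=1e-12)
    d = np.linspace(0, 40, 100)
    np.testing.assert_allclose(fit.invert(fit.predict(d)), d, atol=1e-12)


# ---------------------------------------------------------------------------
# 2D histogram and isocontours

def test_histogram_conservation_and_single_bin():
    df = _samples_from([0.2] * 7, [0.3] * 7, rCaS=[True] * 7)
    h = ecc_distance_histogram(df)
    assert h.total == 7
    assert (h.counts > 0).sum() == 1
    for polys in h.isocontours["rCaS"].values():
        assert len(polys) >= 1
        # contour encloses the argmax bin center (0.25 deg, 0.5 mm)
        assert any(MplPath(p[:, ::-1]).contains_point((0.5, 0.25))
                   for p in polys)


def test_histogram_permutation_invariance(human_subject, human_delineation):
    pial, white, truth, preset = human_subject
    samples = sm.collect_samples(truth.true_map, human_delineation, truth.labels)
    h1 = ecc_distance_histogram(samples)
    h2 = ecc_distance_histogram(samples.sample(frac=1.0, random_state=0))
    np.testing.assert_array_equal(h1.counts, h2.counts)
    assert h1.total == len(samples)
    assert h1.ecc_edges[0] == 0.0 and h1.dist_edges[0] == 0.0
    assert np.allclose(np.diff(h1.ecc_edges), 0.5)
    assert np.allclose(np.diff(h1.dist_edges), 1.0)


def test_two_peak_level_set_matches_flood_fill_oracle():
    """On a two-peak sub-histogram (heights 100 and 40), the 50% level set
    encloses only the taller peak; bins inside contours match an exhaustive
    cell-threshold flood fill."""
    d = np.concatenate([np.full(100, 2.5), np.full(40, 10.5)])
    e = np.concatenate([np.full(100, 1.25), np.full(40, 3.25)])
    df = _samples_from(d, e, rCaS=[True] * 140)
    h = ecc_distance_histogram(df, fractions=(0.5,))
    polys = h.isocontours["rCaS"][0.5]

    # flood-fill oracle: bins >= level, connected components
    counts, _, _ = np.histogram2d(e, d, bins=[h.ecc_edges, h.dist_edges])
    above = counts >= 0.5 * counts.max()
    assert above.sum() == 1  # only the 100-count bin survives the threshold

    def inside(point):
        return any(MplPath(p).contains_point(point) for p in polys)

    for i in range(counts.shape[0]):
        for j in range(counts.shape[1]):
            center = ((i + 0.5) * 0.5, (j + 0.5) * 1.0)  # (ecc, dist)
            if counts[i, j] > 0:
                assert inside(center) == above[i, j]


def test_sulcus_isocontour_ordering(macaque_subject):
    """Macaque preset: the retrocalcarine isocontour cloud sits at larger
    distance and eccentricity than the external calcarine cloud."""
    pial, white, truth, preset = macaque_subject
    d = sm.delineate_v1(truth.true_map, pial, ecc_max=preset.stimulus_radius)
    samples = sm.collect_samples(truth.true_map, d, truth.labels)
    h = ecc_distance_histogram(samples)
    rcas = np.vstack([p for polys in h.isocontours["rCaS"].values() for p in polys])
    ecas = np.vstack([p for polys in h.isocontours["eCaS"].values() for p in polys])
    assert rcas[:, 0].min() > ecas[:, 0].max() - 0.5  # eccentricity axis
    assert rcas[:, 0].mean() > ecas[:, 0].mean()
    assert rcas[:, 1].mean() > ecas[:, 1].mean()      # distance axis
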