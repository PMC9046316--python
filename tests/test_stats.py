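"""ANOVA tests against hand-computed sums of squares and an independent
projection-matrix oracle; group mean/SEM bookkeeping."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import sulcmap as sm
from sulcmap.errors import ParameterError


def _balanced_toy():
    # species effect only: humans all 1, macaques all 3, 2 obs per cell
    values = [1, 1, 1, 1, 3, 3, 3, 3]
    species = ["h"] * 4 + ["m"] * 4
    hemi = ["L", "R", "L", "R", "L", "R", "L", "R"]
    return values, species, hemi


def test_all_equal_gives_zero_F():
    values = [2.0] * 8
    _, species, hemi = _balanced_toy()
    res = sm.two_way_anova(values, species, hemi)
    for eff in ("species", "hemisphere", "interaction"):
        assert res[eff].F == 0.0


def test_balanced_toy_hand_computed():
    """Species-only contrast: F_species = MS_species/MS_error from explicit
    classical sums of squares; hemisphere and interaction F = 0."""
    values, species, hemi = _balanced_toy()
    y = np.array(values, dtype=float)
    # within-cell perturbation: keeps all level and cell means unchanged for
    # hemisphere/interaction, adds error variance
    y = y + np.array([0.1, 0.1, -0.1, -0.1, 0.1, 0.1, -0.1, -0.1])
    res = sm.two_way_anova(y, species, hemi)

    cells = {}
    for val, sp, h in zip(y, species, hemi):
        cells.setdefault((sp, h), []).append(val)
    grand = y.mean()
    mean_sp = {sp: np.mean([v for v, s in zip(y, species) if s == sp])
               for sp in ("h", "m")}
    mean_h = {h: np.mean([v for v, hh in zip(y, hemi) if hh == h])
              for h in ("L", "R")}
    ss_species = 4 * sum((m - grand) ** 2 for m in mean_sp.values())
    ss_hemi = 4 * sum((m - grand) ** 2 for m in mean_h.values())
    ss_cells = 2 * sum((np.mean(v) - grand) ** 2 for v in cells.values())
    ss_int = ss_cells - ss_species - ss_hemi
    ss_err = sum(((np.array(v) - np.mean(v)) ** 2).sum() for v in cells.values())
    ms_err = ss_err / 4  # df = 8 - 4 cells
    assert res["species"].F == pytest.approx(ss_species / ms_err, rel=1e-10)
    assert res["hemisphere"].F == pytest.approx(ss_hemi / ms_err, abs=1e-10)
    assert res["interaction"].F == pytest.approx(max(ss_int, 0.0) / ms_err,
                                                 abs=1e-8)
    assert res["hemisphere"].F <= 1e-12 and res["interaction"].F <= 1e-12
    assert res["species"].df_num == 1
    assert res["species"].df_den == res.grand_n - 4
    assert res.design_balanced and res.ss_type == "I"


def _projection_anova(y, A, B):
    """Independent Type II oracle via explicit projection matrices."""
    y = np.asarray(y, dtype=float)
    n = y.size

    def dummies(f):
        levels = sorted(set(f))
        return np.column_stack([[1.0 if x == lev else 0.0 for x in f]
                                for lev in levels[1:]])

    one = np.ones((n, 1))
    da, db = dummies(A), dummies(B)
    dab = np.column_stack([da[:, i] * db[:, j]
                           for i in range(da.shape[1])
                           for j in range(db.shape[1])])

    def rss(X):
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        return float(r @ r)

    full = np.column_stack([one, da, db, dab])
    rss_full = rss(full)
    df_err = n - full.shape[1]
    ms_err = rss_full / df_err
    # Type II: each main effect adjusted for the other main effect
    out = {}
    out["species"] = (rss(np.column_stack([one, db])) -
                      rss(np.column_stack([one, da, db])))
    out["hemisphere"] = (rss(np.column_stack([one, da])) -
                         rss(np.column_stack([one, da, db])))
    out["interaction"] = rss(np.column_stack([one, da, db])) - rss_full
    return {k: (ss / 1) / ms_err for k, ss in out.items()}, df_err


def test_unbalanced_matches_projection_oracle():
    """24 vs 6 subject-style unbalanced design: F values match the
    projection-matrix Type II computation to 1e-10."""
    rng = np.random.default_rng(2)
    species = ["h"] * 48 + ["m"] * 12
    hemi = (["L", "R"] * 24) + (["L", "R"] * 6)
    y = rng.normal(0, 1, 60) + np.where(np.array(species) == "m", 1.5, 0.0)
    res = sm.two_way_anova(y, species, hemi)
    oracle, df_err = _projection_anova(y, species, hemi)
    for eff in ("species", "hemisphere", "interaction"):
        assert res[eff].F == pytest.approx(oracle[eff], rel=1e-10)
        assert res[eff].df_den == df_err
    assert res.grand_n == 60 and res["species"].df_den == 56
    assert not res.design_balanced and res.ss_type == "II"


def test_balanced_type_I_equals_type_II():
    rng = np.random.default_rng(3)
    y = rng.normal(size=24)
    species = ["h", "m"] * 12
    hemi = ["L"] * 12 + ["R"] * 12
    res = sm.two_way_anova(y, species, hemi)
    oracle, _ = _projection_anova(y, species, hemi)
    for eff in ("species", "hemisphere", "interaction"):
        assert res[eff].F == pytest.approx(oracle[eff], rel=1e-10)


def test_species_F_equals_squared_t():
    """Classical identity: with hemisphere contributing exactly zero sums of
    squares (same values in both hemispheres), the species F equals the
    squared pooled two-sample t up to the error-df ratio, to 1e-10."""
    rng = np.random.default_rng(4)
    ya = rng.normal(0, 1, 10)
    yb = rng.normal(0.8, 1, 10)
    # each hemisphere carries an identical copy of the species samples
    y = np.concatenate([ya, ya, yb, yb])
    species = ["h"] * 20 + ["m"] * 20
    hemi = (["L"] * 10 + ["R"] * 10) * 2
    res = sm.two_way_anova(y, species, hemi)
    t, _ = sps.ttest_ind(y[:20], y[20:])
    n = 40
    # SSE of the two-way model equals the one-way within-group SS here, so
    # the only difference from t^2 is the error df (n-4 vs n-2)
    assert res["species"].F == pytest.approx(t ** 2 * (n - 4) / (n - 2),
                                             rel=1e-10)
    assert res["hemisphere"].F <= 1e-12 and res["interaction"].F <= 1e-12


def test_empty_cell_raises_named_error():
    with pytest.raises(ParameterError, match="macaque.*right|right.*macaque"):
        sm.two_way_anova([1, 2, 3, 4, 5, 6],
                         ["human", "human", "human", "human", "macaque", "macaque"],
                         ["left", "left", "right", "right", "left", "left"])


def test_group_table_bookkeeping():
    rows = []
    for k in range(24):
        rows.append({"species": "human", "sulcus": "rCaS", "mean_ecc": 2.7 + 0.01 * k})
    for k in range(6):
        rows.append({"species": "macaque", "sulcus": "rCaS", "mean_ecc": 7.3})
    rows.append({"species": "human", "sulcus": "eCaS", "mean_ecc": 0.4})
    df = pd.DataFrame(rows)
    table = sm.group_table(df, "mean_ecc")
    t = table.set_index(["species", "sulcus"])
    assert t.loc[("human", "rCaS"), "n"] == 24
    assert t.loc[("macaque", "rCaS"), "n"] == 6
    assert t.loc[("macaque", "rCaS"), "sem"] == 0.0  # constant cell
    assert np.isnan(t.loc[("human", "eCaS"), "sem"])  # single observation
    expected_sem = np.std([2.7 + 0.01 * k for k in range(24)], ddof=1) / np.sqrt(24)
    assert t.loc[("human", "rCaS"), "sem"] == pytest.approx(expected_sem)


def test_holm_correction_monotone():
    p = {"a": 0.01, "b": 0.04, "c": 0.03}
    adj = sm.holm_correction(p)
    assert adj["a"] == pytest.approx(0.03)
    assert adj["a"] <= adj["c"] <= adj["b"]
    assert all(v <= 1 for v in adj.values())
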