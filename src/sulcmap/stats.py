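"""Inferential layer: two-way fixed-effects ANOVA with species and
hemisphere as factors, and group mean +/- SEM tables.

Hemispheres enter as independent observations (so a 24 + 6 subject cohort
contributes 60 observations and the error df is N - 4 for the 2 x 2
design).  Balanced designs use the classical sums of squares; unbalanced
designs (24 vs 6 subjects) use Type II, computed via statsmodels OLS.
No multiple-testing correction is applied by default; Holm correction is
available as a flag for users comparing many measures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .errors import ParameterError


@dataclass
class EffectResult:
    F: float
    df_num: int
    df_den: int
    p: float


@dataclass
class AnovaResult:
    """F tests for species, hemisphere and their interaction."""

    effects: dict[str, EffectResult]
    grand_n: int
    design_balanced: bool
    ss_type: str  # "I" (classical, balanced) or "II"

    def __getitem__(self, effect: str) -> EffectResult:
        return self.effects[effect]


def two_way_anova(values, species, hemisphere) -> AnovaResult:
    """Two-way fixed-effects ANOVA of ``values`` on species x hemisphere.

    Requires at least 2 observations in every cell of the 2 x 2 design;
    raises :class:`ParameterError` naming any empty cell.
    """
    df = pd.DataFrame({
        "y": np.asarray(values, dtype=float),
        "species": pd.Categorical(species),
        "hemisphere": pd.Categorical(hemisphere),
    }).dropna(subset=["y"])
    cells = df.groupby(["species", "hemisphere"], observed=False).size()
    for (sp, hemi), count in cells.items():
        if count == 0:
            raise ParameterError(f"empty design cell: species={sp}, hemisphere={hemi}")
        if count < 2:
            raise ParameterError(
                f"cell species={sp}, hemisphere={hemi} has {count} observation(s); "
                "need >= 2")
    balanced = cells.nunique() == 1
    n = len(df)

    if np.ptp(df["y"].to_numpy()) == 0:
        # constant response: every effect explains nothing (F = 0)
        zero = {eff: EffectResult(F=0.0, df_num=1, df_den=n - 4, p=1.0)
                for eff in ("species", "hemisphere", "interaction")}
        return AnovaResult(effects=zero, grand_n=n,
                           design_balanced=bool(balanced),
                           ss_type="I" if balanced else "II")

    model = smf.ols("y ~ C(species) * C(hemisphere)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    df_den = int(table.loc["Residual", "df"])
    name_map = {
        "C(species)": "species",
        "C(hemisphere)": "hemisphere",
        "C(species):C(hemisphere)": "interaction",
    }
    effects = {}
    for row, effect in name_map.items():
        F = float(table.loc[row, "F"])
        p = float(table.loc[row, "PR(>F)"])
        if not np.isfinite(F):  # zero residual variance: define F = 0 when SS_effect = 0
            ss = float(table.loc[row, "sum_sq"])
            F = 0.0 if np.isclose(ss, 0.0) else float("inf")
            p = 1.0 if F == 0.0 else 0.0
        effects[effect] = EffectResult(F=F, df_num=int(table.loc[row, "df"]),
                                       df_den=df_den, p=p)
    return AnovaResult(effects=effects, grand_n=n, design_balanced=bool(balanced),
                       ss_type="I" if balanced else "II")


def holm_correction(pvals: dict[str, float]) -> dict[str, float]:
    """Holm step-down adjusted p-values for a family of tests."""
    items = sorted(pvals.items(), key=lambda kv: kv[1])
    m = len(items)
    adjusted = {}
    running = 0.0
    for rank, (name, p) in enumerate(items):
        adj = min(1.0, (m - rank) * p)
        running = max(running, adj)
        adjusted[name] = running
    return adjusted


def group_table(summaries: pd.DataFrame, measure: str,
                by: tuple[str, ...] = ("species", "sulcus")) -> pd.DataFrame:
    """Group mean +/- SEM of one measure by species x sulcus.

    SEM = sd / sqrt(n) with ddof=1; a single-observation cell reports SEM
    as missing; a constant cell reports SEM = 0.
    """
    if summaries.empty:
        raise ParameterError("no summaries to tabulate")
    g = summaries.groupby(list(by), observed=False)[measure]
    out = g.agg(mean="mean", sd=lambda x: x.std(ddof=1), n="count").reset_index()
    out["sem"] = out["sd"] / np.sqrt(out["n"])
    return out
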