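"""Per-feature linear models and covariate-adjusted species means.

Each (transformed) feature is modelled as

    feature ~ temperature + humidity + species

and a Type II ANOVA reports the F statistic for dropping each term while
retaining the others — so the species effect is assessed after adjusting
for the environmental covariates, and is invariant to the order the
covariates are written in the formula.

Adjusted species means (e.g. wingbeat frequencies) are model predictions
per species at the sample-mean temperature and humidity, back-transformed
to the original scale (exp for logged features, square for square-rooted
ones); medians come from the per-species back-transformed observations.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multitest import multipletests

from .features import FEATURE_COLUMNS, invert_transform

__all__ = ["feature_anova", "adjusted_species_means"]


def _analysis_frame(features: pd.DataFrame, key: str) -> pd.DataFrame:
    df = features[[key, "species", "temperature", "humidity"]].rename(columns={key: "value"})
    return df.dropna()


def feature_anova(features: pd.DataFrame, feature_keys=None, holm: bool = False) -> pd.DataFrame:
    """Type II ANOVA per feature for species and covariate effects.

    Rows with a missing feature value or covariate are dropped per feature,
    so sample sizes vary across rows. Returns one row per feature with F
    statistics, degrees of freedom and p-values for temperature, humidity
    and species; ``flag`` marks features that could not be fitted (zero
    residual degrees of freedom or no variation). With ``holm=True`` the
    p-values gain Holm-adjusted companions (off by default; the raw Type II
    tests are reported as-is otherwise).
    """
    keys = [k for k in (feature_keys or FEATURE_COLUMNS) if k in features.columns]
    if features["species"].nunique() < 2:
        raise ValueError("need at least two species")
    rows = []
    for key in keys:
        df = _analysis_frame(features, key)
        row = {"feature": key, "n": len(df), "flag": None}
        n_species = df["species"].nunique()
        resid_df = len(df) - 2 - n_species  # intercept + 2 covariates + (k-1) species
        if len(df) == 0 or n_species < 2 or resid_df < 1 or df["value"].nunique() < 2:
            row["flag"] = "not_estimable"
            rows.append(row)
            continue
        model = smf.ols("value ~ temperature + humidity + C(species)", data=df).fit()
        table = sm.stats.anova_lm(model, typ=2)
        for term, label in (("temperature", "temperature"), ("humidity", "humidity"),
                            ("C(species)", "species")):
            row[f"F_{label}"] = float(table.loc[term, "F"])
            row[f"df_{label}"] = float(table.loc[term, "df"])
            row[f"p_{label}"] = float(table.loc[term, "PR(>F)"])
        row["df_residual"] = float(table.loc["Residual", "df"])
        rows.append(row)
    out = pd.DataFrame(rows).set_index("feature")
    if holm:
        for label in ("temperature", "humidity", "species"):
            p = out[f"p_{label}"]
            ok = p.notna()
            adj = pd.Series(np.nan, index=out.index)
            if ok.any():
                adj[ok] = multipletests(p[ok], method="holm")[1]
            out[f"p_{label}_holm"] = adj
    return out


def adjusted_species_means(features: pd.DataFrame, feature_key: str,
                           back_transform: bool = True) -> pd.DataFrame:
    """Covariate-adjusted mean (and raw median) per species for one feature.

    The mean is the model prediction for each species with temperature and
    humidity fixed at their means over the analysis rows; with
    ``back_transform`` the prediction and the medians are mapped back to
    the original scale of the feature.
    """
    if feature_key not in features.columns:
        raise KeyError(f"unknown feature {feature_key!r}")
    df = _analysis_frame(features, feature_key)
    if df.empty:
        raise ValueError(f"no complete observations for {feature_key!r}")
    model = smf.ols("value ~ temperature + humidity + C(species)", data=df).fit()
    species = sorted(df["species"].unique())
    grid = pd.DataFrame({
        "species": species,
        "temperature": df["temperature"].mean(),
        "humidity": df["humidity"].mean(),
    })
    pred = model.predict(grid)
    back = (lambda v: invert_transform(feature_key, v)) if back_transform else (lambda v: v)
    medians = df.groupby("species")["value"].median()
    return pd.DataFrame({
        "species": species,
        "adjusted_mean": [back(v) for v in pred],
        "median": [back(medians[s]) for s in species],
        "n": [int((df["species"] == s).sum()) for s in species],
    }).set_index("species")
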