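"""Morphology analyses: log transforms, a structural-size index,
factorial ANOVA, and climate-regression model selection by AICc.

The model-selection suite compares four OLS models per trait — linear
and quadratic in each of the two leading climate PC axes — ranked by
the small-sample-corrected information criterion

    AICc = n·ln(RSS/n) + 2k + 2k(k+1)/(n−k−1),

with k counting intercept, slopes and the residual variance (so k = 3
for a linear and 4 for a quadratic model), and normalized Akaike
weights w_i = exp(−Δ_i/2)/Σ exp(−Δ_j/2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

__all__ = [
    "preprocess",
    "size_index",
    "factorial_anova",
    "subspecies_anova",
    "aicc",
    "akaike_weights",
    "fit_climate_models",
    "MODEL_TAGS",
]

TRAITS = ("mass", "wing", "tarsus")
MODEL_TAGS = ("PC1", "PC1+PC1^2", "PC2", "PC2+PC2^2")


def preprocess(table: pd.DataFrame) -> pd.DataFrame:
    """Log10-transform mass, wing and tarsus.

    The original natural-unit values are kept in ``<trait>_raw`` columns.
    Non-positive trait values are rejected with the offending record
    named.
    """
    out = table.copy()
    for trait in TRAITS:
        vals = out[trait].to_numpy(dtype=float)
        bad = np.flatnonzero(vals <= 0)
        if bad.size:
            ids = out["individual_id"].iloc[bad].tolist()
            raise ValueError(f"non-positive {trait} for individual(s) {ids}")
        out[f"{trait}_raw"] = out[trait]
        out[trait] = np.log10(vals)
    return out


def size_index(table: pd.DataFrame) -> pd.Series:
    """Structural-size proxy: OLS residuals of log10 wing on log10 tarsus.

    Expects a preprocessed (log10) table.  Residuals are computed on the
    pooled sample and sum to zero by the OLS identity.
    """
    if len(table) < 3:
        raise ValueError("need at least 3 individuals")
    x = table["tarsus"].to_numpy(dtype=float)
    y = table["wing"].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("tarsus is constant; size regression undefined")
    fit = sm.OLS(y, sm.add_constant(x)).fit()
    return pd.Series(fit.resid, index=table.index, name="size")


def factorial_anova(
    table: pd.DataFrame,
    trait: str,
    geography_col: str = "site_id",
    ss_type: int = 2,
) -> pd.DataFrame:
    """Two-way factorial ANOVA: trait ~ geography * sex.

    Returns one row per term with sum_sq, df, F and p.  Type II sums of
    squares by default (I and III by ``ss_type``); with Type III a
    sum-to-zero contrast coding is applied so main effects are
    interpretable.
    """
    if ss_type not in (1, 2, 3):
        raise ValueError("ss_type must be 1, 2 or 3")
    df = table.copy()
    for col in (geography_col, "sex"):
        if df[col].nunique() < 2:
            raise ValueError(f"factor {col!r} needs at least 2 levels")
    cells = df.groupby([geography_col, "sex"], observed=True).size()
    full = df[geography_col].nunique() * df["sex"].nunique()
    if len(cells) < full:
        raise ValueError(
            "empty geography×sex cell(s); drop the interaction or merge sites"
        )
    if np.ptp(df[trait].to_numpy(dtype=float)) == 0:
        raise ValueError(f"trait {trait!r} is constant; ANOVA undefined")
    contrast = ", Sum" if ss_type == 3 else ""
    formula = (
        f"Q('{trait}') ~ C(Q('{geography_col}'){contrast}) * C(sex{contrast})"
    )
    fit = smf.ols(formula, data=df).fit()
    tab = anova_lm(fit, typ=ss_type)
    tab = tab.rename(
        index=lambda s: (
            s.replace(f"C(Q('{geography_col}'){contrast})", "geography").replace(
                f"C(sex{contrast})", "sex"
            )
        )
    )
    return tab


def subspecies_anova(
    table: pd.DataFrame, trait: str, sex_covariate: bool = False
) -> tuple[float, float]:
    """One-way ANOVA of a trait on the two-level group label.

    With ``sex_covariate`` the group term is tested after adjusting for
    sex (Type II).  Returns (F, p) for the group term.
    """
    if sex_covariate:
        fit = smf.ols(f"Q('{trait}') ~ C(group) + C(sex)", data=table).fit()
        tab = anova_lm(fit, typ=2)
        row = tab.loc["C(group)"]
    else:
        fit = smf.ols(f"Q('{trait}') ~ C(group)", data=table).fit()
        tab = anova_lm(fit, typ=1)
        row = tab.loc["C(group)"]
    return float(row["F"]), float(row["PR(>F)"])


def aicc(n: int, k: int, rss: float) -> float:
    """Least-squares AICc; k counts intercept, slopes and residual variance."""
    if rss <= 0:
        raise ValueError("rss must be > 0 (perfect fits make AICc degenerate)")
    if n - k - 1 <= 0:
        raise ValueError(f"AICc undefined for n={n}, k={k} (n-k-1 <= 0)")
    aic = n * np.log(rss / n) + 2 * k
    return float(aic + 2 * k * (k + 1) / (n - k - 1))


def akaike_weights(delta_aicc) -> np.ndarray:
    """Normalized model weights exp(−Δ/2)/Σexp(−Δ/2)."""
    d = np.asarray(delta_aicc, dtype=float)
    if d.size == 0:
        raise ValueError("empty delta vector")
    if not np.all(np.isfinite(d)):
        raise ValueError("deltas must be finite")
    w = np.exp(-d / 2)
    return w / w.sum()


@dataclass
class ModelFit:
    tag: str
    r_squared: float
    p_value: float
    k: int
    aicc: float
    delta_aicc: float = np.nan
    weight: float = np.nan


def fit_climate_models(
    trait_values, pc1_values, pc2_values
) -> pd.DataFrame:
    """Fit the four-model climate suite for one trait.

    Inputs are aligned per individual (site-level PC scores broadcast to
    the site's individuals by the caller).  Returns a DataFrame with one
    row per model: R², overall-F p, K, AICc, ΔAICc and Akaike weight.
    """
    y = np.asarray(trait_values, dtype=float)
    n = y.shape[0]
    if n <= 5:
        raise ValueError("need more than 5 observations")
    pcs = {"PC1": np.asarray(pc1_values, float), "PC2": np.asarray(pc2_values, float)}
    fits: list[ModelFit] = []
    for tag in MODEL_TAGS:
        axis = tag.split("+")[0]
        x = pcs[axis]
        cols = [x] if "^2" not in tag else [x, x * x]
        design = sm.add_constant(np.column_stack(cols))
        k = design.shape[1] + 1  # + residual variance
        res = sm.OLS(y, design).fit()
        fits.append(
            ModelFit(
                tag=tag,
                r_squared=float(res.rsquared),
                p_value=float(res.f_pvalue),
                k=k,
                aicc=aicc(n, k, float(res.ssr)),
            )
        )
    best = min(f.aicc for f in fits)
    for f in fits:
        f.delta_aicc = f.aicc - best
    weights = akaike_weights([f.delta_aicc for f in fits])
    for f, w in zip(fits, weights):
        f.weight = float(w)
    return pd.DataFrame(
        {
            "model": [f.tag for f in fits],
            "r_squared": [f.r_squared for f in fits],
            "p_value": [f.p_value for f in fits],
            "k": [f.k for f in fits],
            "aicc": [f.aicc for f in fits],
            "delta_aicc": [f.delta_aicc for f in fits],
            "weight": [f.weight for f in fits],
        }
    )
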