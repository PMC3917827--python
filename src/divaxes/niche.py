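"""Climatic-niche divergence between labelled groups of occurrence sites.

Workflow: standardize the climate variables and run a correlation-matrix
PCA; quantify divergence on each retained axis as the difference of group
mean scores (the Di statistic); test it against a null built by
reshuffling group labels over the pooled sites; confirm multivariately
with a Wilks'-lambda MANOVA on the leading axes.

The PCA is run on the correlation matrix because bioclim variables mix
units (°C, mm); a covariance PCA would be dominated by the
largest-magnitude precipitation variables.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "load_climate_table",
    "PCAResult",
    "standardize_and_pca",
    "di_observed",
    "DiTestResult",
    "di_permutation_test",
    "ManovaResult",
    "wilks_manova",
]


def load_climate_table(path: str | Path) -> pd.DataFrame:
    """Read a climate occurrence CSV (site_id, group, variables...).

    Rows with any missing variable value are rejected with an error
    naming the offending sites.
    """
    df = pd.read_csv(path)
    for col in ("site_id", "group"):
        if col not in df.columns:
            raise ValueError(f"climate table must contain a {col!r} column")
    bad = df[df.isna().any(axis=1)]
    if not bad.empty:
        raise ValueError(
            f"missing values at sites: {', '.join(map(str, bad['site_id']))}"
        )
    return df


@dataclass
class PCAResult:
    loadings: np.ndarray  # variables × axes
    scores: np.ndarray  # sites × axes
    variance_fraction: np.ndarray
    var_names: list[str]


def standardize_and_pca(table: pd.DataFrame, n_axes: int | None = None) -> PCAResult:
    """Correlation-matrix PCA of the climate variables.

    Each variable is centred and scaled to unit variance (ddof=1); axes
    come from the SVD of the standardized matrix.  Eigenvector sign is
    fixed by flipping each loading vector so that its largest-magnitude
    element is positive.
    """
    var_cols = [c for c in table.columns if c not in ("site_id", "group")]
    x = table[var_cols].to_numpy(dtype=float)
    n, p = x.shape
    if n < 2 or p < 2:
        raise ValueError("need at least 2 sites and 2 variables")

    sd = x.std(axis=0, ddof=1)
    const = [var_cols[i] for i in np.flatnonzero(sd == 0)]
    if const:
        raise ValueError(f"constant variable(s) cannot be standardized: {const}")
    z = (x - x.mean(axis=0)) / sd

    u, s, vt = np.linalg.svd(z, full_matrices=False)
    eigvals = s**2 / (n - 1)
    max_axes = min(n - 1, p)
    if n_axes is None:
        n_axes = max_axes
    if n_axes > max_axes:
        raise ValueError(
            f"n_axes={n_axes} exceeds the maximum data rank {max_axes}"
        )

    loadings = vt.T[:, :n_axes]
    # deterministic sign: largest-|loading| element of each axis positive
    flip = np.sign(loadings[np.abs(loadings).argmax(axis=0), np.arange(n_axes)])
    flip[flip == 0] = 1.0
    loadings = loadings * flip
    scores = z @ loadings
    variance_fraction = eigvals[:n_axes] / p
    return PCAResult(loadings, scores, variance_fraction, var_cols)


def _two_group_masks(
    groups: np.ndarray, order: tuple | None = None
) -> tuple[np.ndarray, np.ndarray, list]:
    labels = list(order) if order is not None else list(pd.unique(groups))
    if len(labels) != 2 or not set(labels) == set(pd.unique(groups)):
        raise ValueError(
            f"exactly two group labels required, got {list(pd.unique(groups))}"
        )
    a = groups == labels[0]
    b = groups == labels[1]
    if a.sum() == 0 or b.sum() == 0:
        raise ValueError("each group needs at least one site")
    return a, b, labels


def di_observed(
    scores: np.ndarray, groups, axis: int, order: tuple | None = None
) -> float:
    """Difference of group mean scores on one PC axis.

    ``order`` fixes which label plays the minuend role (default: order
    of first appearance), so di(A,B) = −di(B,A).
    """
    groups = np.asarray(groups)
    a, b, _ = _two_group_masks(groups, order)
    s = np.asarray(scores)[:, axis]
    return float(s[a].mean() - s[b].mean())


@dataclass
class DiTestResult:
    axis: int
    di_observed: float
    null_sample: np.ndarray
    p_value: float
    n_permutations: int
    seed: int | None
    tail: str
    plus_one: bool


def di_permutation_test(
    scores: np.ndarray,
    groups,
    axis: int,
    n_permutations: int = 9999,
    seed: int | None = None,
    tail: str = "two-sided",
    plus_one: bool = False,
    exact: bool = False,
) -> DiTestResult:
    """Permutation test of the Di statistic.

    The null is built by reshuffling group labels over the pooled sites
    (a permutation, preserving group sizes).  ``tail`` is ``"two-sided"``
    (default: count |Di_null| ≥ |Di_obs|) or ``"greater"`` (literal
    one-sided count Di_null ≥ Di_obs).  With ``plus_one`` the
    (count+1)/(n+1) estimator replaces the raw count/n ratio.  With
    ``exact`` the null enumerates every C(n, n_a) label allocation
    instead of sampling (``n_permutations`` is then ignored).
    """
    if not exact and n_permutations < 99:
        raise ValueError("n_permutations must be >= 99")
    if tail not in ("two-sided", "greater"):
        raise ValueError(f"unknown tail policy {tail!r}")
    groups = np.asarray(groups)
    a_mask, _, _ = _two_group_masks(groups)
    s = np.asarray(scores)[:, axis].astype(float)
    n = s.shape[0]
    n_a = int(a_mask.sum())
    obs = di_observed(scores, groups, axis)
    total = s.sum()

    rng = np.random.default_rng(seed)
    if exact:
        from itertools import combinations

        idx_a = np.array(list(combinations(range(n), n_a)))
        n_permutations = idx_a.shape[0]
    else:
        # vectorized label reshuffle: argsort of noise = random permutation
        order = np.argsort(rng.random((n_permutations, n)), axis=1)
        idx_a = order[:, :n_a]
    sum_a = s[idx_a].sum(axis=1)
    null = sum_a / n_a - (total - sum_a) / (n - n_a)

    if tail == "two-sided":
        count = int(np.sum(np.abs(null) >= np.abs(obs)))
    else:
        count = int(np.sum(null >= obs))
    if plus_one:
        p = (count + 1) / (n_permutations + 1)
    else:
        p = count / n_permutations
    return DiTestResult(axis, obs, null, float(p), n_permutations, seed, tail, plus_one)


@dataclass
class ManovaResult:
    wilks_lambda: float
    approx_F: float
    df: tuple[float, float]
    p_value: float


def wilks_manova(scores: np.ndarray, groups) -> ManovaResult:
    """Two-group MANOVA on the supplied score matrix.

    Wilks' Λ = det(E)/det(E+H) from the within-group (E) and
    between-group (H) cross-product matrices, with Rao's F
    approximation (exact for two groups).
    """
    y = np.atleast_2d(np.asarray(scores, dtype=float))
    if y.ndim == 2 and y.shape[0] == 1:
        y = y.T
    groups = np.asarray(groups)
    labels = list(pd.unique(groups))
    g = len(labels)
    if g < 2:
        raise ValueError("need at least two groups")
    n, p = y.shape
    for lab in labels:
        if (groups == lab).sum() <= p:
            raise ValueError(f"group {lab!r} needs more observations than axes")

    grand = y.mean(axis=0)
    e = np.zeros((p, p))
    h = np.zeros((p, p))
    for lab in labels:
        sub = y[groups == lab]
        mu = sub.mean(axis=0)
        r = sub - mu
        e += r.T @ r
        d = (mu - grand)[:, None]
        h += sub.shape[0] * (d @ d.T)
    det_e = np.linalg.det(e)
    if det_e <= 0:
        raise ValueError("singular within-group matrix; use fewer axes")
    lam = det_e / np.linalg.det(e + h)

    q = g - 1  # hypothesis df
    v = n - g  # error df
    if p * p + q * q - 5 > 0:
        t = np.sqrt((p * p * q * q - 4) / (p * p + q * q - 5))
    else:
        t = 1.0
    w = v + q - (p + q + 1) / 2
    df1 = p * q
    df2 = w * t - (p * q - 2) / 2
    lam_t = lam ** (1 / t)
    f = (1 - lam_t) / lam_t * df2 / df1
    p_val = float(stats.f.sf(f, df1, df2))
    return ManovaResult(float(lam), float(f), (df1, float(df2)), p_val)
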