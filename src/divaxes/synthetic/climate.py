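"""Synthetic occurrence-site climate tables with controlled collinearity.

Real bioclimatic predictor sets (e.g. the 19 WorldClim variables) are
strongly collinear; here that structure is produced by a latent-factor
model: each observed variable is a linear combination of a few latent
axes plus independent noise, and the second group's latent means are
offset by a shift vector.  This gives a known low-rank truth against
which PCA recovery and the niche-divergence permutation test can be
calibrated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ClimateGenSpec", "default_loading_matrix", "generate_climate_occurrences"]


def default_loading_matrix(
    n_vars: int = 19,
    n_latent: int = 3,
    factor_scales: tuple[float, ...] = (3.0, 2.0, 1.2),
    seed: int = 0,
) -> np.ndarray:
    """Deterministic full-column-rank loading matrix.

    Columns are orthonormal directions scaled by ``factor_scales``, so the
    latent factors contribute variance in a fixed, dominant-to-minor
    order — mimicking the way a handful of temperature/precipitation
    gradients dominate a bioclim predictor set.
    """
    if len(factor_scales) < n_latent:
        raise ValueError("need one factor scale per latent axis")
    rng = np.random.default_rng(seed)
    q, _ = np.linalg.qr(rng.standard_normal((n_vars, n_latent)))
    return q * np.asarray(factor_scales[:n_latent])


@dataclass(frozen=True)
class ClimateGenSpec:
    """Specification for a two-group synthetic climate table."""

    n_per_group: tuple[int, int] = (28, 8)
    n_vars: int = 19
    n_latent: int = 3
    loading_matrix: np.ndarray | None = None
    shift_vector: tuple[float, ...] = (0.0, 0.0, 0.0)
    noise_sd: float = 0.5
    seed: int | None = None
    group_names: tuple[str, str] = ("group1", "group2")
    var_names: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        n1, n2 = self.n_per_group
        if n1 < 2 or n2 < 2:
            raise ValueError("each group needs at least 2 sites")
        if not self.noise_sd > 0:
            raise ValueError("noise_sd must be > 0")
        if len(self.shift_vector) != self.n_latent:
            raise ValueError("shift_vector length must equal n_latent")

    def resolved_loadings(self) -> np.ndarray:
        lm = (
            default_loading_matrix(self.n_vars, self.n_latent)
            if self.loading_matrix is None
            else np.asarray(self.loading_matrix, dtype=float)
        )
        if lm.shape != (self.n_vars, self.n_latent):
            raise ValueError(
                f"loading_matrix must be {self.n_vars}×{self.n_latent}, got {lm.shape}"
            )
        if np.linalg.matrix_rank(lm) < self.n_latent:
            raise ValueError("loading_matrix must have full column rank")
        return lm


def generate_climate_occurrences(spec: ClimateGenSpec) -> pd.DataFrame:
    """Draw a (n1+n2)-site climate table.

    Variables are ``loading_matrix @ latent + noise``; group 2's latent
    means are offset by ``shift_vector``.  Identical seeds give identical
    tables.
    """
    lm = spec.resolved_loadings()
    rng = np.random.default_rng(spec.seed)
    n1, n2 = spec.n_per_group
    n = n1 + n2

    latent = rng.standard_normal((n, spec.n_latent))
    latent[n1:] += np.asarray(spec.shift_vector)
    x = latent @ lm.T + rng.normal(scale=spec.noise_sd, size=(n, spec.n_vars))

    var_names = (
        list(spec.var_names)
        if spec.var_names
        else [f"bio{i + 1}" for i in range(spec.n_vars)]
    )
    df = pd.DataFrame(x, columns=var_names)
    df.insert(0, "group", [spec.group_names[0]] * n1 + [spec.group_names[1]] * n2)
    df.insert(0, "site_id", [f"site{i + 1:03d}" for i in range(n)])
    return df
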