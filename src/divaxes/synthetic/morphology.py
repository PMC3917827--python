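"""Synthetic morphology tables: sexual dimorphism, site structure and a
(possibly quadratic) dependence of each trait on a climate axis.

Trait values are generated on the log10 scale —
``intercept + sex_effect·[male] + linear·x + quad·x² + N(0, sd)`` —
and back-transformed to natural units (g, mm), matching the common
practice of log-transforming avian morphometrics before analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["MorphoGenSpec", "TraitParams", "generate_morphology"]

TRAITS = ("mass", "wing", "tarsus")


@dataclass(frozen=True)
class TraitParams:
    """Per-trait generative coefficients on the log10 scale."""

    intercept: float
    sex_effect: float = 0.0
    linear_coeff: float = 0.0
    quad_coeff: float = 0.0
    residual_sd: float = 0.01

    def __post_init__(self) -> None:
        if not self.residual_sd > 0:
            raise ValueError("residual_sd must be > 0")


@dataclass(frozen=True)
class MorphoGenSpec:
    """Specification for a synthetic morphology table.

    ``sites`` holds (site_id, group, climate_axis_value) triples; every
    site receives ``n_per_site`` individuals whose sex is drawn male with
    probability ``sex_ratio``.
    """

    sites: tuple[tuple[str, str, float], ...]
    n_per_site: int = 7
    traits: dict[str, TraitParams] = field(
        default_factory=lambda: {
            # roughly scrub-robin-sized passerine defaults: ~31 g mass,
            # ~84 mm wing, ~28 mm tarsus, males a few percent larger
            "mass": TraitParams(1.49, 0.02, 0.0, -0.01, 0.015),
            "wing": TraitParams(1.92, 0.015, 0.0, -0.006, 0.008),
            "tarsus": TraitParams(1.45, 0.008, 0.0, -0.002, 0.008),
        }
    )
    sex_ratio: float = 0.64
    seed: int | None = None

    def __post_init__(self) -> None:
        if len(self.sites) == 0:
            raise ValueError("site list must not be empty")
        if self.n_per_site < 3:
            raise ValueError("n_per_site must be >= 3 for site-level analyses")
        if not 0.0 <= self.sex_ratio <= 1.0:
            raise ValueError("sex_ratio must be a probability")
        missing = [t for t in TRAITS if t not in self.traits]
        if missing:
            raise ValueError(f"missing trait parameters for {missing}")


def generate_morphology(spec: MorphoGenSpec) -> pd.DataFrame:
    """Draw individuals site by site; reproducible under a fixed seed."""
    rng = np.random.default_rng(spec.seed)
    rows = []
    idx = 0
    for site_id, group, x in spec.sites:
        # draw site sex counts binomially but keep both sexes represented,
        # so the geography×sex factorial downstream has no empty cells
        n_male = int(rng.binomial(spec.n_per_site, spec.sex_ratio))
        n_male = min(max(n_male, 1), spec.n_per_site - 1)
        males = np.zeros(spec.n_per_site, dtype=bool)
        males[:n_male] = True
        rng.shuffle(males)
        for male in males:
            idx += 1
            row: dict[str, object] = {
                "individual_id": f"ind{idx:03d}",
                "site_id": site_id,
                "group": group,
                "sex": "male" if male else "female",
                "climate_axis": x,
            }
            for trait in TRAITS:
                p = spec.traits[trait]
                log_val = (
                    p.intercept
                    + p.sex_effect * male
                    + p.linear_coeff * x
                    + p.quad_coeff * x * x
                    + rng.normal(scale=p.residual_sd)
                )
                row[trait] = 10.0**log_val
            rows.append(row)
    return pd.DataFrame(rows)
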