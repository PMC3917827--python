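from __future__ import annotations

import numpy as np
import pytest

from divaxes.popgen import LocusAlignment


def random_alignment(
    rng: np.random.Generator,
    n: int | None = None,
    length: int | None = None,
    name: str = "rand",
) -> LocusAlignment:
    """Small random alignment: a shared backbone plus scattered variants."""
    n = n or int(rng.integers(3, 13))
    length = length or int(rng.integers(20, 201))
    backbone = rng.choice(list("ACGT"), size=length)
    mat = np.tile(backbone, (n, 1))
    n_var = int(rng.integers(0, max(2, length // 8)))
    for _ in range(n_var):
        col = int(rng.integers(length))
        carriers = rng.random(n) < rng.uniform(0.1, 0.9)
        if carriers.all():
            carriers[int(rng.integers(n))] = False
        alt = rng.choice([b for b in "ACGT" if b != backbone[col]])
        mat[carriers, col] = alt
    return LocusAlignment(
        name, [f"s{i}" for i in range(n)], ["".join(r) for r in mat]
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260928)
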