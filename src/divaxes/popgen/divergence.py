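"""Between-population divergence: Hudson's Kst, fixed differences, Dxy.

Kst = 1 − Ks/Kt contrasts the (size-weighted) mean within-population
pairwise difference count Ks against the pooled mean Kt; significance
comes from permuting sequence→population assignments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alignment import LocusAlignment, PopPartition

__all__ = [
    "pairwise_difference_matrix",
    "KstResult",
    "kst_test",
    "fixed_differences",
    "percent_divergence",
]


def pairwise_difference_matrix(aln: LocusAlignment) -> np.ndarray:
    """n×n matrix of pairwise difference counts at analyzed sites."""
    m = aln.analyzed_matrix()
    n = aln.n
    d = np.zeros((n, n))
    for col in np.flatnonzero(np.any(m != m[0], axis=0)):
        c = m[:, col]
        d += c[:, None] != c[None, :]
    return d


def _ks(d: np.ndarray, pops: np.ndarray, labels: np.ndarray, weighting: str) -> float:
    ks = 0.0
    weights = []
    values = []
    for lab in labels:
        idx = np.flatnonzero(pops == lab)
        nj = idx.size
        sub = d[np.ix_(idx, idx)]
        kj = sub[np.triu_indices(nj, k=1)].mean()
        values.append(kj)
        weights.append(nj if weighting == "n" else nj - 1)
    w = np.asarray(weights, float)
    return float(np.sum(w / w.sum() * np.asarray(values)))


@dataclass
class KstResult:
    ks: float
    kt: float
    kst: float | None
    p_value: float | None
    n_permutations: int
    seed: int | None
    weighting: str


def kst_test(
    aln: LocusAlignment,
    partition: PopPartition,
    n_permutations: int = 999,
    seed: int | None = None,
    weighting: str = "n",
) -> KstResult:
    """Hudson's Kst with a sequence-label permutation test.

    ``weighting`` is ``"n"`` (population sizes, default) or ``"n-1"``.
    The p-value is the (count+1)/(n_permutations+1) upper-tail estimate
    of Pr(Kst_perm ≥ Kst_obs); ``None`` when Kt = 0 (Kst undefined).
    """
    if weighting not in ("n", "n-1"):
        raise ValueError("weighting must be 'n' or 'n-1'")
    pops = partition.populations(aln.sequence_ids)
    labels, counts = np.unique(pops, return_counts=True)
    if labels.size < 2:
        raise ValueError("need at least 2 populations")
    if np.any(counts < 2):
        small = labels[counts < 2].tolist()
        raise ValueError(f"population(s) with < 2 sequences: {small}")

    d = pairwise_difference_matrix(aln)
    n = aln.n
    kt = float(d[np.triu_indices(n, k=1)].mean())
    if kt == 0:
        return KstResult(0.0, 0.0, None, None, n_permutations, seed, weighting)
    ks = _ks(d, pops, labels, weighting)
    kst = 1.0 - ks / kt

    rng = np.random.default_rng(seed)
    count = 0
    perm = pops.copy()
    for _ in range(n_permutations):
        rng.shuffle(perm)
        ks_p = _ks(d, perm, labels, weighting)
        if 1.0 - ks_p / kt >= kst:
            count += 1
    p = (count + 1) / (n_permutations + 1)
    return KstResult(ks, kt, float(kst), float(p), n_permutations, seed, weighting)


def _two_pop_masks(
    aln: LocusAlignment, partition: PopPartition
) -> tuple[np.ndarray, np.ndarray]:
    pops = partition.populations(aln.sequence_ids)
    labels = np.unique(pops)
    if labels.size != 2:
        raise ValueError(f"exactly two populations required, got {labels.tolist()}")
    return pops == labels[0], pops == labels[1]


def fixed_differences(aln: LocusAlignment, partition: PopPartition) -> int:
    """Analyzed sites where the two populations share no base."""
    m1, m2 = _two_pop_masks(aln, partition)
    mat = aln.analyzed_matrix()
    count = 0
    for col in range(mat.shape[1]):
        if not set(mat[m1, col]) & set(mat[m2, col]):
            count += 1
    return count


def percent_divergence(
    aln: LocusAlignment, partition: PopPartition, net: bool = False
) -> float:
    """Between-population divergence as a percentage of analyzed sites.

    Raw Dxy (mean cross-population pairwise difference / L) by default;
    with ``net`` the mean within-population diversity is subtracted
    (Nei's Da).
    """
    m1, m2 = _two_pop_masks(aln, partition)
    d = pairwise_difference_matrix(aln)
    L = aln.L
    dxy = d[np.ix_(m1, m2)].mean() / L
    if net:
        def _within(mask: np.ndarray) -> float:
            idx = np.flatnonzero(mask)
            if idx.size < 2:
                return 0.0
            sub = d[np.ix_(idx, idx)]
            return float(sub[np.triu_indices(idx.size, k=1)].mean()) / L

        dxy -= (_within(m1) + _within(m2)) / 2
    return float(dxy * 100.0)
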