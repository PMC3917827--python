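"""Analysis of molecular variance (AMOVA) on haplotype distance matrices.

Pairwise difference counts between sequences are partitioned into
hierarchical components — among groups (σ_a²), among populations within
groups (σ_b²) and within populations (σ_c²) — via sums of squared
deviations and expected mean squares with unequal-sample-size
coefficients.  Fixation indices:

    F_CT = σ_a² / σ_T²          (among groups)
    F_SC = σ_b² / (σ_b² + σ_c²) (among populations within groups)
    F_ST = (σ_a² + σ_b²) / σ_T² (overall)

Permutation nulls follow the standard schemes: whole populations among
groups for F_CT, sequences among populations within groups for F_SC and
sequences among all populations for F_ST.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .alignment import LocusAlignment, PopPartition
from .divergence import pairwise_difference_matrix

__all__ = ["AmovaResult", "amova", "amova_single_level"]


@dataclass
class AmovaResult:
    sigma_a: float  # among groups
    sigma_b: float  # among populations within groups
    sigma_c: float  # within populations
    percentages: tuple[float, float, float]
    f_ct: float
    f_sc: float
    f_st: float
    p_f_ct: float | None = None
    p_f_sc: float | None = None
    p_f_st: float | None = None
    n_permutations: int = 0
    seed: int | None = None
    df: dict = field(default_factory=dict)


def _ssd_within(d: np.ndarray, masks: list[np.ndarray]) -> float:
    """Σ over units of (1/n_u)·Σ_{i<j∈u} d_ij."""
    total = 0.0
    for mask in masks:
        idx = np.flatnonzero(mask)
        if idx.size:
            sub = d[np.ix_(idx, idx)]
            total += sub[np.triu_indices(idx.size, k=1)].sum() / idx.size
    return total


def _components(
    d: np.ndarray, pops: np.ndarray, groups: np.ndarray
) -> tuple[float, float, float, dict]:
    n = d.shape[0]
    pop_labels = np.unique(pops)
    group_labels = np.unique(groups)
    P, G = pop_labels.size, group_labels.size

    pop_masks = [pops == p for p in pop_labels]
    group_masks = [groups == g for g in group_labels]
    n_p = np.array([m.sum() for m in pop_masks], float)
    n_g = np.array([m.sum() for m in group_masks], float)

    ssd_total = d[np.triu_indices(n, k=1)].sum() / n
    ssd_wp = _ssd_within(d, pop_masks)
    ssd_wg = _ssd_within(d, group_masks)
    ssd_ap = ssd_wg - ssd_wp
    ssd_ag = ssd_total - ssd_wg

    df_ag, df_ap, df_wp = G - 1, P - G, n - P
    if df_ag < 1:
        raise ValueError("AMOVA needs at least two groups")
    if df_ap < 1:
        raise ValueError(
            "AMOVA needs more populations than groups for the within-group level"
        )
    if df_wp < 1:
        raise ValueError("AMOVA needs within-population replication")

    ms_wp = ssd_wp / df_wp
    ms_ap = ssd_ap / df_ap
    ms_ag = ssd_ag / df_ag

    # unequal-size coefficients for the expected mean squares
    group_of_pop = np.array(
        [groups[pops == p][0] for p in pop_labels]
    )
    sum_np2_over_ng = 0.0
    for g, ng in zip(group_labels, n_g):
        in_g = n_p[group_of_pop == g]
        sum_np2_over_ng += np.sum(in_g**2) / ng
    n1 = (n - sum_np2_over_ng) / df_ap
    n2 = (sum_np2_over_ng - np.sum(n_p**2) / n) / df_ag
    n3 = (n - np.sum(n_g**2) / n) / df_ag

    sigma_c = ms_wp
    sigma_b = (ms_ap - sigma_c) / n1
    sigma_a = (ms_ag - sigma_c - n2 * sigma_b) / n3
    dfs = {"among_groups": df_ag, "among_pops": df_ap, "within_pops": df_wp}
    return sigma_a, sigma_b, sigma_c, dfs


def _fixation(sigma_a: float, sigma_b: float, sigma_c: float) -> tuple[float, float, float]:
    total = sigma_a + sigma_b + sigma_c
    if total == 0:
        raise ValueError("total molecular variance is zero (no polymorphism)")
    f_sc = sigma_b / (sigma_b + sigma_c) if sigma_b + sigma_c != 0 else np.nan
    return sigma_a / total, f_sc, (sigma_a + sigma_b) / total


def amova(
    aln: LocusAlignment,
    partition: PopPartition,
    n_permutations: int = 0,
    seed: int | None = None,
) -> AmovaResult:
    """Two-level AMOVA with optional permutation p-values.

    Negative variance components are reported as estimated (with a
    warning), not clamped; percentages therefore always sum to 100.
    """
    pops = partition.populations(aln.sequence_ids)
    groups = partition.groups(aln.sequence_ids)
    d = pairwise_difference_matrix(aln)
    if not d[np.triu_indices(aln.n, k=1)].any():
        raise ValueError("all sequences identical: AMOVA components undefined")
    for p in np.unique(pops):
        if (pops == p).sum() < 2:
            raise ValueError(f"population {p!r} has < 2 sequences")

    sigma_a, sigma_b, sigma_c, dfs = _components(d, pops, groups)
    if sigma_a < 0 or sigma_b < 0:
        warnings.warn(
            "negative AMOVA variance component(s) reported unclamped",
            stacklevel=2,
        )
    f_ct, f_sc, f_st = _fixation(sigma_a, sigma_b, sigma_c)
    total = sigma_a + sigma_b + sigma_c
    pct = tuple(100 * s / total for s in (sigma_a, sigma_b, sigma_c))
    res = AmovaResult(
        sigma_a, sigma_b, sigma_c, pct, f_ct, f_sc, f_st,
        n_permutations=n_permutations, seed=seed, df=dfs,
    )
    if n_permutations > 0:
        res.p_f_ct, res.p_f_sc, res.p_f_st = _permutation_p(
            d, pops, groups, (f_ct, f_sc, f_st), n_permutations, seed
        )
    return res


def _permutation_p(
    d: np.ndarray,
    pops: np.ndarray,
    groups: np.ndarray,
    observed: tuple[float, float, float],
    n_permutations: int,
    seed: int | None,
) -> tuple[float, float, float]:
    rng = np.random.default_rng(seed)
    pop_labels = np.unique(pops)
    group_of_pop = {p: groups[pops == p][0] for p in pop_labels}
    counts = np.zeros(3)
    valid = np.zeros(3)
    obs = np.asarray(observed)

    for _ in range(n_permutations):
        # F_CT: permute whole populations among groups
        perm_assign = rng.permutation([group_of_pop[p] for p in pop_labels])
        g_ct = np.empty_like(groups)
        for p, g in zip(pop_labels, perm_assign):
            g_ct[pops == p] = g
        # F_SC: permute sequences among populations within groups
        p_sc = pops.copy()
        for g in np.unique(groups):
            idx = np.flatnonzero(groups == g)
            p_sc[idx] = p_sc[idx[rng.permutation(idx.size)]]
        # F_ST: permute sequences among all populations
        order = rng.permutation(pops.size)
        p_st, g_st = pops[order], groups[order]

        for i, (pp, gg) in enumerate(
            ((pops, g_ct), (p_sc, groups), (p_st, g_st))
        ):
            try:
                stat = _fixation(*_components(d, pp, gg)[:3])[i]
            except ValueError:
                continue
            if np.isnan(stat):
                continue
            valid[i] += 1
            if stat >= obs[i]:
                counts[i] += 1
    p = (counts + 1) / (valid + 1)
    return float(p[0]), float(p[1]), float(p[2])


def amova_single_level(aln: LocusAlignment, partition: PopPartition) -> float:
    """One-level AMOVA F_ST over populations (group level collapsed)."""
    pops = partition.populations(aln.sequence_ids)
    d = pairwise_difference_matrix(aln)
    n = aln.n
    pop_labels = np.unique(pops)
    P = pop_labels.size
    if P < 2:
        raise ValueError("need at least two populations")
    masks = [pops == p for p in pop_labels]
    n_p = np.array([m.sum() for m in masks], float)
    ssd_total = d[np.triu_indices(n, k=1)].sum() / n
    ssd_wp = _ssd_within(d, masks)
    ms_wp = ssd_wp / (n - P)
    ms_ap = (ssd_total - ssd_wp) / (P - 1)
    n1 = (n - np.sum(n_p**2) / n) / (P - 1)
    sigma_c = ms_wp
    sigma_b = (ms_ap - sigma_c) / n1
    if sigma_b + sigma_c == 0:
        raise ValueError("no molecular variance")
    return float(sigma_b / (sigma_b + sigma_c))
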