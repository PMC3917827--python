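"""Desk-scale calibration experiments for the whole pipeline.

Each function runs a fixed, documented experiment on synthetic data and
returns the summary quantity it measures.  The default problem sizes are
the package's standard calibration conditions:

* neutral coalescent: n = 10, θ = 5 for E[S] (2000 replicates);
  n = 20, θ = 5 for Tajima's D (1000 replicates);
* permutation-test null: 14 + 14 sites, 19 collinear climate variables,
  999 permutations, 500 replicate datasets;
* divergence recovery: θ = 5, 10 + 10 sequences, deep split with no
  migration, 100 replicates.
"""

from __future__ import annotations

import warnings

import numpy as np

from . import morpho, niche
from .popgen import (
    LocusAlignment,
    PopPartition,
    amova,
    kst_test,
    tajimas_d,
)
from .synthetic import (
    ClimateGenSpec,
    IMParams,
    MorphoGenSpec,
    TraitParams,
    generate_climate_occurrences,
    generate_morphology,
    simulate_im_locus,
)

__all__ = [
    "mean_segregating_sites",
    "mean_tajimas_d",
    "di_type_one_error_rate",
    "divergence_recovery",
    "quadratic_model_weight",
]


def _spawn(seed: int, n: int) -> list[int]:
    return [int(s.generate_state(1)[0] % 2**31) for s in np.random.SeedSequence(seed).spawn(n)]


def mean_segregating_sites(
    reps: int = 2000, n: int = 10, theta: float = 5.0, seed: int = 0
) -> float:
    """Mean S over single-deme neutral replicates (expectation θ·a1)."""
    seeds = _spawn(seed, reps)
    half = n // 2
    total = 0
    for s in seeds:
        sim = simulate_im_locus(
            IMParams(theta=theta, split_time=0.0, n_samples=(half, n - half),
                     locus_length=400, seed=s)
        )
        total += sim.mutation_count
    return total / reps


def mean_tajimas_d(
    reps: int = 1000, n: int = 20, theta: float = 5.0, seed: int = 1
) -> float:
    """Mean Tajima's D over neutral constant-size replicates (≈ 0)."""
    seeds = _spawn(seed, reps)
    half = n // 2
    vals = []
    for s in seeds:
        sim = simulate_im_locus(
            IMParams(theta=theta, split_time=0.0, n_samples=(half, n - half),
                     locus_length=600, seed=s)
        )
        aln = LocusAlignment("cal", [f"s{i}" for i in range(n)], sim.alignment)
        d = tajimas_d(aln)
        if d is not None:
            vals.append(d)
    return float(np.mean(vals))


def di_type_one_error_rate(
    reps: int = 500,
    n_per_group: tuple[int, int] = (14, 14),
    n_permutations: int = 999,
    alpha: float = 0.05,
    seed: int = 2,
) -> float:
    """Empirical type-I error of the Di test on the dominant PC axis
    under the null climate generator (no group shift)."""
    seeds = _spawn(seed, reps)
    rejections = 0
    for s in seeds:
        table = generate_climate_occurrences(
            ClimateGenSpec(n_per_group=n_per_group, shift_vector=(0.0, 0.0, 0.0),
                           seed=s)
        )
        pca = niche.standardize_and_pca(table, n_axes=1)
        res = niche.di_permutation_test(
            pca.scores, table["group"].to_numpy(), 0,
            n_permutations=n_permutations, seed=s + 1,
        )
        if res.p_value < alpha:
            rejections += 1
    return rejections / reps


def divergence_recovery(
    reps: int = 100,
    theta: float = 5.0,
    split_time: float = 5.0,
    n_per_deme: int = 10,
    kst_permutations: int = 999,
    seed: int = 3,
) -> dict:
    """Deep-split, zero-migration IM replicates: fraction where Kst > 0.5
    with permutation p ≤ 0.01 and AMOVA F_CT > 0.5, plus the mean values.

    Each deme is split into two populations of equal size so the
    among-group level of the AMOVA sits above real population structure.
    """
    seeds = _spawn(seed, reps)
    kst_vals, fct_vals, successes = [], [], 0
    half = n_per_deme // 2
    for s in seeds:
        sim = simulate_im_locus(
            IMParams(theta=theta, split_time=split_time, n_samples=(n_per_deme, n_per_deme),
                     locus_length=800, seed=s)
        )
        ids = [f"s{i}" for i in range(2 * n_per_deme)]
        aln = LocusAlignment("div", ids, sim.alignment)
        pops = {}
        for i, d in enumerate(sim.deme_labels):
            sub = 1 if (i % n_per_deme) < half else 2
            pops[ids[i]] = f"g{d + 1}p{sub}"
        groups = {p: p[:2] for p in set(pops.values())}

        kst = kst_test(
            aln, PopPartition({i: pops[i][:2] for i in ids}),
            n_permutations=kst_permutations, seed=s + 7,
        )
        with warnings.catch_warnings():
            # the arbitrary within-deme split has no real structure, so a
            # slightly negative among-population component is expected
            warnings.simplefilter("ignore", UserWarning)
            am = amova(aln, PopPartition(pops, groups))
        kst_vals.append(kst.kst)
        fct_vals.append(am.f_ct)
        if kst.kst is not None and kst.kst > 0.5 and kst.p_value <= 0.01 and am.f_ct > 0.5:
            successes += 1
    return {
        "success_rate": successes / reps,
        "mean_kst": float(np.mean(kst_vals)),
        "mean_f_ct": float(np.mean(fct_vals)),
    }


def quadratic_model_weight(
    n_sites: int = 10, n_per_site: int = 8, seed: int = 4
) -> float:
    """Akaike weight of the quadratic climate model on quadratic-truth
    synthetic morphology (n = 80, moderate noise)."""
    rng = np.random.default_rng(seed)
    sites = tuple(
        (f"s{i}", "g1" if i < n_sites // 2 else "g2", float(x))
        for i, x in enumerate(np.linspace(-2, 2, n_sites))
    )
    traits = {
        "mass": TraitParams(1.5, 0.02, 0.0, -0.02, 0.015),
        "wing": TraitParams(1.9, 0.01, 0.0, -0.01, 0.01),
        "tarsus": TraitParams(1.45, 0.0, 0.0, 0.0, 0.01),
    }
    df = generate_morphology(
        MorphoGenSpec(sites=sites, n_per_site=n_per_site, traits=traits, seed=seed)
    )
    df = morpho.preprocess(df)
    pc1 = dict(zip(df["site_id"].unique(), rng.standard_normal(n_sites)))
    comp = morpho.fit_climate_models(
        df["mass"], df["site_id"].map(pc1), df["climate_axis"]
    )
    return float(comp.set_index("model").loc["PC2+PC2^2", "weight"])
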