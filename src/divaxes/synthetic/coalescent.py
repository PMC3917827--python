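"""Two-deme isolation-with-migration (IM) coalescent simulator.

Simulates genealogies for samples drawn from two demes that exchange
migrants until ``split_time`` (looking backwards in time), after which all
lineages reside in a single ancestral deme.  Mutations follow the
infinite-sites model: each mutation gets its own column of the alignment.

Conventions (ms-style):

* time is measured in units of 4N_ref generations;
* within a deme of relative size ``x`` a pair of lineages coalesces at
  rate ``2/x``;
* ``mig_12`` is the scaled rate (4N·m) at which a lineage currently in
  deme 1 traces its ancestry into deme 2, and vice versa for ``mig_21``;
* mutations fall on the genealogy as a Poisson process with total mean
  ``theta × L`` where ``L`` is the total branch length in 4N units, so
  that for a single panmictic deme E[S] = theta · a1 with
  a1 = sum_{i<n} 1/i;
* the inheritance scalar multiplies the effective theta and both
  migration rates, shrinking marker-specific effective size (mtDNA 0.25,
  Z-linked 0.75, autosomes 1.0).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["IMParams", "SimulatedLocus", "simulate_im_locus"]

_ALLOWED_SCALARS = (1.0, 0.75, 0.25)
_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class IMParams:
    """Parameters of a single-locus two-deme IM simulation.

    theta
        Per-locus scaled mutation rate 4N·mu (before the inheritance
        scalar is applied).
    split_time
        Divergence time in units of 4N_ref generations; 0 collapses the
        model to a single panmictic deme.
    mig_12, mig_21
        Scaled migration rates 4N·m (backwards-in-time lineage movement
        out of deme 1 and deme 2 respectively).
    n_samples
        Sampled sequences per deme.
    locus_length
        Alignment length in bp; bounds the number of infinite-sites
        mutations that can be placed.
    inheritance_scalar
        1.0 (autosomal), 0.75 (Z-linked) or 0.25 (mitochondrial).
    ancestral_size
        Size of the ancestral deme relative to each daughter deme.
    """

    theta: float
    split_time: float = 0.0
    mig_12: float = 0.0
    mig_21: float = 0.0
    n_samples: tuple[int, int] = (10, 10)
    locus_length: int = 1000
    inheritance_scalar: float = 1.0
    ancestral_size: float = 1.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if not self.theta > 0:
            raise ValueError("theta must be > 0")
        if self.split_time < 0:
            raise ValueError("split_time must be >= 0")
        if self.mig_12 < 0 or self.mig_21 < 0:
            raise ValueError("migration rates must be >= 0")
        n1, n2 = self.n_samples
        if n1 < 1 or n2 < 1:
            raise ValueError("need at least one sampled sequence per deme")
        if self.locus_length < 1:
            raise ValueError("locus_length must be >= 1")
        if self.inheritance_scalar not in _ALLOWED_SCALARS:
            raise ValueError(
                f"inheritance_scalar must be one of {_ALLOWED_SCALARS} "
                f"(got {self.inheritance_scalar})"
            )
        if not self.ancestral_size > 0:
            raise ValueError("ancestral_size must be > 0")


@dataclass
class SimulatedLocus:
    """Alignment produced by one IM simulation plus diagnostics."""

    alignment: list[str]
    deme_labels: list[int]
    mutation_count: int
    tree_depth: float
    positions: list[int] = field(default_factory=list)


def _simulate_genealogy(
    params: IMParams, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Return (parent, node_time) arrays for a structured coalescent tree.

    Tips are nodes 0..n-1 (deme-1 samples first); internal nodes are
    appended in coalescence order; the root's parent is -1.
    """
    n1, n2 = params.n_samples
    n = n1 + n2
    scal = params.inheritance_scalar
    m1, m2 = params.mig_12 * scal, params.mig_21 * scal

    parent = np.full(2 * n - 1, -1, dtype=np.int64)
    node_time = np.zeros(2 * n - 1)
    # active lineages: node index -> deme
    active: dict[int, int] = {i: (0 if i < n1 else 1) for i in range(n)}
    next_node = n
    t = 0.0
    merged = params.split_time == 0.0
    if merged:
        for k in active:
            active[k] = 0

    while len(active) > 1:
        k0 = sum(1 for d in active.values() if d == 0)
        k1 = len(active) - k0
        if merged:
            rate_c0 = k0 * (k0 - 1) / params.ancestral_size
            rates = np.array([rate_c0, 0.0, 0.0, 0.0])
        else:
            rates = np.array(
                [
                    float(k0 * (k0 - 1)),  # coalescence in deme 1
                    float(k1 * (k1 - 1)),  # coalescence in deme 2
                    k0 * m1,  # lineage moves deme 1 -> deme 2
                    k1 * m2,  # lineage moves deme 2 -> deme 1
                ]
            )
        total = rates.sum()
        if total == 0.0:
            # isolated singleton lineages; jump straight to the split
            t = params.split_time
            merged = True
            for k in active:
                active[k] = 0
            continue
        dt = rng.exponential(1.0 / total)
        if not merged and t + dt >= params.split_time:
            t = params.split_time
            merged = True
            for k in active:
                active[k] = 0
            continue
        t += dt
        event = rng.choice(4, p=rates / total)
        if event in (0, 1):
            deme = int(event)
            pool = [k for k, d in active.items() if d == deme]
            i, j = rng.choice(len(pool), size=2, replace=False)
            a, b = pool[i], pool[j]
            parent[a] = parent[b] = next_node
            node_time[next_node] = t
            del active[a], active[b]
            active[next_node] = deme
            next_node += 1
        else:
            src = 0 if event == 2 else 1
            pool = [k for k, d in active.items() if d == src]
            mover = pool[rng.integers(len(pool))]
            active[mover] = 1 - src
    return parent, node_time


def _descendant_tips(parent: np.ndarray, n_tips: int) -> list[np.ndarray]:
    """Boolean tip-membership mask for every node (tips included)."""
    n_nodes = parent.shape[0]
    masks = [np.zeros(n_tips, dtype=bool) for _ in range(n_nodes)]
    for tip in range(n_tips):
        masks[tip][tip] = True
        node = parent[tip]
        while node != -1:
            masks[node][tip] = True
            node = parent[node]
    return masks


def simulate_im_locus(params: IMParams) -> SimulatedLocus:
    """Simulate one locus under the two-deme IM model.

    Raises
    ------
    ValueError
        If the Poisson mutation count exceeds ``locus_length`` (the
        infinite-sites mapping would collide): increase ``locus_length``
        or decrease ``theta``.
    """
    rng = np.random.default_rng(params.seed)
    n1, n2 = params.n_samples
    n = n1 + n2
    theta_eff = params.theta * params.inheritance_scalar

    if n == 1:
        raise ValueError("cannot build an alignment from a single sequence")

    parent, node_time = _simulate_genealogy(params, rng)
    branch_len = np.where(parent >= 0, node_time[parent] - node_time, 0.0)
    total_len = branch_len.sum()
    tree_depth = node_time.max()

    n_mut = int(rng.poisson(theta_eff * total_len))
    if n_mut > params.locus_length:
        raise ValueError(
            f"{n_mut} mutations exceed locus_length={params.locus_length}; "
            "infinite-sites placement would collide — increase locus_length "
            "or decrease theta"
        )

    ancestral = rng.choice(_BASES, size=params.locus_length)
    seqs = np.tile(ancestral, (n, 1))
    positions: list[int] = []
    if n_mut > 0:
        positions = sorted(
            int(p) for p in rng.choice(params.locus_length, size=n_mut, replace=False)
        )
        branches = rng.choice(
            parent.shape[0], size=n_mut, p=branch_len / total_len
        )
        masks = _descendant_tips(parent, n)
        for pos, node in zip(positions, branches):
            anc = ancestral[pos]
            derived = rng.choice(_BASES[_BASES != anc])
            seqs[masks[node], pos] = derived

    alignment = ["".join(row) for row in seqs]
    deme_labels = [0] * n1 + [1] * n2
    return SimulatedLocus(
        alignment=alignment,
        deme_labels=deme_labels,
        mutation_count=n_mut,
        tree_depth=float(tree_depth),
        positions=positions,
    )
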