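"""Within-sample diversity statistics: S, Hd, π, Watterson's θ, Tajima's D.

All statistics are computed over analyzed sites only (see
:mod:`divaxes.popgen.alignment`).  π and S use a per-column
frequency-spectrum formulation equivalent to — and tested against — the
O(n²L) brute-force pairwise count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alignment import LocusAlignment

__all__ = [
    "segregating_sites",
    "haplotype_diversity",
    "nucleotide_diversity",
    "mean_pairwise_differences",
    "watterson_theta",
    "tajimas_d",
    "LocusStats",
    "locus_stats",
]


def _harmonics(n: int) -> tuple[float, float]:
    i = np.arange(1, n)
    return float(np.sum(1.0 / i)), float(np.sum(1.0 / i**2))


def _variable_columns(m: np.ndarray) -> np.ndarray:
    """Indices of columns with at least two distinct states."""
    return np.flatnonzero(np.any(m != m[0], axis=0))


def segregating_sites(aln: LocusAlignment) -> int:
    """Number of analyzed columns with at least two distinct bases."""
    return int(_variable_columns(aln.analyzed_matrix()).size)


def haplotype_diversity(aln: LocusAlignment) -> float:
    """Hd = n(1 − Σp_i²)/(n−1) over distinct analyzed-site haplotypes."""
    n = aln.n
    if n < 2:
        raise ValueError("haplotype diversity needs n >= 2")
    m = aln.analyzed_matrix()
    haplotypes = ["".join(row) for row in m]
    _, counts = np.unique(haplotypes, return_counts=True)
    p = counts / n
    return float(n * (1.0 - np.sum(p**2)) / (n - 1))


def mean_pairwise_differences(aln: LocusAlignment) -> float:
    """Mean number of differences over all C(n,2) sequence pairs (per
    locus, not per site)."""
    m = aln.analyzed_matrix()
    n = aln.n
    if n < 2:
        raise ValueError("need n >= 2")
    pairs = n * (n - 1) / 2
    total = 0.0
    for col in _variable_columns(m):
        _, counts = np.unique(m[:, col], return_counts=True)
        total += pairs - np.sum(counts * (counts - 1) / 2)
    return float(total / pairs)


def nucleotide_diversity(aln: LocusAlignment) -> float:
    """Per-site π: mean pairwise differences divided by analyzed length."""
    if aln.L == 0:
        raise ValueError("no analyzed sites")
    return mean_pairwise_differences(aln) / aln.L


def watterson_theta(aln: LocusAlignment) -> tuple[float, float]:
    """Per-site Watterson θ̂ = S/(a1·L) and its standard error.

    The SE uses the neutral sampling variance of S,
    Var(S) = a1·θ_locus + a2·θ_locus², with θ_locus estimated by S/a1,
    divided through by (a1·L)²:

        Var(θ̂_site) = (a1·θ̂_locus + a2·θ̂_locus²) / (a1·L)²
    """
    n, L = aln.n, aln.L
    if L == 0:
        raise ValueError("no analyzed sites")
    if n < 2:
        raise ValueError("need n >= 2")
    s = segregating_sites(aln)
    a1, a2 = _harmonics(n)
    theta_site = s / (a1 * L)
    if s == 0:
        return 0.0, 0.0
    theta_locus = s / a1
    var = (a1 * theta_locus + a2 * theta_locus**2) / (a1 * L) ** 2
    return float(theta_site), float(np.sqrt(var))


def tajimas_d(aln: LocusAlignment) -> float | None:
    """Tajima's D; ``None`` (undefined) when there is no polymorphism.

    D = (π_locus − S/a1) / sqrt(e1·S + e2·S(S−1)) with the standard
    constants b1 = (n+1)/(3(n−1)), b2 = 2(n²+n+3)/(9n(n−1)),
    c1 = b1 − 1/a1, c2 = b2 − (n+2)/(a1·n) + a2/a1²,
    e1 = c1/a1, e2 = c2/(a1²+a2).
    """
    n = aln.n
    if n < 3:
        raise ValueError("Tajima's D needs n >= 3")
    s = segregating_sites(aln)
    if s == 0:
        return None
    a1, a2 = _harmonics(n)
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    var = e1 * s + e2 * s * (s - 1)
    if var <= 0:
        # n=3 collapses both variance constants to zero: D is undefined
        return None
    pi_locus = mean_pairwise_differences(aln)
    return float((pi_locus - s / a1) / np.sqrt(var))


@dataclass
class LocusStats:
    """Per-locus diversity summary (one row of a Table-2-style report)."""

    name: str
    n: int
    L: int
    S: int
    Hd: float
    theta_w_site: float
    theta_w_se: float
    pi_site: float
    tajimas_d: float | None


def locus_stats(aln: LocusAlignment) -> LocusStats:
    theta, se = watterson_theta(aln)
    return LocusStats(
        name=aln.name,
        n=aln.n,
        L=aln.L,
        S=segregating_sites(aln),
        Hd=haplotype_diversity(aln),
        theta_w_site=theta,
        theta_w_se=se,
        pi_site=nucleotide_diversity(aln),
        tajimas_d=tajimas_d(aln) if aln.n >= 3 else None,
    )
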