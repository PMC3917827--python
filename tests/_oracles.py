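"""Independent brute-force oracles used by the test suite.

These deliberately use naive O(n²L) pairwise loops and plain Python so
they share no code path with the package implementations they check.
"""

from __future__ import annotations

from itertools import combinations


def pair_diffs(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def brute_S(seqs: list[str]) -> int:
    return sum(
        1 for col in range(len(seqs[0])) if len({s[col] for s in seqs}) > 1
    )


def brute_pi_locus(seqs: list[str]) -> float:
    pairs = list(combinations(range(len(seqs)), 2))
    return sum(pair_diffs(seqs[i], seqs[j]) for i, j in pairs) / len(pairs)


def brute_hd(seqs: list[str]) -> float:
    n = len(seqs)
    counts: dict[str, int] = {}
    for s in seqs:
        counts[s] = counts.get(s, 0) + 1
    return n * (1 - sum((c / n) ** 2 for c in counts.values())) / (n - 1)


def brute_kst(seqs: list[str], pops: list[str]) -> float | None:
    """Size-weighted Kst = 1 − Ks/Kt from raw pairwise loops."""
    n = len(seqs)
    pairs = list(combinations(range(n), 2))
    kt = sum(pair_diffs(seqs[i], seqs[j]) for i, j in pairs) / len(pairs)
    if kt == 0:
        return None
    ks = 0.0
    for lab in sorted(set(pops)):
        idx = [i for i, p in enumerate(pops) if p == lab]
        within = list(combinations(idx, 2))
        kj = sum(pair_diffs(seqs[i], seqs[j]) for i, j in within) / len(within)
        ks += len(idx) / n * kj
    return 1 - ks / kt


def brute_fixed_differences(seqs: list[str], pops: list[str]) -> int:
    labs = sorted(set(pops))
    assert len(labs) == 2
    count = 0
    for col in range(len(seqs[0])):
        b1 = {seqs[i][col] for i, p in enumerate(pops) if p == labs[0]}
        b2 = {seqs[i][col] for i, p in enumerate(pops) if p == labs[1]}
        if not b1 & b2:
            count += 1
    return count
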