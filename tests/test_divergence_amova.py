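import numpy as np
import pytest

from divaxes.popgen import (
    LocusAlignment,
    PopPartition,
    amova,
    amova_single_level,
    fixed_differences,
    kst_test,
    percent_divergence,
)

from _oracles import brute_fixed_differences, brute_kst
from conftest import random_alignment


def _aln(seqs, name="t"):
    return LocusAlignment(name, [f"s{i}" for i in range(len(seqs))], list(seqs))


def _part(labels, groups=None):
    seq_to_pop = {f"s{i}": lab for i, lab in enumerate(labels)}
    return PopPartition(seq_to_pop, groups or {})


# ------------------------------------------------------------------ Kst


def test_kst_one_when_within_identical_between_different():
    seqs = ["AAAA"] * 6 + ["TTTT"] * 6
    res = kst_test(_aln(seqs), _part(["p1"] * 6 + ["p2"] * 6), 199, seed=0)
    assert res.ks == 0.0
    assert res.kst == pytest.approx(1.0)
    # only 2 of C(12,6) label allocations reproduce the perfect split
    assert res.p_value <= 0.05


def test_kst_undefined_without_polymorphism():
    res = kst_test(_aln(["AAAA"] * 6), _part(["p1"] * 3 + ["p2"] * 3), 99, seed=0)
    assert res.kst is None and res.p_value is None


def test_kst_null_centred_near_zero(rng):
    """Random labels over one panmictic pool: Kst averages about 0."""
    vals = []
    for k in range(25):
        aln = random_alignment(rng, n=10, length=80, name=f"r{k}")
        while True:
            labels = rng.permutation(["p1"] * 5 + ["p2"] * 5)
            res = kst_test(aln, _part(list(labels)), 99, seed=k)
            break
        if res.kst is not None:
            vals.append(res.kst)
    assert abs(np.mean(vals)) < 0.05


def test_kst_matches_bruteforce_oracle(rng):
    for k in range(40):
        aln = random_alignment(rng, n=8, length=100, name=f"o{k}")
        labels = ["p1"] * 4 + ["p2"] * 4
        res = kst_test(aln, _part(labels), 99, seed=k)
        oracle = brute_kst(aln.sequences, labels)
        if oracle is None:
            assert res.kst is None
        else:
            assert res.kst == pytest.approx(oracle)


def test_kst_reproducible_from_seed(rng):
    aln = random_alignment(rng, n=8, length=60)
    part = _part(["p1"] * 4 + ["p2"] * 4)
    a = kst_test(aln, part, 199, seed=11)
    b = kst_test(aln, part, 199, seed=11)
    assert a.p_value == b.p_value


def test_kst_requires_two_populations():
    with pytest.raises(ValueError):
        kst_test(_aln(["AAAA"] * 4), _part(["p1"] * 4), 99)


# ------------------------------------------------- fixed diffs and Dxy


def test_fixed_differences_hand_cases():
    # one fully fixed site; one site with a shared allele does not count
    seqs = ["AC", "AC", "TC", "TC"]
    assert fixed_differences(_aln(seqs), _part(["p1", "p1", "p2", "p2"])) == 1
    seqs = ["AC", "TC", "TC", "TC"]  # pop1 = {A,T}: shared with pop2
    assert fixed_differences(_aln(seqs), _part(["p1", "p1", "p2", "p2"])) == 0


def test_fixed_differences_matches_bruteforce(rng):
    for k in range(40):
        aln = random_alignment(rng, n=8, length=100, name=f"f{k}")
        labels = ["p1"] * 4 + ["p2"] * 4
        assert fixed_differences(aln, _part(labels)) == brute_fixed_differences(
            aln.sequences, labels
        )


def test_percent_divergence_hand_cases():
    part = _part(["p1", "p2"])
    seqs = ["A" * 95 + "TTTTT", "A" * 100]
    assert percent_divergence(_aln(seqs), part) == pytest.approx(5.0)
    assert percent_divergence(_aln(["A" * 50, "A" * 50]), part) == 0.0


def test_percent_divergence_net_subtracts_within(rng):
    aln = random_alignment(rng, n=8, length=100)
    part = _part(["p1"] * 4 + ["p2"] * 4)
    raw = percent_divergence(aln, part, net=False)
    net = percent_divergence(aln, part, net=True)
    assert net <= raw + 1e-12


# ---------------------------------------------------------------- AMOVA


def _hierarchy(seqs, pops, groups):
    ids = [f"s{i}" for i in range(len(seqs))]
    seq_to_pop = dict(zip(ids, pops))
    return _aln(seqs), PopPartition(seq_to_pop, groups)


def test_amova_all_variance_among_groups():
    seqs = ["A" * 20] * 6 + ["T" * 10 + "A" * 10] * 6
    pops = ["p1"] * 3 + ["p2"] * 3 + ["p3"] * 3 + ["p4"] * 3
    groups = {"p1": "g1", "p2": "g1", "p3": "g2", "p4": "g2"}
    aln, part = _hierarchy(seqs, pops, groups)
    res = amova(aln, part)
    assert res.f_ct == pytest.approx(1.0)
    assert res.percentages[0] == pytest.approx(100.0)


def test_amova_identical_sequences_rejected():
    aln, part = _hierarchy(
        ["AAAA"] * 12,
        ["p1"] * 3 + ["p2"] * 3 + ["p3"] * 3 + ["p4"] * 3,
        {"p1": "g1", "p2": "g1", "p3": "g2", "p4": "g2"},
    )
    with pytest.raises(ValueError, match="identical"):
        amova(aln, part)


def test_amova_single_group_rejected():
    aln, part = _hierarchy(
        ["AAAA", "AAAT"] * 3,
        ["p1"] * 3 + ["p2"] * 3,
        {"p1": "g1", "p2": "g1"},
    )
    with pytest.raises(ValueError):
        amova(aln, part)


def test_amova_balanced_hand_worked_fixture():
    """2 groups × 2 pops × 3 identical sequences; 1 difference between
    pops within groups, ~10 between groups.  Hand expected-mean-squares
    solution: σa=5, σb=0.5, σc=0 → F_CT=10/11, F_SC=1, F_ST=1."""
    base = "A" * 30

    def mut(s, sites):
        l = list(s)
        for p in sites:
            l[p] = "T"
        return "".join(l)

    seqs = (
        [base] * 3
        + [mut(base, [0])] * 3
        + [mut(base, range(10, 20))] * 3
        + [mut(base, list(range(10, 20)) + [1])] * 3
    )
    pops = ["p1"] * 3 + ["p2"] * 3 + ["p3"] * 3 + ["p4"] * 3
    groups = {"p1": "g1", "p2": "g1", "p3": "g2", "p4": "g2"}
    aln, part = _hierarchy(seqs, pops, groups)
    res = amova(aln, part)
    assert res.sigma_a == pytest.approx(5.0)
    assert res.sigma_b == pytest.approx(0.5)
    assert res.sigma_c == pytest.approx(0.0, abs=1e-12)
    assert res.f_ct == pytest.approx(10 / 11)
    assert res.f_sc == pytest.approx(1.0)
    assert res.f_st == pytest.approx(1.0)
    assert sum(res.percentages) == pytest.approx(100.0, abs=1e-6)


def test_amova_negative_component_reported_with_warning(rng):
    # more variation within pops than between: sigma_b estimates negative
    aln = random_alignment(rng, n=16, length=120)
    pops = list(rng.permutation(["p1"] * 4 + ["p2"] * 4 + ["p3"] * 4 + ["p4"] * 4))
    groups = {"p1": "g1", "p2": "g1", "p3": "g2", "p4": "g2"}
    part = PopPartition({f"s{i}": p for i, p in enumerate(pops)}, groups)
    with pytest.warns(UserWarning, match="negative"):
        res = amova(aln, part)
    assert res.sigma_a < 0 or res.sigma_b < 0
    assert sum(res.percentages) == pytest.approx(100.0, abs=1e-6)


def test_amova_single_level_reduction(rng):
    """Collapsing the hierarchy: the one-level F_ST equals the two-level
    F_ST when each group holds symmetric populations with no among-group
    structure beyond the population level."""
    seqs = ["A" * 20] * 3 + ["T" * 5 + "A" * 15] * 3 + ["C" * 5 + "A" * 15] * 3 + [
        "G" * 5 + "A" * 15
    ] * 3
    pops = ["p1"] * 3 + ["p2"] * 3 + ["p3"] * 3 + ["p4"] * 3
    part = PopPartition({f"s{i}": p for i, p in enumerate(pops)}, {})
    fst = amova_single_level(_aln(seqs), part)
    assert 0 < fst <= 1


def test_amova_permutation_p_values(rng):
    seqs = ["A" * 20] * 6 + ["T" * 8 + "A" * 12] * 6
    pops = ["p1"] * 3 + ["p2"] * 3 + ["p3"] * 3 + ["p4"] * 3
    groups = {"p1": "g1", "p2": "g1", "p3": "g2", "p4": "g2"}
    aln, part = _hierarchy(seqs, pops, groups)
    res = amova(aln, part, n_permutations=199, seed=5)
    assert res.p_f_st is not None and res.p_f_st <= 0.05
    # repeatability from the stored seed
    res2 = amova(aln, part, n_permutations=199, seed=5)
    assert res.p_f_ct == res2.p_f_ct
    assert res.p_f_sc == res2.p_f_sc
    assert res.p_f_st == res2.p_f_st
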