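"""AMOVA variance partitioning and SAMOVA group search."""

import itertools

import numpy as np
import pandas as pd
import pytest

from phylorefugia.amova_samova import (amova, amova_permutation_test,
                                       pairwise_distance_matrix,
                                       population_adjacency, samova)
from phylorefugia.seqio_haplotypes import PopulationMap


# -- distances -------------------------------------------------------------

def test_raw_distance_counts_mismatches():
    aln = {"a": "A" * 1000, "b": "A" * 999 + "T"}
    d = pairwise_distance_matrix(aln, model="raw")
    assert d.loc["a", "b"] == 1.0
    assert d.loc["a", "a"] == 0.0


def test_tn93_matches_independent_reference():
    # value cross-checked against ape::dist.dna(model="TN93")
    a = "ACGTACGTACGTAAGGCCTTACGTACGTGGCCAATTACGT"
    b = "ACGTACGAACGTAAGGCCTAACGTACGTGACCAATTACGC"
    d = pairwise_distance_matrix({"a": a, "b": b}, model="tamura_nei")
    assert d.loc["a", "b"] / 40 == pytest.approx(0.107662743428, abs=1e-10)


def test_tn93_falls_back_on_missing_bases():
    aln = {"a": "AAAA", "b": "AAAT"}   # no C/G: zero frequencies
    with pytest.warns(UserWarning, match="TN93 undefined"):
        d = pairwise_distance_matrix(aln, model="tamura_nei")
    assert d.loc["a", "b"] == 1.0


# -- AMOVA oracle ----------------------------------------------------------

def brute_force_amova(sqd, pops, group_of):
    """Independent ANOVA table from explicit squared-distance sums."""
    samples = list(range(len(pops)))
    N = len(samples)
    pop_names = sorted(set(pops))
    groups = sorted({group_of[p] for p in pop_names})
    by_pop = {p: [i for i in samples if pops[i] == p] for p in pop_names}
    by_grp = {g: [i for i in samples if group_of[pops[i]] == g] for g in groups}

    def pair_sum(idx):
        return sum(sqd[i][j] for i, j in itertools.combinations(idx, 2))

    ss_total = pair_sum(samples) / N
    ss_wp = sum(pair_sum(v) / len(v) for v in by_pop.values())
    ss_wg = sum(pair_sum(v) / len(v) for v in by_grp.values())
    ss_ag, ss_ap = ss_total - ss_wg, ss_wg - ss_wp
    P, G = len(pop_names), len(groups)
    n = {p: len(v) for p, v in by_pop.items()}
    Ng = {g: len(v) for g, v in by_grp.items()}
    sum_n2_grp = sum(sum(n[p] ** 2 for p in pop_names if group_of[p] == g) / Ng[g]
                     for g in groups)
    n1 = (N - sum_n2_grp) / (P - G)
    n2 = (sum_n2_grp - sum(v ** 2 for v in n.values()) / N) / (G - 1)
    n3 = (N - sum(v ** 2 for v in Ng.values()) / N) / (G - 1)
    sc = ss_wp / (N - P)
    sb = (ss_ap / (P - G) - sc) / n1
    sa = (ss_ag / (G - 1) - sc - n2 * sb) / n3
    return {"ss": (ss_ag, ss_ap, ss_wp), "sigma": (sa, sb, sc)}


def random_amova_instance(rng):
    n_groups = int(rng.integers(2, 4))
    pops, group_of = [], {}
    pop_id = 0
    for g in range(n_groups):
        for _ in range(int(rng.integers(2, 4))):
            name = f"P{pop_id}"
            group_of[name] = f"G{g}"
            pops.extend([name] * int(rng.integers(2, 6)))
            pop_id += 1
    n = len(pops)
    d = rng.integers(0, 10, size=(n, n)).astype(float)
    sqd = np.triu(d, 1)
    sqd = sqd + sqd.T
    return sqd, pops, group_of


@pytest.mark.parametrize("seed", range(5))
def test_amova_components_match_brute_force(seed):
    rng = np.random.default_rng(seed)
    sqd, pops, group_of = random_amova_instance(rng)
    res = amova(sqd, pops, group_of)
    oracle = brute_force_amova(sqd.tolist(), pops, group_of)
    got_ss = (res.ss["among_groups"],
              res.ss["among_populations_within_groups"],
              res.ss["within_populations"])
    got_sigma = (res.sigma["among_groups"],
                 res.sigma["among_populations_within_groups"],
                 res.sigma["within_populations"])
    assert got_ss == pytest.approx(oracle["ss"], rel=1e-10)
    assert got_sigma == pytest.approx(oracle["sigma"], rel=1e-10, abs=1e-10)
    sa, sb, sc = oracle["sigma"]
    assert res.phi_ct == pytest.approx(sa / (sa + sb + sc), rel=1e-9)


def test_identical_sequences_flagged():
    res = amova(np.zeros((6, 6)), ["A"] * 3 + ["B"] * 3)
    assert not np.isfinite(res.phi_st)
    assert any("undefined" in f for f in res.flags)


def test_two_fixed_groups_put_all_variance_among_groups():
    aln = {f"a{i}": "AAAA" for i in range(3)} | {f"b{i}": "TTTT" for i in range(3)}
    dist = pairwise_distance_matrix(aln)
    pops = ["A1", "A1", "A2", "B1", "B1", "B2"]
    groups = {"A1": "GA", "A2": "GA", "B1": "GB", "B2": "GB"}
    res = amova(dist.to_numpy(), pops, groups)
    assert res.percent["among_groups"] == pytest.approx(100.0, abs=1e-6)
    assert res.phi_st == pytest.approx(1.0)
    assert sum(res.percent.values()) == pytest.approx(100.0, abs=0.01)


def test_df_sum_to_n_minus_one(deep_split_dataset):
    ds = deep_split_dataset
    pm = PopulationMap(ds.pop_map)
    dist = pairwise_distance_matrix(ds.alignment)
    res = amova(dist, pm)
    assert sum(res.df.values()) == len(ds.alignment) - 1


def test_every_pop_own_group_reduces_to_two_level(deep_split_dataset):
    ds = deep_split_dataset
    pm = PopulationMap(ds.pop_map)
    dist = pairwise_distance_matrix(ds.alignment)
    own = {p: p for p in pm.populations}
    three = amova(dist, pm, groups=own)
    two = amova(dist, [pm.population_of[s] for s in dist.index])
    # among-groups absorbs the among-populations level
    assert three.ss["among_groups"] == pytest.approx(
        two.ss["among_populations"], rel=1e-9)
    assert three.phi_ct == pytest.approx(two.phi_st, rel=1e-6)


def test_permutations_extreme_case_and_reproducibility():
    aln = ({f"a{i}": "AAAAAAAA" for i in range(5)}
           | {f"b{i}": "TTTTTTTT" for i in range(5)})
    dist = pairwise_distance_matrix(aln)
    pops = ["A"] * 5 + ["B"] * 5
    p1 = amova_permutation_test(dist.to_numpy(), pops, n=500, seed=9)
    p2 = amova_permutation_test(dist.to_numpy(), pops, n=500, seed=9)
    assert p1 == p2
    assert p1["p_phi_st"] <= 0.05


def test_phi_ct_permutation_exhaustive_on_small_systems(deep_split_dataset):
    """With few populations the group permutation enumerates all distinct
    arrangements, so the p-value is exact and seed-independent."""
    ds = deep_split_dataset
    pm = PopulationMap(ds.pop_map)
    dist = pairwise_distance_matrix(ds.alignment)
    pa = amova_permutation_test(dist, pm, n=1000, seed=1)
    pb = amova_permutation_test(dist, pm, n=1000, seed=2)
    # 8 pops in two groups of 4 -> C(8,4)=70 arrangements, exhaustive
    assert pa["p_phi_ct"] == pb["p_phi_ct"]
    assert pa["p_phi_ct"] <= 0.05


# -- SAMOVA ----------------------------------------------------------------

def contiguous_bipartitions(pops, adj):
    """All 2-partitions with both sides connected (exhaustive oracle)."""
    out = []
    for r in range(1, len(pops)):
        for side in itertools.combinations(pops, r):
            side = set(side)
            rest = set(pops) - side
            if _connected(side, adj) and _connected(rest, adj):
                out.append((side, rest))
    return out


def _connected(members, adj):
    seen, stack = set(), [next(iter(members))]
    while stack:
        x = stack.pop()
        if x in seen:
            continue
        seen.add(x)
        stack.extend(adj[x] & members - seen)
    return seen == members


def test_samova_k2_matches_exhaustive_search(deep_split_dataset):
    ds = deep_split_dataset
    pm = PopulationMap(ds.pop_map)
    dist = pairwise_distance_matrix(ds.alignment)
    coords = pm.coordinates()
    adj = population_adjacency(coords)
    res = samova(dist, pm, coords, 2, n_runs=12, n_steps=300, seed=0)

    best = -np.inf
    pops = pm.populations
    pop_of = pm.population_of
    for side, rest in contiguous_bipartitions(pops, adj):
        grouping = {p: ("L" if p in side else "R") for p in pops}
        r = amova(dist, pm, groups=grouping)
        best = max(best, r.phi_ct)
    assert res.phi_ct == pytest.approx(best, abs=1e-9)
    # the recovered partition separates the two simulated groups
    north = {p for p, g in res.assignment.items()
             if g == res.assignment[pops[0]]}
    true_north = {p for p in pops if pm.group_of[p] == "north"}
    assert north in (true_north, set(pops) - true_north)


def test_samova_beats_random_contiguous_partitions(deep_split_dataset):
    ds = deep_split_dataset
    pm = PopulationMap(ds.pop_map)
    dist = pairwise_distance_matrix(ds.alignment)
    coords = pm.coordinates()
    adj = population_adjacency(coords)
    res = samova(dist, pm, coords, 3, n_runs=8, n_steps=200, seed=1)
    from phylorefugia.amova_samova import _random_contiguous_partition
    rng = np.random.default_rng(2)
    pops = pm.populations
    for _ in range(100):
        assign = _random_contiguous_partition(pops, adj, 3, rng)
        r = amova(dist, pm, groups={p: f"g{g}" for p, g in assign.items()})
        assert res.phi_ct >= r.phi_ct - 1e-9


def test_samova_rejects_bad_k(deep_split_dataset):
    ds = deep_split_dataset
    pm = PopulationMap(ds.pop_map)
    dist = pairwise_distance_matrix(ds.alignment)
    with pytest.raises(ValueError, match="k must"):
        samova(dist, pm, pm.coordinates(), len(pm.populations))


def test_adjacency_handles_collinear_points():
    coords = pd.DataFrame({"latitude": [0.0] * 5,
                           "longitude": [0.0, 1, 2, 3, 4]},
                          index=[f"P{i}" for i in range(5)])
    adj = population_adjacency(coords)
    assert adj["P0"] == {"P1"}
    assert adj["P2"] == {"P1", "P3"}
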