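"""Alignment I/O, haplotype collapsing, connection limit, and networks."""

import math

import numpy as np
import pandas as pd
import pytest

from phylorefugia.seqio_haplotypes import (HaplotypeTable, PopulationMap,
                                           build_network, collapse_haplotypes,
                                           parsimony_connection_limit,
                                           parsimony_probability,
                                           read_alignment, read_popmap,
                                           sequence_distance)


# -- I/O -------------------------------------------------------------------

def test_read_alignment_roundtrip(tmp_path):
    path = tmp_path / "a.fasta"
    path.write_text(">s1\nACGT\n>s2\nACGA\n>s3\nACGT\n")
    aln = read_alignment(str(path))
    assert list(aln) == ["s1", "s2", "s3"]
    assert aln["s2"] == "ACGA"


def test_read_alignment_rejects_ragged(tmp_path):
    path = tmp_path / "bad.fasta"
    path.write_text(">s1\nACGT\n>s2\nACG\n")
    with pytest.raises(ValueError, match="s2"):
        read_alignment(str(path))


def test_read_popmap_rejects_duplicates(tmp_path):
    path = tmp_path / "m.tsv"
    path.write_text("sample\tpopulation\tgroup\tlatitude\tlongitude\n"
                    "a\tP1\tG1\t0\t0\na\tP1\tG1\t0\t0\n")
    with pytest.raises(ValueError, match="duplicate"):
        read_popmap(str(path))


def test_popmap_requires_columns():
    with pytest.raises(ValueError, match="missing columns"):
        PopulationMap(pd.DataFrame({"sample": ["a"]}))


# -- collapsing ------------------------------------------------------------

def test_collapse_basic_counts():
    aln = {"x": "ACGT", "y": "ACGT", "z": "ACGA"}
    table = collapse_haplotypes(aln)
    assert table.n_haplotypes == 2
    assert sorted(table.frequencies) == [1, 2]
    assert sum(table.frequencies) == 3


def test_gap_mode_changes_identity():
    aln = {"x": "AC-T", "y": "ACGT"}
    assert collapse_haplotypes(aln, gap_mode="missing").n_haplotypes == 1
    assert collapse_haplotypes(aln, gap_mode="fifth_state").n_haplotypes == 2


def test_fifth_state_never_fewer_haplotypes():
    rng = np.random.default_rng(0)
    for _ in range(20):
        aln = {}
        for i in range(12):
            aln[f"s{i}"] = "".join(rng.choice(list("ACGT-"), size=30,
                                              p=[0.23, 0.23, 0.23, 0.23, 0.08]))
        n_missing = collapse_haplotypes(aln, gap_mode="missing").n_haplotypes
        n_fifth = collapse_haplotypes(aln, gap_mode="fifth_state").n_haplotypes
        assert n_fifth >= n_missing


def test_collapse_is_idempotent_and_conserves_samples():
    rng = np.random.default_rng(1)
    aln = {f"s{i}": "".join(rng.choice(list("ACGT"), size=20)) for i in range(15)}
    t1 = collapse_haplotypes(aln)
    reps = dict(t1.sequences)
    t2 = collapse_haplotypes(reps)
    assert t2.n_haplotypes == t1.n_haplotypes
    assert int(t1.counts.sum().sum()) == 15


def test_collapse_empty_raises():
    with pytest.raises(ValueError, match="empty"):
        collapse_haplotypes({})


def test_per_population_counts(toy_popmap):
    aln = {"a1": "AAAA", "a2": "AAAT", "b1": "AAAT", "b2": "AAAT"}
    table = collapse_haplotypes(aln, toy_popmap)
    assert table.counts.loc["H1", "A"] == 1
    assert table.counts.loc["H2", "A"] == 1
    assert table.counts.loc["H2", "B"] == 2
    assert table.counts.sum().tolist() == [2, 2]


# -- connection limit ------------------------------------------------------

def oracle_parsimony_probability(j, m, kmax=60):
    """Independent evaluation via explicit Poisson series for the
    Jukes–Cantor chain: P(differ | k hits) = 3/4 (1 - (-1/3)^k)."""
    p_obs = min(j / m, 0.7499)
    lam = -0.75 * math.log(1 - 4 * p_obs / 3)
    pois = [math.exp(-lam) * lam ** k / math.factorial(k) for k in range(kmax)]
    p_diff_k = [0.75 * (1 - (-1 / 3) ** k) for k in range(kmax)]
    p_diff = sum(p * d for p, d in zip(pois, p_diff_k))
    p_same = sum(p * (1 - d) for p, d in zip(pois, p_diff_k))
    p1 = pois[1] * p_diff_k[1] / p_diff
    p0 = pois[0] * 1.0 / p_same
    return p1 ** j * p0 ** (m - j)


def test_parsimony_probability_matches_series_oracle():
    for m in (100, 600, 1417):
        for j in (1, 3, 8, 15):
            assert parsimony_probability(j, m) == pytest.approx(
                oracle_parsimony_probability(j, m), rel=1e-9)


def test_connection_limit_matches_oracle_scan():
    for m in (100, 600, 1417):
        expected = 0
        for j in range(1, m + 1):
            if oracle_parsimony_probability(j, m) > 0.95:
                expected = j
            else:
                break
        assert parsimony_connection_limit(m, 0.95) == expected


def test_connection_limit_monotone_in_length():
    limits = [parsimony_connection_limit(m, 0.95)
              for m in (50, 200, 600, 1417, 5000)]
    assert limits == sorted(limits)


def test_connection_limit_edge_confidences():
    assert parsimony_connection_limit(50, 1e-300) == 50
    assert parsimony_connection_limit(50, 1 - 1e-12) == 0
    with pytest.raises(ValueError):
        parsimony_connection_limit(50, 1.5)
    with pytest.raises(ValueError):
        parsimony_connection_limit(0, 0.95)


# -- network ---------------------------------------------------------------

def table_from_seqs(seqs, counts=None):
    counts = counts or {h: 1 for h in seqs}
    ids = list(seqs)
    df = pd.DataFrame({"all": [counts[h] for h in ids]}, index=ids)
    return HaplotypeTable(sequences=dict(seqs), counts=df,
                          assignment={}, gap_mode="fifth_state")


def test_single_step_pair_direct_edge():
    net = build_network(table_from_seqs({"H1": "AAAA", "H2": "AAAT"}), limit=5)
    assert net.haplotype_edges == [("H1", "H2", 1)]
    assert all(net.graph.nodes[n]["kind"] == "haplotype" for n in net.graph)


def test_three_step_pair_gets_two_intermediates():
    net = build_network(table_from_seqs({"H1": "AAAA", "H2": "ATTT"}), limit=5)
    inter = [n for n in net.graph if net.graph.nodes[n]["kind"] == "intermediate"]
    assert len(inter) == 2
    assert all(net.graph.degree[n] == 2 for n in inter)
    assert net.graph.number_of_edges() == 3


def test_hub_topology_avoids_redundant_edge():
    # distances: H1-H2 = 1, H1-H3 = 1, H2-H3 = 2 -> hub through H1
    seqs = {"H1": "AAAA", "H2": "AAAT", "H3": "AAGA"}
    net = build_network(table_from_seqs(seqs), limit=5)
    edges = {frozenset(e[:2]) for e in net.haplotype_edges}
    assert edges == {frozenset({"H1", "H2"}), frozenset({"H1", "H3"})}


def test_equal_length_loop_resolved_by_frequency():
    # square: H1-H2, H2-H3, H3-H4, H4-H1 all distance 1; one edge must go
    seqs = {"H1": "AA", "H2": "AT", "H3": "TT", "H4": "TA"}
    counts = {"H1": 10, "H2": 8, "H3": 1, "H4": 2}
    net = build_network(table_from_seqs(seqs, counts), limit=5)
    assert len(net.haplotype_edges) == 3
    assert len(net.discarded_alternatives) >= 1
    # the highest-frequency adjacent pair is kept
    assert ("H1", "H2", 1) in net.haplotype_edges


def test_connection_limit_splits_components():
    seqs = {"H1": "AAAAAAAA", "H2": "AAAAAAAT", "H3": "TTTTTTTT"}
    net = build_network(table_from_seqs(seqs), limit=2)
    comps = sorted(sorted(c) for c in net.components)
    assert comps == [["H1", "H2"], ["H3"]]


def test_tree_edge_count_when_loop_free():
    rng = np.random.default_rng(3)
    seqs = {f"H{i}": "".join(rng.choice(list("ACGT"), size=40)) for i in range(6)}
    net = build_network(table_from_seqs(seqs), limit=100)
    n_haps = 6
    assert len(net.haplotype_edges) == n_haps - len(net.components)


def test_sequence_distance_modes():
    assert sequence_distance("AC-T", "ACGT", "missing") == 0
    assert sequence_distance("AC-T", "ACGT", "fifth_state") == 1
    assert sequence_distance("AAAA", "TTTT", "missing") == 4
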