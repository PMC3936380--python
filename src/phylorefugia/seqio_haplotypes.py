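"""Alignment and population-map I/O, haplotype collapsing, and
statistical-parsimony networks.

Haplotype collapsing supports two gap conventions used with chloroplast
alignments: ``missing`` (a site where either sequence carries a gap is
ignored in the identity comparison, the treatment used when combining
datasets of unequal coverage) and ``fifth_state`` (a gap is a distinct
character, appropriate when indels are phylogenetically informative).

Networks follow the statistical-parsimony construction: haplotype pairs
are linked through chains of single-step intermediates, closest pairs
first, up to a connection limit chosen so that the probability the
connection is free of superimposed changes exceeds a confidence level
(0.95 by default).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "PopulationMap",
    "HaplotypeTable",
    "ParsimonyNetwork",
    "read_alignment",
    "read_popmap",
    "collapse_haplotypes",
    "sequence_distance",
    "parsimony_probability",
    "parsimony_connection_limit",
    "build_network",
]


@dataclass
class PopulationMap:
    """sample -> (population, group, latitude, longitude)."""

    table: pd.DataFrame

    REQUIRED = ("sample", "population", "group", "latitude", "longitude")

    def __post_init__(self):
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"population map missing columns: {missing}")
        dup = self.table["sample"][self.table["sample"].duplicated()]
        if len(dup):
            raise ValueError(f"duplicate sample ids in population map: {sorted(set(dup))}")
        coords = self.table[["latitude", "longitude"]].to_numpy(float)
        if not np.isfinite(coords).all():
            raise ValueError("non-finite coordinates in population map")

    @property
    def population_of(self) -> dict[str, str]:
        return dict(zip(self.table["sample"], self.table["population"]))

    @property
    def group_of(self) -> dict[str, str]:
        return dict(zip(self.table["population"], self.table["group"]))

    @property
    def populations(self) -> list[str]:
        return list(dict.fromkeys(self.table["population"]))

    def coordinates(self) -> pd.DataFrame:
        """One (latitude, longitude) row per population (first occurrence)."""
        return (self.table.groupby("population", sort=False)
                [["latitude", "longitude"]].first())


def read_alignment(path: str) -> dict[str, str]:
    """Read an aligned FASTA into an ordered ``{id: sequence}`` mapping."""
    records = list(SeqIO.parse(path, "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    seqs: dict[str, str] = {}
    length = len(records[0].seq)
    for rec in records:
        if rec.id in seqs:
            raise ValueError(f"duplicate FASTA id {rec.id!r}")
        if len(rec.seq) != length:
            raise ValueError(
                f"ragged alignment: record {rec.id!r} has length "
                f"{len(rec.seq)}, expected {length}"
            )
        seqs[rec.id] = str(rec.seq).upper()
    return seqs


def read_popmap(path: str) -> PopulationMap:
    """Read a TSV with columns sample, population, group, latitude, longitude."""
    return PopulationMap(pd.read_csv(path, sep="\t"))


def check_alignment_mapped(alignment: Mapping[str, str], popmap: PopulationMap) -> None:
    unmapped = sorted(set(alignment) - set(popmap.table["sample"]))
    if unmapped:
        raise KeyError(f"samples missing from population map: {unmapped}")


# -- haplotype collapsing --------------------------------------------------

def _same_haplotype(a: str, b: str, gap_mode: str) -> bool:
    if gap_mode == "fifth_state":
        return a == b
    return all(x == y for x, y in zip(a, b) if x != "-" and y != "-")


@dataclass
class HaplotypeTable:
    """Collapsed haplotypes with per-population counts.

    ``counts`` is a haplotype x population integer DataFrame;
    ``assignment`` maps each sample to its haplotype id.
    """

    sequences: dict[str, str]          # haplotype id -> representative sequence
    counts: pd.DataFrame
    assignment: dict[str, str]
    gap_mode: str

    @property
    def n_haplotypes(self) -> int:
        return len(self.sequences)

    @property
    def frequencies(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def distance_matrix(self) -> pd.DataFrame:
        """Pairwise mutational distances between representative sequences."""
        ids = list(self.sequences)
        n = len(ids)
        mat = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                d = sequence_distance(self.sequences[ids[i]],
                                      self.sequences[ids[j]], self.gap_mode)
                mat[i, j] = mat[j, i] = d
        return pd.DataFrame(mat, index=ids, columns=ids)


def collapse_haplotypes(alignment: Mapping[str, str],
                        popmap: PopulationMap | None = None,
                        gap_mode: str = "fifth_state") -> HaplotypeTable:
    """Collapse aligned sequences into haplotypes under ``gap_mode``.

    Under ``missing``, gap-containing sites are excluded pairwise from the
    identity comparison (which is not transitive for heavily gapped data;
    samples are assigned greedily, in input order, to the first matching
    haplotype's representative).  Under ``fifth_state`` identity is exact
    string equality.
    """
    if not alignment:
        raise ValueError("empty alignment")
    if gap_mode not in ("missing", "fifth_state"):
        raise ValueError(f"unknown gap_mode {gap_mode!r}")
    if popmap is not None:
        check_alignment_mapped(alignment, popmap)
        pop_of = popmap.population_of
        pops = popmap.populations
    else:
        pop_of = {s: "all" for s in alignment}
        pops = ["all"]

    reps: list[tuple[str, str]] = []   # (haplotype id, representative sequence)
    assignment: dict[str, str] = {}
    if gap_mode == "fifth_state":
        index: dict[str, str] = {}
        for sample, seq in alignment.items():
            hap = index.get(seq)
            if hap is None:
                hap = f"H{len(reps) + 1}"
                reps.append((hap, seq))
                index[seq] = hap
            assignment[sample] = hap
    else:
        for sample, seq in alignment.items():
            for hap, rep in reps:
                if _same_haplotype(seq, rep, gap_mode):
                    assignment[sample] = hap
                    break
            else:
                hap = f"H{len(reps) + 1}"
                reps.append((hap, seq))
                assignment[sample] = hap

    ids = [h for h, _ in reps]
    counts = pd.DataFrame(0, index=ids, columns=pops, dtype=int)
    for sample, hap in assignment.items():
        counts.loc[hap, pop_of[sample]] += 1
    return HaplotypeTable(sequences=dict(reps), counts=counts,
                          assignment=assignment, gap_mode=gap_mode)


def sequence_distance(a: str, b: str, gap_mode: str = "missing") -> int:
    """Mutational steps between two aligned sequences.

    ``missing``: mismatches over sites where neither sequence has a gap
    (pairwise deletion).  ``fifth_state``: plain mismatch count with '-'
    as an ordinary symbol.
    """
    if gap_mode == "fifth_state":
        return sum(x != y for x, y in zip(a, b))
    return sum(x != y for x, y in zip(a, b) if x != "-" and y != "-")


# -- statistical parsimony connection limit --------------------------------

def parsimony_probability(j: int, locus_length: int) -> float:
    """Probability that j observed differences reflect j true mutations.

    Follows the probability-of-parsimony logic of statistical parsimony:
    per-site mutation counts are Poisson with mean lam chosen so that the
    expected proportion of differing sites under Jukes–Cantor equals
    j / locus_length; the connection between two haplotypes is parsimonious
    when every differing site mutated exactly once and every identical
    site not at all.  Divergences at or beyond the Jukes–Cantor saturation
    point (3/4) are capped there.
    """
    m = locus_length
    if j == 0:
        return 1.0
    p_diff_obs = min(j / m, 0.7499)
    lam = -0.75 * math.log1p(-4.0 * p_diff_obs / 3.0)
    e = math.exp(-lam)
    e43 = math.exp(-4.0 * lam / 3.0)
    p_diff = 0.75 * (1.0 - e43)            # P(site differs) under JC
    p_same = 0.25 + 0.75 * e43
    p1 = min(lam * e / p_diff, 1.0)        # P(one mutation | site differs)
    p0 = min(e / p_same, 1.0)              # P(no mutation | site identical)
    return p1 ** j * p0 ** (m - j)


def parsimony_connection_limit(locus_length: int, confidence: float = 0.95) -> int:
    """Largest number of steps whose parsimony probability exceeds ``confidence``."""
    if locus_length < 1:
        raise ValueError("locus_length must be >= 1")
    if not 0.0 < confidence < 1.0:
        raise ValueError("confidence must lie in (0, 1)")
    limit = 0
    for j in range(1, locus_length + 1):
        if parsimony_probability(j, locus_length) > confidence:
            limit = j
        else:
            break
    return limit


# -- network construction --------------------------------------------------

@dataclass
class ParsimonyNetwork:
    """Haplotype graph with single-step edges via inferred intermediates.

    ``graph`` holds haplotypes (node attribute ``kind='haplotype'``, with
    ``frequency``) and anonymous intermediates (``kind='intermediate'``,
    frequency 0); every edge is one mutational step.  ``haplotype_edges``
    lists the underlying haplotype-to-haplotype connections with their
    step counts; ``discarded_alternatives`` records equal-length
    connections dropped by the frequency criterion.
    """

    graph: nx.Graph
    connection_limit: int
    haplotype_edges: list[tuple[str, str, int]]
    components: list[set[str]]
    discarded_alternatives: list[tuple[str, str, int]] = field(default_factory=list)

    def edge_list(self) -> pd.DataFrame:
        rows = [{"node1": u, "node2": v, "steps": 1} for u, v in self.graph.edges]
        return pd.DataFrame(rows, columns=["node1", "node2", "steps"])


def build_network(haplotypes: HaplotypeTable,
                  limit: int | None = None,
                  confidence: float = 0.95) -> ParsimonyNetwork:
    """Build a statistical-parsimony network from a haplotype table.

    Pairs are considered in order of increasing mutational distance (a
    minimum-spanning construction): an edge is added when it joins two
    distinct components and its length does not exceed the connection
    limit.  When several equal-length connections would join the same
    components, the pair with the higher total haplotype frequency is
    kept (simplified frequency criterion) and the alternatives recorded.
    Multi-step edges are expanded into chains of inferred intermediates.
    """
    ids = list(haplotypes.sequences)
    if limit is None:
        L = len(next(iter(haplotypes.sequences.values())))
        limit = parsimony_connection_limit(L, confidence)
    dist = haplotypes.distance_matrix()
    freq = haplotypes.frequencies

    pairs = []
    for i, u in enumerate(ids):
        for v in ids[i + 1:]:
            d = int(dist.loc[u, v])
            if d == 0:
                warnings.warn(f"haplotypes {u} and {v} at distance 0; "
                              "check gap_mode consistency")
            pairs.append((d, -(freq[u] + freq[v]), u, v))
    pairs.sort()

    parent = {h: h for h in ids}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    chosen: list[tuple[str, str, int]] = []
    discarded: list[tuple[str, str, int]] = []
    i = 0
    while i < len(pairs):
        # process one distance class at a time so that equal-length
        # alternatives closing a loop are detected and reported
        d = pairs[i][0]
        block = []
        while i < len(pairs) and pairs[i][0] == d:
            block.append(pairs[i])
            i += 1
        if d > limit:
            break
        at_block_start = {h: find(h) for h in ids}
        for dd, negf, u, v in block:
            ru, rv = find(u), find(v)
            if ru == rv:
                # a genuine equal-length alternative only if the two
                # haplotypes were joined within this distance class
                if at_block_start[u] != at_block_start[v]:
                    discarded.append((u, v, dd))
                continue
            parent[ru] = rv
            chosen.append((u, v, dd))

    graph = nx.Graph()
    for h in ids:
        graph.add_node(h, kind="haplotype", frequency=int(freq[h]))
    for u, v, d in chosen:
        prev = u
        for k in range(1, d):
            mid = f"{u}~{v}.{k}"
            graph.add_node(mid, kind="intermediate", frequency=0)
            graph.add_edge(prev, mid, steps=1)
            prev = mid
        graph.add_edge(prev, v, steps=1)

    comp_sets = []
    for comp in nx.connected_components(graph):
        haps = {n for n in comp if graph.nodes[n]["kind"] == "haplotype"}
        if haps:
            comp_sets.append(haps)
    return ParsimonyNetwork(graph=graph, connection_limit=int(limit),
                            haplotype_edges=chosen, components=comp_sets,
                            discarded_alternatives=discarded)
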