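"""Hierarchical analysis of molecular variance and spatial group search.

AMOVA partitions squared pairwise sequence distances into hierarchical
variance components (among groups, among populations within groups,
within populations) following the Excoffier–Smouse–Quattro sums-of-squares
construction with unequal-sample-size coefficients, yielding the fixation
indices Phi_CT, Phi_SC and Phi_ST.  Significance is assessed by
permutation at the appropriate level.  SAMOVA searches, by simulated
annealing over geographically contiguous partitions of populations, for
the K groups maximizing Phi_CT.

Note on distances: following common practice for haplotype data, the
number of pairwise differences is used directly as the squared distance
entering the sums of squares.  A Tamura–Nei (TN93) corrected alternative
is provided.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.spatial import Delaunay, QhullError

from .seqio_haplotypes import PopulationMap

__all__ = [
    "pairwise_distance_matrix",
    "AmovaResult",
    "amova",
    "amova_permutation_test",
    "SamovaResult",
    "samova",
    "population_adjacency",
]


# -- distances -------------------------------------------------------------

def _tn93_pair(a: str, b: str) -> float:
    """TN93 distance per site for one pair; raises on undefined logs."""
    pairs = [(x, y) for x, y in zip(a, b) if x != "-" and y != "-"
             and x in "ACGT" and y in "ACGT"]
    n = len(pairs)
    if n == 0:
        raise ValueError("no comparable sites")
    freqs = {c: 0.0 for c in "ACGT"}
    for x, y in pairs:
        freqs[x] += 0.5 / n
        freqs[y] += 0.5 / n
    gA, gC, gG, gT = freqs["A"], freqs["C"], freqs["G"], freqs["T"]
    gR, gY = gA + gG, gC + gT
    p1 = sum(1 for x, y in pairs if {x, y} == {"A", "G"}) / n   # purine transitions
    p2 = sum(1 for x, y in pairs if {x, y} == {"C", "T"}) / n   # pyrimidine transitions
    q = sum(1 for x, y in pairs if (x in "AG") != (y in "AG")) / n  # transversions
    if min(gA * gG, gC * gT, gR * gY) <= 0:
        raise ValueError("zero base frequency")
    k1 = 2 * gA * gG / gR
    k2 = 2 * gC * gT / gY
    k3 = 2 * (gR * gY - gA * gG * gY / gR - gC * gT * gR / gY)
    w1 = 1 - p1 / k1 - q / (2 * gR)
    w2 = 1 - p2 / k2 - q / (2 * gY)
    w3 = 1 - q / (2 * gR * gY)
    if min(w1, w2, w3) <= 0:
        raise ValueError("TN93 distance undefined (saturation)")
    return -k1 * math.log(w1) - k2 * math.log(w2) - k3 * math.log(w3)


def pairwise_distance_matrix(alignment: Mapping[str, str], model: str = "raw",
                             gap_mode: str = "missing") -> pd.DataFrame:
    """Sample x sample distance matrix.

    ``raw`` counts pairwise mismatches (pairwise deletion of gapped sites
    under ``gap_mode='missing'``).  ``tamura_nei`` applies the TN93
    correction and rescales by the number of compared sites, falling back
    to the raw count (with a warning) where the correction is undefined.
    """
    from .seqio_haplotypes import sequence_distance

    names = list(alignment)
    n = len(names)
    mat = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        a, b = alignment[names[i]], alignment[names[j]]
        raw = sequence_distance(a, b, gap_mode)
        if model == "raw":
            d = float(raw)
        elif model == "tamura_nei":
            valid = sum(1 for x, y in zip(a, b) if x != "-" and y != "-")
            try:
                d = _tn93_pair(a, b) * valid
            except ValueError as err:
                warnings.warn(f"TN93 undefined for pair ({names[i]}, {names[j]}): "
                              f"{err}; using raw count")
                d = float(raw)
        else:
            raise ValueError(f"unknown model {model!r}")
        mat[i, j] = mat[j, i] = d
    return pd.DataFrame(mat, index=names, columns=names)


# -- AMOVA -----------------------------------------------------------------

@dataclass
class AmovaResult:
    """Hierarchical variance components and Phi fixation indices."""

    df: dict[str, int]
    ss: dict[str, float]
    sigma: dict[str, float]            # variance components, as computed
    percent: dict[str, float]
    phi_ct: float
    phi_sc: float
    phi_st: float
    flags: list[str] = field(default_factory=list)

    def table(self) -> pd.DataFrame:
        rows = []
        for level in self.df:
            rows.append({"source": level, "df": self.df[level],
                         "sum_of_squares": self.ss[level],
                         "variance_component": self.sigma.get(level, np.nan),
                         "percent_variation": self.percent.get(level, np.nan)})
        rows.append({"source": "Total", "df": sum(self.df.values()),
                     "sum_of_squares": sum(self.ss.values()),
                     "variance_component": sum(self.sigma.values()),
                     "percent_variation": np.nan})
        return pd.DataFrame(rows)


class _PairSums:
    """Population-level aggregation of a squared-distance matrix.

    Stores ``pp[p, q]`` = sum of squared distances over sample pairs with
    one member in population p and the other in q (within-population pair
    sums on the diagonal), enabling O(P^2) evaluation of any grouping —
    the workhorse of the SAMOVA search.
    """

    def __init__(self, sqd: np.ndarray, pop_index: np.ndarray, n_pops: int):
        self.n = np.bincount(pop_index, minlength=n_pops).astype(float)
        P = n_pops
        pp = np.zeros((P, P))
        # accumulate via indicator matrix: M[p, i] = 1 if sample i in pop p
        M = np.zeros((P, len(pop_index)))
        M[pop_index, np.arange(len(pop_index))] = 1.0
        full = M @ sqd @ M.T
        pp = full / 2.0
        np.fill_diagonal(pp, np.diag(full) / 2.0)
        self.pp = pp
        self.N = float(self.n.sum())
        self.total_pair_sum = float(np.triu(sqd, 1).sum())
        self.ss_wp = float(sum(pp[p, p] / self.n[p] for p in range(P) if self.n[p] > 0))

    def ss_within_groups(self, group_of_pop: np.ndarray, n_groups: int) -> float:
        ss = 0.0
        for g in range(n_groups):
            pops = np.flatnonzero(group_of_pop == g)
            if len(pops) == 0:
                continue
            Ng = self.n[pops].sum()
            ss += self.pp[np.ix_(pops, pops)].sum() / Ng
        return ss


def _components(ps: _PairSums, group_of_pop: np.ndarray, n_groups: int):
    """Variance components from pair sums for a given grouping."""
    n = ps.n
    N = ps.N
    P = int((n > 0).sum())
    G = n_groups
    ss_total = ps.total_pair_sum / N
    ss_wp = ps.ss_wp
    if G <= 1:
        df_ap, df_wp = P - 1, int(N) - P
        ss_ap = ss_total - ss_wp
        sigma_c = ss_wp / df_wp if df_wp > 0 else 0.0
        n_prime = (N - (n ** 2).sum() / N) / df_ap
        sigma_a = (ss_ap / df_ap - sigma_c) / n_prime
        return {"among_populations": (df_ap, ss_ap, sigma_a),
                "within_populations": (df_wp, ss_wp, sigma_c)}

    ss_wg = ps.ss_within_groups(group_of_pop, G)
    ss_ag = ss_total - ss_wg
    ss_ap = ss_wg - ss_wp
    df_ag, df_ap, df_wp = G - 1, P - G, int(N) - P
    Ng = np.array([n[np.flatnonzero(group_of_pop == g)].sum() for g in range(G)])
    sum_n2_by_group = np.array([
        (n[np.flatnonzero(group_of_pop == g)] ** 2).sum() / Ng[g] if Ng[g] > 0 else 0.0
        for g in range(G)])
    n2 = (sum_n2_by_group.sum() - (n ** 2).sum() / N) / df_ag
    n3 = (N - (Ng ** 2).sum() / N) / df_ag
    sigma_c = ss_wp / df_wp if df_wp > 0 else 0.0
    if df_ap > 0:
        n1 = (N - sum_n2_by_group.sum()) / df_ap
        sigma_b = (ss_ap / df_ap - sigma_c) / n1
    else:
        sigma_b = 0.0  # every group is a single population
    sigma_a = (ss_ag / df_ag - sigma_c - n2 * sigma_b) / n3
    return {"among_groups": (df_ag, ss_ag, sigma_a),
            "among_populations_within_groups": (df_ap, ss_ap, sigma_b),
            "within_populations": (df_wp, ss_wp, sigma_c)}


def _prepare(distances, populations, groups):
    D = distances.to_numpy(float) if isinstance(distances, pd.DataFrame) else np.asarray(distances, float)
    if isinstance(populations, PopulationMap):
        if not isinstance(distances, pd.DataFrame):
            raise ValueError("PopulationMap input requires a labeled distance DataFrame")
        pop_of = populations.population_of
        pop_labels = [pop_of[s] for s in distances.index]
        if groups is None:
            groups = populations.group_of
    else:
        pop_labels = list(populations)
    pop_names = list(dict.fromkeys(pop_labels))
    pop_index = np.array([pop_names.index(p) for p in pop_labels])
    if groups is None:
        group_of_pop = np.zeros(len(pop_names), dtype=int)
        group_names = ["all"]
    else:
        group_names = list(dict.fromkeys(groups[p] for p in pop_names))
        group_of_pop = np.array([group_names.index(groups[p]) for p in pop_names])
    return D, pop_index, pop_names, group_of_pop, group_names


def amova(distances, populations, groups: Mapping[str, str] | None = None) -> AmovaResult:
    """Hierarchical AMOVA on a (squared) distance matrix.

    ``distances``: sample x sample matrix (DataFrame indexed by sample ids
    or plain array); entries are treated as squared distances (pairwise
    difference counts, per the usual convention for haplotype data).
    ``populations``: a PopulationMap, or a sequence of population labels
    aligned with the matrix rows.  ``groups`` maps population -> group; if
    omitted (and not implied by a PopulationMap), a two-level analysis is
    performed.
    """
    D, pop_index, pop_names, group_of_pop, group_names = _prepare(
        distances, populations, groups)
    if len(pop_names) < 2:
        raise ValueError("AMOVA requires at least 2 populations")
    ps = _PairSums(D, pop_index, len(pop_names))
    comp = _components(ps, group_of_pop, len(group_names))

    df = {k: v[0] for k, v in comp.items()}
    ss = {k: v[1] for k, v in comp.items()}
    sigma = {k: v[2] for k, v in comp.items()}
    total = sum(sigma.values())
    flags = []
    if total <= 0:
        flags.append("total variance <= 0: fixation indices undefined")
        percent = {k: np.nan for k in sigma}
        phi_ct = phi_sc = phi_st = np.nan
    else:
        percent = {k: 100.0 * v / total for k, v in sigma.items()}
        if "among_groups" in sigma:
            a = sigma["among_groups"]
            b = sigma["among_populations_within_groups"]
            c = sigma["within_populations"]
            phi_ct = a / total
            phi_sc = b / (b + c) if (b + c) != 0 else np.nan
            phi_st = (a + b) / total
        else:
            a = sigma["among_populations"]
            phi_ct = np.nan
            phi_sc = np.nan
            phi_st = a / total
    if any(v < 0 for v in sigma.values()):
        flags.append("negative variance component (reported as computed)")
    return AmovaResult(df=df, ss=ss, sigma=sigma, percent=percent,
                       phi_ct=phi_ct, phi_sc=phi_sc, phi_st=phi_st, flags=flags)


def _count_group_label_arrangements(group_of_pop: np.ndarray) -> float:
    counts = np.bincount(group_of_pop)
    total = math.factorial(len(group_of_pop))
    for c in counts:
        total //= math.factorial(int(c))
    return total


def amova_permutation_test(distances, populations, groups: Mapping[str, str] | None = None,
                           n: int = 10000, seed=None) -> dict[str, float]:
    """Permutation p-values for the AMOVA fixation indices.

    Phi_ST: individuals permuted among populations across the whole
    system; Phi_SC: individuals permuted among populations within their
    group; Phi_CT: whole populations permuted among groups (exhaustively
    when fewer than ``n`` distinct arrangements exist).  p-values use the
    (count >= observed + 1) / (n + 1) convention.
    """
    rng = np.random.default_rng(seed)
    D, pop_index, pop_names, group_of_pop, group_names = _prepare(
        distances, populations, groups)
    P, G = len(pop_names), len(group_names)
    ps = _PairSums(D, pop_index, P)
    comp = _components(ps, group_of_pop, G)

    def phis(comp):
        sigma = {k: v[2] for k, v in comp.items()}
        total = sum(sigma.values())
        if total <= 0:
            return np.nan, np.nan, np.nan
        if "among_groups" in sigma:
            a, b, c = (sigma["among_groups"],
                       sigma["among_populations_within_groups"],
                       sigma["within_populations"])
            return a / total, (b / (b + c) if b + c != 0 else np.nan), (a + b) / total
        return np.nan, np.nan, sigma["among_populations"] / total

    obs_ct, obs_sc, obs_st = phis(comp)
    out: dict[str, float] = {}

    # Phi_ST: shuffle individuals across the whole system
    if np.isfinite(obs_st):
        count = 0
        for _ in range(n):
            perm = rng.permutation(pop_index)
            c = _components(_PairSums(D, perm, P), group_of_pop, G)
            st = phis(c)[2]
            count += np.isfinite(st) and st >= obs_st - 1e-12
        out["p_phi_st"] = (count + 1.0) / (n + 1.0)
    else:
        out["p_phi_st"] = np.nan

    if G > 1:
        # Phi_SC: shuffle individuals among populations within groups
        if np.isfinite(obs_sc):
            group_of_sample = group_of_pop[pop_index]
            count = 0
            for _ in range(n):
                perm = pop_index.copy()
                for g in range(G):
                    idx = np.flatnonzero(group_of_sample == g)
                    perm[idx] = perm[rng.permutation(idx)]
                c = _components(_PairSums(D, perm, P), group_of_pop, G)
                sc = phis(c)[1]
                count += np.isfinite(sc) and sc >= obs_sc - 1e-12
            out["p_phi_sc"] = (count + 1.0) / (n + 1.0)
        else:
            out["p_phi_sc"] = np.nan

        # Phi_CT: permute populations among groups
        if np.isfinite(obs_ct):
            n_arrangements = _count_group_label_arrangements(group_of_pop)
            count = 0
            if n_arrangements <= n:
                from sympy.utilities.iterables import multiset_permutations
                n_eff = 0
                for arrangement in multiset_permutations(list(group_of_pop)):
                    c = _components(ps, np.array(arrangement), G)
                    ct = phis(c)[0]
                    count += np.isfinite(ct) and ct >= obs_ct - 1e-12
                    n_eff += 1
                out["p_phi_ct"] = count / n_eff  # exhaustive: exact proportion
            else:
                for _ in range(n):
                    c = _components(ps, rng.permutation(group_of_pop), G)
                    ct = phis(c)[0]
                    count += np.isfinite(ct) and ct >= obs_ct - 1e-12
                out["p_phi_ct"] = (count + 1.0) / (n + 1.0)
        else:
            out["p_phi_ct"] = np.nan
    return out


# -- SAMOVA ----------------------------------------------------------------

def population_adjacency(coords: pd.DataFrame) -> dict[str, set[str]]:
    """Neighborhood graph of populations from a Delaunay triangulation.

    ``coords``: DataFrame indexed by population with latitude/longitude
    columns.  Degenerate (collinear) layouts fall back to a chain along
    the principal axis; disconnected graphs are repaired by adding the
    shortest bridging edge (with a warning).
    """
    pops = list(coords.index)
    pts = coords[["longitude", "latitude"]].to_numpy(float)
    adj: dict[str, set[str]] = {p: set() for p in pops}
    if len(pops) < 2:
        return adj
    if len(pops) == 2:
        adj[pops[0]].add(pops[1]); adj[pops[1]].add(pops[0])
        return adj
    try:
        tri = Delaunay(pts)
        for simplex in tri.simplices:
            for i, j in itertools.combinations(simplex, 2):
                adj[pops[i]].add(pops[j])
                adj[pops[j]].add(pops[i])
    except QhullError:
        centered = pts - pts.mean(axis=0)
        axis = np.linalg.svd(centered, full_matrices=False)[2][0]
        order = np.argsort(centered @ axis)
        for a, b in zip(order, order[1:]):
            adj[pops[a]].add(pops[b])
            adj[pops[b]].add(pops[a])
        return adj

    # repair disconnected components (possible with duplicate points)
    comps = _graph_components(adj)
    while len(comps) > 1:
        warnings.warn("adjacency graph disconnected; bridging nearest components")
        best = None
        for ca, cb in itertools.combinations(comps, 2):
            for a, b in itertools.product(ca, cb):
                d = np.linalg.norm(pts[pops.index(a)] - pts[pops.index(b)])
                if best is None or d < best[0]:
                    best = (d, a, b)
        _, a, b = best
        adj[a].add(b); adj[b].add(a)
        comps = _graph_components(adj)
    return adj


def _graph_components(adj: Mapping[str, set[str]]) -> list[set[str]]:
    seen, comps = set(), []
    for start in adj:
        if start in seen:
            continue
        comp, stack = set(), [start]
        while stack:
            x = stack.pop()
            if x in comp:
                continue
            comp.add(x)
            stack.extend(adj[x] - comp)
        seen |= comp
        comps.append(comp)
    return comps


def _is_connected(members: set[str], adj: Mapping[str, set[str]]) -> bool:
    if not members:
        return False
    stack = [next(iter(members))]
    seen = set()
    while stack:
        x = stack.pop()
        if x in seen:
            continue
        seen.add(x)
        stack.extend((adj[x] & members) - seen)
    return seen == members


@dataclass
class SamovaResult:
    """Best geographically contiguous K-partition found by annealing."""

    k: int
    assignment: dict[str, int]
    phi_ct: float
    run_best: list[float]
    n_runs: int


def _random_contiguous_partition(pops, adj, k, rng):
    seeds = rng.choice(len(pops), size=k, replace=False)
    assign = {pops[s]: g for g, s in enumerate(seeds)}
    frontier = True
    while frontier:
        frontier = False
        order = rng.permutation(len(pops))
        for i in order:
            p = pops[i]
            if p in assign:
                continue
            neighbor_groups = {assign[q] for q in adj[p] if q in assign}
            if neighbor_groups:
                assign[p] = list(neighbor_groups)[rng.integers(len(neighbor_groups))]
                frontier = True
    # isolated pops (shouldn't happen on a connected graph)
    for p in pops:
        assign.setdefault(p, int(rng.integers(k)))
    return assign


def samova(distances, populations, coords: pd.DataFrame, k: int,
           n_runs: int = 100, n_steps: int = 1000, seed=None,
           adjacency: Mapping[str, set[str]] | None = None) -> SamovaResult:
    """Search for the K contiguous groups of populations maximizing Phi_CT.

    ``coords`` is indexed by population (latitude/longitude); contiguity
    is enforced on the Delaunay neighborhood graph.  Each of ``n_runs``
    annealing runs starts from a random contiguous K-partition and
    proposes single-population moves to adjacent groups, accepting
    improvements always and worse moves with probability
    exp(delta/T) under geometric cooling.
    """
    D, pop_index, pop_names, _, _ = _prepare(distances, populations, None)
    if not 2 <= k < len(pop_names):
        raise ValueError(f"k must satisfy 2 <= k < {len(pop_names)}")
    adj = adjacency if adjacency is not None else population_adjacency(
        coords.loc[pop_names])
    ps = _PairSums(D, pop_index, len(pop_names))
    rng = np.random.default_rng(seed)
    pidx = {p: i for i, p in enumerate(pop_names)}

    def phi_ct_of(assign: Mapping[str, int]) -> float:
        gop = np.array([assign[p] for p in pop_names])
        comp = _components(ps, gop, k)
        sigma = {kk: v[2] for kk, v in comp.items()}
        total = sum(sigma.values())
        if total <= 0:
            return -np.inf
        return sigma["among_groups"] / total

    best_assign, best_phi = None, -np.inf
    run_best = []
    for _ in range(n_runs):
        assign = _random_contiguous_partition(pop_names, adj, k, rng)
        phi = phi_ct_of(assign)

        def proposals():
            out = []
            group_members = {}
            for p, g in assign.items():
                group_members.setdefault(g, set()).add(p)
            for p in pop_names:
                g = assign[p]
                if len(group_members[g]) < 2:
                    continue
                targets = {assign[q] for q in adj[p]} - {g}
                if not targets:
                    continue
                if not _is_connected(group_members[g] - {p}, adj):
                    continue
                out.extend((p, t) for t in targets)
            return out

        # initial temperature: accept ~half of typical worsening moves
        deltas = []
        for p, t in proposals()[:20]:
            old = assign[p]
            assign[p] = t
            deltas.append(abs(phi_ct_of(assign) - phi))
            assign[p] = old
        temp = (np.median(deltas) / math.log(2.0)) if deltas and np.median(deltas) > 0 else 0.01

        local_best, local_assign = phi, dict(assign)
        stage = max(1, n_steps // 50)
        for step in range(n_steps):
            moves = proposals()
            if not moves:
                break
            p, t = moves[rng.integers(len(moves))]
            old = assign[p]
            assign[p] = t
            new_phi = phi_ct_of(assign)
            delta = new_phi - phi
            if delta >= 0 or rng.random() < math.exp(delta / max(temp, 1e-12)):
                phi = new_phi
                if phi > local_best:
                    local_best, local_assign = phi, dict(assign)
            else:
                assign[p] = old
            if (step + 1) % stage == 0:
                temp *= 0.9
        run_best.append(local_best)
        if local_best > best_phi:
            best_phi, best_assign = local_best, local_assign
    return SamovaResult(k=k, assignment=best_assign, phi_ct=float(best_phi),
                        run_best=run_best, n_runs=n_runs)
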