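"""Population diversity and differentiation statistics.

Per-population haplotype diversity (Nei's unbiased h) and nucleotide
diversity (pi), pairwise Phi_ST between populations from sequence
distances, and the Pons–Petit unordered/ordered framework: h_S, h_T
(haplotype identity), v_S, v_T (mutational distances), the derived
coefficients G_ST = 1 - h_S/h_T and N_ST = 1 - v_S/v_T, and the one-sided
permutation test of N_ST > G_ST that diagnoses phylogeographic structure
(related haplotypes co-occurring within populations).

Estimators follow the Pons–Petit unbiased construction for unequal
sample sizes: within-population diversities carry the n/(n-1) correction
and are averaged with the harmonic mean sample size; the total diversity
uses unweighted mean haplotype frequencies across populations with a
sampling-variance correction.  Standard errors are obtained by
delete-one-population jackknife.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .seqio_haplotypes import PopulationMap, sequence_distance

__all__ = [
    "haplotype_diversity",
    "nucleotide_diversity",
    "population_diversity",
    "PermutResult",
    "pons_petit",
    "PairwiseFstMatrix",
    "pairwise_fst",
]


def haplotype_diversity(counts: Sequence[int]) -> float:
    """Nei's unbiased haplotype diversity h = n/(n-1) (1 - sum p_i^2)."""
    counts = np.asarray(counts, dtype=float)
    n = counts.sum()
    if n < 2:
        raise ValueError("haplotype diversity undefined for n < 2")
    p = counts / n
    return float(n / (n - 1.0) * (1.0 - np.sum(p ** 2)))


def nucleotide_diversity(alignment: Mapping[str, str], gap_mode: str = "missing") -> float:
    """Mean pairwise proportion of differing sites (per site).

    Under ``missing`` gaps are excluded pairwise from both the mismatch
    count and the site total.
    """
    seqs = list(alignment.values())
    if len(seqs) < 2:
        raise ValueError("nucleotide diversity requires at least 2 sequences")
    total = 0.0
    n_pairs = 0
    for a, b in itertools.combinations(seqs, 2):
        if gap_mode == "missing":
            valid = sum(1 for x, y in zip(a, b) if x != "-" and y != "-")
            diffs = sequence_distance(a, b, "missing")
        else:
            valid = len(a)
            diffs = sequence_distance(a, b, "fifth_state")
        if valid:
            total += diffs / valid
        n_pairs += 1
    return total / n_pairs


def population_diversity(alignment: Mapping[str, str], popmap: PopulationMap,
                         gap_mode: str = "missing") -> pd.DataFrame:
    """Per-population table of n, haplotype diversity h, and pi.

    Populations with a single sample get NaN diversities.
    """
    from .seqio_haplotypes import collapse_haplotypes
    rows = []
    pop_of = popmap.population_of
    for pop in popmap.populations:
        sub = {s: alignment[s] for s in alignment if pop_of.get(s) == pop}
        n = len(sub)
        if n < 2:
            rows.append({"population": pop, "n": n, "h": np.nan, "pi": np.nan})
            continue
        table = collapse_haplotypes(sub, gap_mode=gap_mode)
        rows.append({
            "population": pop,
            "n": n,
            "h": haplotype_diversity(table.frequencies.to_numpy()),
            "pi": nucleotide_diversity(sub, gap_mode),
        })
    return pd.DataFrame(rows).set_index("population")


# -- Pons & Petit ----------------------------------------------------------

def _pp_components(counts: np.ndarray, dmat: np.ndarray) -> tuple[float, float]:
    """Pons–Petit (v_S, v_T) for a haplotype count matrix and distance matrix.

    ``counts``: haplotypes x populations; ``dmat``: haplotype distances
    (identity 0/1 matrix for the unordered statistics).
    """
    n_k = counts.sum(axis=0)
    keep = n_k >= 1
    counts = counts[:, keep]
    n_k = n_k[keep]
    K = counts.shape[1]
    x = counts / n_k                      # sample frequencies per population
    n_tilde = K / np.sum(1.0 / n_k)      # harmonic mean sample size
    d_within = np.einsum("ik,jk,ij->k", x, x, dmat)
    v_s = n_tilde / (n_tilde - 1.0) * d_within.mean()
    xbar = x.mean(axis=1)
    v_t = float(xbar @ dmat @ xbar) + v_s / (K * n_tilde)
    return float(v_s), float(v_t)


@dataclass
class PermutResult:
    """Pons–Petit diversities, differentiation coefficients, and the
    N_ST > G_ST permutation test."""

    hS: float
    hT: float
    vS: float
    vT: float
    GST: float
    NST: float
    se_hS: float
    se_hT: float
    se_vS: float
    se_vT: float
    se_GST: float
    se_NST: float
    p_value: float
    n_permutations: int
    flags: list[str]


def _gst_nst(counts: np.ndarray, identity: np.ndarray, dmat: np.ndarray):
    hS, hT = _pp_components(counts, identity)
    vS, vT = _pp_components(counts, dmat)
    gst = 1.0 - hS / hT if hT > 0 else np.nan
    nst = 1.0 - vS / vT if vT > 0 else np.nan
    return hS, hT, vS, vT, gst, nst


def pons_petit(counts: pd.DataFrame | np.ndarray,
               distances: pd.DataFrame | np.ndarray,
               n_permutations: int = 1000, seed=None) -> PermutResult:
    """Unordered/ordered differentiation with the N_ST > G_ST test.

    ``counts`` is haplotypes x populations; ``distances`` the symmetric,
    zero-diagonal mutational distance matrix between haplotypes (e.g.
    network step counts).  The permutation test shuffles haplotype
    identities on the distance matrix (rows and columns together) and
    recomputes N_ST; the one-sided p-value is the fraction of permutations
    with N_ST - G_ST at least as large as observed (with the +1
    small-sample correction).  Negative estimates are reported as computed
    and flagged.
    """
    C = np.asarray(counts, dtype=float)
    D = np.asarray(distances, dtype=float)
    if C.shape[1] < 2:
        raise ValueError("need at least 2 populations")
    if D.shape != (C.shape[0], C.shape[0]):
        raise ValueError("distance matrix shape does not match haplotype count")
    if not np.allclose(D, D.T) or np.any(np.diag(D) != 0):
        raise ValueError("distance matrix must be symmetric with zero diagonal")

    identity = 1.0 - np.eye(C.shape[0])
    hS, hT, vS, vT, gst, nst = _gst_nst(C, identity, D)
    flags = []
    if not np.isfinite(gst) or not np.isfinite(nst):
        flags.append("undefined: no total diversity (all populations share one haplotype)")
    for name, val in (("GST", gst), ("NST", nst)):
        if np.isfinite(val) and val < 0:
            flags.append(f"{name} < 0 (sampling noise)")

    # delete-one-population jackknife SEs
    K = C.shape[1]
    jack = []
    if K > 2:
        for k in range(K):
            sub = np.delete(C, k, axis=1)
            if (sub.sum(axis=1) > 0).sum() >= 1:
                jack.append(_gst_nst(sub, identity, D))
    jack = np.array([j for j in jack if np.all(np.isfinite(j))])
    if len(jack) >= 2:
        m = len(jack)
        se = np.sqrt((m - 1.0) / m * np.sum((jack - jack.mean(axis=0)) ** 2, axis=0))
    else:
        se = np.full(6, np.nan)

    rng = np.random.default_rng(seed)
    observed = nst - gst
    count = 0
    if np.isfinite(observed):
        for _ in range(n_permutations):
            perm = rng.permutation(C.shape[0])
            Dp = D[np.ix_(perm, perm)]
            vS_p, vT_p = _pp_components(C, Dp)
            nst_p = 1.0 - vS_p / vT_p if vT_p > 0 else np.nan
            if np.isfinite(nst_p) and nst_p - gst >= observed - 1e-12:
                count += 1
        p = (count + 1.0) / (n_permutations + 1.0)
    else:
        p = np.nan

    return PermutResult(hS=hS, hT=hT, vS=vS, vT=vT, GST=gst, NST=nst,
                        se_hS=se[0], se_hT=se[1], se_vS=se[2], se_vT=se[3],
                        se_GST=se[4], se_NST=se[5],
                        p_value=p, n_permutations=n_permutations, flags=flags)


# -- pairwise Phi_ST -------------------------------------------------------

@dataclass
class PairwiseFstMatrix:
    """Pairwise Phi_ST estimates between populations with permutation p-values."""

    fst: pd.DataFrame
    p_values: pd.DataFrame
    excluded: list[str]


def pairwise_fst(distances: pd.DataFrame, popmap: PopulationMap,
                 n_permutations: int = 1000, seed=None) -> PairwiseFstMatrix:
    """Pairwise Phi_ST from a sample x sample (squared) distance matrix.

    Each population pair is analysed as a two-population AMOVA; the
    p-value permutes individuals between the two populations.  Populations
    with fewer than 2 samples are excluded with a warning.
    """
    from .amova_samova import amova

    rng = np.random.default_rng(seed)
    pop_of = popmap.population_of
    samples_by_pop: dict[str, list[str]] = {}
    for s in distances.index:
        samples_by_pop.setdefault(pop_of[s], []).append(s)
    excluded = [p for p, ss in samples_by_pop.items() if len(ss) < 2]
    if excluded:
        warnings.warn(f"populations excluded from pairwise Phi_ST (n < 2): {excluded}")
    pops = [p for p in popmap.populations if p not in excluded and p in samples_by_pop]

    fst = pd.DataFrame(0.0, index=pops, columns=pops)
    pvals = pd.DataFrame(1.0, index=pops, columns=pops)
    D = distances.to_numpy(float)
    idx_of = {s: i for i, s in enumerate(distances.index)}

    for a, b in itertools.combinations(pops, 2):
        samples = samples_by_pop[a] + samples_by_pop[b]
        sub = D[np.ix_([idx_of[s] for s in samples], [idx_of[s] for s in samples])]
        labels = np.array([0] * len(samples_by_pop[a]) + [1] * len(samples_by_pop[b]))

        def phi_st(lab):
            res = amova(sub, lab)
            return res.phi_st

        obs = phi_st(labels)
        count = 0
        for _ in range(n_permutations):
            count += phi_st(rng.permutation(labels)) >= obs - 1e-12
        p = (count + 1.0) / (n_permutations + 1.0)
        fst.loc[a, b] = fst.loc[b, a] = obs
        pvals.loc[a, b] = pvals.loc[b, a] = p
    np.fill_diagonal(pvals.values, np.nan)
    return PairwiseFstMatrix(fst=fst, p_values=pvals, excluded=excluded)
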