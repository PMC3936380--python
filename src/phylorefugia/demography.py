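"""Neutrality tests and mismatch-distribution analysis.

Tajima's D contrasts pairwise diversity with the Watterson estimate from
segregating sites; Fu's Fs measures the excess of haplotypes relative to
the Ewens sampling expectation at the observed pairwise diversity — both
are driven negative by population growth.  Significance comes from
neutral coalescent simulation (conditioned on S for D, on theta_pi for
Fs).  The mismatch distribution is fit to the sudden-expansion model of
a population jumping from theta0 to theta1 at scaled time tau; fit is by
bounded least squares on the sum of squared deviations (SSD), and the SSD
and Harpending raggedness goodness-of-fit p-values come from a parametric
bootstrap (re-simulating and re-fitting under the fitted expansion).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares
from scipy.special import gammaln, logsumexp

from .seqio_haplotypes import sequence_distance

__all__ = [
    "segregating_sites",
    "mean_pairwise_differences",
    "NeutralityResult",
    "tajimas_d",
    "fus_fs",
    "log_ewens_pmf",
    "MismatchResult",
    "expected_mismatch",
    "raggedness",
    "mismatch_fit",
]


# -- summary statistics ----------------------------------------------------

def segregating_sites(alignment: Mapping[str, str], gap_mode: str = "missing") -> int:
    """Number of polymorphic sites (gapped states ignored under ``missing``)."""
    seqs = list(alignment.values())
    S = 0
    for col in zip(*seqs):
        states = set(col)
        if gap_mode == "missing":
            states -= {"-"}
        if len(states) > 1:
            S += 1
    return S


def mean_pairwise_differences(alignment: Mapping[str, str],
                              gap_mode: str = "missing") -> float:
    """Average number of pairwise sequence differences (per locus)."""
    seqs = list(alignment.values())
    if len(seqs) < 2:
        return 0.0
    diffs = [sequence_distance(a, b, gap_mode)
             for a, b in itertools.combinations(seqs, 2)]
    return float(np.mean(diffs))


@dataclass
class NeutralityResult:
    statistic: float
    p_value: float
    n: int
    S: int
    flags: list[str]


# -- Tajima's D ------------------------------------------------------------

def _tajima_constants(n: int):
    a1 = np.sum(1.0 / np.arange(1, n))
    a2 = np.sum(1.0 / np.arange(1, n) ** 2)
    b1 = (n + 1.0) / (3.0 * (n - 1.0))
    b2 = 2.0 * (n ** 2 + n + 3.0) / (9.0 * n * (n - 1.0))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2.0) / (a1 * n) + a2 / a1 ** 2
    e1 = c1 / a1
    e2 = c2 / (a1 ** 2 + a2)
    return a1, a2, e1, e2


def _tajima_d_from_summaries(n: int, S: int, pi: float) -> float:
    a1, _, e1, e2 = _tajima_constants(n)
    var = e1 * S + e2 * S * (S - 1.0)
    return (pi - S / a1) / math.sqrt(var)


def _simulate_coalescent_tree_lengths(n: int, rng) -> tuple[np.ndarray, np.ndarray]:
    """Branch structure of a neutral coalescent: per-coalescence intervals.

    Returns (interval lengths in coalescent units, lineage counts per
    interval) for k = n..2.
    """
    ks = np.arange(n, 1, -1)
    rates = ks * (ks - 1) / 2.0
    times = rng.exponential(1.0 / rates)
    return times, ks


def _simulate_sample_infinite_sites(n: int, rng, S: int | None = None,
                                    theta: float | None = None):
    """Mutation sets per tip under a neutral coalescent.

    Either conditioned on S segregating sites (mutations placed uniformly
    on branches) or with mutations Poisson(theta/2 per unit branch).
    Returns a list of frozensets of mutation ids, one per tip.
    """
    # build the tree explicitly (small n: fine)
    nodes = [{"children": [], "length": 0.0, "tips": [i]} for i in range(n)]
    active = list(range(n))
    t = 0.0
    all_nodes = list(nodes)
    while len(active) > 1:
        k = len(active)
        t_wait = rng.exponential(2.0 / (k * (k - 1)))
        for idx in active:
            all_nodes[idx]["length"] += t_wait
        i, j = rng.choice(k, size=2, replace=False)
        a, b = active[i], active[j]
        parent = {"children": [a, b], "length": 0.0,
                  "tips": all_nodes[a]["tips"] + all_nodes[b]["tips"]}
        all_nodes.append(parent)
        active = [x for x in active if x not in (a, b)] + [len(all_nodes) - 1]
        t += t_wait
    lengths = np.array([nd["length"] for nd in all_nodes[:-1]])  # root has no branch
    total = lengths.sum()
    tip_sets = [set() for _ in range(n)]
    if S is not None:
        branches = rng.choice(len(lengths), size=S, p=lengths / total)
    else:
        n_mut = rng.poisson(theta / 2.0 * total)
        branches = rng.choice(len(lengths), size=n_mut, p=lengths / total) if n_mut else []
    for mut_id, br in enumerate(branches):
        for tip in all_nodes[br]["tips"]:
            tip_sets[tip].add(mut_id)
    return [frozenset(s) for s in tip_sets]


def _pi_from_sets(tip_sets) -> float:
    diffs = [len(a ^ b) for a, b in itertools.combinations(tip_sets, 2)]
    return float(np.mean(diffs))


def tajimas_d(alignment: Mapping[str, str], gap_mode: str = "missing",
              n_sims: int = 10000, seed=None) -> NeutralityResult:
    """Tajima's D with a coalescent-simulation p-value conditioned on S.

    The p-value is one-tailed in the direction of the observed departure
    (fraction of neutral simulations at least as extreme).
    """
    n = len(alignment)
    if n < 4:
        raise ValueError("Tajima's D requires n >= 4")
    S = segregating_sites(alignment, gap_mode)
    if S == 0:
        return NeutralityResult(np.nan, np.nan, n, 0,
                                ["undefined: no segregating sites"])
    pi = mean_pairwise_differences(alignment, gap_mode)
    d_obs = _tajima_d_from_summaries(n, S, pi)
    rng = np.random.default_rng(seed)
    sims = np.empty(n_sims)
    for i in range(n_sims):
        tip_sets = _simulate_sample_infinite_sites(n, rng, S=S)
        sims[i] = _tajima_d_from_summaries(n, S, _pi_from_sets(tip_sets))
    if d_obs <= 0:
        p = float(np.mean(sims <= d_obs))
    else:
        p = float(np.mean(sims >= d_obs))
    return NeutralityResult(float(d_obs), p, n, S, [])


# -- Fu's Fs ---------------------------------------------------------------

@lru_cache(maxsize=64)
def _log_unsigned_stirling_first(n: int) -> np.ndarray:
    """log |s(n, k)| for k = 0..n via |s(m,k)| = (m-1)|s(m-1,k)| + |s(m-1,k-1)|."""
    prev = np.full(n + 1, -np.inf)
    prev[0] = 0.0
    for m in range(1, n + 1):
        cur = np.full(n + 1, -np.inf)
        with np.errstate(divide="ignore"):
            grown = math.log(m - 1) + prev if m > 1 else np.full(n + 1, -np.inf)
        cur[1:m + 1] = np.logaddexp(grown[1:m + 1], prev[0:m])
        prev = cur
    prev.setflags(write=False)
    return prev


def log_ewens_pmf(n: int, theta: float) -> np.ndarray:
    """log P(K = k) for k = 1..n under the Ewens sampling distribution.

    P(K = k) = |s(n, k)| theta^k / theta^(n), with theta^(n) the rising
    factorial theta(theta+1)...(theta+n-1).
    """
    if theta <= 0:
        raise ValueError("theta must be positive")
    log_stirling = _log_unsigned_stirling_first(n)[1:]
    ks = np.arange(1, n + 1)
    log_rising = np.sum(np.log(theta + np.arange(n)))
    return log_stirling + ks * math.log(theta) - log_rising


def _fs_from_counts(n: int, k_observed: int, theta_pi: float) -> float:
    logp = log_ewens_pmf(n, theta_pi)
    log_sp = logsumexp(logp[k_observed - 1:])   # log P(K >= k_obs)
    sp = math.exp(log_sp)
    if sp >= 1.0:
        sp = 1.0 - 1e-15
    log_one_minus = logsumexp(logp[:k_observed - 1]) if k_observed > 1 else None
    if log_one_minus is None:
        one_minus = 1.0 - sp
    else:
        one_minus = math.exp(log_one_minus)
    if one_minus <= 0:
        one_minus = 1e-300
    return log_sp - math.log(one_minus)


def fus_fs(n: int, k_observed: int, theta_pi: float, n_sims: int = 1000,
           seed=None) -> NeutralityResult:
    """Fu's Fs = logit of P(K >= k_observed | theta = theta_pi).

    The p-value is the fraction of neutral constant-size coalescent
    simulations at theta_pi whose Fs is at least as small as observed
    (Fu's convention: small Fs signals haplotype excess / growth).
    """
    if n < 2:
        raise ValueError("Fu's Fs requires n >= 2")
    if not 1 <= k_observed <= n:
        raise ValueError("k_observed must be in 1..n")
    if theta_pi <= 0:
        raise ValueError("theta_pi must be positive; "
                         "Fs undefined for monomorphic samples")
    fs_obs = _fs_from_counts(n, k_observed, theta_pi)
    rng = np.random.default_rng(seed)
    p = np.nan
    if n_sims:
        sims = []
        for _ in range(n_sims):
            tip_sets = _simulate_sample_infinite_sites(n, rng, theta=theta_pi)
            k_sim = len(set(tip_sets))
            pi_sim = _pi_from_sets(tip_sets)
            if pi_sim > 0:
                sims.append(_fs_from_counts(n, k_sim, pi_sim))
        if sims:
            p = float(np.mean(np.asarray(sims) <= fs_obs))
    return NeutralityResult(float(fs_obs), p, n, k_observed, [])


def fus_fs_from_alignment(alignment: Mapping[str, str], gap_mode: str = "missing",
                          n_sims: int = 1000, seed=None) -> NeutralityResult:
    from .seqio_haplotypes import collapse_haplotypes
    n = len(alignment)
    k = collapse_haplotypes(alignment, gap_mode=gap_mode).n_haplotypes
    theta_pi = mean_pairwise_differences(alignment, gap_mode)
    if theta_pi == 0:
        return NeutralityResult(np.nan, np.nan, n, k,
                                ["undefined: no pairwise differences"])
    return fus_fs(n, k, theta_pi, n_sims=n_sims, seed=seed)


# -- mismatch distribution -------------------------------------------------

def _geometric_f(theta: float, support: np.ndarray) -> np.ndarray:
    """Equilibrium pairwise-difference pmf F_i = theta^i / (1+theta)^(i+1)."""
    if theta == 0:
        return (support == 0).astype(float)
    # log space: large theta and support overflow the direct form
    return np.exp(support * math.log(theta)
                  - (support + 1.0) * math.log1p(theta))


def expected_mismatch(support: np.ndarray, tau: float, theta0: float,
                      theta1: float) -> np.ndarray:
    """Sudden-expansion expected mismatch distribution on ``support``.

    F_i(tau, theta0, theta1) = F_i(theta1)
      + exp(-tau (theta1 + 1) / theta1) * sum_{j<=i} tau^j/j! [F_{i-j}(theta0) - F_{i-j}(theta1)]
    """
    support = np.asarray(support)
    i_max = int(support.max())
    idx = np.arange(i_max + 1)
    f0 = _geometric_f(theta0, idx)
    f1 = _geometric_f(theta1, idx)
    if theta1 <= 0:
        raise ValueError("theta1 must be positive")
    log_pois = -tau + idx * np.log(tau) - gammaln(idx + 1) if tau > 0 else None
    out = np.empty(len(support))
    for pos, i in enumerate(support):
        if tau <= 0:
            out[pos] = f0[i]
            continue
        j = np.arange(i + 1)
        weights = np.exp(log_pois[j] - tau / theta1)
        out[pos] = f1[i] + np.sum(weights * (f0[i - j] - f1[i - j]))
    return np.clip(out, 0.0, None)


def raggedness(freqs: Sequence[float]) -> float:
    """Harpending's raggedness: sum of squared successive differences."""
    f = np.asarray(freqs, dtype=float)
    return float(np.sum(np.diff(f) ** 2))


@dataclass
class MismatchResult:
    tau: float
    theta0: float
    theta1: float
    observed: np.ndarray
    expected: np.ndarray
    ssd: float
    hri: float
    p_ssd: float
    p_hri: float
    n_bootstrap: int
    flags: list[str]


def _observed_mismatch(diffs: np.ndarray) -> np.ndarray:
    counts = np.bincount(diffs)
    return counts / counts.sum()


def _fit_expansion(obs: np.ndarray) -> tuple[float, float, float, float]:
    """Least-squares fit of (tau, theta0, theta1) to an observed pmf."""
    support = np.arange(len(obs))
    mean_d = float(support @ obs)

    def residuals(params):
        tau, theta0, dtheta = params
        return expected_mismatch(support, tau, theta0, theta0 + dtheta) - obs

    best = None
    starts = [(max(mean_d, 0.1), 0.1, max(10.0 * mean_d, 1.0)),
              (max(mean_d / 2, 0.1), 0.5, max(2.0 * mean_d, 1.0)),
              (max(2 * mean_d, 0.2), 0.01, 100.0)]
    hi = max(4.0 * len(obs), 10.0)
    for x0 in starts:
        try:
            fit = least_squares(residuals, x0=x0,
                                bounds=([0.0, 1e-6, 0.0], [hi, hi, 1e4]))
        except Exception:
            continue
        ssd = float(np.sum(fit.fun ** 2))
        if best is None or ssd < best[0]:
            best = (ssd, fit.x)
    ssd, (tau, theta0, dtheta) = best
    return tau, theta0, theta0 + dtheta, ssd


def _simulate_expansion_tip_sets(n: int, tau: float, theta0: float,
                                 theta1: float, rng) -> list[set]:
    """Infinite-sites mutation sets per tip under sudden expansion.

    Coalescent simulated on the mutational time axis x = 2ut: pair
    coalescence rate 1/theta(x) (theta1 before tau, theta0 after), each
    lineage accruing Poisson(length/2) infinite-sites mutations.
    """
    # coalescence times on the x axis
    active = list(range(n))
    nodes = [{"length": 0.0, "tips": [i]} for i in range(n)]
    x = 0.0
    while len(active) > 1:
        k = len(active)
        rate_unit = k * (k - 1) / 2.0
        theta = theta1 if x < tau else theta0
        wait = rng.exponential(theta / rate_unit)
        if x < tau and x + wait > tau:
            # advance to the epoch change, re-draw in the older epoch
            for idx in active:
                nodes[idx]["length"] += tau - x
            x = tau
            continue
        for idx in active:
            nodes[idx]["length"] += wait
        x += wait
        i, j = rng.choice(k, size=2, replace=False)
        a, b = active[i], active[j]
        nodes.append({"length": 0.0, "tips": nodes[a]["tips"] + nodes[b]["tips"]})
        active = [y for y in active if y not in (a, b)] + [len(nodes) - 1]
    tip_sets = [set() for _ in range(n)]
    for mut_src, nd in enumerate(nodes[:-1]):
        n_mut = rng.poisson(nd["length"] / 2.0)
        for m in range(n_mut):
            for tip in nd["tips"]:
                tip_sets[tip].add((mut_src, m))
    return [frozenset(s) for s in tip_sets]


def _simulate_mismatch_sample(n: int, tau: float, theta0: float, theta1: float,
                              rng) -> np.ndarray:
    """Pairwise-difference counts for n samples under sudden expansion."""
    tip_sets = _simulate_expansion_tip_sets(n, tau, theta0, theta1, rng)
    return np.array([len(a ^ b) for a, b in itertools.combinations(tip_sets, 2)])


def mismatch_fit(alignment: Mapping[str, str], gap_mode: str = "missing",
                 n_bootstrap: int = 1000, seed=None) -> MismatchResult:
    """Fit the sudden-expansion model to the observed mismatch distribution.

    Goodness of fit: SSD between observed and fitted distributions and
    Harpending's raggedness, each with a parametric-bootstrap p-value
    (datasets simulated under the fitted expansion, re-fit, p = fraction
    with statistic >= observed).  A model that fits yields large p.
    """
    n = len(alignment)
    if n < 3:
        raise ValueError("mismatch analysis requires n >= 3")
    seqs = list(alignment.values())
    diffs = np.array([sequence_distance(a, b, gap_mode)
                      for a, b in itertools.combinations(seqs, 2)])
    obs = _observed_mismatch(diffs)
    hri_obs = raggedness(obs)
    if diffs.max() == 0:
        return MismatchResult(0.0, 0.0, 0.0, obs, obs.copy(), 0.0, hri_obs,
                              1.0, 1.0, 0, ["degenerate: all sequences identical"])
    tau, theta0, theta1, ssd_obs = _fit_expansion(obs)
    expected = expected_mismatch(np.arange(len(obs)), tau, theta0, theta1)

    rng = np.random.default_rng(seed)
    n_ssd = n_hri = 0
    n_eff = 0
    for _ in range(n_bootstrap):
        sim = _simulate_mismatch_sample(n, tau, theta0, theta1, rng)
        sim_obs = _observed_mismatch(sim)
        if len(sim_obs) < 2:
            sim_obs = np.append(sim_obs, 0.0)
        _, _, _, ssd_b = _fit_expansion(sim_obs)
        n_ssd += ssd_b >= ssd_obs
        n_hri += raggedness(sim_obs) >= hri_obs
        n_eff += 1
    p_ssd = (n_ssd + 1.0) / (n_eff + 1.0) if n_eff else np.nan
    p_hri = (n_hri + 1.0) / (n_eff + 1.0) if n_eff else np.nan
    return MismatchResult(tau=float(tau), theta0=float(theta0), theta1=float(theta1),
                          observed=obs, expected=expected, ssd=float(ssd_obs),
                          hri=float(hri_obs), p_ssd=p_ssd, p_hri=p_hri,
                          n_bootstrap=n_eff, flags=[])
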