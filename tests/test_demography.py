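"""Neutrality tests and mismatch analysis."""

import itertools
import math

import numpy as np
import pytest

from phylorefugia.demography import (expected_mismatch, fus_fs,
                                     fus_fs_from_alignment, log_ewens_pmf,
                                     mean_pairwise_differences, mismatch_fit,
                                     raggedness, segregating_sites, tajimas_d)


# -- Tajima's D ------------------------------------------------------------

def oracle_tajima_d(n, S, pi):
    """Independent constant-by-constant transcription of the statistic."""
    a1 = sum(1 / i for i in range(1, n))
    a2 = sum(1 / i ** 2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n ** 2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1 ** 2
    e1 = c1 / a1
    e2 = c2 / (a1 ** 2 + a2)
    return (pi - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1))


def test_tajimas_d_matches_hand_oracle():
    aln = {"a": "AAAAAAAAAA", "b": "AAAAAAAAAT",
           "c": "AAAAAAAAAA", "d": "TAAAAAAAAT"}
    n, S = 4, 2
    pi = mean_pairwise_differences(aln)
    res = tajimas_d(aln, n_sims=50, seed=0)
    assert res.S == S
    assert res.statistic == pytest.approx(oracle_tajima_d(n, S, pi), rel=1e-12)
    assert 0.0 <= res.p_value <= 1.0


def test_tajimas_d_undefined_without_variation():
    aln = {c: "AAAA" for c in "abcd"}
    res = tajimas_d(aln, n_sims=10, seed=0)
    assert not np.isfinite(res.statistic)
    assert res.flags


def test_tajimas_d_requires_four_samples():
    with pytest.raises(ValueError):
        tajimas_d({"a": "AT", "b": "AA", "c": "AT"})


def test_neutral_simulations_center_d_near_zero():
    """Mean D over neutral constant-size replicates is close to 0."""
    rng = np.random.default_rng(0)
    from phylorefugia.demography import (_pi_from_sets,
                                         _simulate_sample_infinite_sites,
                                         _tajima_d_from_summaries)
    vals = []
    n = 15
    for _ in range(1000):
        sets = _simulate_sample_infinite_sites(n, rng, theta=4.0)
        S = len(set().union(*sets)) if any(sets) else 0
        if S == 0:
            continue
        vals.append(_tajima_d_from_summaries(n, S, _pi_from_sets(sets)))
    assert abs(np.mean(vals)) < 0.1


# -- Fu's Fs ---------------------------------------------------------------

def test_ewens_pmf_matches_tabulated_stirling_numbers():
    """n=5: |s(5,k)| = 24, 50, 35, 10, 1; theta=1 -> rising factorial 120."""
    p = np.exp(log_ewens_pmf(5, 1.0))
    assert p == pytest.approx(np.array([24, 50, 35, 10, 1]) / 120.0, rel=1e-12)


def test_fus_fs_exact_logit_example():
    # P(K >= 2) = 96/120 = 0.8 -> Fs = ln(0.8/0.2) = ln 4
    res = fus_fs(5, 2, 1.0, n_sims=0)
    assert res.statistic == pytest.approx(math.log(4.0), rel=1e-12)


def test_fs_zero_at_even_odds():
    """If P(K >= k) = 0.5 the logit vanishes; locate such a case by scan."""
    p = np.exp(log_ewens_pmf(6, 2.0))
    cum = np.cumsum(p[::-1])[::-1]
    # identity check rather than a magic case: logit(cum_k) for all k
    for k in range(1, 7):
        res = fus_fs(6, k, 2.0, n_sims=0)
        expected = math.log(cum[k - 1] / (1 - cum[k - 1])) \
            if 0 < cum[k - 1] < 1 else res.statistic
        assert res.statistic == pytest.approx(expected, rel=1e-9)


def ewens_enumeration(n, theta):
    """Exact Ewens pmf by enumerating set partitions (oracle, n <= 8)."""
    from sympy.functions.combinatorial.numbers import stirling
    probs = []
    rising = 1.0
    for i in range(n):
        rising *= theta + i
    for k in range(1, n + 1):
        s = float(stirling(n, k, kind=1, signed=False))
        probs.append(s * theta ** k / rising)
    return np.array(probs)


@pytest.mark.parametrize("n,theta", [(4, 0.5), (6, 1.7), (8, 3.0)])
def test_stirling_recurrence_equals_exact_enumeration(n, theta):
    ours = np.exp(log_ewens_pmf(n, theta))
    oracle = ewens_enumeration(n, theta)
    assert ours == pytest.approx(oracle, rel=1e-9, abs=1e-12)


def test_fs_negative_under_expansion():
    """Growth leaves too many haplotypes for the observed diversity, so
    Fs is negative for star-like expansion samples."""
    from phylorefugia.demography import (_pi_from_sets,
                                         _simulate_expansion_tip_sets)
    rng = np.random.default_rng(1)
    negative = 0
    trials = 20
    for _ in range(trials):
        sets = _simulate_expansion_tip_sets(25, 5.0, 0.05, 5.0, rng)
        pi = _pi_from_sets(sets)
        if pi == 0:
            continue
        res = fus_fs(25, len(set(sets)), pi, n_sims=0)
        negative += res.statistic < 0
    assert negative / trials >= 0.8


def test_fus_fs_input_validation():
    with pytest.raises(ValueError):
        fus_fs(1, 1, 1.0)
    with pytest.raises(ValueError):
        fus_fs(5, 6, 1.0)
    with pytest.raises(ValueError):
        fus_fs(5, 2, 0.0)


# -- mismatch --------------------------------------------------------------

def test_raggedness_of_smooth_vector():
    assert raggedness([0.4, 0.3, 0.2, 0.1]) == pytest.approx(0.03)


def test_expected_mismatch_sums_to_one():
    support = np.arange(400)
    for tau, t0, t1 in [(0.0, 1.0, 1.0), (3.0, 0.5, 20.0), (10.0, 2.0, 80.0)]:
        f = expected_mismatch(support, tau, t0, t1)
        assert f.sum() == pytest.approx(1.0, abs=1e-3)


def test_expected_mismatch_reduces_to_geometric_at_tau_zero():
    support = np.arange(50)
    f = expected_mismatch(support, 0.0, 2.0, 30.0)
    geo = 2.0 ** support / 3.0 ** (support + 1.0)
    assert f == pytest.approx(geo, rel=1e-9)


def test_identical_sequences_degenerate_fit():
    aln = {c: "AAAA" for c in "abcde"}
    res = mismatch_fit(aln, n_bootstrap=5, seed=0)
    assert res.ssd == 0.0
    assert res.observed[0] == 1.0
    assert res.p_ssd == 1.0
    assert res.flags


def test_mismatch_fit_recovers_expansion_location():
    """On data simulated under sudden expansion the fitted tau should be
    near the mean pairwise difference (which the model centers at tau)."""
    from phylorefugia.demography import _simulate_mismatch_sample, _observed_mismatch, _fit_expansion
    rng = np.random.default_rng(7)
    taus = []
    for _ in range(10):
        diffs = _simulate_mismatch_sample(30, 6.0, 0.2, 100.0, rng)
        tau, t0, t1, ssd = _fit_expansion(_observed_mismatch(diffs))
        taus.append(tau)
    assert 3.0 < np.median(taus) < 10.0


def test_mismatch_requires_three_sequences():
    with pytest.raises(ValueError):
        mismatch_fit({"a": "AT", "b": "AA"})


def alignment_from_tip_sets(tip_sets):
    """Binary infinite-sites alignment: one column per mutation."""
    muts = sorted(set().union(*tip_sets))
    return {f"s{i}": "".join("T" if m in s else "A" for m in muts)
            for i, s in enumerate(tip_sets)}


def test_ssd_test_does_not_reject_true_expansion():
    """Data simulated under sudden expansion should rarely be rejected by
    the SSD parametric bootstrap."""
    from phylorefugia.demography import _simulate_expansion_tip_sets
    rng = np.random.default_rng(9)
    rejections = 0
    trials = 15
    for _ in range(trials):
        sets = _simulate_expansion_tip_sets(20, 4.0, 0.3, 40.0, rng)
        aln = alignment_from_tip_sets(sets)
        if segregating_sites(aln) == 0:
            continue
        res = mismatch_fit(aln, n_bootstrap=60, seed=int(rng.integers(2 ** 31)))
        if res.p_ssd <= 0.05:
            rejections += 1
    assert rejections <= 0.2 * trials
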