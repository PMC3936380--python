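"""Deterministic demographic unit conversions.

Pure arithmetic used to move between the mutation-scaled parameters of an
isolation-with-migration (IM) analysis and demographic units (years,
effective sizes, migrants per generation), plus the life-history
generation-time formula and the derivation of a lineage-specific
substitution rate from between-clade divergence.

All functions are exact; rounding (e.g. to one or two decimals of MYA)
belongs to the reporting layer.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

__all__ = [
    "generation_time",
    "RateEstimate",
    "substitution_rate_from_divergence",
    "scale_ima_time",
    "ImaScaled",
    "scale_ima_popsize_and_migration",
    "scale_ima_table",
    "MU_GRID",
    "GENERATION_TIMES",
]

# default scenario grid: chloroplast-wide angiosperm rates bracketing a
# lineage-specific estimate, and low/high generation times for a
# long-lived tree (25 y to maturity, adult survival 0.9 or 0.99)
MU_GRID: tuple[float, ...] = (1.0e-9, 1.59e-9, 3.0e-9)   # subs/site/year
GENERATION_TIMES: tuple[float, ...] = (34.0, 124.0)      # years


def generation_time(age_at_maturity_years: float, adult_survival: float) -> float:
    """T = a + s/(1-s): mean age of reproduction for iteroparous adults.

    ``a`` is age at first reproduction (years); ``s`` the annual adult
    survival probability.  s -> 1 diverges (immortal adults).
    """
    if age_at_maturity_years <= 0:
        raise ValueError("age at maturity must be positive")
    if not 0.0 <= adult_survival < 1.0:
        raise ValueError("adult survival must lie in [0, 1)")
    return age_at_maturity_years + adult_survival / (1.0 - adult_survival)


@dataclass(frozen=True)
class RateEstimate:
    """Substitution rate derived from between-clade divergence.

    ``dxy`` is the between-clade divergence per site, halved into a
    per-lineage divergence, then divided by twice the crown divergence
    time in Myr."""

    dxy: float
    t_div_ma: float
    per_lineage_divergence: float
    rate_per_myr: float
    rate_per_year: float


def substitution_rate_from_divergence(dxy: float, t_div_ma: float) -> RateEstimate:
    """Per-lineage substitution rate from divergence dxy and time in Ma."""
    if dxy < 0:
        raise ValueError("divergence must be non-negative")
    if t_div_ma <= 0:
        raise ValueError("divergence time must be positive")
    per_lineage = dxy / 2.0
    rate_per_myr = per_lineage / (2.0 * t_div_ma)
    return RateEstimate(dxy=dxy, t_div_ma=t_div_ma,
                        per_lineage_divergence=per_lineage,
                        rate_per_myr=rate_per_myr,
                        rate_per_year=rate_per_myr / 1.0e6)


def scale_ima_time(t_raw: float, mu_site_year: float, locus_length: int) -> float:
    """Convert a mutation-scaled IM divergence time to years.

    years = t / (mu * L): the raw parameter is divided by the per-locus
    mutation rate per year.
    """
    if t_raw < 0:
        raise ValueError("t must be non-negative")
    if mu_site_year <= 0 or locus_length <= 0:
        raise ValueError("mutation rate and locus length must be positive")
    return t_raw / (mu_site_year * locus_length)


@dataclass(frozen=True)
class ImaScaled:
    """IM parameters converted to demographic units for one rate choice."""

    mu_site_year: float
    locus_length_bp: int
    generation_time_years: float
    inheritance_scalar: float
    ne_1: float
    ne_2: float
    ne_ancestral: float
    nm_1: float
    nm_2: float
    divergence_years: float


def scale_ima_popsize_and_migration(
        q1: float, q2: float, qA: float, m1: float, m2: float, t: float,
        mu_site_year: float, locus_length_bp: int, generation_time_years: float,
        inheritance_scalar: float = 2.0) -> ImaScaled:
    """Scale mutation-scaled IM output to Ne, Nm, and divergence years.

    Ne = q / (c * mu * L * g) with c the inheritance scalar (default 2,
    matching q = 2*N*u for a haploid uniparentally inherited locus and a
    per-generation locus rate u = mu * L * g); Nm = q * m / c is the
    population migration rate in genes per generation.
    """
    if min(mu_site_year, locus_length_bp, generation_time_years,
           inheritance_scalar) <= 0:
        raise ValueError("rate, length, generation time and scalar must be positive")
    u_locus_gen = mu_site_year * locus_length_bp * generation_time_years
    ne = lambda q: q / (inheritance_scalar * u_locus_gen)
    return ImaScaled(
        mu_site_year=mu_site_year, locus_length_bp=locus_length_bp,
        generation_time_years=generation_time_years,
        inheritance_scalar=inheritance_scalar,
        ne_1=ne(q1), ne_2=ne(q2), ne_ancestral=ne(qA),
        nm_1=q1 * m1 / inheritance_scalar, nm_2=q2 * m2 / inheritance_scalar,
        divergence_years=scale_ima_time(t, mu_site_year, locus_length_bp),
    )


def scale_ima_table(table: pd.DataFrame, mu_site_year: float, locus_length_bp: int,
                    generation_time_years: float,
                    inheritance_scalar: float = 2.0) -> pd.DataFrame:
    """Append demographic units to a table of raw IM estimates.

    ``table`` needs columns q1, q2, qA, m1, m2, t (one row per split).
    """
    rows = []
    for _, r in table.iterrows():
        s = scale_ima_popsize_and_migration(
            r["q1"], r["q2"], r["qA"], r["m1"], r["m2"], r["t"],
            mu_site_year, locus_length_bp, generation_time_years,
            inheritance_scalar)
        rows.append({"ne_1": s.ne_1, "ne_2": s.ne_2, "ne_ancestral": s.ne_ancestral,
                     "nm_1": s.nm_1, "nm_2": s.nm_2,
                     "divergence_years": s.divergence_years,
                     "divergence_mya": s.divergence_years / 1e6})
    return pd.concat([table.reset_index(drop=True), pd.DataFrame(rows)], axis=1)
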