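"""Per-agent biology and social learning.

Mortality hazard, resource production, the childrearing cost schedule,
genetic inheritance of quality, and the unbiased cultural-transmission rule
by which the cooperative trait is acquired at adulthood.  All curve functions
accept scalars or NumPy arrays and broadcast.
"""
from __future__ import annotations

import numpy as np

from .params import CostScheduleParams, HazardCurveParams, ProductionCurveParams

__all__ = [
    "baseline_hazard",
    "mortality_probability",
    "resource_production",
    "child_cost",
    "inherit_quality",
    "assign_cooperativity",
    "survival_to_adulthood",
]


def baseline_hazard(age, params: HazardCurveParams):
    """Quality-independent part of the yearly death probability.

    High in infancy, decaying geometrically to the adult baseline by
    ``child_floor_age``; flat through adulthood; rising geometrically from
    ``senescence_onset`` to 1 at ``terminal_age``.
    """
    age = np.asarray(age, dtype=float)
    p0 = params.infant_mortality
    pa = params.adult_baseline
    a1 = params.child_floor_age
    a2 = params.senescence_onset
    a3 = params.terminal_age
    m = np.where(
        age < a1,
        p0 * (pa / p0) ** (age / a1),
        np.where(
            age <= a2,
            pa,
            pa * (1.0 / pa) ** ((np.minimum(age, a3) - a2) / (a3 - a2)),
        ),
    )
    m = np.where(age >= a3, 1.0, m)
    return m


def mortality_probability(age, q, params: HazardCurveParams):
    """Yearly probability of death as a function of age and genetic quality.

    The baseline hazard is scaled by ``1 + quality_load * (1 - q)``, so
    low-quality agents die more at every age, and capped at 1.  Death at
    ``terminal_age`` is certain regardless of quality.
    """
    m = baseline_hazard(age, params)
    p = m * (1.0 + params.quality_load * (1.0 - np.asarray(q, dtype=float)))
    p = np.minimum(p, 1.0)
    p = np.where(np.asarray(age, dtype=float) >= params.terminal_age, 1.0, p)
    if p.ndim == 0:
        return float(p)
    return p


def resource_production(age, q, params: ProductionCurveParams):
    """Resources an agent collects in one year.

    Zero before adulthood; otherwise
    ``(quality_floor + (1 - quality_floor) * q) * peak_output * tent(age)``
    where the tent rises from ``onset_level`` at the onset age to 1 at the
    peak age (elderhood) and declines to ``terminal_level`` at the terminal
    age.  With the default ``quality_floor = 0`` output is proportional to q.
    """
    age = np.asarray(age, dtype=float)
    a0, a1, a2 = params.onset_age, params.peak_age, params.terminal_age
    lo, hi = params.onset_level, params.terminal_level
    tent = np.where(
        age < a0,
        0.0,
        np.where(
            age <= a1,
            lo + (1.0 - lo) * (age - a0) / (a1 - a0),
            np.maximum(1.0 + (hi - 1.0) * (age - a1) / (a2 - a1), hi),
        ),
    )
    qf = params.quality_floor
    qeff = qf + (1.0 - qf) * np.asarray(q, dtype=float)
    r = qeff * params.peak_output * tent
    if r.ndim == 0:
        return float(r)
    return r


def child_cost(age, beta_effective: float, params: CostScheduleParams):
    """Cost of supporting a child of a given age this year.

    Equals ``beta_effective`` (the effective cost of childrearing, which is
    also the cost of giving birth) at age 0 and decreases with age; zero is
    reached only at maturity.  Ages at or past ``maturity_age`` are a contract
    violation: adults are never a cost.
    """
    age_arr = np.asarray(age, dtype=float)
    if np.any(age_arr < 0) or np.any(age_arr >= params.maturity_age):
        raise ValueError(f"child_cost requires 0 <= age < {params.maturity_age}")
    if beta_effective < 0:
        raise ValueError("beta_effective must be >= 0")
    if params.shape == "linear":
        c = beta_effective * (1.0 - age_arr / params.maturity_age)
    else:
        c = beta_effective * np.exp(-age_arr / params.decay_time)
    if c.ndim == 0:
        return float(c)
    return c


def inherit_quality(q_mother, q_father, mutation_sd: float, gamma: float, rng, size=None):
    """Genetic quality of a newborn: mid-parent value plus Gaussian error.

    The result is clamped to [0, gamma]; the ceiling gamma models limited
    genetic adaptability to a novel environment.
    """
    mid = (np.asarray(q_mother, dtype=float) + np.asarray(q_father, dtype=float)) / 2.0
    if size is None:
        size = mid.shape if mid.ndim else None
    err = rng.normal(0.0, mutation_sd, size=size)
    out = np.clip(mid + err, 0.0, gamma)
    if np.ndim(out) == 0:
        return float(out)
    return out


def assign_cooperativity(natal_coop, fallback: float, rng) -> bool:
    """Unbiased social learning of the cooperative trait at age 18.

    ``natal_coop`` holds the trait values (booleans) of the trait-bearing
    adults of the agent's natal family group; the agent becomes a cooperator
    with probability equal to the cooperator frequency among them, which is
    equivalent to copying one group adult at random.  If the natal group has
    no trait-bearing members the ``fallback`` probability (conventionally the
    population-wide cooperator frequency) is used instead.
    """
    natal_coop = np.asarray(natal_coop, dtype=bool)
    freq = float(natal_coop.mean()) if natal_coop.size else float(fallback)
    return bool(rng.random() < freq)


def survival_to_adulthood(q, params: HazardCurveParams, adulthood_age: int = 18):
    """Probability of surviving every childhood year (ages 0..17) at quality q."""
    ages = np.arange(adulthood_age)
    p = mortality_probability(ages, np.asarray(q, dtype=float)[..., None], params)
    out = np.prod(1.0 - p, axis=-1)
    if np.ndim(out) == 0:
        return float(out)
    return out
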