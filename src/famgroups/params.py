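"""Model parameters.

Every free parameter of the family-group model lives here, grouped into the
three life-history curve structs (mortality hazard, resource production,
childrearing cost) plus the top-level :class:`ModelParams`.  All structs are
plain dataclasses that validate on construction and round-trip through
``to_dict``/``from_dict`` for the scenario-config file.

Units: resources are in abstract "resource units per year" (an adult at peak
age and maximal genetic quality produces ``peak_output`` units per year);
ages are integer years; probabilities are per-year.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any

__all__ = [
    "HazardCurveParams",
    "ProductionCurveParams",
    "CostScheduleParams",
    "ModelParams",
    "ConfigError",
]


class ConfigError(ValueError):
    """Raised when a parameter value or config key is invalid."""


@dataclass
class HazardCurveParams:
    """Yearly mortality hazard: U-shaped in age, decreasing in genetic quality.

    The baseline hazard m(age) is piecewise geometric: it starts at
    ``infant_mortality`` at age 0, decays geometrically to ``adult_baseline``
    by ``child_floor_age``, stays flat through adulthood, then rises
    geometrically from ``senescence_onset`` to reach 1 at ``terminal_age``.
    Genetic quality q scales the hazard by (1 + quality_load * (1 - q)),
    capped at 1.  Death at ``terminal_age`` is certain for every q.
    """

    infant_mortality: float = 0.15
    child_floor_age: int = 5
    adult_baseline: float = 0.01
    senescence_onset: int = 50
    terminal_age: int = 100
    quality_load: float = 1.0

    def validate(self) -> None:
        if not (0.0 < self.infant_mortality <= 1.0):
            raise ConfigError("hazard.infant_mortality must be in (0, 1]")
        if not (0.0 < self.adult_baseline <= 1.0):
            raise ConfigError("hazard.adult_baseline must be in (0, 1]")
        if self.quality_load < 0.0:
            raise ConfigError("hazard.quality_load must be >= 0")
        if not (0 < self.child_floor_age < self.senescence_onset < self.terminal_age):
            raise ConfigError(
                "hazard ages must satisfy 0 < child_floor_age < senescence_onset < terminal_age"
            )


@dataclass
class ProductionCurveParams:
    """Yearly resource production: a tent profile in age, increasing in quality.

    Production is zero before ``onset_age`` (children), rises linearly from
    ``onset_level * peak_output`` at onset to ``peak_output`` at ``peak_age``
    (the age of elderhood), then declines linearly to
    ``terminal_level * peak_output`` at ``terminal_age``.  The whole profile
    scales with genetic quality as ``quality_floor + (1 - quality_floor) * q``
    and is jointly capped, per family group, by the territory's finite yearly
    yield ``patch_yield``.
    """

    peak_output: float = 100.0
    onset_age: int = 18
    peak_age: int = 50
    terminal_age: int = 100
    onset_level: float = 0.5
    terminal_level: float = 0.2
    quality_floor: float = 0.5
    """Fraction of the age profile produced even at q = 0; output scales as
    quality_floor + (1 - quality_floor) * q, strictly increasing in q."""
    patch_yield: float = 2600.0
    """Maximum total resources one patch yields per year.  A group whose
    summed potential production exceeds this extracts it pro rata, so
    per-capita resources fall as a group grows — the territory, not the
    headcount cap, is what limits a well-fed group's size.  ``inf`` disables
    the limit."""

    def validate(self) -> None:
        if self.peak_output <= 0:
            raise ConfigError("production.peak_output must be > 0")
        if not (0.0 <= self.quality_floor < 1.0):
            raise ConfigError("production.quality_floor must be in [0, 1)")
        if self.patch_yield <= 0:
            raise ConfigError("production.patch_yield must be > 0")
        if not (0 < self.onset_age < self.peak_age < self.terminal_age):
            raise ConfigError(
                "production ages must satisfy 0 < onset_age < peak_age < terminal_age"
            )
        if not (0.0 <= self.terminal_level <= 1.0 and 0.0 <= self.onset_level <= 1.0):
            raise ConfigError("production onset/terminal levels must be in [0, 1]")


@dataclass
class CostScheduleParams:
    """Yearly cost of supporting a child of a given age.

    The cost equals the effective childrearing cost beta' at age 0 (birth) and
    decreases with age, reaching 0 at ``maturity_age`` when the child becomes
    an adult.  Two shapes are provided:

    - ``"exponential"`` (default): c(a) = beta' * exp(-a / decay_time).
      Front-loaded, reflecting that infants need full-time care and
      provisioning while older children increasingly fend for themselves.
    - ``"linear"``: c(a) = beta' * (1 - a / maturity_age).
    """

    maturity_age: int = 18
    shape: str = "exponential"
    decay_time: float = 1.5

    def validate(self) -> None:
        if self.shape not in ("exponential", "linear"):
            raise ConfigError("cost.shape must be 'exponential' or 'linear'")
        if self.maturity_age <= 0:
            raise ConfigError("cost.maturity_age must be > 0")
        if self.decay_time <= 0:
            raise ConfigError("cost.decay_time must be > 0")


@dataclass
class ModelParams:
    """All free parameters of the family-group model.

    Parameters
    ----------
    beta
        Base cost of childrearing (resource units); equals the cost of giving
        birth.  The primary knob of environmental harshness.
    gamma
        Maximum attainable genetic quality, in (0, 1].  Lowering gamma below 1
        models a population genetically maladapted to a novel environment.
    sigma_nu
        Standard deviation of the yearly noise added to beta (resource
        units).  Each year beta' = max(0, beta + Normal(0, sigma_nu)) applies
        world-wide.
    K
        Patch carrying capacity (maximum family-group size).
    n_initial_groups, n_patches
        Number of family groups at initialization and number of patches.  By
        default n_patches == n_initial_groups, so free territory only appears
        when a group dies out.
    group_size_init
        Agents per group at initialization; must be divisible by 8 (equal
        counts in each sex x {child, unwed adult, parent, elder} cell).
    initial_coop_freq
        Probability that each initial adult is a cooperator.
    initial_q_mean, initial_q_sd
        Mean and SD of the clamped-normal initial genetic quality.  A mean of
        ``None`` resolves to gamma / 2.
    high_fitness_init
        If True, initial quality is drawn from a left-skewed distribution with
        mode at gamma and mean 0.86 * gamma instead of the clamped normal.
    q_mutation_sd
        SD of the Gaussian transmission error added to the mid-parent quality
        at birth.
    coop_fraction, defect_fraction
        Fraction of yearly production donated to the group's mothers by
        cooperators and defectors.
    dispersal_sex
        Which sex leaves its natal group at marriage ("female" default).
    mate_choosiness
        Exponent scale s0 of the mate-acceptance rule
        P(i accepts j) = q_j ** (s0 * max(0, (49 - age_i) / 31)); choosiness
        relaxes linearly with age so older agents accept lower-quality mates.
    """

    beta: float = 50.0
    gamma: float = 1.0
    sigma_nu: float = 0.0
    K: int = 300
    n_initial_groups: int = 50
    n_patches: int | None = None
    group_size_init: int = 40
    adulthood_age: int = 18
    elder_age: int = 50
    max_age: int = 100
    coop_fraction: float = 0.9
    defect_fraction: float = 0.1
    p_female_birth: float = 0.5
    initial_coop_freq: float = 0.5
    initial_q_mean: float | None = None
    initial_q_sd: float = 0.24
    high_fitness_init: bool = False
    q_mutation_sd: float = 0.05
    dispersal_sex: str = "female"
    mate_choosiness: float = 3.0
    hazard: HazardCurveParams = field(default_factory=HazardCurveParams)
    production: ProductionCurveParams = field(default_factory=ProductionCurveParams)
    cost: CostScheduleParams = field(default_factory=CostScheduleParams)

    def __post_init__(self) -> None:
        if self.n_patches is None:
            self.n_patches = self.n_initial_groups
        if isinstance(self.hazard, dict):
            self.hazard = _from_mapping(HazardCurveParams, self.hazard, "hazard")
        if isinstance(self.production, dict):
            self.production = _from_mapping(ProductionCurveParams, self.production, "production")
        if isinstance(self.cost, dict):
            self.cost = _from_mapping(CostScheduleParams, self.cost, "cost")
        self.validate()

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        if not (0.0 < self.gamma <= 1.0):
            raise ConfigError("gamma must be in (0, 1]")
        if self.beta < 0:
            raise ConfigError("beta must be >= 0")
        if self.sigma_nu < 0:
            raise ConfigError("sigma_nu must be >= 0")
        if self.K <= 0:
            raise ConfigError("K must be > 0")
        if self.n_initial_groups <= 0:
            raise ConfigError("n_initial_groups must be > 0")
        assert self.n_patches is not None
        if self.n_initial_groups > self.n_patches:
            raise ConfigError("n_initial_groups must be <= n_patches")
        if self.group_size_init % 8 != 0 or self.group_size_init <= 0:
            raise ConfigError(
                "group_size_init must be a positive multiple of 8 "
                "(equal counts per sex x age-class cell)"
            )
        for name in ("coop_fraction", "defect_fraction", "p_female_birth", "initial_coop_freq"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name} must be in [0, 1]")
        if not (0 < self.adulthood_age < self.elder_age < self.max_age):
            raise ConfigError("ages must satisfy 0 < adulthood_age < elder_age < max_age")
        if self.initial_q_mean is not None and not (0.0 <= self.initial_q_mean <= self.gamma):
            raise ConfigError("initial_q_mean must be in [0, gamma]")
        if self.initial_q_sd < 0:
            raise ConfigError("initial_q_sd must be >= 0")
        if self.q_mutation_sd < 0:
            raise ConfigError("q_mutation_sd must be >= 0")
        if self.dispersal_sex not in ("female", "male"):
            raise ConfigError("dispersal_sex must be 'female' or 'male'")
        if self.mate_choosiness < 0:
            raise ConfigError("mate_choosiness must be >= 0")
        self.hazard.validate()
        self.production.validate()
        self.cost.validate()

    # -- resolved values -------------------------------------------------
    @property
    def resolved_q_mean(self) -> float:
        """Initial mean quality; defaults to gamma / 2 as in the gamma sweeps."""
        return self.gamma / 2.0 if self.initial_q_mean is None else self.initial_q_mean

    # -- (de)serialization -----------------------------------------------
    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "ModelParams":
        return _from_mapping(cls, data, "model")

    def replace(self, **changes: Any) -> "ModelParams":
        return dataclasses.replace(self, **changes)


def _from_mapping(cls: type, data: dict[str, Any], path: str):
    """Build a dataclass from a mapping, rejecting unknown keys by path."""
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: expected a mapping")
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ConfigError(f"{path}: unknown key(s) {sorted(unknown)}")
    return cls(**data)
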