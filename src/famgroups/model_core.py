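"""Population container, random-number contract, and initialization.

The population is stored struct-of-arrays: one NumPy array per agent field,
indexed by position.  Positions are transient (the arrays are compacted after
every completed year); stable identifiers live in ``World.ids``.  Family
groups coincide with patches: group *g* is the set of living agents whose
``group`` field equals patch index *g*, a patch is free iff no living agent
occupies it, so ``n_active_groups + n_free_patches == n_patches`` holds by
construction.

Sex is encoded 0 = female, 1 = male.  The cooperativity trait is encoded
-1 = unset (children), 0 = defector, 1 = cooperator.  ``spouse`` and
``mother`` hold positional indices, -1 meaning none.

Random-number contract: every draw in a run flows through ``World.rng``
(a ``numpy.random.Generator``); identical seed plus identical parameters
gives a bit-identical run.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np
import pandas as pd

from .params import ConfigError, ModelParams

__all__ = [
    "World",
    "AgentView",
    "GroupView",
    "FEMALE",
    "MALE",
    "COOP_UNSET",
    "sample_initial_quality",
    "sample_high_fitness_quality",
    "init_population",
    "count_metrics",
]

FEMALE = 0
MALE = 1
COOP_UNSET = -1

# mean of a half-normal is sd * sqrt(2/pi); choosing sd = 0.14 * sqrt(pi/2)
# makes gamma - |N(0, sd)| have mode gamma and mean 0.86 * gamma
_HIGH_FITNESS_SD = 0.14 * np.sqrt(np.pi / 2.0)


@dataclass(frozen=True)
class AgentView:
    """Read-only snapshot of one agent (for inspection and tests)."""

    id: int
    sex: int
    age: int
    q: float
    cooperator: int  # -1 unset, 0 defector, 1 cooperator
    spouse_id: int  # -1 none
    mother_id: int  # -1 none
    group: int
    alive: bool


@dataclass(frozen=True)
class GroupView:
    """Read-only snapshot of one family group (the set of living members)."""

    id: int
    member_indices: np.ndarray

    @property
    def size(self) -> int:
        return int(self.member_indices.size)


class World:
    """All agents, patches, and the per-year environmental state."""

    __slots__ = (
        "params",
        "rng",
        "year",
        "beta_effective",
        "alive",
        "sex",
        "age",
        "q",
        "coop",
        "spouse",
        "mother",
        "group",
        "ids",
        "_next_id",
        "total_births",
        "female_births",
        "event_log",
    )

    def __init__(self, params: ModelParams, rng: np.random.Generator):
        self.params = params
        self.rng = rng
        self.year = 0
        self.beta_effective = params.beta
        self.alive = np.zeros(0, dtype=bool)
        self.sex = np.zeros(0, dtype=np.int8)
        self.age = np.zeros(0, dtype=np.int32)
        self.q = np.zeros(0, dtype=np.float64)
        self.coop = np.zeros(0, dtype=np.int8)
        self.spouse = np.zeros(0, dtype=np.int64)
        self.mother = np.zeros(0, dtype=np.int64)
        self.group = np.zeros(0, dtype=np.int64)
        self.ids = np.zeros(0, dtype=np.int64)
        self._next_id = 0
        self.total_births = 0
        self.female_births = 0
        self.event_log: list[tuple] | None = None

    # ------------------------------------------------------------------
    @property
    def size(self) -> int:
        """Length of the agent arrays (including dead rows before compaction)."""
        return self.alive.size

    @property
    def n_alive(self) -> int:
        return int(self.alive.sum())

    def group_sizes(self) -> np.ndarray:
        """Living members per patch, length n_patches."""
        return np.bincount(
            self.group[self.alive], minlength=self.params.n_patches
        )

    @property
    def n_groups(self) -> int:
        return int((self.group_sizes() > 0).sum())

    def free_patches(self) -> np.ndarray:
        return np.flatnonzero(self.group_sizes() == 0)

    def groups(self) -> Iterator[GroupView]:
        sizes = self.group_sizes()
        for g in np.flatnonzero(sizes > 0):
            yield GroupView(int(g), np.flatnonzero(self.alive & (self.group == g)))

    def agent(self, i: int) -> AgentView:
        sp, mo = int(self.spouse[i]), int(self.mother[i])
        return AgentView(
            id=int(self.ids[i]),
            sex=int(self.sex[i]),
            age=int(self.age[i]),
            q=float(self.q[i]),
            cooperator=int(self.coop[i]),
            spouse_id=int(self.ids[sp]) if sp >= 0 else -1,
            mother_id=int(self.ids[mo]) if mo >= 0 else -1,
            group=int(self.group[i]),
            alive=bool(self.alive[i]),
        )

    # ------------------------------------------------------------------
    def add_agents(
        self,
        *,
        sex: np.ndarray,
        age: np.ndarray,
        q: np.ndarray,
        coop: np.ndarray,
        spouse: np.ndarray,
        mother: np.ndarray,
        group: np.ndarray,
    ) -> np.ndarray:
        """Append agents; link fields refer to current positions.  Returns new positions."""
        n = len(sex)
        start = self.size
        self.alive = np.concatenate([self.alive, np.ones(n, dtype=bool)])
        self.sex = np.concatenate([self.sex, np.asarray(sex, dtype=np.int8)])
        self.age = np.concatenate([self.age, np.asarray(age, dtype=np.int32)])
        self.q = np.concatenate([self.q, np.asarray(q, dtype=np.float64)])
        self.coop = np.concatenate([self.coop, np.asarray(coop, dtype=np.int8)])
        self.spouse = np.concatenate([self.spouse, np.asarray(spouse, dtype=np.int64)])
        self.mother = np.concatenate([self.mother, np.asarray(mother, dtype=np.int64)])
        self.group = np.concatenate([self.group, np.asarray(group, dtype=np.int64)])
        self.ids = np.concatenate(
            [self.ids, np.arange(self._next_id, self._next_id + n, dtype=np.int64)]
        )
        self._next_id += n
        return np.arange(start, start + n)

    def compact(self) -> None:
        """Drop dead rows and remap spouse/mother indices."""
        keep = np.flatnonzero(self.alive)
        remap = np.full(self.size + 1, -1, dtype=np.int64)  # slot for index -1
        remap[keep] = np.arange(keep.size)
        for name in ("alive", "sex", "age", "q", "coop", "ids", "group"):
            setattr(self, name, getattr(self, name)[keep])
        self.spouse = remap[self.spouse[keep]]
        self.mother = remap[self.mother[keep]]

    # ------------------------------------------------------------------
    def to_dataframe(self) -> pd.DataFrame:
        """Snapshot of living agents, one row per agent, sorted by id."""
        keep = np.flatnonzero(self.alive)
        id_of = np.full(self.size + 1, -1, dtype=np.int64)
        id_of[: self.size] = self.ids
        df = pd.DataFrame(
            {
                "id": self.ids[keep],
                "group": self.group[keep],
                "sex": np.where(self.sex[keep] == FEMALE, "F", "M"),
                "age": self.age[keep],
                "q": self.q[keep],
                "cooperator": self.coop[keep],
                "spouse_id": id_of[self.spouse[keep]],
                "mother_id": id_of[self.mother[keep]],
            }
        )
        return df.sort_values("id", ignore_index=True)

    def to_csv(self, path=None):
        """Line-oriented CSV snapshot (see :meth:`to_dataframe` for columns)."""
        return self.to_dataframe().to_csv(path, index=False)


# ----------------------------------------------------------------------
def sample_initial_quality(mean: float, sd: float, gamma: float, rng, size=None):
    """Initial genetic quality: Normal(mean, sd) clamped to [0, gamma]."""
    if not (0.0 < gamma <= 1.0):
        raise ConfigError("gamma must be in (0, 1]")
    if sd < 0:
        raise ConfigError("sd must be >= 0")
    if not (0.0 <= mean <= gamma):
        raise ConfigError("initial quality mean must lie in [0, gamma]")
    draw = rng.normal(mean, sd, size=size)
    out = np.clip(draw, 0.0, gamma)
    if np.ndim(out) == 0:
        return float(out)
    return out


def sample_high_fitness_quality(gamma: float, rng, size=None):
    """Left-skewed initial quality with mode gamma and mean 0.86 * gamma.

    Draws ``gamma - |Normal(0, s)|`` with s chosen so the half-normal shift
    has mean 0.14 * gamma, emulating a population already well adapted to its
    environment (modal quality at the ceiling).
    """
    if not (0.0 < gamma <= 1.0):
        raise ConfigError("gamma must be in (0, 1]")
    out = np.clip(gamma - np.abs(rng.normal(0.0, _HIGH_FITNESS_SD * gamma, size=size)), 0.0, gamma)
    if np.ndim(out) == 0:
        return float(out)
    return out


def _draw_initial_q(params: ModelParams, rng, size: int) -> np.ndarray:
    if params.high_fitness_init:
        return sample_high_fitness_quality(params.gamma, rng, size)
    return sample_initial_quality(
        params.resolved_q_mean, params.initial_q_sd, params.gamma, rng, size
    )


def init_population(params: ModelParams, rng: np.random.Generator | int) -> World:
    """Build the initial world.

    Each of the ``n_initial_groups`` groups receives an equal number of
    individuals of each sex and of each of the four age categories (children,
    unwed adults, parents, elders), ages drawn uniformly within each
    category's limits.  Parents are pre-paired into married couples; each
    child is attached to a random parent female of its group.  Every adult is
    independently a cooperator with probability ``initial_coop_freq``.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    if params.group_size_init > params.K:
        raise ConfigError("initial group size must not exceed the carrying capacity K")
    world = World(params, rng)
    per_cell = params.group_size_init // 8  # sex x {child, unwed, parent, elder}
    a_ad, a_el, a_mx = params.adulthood_age, params.elder_age, params.max_age

    for g in range(params.n_initial_groups):
        ages, sexes, classes = [], [], []
        for sex in (FEMALE, MALE):
            for cls, (lo, hi) in enumerate(
                [(0, a_ad), (a_ad, a_el), (a_ad, a_el), (a_el, a_mx)]
            ):
                ages.append(rng.integers(lo, hi, size=per_cell))
                sexes.append(np.full(per_cell, sex, dtype=np.int8))
                classes.append(np.full(per_cell, cls, dtype=np.int8))
        ages = np.concatenate(ages)
        sexes = np.concatenate(sexes)
        classes = np.concatenate(classes)
        n = ages.size

        q = _draw_initial_q(params, rng, n)
        coop = np.full(n, COOP_UNSET, dtype=np.int8)
        adult = classes > 0
        coop[adult] = (rng.random(adult.sum()) < params.initial_coop_freq).astype(np.int8)

        spouse = np.full(n, -1, dtype=np.int64)
        mother = np.full(n, -1, dtype=np.int64)
        pos = world.add_agents(
            sex=sexes, age=ages, q=q, coop=coop,
            spouse=spouse, mother=mother,
            group=np.full(n, g, dtype=np.int64),
        )
        # marry the parents: random female<->male pairing within the group
        pf = pos[(classes == 2) & (sexes == FEMALE)]
        pm = pos[(classes == 2) & (sexes == MALE)]
        pf, pm = rng.permutation(pf), rng.permutation(pm)
        npairs = min(pf.size, pm.size)
        world.spouse[pf[:npairs]] = pm[:npairs]
        world.spouse[pm[:npairs]] = pf[:npairs]
        # attach children to random parent females
        kids = pos[classes == 0]
        if kids.size:
            if npairs == 0:
                raise ConfigError("initial groups need at least one parent couple")
            world.mother[kids] = rng.choice(pf[:npairs], size=kids.size)
    return world


def count_metrics(world: World) -> tuple[int, float, float, int]:
    """(population size, cooperator frequency, mean genetic quality, group count).

    Cooperator frequency is computed over trait-bearing agents only (those
    with an assigned trait); frequency and mean quality are NaN when the
    population (or trait-bearing set) is empty.
    """
    alive = world.alive
    pop = int(alive.sum())
    if pop == 0:
        return 0, float("nan"), float("nan"), 0
    has_trait = alive & (world.coop != COOP_UNSET)
    n_trait = int(has_trait.sum())
    coop_freq = float((world.coop[has_trait] == 1).mean()) if n_trait else float("nan")
    mean_q = float(world.q[alive].mean())
    return pop, coop_freq, mean_q, world.n_groups
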