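"""Shared fixtures: small parameter sets, a hand-built world helper, and
invariant checks used across the suite."""
from __future__ import annotations

import numpy as np
import pytest

from famgroups.model_core import COOP_UNSET, FEMALE, MALE, World
from famgroups.params import ModelParams


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def tiny_params(**over) -> ModelParams:
    """A small, fast population for structural tests."""
    base = dict(n_initial_groups=4, K=60, group_size_init=16, beta=20.0)
    base.update(over)
    return ModelParams(**base)


@pytest.fixture
def small_params():
    return tiny_params()


def build_world(params: ModelParams, agents: list[dict], seed: int = 0) -> World:
    """Construct a world from explicit agent rows.

    Each row: dict with keys sex, age, q, group and optional coop (-1/0/1),
    spouse (row index), mother (row index).
    """
    world = World(params, np.random.default_rng(seed))
    n = len(agents)
    world.add_agents(
        sex=np.array([a["sex"] for a in agents], dtype=np.int8),
        age=np.array([a["age"] for a in agents], dtype=np.int32),
        q=np.array([a.get("q", 0.5) for a in agents], dtype=float),
        coop=np.array(
            [a.get("coop", 1 if a["age"] >= params.adulthood_age else COOP_UNSET) for a in agents],
            dtype=np.int8,
        ),
        spouse=np.array([a.get("spouse", -1) for a in agents], dtype=np.int64),
        mother=np.array([a.get("mother", -1) for a in agents], dtype=np.int64),
        group=np.array([a["group"] for a in agents], dtype=np.int64),
    )
    return world


def couple(age_f, age_m, q, group, base_idx):
    """Two rows forming a married couple; returns (rows, female_idx)."""
    rows = [
        dict(sex=FEMALE, age=age_f, q=q, group=group, spouse=base_idx + 1),
        dict(sex=MALE, age=age_m, q=q, group=group, spouse=base_idx),
    ]
    return rows, base_idx


def check_invariants(world: World) -> None:
    """Structural invariants that must hold after every completed year."""
    p = world.params
    alive = world.alive
    # carrying capacity and patch bookkeeping
    sizes = world.group_sizes()
    assert sizes.max(initial=0) <= p.K
    assert (sizes > 0).sum() + (sizes == 0).sum() == p.n_patches
    # ages and quality
    assert not np.any(world.age[alive] > p.max_age)
    assert np.all((world.q[alive] >= 0) & (world.q[alive] <= p.gamma))
    # trait set exactly for adults
    adult = alive & (world.age >= p.adulthood_age)
    assert np.all(world.coop[adult] != COOP_UNSET)
    assert np.all(world.coop[alive & ~adult] == COOP_UNSET)
    # spouse links: symmetric, opposite sex, same group, both alive
    sp = world.spouse
    married = np.flatnonzero(alive & (sp >= 0))
    if married.size:
        assert np.all(alive[sp[married]])
        assert np.all(sp[sp[married]] == married)
        assert np.all(world.sex[married] != world.sex[sp[married]])
        assert np.all(world.group[married] == world.group[sp[married]])
    # living children: living mother in the same group
    kids = np.flatnonzero(alive & (world.age < p.adulthood_age))
    if kids.size:
        mo = world.mother[kids]
        assert np.all(mo >= 0)
        assert np.all(alive[mo])
        assert np.all(world.group[kids] == world.group[mo])
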