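"""The five-stage yearly schedule.

Each simulated year executes, in fixed order:

1. *Matchmaking* — unmarried reproductive-age adults are randomly paired
   across groups; acceptance depends on the candidate's genetic quality and
   the chooser's age; on marriage the dispersal-sex spouse moves.
2. *Family fissioning* — groups larger than half the carrying capacity split
   onto a free patch if one is available.
3. *Resource contribution* — adults pool a trait-dependent fraction of their
   production (cooperators 90%, defectors 10%); the pool is divided equally
   among the group's married reproductive-age females.
4. *Childbirth, childrearing, and child death* — mothers sustain existing
   children (youngest starving first when the budget falls short), then give
   birth if the residual covers the birth cost and the group is below
   capacity; all children then face the age- and quality-dependent hazard.
5. *Adult aging and death* — adults face the hazard, orphans are adopted or
   die, everyone ages one year, and agents turning 18 learn their
   cooperativity from their natal group.

Before stage 1 the year's effective cost of childrearing beta' is drawn once
and applied world-wide.
"""
from __future__ import annotations

import numpy as np

from .life_history import child_cost, inherit_quality, mortality_probability, resource_production
from .model_core import COOP_UNSET, FEMALE, MALE, World, count_metrics

__all__ = [
    "draw_effective_beta",
    "acceptance_probability",
    "matchmaking",
    "family_fission",
    "contribute_resources",
    "allocate_child_support",
    "childbirth_and_child_mortality",
    "adult_aging_and_death",
    "step",
]


def draw_effective_beta(beta: float, sigma_nu: float, rng) -> float:
    """This year's cost of childrearing: max(0, beta + Normal(0, sigma_nu)).

    The noise models yearly environmental fluctuation shared by the whole
    population; the floor at zero means that for very small beta the expected
    effective cost exceeds beta.
    """
    if sigma_nu < 0:
        raise ValueError("sigma_nu must be >= 0")
    if sigma_nu == 0:
        return float(beta)
    return float(max(0.0, beta + rng.normal(0.0, sigma_nu)))


# ----------------------------------------------------------------------
# Stage 1: matchmaking
# ----------------------------------------------------------------------
def acceptance_probability(age_i, q_j, params) -> np.ndarray | float:
    """P that an age-``age_i`` chooser accepts a mate of quality ``q_j``.

    ``q_j ** (s0 * max(0, (a_max - age_i) / (a_max - 18)))`` with
    ``a_max = elder_age - 1``: choosiness is maximal at 18 and vanishes by the
    end of the reproductive window, so older agents accept mates of any
    quality.
    """
    a_max = params.elder_age - 1
    s = params.mate_choosiness * np.clip(
        (a_max - np.asarray(age_i, dtype=float)) / (a_max - params.adulthood_age), 0.0, None
    )
    p = np.asarray(q_j, dtype=float) ** s
    if p.ndim == 0:
        return float(p)
    return p


def _reproductive(world: World) -> np.ndarray:
    p = world.params
    return world.alive & (world.age >= p.adulthood_age) & (world.age < p.elder_age)


def matchmaking(world: World) -> None:
    """Pair unmarried reproductive-age adults across groups; marry on mutual acceptance."""
    p, rng = world.params, world.rng
    single = _reproductive(world) & (world.spouse < 0)
    F = np.flatnonzero(single & (world.sex == FEMALE))
    M = np.flatnonzero(single & (world.sex == MALE))
    n = min(F.size, M.size)
    if n == 0:
        return
    F = rng.permutation(F)[:n]
    M = rng.permutation(M)[:n]
    # repair same-group pairings by rotating the clashing males once
    clash = np.flatnonzero(world.group[F] == world.group[M])
    if clash.size:
        M[clash] = M[np.roll(clash, 1)]
        ok = world.group[F] != world.group[M]
        F, M = F[ok], M[ok]
    if F.size == 0:
        return
    acc_f = rng.random(F.size) < acceptance_probability(world.age[F], world.q[M], p)
    acc_m = rng.random(F.size) < acceptance_probability(world.age[M], world.q[F], p)
    wed = acc_f & acc_m
    Fw, Mw = F[wed], M[wed]
    if Fw.size == 0:
        return
    # a marriage moves the dispersal-sex spouse (plus, for female dispersal,
    # her dependent children); it is blocked when the receiving patch would
    # exceed its carrying capacity
    female_moves = p.dispersal_sex == "female"
    n_dep = np.zeros(world.size, dtype=np.int64)
    if female_moves:
        kmom = world.mother[world.alive & (world.age < p.adulthood_age)]
        np.add.at(n_dep, kmom[kmom >= 0], 1)
    sizes = world.group_sizes()
    keep = np.ones(Fw.size, dtype=bool)
    for k in range(Fw.size):
        mover = Fw[k] if female_moves else Mw[k]
        dest = world.group[Mw[k] if female_moves else Fw[k]]
        headcount = 1 + (n_dep[mover] if female_moves else 0)
        if sizes[dest] + headcount > p.K:
            keep[k] = False
            continue
        sizes[dest] += headcount
        sizes[world.group[mover]] -= headcount
    Fw, Mw = Fw[keep], Mw[keep]
    if Fw.size == 0:
        return
    world.spouse[Fw] = Mw
    world.spouse[Mw] = Fw
    if female_moves:
        movers, dest = Fw, world.group[Mw].copy()
    else:
        movers, dest = Mw, world.group[Fw].copy()
    world.group[movers] = dest
    if female_moves:
        _move_children_with_mothers(world, movers)
    if world.event_log is not None:
        for f, m in zip(Fw, Mw):
            world.event_log.append(
                (world.year, "marriage", int(world.group[f]), int(world.ids[f]))
            )


def _move_children_with_mothers(world: World, moved_mothers: np.ndarray) -> None:
    """Children reside in their mother's group while she lives."""
    if moved_mothers.size == 0:
        return
    dest = np.full(world.size + 1, -1, dtype=np.int64)
    dest[moved_mothers] = world.group[moved_mothers]
    kids = np.flatnonzero(world.alive & (world.age < world.params.adulthood_age))
    moved = dest[world.mother[kids]] >= 0
    world.group[kids[moved]] = dest[world.mother[kids[moved]]]


# ----------------------------------------------------------------------
# Stage 2: family fissioning
# ----------------------------------------------------------------------
def family_fission(world: World) -> None:
    """Split each group exceeding K/2 onto a free patch, while patches remain.

    Married couples split as units; unmarried adults and elders split within
    each class-by-sex cell, randomly halved (odd remainders assigned at
    random); children accompany their mothers.
    """
    p, rng = world.params, world.rng
    sizes = world.group_sizes()
    cand = np.flatnonzero(sizes > p.K / 2)
    if cand.size == 0:
        return
    free = list(rng.permutation(np.flatnonzero(sizes == 0)))
    if not free:
        return
    for g in rng.permutation(cand):
        if not free:
            break
        _split_group(world, int(g), int(free.pop()))


def _split_group(world: World, g: int, dest: int) -> None:
    p, rng = world.params, world.rng
    members = np.flatnonzero(world.alive & (world.group == g))
    is_adult = world.age[members] >= p.adulthood_age
    sp = world.spouse[members]
    married = sp >= 0
    # units: couples keyed by their female; singles by class x sex
    couple_f = members[married & (world.sex[members] == FEMALE)]
    moved_units: list[np.ndarray] = []
    cells = [couple_f]
    for cls_mask in (
        is_adult & (world.age[members] < p.elder_age),  # unmarried adults
        world.age[members] >= p.elder_age,  # elders
    ):
        for sex in (FEMALE, MALE):
            cells.append(members[cls_mask & ~married & (world.sex[members] == sex)])
    for cell in cells:
        if cell.size == 0:
            continue
        cell = rng.permutation(cell)
        n_move = cell.size // 2
        if cell.size % 2 == 1 and world.rng.random() < 0.5:
            n_move += 1
        moved_units.append(cell[:n_move])
    if not moved_units:
        return
    movers = np.concatenate(moved_units)
    # couples move together
    spouses = world.spouse[movers]
    movers = np.concatenate([movers, spouses[spouses >= 0]])
    world.group[movers] = dest
    _move_children_with_mothers(world, movers[world.sex[movers] == FEMALE])
    if world.event_log is not None:
        world.event_log.append((world.year, "fission", g, -1))


# ----------------------------------------------------------------------
# Stage 3: resource collection and contribution
# ----------------------------------------------------------------------
def contribute_resources(world: World) -> tuple[np.ndarray, np.ndarray]:
    """Pool adult contributions per group and compute mothers' budgets.

    Returns ``(budgets, pools)``: ``budgets`` is an array over agent
    positions (nonzero only for females with a childrearing budget this
    year), ``pools`` the donated resources per patch.  Production is capped
    by the patch's yearly yield, extracted pro rata when the group's summed
    potential exceeds it.  Each adult donates a
    fraction of its production — ``coop_fraction`` for cooperators,
    ``defect_fraction`` for defectors — and the group's pool is divided
    equally among its married reproductive-age females.  A female's budget is
    her retained production plus her pool share.  Mothers outside the
    recipient set (widowed, or already elders while a child is still a minor)
    keep only their own retained production for childrearing.  Retained
    resources of everyone else play no further role, and pools of groups
    without recipients are discarded.
    """
    p = world.params
    adult = world.alive & (world.age >= p.adulthood_age)
    r = np.zeros(world.size)
    r[adult] = resource_production(world.age[adult], world.q[adult], p.production)
    # finite patch yield: the cap binds on the group's age-profile gathering
    # effort (pro rata), while genetic quality scales what each individual
    # makes of its share — so a poorly adapted group extracts less from the
    # same territory than a well-adapted one
    if np.isfinite(p.production.patch_yield):
        effort = np.zeros(world.size)
        effort[adult] = resource_production(
            world.age[adult], np.ones(int(adult.sum())), p.production
        )
        potential = np.bincount(world.group[adult], weights=effort[adult], minlength=p.n_patches)
        with np.errstate(divide="ignore", invalid="ignore"):
            scale = np.minimum(1.0, p.production.patch_yield / potential)
        scale[~np.isfinite(scale)] = 1.0
        r *= scale[world.group]
    f = np.where(world.coop == 1, p.coop_fraction, p.defect_fraction)
    pools = np.bincount(
        world.group[adult], weights=(f * r)[adult], minlength=p.n_patches
    ).astype(float)
    recip = _reproductive(world) & (world.sex == FEMALE) & (world.spouse >= 0)
    n_rec = np.bincount(world.group[recip], minlength=p.n_patches)
    share = np.divide(pools, n_rec, out=np.zeros(p.n_patches), where=n_rec > 0)

    budgets = np.zeros(world.size)
    kids = world.alive & (world.age < p.adulthood_age)
    moms = np.unique(world.mother[kids])
    moms = moms[moms >= 0]
    budgets[moms] = ((1.0 - f) * r)[moms]
    budgets[recip] = ((1.0 - f) * r)[recip] + share[world.group[recip]]
    return budgets, pools


# ----------------------------------------------------------------------
# Stage 4: childbirth, childrearing, and child death
# ----------------------------------------------------------------------
def allocate_child_support(child_ages, budget: float, beta_effective: float, cost_params):
    """Youngest-first starvation rule for one mother.

    While the budget cannot cover the summed yearly costs of all living
    children, the youngest dies; the survivors are thus the maximal set of
    oldest children whose total cost fits the budget.  Returns
    ``(keep_mask, residual)`` where ``keep_mask`` aligns with ``child_ages``.
    """
    ages = np.asarray(child_ages)
    costs = child_cost(ages, beta_effective, cost_params)
    order = np.argsort(-ages, kind="stable")  # oldest first
    cum = np.cumsum(costs[order])
    kept = cum <= budget + 1e-9
    keep = np.zeros(ages.size, dtype=bool)
    keep[order[kept]] = True
    residual = budget - (costs[keep].sum() if keep.any() else 0.0)
    return keep, float(residual)


def childbirth_and_child_mortality(world: World, budgets: np.ndarray) -> None:
    """Sustain children, bear newborns, then apply the childhood hazard."""
    p, rng = world.params, world.rng
    beta_eff = world.beta_effective
    kid_pos = np.flatnonzero(world.alive & (world.age < p.adulthood_age))
    kept_cost = np.zeros(world.size)
    if kid_pos.size:
        kmom = world.mother[kid_pos]
        kcost = child_cost(world.age[kid_pos], beta_eff, p.cost)
        # per mother: oldest-first cumulative cost <= budget survives,
        # i.e. the youngest starve first; ties broken by the run RNG
        tie = rng.random(kid_pos.size)
        order = np.lexsort((tie, -world.age[kid_pos], kmom))
        kid_pos, kmom, kcost = kid_pos[order], kmom[order], kcost[order]
        seg_start = np.flatnonzero(np.r_[True, kmom[1:] != kmom[:-1]])
        seg_len = np.diff(np.r_[seg_start, kmom.size])
        cum = np.cumsum(kcost)
        base = np.repeat(cum[seg_start] - kcost[seg_start], seg_len)
        keep = (cum - base) <= budgets[kmom] + 1e-9
        starved = kid_pos[~keep]
        world.alive[starved] = False
        if world.event_log is not None:
            for i in starved:
                world.event_log.append(
                    (world.year, "child_death_resources", int(world.group[i]), int(world.ids[i]))
                )
        np.add.at(kept_cost, kmom[keep], kcost[keep])
    residual = budgets - kept_cost

    # births: married reproductive-age females with residual >= birth cost,
    # capped by patch carrying capacity (excess candidates drop out at random)
    recip = _reproductive(world) & (world.sex == FEMALE) & (world.spouse >= 0)
    cand = np.flatnonzero(recip & (residual >= beta_eff) & (world.spouse >= 0))
    if cand.size:
        sizes = world.group_sizes()
        room = np.maximum(p.K - sizes, 0)
        cand = rng.permutation(cand)
        g = world.group[cand]
        order = np.argsort(g, kind="stable")
        gs = g[order]
        seg = np.flatnonzero(np.r_[True, gs[1:] != gs[:-1]])
        rank = np.arange(gs.size) - np.repeat(seg, np.diff(np.r_[seg, gs.size]))
        mothers = cand[order][rank < room[gs]]
        if mothers.size:
            fathers = world.spouse[mothers]
            q_new = inherit_quality(
                world.q[mothers], world.q[fathers], p.q_mutation_sd, p.gamma, rng,
                size=mothers.size,
            )
            sex_new = np.where(
                rng.random(mothers.size) < p.p_female_birth, FEMALE, MALE
            ).astype(np.int8)
            pos = world.add_agents(
                sex=sex_new,
                age=np.zeros(mothers.size, dtype=np.int32),
                q=np.atleast_1d(q_new),
                coop=np.full(mothers.size, COOP_UNSET, dtype=np.int8),
                spouse=np.full(mothers.size, -1, dtype=np.int64),
                mother=mothers,
                group=world.group[mothers],
            )
            world.total_births += mothers.size
            world.female_births += int((sex_new == FEMALE).sum())
            if world.event_log is not None:
                for i in pos:
                    world.event_log.append(
                        (world.year, "birth", int(world.group[i]), int(world.ids[i]))
                    )

    # childhood hazard (newborns included)
    kid_pos = np.flatnonzero(world.alive & (world.age < p.adulthood_age))
    if kid_pos.size:
        pdie = mortality_probability(world.age[kid_pos], world.q[kid_pos], p.hazard)
        dead = kid_pos[rng.random(kid_pos.size) < pdie]
        world.alive[dead] = False
        if world.event_log is not None:
            for i in dead:
                world.event_log.append(
                    (world.year, "child_death_hazard", int(world.group[i]), int(world.ids[i]))
                )


# ----------------------------------------------------------------------
# Stage 5: adult aging and death
# ----------------------------------------------------------------------
def reassign_orphans(world: World) -> None:
    """Children of dead mothers are adopted by a random married
    reproductive-age female of their group; without one they die."""
    p, rng = world.params, world.rng
    kid_pos = np.flatnonzero(world.alive & (world.age < p.adulthood_age))
    if kid_pos.size == 0:
        return
    mom_alive = np.zeros(world.size + 1, dtype=bool)
    mom_alive[: world.size] = world.alive
    orphans = kid_pos[~mom_alive[world.mother[kid_pos]]]
    if orphans.size == 0:
        return
    foster_ok = _reproductive(world) & (world.sex == FEMALE) & (world.spouse >= 0)
    for g in np.unique(world.group[orphans]):
        kids_g = orphans[world.group[orphans] == g]
        fosters = np.flatnonzero(foster_ok & (world.group == g))
        if fosters.size:
            world.mother[kids_g] = rng.choice(fosters, size=kids_g.size)
        else:
            world.alive[kids_g] = False
            if world.event_log is not None:
                for i in kids_g:
                    world.event_log.append(
                        (world.year, "child_death_resources", int(g), int(world.ids[i]))
                    )


def adult_aging_and_death(world: World) -> None:
    """Adult mortality, orphan handling, aging, and trait assignment at 18."""
    p, rng = world.params, world.rng
    sizes_before = world.group_sizes()
    adult_pos = np.flatnonzero(world.alive & (world.age >= p.adulthood_age))
    if adult_pos.size:
        pdie = mortality_probability(world.age[adult_pos], world.q[adult_pos], p.hazard)
        dead = adult_pos[rng.random(adult_pos.size) < pdie]
        world.alive[dead] = False
        # widowed survivors' spouse links are cleared
        sp = world.spouse[dead]
        sp = sp[sp >= 0]
        world.spouse[sp[world.alive[sp]]] = -1
        world.spouse[dead] = -1
        if world.event_log is not None:
            for i in dead:
                world.event_log.append(
                    (world.year, "adult_death", int(world.group[i]), int(world.ids[i]))
                )

    reassign_orphans(world)

    # aging, then trait assignment for the cohort reaching adulthood;
    # natal-group trait frequencies are computed once, before the new cohort
    # itself bears the trait, so maturing agents do not influence one another
    world.age[world.alive] += 1
    mat = np.flatnonzero(world.alive & (world.age == p.adulthood_age))
    if mat.size:
        has_trait = world.alive & (world.coop != COOP_UNSET)
        coop_cnt = np.bincount(
            world.group[has_trait & (world.coop == 1)], minlength=p.n_patches
        )
        trait_cnt = np.bincount(world.group[has_trait], minlength=p.n_patches)
        total_trait = trait_cnt.sum()
        pop_freq = coop_cnt.sum() / total_trait if total_trait else 0.5
        freq = np.divide(
            coop_cnt, trait_cnt, out=np.full(p.n_patches, pop_freq), where=trait_cnt > 0
        )
        prob = freq[world.group[mat]]
        world.coop[mat] = (rng.random(mat.size) < prob).astype(np.int8)
        world.mother[mat] = -1

    if world.event_log is not None:
        died_out = np.flatnonzero((sizes_before > 0) & (world.group_sizes() == 0))
        for g in died_out:
            world.event_log.append((world.year, "group_extinction", int(g), -1))


# ----------------------------------------------------------------------
def step(world: World) -> tuple[int, float, float, int]:
    """Advance the world one year; returns the post-step metrics tuple."""
    p = world.params
    world.beta_effective = draw_effective_beta(p.beta, p.sigma_nu, world.rng)
    matchmaking(world)
    family_fission(world)
    budgets, _ = contribute_resources(world)
    childbirth_and_child_mortality(world, budgets)
    adult_aging_and_death(world)
    world.year += 1
    world.compact()
    return count_metrics(world)
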