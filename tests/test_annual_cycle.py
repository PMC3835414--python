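"""The five-stage yearly schedule: each stage in isolation, then whole steps."""
import numpy as np
import pytest
from scipy.stats import norm

from famgroups.annual_cycle import (
    acceptance_probability,
    adult_aging_and_death,
    allocate_child_support,
    childbirth_and_child_mortality,
    contribute_resources,
    draw_effective_beta,
    family_fission,
    matchmaking,
    reassign_orphans,
    step,
)
from famgroups.life_history import resource_production
from famgroups.model_core import COOP_UNSET, FEMALE, MALE, count_metrics, init_population
from famgroups.params import CostScheduleParams, ModelParams

from conftest import build_world, check_invariants, tiny_params


class TestEffectiveBeta:
    def test_noiseless_limit(self, rng):
        assert all(draw_effective_beta(100.0, 0.0, rng) == 100.0 for _ in range(5))

    def test_moments(self, rng):
        draws = np.array([draw_effective_beta(100.0, 10.0, rng) for _ in range(100_000)])
        assert abs(draws.mean() - 100.0) < 0.15
        assert abs(draws.std() - 10.0) < 0.15

    def test_floor_raises_expected_cost(self, rng):
        # closed form for E[max(0, N(mu, s))] as the independent oracle
        mu, s = 5.0, 10.0
        expected = mu * norm.cdf(mu / s) + s * norm.pdf(mu / s)
        draws = np.array([draw_effective_beta(mu, s, rng) for _ in range(200_000)])
        assert draws.min() >= 0.0
        assert draws.mean() > mu
        assert abs(draws.mean() - expected) < 0.1


class TestMatchmaking:
    def test_acceptance_probability_values(self):
        p = tiny_params()
        assert acceptance_probability(30, 1.0, p) == 1.0
        assert acceptance_probability(49, 0.2, p) == 1.0  # choosiness gone by 49
        assert acceptance_probability(18, 0.5, p) == pytest.approx(0.125)  # 0.5**3

    def _pair_world(self, **over):
        params = tiny_params(n_initial_groups=2, n_patches=2, **over)
        rows = [
            dict(sex=FEMALE, age=30, q=1.0, group=0),
            dict(sex=MALE, age=30, q=1.0, group=1),
            dict(sex=FEMALE, age=3, q=1.0, group=0, mother=0),
        ]
        return build_world(params, rows), params

    def test_marriage_and_female_dispersal_with_children(self):
        world, _ = self._pair_world()
        matchmaking(world)  # q = 1 on both sides: mutual acceptance certain
        assert world.spouse[0] == 1 and world.spouse[1] == 0
        assert world.group[0] == 1
        assert world.group[2] == 1  # child accompanies mother

    def test_male_dispersal_variant(self):
        world, _ = self._pair_world(dispersal_sex="male")
        matchmaking(world)
        assert world.spouse[0] == 1
        assert world.group[1] == 0 and world.group[0] == 0
        assert world.group[2] == 0  # child never moved

    def test_no_within_group_marriage(self):
        params = tiny_params(n_initial_groups=1, n_patches=1)
        world = build_world(params, [
            dict(sex=FEMALE, age=30, q=1.0, group=0),
            dict(sex=MALE, age=30, q=1.0, group=0),
        ])
        matchmaking(world)
        assert world.spouse[0] == -1 and world.spouse[1] == -1

    def test_elders_do_not_remarry(self):
        world = build_world(tiny_params(n_initial_groups=2, n_patches=2), [
            dict(sex=FEMALE, age=60, q=1.0, group=0),
            dict(sex=MALE, age=60, q=1.0, group=1),
        ])
        matchmaking(world)
        assert np.all(world.spouse == -1)

    def test_full_group_blocks_immigration(self):
        params = tiny_params(n_initial_groups=2, n_patches=2, K=8, group_size_init=8)
        rows = [dict(sex=FEMALE, age=30, q=1.0, group=0)]
        rows += [dict(sex=MALE, age=30 + i, q=1.0, group=1, coop=1) for i in range(8)]
        world = build_world(params, rows)
        matchmaking(world)
        assert world.spouse[0] == -1  # destination already at capacity
        assert world.group_sizes().max() <= 8


class TestFission:
    def _elder_males(self, n, params):
        return build_world(params, [
            dict(sex=MALE, age=60, q=0.5, group=0, coop=0) for _ in range(n)
        ])

    def test_even_split_of_a_cell(self):
        params = tiny_params(n_initial_groups=1, n_patches=2, K=16, group_size_init=8)
        world = self._elder_males(10, params)
        family_fission(world)
        assert sorted(world.group_sizes()[world.group_sizes() > 0]) == [5, 5]

    def test_exact_half_capacity_does_not_split(self):
        params = tiny_params(n_initial_groups=1, n_patches=2, K=20, group_size_init=8)
        world = self._elder_males(10, params)
        family_fission(world)
        assert world.n_groups == 1

    def test_no_free_patch_no_split(self):
        params = tiny_params(n_initial_groups=1, n_patches=1, K=16, group_size_init=8)
        world = self._elder_males(10, params)
        family_fission(world)
        assert world.n_groups == 1

    def test_couples_and_children_move_as_units(self):
        params = tiny_params(n_initial_groups=1, n_patches=2, K=10, group_size_init=8)
        rows = []
        for c in range(3):  # three couples, one child each
            rows += [
                dict(sex=FEMALE, age=30, q=0.5, group=0, spouse=2 * c + 1),
                dict(sex=MALE, age=32, q=0.5, group=0, spouse=2 * c),
            ]
        rows += [dict(sex=FEMALE, age=2, q=0.5, group=0, mother=2 * c) for c in range(3)]
        world = build_world(params, rows)
        family_fission(world)  # size 9 > K/2 = 5
        assert world.n_groups == 2
        for c in range(3):
            f, m, kid = 2 * c, 2 * c + 1, 6 + c
            assert world.group[f] == world.group[m] == world.group[kid]


class TestContribution:
    def test_pool_and_budget_follow_contribution_rule(self):
        params = tiny_params(n_initial_groups=1, n_patches=1)
        # cooperator mother (married, reproductive age) + cooperator elder
        world = build_world(params, [
            dict(sex=FEMALE, age=30, q=1.0, group=0, coop=1, spouse=1),
            dict(sex=MALE, age=65, q=1.0, group=0, coop=1, spouse=0),
        ])
        budgets, pools = contribute_resources(world)
        r_m = resource_production(30, 1.0, params.production)
        r_e = resource_production(65, 1.0, params.production)
        assert pools[0] == pytest.approx(0.9 * (r_m + r_e))
        assert budgets[0] == pytest.approx(0.1 * r_m + 0.9 * (r_m + r_e))
        assert budgets[1] == 0.0

    def test_all_defector_group(self):
        params = tiny_params(n_initial_groups=1, n_patches=1)
        rows = [dict(sex=FEMALE, age=40, q=0.5, group=0, coop=0, spouse=1),
                dict(sex=MALE, age=40, q=0.5, group=0, coop=0, spouse=0)]
        rows += [dict(sex=MALE, age=45, q=0.5, group=0, coop=0) for _ in range(3)]
        world = build_world(params, rows)
        budgets, pools = contribute_resources(world)
        rs = resource_production(world.age[world.alive], world.q[world.alive],
                                 params.production)
        assert pools[0] == pytest.approx(0.1 * rs.sum())
        assert budgets[0] == pytest.approx(0.9 * rs[0] + 0.1 * rs.sum())

    def test_pool_discarded_without_recipients(self):
        params = tiny_params(n_initial_groups=1, n_patches=1)
        world = build_world(params, [
            dict(sex=MALE, age=40, q=0.5, group=0, coop=1) for _ in range(4)
        ])
        budgets, pools = contribute_resources(world)
        assert pools[0] > 0
        assert np.all(budgets == 0.0)

    def test_widowed_mother_keeps_retained_production_only(self):
        params = tiny_params(n_initial_groups=1, n_patches=1)
        world = build_world(params, [
            dict(sex=FEMALE, age=40, q=1.0, group=0, coop=0),
            dict(sex=FEMALE, age=4, q=0.5, group=0, mother=0),
            dict(sex=MALE, age=40, q=1.0, group=0, coop=1),
        ])
        budgets, _ = contribute_resources(world)
        assert budgets[0] == pytest.approx(0.9 * resource_production(40, 1.0, params.production))

    def test_patch_yield_caps_group_extraction(self):
        from famgroups.params import ProductionCurveParams

        pp = ProductionCurveParams(peak_output=10.0, quality_floor=0.0, patch_yield=12.0)
        params = tiny_params(n_initial_groups=1, n_patches=1, production=pp)
        # two peak-age adults produce 20 potential > 12: scaled pro rata
        world = build_world(params, [
            dict(sex=FEMALE, age=50, q=1.0, group=0, coop=1),
            dict(sex=MALE, age=50, q=1.0, group=0, coop=1),
        ])
        _, pools = contribute_resources(world)
        assert pools[0] == pytest.approx(0.9 * 12.0)

    def test_resource_conservation(self):
        # recipient shares per group sum back to the pool
        from famgroups.params import ProductionCurveParams

        world = init_population(
            tiny_params(production=ProductionCurveParams(patch_yield=float("inf"))), 17
        )
        budgets, pools = contribute_resources(world)
        p = world.params
        recip = (world.alive & (world.sex == FEMALE) & (world.spouse >= 0)
                 & (world.age >= 18) & (world.age < 50))
        f = np.where(world.coop == 1, 0.9, 0.1)
        r = np.zeros(world.size)
        adult = world.alive & (world.age >= 18)
        r[adult] = resource_production(world.age[adult], world.q[adult], p.production)
        shares = budgets[recip] - ((1 - f) * r)[recip]
        got = np.bincount(world.group[recip], weights=shares, minlength=p.n_patches)
        has = np.bincount(world.group[recip], minlength=p.n_patches) > 0
        assert np.allclose(got[has], pools[has])


class TestChildAllocation:
    CP = CostScheduleParams(shape="linear")  # cost(age) = beta' * (1 - age/18)

    def test_sufficient_budget_keeps_all(self):
        # beta' = 18: children aged 9 and 14 cost 9 + 4 = 13 <= 15.4
        keep, residual = allocate_child_support([9, 14], 15.4, 18.0, self.CP)
        assert keep.all()
        assert residual == pytest.approx(2.4)

    def test_youngest_starves_first(self):
        keep, residual = allocate_child_support([9, 14], 5.0, 18.0, self.CP)
        assert not keep[0] and keep[1]  # the 9-year-old dies, 5 >= 4 keeps the elder
        assert residual == pytest.approx(1.0)

    def test_empty_budget_starves_all(self):
        keep, residual = allocate_child_support([0, 3, 7], 0.0, 18.0, self.CP)
        assert not keep.any()
        assert residual == 0.0


class TestChildbirth:
    def _mother_world(self, K=60, beta=10.0):
        params = tiny_params(n_initial_groups=1, n_patches=1, K=K, beta=beta)
        world = build_world(params, [
            dict(sex=FEMALE, age=30, q=1.0, group=0, coop=1, spouse=1),
            dict(sex=MALE, age=30, q=1.0, group=0, coop=1, spouse=0),
        ])
        world.beta_effective = beta
        return world

    def test_birth_when_budget_covers_cost(self):
        world = self._mother_world()
        budgets = np.zeros(world.size)
        budgets[0] = 1000.0
        childbirth_and_child_mortality(world, budgets)
        assert world.total_births == 1
        newborn = world.size - 1
        assert world.age[newborn] == 0
        assert world.mother[newborn] == 0
        assert world.group[newborn] == 0
        assert world.coop[newborn] == COOP_UNSET

    def test_no_birth_when_group_at_capacity(self):
        world = self._mother_world(K=2)
        budgets = np.zeros(world.size)
        budgets[0] = 1000.0
        childbirth_and_child_mortality(world, budgets)
        assert world.total_births == 0

    def test_no_birth_below_cost(self):
        world = self._mother_world(beta=10.0)
        budgets = np.zeros(world.size)
        budgets[0] = 9.99
        childbirth_and_child_mortality(world, budgets)
        assert world.total_births == 0

    def test_unmarried_female_cannot_give_birth(self):
        params = tiny_params(n_initial_groups=1, n_patches=1)
        world = build_world(params, [dict(sex=FEMALE, age=30, q=1.0, group=0, coop=1)])
        world.beta_effective = 10.0
        budgets = np.full(world.size, 1000.0)
        childbirth_and_child_mortality(world, budgets)
        assert world.total_births == 0


class TestAgingAndDeath:
    def test_certain_death_at_max_age_and_widowing(self):
        params = tiny_params(n_initial_groups=1, n_patches=1)
        world = build_world(params, [
            dict(sex=FEMALE, age=40, q=1.0, group=0, coop=1, spouse=1),
            dict(sex=MALE, age=100, q=1.0, group=0, coop=1, spouse=0),
        ])
        adult_aging_and_death(world)
        assert not world.alive[1]
        assert world.spouse[0] == -1  # widow's link cleared

    def test_maturation_assigns_trait_and_detaches_mother(self):
        params = tiny_params(n_initial_groups=1, n_patches=1)
        rows = [dict(sex=FEMALE, age=30, q=1.0, group=0, coop=1, spouse=1),
                dict(sex=MALE, age=30, q=1.0, group=0, coop=1, spouse=0),
                dict(sex=FEMALE, age=17, q=1.0, group=0, mother=0)]
        world = build_world(params, rows, seed=5)
        adult_aging_and_death(world)
        assert world.age[2] == 18
        assert world.coop[2] == 1  # all-cooperator natal group: certainty
        assert world.mother[2] == -1

    def test_all_defector_group_produces_defector(self):
        params = tiny_params(n_initial_groups=1, n_patches=1)
        rows = [dict(sex=FEMALE, age=30, q=1.0, group=0, coop=0, spouse=1),
                dict(sex=MALE, age=30, q=1.0, group=0, coop=0, spouse=0),
                dict(sex=MALE, age=17, q=1.0, group=0, mother=0)]
        world = build_world(params, rows, seed=5)
        adult_aging_and_death(world)
        assert world.coop[2] == 0

    def test_orphan_adopted_by_group_mother(self):
        params = tiny_params(n_initial_groups=1, n_patches=1)
        rows = [dict(sex=FEMALE, age=40, q=1.0, group=0, coop=1),  # dead below
                dict(sex=FEMALE, age=30, q=1.0, group=0, coop=1, spouse=2),
                dict(sex=MALE, age=30, q=1.0, group=0, coop=1, spouse=1),
                dict(sex=FEMALE, age=5, q=0.5, group=0, mother=0)]
        world = build_world(params, rows)
        world.alive[0] = False
        reassign_orphans(world)
        assert world.alive[3]
        assert world.mother[3] == 1

    def test_orphan_dies_without_foster_mother(self):
        params = tiny_params(n_initial_groups=1, n_patches=1)
        rows = [dict(sex=FEMALE, age=40, q=1.0, group=0, coop=1),
                dict(sex=MALE, age=45, q=1.0, group=0, coop=1),
                dict(sex=FEMALE, age=5, q=0.5, group=0, mother=0)]
        world = build_world(params, rows)
        world.alive[0] = False
        reassign_orphans(world)
        assert not world.alive[2]


class TestStep:
    def test_empty_world_stays_empty(self, rng):
        from famgroups.model_core import World

        world = World(tiny_params(), rng)
        pop, coop, q, ng = step(world)
        assert pop == 0 and ng == 0
        assert np.isnan(coop)

    def test_determinism_bit_identical(self):
        snaps = []
        for _ in range(2):
            world = init_population(tiny_params(), 77)
            for _ in range(10):
                step(world)
            snaps.append(world.to_csv())
        assert snaps[0] == snaps[1]

    def test_marriage_can_precede_birth_within_one_year(self):
        # a couple formed in stage 1 can produce a newborn in stage 4
        params = tiny_params(n_initial_groups=2, n_patches=2, beta=1.0)
        world = build_world(params, [
            dict(sex=FEMALE, age=30, q=1.0, group=0, coop=1),
            dict(sex=MALE, age=30, q=1.0, group=1, coop=1),
        ], seed=3)
        step(world)
        assert world.total_births == 1

    def test_noiseless_beta_constant(self):
        world = init_population(tiny_params(sigma_nu=0.0, beta=20.0), 5)
        for _ in range(5):
            step(world)
            assert world.beta_effective == 20.0

    def test_zero_cooperators_is_absorbing(self):
        world = init_population(tiny_params(initial_coop_freq=0.0), 13)
        for _ in range(40):
            _, coop, _, _ = step(world)
            if world.n_alive == 0:
                break
            assert coop == 0.0

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_invariants_hold_through_random_battery(self, seed):
        world = init_population(tiny_params(beta=30.0, sigma_nu=5.0), seed)
        for _ in range(40):
            step(world)
            check_invariants(world)

    def test_metrics_recorded_after_step(self):
        world = init_population(tiny_params(), 1)
        pop, coop, q, ng = step(world)
        assert world.year == 1
        assert pop == world.n_alive
        assert 0 <= coop <= 1
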