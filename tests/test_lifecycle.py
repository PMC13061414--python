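import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dolsim import (
    BenefitMode, FecundityMode, Parameters, Role, ScenarioConfig, Task,
    effective_group_help, fecundity_mean, init_population, step_cycle,
    validate_parameters,
)
from dolsim.lifecycle import (
    dispersal_step, fill_vacancies, help_step, reproduce, sample_bidders,
    survival_probability, survival_step,
)
from dolsim.model_core import ALPHA, BETA, GAMMA_0, GAMMA_R, NEUTRAL
from dolsim.reference import step_cycle_reference

from conftest import make_population

nonneg = st.floats(min_value=0, max_value=1e6, allow_nan=False)


class TestEffectiveGroupHelp:
    def test_balanced_below_cap_unchanged(self):
        d, w = effective_group_help(3.0, 3.0, 0.1, FecundityMode.DOL)
        assert (d, w) == (3.0, 3.0)

    def test_imbalance_truncated_at_hmax(self):
        d, w = effective_group_help(2.0, 4.0, 0.1, FecundityMode.DOL)
        assert d == 2.0
        assert w == pytest.approx(3.1)

    def test_no_dol_identity(self):
        d, w = effective_group_help(0.0, 7.0, 0.1, FecundityMode.NO_DOL)
        assert (d, w) == (0.0, 7.0)


class TestFecundity:
    def test_no_help_baseline(self):
        assert fecundity_mean(1.0, 1.0, 0.0, 0.0) == 1.0

    def test_halfway_point(self):
        assert fecundity_mean(1.0, 1.0, 1.0, 0.0) == pytest.approx(1.5)

    def test_saturation(self):
        assert fecundity_mean(1.0, 1.0, 1e9, 1e9) == pytest.approx(2.0, abs=1e-6)

    @given(d=nonneg, w=nonneg)
    def test_bounded_k0_to_k0_plus_kh(self, d, w):
        K = fecundity_mean(1.0, 1.0, d, w)
        assert 1.0 <= K <= 2.0

    @given(d=nonneg, w=nonneg)
    def test_dol_imbalance_never_increases_fecundity(self, d, w):
        """With k_m=0, any split of a total is at most as fecund as the even split."""
        ed, ew = effective_group_help(d, w, 0.0, FecundityMode.DOL)
        K = fecundity_mean(1.0, 1.0, ed, ew)
        half = (d + w) / 2.0
        K_even = fecundity_mean(1.0, 1.0, *effective_group_help(half, half, 0.0, FecundityMode.DOL))
        assert K <= K_even + 1e-12


class TestReproduce:
    def test_vacant_territory_produces_nothing(self, rng):
        pop = make_population(3, breeders=[0, 2])  # territory 1 vacant
        params, scen = validate_parameters(Parameters(N_b=3, mu=0.0), ScenarioConfig())
        n = reproduce(pop, params, scen, rng)
        assert np.all(pop.group[pop.role == Role.SUBORDINATE] != 1)
        assert n == pop.n - 2

    def test_offspring_mean_matches_poisson(self, rng):
        """No help: offspring per breeder ~ Poisson(k_0 = 1)."""
        n_terr = 100_000
        pop = make_population(n_terr, breeders=range(n_terr))
        params, scen = validate_parameters(Parameters(N_b=n_terr, mu=0.0), ScenarioConfig())
        n = reproduce(pop, params, scen, rng)
        assert n / n_terr == pytest.approx(1.0, abs=4 / math.sqrt(n_terr))

    def test_offspring_mean_with_help(self, rng):
        """Prev sums (5,5) in DoL mode: K = 1 + 10/11."""
        n_terr = 50_000
        pop = make_population(n_terr, breeders=range(n_terr))
        pop.prev_sum_def[:] = 5.0
        pop.prev_sum_work[:] = 5.0
        params, scen = validate_parameters(Parameters(N_b=n_terr, mu=0.0), ScenarioConfig())
        n = reproduce(pop, params, scen, rng)
        expect = 1.0 + 10.0 / 11.0
        assert n / n_terr == pytest.approx(expect, abs=4 * math.sqrt(expect / n_terr))

    def test_offspring_inherit_parent_genome_without_mutation(self, rng):
        pop = make_population(5, breeders=range(5))
        pop.genes[:, ALPHA] = np.arange(5.0)
        params, scen = validate_parameters(Parameters(N_b=5, mu=0.0), ScenarioConfig())
        reproduce(pop, params, scen, rng)
        newborn = pop.age == 1
        newborn[:5] = False
        for i in np.nonzero(newborn)[0]:
            assert pop.genes[i, ALPHA] == pop.group[i]


class TestDispersalStep:
    def test_absolute_dispersal_empties_groups(self, rng):
        pop = make_population(4, breeders=[0, 1, 2, 3],
                              subordinates=[(0, 2, 0.0), (1, 3, 0.0), (2, 1, 0.0)])
        params, scen = validate_parameters(Parameters(N_b=4), ScenarioConfig())
        dispersal_step(pop, params, scen, rng)  # beta = 1 everywhere
        assert np.count_nonzero(pop.role == Role.SUBORDINATE) == 0
        assert pop.n_floaters == 3

    def test_certain_philopatry_is_identity(self, rng):
        pop = make_population(4, breeders=[0, 1],
                              subordinates=[(0, 2, 0.0), (1, 3, 0.0)])
        pop.genes[:, BETA] = 0.0
        params, scen = validate_parameters(Parameters(N_b=4), ScenarioConfig())
        roles, groups = pop.role.copy(), pop.group.copy()
        dispersal_step(pop, params, scen, rng)
        assert np.array_equal(pop.role, roles)
        assert np.array_equal(pop.group, groups)

    def test_cross_foster_shuffles_newborn_group_labels(self):
        """GA-only: philopatric newborns land in a natal group with the
        2-element-permutation null rate of 1/2."""
        params, scen = validate_parameters(
            Parameters(N_b=2),
            ScenarioConfig(benefit_mode=BenefitMode.GA_ONLY))
        stayed = 0
        n_rep = 800
        for seed in range(n_rep):
            pop = make_population(2, breeders=[0, 1],
                                  subordinates=[(0, 1, 0.0), (1, 1, 0.0)])
            pop.genes[:, BETA] = 0.0
            r = np.random.default_rng(seed)
            dispersal_step(pop, params, scen, r)
            newborn = (pop.age == 1) & (pop.role == Role.SUBORDINATE)
            stayed += int(pop.group[np.nonzero(newborn)[0][0]] == 0)
        assert stayed / n_rep == pytest.approx(0.5, abs=4 * 0.5 / math.sqrt(n_rep))


class TestHelpStep:
    def test_no_help_gives_zero_sums(self, rng):
        pop = make_population(3, breeders=[0, 1, 2],
                              subordinates=[(0, 2, 0.0), (1, 1, 0.0)])
        params, _ = validate_parameters(Parameters(N_b=3), ScenarioConfig())
        sd, sw = help_step(pop, params, rng)
        assert np.all(sd == 0) and np.all(sw == 0)

    def test_deterministic_defense(self, rng):
        pop = make_population(1, breeders=[0], subordinates=[(0, 2, 2.0)])
        pop.genes[:, GAMMA_0] = 60.0  # T ~ 1: always defend
        params, _ = validate_parameters(Parameters(N_b=1), ScenarioConfig())
        sd, sw = help_step(pop, params, rng)
        assert sd[0] == pytest.approx(2.0)
        assert sw[0] == 0.0
        assert pop.task[1] == Task.DEFENSE

    def test_task_split_matches_binomial(self, rng):
        """10^4 helpers with H=1 and T=0.25: defense sum ~ 2500."""
        n = 10_000
        pop = make_population(1, breeders=[0],
                              subordinates=[(0, 1, 1.0)] * n)
        T = 0.25
        pop.genes[1:, GAMMA_0] = -math.log((1 - T) / T)  # gamma_R = 0
        params, _ = validate_parameters(Parameters(N_b=1), ScenarioConfig())
        sd, sw = help_step(pop, params, rng)
        margin = 4 * math.sqrt(n * T * (1 - T))
        assert abs(sd[0] - n * T) < margin
        assert sd[0] + sw[0] == pytest.approx(n)


class TestSurvival:
    def test_floater_closed_form(self):
        pop = make_population(1, floaters=[(3, 0.0)])
        params, _ = validate_parameters(Parameters(N_b=1, m=0.1, x_0=1.5), ScenarioConfig())
        s = survival_probability(pop, params)
        assert s[0] == pytest.approx(0.9 / (1 + math.exp(-1.5)), abs=1e-12)

    def test_nonhelping_subordinate_without_group_benefit_equals_floater(self):
        pop = make_population(1, breeders=[0], subordinates=[(0, 2, 1.5)],
                              floaters=[(2, 1.5)])
        params, scen = validate_parameters(
            Parameters(N_b=1, x_n=3.0),
            ScenarioConfig(benefit_mode=BenefitMode.KS_ONLY))
        s = survival_probability(pop, params)  # x_n forced to 0, nobody defends
        assert s[1] == pytest.approx(s[2], abs=1e-12)

    def test_total_mortality_kills_everyone(self, rng):
        pop = make_population(2, breeders=[0, 1], floaters=[(1, 0.0)] * 5)
        params, _ = validate_parameters(Parameters(N_b=2, m=1.0), ScenarioConfig())
        survival_step(pop, params, rng)
        assert pop.n == 0

    def test_defense_cost_decreases_survival(self):
        pop = make_population(1, breeders=[0],
                              subordinates=[(0, 2, 0.5), (0, 2, 1.5)])
        pop.task[1:] = Task.DEFENSE
        params, _ = validate_parameters(Parameters(N_b=1, x_h=5.0), ScenarioConfig())
        s = survival_probability(pop, params)
        assert s[2] < s[1] < s[0]

    def test_group_size_benefit_saturates_below_one_minus_m(self):
        params, _ = validate_parameters(Parameters(N_b=1, m=0.2, x_n=3.0), ScenarioConfig())
        prev = 0.0
        for n_subs in (0, 1, 2, 5):
            pop = make_population(1, breeders=[0],
                                  subordinates=[(0, 2, 0.0)] * n_subs)
            s = survival_probability(pop, params)
            assert prev < s[0] < 1.0 - params.m
            prev = s[0]
        pop = make_population(1, breeders=[0], subordinates=[(0, 2, 0.0)] * 20)
        assert survival_probability(pop, params)[0] == pytest.approx(1.0 - params.m, abs=1e-6)


class TestVacancies:
    def test_bidder_sampling_mean_and_exclusivity(self, rng):
        N_f, N_b, f, n_vac = 10_000, 5_000, 2.0, 400
        sets = sample_bidders(n_vac, N_f, N_b, f, rng)
        counts = [len(s) for s in sets]
        assert np.mean(counts) == pytest.approx(f * N_f / N_b, rel=0.1)
        flat = np.concatenate(sets)
        assert len(np.unique(flat)) == len(flat)  # one bid per floater

    @pytest.mark.parametrize("N_f,f", [(0, 2.0), (50, 0.0)])
    def test_empty_candidate_sets(self, rng, N_f, f):
        sets = sample_bidders(10, N_f, 100, f, rng)
        assert all(len(s) == 0 for s in sets)

    def test_lottery_frequencies_proportional_to_dominance(self):
        """Candidates with R = (3, 1) win with probability (3/4, 1/4)."""
        wins = 0
        n_rep = 20_000
        params, _ = validate_parameters(Parameters(N_b=1, f=0.0, y_h=0.0), ScenarioConfig())
        for seed in range(n_rep):
            pop = make_population(1, subordinates=[(0, 3, 0.0), (0, 1, 0.0)])
            r = np.random.default_rng(seed)
            fill_vacancies(pop, params, r)
            winner = np.nonzero(pop.role == Role.BREEDER)[0][0]
            wins += int(pop.age[winner] == 3)
        assert wins / n_rep == pytest.approx(0.75, abs=4 * math.sqrt(0.1875 / n_rep))

    def test_single_candidate_wins(self, rng):
        pop = make_population(2, breeders=[1], subordinates=[(0, 4, 0.0)])
        params, _ = validate_parameters(Parameters(N_b=2, f=0.0), ScenarioConfig())
        fill_vacancies(pop, params, rng)
        assert pop.role[1] == Role.BREEDER
        assert pop.group[1] == 0

    def test_all_zero_dominance_uniform_lottery(self):
        """Helpers whose work cost zeroes dominance draw a uniform lottery."""
        wins = 0
        n_rep = 4_000
        params, _ = validate_parameters(Parameters(N_b=1, f=0.0, y_h=10.0), ScenarioConfig())
        for seed in range(n_rep):
            pop = make_population(1, subordinates=[(0, 1, 5.0), (0, 1, 9.0)])
            pop.task[:] = Task.WORK  # R = max(0, 1 - 10*H) = 0 for both
            r = np.random.default_rng(seed)
            fill_vacancies(pop, params, r)
            winner = np.nonzero(pop.role == Role.BREEDER)[0][0]
            wins += int(pop.genes[winner, ALPHA] == 5.0)
        assert wins / n_rep == pytest.approx(0.5, abs=4 * 0.5 / math.sqrt(n_rep))

    def test_no_candidates_leaves_vacancy(self, rng):
        pop = make_population(2, breeders=[1])
        params, _ = validate_parameters(Parameters(N_b=2, f=2.0), ScenarioConfig())
        fill_vacancies(pop, params, rng)
        assert pop.breeder_of()[0] == -1


class TestStepCycle:
    def test_safe_world_one_cycle_hand_trace(self):
        """m=0 and a huge survival intercept: every breeder lives, every
        newborn (absolute dispersal, no floater settlement) ends a floater."""
        params, scen = validate_parameters(
            Parameters(N_b=3, m=0.0, x_0=50.0, mu=0.0), ScenarioConfig())
        rng = np.random.default_rng(5)
        pop = init_population(params, rng)
        neutral0 = pop.genes[:, NEUTRAL].copy()
        step_cycle(pop, params, scen, rng)
        breeders = pop.role == Role.BREEDER
        assert breeders.sum() == 3
        assert np.array_equal(np.sort(pop.group[breeders]), np.arange(3))
        assert np.all(np.isin(pop.genes[breeders, NEUTRAL], neutral0))
        assert np.count_nonzero(pop.role == Role.SUBORDINATE) == 0
        assert pop.n - 3 == pop.n_floaters  # newborns all float
        assert np.all(pop.age[pop.role == Role.FLOATER] == 2)  # born age 1, then ascended

    def test_total_mortality_extinction(self, rng):
        params, scen = validate_parameters(Parameters(N_b=10, m=1.0), ScenarioConfig())
        pop = init_population(params, rng)
        step_cycle(pop, params, scen, rng)
        assert pop.n == 0

    def test_conservation_of_individuals(self, rng):
        """After each cycle the census equals this cycle's survivor tally."""
        params, scen = validate_parameters(
            Parameters(N_b=40, m=0.2, x_n=3.0), ScenarioConfig())
        pop = init_population(params, rng)
        for _ in range(30):
            tally = step_cycle(pop, params, scen, rng)
            assert pop.n == sum(tally.survived.values())
            # every individual in exactly one container
            floaters = pop.role == Role.FLOATER
            assert np.all(pop.group[floaters] == -1)
            assert np.all(pop.group[~floaters] >= 0)
            b = pop.group[pop.role == Role.BREEDER]
            assert len(np.unique(b)) == len(b)  # at most one breeder per territory


@pytest.mark.parametrize("benefit_mode", list(BenefitMode))
def test_engine_matches_per_individual_reference(benefit_mode):
    """The vectorized engine and the scalar reference engine produce
    bit-identical states from the same seed over several cycles."""
    params, scen = validate_parameters(
        Parameters(N_b=20, m=0.25, mu=0.2, sigma_mu=0.2),
        ScenarioConfig(benefit_mode=benefit_mode))
    r1, r2 = np.random.default_rng(3), np.random.default_rng(3)
    pop1, pop2 = init_population(params, r1), init_population(params, r2)
    start = np.random.default_rng(8)
    pop1.genes[:, ALPHA] = start.normal(0.5, 1.0, params.N_b)
    pop1.genes[:, BETA] = start.normal(0.5, 0.5, params.N_b)
    pop2.genes[:] = pop1.genes
    for _ in range(10):
        step_cycle(pop1, params, scen, r1)
        step_cycle_reference(pop2, params, scen, r2)
        assert pop1.n == pop2.n
        assert np.array_equal(pop1.genes, pop2.genes)
        assert np.array_equal(pop1.age, pop2.age)
        assert np.array_equal(pop1.role, pop2.role)
        assert np.array_equal(pop1.group, pop2.group)
        assert np.array_equal(pop1.task, pop2.task)
        assert np.array_equal(pop1.prev_sum_def, pop2.prev_sum_def)
        assert np.array_equal(pop1.prev_sum_work, pop2.prev_sum_work)
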