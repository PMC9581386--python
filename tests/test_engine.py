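import math

import numpy as np
import pytest
from scipy import stats

from crossfeed.engine import (
    BoundaryError,
    NoReactionError,
    execute_diffusion,
    execute_division,
    execute_excretion,
    execute_uptake,
    run_simulation,
    select_event,
    step,
    time_increment,
)
from crossfeed.model import (
    SPECIES_1,
    SPECIES_2,
    ColonyState,
    ModelParams,
    propensities,
)


class TestSelectEvent:
    def test_single_active_channel(self):
        k = np.array([2.0, 0, 0, 0, 0, 0, 0, 0])
        for r1 in (0.01, 0.5, 0.999):
            assert select_event(k, r1) == 1

    def test_boundary_inclusive_on_upper_edge(self):
        # k0*r1 = 1.0 <= k1 -> channel 1 via the printed "<="
        k = np.array([1.0, 1.0, 0, 0, 0, 0, 0, 0])
        assert select_event(k, 0.5) == 1

    def test_interior_point_picks_second(self):
        k = np.array([1.0, 1.0, 0, 0, 0, 0, 0, 0])
        assert select_event(k, 0.75) == 2

    def test_zero_propensity_channel_skipped(self):
        k = np.array([0.0, 0.0, 3.0, 0, 0, 0, 0, 0])
        assert select_event(k, 0.0001) == 3

    def test_all_zero_raises(self):
        with pytest.raises(NoReactionError):
            select_event(np.zeros(8), 0.5)

    def test_empirical_frequencies_match_propensities(self):
        # channel-selection oracle: chi-square over 1e5 draws
        k = np.array([3.0, 1.0, 0.0, 2.0, 0.5, 0.0, 5.0, 0.5])
        rng = np.random.default_rng(7)
        draws = rng.random(100_000)
        counts = np.zeros(8)
        for r1 in draws:
            counts[select_event(k, r1) - 1] += 1
        expected = k / k.sum() * len(draws)
        sel = expected > 0
        chi2 = stats.chisquare(counts[sel], expected[sel])
        assert chi2.pvalue > 0.01


class TestTimeIncrement:
    @pytest.mark.parametrize("r2,k0,expected", [
        (1.0, 5.0, 0.0),
        (math.exp(-1), 1.0, 1.0),
        (math.exp(-3), 2.0, 1.5),
    ])
    def test_closed_forms(self, r2, k0, expected):
        assert time_increment(k0, r2) == pytest.approx(expected)

    def test_invalid_k0(self):
        with pytest.raises(ValueError):
            time_increment(0.0, 0.5)

    def test_waiting_times_exponential(self):
        # KS oracle against Exponential(k0)
        k0 = 3.7
        rng = np.random.default_rng(11)
        dts = np.array([time_increment(k0, r2)
                        for r2 in rng.random(100_000)])
        ks = stats.kstest(dts, "expon", args=(0, 1 / k0))
        assert ks.pvalue > 0.01


def _state_with_cell(n=9, species=SPECIES_1, at=(4, 4)):
    state = ColonyState.empty(n)
    state.cell_grid[at] = species
    return state


class TestExecuteDivision:
    def test_blocked_cell_is_null_event(self, scripted_rng, default_params):
        state = _state_with_cell()
        state.nutrient_A[4, 4] = 100  # nutrient-rich: Monod accepts
        for dx, dy in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            state.cell_grid[4 + dx, 4 + dy] = SPECIES_2
        before = state.copy()
        out = execute_division(state, SPECIES_1,
                               scripted_rng(uniforms=[0.0], ints=[0]),
                               default_params)
        assert not out.executed
        assert state.cell_grid.tolist() == before.cell_grid.tolist()

    def test_scripted_acceptance_places_daughter(self, scripted_rng,
                                                 default_params):
        state = _state_with_cell()
        state.nutrient_A[4, 4] = 10 ** 6  # S >> K: acceptance prob ~ 1
        rng = scripted_rng(uniforms=[0.0], ints=[0, 0])
        out = execute_division(state, SPECIES_1, rng, default_params)
        assert out.executed
        assert state.rho1 == 2
        # daughter on the first in-lattice neighbour in scan order: (5, 4)
        assert state.cell_grid[5, 4] == SPECIES_1

    def test_zero_nutrient_always_null(self, scripted_rng, default_params):
        state = _state_with_cell()
        out = execute_division(state, SPECIES_1,
                               scripted_rng(uniforms=[0.0], ints=[0]),
                               default_params)
        assert not out.executed and state.rho1 == 1

    def test_choose_then_reject_rule(self, scripted_rng):
        p = ModelParams(division_site_rule="choose-then-reject",
                        lattice_size=21)
        state = _state_with_cell()
        state.nutrient_A[4, 4] = 10 ** 6
        state.cell_grid[5, 4] = SPECIES_2  # neighbour 0 occupied
        out = execute_division(state, SPECIES_1,
                               scripted_rng(uniforms=[0.0], ints=[0, 0]), p)
        assert not out.executed  # picked the occupied site, no re-draw


class TestExecuteExcretion:
    def test_species1_places_B_east(self, scripted_rng, default_params):
        state = _state_with_cell(at=(5, 5))
        out = execute_excretion(state, SPECIES_1,
                                scripted_rng(ints=[0, 0]), default_params)
        assert out.executed
        assert state.nutrient_B[6, 5] == 1 and state.n_B == 1
        assert state.n_A == 0

    def test_corner_cell_uses_in_lattice_neighbors(self, default_params):
        state = _state_with_cell(at=(0, 0))
        rng = np.random.default_rng(3)
        for _ in range(50):
            execute_excretion(state, SPECIES_1, rng, default_params)
        assert state.n_B == 50
        # only the two in-lattice neighbours receive molecules
        assert state.nutrient_B[1, 0] + state.nutrient_B[0, 1] == 50

    def test_uniform_quarter_frequencies(self, default_params):
        state = _state_with_cell(at=(4, 4))
        rng = np.random.default_rng(19)
        n = 10_000
        for _ in range(n):
            execute_excretion(state, SPECIES_1, rng, default_params)
        counts = [state.nutrient_B[5, 4], state.nutrient_B[3, 4],
                  state.nutrient_B[4, 5], state.nutrient_B[4, 3]]
        chi2 = stats.chisquare(counts)
        assert chi2.pvalue > 0.01


class TestExecuteUptake:
    def test_no_molecules_is_null(self, scripted_rng, default_params):
        state = _state_with_cell()
        out = execute_uptake(state, SPECIES_1, scripted_rng(ints=[0]),
                             default_params)
        assert not out.executed

    def test_forced_choice_single_site(self, scripted_rng, default_params):
        state = _state_with_cell(at=(4, 4))
        state.nutrient_A[5, 4] = 3
        out = execute_uptake(state, SPECIES_1,
                             scripted_rng(uniforms=[0.0, 0.0], ints=[0]),
                             default_params)
        assert out.executed
        assert state.nutrient_A[5, 4] == 2 and state.n_A == 2

    def test_own_site_molecules_not_taken(self, scripted_rng, default_params):
        # uptake neighbourhood is the 4 n.n. only
        state = _state_with_cell(at=(4, 4))
        state.nutrient_A[4, 4] = 5
        out = execute_uptake(state, SPECIES_1,
                             scripted_rng(uniforms=[0.0, 0.0], ints=[0]),
                             default_params)
        assert not out.executed and state.n_A == 5

    def test_count_proportional_site_choice(self, default_params):
        taken = {(5, 4): 0, (3, 4): 0}
        rng = np.random.default_rng(23)
        n = 4000
        for _ in range(n):
            state = _state_with_cell(at=(4, 4))
            state.nutrient_A[5, 4] = 3
            state.nutrient_A[3, 4] = 1
            out = execute_uptake(state, SPECIES_1, rng, default_params)
            if out.executed:
                taken[out.details["removed"]] += 1
        total = sum(taken.values())
        assert taken[(5, 4)] / total == pytest.approx(0.75, abs=0.03)


class TestExecuteDiffusion:
    def test_conservation(self, default_params, rng):
        state = ColonyState.empty(9)
        state.nutrient_A[4, 4] = 10
        for _ in range(200):
            execute_diffusion(state, "A", rng, default_params)
            assert state.n_A == 10

    def test_interior_destinations_uniform(self, default_params):
        counts = {}
        rng = np.random.default_rng(5)
        for _ in range(8000):
            state = ColonyState.empty(9)
            state.nutrient_A[4, 4] = 1
            out = execute_diffusion(state, "A", rng, default_params)
            counts[out.details["moved_to"]] = \
                counts.get(out.details["moved_to"], 0) + 1
        chi2 = stats.chisquare(list(counts.values()))
        assert len(counts) == 4 and chi2.pvalue > 0.01

    def test_reflection_at_boundary(self, scripted_rng, default_params):
        state = ColonyState.empty(9)
        state.nutrient_A[0, 0] = 1
        out = execute_diffusion(state, "A", scripted_rng(ints=[0, 1]),
                                default_params)
        assert not out.executed
        assert state.nutrient_A[0, 0] == 1


class TestThinningExactness:
    def test_realized_division_rate_matches_monod(self):
        # frozen nutrient field on a 3x3 lattice: the time to the first
        # executed division must be Exponential(lambda* . S/(S+K))
        p = ModelParams(gamma_A=0.0, gamma_B=0.0, D_A=0.0, D_B=0.0,
                        Y_A=1e12, Y_B=1e12, lattice_size=3, L0=3, rho0=2 / 9)
        proto = ColonyState.empty(3)
        proto.cell_grid[1, 1] = SPECIES_1
        proto.nutrient_A[1, 1] = 2
        proto.nutrient_A[0, 1] = 1  # S = 3 -> rate = 1 * 3/4
        rate = 0.75
        rng = np.random.default_rng(7)
        times = []
        for _ in range(1500):
            state = proto.copy()
            while True:
                out = step(state, p, rng)
                if out.channel in (1, 4) and out.executed:
                    times.append(state.t)
                    break
        ks = stats.kstest(times, "expon", args=(0, 1 / rate))
        assert ks.pvalue > 0.01


class TestRunSimulation:
    def test_determinism(self):
        p = ModelParams(T_max=3.0, preseed_A=2, preseed_B=2,
                        lattice_size=41, seed=9)
        t1 = run_simulation(p, sample_interval=0.5)
        t2 = run_simulation(p, sample_interval=0.5)
        assert np.array_equal(t1.samples.rho1, t2.samples.rho1)
        assert np.array_equal(t1.samples.radius, t2.samples.radius)
        assert np.array_equal(t1.event_counts, t2.event_counts)

    def test_monotone_populations_and_time(self):
        p = ModelParams(T_max=4.0, preseed_A=3, preseed_B=3,
                        lattice_size=41, seed=2)
        traj = run_simulation(p, sample_interval=0.25)
        traj.samples.validate()

    def test_diffusion_only_keeps_populations_constant(self):
        p = ModelParams(lambda_max_1=0.0, lambda_max_2=0.0,
                        gamma_A=0.0, gamma_B=0.0, preseed_A=2, preseed_B=2,
                        T_max=2.0, lattice_size=31, seed=4)
        traj = run_simulation(p, sample_interval=0.5)
        assert np.all(traj.samples.rho1 == traj.samples.rho1[0])
        assert np.all(traj.samples.rho2 == traj.samples.rho2[0])
        assert np.all(traj.samples.nA == traj.samples.nA[0])

    def test_nutrient_conservation_bookkeeping(self):
        # nA changes only via excretion by species 2 and uptake by species 1
        p = ModelParams(T_max=3.0, lattice_size=41, seed=12)
        traj = run_simulation(p, sample_interval=1.0)
        ev = traj.event_counts
        nA_expected = ev[4, 0] - ev[2, 0]   # excrete_A minus uptake_A
        nB_expected = ev[1, 0] - ev[5, 0]
        assert traj.samples.nA[-1] == nA_expected
        assert traj.samples.nB[-1] == nB_expected

    def test_stasis_when_all_rates_zero(self):
        p = ModelParams(lambda_max_1=0.0, lambda_max_2=0.0,
                        gamma_A=0.0, gamma_B=0.0, D_A=0.0, D_B=0.0,
                        T_max=1.0, lattice_size=31, seed=1)
        with pytest.warns(RuntimeWarning):
            traj = run_simulation(p, sample_interval=0.5)
        assert traj.stasis

    def test_boundary_abort(self):
        p = ModelParams(T_max=50.0, preseed_A=50, preseed_B=50,
                        lattice_size=26, L0=20, seed=3)
        with pytest.raises(BoundaryError):
            run_simulation(p, sample_interval=1.0)

    def test_label_swap_symmetric_distributions(self):
        finals1, finals2 = [], []
        for seed in range(20):
            p = ModelParams(T_max=4.0, preseed_A=4, preseed_B=4, L0=10,
                            rho0=0.2, lattice_size=41, seed=seed)
            traj = run_simulation(p, sample_interval=4.0)
            finals1.append(traj.samples.rho1[-1])
            finals2.append(traj.samples.rho2[-1])
        res = stats.mannwhitneyu(finals1, finals2)
        assert res.pvalue > 0.01

    def test_kernel_matches_python_reference_stepper(self):
        # same model, two independent implementations: compare mean growth
        p = ModelParams(T_max=1.5, preseed_A=3, preseed_B=3, L0=6, rho0=0.5,
                        lattice_size=15, seed=0)
        from crossfeed.scenarios import initial_state
        py_finals = []
        for seed in range(12):
            rng = np.random.default_rng(1000 + seed)
            state = initial_state(p.replace(seed=seed), rng=rng)
            while state.t < p.T_max:
                step(state, p, rng)
            py_finals.append(state.rho1 + state.rho2)
        km_finals = []
        for seed in range(24):
            traj = run_simulation(p.replace(seed=seed), sample_interval=1.5)
            km_finals.append(traj.samples.rho1[-1] + traj.samples.rho2[-1])
        res = stats.mannwhitneyu(py_finals, km_finals)
        assert res.pvalue > 0.01
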