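"""Birth-death core: initialization, seed arrival, lottery, mortality."""

import numpy as np
import pytest

from fragkern.engine import (DemographyParams, SimulationState,
                             init_population, lottery_draw, mortality_all,
                             mortality_of, seed_arrival, step)
from fragkern.geometry import N_CLASSES, RingGeometry
from fragkern.kernels import MutationParams, preset_kernel
from fragkern.landscape import (FragmentationParams, FragmentationSchedule,
                                LandscapeParams, build_schedule,
                                generate_susceptibility)
from fragkern.recorder import Recorder


def empty_schedule(L):
    e = np.empty(0, dtype=np.int64)
    return FragmentationSchedule(e, e.copy(), L)


def fresh_state(L=8, kernel="uniform", seed=0, habitable=None):
    rings = RingGeometry.for_side(L)
    if habitable is None:
        habitable = np.ones(rings.n_cells, dtype=bool)
    return init_population(habitable, preset_kernel(kernel),
                           DemographyParams(), np.random.default_rng(seed),
                           rings=rings)


class TestInitPopulation:
    def test_every_habitable_cell_occupied(self):
        state = fresh_state(L=32)
        assert state.n_individuals == 1024
        assert state.n_habitable == 1024
        np.testing.assert_array_equal(state.occupied, state.habitable)

    def test_shared_initial_kernel(self):
        state = fresh_state(L=8, kernel="bimodal")
        for cell in state.occupied_cells():
            np.testing.assert_array_equal(state.kernels[cell],
                                          preset_kernel("bimodal"))

    def test_age_and_lifespan_distributions(self):
        # pool draws across many small initializations: integer ages
        # uniform on 1..125, lifespans ~ Normal(100, 5)
        ages, spans = [], []
        for s in range(100):
            st = fresh_state(L=8, seed=s)
            cells = st.occupied_cells()
            ages.extend(st.age[cells].tolist())
            spans.extend(st.lifespan[cells].tolist())
        ages, spans = np.asarray(ages), np.asarray(spans)
        assert ages.min() >= 1 and ages.max() <= 125
        assert np.all(ages == ages.astype(int))
        assert abs(spans.mean() - 100.0) < 3 * 5 / np.sqrt(len(spans))
        assert abs(ages.mean() - 63.0) < 3 * 36 / np.sqrt(len(ages))


class TestSeedArrival:
    def test_sole_nondispersing_occupant_weight_one(self):
        # only one individual, on the focal cell itself, with d_0 = 1
        rings = RingGeometry.for_side(8)
        habitable = np.zeros(64, dtype=bool)
        habitable[10] = True
        state = fresh_state(L=8, kernel="non_dispersal", habitable=habitable)
        w = seed_arrival(state, 10)
        assert w.shape == (1,)
        assert w[0] == pytest.approx(1.0)

    def test_uniform_weights_follow_ring_sizes(self, rings32):
        state = fresh_state(L=32, kernel="uniform")
        cell = 0
        pool = state.occupied_cells()
        w = seed_arrival(state, cell, pool)
        cls = rings32.pair_classes[pool, cell]
        g = rings32.ring_counts
        for k in (0, 1, 100, 500):
            i = cls[k]
            expected = (1 / 15) / g[i] if i <= 14 else 0.0
            assert w[k] == pytest.approx(expected)
        # individuals beyond class 14 contribute nothing
        assert np.all(w[cls > 14] == 0)
        assert np.any(cls > 14)

    def test_all_zero_arrival_is_valid(self):
        # lone long-distance disperser cannot seed its own cell
        habitable = np.zeros(64, dtype=bool)
        habitable[0] = True
        state = fresh_state(L=8, kernel="long_distance", habitable=habitable)
        w = seed_arrival(state, 0)
        assert np.all(w == 0)


class TestLottery:
    def test_frequencies_match_brute_force_weights_4x4(self):
        # 4x4 torus fixture: recruitment frequencies over 1e5 draws match
        # the normalized seed-arrival weights within 3 binomial sigma
        state = fresh_state(L=4, kernel="uniform", seed=3)
        rng = np.random.default_rng(12)
        # individualize kernels so weights differ between pool members
        for cell in state.occupied_cells():
            state.kernels[cell] = rng.dirichlet(np.ones(N_CLASSES))
        pool = state.occupied_cells()
        w = seed_arrival(state, 5, pool)
        p = w / w.sum()
        n_draw = 100_000
        counts = np.zeros(pool.size)
        for _ in range(n_draw):
            counts[lottery_draw(w, rng)] += 1
        sigma = np.sqrt(n_draw * p * (1 - p))
        assert np.all(np.abs(counts - n_draw * p) <= 3 * sigma + 1)

    def test_zero_total_weight_returns_sentinel(self):
        assert lottery_draw(np.zeros(5), np.random.default_rng(0)) == -1


class TestMortality:
    def test_zero_on_fully_habitable_landscape(self):
        # L >= 20 so every kernel class has cells to land on
        state = fresh_state(L=20, kernel="uniform", seed=4)
        assert np.all(mortality_all(state) == 0)
        assert mortality_of(state, 0) == 0.0

    def test_half_of_ring_one_lost(self):
        # kernel d_1 = 1 and exactly 4 of the 8 ring-1 cells uninhabitable
        rings = RingGeometry.for_side(8)
        state = fresh_state(L=8, kernel="uniform", seed=5)
        focal = 9  # (1, 1)
        ring1 = np.nonzero(rings.pair_classes[:, focal] == 1)[0]
        state.make_uninhabitable(ring1[:4])
        d = np.zeros(N_CLASSES)
        d[1] = 1.0
        assert mortality_of(state, focal, kernel=d) == pytest.approx(0.5)

    def test_non_dispersal_never_dies(self):
        state = fresh_state(L=8, kernel="non_dispersal", seed=6)
        state.make_uninhabitable(np.arange(32))
        focal = int(state.occupied_cells()[0])
        assert mortality_of(state, focal) == 0.0

    def test_empty_class_mass_is_lost(self):
        # L=16 has no cells at classes 12..14; a kernel massing them loses
        # those seeds even on a fully habitable landscape
        state = fresh_state(L=16, kernel="uniform", seed=7)
        focal = int(state.occupied_cells()[0])
        assert mortality_of(state, focal) == pytest.approx(3 / 15)


class TestStep:
    def test_quiet_step_only_ages(self):
        state = fresh_state(L=8, seed=8)
        state.age[state.occupied] = 1  # nobody near death
        ages_before = state.age.copy()
        kernels_before = state.kernels.copy()
        step(state, empty_schedule(8), MutationParams(mu=0.0),
             DemographyParams())
        np.testing.assert_array_equal(state.age[state.occupied],
                                      ages_before[state.occupied] + 1)
        np.testing.assert_array_equal(state.kernels, kernels_before)
        assert state.t == 1

    def test_occupied_subset_habitable_through_fuzz_run(self):
        # 2,000-step fuzz with ongoing fragmentation and mutation
        L = 8
        rng_land = np.random.default_rng(9)
        fld = generate_susceptibility(LandscapeParams(L, 0.2, seed=rng_land))
        sch = build_schedule(fld, FragmentationParams(0.20, 1500))
        state = fresh_state(L=L, kernel="uniform", seed=10)
        mut = MutationParams(mu=2 / 15)
        demo = DemographyParams()
        for t in range(1, 2001):
            step(state, sch, mut, demo)
            assert not np.any(state.occupied & ~state.habitable)
            assert state.n_habitable == 64 - sch.cumulative_events(t)
            occ = state.occupied_cells()
            if occ.size:
                sums = state.kernels[occ].sum(axis=1)
                np.testing.assert_allclose(sums, 1.0, atol=1e-9)

    def test_parent_can_be_replaced_by_own_offspring(self):
        # a lone non-dispersing individual dying this step reseeds itself
        habitable = np.zeros(64, dtype=bool)
        habitable[20] = True
        state = fresh_state(L=8, kernel="non_dispersal", habitable=habitable)
        state.age[20] = 200  # will exceed its lifespan on the next step
        step(state, empty_schedule(8), MutationParams(mu=0.0),
             DemographyParams())
        assert state.occupied[20]
        assert state.age[20] == 0

    def test_fragmentation_kills_without_replacement(self):
        # instantaneous loss of all but one cell, occupant non-dispersing:
        # lost occupants die immediately and are not replaced
        L = 8
        fld = generate_susceptibility(LandscapeParams(L, 0.2, seed=11))
        sch = build_schedule(
            fld, FragmentationParams(1 / 64, 1, "instantaneous"))
        state = fresh_state(L=L, kernel="non_dispersal", seed=12)
        step(state, sch, MutationParams(mu=0.0), DemographyParams())
        assert state.n_habitable == 1
        assert state.n_individuals <= 1

    def test_recruitment_probabilities_three_cell_fixture(self):
        # three habitable cells on an 8-torus; the middle occupant dies and
        # the replacement lottery must match hand-computed weights
        L = 8
        rings = RingGeometry.for_side(L)
        cells = [0, 1, 3]  # offsets: classes to cell 1 are 1, 0, 2
        habitable = np.zeros(64, dtype=bool)
        habitable[cells] = True
        d_a = np.zeros(N_CLASSES); d_a[1] = 1.0          # only class 1
        d_b = np.zeros(N_CLASSES); d_b[0] = 0.5; d_b[2] = 0.5
        d_c = np.zeros(N_CLASSES); d_c[2] = 1.0
        g = rings.ring_counts
        # weights for vacancy at cell 1: a at class 1, b itself, c at class 2
        expect = np.array([1.0 / g[1], 0.5 / g[0], 1.0 / g[2]])
        wins = np.zeros(3)
        n_trials = 20_000
        state = SimulationState(rings, habitable, np.random.default_rng(0))
        for trial in range(n_trials):
            state.rng = np.random.default_rng(1000 + trial)
            state.t = 0
            for cell, d in zip(cells, (d_a, d_b, d_c)):
                state.occupied[cell] = True
                state.age[cell] = 1
                state.lifespan[cell] = 100.0
                state.kernels[cell] = d
            state.age[1] = 200  # dies of age this step
            step(state, empty_schedule(L), MutationParams(mu=0.0),
                 DemographyParams())
            assert state.occupied[1]
            winner = np.nonzero([
                np.array_equal(state.kernels[1], d) for d in (d_a, d_b, d_c)
            ])[0][0]
            wins[winner] += 1
        p = expect / expect.sum()
        sigma = np.sqrt(n_trials * p * (1 - p))
        assert np.all(np.abs(wins - n_trials * p) <= 4 * sigma)

    def test_constant_mean_kernel_without_mutation_or_fragmentation(self):
        state = fresh_state(L=20, kernel="bimodal", seed=13)
        rec = Recorder(every=100)
        for _ in range(1500):
            step(state, empty_schedule(20), MutationParams(mu=0.0),
                 DemographyParams(), rec)
        km = rec.record.kernel_matrix()
        np.testing.assert_allclose(
            km, np.tile(preset_kernel("bimodal"), (len(rec.record), 1)),
            atol=1e-12)
        np.testing.assert_array_equal(rec.record.mortality_mean,
                                      np.zeros(len(rec.record)))

    def test_extinction_flagged(self):
        # a lone long-distance disperser on one habitable cell cannot
        # reseed itself; the replicate halts with the extinct flag
        habitable = np.zeros(64, dtype=bool)
        habitable[0] = True
        state = fresh_state(L=8, kernel="long_distance", habitable=habitable)
        state.age[0] = 300
        step(state, empty_schedule(8), MutationParams(mu=0.0),
             DemographyParams())
        assert state.extinct
        assert state.n_individuals == 0

    def test_vacancy_with_no_arrivals_is_retried_later(self):
        # adjacent cells 0 and 1: the occupant of 0 dies while its
        # neighbour disperses only to class 2, so no seed reaches the
        # vacancy and it persists; once the neighbour's kernel gains
        # class-1 mass, the carried-over vacancy is filled on the next step
        habitable = np.zeros(64, dtype=bool)
        habitable[[0, 1]] = True
        rings = RingGeometry.for_side(8)
        state = SimulationState(rings, habitable, np.random.default_rng(14))
        d2 = np.zeros(N_CLASSES); d2[2] = 1.0
        for cell in (0, 1):
            state.occupied[cell] = True
            state.age[cell] = 1
            state.lifespan[cell] = 100.0
            state.kernels[cell] = d2
        state.age[0] = 200
        step(state, empty_schedule(8), MutationParams(mu=0.0),
             DemographyParams())
        assert not state.occupied[0] and state.habitable[0]
        assert state.occupied[1]
        d1 = np.zeros(N_CLASSES); d1[1] = 1.0
        state.kernels[1] = d1
        step(state, empty_schedule(8), MutationParams(mu=0.0),
             DemographyParams())
        assert state.occupied[0]
        np.testing.assert_array_equal(state.kernels[0], d1)
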