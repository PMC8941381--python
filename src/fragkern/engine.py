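"""Birth-death, dispersal and lottery recruitment on the torus lattice.

Every habitable cell holds at most one individual.  Each individual has an
age, a lifespan drawn from Normal(100, 5) (time-steps; one hundredth of a
life expectancy each), and a dispersal kernel.  One time-step applies, in
order:

1. the fragmentation schedule's habitat-loss events for this step —
   occupants of lost cells die without replacement;
2. ageing: every age increments, and individuals whose age reaches their
   lifespan die of age;
3. the seed pool is frozen: every individual alive at the start of the
   ageing sub-step whose cell is still habitable contributes seeds, so a
   parent dying this step can be replaced by its own offspring;
4. every vacant habitable cell computes its seed-arrival distribution
   S (weight s_k = d_{i_k} / g_{i_k} for each pool member k at distance
   class i_k) and, if any seed arrives, recruits one parent by lottery;
   the recruit starts at age 0 with a fresh lifespan and a mutated copy
   of the parent's kernel.  Cells where no seed arrives stay vacant and
   are retried every subsequent step;
5. the recorder observes the new state and the clock advances.

The only cost of dispersal is emergent: seeds landing on uninhabitable
cells (or assigned to distance classes with no cells, possible only on
tori smaller than 20 a side) are lost, which ``mortality_of`` quantifies
per individual.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import MAX_CLASS, N_CLASSES, RingGeometry
from .kernels import MutationParams, mutate_batch
from .landscape import FragmentationSchedule

__all__ = [
    "DemographyParams",
    "SimulationState",
    "init_population",
    "seed_arrival",
    "lottery_draw",
    "step",
    "mortality_of",
    "mortality_all",
]


@dataclass(frozen=True)
class DemographyParams:
    """Lifespan and initial-age distributions (units: time-steps)."""

    lifespan_mean: float = 100.0
    lifespan_sd: float = 5.0
    init_age_min: int = 1
    init_age_max: int = 125

    def __post_init__(self):
        if self.lifespan_mean <= 0:
            raise ValueError("lifespan_mean must be positive")
        if self.lifespan_sd < 0:
            raise ValueError("lifespan_sd must be non-negative")

    def draw_lifespans(self, n: int, rng) -> np.ndarray:
        draws = rng.normal(self.lifespan_mean, self.lifespan_sd, size=n)
        return np.maximum(draws, 1.0)  # truncated below at one step


class SimulationState:
    """Mutable state of one replicate, stored as flat per-cell arrays.

    Attributes
    ----------
    t : int
        Current time-step (0 before the first step).
    habitable, occupied : bool arrays of length L*L
    age : int array; lifespan : float array (meaningful where occupied)
    kernels : (L*L, 15) float array of occupants' dispersal kernels
    lost_counts : (L*L, 15) float array
        Per focal cell, the number of *uninhabitable* cells in each of its
        distance rings; maintained incrementally as cells are lost.
    rng : numpy Generator driving all demographic/mutational randomness.
    """

    def __init__(self, rings: RingGeometry, habitable: np.ndarray,
                 rng: np.random.Generator):
        n = rings.n_cells
        habitable = np.asarray(habitable, dtype=bool).ravel()
        if habitable.size != n:
            raise ValueError("habitability mask does not match the torus size")
        self.rings = rings
        self.t = 0
        self.habitable = habitable.copy()
        self.occupied = np.zeros(n, dtype=bool)
        self.age = np.zeros(n, dtype=np.int64)
        self.lifespan = np.zeros(n, dtype=float)
        self.kernels = np.zeros((n, N_CLASSES))
        self.rng = rng
        self.lost_counts = np.zeros((n, N_CLASSES))
        lost = np.nonzero(~self.habitable)[0]
        for cell in lost:
            self._register_loss(cell)
        self.extinct = False

    # -- derived views ----------------------------------------------------
    @property
    def n_habitable(self) -> int:
        return int(self.habitable.sum())

    @property
    def n_individuals(self) -> int:
        return int(self.occupied.sum())

    def occupied_cells(self) -> np.ndarray:
        return np.nonzero(self.occupied)[0]

    def mean_kernel(self) -> np.ndarray:
        occ = self.occupied
        if not occ.any():
            return np.full(N_CLASSES, np.nan)
        return self.kernels[occ].mean(axis=0)

    # -- internals --------------------------------------------------------
    def _register_loss(self, cell: int) -> None:
        """Update every focal cell's uninhabitable-ring counts for one loss."""
        cls = self.rings.pair_classes[:, cell]
        in_range = cls <= MAX_CLASS
        rows = np.nonzero(in_range)[0]
        self.lost_counts[rows, cls[rows]] += 1.0

    def make_uninhabitable(self, cells: np.ndarray) -> None:
        for cell in np.atleast_1d(cells):
            if self.habitable[cell]:
                self.habitable[cell] = False
                self.occupied[cell] = False
                self._register_loss(int(cell))


def init_population(habitable: np.ndarray, initial_kernel: np.ndarray,
                    demography: DemographyParams, rng,
                    rings: RingGeometry | None = None) -> SimulationState:
    """Fill every habitable cell with an individual of the shared kernel.

    Ages are integers drawn uniformly on {init_age_min, ..., init_age_max}
    (default 1..125), so the initial population is demographically
    heterogeneous; lifespans are fresh Normal(100, 5) draws.
    """
    habitable = np.asarray(habitable, dtype=bool)
    if rings is None:
        L = int(np.sqrt(habitable.size))
        rings = RingGeometry.for_side(L)
    state = SimulationState(rings, habitable, rng)
    cells = np.nonzero(state.habitable)[0]
    n = cells.size
    state.occupied[cells] = True
    state.age[cells] = rng.integers(demography.init_age_min,
                                    demography.init_age_max + 1, size=n)
    state.lifespan[cells] = demography.draw_lifespans(n, rng)
    state.kernels[cells] = np.asarray(initial_kernel, dtype=float)
    return state


def seed_arrival(state: SimulationState, cell: int,
                 pool_cells: np.ndarray | None = None) -> np.ndarray:
    """Seed-arrival weights s_k = d_{i_k} / g_{i_k} for one vacant cell.

    ``pool_cells`` defaults to the currently occupied cells; during a step
    the engine passes the frozen per-step pool instead.  Pool members
    beyond distance class 14, or at classes with no cells, contribute 0.
    An all-zero vector is a valid result (the vacancy stays empty).
    """
    if pool_cells is None:
        pool_cells = state.occupied_cells()
    cls = state.rings.pair_classes[pool_cells, cell].astype(np.int64)
    g = state.rings.ring_counts
    in_range = cls <= MAX_CLASS
    safe_cls = np.where(in_range, cls, 0)
    g_at = g[safe_cls]
    ok = in_range & (g_at > 0)
    weights = np.where(
        ok,
        state.kernels[pool_cells, safe_cls] / np.where(g_at > 0, g_at, 1),
        0.0,
    )
    return weights


def lottery_draw(weights: np.ndarray, rng) -> int:
    """Sample one index with probability proportional to its weight.

    Returns -1 when the total weight is zero (no seed arrives).
    """
    total = weights.sum()
    if total <= 0.0:
        return -1
    cum = np.cumsum(weights)
    u = rng.random() * cum[-1]
    return int(np.searchsorted(cum, u, side="right"))


def step(state: SimulationState, schedule: FragmentationSchedule,
         mutation: MutationParams, demography: DemographyParams,
         recorder=None) -> SimulationState:
    """Advance the state by one time-step (see module docstring for order)."""
    t = state.t + 1

    # (1) habitat loss scheduled for this step
    lost = schedule.events_at(t)
    if lost.size:
        state.make_uninhabitable(lost)

    # (2) ageing and deaths of age
    occ = state.occupied
    state.age[occ] += 1
    pool_cells = np.nonzero(occ)[0]  # alive at start of ageing, still habitable
    dying = pool_cells[state.age[pool_cells] >= state.lifespan[pool_cells]]
    state.occupied[dying] = False

    # (3)+(4) lottery recruitment into every vacant habitable cell,
    # from the common pre-replacement pool
    vacant = np.nonzero(state.habitable & ~state.occupied)[0]
    if vacant.size and pool_cells.size:
        pool_kernels = state.kernels[pool_cells]
        g = state.rings.ring_counts
        recruits = []
        parents = []
        for cell in vacant:
            cls = state.rings.pair_classes[pool_cells, cell].astype(np.int64)
            in_range = cls <= MAX_CLASS
            safe_cls = np.where(in_range, cls, 0)
            g_at = g[safe_cls]
            ok = in_range & (g_at > 0)
            w = np.where(ok,
                         pool_kernels[np.arange(pool_cells.size), safe_cls]
                         / np.where(g_at > 0, g_at, 1),
                         0.0)
            k = lottery_draw(w, state.rng)
            if k >= 0:
                recruits.append(cell)
                parents.append(k)
        if recruits:
            rcells = np.asarray(recruits)
            offspring = mutate_batch(pool_kernels[parents], mutation, state.rng)
            state.occupied[rcells] = True
            state.age[rcells] = 0
            state.lifespan[rcells] = demography.draw_lifespans(
                len(recruits), state.rng)
            state.kernels[rcells] = offspring

    if not state.occupied.any():
        state.extinct = True

    state.t = t
    if recorder is not None:
        recorder.observe(state)
    return state


def mortality_of(state: SimulationState, cell: int,
                 kernel: np.ndarray | None = None) -> float:
    """Dispersal-related seed mortality of the individual at ``cell``.

    The proportion of its seeds landing on uninhabitable cells:
    sum_i (d_i / g_i) * u_i with u_i the number of uninhabitable cells in
    ring i.  Classes with g_i = 0 (only on tori with L < 20) lose their
    entire mass d_i.  The focal cell itself is habitable, so d_0 never
    contributes.
    """
    if kernel is None:
        kernel = state.kernels[cell]
    g = state.rings.ring_counts
    u = state.lost_counts[cell]
    frac_lost = np.divide(u, g, out=np.ones(N_CLASSES), where=g > 0)
    return float(kernel @ frac_lost)


def mortality_all(state: SimulationState) -> np.ndarray:
    """Vector of seed mortalities, one per living individual."""
    cells = state.occupied_cells()
    g = state.rings.ring_counts
    frac_lost = np.divide(state.lost_counts[cells], g,
                          out=np.ones((cells.size, N_CLASSES)), where=g > 0)
    return np.einsum("ij,ij->i", state.kernels[cells], frac_lost)
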