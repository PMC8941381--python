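"""Dispersal kernels and their mutation operators.

A dispersal kernel is a discrete distribution d = (d_0, ..., d_14) giving
the proportion of an individual's seeds dispersing to each distance class;
d_0 is the non-dispersed fraction.  Each single cell at class i receives
the per-cell share e_i = d_i / g_i, where g_i is the ring size at class i.

Two mutation operators turn a parent kernel into an offspring kernel:

* ``mutate_continuous`` — the polygenic-trait proxy.  A mutation event at
  class i shifts probability mass between d_i and an adjacent class
  d_{i-1} or d_{i+1}, so the kernel can only drift gradually through
  phenotype space (an individual dispersing at most to class 10 can gain
  class 11 in one generation, but not class 14).
* ``mutate_unconstrained`` — the large-effect-locus proxy.  Each class is
  perturbed independently, so mass can appear at any distance class in a
  single generation.

Both use the same per-class mutation probability ``mu`` and maximal
effect size ``m``, and both renormalize the offspring kernel to sum to 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import N_CLASSES, RingGeometry

__all__ = [
    "MutationParams",
    "preset_kernel",
    "validate_kernel",
    "per_cell_share",
    "mutate_continuous",
    "mutate_unconstrained",
    "mutate_batch",
    "PRESET_NAMES",
]

PRESET_NAMES = ("non_dispersal", "uniform", "long_distance", "bimodal")

#: Tolerance on the sum-to-one invariant.
NORMALIZATION_TOL = 1e-9


@dataclass(frozen=True)
class MutationParams:
    """Mutation model parameters.

    mu
        Per-distance-class mutation probability.  The default 2/15 means
        two classes mutate per reproduction event on average.
    m
        Maximal mutation magnitude; each event's realized magnitude m' is
        uniform on the open interval (-m, m).
    model
        ``continuous`` (adjacent-class shifting) or ``unconstrained``
        (independent per-class perturbation).
    """

    mu: float = 2.0 / N_CLASSES
    m: float = 0.5
    model: str = "continuous"

    def __post_init__(self):
        if not (0.0 <= self.mu <= 1.0):
            raise ValueError(f"mu must lie in [0, 1], got {self.mu}")
        if self.m <= 0:
            raise ValueError(f"m must be positive, got {self.m}")
        if self.model not in ("continuous", "unconstrained"):
            raise ValueError(f"unknown mutation model {self.model!r}")


def preset_kernel(name: str) -> np.ndarray:
    """One of the four initial dispersal strategies.

    non_dispersal: all seeds stay in the parent cell (d_0 = 1).
    uniform: equal mass on every class (d_i = 1/15).
    long_distance: all seeds to the maximal class (d_14 = 1).
    bimodal: mass split between d_0 and d_14 (1/2 each).
    """
    d = np.zeros(N_CLASSES)
    if name == "non_dispersal":
        d[0] = 1.0
    elif name == "uniform":
        d[:] = 1.0 / N_CLASSES
    elif name == "long_distance":
        d[-1] = 1.0
    elif name == "bimodal":
        d[0] = d[-1] = 0.5
    else:
        raise ValueError(
            f"unknown kernel preset {name!r}; expected one of {PRESET_NAMES}")
    return d


def validate_kernel(d: np.ndarray) -> np.ndarray:
    """Check non-negativity and normalization; return as float array."""
    d = np.asarray(d, dtype=float)
    if d.shape != (N_CLASSES,):
        raise ValueError(f"kernel must have {N_CLASSES} entries, got {d.shape}")
    if np.any(d < 0):
        raise ValueError("kernel entries must be non-negative")
    if abs(d.sum() - 1.0) > NORMALIZATION_TOL:
        raise ValueError(f"kernel must sum to 1, got {d.sum()!r}")
    return d


def per_cell_share(kernel: np.ndarray, rings: RingGeometry) -> np.ndarray:
    """Per-cell seed share e_i = d_i / g_i for each distance class.

    On tori too small to realize every class (L < 20) the empty classes
    have g_i = 0; their share is reported as 0 — the corresponding seed
    mass reaches no cell and is lost (see ``engine.mortality_of``).
    """
    g = rings.ring_counts
    return np.divide(kernel, g, out=np.zeros(N_CLASSES), where=g > 0)


def _draw_events(n: int, params: MutationParams, rng) -> tuple:
    """Draw all per-class randomness for n kernels at once.

    Returns (mutates, upper, magnitudes), each shaped (n, N_CLASSES):
    whether each class mutates, whether the adjacent target is i+1
    (continuous model only), and the realized magnitude m'.
    """
    mutates = rng.random((n, N_CLASSES)) < params.mu
    upper = rng.random((n, N_CLASSES)) < 0.5
    magnitudes = rng.uniform(-params.m, params.m, size=(n, N_CLASSES))
    return mutates, upper, magnitudes


def mutate_batch(kernels: np.ndarray, params: MutationParams, rng,
                 with_events: bool = False) -> np.ndarray:
    """Mutate a (n, 15) batch of parent kernels row-independently.

    Continuous model, per row: classes are processed in increasing index
    order on a working copy.  A mutating class i picks i' = i-1 or i+1
    equiprobably (trials falling outside 0..14 are consumed with no
    effect) and draws m' uniform on (-m, m); m' is then added to entry i
    and subtracted from entry i', with the realized transfer bounded by
    the donating entry's mass so that both entries stay in [0, 1].  The
    bound keeps the operator strictly local: probability mass can only
    *shift* between adjacent classes, never appear at an isolated empty
    class (which an unbounded add-then-clip would allow).  After all
    classes, the row is renormalized to sum to 1 (a no-op except for
    rounding, since bounded transfers conserve mass).

    Unconstrained model: every mutating class i independently gets
    d_i + m' clamped into [0, 1]; the row is then renormalized.  A row
    driven entirely to zero (possible only for near-degenerate kernels)
    falls back to its parent unchanged.

    Parents are never modified.  With ``with_events=True`` also returns
    the number of realized mutation trials per row (out-of-range targets
    included: the trial consumed the class's mutation draw).
    """
    kernels = np.atleast_2d(np.asarray(kernels, dtype=float))
    n = kernels.shape[0]
    work = kernels.copy()
    mutates, upper, magnitudes = _draw_events(n, params, rng)

    if params.model == "continuous":
        for i in range(N_CLASSES):
            hit = mutates[:, i]
            if not hit.any():
                continue
            target = np.where(upper[:, i], i + 1, i - 1)
            valid = hit & (target >= 0) & (target < N_CLASSES)
            rows = np.nonzero(valid)[0]
            if rows.size == 0:
                continue
            tgt = target[rows]
            # transfer m' from entry i' to entry i, bounded by the mass
            # actually available at the donating end
            transfer = np.clip(magnitudes[rows, i],
                               -work[rows, i], work[rows, tgt])
            work[rows, i] += transfer
            work[rows, tgt] -= transfer
        totals = work.sum(axis=1)
        out = work / totals[:, None]
    else:
        hit = mutates
        work = np.where(hit, np.clip(work + magnitudes, 0.0, 1.0), work)
        totals = work.sum(axis=1)
        degenerate = totals <= 0.0
        safe = np.where(degenerate, 1.0, totals)
        out = work / safe[:, None]
        if degenerate.any():
            out[degenerate] = kernels[degenerate]

    if with_events:
        return out, mutates.sum(axis=1)
    return out


def _mutate_one(kernel: np.ndarray, params: MutationParams, rng) -> np.ndarray:
    out = mutate_batch(kernel[None, :], params, rng)
    return out[0]


def mutate_continuous(kernel: np.ndarray, params: MutationParams,
                      rng) -> np.ndarray:
    """Offspring kernel under the continuous-shifting (polygenic) model."""
    if params.model != "continuous":
        params = MutationParams(params.mu, params.m, "continuous")
    return _mutate_one(kernel, params, rng)


def mutate_unconstrained(kernel: np.ndarray, params: MutationParams,
                         rng) -> np.ndarray:
    """Offspring kernel under the unconstrained (large-effect) model."""
    if params.model != "unconstrained":
        params = MutationParams(params.mu, params.m, "unconstrained")
    return _mutate_one(kernel, params, rng)
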