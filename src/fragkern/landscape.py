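"""Autocorrelated landscapes and fragmentation schedules.

A landscape is an L x L torus of cells.  Each cell carries a real-valued
habitat-loss susceptibility; fragmentation removes cells in descending
order of susceptibility at a constant rate until only a fraction ``phi``
of the landscape remains habitable.  Susceptibility surfaces are
synthesized in the frequency domain (random-phase spectral synthesis) so
that the spatial autocorrelation of the surface — and hence the patchiness
of the emerging fragmented landscape — is controlled by a single Hurst
index ``H`` in (0, 1).  Only the *ordering* of cells matters downstream,
so the surface is defined up to any monotone transform.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LandscapeParams",
    "SusceptibilityField",
    "FragmentationParams",
    "FragmentationSchedule",
    "generate_susceptibility",
    "build_schedule",
    "morans_i_rook",
]

#: Amplitude of the deterministic per-cell jitter used to break ties.
_TIE_JITTER = 1e-12

#: Fragmentation-duration presets, in time-steps.
DURATION_PRESETS = {"rapid": 900, "intermediate": 9_000, "slow": 90_000}


@dataclass(frozen=True)
class LandscapeParams:
    """Parameters of the susceptibility surface.

    side_length
        Cells per axis of the torus (>= 4).
    hurst
        Hurst index in (0, 1); larger values give smoother, more
        autocorrelated surfaces and hence blockier fragmentation.
    seed
        Seed (int or numpy SeedSequence/Generator) for the synthesis.
    """

    side_length: int = 32
    hurst: float = 0.2
    seed: object = None

    def __post_init__(self):
        if self.side_length < 4:
            raise ValueError(f"side_length must be >= 4, got {self.side_length}")
        if not (0.0 < self.hurst < 1.0):
            raise ValueError(f"hurst must lie in (0, 1), got {self.hurst}")


@dataclass(frozen=True)
class SusceptibilityField:
    """Real-valued L x L surface ranking cells by habitat-loss susceptibility."""

    values: np.ndarray = field(repr=False)

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("susceptibility field must be a square matrix")
        if not np.all(np.isfinite(v)):
            raise ValueError("susceptibility values must be finite")
        object.__setattr__(self, "values", v)

    @property
    def side_length(self) -> int:
        return self.values.shape[0]

    def ranking(self) -> np.ndarray:
        """Flat (row-major) cell indices sorted by decreasing susceptibility."""
        return np.argsort(-self.values.ravel(), kind="stable")

    def to_text(self, path) -> None:
        np.savetxt(path, self.values, delimiter="\t", fmt="%.17g")

    @classmethod
    def from_text(cls, path) -> "SusceptibilityField":
        return cls(np.loadtxt(path, delimiter="\t"))


@dataclass(frozen=True)
class FragmentationParams:
    """How much habitat is lost, over how long, and in what mode.

    final_habitable_fraction
        Fraction phi in (0, 1] of cells that remain habitable at the end.
    duration
        T_f, the number of time-steps over which gradual loss is spread.
        Presets: rapid = 900, intermediate = 9,000, slow = 90,000.
    mode
        ``gradual`` (constant-rate loss), ``instantaneous`` (all loss at
        step 1) or ``none`` (no loss; control scenario).
    """

    final_habitable_fraction: float = 0.10
    duration: int = 90_000
    mode: str = "gradual"

    def __post_init__(self):
        if not (0.0 < self.final_habitable_fraction <= 1.0):
            raise ValueError(
                f"final_habitable_fraction must lie in (0, 1], got "
                f"{self.final_habitable_fraction}")
        if self.mode not in ("gradual", "instantaneous", "none"):
            raise ValueError(f"unknown fragmentation mode {self.mode!r}")
        if self.mode == "gradual" and self.duration < 1:
            raise ValueError("duration must be >= 1 for gradual fragmentation")

    @classmethod
    def preset(cls, name: str, final_habitable_fraction: float = 0.10,
               duration: int | None = None) -> "FragmentationParams":
        """Named presets: rapid | intermediate | slow | instant | none."""
        if name in DURATION_PRESETS:
            return cls(final_habitable_fraction, DURATION_PRESETS[name], "gradual")
        if name in ("instant", "instantaneous"):
            return cls(final_habitable_fraction, 1, "instantaneous")
        if name == "none":
            return cls(final_habitable_fraction, 1, "none")
        raise ValueError(f"unknown fragmentation preset {name!r}")


@dataclass(frozen=True)
class FragmentationSchedule:
    """Time-stamped habitat-loss events.

    ``times[j]`` is the time-step at which flat cell ``cells[j]`` becomes
    uninhabitable.  Events are ordered by time, and within the whole list
    by decreasing susceptibility of the lost cell.
    """

    times: np.ndarray = field(repr=False)
    cells: np.ndarray = field(repr=False)
    side_length: int = 0

    @property
    def n_events(self) -> int:
        return len(self.times)

    def events_at(self, t: int) -> np.ndarray:
        """Flat indices of the cells lost at time-step t."""
        lo = np.searchsorted(self.times, t, side="left")
        hi = np.searchsorted(self.times, t, side="right")
        return self.cells[lo:hi]

    def cumulative_events(self, t: int) -> int:
        """Number of cells lost at or before time-step t."""
        return int(np.searchsorted(self.times, t, side="right"))

    def to_table(self) -> np.ndarray:
        """2-column (time_step, flat cell index) array."""
        return np.column_stack([self.times, self.cells])

    def to_text(self, path) -> None:
        np.savetxt(path, self.to_table(), delimiter="\t", fmt="%d",
                   header="time_step\tcell", comments="")


def generate_susceptibility(params: LandscapeParams) -> SusceptibilityField:
    """Synthesize a susceptibility surface by random-phase spectral synthesis.

    A complex spectrum with independent Gaussian real/imaginary parts is
    shaped by a radial power-law filter ``f**-(H+1)`` (power-spectrum
    exponent 2H+2, the fractional-Brownian convention for a surface of
    Hurst index H), the zero-frequency amplitude is removed, and the real
    part of the inverse FFT gives a periodic (torus) surface.  A per-cell
    jitter of magnitude ~1e-12, ordered by a seeded random permutation,
    makes all values pairwise distinct so cell orderings are unambiguous.
    """
    L, H = params.side_length, params.hurst
    rng = _as_generator(params.seed)
    f = np.fft.fftfreq(L)
    radial = np.hypot(f[:, None], f[None, :])
    with np.errstate(divide="ignore"):
        amplitude = np.where(radial > 0, radial ** -(H + 1.0), 0.0)
    spectrum = amplitude * (rng.standard_normal((L, L))
                            + 1j * rng.standard_normal((L, L)))
    surface = np.fft.ifft2(spectrum).real
    surface = (surface - surface.mean()) / (surface.std() or 1.0)
    jitter = _TIE_JITTER * rng.permutation(L * L).reshape(L, L)
    return SusceptibilityField(surface + jitter)


def build_schedule(fld: SusceptibilityField, params: FragmentationParams,
                   rng=None) -> FragmentationSchedule:
    """Turn a susceptibility surface into a loss schedule.

    Gradual mode removes the ``n_total = L**2 - round(phi * L**2)`` most
    susceptible cells at a constant rate: event k (1-based, cells in
    decreasing susceptibility) happens at step ``ceil(k * T_f / n_total)``,
    so the cumulative number of lost cells at step t is exactly
    ``floor(n_total * t / T_f)``.  Instantaneous mode applies every loss
    at step 1; ``none`` returns an empty schedule.  ``rng`` is accepted
    for interface symmetry; the schedule is fully deterministic.
    """
    L = fld.side_length
    n_cells = L * L
    phi = params.final_habitable_fraction
    n_keep = int(round(phi * n_cells))
    if n_keep < 1:
        raise ValueError("final habitable fraction keeps less than one cell")
    n_total = n_cells - n_keep
    if params.mode == "none" or n_total == 0:
        empty = np.empty(0, dtype=np.int64)
        return FragmentationSchedule(empty, empty.copy(), L)
    doomed = fld.ranking()[:n_total]
    if params.mode == "instantaneous":
        times = np.ones(n_total, dtype=np.int64)
    else:
        k = np.arange(1, n_total + 1, dtype=np.int64)
        times = -((-k * params.duration) // n_total)  # ceil division
    return FragmentationSchedule(times, doomed.astype(np.int64), L)


def morans_i_rook(values: np.ndarray) -> float:
    """Moran's I of a square matrix under rook (4-neighbour) torus weights.

    Diagnostic used to characterise surface autocorrelation; larger Hurst
    indices yield larger expected values.
    """
    x = np.asarray(values, dtype=float)
    z = x - x.mean()
    denom = (z * z).sum()
    if denom == 0:
        return 0.0
    num = sum((z * np.roll(z, shift, axis)).sum()
              for shift in (1, -1) for axis in (0, 1))
    n = x.size
    w_total = 4 * n
    return float((n / w_total) * (num / denom))


def _as_generator(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)
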