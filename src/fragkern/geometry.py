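"""Torus distance-class arithmetic.

All dispersal, recruitment and mortality computations share one notion of
distance: the Euclidean distance between cell centres on an L x L torus,
reduced to the minimum image and rounded to the nearest integer.  Cells at
the same rounded distance *i* from a focal cell form a "ring" of size
``g_i``; by torus homogeneity the ring sizes are identical for every focal
cell.  The dispersal kernel assigns seed mass to classes 0..14 only, so
rings beyond class 14 never receive seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Number of dispersal distance classes (0..14).
N_CLASSES = 15

#: Largest distance class a kernel assigns mass to.
MAX_CLASS = N_CLASSES - 1


def minimum_image(delta: np.ndarray, L: int) -> np.ndarray:
    """Reduce integer axis displacements to the range [-L/2, L/2]."""
    d = np.asarray(delta) % L
    return np.where(d > L / 2, d - L, d)


def distance_class(offset: tuple[int, int], L: int) -> int:
    """Rounded Euclidean distance class of an (dx, dy) offset on the torus.

    The squared minimum-image distance is an integer, so the true distance
    is never a half-integer and the rounding rule has no ties.
    """
    dx, dy = (int(minimum_image(o, L)) for o in offset)
    return int(np.rint(np.hypot(dx, dy)))


@dataclass(frozen=True)
class RingGeometry:
    """Precomputed distance-class tables for an L x L torus.

    Attributes
    ----------
    L : int
        Cells per axis.
    ring_counts : ndarray of shape (N_CLASSES,)
        ``g_i``: number of cells at distance class i from any focal cell.
        Classes with no representative cell on a small torus have count 0.
    offset_classes : ndarray of shape (L, L)
        Distance class of every (dx, dy) offset, dx, dy in 0..L-1.
    pair_classes : ndarray of shape (L*L, L*L)
        Distance class between every pair of flat (row-major) cell indices.
    """

    L: int
    ring_counts: np.ndarray = field(repr=False)
    offset_classes: np.ndarray = field(repr=False)
    pair_classes: np.ndarray = field(repr=False)

    @classmethod
    def for_side(cls, L: int) -> "RingGeometry":
        if L < 4:
            raise ValueError(f"torus side must be >= 4 cells, got {L}")
        dx = minimum_image(np.arange(L), L)
        dist = np.hypot(dx[:, None], dx[None, :])
        offset_classes = np.rint(dist).astype(np.int16)
        counts = np.bincount(offset_classes.ravel())
        ring_counts = np.zeros(N_CLASSES, dtype=np.int64)
        upto = min(N_CLASSES, counts.size)
        ring_counts[:upto] = counts[:upto]
        # pairwise table: class of (cell_a - cell_b) for flat indices
        rows = np.arange(L * L) // L
        cols = np.arange(L * L) % L
        drow = (rows[:, None] - rows[None, :]) % L
        dcol = (cols[:, None] - cols[None, :]) % L
        pair_classes = offset_classes[drow, dcol]
        return cls(L=L, ring_counts=ring_counts, offset_classes=offset_classes,
                   pair_classes=pair_classes)

    @property
    def n_cells(self) -> int:
        return self.L * self.L

    @property
    def empty_classes(self) -> np.ndarray:
        """Boolean mask of kernel classes with no cells on this torus.

        Non-empty for all 15 classes once L >= 20; on smaller tori the
        outermost classes are unreachable and any seed mass a kernel puts
        there is lost (see the kernel and engine modules).
        """
        return self.ring_counts == 0

    def ring_table(self) -> "np.ndarray":
        """(class, count) rows for documentation and export."""
        return np.column_stack([np.arange(N_CLASSES), self.ring_counts])


def ring_sizes(L: int, i_max: int = MAX_CLASS) -> np.ndarray:
    """``g_i`` for classes 0..i_max on an L x L torus."""
    geom = RingGeometry.for_side(L)
    if i_max == MAX_CLASS:
        return geom.ring_counts.copy()
    dx = minimum_image(np.arange(L), L)
    classes = np.rint(np.hypot(dx[:, None], dx[None, :])).astype(int)
    counts = np.bincount(classes.ravel(), minlength=i_max + 1)
    return counts[: i_max + 1]
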