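"""Per-step population summaries and cross-replicate aggregation.

At every recorded step the recorder stores the population-mean dispersal
kernel (each class averaged over all living individuals, equally
weighted), the mean dispersal-related seed mortality, the number of
living individuals and the number of habitable cells.  Replicate records
sharing a time axis can be aggregated into per-step means and standard
deviations; replicates that went extinct drop out of the aggregate from
the step of extinction onward.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .geometry import N_CLASSES
from . import engine

__all__ = ["TimeSeriesRecord", "Recorder", "aggregate_replicates"]

KERNEL_COLS = [f"d{i}" for i in range(N_CLASSES)]
BASE_COLS = ["t", "n_habitable", "n_individuals", "mortality_mean"]


class TimeSeriesRecord:
    """Columnar per-step record of one replicate."""

    def __init__(self):
        self.t: list[int] = []
        self.n_habitable: list[int] = []
        self.n_individuals: list[int] = []
        self.mortality_mean: list[float] = []
        self.kernel_mean: list[np.ndarray] = []
        self.extinct = False

    def __len__(self) -> int:
        return len(self.t)

    def append(self, t, n_habitable, n_individuals, mortality_mean,
               kernel_mean) -> None:
        self.t.append(int(t))
        self.n_habitable.append(int(n_habitable))
        self.n_individuals.append(int(n_individuals))
        self.mortality_mean.append(float(mortality_mean))
        self.kernel_mean.append(np.asarray(kernel_mean, dtype=float))

    def kernel_matrix(self) -> np.ndarray:
        return np.vstack(self.kernel_mean) if self.kernel_mean else \
            np.empty((0, N_CLASSES))

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "t": np.asarray(self.t, dtype=np.int64),
            "n_habitable": np.asarray(self.n_habitable, dtype=np.int64),
            "n_individuals": np.asarray(self.n_individuals, dtype=np.int64),
            "mortality_mean": np.asarray(self.mortality_mean, dtype=float),
        })
        km = self.kernel_matrix()
        for i, col in enumerate(KERNEL_COLS):
            df[col] = km[:, i]
        return df

    def write_tsv(self, path, header_lines: list[str] | None = None) -> None:
        """Tab-separated table, optionally preceded by '#' header lines."""
        df = self.to_dataframe()
        with open(path, "w") as fh:
            for line in header_lines or []:
                fh.write(f"# {line}\n")
            df.to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "TimeSeriesRecord":
        rec = cls()
        km = df[KERNEL_COLS].to_numpy()
        for j, row in enumerate(df.itertuples(index=False)):
            rec.append(row.t, row.n_habitable, row.n_individuals,
                       row.mortality_mean, km[j])
        return rec


class Recorder:
    """Observes a simulation state and appends rows to a record.

    ``every`` thins the recording: a step t is stored when t is a multiple
    of ``every`` (the stored rows are identical to the matching rows of an
    unthinned recording).  Extinct states record population 0 with
    NaN-marked kernel and mortality fields.
    """

    def __init__(self, every: int = 1):
        if every < 1:
            raise ValueError("recording cadence must be >= 1")
        self.every = every
        self.record = TimeSeriesRecord()

    def observe(self, state) -> None:
        if state.t % self.every != 0:
            return
        self.force_observe(state)

    def force_observe(self, state) -> None:
        n = state.n_individuals
        if n == 0:
            self.record.extinct = True
            self.record.append(state.t, state.n_habitable, 0, np.nan,
                               np.full(N_CLASSES, np.nan))
            return
        mort = engine.mortality_all(state).mean()
        self.record.append(state.t, state.n_habitable, n, mort,
                           state.mean_kernel())


def record_step(state, every: int = 1) -> tuple:
    """One-shot summary row for the current state (kernel mean, mortality,
    counts); convenience wrapper over the Recorder logic."""
    rec = Recorder(every=every)
    rec.force_observe(state)
    r = rec.record
    return (r.t[0], r.n_habitable[0], r.n_individuals[0],
            r.mortality_mean[0], r.kernel_mean[0])


def aggregate_replicates(records: list[TimeSeriesRecord]) -> pd.DataFrame:
    """Per-step mean and standard deviation across replicates.

    All records must share the same time axis up to their (possibly
    truncated, if extinct) length.  Columns: every summary with _mean and
    _sd suffixes, plus the derived series ``d0_mean`` (already present as
    a kernel column) highlighted alongside ``tail_gt7_mean`` — the summed
    mean kernel mass at distance classes above 7 — and ``n_replicates``,
    the number of non-extinct replicates contributing at each step.
    """
    if not records:
        raise ValueError("no records to aggregate")
    lengths = [len(r) for r in records]
    tmax = max(lengths)
    taxis = records[lengths.index(tmax)].t
    for r in records:
        if r.t != taxis[: len(r)]:
            raise ValueError("replicates do not share a time axis")
        if len(r) < tmax and not r.extinct:
            raise ValueError("replicates have mismatched horizons")

    cols = BASE_COLS[1:] + KERNEL_COLS
    stacked = np.full((len(records), tmax, len(cols)), np.nan)
    for j, r in enumerate(records):
        df = r.to_dataframe()
        stacked[j, : len(r), :] = df[cols].to_numpy()
        # extinct replicates: rows are NaN past truncation and at the
        # extinction row itself (mortality/kernel are NaN there already)
    contributing = ~np.isnan(stacked[:, :, cols.index("mortality_mean")])
    n_rep = contributing.sum(axis=0)

    out = pd.DataFrame({"t": np.asarray(taxis, dtype=np.int64)})
    with np.errstate(invalid="ignore"):
        means = np.nanmean(stacked, axis=0)
        sds = np.nanstd(stacked, axis=0, ddof=0)
    for k, col in enumerate(cols):
        out[f"{col}_mean"] = means[:, k]
        out[f"{col}_sd"] = sds[:, k]
    d_cols = [f"d{i}_mean" for i in range(8, N_CLASSES)]
    out["tail_gt7_mean"] = out[d_cols].sum(axis=1)
    out["n_replicates"] = n_rep
    out["any_extinct"] = any(r.extinct for r in records)
    return out
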