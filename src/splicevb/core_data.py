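"""Data containers and file I/O for grouped splicing read counts.

Reads for a two-isoform event fall into three identity groups: unique to
isoform 1, unique to isoform 2, or ambiguous.  Counts are held as a dense
``cells x events x 3`` integer tensor (sparse Matrix-Market on disk, one
matrix per group, events as rows and cells as columns), together with the
per-event 2x3 effective-length matrices that link the group proportions to
the splicing ratio.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

__all__ = [
    "GROUP_NAMES",
    "MTX_FILES",
    "ValidationError",
    "SplicingCountData",
    "FeatureMatrices",
    "FilterThresholds",
    "load_counts",
    "write_counts",
    "filter_events",
    "intercept_features",
    "features_from_frame",
    "load_cell_features",
]

GROUP_NAMES = ("isoform1", "isoform2", "ambiguous")
MTX_FILES = ("isoform1.mtx", "isoform2.mtx", "ambiguous.mtx")


class ValidationError(ValueError):
    """Raised when input data violate a structural invariant."""


def _as_str_list(values: Sequence) -> list[str]:
    return [str(v) for v in values]


@dataclasses.dataclass
class SplicingCountData:
    """Grouped read counts and effective lengths for two-isoform events.

    Attributes
    ----------
    cell_ids : list of str, length M
    event_ids : list of str, length N
    counts : ndarray, shape (M, N, 3)
        Non-negative integer counts; last axis indexes the read groups
        (isoform-1-unique, isoform-2-unique, ambiguous).
    lengths : ndarray, shape (N, 2, 3)
        Per-event effective-length matrix L_g; rows are isoforms, columns
        read groups.  Satisfies ``L[:, 0, 1] == L[:, 1, 0] == 0`` and
        ``L[:, 0, 2] == L[:, 1, 2]``.
    event_meta : DataFrame or None
        Optional per-event annotation indexed like ``event_ids``.
    """

    cell_ids: list[str]
    event_ids: list[str]
    counts: np.ndarray
    lengths: np.ndarray
    event_meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.cell_ids = _as_str_list(self.cell_ids)
        self.event_ids = _as_str_list(self.event_ids)
        self.counts = np.asarray(self.counts)
        self.lengths = np.asarray(self.lengths, dtype=float)
        self.validate()

    # -- basic geometry -------------------------------------------------
    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def n_events(self) -> int:
        return len(self.event_ids)

    @property
    def total_counts(self) -> np.ndarray:
        """Per-(cell, event) total read count, shape (M, N)."""
        return self.counts.sum(axis=2)

    def validate(self) -> None:
        M, N = self.n_cells, self.n_events
        if self.counts.shape != (M, N, 3):
            raise ValidationError(
                f"counts shape {self.counts.shape} inconsistent with "
                f"{M} cells x {N} events x 3 groups"
            )
        if self.lengths.shape != (N, 2, 3):
            raise ValidationError(
                f"lengths shape {self.lengths.shape} != ({N}, 2, 3)"
            )
        if not np.issubdtype(self.counts.dtype, np.integer):
            frac = self.counts - np.floor(self.counts)
            if np.any(frac != 0):
                c, g, k = np.argwhere(frac != 0)[0]
                raise ValidationError(
                    f"non-integer count at cell={self.cell_ids[c]}, "
                    f"event={self.event_ids[g]}, group={k + 1}"
                )
            self.counts = self.counts.astype(np.int64)
        if np.any(self.counts < 0):
            c, g, k = np.argwhere(self.counts < 0)[0]
            raise ValidationError(
                f"negative count at cell={self.cell_ids[c]}, "
                f"event={self.event_ids[g]}, group={k + 1}"
            )
        if np.any(self.lengths < 0):
            raise ValidationError("effective lengths must be non-negative")
        if np.any(self.lengths[:, 0, 1] != 0) or np.any(self.lengths[:, 1, 0] != 0):
            raise ValidationError(
                "cross-isoform unique lengths must be zero (l_{1,2} = l_{2,1} = 0)"
            )
        if not np.allclose(self.lengths[:, 0, 2], self.lengths[:, 1, 2], atol=1e-9):
            raise ValidationError(
                "ambiguous-group lengths must match between isoforms (l_{1,3} = l_{2,3})"
            )
        uniq1 = self.counts[:, :, 0].sum(axis=0) > 0
        uniq2 = self.counts[:, :, 1].sum(axis=0) > 0
        bad1 = uniq1 & (self.lengths[:, 0, 0] <= 0)
        bad2 = uniq2 & (self.lengths[:, 1, 1] <= 0)
        if np.any(bad1) or np.any(bad2):
            g = int(np.argmax(bad1 | bad2))
            raise ValidationError(
                f"event {self.event_ids[g]} has unique reads but zero "
                "effective length for that group"
            )
        if self.event_meta is not None and len(self.event_meta) != N:
            raise ValidationError("event_meta row count does not match event_ids")

    # -- subsetting -----------------------------------------------------
    def subset_events(self, index: np.ndarray) -> "SplicingCountData":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        meta = None
        if self.event_meta is not None:
            meta = self.event_meta.iloc[index].reset_index(drop=True)
        return SplicingCountData(
            cell_ids=self.cell_ids,
            event_ids=[self.event_ids[i] for i in index],
            counts=self.counts[:, index, :],
            lengths=self.lengths[index],
            event_meta=meta,
        )

    def subset_cells(self, index: np.ndarray) -> "SplicingCountData":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return SplicingCountData(
            cell_ids=[self.cell_ids[i] for i in index],
            event_ids=self.event_ids,
            counts=self.counts[index],
            lengths=self.lengths,
            event_meta=self.event_meta,
        )


@dataclasses.dataclass
class FilterThresholds:
    """Event-level filtering thresholds (pooled over all cells)."""

    min_total_reads: int = 50
    min_unique_reads: int = 10
    min_cells_with_unique: int = 30
    min_minor_fraction: float = 0.001

    def __post_init__(self) -> None:
        if min(self.min_total_reads, self.min_unique_reads,
               self.min_cells_with_unique) < 0:
            raise ValidationError("filter thresholds must be non-negative")
        if not 0 <= self.min_minor_fraction <= 0.5:
            raise ValidationError("min_minor_fraction must be in [0, 0.5]")


@dataclasses.dataclass
class FeatureMatrices:
    """Gene-level features X (events x D) and cell-level covariates Y (cells x K)."""

    X: np.ndarray
    Y: np.ndarray
    x_names: list[str]
    y_names: list[str]

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.Y = np.atleast_2d(np.asarray(self.Y, dtype=float))
        if self.X.size == 0:
            self.X = self.X.reshape(self.X.shape[0] if self.X.ndim == 2 else 0, 0)
        if np.any(~np.isfinite(self.X)) or np.any(~np.isfinite(self.Y)):
            raise ValidationError("feature matrices must not contain NaN/inf")
        if self.X.shape[1] != len(self.x_names):
            raise ValidationError("x_names length does not match X columns")
        if self.Y.shape[1] != len(self.y_names):
            raise ValidationError("y_names length does not match Y columns")
        n_intercept = sum(self.is_intercept_column(j) for j in range(self.Y.shape[1]))
        if n_intercept > 1:
            raise ValidationError("Y contains more than one intercept column")

    def is_intercept_column(self, j: int) -> bool:
        col = self.Y[:, j]
        return col.size > 0 and np.all(col == 1.0)

    @property
    def has_intercept(self) -> bool:
        return any(self.is_intercept_column(j) for j in range(self.Y.shape[1]))

    def drop_y_column(self, name: str) -> "FeatureMatrices":
        if name not in self.y_names:
            raise KeyError(f"no cell covariate named {name!r}")
        keep = [j for j, n in enumerate(self.y_names) if n != name]
        return FeatureMatrices(
            X=self.X,
            Y=self.Y[:, keep],
            x_names=list(self.x_names),
            y_names=[self.y_names[j] for j in keep],
        )


def intercept_features(cell_ids: Sequence[str], n_events: int = 0) -> FeatureMatrices:
    """Cell covariates consisting of a single constant-1 (intercept) column."""
    M = len(cell_ids)
    return FeatureMatrices(
        X=np.zeros((n_events, 0)),
        Y=np.ones((M, 1)),
        x_names=[],
        y_names=["intercept"],
    )


def features_from_frame(
    frame: pd.DataFrame,
    cell_ids: Sequence[str],
    add_intercept: bool = True,
    n_events: int = 0,
) -> FeatureMatrices:
    """Build cell covariates from a DataFrame indexed (or keyed) by cell id.

    Rows are re-aligned to ``cell_ids``; missing cells raise.
    """
    df = frame
    if "cell_id" in df.columns:
        df = df.set_index("cell_id")
    df.index = df.index.astype(str)
    missing = [c for c in cell_ids if c not in df.index]
    if missing:
        raise ValidationError(f"cell covariates missing for cells: {missing[:5]}")
    df = df.loc[list(map(str, cell_ids))]
    names = list(df.columns)
    Y = df.to_numpy(dtype=float)
    if add_intercept and not np.any([np.all(Y[:, j] == 1.0) for j in range(Y.shape[1])]):
        Y = np.column_stack([np.ones(len(df)), Y])
        names = ["intercept"] + names
    return FeatureMatrices(
        X=np.zeros((n_events, 0)), Y=Y, x_names=[], y_names=names
    )


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def _read_mtx(path: Path) -> sparse.csr_matrix:
    try:
        mat = spio.mmread(str(path))
    except Exception as exc:  # pragma: no cover - scipy error text varies
        raise ValidationError(f"failed to read Matrix-Market file {path}: {exc}")
    return sparse.csr_matrix(mat)


def load_counts(counts_dir: str | Path) -> SplicingCountData:
    """Load grouped counts from a directory of Matrix-Market files + TSV sidecars.

    Expects ``isoform1.mtx``, ``isoform2.mtx``, ``ambiguous.mtx`` (events as
    rows, cells as columns), ``cells.tsv`` (one cell id per line),
    ``events.tsv`` (first column event id) and ``lengths.tsv`` with columns
    ``event_id, l11, l12, l13, l21, l22, l23``.
    """
    d = Path(counts_dir)
    cells = pd.read_csv(d / "cells.tsv", sep="\t", header=None, dtype=str)[0].tolist()
    events_df = pd.read_csv(d / "events.tsv", sep="\t", dtype=str)
    if "event_id" not in events_df.columns:
        events_df = pd.read_csv(d / "events.tsv", sep="\t", header=None, dtype=str)
        events_df.columns = ["event_id"] + [f"col{i}" for i in range(1, events_df.shape[1])]
    events = events_df["event_id"].tolist()

    mats = []
    for fname in MTX_FILES:
        m = _read_mtx(d / fname)
        if m.shape != (len(events), len(cells)):
            raise ValidationError(
                f"{fname}: shape {m.shape} does not match "
                f"{len(events)} events x {len(cells)} cells"
            )
        mats.append(m)

    # events x cells on disk -> cells x events x 3 in memory
    counts = np.stack([np.asarray(m.todense()).T for m in mats], axis=2)

    ldf = pd.read_csv(d / "lengths.tsv", sep="\t")
    ldf["event_id"] = ldf["event_id"].astype(str)
    if len(ldf) != len(events):
        raise ValidationError(
            f"lengths.tsv has {len(ldf)} rows for {len(events)} events"
        )
    ldf = ldf.set_index("event_id")
    missing = [e for e in events if e not in ldf.index]
    if missing:
        raise ValidationError(f"lengths.tsv missing events: {missing[:5]}")
    ldf = ldf.loc[events]
    lengths = ldf[["l11", "l12", "l13", "l21", "l22", "l23"]].to_numpy(float)
    lengths = lengths.reshape(len(events), 2, 3)

    meta = events_df.reset_index(drop=True)
    return SplicingCountData(cells, events, counts, lengths, event_meta=meta)


def write_counts(data: SplicingCountData, counts_dir: str | Path) -> None:
    """Write a dataset in the directory layout understood by :func:`load_counts`."""
    d = Path(counts_dir)
    d.mkdir(parents=True, exist_ok=True)
    for k, fname in enumerate(MTX_FILES):
        mat = sparse.coo_matrix(data.counts[:, :, k].T)  # events x cells
        spio.mmwrite(str(d / fname), mat, field="integer",
                     comment=f"splicevb {GROUP_NAMES[k]} counts; rows=events cols=cells")
    with open(d / "cells.tsv", "w") as fh:
        fh.write("\n".join(data.cell_ids) + "\n")
    if data.event_meta is not None and "event_id" in getattr(data.event_meta, "columns", []):
        data.event_meta.to_csv(d / "events.tsv", sep="\t", index=False)
    else:
        pd.DataFrame({"event_id": data.event_ids}).to_csv(
            d / "events.tsv", sep="\t", index=False
        )
    flat = data.lengths.reshape(data.n_events, 6)
    ldf = pd.DataFrame(flat, columns=["l11", "l12", "l13", "l21", "l22", "l23"])
    ldf.insert(0, "event_id", data.event_ids)
    ldf.to_csv(d / "lengths.tsv", sep="\t", index=False)


# ---------------------------------------------------------------------------
# Event filtering
# ---------------------------------------------------------------------------

def filter_events(
    data: SplicingCountData,
    thresholds: FilterThresholds | None = None,
) -> tuple[SplicingCountData, pd.DataFrame]:
    """Drop uninformative events; return (filtered data, per-event report).

    An event is kept iff, pooling reads over all cells, it has
    (1) total reads >= ``min_total_reads`` and unique reads (groups 1+2)
    >= ``min_unique_reads``, (2) at least ``min_cells_with_unique`` cells
    with >= 1 unique read, and (3) minor-isoform unique-read fraction
    >= ``min_minor_fraction``.  The report records, for each dropped event,
    the first failing rule; event order is preserved.
    """
    t = thresholds or FilterThresholds()
    u1 = data.counts[:, :, 0].sum(axis=0).astype(float)
    u2 = data.counts[:, :, 1].sum(axis=0).astype(float)
    unique = u1 + u2
    total = data.counts.sum(axis=(0, 2)).astype(float)
    cells_with_unique = (data.counts[:, :, :2].sum(axis=2) > 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        minor_frac = np.where(unique > 0, np.minimum(u1, u2) / np.maximum(unique, 1), 0.0)

    reasons = np.full(data.n_events, "", dtype=object)
    fail3 = minor_frac < t.min_minor_fraction
    reasons[fail3] = "minor_fraction"
    fail2 = cells_with_unique < t.min_cells_with_unique
    reasons[fail2] = "min_cells_with_unique"
    fail1b = unique < t.min_unique_reads
    reasons[fail1b] = "min_unique_reads"
    fail1a = total < t.min_total_reads
    reasons[fail1a] = "min_total_reads"

    kept = reasons == ""
    report = pd.DataFrame(
        {
            "event_id": data.event_ids,
            "total_reads": total.astype(int),
            "unique_reads": unique.astype(int),
            "cells_with_unique": cells_with_unique,
            "minor_fraction": minor_frac,
            "kept": kept,
            "drop_reason": reasons,
        }
    )
    return data.subset_events(np.asarray(kept, dtype=bool)), report


def save_json(obj: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
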