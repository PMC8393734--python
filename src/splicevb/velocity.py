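"""Spliced/unspliced adaptation and the cross-boundary directedness metric.

Treating spliced and unspliced RNA as the two "isoforms" of a gene turns
the splicing machinery into a detector of differential momentum genes
(DMGs): genes whose spliced fraction shifts with a cell-level covariate.
Counts arrive pre-assigned, so the effective-length matrix is the unit
convention [[1,0,0],[0,1,0]] and psi is the spliced fraction.

``cbdir`` scores externally computed velocity fields: for each cell of a
source group, the mean cosine between its velocity vector and the
displacement vectors toward neighbouring cells of the known successor
group.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .core_data import FeatureMatrices, SplicingCountData, ValidationError
from .differential import DiffResult, elbo_gain_test
from .inference import FitConfig
from .likelihood import VELOCITY_LENGTHS

__all__ = [
    "VelocityEmbedding",
    "CBDirResult",
    "velocity_to_splicing",
    "detection_rate",
    "detect_dmg",
    "cbdir",
    "knn_neighbors",
]

DMG_THRESHOLD = 5.0


@dataclasses.dataclass
class VelocityEmbedding:
    """Low-dimensional positions, velocity vectors, neighbours and labels."""

    positions: np.ndarray  # (n, d)
    velocities: np.ndarray  # (n, d)
    neighbor_sets: list[np.ndarray]  # per-cell neighbour indices, self excluded
    groups: np.ndarray  # (n,) categorical labels

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.velocities = np.asarray(self.velocities, dtype=float)
        self.groups = np.asarray(self.groups)
        if self.positions.shape != self.velocities.shape:
            raise ValidationError("positions and velocities must share a shape")
        n = self.positions.shape[0]
        if len(self.neighbor_sets) != n or self.groups.shape[0] != n:
            raise ValidationError("neighbor_sets/groups must have one entry per cell")
        for c, nb in enumerate(self.neighbor_sets):
            if c in np.asarray(nb):
                raise ValidationError(f"neighbor set of cell {c} contains itself")


@dataclasses.dataclass
class CBDirResult:
    cell_indices: np.ndarray
    scores: np.ndarray
    mean: float
    n_scored: int
    n_skipped_terms: int


def knn_neighbors(positions: np.ndarray, k: int = 30) -> list[np.ndarray]:
    """Euclidean k-nearest-neighbour fallback (self excluded)."""
    positions = np.asarray(positions, dtype=float)
    n = positions.shape[0]
    k = min(k, n - 1)
    tree = cKDTree(positions)
    _, idx = tree.query(positions, k=k + 1)
    idx = np.atleast_2d(idx)
    return [row[row != c][:k] for c, row in enumerate(idx)]


def velocity_to_splicing(
    spliced: np.ndarray,
    unspliced: np.ndarray,
    cell_ids=None,
    gene_ids=None,
) -> SplicingCountData:
    """Map spliced/unspliced count matrices (cells x genes) to grouped counts.

    Group 1 = spliced, group 2 = unspliced, ambiguous group empty; psi is
    then the spliced fraction of each gene in each cell.
    """
    spliced = np.asarray(spliced)
    unspliced = np.asarray(unspliced)
    if spliced.shape != unspliced.shape:
        raise ValidationError(
            f"spliced {spliced.shape} and unspliced {unspliced.shape} shapes differ"
        )
    M, N = spliced.shape if spliced.ndim == 2 else (0, 0)
    if spliced.ndim != 2:
        raise ValidationError("expected 2-D cells x genes matrices")
    cell_ids = cell_ids if cell_ids is not None else [f"cell{i}" for i in range(M)]
    gene_ids = gene_ids if gene_ids is not None else [f"gene{j}" for j in range(N)]
    counts = np.zeros((M, N, 3), dtype=np.int64)
    counts[:, :, 0] = spliced
    counts[:, :, 1] = unspliced
    lengths = np.broadcast_to(VELOCITY_LENGTHS, (N, 2, 3)).copy()
    return SplicingCountData(list(cell_ids), list(gene_ids), counts, lengths)


def detection_rate(spliced: np.ndarray, unspliced: np.ndarray) -> np.ndarray:
    """Per-cell fraction of genes with >= 1 read (spliced + unspliced)."""
    total = np.asarray(spliced) + np.asarray(unspliced)
    if total.ndim != 2 or total.shape[1] == 0:
        raise ValidationError("expected non-empty cells x genes matrices")
    return (total > 0).mean(axis=1)


def detect_dmg(
    spliced: np.ndarray,
    unspliced: np.ndarray,
    group_indicator: np.ndarray,
    config: FitConfig | None = None,
    threshold: float = DMG_THRESHOLD,
    extra_covariates: pd.DataFrame | None = None,
    cell_ids=None,
    gene_ids=None,
) -> DiffResult:
    """Differential momentum genes for a one-vs-rest group indicator.

    Covariates are the intercept, the per-cell gene detection rate, the
    binary ``group_indicator`` under test, and any ``extra_covariates``.
    """
    group_indicator = np.asarray(group_indicator, dtype=float)
    data = velocity_to_splicing(spliced, unspliced, cell_ids, gene_ids)
    if group_indicator.shape[0] != data.n_cells:
        raise ValidationError("group indicator must have one entry per cell")
    rate = detection_rate(spliced, unspliced)
    cols = {
        "intercept": np.ones(data.n_cells),
        "detection_rate": rate,
        "group": group_indicator,
    }
    if np.all(rate == rate[0]):
        # constant coverage carries no information and would be collinear
        # with the intercept
        del cols["detection_rate"]
    names = list(cols)
    Y = np.column_stack(list(cols.values()))
    if extra_covariates is not None:
        Y = np.column_stack([Y, extra_covariates.to_numpy(dtype=float)])
        names += list(extra_covariates.columns)
    feats = FeatureMatrices(
        X=np.zeros((data.n_events, 0)), Y=Y, x_names=[], y_names=names
    )
    return elbo_gain_test(data, feats, "group", config, threshold=threshold)


def cbdir(emb: VelocityEmbedding, group_a, group_b) -> CBDirResult:
    """Cross-boundary directedness from group A towards successor group B.

    For every A-cell with at least one B-neighbour the score is the mean,
    over those neighbours, of the cosine between the cell's velocity and
    the displacement to the neighbour.  Terms with a zero-norm velocity or
    zero displacement are skipped and counted in ``n_skipped_terms``; cells
    with no scored term are excluded from the mean.
    """
    a_cells = np.flatnonzero(emb.groups == group_a)
    in_b = emb.groups == group_b
    cell_indices: list[int] = []
    scores: list[float] = []
    n_skipped = 0
    for c in a_cells:
        nb = np.asarray(emb.neighbor_sets[c], dtype=int)
        nb_b = nb[in_b[nb]] if nb.size else nb
        if nb_b.size == 0:
            continue
        v = emb.velocities[c]
        v_norm = np.linalg.norm(v)
        terms = []
        for cp in nb_b:
            d = emb.positions[cp] - emb.positions[c]
            d_norm = np.linalg.norm(d)
            if v_norm == 0.0 or d_norm == 0.0:
                n_skipped += 1
                continue
            terms.append(float(v @ d) / (v_norm * d_norm))
        if terms:
            cell_indices.append(int(c))
            scores.append(float(np.mean(terms)))
    scores_arr = np.asarray(scores)
    return CBDirResult(
        cell_indices=np.asarray(cell_indices, dtype=int),
        scores=scores_arr,
        mean=float(scores_arr.mean()) if scores_arr.size else float("nan"),
        n_scored=len(scores),
        n_skipped_terms=n_skipped,
    )
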