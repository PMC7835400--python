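"""Weighted k-means over dummy-expanded mixed-type phenotype data.

Qualitative traits are expanded into 0/1 indicator columns (one per
level), quantitative traits enter as single real columns, and every
column j carries a weight w_j: w for qualitative-derived columns and
1 - w for quantitative ones (w = 0.5 by default, giving the two kinds
equal say). The fit minimises the weighted within-cluster sum of squares

    P(A, W, C) = sum_l sum_i sum_j a_il * w_j * (x_ij - c_lj)^2

by Lloyd alternation. Since sum_j w_j (x_j - c_j)^2 equals the ordinary
squared Euclidean distance after scaling every column by sqrt(w_j), the
weighted problem is solved in the scaled coordinates, where the centroid
update is the plain cluster mean.

The cluster count is chosen as the smallest k whose occupancy proportions
reach all three thresholds: normalised Shannon-Weaver >= 0.90, Nei >= 0.85
and variance explained >= 0.70.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.cluster import kmeans_plusplus

from .diversity_metrics import nei, shannon
from .schema import PhenotypeTable

DEFAULT_WEIGHT = 0.5
DEFAULT_CRITERIA = (0.90, 0.85, 0.70)  # shannon, nei, variance explained


@dataclass
class ExpandedMatrix:
    """Dummy-expanded, column-weighted real coordinates of a table."""

    coordinates: np.ndarray  # n x p
    column_weights: np.ndarray  # p
    column_map: list[tuple[str, str | None]]  # (trait, level or None)
    ids: list[str]

    @property
    def scaled(self) -> np.ndarray:
        """Coordinates scaled by sqrt(w_j); Euclidean here = weighted there."""
        return self.coordinates * np.sqrt(self.column_weights)


@dataclass
class ClusterModel:
    """Result of one weighted k-means fit."""

    k: int
    w: float
    labels: np.ndarray  # n, values in [0, k)
    centroids: np.ndarray  # k x p, expanded coordinates
    objective: float
    variance_explained: float
    ids: list[str] = field(default_factory=list)
    # single-trait models carry enough state to score new accessions
    trait: str | None = None
    standardize: tuple[float, float] | None = None  # (mean, sd)
    criteria_met: bool | None = None
    criteria_table: pd.DataFrame | None = None

    @property
    def cluster_sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.k)

    def assign(self, table: PhenotypeTable, trait: str | None = None) -> np.ndarray:
        """Assign accessions of (a subset) table to the fitted clusters.

        Only defined for single-trait models; missing cells are dropped.
        """
        trait = trait or self.trait
        if trait is None or self.trait is None or trait != self.trait:
            raise ValueError("assign() requires a matching single-trait model")
        x = table.data[trait].dropna().to_numpy(dtype=float)
        mu, sd = self.standardize
        z = (x - mu) / sd
        centers = self.centroids.ravel()
        return np.abs(z[:, None] - centers[None, :]).argmin(axis=1)


def expand_dummies(
    table: PhenotypeTable,
    w: float = DEFAULT_WEIGHT,
    standardize: bool = True,
) -> ExpandedMatrix:
    """Expand a complete mixed-type table into weighted real coordinates.

    Quantitative columns are z-standardised (constant columns become
    all-zero) unless ``standardize=False``, which evaluates the literal
    objective on raw values. Each qualitative trait contributes one 0/1
    indicator column per observed level, so each accession's block sums
    to one.
    """
    if not (0 < w < 1):
        raise ValueError("w must lie strictly between 0 and 1")
    if table.has_missing():
        raise ValueError("table has missing cells; impute before clustering")
    cols: list[np.ndarray] = []
    weights: list[float] = []
    cmap: list[tuple[str, str | None]] = []
    for spec in table.schema:
        if spec.is_quantitative:
            x = table.data[spec.name].to_numpy(dtype=float)
            if standardize:
                sd = x.std()
                x = (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)
            cols.append(x)
            weights.append(1.0 - w)
            cmap.append((spec.name, None))
        else:
            col = table.data[spec.name]
            levels = [lv for lv in (spec.levels or col.unique()) if lv in set(col)]
            for lv in levels:
                cols.append((col == lv).to_numpy(dtype=float))
                weights.append(w)
                cmap.append((spec.name, lv))
    return ExpandedMatrix(
        coordinates=np.column_stack(cols),
        column_weights=np.asarray(weights),
        column_map=cmap,
        ids=table.accession_ids,
    )


def _objective(scaled: np.ndarray, centers: np.ndarray, labels: np.ndarray) -> float:
    return float(((scaled - centers[labels]) ** 2).sum())


def _lloyd(
    scaled: np.ndarray, centers: np.ndarray, max_iter: int
) -> tuple[np.ndarray, np.ndarray, float]:
    """One Lloyd run from given initial centers; objective non-increasing."""
    n = scaled.shape[0]
    labels = np.full(n, -1)
    for _ in range(max_iter):
        d = cdist(scaled, centers, metric="sqeuclidean")
        new_labels = d.argmin(axis=1)
        # empty-cluster repair: reseed to the point farthest from its centroid
        for l in range(centers.shape[0]):
            if not np.any(new_labels == l):
                far = d[np.arange(n), new_labels].argmax()
                centers[l] = scaled[far]
                new_labels[far] = l
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels
        for l in range(centers.shape[0]):
            centers[l] = scaled[labels == l].mean(axis=0)
    return labels, centers, _objective(scaled, centers, labels)


def fit(
    matrix: ExpandedMatrix,
    k: int,
    n_init: int = 25,
    max_iter: int = 300,
    seed: int = 0,
) -> ClusterModel:
    """Weighted k-means fit, best of ``n_init`` k-means++ initialisations."""
    n = matrix.coordinates.shape[0]
    if not (1 <= k <= n):
        raise ValueError(f"k must be in [1, {n}]")
    scaled = matrix.scaled
    rng = np.random.default_rng(seed)
    best: tuple[float, np.ndarray, np.ndarray] | None = None
    for _ in range(max(1, n_init)):
        if k == 1:
            centers = scaled.mean(axis=0, keepdims=True).copy()
        else:
            centers, _ = kmeans_plusplus(
                scaled, k, random_state=int(rng.integers(2**31))
            )
        labels, centers, obj = _lloyd(scaled, centers.copy(), max_iter)
        if best is None or obj < best[0]:
            best = (obj, labels, centers)
    obj, labels, centers = best
    total = _objective(scaled, scaled.mean(axis=0, keepdims=True), np.zeros(n, int))
    var_explained = 1.0 if total == 0 else 1.0 - obj / total
    sqrt_w = np.sqrt(matrix.column_weights)
    sqrt_w = np.where(sqrt_w > 0, sqrt_w, 1.0)
    return ClusterModel(
        k=k,
        w=float(matrix.column_weights.max()) if matrix.column_weights.size else 0.5,
        labels=labels,
        centroids=centers / sqrt_w,  # back to unscaled expanded coordinates
        objective=obj,
        variance_explained=var_explained,
        ids=list(matrix.ids),
    )


def _criteria_row(model: ClusterModel) -> dict:
    sizes = model.cluster_sizes
    return {
        "k": model.k,
        "shannon": shannon(sizes),
        "nei": nei(sizes),
        "variance_explained": model.variance_explained,
    }


def select_k(
    table: PhenotypeTable,
    k_range=range(2, 16),
    criteria: tuple[float, float, float] = DEFAULT_CRITERIA,
    w: float = DEFAULT_WEIGHT,
    n_init: int = 25,
    seed: int = 0,
    standardize: bool = True,
) -> tuple[int, ClusterModel]:
    """Pick the smallest k whose fit meets all three occupancy criteria.

    For each candidate k the model is fitted and scored on its cluster
    occupancy proportions (Shannon, Nei) and variance explained relative
    to the k=1 objective. If no k reaches all thresholds the k maximising
    the minimum criterion margin is returned, flagged ``criteria_met=False``.
    """
    k_range = list(k_range)
    if not k_range:
        raise ValueError("empty k range")
    matrix = expand_dummies(table, w=w, standardize=standardize)
    rows, models = [], {}
    thr = np.asarray(criteria, dtype=float)
    chosen = None
    for k in k_range:
        model = fit(matrix, k, n_init=n_init, seed=seed)
        row = _criteria_row(model)
        rows.append(row)
        models[k] = model
        vals = np.array([row["shannon"], row["nei"], row["variance_explained"]])
        if chosen is None and np.all(vals >= thr):
            chosen = k
            break
    crit_table = pd.DataFrame(rows)
    if chosen is None:
        margins = crit_table[["shannon", "nei", "variance_explained"]].to_numpy() - thr
        chosen = int(crit_table["k"].iloc[margins.min(axis=1).argmax()])
        met = False
    else:
        met = True
    model = models[chosen]
    model.criteria_met = met
    model.criteria_table = crit_table
    return chosen, model


def cluster_single_trait(
    table: PhenotypeTable,
    trait: str,
    k_range=range(2, 13),
    criteria: tuple[float, float, float] = DEFAULT_CRITERIA,
    n_init: int = 25,
    seed: int = 0,
) -> ClusterModel:
    """One-dimensional weighted k-means on a single quantitative trait.

    The column is z-standardised using the fitting collection's mean/SD
    (stored so other collections can later be assigned to the same
    clusters); k is chosen by the same three occupancy criteria. A trait
    with a single distinct value yields the degenerate k=1 model with
    variance explained defined as 1.
    """
    if trait not in table.schema:
        raise KeyError(trait)
    if not table.schema[trait].is_quantitative:
        raise ValueError(
            f"trait {trait!r} is qualitative; its levels are the clusters"
        )
    x = table.data[trait].dropna().to_numpy(dtype=float)
    if x.size == 0:
        raise ValueError(f"trait {trait!r} fully missing")
    mu, sd = float(x.mean()), float(x.std())
    if sd == 0:
        return ClusterModel(
            k=1,
            w=DEFAULT_WEIGHT,
            labels=np.zeros(x.size, int),
            centroids=np.zeros((1, 1)),
            objective=0.0,
            variance_explained=1.0,
            ids=list(table.data[trait].dropna().index),
            trait=trait,
            standardize=(mu, 1.0),
            criteria_met=True,
        )
    z = (x - mu) / sd
    matrix = ExpandedMatrix(
        coordinates=z[:, None],
        column_weights=np.array([1.0]),
        column_map=[(trait, None)],
        ids=list(table.data[trait].dropna().index),
    )
    thr = np.asarray(criteria, dtype=float)
    rows, chosen = [], None
    models = {}
    for k in [k for k in k_range if k <= x.size]:
        model = fit(matrix, k, n_init=n_init, seed=seed)
        row = _criteria_row(model)
        rows.append(row)
        models[k] = model
        vals = np.array([row["shannon"], row["nei"], row["variance_explained"]])
        if np.all(vals >= thr):
            chosen = k
            break
    crit_table = pd.DataFrame(rows)
    if chosen is None:
        margins = crit_table[["shannon", "nei", "variance_explained"]].to_numpy() - thr
        chosen = int(crit_table["k"].iloc[margins.min(axis=1).argmax()])
        met = False
    else:
        met = True
    model = models[chosen]
    model.trait = trait
    model.standardize = (mu, sd)
    model.criteria_met = met
    model.criteria_table = crit_table
    return model
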