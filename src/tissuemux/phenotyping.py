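"""Cell phenotyping: mask overlap, threshold gating and unsupervised clustering.

Three complementary routes from a CellTable to cell identities:

* **compartment / type by mask overlap** — a cell belongs to a compartment if
  at least a minimum fraction of its pixels fall inside the compartment mask
  (boundaries inclusive: "at least 30%" admits exactly 30%); a cell's type is
  the marker mask with the highest overlap among those passing their own
  minimum fractions.
* **gating** — boolean marker-threshold expressions ("CD4 >= 0.1", possibly
  nested under a parent gate) evaluated on the mean intensities.
* **clustering** — z-scored marker intensities, PCA, a union-symmetrised
  k-nearest-neighbour graph, and Louvain community detection at a chosen
  resolution.  Cluster ids are ordered by descending size and the partition is
  invariant to the order in which cells are supplied.
"""

from __future__ import annotations

import logging
import random as _random
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import igraph
import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .errors import ConfigurationError, ParameterError, ShapeError
from .expressions import parse_gate_expression, referenced_names
from .preprocess import BinaryMask
from .segmentation import LabelImage, marker_columns

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class OverlapRule:
    """Assign membership when >= min_fraction of the cell's area is in the mask."""

    mask_name: str
    min_fraction: float

    def __post_init__(self):
        if not 0 <= self.min_fraction <= 1:
            raise ParameterError("min_fraction must be in [0, 1]")


@dataclass(frozen=True)
class GateSpec:
    """A named marker-threshold gate, optionally scoped within a parent gate."""

    name: str
    expression: str
    parent_gate: str | None = None


@dataclass(frozen=True)
class ClusterParams:
    markers: tuple[str, ...]
    scale: bool = True
    n_pcs: int = 10
    k_neighbours: int = 20
    resolution: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.n_pcs < 1:
            raise ParameterError("n_pcs must be >= 1")
        if self.n_pcs > len(self.markers):
            raise ParameterError("n_pcs cannot exceed the number of markers")
        if self.k_neighbours < 2:
            raise ParameterError("k_neighbours must be >= 2")
        if self.resolution <= 0:
            raise ParameterError("resolution must be positive")


def overlap_fractions(labels: LabelImage, mask: BinaryMask) -> np.ndarray:
    """Fraction of each cell's pixels inside the mask (index 0 = cell 1)."""
    if labels.pixels.shape != mask.pixels.shape:
        raise ShapeError("mask and label image dimensions differ")
    flat = labels.pixels.ravel()
    n = labels.n_cells
    areas = np.bincount(flat, minlength=n + 1)[1:]
    inside = np.bincount(
        flat, weights=mask.pixels.ravel().astype(np.float64), minlength=n + 1
    )[1:]
    return inside / areas


def assign_compartment(
    cells: pd.DataFrame, labels: LabelImage, rule: OverlapRule, mask: BinaryMask
) -> pd.DataFrame:
    """Set ``compartment`` on cells overlapping the mask by >= min_fraction."""
    fractions = overlap_fractions(labels, mask)
    out = cells.copy()
    assigned = fractions[out["cell_id"].to_numpy() - 1] >= rule.min_fraction
    out.loc[assigned, "compartment"] = rule.mask_name
    return out


def assign_type_by_highest_overlap(
    cells: pd.DataFrame,
    labels: LabelImage,
    rules: Sequence[OverlapRule],
    masks: Mapping[str, BinaryMask],
) -> pd.DataFrame:
    """Type each cell by the eligible marker mask with the largest overlap.

    A rule is eligible for a cell if the overlap fraction meets that rule's
    own minimum; among eligible rules the highest fraction wins, exact ties
    going to the rule listed first (ties are counted and logged).
    """
    names = [r.mask_name for r in rules]
    if len(set(names)) != len(names):
        raise ConfigurationError("duplicate mask_name across overlap rules")
    fraction_matrix = np.stack(
        [overlap_fractions(labels, masks[r.mask_name]) for r in rules], axis=1
    )
    eligible = fraction_matrix >= np.array([r.min_fraction for r in rules])
    scores = np.where(eligible, fraction_matrix, -1.0)
    best = scores.argmax(axis=1)  # argmax takes the first maximum: tie rule
    has_type = eligible.any(axis=1)
    n_ties = int(
        ((scores == scores.max(axis=1, keepdims=True)).sum(axis=1) > 1)[has_type].sum()
    )
    if n_ties:
        logger.info("%d cells had tied overlap fractions; first rule kept", n_ties)
    out = cells.copy()
    idx = out["cell_id"].to_numpy() - 1
    assigned = has_type[idx]
    out.loc[assigned, "cell_type"] = np.array(names, dtype=object)[best[idx][assigned]]
    return out


def gate_cells(
    cells: pd.DataFrame, gate: GateSpec, parent: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Cells (within the parent's scope) satisfying the gate expression.

    The returned subset is a copy with ``cell_type`` set to the gate name.
    """
    scope = parent if parent is not None else cells
    tree = parse_gate_expression(gate.expression)
    for name in referenced_names(tree):
        if name not in scope.columns:
            raise ConfigurationError(
                f"gate {gate.name!r}: unknown channel {name!r}"
            )
    env = {name: scope[name].to_numpy() for name in referenced_names(tree)}
    selected = tree.evaluate(env)
    out = scope.loc[selected].copy()
    out["cell_type"] = gate.name
    return out


def _canonical_order(coords: np.ndarray) -> np.ndarray:
    """Deterministic cell ordering from rounded PCA coordinates.

    Makes graph construction and Louvain independent of input row order.
    """
    rounded = np.round(coords, 8)
    return np.lexsort(rounded.T[::-1])


def _knn_graph(coords: np.ndarray, k: int) -> igraph.Graph:
    """Union-symmetrised k-nearest-neighbour graph with unit edge weights."""
    nn = NearestNeighbors(n_neighbors=min(k + 1, len(coords)))
    nn.fit(coords)
    _, idx = nn.kneighbors(coords)
    edges = set()
    for i, neigh in enumerate(idx):
        for j in neigh[1:]:  # skip self
            edges.add((min(i, int(j)), max(i, int(j))))
    g = igraph.Graph(n=len(coords), edges=sorted(edges))
    return g


def cluster_cells(
    cells: pd.DataFrame, params: ClusterParams
) -> tuple[np.ndarray, pd.DataFrame]:
    """Louvain clustering of cells on marker expression.

    Pipeline: optional per-marker z-scoring (constant markers dropped with a
    warning) -> PCA to ``n_pcs`` components -> kNN graph -> Louvain at the
    given resolution with a fixed seed.  Returns per-cell labels 1..K ordered
    by descending cluster size and a profile table of mean raw intensity per
    marker per cluster.
    """
    if len(cells) < params.k_neighbours + 1:
        raise ParameterError(
            f"need at least k_neighbours + 1 = {params.k_neighbours + 1} cells"
        )
    X = cells.loc[:, list(params.markers)].to_numpy(dtype=np.float64)
    kept = list(params.markers)
    if params.scale:
        std = X.std(axis=0)
        constant = std == 0
        if constant.any():
            dropped = [m for m, c in zip(kept, constant) if c]
            logger.warning("dropping constant markers: %s", dropped)
            X = X[:, ~constant]
            kept = [m for m, c in zip(kept, constant) if not c]
        if X.shape[1] == 0:
            # every marker constant: all cells identical
            labels = np.ones(len(cells), dtype=np.int64)
            profile = _cluster_profile(cells, labels, list(params.markers))
            return labels, profile
        X = (X - X.mean(axis=0)) / X.std(axis=0)
    n_pcs = min(params.n_pcs, X.shape[1], len(cells))
    coords = PCA(n_components=n_pcs, svd_solver="full").fit_transform(X)
    order = _canonical_order(coords)
    canonical = np.round(coords[order], 8)
    if np.allclose(canonical, canonical[0]):
        labels = np.ones(len(cells), dtype=np.int64)
        return labels, _cluster_profile(cells, labels, list(params.markers))
    graph = _knn_graph(canonical, params.k_neighbours)
    rng = _random.Random(params.seed)
    previous = igraph.set_random_number_generator(rng)
    try:
        communities = graph.community_multilevel(resolution=params.resolution)
    finally:
        igraph.set_random_number_generator(_random)
    membership = np.asarray(communities.membership)
    labels_canonical = _order_clusters_by_size(membership)
    labels = np.empty(len(cells), dtype=np.int64)
    labels[order] = labels_canonical
    return labels, _cluster_profile(cells, labels, list(params.markers))


def _order_clusters_by_size(membership: np.ndarray) -> np.ndarray:
    """Relabel communities 1..K by descending size (ties by first occurrence)."""
    ids, first, counts = np.unique(
        membership, return_index=True, return_counts=True
    )
    order = np.lexsort((first, -counts))
    remap = {int(ids[j]): rank + 1 for rank, j in enumerate(order)}
    return np.array([remap[int(m)] for m in membership], dtype=np.int64)


def _cluster_profile(
    cells: pd.DataFrame, labels: np.ndarray, markers: list[str]
) -> pd.DataFrame:
    """Mean raw intensity of each marker per cluster."""
    tmp = cells.loc[:, markers].copy()
    tmp["cluster_id"] = labels
    profile = tmp.groupby("cluster_id", sort=True).mean()
    profile.insert(0, "n_cells", tmp.groupby("cluster_id", sort=True).size())
    return profile.reset_index()


def embed_2d(cells: pd.DataFrame, params: ClusterParams) -> np.ndarray:
    """Optional 2-D UMAP embedding of the clustering feature space (reporting only)."""
    import umap  # deferred: numba JIT import cost

    X = cells.loc[:, list(params.markers)].to_numpy(dtype=np.float64)
    if params.scale:
        std = X.std(axis=0)
        keep = std > 0
        X = X[:, keep]
        X = (X - X.mean(axis=0)) / X.std(axis=0)
    n_pcs = min(params.n_pcs, X.shape[1], len(cells))
    coords = PCA(n_components=n_pcs, svd_solver="full").fit_transform(X)
    reducer = umap.UMAP(
        n_neighbors=min(params.k_neighbours, len(cells) - 1),
        random_state=params.seed,
        n_components=2,
    )
    return reducer.fit_transform(coords)
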