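"""Spatially resolved statistics on phenotyped cells.

* **Homotypic aggregation** — DBSCAN on the centroids of one cell type.  The
  reachability radius can be given directly in µm or derived from a minimum
  density: a disk of radius eps holding ``min_points`` cells at density
  ``rho`` cells/mm² gives eps = sqrt(min_points / (pi * rho)).
* **Heterotypic distances** — per source cell, the Euclidean distance in µm to
  the nearest cell of a target type within the same sample (a cell present in
  both sets never matches itself).
* **Group comparisons** — distances pooled per sample group, compared with a
  two-sided Wilcoxon rank-sum test (tie-corrected normal approximation with
  continuity correction) and Benjamini–Hochberg FDR across comparisons.  A
  difference is flagged *relevant* only if |Δmedian| meets a biological
  relevance threshold (default 8 µm, about one lymphocyte diameter) and the
  FDR-adjusted q falls below the cutoff (default 0.1).
* **Permutation null** — cell-type labels are reshuffled among all cells
  within each sample (positions fixed, type counts preserved), the
  median-difference statistic recomputed each time, and a two-tailed p-value
  reported as (1 + #{|null| >= |observed|}) / (K + 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist
from scipy.stats import mannwhitneyu
from sklearn.cluster import DBSCAN
from statsmodels.stats.multitest import multipletests

from .errors import ParameterError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class HomotypicParams:
    """DBSCAN settings; give exactly one of density_per_mm2 / eps_um."""

    min_points: int = 5
    density_per_mm2: float | None = None
    eps_um: float | None = None

    def __post_init__(self):
        if self.min_points < 2:
            raise ParameterError("min_points must be >= 2")
        if (self.density_per_mm2 is None) == (self.eps_um is None):
            raise ParameterError("give exactly one of density_per_mm2 or eps_um")
        if self.density_per_mm2 is not None and self.density_per_mm2 <= 0:
            raise ParameterError("density_per_mm2 must be positive")
        if self.eps_um is not None and self.eps_um <= 0:
            raise ParameterError("eps_um must be positive")

    @property
    def resolved_eps_um(self) -> float:
        if self.eps_um is not None:
            return self.eps_um
        # disk of radius eps holding min_points cells at the stated density
        eps_mm = np.sqrt(self.min_points / (np.pi * self.density_per_mm2))
        return float(eps_mm * 1000.0)


@dataclass
class GroupComparison:
    source_type: str
    target_type: str
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    median_a_um: float
    median_b_um: float
    delta_median_um: float
    wilcoxon_p: float
    fdr_q: float = np.nan
    relevant: bool = False


@dataclass
class PermutationResult:
    source_type: str
    target_type: str
    group_a: str
    group_b: str
    observed_delta_um: float
    n_permutations: int
    null_deltas: np.ndarray
    p_two_tailed: float
    seed: int
    fdr_q: float = np.nan


def homotypic_clusters(
    cells: pd.DataFrame, params: HomotypicParams
) -> np.ndarray:
    """DBSCAN labels on cell centroids (µm); 0 = noise, clusters by size desc."""
    coords = cells[["centroid_x_um", "centroid_y_um"]].to_numpy(dtype=np.float64)
    if len(coords) == 0:
        return np.zeros(0, dtype=np.int64)
    raw = DBSCAN(eps=params.resolved_eps_um, min_samples=params.min_points).fit_predict(
        coords
    )
    out = np.zeros(len(raw), dtype=np.int64)
    ids, counts = np.unique(raw[raw >= 0], return_counts=True)
    first = np.array([np.nonzero(raw == i)[0][0] for i in ids])
    for rank, j in enumerate(np.lexsort((first, -counts))):
        out[raw == ids[j]] = rank + 1
    return out


def nearest_distances(
    sources: pd.DataFrame,
    targets: pd.DataFrame,
    source_type: str | None = None,
    target_type: str | None = None,
) -> pd.DataFrame:
    """Per source cell, the distance to the nearest target centroid (per sample).

    Samples with no valid target are skipped with a warning.  Self-matches
    (same sample_id and cell_id present in both sets) are excluded.
    """
    records = []
    src_type = source_type or _single_type(sources)
    tgt_type = target_type or _single_type(targets)
    for sample_id, src in sources.groupby("sample_id", sort=True):
        tgt = targets[targets["sample_id"] == sample_id]
        if len(tgt) == 0:
            logger.warning("sample %s: no target cells; sources skipped", sample_id)
            continue
        t_xy = tgt[["centroid_x_um", "centroid_y_um"]].to_numpy(dtype=np.float64)
        t_ids = tgt["cell_id"].to_numpy()
        s_xy = src[["centroid_x_um", "centroid_y_um"]].to_numpy(dtype=np.float64)
        s_ids = src["cell_id"].to_numpy()
        tree = cKDTree(t_xy)
        k = min(2, len(tgt))
        dist, idx = tree.query(s_xy, k=k)
        if k == 1:
            dist = dist[:, None]
            idx = idx[:, None]
        for i in range(len(src)):
            choice = 0
            if t_ids[idx[i, 0]] == s_ids[i]:
                if k == 1:
                    logger.warning(
                        "sample %s cell %s: only target is itself; skipped",
                        sample_id,
                        s_ids[i],
                    )
                    continue
                choice = 1
            records.append(
                {
                    "cell_id": s_ids[i],
                    "sample_id": sample_id,
                    "source_type": src_type,
                    "target_type": tgt_type,
                    "nearest_distance_um": float(dist[i, choice]),
                    "nearest_target_id": t_ids[idx[i, choice]],
                }
            )
    return pd.DataFrame(
        records,
        columns=[
            "cell_id",
            "sample_id",
            "source_type",
            "target_type",
            "nearest_distance_um",
            "nearest_target_id",
        ],
    )


def _single_type(cells: pd.DataFrame) -> str:
    types = cells["cell_type"].dropna().unique()
    return str(types[0]) if len(types) == 1 else "cells"


def classify_proximity(distances: pd.DataFrame, cutoff_um: float) -> pd.Series:
    """Label each source cell proximal (< cutoff, strictly) or distal."""
    if cutoff_um <= 0:
        raise ParameterError("cutoff_um must be positive")
    return pd.Series(
        np.where(distances["nearest_distance_um"] < cutoff_um, "proximal", "distal"),
        index=distances.index,
        name="proximity",
    )


def compare_groups(
    distances: pd.DataFrame,
    group_map: dict[str, str],
    comparisons: list[tuple[str, str]],
    relevance_um: float = 8.0,
    q_cutoff: float = 0.1,
) -> list[GroupComparison]:
    """Wilcoxon + BH comparison of pooled distance distributions between groups.

    ``group_map`` maps sample_id to a group name; exactly two groups must be
    present.  Comparisons with fewer than 2 cells in either group are skipped
    with a warning.  BH correction runs across all computed comparisons.
    """
    groups = sorted(set(group_map.values()))
    if len(groups) != 2:
        raise ParameterError(f"expected exactly 2 groups, got {groups}")
    ga, gb = groups
    dist = distances.copy()
    dist["group"] = dist["sample_id"].map(group_map)
    results: list[GroupComparison] = []
    for source_type, target_type in comparisons:
        sel = dist[
            (dist["source_type"] == source_type)
            & (dist["target_type"] == target_type)
        ]
        a = sel.loc[sel["group"] == ga, "nearest_distance_um"].to_numpy()
        b = sel.loc[sel["group"] == gb, "nearest_distance_um"].to_numpy()
        if len(a) < 2 or len(b) < 2:
            logger.warning(
                "comparison %s->%s skipped: group sizes %d vs %d",
                source_type,
                target_type,
                len(a),
                len(b),
            )
            continue
        stat = mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic", use_continuity=True
        )
        results.append(
            GroupComparison(
                source_type=source_type,
                target_type=target_type,
                group_a=ga,
                group_b=gb,
                n_a=len(a),
                n_b=len(b),
                median_a_um=float(np.median(a)),
                median_b_um=float(np.median(b)),
                delta_median_um=float(np.median(a) - np.median(b)),
                wilcoxon_p=float(stat.pvalue),
            )
        )
    _apply_bh(results, relevance_um, q_cutoff)
    return results


def _apply_bh(results, relevance_um: float, q_cutoff: float) -> None:
    if not results:
        return
    pvals = [r.wilcoxon_p if hasattr(r, "wilcoxon_p") else r.p_two_tailed for r in results]
    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
    for r, q in zip(results, qvals):
        r.fdr_q = float(q)
        if hasattr(r, "relevant"):
            r.relevant = bool(
                abs(r.delta_median_um) >= relevance_um and r.fdr_q < q_cutoff
            )


def _sample_arrays(
    cells: pd.DataFrame, source_type: str, target_type: str
) -> dict[str, dict]:
    """Per-sample type codes (1=source, 2=target, 0=other) and pairwise distances."""
    out = {}
    for sample_id, sub in cells.groupby("sample_id", sort=True):
        xy = sub[["centroid_x_um", "centroid_y_um"]].to_numpy(dtype=np.float64)
        d = cdist(xy, xy)
        np.fill_diagonal(d, np.inf)  # a cell never matches itself
        types = sub["cell_type"].to_numpy(dtype=object)
        codes = np.zeros(len(types), dtype=np.int8)
        codes[types == source_type] = 1
        codes[types == target_type] = 2
        out[str(sample_id)] = {"codes": codes, "dist": d}
    return out


def _pooled_median_delta(
    samples: dict[str, dict],
    labels: dict[str, np.ndarray],
    group_map: dict[str, str],
    ga: str,
    gb: str,
) -> float:
    pooled = {ga: [], gb: []}
    for sample_id, data in samples.items():
        group = group_map[sample_id]
        codes = labels[sample_id]
        src = codes == 1
        tgt = codes == 2
        if not src.any() or not tgt.any():
            continue
        sub = data["dist"][np.ix_(src, tgt)]
        mins = sub.min(axis=1)
        pooled[group].append(mins[np.isfinite(mins)])
    a = np.concatenate(pooled[ga]) if pooled[ga] else np.array([np.nan])
    b = np.concatenate(pooled[gb]) if pooled[gb] else np.array([np.nan])
    return float(np.median(a) - np.median(b))


def permutation_null(
    cells: pd.DataFrame,
    group_map: dict[str, str],
    source_type: str,
    target_type: str,
    n_permutations: int = 10000,
    seed: int = 0,
) -> PermutationResult:
    """Two-tailed permutation test of the group difference in median distance.

    The statistic is median(pooled nearest distances, group A) minus the same
    for group B.  Each permutation independently reshuffles the cell-type
    labels among all cells within each sample.
    """
    if n_permutations < 1:
        raise ParameterError("n_permutations must be >= 1")
    groups = sorted(set(group_map.values()))
    if len(groups) != 2:
        raise ParameterError(f"expected exactly 2 groups, got {groups}")
    ga, gb = groups
    samples = _sample_arrays(cells, source_type, target_type)
    rng = np.random.default_rng(seed)
    observed_labels = {sid: data["codes"] for sid, data in samples.items()}
    observed = _pooled_median_delta(samples, observed_labels, group_map, ga, gb)
    null = np.empty(n_permutations)
    for k in range(n_permutations):
        permuted = {
            sid: data["codes"][rng.permutation(len(data["codes"]))]
            for sid, data in samples.items()
        }
        null[k] = _pooled_median_delta(samples, permuted, group_map, ga, gb)
    p = (1 + int((np.abs(null) >= abs(observed)).sum())) / (n_permutations + 1)
    return PermutationResult(
        source_type=source_type,
        target_type=target_type,
        group_a=ga,
        group_b=gb,
        observed_delta_um=observed,
        n_permutations=n_permutations,
        null_deltas=null,
        p_two_tailed=p,
        seed=seed,
    )


def permutation_tests(
    cells: pd.DataFrame,
    group_map: dict[str, str],
    comparisons: list[tuple[str, str]],
    n_permutations: int = 10000,
    seed: int = 0,
) -> list[PermutationResult]:
    """Permutation tests over several comparisons with BH correction across them."""
    results = [
        permutation_null(
            cells, group_map, s, t, n_permutations=n_permutations, seed=seed + i
        )
        for i, (s, t) in enumerate(comparisons)
    ]
    if results:
        pvals = [r.p_two_tailed for r in results]
        _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
        for r, q in zip(results, qvals):
            r.fdr_q = float(q)
    return results


def comparisons_to_frame(results: list[GroupComparison]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in results])


def permutations_to_frame(results: list[PermutationResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        row = {k: v for k, v in vars(r).items() if k != "null_deltas"}
        rows.append(row)
    return pd.DataFrame(rows)
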