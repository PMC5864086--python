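"""Group-level statistics: dependent-t maps, cluster permutation, FDR.

Per grid point a dependent (paired) t test compares two per-participant
maps.  Multiple comparisons across the source grid are corrected with a
cluster-based permutation test: the t map is thresholded at the critical
t of the Student distribution, suprathreshold points are grouped into
spatially connected clusters, each cluster is summarised by its summed t
(T_sum), and the observed T_sum values are compared against the
permutation distribution of the maximal cluster statistic obtained by
randomly sign-flipping participants' difference maps.  Post-hoc tests at
peak grid points are corrected with Benjamini-Hochberg FDR.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

__all__ = [
    "TMap",
    "ClusterResult",
    "critical_t",
    "paired_t_map",
    "lattice_adjacency",
    "cluster_permutation",
    "fdr_adjust",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class TMap:
    """Per-grid-point dependent-t statistics."""

    t: np.ndarray
    df: int
    sidedness: str = "two"  # "one" | "two"

    def __post_init__(self):
        object.__setattr__(self, "t", np.asarray(self.t, dtype=float))
        if not np.all(np.isfinite(self.t)):
            raise ValueError("t map contains non-finite values")
        if self.sidedness not in ("one", "two"):
            raise ValueError("sidedness must be 'one' or 'two'")


@dataclass(frozen=True)
class ClusterResult:
    """A spatially connected suprathreshold cluster with permutation p."""

    members: np.ndarray  # grid-point indices
    t_sum: float
    p_cluster: float
    sign: str  # "pos" | "neg"


def critical_t(n_participants: int, alpha: float = 0.05, sidedness: str = "two") -> float:
    """Critical Student-t value for a paired test with df = n - 1.

    For 20 participants and two-tailed alpha = 0.05 this is 2.093,
    i.e. the 2.1 cluster-forming threshold used throughout.
    """
    if n_participants < 2:
        raise ValueError("need >= 2 participants for a t statistic")
    tails = 2.0 if sidedness == "two" else 1.0
    return float(stats.t.ppf(1.0 - alpha / tails, df=n_participants - 1))


def paired_t_map(maps_a: np.ndarray, maps_b: np.ndarray) -> TMap:
    """Elementwise dependent t test between two participants x points arrays.

    Points where all participants show an identical difference (zero
    variance) get t = 0 with a logged warning rather than +/-inf.
    """
    maps_a = np.asarray(maps_a, dtype=float)
    maps_b = np.asarray(maps_b, dtype=float)
    if maps_a.shape != maps_b.shape:
        raise ValueError("condition maps must share shape (participants x points)")
    n = maps_a.shape[0]
    if n < 2:
        raise ValueError("need >= 2 participants for a paired t map")
    return t_from_diffs(maps_a - maps_b)


def t_from_diffs(diffs: np.ndarray) -> TMap:
    """Paired t map from per-participant difference maps."""
    diffs = np.asarray(diffs, dtype=float)
    n = diffs.shape[0]
    mean = diffs.mean(axis=0)
    sd = diffs.std(axis=0, ddof=1)
    # identical differences leave a ~1e-16 rounding residue, not exactly 0
    zero_var = sd <= 1e-12 * np.maximum(np.abs(mean), 1e-12)
    if np.any(zero_var):
        log.warning("%d grid points with zero difference variance: t forced to 0", zero_var.sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(zero_var, 0.0, mean / (sd / math.sqrt(n)))
    return TMap(t=t, df=n - 1)


def lattice_adjacency(coords: np.ndarray, spacing: float | None = None, factor: float = 1.01) -> csr_matrix:
    """Neighbourhood graph: points within ``factor x spacing`` are adjacent.

    On a regular lattice with the default factor this is face adjacency
    (6-connectivity).  ``spacing`` defaults to the smallest non-zero
    inter-point distance.
    """
    coords = np.asarray(coords, dtype=float)
    if spacing is None:
        tree = cKDTree(coords)
        d, _ = tree.query(coords, k=2)
        spacing = float(np.min(d[:, 1]))
    tree = cKDTree(coords)
    pairs = tree.query_pairs(r=factor * spacing, output_type="ndarray")
    n = coords.shape[0]
    if pairs.size == 0:
        return csr_matrix((n, n))
    rows = np.concatenate([pairs[:, 0], pairs[:, 1]])
    cols = np.concatenate([pairs[:, 1], pairs[:, 0]])
    return csr_matrix((np.ones(rows.size, bool), (rows, cols)), shape=(n, n))


def _clusters_from_mask(mask: np.ndarray, adjacency: csr_matrix) -> list[np.ndarray]:
    """Connected components of the suprathreshold subgraph."""
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return []
    sub = adjacency[idx][:, idx]
    n_comp, labels = connected_components(sub, directed=False)
    return [idx[labels == c] for c in range(n_comp)]


def _max_cluster_stat(t: np.ndarray, adjacency: csr_matrix, t_crit: float, sidedness: str) -> float:
    """Maximal cluster statistic of one (permuted) t map.

    Two-sided: max |T_sum| over positive and negative clusters.
    One-sided: max positive T_sum only.
    """
    best = 0.0
    for members in _clusters_from_mask(t > t_crit, adjacency):
        best = max(best, float(t[members].sum()))
    if sidedness == "two":
        for members in _clusters_from_mask(t < -t_crit, adjacency):
            best = max(best, float(-t[members].sum()))
    return best


def cluster_permutation(
    tmap: TMap,
    per_participant_diffs: np.ndarray,
    adjacency: csr_matrix,
    n_perm: int = 1000,
    cluster_alpha: float = 0.05,
    t_crit: float | None = None,
    sidedness: str = "two",
    seed: int | np.random.Generator = 0,
) -> list[ClusterResult]:
    """Cluster-based permutation correction by participant sign-flips.

    The observed t map is thresholded at ``t_crit`` (default: the
    critical t for the participant count at alpha = 0.05, two-tailed);
    connected suprathreshold components are formed per sign, and each
    observed T_sum is compared with the permutation distribution of the
    maximal cluster statistic across ``n_perm`` random sign-flips of the
    participant difference maps.  p-values use the add-one convention
    p = (1 + #{perm >= obs}) / (1 + n_perm) and clusters with
    p <= ``cluster_alpha`` are returned first (all are returned, sorted
    by p; filter on ``p_cluster`` for significance).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100 for a usable p resolution")
    diffs = np.asarray(per_participant_diffs, dtype=float)
    n_part = diffs.shape[0]
    if adjacency.shape[0] != tmap.t.size:
        raise ValueError("adjacency must cover every grid point")
    if t_crit is None:
        t_crit = critical_t(n_part, 0.05, "two")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    observed: list[tuple[np.ndarray, float, str]] = []
    for members in _clusters_from_mask(tmap.t > t_crit, adjacency):
        observed.append((members, float(tmap.t[members].sum()), "pos"))
    if sidedness == "two":
        for members in _clusters_from_mask(tmap.t < -t_crit, adjacency):
            observed.append((members, float(tmap.t[members].sum()), "neg"))
    if not observed:
        return []

    # permutation null of the max cluster statistic under sign-flips
    signs = rng.choice([-1.0, 1.0], size=(n_perm, n_part))
    null_max = np.empty(n_perm)
    for q in range(n_perm):
        flipped = signs[q][:, None] * diffs
        null_max[q] = _max_cluster_stat(
            t_from_diffs(flipped).t, adjacency, t_crit, sidedness
        )

    results = []
    for members, t_sum, sign in observed:
        stat = abs(t_sum) if sidedness == "two" else t_sum
        p = (1.0 + np.sum(null_max >= stat)) / (1.0 + n_perm)
        results.append(
            ClusterResult(members=members, t_sum=t_sum, p_cluster=float(p), sign=sign)
        )
    results.sort(key=lambda c: c.p_cluster)
    return results


def fdr_adjust(p: np.ndarray, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up adjusted p-values and rejection mask.

    Returns (adjusted p, reject at level ``q``); adjusted values are
    monotone non-decreasing in the sorted order and capped at 1.
    """
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.empty(m)
    adjusted[order] = np.minimum(adjusted_sorted, 1.0)
    return adjusted, adjusted <= q
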