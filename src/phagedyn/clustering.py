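"""Ward clustering of growth curves into growth-dynamics pattern groups.

Curves are clustered by hierarchical agglomeration with the ward.D
convention — the Ward Lance–Williams update applied directly to the
supplied (unsquared) Euclidean dissimilarities.  The number of top-level
groups is chosen by the gap statistic (B reference sets sampled uniformly
over the bounding box of a classical-scaling embedding).  Clusters are
then given semantic labels from curve features rather than by eye:

* Group 1 — resistant combinations: highest median final OD, no regrowth
  (includes the phage-free controls);
* Group 2 — fully susceptible: lowest median peak OD (bacteria killed);
* Group 3 — everything in between, subdivided into five patterns
  (3.1–3.3 killing-then-regrowth, ordered by lag then final OD;
  3.4–3.5 impaired growth, ordered by final OD).

A repeatability audit checks that replicates of the same
phage–bacterium–MOI combination land in the same (sub)group.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist

from .curves import CombinationKey, GrowthCurve
from .features import PatternFeatures, extract_pattern_features
from .ordination import DistanceMatrix, curve_distance_matrix

__all__ = [
    "ClusterAssignment",
    "RepeatabilityReport",
    "ward_linkage",
    "cut_tree",
    "select_k",
    "assign_groups",
    "subcluster_group3",
    "repeatability",
]

logger = logging.getLogger(__name__)

SUBGROUPS_REGROWTH = ("3.1", "3.2", "3.3")
SUBGROUPS_IMPAIRED = ("3.4", "3.5")


@dataclass(frozen=True)
class ClusterAssignment:
    key: CombinationKey
    group: int
    subgroup: str = "none"

    def __post_init__(self):
        # subgroups exist only inside group 3 ("none" is a valid placeholder
        # for group-3 curves that have not been subclustered yet)
        if self.subgroup != "none" and self.group != 3:
            raise ValueError("subgroup labels apply only to group 3")


@dataclass(frozen=True)
class RepeatabilityReport:
    """Per-combination replicate agreement and per-phage discrepancy counts."""

    per_combination: pd.DataFrame
    per_phage: pd.DataFrame
    n_discrepant: int


# ---------------------------------------------------------------------------
# ward.D linkage
# ---------------------------------------------------------------------------

def ward_linkage(d: DistanceMatrix) -> np.ndarray:
    """Agglomerate with the Ward Lance–Williams update on unsquared
    dissimilarities (the "ward.D" convention).

    Returns a scipy-style linkage matrix: row t merges clusters with ids
    ``Z[t,0] < Z[t,1]`` (originals 0..n-1, merged n+t) at height ``Z[t,2]``
    with resulting size ``Z[t,3]``.  Ties are broken by the lowest pair
    index (row-major over the upper triangle).
    """
    n = d.n
    if n < 2:
        raise ValueError("need >= 2 observations")
    D = d.square().astype(float)
    np.fill_diagonal(D, np.inf)
    iu = np.triu_indices(n, 1)
    D[np.tril_indices(n)] = np.inf
    D[iu] = d.square()[iu]

    sizes = np.ones(n)
    cluster_id = np.arange(n)
    active = np.ones(n, dtype=bool)
    Z = np.zeros((n - 1, 4))
    for t in range(n - 1):
        flat = np.argmin(D)          # row-major: lowest (i, j) wins ties
        i, j = divmod(flat, n)
        h = D[i, j]
        ni, nj = sizes[i], sizes[j]
        # Lance-Williams ward update against every other active cluster
        others = np.flatnonzero(active)
        others = others[(others != i) & (others != j)]
        if others.size:
            dik = np.where(others < i, D[others, i], D[i, others])
            djk = np.where(others < j, D[others, j], D[j, others])
            nk = sizes[others]
            new = ((ni + nk) * dik + (nj + nk) * djk - nk * h) / (ni + nj + nk)
            lo = np.minimum(others, i)
            hi = np.maximum(others, i)
            D[lo, hi] = new
        # retire j
        D[j, :] = np.inf
        D[:, j] = np.inf
        active[j] = False
        a, b = sorted((cluster_id[i], cluster_id[j]))
        Z[t] = (a, b, h, ni + nj)
        sizes[i] = ni + nj
        cluster_id[i] = n + t
    return Z


def cut_tree(Z: np.ndarray, k: int) -> np.ndarray:
    """Labels 0..k-1 from the first n-k merges, numbered by first member."""
    n = Z.shape[0] + 1
    if not 1 <= k <= n:
        raise ValueError(f"k must be in 1..{n}")
    parent = np.arange(2 * n - 1)

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for t in range(n - k):
        a, b = int(Z[t, 0]), int(Z[t, 1])
        parent[find(a)] = parent[find(b)] = n + t
    roots = np.array([find(i) for i in range(n)])
    _, labels = np.unique(roots, return_inverse=True)
    # renumber deterministically by first occurrence
    order = {}
    out = np.empty(n, dtype=int)
    for idx, lab in enumerate(labels):
        if lab not in order:
            order[lab] = len(order)
        out[idx] = order[lab]
    return out


# ---------------------------------------------------------------------------
# gap statistic
# ---------------------------------------------------------------------------

def _within_dispersion(d_sq_condensed: np.ndarray, labels: np.ndarray, n: int) -> float:
    """Tibshirani W_k: sum over clusters of (pairwise squared distances)/(2 n_r)."""
    iu, ju = np.triu_indices(n, 1)
    same = labels[iu] == labels[ju]
    w = 0.0
    for lab in np.unique(labels):
        mask = same & (labels[iu] == lab)
        nr = int(np.sum(labels == lab))
        if nr > 1:
            w += float(d_sq_condensed[mask].sum()) / nr
    return w


def _log_wks(d: DistanceMatrix, k_max: int) -> np.ndarray:
    Z = ward_linkage(d)
    d_sq = d.d ** 2
    return np.array([
        np.log(_within_dispersion(d_sq, cut_tree(Z, k), d.n))
        for k in range(1, k_max + 1)
    ])


def select_k(d: DistanceMatrix, k_max: int = 8, B: int = 100,
             seed: int = 0, k_min: int = 1) -> int:
    """Pick the number of clusters by the gap statistic with ward.D trees.

    Reference datasets are drawn uniformly over the bounding box of a
    classical-scaling embedding of ``d`` (axes aligned with the principal
    directions); the smallest k with
    ``gap(k) >= gap(k+1) - SE(k+1)`` wins (the one-SE rule).
    """
    n = d.n
    if n <= k_max:
        raise ValueError(f"need n > k_max, got n={n}, k_max={k_max}")
    from .ordination import _classical_scaling

    emb = _classical_scaling(d, min(n - 1, 10))
    spread = emb.max(axis=0) - emb.min(axis=0)
    keep = spread > 1e-12 * max(spread.max(), 1.0)
    emb = emb[:, keep]
    if emb.shape[1] == 0:
        raise ValueError("degenerate embedding: all points coincide")
    lo, hi = emb.min(axis=0), emb.max(axis=0)

    log_wk = _log_wks(d, k_max)
    rng = np.random.default_rng(seed)
    ref = np.empty((B, k_max))
    for b in range(B):
        pts = rng.uniform(lo, hi, size=emb.shape)
        ref_d = DistanceMatrix(n=n, d=pdist(pts))
        ref[b] = _log_wks(ref_d, k_max)
    gap = ref.mean(axis=0) - log_wk
    se = ref.std(axis=0, ddof=1) * np.sqrt(1 + 1.0 / B)
    for k in range(k_min, k_max):
        if gap[k - 1] >= gap[k] - se[k]:
            return k
    return k_max


# ---------------------------------------------------------------------------
# semantic labelling
# ---------------------------------------------------------------------------

def _cluster_stats(feats: list[PatternFeatures], labels: np.ndarray) -> pd.DataFrame:
    rows = []
    for lab in np.unique(labels):
        sub = [feats[i] for i in np.flatnonzero(labels == lab)]
        rows.append(
            {
                "cluster": int(lab),
                "n": len(sub),
                "median_final_od": float(np.median([f.final_od for f in sub])),
                "median_max_od": float(np.median([f.max_od for f in sub])),
                "median_lag_h": float(np.median([f.lag_h for f in sub])),
                "regrowth_frac": float(np.mean([f.regrowth for f in sub])),
            }
        )
    return pd.DataFrame(rows)


def assign_groups(curves, k: int = 3, od_thresh: float = 0.1,
                  kill_thresh: float = 0.1) -> list[ClusterAssignment]:
    """Cluster curves at k and map clusters to semantic groups 1/2/3.

    Group 2 is the cluster with the lowest median peak OD; Group 1 the
    non-regrowing cluster with the highest median final OD; everything
    else is Group 3.  Ties break by cluster size (larger first), logged.
    """
    curves = list(curves)
    feats = [extract_pattern_features(c, od_thresh, kill_thresh) for c in curves]
    if k == 1:
        med = float(np.median([f.final_od for f in feats]))
        if med <= 0.5:
            raise ValueError(
                f"single cluster with median final OD {med:.3f}: cannot call it "
                "resistant growth (group 1)"
            )
        return [ClusterAssignment(c.key, 1) for c in curves]

    d = curve_distance_matrix(curves)
    labels = cut_tree(ward_linkage(d), k)
    stats = _cluster_stats(feats, labels).sort_values(
        ["n", "cluster"], ascending=[False, True]
    )
    if stats["median_max_od"].duplicated().any() or stats["median_final_od"].duplicated().any():
        logger.info("tied cluster medians; breaking ties by cluster size")

    g2 = int(stats.sort_values(["median_max_od", "n", "cluster"],
                               ascending=[True, False, True]).iloc[0]["cluster"])
    rest = stats[stats["cluster"] != g2]
    non_regrow = rest[rest["regrowth_frac"] < 0.5]
    pool = non_regrow if len(non_regrow) else rest
    g1 = int(pool.sort_values(["median_final_od", "n", "cluster"],
                              ascending=[False, False, True]).iloc[0]["cluster"])
    mapping = {g1: 1, g2: 2}
    out = []
    for c, lab in zip(curves, labels):
        out.append(ClusterAssignment(c.key, mapping.get(int(lab), 3)))
    return out


def subcluster_group3(curves, k_sub: int = 5, auto_k: bool = False,
                      B: int = 100, seed: int = 0, od_thresh: float = 0.1,
                      kill_thresh: float = 0.1) -> list[str]:
    """Subdivide Group-3 curves into patterns 3.1–3.5.

    Re-runs distance → ward.D → cut on the Group-3 subset (``auto_k``
    replaces the fixed ``k_sub`` with a gap-statistic choice constrained
    to 3..6).  Regrowing clusters get 3.1–3.3 (3.1 = longest lag, then by
    final OD: 3.2 below 3.3); non-regrowing get 3.4–3.5 by ascending
    final OD.
    """
    curves = list(curves)
    if not curves:
        logger.warning("subcluster_group3 called with no group-3 curves")
        return []
    if len(curves) < k_sub + 2:
        raise ValueError(
            f"too few group-3 curves ({len(curves)}) for k_sub={k_sub}"
        )
    d = curve_distance_matrix(curves)
    if auto_k:
        k_sub = select_k(d, k_max=6, B=B, seed=seed, k_min=3)
    labels = cut_tree(ward_linkage(d), k_sub)
    feats = [extract_pattern_features(c, od_thresh, kill_thresh) for c in curves]
    stats = _cluster_stats(feats, labels)

    regrow = stats[stats["regrowth_frac"] >= 0.5]
    steady = stats[stats["regrowth_frac"] < 0.5]
    name_of: dict[int, str] = {}
    # 3.1 = longest median lag among regrowers; then 3.2 < 3.3 by final OD
    regrow = regrow.sort_values(["median_lag_h", "cluster"], ascending=[False, True])
    for pos, cl in enumerate(regrow["cluster"]):
        if pos == 0:
            name_of[int(cl)] = "3.1"
    rest = regrow.iloc[1:].sort_values(["median_final_od", "cluster"])
    for pos, cl in enumerate(rest["cluster"]):
        name_of[int(cl)] = SUBGROUPS_REGROWTH[min(pos + 1, 2)]
    steady = steady.sort_values(["median_final_od", "cluster"])
    for pos, cl in enumerate(steady["cluster"]):
        name_of[int(cl)] = SUBGROUPS_IMPAIRED[min(pos, 1)]
    return [name_of[int(lab)] for lab in labels]


# ---------------------------------------------------------------------------
# repeatability
# ---------------------------------------------------------------------------

def repeatability(assignments) -> RepeatabilityReport:
    """Do replicates of each (phage, bacterium, MOI) combination agree?"""
    rows = [
        {
            "phage_id": a.key.phage_id,
            "bacterium_id": a.key.bacterium_id,
            "moi": a.key.moi,
            "replicate": a.key.replicate,
            "group": a.group,
            "subgroup": a.subgroup,
        }
        for a in assignments
    ]
    df = pd.DataFrame(rows)
    per = (
        df.groupby(["phage_id", "bacterium_id", "moi"])
        .agg(
            n_replicates=("replicate", "size"),
            n_groups=("group", "nunique"),
            n_subgroups=("subgroup", "nunique"),
        )
        .reset_index()
    )
    per["discrepancy"] = (per["n_groups"] > 1) | (per["n_subgroups"] > 1)
    per_phage = (
        per.groupby("phage_id")["discrepancy"].sum().astype(int)
        .rename("n_discrepant_combinations").reset_index()
    )
    return RepeatabilityReport(
        per_combination=per,
        per_phage=per_phage,
        n_discrepant=int(per["discrepancy"].sum()),
    )
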