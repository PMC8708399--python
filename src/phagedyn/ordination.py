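"""Ordination of growth curves: Euclidean distances, nonmetric MDS with
Kruskal stress-1, envfit-style factor fitting, and a PCA sanity check.

The NMDS is implemented from scratch by stress majorization: alternating
isotonic (pool-adjacent-violators) fits of monotone disparities to the
rank order of the observed dissimilarities with Guttman-transform updates
of the configuration.  Stress-1,

    stress = sqrt( sum_ij (dist_ij - dhat_ij)^2 / sum_ij dist_ij^2 ),

is scale-invariant and monotone non-increasing over iterations (checked at
run time).  Ties in the observed dissimilarities get the primary
treatment: tied values may receive unequal disparities.

Fit-quality labels follow the usual reading of Kruskal's scale as used for
these data: < 0.01 good, 0.01–0.02 acceptable, above that poor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform
from sklearn.isotonic import IsotonicRegression

from .curves import GrowthCurve

__all__ = [
    "DistanceMatrix",
    "OrdinationResult",
    "FactorFit",
    "PcaResult",
    "curve_distance_matrix",
    "stress1",
    "NMDS",
    "nmds",
    "envfit_factor",
    "envfit_vector",
    "pca_variance",
    "classify_stress",
]


@dataclass(frozen=True)
class DistanceMatrix:
    """Condensed pairwise Euclidean distances between n OD vectors."""

    n: int
    d: np.ndarray

    def __post_init__(self):
        d = np.asarray(self.d, dtype=float)
        object.__setattr__(self, "d", d)
        if d.shape != (self.n * (self.n - 1) // 2,):
            raise ValueError("condensed distance length inconsistent with n")
        if not np.all(np.isfinite(d)) or np.any(d < 0):
            raise ValueError("distances must be finite and non-negative")

    def square(self) -> np.ndarray:
        return squareform(self.d)


@dataclass(frozen=True)
class OrdinationResult:
    coords: np.ndarray
    stress: float
    n_restarts_used: int
    seed: int
    converged: bool

    @property
    def fit_quality(self) -> str:
        return classify_stress(self.stress)


@dataclass(frozen=True)
class FactorFit:
    variable: str
    kind: str                 # "categorical" | "vector"
    r_squared: float
    p_perm: float
    centroids: dict | None    # categorical: level -> mean coords
    arrow: np.ndarray | None  # vector: unit direction in ordination space
    n_permutations: int
    seed: int


@dataclass(frozen=True)
class PcaResult:
    variances: np.ndarray
    cumulative_fraction: float
    k: int


def classify_stress(stress: float) -> str:
    if stress < 0.01:
        return "good"
    if stress <= 0.02:
        return "acceptable"
    return "poor"


def curve_distance_matrix(curves) -> DistanceMatrix:
    """Euclidean distances between full adjusted OD vectors."""
    curves = list(curves)
    if len(curves) < 3:
        raise ValueError("need >= 3 curves")
    grid = curves[0].grid
    for c in curves:
        if c.grid != grid:
            raise ValueError("curves must share one time grid")
    X = np.vstack([c.od for c in curves])
    return DistanceMatrix(n=len(curves), d=pdist(X))


def _disparities(d_obs: np.ndarray, dist: np.ndarray) -> np.ndarray:
    """Monotone disparities for `dist` against the rank order of `d_obs`
    (primary tie treatment: within tied d_obs, order by dist)."""
    order = np.lexsort((dist, d_obs))
    iso = IsotonicRegression(increasing=True)
    fitted = iso.fit_transform(np.arange(order.size), dist[order])
    dhat = np.empty_like(dist)
    dhat[order] = fitted
    return dhat


def stress1(d: DistanceMatrix, coords: np.ndarray) -> float:
    """Kruskal stress-1 of a configuration against observed dissimilarities."""
    coords = np.asarray(coords, dtype=float)
    if not np.all(np.isfinite(coords)):
        raise ValueError("configuration must be finite")
    dist = pdist(coords)
    denom = float(dist @ dist)
    if denom == 0:
        raise ValueError("all configuration distances are zero")
    dhat = _disparities(d.d, dist)
    return float(np.sqrt(np.sum((dist - dhat) ** 2) / denom))


def _classical_scaling(d: DistanceMatrix, k: int) -> np.ndarray:
    D2 = d.square() ** 2
    n = d.n
    J = np.eye(n) - np.full((n, n), 1.0 / n)
    B = -0.5 * J @ D2 @ J
    w, v = np.linalg.eigh(B)
    idx = np.argsort(w)[::-1][:k]
    w_k = np.clip(w[idx], 0.0, None)
    return v[:, idx] * np.sqrt(w_k)


class NMDS:
    """Nonmetric MDS model for one distance matrix; ``fit()`` returns the
    best :class:`OrdinationResult` over restarts.

    The first start is the classical-scaling configuration; the remaining
    ``n_restarts - 1`` are seeded random Gaussians.  Defaults make the
    final stress reproducible across runs at fixed seed.
    """

    def __init__(self, d: DistanceMatrix, k: int = 2, n_restarts: int = 20,
                 max_iter: int = 300, tol: float = 1e-7, seed: int = 0):
        if d.n < k + 1:
            raise ValueError(f"need at least k+1={k + 1} samples, got {d.n}")
        self.d = d
        self.k = k
        self.n_restarts = n_restarts
        self.max_iter = max_iter
        self.tol = tol
        self.seed = seed

    def _majorize(self, X0: np.ndarray) -> tuple[np.ndarray, float, bool]:
        d_obs = self.d.d
        n = self.d.n
        X = X0.copy()
        prev = np.inf
        converged = False
        trace: list[float] = []
        self.stress_trace_ = trace    # per-iteration stress of the last start
        for _ in range(self.max_iter):
            dist = pdist(X)
            denom = float(dist @ dist)
            if denom == 0:
                break
            dhat = _disparities(d_obs, dist)
            stress = float(np.sqrt(np.sum((dist - dhat) ** 2) / denom))
            trace.append(stress)
            if stress > prev + 1e-8:
                raise RuntimeError(
                    f"stress increased during majorization ({prev} -> {stress})"
                )
            if prev - stress < self.tol:
                prev = stress
                converged = True
                break
            prev = stress
            # Guttman transform
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.where(dist > 0, dhat / dist, 0.0)
            Rm = squareform(ratio)
            B = -Rm
            np.fill_diagonal(B, Rm.sum(axis=1))
            X = (B @ X) / n
        return X, prev, converged

    def fit(self) -> OrdinationResult:
        rng = np.random.default_rng(self.seed)
        best = None
        for restart in range(self.n_restarts):
            if restart == 0:
                X0 = _classical_scaling(self.d, self.k)
                if not np.any(X0):
                    X0 = rng.standard_normal((self.d.n, self.k))
            else:
                X0 = rng.standard_normal((self.d.n, self.k))
            X, stress, conv = self._majorize(X0)
            if best is None or stress < best[1]:
                best = (X, stress, conv)
        X, stress, conv = best
        X = X - X.mean(axis=0)
        # report stress exactly as stress1 of the returned configuration
        return OrdinationResult(
            coords=X, stress=stress1(self.d, X),
            n_restarts_used=self.n_restarts, seed=self.seed, converged=conv,
        )


def nmds(d: DistanceMatrix, k: int = 2, n_restarts: int = 20,
         max_iter: int = 300, tol: float = 1e-7, seed: int = 0) -> OrdinationResult:
    """Functional wrapper around :class:`NMDS`."""
    return NMDS(d, k=k, n_restarts=n_restarts, max_iter=max_iter,
                tol=tol, seed=seed).fit()


# ---------------------------------------------------------------------------
# envfit
# ---------------------------------------------------------------------------

def _r2_categorical(coords: np.ndarray, codes: np.ndarray, n_levels: int) -> float:
    grand = coords.mean(axis=0)
    ss_tot = float(np.sum((coords - grand) ** 2))
    ss_within = 0.0
    for lvl in range(n_levels):
        sub = coords[codes == lvl]
        ss_within += float(np.sum((sub - sub.mean(axis=0)) ** 2))
    return 1.0 - ss_within / ss_tot


def envfit_factor(ordr: OrdinationResult, labels, name: str = "factor",
                  n_perm: int = 999, seed: int = 0) -> FactorFit:
    """Goodness of fit of a categorical variable on the ordination.

    r² compares within-level scatter about level centroids with total
    scatter; significance comes from label permutations.
    """
    labels = np.asarray([str(x) for x in labels])
    coords = ordr.coords
    if labels.size != coords.shape[0]:
        raise ValueError("labels length != number of samples")
    levels, codes = np.unique(labels, return_inverse=True)
    if levels.size < 2:
        raise ValueError(f"factor {name!r} has fewer than 2 levels")
    counts = np.bincount(codes, minlength=levels.size)
    if np.any(counts == 0):
        raise ValueError(f"factor {name!r} has an empty level")

    r2 = _r2_categorical(coords, codes, levels.size)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(codes)
        if _r2_categorical(coords, perm, levels.size) >= r2:
            hits += 1
    p = (1 + hits) / (1 + n_perm)
    centroids = {lvl: coords[codes == i].mean(axis=0)
                 for i, lvl in enumerate(levels)}
    return FactorFit(variable=name, kind="categorical", r_squared=r2, p_perm=p,
                     centroids=centroids, arrow=None,
                     n_permutations=n_perm, seed=seed)


def envfit_vector(ordr: OrdinationResult, x, name: str = "vector",
                  n_perm: int = 999, seed: int = 0) -> FactorFit:
    """Fit a continuous variable as an arrow in ordination space.

    The arrow is the (normalised) least-squares regression of x on the
    coordinates; r² is the coefficient of determination, with a
    permutation p-value.
    """
    x = np.asarray(x, dtype=float)
    coords = ordr.coords
    if x.size != coords.shape[0]:
        raise ValueError("vector length != number of samples")
    if not np.all(np.isfinite(x)):
        raise ValueError("vector must be finite")
    if np.std(x) == 0:
        raise ValueError(f"vector {name!r} has zero variance")

    Xc = coords - coords.mean(axis=0)

    def r2_of(v):
        vc = v - v.mean()
        b, *_ = np.linalg.lstsq(Xc, vc, rcond=None)
        rss = float(np.sum((vc - Xc @ b) ** 2))
        return 1.0 - rss / float(vc @ vc), b

    r2, b = r2_of(x)
    norm = np.linalg.norm(b)
    arrow = b / norm if norm > 0 else b
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        if r2_of(rng.permutation(x))[0] >= r2:
            hits += 1
    p = (1 + hits) / (1 + n_perm)
    return FactorFit(variable=name, kind="vector", r_squared=r2, p_perm=p,
                     centroids=None, arrow=arrow,
                     n_permutations=n_perm, seed=seed)


# ---------------------------------------------------------------------------
# PCA sanity check
# ---------------------------------------------------------------------------

def pca_variance(curves, k: int = 2) -> PcaResult:
    """Cumulative variance fraction of the first k principal components of
    the n x T OD matrix (eigen-decomposition of the sample covariance)."""
    curves = list(curves)
    if len(curves) < 3:
        raise ValueError("need >= 3 curves")
    X = np.vstack([c.od for c in curves])
    Xc = X - X.mean(axis=0)
    if not np.any(Xc):
        raise ValueError("constant curve matrix has no principal components")
    # singular values give the covariance eigenvalues without forming T x T
    s = np.linalg.svd(Xc, compute_uv=False)
    variances = s ** 2 / (X.shape[0] - 1)
    frac = float(variances[:k].sum() / variances.sum())
    return PcaResult(variances=variances, cumulative_fraction=frac, k=k)
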