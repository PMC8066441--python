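"""Geographic distances, Mantel tests, spatial eigenfunctions, forward
selection, CCA and environment/space variation partitioning."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.sparse.csgraph import minimum_spanning_tree

from .tables_io import CountTable, DistanceMatrix, SampleFrame

__all__ = [
    "EARTH_RADIUS_KM",
    "haversine_matrix",
    "mantel",
    "MantelResult",
    "distance_decay",
    "pcnm",
    "SpatialEigenfunctions",
    "hellinger",
    "forward_select",
    "cca",
    "CCAResult",
    "variation_partition",
    "VariationPartition",
]

EARTH_RADIUS_KM = 6371.0088


def haversine_matrix(frame: SampleFrame) -> DistanceMatrix:
    """Great-circle distances (km) between all samples."""
    coords = frame.coords()
    if coords.isna().any().any():
        bad = coords.index[coords.isna().any(axis=1)].tolist()
        raise ValueError(f"missing coordinates for samples: {bad}")
    lat = np.radians(coords["lat"].to_numpy())
    lon = np.radians(coords["lon"].to_numpy())
    dlat = lat[:, None] - lat[None, :]
    dlon = lon[:, None] - lon[None, :]
    a = np.sin(dlat / 2) ** 2 + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dlon / 2) ** 2
    d = 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0, 1)))
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2
    return DistanceMatrix(list(coords.index), d, metric="haversine_km")


@dataclass
class MantelResult:
    statistic: float
    p: float
    n_perm: int
    method: str


def mantel(
    dm1: DistanceMatrix,
    dm2: DistanceMatrix,
    method: str = "spearman",
    n_perm: int = 999,
    seed: int = 0,
) -> MantelResult:
    """Mantel permutation test between two distance matrices.

    The statistic is the Pearson or Spearman correlation of the
    condensed upper triangles; rows and columns of the second matrix are
    permuted jointly.  One-sided p for positive association:
    (1 + #{r_perm >= r_obs}) / (1 + n_perm).
    """
    if dm1.labels != dm2.labels:
        raise ValueError("distance matrices have different labels")
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    if method not in ("spearman", "pearson"):
        raise ValueError("method must be 'spearman' or 'pearson'")
    n = dm1.n
    iu = np.triu_indices(n, k=1)
    x = dm1.values[iu]
    y = dm2.values[iu]
    if method == "spearman":
        x = stats.rankdata(x)

    def corr(v: np.ndarray) -> float:
        if method == "spearman":
            v = stats.rankdata(v)
        return float(np.corrcoef(x, v)[0, 1])

    r_obs = corr(y)
    rng = np.random.default_rng(seed)
    exceed = 0
    B = dm2.values
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if corr(B[np.ix_(perm, perm)][iu]) >= r_obs:
            exceed += 1
    return MantelResult(r_obs, (1 + exceed) / (1 + n_perm), n_perm, method)


def distance_decay(
    geo: DistanceMatrix,
    similarity: DistanceMatrix,
    n_perm: int = 999,
    seed: int = 0,
) -> dict:
    """Spearman decay of community similarity with geographic distance.

    Returns rho over all unordered pairs, a Mantel permutation p-value
    (one-sided for negative association), the pair count n, and the
    ordinary least-squares slope/intercept of similarity on distance.
    """
    if geo.labels != similarity.labels:
        raise ValueError("label mismatch between matrices")
    if geo.n < 5:
        raise ValueError("need at least 5 samples")
    iu = np.triu_indices(geo.n, k=1)
    d = geo.values[iu]
    s = similarity.values[iu]
    rho, _ = stats.spearmanr(d, s)
    rng = np.random.default_rng(seed)
    rd = stats.rankdata(d)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(geo.n)
        sp = similarity.values[np.ix_(perm, perm)][iu]
        r_perm = np.corrcoef(rd, stats.rankdata(sp))[0, 1]
        if r_perm <= rho:  # one-sided: decay means negative correlation
            exceed += 1
    slope, intercept = np.polyfit(d, s, 1)
    return {
        "rho": float(rho),
        "p": (1 + exceed) / (1 + n_perm),
        "n": len(d),
        "slope": float(slope),
        "intercept": float(intercept),
        "n_perm": n_perm,
    }


@dataclass
class SpatialEigenfunctions:
    """Positive-eigenvalue spatial eigenfunctions of a truncated distance
    matrix (one value per sample per eigenfunction)."""

    truncation_km: float
    eigenvalues: np.ndarray
    vectors: pd.DataFrame  # samples x eigenfunctions, columns PCNM1..

    @property
    def n_functions(self) -> int:
        return self.vectors.shape[1]


def pcnm(geo: DistanceMatrix) -> SpatialEigenfunctions:
    """Spatial eigenfunctions from the neighbour-truncated distance matrix.

    Truncation distance t = largest edge of the minimum spanning tree;
    distances beyond t are replaced by 4t; eigenvectors of the
    Gower-centered matrix with positive eigenvalues are retained.
    """
    if geo.n < 4:
        raise ValueError("PCNM needs at least 4 samples")
    mst = minimum_spanning_tree(geo.values).toarray()
    t = float(mst.max())
    if t <= 0:
        raise ValueError("duplicate coordinates: MST truncation distance is 0")
    D = geo.values.copy()
    D[D > t] = 4.0 * t
    np.fill_diagonal(D, 0.0)
    n = geo.n
    J = np.eye(n) - np.ones((n, n)) / n
    G = J @ (-0.5 * D**2) @ J
    evals, evecs = np.linalg.eigh((G + G.T) / 2)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    # positive eigenvalues only, with a relative tolerance
    keep = evals > max(1e-10, 1e-10 * abs(evals[0]))
    vecs = evecs[:, keep]
    cols = [f"PCNM{i+1}" for i in range(keep.sum())]
    return SpatialEigenfunctions(
        truncation_km=t,
        eigenvalues=evals[keep],
        vectors=pd.DataFrame(vecs, index=geo.labels, columns=cols),
    )


# ---------------------------------------------------------------------------
# RDA machinery


def hellinger(table: CountTable) -> pd.DataFrame:
    """Hellinger transform: sqrt of row-normalized relative abundances."""
    mat = table.matrix().astype(float)
    totals = mat.sum(axis=1, keepdims=True)
    if (totals == 0).any():
        raise ValueError("all-zero samples cannot be Hellinger-transformed")
    return pd.DataFrame(
        np.sqrt(mat / totals), index=table.sample_ids, columns=table.taxon_ids
    )


def _rda_r2(Y: np.ndarray, X: np.ndarray) -> float:
    """Fraction of total variance of (centered) Y explained by OLS on X."""
    Yc = Y - Y.mean(axis=0)
    Xc = X - X.mean(axis=0)
    total = float((Yc**2).sum())
    if total == 0:
        return 0.0
    beta, *_ = np.linalg.lstsq(Xc, Yc, rcond=None)
    fitted = Xc @ beta
    return float((fitted**2).sum()) / total


def _adjust_r2(r2: float, n: int, p: int) -> float:
    """Ezekiel adjustment: 1 - (1 - R2)(n - 1)/(n - p - 1)."""
    if n - p - 1 <= 0:
        raise ValueError("too many predictors for the sample size")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


def forward_select(
    response: pd.DataFrame,
    candidates: pd.DataFrame,
    alpha: float = 0.05,
    n_perm: int = 999,
    seed: int = 0,
) -> pd.DataFrame:
    """Forward selection of predictors for multivariate RDA.

    Implements the double stopping rule: a candidate enters only if its
    permutation p-value is <= alpha AND the cumulative adjusted R2 does
    not exceed the adjusted R2 of the model with all candidates.
    Returns a frame of selected variables with per-step p and cumulative
    adjusted R2 (empty if nothing passes).
    """
    if candidates.shape[1] < 1:
        raise ValueError("need at least one candidate")
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    Y = response.to_numpy(dtype=float)
    Y = Y - Y.mean(axis=0)
    n = Y.shape[0]
    X_all = candidates.to_numpy(dtype=float)
    names = list(candidates.columns)
    # drop collinear candidates upfront
    usable = []
    for j, name in enumerate(names):
        col = X_all[:, j]
        if np.ptp(col) < 1e-12:
            warnings.warn(f"constant candidate {name!r} skipped")
            continue
        usable.append(j)
    global_adj = _adjust_r2(_rda_r2(Y, X_all[:, usable]), n, len(usable))
    rng = np.random.default_rng(seed)
    selected: list[int] = []
    records = []
    remaining = list(usable)
    while remaining:
        best_j, best_r2 = None, -np.inf
        for j in remaining:
            X_try = X_all[:, selected + [j]]
            if np.linalg.matrix_rank(X_try - X_try.mean(axis=0)) < len(selected) + 1:
                continue  # collinear with already-selected set
            r2 = _rda_r2(Y, X_try)
            if r2 > best_r2:
                best_j, best_r2 = j, r2
        if best_j is None:
            break
        # permutation test of the added variable (permute response rows)
        base_r2 = _rda_r2(Y, X_all[:, selected]) if selected else 0.0
        gain_obs = best_r2 - base_r2
        exceed = 0
        X_sel = X_all[:, selected + [best_j]]
        X_base = X_all[:, selected]
        for _ in range(n_perm):
            Yp = Y[rng.permutation(n)]
            gain = _rda_r2(Yp, X_sel) - (_rda_r2(Yp, X_base) if selected else 0.0)
            if gain >= gain_obs:
                exceed += 1
        p = (1 + exceed) / (1 + n_perm)
        adj = _adjust_r2(best_r2, n, len(selected) + 1)
        if p > alpha or adj > global_adj:
            break
        selected.append(best_j)
        remaining.remove(best_j)
        records.append(
            {
                "variable": names[best_j],
                "R2_cum": best_r2,
                "adjR2_cum": adj,
                "p": p,
            }
        )
    return pd.DataFrame.from_records(
        records, columns=["variable", "R2_cum", "adjR2_cum", "p"]
    )


@dataclass
class CCAResult:
    site_scores: pd.DataFrame
    eigenvalues: np.ndarray
    constrained_inertia: float
    unconstrained_inertia: float
    total_inertia: float
    anova_p: float
    sole_contributions: pd.Series  # per-variable constrained inertia alone


def _cca_inertia(mat: np.ndarray, X: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """Constrained inertia, eigenvalues, and site scores of a CCA."""
    total = mat.sum()
    P = mat / total
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        Qbar = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    Qbar = np.nan_to_num(Qbar)
    # weighted regression of Qbar rows on standardized predictors
    Xc = X - (r @ X)  # weighted centering
    Xw = Xc * np.sqrt(r)[:, None]
    beta, *_ = np.linalg.lstsq(Xw, Qbar, rcond=None)
    fitted = Xw @ beta
    U, svals, Vt = np.linalg.svd(fitted, full_matrices=False)
    evals = svals**2
    keep = evals > 1e-12
    with np.errstate(divide="ignore", invalid="ignore"):
        scores = (U[:, keep] * svals[keep]) / np.sqrt(r)[:, None]
    return float((fitted**2).sum()), evals[keep], np.nan_to_num(scores)


def cca(
    table: CountTable,
    predictors: pd.DataFrame,
    n_perm: int = 999,
    seed: int = 0,
    log_transform: bool = True,
) -> CCAResult:
    """Canonical correspondence analysis with a permutation ANOVA.

    Counts are log(y + 1) transformed by default before the chi-square
    standardization.  The overall test permutes sample rows of the
    predictor table.
    """
    if table.n_samples <= predictors.shape[1] + 1:
        raise ValueError("need n_samples > n_predictors + 1")
    X = predictors.loc[table.sample_ids].to_numpy(dtype=float)
    if np.linalg.matrix_rank(X - X.mean(axis=0)) < X.shape[1] and X.shape[1] > 1:
        raise ValueError("rank-deficient predictor matrix")
    mat = table.matrix().astype(float)
    if log_transform:
        mat = np.log1p(mat)
    total = mat.sum()
    P = mat / total
    r, c = P.sum(axis=1), P.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        Qbar = np.nan_to_num((P - np.outer(r, c)) / np.sqrt(np.outer(r, c)))
    total_inertia = float((Qbar**2).sum())
    constrained, evals, scores = _cca_inertia(mat, X)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        Xp = X[rng.permutation(table.n_samples)]
        c_perm, _, _ = _cca_inertia(mat, Xp)
        if c_perm >= constrained:
            exceed += 1
    sole = {}
    for name in predictors.columns:
        ci, _, _ = _cca_inertia(mat, predictors.loc[table.sample_ids, [name]].to_numpy(float))
        sole[name] = ci / total_inertia if total_inertia > 0 else 0.0
    axes = [f"CCA{i+1}" for i in range(scores.shape[1])]
    return CCAResult(
        site_scores=pd.DataFrame(scores, index=table.sample_ids, columns=axes),
        eigenvalues=evals,
        constrained_inertia=constrained,
        unconstrained_inertia=total_inertia - constrained,
        total_inertia=total_inertia,
        anova_p=(1 + exceed) / (1 + n_perm),
        sole_contributions=pd.Series(sole),
    )


@dataclass
class VariationPartition:
    """Adjusted-R2 fractions of community variation.

    a = pure environment, b = spatially structured environment (shared),
    c = pure space, d = unexplained; a + b + c + d = 1.
    """

    a: float
    b: float
    c: float
    d: float

    @property
    def total_explained(self) -> float:
        return self.a + self.b + self.c

    def as_series(self) -> pd.Series:
        return pd.Series(
            {"pure_env": self.a, "shared": self.b, "pure_spatial": self.c, "unexplained": self.d}
        )

    def display(self) -> pd.Series:
        """Human-readable fractions with negatives clamped to 0."""
        return self.as_series().clip(lower=0.0)


def variation_partition(
    table: CountTable,
    env_selected: pd.DataFrame,
    spatial: SpatialEigenfunctions | pd.DataFrame,
    linear_trend: pd.DataFrame | None = None,
    transform: str = "hellinger",
) -> VariationPartition:
    """Partition community variation between environment and space.

    The community response is Hellinger-transformed counts (configurable
    to ``"none"`` for a pre-transformed table).  The spatial block is
    the retained spatial eigenfunctions plus optional linear-trend
    (coordinate) columns.  R2 of each RDA model is Ezekiel-adjusted and
    combined into the classic a/b/c/d fractions.
    """
    if transform == "hellinger":
        Y = hellinger(table).to_numpy()
    elif transform == "none":
        Y = table.matrix().astype(float)
    else:
        raise ValueError("transform must be 'hellinger' or 'none'")
    spa = spatial.vectors if isinstance(spatial, SpatialEigenfunctions) else spatial
    spa = spa.loc[table.sample_ids]
    if linear_trend is not None:
        spa = pd.concat([spa, linear_trend.loc[table.sample_ids]], axis=1)
    env = env_selected.loc[table.sample_ids] if len(env_selected.columns) else env_selected
    if env.shape[1] == 0 and spa.shape[1] == 0:
        raise ValueError("no predictors on either side")
    n = table.n_samples
    X_env = env.to_numpy(dtype=float) if env.shape[1] else np.empty((n, 0))
    X_spa = spa.to_numpy(dtype=float)
    X_all = np.hstack([X_env, X_spa])

    def _rank(X: np.ndarray) -> int:
        # collinear predictors must not inflate the adjustment penalty
        return int(np.linalg.matrix_rank(X - X.mean(axis=0))) if X.shape[1] else 0

    p_env, p_spa, p_all = _rank(X_env), _rank(X_spa), _rank(X_all)
    for p in (p_env, p_spa, p_all):
        if p >= n - 1:
            raise ValueError("p >= n - 1; reduce the number of predictors")
    r2_env = _adjust_r2(_rda_r2(Y, X_env), n, p_env) if p_env else 0.0
    r2_spa = _adjust_r2(_rda_r2(Y, X_spa), n, p_spa) if p_spa else 0.0
    r2_all = _adjust_r2(_rda_r2(Y, X_all), n, p_all)
    a = r2_all - r2_spa
    c = r2_all - r2_env
    b = r2_env + r2_spa - r2_all
    d = 1.0 - r2_all
    return VariationPartition(a=a, b=b, c=c, d=d)
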