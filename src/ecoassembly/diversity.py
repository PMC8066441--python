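"""Alpha and beta diversity: indices, group tests, ordination, PERMANOVA."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from .tables_io import CountTable, DistanceMatrix, SampleFrame

__all__ = [
    "alpha_diversity",
    "group_test_kw",
    "env_correlations",
    "bray_curtis",
    "pcoa",
    "Ordination",
    "permanova",
    "PermanovaResult",
]


def alpha_diversity(table: CountTable, simpson_variant: str = "gini") -> pd.DataFrame:
    """Richness, Chao1, Shannon (nats) and Simpson per sample.

    Simpson defaults to the Gini-Simpson form ``1 - sum(p^2)`` (bounded
    in [0, 1]); pass ``simpson_variant="inverse"`` for ``1 / sum(p^2)``.
    Chao1 uses the classic estimator ``S + F1^2 / (2 F2)`` with the
    ``S + F1 (F1 - 1) / 2`` fallback when no doubletons exist.
    """
    if simpson_variant not in ("gini", "inverse"):
        raise ValueError("simpson_variant must be 'gini' or 'inverse'")
    mat = table.matrix()
    totals = mat.sum(axis=1)
    if (totals == 0).any():
        bad = [table.sample_ids[i] for i in np.where(totals == 0)[0]]
        raise ValueError(f"all-zero samples: {bad}")
    rows = []
    for counts in mat:
        nz = counts[counts > 0]
        S = len(nz)
        p = nz / nz.sum()
        shannon = float(-(p * np.log(p)).sum())
        d = float((p**2).sum())
        simpson = 1.0 - d if simpson_variant == "gini" else 1.0 / d
        F1 = int((nz == 1).sum())
        F2 = int((nz == 2).sum())
        chao1 = S + (F1**2 / (2 * F2) if F2 > 0 else F1 * (F1 - 1) / 2)
        rows.append((S, float(chao1), shannon, simpson))
    return pd.DataFrame(
        rows, index=table.sample_ids, columns=["richness", "chao1", "shannon", "simpson"]
    )


@dataclass
class KruskalResult:
    H: float
    p: float
    pairwise: pd.DataFrame  # columns: group_a, group_b, z, p_raw, p_adj
    letters: dict[str, str]


def _dunn_pairwise(values: np.ndarray, groups: np.ndarray) -> pd.DataFrame:
    """Dunn's z-statistics on pooled ranks with tie correction, BH-adjusted."""
    n = len(values)
    ranks = stats.rankdata(values)
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (12.0 * (n - 1))
    labels = pd.unique(groups)
    mean_rank = {g: ranks[groups == g].mean() for g in labels}
    sizes = {g: int((groups == g).sum()) for g in labels}
    recs = []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            a, b = labels[i], labels[j]
            se = np.sqrt(
                (n * (n + 1) / 12.0 - tie_term) * (1.0 / sizes[a] + 1.0 / sizes[b])
            )
            z = (mean_rank[a] - mean_rank[b]) / se
            recs.append((a, b, z, 2 * stats.norm.sf(abs(z))))
    df = pd.DataFrame(recs, columns=["group_a", "group_b", "z", "p_raw"])
    df["p_adj"] = stats.false_discovery_control(df["p_raw"], method="bh")
    return df


def _compact_letters(labels: list[str], pairwise: pd.DataFrame, alpha: float) -> dict[str, str]:
    """Compact letter display: groups sharing a letter are not distinguishable."""
    distinct = {
        frozenset((r.group_a, r.group_b))
        for r in pairwise.itertuples()
        if r.p_adj <= alpha
    }
    letter_sets: list[set[str]] = []  # maximal cliques of indistinguishable groups
    for g in labels:
        placed = False
        for s in letter_sets:
            if all(frozenset((g, o)) not in distinct for o in s):
                s.add(g)
                placed = True
        if not placed:
            letter_sets.append({g})
    # drop letter sets subsumed by another
    letter_sets = [
        s for i, s in enumerate(letter_sets)
        if not any(s < t for j, t in enumerate(letter_sets) if i != j)
    ]
    out = {g: "" for g in labels}
    for k, s in enumerate(letter_sets):
        ch = chr(ord("a") + k)
        for g in labels:
            if g in s:
                out[g] += ch
    return out


def group_test_kw(
    values: pd.Series | np.ndarray,
    groups: pd.Series | np.ndarray,
    alpha: float = 0.05,
) -> KruskalResult:
    """Kruskal-Wallis H test with Dunn/BH post hoc and compact letters."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = list(pd.unique(groups))
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    split = [values[groups == g] for g in labels]
    if any(len(s) < 2 for s in split):
        small = [g for g, s in zip(labels, split) if len(s) < 2]
        raise ValueError(f"groups with fewer than 2 samples: {small}")
    if np.ptp(values) == 0:  # all values identical: H = 0 by convention
        H, p = 0.0, 1.0
        recs = [
            (labels[i], labels[j], 0.0, 1.0, 1.0)
            for i in range(len(labels))
            for j in range(i + 1, len(labels))
        ]
        pw = pd.DataFrame(recs, columns=["group_a", "group_b", "z", "p_raw", "p_adj"])
    else:
        H, p = stats.kruskal(*split)
        pw = _dunn_pairwise(values, groups)
    letters = _compact_letters(labels, pw, alpha)
    return KruskalResult(float(H), float(p), pw, letters)


def env_correlations(alpha: pd.DataFrame, frame: SampleFrame) -> pd.DataFrame:
    """Spearman correlations of each alpha index with each env variable.

    Returns a long-format frame with columns ``index``, ``variable``,
    ``rho``, ``p``, ``stars`` (`**` p<0.01, `***` p<0.001).  Constant
    variables yield missing rho with a warning.
    """
    env = frame.env().loc[alpha.index]
    recs = []
    for idx_name in alpha.columns:
        x = alpha[idx_name].to_numpy(dtype=float)
        for var in env.columns:
            y = env[var].to_numpy(dtype=float)
            ok = ~(np.isnan(x) | np.isnan(y))
            if ok.sum() < 5:
                raise ValueError(f"fewer than 5 paired observations for {var!r}")
            if np.ptp(y[ok]) == 0 or np.ptp(x[ok]) == 0:
                const = var if np.ptp(y[ok]) == 0 else idx_name
                warnings.warn(f"constant variable {const!r}; rho undefined")
                recs.append((idx_name, var, np.nan, np.nan, ""))
                continue
            rho, p = stats.spearmanr(x[ok], y[ok])
            stars = "***" if p < 0.001 else "**" if p < 0.01 else ""
            recs.append((idx_name, var, float(rho), float(p), stars))
    return pd.DataFrame(recs, columns=["index", "variable", "rho", "p", "stars"])


def bray_curtis(table: CountTable) -> DistanceMatrix:
    """Bray-Curtis dissimilarity sum|x-y| / sum(x+y) between samples."""
    mat = table.matrix().astype(float)
    if (mat.sum(axis=1) == 0).any():
        bad = [table.sample_ids[i] for i in np.where(mat.sum(axis=1) == 0)[0]]
        raise ValueError(f"all-zero samples: {bad}")
    dm = squareform(pdist(mat, metric="braycurtis"))
    np.fill_diagonal(dm, 0.0)
    return DistanceMatrix(table.sample_ids, dm, metric="braycurtis")


@dataclass
class Ordination:
    """Principal-coordinate (or constrained) ordination result."""

    coordinates: pd.DataFrame  # samples x axes, scaled by sqrt(eigenvalue)
    eigenvalues: np.ndarray
    proportions: np.ndarray  # of positive-eigenvalue variation
    negative_eigenvalues: np.ndarray


def pcoa(dm: DistanceMatrix, correction: str | None = None) -> Ordination:
    """Classical PCoA: Gower double-centering + eigendecomposition.

    Negative eigenvalues are reported, not corrected, by default;
    ``correction="cailliez"`` adds the Cailliez constant to
    off-diagonal distances first.  Axis proportions are computed over
    the sum of positive eigenvalues.
    """
    n = dm.n
    if n < 3:
        raise ValueError("PCoA needs at least 3 samples")
    D = dm.values.copy()
    if correction == "cailliez":
        D = _cailliez(D)
    elif correction is not None:
        raise ValueError(f"unknown correction {correction!r}")
    A = -0.5 * D**2
    J = np.eye(n) - np.ones((n, n)) / n
    G = J @ A @ J
    evals, evecs = np.linalg.eigh((G + G.T) / 2)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = evals > 1e-10
    coords = evecs[:, pos] * np.sqrt(evals[pos])
    axes = [f"PCo{i+1}" for i in range(pos.sum())]
    props = evals[pos] / evals[pos].sum()
    return Ordination(
        coordinates=pd.DataFrame(coords, index=dm.labels, columns=axes),
        eigenvalues=evals[pos],
        proportions=props,
        negative_eigenvalues=evals[evals < -1e-10],
    )


def _cailliez(D: np.ndarray) -> np.ndarray:
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    A1 = J @ (-0.5 * D**2) @ J
    A2 = J @ (-0.5 * D) @ J
    B = np.block([[np.zeros((n, n)), 2 * A1], [-np.eye(n), -4 * A2]])
    c = float(np.max(np.real(np.linalg.eigvals(B))))
    if c <= 0:
        return D
    out = D + c
    np.fill_diagonal(out, 0.0)
    return out


@dataclass
class PermanovaResult:
    F: float
    R2: float
    p: float
    n_perm: int


def _permanova_f(d2: np.ndarray, groups: np.ndarray) -> tuple[float, float]:
    """Pseudo-F and R2 from squared distances and integer group codes."""
    n = d2.shape[0]
    sst = d2[np.triu_indices(n, 1)].sum() / n
    ssw = 0.0
    n_groups = groups.max() + 1
    for g in range(n_groups):
        idx = np.where(groups == g)[0]
        sub = d2[np.ix_(idx, idx)]
        ssw += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    ssa = sst - ssw
    F = (ssa / (n_groups - 1)) / (ssw / (n - n_groups))
    return F, ssa / sst


def permanova(
    dm: DistanceMatrix,
    groups: pd.Series | np.ndarray,
    n_perm: int = 999,
    seed: int = 0,
) -> PermanovaResult:
    """One-way PERMANOVA with permutation p-value (1 + exceed)/(1 + n_perm)."""
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    if isinstance(groups, pd.Series):
        groups = groups.loc[dm.labels].to_numpy()
    groups = np.asarray(groups)
    labels, codes = np.unique(groups, return_inverse=True)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    sizes = np.bincount(codes)
    if (sizes < 2).any():
        raise ValueError(f"singleton groups: {labels[sizes < 2].tolist()}")
    d2 = dm.values**2
    F_obs, R2 = _permanova_f(d2, codes)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(codes)
        F_perm, _ = _permanova_f(d2, perm)
        if F_perm >= F_obs:
            exceed += 1
    p = (1 + exceed) / (1 + n_perm)
    return PermanovaResult(float(F_obs), float(R2), float(p), n_perm)
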