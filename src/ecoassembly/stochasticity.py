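"""Null-model expectation of beta-diversity and the stochasticity ratio.

The null scheme preserves, for every sample, its observed richness and
total read count; taxon identities are drawn without replacement with
probability proportional to regional occurrence frequency, and reads
are allocated to the chosen taxa proportionally to regional relative
abundance (each chosen taxon keeps at least one read so richness is
exact).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .diversity import _permanova_f, bray_curtis
from .tables_io import CountTable

__all__ = [
    "NullEnsemble",
    "StochasticityResult",
    "generate_null_ensemble",
    "stochasticity_ratio",
    "null_permanova",
]

CONSTRAINTS = (
    "per-sample richness and total preserved; taxa ~ occurrence frequency; "
    "reads ~ regional relative abundance"
)


@dataclass
class NullEnsemble:
    """A stack of randomized count tables sharing the observed constraints."""

    tables: list[np.ndarray]  # each n_samples x n_taxa
    sample_ids: list[str]
    taxon_ids: list[str]
    constraints: str
    seed: int

    @property
    def n_iter(self) -> int:
        return len(self.tables)


@dataclass
class StochasticityResult:
    group: str
    pair_st: pd.DataFrame  # sample_a, sample_b, observed_sim, null_sim, st
    sr_mean: float  # percent
    sr_sd: float  # percent
    n_iter: int


def _null_table(
    counts: np.ndarray,
    occ_freq: np.ndarray,
    rel_abund: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    n_samples, n_taxa = counts.shape
    out = np.zeros_like(counts)
    p_occ = occ_freq / occ_freq.sum()
    for i in range(n_samples):
        richness = int((counts[i] > 0).sum())
        total = int(counts[i].sum())
        chosen = rng.choice(n_taxa, size=richness, replace=False, p=p_occ)
        w = rel_abund[chosen]
        alloc = np.ones(richness, dtype=np.int64)
        extra = total - richness
        if extra > 0:
            alloc += rng.multinomial(extra, w / w.sum())
        out[i, chosen] = alloc
    return out


def generate_null_ensemble(
    table: CountTable, n_iter: int = 1000, seed: int = 0
) -> NullEnsemble:
    """Constrained-randomization ensemble of the count table."""
    if n_iter < 100:
        raise ValueError("n_iter must be >= 100")
    counts = table.matrix()
    occ_freq = (counts > 0).sum(axis=0).astype(float)
    if occ_freq.sum() == 0:
        raise ValueError("empty table")
    pool_size = int((occ_freq > 0).sum())
    max_rich = int((counts > 0).sum(axis=1).max())
    if max_rich > pool_size:
        raise ValueError("sample richness exceeds regional pool size")
    rel_abund = counts.sum(axis=0).astype(float)
    rel_abund = np.where(rel_abund > 0, rel_abund, 1e-12)
    rng = np.random.default_rng(seed)
    tables = [_null_table(counts, occ_freq, rel_abund, rng) for _ in range(n_iter)]
    return NullEnsemble(tables, table.sample_ids, table.taxon_ids, CONSTRAINTS, seed)


def _pair_similarities(counts: np.ndarray) -> np.ndarray:
    """1 - Bray-Curtis for all unordered pairs (condensed order)."""
    from scipy.spatial.distance import pdist

    return 1.0 - pdist(counts.astype(float), metric="braycurtis")


def stochasticity_ratio(
    table: CountTable,
    groups: pd.Series | np.ndarray,
    n_iter: int = 1000,
    seed: int = 0,
    side: str = "similarity",
    ensemble: NullEnsemble | None = None,
) -> dict[str, StochasticityResult]:
    """Stochasticity ratio per group from observed vs null-expected similarity.

    For each within-group pair with observed similarity C and null
    expectation E, ``st = min(C, E) / max(C, E)``; the group ratio is
    ``mean(st) * 100`` +/- sd.  ``side="dissimilarity"`` instead forms
    the same min/max ratio on (1 - C) and (1 - E).
    """
    if side not in ("similarity", "dissimilarity"):
        raise ValueError("side must be 'similarity' or 'dissimilarity'")
    if isinstance(groups, pd.Series):
        groups = groups.loc[table.sample_ids].to_numpy()
    groups = np.asarray(groups)
    results: dict[str, StochasticityResult] = {}
    for g in pd.unique(groups):
        idx = np.where(groups == g)[0]
        if len(idx) < 3:
            raise ValueError(f"group {g!r} has fewer than 3 samples")
        sub = table.select_samples([table.sample_ids[i] for i in idx])
        ens = ensemble or generate_null_ensemble(sub, n_iter=n_iter, seed=seed)
        if ensemble is not None:
            # restrict a shared ensemble to this group's samples
            pos = [ensemble.sample_ids.index(s) for s in sub.sample_ids]
            null_tables = [t[pos] for t in ensemble.tables]
        else:
            null_tables = ens.tables
        obs_sim = _pair_similarities(sub.matrix())
        null_sim = np.mean([_pair_similarities(t) for t in null_tables], axis=0)
        if side == "dissimilarity":
            a, b = 1.0 - obs_sim, 1.0 - null_sim
        else:
            a, b = obs_sim, null_sim
        hi = np.maximum(a, b)
        valid = hi > 0
        if not np.all(valid):
            warnings.warn(
                f"group {g!r}: {int((~valid).sum())} pair(s) with zero "
                "observed and expected similarity excluded"
            )
        st = np.minimum(a, b)[valid] / hi[valid]
        n_s = len(idx)
        ia, ib = np.triu_indices(n_s, k=1)
        pair_df = pd.DataFrame(
            {
                "sample_a": [sub.sample_ids[i] for i in ia],
                "sample_b": [sub.sample_ids[j] for j in ib],
                "observed_sim": obs_sim,
                "null_sim": null_sim,
                "st": np.where(hi > 0, np.minimum(a, b) / np.where(hi > 0, hi, 1), np.nan),
            }
        )
        results[str(g)] = StochasticityResult(
            group=str(g),
            pair_st=pair_df,
            sr_mean=float(st.mean() * 100.0),
            sr_sd=float(st.std(ddof=1) * 100.0) if len(st) > 1 else 0.0,
            n_iter=ens.n_iter if ensemble is None else ensemble.n_iter,
        )
    return results


def null_permanova(
    table: CountTable,
    groups: pd.Series | np.ndarray,
    ensemble: NullEnsemble,
) -> tuple[float, float]:
    """Observed PERMANOVA F against the F distribution over null tables.

    p = (1 + #{F_null >= F_obs}) / (1 + n_iter).
    """
    if ensemble.sample_ids != table.sample_ids:
        raise ValueError("ensemble sample set does not match table")
    if isinstance(groups, pd.Series):
        groups = groups.loc[table.sample_ids].to_numpy()
    _, codes = np.unique(np.asarray(groups), return_inverse=True)
    dm = bray_curtis(table)
    F_obs, _ = _permanova_f(dm.values**2, codes)
    from scipy.spatial.distance import pdist, squareform

    exceed = 0
    for t in ensemble.tables:
        d2 = squareform(pdist(t.astype(float), metric="braycurtis")) ** 2
        F_null, _ = _permanova_f(d2, codes)
        if F_null >= F_obs:
            exceed += 1
    p = (1 + exceed) / (1 + ensemble.n_iter)
    return float(F_obs), float(p)
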