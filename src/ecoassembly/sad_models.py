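"""Species-abundance-distribution curves and model fitting.

Four models are supported: broken-stick (BS, no free parameters),
geometric series (GS, one parameter k), the neutral sampling
distribution for a local community receiving immigrants from a
metacommunity (Volkov; parameters theta and m), and the zero-truncated
Poisson-lognormal (PLN; mu, sigma of the mixing lognormal).

Fitting conventions
-------------------
BS and GS predict an expected abundance per rank and their parameters
are estimated by maximum likelihood under independent Poisson rank
abundances.  Volkov and PLN predict expected species counts per
abundance; Volkov is fitted on octave (doubling abundance class)
frequencies, PLN by per-species zero-truncated maximum likelihood.
For model comparison every fit reports the Poisson log-likelihood of
the observed octave frequencies under its predicted octave counts, so
AIC values are computed on a common basis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .tables_io import CountTable

__all__ = [
    "RankAbundance",
    "SADFit",
    "rank_abundance",
    "normalize_rads",
    "octave_bins",
    "fit_sad",
    "ks_test_sad",
    "compare_models",
    "MODELS",
]

MODELS = ("BS", "GS", "Volkov", "PLN")

_N_PARAMS = {"BS": 0, "GS": 1, "Volkov": 2, "PLN": 2}


@dataclass
class RankAbundance:
    """Descending-sorted positive abundances of one (pooled) community."""

    abundances: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.abundances, dtype=np.int64)
        if a.size == 0:
            raise ValueError("empty rank-abundance vector")
        if np.any(a < 1):
            raise ValueError("rank abundances must be >= 1")
        if np.any(np.diff(a) > 0):
            raise ValueError("abundances must be sorted descending")
        self.abundances = a

    @property
    def S(self) -> int:
        return int(self.abundances.size)

    @property
    def N(self) -> int:
        return int(self.abundances.sum())


@dataclass
class SADFit:
    """A fitted SAD model with predictions and goodness-of-fit."""

    model: str
    params: dict[str, float]
    logLik: float
    AIC: float
    ks_D: float
    ks_p: float
    predicted_rank: np.ndarray
    predicted_octaves: pd.Series
    data_S: int
    data_N: int

    @property
    def n_params(self) -> int:
        return _N_PARAMS[self.model]


def rank_abundance(data: CountTable | Sequence[int] | np.ndarray) -> RankAbundance:
    """Pool counts (if a table), drop zeros, sort descending (stable)."""
    if isinstance(data, CountTable):
        counts = data.taxon_totals().to_numpy()
    else:
        counts = np.asarray(data)
    counts = counts[counts > 0]
    if counts.size == 0:
        raise ValueError("no nonzero taxa")
    # stable descending sort keeps tied taxa in input order
    order = np.argsort(-counts, kind="stable")
    return RankAbundance(counts[order])


def normalize_rads(
    rads: Sequence[RankAbundance],
    target_S: int,
    reps: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Normalized rank-abundance curves at a common species count.

    Each curve is reduced to ``target_S`` ranks by repeatedly drawing
    ``target_S`` species uniformly without replacement, re-sorting and
    renormalizing to relative abundance; the replicates of one curve are
    averaged into a per-sample mean curve.  The returned mean and
    percentile 95% CI are taken across those per-sample curves (the
    subsampling noise itself vanishes as reps grows).
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    for i, ra in enumerate(rads):
        if target_S > ra.S:
            raise ValueError(f"target_S={target_S} exceeds S={ra.S} of curve {i}")
    rng = np.random.default_rng(seed)
    curves = []
    for ra in rads:
        a = ra.abundances.astype(float)
        if ra.S == target_S:
            rel = np.sort(a)[::-1]
            curves.append(rel / rel.sum())
            continue
        acc = np.zeros(target_S)
        for _ in range(reps):
            sub = a[rng.choice(ra.S, size=target_S, replace=False)]
            sub = np.sort(sub)[::-1]
            acc += sub / sub.sum()
        curves.append(acc / reps)
    mat = np.asarray(curves)
    return pd.DataFrame(
        {
            "rank": np.arange(1, target_S + 1),
            "mean": mat.mean(axis=0),
            "ci_lo": np.percentile(mat, 2.5, axis=0),
            "ci_hi": np.percentile(mat, 97.5, axis=0),
        }
    )


def octave_bins(ra: RankAbundance) -> pd.Series:
    """Species count per doubling abundance class [2^j, 2^(j+1))."""
    octs = np.floor(np.log2(ra.abundances)).astype(int)
    n_oct = octs.max() + 1
    counts = np.bincount(octs, minlength=n_oct)
    return pd.Series(counts, index=pd.RangeIndex(n_oct, name="octave"), name="species")


# ---------------------------------------------------------------------------
# model predictions


def broken_stick_ranks(S: int, N: int) -> np.ndarray:
    """Expected abundance of rank i: (N/S) * sum_{x=i..S} 1/x."""
    inv = 1.0 / np.arange(1, S + 1)
    return (N / S) * np.cumsum(inv[::-1])[::-1]


def geometric_series_ranks(S: int, N: int, k: float) -> np.ndarray:
    """Expected abundances N * k(1-k)^(i-1) / (1 - (1-k)^S)."""
    i = np.arange(S)
    w = k * (1 - k) ** i
    return N * w / w.sum()


def _volkov_gamma(J: int, m: float) -> float:
    m = min(m, 1 - 1e-9)
    return m * (J - 1) / (1.0 - m)


def volkov_species_at(n: np.ndarray, J: int, theta: float, m: float, n_quad: int = 160) -> np.ndarray:
    """Expected number of species with abundance n in a neutral local
    community of size J (diversity theta, immigration m).

    Evaluated by Gauss-Legendre quadrature of the sampling formula with
    all gamma-function ratios kept in log space.
    """
    n = np.asarray(n, dtype=float)
    gamma = _volkov_gamma(J, m)
    nodes, weights = np.polynomial.legendre.leggauss(n_quad)
    y = 0.5 * gamma * (nodes + 1.0)  # map [-1,1] -> (0, gamma)
    logw = np.log(0.5 * gamma * weights)
    lg = special.gammaln
    # log integrand, shape (len(n), n_quad)
    li = (
        lg(n[:, None] + y[None, :])
        - lg(1.0 + y[None, :])
        + lg(J - n[:, None] + gamma - y[None, :])
        - lg(gamma - y[None, :])
        - y[None, :] * theta / gamma
    )
    log_integral = special.logsumexp(li + logw[None, :], axis=1)
    log_pref = (
        np.log(theta)
        + lg(J + 1)
        - lg(n + 1)
        - lg(J - n + 1)
        + lg(gamma)
        - lg(J + gamma)
    )
    return np.exp(log_pref + log_integral)


def _pln_log_pmf(n: np.ndarray, mu: float, sigma: float, n_quad: int = 40) -> np.ndarray:
    """log P(n) for the Poisson-lognormal, n >= 0, by mode-centered
    Gauss-Hermite quadrature over t = log(lambda)."""
    n = np.asarray(n, dtype=float)
    s2 = sigma**2
    # Newton for the mode of h(t) = n t - e^t - lgamma(n+1) + log N(t; mu, s2)
    t = np.where(n > 0, np.log(n + 0.5), mu - s2)
    for _ in range(60):
        g = n - np.exp(t) - (t - mu) / s2
        gp = -np.exp(t) - 1.0 / s2
        t = t - g / gp
    scale = 1.0 / np.sqrt(np.exp(t) + 1.0 / s2)  # 1/sqrt(-h''(t*))
    x, w = np.polynomial.hermite.hermgauss(n_quad)
    tk = t[:, None] + np.sqrt(2.0) * scale[:, None] * x[None, :]
    h = (
        n[:, None] * tk
        - np.exp(tk)
        - special.gammaln(n + 1)[:, None]
        - 0.5 * ((tk - mu) / sigma) ** 2
        - np.log(sigma * np.sqrt(2 * np.pi))
    )
    log_int = special.logsumexp(h + np.log(w)[None, :] + x[None, :] ** 2, axis=1)
    return np.log(np.sqrt(2.0) * scale) + log_int


def pln_truncated_log_pmf(n: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    """log P(n | n >= 1) for the zero-truncated Poisson-lognormal."""
    log_p0 = _pln_log_pmf(np.array([0.0]), mu, sigma)[0]
    log_norm = np.log1p(-min(np.exp(log_p0), 1 - 1e-12))
    return _pln_log_pmf(n, mu, sigma) - log_norm


# ---------------------------------------------------------------------------
# octave machinery shared by the abundance-class models


def _octave_edges(n_oct: int) -> list[tuple[int, int]]:
    return [(2**j, 2 ** (j + 1)) for j in range(n_oct)]


def _sum_over_octave(fn: Callable[[np.ndarray], np.ndarray], lo: int, hi: int) -> float:
    """Sum fn(n) over integers n in [lo, hi); wide octaves approximated by
    trapezoidal integration of the smooth density on a geometric grid."""
    width = hi - lo
    if width <= 512:
        return float(fn(np.arange(lo, hi)).sum())
    grid = np.unique(np.round(np.geomspace(lo, hi - 1, 33)).astype(np.int64))
    vals = fn(grid.astype(float))
    return float(np.trapezoid(vals, grid))


def expected_octave_counts(
    fn: Callable[[np.ndarray], np.ndarray], n_oct: int
) -> np.ndarray:
    """Expected species per octave for a species-per-abundance function."""
    return np.array([_sum_over_octave(fn, lo, hi) for lo, hi in _octave_edges(n_oct)])


def _octaves_from_ranks(pred_rank: np.ndarray, n_oct: int) -> np.ndarray:
    octs = np.floor(np.log2(np.maximum(pred_rank, 1e-12))).astype(int)
    octs = np.clip(octs, 0, n_oct - 1)
    return np.bincount(octs, minlength=n_oct).astype(float)


def _octave_poisson_loglik(observed: np.ndarray, expected: np.ndarray) -> float:
    e = np.maximum(expected, 1e-12)
    return float(np.sum(observed * np.log(e) - e - special.gammaln(observed + 1)))


def _ranks_from_distribution(
    fn: Callable[[np.ndarray], np.ndarray], S: int, max_n: int
) -> np.ndarray:
    """Expected abundance per rank via quantiles of the fitted species-
    abundance distribution at plotting positions (i - 0.5)/S."""
    ints = np.arange(1, min(512, max_n) + 1)
    dens_int = np.maximum(fn(ints.astype(float)), 0.0)
    cdf = np.cumsum(dens_int)  # exact over the integer head
    grid = ints.astype(float)
    if max_n > 512:
        geo = np.unique(np.round(np.geomspace(512, max_n, 200)).astype(np.int64))[1:]
        dens_geo = np.maximum(fn(geo.astype(float)), 0.0)
        prev_n, prev_d, tail = 512.0, dens_int[-1], []
        acc = cdf[-1]
        for gn, gd in zip(geo.astype(float), dens_geo):
            acc += (gd + prev_d) / 2 * (gn - prev_n)
            tail.append(acc)
            prev_n, prev_d = gn, gd
        grid = np.concatenate([grid, geo.astype(float)])
        cdf = np.concatenate([cdf, tail])
    if cdf[-1] <= 0:
        return np.full(S, np.nan)
    cdf = cdf / cdf[-1]
    q = (np.arange(1, S + 1) - 0.5) / S  # rank 1 = most abundant
    # survival step-quantiles: rank i gets abundance n where the lower-tail
    # mass first reaches 1 - q (discrete inverse CDF)
    idx = np.clip(np.searchsorted(cdf, 1.0 - q, side="left"), 0, len(grid) - 1)
    return grid[idx]


# ---------------------------------------------------------------------------
# fitting


class FitError(RuntimeError):
    """Raised when a model fit fails to converge."""


def _fit_gs(ra: RankAbundance) -> tuple[float, np.ndarray]:
    obs = ra.abundances.astype(float)

    def nll(k: float) -> float:
        e = np.maximum(geometric_series_ranks(ra.S, ra.N, k), 1e-12)
        return -float(np.sum(obs * np.log(e) - e))

    res = optimize.minimize_scalar(nll, bounds=(1e-6, 1 - 1e-6), method="bounded")
    if not res.success:
        raise FitError(f"GS fit failed: {res.message}")
    k = float(res.x)
    return k, geometric_series_ranks(ra.S, ra.N, k)


def _fit_volkov(ra: RankAbundance, obs_oct: np.ndarray) -> tuple[float, float]:
    J = ra.N
    n_oct = len(obs_oct)

    def nll(params: np.ndarray) -> float:
        log_theta, logit_m = params
        theta = np.exp(log_theta)
        m = 1.0 / (1.0 + np.exp(-logit_m))
        if not np.isfinite(theta) or theta <= 0:
            return 1e12
        fn = lambda n: volkov_species_at(n, J, theta, m)
        exp_oct = expected_octave_counts(fn, n_oct)
        if not np.all(np.isfinite(exp_oct)):
            return 1e12
        return -_octave_poisson_loglik(obs_oct, exp_oct)

    # coarse 5x5 grid start, then Nelder-Mead
    lt_grid = np.log(np.array([5.0, 20.0, 80.0, 320.0, 1280.0]))
    lm_grid = special.logit(np.array([0.02, 0.1, 0.3, 0.6, 0.95]))
    best, best_val = None, np.inf
    for lt in lt_grid:
        for lm in lm_grid:
            v = nll(np.array([lt, lm]))
            if v < best_val:
                best, best_val = np.array([lt, lm]), v
    res = optimize.minimize(
        nll, best, method="Nelder-Mead", options={"xatol": 1e-4, "fatol": 1e-6, "maxiter": 400}
    )
    if not np.isfinite(res.fun):
        raise FitError("Volkov fit diverged")
    theta = float(np.exp(res.x[0]))
    m = float(1.0 / (1.0 + np.exp(-res.x[1])))
    return theta, m


def _fit_pln(ra: RankAbundance) -> tuple[float, float]:
    logs = np.log(ra.abundances.astype(float))
    start = np.array([logs.mean(), np.log(max(logs.std(), 0.1))])
    uniq, counts = np.unique(ra.abundances, return_counts=True)

    def nll(params: np.ndarray) -> float:
        mu, log_sigma = params
        sigma = np.exp(log_sigma)
        if sigma > 20 or sigma < 1e-3:
            return 1e12
        lp = pln_truncated_log_pmf(uniq.astype(float), mu, sigma)
        if not np.all(np.isfinite(lp)):
            return 1e12
        return -float(np.sum(counts * lp))

    res = optimize.minimize(
        nll, start, method="Nelder-Mead", options={"xatol": 1e-5, "fatol": 1e-7, "maxiter": 500}
    )
    if not np.isfinite(res.fun):
        raise FitError("PLN fit diverged")
    return float(res.x[0]), float(np.exp(res.x[1]))


def fit_sad(ra: RankAbundance, model: str) -> SADFit:
    """Fit one SAD model; see module docstring for conventions."""
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}; choose from {MODELS}")
    if model != "BS" and ra.S < 5:
        raise ValueError("parametric SAD fits require S >= 5")
    obs_oct = octave_bins(ra).to_numpy().astype(float)
    n_oct = len(obs_oct)
    max_n = int(ra.abundances.max())

    if model == "BS":
        params: dict[str, float] = {}
        pred_rank = broken_stick_ranks(ra.S, ra.N)
        pred_oct = _octaves_from_ranks(pred_rank, n_oct)
    elif model == "GS":
        k, pred_rank = _fit_gs(ra)
        params = {"k": k}
        pred_oct = _octaves_from_ranks(pred_rank, n_oct)
    elif model == "Volkov":
        theta, m = _fit_volkov(ra, obs_oct)
        params = {"theta": theta, "m": m}
        fn = lambda n: volkov_species_at(n, ra.N, theta, m)
        pred_oct = expected_octave_counts(fn, n_oct)
        pred_rank = _ranks_from_distribution(fn, ra.S, max_n)
    else:  # PLN
        mu, sigma = _fit_pln(ra)
        params = {"mu": mu, "sigma": sigma}
        fn = lambda n: ra.S * np.exp(pln_truncated_log_pmf(n, mu, sigma))
        pred_oct = expected_octave_counts(fn, n_oct)
        pred_rank = _ranks_from_distribution(fn, ra.S, max_n)

    logLik = _octave_poisson_loglik(obs_oct, pred_oct)
    aic = 2 * _N_PARAMS[model] - 2 * logLik
    fit = SADFit(
        model=model,
        params=params,
        logLik=logLik,
        AIC=aic,
        ks_D=np.nan,
        ks_p=np.nan,
        predicted_rank=pred_rank,
        predicted_octaves=pd.Series(pred_oct, name="expected_species"),
        data_S=ra.S,
        data_N=ra.N,
    )
    fit.ks_D, fit.ks_p = ks_test_sad(ra, fit)
    return fit


def ks_test_sad(ra: RankAbundance, fit: SADFit) -> tuple[float, float]:
    """One-sample K-S of the species-abundance CDF against the model CDF.

    The model CDF is built from the predicted rank abundances (fraction
    of species with predicted abundance <= x).  The p-value uses the
    asymptotic K-S distribution and is approximate on discrete data.
    """
    obs = np.sort(ra.abundances.astype(float))
    # predictions are continuous; rounding puts them on the integer support
    # of the observed abundances before the CDFs are compared
    pred = np.sort(np.round(np.asarray(fit.predicted_rank, dtype=float)))
    grid = np.unique(obs)
    # both CDFs are step functions on the integer support, so the sup is
    # attained at the (right-continuous) observed abundance values
    ecdf = np.searchsorted(obs, grid, side="right") / len(obs)
    mcdf = np.searchsorted(pred, grid, side="right") / len(pred)
    D = float(np.max(np.abs(ecdf - mcdf)))
    p = float(stats.kstwobign.sf(D * np.sqrt(len(obs))))
    return D, min(max(p, 0.0), 1.0)


def compare_models(fits: Sequence[SADFit], ks_alpha: float = 0.05) -> pd.DataFrame:
    """Rank fits of one dataset by AIC; flag K-S-rejected models."""
    if len(fits) < 2:
        raise ValueError("need at least 2 fits to compare")
    keys = {(f.data_S, f.data_N) for f in fits}
    if len(keys) > 1:
        raise ValueError("fits were computed on different data")
    df = pd.DataFrame(
        {
            "model": [f.model for f in fits],
            "n_params": [f.n_params for f in fits],
            "logLik": [f.logLik for f in fits],
            "AIC": [f.AIC for f in fits],
            "ks_D": [f.ks_D for f in fits],
            "ks_p": [f.ks_p for f in fits],
        }
    ).sort_values("AIC", kind="stable", ignore_index=True)
    df["delta_AIC"] = df["AIC"] - df["AIC"].iloc[0]
    df["ks_rejected"] = df["ks_p"] < ks_alpha
    return df
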