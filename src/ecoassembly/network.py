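"""Co-occurrence networks: filtering, correlation, RMT thresholding,
topology metrics, node roles and small-world statistics."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .tables_io import CountTable

__all__ = [
    "CorrNetwork",
    "NetworkMetrics",
    "NodeRole",
    "SmallWorld",
    "filter_for_network",
    "correlation_matrix",
    "rmt_threshold",
    "build_network",
    "network_metrics",
    "small_world_sigma",
    "random_ensemble_sigma",
    "node_roles",
    "average_degree",
    "graph_density",
    "edge_sign_percentages",
    "export_network",
]


@dataclass
class CorrNetwork:
    """Signed, thresholded correlation graph over taxa."""

    graph: nx.Graph  # edges carry 'r' and 'sign' attributes
    threshold: float
    method: str = "pearson"

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


@dataclass
class NetworkMetrics:
    n_nodes: int
    n_edges: int
    n_pos: int
    n_neg: int
    pct_pos: float
    pct_neg: float
    modularity: float
    avg_clustering: float
    avg_path_length: float
    diameter: int
    avg_degree: float
    graph_density: float
    modules: dict  # node -> module index
    n_components: int


@dataclass
class NodeRole:
    node: str
    zi: float
    pi: float
    category: str


@dataclass
class SmallWorld:
    avgcc_random: float
    avgcc_random_sd: float
    apl_random: float
    apl_random_sd: float
    modularity_random: float
    modularity_random_sd: float
    sigma: float
    n_random: int


# ---------------------------------------------------------------------------
# closed-form helpers (also used by the acceptance report)


def average_degree(n_nodes: int, n_edges: int) -> float:
    """AD = 2E / N."""
    return 2.0 * n_edges / n_nodes


def graph_density(n_nodes: int, n_edges: int) -> float:
    """GD = 2E / (N (N - 1))."""
    return 2.0 * n_edges / (n_nodes * (n_nodes - 1))


def edge_sign_percentages(n_pos: int, n_neg: int) -> tuple[float, float]:
    """Percent positive and percent negative edges (sum to 100)."""
    total = n_pos + n_neg
    if total == 0:
        raise ValueError("network has no edges")
    return 100.0 * n_pos / total, 100.0 * n_neg / total


def small_world_sigma(
    avgcc: float, avgcc_random: float, apl: float, apl_random: float
) -> float:
    """sigma = (avgCC / avgCC_r) / (APL / APL_r)."""
    return (avgcc / avgcc_random) / (apl / apl_random)


# ---------------------------------------------------------------------------
# construction


def filter_for_network(
    table: CountTable,
    min_rel_abund: float = 0.0005,
    min_occurrence: float = 0.5,
) -> CountTable:
    """Keep taxa with mean relative abundance > min_rel_abund AND present
    in > min_occurrence of samples (both strictly)."""
    if not (0 < min_rel_abund < 1) or not (0 < min_occurrence < 1):
        raise ValueError("thresholds must lie in (0, 1)")
    mat = table.matrix().astype(float)
    rel = mat / mat.sum(axis=1, keepdims=True)
    mean_rel = rel.mean(axis=0)
    occurrence = (mat > 0).mean(axis=0)
    keep = (mean_rel > min_rel_abund) & (occurrence > min_occurrence)
    if not keep.any():
        raise ValueError(
            "no taxa survive the abundance/occurrence filters; relax thresholds"
        )
    kept_cols = [t for t, k in zip(table.taxon_ids, keep) if k]
    lin = table.lineages.loc[kept_cols] if table.lineages is not None else None
    return CountTable(table.counts.loc[:, kept_cols].copy(), lin)


def correlation_matrix(table: CountTable, method: str = "pearson") -> pd.DataFrame:
    """Pearson correlations between taxa on per-sample relative abundances.

    Zero-variance taxa are dropped with a warning.
    """
    if method != "pearson":
        raise ValueError("only 'pearson' is supported")
    if table.n_samples < 4:
        raise ValueError("need at least 4 samples for correlations")
    mat = table.matrix().astype(float)
    rel = mat / mat.sum(axis=1, keepdims=True)
    sd = rel.std(axis=0)
    keep = sd > 0
    if not keep.all():
        dropped = [t for t, k in zip(table.taxon_ids, keep) if not k]
        warnings.warn(f"zero-variance taxa dropped from correlations: {dropped}")
    cols = [t for t, k in zip(table.taxon_ids, keep) if k]
    r = np.corrcoef(rel[:, keep], rowvar=False)
    np.fill_diagonal(r, 1.0)
    return pd.DataFrame(r, index=cols, columns=cols)


def _unfolded_spacings(evals: np.ndarray) -> np.ndarray:
    """Nearest-neighbour spacings after unfolding by a smooth cubic fit of
    the cumulative spectral function."""
    lam = np.sort(evals)
    n = len(lam)
    cdf = np.arange(1, n + 1, dtype=float)
    coef = np.polyfit(lam, cdf, 3)
    unfolded = np.polyval(coef, lam)
    spacings = np.diff(unfolded)
    spacings = spacings[spacings > 0]
    if len(spacings) == 0:
        return spacings
    return spacings / spacings.mean()


def _poisson_spacing_pvalue(spacings: np.ndarray, n_bins: int = 20) -> float:
    """Chi-square goodness of fit of unit-mean spacings against the
    Poisson (exponential) nearest-neighbour spacing law."""
    if len(spacings) < n_bins:
        n_bins = max(len(spacings) // 2, 2)
    edges = -np.log(1 - np.linspace(0, 1, n_bins + 1)[:-1])  # equal-probability bins
    edges = np.append(edges, np.inf)
    obs, _ = np.histogram(spacings, bins=edges)
    expected = len(spacings) / n_bins
    chi2 = float(((obs - expected) ** 2 / expected).sum())
    return float(stats.chi2.sf(chi2, df=n_bins - 1))


def rmt_threshold(
    corr: pd.DataFrame,
    scan: np.ndarray | None = None,
    alpha: float = 0.05,
    fallback: float = 0.8,
) -> tuple[float, pd.DataFrame]:
    """Random-matrix-theory threshold scan.

    For each candidate threshold the correlation matrix is hard-
    thresholded, restricted to taxa retaining at least one edge, and the
    unfolded eigenvalue spacing distribution is tested against the
    Poisson law.  The chosen threshold is the lowest candidate at which
    Poisson statistics are not rejected (chi-square p >= alpha).  If no
    candidate qualifies the configured fallback is returned with a
    warning.  Returns (threshold, diagnostics table).
    """
    if scan is None:
        scan = np.arange(0.3, 0.96, 0.05)
    scan = np.asarray(scan, dtype=float)
    if np.any((scan <= 0) | (scan >= 1)):
        raise ValueError("scan values must lie in (0, 1)")
    R = corr.to_numpy().copy()
    diag = []
    chosen = None
    for s in np.sort(scan):
        M = np.where(np.abs(R) >= s, R, 0.0)
        np.fill_diagonal(M, 1.0)
        deg = (np.abs(M) > 0).sum(axis=1) - 1
        active = deg > 0
        n_active = int(active.sum())
        n_edges = int((np.abs(M[np.ix_(active, active)]) > 0).sum() - n_active) // 2
        if n_active < 10:
            diag.append((s, n_active, n_edges, np.nan))
            continue
        evals = np.linalg.eigvalsh(M[np.ix_(active, active)])
        spacings = _unfolded_spacings(evals)
        p = _poisson_spacing_pvalue(spacings) if len(spacings) > 5 else np.nan
        diag.append((s, n_active, n_edges, p))
        if chosen is None and np.isfinite(p) and p >= alpha:
            chosen = float(s)
    table = pd.DataFrame(diag, columns=["threshold", "n_active", "n_edges", "poisson_p"])
    if chosen is None:
        warnings.warn(
            f"RMT scan found no threshold with Poisson spacings; "
            f"falling back to fixed threshold {fallback}"
        )
        chosen = fallback
    return chosen, table


def build_network(corr: pd.DataFrame, threshold: float) -> CorrNetwork:
    """Edges where |r| >= threshold; isolated nodes dropped."""
    if not (0 < threshold <= 1):
        raise ValueError("threshold must lie in (0, 1]")
    R = corr.to_numpy()
    names = list(corr.columns)
    g = nx.Graph()
    iu, ju = np.triu_indices(len(names), k=1)
    mask = np.abs(R[iu, ju]) >= threshold
    for i, j in zip(iu[mask], ju[mask]):
        r = float(R[i, j])
        g.add_edge(names[i], names[j], r=r, sign=1 if r >= 0 else -1)
    if g.number_of_edges() == 0:
        raise ValueError(f"no edges at threshold {threshold}; relax the threshold")
    return CorrNetwork(graph=g, threshold=threshold)


def _modularity_partition(g: nx.Graph) -> tuple[dict, float]:
    """Fast greedy (CNM) modularity communities on the unsigned graph."""
    communities = nx.community.greedy_modularity_communities(g, weight=None)
    membership = {}
    for k, comm in enumerate(communities):
        for node in sorted(comm):
            membership[node] = k
    q = nx.community.modularity(g, communities, weight=None)
    return membership, float(q)


def network_metrics(net: CorrNetwork) -> NetworkMetrics:
    """Topology panel: N, E, sign split, modularity, avgCC, APL, diameter,
    AD, GD.  Path-based metrics are computed on the largest connected
    component."""
    g = net.graph
    if g.number_of_edges() < 1:
        raise ValueError("network has no edges")
    n, e = g.number_of_nodes(), g.number_of_edges()
    n_pos = sum(1 for _, _, d in g.edges(data=True) if d.get("sign", 1) > 0)
    n_neg = e - n_pos
    pct_pos, pct_neg = edge_sign_percentages(n_pos, n_neg)
    components = list(nx.connected_components(g))
    lcc = g.subgraph(max(components, key=len))
    membership, q = _modularity_partition(g)
    return NetworkMetrics(
        n_nodes=n,
        n_edges=e,
        n_pos=n_pos,
        n_neg=n_neg,
        pct_pos=pct_pos,
        pct_neg=pct_neg,
        modularity=q,
        avg_clustering=float(nx.average_clustering(g)),
        avg_path_length=float(nx.average_shortest_path_length(lcc)) if len(lcc) > 1 else 0.0,
        diameter=int(nx.diameter(lcc)) if len(lcc) > 1 else 0,
        avg_degree=average_degree(n, e),
        graph_density=graph_density(n, e),
        modules=membership,
        n_components=len(components),
    )


def random_ensemble_sigma(
    metrics: NetworkMetrics, n_random: int = 100, seed: int = 0
) -> SmallWorld:
    """Small-world sigma against an Erdos-Renyi G(N, E) ensemble."""
    if n_random < 10:
        raise ValueError("n_random must be >= 10")
    N, E = metrics.n_nodes, metrics.n_edges
    if E > N * (N - 1) // 2:
        raise ValueError("more edges than possible for N nodes")
    rng = np.random.default_rng(seed)
    ccs, apls, mods = [], [], []
    for _ in range(n_random):
        g = nx.gnm_random_graph(N, E, seed=int(rng.integers(2**31)))
        ccs.append(nx.average_clustering(g))
        lcc = g.subgraph(max(nx.connected_components(g), key=len))
        apls.append(nx.average_shortest_path_length(lcc) if len(lcc) > 1 else 0.0)
        _, q = _modularity_partition(g)
        mods.append(q)
    cc_r, apl_r = float(np.mean(ccs)), float(np.mean(apls))
    sigma = small_world_sigma(metrics.avg_clustering, cc_r, metrics.avg_path_length, apl_r)
    return SmallWorld(
        avgcc_random=cc_r,
        avgcc_random_sd=float(np.std(ccs, ddof=1)),
        apl_random=apl_r,
        apl_random_sd=float(np.std(apls, ddof=1)),
        modularity_random=float(np.mean(mods)),
        modularity_random_sd=float(np.std(mods, ddof=1)),
        sigma=float(sigma),
        n_random=n_random,
    )


def node_roles(net: CorrNetwork, modules: dict) -> list[NodeRole]:
    """Within-module degree z-score (zi) and among-module connectivity (Pi)
    with the 2.5 / 0.62 cutlines for the four node categories."""
    g = net.graph
    missing = [v for v in g.nodes if v not in modules]
    if missing:
        raise ValueError(f"nodes without module assignment: {missing}")
    # within-module degree per node
    k_within = {}
    for v in g.nodes:
        k_within[v] = sum(1 for u in g.neighbors(v) if modules[u] == modules[v])
    by_module: dict[int, list] = {}
    for v in g.nodes:
        by_module.setdefault(modules[v], []).append(k_within[v])
    mod_mean = {m: float(np.mean(ks)) for m, ks in by_module.items()}
    mod_sd = {m: float(np.std(ks)) for m, ks in by_module.items()}
    roles = []
    for v in g.nodes:
        m = modules[v]
        zi = (k_within[v] - mod_mean[m]) / mod_sd[m] if mod_sd[m] > 0 else 0.0
        k_total = g.degree(v)
        link_share: dict[int, int] = {}
        for u in g.neighbors(v):
            link_share[modules[u]] = link_share.get(modules[u], 0) + 1
        pi = 1.0 - sum((k / k_total) ** 2 for k in link_share.values()) if k_total else 0.0
        if zi >= 2.5 and pi >= 0.62:
            cat = "network hub"
        elif zi >= 2.5:
            cat = "module hub"
        elif pi >= 0.62:
            cat = "connector"
        else:
            cat = "peripheral"
        roles.append(NodeRole(node=str(v), zi=float(zi), pi=float(pi), category=cat))
    return roles


def export_network(
    net: CorrNetwork,
    metrics: NetworkMetrics,
    roles: list[NodeRole],
    out_dir: str | Path,
    prefix: str = "network",
    phylum: pd.Series | None = None,
) -> dict[str, Path]:
    """Write GraphML, a signed edge list TSV and a node attribute TSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    gml = out_dir / f"{prefix}.graphml"
    nx.write_graphml(net.graph, gml)
    paths["graphml"] = gml
    edges = pd.DataFrame(
        [(u, v, d["r"], d["sign"]) for u, v, d in net.graph.edges(data=True)],
        columns=["source", "target", "r", "sign"],
    )
    ep = out_dir / f"{prefix}_edges.tsv"
    edges.to_csv(ep, sep="\t", index=False)
    paths["edges"] = ep
    role_map = {r.node: r for r in roles}
    nodes = pd.DataFrame(
        {
            "node": list(net.graph.nodes),
            "degree": [net.graph.degree(v) for v in net.graph.nodes],
            "module": [metrics.modules[v] for v in net.graph.nodes],
            "zi": [role_map[str(v)].zi for v in net.graph.nodes],
            "pi": [role_map[str(v)].pi for v in net.graph.nodes],
            "role": [role_map[str(v)].category for v in net.graph.nodes],
        }
    )
    if phylum is not None:
        nodes["phylum"] = [phylum.get(v, "unclassified") for v in nodes["node"]]
    np_path = out_dir / f"{prefix}_nodes.tsv"
    nodes.to_csv(np_path, sep="\t", index=False)
    paths["nodes"] = np_path
    return paths
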