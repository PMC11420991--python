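"""Co-occurrence network inference and global topology.

Per sample group: prevalence filtering, centered log-ratio transform,
all-pairs Spearman correlation, threshold selection (a fixed cutoff or a
random-matrix-theory scan of nearest-neighbour eigenvalue spacings), and a
signed undirected network over the surviving OTU pairs. The topology
record mirrors the conventional global statistics reported for microbial
networks: node/edge counts with sign partition, modularity of a greedy
module partition, power-law fit of the degree distribution, average
degree, average path distance, and geodesic efficiency.

Threshold semantics: an edge is kept when |r| >= threshold (closed rule,
stable under floating point; the open ">" variant differs only on exact
ties). "Total nodes" counts nodes with at least one incident edge —
isolated OTUs are not part of a co-occurrence network.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import networkx as nx
from scipy import stats
from scipy.interpolate import LSQUnivariateSpline

from .io import CountTable

__all__ = [
    "CooccurrenceNetwork",
    "TopologyRecord",
    "RmtScanResult",
    "prevalence_filter",
    "clr_transform",
    "spearman_matrix",
    "rmt_select_threshold",
    "build_network",
    "global_topology",
    "infer_group_network",
]


@dataclass
class CooccurrenceNetwork:
    """Signed weighted undirected graph over OTUs.

    ``edges`` holds (otu_a, otu_b, r) with otu_a < otu_b; nodes are the
    OTUs with at least one incident edge.
    """

    edges: list[tuple[str, str, float]]
    threshold_used: float
    mode: str
    group: str

    def __post_init__(self) -> None:
        canon = []
        seen = set()
        for a, b, r in self.edges:
            if a == b:
                raise ValueError(f"self-edge on {a!r}")
            a, b = (a, b) if a < b else (b, a)
            if (a, b) in seen:
                raise ValueError(f"duplicate edge ({a}, {b})")
            seen.add((a, b))
            canon.append((a, b, float(r)))
        self.edges = sorted(canon)

    @property
    def nodes(self) -> list[str]:
        out: set[str] = set()
        for a, b, _ in self.edges:
            out.add(a)
            out.add(b)
        return sorted(out)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def positive_edges(self) -> int:
        return sum(1 for _, _, r in self.edges if r > 0)

    def negative_edges(self) -> int:
        return sum(1 for _, _, r in self.edges if r < 0)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for a, b, r in self.edges:
            g.add_edge(a, b, r=r, weight=abs(r), sign="+" if r > 0 else "-")
        return g


@dataclass
class TopologyRecord:
    total_nodes: int
    total_edges: int
    positive_edges: int
    negative_edges: int
    n_modules: int
    modularity: float
    powerlaw_r2: float
    average_degree: float
    average_path_distance: float
    geodesic_efficiency: float
    threshold_used: float = float("nan")
    mode: str = ""
    group: str = ""
    empty: bool = False

    def to_series(self) -> pd.Series:
        return pd.Series(
            {
                "total_nodes": self.total_nodes,
                "total_edges": self.total_edges,
                "positive_edges": self.positive_edges,
                "negative_edges": self.negative_edges,
                "n_modules": self.n_modules,
                "modularity": self.modularity,
                "powerlaw_r2": self.powerlaw_r2,
                "average_degree": self.average_degree,
                "average_path_distance": self.average_path_distance,
                "geodesic_efficiency": self.geodesic_efficiency,
                "threshold_used": self.threshold_used,
                "mode": self.mode,
            },
            name=self.group,
        )


@dataclass
class RmtScanResult:
    thresholds: np.ndarray
    chi2: np.ndarray
    pvalues: np.ndarray
    chosen: float
    alpha: float
    degenerate: np.ndarray = field(default_factory=lambda: np.array([], dtype=bool))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "chi2": self.chi2,
                "p_value": self.pvalues,
                "degenerate": self.degenerate,
            }
        )


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def prevalence_filter(
    table: CountTable,
    group_samples: list[str] | None = None,
    min_fraction: float = 7 / 9,
) -> CountTable:
    """Keep OTUs detected in at least ceil(min_fraction * n) group samples.

    With the default 7/9 this is the "present in at least 7 of 9
    replicates" detection-rate rule.
    """
    sub = table if group_samples is None else table.select_samples(group_samples)
    n = sub.shape[0]
    if n < 3:
        raise ValueError("prevalence filter needs at least 3 samples")
    need = int(np.ceil(min_fraction * n))
    present = (sub.counts > 0).sum(axis=0)
    keep = [o for o, c in zip(sub.otu_ids, present) if c >= need]
    if not keep:
        raise ValueError(
            "no OTU passes the prevalence filter; lower min_fraction"
        )
    return sub.select_otus(keep)


def clr_transform(table: CountTable | np.ndarray, pseudocount: float = 1.0) -> np.ndarray:
    """Centered log-ratio transform, row-wise, with a pseudocount for zeros.

    x_ij = log(c_ij + pc) - mean_j log(c_ij + pc); every row sums to zero.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    x = table.counts if isinstance(table, CountTable) else np.asarray(table)
    logs = np.log(x.astype(float) + pseudocount)
    return logs - logs.mean(axis=1, keepdims=True)


def spearman_matrix(x: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """All-pairs Spearman correlation over columns of ``x`` (samples × OTUs).

    Returns (r, p, constant_flag). Ties get average ranks; p-values come
    from the t approximation. Constant columns are flagged and their
    correlations set to 0.
    """
    x = np.asarray(x, dtype=float)
    n, m = x.shape
    if n < 4:
        raise ValueError("need at least 4 samples for correlation")
    ranks = stats.rankdata(x, axis=0)
    constant = ranks.std(axis=0) == 0
    centered = ranks - ranks.mean(axis=0)
    denom = np.sqrt((centered**2).sum(axis=0))
    denom[denom == 0] = 1.0
    normed = centered / denom
    r = normed.T @ normed
    r[constant, :] = 0.0
    r[:, constant] = 0.0
    np.fill_diagonal(r, 1.0)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.isnan(p)] = 0.0  # |r| == 1
    np.fill_diagonal(p, 0.0)
    return r, p, constant


# ---------------------------------------------------------------------------
# RMT threshold selection
# ---------------------------------------------------------------------------

def _nnsd_poisson_test(
    eigenvalues: np.ndarray, n_bins: int = 30, s_max: float = 3.0
) -> tuple[float, float]:
    """Chi-square goodness of fit of the NNSD against the Poisson law e^-s.

    The spectrum is unfolded with a smoothing cubic spline fitted to the
    empirical cumulative spectral density, spacings are normalized to unit
    mean, histogrammed on [0, s_max], and compared to the exponential
    distribution's expected bin masses.
    """
    ev = np.sort(eigenvalues)
    if np.ptp(ev) < 1e-12:
        raise ValueError("degenerate spectrum: all eigenvalues equal")
    # degenerate multiplicities (isolated stars/paths pin eigenvalues at 1)
    # carry no spacing information; unfold distinct eigenvalues only
    uniq = np.unique(np.round(ev, 10))
    if len(uniq) < 10:
        raise ValueError("degenerate spectrum: too few distinct eigenvalues")
    n = len(uniq)
    cdf_u = (np.arange(1, n + 1) - 0.5) / n
    k = min(3, len(uniq) - 1)
    # few interior knots at quantiles: the fit tracks the smooth spectral
    # density, not the staircase, so spacings keep their local fluctuations
    n_knots = int(np.clip(len(uniq) // 8, 3, 10))
    knots = np.unique(np.quantile(uniq, np.linspace(0, 1, n_knots + 2)[1:-1]))
    knots = knots[(knots > uniq[0]) & (knots < uniq[-1])]
    if len(knots) == 0:
        raise ValueError("degenerate spectrum: no usable interior knots")
    spline = LSQUnivariateSpline(uniq, cdf_u, knots, k=k)
    unfolded = n * spline(uniq)
    spacings = np.diff(np.sort(unfolded))
    mean_s = spacings.mean()
    if mean_s <= 0:
        raise ValueError("degenerate spacings")
    spacings = spacings / mean_s
    obs, edges = np.histogram(spacings, bins=n_bins, range=(0.0, s_max))
    expected = np.exp(-edges[:-1]) - np.exp(-edges[1:])
    expected = expected / expected.sum() * obs.sum()
    # merge low-expectation bins to keep the chi-square approximation honest
    obs_m, exp_m = [], []
    acc_o = acc_e = 0.0
    for o, e in zip(obs, expected):
        acc_o += o
        acc_e += e
        if acc_e >= 1.0:
            obs_m.append(acc_o)
            exp_m.append(acc_e)
            acc_o = acc_e = 0.0
    if acc_e > 0:
        if exp_m:
            obs_m[-1] += acc_o
            exp_m[-1] += acc_e
        else:
            obs_m, exp_m = [acc_o], [acc_e]
    obs_a = np.array(obs_m)
    exp_a = np.array(exp_m)
    chi2 = float(((obs_a - exp_a) ** 2 / exp_a).sum())
    df = max(len(obs_a) - 1, 1)
    p = float(stats.chi2.sf(chi2, df))
    return chi2, p


def rmt_select_threshold(
    r: np.ndarray,
    t_min: float = 0.3,
    t_max: float = 0.99,
    step: float = 0.01,
    alpha: float = 0.05,
) -> RmtScanResult:
    """Scan thresholds; choose the smallest whose NNSD fits Poisson.

    For each t the correlation matrix is hard-thresholded (|r| < t zeroed,
    diagonal kept), isolated variables dropped, and the nearest-neighbour
    spacing distribution of the unfolded eigenvalues is tested against the
    Poisson law; the chosen threshold is the smallest t with p > alpha.
    """
    r = np.asarray(r, dtype=float)
    if r.shape[0] != r.shape[1] or not np.allclose(r, r.T, atol=1e-8):
        raise ValueError("correlation matrix must be square and symmetric")
    if r.shape[0] < 20:
        raise ValueError("need at least 20 OTUs for a meaningful spectrum")
    thresholds = np.round(np.arange(t_min, t_max + step / 2, step), 10)
    chi2s, ps, degen = [], [], []
    chosen = None
    off = r - np.diag(np.diag(r))
    for t in thresholds:
        m = np.where(np.abs(off) >= t, off, 0.0)
        connected = (m != 0).any(axis=0)
        sub = m[np.ix_(connected, connected)]
        np.fill_diagonal(sub, 1.0)
        try:
            chi2, p = _nnsd_poisson_test(np.linalg.eigvalsh(sub))
            degen.append(False)
        except (ValueError, np.linalg.LinAlgError):
            chi2, p = np.nan, np.nan
            degen.append(True)
        chi2s.append(chi2)
        ps.append(p)
        if chosen is None and np.isfinite(p) and p > alpha:
            chosen = float(t)
    if chosen is None:
        raise ValueError(
            "no scanned threshold passes the Poisson NNSD test; "
            "consider fixed-threshold mode"
        )
    return RmtScanResult(
        thresholds=thresholds,
        chi2=np.array(chi2s),
        pvalues=np.array(ps),
        chosen=chosen,
        alpha=alpha,
        degenerate=np.array(degen, dtype=bool),
    )


# ---------------------------------------------------------------------------
# Network build + topology
# ---------------------------------------------------------------------------

def build_network(
    r: np.ndarray,
    threshold: float,
    otu_ids: list[str],
    group: str = "",
    mode: str = "fixed",
) -> CooccurrenceNetwork:
    """Signed network with an edge wherever |r| >= threshold (i < j pairs)."""
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    r = np.asarray(r, dtype=float)
    iu = np.triu_indices(len(otu_ids), k=1)
    mask = np.abs(r[iu]) >= threshold
    edges = [
        (otu_ids[i], otu_ids[j], float(r[i, j]))
        for i, j in zip(iu[0][mask], iu[1][mask])
    ]
    return CooccurrenceNetwork(
        edges=edges, threshold_used=float(threshold), mode=mode, group=group
    )


def _powerlaw_r2(degrees: list[int]) -> float:
    """R^2 of OLS on log(frequency) vs log(degree), nonzero-frequency degrees."""
    vals, counts = np.unique(np.asarray(degrees), return_counts=True)
    keep = vals > 0
    vals, counts = vals[keep], counts[keep]
    if len(vals) < 2:
        return 1.0 if len(vals) == 1 else 0.0
    x = np.log(vals.astype(float))
    y = np.log(counts.astype(float))
    slope, intercept = np.polyfit(x, y, 1)
    fitted = slope * x + intercept
    ss_res = float(((y - fitted) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0:
        return 1.0
    return 1.0 - ss_res / ss_tot


def global_topology(net: CooccurrenceNetwork) -> TopologyRecord:
    """Global topological statistics of a co-occurrence network.

    Modules come from deterministic greedy (CNM) modularity maximization on
    the unsigned graph; average path distance averages shortest-path
    lengths over connected ordered pairs; geodesic efficiency averages 1/d
    over all ordered distinct pairs with unreachable pairs contributing 0.
    """
    if net.n_edges == 0:
        return TopologyRecord(
            0, 0, 0, 0, 0, 0.0, 0.0, 0.0, 0.0, 0.0,
            threshold_used=net.threshold_used, mode=net.mode, group=net.group,
            empty=True,
        )
    g = net.to_networkx()
    n = g.number_of_nodes()
    e = g.number_of_edges()
    communities = list(
        nx.community.greedy_modularity_communities(g, weight=None)
    )
    q = nx.community.modularity(g, communities, weight=None)
    degrees = [d for _, d in g.degree()]
    # shortest-path statistics
    sum_d = 0.0
    n_connected_pairs = 0
    sum_inv = 0.0
    for _, dist in nx.all_pairs_shortest_path_length(g):
        for target, dv in dist.items():
            if dv > 0:
                sum_d += dv
                n_connected_pairs += 1
                sum_inv += 1.0 / dv
    apd = sum_d / n_connected_pairs if n_connected_pairs else 0.0
    eff = sum_inv / (n * (n - 1)) if n > 1 else 0.0
    return TopologyRecord(
        total_nodes=n,
        total_edges=e,
        positive_edges=net.positive_edges(),
        negative_edges=net.negative_edges(),
        n_modules=len(communities),
        modularity=float(q),
        powerlaw_r2=_powerlaw_r2(degrees),
        average_degree=2.0 * e / n,
        average_path_distance=apd,
        geodesic_efficiency=eff,
        threshold_used=net.threshold_used,
        mode=net.mode,
        group=net.group,
    )


def infer_group_network(
    table: CountTable,
    group_samples: list[str],
    group_label: str = "",
    min_fraction: float = 7 / 9,
    pseudocount: float = 1.0,
    threshold_mode: str = "fixed",
    fixed_threshold: float = 0.9,
    rmt_kwargs: dict | None = None,
) -> tuple[CooccurrenceNetwork, RmtScanResult | None]:
    """Full inference for one group: filter → CLR → Spearman → threshold → net."""
    filtered = prevalence_filter(table, group_samples, min_fraction)
    x = clr_transform(filtered, pseudocount)
    r, _p, _flags = spearman_matrix(x)
    scan = None
    if threshold_mode == "rmt":
        scan = rmt_select_threshold(r, **(rmt_kwargs or {}))
        threshold = scan.chosen
    elif threshold_mode == "fixed":
        threshold = fixed_threshold
    else:
        raise ValueError(f"unknown threshold mode {threshold_mode!r}")
    net = build_network(
        r, threshold, filtered.otu_ids, group=group_label, mode=threshold_mode
    )
    return net, scan
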