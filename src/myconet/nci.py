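"""Per-sample subnetwork features and the Network Complexity Index (NCI).

Each sample's subnetwork is the group network induced on the OTUs the
sample actually contains. Six topological features are computed per
subnetwork — node count, edge count, average density, transitivity,
diameter and average path length, the last two entering the feature
matrix in inverse form (1/X, so larger = tighter = more complex, with 0
for undefined) — and the NCI is the first principal component of the
pooled, z-scored feature matrix, sign-oriented so that more edges means a
higher index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import networkx as nx

from .io import CountTable, SampleMetadata
from .network import CooccurrenceNetwork

__all__ = [
    "SubnetworkFeatures",
    "NCIResult",
    "FEATURE_COLUMNS",
    "sample_subnetwork",
    "subnetwork_features",
    "feature_table",
    "nci_scores",
]

FEATURE_COLUMNS = (
    "n_nodes",
    "n_edges",
    "average_density",
    "transitivity",
    "diameter_inv",
    "path_length_inv",
)


@dataclass
class SubnetworkFeatures:
    sample_id: str
    n_nodes: int
    n_edges: int
    average_density: float
    transitivity: float
    diameter: float
    average_path_length: float
    diameter_inv: float
    path_length_inv: float

    def feature_vector(self) -> np.ndarray:
        return np.array(
            [
                self.n_nodes,
                self.n_edges,
                self.average_density,
                self.transitivity,
                self.diameter_inv,
                self.path_length_inv,
            ],
            dtype=float,
        )


@dataclass
class NCIResult:
    scores: pd.Series  # sample_id -> NCI (PC1 score)
    loadings: pd.DataFrame  # features × components
    variance_explained: np.ndarray
    means: pd.Series
    sds: pd.Series
    degenerate: bool = False
    dropped_features: list[str] | None = None


def sample_subnetwork(
    net: CooccurrenceNetwork, sample_counts: np.ndarray, otu_ids: list[str]
) -> nx.Graph:
    """Group network induced on the OTUs detected (count > 0) in a sample."""
    present = {o for o, c in zip(otu_ids, sample_counts) if c > 0}
    g = net.to_networkx()
    keep = [n for n in g.nodes if n in present]
    return g.subgraph(keep).copy()


def subnetwork_features(g: nx.Graph, sample_id: str = "") -> SubnetworkFeatures:
    """Six topological features of one sample subnetwork.

    Diameter and average path length are computed on the largest connected
    component; with fewer than 2 nodes or no edges the density,
    transitivity and inverse-form fields are 0.
    """
    n = g.number_of_nodes()
    e = g.number_of_edges()
    if n < 2 or e == 0:
        return SubnetworkFeatures(sample_id, n, e, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0)
    density = 2.0 * e / (n * (n - 1))
    transitivity = nx.transitivity(g)
    comp = max(nx.connected_components(g), key=lambda c: (len(c), sorted(c)))
    sub = g.subgraph(comp)
    if sub.number_of_nodes() >= 2:
        diam = float(nx.diameter(sub))
        apl = float(nx.average_shortest_path_length(sub))
    else:
        diam = apl = 0.0
    diam_inv = 1.0 / diam if diam > 0 else 0.0
    apl_inv = 1.0 / apl if apl > 0 else 0.0
    return SubnetworkFeatures(
        sample_id, n, e, density, transitivity, diam, apl, diam_inv, apl_inv
    )


def feature_table(
    networks: dict[str, CooccurrenceNetwork],
    table: CountTable,
    meta: SampleMetadata,
) -> pd.DataFrame:
    """Subnetwork feature matrix for every sample (rows) × 6 features.

    ``networks`` maps group labels ("DG_Apr", ...) to their group network;
    each sample is cut from its own group's network.
    """
    rows = {}
    for sid in table.sample_ids:
        lu, se = meta.group_of(sid)
        label = f"{lu}_{se}"
        if label not in networks:
            raise KeyError(f"no network for group {label!r}")
        g = sample_subnetwork(
            networks[label], table.counts[table.sample_index(sid)], table.otu_ids
        )
        feats = subnetwork_features(g, sid)
        rows[sid] = dict(zip(FEATURE_COLUMNS, feats.feature_vector()))
    return pd.DataFrame.from_dict(rows, orient="index")[list(FEATURE_COLUMNS)]


def nci_scores(features: pd.DataFrame, sign_feature: str = "n_edges") -> NCIResult:
    """NCI = PC1 scores of the pooled, z-scored subnetwork feature matrix.

    Zero-variance feature columns are dropped (with a record); the PC1
    sign is oriented so the loading on ``sign_feature`` is >= 0. If every
    column is constant the result is flagged degenerate with all scores 0.
    """
    if features.shape[0] < 3:
        raise ValueError("need at least 3 samples for a PCA")
    x = features.to_numpy(dtype=float)
    means = x.mean(axis=0)
    sds = x.std(axis=0, ddof=1)
    keep = sds > 0
    dropped = [c for c, k in zip(features.columns, keep) if not k]
    if not keep.any():
        return NCIResult(
            scores=pd.Series(0.0, index=features.index, name="NCI"),
            loadings=pd.DataFrame(index=features.columns),
            variance_explained=np.array([]),
            means=pd.Series(means, index=features.columns),
            sds=pd.Series(sds, index=features.columns),
            degenerate=True,
            dropped_features=dropped,
        )
    cols = [c for c, k in zip(features.columns, keep) if k]
    z = (x[:, keep] - means[keep]) / sds[keep]
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    var = s**2 / max(len(z) - 1, 1)
    var_explained = var / var.sum()
    loadings = pd.DataFrame(
        vt.T, index=cols, columns=[f"PC{i + 1}" for i in range(vt.shape[0])]
    )
    scores = z @ vt.T
    if sign_feature in cols:
        sgn = np.sign(loadings.loc[sign_feature, "PC1"]) or 1.0
    else:
        sgn = np.sign(loadings["PC1"].sum()) or 1.0
    loadings["PC1"] *= sgn
    pc1 = pd.Series(scores[:, 0] * sgn, index=features.index, name="NCI")
    return NCIResult(
        scores=pc1,
        loadings=loadings,
        variance_explained=var_explained,
        means=pd.Series(means, index=features.columns),
        sds=pd.Series(sds, index=features.columns),
        degenerate=False,
        dropped_features=dropped,
    )
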