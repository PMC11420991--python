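"""Alpha and beta diversity: rarefaction, Shannon, ACE, Bray-Curtis,
Hellinger, NMDS ordination, and Mantel tests.

Alpha indices follow the classical definitions: Shannon entropy
H = -sum p_i log p_i (natural log by default) and the abundance-based
coverage estimator (ACE) of richness with the standard rare-species cutoff
of 10. Beta diversity is Bray-Curtis, with Hellinger standardization
available ahead of ordination.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform, pdist
from scipy import stats
from scipy.stats import spearmanr, pearsonr

from .io import CountTable, TaxonomyTable

__all__ = [
    "DiversityResult",
    "DistanceMatrix",
    "NmdsResult",
    "MantelResult",
    "rarefy",
    "shannon",
    "ace",
    "observed_otus",
    "alpha_diversity",
    "bray_curtis",
    "hellinger",
    "nmds",
    "mantel",
    "euclidean_distance",
    "dominant_phyla",
]


@dataclass
class DiversityResult:
    """Per-sample alpha diversity (observed OTUs, Shannon, ACE)."""

    table: pd.DataFrame  # index sample_id, columns observed_otus/shannon/ace

    def to_dataframe(self) -> pd.DataFrame:
        return self.table


@dataclass
class DistanceMatrix:
    ids: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.d), 0):
            raise ValueError("distance matrix diagonal must be zero")
        if (self.d < -1e-12).any():
            raise ValueError("distances must be non-negative")

    def condensed(self) -> np.ndarray:
        return squareform(self.d, checks=False)


@dataclass
class NmdsResult:
    coordinates: np.ndarray
    stress: float
    k: int
    converged: bool
    ids: list[str]


@dataclass
class MantelResult:
    r: float
    p: float
    n_perm: int
    method: str


# ---------------------------------------------------------------------------
# Rarefaction
# ---------------------------------------------------------------------------

def rarefy(table: CountTable, seed: int | np.random.Generator = 0) -> CountTable:
    """Subsample every sample, without replacement, to the minimum depth.

    Equalizes sequencing effort across samples the way QIIME's single
    rarefaction does. Deterministic given the seed.
    """
    depths = table.depths()
    if (depths == 0).any():
        zero = [s for s, d in zip(table.sample_ids, depths) if d == 0]
        raise ValueError(f"samples with zero depth cannot be rarefied: {zero}")
    target = int(depths.min())
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    out = np.zeros_like(table.counts)
    for i, row in enumerate(table.counts):
        depth = int(row.sum())
        if depth == target:
            out[i] = row
            continue
        # draw `target` reads uniformly from the sample's read pool
        chosen = rng.choice(depth, size=target, replace=False)
        boundaries = np.cumsum(row)
        otu_of_read = np.searchsorted(boundaries, chosen, side="right")
        out[i] = np.bincount(otu_of_read, minlength=len(row))
    return CountTable(list(table.sample_ids), list(table.otu_ids), out)


# ---------------------------------------------------------------------------
# Alpha diversity
# ---------------------------------------------------------------------------

def observed_otus(row: np.ndarray) -> int:
    return int(np.count_nonzero(row))


def shannon(row: np.ndarray, base: float | None = None) -> float:
    """Shannon entropy of a count vector; natural log unless ``base`` given."""
    row = np.asarray(row, dtype=float)
    total = row.sum()
    if total <= 0:
        raise ValueError("Shannon undefined for an all-zero row")
    p = row[row > 0] / total
    h = float(-(p * np.log(p)).sum())
    if base is not None:
        h /= np.log(base)
    return h


def ace(row: np.ndarray, rare_cutoff: int = 10) -> float:
    """Abundance-based coverage estimator of richness (Chao & Lee).

    Species with abundance <= ``rare_cutoff`` are "rare". With F_i the
    number of species seen i times, N_rare the rare individuals and
    C = 1 - F1/N_rare the sample coverage:

        S_ACE = S_abund + S_rare/C + (F1/C) * gamma^2

    where gamma^2 is the squared coefficient of variation of the rare
    abundances, truncated at 0. When every rare individual is a singleton
    (C = 0) the estimator is undefined.
    """
    row = np.asarray(row)
    if row.sum() <= 0:
        raise ValueError("ACE undefined for an all-zero row")
    counts = row[row > 0]
    rare = counts[counts <= rare_cutoff]
    s_abund = int((counts > rare_cutoff).sum())
    s_rare = len(rare)
    if s_rare == 0:
        return float(s_abund)
    n_rare = int(rare.sum())
    f1 = int((rare == 1).sum())
    c_ace = 1.0 - f1 / n_rare
    if c_ace == 0.0:
        raise ValueError(
            "ACE undefined: all rare individuals are singletons (coverage 0); "
            "use a Chao1 fallback"
        )
    i = np.arange(1, rare_cutoff + 1)
    f = np.array([(rare == k).sum() for k in i])
    gamma2 = (s_rare / c_ace) * (i * (i - 1) @ f) / (n_rare * (n_rare - 1)) - 1.0
    if n_rare == 1:
        gamma2 = 0.0
    gamma2 = max(gamma2, 0.0)
    return float(s_abund + s_rare / c_ace + (f1 / c_ace) * gamma2)


def alpha_diversity(
    table: CountTable, shannon_base: float | None = None, rare_cutoff: int = 10
) -> DiversityResult:
    """Observed OTUs, Shannon, and ACE for every sample."""
    rows = {}
    for sid, row in zip(table.sample_ids, table.counts):
        rows[sid] = {
            "observed_otus": observed_otus(row),
            "shannon": shannon(row, base=shannon_base),
            "ace": ace(row, rare_cutoff=rare_cutoff),
        }
    return DiversityResult(pd.DataFrame.from_dict(rows, orient="index"))


# ---------------------------------------------------------------------------
# Beta diversity
# ---------------------------------------------------------------------------

def bray_curtis(table_or_matrix, ids: list[str] | None = None) -> DistanceMatrix:
    """Bray-Curtis dissimilarity d(a,b) = 1 - 2*sum(min)/(sum a + sum b)."""
    if isinstance(table_or_matrix, CountTable):
        x = table_or_matrix.counts.astype(float)
        ids = list(table_or_matrix.sample_ids)
    else:
        x = np.asarray(table_or_matrix, dtype=float)
        if ids is None:
            ids = [str(i) for i in range(x.shape[0])]
    if x.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    sums = x.sum(axis=1)
    if (sums == 0).sum() >= 2:
        raise ValueError("Bray-Curtis undefined between two all-zero samples")
    d = squareform(pdist(x, metric="braycurtis"))
    return DistanceMatrix(ids, d)


def hellinger(table: CountTable) -> np.ndarray:
    """Hellinger transform: sqrt of relative abundance, row-wise."""
    x = table.counts.astype(float)
    sums = x.sum(axis=1, keepdims=True)
    if (sums == 0).any():
        raise ValueError("Hellinger undefined for an all-zero row")
    return np.sqrt(x / sums)


def nmds(
    d: DistanceMatrix,
    k: int = 2,
    seed: int = 0,
    n_restarts: int = 4,
    max_iter: int = 300,
) -> NmdsResult:
    """Non-metric multidimensional scaling (SMACOF), Kruskal stress-1.

    Runs ``n_restarts`` random initializations and keeps the best.
    """
    from sklearn.manifold import MDS

    n = len(d.ids)
    if n < k + 1:
        raise ValueError("need at least k+1 objects")
    # non-metric SMACOF treats 0 dissimilarities as missing; nudge exact ties
    dm = d.d.copy()
    off = ~np.eye(n, dtype=bool)
    dm[off] = np.maximum(dm[off], 1e-12)
    common = dict(
        n_components=k,
        metric_mds=False,
        max_iter=max_iter,
        metric="precomputed",
        normalized_stress=True,
    )
    # one classical-scaling start (usually in the right basin) plus random
    # restarts; keep the lowest-stress solution
    best = None
    for init, n_init in (("classical_mds", 1), ("random", max(n_restarts - 1, 1))):
        mds = MDS(
            init=init,
            n_init=n_init,
            random_state=int(seed) % (2**31),
            **common,
        )
        coords = mds.fit_transform(dm)
        if best is None or mds.stress_ < best[1]:
            best = (coords, float(mds.stress_), mds.n_iter_ < max_iter)
    coords, stress, converged = best
    return NmdsResult(coords, stress, k, converged, list(d.ids))


# ---------------------------------------------------------------------------
# Mantel
# ---------------------------------------------------------------------------

def _mantel_r(v1: np.ndarray, v2: np.ndarray, method: str) -> float:
    if method == "spearman":
        return float(spearmanr(v1, v2).statistic)
    if method == "pearson":
        return float(pearsonr(v1, v2).statistic)
    raise ValueError(f"unknown method {method!r}")


def mantel(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    method: str = "spearman",
    n_perm: int = 999,
    seed: int | np.random.Generator = 0,
) -> MantelResult:
    """Mantel permutation test between two distance matrices.

    The statistic is the (Spearman or Pearson) correlation of the lower
    triangles; significance from simultaneous row/column permutations of
    ``d2``, one-sided (greater):
    p = (1 + #{r_perm >= r_obs}) / (1 + n_perm).
    """
    if d1.ids != d2.ids:
        raise ValueError("distance matrices must share ids and order")
    n = len(d1.ids)
    if n < 4:
        raise ValueError("Mantel needs at least 4 objects")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    tri = np.tril_indices(n, k=-1)
    v1 = d1.d[tri]

    # fast permutation statistic: Pearson on (ranked, for Spearman) triangles
    def stat_vec(v: np.ndarray) -> np.ndarray:
        w = stats.rankdata(v) if method == "spearman" else np.asarray(v, float)
        w = w - w.mean()
        norm = np.sqrt((w**2).sum())
        return w / norm if norm > 0 else w

    u1 = stat_vec(v1)
    r_obs = float(u1 @ stat_vec(d2.d[tri]))
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        r_perm = float(u1 @ stat_vec(d2.d[np.ix_(perm, perm)][tri]))
        if r_perm >= r_obs - 1e-12:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return MantelResult(r=r_obs, p=p, n_perm=n_perm, method=method)


def euclidean_distance(values: np.ndarray, ids: list[str], standardize: bool = True) -> DistanceMatrix:
    """Euclidean distance on (optionally z-scored) scalar variables."""
    x = np.asarray(values, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    if standardize:
        sd = x.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        x = (x - x.mean(axis=0)) / sd
    return DistanceMatrix(ids, squareform(pdist(x)))


# ---------------------------------------------------------------------------
# Dominant phyla
# ---------------------------------------------------------------------------

def dominant_phyla(
    table: CountTable, tax: TaxonomyTable, cutoff: float = 0.01
) -> pd.Series:
    """Phyla whose mean relative abundance across samples exceeds ``cutoff``.

    Per sample, counts are aggregated by phylum and converted to relative
    abundance; the per-phylum mean over samples is compared to the cutoff
    with a strict inequality. OTUs without a phylum go to "Unassigned".
    """
    phyla = [tax.phylum(o) or "Unassigned" for o in table.otu_ids]
    df = pd.DataFrame(table.counts, index=table.sample_ids, columns=table.otu_ids)
    rel = df.div(df.sum(axis=1), axis=0)
    by_phylum = rel.T.groupby(np.array(phyla)).sum().T
    means = by_phylum.mean(axis=0).sort_values(ascending=False)
    return means[means > cutoff]
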