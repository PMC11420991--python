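"""Synthetic soil-fungal community generator with planted structure.

Emulates a 3-land-use (DG desert grassland, SL shrubland, RL converted
cropland) × 2-season (Apr, Sep) × 9-replicate sampling design: per group,
latent log-abundances are drawn from a multivariate normal whose
correlation matrix carries a planted co-occurrence graph (correlation rho
on planted edges, repaired to positive-definite), pushed through a softmax
to composition, and sampled multinomially at the target sequencing depth.
Soil variables are group means plus Gaussian noise, with the study-like
qualitative directions encoded in the defaults: converted cropland has
higher EC, TC, TN, TP, AP and AK; September has higher pH and SWC.

The generator produces what the downstream analysis assumes, not what a
sequencer produces: no chimeras, no sequencing error, no spatial
autocorrelation between sites.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io import (
    CountTable,
    SampleMetadata,
    SampleRecord,
    TaxonomyTable,
    ENV_VARS,
    substream,
)

__all__ = [
    "GroupSpec",
    "SyntheticSpec",
    "PlantedTruth",
    "generate_dataset",
    "planted_edges",
    "environment_truth",
    "DEFAULT_PHYLUM_MIXTURE",
    "DEFAULT_ENV_MEANS",
]

#: Dominant-phyla mixture for OTU taxonomy assignment. The five phyla that
#: dominate arid-soil fungal communities plus a residual bucket.
DEFAULT_PHYLUM_MIXTURE: dict[str, float] = {
    "Ascomycota": 0.56,
    "Basidiomycota": 0.19,
    "Mortierellomycota": 0.10,
    "Glomeromycota": 0.07,
    "Chytridiomycota": 0.06,
    "other": 0.02,
}

_OTHER_PHYLA = ("Rozellomycota", "Zoopagomycota", "Olpidiomycota")

#: Group-mean soil variables. Units: pH unitless, EC µS/cm, SWC %, TC/TN/
#: TOC g/kg, TP g/kg, AN/AP/AK mg/kg. Absolute levels are plausible for
#: arid sandy soils; only the between-group directions are meaningful:
#: cropland (RL) enriched in EC, TC, TN, TP, AP, AK; September wetter
#: (higher SWC) and slightly more alkaline (higher pH) than April.
DEFAULT_ENV_MEANS: dict[tuple[str, str], dict[str, float]] = {}


def _build_default_env() -> dict[tuple[str, str], dict[str, float]]:
    base = {
        "DG": {"pH": 8.6, "EC": 150.0, "SWC": 6.0, "TC": 8.0, "TN": 0.45,
               "TP": 0.35, "TOC": 3.5, "AN": 18.0, "AP": 4.0, "AK": 90.0},
        "SL": {"pH": 8.5, "EC": 170.0, "SWC": 7.0, "TC": 9.0, "TN": 0.55,
               "TP": 0.38, "TOC": 4.0, "AN": 22.0, "AP": 5.0, "AK": 100.0},
        "RL": {"pH": 8.4, "EC": 420.0, "SWC": 10.0, "TC": 13.0, "TN": 0.85,
               "TP": 0.60, "TOC": 5.5, "AN": 35.0, "AP": 14.0, "AK": 160.0},
    }
    sep_shift = {"pH": 0.25, "SWC": 4.0, "TN": 0.08, "AN": 4.0}
    out: dict[tuple[str, str], dict[str, float]] = {}
    for lu, means in base.items():
        out[(lu, "Apr")] = dict(means)
        sep = dict(means)
        for k, dv in sep_shift.items():
            sep[k] = sep[k] + dv
        out[(lu, "Sep")] = sep
    return out


DEFAULT_ENV_MEANS = _build_default_env()

#: Per-group planted-graph densities; ordered so converted cropland in
#: September carries the densest planted structure (RL_Sep > DG_Sep).
DEFAULT_GROUP_DENSITY: dict[tuple[str, str], float] = {
    ("DG", "Apr"): 0.020,
    ("SL", "Apr"): 0.025,
    ("RL", "Apr"): 0.008,
    ("DG", "Sep"): 0.020,
    ("SL", "Sep"): 0.015,
    ("RL", "Sep"): 0.030,
}


@dataclass
class GroupSpec:
    """Planted-graph description for one (land_use, season) group."""

    land_use: str
    season: str
    n_active: int = 120
    edge_density: float = 0.02
    n_modules: int = 4
    env_means: dict[str, float] = field(default_factory=dict)

    @property
    def label(self) -> str:
        return f"{self.land_use}_{self.season}"


@dataclass
class SyntheticSpec:
    """Full description of a synthetic dataset.

    Defaults give the 54-sample study design: 6 groups × 9 replicates,
    600 OTUs, depth 20,000 per sample, planted correlation rho = 0.8.
    """

    groups: list[GroupSpec] = field(default_factory=list)
    replicates: int = 9
    n_otus: int = 600
    depth: int = 20_000
    depth_jitter: float = 0.0  # relative SD of lognormal depth jitter
    phylum_mixture: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PHYLUM_MIXTURE)
    )
    rho: float = 0.8
    env_noise_sd: float = 0.05  # relative to group mean
    latent_sd: float = 1.0
    base_mean_sd: float = 1.2  # lognormal rank-abundance spread
    group_effect_sd: float = 0.8  # per-group composition shift (log scale)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.groups:
            self.groups = [
                GroupSpec(
                    lu,
                    se,
                    n_active=min(120, self.n_otus),
                    edge_density=DEFAULT_GROUP_DENSITY[(lu, se)],
                    env_means=dict(DEFAULT_ENV_MEANS[(lu, se)]),
                )
                for lu in ("DG", "SL", "RL")
                for se in ("Apr", "Sep")
            ]
        for g in self.groups:
            if not g.env_means:
                g.env_means = dict(
                    DEFAULT_ENV_MEANS.get((g.land_use, g.season),
                                          DEFAULT_ENV_MEANS[("DG", "Apr")])
                )
            if not 0 <= g.edge_density < 1:
                raise ValueError("edge density must be in [0, 1)")
            g.n_active = min(g.n_active, self.n_otus)
        if not 0 <= self.rho < 1:
            raise ValueError("rho must be in [0, 1)")
        if self.replicates < 3:
            raise ValueError("need at least 3 replicates per group")
        total = sum(self.phylum_mixture.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("phylum mixture proportions must sum to 1")


@dataclass
class PlantedTruth:
    """Ground truth: planted edge sets and environment means per group."""

    edges: dict[str, set[tuple[str, str]]]
    env_means: dict[str, dict[str, float]]

    def to_json(self, path: str | Path) -> None:
        doc = {
            "edges": {g: sorted(map(list, es)) for g, es in self.edges.items()},
            "env_means": self.env_means,
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1)

    @classmethod
    def from_json(cls, path: str | Path) -> "PlantedTruth":
        with open(path) as fh:
            doc = json.load(fh)
        return cls(
            edges={
                g: {tuple(e) for e in es} for g, es in doc["edges"].items()
            },
            env_means=doc["env_means"],
        )


def planted_edges(truth: PlantedTruth, group: str) -> set[tuple[str, str]]:
    """Symmetric, deduplicated planted edge set for one group label."""
    if group not in truth.edges:
        raise KeyError(
            f"unknown group {group!r}; known: {sorted(truth.edges)}"
        )
    return {tuple(sorted(e)) for e in truth.edges[group]}


def environment_truth(truth: PlantedTruth):
    """Table of planted group-mean environment values (groups × variables)."""
    import pandas as pd

    return pd.DataFrame.from_dict(truth.env_means, orient="index")[list(ENV_VARS)]


# ---------------------------------------------------------------------------
# Internals
# ---------------------------------------------------------------------------

def nearest_positive_definite_correlation(
    target: np.ndarray, eps: float = 1e-6, max_iter: int = 50
) -> np.ndarray:
    """Repair a target correlation matrix to positive definite.

    Alternating projections between the PSD cone (eigenvalue clipping at
    ``eps``) and the unit-diagonal set. A sparse graph with large planted
    correlations is typically indefinite; this repair keeps planted
    entries close to their target while restoring feasibility.
    """
    a = np.array(target, dtype=float)
    for _ in range(max_iter):
        w, v = np.linalg.eigh(a)
        if w.min() >= eps and np.allclose(np.diag(a), 1.0, atol=1e-9):
            return a
        w = np.clip(w, eps, None)
        a = (v * w) @ v.T
        a = (a + a.T) / 2
        d = np.sqrt(np.diag(a))
        a = a / np.outer(d, d)
        np.fill_diagonal(a, 1.0)
    w = np.linalg.eigvalsh(a)
    if w.min() < eps / 10:
        raise ValueError(
            "could not repair the planted correlation matrix to positive "
            "definite; lower the edge density or rho"
        )
    return a


def _planted_graph(
    n_active: int,
    density: float,
    n_modules: int,
    rng: np.random.Generator,
    clique_size: int = 5,
) -> list[tuple[int, int]]:
    """Planted graph: a union of disjoint mini-cliques at the target density.

    A constant correlation rho on a graph is positive-definite-feasible
    only when |rho| <= 1/|lambda_min(adjacency)|; for sparse random graphs
    that bound is far below typical planted strengths, whereas disjoint
    cliques have lambda_min = -1 and carry any rho < 1 exactly. Cliques are
    the co-occurring guild motif the analysis is meant to recover; they are
    grouped round-robin into ``n_modules`` modules (organizational only).
    """
    if density == 0 or n_active < 2:
        return []
    k = max(2, min(clique_size, n_active))
    total_pairs = n_active * (n_active - 1) // 2
    target_edges = int(round(density * total_pairs))
    if target_edges == 0:
        return []
    per_clique = k * (k - 1) // 2
    n_cliques = max(1, int(round(target_edges / per_clique)))
    n_cliques = min(n_cliques, n_active // k)
    if n_cliques == 0:
        return []
    chosen = rng.choice(n_active, size=n_cliques * k, replace=False)
    edges: list[tuple[int, int]] = []
    for c in range(n_cliques):
        members = np.sort(chosen[c * k : (c + 1) * k])
        iu = np.triu_indices(k, 1)
        edges.extend(
            (int(members[i]), int(members[j])) for i, j in zip(*iu)
        )
    return edges


def _softmax(x: np.ndarray) -> np.ndarray:
    z = x - x.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


#: Genus pools per phylum, used to give a fraction of OTUs a genus-level
#: lineage so guild lookup can resolve below phylum.
_GENUS_POOL: dict[str, tuple[str, ...]] = {
    "Ascomycota": (
        "Chaetomium", "Penicillium", "Fusarium", "Alternaria", "Gibberella",
        "Cladosporium", "Tuber", "Metarhizium", "Beauveria",
    ),
    "Basidiomycota": ("Russula", "Inocybe", "Agaricus", "Ustilago"),
    "Mortierellomycota": ("Mortierella",),
    "Glomeromycota": ("Glomus", "Rhizophagus", "Funneliformis"),
}


def _assign_taxonomy(
    otu_ids: list[str], mixture: dict[str, float], rng: np.random.Generator
) -> TaxonomyTable:
    phyla = list(mixture)
    probs = np.array([mixture[p] for p in phyla])
    draws = rng.choice(len(phyla), size=len(otu_ids), p=probs)
    lineages: dict[str, dict[str, str]] = {}
    for otu, k in zip(otu_ids, draws):
        phylum = phyla[k]
        if phylum == "other":
            phylum = _OTHER_PHYLA[int(rng.integers(len(_OTHER_PHYLA)))]
        genus = ""
        pool = _GENUS_POOL.get(phylum, ())
        if pool and rng.random() < 0.6:
            genus = pool[int(rng.integers(len(pool)))]
        lineages[otu] = {
            "kingdom": "Fungi",
            "phylum": phylum,
            "class": "",
            "order": "",
            "family": "",
            "genus": genus,
            "species": "",
        }
    return TaxonomyTable(lineages)


def generate_dataset(
    spec: SyntheticSpec,
) -> tuple[CountTable, TaxonomyTable, SampleMetadata, PlantedTruth]:
    """Generate counts, taxonomy, metadata, and the planted ground truth.

    Per group: a planted graph over the active OTUs defines a target
    correlation matrix (rho on edges), repaired to positive definite;
    latent log-abundances ~ MVN(base means, latent_sd² × correlation) per
    replicate, softmaxed to proportions, multinomially sampled at depth.
    """
    otu_ids = [f"OTU_{i + 1:04d}" for i in range(spec.n_otus)]
    rng_tax = substream(spec.seed, "taxonomy")
    taxonomy = _assign_taxonomy(otu_ids, spec.phylum_mixture, rng_tax)

    # shared lognormal rank-abundance base means so a handful of OTUs dominate
    rng_base = substream(spec.seed, "base-means")
    base_means = rng_base.normal(0.0, spec.base_mean_sd, size=spec.n_otus)

    # group composition offsets lie on a 2-axis (land-use, season) gradient:
    # grouped field designs separate along few environmental axes, which is
    # what makes their 2-D ordinations interpretable
    rng_grad = substream(spec.seed, "group-gradient")
    gradient = rng_grad.normal(0.0, spec.group_effect_sd, size=(spec.n_otus, 2))
    land_uses = sorted({g.land_use for g in spec.groups})
    seasons = sorted({g.season for g in spec.groups})
    lu_code = {lu: i - (len(land_uses) - 1) / 2 for i, lu in enumerate(land_uses)}
    se_code = {se: i - (len(seasons) - 1) / 2 for i, se in enumerate(seasons)}

    counts_rows: list[np.ndarray] = []
    sample_ids: list[str] = []
    records: dict[str, SampleRecord] = {}
    truth_edges: dict[str, set[tuple[str, str]]] = {}
    truth_env: dict[str, dict[str, float]] = {}

    for g in spec.groups:
        label = g.label
        rng_g = substream(spec.seed, f"group:{label}")
        active = np.sort(
            rng_g.choice(spec.n_otus, size=g.n_active, replace=False)
        )
        edges_local = _planted_graph(g.n_active, g.edge_density, g.n_modules, rng_g)
        edges_global = [
            (int(active[i]), int(active[j])) for i, j in edges_local
        ]
        truth_edges[label] = {
            (otu_ids[i], otu_ids[j]) for i, j in edges_global
        }
        # correlation over active OTUs
        corr = np.eye(g.n_active)
        for i, j in edges_local:
            corr[i, j] = corr[j, i] = spec.rho
        if edges_local:
            corr = nearest_positive_definite_correlation(corr)
        chol = np.linalg.cholesky(corr + 1e-10 * np.eye(g.n_active))

        group_offset = (
            gradient[:, 0] * lu_code[g.land_use]
            + gradient[:, 1] * se_code[g.season]
            if len(spec.groups) > 1
            else np.zeros(spec.n_otus)
        )
        z = rng_g.standard_normal((spec.replicates, g.n_active))
        latent = np.tile(base_means + group_offset, (spec.replicates, 1))
        latent[:, active] += spec.latent_sd * (z @ chol.T)
        inactive = np.setdiff1d(np.arange(spec.n_otus), active)
        latent[:, inactive] += spec.latent_sd * rng_g.standard_normal(
            (spec.replicates, len(inactive))
        )
        props = _softmax(latent)

        truth_env[label] = dict(g.env_means)
        for rep in range(1, spec.replicates + 1):
            depth = spec.depth
            if spec.depth_jitter > 0:
                depth = max(
                    1,
                    int(
                        round(
                            spec.depth
                            * rng_g.lognormal(0.0, spec.depth_jitter)
                        )
                    ),
                )
            row = rng_g.multinomial(depth, props[rep - 1])
            sid = f"{label}_{rep:02d}"
            sample_ids.append(sid)
            counts_rows.append(row)
            env = {
                v: float(
                    g.env_means[v]
                    * (1.0 + spec.env_noise_sd * rng_g.standard_normal())
                )
                for v in ENV_VARS
            }
            records[sid] = SampleRecord(sid, g.land_use, g.season, rep, env)

    table = CountTable(sample_ids, otu_ids, np.vstack(counts_rows))
    meta = SampleMetadata(records)
    truth = PlantedTruth(edges=truth_edges, env_means=truth_env)
    return table, taxonomy, meta, truth
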