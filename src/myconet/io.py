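"""File formats and domain containers.

Tables travel as tab-separated UTF-8 text ('#' comment lines allowed in the
header); a BIOM-style JSON reader is provided for count tables. The central
object is :class:`CountTable`, a samples × OTUs non-negative integer matrix.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")
RANK_PREFIXES = ("k__", "p__", "c__", "o__", "f__", "g__", "s__")
LAND_USES = ("DG", "SL", "RL")
SEASONS = ("Apr", "Sep")
ENV_VARS = ("pH", "EC", "SWC", "TC", "TN", "TP", "TOC", "AN", "AP", "AK")


class FormatError(ValueError):
    """Raised for malformed input files or invalid table contents."""


# ---------------------------------------------------------------------------
# CountTable
# ---------------------------------------------------------------------------

@dataclass
class CountTable:
    """Samples × OTUs matrix of non-negative integer counts.

    Parameters
    ----------
    sample_ids : list of str
        Unique sample identifiers (rows).
    otu_ids : list of str
        Unique OTU identifiers (columns).
    counts : ndarray of int, shape (n_samples, n_otus)
    """

    sample_ids: list[str]
    otu_ids: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise FormatError("counts must be a 2-D matrix")
        if len(self.sample_ids) < 1 or len(self.otu_ids) < 1:
            raise FormatError("need at least 1 sample and 1 OTU")
        if self.counts.shape != (len(self.sample_ids), len(self.otu_ids)):
            raise FormatError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.otu_ids)} OTUs"
            )
        if not np.issubdtype(self.counts.dtype, np.integer):
            as_int = self.counts.astype(np.int64)
            if not np.array_equal(as_int, self.counts):
                raise FormatError("non-integer count encountered")
            self.counts = as_int
        if (self.counts < 0).any():
            raise FormatError("negative count encountered")
        for name, ids in (("sample", self.sample_ids), ("OTU", self.otu_ids)):
            if len(set(ids)) != len(ids):
                raise FormatError(f"duplicate {name} ids")

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def depths(self) -> np.ndarray:
        """Per-sample sequencing depth (row sums)."""
        return self.counts.sum(axis=1)

    def sample_index(self, sample_id: str) -> int:
        return self.sample_ids.index(sample_id)

    def select_samples(self, sample_ids: Iterable[str]) -> "CountTable":
        keep = list(sample_ids)
        idx = [self.sample_ids.index(s) for s in keep]
        return CountTable(keep, list(self.otu_ids), self.counts[idx])

    def select_otus(self, otu_ids: Iterable[str]) -> "CountTable":
        keep = list(otu_ids)
        idx = [self.otu_ids.index(o) for o in keep]
        return CountTable(list(self.sample_ids), keep, self.counts[:, idx])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.sample_ids, columns=self.otu_ids)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountTable):
            return NotImplemented
        return (
            self.sample_ids == other.sample_ids
            and self.otu_ids == other.otu_ids
            and np.array_equal(self.counts, other.counts)
        )


def read_count_table(
    path: str | Path,
    format: str = "tsv",
    orientation: str = "samples_by_otus",
) -> CountTable:
    """Read a count table from TSV or BIOM-style JSON.

    ``orientation`` declares the TSV layout: ``samples_by_otus`` (rows are
    samples) or ``otus_by_samples`` (rows are OTUs, the QIIME convention).
    The returned table is always samples × OTUs.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0, comment="#", dtype=str)
        try:
            mat = df.to_numpy(dtype=np.float64)
        except ValueError as exc:
            raise FormatError(f"non-numeric cell in {path}: {exc}") from exc
        if (mat < 0).any():
            raise FormatError("negative count encountered")
        if not np.array_equal(mat, np.round(mat)):
            raise FormatError("non-integer count encountered")
        rows = [str(i) for i in df.index]
        cols = [str(c) for c in df.columns]
        counts = mat.astype(np.int64)
        if orientation == "otus_by_samples":
            return CountTable(cols, rows, counts.T)
        if orientation == "samples_by_otus":
            return CountTable(rows, cols, counts)
        raise ValueError(f"unknown orientation {orientation!r}")
    if format == "biom-json":
        with open(path) as fh:
            doc = json.load(fh)
        otu_ids = [r["id"] for r in doc["rows"]]
        sample_ids = [c["id"] for c in doc["columns"]]
        mat = np.zeros((len(otu_ids), len(sample_ids)))
        if doc.get("matrix_type") == "sparse":
            for i, j, v in doc["data"]:
                mat[i, j] = v
        else:
            mat[:] = np.asarray(doc["data"], dtype=float)
        if (mat < 0).any():
            raise FormatError("negative count encountered")
        return CountTable(sample_ids, otu_ids, mat.T.astype(np.int64))
    raise ValueError(f"unknown format {format!r}")


def write_count_table(
    table: CountTable,
    path: str | Path,
    header_comment: str | None = None,
) -> None:
    """Write a count table as samples × OTUs TSV."""
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        table.to_dataframe().to_csv(fh, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# TaxonomyTable
# ---------------------------------------------------------------------------

@dataclass
class TaxonomyTable:
    """OTU → seven-rank lineage (kingdom..species), unknown ranks empty."""

    lineages: dict[str, dict[str, str]]

    def __post_init__(self) -> None:
        for otu, ranks in self.lineages.items():
            for r in RANKS:
                ranks.setdefault(r, "")

    def phylum(self, otu_id: str) -> str:
        return self.lineages.get(otu_id, {}).get("phylum", "")

    def rank(self, otu_id: str, rank: str) -> str:
        return self.lineages.get(otu_id, {}).get(rank, "")

    def __contains__(self, otu_id: str) -> bool:
        return otu_id in self.lineages

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame.from_dict(self.lineages, orient="index")[list(RANKS)]


def parse_lineage(lineage: str) -> dict[str, str]:
    """Parse a QIIME-style lineage string into a rank dict.

    ``"k__Fungi;p__Glomeromycota"`` → kingdom Fungi, phylum Glomeromycota,
    remaining ranks empty. Prefixes must appear in canonical order.
    """
    out = {r: "" for r in RANKS}
    parts = [p.strip() for p in lineage.split(";") if p.strip()]
    last = -1
    for part in parts:
        prefix = part[:3]
        if prefix not in RANK_PREFIXES:
            raise FormatError(f"unrecognized rank prefix in {part!r}")
        idx = RANK_PREFIXES.index(prefix)
        if idx <= last:
            raise FormatError(f"rank prefixes out of order in {lineage!r}")
        last = idx
        out[RANKS[idx]] = part[3:].strip()
    return out


def read_taxonomy(path: str | Path) -> TaxonomyTable:
    """Read a two-column TSV (otu_id, lineage with rank prefixes)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise FormatError("taxonomy TSV must have otu_id and lineage columns")
    lineages: dict[str, dict[str, str]] = {}
    for otu, lineage in zip(df.iloc[:, 0], df.iloc[:, 1]):
        if otu in lineages:
            raise FormatError(f"duplicate otu_id {otu!r} in taxonomy")
        lineages[otu] = parse_lineage(lineage)
    return TaxonomyTable(lineages)


def write_taxonomy(tax: TaxonomyTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("otu_id\tlineage\n")
        for otu, ranks in tax.lineages.items():
            parts = []
            for prefix, rank in zip(RANK_PREFIXES, RANKS):
                if ranks[rank]:
                    parts.append(f"{prefix}{ranks[rank]}")
            fh.write(f"{otu}\t{';'.join(parts)}\n")


# ---------------------------------------------------------------------------
# SampleMetadata
# ---------------------------------------------------------------------------

@dataclass
class SampleRecord:
    sample_id: str
    land_use: str
    season: str
    replicate: int
    environment: dict[str, float]


@dataclass
class SampleMetadata:
    """Per-sample design factors (land use, season, replicate) + soil variables."""

    records: dict[str, SampleRecord]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.records)

    def group_of(self, sample_id: str) -> tuple[str, str]:
        rec = self.records[sample_id]
        return (rec.land_use, rec.season)

    def groups(self) -> list[tuple[str, str]]:
        seen: list[tuple[str, str]] = []
        for rec in self.records.values():
            g = (rec.land_use, rec.season)
            if g not in seen:
                seen.append(g)
        return seen

    def samples_in_group(self, land_use: str, season: str) -> list[str]:
        return [
            s
            for s, rec in self.records.items()
            if rec.land_use == land_use and rec.season == season
        ]

    def environment_frame(self) -> pd.DataFrame:
        rows = {s: rec.environment for s, rec in self.records.items()}
        return pd.DataFrame.from_dict(rows, orient="index")[list(ENV_VARS)]

    def to_dataframe(self) -> pd.DataFrame:
        rows = {}
        for s, rec in self.records.items():
            row: dict[str, object] = {
                "land_use": rec.land_use,
                "season": rec.season,
                "replicate": rec.replicate,
            }
            row.update(rec.environment)
            rows[s] = row
        return pd.DataFrame.from_dict(rows, orient="index")


def read_metadata(path: str | Path) -> SampleMetadata:
    """Read sample metadata TSV (land_use, season, replicate + 10 soil columns)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    required = ["land_use", "season", "replicate", *ENV_VARS]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"metadata missing columns: {missing}")
    records: dict[str, SampleRecord] = {}
    for sample_id, row in df.iterrows():
        land_use = str(row["land_use"])
        season = str(row["season"])
        if land_use not in LAND_USES:
            raise FormatError(
                f"sample {sample_id!r}: unknown land_use {land_use!r}; "
                f"allowed: {list(LAND_USES)}"
            )
        if season not in SEASONS:
            raise FormatError(
                f"sample {sample_id!r}: unknown season {season!r}; "
                f"allowed: {list(SEASONS)}"
            )
        env = {}
        for v in ENV_VARS:
            try:
                val = float(row[v])
            except (TypeError, ValueError) as exc:
                raise FormatError(
                    f"sample {sample_id!r}: non-numeric value for {v!r}"
                ) from exc
            if not np.isfinite(val):
                raise FormatError(f"sample {sample_id!r}: non-finite {v!r}")
            env[v] = val
        records[str(sample_id)] = SampleRecord(
            str(sample_id), land_use, season, int(row["replicate"]), env
        )
    return SampleMetadata(records)


def write_metadata(meta: SampleMetadata, path: str | Path) -> None:
    meta.to_dataframe().to_csv(path, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# PipelineConfig
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """All tunable knobs of the pipeline, serializable to YAML.

    Randomness flows from ``seed`` through named substreams, one per stage
    (see :func:`substream`), so each stage is independently reproducible.
    """

    seed: int = 0
    rarefaction: bool = False
    shannon_base: float | None = None  # None -> natural log
    prevalence_min_fraction: float = 7 / 9
    clr_pseudocount: float = 1.0
    threshold_mode: str = "fixed"  # fixed | rmt
    fixed_threshold: float = 0.9
    rmt_t_min: float = 0.3
    rmt_t_max: float = 0.99
    rmt_step: float = 0.01
    nci_sign_feature: str = "n_edges"
    guild_min_confidence: str = "Probable"
    n_permutations: int = 999
    nmds_restarts: int = 4
    pooled_network: bool = False  # one all-sample network instead of per-group

    def __post_init__(self) -> None:
        if not 0 < self.prevalence_min_fraction <= 1:
            raise ValueError("prevalence_min_fraction must be in (0, 1]")
        if self.clr_pseudocount <= 0:
            raise ValueError("clr_pseudocount must be positive")
        if self.threshold_mode not in ("fixed", "rmt"):
            raise ValueError("threshold_mode must be 'fixed' or 'rmt'")
        if not 0 < self.fixed_threshold <= 1:
            raise ValueError("fixed_threshold must be in (0, 1]")
        if not self.rmt_t_min < self.rmt_t_max:
            raise ValueError("rmt scan range must be increasing")
        if self.rmt_step <= 0:
            raise ValueError("rmt_step must be positive")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls(**doc)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


def substream(seed: int, stage: str) -> np.random.Generator:
    """Named, stage-specific random substream derived from the config seed."""
    h = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    child = int.from_bytes(h[:4], "big")
    return np.random.default_rng(child)


# ---------------------------------------------------------------------------
# Network IO (graph container lives in myconet.network)
# ---------------------------------------------------------------------------

def write_network(net, path: str | Path, format: str = "edge-tsv", taxonomy: TaxonomyTable | None = None) -> None:
    """Write a co-occurrence network as edge-TSV or GraphML.

    Edges carry the correlation and its sign; nodes carry phylum when a
    taxonomy is supplied.
    """
    import networkx as nx

    path = Path(path)
    if format == "edge-tsv":
        with open(path, "w") as fh:
            fh.write(
                f"# group={net.group} threshold={net.threshold_used:.6g} "
                f"mode={net.mode}\n"
            )
            fh.write("otu_a\totu_b\tr\tsign\n")
            for a, b, r in net.edges:
                sign = "+" if r > 0 else "-"
                fh.write(f"{a}\t{b}\t{r:.6g}\t{sign}\n")
        return
    if format == "graphml":
        g = net.to_networkx()
        for node in g.nodes:
            g.nodes[node]["phylum"] = taxonomy.phylum(node) if taxonomy else ""
        g.graph["group"] = str(net.group)
        g.graph["threshold_used"] = float(net.threshold_used)
        g.graph["mode"] = net.mode
        nx.write_graphml(g, path)
        return
    raise ValueError(f"unknown format {format!r}")


def read_network(path: str | Path, format: str = "edge-tsv"):
    """Read a network written by :func:`write_network`."""
    import networkx as nx

    from .network import CooccurrenceNetwork

    path = Path(path)
    if format == "edge-tsv":
        meta: dict[str, str] = {}
        with open(path) as fh:
            first = fh.readline()
            if first.startswith("#"):
                for tok in first[1:].split():
                    if "=" in tok:
                        k, v = tok.split("=", 1)
                        meta[k] = v
                header = fh.readline()
            else:
                header = first
            edges = []
            for line in fh:
                if not line.strip():
                    continue
                a, b, r, _sign = line.rstrip("\n").split("\t")
                edges.append((a, b, float(r)))
        return CooccurrenceNetwork(
            edges=edges,
            threshold_used=float(meta.get("threshold", 0.0)),
            mode=meta.get("mode", "fixed"),
            group=meta.get("group", ""),
        )
    if format == "graphml":
        g = nx.read_graphml(path)
        edges = [(a, b, float(d["r"])) for a, b, d in g.edges(data=True)]
        return CooccurrenceNetwork(
            edges=edges,
            threshold_used=float(g.graph.get("threshold_used", 0.0)),
            mode=g.graph.get("mode", "fixed"),
            group=g.graph.get("group", ""),
        )
    raise ValueError(f"unknown format {format!r}")
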