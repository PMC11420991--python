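"""Trophic-mode / guild annotation of fungal OTUs from a lookup table.

FUNGuild-style semantics: each record names a taxon at some rank with its
trophic mode(s) (Symbiotroph / Saprotroph / Pathotroph), guild string, and
a confidence rank. An OTU is annotated by the most specific lineage match
at or above the confidence filter. A small curated lookup table covering
the taxa that matter for arid-soil communities ships with the package for
testing; pass a real FUNGuild export for production work.

Multi-mode records ("Pathotroph-Saprotroph") contribute the OTU's full
abundance to each listed mode, so mode shares are reported per mode and
may sum above 1 — they are not a partition.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .io import CountTable, TaxonomyTable, FormatError, RANKS

__all__ = [
    "GuildTable",
    "GuildAssignment",
    "GuildProfile",
    "CONFIDENCE_LEVELS",
    "TROPHIC_MODES",
    "load_guild_db",
    "bundled_guild_db_path",
    "assign_guilds",
    "guild_profile",
]

CONFIDENCE_LEVELS = ("Possible", "Probable", "Highly Probable")
TROPHIC_MODES = ("Symbiotroph", "Saprotroph", "Pathotroph")
#: Guild categories profiled alongside the trophic modes.
GUILD_CATEGORIES = ("Arbuscular Mycorrhizal", "Ectomycorrhizal")

_REQUIRED_COLUMNS = ("taxon", "taxonomicLevel", "trophicMode", "guild", "confidenceRanking")

# search order: species first (most specific), phylum last
_SEARCH_RANKS = tuple(reversed(RANKS[1:]))  # species..phylum


@dataclass
class GuildRecord:
    taxon: str
    taxonomic_level: str
    trophic_modes: tuple[str, ...]
    guild: str
    confidence: str


@dataclass
class GuildTable:
    records: dict[tuple[str, str], GuildRecord]  # (taxon, level) -> record

    def lookup(self, taxon: str, level: str) -> GuildRecord | None:
        return self.records.get((taxon, level))

    def guild_categories(self) -> set[str]:
        return {r.guild for r in self.records.values() if r.guild}


@dataclass
class OtuGuild:
    otu_id: str
    matched_taxon: str | None
    matched_rank: str | None
    trophic_modes: tuple[str, ...]
    guilds: tuple[str, ...]
    confidence: str | None

    @property
    def assigned(self) -> bool:
        return self.matched_taxon is not None


@dataclass
class GuildAssignment:
    assignments: dict[str, OtuGuild]

    def n_assigned(self) -> int:
        return sum(1 for a in self.assignments.values() if a.assigned)

    def to_dataframe(self) -> pd.DataFrame:
        rows = {}
        for otu, a in self.assignments.items():
            rows[otu] = {
                "matched_taxon": a.matched_taxon or "",
                "matched_rank": a.matched_rank or "",
                "trophic_modes": "-".join(a.trophic_modes),
                "guilds": "|".join(a.guilds),
                "confidence": a.confidence or "",
            }
        return pd.DataFrame.from_dict(rows, orient="index")


@dataclass
class GuildProfile:
    """Per-sample relative-abundance shares of modes, key guilds, Unassigned."""

    table: pd.DataFrame  # samples × (3 modes, AM, EcM, Unassigned)

    def to_dataframe(self) -> pd.DataFrame:
        return self.table


def bundled_guild_db_path() -> Path:
    """Path of the curated lookup table shipped with the package."""
    return Path(resources.files("myconet") / "data" / "guild_db.tsv")


def load_guild_db(path: str | Path | None = None) -> GuildTable:
    """Load and validate a FUNGuild-style TSV lookup table."""
    path = bundled_guild_db_path() if path is None else Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"guild table missing column(s): {missing}")
    records: dict[tuple[str, str], GuildRecord] = {}
    for _, row in df.iterrows():
        taxon = row["taxon"].strip()
        level = row["taxonomicLevel"].strip().lower()
        if not taxon:
            raise FormatError("empty taxon in guild table")
        if level not in RANKS:
            raise FormatError(f"unknown taxonomicLevel {level!r} for {taxon!r}")
        conf = row["confidenceRanking"].strip()
        if conf not in CONFIDENCE_LEVELS:
            raise FormatError(
                f"unknown confidence {conf!r} for {taxon!r}; "
                f"allowed: {list(CONFIDENCE_LEVELS)}"
            )
        key = (taxon, level)
        if key in records:
            raise FormatError(f"duplicate (taxon, level) row: {key}")
        modes = tuple(
            m for m in row["trophicMode"].split("-") if m in TROPHIC_MODES
        )
        records[key] = GuildRecord(taxon, level, modes, row["guild"].strip(), conf)
    return GuildTable(records)


def assign_guilds(
    tax: TaxonomyTable,
    db: GuildTable,
    min_confidence: str = "Probable",
) -> GuildAssignment:
    """Annotate every OTU by its most specific lineage match.

    The lineage is searched species → phylum; the first record found at or
    above ``min_confidence`` wins. OTUs with no qualifying match are
    unassigned.
    """
    if min_confidence not in CONFIDENCE_LEVELS:
        raise ValueError(f"unknown confidence level {min_confidence!r}")
    min_idx = CONFIDENCE_LEVELS.index(min_confidence)
    out: dict[str, OtuGuild] = {}
    for otu, ranks in tax.lineages.items():
        hit: OtuGuild | None = None
        for rank in _SEARCH_RANKS:
            name = ranks.get(rank, "")
            if not name:
                continue
            rec = db.lookup(name, rank)
            if rec is None:
                continue
            if CONFIDENCE_LEVELS.index(rec.confidence) < min_idx:
                continue
            guilds = tuple(
                g.strip() for g in rec.guild.split("|") if g.strip()
            )
            hit = OtuGuild(
                otu, name, rank, rec.trophic_modes, guilds, rec.confidence
            )
            break
        out[otu] = hit or OtuGuild(otu, None, None, (), (), None)
    return GuildAssignment(out)


def guild_profile(table: CountTable, assign: GuildAssignment) -> GuildProfile:
    """Per-sample relative abundance of each trophic mode, AM, EcM, Unassigned.

    An OTU's relative abundance is added to every trophic mode it carries
    (so modes are not a partition); AM and EcM are guild-level subsets;
    Unassigned is the share of OTUs with no qualifying match.
    """
    depths = table.depths()
    if (depths == 0).any():
        zero = [s for s, d in zip(table.sample_ids, depths) if d == 0]
        raise ValueError(f"samples with zero total count: {zero}")
    rel = table.counts / depths[:, None]
    cols = [*TROPHIC_MODES, "AM", "EcM", "Unassigned"]
    out = pd.DataFrame(0.0, index=table.sample_ids, columns=cols)
    for j, otu in enumerate(table.otu_ids):
        a = assign.assignments.get(otu)
        col_rel = rel[:, j]
        if a is None or not a.assigned:
            out["Unassigned"] += col_rel
            continue
        for mode in a.trophic_modes:
            out[mode] += col_rel
        if "Arbuscular Mycorrhizal" in a.guilds:
            out["AM"] += col_rel
        if "Ectomycorrhizal" in a.guilds:
            out["EcM"] += col_rel
    return GuildProfile(out)
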