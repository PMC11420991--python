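"""End-to-end orchestration: synthetic or file inputs → result bundle.

Every output TSV starts with a comment line naming the config hash and
seed, so a bundle is traceable to the exact configuration that produced
it. With a fixed seed a re-run is byte-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import diversity as dv
from . import guilds as gd
from . import nci as nc
from . import network as nw
from . import stats as st
from .io import (
    CountTable,
    PipelineConfig,
    SampleMetadata,
    TaxonomyTable,
    read_count_table,
    read_metadata,
    read_taxonomy,
    substream,
    write_count_table,
    write_metadata,
    write_network,
    write_taxonomy,
)
from .synthetic import SyntheticSpec, generate_dataset

log = logging.getLogger("myconet")

__all__ = ["PipelineInputs", "run_all"]


@dataclass
class PipelineInputs:
    table: CountTable
    taxonomy: TaxonomyTable | None
    metadata: SampleMetadata | None


def _header(config: PipelineConfig) -> str:
    return f"# myconet config={config.config_hash()} seed={config.seed}\n"


def _write_tsv(df: pd.DataFrame, path: Path, config: PipelineConfig, index_label="id") -> None:
    with open(path, "w") as fh:
        fh.write(_header(config))
        df.to_csv(fh, sep="\t", index_label=index_label)


def load_inputs(
    counts_path: str | Path,
    taxonomy_path: str | Path | None = None,
    metadata_path: str | Path | None = None,
    counts_format: str = "tsv",
    orientation: str = "samples_by_otus",
) -> PipelineInputs:
    table = read_count_table(counts_path, format=counts_format, orientation=orientation)
    tax = read_taxonomy(taxonomy_path) if taxonomy_path else None
    meta = read_metadata(metadata_path) if metadata_path else None
    return PipelineInputs(table, tax, meta)


def run_all(
    config: PipelineConfig,
    outdir: str | Path,
    inputs: PipelineInputs | None = None,
    synthetic_spec: SyntheticSpec | None = None,
    guild_db_path: str | Path | None = None,
    stages: tuple[str, ...] = ("diversity", "network", "nci", "guilds", "stats"),
) -> dict:
    """Run the pipeline; write the result bundle under ``outdir``.

    Exactly one of ``inputs`` / ``synthetic_spec`` must be given (with
    neither, a default synthetic dataset at the config seed is generated).
    Returns a dict of the in-memory results keyed by stage.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    results: dict = {}

    if inputs is not None and synthetic_spec is not None:
        raise ValueError("give either real inputs or a synthetic spec, not both")
    if inputs is None:
        spec = synthetic_spec or SyntheticSpec(seed=config.seed)
        log.info("generating synthetic dataset (seed=%d)", spec.seed)
        table, tax, meta, truth = generate_dataset(spec)
        truth.to_json(outdir / "planted_truth.json")
        write_count_table(table, outdir / "counts.tsv",
                          header_comment=_header(config).strip("# \n"))
        write_taxonomy(tax, outdir / "taxonomy.tsv")
        write_metadata(meta, outdir / "metadata.tsv")
        results["truth"] = truth
    else:
        table, tax, meta = inputs.table, inputs.taxonomy, inputs.metadata

    config.to_yaml(outdir / "config.yaml")
    results.update(table=table, taxonomy=tax, metadata=meta)

    work = table
    if config.rarefaction:
        log.info("rarefying to minimum depth")
        work = dv.rarefy(table, substream(config.seed, "rarefy"))

    if "diversity" in stages:
        log.info("stage: diversity")
        try:
            alpha = dv.alpha_diversity(work, shannon_base=config.shannon_base)
            _write_tsv(alpha.to_dataframe(), outdir / "alpha_diversity.tsv",
                       config, index_label="sample_id")
            hel = dv.hellinger(work)
            bc = dv.bray_curtis(hel, ids=list(work.sample_ids))
            _write_tsv(
                pd.DataFrame(bc.d, index=bc.ids, columns=bc.ids),
                outdir / "bray_curtis.tsv", config, index_label="sample_id",
            )
            nm = dv.nmds(bc, seed=config.seed, n_restarts=config.nmds_restarts)
            coords = pd.DataFrame(
                nm.coordinates, index=bc.ids,
                columns=[f"NMDS{i + 1}" for i in range(nm.k)],
            )
            coords["stress"] = nm.stress
            _write_tsv(coords, outdir / "nmds.tsv", config, index_label="sample_id")
            results["diversity"] = alpha
            results["bray_curtis"] = bc
            results["nmds"] = nm
            if tax is not None:
                dom = dv.dominant_phyla(work, tax)
                _write_tsv(dom.to_frame("mean_relative_abundance"),
                           outdir / "dominant_phyla.tsv", config,
                           index_label="phylum")
                results["dominant_phyla"] = dom
        except Exception as exc:
            raise RuntimeError(f"diversity stage failed: {exc}") from exc

    networks: dict[str, nw.CooccurrenceNetwork] = {}
    if "network" in stages:
        log.info("stage: network")
        try:
            if meta is None:
                raise ValueError("network stage requires sample metadata")
            group_map: dict[str, list[str]] = {}
            if config.pooled_network:
                group_map["all"] = list(table.sample_ids)
            else:
                for lu, se in meta.groups():
                    group_map[f"{lu}_{se}"] = meta.samples_in_group(lu, se)
            topo_rows = []
            for label, samples in group_map.items():
                net, scan = nw.infer_group_network(
                    table, samples, group_label=label,
                    min_fraction=config.prevalence_min_fraction,
                    pseudocount=config.clr_pseudocount,
                    threshold_mode=config.threshold_mode,
                    fixed_threshold=config.fixed_threshold,
                    rmt_kwargs={
                        "t_min": config.rmt_t_min,
                        "t_max": config.rmt_t_max,
                        "step": config.rmt_step,
                    },
                )
                networks[label] = net
                write_network(net, outdir / f"network_{label}.tsv",
                              format="edge-tsv")
                write_network(net, outdir / f"network_{label}.graphml",
                              format="graphml", taxonomy=tax)
                topo_rows.append(nw.global_topology(net).to_series())
                if scan is not None:
                    _write_tsv(scan.to_dataframe(),
                               outdir / f"rmt_scan_{label}.tsv", config,
                               index_label="i")
            topo = pd.DataFrame(topo_rows)
            _write_tsv(topo, outdir / "topology.tsv", config, index_label="group")
            results["networks"] = networks
            results["topology"] = topo
        except Exception as exc:
            raise RuntimeError(f"network stage failed: {exc}") from exc

    if "nci" in stages:
        log.info("stage: nci")
        try:
            if not networks:
                raise ValueError("nci stage requires the network stage")
            feats = nc.feature_table(networks, table, meta)
            _write_tsv(feats, outdir / "subnetwork_features.tsv", config,
                       index_label="sample_id")
            res = nc.nci_scores(feats, sign_feature=config.nci_sign_feature)
            nci_df = res.scores.to_frame("NCI")
            nci_df["group"] = [
                "_".join(meta.group_of(s)) for s in nci_df.index
            ]
            if len(res.variance_explained):
                nci_df["pc1_variance_explained"] = res.variance_explained[0]
            _write_tsv(nci_df, outdir / "nci.tsv", config, index_label="sample_id")
            results["nci"] = res
            results["nci_features"] = feats
        except Exception as exc:
            raise RuntimeError(f"nci stage failed: {exc}") from exc

    if "guilds" in stages:
        log.info("stage: guilds")
        try:
            if tax is None:
                raise ValueError("guild stage requires taxonomy")
            db = gd.load_guild_db(guild_db_path)
            assign = gd.assign_guilds(tax, db,
                                      min_confidence=config.guild_min_confidence)
            _write_tsv(assign.to_dataframe(), outdir / "guild_assignments.tsv",
                       config, index_label="otu_id")
            profile = gd.guild_profile(work, assign)
            _write_tsv(profile.to_dataframe(), outdir / "guild_profile.tsv",
                       config, index_label="sample_id")
            results["guild_assignment"] = assign
            results["guild_profile"] = profile
        except Exception as exc:
            raise RuntimeError(f"guild stage failed: {exc}") from exc

    if "stats" in stages:
        log.info("stage: stats")
        try:
            if meta is None:
                raise ValueError("stats stage requires sample metadata")
            env = meta.environment_frame()
            # ANOVA per environment variable across (land_use, season) groups
            anova_rows = []
            group_of = {
                s: "_".join(meta.group_of(s)) for s in meta.sample_ids
            }
            for var in env.columns:
                by_group: dict[str, list[float]] = {}
                for s in env.index:
                    by_group.setdefault(group_of[s], []).append(env.loc[s, var])
                try:
                    a = st.one_way_anova(
                        {g: pd.Series(v).to_numpy() for g, v in by_group.items()},
                        variable=var,
                    )
                except ValueError:
                    continue
                anova_rows.append({
                    "variable": var, "F": a.f, "p": a.p,
                    **{f"letter_{g}": l for g, l in a.letters.items()},
                })
            if anova_rows:
                _write_tsv(pd.DataFrame(anova_rows).set_index("variable"),
                           outdir / "anova_environment.tsv", config,
                           index_label="variable")
            if "diversity" in results:
                mantel_df = st.alpha_env_mantel_preset(
                    results["diversity"], env,
                    n_perm=config.n_permutations, seed=config.seed,
                )
                _write_tsv(mantel_df, outdir / "mantel_alpha_env.tsv", config,
                           index_label="variable")
                results["mantel_alpha_env"] = mantel_df
            if "nci" in results and not results["nci"].degenerate:
                panel = st.spearman_panel(
                    results["nci"].scores.to_frame("NCI"), env
                )
                _write_tsv(panel.r, outdir / "nci_env_spearman_r.tsv", config,
                           index_label="row")
                rf = st.rf_importance(
                    results["nci"].scores, env,
                    seed=config.seed,
                )
                _write_tsv(rf.importances.to_frame("importance"),
                           outdir / "rf_importance.tsv", config,
                           index_label="variable")
                results["rf_importance"] = rf
            rda_res = st.rda(work, env)
            _write_tsv(rda_res.env_scores, outdir / "rda_env_scores.tsv",
                       config, index_label="variable")
            results["rda"] = rda_res
        except RuntimeError:
            raise
        except Exception as exc:
            raise RuntimeError(f"stats stage failed: {exc}") from exc

    log.info("bundle written to %s", outdir)
    return results
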