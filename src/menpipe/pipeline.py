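"""End-to-end orchestration: one YAML config drives simulate/ingest,
preprocessing, per-kingdom and interdomain networks, topology, modules,
eigengene-trait correlations, and community statistics.

Every stochastic stage receives an explicit child seed derived from the
config seed, so a rerun with the same config produces byte-identical
outputs.  A run manifest records every seed and threshold actually used.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import association, community_stats, module_traits, preprocess, topology
from .io_formats import (
    CountTable,
    SampleMetadata,
    read_count_table,
    read_metadata,
    write_count_table,
    write_metadata,
    write_network,
)
from .synthetic_community import (
    DEFAULT_GROUP_SIZES,
    FluxLink,
    SyntheticTruth,
    generate_truth,
    simulate_kingdom_tables,
    simulate_metadata,
)

logger = logging.getLogger("menpipe")

KINGDOM_ORDER = ("prokaryote", "fungus", "cercozoa")

#: the wetland study's per-kingdom fixed correlation thresholds and its
#: RMT-derived interdomain threshold, for re-analyses of comparable data
STUDY_FIXED_THRESHOLDS = {
    "prokaryote": 0.960,
    "fungus": 0.840,
    "cercozoa": 0.890,
    "interdomain": 0.85,
}

#: default thresholds for the synthetic demo: kept consistent across
#: communities (the fair-comparison convention) at the interdomain value,
#: which planted rho = 0.9 blocks can reach at a few dozen samples
DEFAULT_FIXED_THRESHOLDS = {
    "prokaryote": 0.85,
    "fungus": 0.85,
    "cercozoa": 0.85,
    "interdomain": 0.85,
}


@dataclass
class PipelineConfig:
    seed: int = 0
    outdir: str = "menpipe_out"
    # synthetic generator (used when input paths are absent)
    synthetic: dict = field(default_factory=dict)
    # real inputs: {"counts": {kingdom: path}, "metadata": path}
    inputs: dict = field(default_factory=dict)
    depths: dict = field(default_factory=lambda: dict(preprocess.DEFAULT_DEPTHS))
    min_prevalence: float = preprocess.DEFAULT_MIN_PREVALENCE
    threshold_mode: str = "fixed"  # "fixed" | "rmt"
    fixed_thresholds: dict = field(
        default_factory=lambda: dict(DEFAULT_FIXED_THRESHOLDS)
    )
    rmt: dict = field(
        default_factory=lambda: {"s_min": 0.30, "s_max": 0.99, "step": 0.01, "alpha": 0.05}
    )
    mantel_permutations: int = 999
    dissimilarity_permutations: int = 999
    robustness: dict = field(
        default_factory=lambda: {"removal_fraction": 0.5, "replicates": 100}
    )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def child_seed(self, stage: str) -> int:
        """Deterministic per-stage seed below 2^31 (stable across processes)."""
        ss = np.random.SeedSequence([self.seed, zlib.crc32(stage.encode())])
        return int(ss.generate_state(1)[0] % 2**31)


def _tsv(df: pd.DataFrame, path, **kw) -> None:
    df.to_csv(path, sep="\t", float_format="%.10g", **kw)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and write the artifact bundle to config.outdir.

    Returns a dict of the in-memory results keyed by stage.  Any stage
    failure raises with a stage-named diagnostic.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}, "thresholds": {}}
    results: dict = {}

    def stage(name):
        logger.info("stage: %s", name)
        manifest["stages"][name] = "ok"

    try:
        # -- ingest / simulate ----------------------------------------
        stage("ingest")
        truth = None
        if config.inputs.get("counts"):
            tables = {
                k: read_count_table(p, kingdom=k)
                for k, p in config.inputs["counts"].items()
            }
            metadata = read_metadata(config.inputs["metadata"])
        else:
            syn = dict(config.synthetic)
            n_samples = syn.pop("n_samples", sum(DEFAULT_GROUP_SIZES.values()))
            group_sizes = syn.pop("group_sizes", None)
            env_spec = syn.pop("env_spec", None)
            raw_depths = syn.pop(
                "raw_depths", {k: int(1.2 * d) for k, d in config.depths.items()}
            )
            if "flux_link" in syn and isinstance(syn["flux_link"], dict):
                syn["flux_link"] = FluxLink(**syn["flux_link"])
            truth = generate_truth(seed=config.child_seed("truth"), **syn)
            tables = simulate_kingdom_tables(
                truth, n_samples, raw_depths, seed=config.child_seed("counts")
            )
            merged_raw = association.merge_tables(
                [tables[k] for k in KINGDOM_ORDER if k in tables]
            )
            metadata = simulate_metadata(
                truth,
                merged_raw,
                group_sizes=group_sizes,
                env_spec=env_spec,
                seed=config.child_seed("metadata"),
            )
            truth.to_json(out / "truth.json")
        results["truth"] = truth

        # -- preprocess ------------------------------------------------
        stage("preprocess")
        rarefied = {}
        alpha_frames = []
        for k in KINGDOM_ORDER:
            if k not in tables:
                continue
            t = preprocess.rarefy(
                tables[k], config.depths[k], seed=config.child_seed(f"rarefy:{k}")
            )
            if k == "prokaryote":
                t = preprocess.annotate_guilds(t)
            rarefied[k] = t
            write_count_table(t, out / f"counts_{k}_rarefied.tsv")
            a = preprocess.alpha_diversity(t)
            a.insert(0, "kingdom", k)
            alpha_frames.append(a)
        metadata = preprocess.assign_groups(metadata)
        write_metadata(metadata, out / "metadata.tsv")
        _tsv(pd.concat(alpha_frames), out / "alpha_diversity.tsv", index_label="sample_id")
        results["tables"] = rarefied
        results["metadata"] = metadata

        # -- per-kingdom networks --------------------------------------
        stage("kingdom_networks")
        nets = {}
        for k, t in rarefied.items():
            filtered = preprocess.prevalence_filter(t, config.min_prevalence)
            corr = association.spearman_matrix(filtered)
            if config.threshold_mode == "rmt":
                scan = association.rmt_select_threshold(corr, **config.rmt)
                scan.to_tsv(out / f"rmt_scan_{k}.tsv")
                thr = scan.selected
            else:
                thr = config.fixed_thresholds[k]
            manifest["thresholds"][k] = thr
            net = association.build_network(corr, thr, filtered)
            write_network(
                net,
                out / f"network_{k}_edges.tsv",
                out / f"network_{k}_nodes.tsv",
                out / f"network_{k}.graphml",
            )
            nets[k] = net
        results["kingdom_networks"] = nets

        # -- interdomain network ---------------------------------------
        stage("interdomain_network")
        filtered_tables = [
            preprocess.prevalence_filter(rarefied[k], config.min_prevalence)
            for k in KINGDOM_ORDER
            if k in rarefied
        ]
        merged = association.merge_tables(filtered_tables)
        corr = association.spearman_matrix(merged)
        if config.threshold_mode == "rmt":
            scan = association.rmt_select_threshold(corr, **config.rmt)
            scan.to_tsv(out / "rmt_scan_interdomain.tsv")
            inter_thr = scan.selected
        else:
            inter_thr = config.fixed_thresholds["interdomain"]
        manifest["thresholds"]["interdomain"] = inter_thr
        inter = association.build_network(corr, inter_thr, merged)
        results["interdomain_network"] = inter
        results["merged_table"] = merged
        _tsv(
            association.category_counts(inter).rename("n_nodes").to_frame(),
            out / "interdomain_categories.tsv",
            index_label="category",
        )

        # -- topology --------------------------------------------------
        stage("topology")
        topo_rows = []
        for name, net in {**nets, "interdomain": inter}.items():
            summary = topology.global_properties(net).as_dict()
            summary["network"] = name
            topo_rows.append(summary)
        _tsv(pd.DataFrame(topo_rows).set_index("network"), out / "topology.tsv")
        rb = {}
        for strategy in ("random", "target_hubs"):
            res = topology.robustness(
                inter,
                removal_fraction=config.robustness["removal_fraction"],
                strategy=strategy,
                replicates=config.robustness["replicates"],
                seed=config.child_seed(f"robustness:{strategy}"),
            )
            rb[strategy] = res
        _tsv(
            pd.DataFrame(
                {
                    s: {"mean": r.mean, "sd": r.sd, "removal_fraction": r.removal_fraction}
                    for s, r in rb.items()
                }
            ).T,
            out / "robustness.tsv",
            index_label="strategy",
        )
        results["robustness"] = rb

        # -- modules / roles / eigengenes ------------------------------
        stage("modules")
        partition = module_traits.detect_modules(inter)
        roles = module_traits.zi_pi(inter, partition)
        frame = roles.to_frame()
        frame["module"] = pd.Series(partition.assignment)
        _tsv(frame, out / "node_roles.tsv", index_label="otu_id")
        for node in inter.nodes:
            inter.nodes[node].update(
                module=int(partition.assignment[node]),
                Zi=float(roles.roles[node].zi),
                Pi=float(roles.roles[node].pi),
                role=roles.roles[node].role,
            )
        write_network(
            inter,
            out / "network_interdomain_edges.tsv",
            out / "network_interdomain_nodes.tsv",
            out / "network_interdomain.graphml",
        )
        eigs = module_traits.eigengene_set(merged, partition)
        _tsv(eigs.matrix(), out / "eigengenes.tsv", index_label="sample_id")
        traits = module_traits.eigengene_trait_correlation(eigs, metadata)
        _tsv(traits, out / "module_trait_correlation.tsv", index=False)
        results["partition"] = partition
        results["roles"] = roles
        results["eigengenes"] = eigs
        results["module_traits"] = traits
        for guild in ("methanogen", "methanotroph"):
            sub = module_traits.guild_subnetwork(inter, guild)
            if sub.number_of_nodes():
                write_network(
                    sub,
                    out / f"subnetwork_{guild}_edges.tsv",
                    out / f"subnetwork_{guild}_nodes.tsv",
                )

        # -- community statistics --------------------------------------
        stage("community_stats")
        distances = {
            k: community_stats.jaccard_distance(t) for k, t in rarefied.items()
        }
        mantel = community_stats.mantel_table(
            distances,
            metadata.trait_table().loc[list(rarefied.values())[0].sample_ids],
            permutations=config.mantel_permutations,
            seed=config.child_seed("mantel"),
        )
        _tsv(mantel, out / "mantel_tests.tsv", index=False)
        diss_rows = []
        groups = metadata.group
        for k, dm in distances.items():
            res = community_stats.dissimilarity_tests(
                dm,
                groups.loc[dm.ids],
                permutations=config.dissimilarity_permutations,
                seed=config.child_seed(f"dissimilarity:{k}"),
            )
            res.insert(0, "community", k)
            diss_rows.append(res)
        _tsv(pd.concat(diss_rows), out / "dissimilarity_tests.tsv", index=False)
        ords = {k: community_stats.pca_ordination(t) for k, t in rarefied.items()}
        _tsv(
            pd.concat(
                [o.scores.assign(kingdom=k) for k, o in ords.items()]
            ),
            out / "pca_scores.tsv",
            index_label="sample_id",
        )
        flux = metadata.ch4_flux
        f_stat, p_anova = community_stats.group_anova(flux, groups)
        reg_rows = [{"response": "ch4_flux~group", "statistic": f_stat, "p": p_anova}]
        for gene in ("mcrA_copies", "pmoA_copies"):
            if gene in metadata.table.columns:
                reg = community_stats.flux_regression(
                    metadata.table[gene], flux
                )
                reg_rows.append(
                    {"response": f"ch4_flux~{gene}", "statistic": reg.r_squared, "p": reg.p}
                )
        _tsv(pd.DataFrame(reg_rows), out / "flux_models.tsv", index=False)
        results["mantel"] = mantel

        manifest["outputs"] = sorted(
            {p.name for p in out.iterdir() if p.is_file()} | {"manifest.json"}
        )
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
        return results
    except Exception as exc:
        failed = [s for s in manifest["stages"]][-1] if manifest["stages"] else "setup"
        raise RuntimeError(f"pipeline failed in stage {failed!r}: {exc}") from exc
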