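"""Rarefaction, prevalence filtering, alpha diversity, guild annotation and
inundation-group assignment.

Defaults follow the wetland study design this pipeline emulates: per-kingdom
rarefaction depths of 50,000 (prokaryotes), 51,591 (fungi) and 33,548
(cercozoa) reads, a strict >80% prevalence filter before network
construction, and three inundation groups (IL: control + 0 cm saturation,
IM: 5/10/20 cm, IH: 30/40 cm).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .io_formats import CountTable, GuildRuleSet, SampleMetadata

logger = logging.getLogger("menpipe")

#: per-kingdom rarefaction depths (reads per sample)
DEFAULT_DEPTHS = {"prokaryote": 50_000, "fungus": 51_591, "cercozoa": 33_548}

DEFAULT_MIN_PREVALENCE = 0.8

#: taxonomy substring -> guild.  Methanogen orders are the classical
#: Euryarchaeotal orders plus Methanocellales/Methanomassiliicoccales;
#: methanotroph markers cover the pmoA-bearing aerobic orders.
DEFAULT_GUILD_RULES = GuildRuleSet(
    [
        ("Methanopyrales", "methanogen"),
        ("Methanococcales", "methanogen"),
        ("Methanobacteriales", "methanogen"),
        ("Methanomicrobiales", "methanogen"),
        ("Methanosarcinales", "methanogen"),
        ("Methanocellales", "methanogen"),
        ("Methanomassiliicoccales", "methanogen"),
        ("Methylococcales", "methanotroph"),
        ("Methylocystales", "methanotroph"),
    ]
)

#: inundation depth -> group.  Depths are cm of standing water; "control"
#: received natural precipitation only and 0 means inundation to saturation.
GROUP_BY_DEPTH = {
    "control": "IL",
    "0": "IL",
    "5": "IM",
    "10": "IM",
    "20": "IM",
    "30": "IH",
    "40": "IH",
}


def rarefy(table: CountTable, depth: int, seed: int) -> CountTable:
    """Subsample every sample to exactly ``depth`` reads without replacement.

    Samples with fewer than ``depth`` total reads are dropped with a logged
    warning; OTUs left with all-zero rows are removed.
    """
    if depth <= 0:
        raise ValueError("rarefaction depth must be positive")
    rng = np.random.default_rng(seed)
    kept_cols = {}
    for sample in table.sample_ids:
        col = table.counts[sample].to_numpy()
        total = int(col.sum())
        if total < depth:
            logger.warning(
                "dropping sample %s: %d reads < depth %d", sample, total, depth
            )
            continue
        if total == depth:
            kept_cols[sample] = col
        else:
            kept_cols[sample] = rng.multivariate_hypergeometric(
                col, depth, method="marginals"
            )
    if not kept_cols:
        raise ValueError("no sample reaches the rarefaction depth")
    counts = pd.DataFrame(kept_cols, index=table.counts.index)
    nonzero = counts.sum(axis=1) > 0
    return CountTable(
        counts.loc[nonzero],
        table.taxonomy.loc[nonzero].copy(),
        table.kingdom.loc[nonzero].copy(),
        table.guild.loc[nonzero].copy(),
    )


def prevalence_filter(
    table: CountTable, min_prevalence: float = DEFAULT_MIN_PREVALENCE
) -> CountTable:
    """Keep OTUs present (count > 0) in strictly more than ``min_prevalence``
    of samples — a "shared by more than 80%" rule at the default."""
    if table.shape[1] == 0:
        raise ValueError("empty count table")
    presence = (table.counts > 0).sum(axis=1) / table.shape[1]
    return table.subset_otus(table.counts.index[presence > min_prevalence])


def alpha_diversity(table: CountTable) -> pd.DataFrame:
    """Shannon (nats), Pielou evenness, bias-corrected Chao1 and observed
    richness per sample.

    Chao1 = S + F1(F1-1) / (2(F2+1)) with F1 singletons and F2 doubletons.
    Pielou = H / ln S, undefined (NaN) for S <= 1.  All-zero samples are
    reported as missing.
    """
    records = {}
    for sample in table.sample_ids:
        col = table.counts[sample].to_numpy()
        total = col.sum()
        if total == 0:
            records[sample] = dict.fromkeys(
                ("shannon", "pielou", "chao1", "richness"), np.nan
            )
            continue
        p = col[col > 0] / total
        h = float(-(p * np.log(p)).sum())
        s = int((col > 0).sum())
        f1 = int((col == 1).sum())
        f2 = int((col == 2).sum())
        records[sample] = {
            "shannon": h,
            "pielou": h / np.log(s) if s > 1 else np.nan,
            "chao1": s + f1 * (f1 - 1) / (2 * (f2 + 1)),
            "richness": s,
        }
    return pd.DataFrame.from_dict(records, orient="index")


def annotate_guilds(
    table: CountTable, rules: GuildRuleSet = DEFAULT_GUILD_RULES
) -> CountTable:
    """Assign a guild to every OTU from the first matching taxonomy substring."""
    guild = table.taxonomy.map(rules.classify).rename("guild")
    return CountTable(
        table.counts.copy(), table.taxonomy.copy(), table.kingdom.copy(), guild
    )


def assign_groups(metadata: SampleMetadata) -> SampleMetadata:
    """Map inundation depth to the IL / IM / IH group labels."""
    if "inundation_depth_cm" not in metadata.table.columns:
        raise ValueError("metadata lacks 'inundation_depth_cm'")

    def to_group(value) -> str:
        key = str(value).strip()
        if key.endswith(".0"):
            key = key[:-2]
        if key not in GROUP_BY_DEPTH:
            raise ValueError(f"unknown inundation depth {value!r}")
        return GROUP_BY_DEPTH[key]

    table = metadata.table.copy()
    table["group"] = table["inundation_depth_cm"].map(to_group)
    return SampleMetadata(table, list(metadata.warnings))
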