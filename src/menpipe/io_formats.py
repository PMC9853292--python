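"""Reading and writing the tables and network formats used by the pipeline.

Canonical table dialect is UTF-8 TSV with "." decimals, the convention of
amplicon pipelines.  Taxonomy strings are semicolon-delimited ranks
(RDP/UNITE/PR2 style).  Networks are exported both as Cytoscape-loadable
edge-list/attribute TSVs and as GraphML.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger("menpipe")

KINGDOMS = ("prokaryote", "fungus", "cercozoa")
GUILDS = ("methanogen", "methanotroph", "none")

#: metadata columns with reserved meaning; everything else numeric is an
#: environmental variable
RESERVED_META_COLUMNS = (
    "inundation_depth_cm",
    "group",
    "ch4_flux",
    "mcrA_copies",
    "pmoA_copies",
)


class FormatError(ValueError):
    """Raised when an input file violates the expected table format."""


@dataclass
class CountTable:
    """OTU x sample integer count matrix with per-OTU annotations.

    ``counts`` is indexed by OTU id (rows) and sample id (columns);
    ``taxonomy``, ``kingdom`` and ``guild`` are Series over the same OTU ids.
    """

    counts: pd.DataFrame
    taxonomy: pd.Series
    kingdom: pd.Series
    guild: pd.Series

    def __post_init__(self) -> None:
        self.validate()

    # -- constructors -------------------------------------------------
    @classmethod
    def from_arrays(
        cls,
        otu_ids,
        sample_ids,
        counts,
        taxonomy=None,
        kingdom="prokaryote",
        guild=None,
    ) -> "CountTable":
        otu_ids = list(otu_ids)
        counts = pd.DataFrame(
            np.asarray(counts), index=otu_ids, columns=list(sample_ids)
        )
        if taxonomy is None:
            taxonomy = ["Unclassified"] * len(otu_ids)
        if isinstance(kingdom, str):
            kingdom = [kingdom] * len(otu_ids)
        if guild is None:
            guild = ["none"] * len(otu_ids)
        return cls(
            counts,
            pd.Series(list(taxonomy), index=otu_ids, name="taxonomy"),
            pd.Series(list(kingdom), index=otu_ids, name="kingdom"),
            pd.Series(list(guild), index=otu_ids, name="guild"),
        )

    # -- contract -----------------------------------------------------
    def validate(self) -> None:
        if self.counts.index.has_duplicates:
            raise FormatError("duplicate OTU ids in count table")
        if self.counts.columns.has_duplicates:
            raise FormatError("duplicate sample ids in count table")
        arr = self.counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise FormatError("non-numeric counts")
        if (arr < 0).any():
            raise FormatError("negative counts")
        if np.any(arr != np.floor(arr)):
            raise FormatError("non-integer counts")
        self.counts = self.counts.astype(np.int64)
        for name, s in (
            ("taxonomy", self.taxonomy),
            ("kingdom", self.kingdom),
            ("guild", self.guild),
        ):
            if len(s) != len(self.counts.index) or not s.index.equals(
                self.counts.index
            ):
                raise FormatError(f"{name} not aligned with OTU ids")
        bad = set(self.guild) - set(GUILDS)
        if bad:
            raise FormatError(f"unknown guild labels: {sorted(bad)}")

    # -- convenience --------------------------------------------------
    @property
    def otu_ids(self) -> list:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list:
        return list(self.counts.columns)

    @property
    def shape(self) -> tuple:
        return self.counts.shape

    def relative_abundance(self) -> pd.DataFrame:
        """Column-closed relative abundances (columns sum to 1)."""
        totals = self.counts.sum(axis=0)
        return self.counts / totals.replace(0, np.nan)

    def subset_otus(self, otu_ids) -> "CountTable":
        idx = list(otu_ids)
        return CountTable(
            self.counts.loc[idx].copy(),
            self.taxonomy.loc[idx].copy(),
            self.kingdom.loc[idx].copy(),
            self.guild.loc[idx].copy(),
        )

    def subset_samples(self, sample_ids) -> "CountTable":
        cols = list(sample_ids)
        return CountTable(
            self.counts[cols].copy(),
            self.taxonomy.copy(),
            self.kingdom.copy(),
            self.guild.copy(),
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, CountTable):
            return NotImplemented
        return (
            self.counts.equals(other.counts)
            and self.taxonomy.equals(other.taxonomy)
            and self.kingdom.equals(other.kingdom)
            and self.guild.equals(other.guild)
        )


@dataclass
class SampleMetadata:
    """Per-sample environmental variables, inundation depth/group and fluxes.

    Backed by a single DataFrame indexed by sample id.  Reserved columns
    (depth, group, CH4 flux, gene copies) are split from the free-form
    environmental variables by :attr:`env`.
    """

    table: pd.DataFrame
    warnings: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.table.index.has_duplicates:
            raise FormatError("duplicate sample ids in metadata")

    @property
    def sample_ids(self) -> list:
        return list(self.table.index)

    @property
    def env(self) -> pd.DataFrame:
        """Environmental variables only (reserved columns stripped)."""
        cols = [c for c in self.table.columns if c not in RESERVED_META_COLUMNS]
        return self.table[cols]

    @property
    def group(self) -> pd.Series:
        return self.table["group"]

    @property
    def ch4_flux(self) -> pd.Series:
        return self.table["ch4_flux"]

    def trait_table(self, traits=None) -> pd.DataFrame:
        """Numeric traits for correlation analyses (env + flux + gene copies)."""
        numeric = self.table.select_dtypes(include=[np.number])
        if traits is not None:
            numeric = numeric[list(traits)]
        return numeric

    def __eq__(self, other) -> bool:
        if not isinstance(other, SampleMetadata):
            return NotImplemented
        return self.table.equals(other.table)


@dataclass
class GuildRuleSet:
    """Ordered (taxonomy substring, guild) rules; the first match wins."""

    rules: list

    def __post_init__(self) -> None:
        if not self.rules:
            raise FormatError("empty guild rule set")
        for pattern, label in self.rules:
            if label not in GUILDS:
                raise FormatError(f"unknown guild label {label!r}")

    def classify(self, taxonomy: str) -> str:
        for pattern, label in self.rules:
            if pattern in taxonomy:
                return label
        return "none"


# ---------------------------------------------------------------------------
# count tables
# ---------------------------------------------------------------------------

def read_count_table(path, kingdom: str = "prokaryote") -> CountTable:
    """Read an OTU count TSV: sample-id header, one OTU per row, trailing
    ``taxonomy`` column (and optional ``guild`` column before it)."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.index.has_duplicates:
        raise FormatError(f"{path}: duplicate OTU ids")
    if df.columns.has_duplicates:
        raise FormatError(f"{path}: duplicate sample columns")
    if "taxonomy" not in df.columns:
        raise FormatError(f"{path}: missing 'taxonomy' column")
    taxonomy = df.pop("taxonomy")
    guild = df.pop("guild") if "guild" in df.columns else None
    try:
        counts = df.astype(np.int64)
    except (ValueError, TypeError) as exc:
        raise FormatError(f"{path}: non-numeric counts ({exc})") from exc
    return CountTable(
        counts,
        taxonomy.rename("taxonomy"),
        pd.Series(kingdom, index=counts.index, name="kingdom"),
        (guild if guild is not None else pd.Series("none", index=counts.index)).rename(
            "guild"
        ),
    )


def write_count_table(table: CountTable, path) -> None:
    out = table.counts.copy()
    out["guild"] = table.guild
    out["taxonomy"] = table.taxonomy
    out.to_csv(path, sep="\t", index_label="otu_id")


# ---------------------------------------------------------------------------
# sample metadata
# ---------------------------------------------------------------------------

def read_metadata(path, count_table: CountTable | None = None) -> SampleMetadata:
    """Read a sample metadata TSV keyed by sample id.

    All columns except ``inundation_depth_cm`` and ``group`` must be numeric;
    a non-numeric cell raises :class:`FormatError` naming row and column.
    When ``count_table`` is given, sample ids absent from it are collected in
    ``SampleMetadata.warnings``.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    parsed = {}
    for col in df.columns:
        if col in ("inundation_depth_cm", "group"):
            parsed[col] = df[col]
            continue
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna() & (df[col].str.strip() != "")
        if bad.any():
            row = df.index[bad.to_numpy().nonzero()[0][0]]
            raise FormatError(
                f"{path}: non-numeric value in column {col!r}, row {row!r}"
            )
        parsed[col] = vals
    meta = SampleMetadata(pd.DataFrame(parsed, index=df.index))
    if count_table is not None:
        missing = [s for s in meta.sample_ids if s not in count_table.sample_ids]
        if missing:
            meta.warnings.append(
                f"sample ids not in count table: {missing}"
            )
            logger.warning("metadata samples missing from counts: %s", missing)
    return meta


def write_metadata(meta: SampleMetadata, path) -> None:
    meta.table.to_csv(path, sep="\t", index_label="sample_id", float_format="%.10g")


# ---------------------------------------------------------------------------
# guild rules
# ---------------------------------------------------------------------------

def read_guild_rules(path) -> GuildRuleSet:
    df = pd.read_csv(path, sep="\t", header=None, names=["pattern", "guild"])
    return GuildRuleSet(list(df.itertuples(index=False, name=None)))


def write_guild_rules(rules: GuildRuleSet, path) -> None:
    pd.DataFrame(rules.rules).to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# networks
# ---------------------------------------------------------------------------

NODE_ATTR_COLUMNS = ("kingdom", "guild", "taxonomy", "category", "module", "Zi", "Pi", "role")


def write_network(net: nx.Graph, edge_path, attr_path, graphml_path=None) -> None:
    """Export a thresholded correlation network.

    Writes a Cytoscape-style edge list (source, sign, weight, target), a node
    attribute table, and optionally GraphML carrying the same attributes.
    """
    rows = [
        (u, d.get("sign", "positive"), d.get("weight", np.nan), v)
        for u, v, d in sorted(net.edges(data=True))
    ]
    pd.DataFrame(rows, columns=["source", "sign", "weight", "target"]).to_csv(
        edge_path, sep="\t", index=False, float_format="%.10g"
    )
    attr_rows = []
    for n, d in sorted(net.nodes(data=True)):
        attr_rows.append(
            {"id": n, **{k: d.get(k, "") for k in NODE_ATTR_COLUMNS if k in d}}
        )
    pd.DataFrame(attr_rows).to_csv(
        attr_path, sep="\t", index=False, float_format="%.10g"
    )
    if graphml_path is not None:
        nx.write_graphml(net, graphml_path)


def read_network(graphml_path) -> nx.Graph:
    """Re-import a GraphML export (round-trips node/edge sets and attributes)."""
    return nx.read_graphml(graphml_path)
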