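"""Synthetic multi-kingdom communities with planted co-occurrence modules.

The generator emulates the statistical structure the network analysis
assumes: three kingdom tables (prokaryotes at the hundreds-of-OTUs scale,
fungi and cercozoa at tens), compositional counts at fixed sequencing
depths, block-correlated OTU modules spanning kingdoms, designated
methanogen/methanotroph OTUs inside the prokaryote pool, three inundation
groups (IL/IM/IH, default sizes 7/12/8), environmental traits, and a CH4
flux variable linearly linked to one planted module's eigengene.

Counts follow a log-normal/multinomial compositional model: a latent
multivariate Gaussian with the planted block correlation (converted from
the target Spearman scale via the Gaussian-copula relation
r = 2 sin(pi * rho / 6)) is exponentiated to relative abundances and each
sample is multinomially resampled to exactly the requested depth.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .io_formats import CountTable, SampleMetadata

logger = logging.getLogger("menpipe")

DEFAULT_KINGDOM_SIZES = {"prokaryote": 120, "fungus": 40, "cercozoa": 40}
DEFAULT_GUILD_FRACTIONS = {"methanogen": 0.10, "methanotroph": 0.05}
#: inundation-group sizes of the emulated study design
DEFAULT_GROUP_SIZES = {"IL": 7, "IM": 12, "IH": 8}
DEPTHS_BY_GROUP = {"IL": ["control", "0"], "IM": ["5", "10", "20"], "IH": ["30", "40"]}

_PREFIX = {"prokaryote": "PRO", "fungus": "FUN", "cercozoa": "CER"}

_METHANOGEN_ORDERS = (
    "Methanomicrobiales",
    "Methanosarcinales",
    "Methanobacteriales",
    "Methanomassiliicoccales",
    "Methanocellales",
)
_METHANOTROPH_ORDERS = ("Methylococcales", "Methylocystales")

#: environmental variables: (mean, sd, per-group additive shift).  Units
#: follow the emulated field survey (TN/TP/ammonium/nitrate mg/kg, organic
#: matter %, pH, salinity ppt, oxygen vol%); shifts encode the reported
#: directions (pH and oxygen depressed under inundation, nitrate declining).
DEFAULT_ENV_SPEC = {
    "TN": (500.0, 100.0, {}),
    "TP": (600.0, 80.0, {"IH": 100.0}),
    "ammonium": (5.0, 2.0, {}),
    "nitrate": (2.0, 0.6, {"IM": -0.5, "IH": -1.0}),
    "organic_matter": (1.5, 0.5, {}),
    "pH": (8.2, 0.2, {"IM": -0.4, "IH": -0.2}),
    "salinity": (3.0, 1.0, {}),
    "oxygen": (15.0, 4.0, {"IM": -5.0, "IH": -8.0}),
}


@dataclass
class FluxLink:
    """CH4 flux = beta * module eigengene + Normal(0, noise_sd * sd(eigengene)).

    ``noise_sd`` is expressed relative to the eigengene's per-sample spread,
    so the population flux-eigengene correlation is beta/sqrt(beta^2 +
    noise_sd^2) (0.8 at the defaults).
    """

    module_id: int = 1
    beta: float = 1.0
    noise_sd: float = 0.75


@dataclass
class SyntheticTruth:
    otu_ids: list
    kingdom: dict
    taxonomy: dict
    module_assignment: dict  # otu id -> module id (0 = background)
    guild_truth: dict
    rho_within: float
    flux_link: FluxLink
    seed: int

    @property
    def latent_correlation(self) -> pd.DataFrame:
        """Target OTU x OTU Spearman structure (rho_within inside planted
        modules, 0 elsewhere, unit diagonal)."""
        mods = np.array([self.module_assignment[o] for o in self.otu_ids])
        same = (mods[:, None] == mods[None, :]) & (mods[:, None] > 0)
        rho = np.where(same, self.rho_within, 0.0)
        np.fill_diagonal(rho, 1.0)
        return pd.DataFrame(rho, index=self.otu_ids, columns=self.otu_ids)

    def module_members(self, module_id: int) -> list:
        return [o for o in self.otu_ids if self.module_assignment[o] == module_id]

    def to_json(self, path) -> None:
        payload = {
            "otu_ids": self.otu_ids,
            "kingdom": self.kingdom,
            "taxonomy": self.taxonomy,
            "module_assignment": self.module_assignment,
            "guild_truth": self.guild_truth,
            "rho_within": self.rho_within,
            "flux_link": asdict(self.flux_link),
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path) as fh:
            payload = json.load(fh)
        payload["flux_link"] = FluxLink(**payload["flux_link"])
        payload["module_assignment"] = {
            k: int(v) for k, v in payload["module_assignment"].items()
        }
        return cls(**payload)


def _taxonomy_string(kingdom: str, guild: str, index: int) -> str:
    if guild == "methanogen":
        order = _METHANOGEN_ORDERS[index % len(_METHANOGEN_ORDERS)]
        return f"Archaea;Euryarchaeota;Methanomicrobia;{order};Family{index:03d}"
    if guild == "methanotroph":
        order = _METHANOTROPH_ORDERS[index % len(_METHANOTROPH_ORDERS)]
        return (
            f"Bacteria;Proteobacteria;Gammaproteobacteria;{order};Family{index:03d}"
        )
    domain = {
        "prokaryote": "Bacteria;Phylum{p};Class{p};Order{p}",
        "fungus": "Fungi;Ascomycota;Class{p};Order{p}",
        "cercozoa": "Eukaryota;Cercozoa;Class{p};Order{p}",
    }[kingdom]
    return domain.format(p=f"{index % 17:02d}") + f";Family{index:03d}"


def generate_truth(
    n_otus_per_kingdom: dict | None = None,
    n_modules: int = 4,
    rho_within: float = 0.9,
    guild_fractions: dict | None = None,
    flux_link: FluxLink | None = None,
    seed: int = 0,
    module_size: int = 20,
) -> SyntheticTruth:
    """Plant a block-structured target correlation over a multi-kingdom pool.

    ``module_size`` OTUs per module are taken from an interleaving of the
    kingdoms, so modules span kingdoms; remaining OTUs are background
    (module 0).  Guild OTUs are drawn from the prokaryote pool.
    """
    sizes = dict(n_otus_per_kingdom or DEFAULT_KINGDOM_SIZES)
    fractions = dict(guild_fractions or DEFAULT_GUILD_FRACTIONS)
    link = flux_link or FluxLink()
    if not -1 < rho_within < 1:
        raise ValueError("|rho_within| must be < 1")
    if module_size < 3:
        raise ValueError("each planted module needs at least 3 OTUs")
    total = sum(sizes.values())
    if n_modules * module_size > total:
        raise ValueError("planted modules do not fit in the OTU pool")
    if not 1 <= link.module_id <= n_modules:
        raise ValueError("flux_link module does not exist")

    rng = np.random.default_rng(seed)
    otu_ids, kingdom = [], {}
    for k, n_k in sizes.items():
        for i in range(n_k):
            oid = f"{_PREFIX.get(k, k[:3].upper())}_{i + 1:04d}"
            otu_ids.append(oid)
            kingdom[oid] = k

    # interleave kingdoms by fractional rank so modules span kingdoms
    frac_rank = {
        oid: (i + 0.5) / sizes[kingdom[oid]]
        for k, n_k in sizes.items()
        for i, oid in enumerate(o for o in otu_ids if kingdom[o] == k)
    }
    interleaved = sorted(otu_ids, key=lambda o: (frac_rank[o], o))
    module_assignment = dict.fromkeys(otu_ids, 0)
    for j, oid in enumerate(interleaved[: n_modules * module_size]):
        module_assignment[oid] = (j % n_modules) + 1

    prok = [o for o in otu_ids if kingdom[o] == "prokaryote"]
    guild_truth = dict.fromkeys(otu_ids, "none")
    n_gen = int(round(fractions.get("methanogen", 0) * len(prok)))
    n_oxi = int(round(fractions.get("methanotroph", 0) * len(prok)))
    chosen = rng.choice(len(prok), size=n_gen + n_oxi, replace=False)
    for j, idx in enumerate(chosen):
        guild_truth[prok[idx]] = "methanogen" if j < n_gen else "methanotroph"

    taxonomy = {
        oid: _taxonomy_string(kingdom[oid], guild_truth[oid], i)
        for i, oid in enumerate(otu_ids)
    }
    return SyntheticTruth(
        otu_ids=otu_ids,
        kingdom=kingdom,
        taxonomy=taxonomy,
        module_assignment=module_assignment,
        guild_truth=guild_truth,
        rho_within=float(rho_within),
        flux_link=link,
        seed=int(seed),
    )


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------

#: spread of per-OTU log-mean abundances.  Planted module members form the
#: common co-occurring core (any OTU surviving an 80% prevalence filter is
#: common by definition) and get one log-unit of spread; background OTUs get
#: two, producing a steep rank-abundance curve whose rare tail drops below
#: one read per sample at the study sequencing depths, so presence/absence
#: (and hence Jaccard structure) varies across samples as in real tables.
LOG_MEAN_SD_MODULE = 1.0
LOG_MEAN_SD_BACKGROUND = 2.0


def _latent_abundances(
    truth: SyntheticTruth, n_samples: int, rng: np.random.Generator
) -> pd.DataFrame:
    """Log-normal relative abundances with the planted rank correlation
    (samples x OTUs, rows sum to 1)."""
    target = truth.latent_correlation.to_numpy()
    # Gaussian copula: Pearson correlation reproducing the target Spearman
    pearson = 2 * np.sin(np.pi * target / 6)
    np.fill_diagonal(pearson, 1.0)
    chol = np.linalg.cholesky(pearson)
    z = rng.standard_normal((n_samples, len(truth.otu_ids))) @ chol.T
    sd = np.array(
        [
            LOG_MEAN_SD_MODULE
            if truth.module_assignment[o] > 0
            else LOG_MEAN_SD_BACKGROUND
            for o in truth.otu_ids
        ]
    )
    log_mean = rng.normal(0.0, 1.0, len(truth.otu_ids)) * sd  # rank-abundance curve
    raw = np.exp(z + log_mean)
    rel = raw / raw.sum(axis=1, keepdims=True)
    return pd.DataFrame(rel, columns=truth.otu_ids)


def _sample_ids(n_samples: int) -> list:
    return [f"S{i + 1:02d}" for i in range(n_samples)]


def _to_table(counts: np.ndarray, truth: SyntheticTruth, otu_ids, sample_ids) -> CountTable:
    return CountTable.from_arrays(
        otu_ids,
        sample_ids,
        counts,
        taxonomy=[truth.taxonomy[o] for o in otu_ids],
        kingdom=[truth.kingdom[o] for o in otu_ids],
        guild=[truth.guild_truth[o] for o in otu_ids],
    )


def simulate_counts(
    truth: SyntheticTruth, n_samples: int, depth: int, seed: int
) -> CountTable:
    """One joint count table: every sample multinomially resampled to exactly
    ``depth`` reads from the latent log-normal relative abundances."""
    if n_samples < 4:
        raise ValueError("need at least 4 samples")
    if depth < len(truth.otu_ids):
        logger.warning("depth %d < %d OTUs: table will be sparse", depth, len(truth.otu_ids))
    rng = np.random.default_rng(seed)
    rel = _latent_abundances(truth, n_samples, rng)
    counts = np.vstack([rng.multinomial(depth, p) for p in rel.to_numpy()]).T
    return _to_table(counts, truth, truth.otu_ids, _sample_ids(n_samples))


def simulate_kingdom_tables(
    truth: SyntheticTruth, n_samples: int, depths: dict, seed: int
) -> dict:
    """Per-kingdom tables from one shared latent draw, each kingdom closed
    and multinomially sampled at its own sequencing depth."""
    if n_samples < 4:
        raise ValueError("need at least 4 samples")
    rng = np.random.default_rng(seed)
    rel = _latent_abundances(truth, n_samples, rng)
    samples = _sample_ids(n_samples)
    tables = {}
    for k, depth in depths.items():
        cols = [o for o in truth.otu_ids if truth.kingdom[o] == k]
        sub = rel[cols].to_numpy()
        sub = sub / sub.sum(axis=1, keepdims=True)
        counts = np.vstack([rng.multinomial(int(depth), p) for p in sub]).T
        tables[k] = _to_table(counts, truth, cols, samples)
    return tables


# ---------------------------------------------------------------------------
# metadata
# ---------------------------------------------------------------------------

def _flux_module_eigengene(truth: SyntheticTruth, counts: CountTable) -> pd.Series:
    """Eigengene of the flux-linked module, computed by the same operation
    the analysis uses (single definition, no drift)."""
    from .module_traits import ModulePartition, module_eigengene

    assignment = {
        o: truth.module_assignment[o]
        for o in counts.counts.index
        if o in truth.module_assignment
    }
    partition = ModulePartition(assignment, np.nan)
    return module_eigengene(counts, partition, truth.flux_link.module_id).vector


def simulate_metadata(
    truth: SyntheticTruth,
    counts: CountTable,
    group_sizes: dict | None = None,
    env_spec: dict | None = None,
    seed: int = 0,
) -> SampleMetadata:
    """Sample metadata with IL/IM/IH groups, environmental traits, gene
    copies, and CH4 flux linked to the planted module's eigengene."""
    sizes = dict(group_sizes or DEFAULT_GROUP_SIZES)
    spec = dict(env_spec or DEFAULT_ENV_SPEC)
    samples = counts.sample_ids
    if sum(sizes.values()) != len(samples):
        raise ValueError(
            f"group sizes {sizes} do not sum to {len(samples)} samples"
        )
    rng = np.random.default_rng(seed)
    groups, depths = [], []
    for g in ("IL", "IM", "IH"):
        for i in range(sizes.get(g, 0)):
            groups.append(g)
            depths.append(DEPTHS_BY_GROUP[g][i % len(DEPTHS_BY_GROUP[g])])

    eig = _flux_module_eigengene(truth, counts).loc[samples]
    link = truth.flux_link
    scale = float(eig.std(ddof=1))
    flux = link.beta * eig.to_numpy() + rng.normal(
        0.0, link.noise_sd * scale, len(samples)
    )

    table = pd.DataFrame(index=pd.Index(samples, name="sample_id"))
    table["inundation_depth_cm"] = depths
    table["group"] = groups
    for name, (mean, sd, shifts) in spec.items():
        shift = np.array([shifts.get(g, 0.0) for g in groups])
        table[name] = rng.normal(mean, sd, len(samples)) + shift
    table["ch4_flux"] = flux
    # gene copies weakly tracking flux (log-normal around 1e7 copies/g)
    flux_z = (flux - flux.mean()) / (flux.std() or 1.0)
    for gene in ("mcrA_copies", "pmoA_copies"):
        noise = rng.normal(0.0, np.sqrt(1 - 0.15), len(samples))
        table[gene] = np.exp(np.log(1e7) + 0.8 * (0.39 * flux_z + noise))
    return SampleMetadata(table)
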