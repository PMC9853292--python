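"""Spearman association matrices, random-matrix-theory (RMT) threshold
selection, and network assembly.

The RMT rationale: below the right correlation cutoff a thresholded
correlation matrix behaves like a dense random matrix, whose unfolded
eigenvalue nearest-neighbour spacing distribution (NNSD) follows the
Gaussian orthogonal ensemble (Wigner surmise, level repulsion); once noise
correlations are pruned the spectrum decomposes into weakly coupled modular
blocks and the NNSD relaxes to Poisson statistics.  The selected threshold
is the smallest scanned cutoff at which a chi-square test no longer rejects
the Poisson spacing law.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import interpolate, stats

from .io_formats import CountTable

logger = logging.getLogger("menpipe")

#: NNSD histogram: bin width 0.1 on [0, 3]
NNSD_BIN_WIDTH = 0.1
NNSD_MAX = 3.0
#: adjacent histogram bins are pooled until the expected count reaches this
#: value before the chi-square statistic is formed (Cochran's rule)
MIN_EXPECTED_PER_BIN = 5.0
#: the monotone unfolding fit passes through every UNFOLD_KNOT_EVERY-th
#: eigenvalue; small enough to track the secular spectral density, large
#: enough not to whiten genuine spacing fluctuations
UNFOLD_KNOT_EVERY = 8
#: eigenvalues closer than this are treated as degenerate and collapsed
DEGENERACY_TOL = 1e-8


class ThresholdError(RuntimeError):
    """Raised when the RMT scan finds no GOE-to-Poisson transition."""


@dataclass
class CorrelationMatrix:
    """Symmetric Spearman correlation matrix over OTUs."""

    ids: list
    rho: np.ndarray
    n_samples: int

    def __post_init__(self) -> None:
        rho = np.asarray(self.rho, dtype=float)
        if rho.shape != (len(self.ids), len(self.ids)):
            raise ValueError("rho shape does not match ids")
        if not np.allclose(rho, rho.T, atol=1e-12):
            raise ValueError("rho not symmetric")
        if np.nanmax(np.abs(rho)) > 1 + 1e-12:
            raise ValueError("|rho| > 1")
        if not np.allclose(np.diag(rho), 1.0):
            raise ValueError("diagonal of rho must be 1")
        self.rho = rho


def spearman_matrix(table: CountTable) -> CorrelationMatrix:
    """Pairwise Spearman rho over OTUs, average ranks for ties, computed on
    relative abundances (ranks are invariant to the compositional closure).

    Zero-variance OTUs get rho = 0 against everything (with a warning).
    """
    if table.shape[1] < 4:
        raise ValueError("need at least 4 samples for Spearman correlations")
    rel = table.relative_abundance().to_numpy()
    rho = np.asarray(stats.spearmanr(rel, axis=1).statistic, dtype=float)
    if rho.ndim == 0:  # scipy collapses the 2-OTU case to a scalar
        rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
    rho = np.nan_to_num(rho, nan=0.0)
    constant = np.std(rel, axis=1) == 0
    if constant.any():
        logger.warning(
            "%d zero-variance OTUs: correlations set to 0", int(constant.sum())
        )
        rho[constant, :] = 0.0
        rho[:, constant] = 0.0
    np.fill_diagonal(rho, 1.0)
    rho = np.clip((rho + rho.T) / 2, -1.0, 1.0)
    return CorrelationMatrix(table.otu_ids, rho, table.shape[1])


# ---------------------------------------------------------------------------
# RMT threshold selection
# ---------------------------------------------------------------------------

def _poisson_cdf(x: np.ndarray) -> np.ndarray:
    return 1.0 - np.exp(-np.asarray(x, dtype=float))


def _goe_cdf(x: np.ndarray) -> np.ndarray:
    # Wigner surmise for the GOE spacing law
    x = np.asarray(x, dtype=float)
    return 1.0 - np.exp(-np.pi * x**2 / 4.0)


def unfold_spacings(
    eigenvalues: np.ndarray, knot_every: int = UNFOLD_KNOT_EVERY
) -> np.ndarray | None:
    """Nearest-neighbour spacings of the unfolded spectrum.

    Degenerate eigenvalues are collapsed, then the cumulative spectral
    function is fit with a monotone piecewise-cubic (PCHIP) through every
    ``knot_every``-th eigenvalue.  Endpoints are interpolated exactly, so the
    unfolded spacings are non-negative with mean exactly 1.  Returns None for
    degenerate spectra (fewer than 20 distinct eigenvalues).
    """
    lam = np.sort(np.asarray(eigenvalues, dtype=float))
    keep = np.concatenate([[True], np.diff(lam) > DEGENERACY_TOL])
    lam = lam[keep]
    n = len(lam)
    if n < 20:
        return None
    cumulative = np.arange(1, n + 1, dtype=float)
    idx = np.unique(np.r_[np.arange(0, n, knot_every), n - 1])
    fit = interpolate.PchipInterpolator(lam[idx], cumulative[idx])
    return np.diff(fit(lam))


def chi_square_gof(spacings: np.ndarray, cdf) -> tuple[float, float, int]:
    """Chi-square goodness of fit of spacings against a spacing law CDF.

    Histogram with bin width 0.1 on [0, 3] (upper tail clipped into the last
    bin); adjacent bins pooled to an expected count of at least 5; df =
    pooled bins - 1.  Returns (chi2, p, df).
    """
    d = np.asarray(spacings, dtype=float)
    nbins = int(round(NNSD_MAX / NNSD_BIN_WIDTH))
    edges = np.linspace(0.0, NNSD_MAX, nbins + 1)
    observed, _ = np.histogram(np.clip(d, 0.0, NNSD_MAX - 1e-12), bins=edges)
    expected = np.diff(cdf(edges)) * len(d)
    # tail mass beyond the histogram range belongs to the last bin
    expected[-1] += (1.0 - cdf(np.array([NNSD_MAX]))[0]) * len(d)
    pooled_obs, pooled_exp = [], []
    acc_o = acc_e = 0.0
    for o, e in zip(observed, expected):
        acc_o += o
        acc_e += e
        if acc_e >= MIN_EXPECTED_PER_BIN:
            pooled_obs.append(acc_o)
            pooled_exp.append(acc_e)
            acc_o = acc_e = 0.0
    if acc_e > 0 and pooled_exp:
        pooled_obs[-1] += acc_o
        pooled_exp[-1] += acc_e
    if len(pooled_obs) < 3:
        return np.nan, np.nan, 0
    o = np.array(pooled_obs)
    e = np.array(pooled_exp)
    chi2 = float(((o - e) ** 2 / e).sum())
    df = len(o) - 1
    return chi2, float(stats.chi2.sf(chi2, df)), df


@dataclass
class RMTScan:
    """Per-threshold NNSD diagnostics and the selected threshold."""

    records: pd.DataFrame
    selected: float
    alpha: float
    s_min: float
    s_max: float
    step: float

    def to_tsv(self, path) -> None:
        self.records.to_csv(path, sep="\t", index=False, float_format="%.10g")


def threshold_matrix(corr: CorrelationMatrix, s: float) -> np.ndarray:
    """Zero out entries with |rho| < s, keeping signed values and unit diagonal."""
    m = np.where(np.abs(corr.rho) >= s, corr.rho, 0.0)
    np.fill_diagonal(m, 1.0)
    return m


def rmt_select_threshold(
    corr: CorrelationMatrix,
    s_min: float = 0.30,
    s_max: float = 0.99,
    step: float = 0.01,
    alpha: float = 0.05,
) -> RMTScan:
    """Scan thresholds ascending; select the smallest whose unfolded NNSD is
    not rejected against the Poisson spacing law (chi-square p > alpha).

    Each scanned record carries the spacing-mean diagnostic and the p-values
    against both the Poisson law and the GOE Wigner surmise.  Thresholds with
    degenerate spectra are skipped with a diagnostic.
    """
    n = len(corr.ids)
    if n < 30:
        raise ValueError("need at least 30 OTUs for a meaningful spectrum")
    rows = []
    selected = None
    for s in np.round(np.arange(s_min, s_max + step / 2, step), 10):
        m = threshold_matrix(corr, float(s))
        spacings = unfold_spacings(np.linalg.eigvalsh(m))
        if spacings is None:
            rows.append(
                {
                    "threshold": s,
                    "n_distinct_eigenvalues": np.nan,
                    "spacing_mean": np.nan,
                    "chi2_poisson": np.nan,
                    "p_poisson": np.nan,
                    "p_goe": np.nan,
                    "note": "degenerate spectrum, skipped",
                }
            )
            continue
        chi2_p, p_pois, _ = chi_square_gof(spacings, _poisson_cdf)
        _, p_goe, _ = chi_square_gof(spacings, _goe_cdf)
        rows.append(
            {
                "threshold": s,
                "n_distinct_eigenvalues": len(spacings) + 1,
                "spacing_mean": float(spacings.mean()),
                "chi2_poisson": chi2_p,
                "p_poisson": p_pois,
                "p_goe": p_goe,
                "note": "",
            }
        )
        if selected is None and np.isfinite(p_pois) and p_pois > alpha:
            selected = float(s)
            break
    records = pd.DataFrame(rows)
    if selected is None:
        raise ThresholdError(
            "no GOE-to-Poisson transition found in "
            f"[{s_min}, {s_max}]; widen the scan range or lower alpha"
        )
    return RMTScan(records, selected, alpha, s_min, s_max, step)


# ---------------------------------------------------------------------------
# network assembly
# ---------------------------------------------------------------------------

def build_network(
    corr: CorrelationMatrix, threshold: float, table: CountTable
) -> nx.Graph:
    """Graph with an edge wherever |rho| >= threshold; weight = signed rho.

    Node attributes (kingdom, guild, taxonomy, category) come from the count
    table; isolated nodes are dropped.  An empty result raises with a
    threshold diagnostic.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    net = nx.Graph(threshold=float(threshold))
    ids = corr.ids
    iu, ju = np.triu_indices(len(ids), k=1)
    strong = np.abs(corr.rho[iu, ju]) >= threshold
    for i, j in zip(iu[strong], ju[strong]):
        rho = float(corr.rho[i, j])
        net.add_edge(
            ids[i], ids[j], weight=rho, sign="positive" if rho >= 0 else "negative"
        )
    if net.number_of_edges() == 0:
        raise ThresholdError(
            f"no edge satisfies |rho| >= {threshold}; max off-diagonal |rho| = "
            f"{np.abs(corr.rho[iu, ju]).max():.3f}"
        )
    for node in net.nodes:
        kingdom = str(table.kingdom.loc[node])
        guild = str(table.guild.loc[node])
        net.nodes[node].update(
            kingdom=kingdom,
            guild=guild,
            taxonomy=str(table.taxonomy.loc[node]),
            category=guild if guild != "none" else kingdom,
        )
    return net


def merge_tables(tables: list[CountTable]) -> CountTable:
    """Concatenate kingdom tables on the intersection of their samples."""
    shared = list(tables[0].sample_ids)
    for t in tables[1:]:
        shared = [s for s in shared if s in t.sample_ids]
    if not shared:
        raise ValueError("kingdom tables share no samples")
    for t in tables:
        if len(shared) < len(t.sample_ids):
            logger.warning(
                "sample sets differ across kingdom tables; using %d shared samples",
                len(shared),
            )
            break
    aligned = [t.subset_samples(shared) for t in tables]
    counts = pd.concat([t.counts for t in aligned])
    if counts.index.has_duplicates:
        raise ValueError("OTU ids collide across kingdom tables")
    return CountTable(
        counts,
        pd.concat([t.taxonomy for t in aligned]),
        pd.concat([t.kingdom for t in aligned]),
        pd.concat([t.guild for t in aligned]),
    )


def build_interdomain_network(
    tables: list[CountTable],
    threshold: float = 0.85,
    min_prevalence: float | None = None,
) -> tuple[nx.Graph, CountTable]:
    """Interdomain network across kingdoms plus methane guild categories.

    Methanogen/methanotroph OTUs (annotated guilds) become their own node
    categories, disjoint from "prokaryote".  Returns the network and the
    merged table it was computed from.
    """
    from .preprocess import prevalence_filter

    merged = merge_tables(tables)
    if min_prevalence is not None:
        merged = prevalence_filter(merged, min_prevalence)
    corr = spearman_matrix(merged)
    net = build_network(corr, threshold, merged)
    return net, merged


def category_counts(net: nx.Graph) -> pd.Series:
    """Node counts per category (prokaryote/fungus/cercozoa/methanogen/
    methanotroph); categories partition the node set."""
    return pd.Series(
        [d["category"] for _, d in net.nodes(data=True)], dtype=object
    ).value_counts()
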