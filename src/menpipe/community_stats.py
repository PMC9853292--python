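"""Community-level statistics around the networks: Jaccard distances,
Mantel tests, PCA ordination, dissimilarity tests (MRPP / ANOSIM /
PERMANOVA), one-way ANOVA and flux regressions.

All permutation tests share a seeded NumPy Generator and use the upper-tail
convention with the +1 correction, p = (1 + #{T_perm at least as extreme}) /
(1 + permutations); an exact mode enumerates every label permutation instead
(used for small-n Mantel tests).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .io_formats import CountTable

logger = logging.getLogger("menpipe")


@dataclass
class DistanceMatrix:
    ids: list
    data: np.ndarray
    metric: str

    def __post_init__(self) -> None:
        d = np.asarray(self.data, dtype=float)
        if d.shape != (len(self.ids), len(self.ids)):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(d, d.T, atol=1e-12):
            raise ValueError("distance matrix not symmetric")
        if not np.allclose(np.diag(d), 0.0):
            raise ValueError("distance matrix diagonal must be 0")
        if (d < -1e-12).any():
            raise ValueError("negative distances")
        self.data = d

    def condensed(self) -> np.ndarray:
        iu = np.triu_indices(len(self.ids), k=1)
        return self.data[iu]

    def reorder(self, ids: list) -> "DistanceMatrix":
        idx = [self.ids.index(i) for i in ids]
        return DistanceMatrix(list(ids), self.data[np.ix_(idx, idx)], self.metric)


def jaccard_distance(table: CountTable) -> DistanceMatrix:
    """Binary Jaccard distance between samples: d = 1 - |A∩B| / |A∪B|.

    Empty samples are flagged; their distance to any non-empty sample is 1
    and to another empty sample 0.
    """
    presence = (table.counts.to_numpy() > 0).astype(float)  # OTU x sample
    empty = presence.sum(axis=0) == 0
    if empty.any():
        logger.warning(
            "empty samples in Jaccard computation: %s",
            [s for s, e in zip(table.sample_ids, empty) if e],
        )
    inter = presence.T @ presence
    sizes = presence.sum(axis=0)
    union = sizes[:, None] + sizes[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        d = 1.0 - inter / union
    d[union == 0] = 0.0  # two empty samples are identical
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(table.sample_ids, d, "jaccard")


def euclidean_trait_distance(values: pd.Series) -> DistanceMatrix:
    """Euclidean distance on a single standardized trait (Mantel input)."""
    x = values.to_numpy(dtype=float)
    sd = x.std(ddof=1)
    z = (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)
    return DistanceMatrix(
        list(values.index), np.abs(z[:, None] - z[None, :]), "euclidean"
    )


# ---------------------------------------------------------------------------
# Mantel
# ---------------------------------------------------------------------------

@dataclass
class MantelResult:
    r: float
    p: float
    permutations: int
    method: str


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    na = np.sqrt((a * a).sum())
    nb = np.sqrt((b * b).sum())
    if na == 0 or nb == 0:
        return np.nan
    return float((a * b).sum() / (na * nb))


def mantel_test(
    dx: DistanceMatrix,
    dy: DistanceMatrix,
    permutations: int = 999,
    seed: int | None = None,
    exact: bool = False,
) -> MantelResult:
    """One-sided (upper-tail) Mantel test of two distance matrices.

    r is the Pearson correlation of the off-diagonal triangles; the null
    distribution permutes one matrix's sample labels jointly over rows and
    columns.  ``exact=True`` enumerates all n! permutations (identity
    included), giving p = #{r_perm >= r_obs} / n!.
    """
    if set(dx.ids) != set(dy.ids):
        raise ValueError("sample sets differ between matrices")
    n = len(dx.ids)
    if n < 4:
        raise ValueError("Mantel test needs at least 4 samples")
    dy = dy.reorder(dx.ids)
    iu = np.triu_indices(n, k=1)
    x = dx.data[iu]
    r_obs = _pearson(x, dy.data[iu])
    if not np.isfinite(r_obs):
        logger.warning("Mantel undefined: a distance matrix is constant")
        return MantelResult(np.nan, np.nan, 0, "degenerate")
    if exact:
        count = 0
        total = math.factorial(n)
        for perm in itertools.permutations(range(n)):
            yp = dy.data[np.ix_(perm, perm)][iu]
            if _pearson(x, yp) >= r_obs - 1e-12:
                count += 1
        return MantelResult(r_obs, count / total, total, "exact")
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(permutations):
        perm = rng.permutation(n)
        yp = dy.data[np.ix_(perm, perm)][iu]
        if _pearson(x, yp) >= r_obs:
            count += 1
    return MantelResult(
        r_obs, (1 + count) / (1 + permutations), permutations, "permutation"
    )


# ---------------------------------------------------------------------------
# ordination
# ---------------------------------------------------------------------------

@dataclass
class Ordination:
    scores: pd.DataFrame  # samples x first two axes
    explained_variance_ratio: np.ndarray


def pca_ordination(table: CountTable) -> Ordination:
    """PCA of centered relative abundances (samples as observations)."""
    if table.shape[1] < 3:
        raise ValueError("PCA ordination needs at least 3 samples")
    x = table.relative_abundance().to_numpy().T  # samples x OTUs
    pca = PCA(svd_solver="full")
    scores = pca.fit_transform(x)
    k = min(2, scores.shape[1])
    return Ordination(
        pd.DataFrame(
            scores[:, :k],
            index=table.sample_ids,
            columns=[f"PC{i + 1}" for i in range(k)],
        ),
        pca.explained_variance_ratio_,
    )


# ---------------------------------------------------------------------------
# dissimilarity tests
# ---------------------------------------------------------------------------

def _group_setup(dm: DistanceMatrix, groups) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(
        [groups[i] for i in dm.ids]
        if isinstance(groups, (dict, pd.Series))
        else groups
    )
    if len(labels) != len(dm.ids):
        raise ValueError("group labels do not match samples")
    uniq, counts = np.unique(labels, return_counts=True)
    singles = uniq[counts < 2]
    if len(singles):
        logger.warning("excluding singleton groups: %s", list(singles))
        keep = ~np.isin(labels, singles)
        idx = np.flatnonzero(keep)
        dm = DistanceMatrix(
            [dm.ids[i] for i in idx], dm.data[np.ix_(idx, idx)], dm.metric
        )
        labels = labels[keep]
        uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("need at least 2 non-singleton groups")
    return dm.data, labels


def _mrpp_delta(d: np.ndarray, labels: np.ndarray) -> float:
    n = len(labels)
    delta = 0.0
    for g in np.unique(labels):
        idx = np.flatnonzero(labels == g)
        iu = np.triu_indices(len(idx), k=1)
        delta += (len(idx) / n) * d[np.ix_(idx, idx)][iu].mean()
    return delta


def _anosim_r(rank_matrix: np.ndarray, within_mask: np.ndarray, n: int) -> float:
    rb = rank_matrix[~within_mask].mean()
    rw = rank_matrix[within_mask].mean()
    return (rb - rw) / (n * (n - 1) / 4)


def _permanova_f(d2: np.ndarray, labels: np.ndarray) -> float:
    n = len(labels)
    k = len(np.unique(labels))
    iu = np.triu_indices(n, k=1)
    ss_total = d2[iu].sum() / n
    ss_within = 0.0
    for g in np.unique(labels):
        idx = np.flatnonzero(labels == g)
        giu = np.triu_indices(len(idx), k=1)
        ss_within += d2[np.ix_(idx, idx)][giu].sum() / len(idx)
    ss_among = ss_total - ss_within
    if ss_within == 0:  # perfect separation
        return np.inf
    return (ss_among / (k - 1)) / (ss_within / (n - k))


def dissimilarity_tests(
    dm: DistanceMatrix,
    groups,
    permutations: int = 999,
    seed: int | None = None,
) -> pd.DataFrame:
    """MRPP (delta, A), ANOSIM (R) and PERMANOVA (pseudo-F) with permutation
    p-values under a shared label-shuffling null."""
    d, labels = _group_setup(dm, groups)
    n = len(labels)
    iu_all = np.triu_indices(n, k=1)
    if np.ptp(d[iu_all]) == 0:
        logger.warning("dissimilarity tests undefined: all distances equal")
        nan_row = {"statistic": np.nan, "effect": np.nan, "p": np.nan}
        return pd.DataFrame(
            [{"test": t, **nan_row} for t in ("MRPP", "ANOSIM", "PERMANOVA")]
        )
    rng = np.random.default_rng(seed)
    perms = [rng.permutation(n) for _ in range(permutations)]

    # MRPP: small delta indicates within-group homogeneity (lower tail)
    delta_obs = _mrpp_delta(d, labels)
    perm_deltas = np.array([_mrpp_delta(d, labels[p]) for p in perms])
    mrpp_p = (1 + (perm_deltas <= delta_obs).sum()) / (1 + permutations)
    mrpp_a = 1 - delta_obs / perm_deltas.mean()

    # ANOSIM on ranked distances (upper tail)
    iu = np.triu_indices(n, k=1)
    ranks = np.zeros_like(d)
    ranks[iu] = stats.rankdata(d[iu])
    ranks = ranks + ranks.T
    within = labels[:, None] == labels[None, :]
    offdiag = ~np.eye(n, dtype=bool)
    r_obs = _anosim_r(ranks[offdiag], within[offdiag], n)
    perm_r = np.array(
        [_anosim_r(ranks[offdiag], (labels[p][:, None] == labels[p][None, :])[offdiag], n) for p in perms]
    )
    anosim_p = (1 + (perm_r >= r_obs).sum()) / (1 + permutations)

    # PERMANOVA on squared distances (upper tail)
    d2 = d**2
    f_obs = _permanova_f(d2, labels)
    perm_f = np.array([_permanova_f(d2, labels[p]) for p in perms])
    permanova_p = (1 + (perm_f >= f_obs).sum()) / (1 + permutations)

    return pd.DataFrame(
        [
            {"test": "MRPP", "statistic": delta_obs, "effect": mrpp_a, "p": mrpp_p},
            {"test": "ANOSIM", "statistic": r_obs, "effect": r_obs, "p": anosim_p},
            {"test": "PERMANOVA", "statistic": f_obs, "effect": f_obs, "p": permanova_p},
        ]
    )


# ---------------------------------------------------------------------------
# ANOVA / regression
# ---------------------------------------------------------------------------

def group_anova(values, groups) -> tuple[float, float]:
    """Classical one-way ANOVA F and p across groups.

    Degenerate case (zero variance everywhere, equal means) reports F = 0,
    p = 1.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    samples = [values[groups == g] for g in np.unique(groups)]
    if len(samples) < 2:
        raise ValueError("need at least 2 groups")
    means = [s.mean() for s in samples]
    if all(s.std() == 0 for s in samples) and np.ptp(means) == 0:
        return 0.0, 1.0
    f, p = stats.f_oneway(*samples)
    return float(f), float(p)


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p: float


def flux_regression(x, y) -> RegressionResult:
    """Ordinary least squares of y on x with R^2 and the slope t-test p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    fit = stats.linregress(x, y)
    return RegressionResult(
        float(fit.slope), float(fit.intercept), float(fit.rvalue**2), float(fit.pvalue)
    )


def mantel_table(
    community_distances: dict,
    metadata_traits: pd.DataFrame,
    permutations: int = 999,
    seed: int | None = None,
) -> pd.DataFrame:
    """Mantel r and p per (community, trait), traits as standardized
    Euclidean distances — the layout of a community x variable Mantel table."""
    rows = []
    seq = np.random.SeedSequence(seed).spawn(
        len(community_distances) * max(1, metadata_traits.shape[1])
    )
    k = 0
    for name, dm in community_distances.items():
        for trait in metadata_traits.columns:
            td = euclidean_trait_distance(metadata_traits[trait].loc[dm.ids])
            res = mantel_test(
                dm, td, permutations=permutations, seed=seq[k]
            )
            k += 1
            rows.append(
                {"community": name, "trait": trait, "r": res.r, "p": res.p}
            )
    return pd.DataFrame(rows)
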