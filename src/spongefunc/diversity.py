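"""Alpha/beta diversity and distance-based group statistics.

Shannon diversity (natural log), Bray-Curtis dissimilarity on log2-transformed
abundances, principal coordinates analysis (classical metric scaling),
PERMANOVA with exhaustive or sampled label permutations, homogeneity of
multivariate dispersions, and within-group variability summaries.

The Bray-Curtis input convention follows common amplicon practice: relative
abundances are scaled to counts-per-million, shifted by one, and log2
transformed (``log2(ra * 1e6 + 1)``) before distances are computed.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import entropy, f_oneway
from skbio.stats.distance import DistanceMatrix
from statsmodels.stats.multitest import multipletests
from sympy.utilities.iterables import multiset_permutations

logger = logging.getLogger(__name__)

__all__ = [
    "OrdinationResult",
    "PermanovaResult",
    "shannon",
    "log2_transform",
    "bray_curtis",
    "pcoa",
    "permanova",
    "pairwise_permanova",
    "dispersion_homogeneity",
    "group_variability",
    "variability_contrast",
]


def shannon(counts) -> float:
    """Shannon diversity H = -sum p ln p (nats) of one sample's counts."""
    x = np.asarray(counts, dtype=float)
    if (x < 0).any():
        raise ValueError("negative counts")
    total = x.sum()
    if total <= 0:
        raise ValueError("all-zero count vector")
    return float(entropy(x / total))


def log2_transform(abundances: pd.DataFrame, scale: float = 1e6) -> pd.DataFrame:
    """``log2(x * scale + 1)`` — pseudocount-1 log transform on scaled values."""
    return np.log2(abundances * scale + 1.0)


def bray_curtis(matrix: pd.DataFrame) -> DistanceMatrix:
    """Bray-Curtis dissimilarities between the rows of a sample x feature matrix.

    ``d(i, j) = sum|x_i - x_j| / sum(x_i + x_j)``; undefined (and rejected)
    when two samples are both all-zero.
    """
    values = matrix.to_numpy(dtype=float)
    if (values < 0).any():
        raise ValueError("Bray-Curtis requires non-negative abundances")
    zero_rows = matrix.index[values.sum(axis=1) == 0].tolist()
    if len(zero_rows) >= 2:
        raise ValueError(f"Bray-Curtis undefined between all-zero samples: {zero_rows}")
    condensed = pdist(values, metric="braycurtis")
    return DistanceMatrix(squareform(condensed), ids=[str(i) for i in matrix.index])


# ---------------------------------------------------------------------------
# PCoA


@dataclass
class OrdinationResult:
    """Principal-coordinate embedding of a distance matrix.

    Coordinates cover the positive-eigenvalue axes only; negative eigenvalues
    are reported (for diagnostics) but their axes are excluded.
    """

    coordinates: pd.DataFrame  # samples x positive axes
    eigenvalues: np.ndarray  # all eigenvalues, descending
    proportion_explained: np.ndarray  # over the positive eigenvalue mass


def pcoa(dm: DistanceMatrix, tol: float = 1e-10) -> OrdinationResult:
    """Classical metric scaling: Gower-center -d^2/2 and eigendecompose."""
    d = dm.data
    n = d.shape[0]
    if n < 2:
        raise ValueError("PCoA requires at least two samples")
    d2 = d ** 2
    centerer = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * centerer @ d2 @ centerer
    eigvals, eigvecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    positive = eigvals > tol * max(abs(eigvals[0]), 1.0)
    coords = eigvecs[:, positive] * np.sqrt(eigvals[positive])
    pos_mass = eigvals[positive].sum()
    prop = eigvals[positive] / pos_mass if pos_mass > 0 else eigvals[positive]
    neg = eigvals[eigvals < -tol]
    if len(neg):
        logger.info(
            "PCoA dropped %d negative-eigenvalue axes (largest magnitude %.3g)",
            len(neg),
            float(-neg.min()),
        )
    return OrdinationResult(
        coordinates=pd.DataFrame(
            coords,
            index=pd.Index(dm.ids, name="sample_id"),
            columns=[f"PC{i + 1}" for i in range(coords.shape[1])],
        ),
        eigenvalues=eigvals,
        proportion_explained=prop,
    )


# ---------------------------------------------------------------------------
# PERMANOVA


@dataclass
class PermanovaResult:
    pseudo_f: float
    r2: float
    p_value: float
    n_permutations: int
    term: str
    method: str = "sampled"  # "exact" or "sampled"


def _align_groups(dm: DistanceMatrix, groups) -> np.ndarray:
    g = pd.Series(groups)
    if set(map(str, g.index)) >= set(dm.ids):
        g.index = g.index.map(str)
        g = g.loc[list(dm.ids)]
    codes, _ = pd.factorize(g.to_numpy())
    return codes


def _permanova_f(d2: np.ndarray, labels: np.ndarray) -> float:
    """Pseudo-F from squared distances and integer group labels."""
    n = d2.shape[0]
    iu = np.triu_indices(n, k=1)
    ss_total = d2[iu].sum() / n
    ss_within = 0.0
    groups, counts = np.unique(labels, return_counts=True)
    for g, n_g in zip(groups, counts):
        idx = np.flatnonzero(labels == g)
        if len(idx) > 1:
            sub = d2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(len(idx), k=1)].sum() / n_g
    a = len(groups)
    ss_between = ss_total - ss_within
    if ss_within <= 0:
        return math.inf
    return (ss_between / (a - 1)) / (ss_within / (n - a))


def _count_distinct_assignments(labels: np.ndarray) -> int:
    n = len(labels)
    total = math.factorial(n)
    for _, c in zip(*np.unique(labels, return_counts=True)):
        total //= math.factorial(c)
    return total


def permanova(
    dm: DistanceMatrix,
    groups,
    n_permutations: int = 999,
    seed: int | np.random.Generator | None = None,
    method: str = "auto",
    exact_limit: int = 10000,
    term: str = "group",
) -> PermanovaResult:
    """One-factor PERMANOVA on a distance matrix.

    ``method='exact'`` enumerates every distinct assignment of the group-label
    multiset (p = fraction of assignments, including the observed one, with
    pseudo-F >= observed).  ``method='sampled'`` draws ``n_permutations``
    random relabelings and applies the +1 correction, so p >= 1/(n_perm + 1).
    ``'auto'`` uses exact enumeration when there are at most ``exact_limit``
    distinct assignments.
    """
    labels = _align_groups(dm, groups)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("PERMANOVA requires at least two groups")
    if (counts < 1).any():
        raise ValueError("empty group")
    d2 = dm.data ** 2
    f_obs = _permanova_f(d2, labels)
    n = len(labels)
    iu = np.triu_indices(n, k=1)
    ss_total = d2[iu].sum() / n

    # R^2 from the observed partition
    ss_within = 0.0
    for g, n_g in zip(classes, counts):
        idx = np.flatnonzero(labels == g)
        if len(idx) > 1:
            sub = d2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(len(idx), k=1)].sum() / n_g
    r2 = (ss_total - ss_within) / ss_total if ss_total > 0 else 0.0

    n_distinct = _count_distinct_assignments(labels)
    if method == "auto":
        method = "exact" if n_distinct <= exact_limit else "sampled"

    tol = 1e-10 * max(abs(f_obs), 1.0) if math.isfinite(f_obs) else 0.0
    if method == "exact":
        count_ge = 0
        for perm in multiset_permutations(labels.tolist()):
            f_perm = _permanova_f(d2, np.asarray(perm))
            if f_perm >= f_obs - tol:
                count_ge += 1
        p = count_ge / n_distinct
        return PermanovaResult(f_obs, float(r2), p, n_distinct, term, "exact")

    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    count_ge = 0
    for _ in range(n_permutations):
        f_perm = _permanova_f(d2, rng.permutation(labels))
        if f_perm >= f_obs - tol:
            count_ge += 1
    p = (1 + count_ge) / (1 + n_permutations)
    return PermanovaResult(f_obs, float(r2), p, n_permutations, term, "sampled")


def pairwise_permanova(
    dm: DistanceMatrix,
    groups,
    n_permutations: int = 999,
    seed: int | None = None,
    method: str = "auto",
) -> pd.DataFrame:
    """PERMANOVA for each group pair, with BH adjustment across pairs."""
    g = pd.Series(groups)
    g.index = g.index.map(str)
    g = g.loc[list(dm.ids)]
    levels = list(pd.unique(g))
    rng = np.random.default_rng(seed)
    rows = []
    for a, b in itertools.combinations(levels, 2):
        ids = g.index[g.isin([a, b])].tolist()
        sub = dm.filter(ids)
        res = permanova(
            sub, g.loc[ids], n_permutations, rng, method=method, term=f"{a} vs {b}"
        )
        rows.append(
            {
                "group_a": a,
                "group_b": b,
                "pseudo_f": res.pseudo_f,
                "r2": res.r2,
                "p_value": res.p_value,
                "method": res.method,
            }
        )
    out = pd.DataFrame(rows)
    out["p_adjusted"] = multipletests(out["p_value"], method="fdr_bh")[1]
    return out


# ---------------------------------------------------------------------------
# Dispersion and variability


def dispersion_homogeneity(dm: DistanceMatrix, groups):
    """Test homogeneity of multivariate dispersions across groups.

    Samples are embedded by PCoA (positive axes); each sample's distance to
    its own group centroid in that space is returned, together with a one-way
    ANOVA F and p across groups.  Groups of size one are excluded with a
    warning.
    """
    g = pd.Series(groups)
    g.index = g.index.map(str)
    g = g.loc[list(dm.ids)]
    sizes = g.value_counts()
    singletons = sizes[sizes < 2].index.tolist()
    if singletons:
        logger.warning("excluding size-1 groups from dispersion test: %s", singletons)
        keep = g.index[~g.isin(singletons)].tolist()
        dm = dm.filter(keep)
        g = g.loc[keep]
    if g.nunique() < 2:
        raise ValueError("dispersion test requires >= 2 groups with >= 2 samples")
    coords = pcoa(dm).coordinates
    dists = pd.Series(0.0, index=coords.index, name="centroid_distance")
    for level, idx in coords.groupby(g).groups.items():
        sub = coords.loc[idx]
        centroid = sub.mean(axis=0)
        dists.loc[idx] = np.sqrt(((sub - centroid) ** 2).sum(axis=1))
    samples = [dists[g == level].to_numpy() for level in pd.unique(g)]
    f_stat, p = f_oneway(*samples)
    return dists, float(f_stat), float(p)


def group_variability(dm: DistanceMatrix, groups) -> pd.Series:
    """Mean within-group pairwise dissimilarity, per group (sizes >= 2)."""
    g = pd.Series(groups)
    g.index = g.index.map(str)
    g = g.loc[list(dm.ids)]
    out = {}
    for level in pd.unique(g):
        ids = g.index[g == level].tolist()
        if len(ids) < 2:
            raise ValueError(f"group {level!r} has fewer than 2 samples")
        sub = dm.filter(ids).data
        out[level] = float(sub[np.triu_indices(len(ids), k=1)].mean())
    return pd.Series(out, name="mean_within_dissimilarity")


def variability_contrast(dm: DistanceMatrix, groups, habitats):
    """Compare within-group dissimilarities between habitat classes by ANOVA.

    ``habitats`` maps each sample to ``deep`` / ``shallow``; every group must
    be habitat-pure.  Returns (per-habitat pooled within-group distances,
    ANOVA F, p).
    """
    g = pd.Series(groups)
    g.index = g.index.map(str)
    h = pd.Series(habitats)
    h.index = h.index.map(str)
    pooled: dict[str, list[float]] = {}
    for level in pd.unique(g.loc[list(dm.ids)]):
        ids = g.index[g == level].tolist()
        ids = [i for i in ids if i in dm.ids]
        if len(ids) < 2:
            continue
        habs = set(h.loc[ids])
        if len(habs) != 1:
            raise ValueError(f"group {level!r} mixes habitats {sorted(habs)}")
        sub = dm.filter(ids).data
        values = sub[np.triu_indices(len(ids), k=1)].tolist()
        pooled.setdefault(habs.pop(), []).extend(values)
    if len(pooled) < 2:
        raise ValueError("need within-group distances from >= 2 habitat classes")
    arrays = {k: np.asarray(v) for k, v in pooled.items()}
    f_stat, p = f_oneway(*arrays.values())
    return arrays, float(f_stat), float(p)
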