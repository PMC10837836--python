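"""Shared/specific feature sets and filtered differential testing.

Presence of a feature in a group is defined by a strict abundance threshold in
at least one sample of the group (relative abundance > 0.01% for ASVs,
TMM-normalized abundance > 1 for transcripts).  Differential features are
filtered first (relative abundance > 0.001% for ASVs, CPM > 10 for
transcripts, in at least 2 samples), TMM-normalized, and tested with a
permutation test on the difference of group means of log2-CPM; features pass
when the BH-adjusted p-value is below 0.01 and the fold change is at least
2-fold.

Because small designs (3 vs 3 samples) admit only ten distinct label
partitions, null statistics are pooled across features before p-values are
computed; the pooled null gives the test enough resolution for BH correction
at small n while remaining a plain label-permutation null.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .expression import TmmFactors, cpm, tmm_factors

logger = logging.getLogger(__name__)

__all__ = [
    "SharedSetResult",
    "shared_features",
    "differential_features",
    "apply_differential_thresholds",
    "ASV_PRESENCE_RA",
    "TRANSCRIPT_PRESENCE_TMM",
    "ASV_FILTER_RA",
    "TRANSCRIPT_FILTER_CPM",
]

# presence thresholds for shared/specific sets (strict >)
ASV_PRESENCE_RA = 1e-4  # 0.01% relative abundance
TRANSCRIPT_PRESENCE_TMM = 1.0  # 1 TMM-normalized CPM-scale unit

# abundance filters applied before differential testing (in >= 2 samples)
ASV_FILTER_RA = 1e-5  # 0.001% relative abundance
TRANSCRIPT_FILTER_CPM = 10.0


@dataclass
class SharedSetResult:
    """Intersection structure of per-group feature presence sets.

    ``inclusive`` holds, for every non-empty group combination, the features
    present in *all* groups of the combination; ``exclusive`` holds the
    features present in exactly that combination (the exclusive sets partition
    the union of all present features).  ``pairwise`` summarizes each group
    pair: number shared, percent shared of the pair's union, and the percent
    of each group's abundance mass the shared features represent.
    """

    presence: dict[str, frozenset]
    inclusive: dict[tuple, frozenset]
    exclusive: dict[tuple, frozenset]
    pairwise: pd.DataFrame


def shared_features(
    values_by_group: dict[str, pd.DataFrame],
    threshold: float,
) -> SharedSetResult:
    """Shared/specific feature sets across groups.

    Parameters
    ----------
    values_by_group : mapping of group label to a samples x features matrix in
        the presence unit (relative abundance for ASVs, TMM-normalized
        abundance for transcripts).
    threshold : presence threshold; a feature is present in a group when its
        value strictly exceeds the threshold in at least one sample.
    """
    if len(values_by_group) < 2:
        raise ValueError("need at least two groups")
    presence: dict[str, frozenset] = {}
    for group, values in values_by_group.items():
        if values.shape[0] == 0:
            raise ValueError(f"group {group!r} has no samples")
        present = values.columns[(values > threshold).any(axis=0)]
        presence[group] = frozenset(present)

    groups = list(presence)
    inclusive: dict[tuple, frozenset] = {}
    exclusive: dict[tuple, frozenset] = {}
    for r in range(1, len(groups) + 1):
        for combo in itertools.combinations(groups, r):
            inter = frozenset.intersection(*(presence[g] for g in combo))
            inclusive[combo] = inter
            others = [presence[g] for g in groups if g not in combo]
            excl = inter.difference(*others) if others else inter
            exclusive[combo] = frozenset(excl)

    rows = []
    for a, b in itertools.combinations(groups, 2):
        shared = presence[a] & presence[b]
        union = presence[a] | presence[b]
        row = {
            "group_a": a,
            "group_b": b,
            "n_shared": len(shared),
            "pct_shared": 100.0 * len(shared) / len(union) if union else 0.0,
        }
        for label, group in (("a", a), ("b", b)):
            values = values_by_group[group]
            mean_ab = values.mean(axis=0)
            mass_present = mean_ab[list(presence[group])].sum()
            mass_shared = mean_ab[list(shared)].sum()
            row[f"pct_abundance_{label}"] = (
                100.0 * mass_shared / mass_present if mass_present > 0 else 0.0
            )
        rows.append(row)
    return SharedSetResult(
        presence=presence,
        inclusive=inclusive,
        exclusive=exclusive,
        pairwise=pd.DataFrame(rows),
    )


# ---------------------------------------------------------------------------
# Differential testing


def _distinct_partitions(labels: np.ndarray) -> list[np.ndarray]:
    """All distinct boolean partitions of a two-level label vector.

    Mirror-image assignments (swapping the two group names) give the same
    |statistic| and are deduplicated.
    """
    n = len(labels)
    n1 = int(labels.sum())
    masks = []
    seen = set()
    for combo in itertools.combinations(range(n), n1):
        mask = np.zeros(n, dtype=bool)
        mask[list(combo)] = True
        key = tuple(mask) if mask[0] else tuple(~mask)
        if key in seen:
            continue
        seen.add(key)
        masks.append(mask)
    return masks


def apply_differential_thresholds(
    log2fc: pd.Series, p_adjusted: pd.Series, alpha: float = 0.01, fc_threshold: float = 2.0
) -> pd.Series:
    """The dual pass criterion: BH-adjusted p < alpha AND |log2FC| >= log2(fc)."""
    return (p_adjusted < alpha) & (log2fc.abs() >= math.log2(fc_threshold))


def differential_features(
    counts: pd.DataFrame,
    groups,
    feature_kind: str = "transcript",
    alpha: float = 0.01,
    fc_threshold: float = 2.0,
    n_permutations: int = 10000,
    seed: int | np.random.Generator | None = None,
    min_samples: int = 2,
) -> pd.DataFrame:
    """Permutation test for differential abundance/expression between two groups.

    Features are filtered by the kind-specific abundance rule, TMM-normalized,
    and scored by the difference of group means of ``log2(CPM + 1)`` (which is
    also the reported log2 fold change).  The null distribution pools the
    statistic over all features and all distinct non-observed label partitions
    (exhaustively if there are at most ``n_permutations``, otherwise sampled);
    p-values use the +1 correction and are BH-adjusted across the surviving
    features.

    Returns a per-feature DataFrame with ``log2fc``, ``p_value``, ``p_adjusted``,
    ``direction`` (up = higher in the second group level), and ``passed``.
    """
    g = pd.Series(groups)
    g.index = g.index.map(str)
    g = g.loc[[str(c) for c in counts.columns]]
    levels = list(pd.unique(g))
    if len(levels) != 2:
        raise ValueError(f"need a two-level factor, got levels {levels}")
    mask_obs = (g == levels[1]).to_numpy()
    n1, n2 = int((~mask_obs).sum()), int(mask_obs.sum())
    if n1 < 2 or n2 < 2:
        raise ValueError("need >= 2 samples per group")

    # kind-specific abundance filter
    if feature_kind == "asv":
        ra = counts.div(counts.sum(axis=0), axis=1)
        keep = (ra > ASV_FILTER_RA).sum(axis=1) >= min_samples
    elif feature_kind == "transcript":
        raw_cpm = cpm(counts, tmm_factors(counts))
        keep = (raw_cpm > TRANSCRIPT_FILTER_CPM).sum(axis=1) >= min_samples
    else:
        raise ValueError(f"unknown feature kind {feature_kind!r}")
    filtered = counts.loc[keep]
    logger.info(
        "differential filter (%s) kept %d/%d features", feature_kind, keep.sum(), len(keep)
    )
    if filtered.empty:
        return pd.DataFrame(
            columns=["log2fc", "p_value", "p_adjusted", "direction", "passed"]
        )

    factors = tmm_factors(filtered)
    logcpm = np.log2(cpm(filtered, factors) + 1.0)
    x = logcpm.to_numpy()

    def stats_for(mask: np.ndarray) -> np.ndarray:
        return x[:, mask].mean(axis=1) - x[:, ~mask].mean(axis=1)

    obs = stats_for(mask_obs)

    partitions = _distinct_partitions(mask_obs)
    same = [
        p for p in partitions if np.array_equal(p, mask_obs) or np.array_equal(p, ~mask_obs)
    ]
    null_masks = [
        p
        for p in partitions
        if not (np.array_equal(p, mask_obs) or np.array_equal(p, ~mask_obs))
    ]
    if len(null_masks) > n_permutations:
        rng = (
            seed
            if isinstance(seed, np.random.Generator)
            else np.random.default_rng(seed)
        )
        chosen = rng.choice(len(null_masks), size=n_permutations, replace=False)
        null_masks = [null_masks[i] for i in chosen]
    if len(null_masks) < 2:
        raise ValueError("fewer than 2 distinct label permutations available")

    null = np.abs(np.concatenate([stats_for(m) for m in null_masks]))
    null.sort()
    n_null = null.size
    # +1-corrected pooled-null p-values (searchsorted counts null >= |obs|)
    count_ge = n_null - np.searchsorted(null, np.abs(obs), side="left")
    p_values = (1.0 + count_ge) / (1.0 + n_null)
    p_adjusted = multipletests(p_values, method="fdr_bh")[1]

    out = pd.DataFrame(
        {
            "log2fc": obs,
            "p_value": p_values,
            "p_adjusted": p_adjusted,
            "direction": np.where(obs >= 0, "up", "down"),
        },
        index=filtered.index,
    )
    out["passed"] = apply_differential_thresholds(
        out["log2fc"], out["p_adjusted"], alpha, fc_threshold
    )
    out.attrs["levels"] = levels
    out.attrs["n_null"] = int(n_null)
    return out
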