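"""Compositional preprocessing of ASV tables.

Rarefaction (random subsampling without replacement to a common depth),
conversion to relative abundances, taxonomic collapse, and minimum
relative-abundance filtering.  These are applied before any diversity
statistic so that sampling depth does not masquerade as community structure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import LINEAGE_RANKS, AsvTable

logger = logging.getLogger(__name__)

__all__ = [
    "RelativeAbundanceTable",
    "rarefy",
    "to_relative_abundance",
    "collapse_taxonomy",
    "filter_min_relative_abundance",
]


@dataclass
class RelativeAbundanceTable:
    """Sample x feature proportions (rows sum to 1) with a level tag."""

    proportions: pd.DataFrame
    level: str = "asv"

    def __post_init__(self):
        rowsums = self.proportions.sum(axis=1)
        if not np.allclose(rowsums, 1.0, atol=1e-9):
            raise ValueError("relative-abundance rows must sum to 1")


def rarefy(table: AsvTable, depth: int, seed: int | np.random.Generator = 0) -> AsvTable:
    """Subsample every sample without replacement to exactly ``depth`` counts.

    Samples whose total is below ``depth`` are dropped with a logged warning;
    a sample whose total equals ``depth`` is returned unchanged.  A single
    draw is taken (no averaging over replicate draws); the draw is fully
    determined by ``seed``.
    """
    if depth < 1:
        raise ValueError(f"rarefaction depth must be >= 1, got {depth}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    totals = table.totals()
    keep = totals[totals >= depth].index
    dropped = totals.index.difference(keep)
    if len(dropped):
        logger.warning(
            "dropping %d samples below rarefaction depth %d: %s",
            len(dropped),
            depth,
            dropped.tolist(),
        )
    rows = {}
    for sample in keep:
        row = table.counts.loc[sample].to_numpy(dtype=np.int64)
        if row.sum() == depth:
            rows[sample] = row
        else:
            rows[sample] = rng.multivariate_hypergeometric(row, depth)
    counts = pd.DataFrame.from_dict(rows, orient="index", dtype=np.int64)
    counts.columns = table.counts.columns
    counts.index.name = "sample_id"
    return AsvTable(
        counts=counts,
        taxonomy=table.taxonomy.copy(),
        metadata=table.metadata.loc[keep].copy(),
    )


def to_relative_abundance(table: AsvTable, level: str = "asv") -> RelativeAbundanceTable:
    totals = table.totals()
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"samples with zero total counts: {zero.index.tolist()}")
    return RelativeAbundanceTable(
        proportions=table.counts.div(totals, axis=0), level=level
    )


def collapse_taxonomy(table: AsvTable, rank: str) -> AsvTable:
    """Sum ASV counts over shared lineage prefixes up to ``rank``.

    ASVs unclassified at ``rank`` are pooled per parent lineage into an
    ``unclassified_<parent>`` feature rather than discarded, so per-sample
    totals are conserved exactly.
    """
    if rank not in LINEAGE_RANKS:
        raise ValueError(f"unknown rank {rank!r}; must be one of {LINEAGE_RANKS}")
    depth = LINEAGE_RANKS.index(rank)
    used = list(LINEAGE_RANKS[: depth + 1])

    def feature_name(row) -> str:
        values = [row[r] for r in used]
        values = [None if (pd.isna(v) or v == "") else str(v) for v in values]
        if values[-1] is None:
            classified = [v for v in values if v is not None]
            parent = classified[-1] if classified else "root"
            return f"unclassified_{parent}"
        return ";".join(v for v in values if v is not None)

    names = table.taxonomy.apply(feature_name, axis=1)
    collapsed = table.counts.T.groupby(names.reindex(table.counts.columns)).sum().T
    collapsed.columns.name = "asv_id"

    tax_rows = {}
    for feature, members in names.groupby(names).groups.items():
        first = table.taxonomy.loc[members[0]]
        lineage = {r: first[r] for r in used}
        for r in LINEAGE_RANKS[depth + 1 :]:
            lineage[r] = np.nan
        if str(feature).startswith("unclassified_"):
            lineage[rank] = np.nan
        tax_rows[feature] = lineage
    taxonomy = pd.DataFrame.from_dict(tax_rows, orient="index").loc[collapsed.columns]
    taxonomy.index.name = "asv_id"
    return AsvTable(counts=collapsed, taxonomy=taxonomy, metadata=table.metadata.copy())


def filter_min_relative_abundance(
    table: AsvTable, threshold: float
) -> tuple[AsvTable, pd.Series]:
    """Keep features reaching ``threshold`` relative abundance in >= 1 sample.

    The comparison is inclusive (``>=``).  Returns the filtered table together
    with the retained fraction of total abundance per sample.
    """
    if not (0 <= threshold < 1):
        raise ValueError(f"threshold must be in [0, 1), got {threshold}")
    ra = to_relative_abundance(table).proportions
    keep = ra.columns[(ra >= threshold).any(axis=0)]
    retained = ra[keep].sum(axis=1)
    logger.info(
        "min-RA filter %.6g kept %d/%d features; retained abundance %.1f%%-%.1f%%",
        threshold,
        len(keep),
        ra.shape[1],
        100 * retained.min(),
        100 * retained.max(),
    )
    filtered = AsvTable(
        counts=table.counts[keep].copy(),
        taxonomy=table.taxonomy.loc[keep].copy(),
        metadata=table.metadata.copy(),
    )
    return filtered, retained
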