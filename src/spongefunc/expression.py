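"""ORF-level expression quantification and normalization.

Assembled bacterial transcripts usually carry several ORFs, so transcript-level
expected counts overstate the expression of any single protein.  The chain here
apportions each transcript's expected count to its peptides proportionally to
peptide length (amino acids), converts the apportioned counts to
length-normalized TPM, and aggregates peptide TPM into KO-level expression.
``aTPM`` is the arithmetic mean of a KO's TPM across samples.

For count-based filtering and differential testing, between-sample scaling
factors follow the trimmed mean of M-values (TMM) method of Robinson &
Oshlack as implemented in edgeR (30% trim on M, 5% on A, inverse-variance
weights, upper-quartile reference), and CPM divides by the TMM-adjusted
effective library size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import OrfAnnotation, TranscriptCounts

logger = logging.getLogger(__name__)

__all__ = [
    "PeptideExpression",
    "KoExpression",
    "TmmFactors",
    "apportion_counts",
    "peptide_tpm",
    "aggregate_to_ko",
    "tmm_factors",
    "cpm",
]


@dataclass
class PeptideExpression:
    """Per-peptide apportioned counts (and, once computed, TPM)."""

    counts: pd.DataFrame  # peptides x samples
    lengths: pd.Series  # amino acids, indexed by peptide_id
    tpm: pd.DataFrame | None = None


@dataclass
class KoExpression:
    """KO x sample aggregated TPM, plus the across-sample mean (aTPM)."""

    tpm: pd.DataFrame
    atpm: pd.Series
    unannotated: pd.Series  # TPM mass of peptides without a KO, per sample


@dataclass
class TmmFactors:
    factors: pd.Series  # per-sample scaling factor, geometric mean 1
    reference: str


def apportion_counts(tc: TranscriptCounts, ann: OrfAnnotation) -> PeptideExpression:
    """Apportion transcript expected counts to peptides by peptide length.

    ``count(p, s) = count(t, s) * len(p) / sum(len(p') for p' in t)``, so the
    peptide counts of a transcript sum exactly to its expected count.
    Transcripts without any annotation record are dropped (tally logged), as
    are annotation records whose transcript has no counts.
    """
    rec = ann.records
    known = rec["transcript_id"].isin(tc.expected_counts.index)
    n_orphan = int((~known).sum())
    if n_orphan:
        logger.info("dropping %d ORF records with no matching transcript", n_orphan)
    rec = rec.loc[known]
    if rec.empty:
        raise ValueError("no ORF annotation records match the transcript counts")
    n_unannotated = tc.expected_counts.index.difference(rec["transcript_id"]).size
    if n_unannotated:
        logger.info("dropping %d transcripts without ORF annotation", n_unannotated)

    lengths = rec["peptide_length"].astype(float).to_numpy()
    total_len = rec.groupby("transcript_id")["peptide_length"].transform("sum")
    if (total_len <= 0).any():
        bad = rec.loc[total_len <= 0, "transcript_id"].unique().tolist()
        raise ValueError(f"zero total peptide length for transcripts: {bad}")
    weights = lengths / total_len.to_numpy()

    tmat = tc.expected_counts.loc[rec["transcript_id"]].to_numpy()
    counts = pd.DataFrame(
        tmat * weights[:, None],
        index=pd.Index(rec["peptide_id"], name="peptide_id"),
        columns=tc.expected_counts.columns,
    )
    return PeptideExpression(
        counts=counts,
        lengths=rec.set_index("peptide_id")["peptide_length"].astype(float),
    )


def peptide_tpm(pe: PeptideExpression) -> PeptideExpression:
    """Convert apportioned counts to TPM.

    Per sample: ``rate = count / length``; ``tpm = rate / sum(rate) * 1e6``.
    Every sample column of the result sums to 1e6.
    """
    rates = pe.counts.div(pe.lengths, axis=0)
    denom = rates.sum(axis=0)
    zero = denom[denom <= 0]
    if len(zero):
        raise ValueError(f"samples with no apportioned counts: {zero.index.tolist()}")
    tpm = rates.div(denom, axis=1) * 1e6
    return PeptideExpression(counts=pe.counts, lengths=pe.lengths, tpm=tpm)


def aggregate_to_ko(pe: PeptideExpression, ann: OrfAnnotation) -> KoExpression:
    """Sum peptide TPM into KO-level expression.

    Peptides without a KO term are pooled into an ``unannotated`` mass per
    sample so that KO totals plus unannotated mass reconstruct the 1e6 column
    sum exactly.
    """
    if pe.tpm is None:
        raise ValueError("peptide TPM not computed; run peptide_tpm first")
    kos = ann.kos().reindex(pe.tpm.index)
    annotated = kos.notna()
    ko_tpm = pe.tpm.loc[annotated].groupby(kos[annotated]).sum()
    ko_tpm.index.name = "ko"
    unannotated = pe.tpm.loc[~annotated].sum(axis=0)
    logger.info(
        "aggregated %d peptides into %d KOs; unannotated TPM mass mean %.0f",
        int(annotated.sum()),
        ko_tpm.shape[0],
        float(unannotated.mean()) if len(unannotated) else 0.0,
    )
    return KoExpression(tpm=ko_tpm, atpm=ko_tpm.mean(axis=1), unannotated=unannotated)


# ---------------------------------------------------------------------------
# TMM / CPM


def _quantile_factor(counts: np.ndarray, libsize: np.ndarray, p: float = 0.75):
    return np.quantile(counts / libsize, p, axis=0)


def tmm_factors(
    counts: pd.DataFrame,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
    reference: str | None = None,
) -> TmmFactors:
    """Trimmed-mean-of-M-values scaling factors (edgeR algorithm).

    The reference is the sample whose 75th-percentile count fraction is closest
    to the mean; each sample's factor is 2 to the inverse-variance-weighted
    mean of M-values against the reference after doubly trimming the most
    extreme ``trim_m`` of M-values and ``trim_a`` of A-values.  Factors are
    re-centered to geometric mean 1.
    """
    if counts.shape[1] < 2:
        raise ValueError("TMM requires at least two samples")
    mat = counts.to_numpy(dtype=float)
    libsize = mat.sum(axis=0)
    if (libsize <= 0).any():
        bad = counts.columns[libsize <= 0].tolist()
        raise ValueError(f"zero library size for samples: {bad}")

    if reference is None:
        f75 = _quantile_factor(mat, libsize)
        ref_idx = int(np.argmin(np.abs(f75 - f75.mean())))
    else:
        ref_idx = counts.columns.get_loc(reference)
    ref = mat[:, ref_idx]
    ref_lib = libsize[ref_idx]

    log_factors = np.zeros(mat.shape[1])
    for j in range(mat.shape[1]):
        if j == ref_idx:
            continue
        obs = mat[:, j]
        lib = libsize[j]
        keep = (obs > 0) & (ref > 0)
        if not keep.any():
            raise ValueError(
                f"sample {counts.columns[j]!r} shares no expressed features "
                f"with reference {counts.columns[ref_idx]!r}"
            )
        p_obs = obs[keep] / lib
        p_ref = ref[keep] / ref_lib
        m = np.log2(p_obs / p_ref)
        a = 0.5 * np.log2(p_obs * p_ref)
        # asymptotic (delta-method) variance of M
        w = (lib - obs[keep]) / (lib * obs[keep]) + (ref_lib - ref[keep]) / (
            ref_lib * ref[keep]
        )
        if np.allclose(m, m[0]):
            log_factors[j] = m[0]
            continue
        n = m.size
        lo_m = np.floor(n * trim_m) + 1
        hi_m = n + 1 - lo_m
        lo_a = np.floor(n * trim_a) + 1
        hi_a = n + 1 - lo_a
        rank_m = pd.Series(m).rank().to_numpy()
        rank_a = pd.Series(a).rank().to_numpy()
        keep2 = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
        if not keep2.any():
            log_factors[j] = 0.0
            continue
        f = np.sum(m[keep2] / w[keep2]) / np.sum(1.0 / w[keep2])
        log_factors[j] = f if np.isfinite(f) else 0.0

    factors = 2.0 ** log_factors
    factors = factors / np.exp(np.mean(np.log(factors)))  # geometric mean 1
    return TmmFactors(
        factors=pd.Series(factors, index=counts.columns, name="tmm_factor"),
        reference=str(counts.columns[ref_idx]),
    )


def cpm(counts: pd.DataFrame, factors: TmmFactors | None = None) -> pd.DataFrame:
    """Counts per million over the (optionally TMM-adjusted) library size."""
    libsize = counts.sum(axis=0)
    if factors is not None:
        libsize = libsize * factors.factors.reindex(counts.columns)
    libsize = libsize.replace(0, np.nan)
    return (counts.div(libsize, axis=1) * 1e6).fillna(0.0)
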