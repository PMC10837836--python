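"""Shared/specific features between species, and differential transcripts at
the study thresholds (BH-adjusted p < 0.01 and 2-fold change) compared against
the planted truth.

Reads results/data/, writes tables under results/comparison/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from spongefunc import amplicon as amp
from spongefunc.comparison import (
    ASV_PRESENCE_RA,
    TRANSCRIPT_PRESENCE_TMM,
    differential_features,
    shared_features,
)
from spongefunc.expression import cpm, tmm_factors
from spongefunc.io_formats import read_asv_table, read_transcript_counts, read_truth

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "results" / "data"
OUT = ROOT / "results" / "comparison"
SEED = 13


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    table = read_asv_table(
        DATA / "asv_counts.tsv", DATA / "asv_taxonomy.tsv", DATA / "sample_metadata.tsv"
    )
    tc = read_transcript_counts(DATA / "transcript_counts.tsv")
    truth = read_truth(DATA / "truth.json")
    meta = table.metadata

    # shared ASVs between species (presence: RA > 0.01% in >= 1 sample)
    ra = amp.to_relative_abundance(table).proportions
    asv_groups = {g: ra.loc[idx] for g, idx in ra.groupby(meta["species"]).groups.items()}
    shared_asv = shared_features(asv_groups, ASV_PRESENCE_RA)
    shared_asv.pairwise.to_csv(OUT / "shared_asvs_species.tsv", sep="\t", index=False)
    lo, hi = shared_asv.pairwise["pct_shared"].agg(["min", "max"])
    alo, ahi = (
        shared_asv.pairwise[["pct_abundance_a", "pct_abundance_b"]].to_numpy().min(),
        shared_asv.pairwise[["pct_abundance_a", "pct_abundance_b"]].to_numpy().max(),
    )
    print(f"shared ASVs between species: {lo:.0f}%-{hi:.0f}%, "
          f"representing {alo:.0f}%-{ahi:.0f}% of relative abundance")

    # shared transcripts (presence: TMM-normalized abundance > 1)
    tmm = cpm(tc.expected_counts, tmm_factors(tc.expected_counts)).T
    tr_groups = {g: tmm.loc[idx] for g, idx in tmm.groupby(meta["species"]).groups.items()}
    shared_tr = shared_features(tr_groups, TRANSCRIPT_PRESENCE_TMM)
    shared_tr.pairwise.to_csv(OUT / "shared_transcripts_species.tsv", sep="\t", index=False)
    print(f"shared transcripts between species: "
          f"{shared_tr.pairwise['pct_shared'].min():.0f}%-"
          f"{shared_tr.pairwise['pct_shared'].max():.0f}%")

    # differential transcripts for each species pair
    levels = sorted(meta["species"].unique())
    planted = truth["differential_features"]
    summary = []
    for i in range(len(levels)):
        for j in range(i + 1, len(levels)):
            pair = (levels[i], levels[j])
            samples = meta.index[meta["species"].isin(pair)]
            res = differential_features(
                tc.expected_counts[samples], meta.loc[samples, "species"],
                "transcript", seed=SEED,
            )
            res.to_csv(OUT / f"differential_{pair[0]}_vs_{pair[1]}.tsv", sep="\t")
            called = set(res.index[res["passed"]])
            relevant = {
                t for t, info in planted.items() if info["group"] in pair
            }
            summary.append(
                {
                    "pair": f"{pair[0]} vs {pair[1]}",
                    "n_tested": len(res),
                    "n_differential": len(called),
                    "planted_in_pair": len(relevant),
                    "planted_recovered": len(called & relevant),
                }
            )
    summary = pd.DataFrame(summary)
    summary.to_csv(OUT / "differential_summary.tsv", sep="\t", index=False)
    print(summary.to_string(index=False))
    rec = summary["planted_recovered"].sum() / max(1, summary["planted_in_pair"].sum())
    print(f"overall planted-feature recovery across pairs: {100 * rec:.0f}%")


if __name__ == "__main__":
    main()
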