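"""Compositional arm: rarefaction, abundance filtering, alpha/beta diversity,
ordination, PERMANOVA, and the deep/shallow variability contrast on the
simulated ASV table.

Reads results/data/, writes tables under results/community/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from spongefunc import amplicon as amp, diversity as dv
from spongefunc.comparison import ASV_PRESENCE_RA
from spongefunc.io_formats import read_asv_table

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "results" / "data"
OUT = ROOT / "results" / "community"
SEED = 11


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    table = read_asv_table(
        DATA / "asv_counts.tsv", DATA / "asv_taxonomy.tsv", DATA / "sample_metadata.tsv"
    )
    depth = int(table.totals().min())
    rarefied = amp.rarefy(table, depth, seed=SEED)
    print(f"rarefied {len(rarefied.sample_ids)} samples to {depth} counts")

    filtered, retained = amp.filter_min_relative_abundance(rarefied, ASV_PRESENCE_RA)
    print(
        f"0.01% RA filter kept {filtered.counts.shape[1]}/{rarefied.counts.shape[1]} "
        f"ASVs, {100 * retained.min():.1f}%-{100 * retained.max():.1f}% of abundance"
    )

    shannon = rarefied.counts.apply(dv.shannon, axis=1).rename("shannon")
    shannon.to_frame().join(rarefied.metadata).to_csv(OUT / "shannon.tsv", sep="\t")

    ra = amp.to_relative_abundance(rarefied).proportions
    dm = dv.bray_curtis(dv.log2_transform(ra))
    pd.DataFrame(dm.data, index=list(dm.ids), columns=list(dm.ids)).to_csv(
        OUT / "bray_curtis.tsv", sep="\t"
    )
    ordination = dv.pcoa(dm)
    coords = ordination.coordinates.join(rarefied.metadata)
    coords.to_csv(OUT / "pcoa_coordinates.tsv", sep="\t")
    print(
        "PCoA axes 1-2 explain "
        f"{100 * ordination.proportion_explained[:2].sum():.1f}% of positive inertia"
    )

    # species are compared within the deep site (as in the sampling design,
    # where all species co-occur); the habitat factor is tested on all samples
    deep_ids = rarefied.metadata.index[rarefied.metadata["habitat"] == "deep"]
    dm_deep = dm.filter([str(i) for i in deep_ids])
    rows = []
    for factor, sub_dm, meta in (
        ("species (deep site)", dm_deep, rarefied.metadata.loc[deep_ids, "species"]),
        ("habitat", dm, rarefied.metadata["habitat"]),
    ):
        res = dv.permanova(sub_dm, meta, n_permutations=999, seed=SEED)
        rows.append(
            {"term": factor, "pseudo_f": res.pseudo_f, "r2": res.r2,
             "p_value": res.p_value, "method": res.method}
        )
        print(f"PERMANOVA {factor}: F={res.pseudo_f:.2f} R2={res.r2:.3f} p={res.p_value:.4f}")
    pd.DataFrame(rows).to_csv(OUT / "permanova_global.tsv", sep="\t", index=False)

    pairwise = dv.pairwise_permanova(
        dm_deep, rarefied.metadata.loc[deep_ids, "species"], n_permutations=999, seed=SEED
    )
    pairwise.to_csv(OUT / "permanova_pairwise_species.tsv", sep="\t", index=False)

    dists, f_stat, p = dv.dispersion_homogeneity(dm, rarefied.metadata["habitat"])
    variability = dv.group_variability(dm, rarefied.metadata["habitat"])
    variability.to_frame().to_csv(OUT / "habitat_variability.tsv", sep="\t")
    print(
        f"within-habitat Bray-Curtis: deep={variability['deep']:.3f} "
        f"shallow={variability['shallow']:.3f}; dispersion ANOVA F={f_stat:.2f} p={p:.2g}"
    )

    genus = amp.collapse_taxonomy(rarefied, "genus")
    print(f"genus-level table: {genus.counts.shape[1]} features "
          f"(totals conserved: {bool((genus.totals() == rarefied.totals()).all())})")


if __name__ == "__main__":
    main()
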