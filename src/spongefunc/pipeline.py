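"""End-to-end orchestration: simulate -> amplicon -> diversity -> expression
-> modules -> compare, under one YAML-style configuration and one seed.

Each enabled stage writes TSV outputs into the run directory; a
``manifest.json`` records the configuration, the seed, and a SHA-256 checksum
of every output so that reruns can be verified bit-for-bit.  Outputs are
written to a ``.partial`` name first and renamed on stage success, so a failed
stage leaves its partial files behind for inspection.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import amplicon, comparison, diversity, expression, kegg_modules
from .io_formats import (
    read_asv_table,
    read_module_catalog,
    read_orf_annotation,
    read_transcript_counts,
)
from .synthetic import SimConfig, example_catalog, simulate_dataset, write_dataset

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline", "DEFAULT_STAGES"]

DEFAULT_STAGES = ("simulate", "amplicon", "diversity", "expression", "modules", "compare")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class _StageWriter:
    """Writes stage outputs atomically and records their checksums."""

    def __init__(self, outdir: Path, manifest: dict):
        self.outdir = outdir
        self.manifest = manifest

    def write_frame(self, df: pd.DataFrame, name: str, **to_csv):
        final = self.outdir / name
        partial = final.with_suffix(final.suffix + ".partial")
        df.to_csv(partial, sep="\t", **to_csv)
        partial.rename(final)
        self.manifest["outputs"][name] = _sha256(final)
        return final

    def write_json(self, obj, name: str):
        final = self.outdir / name
        partial = final.with_suffix(final.suffix + ".partial")
        partial.write_text(json.dumps(obj, indent=2, sort_keys=True, default=str))
        partial.rename(final)
        self.manifest["outputs"][name] = _sha256(final)
        return final


def run_pipeline(config: dict, outdir=None) -> dict:
    """Run the configured stages and return the manifest.

    ``config`` keys: ``seed`` (required when any stochastic stage is enabled),
    ``outdir``, ``stages`` (subset of :data:`DEFAULT_STAGES`), an optional
    ``simulate`` block (SimConfig fields) or an ``inputs`` block with paths
    (``asv_counts``, ``asv_taxonomy``, ``sample_metadata``,
    ``transcript_counts``, ``orf_annotation``, optionally ``module_catalog``),
    and per-stage parameter blocks (``amplicon``, ``diversity``, ``modules``,
    ``compare``).
    """
    outdir = Path(outdir or config.get("outdir", "spongefunc_run"))
    outdir.mkdir(parents=True, exist_ok=True)
    stages = tuple(config.get("stages", DEFAULT_STAGES))
    unknown = set(stages) - set(DEFAULT_STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    seed = config.get("seed")
    if seed is None and ("simulate" in stages or "diversity" in stages or "compare" in stages):
        raise ValueError("a seed is mandatory when stochastic stages are enabled")

    manifest: dict = {
        "config": config,
        "seed": seed,
        "stages": list(stages),
        "outputs": {},
    }
    writer = _StageWriter(outdir, manifest)

    asv = tc = ann = None
    catalog = None
    truth = None

    if "simulate" in stages:
        sim_cfg = SimConfig(**{**config.get("simulate", {}), "seed": seed})
        catalog = _load_catalog(config)
        ds = simulate_dataset(sim_cfg, catalog)
        paths = write_dataset(ds, outdir / "inputs")
        for name, path in paths.items():
            manifest["outputs"][f"inputs/{path.name}"] = _sha256(path)
        asv, tc, ann, truth = ds.asv_table, ds.transcript_counts, ds.orf_annotation, ds.truth
    elif "inputs" in config:
        paths = config["inputs"]
        asv = read_asv_table(
            paths["asv_counts"], paths["asv_taxonomy"], paths["sample_metadata"]
        )
        tc = read_transcript_counts(paths["transcript_counts"])
        ann = read_orf_annotation(paths["orf_annotation"])
        catalog = _load_catalog(config)

    if "amplicon" in stages:
        params = config.get("amplicon", {})
        depth = params.get("depth")
        if depth is None:
            depth = int(asv.totals().min())
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 1]))
        rarefied = amplicon.rarefy(asv, depth, rng)
        min_ra = params.get("min_ra", comparison.ASV_PRESENCE_RA)
        filtered, retained = amplicon.filter_min_relative_abundance(rarefied, min_ra)
        writer.write_frame(filtered.counts, "asv_filtered_counts.tsv")
        writer.write_frame(retained.to_frame("retained_abundance"), "asv_retained_abundance.tsv")
        asv = rarefied
        manifest.setdefault("amplicon", {})["depth"] = depth
        manifest["amplicon"]["n_features_after_filter"] = int(filtered.counts.shape[1])

    if "diversity" in stages:
        params = config.get("diversity", {})
        factor = params.get("factor", "species")
        ra = amplicon.to_relative_abundance(asv).proportions
        dm = diversity.bray_curtis(diversity.log2_transform(ra))
        alpha_div = asv.counts.apply(diversity.shannon, axis=1).rename("shannon")
        ord_res = diversity.pcoa(dm)
        groups = asv.metadata[factor]
        res = diversity.permanova(
            dm, groups, n_permutations=params.get("permutations", 999),
            seed=np.random.default_rng(np.random.SeedSequence([int(seed), 2])),
        )
        pairwise = diversity.pairwise_permanova(
            dm, groups, n_permutations=params.get("permutations", 999), seed=int(seed) + 3
        )
        writer.write_frame(alpha_div.to_frame(), "shannon.tsv")
        writer.write_frame(
            pd.DataFrame(dm.data, index=list(dm.ids), columns=list(dm.ids)),
            "bray_curtis.tsv",
        )
        writer.write_frame(ord_res.coordinates, "pcoa_coordinates.tsv")
        writer.write_frame(pairwise, "permanova_pairwise.tsv", index=False)
        writer.write_json(
            {
                "term": res.term,
                "pseudo_f": res.pseudo_f,
                "r2": res.r2,
                "p_value": res.p_value,
                "method": res.method,
                "n_permutations": res.n_permutations,
            },
            "permanova_global.json",
        )

    ko = None
    pe = None
    if "expression" in stages:
        pe = expression.peptide_tpm(expression.apportion_counts(tc, ann))
        ko = expression.aggregate_to_ko(pe, ann)
        writer.write_frame(ko.tpm, "ko_tpm.tsv")
        writer.write_frame(ko.atpm.to_frame("atpm"), "ko_atpm.tsv")

    if "modules" in stages:
        if catalog is None:
            catalog = _load_catalog(config)
        if ko is None:
            pe = expression.peptide_tpm(expression.apportion_counts(tc, ann))
            ko = expression.aggregate_to_ko(pe, ann)
        profile = kegg_modules.module_expression(ko.tpm, catalog)
        writer.write_frame(profile.to_frame(), "module_profile.tsv")
        rank = config.get("modules", {}).get("taxa_rank", "phylum")
        split = kegg_modules.taxon_split_expression(pe, ann, catalog, rank=rank)
        writer.write_frame(split, "module_taxon_split.tsv")
        mult = kegg_modules.ko_multiplicity(catalog)
        writer.write_frame(mult, "ko_multiplicity.tsv")

    if "compare" in stages:
        params = config.get("compare", {})
        by = params.get("by", "species")
        meta = asv.metadata
        ra = amplicon.to_relative_abundance(asv).proportions
        by_group = {
            level: ra.loc[idx] for level, idx in ra.groupby(meta[by]).groups.items()
        }
        shared = comparison.shared_features(by_group, comparison.ASV_PRESENCE_RA)
        writer.write_frame(shared.pairwise, "shared_asv_pairwise.tsv", index=False)
        levels = list(pd.unique(meta[by]))
        if len(levels) >= 2:
            pair = levels[:2]
            samples = meta.index[meta[by].isin(pair)]
            diff = comparison.differential_features(
                tc.expected_counts[samples],
                meta.loc[samples, by],
                feature_kind="transcript",
                alpha=params.get("alpha", 0.01),
                fc_threshold=params.get("fc", 2.0),
                n_permutations=params.get("permutations", 10000),
                seed=np.random.default_rng(np.random.SeedSequence([int(seed), 4])),
            )
            writer.write_frame(diff, "differential_transcripts.tsv")
            manifest.setdefault("compare", {})["n_differential"] = int(diff["passed"].sum())

    if truth is not None:
        writer.write_json(truth, "truth.json")
    # the manifest itself is not checksummed (it embeds run-specific paths)
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=str)
    )
    return manifest


def _load_catalog(config: dict):
    spec = config.get("modules", {}).get("catalog", "example")
    if spec == "example":
        return example_catalog()
    return read_module_catalog(spec)
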