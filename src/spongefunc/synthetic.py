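"""Synthetic sponge-holobiont datasets with planted, recoverable structure.

The generator emulates the data shapes of a deep-sea sponge microbiome study:
a 16S ASV count table over a species x location x replicate design with
high-microbial-abundance-like composition (a few dominant phyla, many rare
ASVs), and a metatranscriptome in which assembled transcripts carry 1-12 ORFs
(single-ORF fraction ~36.6%), with sparse KO annotation and taxon lineages.

Structure is *planted* so every downstream stage can be tested against a known
truth record:

* designated ASV subsets get a log-scale abundance shift in their assigned
  species/location group (drives PERMANOVA signal),
* designated transcripts get a log2 fold change in one species group
  (drives the differential caller),
* every non-optional KO of the ``planted_complete_modules`` is attached to an
  expressed peptide (drives completeness calls), and
* ``planted_absent_kos`` are never assigned, so modules requiring them are
  guaranteed incomplete.

A single seed is expanded into per-stage substreams, so the ASV and
metatranscriptome arms are independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import (
    AsvTable,
    ModuleCatalog,
    OrfAnnotation,
    TranscriptCounts,
    write_asv_table,
    write_orf_annotation,
    write_transcript_counts,
    write_truth,
)
from .kegg_modules import (
    Alternative,
    Complex,
    Leaf,
    OptionalPart,
    StepSequence,
    leaf_kos,
    required_kos,
    serialize,
)

__all__ = [
    "SimConfig",
    "SyntheticDataset",
    "ConfigurationError",
    "sample_design",
    "simulate_asv_table",
    "simulate_metatranscriptome",
    "simulate_dataset",
    "write_dataset",
    "example_catalog",
    "random_module_definition",
    "DEFAULT_KO_UNIVERSE",
    "DEFAULT_TAXON_UNIVERSE",
]


class ConfigurationError(ValueError):
    """Inconsistent simulation configuration."""


# Lineages drawn from taxa typical of high-microbial-abundance sponges
# (domain;phylum;class;order;family;genus). Genus-level names are synthetic.
DEFAULT_TAXON_UNIVERSE = (
    "Bacteria;Chloroflexi;Dehalococcoidia;Dehalococcoidales;Dehalococcoidaceae;Dhc01",
    "Bacteria;Chloroflexi;SAR202_clade;SAR202_o;SAR202_f;Sar01",
    "Archaea;Thaumarchaeota;Nitrososphaeria;Nitrosopumilales;Nitrosopumilaceae;Npu01",
    "Bacteria;Proteobacteria;Gammaproteobacteria;UBA10353;UBA10353_f;Gam01",
    "Bacteria;Proteobacteria;Alphaproteobacteria;Rhodospirillales;AEGEAN-169;Alp01",
    "Bacteria;Poribacteria;Omnitrophia;Omnitrophales;Omnitrophaceae;Por01",
    "Bacteria;Acidobacteria;Thermoanaerobaculia;Subgroup_23;Subgroup_23_f;Aci01",
    "Bacteria;Actinobacteria;Acidimicrobiia;Microtrichales;Microtrichaceae;Act01",
    "Bacteria;Nitrospirae;Nitrospira;Nitrospirales;Nitrospiraceae;Nsp01",
    "Bacteria;Gemmatimonadetes;BD2-11_terrestrial_group;BD2-11_o;BD2-11_f;Gem01",
)

# KOs used by the example module catalog (nitrogen, carbon-fixation, sulfur,
# methane energy metabolism) plus generic filler identifiers.
_CATALOG_KOS = (
    "K10944", "K10945", "K10946", "K10535",  # amoCAB, hao
    "K00370", "K00371", "K02567", "K02568",  # narGH, napAB
    "K00368", "K15864", "K04561", "K02305", "K00376",  # nirK/nirS, norBC, nosZ
    "K00169", "K00170", "K00171", "K00172", "K01007", "K01595",  # rTCA steps
    "K01601", "K01602", "K00855",  # rubisco, prkB
    "K00958", "K00394", "K00395", "K11180", "K11181",  # sat, aprAB, dsrAB
    "K16157", "K16158", "K16159", "K14028",  # mmoXYZ, mxaF
    "K10439", "K10440", "K10441",  # ribose/sugar ABC transporter
    "K02588", "K02586", "K02591",  # nifHDK
)
DEFAULT_KO_UNIVERSE = _CATALOG_KOS + tuple(
    f"K{20000 + i:05d}" for i in range(160)
)


def example_catalog() -> ModuleCatalog:
    """A small, hand-written module catalog in the energy-metabolism domain.

    Definitions follow the module grammar (steps / alternatives / complexes /
    optional subunits) with KO content modeled on nitrification,
    denitrification, nitrogen fixation, carbon fixation (reductive citrate and
    Calvin cycles), sulfate reduction, and methane oxidation.
    """
    rows = [
        ("M_NIT", "Nitrification", "Energy metabolism", "Nitrogen metabolism",
         "K10944+K10945+K10946 K10535"),
        ("M_DEN", "Denitrification", "Energy metabolism", "Nitrogen metabolism",
         "K00370+K00371,K02567+K02568 K00368,K15864 K04561+K02305 K00376"),
        ("M_NFIX", "Nitrogen fixation", "Energy metabolism", "Nitrogen metabolism",
         "K02588+K02586+K02591"),
        ("M_RTCA", "Reductive citrate cycle", "Energy metabolism", "Carbon fixation",
         "K00169+K00170-K00171+K00172 K01007 K01595"),
        ("M_CBB", "Calvin cycle", "Energy metabolism", "Carbon fixation",
         "K01601-K01602 K00855"),
        ("M_ASR", "Assimilatory sulfate reduction", "Energy metabolism", "Sulfur metabolism",
         "K00958 K00394+K00395 K11180+K11181"),
        # methane monooxygenase alternatives share the amo/pmo KOs with
        # nitrification, exercising cross-module KO multiplicity
        ("M_MOX", "Methane oxidation", "Energy metabolism", "Methane metabolism",
         "K10944+K10945+K10946,K16157+K16158+K16159 K14028"),
        ("M_ABC", "Sugar ABC transport", "Environmental information processing",
         "Membrane transport", "K10439+K10440+K10441"),
    ]
    entries = pd.DataFrame(
        rows, columns=["module_id", "name", "level_B", "level_C", "definition"]
    )
    return ModuleCatalog(entries=entries)


@dataclass
class SimConfig:
    """Parameters of the synthetic holobiont study.

    The defaults describe a desk-scale version of a deep-sea sponge survey:
    three species crossed with two locations (one deep, one shallow habitat
    class), three replicates per cell, a few hundred ASVs at a rarefaction-like
    depth of 20 000 counts, and a metatranscriptome of a few thousand
    transcripts at about one million mapped reads per sample with a 36.6%
    single-ORF fraction and at most 12 ORFs per transcript.
    """

    n_species: int = 3
    n_locations: int = 2
    replicates_per_group: int = 3
    n_asvs: int = 300
    seq_depth_mean: int = 20000
    dirichlet_concentration: float = 150.0
    group_effect_size: float = 1.0
    n_transcripts: int = 2000
    single_orf_fraction: float = 0.366
    max_orfs: int = 12
    ko_universe: tuple = DEFAULT_KO_UNIVERSE
    taxon_universe: tuple = DEFAULT_TAXON_UNIVERSE
    planted_complete_modules: tuple = ()
    planted_absent_kos: tuple = ()
    n_differential_features: int = 20
    differential_log2fc: float = 2.0
    seed: int = 0
    # secondary knobs (held fixed across the study)
    transcript_depth_mean: int = 1_000_000
    peptide_length_mu: float = 5.2  # log-normal on amino acids
    peptide_length_sigma: float = 0.6
    min_peptide_length: int = 50
    ko_fraction: float = 0.6  # fraction of peptides carrying a KO term
    taxon_fraction: float = 0.7  # fraction of peptides with a lineage
    sample_noise_sigma: float = 0.25  # per-sample log-normal expression noise
    effect_asvs_per_group: int = 10
    habitat_dispersion_factor: float = 1.0  # conc divisor for shallow samples

    def validate(self) -> None:
        if not (0.0 <= self.single_orf_fraction <= 1.0):
            raise ConfigurationError("single_orf_fraction must be in [0, 1]")
        if self.max_orfs < 1:
            raise ConfigurationError("max_orfs must be >= 1")
        if self.seq_depth_mean <= 0 or self.transcript_depth_mean <= 0:
            raise ConfigurationError("sequencing depths must be positive")
        if self.dirichlet_concentration <= 0:
            raise ConfigurationError("dirichlet_concentration must be positive")
        if self.group_effect_size < 0:
            raise ConfigurationError("group_effect_size must be non-negative")
        if min(self.n_species, self.n_locations, self.replicates_per_group) < 1:
            raise ConfigurationError("design dimensions must be >= 1")
        unknown = set(self.planted_absent_kos) - set(self.ko_universe)
        if unknown:
            raise ConfigurationError(f"planted_absent_kos not in ko_universe: {sorted(unknown)}")


@dataclass
class SyntheticDataset:
    asv_table: AsvTable
    transcript_counts: TranscriptCounts
    orf_annotation: OrfAnnotation
    truth: dict


def _streams(seed: int, n: int = 4) -> list[np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(n)
    return [np.random.default_rng(c) for c in children]


def sample_design(cfg: SimConfig) -> pd.DataFrame:
    """The sample sheet implied by the design: species x location x replicate.

    Locations in the first half of the index are labelled ``deep``, the rest
    ``shallow`` (a single location is deep).
    """
    n_deep = max(1, (cfg.n_locations + 1) // 2)
    rows = []
    for s in range(cfg.n_species):
        for l in range(cfg.n_locations):
            for r in range(cfg.replicates_per_group):
                rows.append(
                    {
                        "sample_id": f"sp{s + 1}_loc{l + 1}_r{r + 1}",
                        "species": f"species_{s + 1}",
                        "location": f"location_{l + 1}",
                        "habitat": "deep" if l < n_deep else "shallow",
                    }
                )
    return pd.DataFrame(rows).set_index("sample_id")


def _group_effect_assignment(cfg: SimConfig) -> dict[str, list[int]]:
    """Round-robin blocks of ASV indices carrying each group's planted shift."""
    groups = [f"species_{s + 1}" for s in range(cfg.n_species)] + [
        f"location_{l + 1}" for l in range(cfg.n_locations)
    ]
    assignment: dict[str, list[int]] = {}
    cursor = 0
    for group in groups:
        block = [
            (cursor + k) % cfg.n_asvs for k in range(cfg.effect_asvs_per_group)
        ]
        assignment[group] = block
        cursor += cfg.effect_asvs_per_group
    return assignment


def simulate_asv_table(cfg: SimConfig, rng: np.random.Generator | None = None) -> AsvTable:
    """Dirichlet-multinomial ASV counts over the study design.

    Each sample's composition is drawn from a Dirichlet centred on a shared
    base composition (concentration = ``dirichlet_concentration``; divided by
    ``habitat_dispersion_factor`` for shallow samples, making them noisier),
    and counts are Multinomial at a Poisson depth around ``seq_depth_mean``.
    The designated ASV block of each species/location group has its base
    abundance multiplied by ``exp(group_effect_size)`` in that group's samples.
    """
    cfg.validate()
    if rng is None:
        rng = _streams(cfg.seed)[0]
    design = sample_design(cfg)
    base = rng.dirichlet(np.full(cfg.n_asvs, 0.8))  # skewed: few dominant taxa
    effects = _group_effect_assignment(cfg)

    counts = np.zeros((len(design), cfg.n_asvs), dtype=np.int64)
    for i, (sample, row) in enumerate(design.iterrows()):
        props = base.copy()
        if cfg.group_effect_size > 0:
            for group in (row["species"], row["location"]):
                idx = effects.get(group)
                if idx:
                    props[idx] *= np.exp(cfg.group_effect_size)
        props /= props.sum()
        conc = cfg.dirichlet_concentration
        if row["habitat"] == "shallow":
            conc /= cfg.habitat_dispersion_factor
        p = rng.dirichlet(conc * props)
        depth = max(1, rng.poisson(cfg.seq_depth_mean))
        counts[i] = rng.multinomial(depth, p)

    asv_ids = [f"ASV{i + 1:04d}" for i in range(cfg.n_asvs)]
    lineages = [
        cfg.taxon_universe[i % len(cfg.taxon_universe)].split(";")
        for i in range(cfg.n_asvs)
    ]
    taxonomy = pd.DataFrame(
        lineages,
        index=pd.Index(asv_ids, name="asv_id"),
        columns=["domain", "phylum", "class", "order", "family", "genus"],
    )
    # make genus labels unique per ASV so genus-level collapse stays non-trivial
    taxonomy["genus"] = [
        f"{g}_{i // len(cfg.taxon_universe) + 1}"
        for i, g in enumerate(taxonomy["genus"])
    ]
    return AsvTable(
        counts=pd.DataFrame(
            counts, index=design.index.copy(), columns=pd.Index(asv_ids, name="asv_id")
        ),
        taxonomy=taxonomy,
        metadata=design,
    )


def simulate_metatranscriptome(
    cfg: SimConfig,
    catalog: ModuleCatalog | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[TranscriptCounts, OrfAnnotation, dict]:
    """Transcript expected counts plus ORF/KO/taxon annotation, with truth.

    Each transcript carries one ORF with probability ``single_orf_fraction``,
    otherwise a uniform 2..``max_orfs``.  Peptide lengths are log-normal
    (truncated at ``min_peptide_length`` aa).  Baseline transcript expression
    is log-normal; counts per sample are Multinomial at a Poisson depth, with
    per-sample log-normal noise.  Planted differential transcripts (chosen
    among transcripts with above-median baseline so the effect is observable
    after abundance filtering) get ``differential_log2fc`` applied in their
    round-robin-assigned species group.  Every non-optional KO of each planted
    complete module is attached to a peptide of an expressed transcript;
    ``planted_absent_kos`` are never assigned.
    """
    cfg.validate()
    if rng is None:
        rng = _streams(cfg.seed)[1]
    if cfg.planted_complete_modules:
        if catalog is None:
            raise ConfigurationError("planted_complete_modules requires a catalog")
        known = set(catalog.entries["module_id"])
        missing = set(cfg.planted_complete_modules) - known
        if missing:
            raise ConfigurationError(f"planted modules not in catalog: {sorted(missing)}")
        for mid in cfg.planted_complete_modules:
            need = set(required_kos(catalog.trees[mid]))
            outside = need - set(cfg.ko_universe)
            if outside:
                raise ConfigurationError(
                    f"module {mid} requires KOs outside ko_universe: {sorted(outside)}"
                )
            absent = need & set(cfg.planted_absent_kos)
            if absent:
                raise ConfigurationError(
                    f"module {mid} requires planted-absent KOs: {sorted(absent)}"
                )

    design = sample_design(cfg)
    n_t = cfg.n_transcripts
    transcript_ids = [f"TR{i + 1:06d}" for i in range(n_t)]

    # ORF structure
    single = rng.random(n_t) < cfg.single_orf_fraction
    n_orfs = np.where(
        single,
        1,
        rng.integers(2, cfg.max_orfs + 1, size=n_t) if cfg.max_orfs >= 2 else 1,
    )
    total_orfs = int(n_orfs.sum())
    lengths = rng.lognormal(cfg.peptide_length_mu, cfg.peptide_length_sigma, total_orfs)
    while (lengths < cfg.min_peptide_length).any():
        redo = lengths < cfg.min_peptide_length
        lengths[redo] = rng.lognormal(
            cfg.peptide_length_mu, cfg.peptide_length_sigma, int(redo.sum())
        )
    lengths = np.round(lengths).astype(int)

    # baseline expression and planted differential effects
    baseline = rng.lognormal(0.0, 1.2, n_t)
    species_levels = sorted(design["species"].unique())
    eligible = np.flatnonzero(baseline >= np.median(baseline))
    n_diff = min(cfg.n_differential_features, len(eligible))
    diff_idx = rng.choice(eligible, size=n_diff, replace=False)
    diff_group = {
        transcript_ids[t]: species_levels[k % len(species_levels)]
        for k, t in enumerate(diff_idx)
    }

    counts = np.zeros((n_t, len(design)))
    fold = 2.0 ** cfg.differential_log2fc
    for j, (sample, row) in enumerate(design.iterrows()):
        mean = baseline * rng.lognormal(0.0, cfg.sample_noise_sigma, n_t)
        for k, t in enumerate(diff_idx):
            if row["species"] == species_levels[k % len(species_levels)]:
                mean[t] *= fold
        p = mean / mean.sum()
        depth = max(1, rng.poisson(cfg.transcript_depth_mean))
        counts[:, j] = rng.multinomial(depth, p)

    tc = TranscriptCounts(
        expected_counts=pd.DataFrame(
            counts,
            index=pd.Index(transcript_ids, name="transcript_id"),
            columns=design.index.copy(),
        )
    )

    # KO / taxon annotation
    allowed = [k for k in cfg.ko_universe if k not in set(cfg.planted_absent_kos)]
    if not allowed:
        raise ConfigurationError("ko_universe is empty after removing absent KOs")
    peptide_rows = []
    cursor = 0
    for t, tid in enumerate(transcript_ids):
        for j in range(n_orfs[t]):
            ko = (
                allowed[rng.integers(0, len(allowed))]
                if rng.random() < cfg.ko_fraction
                else None
            )
            taxon = (
                cfg.taxon_universe[rng.integers(0, len(cfg.taxon_universe))]
                if rng.random() < cfg.taxon_fraction
                else None
            )
            peptide_rows.append(
                {
                    "transcript_id": tid,
                    "peptide_id": f"{tid}_p{j + 1}",
                    "peptide_length": int(lengths[cursor]),
                    "ko": ko,
                    "taxon": taxon,
                }
            )
            cursor += 1
    records = pd.DataFrame(peptide_rows)

    # guarantee expression of every KO required by the planted complete modules
    if cfg.planted_complete_modules:
        expressed = set(
            tc.expected_counts.index[tc.expected_counts.sum(axis=1) > 0]
        )
        host_pool = records.index[records["transcript_id"].isin(expressed)].tolist()
        if not host_pool:
            raise ConfigurationError("no expressed transcripts to host planted KOs")
        need = []
        for mid in cfg.planted_complete_modules:
            need.extend(required_kos(catalog.trees[mid]))
        need = list(dict.fromkeys(need))
        hosts = rng.choice(host_pool, size=len(need), replace=len(host_pool) < len(need))
        for ko, idx in zip(need, hosts):
            records.loc[idx, "ko"] = ko

    ann = OrfAnnotation(records=records)
    incomplete = []
    if catalog is not None and cfg.planted_absent_kos:
        absent = set(cfg.planted_absent_kos)
        for mid, tree in catalog.trees.items():
            if set(required_kos(tree)) & absent:
                incomplete.append(mid)
    truth = {
        "differential_features": {
            tid: {"group": grp, "log2fc": cfg.differential_log2fc}
            for tid, grp in diff_group.items()
        },
        "planted_complete_modules": list(cfg.planted_complete_modules),
        "planted_incomplete_modules": incomplete,
        "planted_absent_kos": list(cfg.planted_absent_kos),
    }
    return tc, ann, truth


def simulate_dataset(cfg: SimConfig, catalog: ModuleCatalog | None = None) -> SyntheticDataset:
    """Full synthetic dataset: ASV arm, transcriptome arm, and truth record."""
    cfg.validate()
    asv_rng, mtx_rng, *_ = _streams(cfg.seed)
    asv = simulate_asv_table(cfg, asv_rng)
    tc, ann, truth = simulate_metatranscriptome(cfg, catalog, mtx_rng)
    truth["group_effect_asvs"] = {
        group: [f"ASV{i + 1:04d}" for i in idx]
        for group, idx in _group_effect_assignment(cfg).items()
    }
    truth["group_effect_size"] = cfg.group_effect_size
    return SyntheticDataset(
        asv_table=asv, transcript_counts=tc, orf_annotation=ann, truth=truth
    )


def write_dataset(ds: SyntheticDataset, outdir) -> dict[str, Path]:
    """Write the four input TSVs plus the truth.json sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "asv_counts": outdir / "asv_counts.tsv",
        "asv_taxonomy": outdir / "asv_taxonomy.tsv",
        "sample_metadata": outdir / "sample_metadata.tsv",
        "transcript_counts": outdir / "transcript_counts.tsv",
        "orf_annotation": outdir / "orf_annotation.tsv",
        "truth": outdir / "truth.json",
    }
    write_asv_table(
        ds.asv_table, paths["asv_counts"], paths["asv_taxonomy"], paths["sample_metadata"]
    )
    write_transcript_counts(ds.transcript_counts, paths["transcript_counts"])
    write_orf_annotation(ds.orf_annotation, paths["orf_annotation"])
    write_truth(ds.truth, paths["truth"])
    return paths


# ---------------------------------------------------------------------------
# Random definitions (for oracle-based grammar testing)


def random_module_definition(
    rng: np.random.Generator,
    n_leaves: int,
    ko_pool: tuple | None = None,
    _depth: int = 0,
) -> str:
    """A random well-formed module definition with exactly ``n_leaves`` leaves."""
    tree = _random_tree(rng, n_leaves, ko_pool or DEFAULT_KO_UNIVERSE, 0)
    return serialize(tree)


def _random_tree(rng, n_leaves, pool, depth):
    if n_leaves == 1:
        return Leaf(pool[rng.integers(0, len(pool))])
    n_parts = int(rng.integers(2, min(n_leaves, 4) + 1))
    # split the leaf budget across parts
    cuts = np.sort(rng.choice(np.arange(1, n_leaves), size=n_parts - 1, replace=False))
    sizes = np.diff(np.concatenate([[0], cuts, [n_leaves]]))
    children = [_random_tree(rng, int(s), pool, depth + 1) for s in sizes]
    kind = rng.integers(0, 3)
    if kind == 0:
        return StepSequence(tuple(children))
    if kind == 1:
        return Alternative(tuple(children))
    parts = [children[0]]
    for c in children[1:]:
        parts.append(OptionalPart(c) if rng.random() < 0.2 else c)
    return Complex(tuple(parts))
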