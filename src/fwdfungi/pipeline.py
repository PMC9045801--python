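"""End-to-end orchestration: simulate -> prep -> statistics -> report.

A run is driven by a flat key/value config (YAML mapping of scalars), every
stage writes its tables through :mod:`fwdfungi.tables`, and all randomness
descends from the single master seed, so re-running the same config gives
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import diversity as div
from . import multivariate as mv
from . import prep, simulate, succession, tables

__all__ = ["RunConfig", "load_config", "run_pipeline"]


@dataclass
class RunConfig:
    """Settings of one pipeline run; defaults mirror the study design."""

    seed: int = 0
    n_blocks: int = 4
    n_years: int = 6
    n_taxa: int = 200
    specialist_fraction: float = 0.5
    overdispersion: float = 0.01
    chem_noise_sd: float = 0.05
    depth: int = 2000  # rarefaction depth (reads per sample)
    filter_preset: str = "fig2"
    distance: str = "euclidean"  # on Hellinger coordinates
    n_perm_permanova: int = 9999
    n_perm_mantel: int = 99999
    n_perm_envfit: int = 999
    n_perm_varpart: int = 999
    nmds_starts: int = 4
    duration_method: str = "contiguous"
    out_dir: str = "fwdfungi_run"

    def __post_init__(self) -> None:
        if self.filter_preset not in prep.FILTER_PRESETS:
            raise ValueError(
                f"unknown filter preset {self.filter_preset!r}; expected one of {prep.FILTER_PRESETS}"
            )
        if self.distance not in ("euclidean", "bray_curtis", "bray"):
            raise ValueError(f"unknown distance {self.distance!r}")
        if self.depth < 1:
            raise ValueError("depth must be positive")


def load_config(path: str | Path) -> RunConfig:
    """Read a flat YAML mapping into a :class:`RunConfig`.

    Unknown keys are an error (listed), so typos fail before any work.
    """
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a flat key/value mapping")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = sorted(set(raw) - known)
    if unknown:
        raise ValueError(f"{path}: unknown config keys {unknown}")
    return RunConfig(**raw)


def _stage_seed(master: int, stage: str) -> int:
    return int(np.random.SeedSequence(master, spawn_key=(simulate.hash_label(stage),)).generate_state(1)[0] % (2**31))


def _synthetic_taxonomy(truth: pd.DataFrame) -> list[tables.TaxonomyRecord]:
    records = []
    for i, (taxon_id, row) in enumerate(truth.iterrows()):
        genus = f"Genus{i + 1:04d}"
        records.append(
            tables.TaxonomyRecord(
                otu_id=str(taxon_id),
                best_species=f"{genus} simulatus",
                best_genus=genus,
                identity_pct=99.0,
                coverage_pct=100.0,
                kingdom_flag="fungal",
            )
        )
    return records


def run_pipeline(config: RunConfig) -> dict:
    """Run the whole analysis and write its artifacts to ``config.out_dir``.

    Returns the summary dictionary that is also written to
    ``summary.json``. Stage order: design/community/chemistry simulation,
    rarefaction, relative abundance + Hellinger, diversity, succession
    statistics, NMDS + envfit, PERMANOVA, Mantel, variation partitioning.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: dict = {"config": dataclasses.asdict(config), "stages": {}}

    # --- simulation -------------------------------------------------------
    design = simulate.generate_design(config.n_blocks, config.n_years, config.seed)
    taxa = simulate.generate_taxa(
        config.n_taxa,
        specialist_fraction=config.specialist_fraction,
        seed=_stage_seed(config.seed, "taxa"),
        temporal_range=(1.0, float(config.n_years)),
    )
    counts, truth = simulate.generate_community_counts(
        design,
        taxa,
        depth=config.depth * 2,  # pre-rarefaction depth: twice the target
        overdispersion=config.overdispersion,
        seed=_stage_seed(config.seed, "community"),
    )
    chem = simulate.generate_chemistry(
        design, noise_sd=config.chem_noise_sd, seed=_stage_seed(config.seed, "chemistry")
    )
    taxonomy = _synthetic_taxonomy(truth)
    guild_map = tables.GuildMap(
        {rec.best_genus: g for rec, g in zip(taxonomy, truth["guild"]) if g in tables.GUILDS}
    )
    tables.write_metadata(design, out / "metadata.tsv")
    tables.write_count_table(counts, out / "counts_raw.tsv")
    truth.to_csv(out / "truth.tsv", sep="\t")
    tables.write_taxonomy(taxonomy, out / "taxonomy.tsv")
    tables.write_guild_map(guild_map, out / "guild_map.tsv")
    simulate.chemistry_frame(chem).to_csv(out / "chemistry.tsv", sep="\t")
    log["stages"]["simulate"] = {
        "n_samples": len(design),
        "n_taxa": len(taxa),
        "samples_per_year": len(design) // config.n_years,
    }

    # --- preparation ------------------------------------------------------
    rar = prep.rarefy(counts, depth=config.depth, seed=_stage_seed(config.seed, "rarefy"))
    tables.write_count_table(rar.table, out / "counts_rarefied.tsv")
    rel = prep.relative_abundance(rar.table)
    hel = prep.hellinger(rel)
    design_kept = [s for s in design if s.sample_id in set(rar.table.sample_ids)]
    kept_taxa = prep.apply_abundance_filter(rel, config.filter_preset, design_kept)
    log["stages"]["prep"] = {
        "dropped_samples": rar.dropped,
        "filter_preset": config.filter_preset,
        "taxa_passing_filter": len(kept_taxa),
    }

    # --- diversity --------------------------------------------------------
    diversity_tbl = div.diversity_table(rar.table)
    diversity_tbl.to_csv(out / "diversity.tsv", sep="\t")
    log["stages"]["diversity"] = {
        "mean_richness": float(diversity_tbl["richness"].mean()),
        "mean_shannon": float(diversity_tbl["shannon"].mean()),
    }

    # --- succession -------------------------------------------------------
    succ = succession.succession_table(rel, design_kept, duration_method=config.duration_method)
    succ.to_csv(out / "succession.tsv", sep="\t")
    rho, p_rho = succession.specificity_vs_time(succ, "tree")
    log["stages"]["succession"] = {
        "n_taxa": len(succ),
        "tree_specific": int((succ["class_tree"] != "unspecific").sum()),
        "spearman_time_vs_tree_specificity": {"rho": rho, "p": p_rho},
    }

    # --- multivariate -----------------------------------------------------
    meta = tables.metadata_frame(design_kept)
    if config.distance == "euclidean":
        dmat = mv.pairwise_distances(hel.T, "euclidean")
    else:
        dmat = mv.pairwise_distances(rel.to_frame().T, "bray_curtis")
    ord_res = mv.nmds(
        dmat, n_starts=config.nmds_starts, seed=_stage_seed(config.seed, "nmds")
    )
    coords = pd.DataFrame(ord_res.coordinates, index=dmat.ids, columns=["NMDS1", "NMDS2"])
    coords.to_csv(out / "nmds_coordinates.tsv", sep="\t")
    chem_frame = simulate.chemistry_frame(chem).loc[dmat.ids]
    fits = {}
    for var in chem_frame.columns:
        res = mv.envfit(
            ord_res.coordinates,
            chem_frame[var].to_numpy(),
            n_perm=config.n_perm_envfit,
            seed=_stage_seed(config.seed, f"envfit:{var}"),
        )
        fits[var] = {"r2": res.r2, "p": res.p_value, "direction": list(res.direction)}
    perma = mv.permanova(
        dmat,
        meta[["tree", "canopy"]],
        n_perm=config.n_perm_permanova,
        seed=_stage_seed(config.seed, "permanova"),
    )
    chem_std = (chem_frame - chem_frame.mean()) / chem_frame.std(ddof=0)
    d_chem = mv.pairwise_distances(chem_std, "euclidean", ids=dmat.ids)
    mant = mv.mantel(
        dmat, d_chem, n_perm=config.n_perm_mantel, seed=_stage_seed(config.seed, "mantel")
    )
    vp = mv.variation_partitioning(
        hel.T.to_numpy(),
        meta[["tree"]],
        meta[["canopy"]],
        n_perm=config.n_perm_varpart,
        seed=_stage_seed(config.seed, "varpart"),
    )
    log["stages"]["multivariate"] = {
        "nmds_stress": ord_res.stress,
        "nmds_converged": ord_res.converged,
        "envfit": fits,
        "permanova": {
            t: {"pseudo_F": r.statistic, "R2": r.effect_size, "p": r.p_value}
            for t, r in perma.items()
        },
        "mantel_community_vs_chemistry": {"r": mant.statistic, "p": mant.p_value},
        "varpart": {
            "pure_tree": vp.a,
            "shared": vp.b,
            "pure_canopy": vp.c,
            "residual": vp.residual,
            "p_values": vp.p_values,
        },
    }

    log = _to_builtin(log)
    with open(out / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(log, fh, indent=2, sort_keys=True)
    with open(out / "summary.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(log, fh, sort_keys=True)
    return log


def _to_builtin(obj):
    """Recursively coerce numpy scalars so YAML/JSON serialisation is clean."""
    if isinstance(obj, dict):
        return {str(k): _to_builtin(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_builtin(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.bool_):
        return bool(obj)
    return obj
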