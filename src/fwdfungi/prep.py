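"""Preparation of analysis-ready community matrices.

Raw OTU tables become the matrices the downstream statistics consume:
species-aggregated counts, rarefied counts at a fixed depth, relative
abundances, Hellinger coordinates, abundance-filtered taxon sets, and
guild composition profiles.
"""

from __future__ import annotations

from collections import OrderedDict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tables import CountTable, GuildMap, SampleMetadata, TaxonomyRecord, metadata_frame

__all__ = [
    "RelAbundanceTable",
    "RarefactionResult",
    "FILTER_PRESETS",
    "rarefy",
    "relative_abundance",
    "hellinger",
    "aggregate_to_species",
    "apply_abundance_filter",
    "guild_profile",
]


@dataclass
class RelAbundanceTable:
    """Taxa-by-sample proportions; every sample column sums to 1."""

    taxon_ids: list[str]
    sample_ids: list[str]
    proportions: np.ndarray

    def __post_init__(self) -> None:
        props = np.asarray(self.proportions, dtype=float)
        if props.shape != (len(self.taxon_ids), len(self.sample_ids)):
            raise ValueError("proportion matrix shape mismatch")
        if props.size:
            sums = props.sum(axis=0)
            if not np.allclose(sums, 1.0, atol=1e-9):
                bad = [self.sample_ids[i] for i in np.nonzero(~np.isclose(sums, 1.0, atol=1e-9))[0]]
                raise ValueError(f"sample columns do not sum to 1: {bad}")
        self.proportions = props

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.proportions, index=self.taxon_ids, columns=self.sample_ids)


@dataclass
class RarefactionResult:
    """Rarefied table plus the audit log of samples dropped for low depth."""

    table: CountTable
    dropped: list[str] = field(default_factory=list)


def rarefy(table: CountTable, depth: int = 2000, seed: int = 0) -> RarefactionResult:
    """Subsample each sample to ``depth`` reads without replacement.

    Samples with fewer than ``depth`` total reads cannot be subsampled at
    that depth and are dropped; their ids are listed in the result's log.
    A sample holding exactly ``depth`` reads is returned unchanged (the
    without-replacement draw exhausts it).
    """
    if depth < 1:
        raise ValueError("depth must be at least 1")
    rng = np.random.default_rng(seed)
    totals = table.sample_sums()
    keep = totals >= depth
    dropped = [s for s, k in zip(table.sample_ids, keep) if not k]
    kept_ids = [s for s, k in zip(table.sample_ids, keep) if k]
    sub = np.empty((len(table.taxon_ids), len(kept_ids)), dtype=np.int64)
    col = 0
    for j, keep_j in enumerate(keep):
        if not keep_j:
            continue
        column = table.counts[:, j]
        if column.sum() == depth:
            sub[:, col] = column
        else:
            sub[:, col] = rng.multivariate_hypergeometric(column, depth)
        col += 1
    return RarefactionResult(CountTable(list(table.taxon_ids), kept_ids, sub), dropped)


def relative_abundance(table: CountTable) -> RelAbundanceTable:
    """Counts to per-sample proportions; zero-total samples are an error."""
    totals = table.sample_sums().astype(float)
    zero = [s for s, t in zip(table.sample_ids, totals) if t == 0]
    if zero:
        raise ValueError(f"zero-total samples: {zero}")
    props = table.counts / totals
    return RelAbundanceTable(list(table.taxon_ids), list(table.sample_ids), props)


def hellinger(table: CountTable | RelAbundanceTable) -> pd.DataFrame:
    """Hellinger transform: square root of relative abundances.

    Each sample column of the returned taxa-by-sample matrix has unit
    Euclidean norm, which makes Euclidean distances between samples
    ecologically sensible for species data.
    """
    if isinstance(table, CountTable):
        table = relative_abundance(table)
    return pd.DataFrame(
        np.sqrt(table.proportions), index=table.taxon_ids, columns=table.sample_ids
    )


def aggregate_to_species(
    table: CountTable,
    taxonomy: list[TaxonomyRecord],
    identity_threshold: float = 97.0,
    coverage_threshold: float = 95.0,
) -> CountTable:
    """Collapse OTUs to species-level rows by their best database hit.

    OTUs whose best hit meets both the identity and coverage thresholds
    merge under the hit's binomial; weaker hits merge under
    ``"<genus> sp."``. OTUs flagged as host plant or otherwise non-fungal
    are discarded before merging. Row order follows first appearance.
    """
    by_otu = {r.otu_id: r for r in taxonomy}
    orphans = [t for t in table.taxon_ids if t not in by_otu]
    if orphans:
        raise ValueError(f"taxa without taxonomy records: {orphans}")
    labels: "OrderedDict[str, np.ndarray]" = OrderedDict()
    for i, otu in enumerate(table.taxon_ids):
        rec = by_otu[otu]
        if rec.kingdom_flag != "fungal":
            continue
        if (
            rec.best_species
            and rec.identity_pct >= identity_threshold
            and rec.coverage_pct >= coverage_threshold
        ):
            key = rec.best_species
        else:
            key = f"{rec.best_genus} sp."
        if key in labels:
            labels[key] = labels[key] + table.counts[i]
        else:
            labels[key] = table.counts[i].copy()
    if labels:
        counts = np.vstack(list(labels.values()))
    else:
        counts = np.zeros((0, len(table.sample_ids)), dtype=np.int64)
    return CountTable(list(labels.keys()), list(table.sample_ids), counts)


#: Abundance-filter presets for the displayed-taxon subsets.
#: fig2 — community overview: relative abundance over 0.5% in >= 3 samples.
#: fig5 — succession heatmap: within-treatment yearly mean abundance over 1%
#:        in >= 3 years, or a single yearly mean over 2%.
#: fig6 — specificity scatter: over 0.5% in >= 3 samples AND over 1% in at
#:        least one sample.
FILTER_PRESETS = ("fig2", "fig5", "fig6")


def apply_abundance_filter(
    rel: RelAbundanceTable,
    preset: str,
    metadata: list[SampleMetadata] | None = None,
    *,
    per_treatment: bool = True,
) -> list[str]:
    """Return the taxon ids that survive an abundance-filter preset.

    All thresholds are strict inequalities. The ``fig5`` preset needs year
    metadata; its "yearly observation" is the mean relative abundance of the
    taxon over the samples of one year within one treatment (tree x canopy
    combination). With ``per_treatment=False`` yearly means pool all samples
    of a year instead.
    """
    if preset not in FILTER_PRESETS:
        raise ValueError(f"unknown filter preset {preset!r}; expected one of {FILTER_PRESETS}")
    props = rel.proportions
    if props.size == 0:
        return []
    if preset == "fig2":
        keep = (props > 0.005).sum(axis=1) >= 3
    elif preset == "fig6":
        keep = ((props > 0.005).sum(axis=1) >= 3) & ((props > 0.01).sum(axis=1) >= 1)
    else:  # fig5
        if metadata is None:
            raise ValueError("fig5 preset requires sample metadata (years)")
        meta = metadata_frame(metadata).loc[rel.sample_ids]
        if per_treatment:
            groups = meta.groupby(["tree", "canopy", "year"], observed=True).groups
        else:
            groups = meta.groupby(["year"]).groups
        keep = np.zeros(len(rel.taxon_ids), dtype=bool)
        frame = rel.to_frame()
        # yearly profile per treatment: taxa x year matrix of means
        treatments: dict[tuple, dict[int, np.ndarray]] = {}
        for key, sample_idx in groups.items():
            if per_treatment:
                tree, canopy, year = key
                tkey = (tree, canopy)
            else:
                (year,) = key if isinstance(key, tuple) else (key,)
                tkey = ("all",)
            yearly = frame[list(sample_idx)].mean(axis=1).to_numpy()
            treatments.setdefault(tkey, {})[int(year)] = yearly
        for profile_by_year in treatments.values():
            yearly = np.column_stack([profile_by_year[y] for y in sorted(profile_by_year)])
            keep |= ((yearly > 0.01).sum(axis=1) >= 3) | (yearly.max(axis=1) > 0.02)
    return [t for t, k in zip(rel.taxon_ids, keep) if k]


def guild_profile(
    rel: RelAbundanceTable,
    taxonomy: list[TaxonomyRecord],
    guild_map: GuildMap,
    metadata: list[SampleMetadata],
    grouping: list[str],
) -> pd.DataFrame:
    """Mean guild shares per sample group.

    Each taxon's proportion is attributed to the guild of its best-hit
    genus ("unclassified" when the genus is unmapped); per-sample guild
    shares are averaged within each group defined by the ``grouping``
    factor columns (e.g. ``["tree", "year"]``). Shares within a group sum
    to 1 including the unclassified share.
    """
    if not grouping:
        raise ValueError("grouping factors must be non-empty")
    by_otu = {r.otu_id: r for r in taxonomy}
    guilds = []
    for taxon in rel.taxon_ids:
        rec = by_otu.get(taxon)
        genus = rec.best_genus if rec is not None else taxon.split()[0]
        guilds.append(guild_map[genus])
    frame = rel.to_frame()
    frame["guild"] = guilds
    per_sample = frame.groupby("guild").sum()  # guild x sample, columns sum to 1
    meta = metadata_frame(metadata).loc[rel.sample_ids]
    out = {}
    for key, sample_idx in meta.groupby(grouping, observed=True).groups.items():
        samples = list(sample_idx)
        if not samples:
            raise ValueError(f"empty group {key}")
        out[key] = per_sample[samples].mean(axis=1)
    result = pd.DataFrame(out).T
    result.index.names = grouping if len(grouping) > 1 else [grouping[0]]
    return result
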