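"""Tabular containers and strict TSV readers/writers.

All pipeline artifacts are plain UTF-8 tab-separated files with a header
row and ``NA`` for missing values, so a run is inspectable with standard
command-line tools and round-trips losslessly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "CountTable",
    "SampleMetadata",
    "TaxonomyRecord",
    "TableFormatError",
    "read_count_table",
    "write_count_table",
    "read_metadata",
    "write_metadata",
    "read_taxonomy",
    "write_taxonomy",
    "read_guild_map",
    "write_guild_map",
    "GUILDS",
]

#: Recognised ecological guilds for wood-inhabiting fungi.
GUILDS = (
    "white_rot",
    "brown_rot",
    "soft_rot",
    "saprotroph",
    "plant_pathogen",
    "ectomycorrhiza",
    "yeast",
    "endophyte",
    "lichen",
    "unclassified",
    "other",
)

TREES = ("beech", "fir")
CANOPIES = ("open", "closed")


class TableFormatError(ValueError):
    """Raised when a tabular artifact violates its format contract."""


@dataclass
class CountTable:
    """An OTU/species-by-sample matrix of non-negative integer read counts.

    Rows are taxa, columns are samples; both orders are significant and
    preserved by every operation. Joins elsewhere in the pipeline are by
    identifier, never by position.
    """

    taxon_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray  # (n_taxa, n_samples), integer dtype

    def __post_init__(self) -> None:
        self.taxon_ids = [str(t) for t in self.taxon_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        counts = np.asarray(self.counts)
        if counts.ndim != 2 or counts.shape != (len(self.taxon_ids), len(self.sample_ids)):
            raise TableFormatError(
                f"count matrix shape {counts.shape} does not match "
                f"{len(self.taxon_ids)} taxa x {len(self.sample_ids)} samples"
            )
        if counts.size and not np.issubdtype(counts.dtype, np.integer):
            if not np.allclose(counts, np.round(counts)):
                raise TableFormatError("counts must be integral")
            counts = counts.astype(np.int64)
        if counts.size and counts.min() < 0:
            raise TableFormatError("counts must be non-negative")
        if len(set(self.taxon_ids)) != len(self.taxon_ids):
            raise TableFormatError("duplicate taxon ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise TableFormatError("duplicate sample ids")
        self.counts = counts.astype(np.int64)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.taxon_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "CountTable":
        return cls(list(frame.index), list(frame.columns), frame.to_numpy())

    def sample_sums(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def select_samples(self, sample_ids: Iterable[str]) -> "CountTable":
        wanted = list(sample_ids)
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in wanted if s not in pos]
        if missing:
            raise KeyError(f"unknown sample ids: {missing}")
        idx = [pos[s] for s in wanted]
        return CountTable(list(self.taxon_ids), wanted, self.counts[:, idx])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountTable):
            return NotImplemented
        return (
            self.taxon_ids == other.taxon_ids
            and self.sample_ids == other.sample_ids
            and np.array_equal(self.counts, other.counts)
        )


@dataclass(frozen=True)
class SampleMetadata:
    """Factor assignment of one composite drill-dust sample."""

    sample_id: str
    tree: str  # beech | fir
    canopy: str  # open | closed
    block: int
    plot: str
    mixture: bool  # True when the plot holds deadwood of both species
    year: int  # 1-based year of decomposition

    def __post_init__(self) -> None:
        if self.tree not in TREES:
            raise TableFormatError(f"unknown tree species {self.tree!r} (expected one of {TREES})")
        if self.canopy not in CANOPIES:
            raise TableFormatError(f"unknown canopy level {self.canopy!r} (expected one of {CANOPIES})")
        if int(self.year) < 1:
            raise TableFormatError(f"year must be a positive integer, got {self.year}")


@dataclass(frozen=True)
class TaxonomyRecord:
    """Best BLAST-style hit of one OTU against a fungal reference database."""

    otu_id: str
    best_species: str  # empty when no species-level hit
    best_genus: str
    identity_pct: float
    coverage_pct: float
    kingdom_flag: str = "fungal"  # fungal | host_plant | other

    def __post_init__(self) -> None:
        for name, v in (("identity_pct", self.identity_pct), ("coverage_pct", self.coverage_pct)):
            if not (0.0 <= float(v) <= 100.0):
                raise TableFormatError(f"{name} must lie in [0, 100], got {v}")
        if self.kingdom_flag not in ("fungal", "host_plant", "other"):
            raise TableFormatError(f"unknown kingdom_flag {self.kingdom_flag!r}")


# ---------------------------------------------------------------------------
# count table


def write_count_table(table: CountTable, path: str | Path) -> None:
    frame = table.to_frame()
    frame.index.name = "otu_id"
    frame.to_csv(path, sep="\t", encoding="utf-8")


def read_count_table(path: str | Path) -> CountTable:
    """Read a taxa-by-sample TSV of integer counts, validating strictly.

    Duplicate identifiers, ragged rows and negative or non-integer cells
    raise :class:`TableFormatError` naming the offending line.
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n")
        if not header:
            raise TableFormatError(f"{path}: empty file")
        cols = header.split("\t")
        sample_ids = cols[1:]
        if len(set(sample_ids)) != len(sample_ids):
            raise TableFormatError(f"{path}: duplicate sample ids in header")
        taxon_ids: list[str] = []
        rows: list[list[int]] = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            cells = line.split("\t")
            if len(cells) != len(cols):
                raise TableFormatError(
                    f"{path}:{lineno}: expected {len(cols)} fields, found {len(cells)}"
                )
            taxon_ids.append(cells[0])
            row = []
            for cell in cells[1:]:
                try:
                    value = int(cell)
                except ValueError:
                    raise TableFormatError(
                        f"{path}:{lineno}: non-integer count {cell!r}"
                    ) from None
                if value < 0:
                    raise TableFormatError(f"{path}:{lineno}: negative count {value}")
                row.append(value)
            rows.append(row)
    if len(set(taxon_ids)) != len(taxon_ids):
        raise TableFormatError(f"{path}: duplicate taxon ids")
    counts = np.asarray(rows, dtype=np.int64).reshape(len(taxon_ids), len(sample_ids))
    return CountTable(taxon_ids, sample_ids, counts)


# ---------------------------------------------------------------------------
# metadata

_META_COLUMNS = ["sample_id", "tree", "canopy", "block", "plot", "mixture", "year"]


def write_metadata(records: Iterable[SampleMetadata], path: str | Path) -> None:
    frame = pd.DataFrame(
        [
            (r.sample_id, r.tree, r.canopy, r.block, r.plot, int(r.mixture), r.year)
            for r in records
        ],
        columns=_META_COLUMNS,
    )
    frame.to_csv(path, sep="\t", index=False, encoding="utf-8")


def read_metadata(path: str | Path) -> list[SampleMetadata]:
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _META_COLUMNS if c not in frame.columns]
    if missing:
        raise TableFormatError(f"{path}: missing metadata columns {missing}")
    records = []
    for _, row in frame.iterrows():
        try:
            year = int(row["year"])
            block = int(row["block"])
        except ValueError as exc:
            raise TableFormatError(f"{path}: non-integer block/year in row {row.to_dict()}") from exc
        records.append(
            SampleMetadata(
                sample_id=row["sample_id"],
                tree=row["tree"],
                canopy=row["canopy"],
                block=block,
                plot=row["plot"],
                mixture=bool(int(row["mixture"])),
                year=year,
            )
        )
    ids = [r.sample_id for r in records]
    if len(set(ids)) != len(ids):
        raise TableFormatError(f"{path}: duplicate sample ids")
    return records


def metadata_frame(records: Iterable[SampleMetadata]) -> pd.DataFrame:
    """Metadata as a sample-indexed DataFrame (convenience for analyses)."""
    frame = pd.DataFrame(
        [
            (r.sample_id, r.tree, r.canopy, r.block, r.plot, r.mixture, r.year)
            for r in records
        ],
        columns=_META_COLUMNS,
    )
    return frame.set_index("sample_id")


# ---------------------------------------------------------------------------
# taxonomy and guilds

_TAX_COLUMNS = ["otu_id", "species", "genus", "identity_pct", "coverage_pct", "kingdom_flag"]


def write_taxonomy(records: Iterable[TaxonomyRecord], path: str | Path) -> None:
    frame = pd.DataFrame(
        [
            (r.otu_id, r.best_species or "NA", r.best_genus, r.identity_pct, r.coverage_pct, r.kingdom_flag)
            for r in records
        ],
        columns=_TAX_COLUMNS,
    )
    frame.to_csv(path, sep="\t", index=False, encoding="utf-8")


def read_taxonomy(path: str | Path) -> list[TaxonomyRecord]:
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _TAX_COLUMNS[:5] if c not in frame.columns]
    if missing:
        raise TableFormatError(f"{path}: missing taxonomy columns {missing}")
    records = []
    for _, row in frame.iterrows():
        species = row["species"]
        if species == "NA":
            species = ""
        records.append(
            TaxonomyRecord(
                otu_id=row["otu_id"],
                best_species=species,
                best_genus=row["genus"],
                identity_pct=float(row["identity_pct"]),
                coverage_pct=float(row["coverage_pct"]),
                kingdom_flag=row.get("kingdom_flag", "fungal") or "fungal",
            )
        )
    return records


class GuildMap(dict):
    """Genus-to-guild mapping; genera absent from the map are ``unclassified``."""

    def __missing__(self, key: str) -> str:
        return "unclassified"


def write_guild_map(mapping: Mapping[str, str], path: str | Path) -> None:
    frame = pd.DataFrame(sorted(mapping.items()), columns=["genus", "guild"])
    frame.to_csv(path, sep="\t", index=False, encoding="utf-8")


def read_guild_map(path: str | Path) -> GuildMap:
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("genus", "guild"):
        if col not in frame.columns:
            raise TableFormatError(f"{path}: missing guild map column {col!r}")
    mapping = GuildMap()
    for _, row in frame.iterrows():
        guild = row["guild"]
        if guild not in GUILDS:
            raise TableFormatError(f"{path}: unknown guild {guild!r}")
        mapping[row["genus"]] = guild
    return mapping
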