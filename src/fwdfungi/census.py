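"""Fine-woody-debris (FWD) stock estimation from small census plots.

Field crews collect every FWD piece (diameter 0.5-10 cm) from small square
plots (default 2 x 2 m), record wet mass and piece counts per diameter
class, and determine the dry-mass fraction per class in the laboratory.
Per-hectare dry stock follows by scaling plot dry mass with 10,000 / area
and averaging over plots. Because fine deadwood turns over several times
faster than coarse woody debris (CWD), the standing FWD stock can be
expressed as the CWD stock that would represent the same yearly deadwood
production: stock x turnover ratio.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SIZE_CLASSES",
    "CensusPlotRecord",
    "StockEstimate",
    "estimate_stock",
    "cwd_equivalent",
    "read_census",
    "write_stock_estimate",
]

#: Diameter classes of the census protocol (cm).
SIZE_CLASSES = ("d0.5-1.5", "d1.6-5.0", "d5.1-10.0")


@dataclass(frozen=True)
class CensusPlotRecord:
    """One plot x size-class census entry.

    The field rule for edge pieces (collect those intersecting the eastern
    and southern plot borders, skip the others) is a sampling protocol, not
    a computable quantity; records are assumed to follow it.
    """

    plot_id: str
    size_class: str
    piece_count: int
    wet_mass_kg: float
    dry_fraction: float
    area_m2: float = 4.0

    def __post_init__(self) -> None:
        if self.size_class not in SIZE_CLASSES:
            raise ValueError(f"unknown size class {self.size_class!r}; expected {SIZE_CLASSES}")
        if self.piece_count < 0 or self.wet_mass_kg < 0:
            raise ValueError("piece counts and masses must be non-negative")
        if not (0.0 < self.dry_fraction <= 1.0):
            raise ValueError("dry_fraction must lie in (0, 1]")
        if self.area_m2 <= 0:
            raise ValueError("plot area must be positive")


@dataclass(frozen=True)
class StockEstimate:
    """Per-hectare FWD stock: dry tonnes by size class and in total."""

    per_class_t_ha: dict
    total_t_ha: float
    per_class_share_pct: dict  # NaN when the total stock is zero
    piece_density_ha: dict

    def rounded_share(self, size_class: str) -> float:
        share = self.per_class_share_pct[size_class]
        return float("nan") if np.isnan(share) else round(share)


def estimate_stock(records: list[CensusPlotRecord]) -> StockEstimate:
    """Mean per-hectare dry stock over census plots, by size class.

    Per plot and class: dry mass = wet mass x dry fraction, scaled by
    10,000 / area to a hectare and converted to tonnes; plots missing a
    class contribute zero for it. Shares are class means over the total;
    with zero total stock they are undefined and reported as NaN.
    """
    if not records:
        raise ValueError("no census records")
    frame = pd.DataFrame(
        [
            (r.plot_id, r.size_class, r.piece_count, r.wet_mass_kg, r.dry_fraction, r.area_m2)
            for r in records
        ],
        columns=["plot_id", "size_class", "pieces", "wet_kg", "dry_fraction", "area_m2"],
    )
    frame["dry_t_ha"] = frame.wet_kg * frame.dry_fraction * (10_000 / frame.area_m2) / 1000.0
    frame["pieces_ha"] = frame.pieces * (10_000 / frame.area_m2)
    plots = frame.plot_id.unique()
    per_class = (
        frame.pivot_table(index="plot_id", columns="size_class", values="dry_t_ha", aggfunc="sum")
        .reindex(index=plots, columns=SIZE_CLASSES)
        .fillna(0.0)
    )
    class_means = per_class.mean(axis=0)
    total = float(class_means.sum())
    shares = {
        c: (100.0 * class_means[c] / total if total > 0 else float("nan")) for c in SIZE_CLASSES
    }
    density = (
        frame.pivot_table(index="plot_id", columns="size_class", values="pieces_ha", aggfunc="sum")
        .reindex(index=plots, columns=SIZE_CLASSES)
        .fillna(0.0)
        .mean(axis=0)
    )
    return StockEstimate(
        per_class_t_ha={c: float(class_means[c]) for c in SIZE_CLASSES},
        total_t_ha=total,
        per_class_share_pct=shares,
        piece_density_ha={c: float(density[c]) for c in SIZE_CLASSES},
    )


def cwd_equivalent(fwd_stock_t_ha: float, turnover_ratio: float = 5.0) -> float:
    """CWD stock equivalent, in yearly-production terms, of an FWD stock.

    FWD decomposes roughly ``turnover_ratio`` times faster than CWD, so a
    standing FWD stock corresponds to that many times its mass in CWD.
    """
    if fwd_stock_t_ha < 0:
        raise ValueError("stock must be non-negative")
    if turnover_ratio <= 0:
        raise ValueError("turnover ratio must be positive")
    return fwd_stock_t_ha * turnover_ratio


def read_census(path: str | Path) -> list[CensusPlotRecord]:
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    needed = ["plot_id", "size_class", "piece_count", "wet_mass_kg", "dry_fraction"]
    missing = [c for c in needed if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing census columns {missing}")
    records = []
    for _, row in frame.iterrows():
        records.append(
            CensusPlotRecord(
                plot_id=row["plot_id"],
                size_class=row["size_class"],
                piece_count=int(row["piece_count"]),
                wet_mass_kg=float(row["wet_mass_kg"]),
                dry_fraction=float(row["dry_fraction"]),
                area_m2=float(row["area_m2"]) if "area_m2" in frame.columns else 4.0,
            )
        )
    return records


def write_stock_estimate(estimate: StockEstimate, path: str | Path) -> None:
    rows = [
        (c, estimate.per_class_t_ha[c], estimate.per_class_share_pct[c], estimate.piece_density_ha[c])
        for c in SIZE_CLASSES
    ]
    rows.append(("total", estimate.total_t_ha, 100.0 if estimate.total_t_ha > 0 else float("nan"), sum(estimate.piece_density_ha.values())))
    frame = pd.DataFrame(rows, columns=["size_class", "dry_t_ha", "share_pct", "pieces_ha"])
    frame.to_csv(path, sep="\t", index=False, na_rep="NA", encoding="utf-8")
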