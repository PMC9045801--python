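"""Per-taxon succession statistics.

Four quantities characterise where and when a taxon lives on deadwood:

* **specificity** S — the fraction of a taxon's total relative abundance
  found on the reference substrate level (beech for the tree factor,
  closed canopy for the microclimate factor). S = 1 means the taxon was
  found exclusively on the reference level, 0.5 means it is equally
  abundant on both levels, 0 means exclusive to the alternative.
* **specificity class** — taxa with S in [0.95, 1.0] are specific to the
  reference level, those with S in [0.00, 0.05] specific to the
  alternative, everything else unspecific; bounds inclusive.
* **succession time** T — the relative-abundance-weighted mean year of a
  taxon's occurrence (its average position in succession).
* **occurrence duration** D — the length in whole years of the shortest
  contiguous run of years covering at least 90% of the taxon's summed
  relative abundance (ties broken by the earliest window). A central-
  interval variant (years spanned between the 5th and 95th percentile of
  the cumulative profile) is available by flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .prep import RelAbundanceTable
from .tables import SampleMetadata, metadata_frame
from . import multivariate

__all__ = [
    "SuccessionRecord",
    "taxon_specificity",
    "classify_specificity",
    "succession_time",
    "occurrence_duration",
    "yearly_profiles",
    "succession_table",
    "specificity_vs_time",
]

REFERENCE_LEVEL = {"tree": "beech", "canopy": "closed"}
_CLASS_NAMES = {
    "tree": ("beech_specific", "fir_specific"),
    "canopy": ("closed_specific", "open_specific"),
}


@dataclass(frozen=True)
class SuccessionRecord:
    taxon_id: str
    s_tree: float
    class_tree: str
    s_canopy: float
    class_canopy: str
    succession_time: float
    duration: int


def taxon_specificity(
    rel: RelAbundanceTable, metadata: list[SampleMetadata], factor: str
) -> pd.Series:
    """Specificity of every taxon for the reference level of a factor.

    S = (sum of relative abundances over reference-level samples) /
    (sum over all samples). Taxa absent from every sample have no defined
    specificity and are returned as NaN, never as 0 or 1. The reference
    level (beech; closed) is recorded in the series name.
    """
    if factor not in REFERENCE_LEVEL:
        raise ValueError(f"factor must be 'tree' or 'canopy', got {factor!r}")
    reference = REFERENCE_LEVEL[factor]
    meta = metadata_frame(metadata).loc[rel.sample_ids]
    mask = (meta[factor] == reference).to_numpy()
    ref_sum = rel.proportions[:, mask].sum(axis=1)
    all_sum = rel.proportions.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        s = np.where(all_sum > 0, ref_sum / np.where(all_sum > 0, all_sum, 1.0), np.nan)
    s = np.clip(s, 0.0, 1.0)  # guard float round-off at the boundaries
    return pd.Series(s, index=rel.taxon_ids, name=f"specificity_{factor}[ref={reference}]")


def classify_specificity(s: float, factor: str = "tree") -> str:
    """Classify a specificity value; 0.95 and 0.05 belong to the specific classes."""
    if np.isnan(s):
        return "missing"
    if not (0.0 <= s <= 1.0):
        raise ValueError(f"specificity must lie in [0, 1], got {s}")
    ref_class, alt_class = _CLASS_NAMES[factor]
    if s >= 0.95:
        return ref_class
    if s <= 0.05:
        return alt_class
    return "unspecific"


def succession_time(yearly_profile: dict[int, float] | pd.Series) -> float:
    """Abundance-weighted mean year of occurrence.

    Invariant to rescaling the profile by any positive constant.
    """
    profile = pd.Series(yearly_profile, dtype=float)
    if profile.min() < 0:
        raise ValueError("yearly profile must be non-negative")
    total = profile.sum()
    if total <= 0:
        raise ValueError("yearly profile sums to zero")
    years = profile.index.to_numpy(dtype=float)
    return float((years * profile.to_numpy()).sum() / total)


def occurrence_duration(
    yearly_profile: dict[int, float] | pd.Series,
    coverage: float = 0.9,
    *,
    method: str = "contiguous",
) -> int:
    """Years needed to cover ``coverage`` of a taxon's summed abundance.

    ``contiguous`` (default): length of the shortest contiguous run of
    years whose summed weight reaches the coverage, earliest window on
    ties. ``central``: number of years spanned between the 5th and 95th
    percentile of the cumulative profile (for coverage 0.9).
    """
    profile = pd.Series(yearly_profile, dtype=float).sort_index()
    if profile.min() < 0:
        raise ValueError("yearly profile must be non-negative")
    total = profile.sum()
    if total <= 0:
        raise ValueError("yearly profile sums to zero")
    w = profile.to_numpy()
    n = len(w)
    target = coverage * total
    if method == "central":
        tail = (1.0 - coverage) / 2.0
        cum = np.cumsum(w)
        lo = int(np.searchsorted(cum, tail * total + 1e-12 * total))
        hi = int(np.searchsorted(cum, (1.0 - tail) * total - 1e-12 * total))
        return int(hi - lo + 1)
    if method != "contiguous":
        raise ValueError(f"unknown duration method {method!r}")
    tol = 1e-12 * total
    for length in range(1, n + 1):
        for start in range(0, n - length + 1):
            if w[start : start + length].sum() >= target - tol:
                return length
    return n


def yearly_profiles(
    rel: RelAbundanceTable, metadata: list[SampleMetadata]
) -> pd.DataFrame:
    """Taxa-by-year matrix of mean relative abundance, pooled over treatments."""
    meta = metadata_frame(metadata).loc[rel.sample_ids]
    frame = rel.to_frame()
    cols = {}
    for year, sample_idx in meta.groupby("year").groups.items():
        cols[int(year)] = frame[list(sample_idx)].mean(axis=1)
    return pd.DataFrame(cols).sort_index(axis=1)


def succession_table(
    rel: RelAbundanceTable,
    metadata: list[SampleMetadata],
    *,
    duration_method: str = "contiguous",
) -> pd.DataFrame:
    """Full per-taxon succession summary.

    Columns: s_tree, class_tree, s_canopy, class_canopy, succession_time,
    duration. Taxa absent everywhere are dropped (their statistics are
    undefined).
    """
    s_tree = taxon_specificity(rel, metadata, "tree")
    s_canopy = taxon_specificity(rel, metadata, "canopy")
    profiles = yearly_profiles(rel, metadata)
    rows = []
    for taxon in rel.taxon_ids:
        st = s_tree[taxon]
        if np.isnan(st):
            continue
        profile = profiles.loc[taxon]
        rows.append(
            (
                taxon,
                st,
                classify_specificity(st, "tree"),
                s_canopy[taxon],
                classify_specificity(s_canopy[taxon], "canopy"),
                succession_time(profile),
                occurrence_duration(profile, method=duration_method),
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "taxon_id",
            "s_tree",
            "class_tree",
            "s_canopy",
            "class_canopy",
            "succession_time",
            "duration",
        ],
    ).set_index("taxon_id")


def specificity_vs_time(records: pd.DataFrame, factor: str = "tree"):
    """Spearman correlation between succession time and specificity.

    ``records`` is a :func:`succession_table` frame. Returns (rho, p);
    both NaN when the specificity has zero rank variance.
    """
    if len(records) < 3:
        raise ValueError("need at least 3 taxa for a rank correlation")
    s_col = {"tree": "s_tree", "canopy": "s_canopy"}[factor]
    return multivariate.spearman(
        records["succession_time"].to_numpy(), records[s_col].to_numpy()
    )
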