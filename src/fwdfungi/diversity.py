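"""Per-sample alpha-diversity estimates on rarefied counts.

Shannon entropy is in nats; evenness is Pielou's J = H / ln(S); Chao1 uses
the bias-corrected form S + F1(F1-1) / (2(F2+1)), which stays defined when
the sample has no doubletons. The classic form S + F1^2 / (2 F2) is
available by flag and is NaN when F2 = 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tables import CountTable

__all__ = ["DiversityRecord", "diversity_indices", "diversity_table"]


@dataclass(frozen=True)
class DiversityRecord:
    sample_id: str
    richness: int
    chao1: float
    shannon: float
    evenness: float


def diversity_indices(
    sample_counts: np.ndarray, sample_id: str = "", *, bias_corrected: bool = True
) -> DiversityRecord:
    """Richness, Chao1, Shannon H and Pielou evenness of one count vector.

    A single-taxon sample has H = 0 and J = 1 by convention. An all-zero
    vector is an error.
    """
    counts = np.asarray(sample_counts)
    if counts.ndim != 1:
        raise ValueError("sample_counts must be a 1-D vector")
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    total = counts.sum()
    if total == 0:
        raise ValueError(f"sample {sample_id or '<unnamed>'} has no reads")
    positive = counts[counts > 0]
    s = int(positive.size)
    p = positive / total
    shannon = float(-(p * np.log(p)).sum())
    evenness = 1.0 if s == 1 else float(shannon / np.log(s))
    f1 = int((positive == 1).sum())
    f2 = int((positive == 2).sum())
    if bias_corrected:
        chao1 = s + f1 * (f1 - 1) / (2.0 * (f2 + 1))
    else:
        chao1 = s + f1**2 / (2.0 * f2) if f2 > 0 else float("nan")
    return DiversityRecord(sample_id, s, float(chao1), shannon, evenness)


def diversity_table(table: CountTable, *, bias_corrected: bool = True) -> pd.DataFrame:
    """Diversity indices for every sample of a count table."""
    rows = []
    for j, sid in enumerate(table.sample_ids):
        rec = diversity_indices(table.counts[:, j], sid, bias_corrected=bias_corrected)
        rows.append((rec.sample_id, rec.richness, rec.chao1, rec.shannon, rec.evenness))
    return pd.DataFrame(
        rows, columns=["sample_id", "richness", "chao1", "shannon", "evenness"]
    ).set_index("sample_id")
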