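"""Taxonomic diversity of window families and score-matrix clustering.

Diversity of a window family across taxa at one rank is Shannon entropy
in bits, H = -sum_i p_i log2 p_i with p_i the relative abundance of taxon
i among the family's windows. H values across families are categorized
against the interquartile range of their distribution: values up to Q3
are "low", values up to the right whisker (Q3 + 1.5 IQR) are "medium",
and values beyond it are "high".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

logger = logging.getLogger(__name__)


@dataclass
class TaxonCounts:
    family_id: str
    counts: dict[str, int]
    level: str = "genus"

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.counts.values()):
            raise ValueError("negative taxon count")

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def n_taxa(self) -> int:
        return sum(1 for c in self.counts.values() if c > 0)


@dataclass
class EntropyReport:
    family_id: str
    H: float  # bits
    category: str  # low | medium | high
    n_taxa: int


def shannon_entropy(counts: TaxonCounts | Mapping[str, int] | Sequence[int]) -> float:
    """Shannon entropy in bits; zero-count taxa contribute nothing."""
    if isinstance(counts, TaxonCounts):
        values = list(counts.counts.values())
    elif isinstance(counts, Mapping):
        values = list(counts.values())
    else:
        values = list(counts)
    arr = np.asarray(values, dtype=float)
    if arr.sum() <= 0:
        raise ValueError("entropy undefined for all-zero counts")
    p = arr[arr > 0] / arr.sum()
    return float(-(p * np.log2(p)).sum())


def categorize_entropy(values: Sequence[float]) -> dict[float, str]:
    """Map each H value to low / medium / high by the IQR rule.

    Quartiles use linear interpolation. low: H <= Q3 (including sub-Q1
    values, which are low-diversity by construction); medium: Q3 < H <=
    Q3 + 1.5 IQR; high: beyond the right whisker. With fewer than 4
    values the quartiles are meaningless and everything is labeled low.
    """
    values = list(values)
    if len(values) < 4:
        logger.warning("categorize_entropy: %d < 4 values, all labeled low",
                       len(values))
        return {v: "low" for v in values}
    q1, q3 = np.percentile(values, [25, 75])
    whisker = q3 + 1.5 * (q3 - q1)
    out = {}
    for v in values:
        if v <= q3:
            out[v] = "low"
        elif v <= whisker:
            out[v] = "medium"
        else:
            out[v] = "high"
    return out


def entropy_reports(families: Sequence[TaxonCounts]) -> list[EntropyReport]:
    entropies = {f.family_id: shannon_entropy(f) for f in families}
    categories = categorize_entropy(list(entropies.values()))
    return [EntropyReport(f.family_id, entropies[f.family_id],
                          categories[entropies[f.family_id]], f.n_taxa)
            for f in families]


@dataclass
class ClusterOrder:
    leaves: list[str]  # window ids in dendrogram leaf order
    linkage: np.ndarray = field(default_factory=lambda: np.empty((0, 4)))


def cluster_gfs(matrix) -> ClusterOrder:
    """Leaf ordering of the score matrix for the clustered heatmap.

    Rows (window score vectors) are compared by Euclidean distance and
    clustered agglomeratively with complete linkage.
    """
    if isinstance(matrix, pd.DataFrame):
        df = matrix
    elif hasattr(matrix, "values") and isinstance(matrix.values, pd.DataFrame):
        df = matrix.values
    else:
        df = pd.DataFrame(matrix)
    if df.isna().any().any():
        raise ValueError("score matrix contains NaN cells")
    ids = [str(i) for i in df.index]
    if len(ids) == 1:
        return ClusterOrder(leaves=ids)
    dist = pdist(df.to_numpy(dtype=float), metric="euclidean")
    linkage = hierarchy.linkage(dist, method="complete")
    order = hierarchy.leaves_list(linkage)
    return ClusterOrder(leaves=[ids[i] for i in order], linkage=linkage)


def load_taxonomy(path) -> pd.DataFrame:
    """TSV of genome or window id -> rank labels (first column = id)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError("taxonomy TSV needs an id column plus >=1 rank column")
    return df.set_index(df.columns[0])


def family_counts(window_genomes: Sequence[str], taxonomy: pd.DataFrame,
                  level: str, family_id: str = "family") -> TaxonCounts:
    """Count a family's windows per taxon at one rank.

    ``window_genomes`` are the genome (or window) ids of the family
    members; ids missing from the taxonomy are counted as 'unclassified'.
    """
    if level not in taxonomy.columns:
        raise ValueError(f"rank {level!r} not in taxonomy columns {list(taxonomy.columns)}")
    counts: dict[str, int] = {}
    for gid in window_genomes:
        label = taxonomy[level].get(gid, "unclassified")
        counts[label] = counts.get(label, 0) + 1
    return TaxonCounts(family_id, counts, level)
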