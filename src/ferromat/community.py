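"""Community succession analytics for Fe(III)-oxide mats.

Covers the molecular-survey side of mat development: copy-number
corrected relative abundances from 16S amplicon counts, Bray-Curtis
dissimilarities and hierarchical clustering of samples over time/depth,
taxon decline rates with linear extrapolation, primer-bias diagnostics
of amplicon surveys against random-metagenome references, and a
rule-based classifier for the four stages of mat development
(I primary lithoautotroph colonization, II visible Fe(III)-oxide
accretion, III heterotroph colonization with O2 gradients, IV mature
thick mats dominated by organoheterotrophs).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial import distance
from skbio import DistanceMatrix

from .config import StageThresholds

__all__ = [
    "AbundanceTable",
    "MatState",
    "Dendrogram",
    "relative_abundance",
    "bray_curtis",
    "bray_curtis_matrix",
    "cluster_dendrogram",
    "decline_rate",
    "extrapolate",
    "primer_bias",
    "classify_stage",
]


@dataclass
class AbundanceTable:
    """Taxon x sample table of counts or proportions.

    ``values`` is a DataFrame indexed by taxon with one column per
    sample; ``sample_meta`` (optional) is indexed by sample with
    columns like site, day, depth_zone; ``copy_numbers`` maps taxa to
    16S rRNA gene copies (default 1).
    """

    values: pd.DataFrame
    mode: str = "counts"  # "counts" | "proportions"
    copy_numbers: pd.Series | None = None
    sample_meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("counts", "proportions"):
            raise ValueError("mode must be 'counts' or 'proportions'")
        if self.values.columns.duplicated().any():
            dupes = self.values.columns[self.values.columns.duplicated()].tolist()
            raise ValueError(f"duplicate sample IDs: {dupes}")
        if (self.values.values < 0).any():
            raise ValueError("abundances must be nonnegative")
        if self.copy_numbers is None:
            self.copy_numbers = pd.Series(1.0, index=self.values.index)
        else:
            self.copy_numbers = self.copy_numbers.reindex(self.values.index).fillna(1.0)
            if (self.copy_numbers < 1).any():
                raise ValueError("copy numbers must be >= 1")
        if self.mode == "proportions":
            sums = self.values.sum(axis=0)
            if not np.allclose(sums, 1.0, atol=1e-9):
                raise ValueError("proportion columns must sum to 1 within 1e-9")

    @property
    def taxa(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class MatState:
    """Snapshot of mat development used by the stage classifier."""

    day: float
    mat_depth_mm: float
    visible_fe: bool
    heterotroph_fraction: float
    o2_gradient_present: bool = False

    def __post_init__(self) -> None:
        if self.mat_depth_mm < 0:
            raise ValueError("mat depth must be nonnegative")
        if not (0 <= self.heterotroph_fraction <= 1):
            raise ValueError("heterotroph fraction must lie in [0, 1]")

    @property
    def lithoautotroph_fraction(self) -> float:
        return 1.0 - self.heterotroph_fraction


def relative_abundance(table: AbundanceTable) -> AbundanceTable:
    """Copy-number corrected proportions from a counts table.

    Each taxon's counts are divided by its 16S copy number (taxa with
    multiple rRNA operons, e.g. *Hydrogenobaculum* with two copies,
    are otherwise over-counted), then each sample is normalised to 1.
    """
    if table.mode != "counts":
        raise ValueError("relative_abundance expects a counts-mode table")
    corrected = table.values.div(table.copy_numbers, axis=0)
    sums = corrected.sum(axis=0)
    zero = sums[sums == 0].index.tolist()
    if zero:
        raise ValueError(f"samples with all-zero counts: {zero}")
    props = corrected.div(sums, axis=1)
    return AbundanceTable(
        values=props, mode="proportions",
        copy_numbers=table.copy_numbers.copy(), sample_meta=table.sample_meta,
    )


def bray_curtis(x, y) -> float:
    """Bray-Curtis dissimilarity sum|x-y| / sum(x+y), in [0, 1]."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    if (x < 0).any() or (y < 0).any():
        raise ValueError("vectors must be nonnegative")
    if x.sum() + y.sum() == 0:
        raise ValueError("vectors must not both be all-zero")
    return float(distance.braycurtis(x, y))


def bray_curtis_matrix(table: AbundanceTable, axis: str = "samples") -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarities between samples (or taxa)."""
    data = table.values.T if axis == "samples" else table.values
    labels = [str(l) for l in data.index]
    condensed = distance.pdist(data.to_numpy(dtype=float), metric="braycurtis")
    return DistanceMatrix(distance.squareform(condensed), ids=labels)


@dataclass
class Dendrogram:
    """Agglomerative clustering result, serialisable as Newick."""

    linkage: np.ndarray
    labels: list[str] = field(default_factory=list)

    def merge_heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def to_newick(self) -> str:
        """Newick string with branch lengths = height differences."""
        tree = hierarchy.to_tree(self.linkage)

        def quote(label: str) -> str:
            return f"'{label}'" if any(c in label for c in " \t(),:;'") else label

        def render(node, parent_height: float) -> str:
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{quote(self.labels[node.id])}:{length:.10g}"
            left = render(node.left, node.dist)
            right = render(node.right, node.dist)
            return f"({left},{right}):{length:.10g}"

        root = tree
        left = render(root.left, root.dist)
        right = render(root.right, root.dist)
        return f"({left},{right});"


def cluster_dendrogram(matrix: DistanceMatrix, linkage: str = "complete") -> Dendrogram:
    """Hierarchical clustering of a dissimilarity matrix.

    Complete linkage by default (average available).  Labels are sorted
    before clustering so tie-breaking is deterministic in label order.
    """
    if linkage not in ("complete", "average"):
        raise ValueError("linkage must be 'complete' or 'average'")
    ids = sorted(matrix.ids)
    if len(ids) < 2:
        raise ValueError("need at least 2 labels to cluster")
    reordered = matrix.filter(ids)
    condensed = distance.squareform(reordered.data, checks=False)
    Z = hierarchy.linkage(condensed, method=linkage)
    return Dendrogram(linkage=Z, labels=ids)


def decline_rate(days, percent) -> float:
    """Average decline of a taxon's relative abundance, in %/day.

    OLS slope of percentage against day, sign-flipped so a declining
    taxon has a positive rate.
    """
    days = np.asarray(days, dtype=float)
    percent = np.asarray(percent, dtype=float)
    if days.size < 2 or np.ptp(days) == 0:
        raise ValueError("need at least 2 distinct days")
    slope = np.polyfit(days, percent, 1)[0]
    return float(-slope)


def extrapolate(rate: float, from_day: float, from_value: float, to_day: float) -> float:
    """Linear extrapolation of a declining percentage, floored at 0."""
    return float(max(from_value - rate * (to_day - from_day), 0.0))


def primer_bias(itag: AbundanceTable, reference: AbundanceTable) -> pd.DataFrame:
    """Per-taxon amplicon/reference abundance ratios with bias flags.

    For every sample shared by the two tables and every taxon present
    in either, the ratio iTag / reference is reported with a flag:
    ``over`` (> 1), ``under`` (< 1), ``unbiased`` (= 1), or ``absent``
    when the taxon is missing (NaN) from one of the tables — an
    amplicon dropout (e.g. a primer mismatch) is evidence of bias, not
    a zero abundance.
    """
    shared = [s for s in itag.samples if s in reference.samples]
    if not shared:
        raise ValueError("tables share no samples")
    taxa = sorted(set(itag.taxa) | set(reference.taxa))
    rows = []
    for sample in shared:
        for taxon in taxa:
            a = itag.values.at[taxon, sample] if taxon in itag.values.index else np.nan
            b = (reference.values.at[taxon, sample]
                 if taxon in reference.values.index else np.nan)
            if np.isnan(a) or np.isnan(b):
                ratio, flag = np.nan, "absent"
            elif b == 0:
                ratio, flag = np.nan, "absent"
            else:
                ratio = a / b
                flag = "over" if ratio > 1 else ("under" if ratio < 1 else "unbiased")
            rows.append({"sample": sample, "taxon": taxon, "itag": a,
                         "reference": b, "ratio": ratio, "flag": flag})
    return pd.DataFrame(rows)


def classify_stage(state: MatState, thresholds: StageThresholds | None = None) -> str:
    """Assign a mat-development stage from depth, visible Fe and guild mix.

    Rule cascade (thresholds configurable): IV for mature thick mats,
    III once the mat is deep enough for O2 gradients or heterotrophs
    are established, II once Fe(III)-oxide accretion is visible,
    otherwise I (primary lithoautotroph colonization).
    """
    th = thresholds or StageThresholds()
    if state.mat_depth_mm >= th.mature_depth_mm:
        return "IV"
    if (state.mat_depth_mm >= th.gradient_depth_mm
            or state.heterotroph_fraction >= th.heterotroph_fraction):
        return "III"
    if state.visible_fe:
        return "II"
    return "I"
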