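"""Cross-sample DMR comparison and transgenerational stability classification.

Overlap matrices are *asymmetric*: entry (i, j) is the percentage of sample
i's DMRs that touch (>= 1 bp) at least one DMR of sample j. Common DMRs are
the first sample's regions hit in every other sample. Methylation heat-map
matrices hold pooled #C/(#C+#T) per region per sample and are clustered with
complete linkage on Euclidean distance.

Stability of a T2-defined hypomethylated region over the T4 and T6
generations uses the half-of-wild-type rule: a generation has "lost"
methylation when its pooled level is below half the wild-type level, and has
"gained" (recovered) it otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .dmr import DMR, dmrs_to_frame
from .intervals import GenomicInterval, IntervalIndex
from .io import MethylomeSample, PooledMethylation

__all__ = [
    "StabilityCall",
    "overlap_matrix",
    "common_dmrs",
    "methylation_matrix",
    "hierarchical_cluster",
    "stability_category",
    "classify_stability",
    "classify_stability_many",
    "linkage_to_newick",
]

STABILITY_CATEGORIES = ("stable_loss", "recovered_T4", "recovered_T6_only", "transient_T4")


def _dmr_frame(dmrs) -> pd.DataFrame:
    if isinstance(dmrs, pd.DataFrame):
        return dmrs
    rows = [(d.chrom, d.start, d.end) for d in dmrs]
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def overlap_matrix(dmr_sets: Mapping[str, Sequence[DMR]]) -> pd.DataFrame:
    """Pairwise asymmetric percent overlap between per-sample DMR sets.

    Entry (i, j) = 100 * fraction of set i's DMRs overlapping >= 1 bp some DMR
    of set j. The diagonal of a non-empty set is 100; rows of empty sets are
    NaN (undefined, reported missing).
    """
    ids = list(dmr_sets)
    frames = {sid: _dmr_frame(dmr_sets[sid]) for sid in ids}
    indexes = {sid: IntervalIndex.from_frame(frames[sid]) for sid in ids}
    out = pd.DataFrame(np.nan, index=ids, columns=ids, dtype=float)
    for i in ids:
        qi = frames[i]
        if qi.empty:
            continue
        for j in ids:
            hit = indexes[j].count_overlapping(qi)
            out.at[i, j] = 100.0 * hit / len(qi)
    return out


def common_dmrs(dmr_sets: Sequence[Sequence[DMR]]) -> list[GenomicInterval]:
    """Regions of the first set overlapping >= 1 bp a DMR in *every* other set.

    The reference set anchors the output because DMRs are sample-defined
    entities; the result is sorted by (chrom, start).
    """
    if len(dmr_sets) == 0:
        raise ValueError("need at least one DMR set")
    if len(dmr_sets) < 2:
        raise ValueError("need >= 2 DMR sets to intersect")
    reference = _dmr_frame(dmr_sets[0])
    keep = np.ones(len(reference), dtype=bool)
    for other in dmr_sets[1:]:
        idx = IntervalIndex.from_frame(_dmr_frame(other))
        hits = np.zeros(len(reference), dtype=bool)
        for chrom, sub in reference.groupby("chrom", sort=False):
            hits[sub.index] = idx.overlaps_any(
                str(chrom), sub["start"].to_numpy(), sub["end"].to_numpy()
            )
        keep &= hits
    out = [
        GenomicInterval(row.chrom, int(row.start), int(row.end))
        for row in reference[keep].itertuples(index=False)
    ]
    return sorted(out)


def _pooled_levels(
    sample: MethylomeSample, intervals: Sequence[GenomicInterval], context: str
) -> np.ndarray:
    """Pooled methylation per interval via per-chromosome prefix sums."""
    pooled = PooledMethylation(sample.calls, context)
    return np.array([pooled.level(iv.chrom, iv.start, iv.end) for iv in intervals])


def methylation_matrix(
    dmr_union: Sequence[GenomicInterval],
    samples: Sequence[MethylomeSample],
    context: str,
) -> tuple[pd.DataFrame, pd.Series]:
    """Pooled methylation per region (rows) per sample (columns).

    Returns (matrix, flagged) where ``flagged`` marks rows containing any
    undefined (zero-coverage) value; such rows are removed before clustering.
    """
    intervals = list(dmr_union)
    for a, b in zip(sorted(intervals), sorted(intervals)[1:]):
        if a.overlaps(b):
            raise ValueError(f"intervals must be disjoint: {a} overlaps {b}")
    labels = [f"{iv.chrom}:{iv.start}-{iv.end}" for iv in intervals]
    data = {s.sample_id: _pooled_levels(s, intervals, context) for s in samples}
    matrix = pd.DataFrame(data, index=labels)
    flagged = matrix.isna().any(axis=1)
    flagged.name = "missing"
    return matrix, flagged


def hierarchical_cluster(matrix: pd.DataFrame) -> tuple[list, np.ndarray]:
    """Complete-linkage agglomerative clustering with Euclidean distance.

    Returns (leaf order as row labels, scipy linkage matrix). Rows must be
    complete (drop flagged rows first). Ties break deterministically by the
    input row order.
    """
    if matrix.isna().any().any():
        raise ValueError("matrix contains missing values; drop flagged rows first")
    if len(matrix) < 2:
        raise ValueError("need >= 2 rows to cluster")
    linkage = hierarchy.linkage(matrix.to_numpy(float), method="complete", metric="euclidean")
    order = hierarchy.leaves_list(linkage)
    return [matrix.index[i] for i in order], linkage


def linkage_to_newick(linkage: np.ndarray, labels: Sequence[str]) -> str:
    """Serialize a scipy linkage matrix as a Newick tree with branch lengths."""
    tree = hierarchy.to_tree(linkage)

    def recurse(node, parent_height) -> str:
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{labels[node.id]}:{length:g}"
        left = recurse(node.left, node.dist)
        right = recurse(node.right, node.dist)
        return f"({left},{right}):{length:g}"

    return recurse(tree, tree.dist) + ";"


# ---------------------------------------------------------------------------
# stability across generations
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StabilityCall:
    """Fate of a T2-defined hypomethylated region across T4 and T6."""

    dmr: DMR
    wt_level: float
    t2_level: float
    t4_level: float
    t6_level: float
    category: str

    def __post_init__(self) -> None:
        if self.category not in STABILITY_CATEGORIES:
            raise ValueError(f"bad category {self.category!r}")


def stability_category(wt_level: float, t4_level: float, t6_level: float) -> str:
    """Half-of-wild-type rule applied to the T4 and T6 levels.

    A generation shows "loss" when its level is strictly below half the
    wild-type level, "gain" otherwise (equality counts as gain — loss is the
    strict category and the tie is measure-zero on real data).
    """
    for name, level in (("wt", wt_level), ("t4", t4_level), ("t6", t6_level)):
        if math.isnan(level):
            raise ValueError(f"zero coverage: {name} level undefined")
    half = 0.5 * wt_level
    lost_t4 = t4_level < half
    lost_t6 = t6_level < half
    if lost_t4 and lost_t6:
        return "stable_loss"
    if not lost_t4 and not lost_t6:
        return "recovered_T4"
    if lost_t4 and not lost_t6:
        return "recovered_T6_only"
    return "transient_T4"


def classify_stability(
    dmr: DMR,
    wt: MethylomeSample,
    t2: MethylomeSample,
    t4: MethylomeSample,
    t6: MethylomeSample,
    context: str = "CG",
) -> StabilityCall:
    """Classify one T2 hypo-DMR from pooled levels in all four samples.

    Raises ``ValueError`` when any generation has zero coverage over the
    region (unclassifiable; callers report those separately).
    """
    iv = dmr.interval
    wt_level, t2_level, t4_level, t6_level = (
        _pooled_levels(s, [iv], context)[0] for s in (wt, t2, t4, t6)
    )
    category = stability_category(wt_level, t4_level, t6_level)
    return StabilityCall(dmr, wt_level, t2_level, t4_level, t6_level, category)


def classify_stability_many(
    dmrs: Sequence[DMR],
    wt: MethylomeSample,
    t2: MethylomeSample,
    t4: MethylomeSample,
    t6: MethylomeSample,
    context: str = "CG",
) -> tuple[list[StabilityCall], list[DMR]]:
    """Classify a DMR list; returns (calls, unclassifiable DMRs)."""
    pooled = [PooledMethylation(s.calls, context) for s in (wt, t2, t4, t6)]
    calls: list[StabilityCall] = []
    unclassifiable: list[DMR] = []
    for dmr in dmrs:
        wt_l, t2_l, t4_l, t6_l = (
            p.level(dmr.chrom, dmr.start, dmr.end) for p in pooled
        )
        try:
            category = stability_category(wt_l, t4_l, t6_l)
        except ValueError:
            unclassifiable.append(dmr)
            continue
        calls.append(StabilityCall(dmr, wt_l, t2_l, t4_l, t6_l, category))
    return calls, unclassifiable


def stability_calls_to_frame(calls: Sequence[StabilityCall]) -> pd.DataFrame:
    base = dmrs_to_frame([c.dmr for c in calls])
    base["wt_level"] = [c.wt_level for c in calls]
    base["t2_level"] = [c.t2_level for c in calls]
    base["t4_level"] = [c.t4_level for c in calls]
    base["t6_level"] = [c.t6_level for c in calls]
    base["category"] = [c.category for c in calls]
    return base
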