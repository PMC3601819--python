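"""RPKM quantification, fourfold/FDR differential expression, siRNA filtering.

Differential expression between two libraries uses a two-sided Fisher's exact
test on each gene's count against the remainder of its library, BH-corrected
across tested genes, gated on a fourfold normalized change. Genes with zero
reads in both libraries are excluded from every denominator. Fold changes use
a +0.5 pseudocount so a zero on one side stays finite (zero-in-both genes are
already excluded).
"""

from __future__ import annotations

from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .dmr import bh_adjust, fisher_exact_many

__all__ = [
    "rpkm",
    "call_de",
    "deregulation_by_distance",
    "filter_by_length",
    "read_smrna_table",
    "write_smrna_table",
]

DE_STATUSES = ("up", "down", "unchanged", "excluded_zero")


def rpkm(count: float, gene_length_bp: float, library_size_reads: float) -> float:
    """Reads per kilobase of gene model per million uniquely mapped reads."""
    if gene_length_bp <= 0:
        raise ValueError("gene_length_bp must be > 0")
    if library_size_reads <= 0:
        raise ValueError("library_size_reads must be > 0")
    return count / (gene_length_bp / 1000.0) / (library_size_reads / 1e6)


def _fisher_library_test(
    counts_sample: np.ndarray,
    counts_control: np.ndarray,
    libsize_sample: float,
    libsize_control: float,
) -> np.ndarray:
    return fisher_exact_many(
        counts_sample,
        np.asarray(libsize_sample - counts_sample, dtype=np.int64),
        counts_control,
        np.asarray(libsize_control - counts_control, dtype=np.int64),
    )


def call_de(
    counts_sample: pd.Series,
    counts_control: pd.Series,
    libsize_sample: float,
    libsize_control: float,
    fold_cut: float = 4.0,
    fdr: float = 0.01,
    test: Callable[..., np.ndarray] | None = None,
) -> pd.DataFrame:
    """Per-gene differential expression calls between one sample and a control.

    Returns a DataFrame indexed by gene with columns ``count_sample,
    count_control, rpkm-normalized fold_change, p_value, q_value, status``;
    ``status`` is ``excluded_zero`` (zero in both libraries, never tested),
    ``up`` (fold >= fold_cut and q < fdr), ``down`` (symmetric) or
    ``unchanged``. The test statistic is pluggable; the default is the
    two-sided Fisher count-vs-library-remainder test.
    """
    if not counts_sample.index.equals(counts_control.index):
        raise ValueError("mismatched gene sets")
    if libsize_sample <= 0 or libsize_control <= 0:
        raise ValueError("library sizes must be > 0")
    test = test or _fisher_library_test
    cs = counts_sample.to_numpy(np.int64)
    cc = counts_control.to_numpy(np.int64)
    excluded = (cs == 0) & (cc == 0)

    fold = ((cs + 0.5) / libsize_sample) / ((cc + 0.5) / libsize_control)
    p = np.full(cs.shape, np.nan)
    q = np.full(cs.shape, np.nan)
    tested = ~excluded
    if tested.any():
        p[tested] = test(cs[tested], cc[tested], libsize_sample, libsize_control)
        q[tested] = bh_adjust(p[tested])

    status = np.full(cs.shape, "unchanged", dtype=object)
    status[excluded] = "excluded_zero"
    significant = tested & (q < fdr)
    status[significant & (fold >= fold_cut)] = "up"
    status[significant & (fold <= 1.0 / fold_cut)] = "down"
    return pd.DataFrame(
        {
            "count_sample": cs,
            "count_control": cc,
            "fold_change": fold,
            "p_value": p,
            "q_value": q,
            "status": status,
        },
        index=counts_sample.index,
    )


def deregulation_by_distance(
    gene_distances: Mapping[str, int],
    de_records: pd.DataFrame,
    distance_bins: Sequence[tuple[int, int]] = ((0, 500), (500, 1000), (1000, 2000)),
) -> pd.Series:
    """Fraction of DMR-proximal genes deregulated, per TSS-distance bin.

    ``gene_distances`` maps gene id -> absolute distance (bp) from its nearest
    promoter hypo-DMR to the TSS. Per bin [lo, hi): the fraction of those
    genes with status up or down, among genes not excluded for zero counts.
    Bins with no genes are NaN (undefined).
    """
    labels = [f"[{lo},{hi})" for lo, hi in distance_bins]
    out = pd.Series(np.nan, index=labels, dtype=float)
    status = de_records["status"]
    for (lo, hi), label in zip(distance_bins, labels):
        genes = [
            g
            for g, d in gene_distances.items()
            if lo <= abs(d) < hi and g in status.index and status[g] != "excluded_zero"
        ]
        if genes:
            dereg = sum(status[g] in ("up", "down") for g in genes)
            out[label] = dereg / len(genes)
    return out


def filter_by_length(records: pd.DataFrame, length: int = 24) -> pd.DataFrame:
    """Small-RNA records of exactly the requested read length."""
    return records[records["length"] == length].reset_index(drop=True)


def read_smrna_table(path) -> pd.DataFrame:
    """Tab-separated (chrom, start, length, count), 0-based starts."""
    frame = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        names=["chrom", "start", "length", "count"],
        dtype={"chrom": str, "start": np.int64, "length": np.int64, "count": np.int64},
    )
    bad = (frame["length"] < 18) | (frame["length"] > 30) | (frame["count"] < 1)
    if bad.any():
        raise ValueError(f"{path}: {int(bad.sum())} records with invalid length/count")
    return frame


def write_smrna_table(records: pd.DataFrame, path) -> None:
    with open(path, "wt") as handle:
        handle.write("#chrom\tstart\tlength\tcount\n")
        records.to_csv(handle, sep="\t", header=False, index=False,
                       columns=["chrom", "start", "length", "count"])
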