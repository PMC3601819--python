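"""Differentially methylated region calling against a wild-type control.

The caller implements a binned Fisher strategy: pool #C/#T read counts of one
cytosine context over 100-bp genome bins, test each eligible bin with a
two-sided Fisher's exact test against the control, correct genome-wide with
Benjamini-Hochberg, require a large absolute methylation difference
(0.7 / 0.5 / 0.1 for CG / CHG / CHH by default), and merge nearby significant
bins of the same direction into DMRs. A bin is *eligible* only when both the
sample and the control contain at least 10 informative cytosines (covered by
>= 4 reads) of the context.

Non-conversion error rates are estimated from organelle (chloroplast)
cytosines, which are biologically unmethylated: any methylated call there is a
chemistry/sequencing artifact.
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from numba import njit

from .intervals import GenomicInterval
from .io import CONTEXTS, MethylomeSample, PooledMethylation, fractional_methylation

__all__ = [
    "DMRCallingParams",
    "DMR",
    "estimate_error_rate",
    "bin_counts",
    "fisher_exact_two_sided",
    "fisher_exact_many",
    "bh_adjust",
    "call_dmrs",
    "dmr_genome_coverage",
    "dmr_size_histogram",
    "dmrs_to_frame",
    "frame_to_dmrs",
    "write_dmr_bed",
    "read_dmr_bed",
]

#: relative tolerance when comparing hypergeometric point probabilities for the
#: two-sided tail (tables "as extreme as" the observed one)
_TIE_REL_TOL = 1e-7


@dataclass(frozen=True)
class DMRCallingParams:
    """All thresholds of the DMR definition."""

    bin_size: int = 100
    fdr: float = 0.01
    min_abs_diff: Mapping[str, float] = field(
        default_factory=lambda: {"CG": 0.7, "CHG": 0.5, "CHH": 0.1}
    )
    min_informative_cytosines: int = 10  # per bin, in BOTH sample and control
    min_reads_per_cytosine: int = 4  # defines "informative"
    merge_gap: int = 100
    filter_stage: str = "pre"  # informative filter before ("pre") or after ("post") BH

    def __post_init__(self) -> None:
        if self.bin_size <= 0 or self.merge_gap < 0:
            raise ValueError("bin_size must be > 0 and merge_gap >= 0")
        if not 0 < self.fdr <= 1:
            raise ValueError("fdr must be in (0, 1]")
        for ctx, diff in self.min_abs_diff.items():
            if not 0 < diff <= 1:
                raise ValueError(f"min_abs_diff[{ctx}] must be in (0, 1]")
        if self.filter_stage not in ("pre", "post"):
            raise ValueError("filter_stage must be 'pre' or 'post'")


@dataclass(frozen=True)
class DMR:
    """A merged differentially methylated region."""

    chrom: str
    start: int
    end: int
    context: str
    direction: str  # hypo | hyper
    frac_sample: float
    frac_control: float
    n_bins: int
    sample_id: str = ""
    control_id: str = ""

    def __post_init__(self) -> None:
        if self.direction not in ("hypo", "hyper"):
            raise ValueError(f"bad direction {self.direction!r}")
        if self.context not in CONTEXTS:
            raise ValueError(f"bad context {self.context!r}")
        if self.start >= self.end:
            raise ValueError("empty DMR")

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end)

    def __len__(self) -> int:
        return self.end - self.start


# ---------------------------------------------------------------------------
# error rate
# ---------------------------------------------------------------------------


def estimate_error_rate(sample: MethylomeSample, context: str) -> float:
    """Pooled organelle methylation of `context` = apparent non-conversion rate."""
    if context not in CONTEXTS:
        raise ValueError(f"bad context {context!r}")
    org = sample.organelle_calls()
    org = org[org["context"] == context]
    total = int(org["n_total"].sum())
    if total == 0:
        raise ValueError(
            f"sample {sample.sample_id}: no covered organelle {context} cytosines; "
            "error rate undefined"
        )
    return float(org["n_meth"].sum()) / total


# ---------------------------------------------------------------------------
# binning
# ---------------------------------------------------------------------------


def _bin_one(calls: pd.DataFrame, context: str, bin_size: int, min_reads: int) -> pd.DataFrame:
    sub = calls[calls["context"] == context]
    if sub.empty:
        return pd.DataFrame(columns=["chrom", "bin", "mC", "total", "n_inf"])
    bins = sub["pos"].to_numpy(np.int64) // bin_size
    grouped = (
        pd.DataFrame(
            {
                "chrom": sub["chrom"].to_numpy(),
                "bin": bins,
                "mC": sub["n_meth"].to_numpy(np.int64),
                "total": sub["n_total"].to_numpy(np.int64),
                "inf": (sub["n_total"].to_numpy(np.int64) >= min_reads).astype(np.int64),
            }
        )
        .groupby(["chrom", "bin"], sort=False)
        .agg(mC=("mC", "sum"), total=("total", "sum"), n_inf=("inf", "sum"))
        .reset_index()
    )
    return grouped


def bin_counts(
    sample: MethylomeSample,
    control: MethylomeSample,
    params: DMRCallingParams,
    context: str,
    chrom_sizes: Mapping[str, int],
) -> pd.DataFrame:
    """Pool context counts over bins, both strands, sample vs control.

    Returns one row per bin with data in either sample (bins with no context
    cytosine carry no information and are never eligible), columns::

        chrom start end context mC_sample uC_sample mC_control uC_control
        frac_sample frac_control diff n_informative_sample
        n_informative_control eligible
    """
    if context not in CONTEXTS:
        raise ValueError(f"bad context {context!r}")
    for methylome in (sample, control):
        unknown = set(methylome.nuclear_calls()["chrom"].unique()) - set(chrom_sizes)
        if unknown:
            raise KeyError(
                f"sample {methylome.sample_id}: chromosomes {sorted(unknown)} absent "
                "from chrom_sizes"
            )
    s = _bin_one(sample.nuclear_calls(), context, params.bin_size, params.min_reads_per_cytosine)
    c = _bin_one(control.nuclear_calls(), context, params.bin_size, params.min_reads_per_cytosine)
    merged = s.merge(c, on=["chrom", "bin"], how="outer", suffixes=("_s", "_c")).fillna(0)
    for col in ("mC_s", "total_s", "n_inf_s", "mC_c", "total_c", "n_inf_c"):
        merged[col] = merged[col].astype(np.int64)

    out = pd.DataFrame(
        {
            "chrom": merged["chrom"],
            "start": merged["bin"] * params.bin_size,
            "end": (merged["bin"] + 1) * params.bin_size,
            "context": context,
            "mC_sample": merged["mC_s"],
            "uC_sample": merged["total_s"] - merged["mC_s"],
            "mC_control": merged["mC_c"],
            "uC_control": merged["total_c"] - merged["mC_c"],
            "n_informative_sample": merged["n_inf_s"],
            "n_informative_control": merged["n_inf_c"],
        }
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        out["frac_sample"] = out["mC_sample"] / (out["mC_sample"] + out["uC_sample"])
        out["frac_control"] = out["mC_control"] / (out["mC_control"] + out["uC_control"])
    out["diff"] = out["frac_sample"] - out["frac_control"]
    out["eligible"] = (out["n_informative_sample"] >= params.min_informative_cytosines) & (
        out["n_informative_control"] >= params.min_informative_cytosines
    )
    return out.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# Fisher's exact test (two-sided, point-probability rule)
# ---------------------------------------------------------------------------


@njit(cache=True)
def _log_binom(n: int, k: int) -> float:
    return (
        math.lgamma(n + 1.0) - math.lgamma(k + 1.0) - math.lgamma(n - k + 1.0)
    )


@njit(cache=True)
def _fisher_one(a: int, b: int, c: int, d: int) -> float:
    r1 = a + b
    r2 = c + d
    c1 = a + c
    n = r1 + r2
    if n == 0:
        return 1.0
    kmin = c1 - r2 if c1 - r2 > 0 else 0
    kmax = c1 if c1 < r1 else r1
    log_denom = _log_binom(n, c1)
    lp_obs = _log_binom(r1, a) + _log_binom(r2, c1 - a) - log_denom
    cutoff = lp_obs + _TIE_REL_TOL  # pmf(k) <= pmf(obs) * (1 + ~1e-7)
    total = 0.0
    for k in range(kmin, kmax + 1):
        lp = _log_binom(r1, k) + _log_binom(r2, c1 - k) - log_denom
        if lp <= cutoff:
            total += math.exp(lp)
    return total if total < 1.0 else 1.0


@njit(cache=True)
def _fisher_vec(a, b, c, d):
    out = np.empty(a.size, dtype=np.float64)
    for i in range(a.size):
        out[i] = _fisher_one(a[i], b[i], c[i], d[i])
    return out


def fisher_exact_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher's exact p for the 2x2 table [[a, b], [c, d]].

    Sums hypergeometric probabilities of every table with the observed margins
    whose point probability does not exceed the observed one (within a small
    relative tolerance for floating-point ties). An all-zero table yields 1.
    """
    for x in (a, b, c, d):
        if x < 0:
            raise ValueError("counts must be >= 0")
    return float(_fisher_one(int(a), int(b), int(c), int(d)))


def fisher_exact_many(a, b, c, d) -> np.ndarray:
    """Vectorized :func:`fisher_exact_two_sided` over count arrays."""
    a = np.ascontiguousarray(a, dtype=np.int64)
    b = np.ascontiguousarray(b, dtype=np.int64)
    c = np.ascontiguousarray(c, dtype=np.int64)
    d = np.ascontiguousarray(d, dtype=np.int64)
    if np.any(a < 0) or np.any(b < 0) or np.any(c < 0) or np.any(d < 0):
        raise ValueError("counts must be >= 0")
    return _fisher_vec(a, b, c, d)


# ---------------------------------------------------------------------------
# Benjamini-Hochberg
# ---------------------------------------------------------------------------


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Step-up BH adjusted q-values, returned in the input order."""
    p = np.asarray(p_values, dtype=np.float64)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m, dtype=np.float64)
    q[order] = q_sorted
    return q


# ---------------------------------------------------------------------------
# the caller
# ---------------------------------------------------------------------------


def call_dmrs(
    sample: MethylomeSample,
    control: MethylomeSample,
    params: DMRCallingParams,
    context: str,
    chrom_sizes: Mapping[str, int],
) -> list[DMR]:
    """Full DMR pipeline for one (sample, control, context) comparison.

    Bins are tested with the two-sided Fisher test, BH-corrected genome-wide
    over the eligible bins of the context, thresholded on FDR and the
    per-context absolute difference, split by direction, and merged when the
    gap between consecutive significant same-direction bins is at most
    ``merge_gap``. Pooled methylation levels are recomputed over each merged
    span. The result is sorted by (chrom, start).
    """
    if sample is control:
        warnings.warn("self-comparison: sample and control are the same object; no DMRs expected")
    bins = bin_counts(sample, control, params, context, chrom_sizes)
    return _dmrs_from_bins(bins, sample, control, params, context)


def _dmrs_from_bins(
    bins: pd.DataFrame,
    sample: MethylomeSample,
    control: MethylomeSample,
    params: DMRCallingParams,
    context: str,
) -> list[DMR]:
    testable = bins if params.filter_stage == "post" else bins[bins["eligible"]]
    testable = testable[(testable["mC_sample"] + testable["uC_sample"] > 0)
                        & (testable["mC_control"] + testable["uC_control"] > 0)]
    if testable.empty:
        return []
    p = fisher_exact_many(
        testable["mC_sample"].to_numpy(),
        testable["uC_sample"].to_numpy(),
        testable["mC_control"].to_numpy(),
        testable["uC_control"].to_numpy(),
    )
    q = bh_adjust(p)
    threshold = params.min_abs_diff[context]
    significant = (
        (q < params.fdr)
        & (np.abs(testable["diff"].to_numpy()) >= threshold)
        & testable["eligible"].to_numpy()  # no-op for filter_stage="pre"
    )
    hits = testable[significant].sort_values(["chrom", "start"], kind="stable")
    if hits.empty:
        return []

    pooled_sample = PooledMethylation(sample.nuclear_calls(), context)
    pooled_control = PooledMethylation(control.nuclear_calls(), context)
    dmrs: list[DMR] = []
    current: dict | None = None

    def flush() -> None:
        if current is None:
            return
        frac_s = pooled_sample.level(current["chrom"], current["start"], current["end"])
        frac_c = pooled_control.level(current["chrom"], current["start"], current["end"])
        dmrs.append(
            DMR(
                chrom=current["chrom"],
                start=int(current["start"]),
                end=int(current["end"]),
                context=context,
                direction=current["direction"],
                frac_sample=frac_s,
                frac_control=frac_c,
                n_bins=current["n_bins"],
                sample_id=sample.sample_id,
                control_id=control.sample_id,
            )
        )

    for row in hits.itertuples(index=False):
        direction = "hypo" if row.diff < 0 else "hyper"
        if (
            current is not None
            and row.chrom == current["chrom"]
            and direction == current["direction"]
            and row.start - current["end"] <= params.merge_gap
        ):
            current["end"] = row.end
            current["n_bins"] += 1
        else:
            flush()
            current = {
                "chrom": row.chrom,
                "start": row.start,
                "end": row.end,
                "direction": direction,
                "n_bins": 1,
            }
    flush()
    dmrs.sort(key=lambda d: (d.chrom, d.start))
    return dmrs


# ---------------------------------------------------------------------------
# summaries and serialization
# ---------------------------------------------------------------------------


def dmr_genome_coverage(dmrs: Sequence[DMR], genome_size: int) -> float:
    """Fraction of the genome covered by a (disjoint) DMR set."""
    if genome_size <= 0:
        raise ValueError("genome_size must be > 0")
    by_group: dict[tuple, list[DMR]] = {}
    for d in dmrs:
        by_group.setdefault((d.sample_id, d.context, d.direction, d.chrom), []).append(d)
    for group in by_group.values():
        group.sort(key=lambda d: d.start)
        for prev, nxt in zip(group, group[1:]):
            if nxt.start < prev.end:
                raise ValueError(
                    f"overlapping DMRs in one set: {prev.chrom}:{prev.start}-{prev.end} "
                    f"and {nxt.chrom}:{nxt.start}-{nxt.end}"
                )
    return sum(len(d) for d in dmrs) / genome_size


def dmr_size_histogram(dmrs: Sequence[DMR]) -> Counter:
    """Multiset of DMR sizes in bp (minimum possible size = bin size)."""
    return Counter(len(d) for d in dmrs)


_FRAME_COLUMNS = [
    "chrom",
    "start",
    "end",
    "context",
    "direction",
    "frac_sample",
    "frac_control",
    "n_bins",
    "sample_id",
    "control_id",
]


def dmrs_to_frame(dmrs: Sequence[DMR]) -> pd.DataFrame:
    return pd.DataFrame(
        [[getattr(d, col) for col in _FRAME_COLUMNS] for d in dmrs], columns=_FRAME_COLUMNS
    )


def frame_to_dmrs(frame: pd.DataFrame) -> list[DMR]:
    return [
        DMR(**{col: row[col] for col in _FRAME_COLUMNS}) for _, row in frame.iterrows()
    ]


def write_dmr_bed(dmrs: Sequence[DMR], path) -> None:
    """BED6: name = context:direction, score = round(1000 * |diff|)."""
    with open(path, "wt") as handle:
        for d in dmrs:
            diff = d.frac_sample - d.frac_control
            score = int(round(1000 * abs(diff))) if not math.isnan(diff) else 0
            handle.write(
                f"{d.chrom}\t{d.start}\t{d.end}\t{d.context}:{d.direction}\t{score}\t.\n"
            )


def read_dmr_bed(path, sample_id: str = "", control_id: str = "") -> list[DMR]:
    """Read DMRs back from BED6 (levels are not stored in BED; NaN)."""
    dmrs = []
    with open(path) as handle:
        for line in handle:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            chrom, start, end, name, _score, _strand = line.split("\t")[:6]
            context, _, direction = name.partition(":")
            dmrs.append(
                DMR(
                    chrom=chrom,
                    start=int(start),
                    end=int(end),
                    context=context,
                    direction=direction,
                    frac_sample=math.nan,
                    frac_control=math.nan,
                    n_bins=0,
                    sample_id=sample_id,
                    control_id=control_id,
                )
            )
    return dmrs
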