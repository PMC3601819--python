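"""Average scaled profiles of methylation or read coverage over interval sets.

Each region is stretched to a fixed number of windows with equal-length
flanking regions on both sides (flank length = region length, the convention
of the emulated average plots); the profile is the across-region mean of the
per-window signal. Methylation per window is the *pooled* #C/(#C+#T) over the
window's cytosines, consistent with the DMR caller; read coverage is reads
per bp. Windows with no data are excluded from that region's contribution.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .intervals import GenomicInterval
from .io import MethylomeSample

__all__ = ["ScaledProfile", "MethylationSignal", "CoverageSignal", "scaled_profile"]


class MethylationSignal:
    """Pooled methylation of one context, queryable over arbitrary windows."""

    def __init__(self, sample, context: str) -> None:
        calls = sample.calls if isinstance(sample, MethylomeSample) else sample
        sub = calls[calls["context"] == context]
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, grp in sub.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy(np.int64)
            order = np.argsort(pos, kind="stable")
            self._by_chrom[str(chrom)] = (
                pos[order],
                np.concatenate([[0], np.cumsum(grp["n_meth"].to_numpy(np.float64)[order])]),
                np.concatenate([[0], np.cumsum(grp["n_total"].to_numpy(np.float64)[order])]),
            )

    def window_value(self, chrom: str, start: float, end: float) -> float | None:
        if chrom not in self._by_chrom:
            return None
        pos, meth, total = self._by_chrom[chrom]
        lo = np.searchsorted(pos, start, side="left")
        hi = np.searchsorted(pos, end, side="left")
        denom = total[hi] - total[lo]
        if denom <= 0:
            return None
        return float((meth[hi] - meth[lo]) / denom)


class CoverageSignal:
    """Read density (reads per bp) from (chrom, start, length, count) records."""

    def __init__(self, records: pd.DataFrame) -> None:
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom, grp in records.groupby("chrom", sort=False):
            pos = grp["start"].to_numpy(np.int64)
            order = np.argsort(pos, kind="stable")
            self._by_chrom[str(chrom)] = (
                pos[order],
                np.concatenate([[0], np.cumsum(grp["count"].to_numpy(np.float64)[order])]),
            )

    def window_value(self, chrom: str, start: float, end: float) -> float | None:
        width = end - start
        if width <= 0:
            return None
        if chrom not in self._by_chrom:
            return 0.0
        pos, counts = self._by_chrom[chrom]
        lo = np.searchsorted(pos, start, side="left")
        hi = np.searchsorted(pos, end, side="left")
        return float((counts[hi] - counts[lo]) / width)


@dataclass
class ScaledProfile:
    """Mean signal per window over upstream flank, body and downstream flank."""

    n_windows_body: int
    n_windows_flank: int
    values: np.ndarray  # length 2*n_windows_flank + n_windows_body
    n_regions: np.ndarray  # contributing regions per window
    n_truncated_flanks: int = 0  # regions whose flank hit a chromosome edge

    @property
    def zones(self) -> list[str]:
        return (
            ["upstream"] * self.n_windows_flank
            + ["body"] * self.n_windows_body
            + ["downstream"] * self.n_windows_flank
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "window_index": np.arange(self.values.size),
                "zone": self.zones,
                "value": self.values,
                "n_regions": self.n_regions,
            }
        )


def scaled_profile(
    regions: Sequence[GenomicInterval],
    signal,
    n_windows_body: int = 20,
    n_windows_flank: int = 20,
    strand_aware: bool = False,
    strands: Sequence[str] | None = None,
    chrom_sizes=None,
) -> ScaledProfile:
    """Across-region mean profile with equal-length flanks.

    Each region of length L gets flanks of length L; body and each flank are
    divided into the configured number of (fractional) windows; per window the
    signal's pooled value is taken, missing windows are skipped, and the
    profile averages across regions. With ``strand_aware`` the window order of
    minus-strand regions is reversed so all regions read 5'->3'. Flanks
    truncated at a chromosome edge contribute their available span and are
    counted in ``n_truncated_flanks``.
    """
    if not regions:
        raise ValueError("regions must be non-empty")
    total = 2 * n_windows_flank + n_windows_body
    sums = np.zeros(total)
    counts = np.zeros(total, dtype=np.int64)
    truncated = 0
    for ri, region in enumerate(regions):
        L = region.end - region.start
        size = None if chrom_sizes is None else chrom_sizes.get(region.chrom)
        zones = [
            (region.start - L, region.start, n_windows_flank),
            (region.start, region.end, n_windows_body),
            (region.end, region.end + L, n_windows_flank),
        ]
        values: list[float | None] = []
        for zone_start, zone_end, n_win in zones:
            clipped_start = max(0, zone_start)
            clipped_end = zone_end if size is None else min(size, zone_end)
            if (clipped_start, clipped_end) != (zone_start, zone_end):
                truncated += 1
            if n_win == 0:
                continue
            edges = np.linspace(clipped_start, clipped_end, n_win + 1)
            for w in range(n_win):
                if edges[w + 1] <= edges[w]:
                    values.append(None)
                else:
                    values.append(signal.window_value(region.chrom, edges[w], edges[w + 1]))
        if strand_aware and strands is not None and strands[ri] == "-":
            values = values[::-1]
        for w, v in enumerate(values):
            if v is not None:
                sums[w] += v
                counts[w] += 1
    with np.errstate(invalid="ignore"):
        means = np.divide(sums, counts, out=np.full(total, np.nan), where=counts > 0)
    return ScaledProfile(
        n_windows_body=n_windows_body,
        n_windows_flank=n_windows_flank,
        values=means,
        n_regions=counts,
        n_truncated_flanks=truncated,
    )
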