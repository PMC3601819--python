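"""Light-weight genomic interval arithmetic on half-open [start, end) coordinates.

Everything here operates on plain numpy arrays grouped by chromosome; a one-bp
overlap counts as an overlap throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["GenomicInterval", "IntervalIndex", "overlaps_any"]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval [start, end), 0-based."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self.start}")
        if self.start >= self.end:
            raise ValueError(f"empty interval [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


class IntervalIndex:
    """Query structure answering "does [start, end) hit any subject interval?".

    Subjects are sorted per chromosome by start; a running maximum of the ends
    allows each query to be answered with one binary search, which keeps the
    randomization-based enrichment test cheap (tens of thousands of queries).
    """

    def __init__(self, chroms, starts, ends) -> None:
        chroms = np.asarray(chroms, dtype=object)
        starts = np.asarray(starts, dtype=np.int64)
        ends = np.asarray(ends, dtype=np.int64)
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom in pd.unique(chroms):
            mask = chroms == chrom
            s = starts[mask]
            e = ends[mask]
            order = np.argsort(s, kind="stable")
            s = s[order]
            # prefix running max of ends: cummax[i] = max(ends[:i+1])
            cummax = np.maximum.accumulate(e[order])
            self._by_chrom[str(chrom)] = (s, cummax)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "IntervalIndex":
        return cls(frame["chrom"].to_numpy(), frame["start"].to_numpy(), frame["end"].to_numpy())

    def overlaps_any(self, chrom, starts, ends) -> np.ndarray:
        """Vectorized: True where query i overlaps >=1 subject on `chrom`."""
        starts = np.atleast_1d(np.asarray(starts, dtype=np.int64))
        ends = np.atleast_1d(np.asarray(ends, dtype=np.int64))
        if chrom not in self._by_chrom:
            return np.zeros(starts.shape, dtype=bool)
        s, cummax = self._by_chrom[chrom]
        # subjects with start < query end are candidates; among those the
        # largest end decides whether any reaches past query start.
        idx = np.searchsorted(s, ends, side="left")
        out = np.zeros(starts.shape, dtype=bool)
        nonzero = idx > 0
        out[nonzero] = cummax[idx[nonzero] - 1] > starts[nonzero]
        return out

    def count_overlapping(self, frame: pd.DataFrame) -> int:
        """Number of rows of `frame` (chrom/start/end) hitting >=1 subject."""
        n = 0
        for chrom, sub in frame.groupby("chrom", sort=False, observed=True):
            n += int(
                self.overlaps_any(
                    str(chrom), sub["start"].to_numpy(), sub["end"].to_numpy()
                ).sum()
            )
        return n


def overlaps_any(queries: pd.DataFrame, subjects: pd.DataFrame) -> np.ndarray:
    """Boolean per query row: overlaps (>=1 bp) any subject interval."""
    index = IntervalIndex.from_frame(subjects)
    out = np.zeros(len(queries), dtype=bool)
    pos = np.arange(len(queries))
    for chrom, sub in queries.groupby("chrom", sort=False, observed=True):
        hits = index.overlaps_any(str(chrom), sub["start"].to_numpy(), sub["end"].to_numpy())
        out[pos[queries["chrom"].to_numpy() == chrom]] = hits
    return out
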