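"""Genomic interval sets (0-based, half-open) and interval arithmetic.

Intervals are the common currency between the scan modules: islands of
divergence, introgressed windows, ancestry tracts and planted truth sets are
all ``IntervalSet`` objects backed by a pandas DataFrame with columns
``chrom``, ``start``, ``end`` and an optional ``label``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

_COLUMNS = ["chrom", "start", "end", "label"]


@dataclass
class IntervalSet:
    """A set of half-open genomic intervals ``[start, end)``.

    Parameters
    ----------
    df : pandas.DataFrame
        Must carry ``chrom``, ``start``, ``end``; a ``label`` column is
        added (empty) if absent.  Rows with ``start >= end`` raise.
    """

    df: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=_COLUMNS))

    def __post_init__(self) -> None:
        df = self.df.copy()
        if "label" not in df.columns:
            df["label"] = ""
        df = df[_COLUMNS].reset_index(drop=True)
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        if (df["start"] >= df["end"]).any():
            bad = df[df["start"] >= df["end"]].iloc[0]
            raise ValueError(
                f"interval start >= end: {bad['chrom']}:{bad['start']}-{bad['end']}"
            )
        self.df = df.sort_values(["chrom", "start", "end"]).reset_index(drop=True)

    @classmethod
    def from_records(cls, records, label: str = "") -> "IntervalSet":
        """Build from an iterable of ``(chrom, start, end)`` tuples."""
        rows = [(c, s, e, label) for c, s, e in records]
        return cls(pd.DataFrame(rows, columns=_COLUMNS))

    def __len__(self) -> int:
        return len(self.df)

    def __iter__(self):
        for row in self.df.itertuples(index=False):
            yield (row.chrom, int(row.start), int(row.end))

    def total_bases(self) -> int:
        return int((self.df["end"] - self.df["start"]).sum())

    def merge(self, gap: int = 0) -> "IntervalSet":
        """Union of overlapping or book-ended intervals (<= ``gap`` apart)."""
        out = []
        for chrom, sub in self.df.groupby("chrom", sort=True):
            cur_s = cur_e = None
            for s, e in zip(sub["start"], sub["end"]):
                if cur_s is None:
                    cur_s, cur_e = s, e
                elif s <= cur_e + gap:
                    cur_e = max(cur_e, e)
                else:
                    out.append((chrom, cur_s, cur_e))
                    cur_s, cur_e = s, e
            if cur_s is not None:
                out.append((chrom, cur_s, cur_e))
        return IntervalSet.from_records(out)

    def intersect(self, other: "IntervalSet") -> "IntervalSet":
        """Base-level intersection of two merged interval sets."""
        a = self.merge().df
        b = other.merge().df
        out = []
        for chrom in sorted(set(a["chrom"]) & set(b["chrom"])):
            sa = a[a["chrom"] == chrom]
            sb = b[b["chrom"] == chrom]
            i = j = 0
            A = list(zip(sa["start"], sa["end"]))
            B = list(zip(sb["start"], sb["end"]))
            while i < len(A) and j < len(B):
                s = max(A[i][0], B[j][0])
                e = min(A[i][1], B[j][1])
                if s < e:
                    out.append((chrom, s, e))
                if A[i][1] <= B[j][1]:
                    i += 1
                else:
                    j += 1
        return IntervalSet.from_records(out)

    def coverage_mask(self, chrom: str, length: int) -> np.ndarray:
        """Boolean per-base occupancy vector for one chromosome."""
        mask = np.zeros(length, dtype=bool)
        sub = self.df[self.df["chrom"] == chrom]
        for s, e in zip(sub["start"], sub["end"]):
            mask[max(0, s) : min(length, e)] = True
        return mask

    def overlap_bases(self, other: "IntervalSet") -> int:
        return self.intersect(other).total_bases()

    # -- I/O -------------------------------------------------------------
    def to_bed(self, path) -> None:
        with open(path, "w") as fh:
            for row in self.df.itertuples(index=False):
                name = row.label if row.label else "."
                fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{name}\n")

    @classmethod
    def read_bed(cls, path) -> "IntervalSet":
        path = Path(path)
        rows = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t")
                label = parts[3] if len(parts) > 3 and parts[3] != "." else ""
                rows.append((parts[0], int(parts[1]), int(parts[2]), label))
        return cls(pd.DataFrame(rows, columns=_COLUMNS))


def merge_intervals(iset: IntervalSet) -> IntervalSet:
    """Union of overlapping or book-ended intervals; sorted output."""
    return iset.merge()
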