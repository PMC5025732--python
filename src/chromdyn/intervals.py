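"""Core genomic coordinate types.

All coordinates are 0-based half-open throughout the package; 1-based
inclusive dialects (GTF/GFF) are converted at the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterator, Mapping

import pandas as pd

STRANDS = ("+", "-", ".")

#: column layout of a read table (one row per mapped read)
READ_COLUMNS = ["chrom", "start", "end", "strand"]


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open interval [start, end) on a named chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "need 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"unknown strand symbol {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlap_len(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


class ChromSizes(Mapping[str, int]):
    """Chromosome name -> length table; the validation surface for all input."""

    def __init__(self, sizes: Dict[str, int]):
        for name, length in sizes.items():
            if length <= 0:
                raise ValueError(f"chromosome {name} has non-positive length")
        self._sizes = dict(sizes)

    def __getitem__(self, name: str) -> int:
        return self._sizes[name]

    def __iter__(self) -> Iterator[str]:
        return iter(self._sizes)

    def __len__(self) -> int:
        return len(self._sizes)

    def validate_interval(self, iv: GenomicInterval) -> None:
        if iv.chrom not in self._sizes:
            raise KeyError(f"unknown chromosome {iv.chrom!r}")
        if iv.end > self._sizes[iv.chrom]:
            raise ValueError(
                f"interval {iv.chrom}:{iv.start}-{iv.end} exceeds chromosome "
                f"length {self._sizes[iv.chrom]}"
            )

    @classmethod
    def from_tsv(cls, path) -> "ChromSizes":
        df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"],
                         dtype={"chrom": str, "length": int})
        return cls(dict(zip(df["chrom"], df["length"])))

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for name, length in self._sizes.items():
                fh.write(f"{name}\t{length}\n")


def validate_reads(reads: pd.DataFrame, sizes: ChromSizes | None = None) -> None:
    """Check read-table invariants: positive length, known strand, in bounds."""
    missing = [c for c in READ_COLUMNS if c not in reads.columns]
    if missing:
        raise ValueError(f"read table missing columns {missing}")
    if len(reads) == 0:
        return
    if (reads["start"] < 0).any():
        raise ValueError("read with negative start")
    if (reads["end"] <= reads["start"]).any():
        raise ValueError("read with start >= end")
    bad = ~reads["strand"].isin(("+", "-"))
    if bad.any():
        sym = reads.loc[bad, "strand"].iloc[0]
        raise ValueError(f"unknown strand symbol {sym!r} in read table")
    if sizes is not None:
        for chrom, sub in reads.groupby("chrom", observed=True):
            if chrom not in sizes:
                raise KeyError(f"unknown chromosome {chrom!r} in read table")
            if (sub["end"] > sizes[chrom]).any():
                raise ValueError(f"read beyond end of chromosome {chrom}")
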