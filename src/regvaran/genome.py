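"""Genome model: chromosome sizes and excluded (unusable) intervals.

Coordinates are 0-based half-open throughout the package. Excluded
intervals typically model centromeres and telomeres, where random
control regions must not be placed and which are ignored when
computing genome coverage of usable space.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable


@dataclass
class GenomeModel:
    """Chromosome name -> length (bp) plus excluded half-open intervals."""

    lengths: dict[str, int]
    excluded: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for chrom, length in self.lengths.items():
            if length <= 0:
                raise ValueError(f"chromosome {chrom!r} has non-positive length {length}")
        for chrom, ivs in self.excluded.items():
            if chrom not in self.lengths:
                raise ValueError(f"excluded interval on unknown chromosome {chrom!r}")
            for start, end in ivs:
                if not (0 <= start < end <= self.lengths[chrom]):
                    raise ValueError(
                        f"excluded interval ({start},{end}) outside {chrom} "
                        f"(length {self.lengths[chrom]})"
                    )

    @property
    def chromosomes(self) -> list[str]:
        return list(self.lengths)

    @property
    def total_length(self) -> int:
        return sum(self.lengths.values())

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.lengths

    def usable_intervals(self, chrom: str) -> list[tuple[int, int]]:
        """Complement of the excluded intervals on one chromosome."""
        length = self.lengths[chrom]
        ivs = sorted(self.excluded.get(chrom, []))
        out: list[tuple[int, int]] = []
        cursor = 0
        for start, end in ivs:
            if start > cursor:
                out.append((cursor, start))
            cursor = max(cursor, end)
        if cursor < length:
            out.append((cursor, length))
        return out

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("chrom\tlength\n")
            for chrom, length in self.lengths.items():
                fh.write(f"{chrom}\t{length}\n")

    @classmethod
    def from_tsv(cls, path: str | Path, exclude_bed: str | Path | None = None) -> "GenomeModel":
        lengths: dict[str, int] = {}
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("chrom"):  # headerless two-column file
                chrom, length = header.split()[:2]
                lengths[chrom] = int(length)
            for line in fh:
                if not line.strip():
                    continue
                chrom, length = line.split()[:2]
                lengths[chrom] = int(length)
        excluded: dict[str, list[tuple[int, int]]] = {}
        if exclude_bed is not None:
            for chrom, start, end in read_bed3(exclude_bed):
                excluded.setdefault(chrom, []).append((start, end))
        return cls(lengths, excluded)


def read_bed3(path: str | Path) -> Iterable[tuple[str, int, int]]:
    """Yield (chrom, start, end) from a BED3+ file, skipping headers."""
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            yield parts[0], int(parts[1]), int(parts[2])


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping/adjacent half-open intervals into a minimal sorted set."""
    ivs = sorted(intervals)
    out: list[tuple[int, int]] = []
    for start, end in ivs:
        if out and start <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], end))
        else:
            out.append((start, end))
    return out


def covered_bases(intervals: Iterable[tuple[int, int]]) -> int:
    return sum(end - start for start, end in merge_intervals(intervals))
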