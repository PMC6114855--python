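"""Fixed-width genome windows and per-window read coverage.

The analysis resolution is a tiling of each chromosome into fixed-width
windows (100 bp by default).  Reads are assigned to exactly one window --
the one containing the read midpoint -- so per-window counts stay integral,
as required by the exact count test downstream.  Coordinates are 0-based
half-open internally; 1-based starts appear only in human-readable reports.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "WindowGrid",
    "WindowCountMatrix",
    "RpkmMatrix",
    "make_windows",
    "count_reads",
    "rpkm",
    "read_bed_intervals",
]


@dataclass(frozen=True)
class WindowGrid:
    """Tiling of chromosomes into fixed-width windows.

    Windows tile each chromosome without gaps or overlap; the terminal
    window of a chromosome may be shorter than ``window_bp`` and is
    retained (its true length is used wherever a length enters a
    normalisation).
    """

    chrom_lengths: dict[str, int]
    window_bp: int
    chroms: np.ndarray = field(repr=False)
    starts: np.ndarray = field(repr=False)
    ends: np.ndarray = field(repr=False)

    @property
    def n_windows(self) -> int:
        return len(self.starts)

    def lengths(self) -> np.ndarray:
        return self.ends - self.starts

    def chrom_offset(self, chrom: str) -> int:
        """Index of the first window of *chrom* in the global ordering."""
        off = 0
        for c in sorted(self.chrom_lengths):
            if c == chrom:
                return off
            off += -(-self.chrom_lengths[c] // self.window_bp)
        raise KeyError(chrom)

    def window_index(self, chrom: str, pos: int) -> int:
        """Global index of the window containing base *pos* (0-based)."""
        if chrom not in self.chrom_lengths:
            raise KeyError(f"unknown chromosome: {chrom!r}")
        if not 0 <= pos < self.chrom_lengths[chrom]:
            raise ValueError(f"position {pos} outside {chrom}")
        return self.chrom_offset(chrom) + pos // self.window_bp

    def to_bed3(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"chrom": self.chroms, "start": self.starts, "end": self.ends}
        )


@dataclass
class WindowCountMatrix:
    """Integer read counts over grid windows x samples."""

    grid: WindowGrid
    counts: np.ndarray  # (n_windows, n_samples) non-negative ints
    sample_ids: list[str]
    library_sizes: dict[str, int]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (self.grid.n_windows, len(self.sample_ids)):
            raise ValueError("counts shape does not match grid/samples")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    def library_size_vector(self) -> np.ndarray:
        return np.array([self.library_sizes[s] for s in self.sample_ids], dtype=float)

    def to_tsv(self, path) -> None:
        df = self.grid.to_bed3()
        for j, s in enumerate(self.sample_ids):
            df[s] = self.counts[:, j]
        with open(path, "w") as fh:
            fh.write(
                "#library_sizes\t"
                + "\t".join(f"{s}={self.library_sizes[s]}" for s in self.sample_ids)
                + "\n"
            )
            df.to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "WindowCountMatrix":
        with open(path) as fh:
            first = fh.readline()
            if not first.startswith("#library_sizes"):
                raise ValueError("missing #library_sizes header line")
            lib = {}
            for tok in first.strip().split("\t")[1:]:
                k, v = tok.split("=")
                lib[k] = int(v)
            df = pd.read_csv(fh, sep="\t")
        sample_ids = [c for c in df.columns if c not in ("chrom", "start", "end")]
        chrom_lengths = df.groupby("chrom")["end"].max().to_dict()
        window_bp = int((df["end"] - df["start"]).max())
        grid = make_windows(chrom_lengths, window_bp)
        counts = df[sample_ids].to_numpy(dtype=np.int64)
        return cls(grid, counts, sample_ids, {s: lib[s] for s in sample_ids})


@dataclass
class RpkmMatrix:
    """Reads per kilobase of window per million mapped reads."""

    grid: WindowGrid
    values: np.ndarray
    sample_ids: list[str]


def make_windows(chrom_lengths: Mapping[str, int], window_bp: int = 100) -> WindowGrid:
    """Tile chromosomes into windows of ``window_bp`` (terminal remainder kept).

    Windows are ordered by chromosome name (lexicographic) then start.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    chroms: list[str] = []
    starts: list[np.ndarray] = []
    ends: list[np.ndarray] = []
    for chrom in sorted(chrom_lengths):
        L = int(chrom_lengths[chrom])
        if L <= 0:
            raise ValueError(f"chromosome {chrom!r} has non-positive length {L}")
        s = np.arange(0, L, window_bp, dtype=np.int64)
        e = np.minimum(s + window_bp, L)
        chroms.extend([chrom] * len(s))
        starts.append(s)
        ends.append(e)
    return WindowGrid(
        chrom_lengths=dict(chrom_lengths),
        window_bp=int(window_bp),
        chroms=np.array(chroms, dtype=object),
        starts=np.concatenate(starts),
        ends=np.concatenate(ends),
    )


def count_reads(
    alignments: Mapping[str, Iterable[tuple[str, int, int]]],
    grid: WindowGrid,
) -> WindowCountMatrix:
    """Count reads per window for each sample.

    Each read is assigned to the single window containing its midpoint
    ``(start + end) // 2``.  Reads are unstranded (MeDIP fragments carry no
    strand information for coverage purposes).  The per-sample library size
    is the number of reads counted.
    """
    sample_ids = list(alignments)
    counts = np.zeros((grid.n_windows, len(sample_ids)), dtype=np.int64)
    library_sizes: dict[str, int] = {}
    offsets = {c: grid.chrom_offset(c) for c in grid.chrom_lengths}
    for j, sample in enumerate(sample_ids):
        n = 0
        idx: list[int] = []
        for rec in alignments[sample]:
            chrom, start, end = rec[0], int(rec[1]), int(rec[2])
            if chrom not in offsets:
                raise ValueError(
                    f"read {chrom}:{start}-{end} (sample {sample}): unknown chromosome"
                )
            mid = (start + end) // 2
            if not 0 <= mid < grid.chrom_lengths[chrom]:
                raise ValueError(
                    f"read {chrom}:{start}-{end} (sample {sample}): midpoint off chromosome"
                )
            idx.append(offsets[chrom] + mid // grid.window_bp)
            n += 1
        if idx:
            np.add.at(counts[:, j], np.asarray(idx), 1)
        library_sizes[sample] = n
    return WindowCountMatrix(grid, counts, sample_ids, library_sizes)


def rpkm(matrix: WindowCountMatrix) -> RpkmMatrix:
    """RPKM per window: count / (window_kb * library_size / 1e6)."""
    lib = matrix.library_size_vector()
    if np.any(lib <= 0):
        bad = [s for s, l in zip(matrix.sample_ids, lib) if l <= 0]
        raise ValueError(f"non-positive library size for samples: {bad}")
    len_kb = matrix.grid.lengths() / 1000.0
    values = matrix.counts / (len_kb[:, None] * (lib[None, :] / 1e6))
    return RpkmMatrix(matrix.grid, values, list(matrix.sample_ids))


def read_bed_intervals(path) -> list[tuple[str, int, int]]:
    """Read a BED3+ file as (chrom, start, end) tuples (0-based half-open)."""
    out: list[tuple[str, int, int]] = []
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{i}: fewer than 3 BED fields")
            out.append((parts[0], int(parts[1]), int(parts[2])))
    return out
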