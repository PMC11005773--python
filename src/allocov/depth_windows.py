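"""Windowed median read-depth tracks over a concatenated reference pair.

Reads aligned competitively to two concatenated subgenome references are
filtered to uniquely mapped, properly paired, non-duplicate primary records,
then summarized as the median per-position depth in fixed-size windows
(default 100 kb).  The median — rather than the mean — is used because
repetitive regions produce depth spikes that would distort a mean but leave
the median of 100 000 positions essentially untouched.  Zero-coverage
positions are included in the median so that absent/deleted regions score 0
instead of being skipped.

Coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
import pysam

DEFAULT_WINDOW_SIZE = 100_000

DEPTH_COLUMNS = [
    "track_id",
    "reference_id",
    "chrom",
    "start",
    "end",
    "median_depth",
]


@dataclass(frozen=True)
class WindowGrid:
    """Fixed-size tiling windows over one reference's chromosomes.

    Windows are non-overlapping, 0-based half-open, with the last window of
    each chromosome truncated at the chromosome length.
    """

    reference_id: str
    chrom_lengths: dict[str, int] = field(default_factory=dict)
    window_size: int = DEFAULT_WINDOW_SIZE

    def __post_init__(self):
        if self.window_size <= 0:
            raise ValueError("window_size must be positive")
        for chrom, length in self.chrom_lengths.items():
            if length <= 0:
                raise ValueError(f"non-positive length for chromosome {chrom}")

    @classmethod
    def from_fai(cls, path: str | Path, reference_id: str,
                 window_size: int = DEFAULT_WINDOW_SIZE) -> "WindowGrid":
        fai = pd.read_csv(path, sep="\t", header=None, usecols=[0, 1],
                          names=["chrom", "length"])
        return cls(reference_id, dict(zip(fai["chrom"], fai["length"])), window_size)

    def n_windows(self, chrom: str) -> int:
        length = self.chrom_lengths[chrom]
        return -(-length // self.window_size)

    def windows(self, chrom: str) -> Iterator[tuple[int, int]]:
        length = self.chrom_lengths[chrom]
        for start in range(0, length, self.window_size):
            yield start, min(start + self.window_size, length)

    def window_index(self, chrom: str, pos: int) -> int:
        if not 0 <= pos < self.chrom_lengths[chrom]:
            raise ValueError(f"position {pos} outside chromosome {chrom}")
        return pos // self.window_size

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"reference_id": self.reference_id, "chrom": c, "start": s, "end": e}
            for c in self.chrom_lengths
            for s, e in self.windows(c)
        ]
        return pd.DataFrame(rows)


def filter_alignments(bam: pysam.AlignmentFile) -> Iterator[pysam.AlignedSegment]:
    """Yield only uniquely mapped, properly paired, primary, non-duplicate reads.

    Uniqueness follows the bwa convention: records carrying an XA (alternative
    hits) or SA (supplementary/chimeric) tag are discarded.
    """
    for read in bam.fetch(until_eof=True):
        if read.is_unmapped or read.is_secondary or read.is_supplementary:
            continue
        if read.is_duplicate or not read.is_proper_pair:
            continue
        if read.has_tag("XA") or read.has_tag("SA"):
            continue
        yield read


def _per_base_from_reads(
    reads: Iterable[pysam.AlignedSegment], chrom_lengths: dict[str, int]
) -> dict[str, np.ndarray]:
    """Per-position depth from read start..end spans (CIGAR deletions ignored;
    negligible at 100-kb window scale)."""
    deltas = {c: np.zeros(n + 1, dtype=np.int64) for c, n in chrom_lengths.items()}
    for read in reads:
        chrom = read.reference_name
        if chrom not in deltas:
            raise ValueError(f"chromosome {chrom} absent from grid")
        start = max(read.reference_start, 0)
        end = min(read.reference_end, chrom_lengths[chrom])
        if end > start:
            deltas[chrom][start] += 1
            deltas[chrom][end] -= 1
    return {c: np.cumsum(d[:-1]) for c, d in deltas.items()}


def _per_base_from_bedgraph(
    bedgraph: pd.DataFrame | str | Path, chrom_lengths: dict[str, int]
) -> dict[str, np.ndarray]:
    """Expand (chrom, start, end, depth) intervals to per-position arrays.

    Positions not covered by any interval get depth 0 (bedtools -bga output
    is explicit about zero runs; plain -bg output is not, and the zeros are
    filled in here either way).
    """
    if not isinstance(bedgraph, pd.DataFrame):
        bedgraph = pd.read_csv(
            bedgraph, sep="\t", header=None,
            names=["chrom", "start", "end", "depth"], comment="#",
        )
    depth = {c: np.zeros(n, dtype=float) for c, n in chrom_lengths.items()}
    for rec in bedgraph.itertuples(index=False):
        if rec.chrom not in depth:
            raise ValueError(f"chromosome {rec.chrom} absent from grid")
        depth[rec.chrom][rec.start : rec.end] = rec.depth
    return depth


def _medians_on_grid(
    per_base: dict[str, np.ndarray], grid: WindowGrid, track_id: str
) -> pd.DataFrame:
    rows = []
    for chrom in grid.chrom_lengths:
        arr = per_base.get(chrom)
        if arr is None:
            arr = np.zeros(grid.chrom_lengths[chrom])
        for start, end in grid.windows(chrom):
            rows.append(
                {
                    "track_id": track_id,
                    "reference_id": grid.reference_id,
                    "chrom": chrom,
                    "start": start,
                    "end": end,
                    "median_depth": float(np.median(arr[start:end])),
                }
            )
    return pd.DataFrame(rows, columns=DEPTH_COLUMNS)


def window_median_depth_from_bam(
    path: str | Path, grid: WindowGrid, track_id: str
) -> pd.DataFrame:
    """Filtered per-base depth from a BAM/SAM, summarized as window medians."""
    path = str(path)
    mode = "r" if path.endswith(".sam") else "rb"
    with pysam.AlignmentFile(path, mode) as bam:
        per_base = _per_base_from_reads(filter_alignments(bam), grid.chrom_lengths)
    return _medians_on_grid(per_base, grid, track_id)


def window_median_depth_from_bedgraph(
    bedgraph: pd.DataFrame | str | Path, grid: WindowGrid, track_id: str
) -> pd.DataFrame:
    """Window medians from a pre-computed per-base BEDGraph depth track."""
    per_base = _per_base_from_bedgraph(bedgraph, grid.chrom_lengths)
    return _medians_on_grid(per_base, grid, track_id)


def pool_tracks(tracks: Sequence[pd.DataFrame], pool_id: str) -> pd.DataFrame:
    """Window-wise sum of depth tracks sharing one grid.

    On the window-depth scale this is the pooled-sample equivalent of merging
    the underlying BAM files before computing depth.
    """
    if not tracks:
        raise ValueError("no tracks to pool")
    key = ["reference_id", "chrom", "start", "end"]
    base = tracks[0][key].reset_index(drop=True)
    total = np.zeros(len(base))
    for t in tracks:
        t = t.sort_values(["reference_id", "chrom", "start"]).reset_index(drop=True)
        ref = base.sort_values(["reference_id", "chrom", "start"]).reset_index(drop=True)
        if len(t) != len(base) or not t[key].equals(ref[key]):
            raise ValueError("depth tracks have mismatched window grids")
        total = total + t["median_depth"].to_numpy()
    out = base.sort_values(["reference_id", "chrom", "start"]).reset_index(drop=True)
    out.insert(0, "track_id", pool_id)
    out["median_depth"] = total
    return out[DEPTH_COLUMNS]


def write_depth(track: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# windowed median depth; coordinates 0-based half-open\n")
        track.to_csv(fh, sep="\t", index=False)


def read_depth(path: str | Path) -> pd.DataFrame:
    track = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in DEPTH_COLUMNS if c not in track.columns]
    if missing:
        raise ValueError(f"depth TSV {path} missing columns: {missing}")
    return track
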