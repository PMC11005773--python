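"""Window pairing between two references from a whole-genome alignment.

Depth can only be compared between subgenomes over regions that are actually
homologous, so each fixed-size window of one reference is assigned the window
of the other reference with which it shares the most aligned bases, according
to a whole-genome alignment in PAF format (e.g. minimap2 -x asm10 output).
Windows whose best partner accounts for less than a minimum fraction of the
window (default 20 %) are marked unmapped and excluded downstream.  The map
is produced in both directions because chromosome lengths and conserved
content differ between the references.

Within each PAF block, query and target coordinates are assumed collinear
base-for-base (block-internal indels are ignored; at 100-kb window scale the
resulting assignment error is negligible).  Strand is ignored for pairing
since depth is strand-symmetric.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .depth_windows import WindowGrid

PAF_COLUMNS = [
    "query_name", "query_length", "query_start", "query_end", "strand",
    "target_name", "target_length", "target_start", "target_end",
    "matches", "block_length", "mapq",
]

MAP_COLUMNS = [
    "direction",
    "ref1_chrom", "ref1_start", "ref1_end",
    "ref2_chrom", "ref2_start", "ref2_end",
    "aligned_bases",
]

DEFAULT_MIN_FRACTION = 0.2


def parse_paf(path: str | Path) -> pd.DataFrame:
    """Parse the 12 mandatory PAF columns; optional tags are dropped."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 12:
                raise ValueError(
                    f"malformed PAF line {lineno} in {path}: "
                    f"{len(parts)} fields (12 required)"
                )
            try:
                rows.append(
                    {
                        "query_name": parts[0],
                        "query_length": int(parts[1]),
                        "query_start": int(parts[2]),
                        "query_end": int(parts[3]),
                        "strand": parts[4],
                        "target_name": parts[5],
                        "target_length": int(parts[6]),
                        "target_start": int(parts[7]),
                        "target_end": int(parts[8]),
                        "matches": int(parts[9]),
                        "block_length": int(parts[10]),
                        "mapq": int(parts[11]),
                    }
                )
            except ValueError as exc:
                raise ValueError(
                    f"malformed PAF line {lineno} in {path}: {exc}"
                ) from exc
    return pd.DataFrame(rows, columns=PAF_COLUMNS)


def _accumulate(
    blocks: pd.DataFrame,
    src_grid: WindowGrid,
    dst_grid: WindowGrid,
    src_is_query: bool,
) -> dict[tuple, dict[tuple, int]]:
    """aligned-base tally: source window -> {destination window: bases}."""
    votes: dict[tuple, dict[tuple, int]] = {}
    for blk in blocks.itertuples(index=False):
        if src_is_query:
            s_chrom, s0, s1 = blk.query_name, blk.query_start, blk.query_end
            d_chrom, d0, d1 = blk.target_name, blk.target_start, blk.target_end
        else:
            s_chrom, s0, s1 = blk.target_name, blk.target_start, blk.target_end
            d_chrom, d0, d1 = blk.query_name, blk.query_start, blk.query_end
        if s_chrom not in src_grid.chrom_lengths or d_chrom not in dst_grid.chrom_lengths:
            continue
        reverse = blk.strand == "-"
        ws = src_grid.window_size
        first = (s0 // ws) * ws
        for wstart in range(first, s1, ws):
            ov0, ov1 = max(wstart, s0), min(wstart + ws, s1)
            if ov1 <= ov0:
                continue
            # collinear mapping of the overlapping source slice onto the target
            if not reverse:
                t0 = d0 + (ov0 - s0)
                t1 = d0 + (ov1 - s0)
            else:
                t1 = d1 - (ov0 - s0)
                t0 = d1 - (ov1 - s0)
            src_key = (s_chrom, wstart)
            dst_ws = dst_grid.window_size
            dfirst = (t0 // dst_ws) * dst_ws
            for dstart in range(dfirst, t1, dst_ws):
                bases = min(dstart + dst_ws, t1) - max(dstart, t0)
                if bases <= 0:
                    continue
                votes.setdefault(src_key, {}).setdefault((d_chrom, dstart), 0)
                votes[src_key][(d_chrom, dstart)] += bases
    return votes


def _direction_frame(
    votes: dict,
    src_grid: WindowGrid,
    dst_grid: WindowGrid,
    direction: str,
    min_fraction: float,
) -> pd.DataFrame:
    rows = []
    for chrom in src_grid.chrom_lengths:
        for start, end in src_grid.windows(chrom):
            candidates = votes.get((chrom, start), {})
            row = {
                "direction": direction,
                "ref1_chrom": chrom, "ref1_start": start, "ref1_end": end,
                "ref2_chrom": None, "ref2_start": np.nan, "ref2_end": np.nan,
                "aligned_bases": 0,
            }
            if candidates:
                # majority overlap; ties broken toward the smaller start
                best = max(
                    sorted(candidates, key=lambda k: (k[0], k[1])),
                    key=lambda k: candidates[k],
                )
                if candidates[best] >= min_fraction * (end - start):
                    d_chrom, d_start = best
                    d_end = min(d_start + dst_grid.window_size,
                                dst_grid.chrom_lengths[d_chrom])
                    row.update(
                        ref2_chrom=d_chrom, ref2_start=d_start, ref2_end=d_end,
                        aligned_bases=candidates[best],
                    )
            rows.append(row)
    return pd.DataFrame(rows, columns=MAP_COLUMNS)


def build_window_map(
    blocks: pd.DataFrame,
    grid1: WindowGrid,
    grid2: WindowGrid,
    min_fraction: float = DEFAULT_MIN_FRACTION,
) -> pd.DataFrame:
    """Assign each window its majority-overlap partner, in both directions.

    The PAF query side is taken to be ``grid1``'s reference and the target
    side ``grid2``'s.  In the returned frame, ``ref1_*`` columns always hold
    the source window of the row's direction and ``ref2_*`` the assigned
    partner (NaN when unmapped).
    """
    if not 0 <= min_fraction <= 1:
        raise ValueError("min_fraction must be in [0, 1]")
    fwd = _direction_frame(
        _accumulate(blocks, grid1, grid2, src_is_query=True),
        grid1, grid2, f"{grid1.reference_id}->{grid2.reference_id}", min_fraction,
    )
    rev = _direction_frame(
        _accumulate(blocks, grid2, grid1, src_is_query=False),
        grid2, grid1, f"{grid2.reference_id}->{grid1.reference_id}", min_fraction,
    )
    return pd.concat([fwd, rev], ignore_index=True)


def write_window_map(wmap: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# window homology map; coordinates 0-based half-open; "
                 "ref1 = source window of the row's direction\n")
        wmap.to_csv(fh, sep="\t", index=False)


def read_window_map(path: str | Path) -> pd.DataFrame:
    wmap = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in MAP_COLUMNS if c not in wmap.columns]
    if missing:
        raise ValueError(f"window map TSV {path} missing columns: {missing}")
    return wmap
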