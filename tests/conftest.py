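import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


def sam_line(qname, flag, chrom, pos0, length=100, tags=(), cigar=None, mapq=60):
    """One SAM record; pos0 is 0-based (converted to SAM's 1-based)."""
    if flag & 0x4:
        chrom, pos1, cigar, mapq = "*", 0, "*", 0
        seq = "A" * length
    else:
        pos1 = pos0 + 1
        cigar = cigar or f"{length}M"
        seq = "A" * length
    fields = [qname, str(flag), chrom, str(pos1), str(mapq), cigar,
              "*", "0", "0", seq, "*"]
    fields.extend(tags)
    return "\t".join(fields)


def write_sam(path, chrom_lengths, lines):
    header = ["@HD\tVN:1.6\tSO:unsorted"]
    header += [f"@SQ\tSN:{c}\tLN:{n}" for c, n in chrom_lengths.items()]
    path.write_text("\n".join(header + list(lines)) + "\n")
    return str(path)


def identity_window_map(chrom_lengths, window_size, ref1="A", ref2="B",
                        unmapped=()):
    """Identity map between two same-layout references; ``unmapped`` is a set
    of (chrom, start) windows left unpaired in both directions."""
    rows = []
    for direction in (f"{ref1}->{ref2}", f"{ref2}->{ref1}"):
        for chrom, length in chrom_lengths.items():
            for start in range(0, length, window_size):
                end = min(start + window_size, length)
                keep = (chrom, start) not in unmapped
                rows.append({
                    "direction": direction,
                    "ref1_chrom": chrom, "ref1_start": start, "ref1_end": end,
                    "ref2_chrom": chrom if keep else None,
                    "ref2_start": start if keep else np.nan,
                    "ref2_end": end if keep else np.nan,
                    "aligned_bases": end - start if keep else 0,
                })
    return pd.DataFrame(rows)


def depth_track(chrom_lengths, window_size, depth_fn, track_id="t", ref="A"):
    """Depth track with median_depth = depth_fn(chrom, start)."""
    rows = []
    for chrom, length in chrom_lengths.items():
        for start in range(0, length, window_size):
            rows.append({
                "track_id": track_id, "reference_id": ref, "chrom": chrom,
                "start": start, "end": min(start + window_size, length),
                "median_depth": float(depth_fn(chrom, start)),
            })
    return pd.DataFrame(rows)


@pytest.fixture
def two_chrom_lengths():
    return {"chr1": 300_000, "chr2": 250_000}
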