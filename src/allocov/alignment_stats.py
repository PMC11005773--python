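"""Per-sample alignment summary statistics against one or more references.

The central table records, for each (sample, reference, scope) triple, the
number of primary records and the number of properly paired records, plus the
derived percentage of properly paired reads (``pp_percent``).  Scope is either
the whole genome (:data:`GENOME_SCOPE`) or a single chromosome name.  These
percentages are the raw material that the RAA normalization in
:mod:`allocov.raa` operates on.

Counting semantics follow samtools-flagstat "primary" semantics: secondary
and supplementary alignment records are excluded from both the totals and the
properly-paired counts.  Reads on unplaced scaffolds (or unmapped reads) are
counted in the genome scope only.
"""

from __future__ import annotations

import re
import warnings
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import pysam

GENOME_SCOPE = "genome"

#: canonical column order of an AlignmentStatsTable
STATS_COLUMNS = [
    "sample_id",
    "reference_id",
    "scope",
    "total_reads",
    "properly_paired",
    "pp_percent",
]

#: internal precision of pp_percent (the field convention is to print 1 dp;
#: rounding to presentation precision happens only at plot/report time)
PP_DECIMALS = 4

_HEADER_NOTE = (
    "# total_reads and properly_paired count primary records only "
    "(secondary/supplementary excluded); unplaced reads counted in genome scope only; "
    "coordinates elsewhere in this toolkit are 0-based half-open"
)


def pp_percent(properly_paired: int, total_reads: int) -> float:
    """Percentage of properly paired reads, 0.0 for an empty denominator."""
    if total_reads <= 0:
        return 0.0
    return round(100.0 * properly_paired / total_reads, PP_DECIMALS)


def make_stats_row(
    sample_id: str,
    reference_id: str,
    scope: str,
    total_reads: int,
    properly_paired: int,
) -> dict:
    if properly_paired > total_reads:
        raise ValueError(
            f"properly_paired ({properly_paired}) exceeds total_reads "
            f"({total_reads}) for {sample_id}/{reference_id}/{scope}"
        )
    if total_reads == 0:
        warnings.warn(
            f"zero total reads for {sample_id}/{reference_id}/{scope}; "
            "pp_percent defined as 0",
            stacklevel=2,
        )
    return {
        "sample_id": sample_id,
        "reference_id": reference_id,
        "scope": scope,
        "total_reads": int(total_reads),
        "properly_paired": int(properly_paired),
        "pp_percent": pp_percent(properly_paired, total_reads),
    }


def validate_stats(table: pd.DataFrame) -> pd.DataFrame:
    """Check AlignmentStatsTable invariants; return the table unchanged.

    Raises ``ValueError`` on missing columns, duplicate (sample, reference,
    scope) keys, counts out of order, percentages out of [0, 100], or a
    pp_percent inconsistent with its counts (beyond 4-dp rounding).
    """
    missing = [c for c in STATS_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"stats table missing columns: {missing}")
    key = ["sample_id", "reference_id", "scope"]
    dup = table.duplicated(subset=key)
    if dup.any():
        first = table.loc[dup, key].iloc[0].tolist()
        raise ValueError(f"duplicate (sample, reference, scope) key: {first}")
    if (table["properly_paired"] > table["total_reads"]).any():
        raise ValueError("properly_paired exceeds total_reads in some rows")
    if ((table["pp_percent"] < 0) | (table["pp_percent"] > 100)).any():
        raise ValueError("pp_percent outside [0, 100]")
    recomputed = [
        pp_percent(p, t)
        for p, t in zip(table["properly_paired"], table["total_reads"])
    ]
    bad = (table["pp_percent"] - pd.Series(recomputed, index=table.index)).abs() > 1e-3
    if bad.any():
        row = table.loc[bad].iloc[0]
        raise ValueError(
            "pp_percent inconsistent with counts for "
            f"{row['sample_id']}/{row['reference_id']}/{row['scope']}: "
            f"stored {row['pp_percent']}, counts give "
            f"{pp_percent(row['properly_paired'], row['total_reads'])}"
        )
    return table


def concat_stats(tables: Iterable[pd.DataFrame]) -> pd.DataFrame:
    """Concatenate stats tables, enforcing key uniqueness across them."""
    out = pd.concat(list(tables), ignore_index=True)
    return validate_stats(out)


_FLAGSTAT_PRIMARY = re.compile(r"^(\d+) \+ (\d+) primary$")
_FLAGSTAT_TOTAL = re.compile(r"^(\d+) \+ (\d+) in total")
_FLAGSTAT_PP = re.compile(r"^(\d+) \+ (\d+) properly paired")


def parse_flagstat(text: str, sample_id: str, reference_id: str) -> pd.DataFrame:
    """Parse a samtools-flagstat text report into a one-row genome-scope table.

    Uses the "primary" line for the denominator when present (samtools >= 1.13
    reports it), otherwise the "in total" line.  QC-failed counts (the second
    number of each line) are ignored.
    """
    total = primary = properly = None
    for line in text.splitlines():
        line = line.strip()
        if m := _FLAGSTAT_PRIMARY.match(line):
            primary = int(m.group(1))
        elif m := _FLAGSTAT_TOTAL.match(line):
            total = int(m.group(1))
        elif m := _FLAGSTAT_PP.match(line):
            properly = int(m.group(1))
    if total is None and primary is None:
        raise ValueError("flagstat parse error: no 'in total' line found")
    if properly is None:
        raise ValueError("flagstat parse error: no 'properly paired' line found")
    denominator = primary if primary is not None else total
    row = make_stats_row(sample_id, reference_id, GENOME_SCOPE, denominator, properly)
    return pd.DataFrame([row], columns=STATS_COLUMNS)


def stats_from_bam(
    path: str | Path,
    sample_id: str,
    reference_id: str,
    chromosomes: Sequence[str] | None = None,
    per_chromosome: bool = True,
) -> pd.DataFrame:
    """Compute an AlignmentStatsTable directly from a BAM/SAM file.

    Produces one genome-scope row and, when ``per_chromosome``, one row per
    chromosome (default: every reference sequence in the header, or the
    subset given in ``chromosomes``).  The genome totals equal the sum over
    chromosome rows plus reads on unlisted contigs and unmapped reads.
    """
    path = str(path)
    mode = "r" if path.endswith(".sam") else "rb"
    genome_total = genome_pp = 0
    per_chrom: dict[str, list[int]] = {}
    with pysam.AlignmentFile(path, mode) as bam:
        if chromosomes is None:
            chromosomes = list(bam.references)
        per_chrom = {c: [0, 0] for c in chromosomes}
        n_records = 0
        for read in bam.fetch(until_eof=True):
            n_records += 1
            if read.is_secondary or read.is_supplementary:
                continue
            genome_total += 1
            proper = read.is_proper_pair
            if proper:
                genome_pp += 1
            if not read.is_unmapped and read.reference_name in per_chrom:
                counts = per_chrom[read.reference_name]
                counts[0] += 1
                if proper:
                    counts[1] += 1
    if n_records == 0:
        raise ValueError(f"empty alignment file: {path}")
    rows = [
        make_stats_row(sample_id, reference_id, GENOME_SCOPE, genome_total, genome_pp)
    ]
    if per_chromosome:
        for chrom in chromosomes:
            total, proper = per_chrom[chrom]
            rows.append(
                make_stats_row(sample_id, reference_id, chrom, total, proper)
            )
    return pd.DataFrame(rows, columns=STATS_COLUMNS)


def write_stats(table: pd.DataFrame, path: str | Path) -> None:
    """Write a stats table as TSV with a counting-semantics header comment."""
    validate_stats(table)
    with open(path, "w") as fh:
        fh.write(_HEADER_NOTE + "\n")
        table.to_csv(fh, sep="\t", index=False)


def read_stats(path: str | Path) -> pd.DataFrame:
    """Read a stats TSV back, validating invariants.

    Unknown extra columns are preserved untouched.  A malformed numeric field
    raises ``ValueError`` naming the offending line number.
    """
    try:
        table = pd.read_csv(path, sep="\t", comment="#")
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed stats TSV {path}: {exc}") from exc
    for col in ("total_reads", "properly_paired", "pp_percent"):
        if col not in table.columns:
            raise ValueError(f"stats TSV {path} missing column {col!r}")
        coerced = pd.to_numeric(table[col], errors="coerce")
        if coerced.isna().any() and not table[col].isna().all():
            bad_idx = coerced.index[coerced.isna() & table[col].notna()][0]
            # +2: header line + 1-based; comment lines shift this upward
            raise ValueError(
                f"malformed value {table.loc[bad_idx, col]!r} in column {col!r} "
                f"of {path}, data row {bad_idx + 1}"
            )
        table[col] = coerced
    return validate_stats(table)
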