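"""Relative Coverage: normalized paired depth, dosage calls, segmentation.

For a hybrid accession aligned competitively to a concatenated pair of
subgenome references, the per-window depths ``d_anchor`` (on the reference
the plot is anchored on) and ``d_partner`` (on its homologous window in the
other reference) are normalized by the chromosome-level mean

    M_c = mean over mapped windows of chromosome c of (d_anchor + d_partner) / 2
    r   = d / M_c

which puts both tracks on a common 0-2 scale: at total ploidy *p*, a window
carrying *a* copies on the anchor subgenome has expected relative coverage

    E[r_anchor] = 2 (a (1 - beta) + (p - a) beta) / p

where ``beta`` is the cross-mapping background rate — the fraction of reads
from one subgenome that aligners place on the other within conserved
sequence.  An AAB accession therefore sits at r_A = 4/3, r_B = 2/3 (the 2:1
depth ratio), an ABB chromosome at 2/3 vs 4/3 (1:2), a full B-replaced
chromosome at ~0 vs ~2 (0:3), up to the background.  Deviations of a run of
windows from the accession's modal composition are homoeologous exchanges /
introgressions and are reported as segments.

Because ``d_anchor + d_partner`` is (in expectation) independent of how the
*p* copies are split — reads have to land somewhere — M_c is insensitive to
dosage, which is what keeps full-chromosome exchanges visible at r = 2/0
instead of being renormalized away.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

RC_COLUMNS = [
    "track_id", "anchor", "partner",
    "chrom", "start", "end",
    "partner_chrom", "partner_start", "partner_end",
    "d_anchor", "d_partner", "r_anchor", "r_partner", "m_c",
]

SEGMENT_COLUMNS = [
    "chrom", "start", "end", "composition",
    "n_windows", "mean_r_anchor", "whole_chromosome",
]


@dataclass
class BackgroundModel:
    """Cross-mapping background rate between a reference pair.

    ``beta`` is the fraction of reads from copies of one subgenome that end
    up on the homoeologous reference within conserved (mapped) windows.
    """

    beta: float
    n_iterations: int = 0
    n_pure_windows: int = 0
    converged: bool = True
    from_fallback: bool = False

    def __post_init__(self):
        if not 0 <= self.beta < 0.5:
            raise ValueError(f"beta must be in [0, 0.5), got {self.beta}")


def normalize(
    anchor_depth: pd.DataFrame,
    partner_depth: pd.DataFrame,
    window_map: pd.DataFrame,
    direction: str | None = None,
    baseline: str = "chromosome",
) -> pd.DataFrame:
    """Relative Coverage track anchored on ``anchor_depth``'s reference.

    Only windows mapped in ``window_map`` (in the anchor->partner direction)
    enter the track.  ``baseline="chromosome"`` (default) normalizes each
    chromosome by its own combined mean M_c, which reads out dosage ratios;
    ``baseline="genome"`` uses a single genome-wide normalizer, which instead
    exposes whole-chromosome total aneuploidy that a per-chromosome baseline
    masks.
    """
    anchor_ref = anchor_depth["reference_id"].iloc[0]
    partner_ref = partner_depth["reference_id"].iloc[0]
    if direction is None:
        direction = f"{anchor_ref}->{partner_ref}"
    sub = window_map[
        (window_map["direction"] == direction) & window_map["ref2_chrom"].notna()
    ].copy()
    if not len(sub):
        raise ValueError(f"window map has no mapped windows for direction {direction}")
    merged = sub.merge(
        anchor_depth.rename(columns={"median_depth": "d_anchor"}),
        left_on=["ref1_chrom", "ref1_start"],
        right_on=["chrom", "start"],
        how="inner",
    ).merge(
        partner_depth.rename(columns={"median_depth": "d_partner"})[
            ["chrom", "start", "d_partner"]
        ],
        left_on=["ref2_chrom", "ref2_start"],
        right_on=["chrom", "start"],
        how="inner",
        suffixes=("", "_p"),
    )
    merged["combined"] = (merged["d_anchor"] + merged["d_partner"]) / 2.0
    if baseline == "genome":
        m = merged["combined"].mean()
        if m == 0:
            raise ValueError("genome-wide mean depth is zero")
        merged["m_c"] = m
    elif baseline == "chromosome":
        means = merged.groupby("ref1_chrom")["combined"].transform("mean")
        zero = means == 0
        if zero.any():
            bad = sorted(merged.loc[zero, "ref1_chrom"].unique())
            raise ValueError(f"zero combined depth on chromosome(s) {bad}")
        merged["m_c"] = means
    else:
        raise ValueError(f"unknown baseline {baseline!r}")
    missing = set(window_map.loc[window_map["direction"] == direction, "ref1_chrom"]) \
        - set(merged["ref1_chrom"])
    if missing:
        warnings.warn(
            f"chromosome(s) with no mapped windows skipped: {sorted(missing)}",
            stacklevel=2,
        )
    merged["r_anchor"] = merged["d_anchor"] / merged["m_c"]
    merged["r_partner"] = merged["d_partner"] / merged["m_c"]
    out = pd.DataFrame(
        {
            "track_id": merged["track_id"],
            "anchor": anchor_ref,
            "partner": partner_ref,
            "chrom": merged["ref1_chrom"],
            "start": merged["ref1_start"],
            "end": merged["ref1_end"],
            "partner_chrom": merged["ref2_chrom"],
            "partner_start": merged["ref2_start"],
            "partner_end": merged["ref2_end"],
            "d_anchor": merged["d_anchor"],
            "d_partner": merged["d_partner"],
            "r_anchor": merged["r_anchor"],
            "r_partner": merged["r_partner"],
            "m_c": merged["m_c"],
        }
    )
    return out.sort_values(["chrom", "start"]).reset_index(drop=True)


def expected_levels(ploidy: int, beta: float) -> np.ndarray:
    """Expected r_anchor for each anchor copy number a = 0..p (ascending)."""
    a = np.arange(ploidy + 1)
    return 2.0 * (a * (1.0 - beta) + (ploidy - a) * beta) / ploidy


def composition_label(a: int, ploidy: int, anchor_letter: str, partner_letter: str) -> str:
    return anchor_letter * a + partner_letter * (ploidy - a)


def classify_dosage(
    rc: pd.DataFrame,
    ploidy: int,
    background: BackgroundModel | float = 0.0,
    anchor_letter: str | None = None,
    partner_letter: str | None = None,
    anomaly_tolerance: float = 0.1,
) -> pd.DataFrame:
    """Per-window anchor copy number: nearest expected level to r_anchor.

    Ties between equidistant levels break toward the smaller copy number.
    Windows with r_anchor above 2 (1 + tolerance) are flagged anomalous but
    still classified.
    """
    if ploidy < 1:
        raise ValueError("ploidy must be >= 1")
    beta = background.beta if isinstance(background, BackgroundModel) else float(background)
    if anchor_letter is None:
        anchor_letter = str(rc["anchor"].iloc[0])[0].upper()
    if partner_letter is None:
        partner_letter = str(rc["partner"].iloc[0])[0].upper()
    levels = expected_levels(ploidy, beta)
    r = rc["r_anchor"].to_numpy()
    dist = np.abs(r[:, None] - levels[None, :])
    # first index within fp tolerance of the minimum -> ties go to smaller a
    dmin = dist.min(axis=1, keepdims=True)
    a_hat = (dist <= dmin + 1e-9).argmax(axis=1)
    calls = rc.copy()
    calls["a_hat"] = a_hat
    calls["b_hat"] = ploidy - a_hat
    calls["ploidy"] = ploidy
    calls["composition"] = [
        composition_label(a, ploidy, anchor_letter, partner_letter) for a in a_hat
    ]
    calls["residual"] = r - levels[a_hat]
    calls["anomalous"] = r > 2.0 * (1.0 + anomaly_tolerance)
    return calls


def estimate_background(
    rc: pd.DataFrame,
    ploidy: int,
    fallback_beta: float = 0.0,
    max_iterations: int = 10,
    tolerance: float = 1e-4,
) -> BackgroundModel:
    """Iterative background estimate from dosage-pure windows.

    Starting at beta = 0, windows are classified, and beta is re-estimated as
    the median of (minor-side r) / 2 over windows called pure (all copies on
    one subgenome): for a = p the minor side is r_partner, for a = 0 it is
    r_anchor.  Iterates until the change falls below ``tolerance``.  If no
    window is ever called pure, the configured fallback is returned with a
    warning.
    """
    beta = 0.0
    n_pure = 0
    for iteration in range(1, max_iterations + 1):
        calls = classify_dosage(rc, ploidy, beta)
        pure_hi = calls["a_hat"] == ploidy
        pure_lo = calls["a_hat"] == 0
        minor = np.concatenate(
            [calls.loc[pure_hi, "r_partner"].to_numpy(),
             calls.loc[pure_lo, "r_anchor"].to_numpy()]
        )
        n_pure = len(minor)
        if n_pure == 0:
            warnings.warn(
                "no dosage-pure windows found; returning fallback beta "
                f"{fallback_beta}",
                stacklevel=2,
            )
            return BackgroundModel(
                beta=fallback_beta, n_iterations=iteration,
                n_pure_windows=0, converged=False, from_fallback=True,
            )
        new_beta = float(np.clip(np.median(minor) / 2.0, 0.0, 0.499))
        if abs(new_beta - beta) < tolerance:
            return BackgroundModel(
                beta=new_beta, n_iterations=iteration,
                n_pure_windows=n_pure, converged=True,
            )
        beta = new_beta
    return BackgroundModel(
        beta=beta, n_iterations=max_iterations,
        n_pure_windows=n_pure, converged=False,
    )


def _smooth_labels(labels: list, k: int) -> list:
    """Rolling-majority vote over a centred window of k labels (ties keep the
    earliest-seen label within the window, preserving runs at boundaries)."""
    if k <= 1 or len(labels) <= 1:
        return list(labels)
    half = k // 2
    out = []
    for i in range(len(labels)):
        lo, hi = max(0, i - half), min(len(labels), i + half + 1)
        counts = Counter(labels[lo:hi])
        out.append(counts.most_common(1)[0][0])
    return out


def segment(
    calls: pd.DataFrame,
    min_windows: int = 5,
    smooth_k: int = 5,
    modal_composition: str | None = None,
    whole_chromosome_fraction: float = 0.95,
) -> pd.DataFrame:
    """Runs of windows whose (smoothed) composition deviates from the mode.

    The accession's modal composition is the most frequent call genome-wide
    unless given explicitly.  Runs shorter than ``min_windows`` are dropped.
    A run covering at least ``whole_chromosome_fraction`` of a chromosome's
    mapped windows is flagged as a whole-chromosome exchange.  Coordinates
    are on the anchor reference, 0-based half-open.
    """
    if modal_composition is None:
        modal_composition = calls["composition"].mode().iloc[0]
    segments = []
    for chrom, grp in calls.groupby("chrom", sort=False):
        grp = grp.sort_values("start").reset_index(drop=True)
        labels = _smooth_labels(list(grp["composition"]), smooth_k)
        n_mapped = len(grp)
        i = 0
        while i < n_mapped:
            j = i
            while j < n_mapped and labels[j] == labels[i]:
                j += 1
            label = labels[i]
            if label != modal_composition and (j - i) >= min_windows:
                run = grp.iloc[i:j]
                segments.append(
                    {
                        "chrom": chrom,
                        "start": int(run["start"].iloc[0]),
                        "end": int(run["end"].iloc[-1]),
                        "composition": label,
                        "n_windows": j - i,
                        "mean_r_anchor": float(run["r_anchor"].mean()),
                        "whole_chromosome": (j - i) >= whole_chromosome_fraction * n_mapped,
                    }
                )
            i = j
    return pd.DataFrame(segments, columns=SEGMENT_COLUMNS)


def chromosome_ratio_table(rc: pd.DataFrame) -> pd.DataFrame:
    """Per-chromosome mean anchor/partner relative-coverage ratio.

    A zero partner mean yields an infinite sentinel rather than an error, so
    fully anchor-pure chromosomes stay visible in the summary.
    """
    rows = []
    for (track_id, chrom), grp in rc.groupby(["track_id", "chrom"]):
        mean_a = grp["r_anchor"].mean()
        mean_p = grp["r_partner"].mean()
        ratio = np.inf if mean_p == 0 else mean_a / mean_p
        rows.append(
            {"track_id": track_id, "chrom": chrom,
             "mean_r_anchor": mean_a, "mean_r_partner": mean_p, "ratio": ratio}
        )
    return pd.DataFrame(rows)


def segments_to_bed(segments: pd.DataFrame, path: str | Path, track_id: str = "segments") -> None:
    """BED6: name = composition, score = n_windows, strand '.'"""
    with open(path, "w") as fh:
        fh.write(f'track name="{track_id}" description="dosage-deviant segments; '
                 '0-based half-open"\n')
        for seg in segments.itertuples(index=False):
            fh.write(
                f"{seg.chrom}\t{seg.start}\t{seg.end}\t{seg.composition}\t"
                f"{seg.n_windows}\t.\n"
            )


def write_rc(rc: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# relative coverage track; coordinates 0-based half-open\n")
        rc.to_csv(fh, sep="\t", index=False)


def read_rc(path: str | Path) -> pd.DataFrame:
    rc = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in RC_COLUMNS if c not in rc.columns]
    if missing:
        raise ValueError(f"relative coverage TSV {path} missing columns: {missing}")
    return rc
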