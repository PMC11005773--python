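"""Relative-coverage and RAA figures.

Colour conventions are fixed: A-subgenome blue, B-subgenome red, S-subgenome
yellow, so panels from different accessions and reference pairs read the
same way.  Relative-coverage figures show, per anchor direction, the anchor
track bars (0-2) with the partner track below, one row per chromosome, with
dosage-deviant segments outlined as boxes.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import pandas as pd
from matplotlib.patches import Rectangle

SUBGENOME_COLORS = {"A": "tab:blue", "B": "tab:red", "S": "gold"}

_FALLBACK_CYCLE = ["tab:green", "tab:purple", "tab:orange", "tab:brown"]


def _color(reference_id: str, i: int = 0) -> str:
    return SUBGENOME_COLORS.get(
        str(reference_id)[0].upper(), _FALLBACK_CYCLE[i % len(_FALLBACK_CYCLE)]
    )


def plot_relative_coverage(
    rc_by_anchor: dict[str, pd.DataFrame],
    segments_by_anchor: dict[str, pd.DataFrame] | None = None,
    out: str | Path | None = None,
) -> plt.Figure:
    """Two-column relative-coverage figure, one column per anchor direction.

    ``rc_by_anchor`` maps anchor reference id -> relative coverage track.
    With only one direction available a single-column figure is produced
    with a warning.  Inputs are not mutated.
    """
    import warnings

    anchors = list(rc_by_anchor)
    if len(anchors) == 1:
        warnings.warn("only one anchor direction available; single-panel figure",
                      stacklevel=2)
    chroms = sorted(
        {c for rc in rc_by_anchor.values() for c in rc["chrom"].unique()},
        key=lambda c: (len(c), c),
    )
    n_rows = max(len(chroms), 1)
    fig, axes = plt.subplots(
        n_rows, len(anchors),
        figsize=(6 * len(anchors), 1.4 * n_rows),
        squeeze=False,
    )
    for col, anchor in enumerate(anchors):
        rc = rc_by_anchor[anchor]
        partner = rc["partner"].iloc[0]
        ca, cp = _color(anchor), _color(partner, 1)
        segs = None
        if segments_by_anchor is not None:
            segs = segments_by_anchor.get(anchor)
        for row, chrom in enumerate(chroms):
            ax = axes[row][col]
            sub = rc[rc["chrom"] == chrom]
            width = (sub["end"] - sub["start"]).median() if len(sub) else 1
            ax.bar(sub["start"], sub["r_anchor"], width=width, align="edge",
                   color=ca, linewidth=0)
            ax.bar(sub["start"], -sub["r_partner"], width=width, align="edge",
                   color=cp, linewidth=0)
            ax.set_ylim(-2.1, 2.1)
            ax.axhline(0, color="black", linewidth=0.5)
            ax.set_ylabel(chrom, rotation=0, ha="right", fontsize=8)
            ax.set_yticks([-2, 0, 2])
            if segs is not None and len(segs):
                for seg in segs[segs["chrom"] == chrom].itertuples(index=False):
                    ax.add_patch(
                        Rectangle(
                            (seg.start, -2.05), seg.end - seg.start, 4.1,
                            fill=False, edgecolor="black", linewidth=1.0,
                        )
                    )
            if row == 0:
                ax.set_title(f"anchor {anchor} (top) / {partner} (bottom)",
                             fontsize=9)
    fig.tight_layout()
    if out is not None:
        fig.savefig(out, dpi=150)
    return fig


def plot_raa(
    raa: pd.DataFrame,
    clusters: pd.DataFrame,
    out: str | Path | None = None,
    per_chromosome: bool = False,
) -> plt.Figure:
    """Dot plot of RAA per cluster, coloured by reference.

    With ``per_chromosome`` the plot is faceted per chromosome-scope entry
    in the table.  Inputs are not mutated.
    """
    merged = raa.merge(clusters, on="sample_id")
    if per_chromosome:
        scopes = sorted(s for s in merged["scope"].unique() if s != "genome")
    else:
        scopes = ["genome"]
    labels = sorted(merged["cluster_label"].unique())
    refs = sorted(merged["reference_id"].unique())
    fig, axes = plt.subplots(
        len(scopes), 1, figsize=(max(6, 0.8 * len(labels)), 3 * len(scopes)),
        squeeze=False,
    )
    for row, scope in enumerate(scopes):
        ax = axes[row][0]
        sub = merged[merged["scope"] == scope]
        for i, ref in enumerate(refs):
            refsub = sub[sub["reference_id"] == ref]
            x = [labels.index(lab) + (i - len(refs) / 2) * 0.08
                 for lab in refsub["cluster_label"]]
            ax.plot(x, refsub["raa"], "o", ms=4, color=_color(ref, i), label=ref)
        ax.set_xticks(range(len(labels)))
        ax.set_xticklabels(labels, rotation=45, ha="right", fontsize=8)
        ax.set_ylabel("RAA (%)" if scope == "genome" else f"RAA {scope} (%)")
        if row == 0:
            ax.legend(fontsize=8, title="reference")
    fig.tight_layout()
    if out is not None:
        fig.savefig(out, dpi=150)
    return fig
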