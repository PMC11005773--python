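"""Relative Averaged Alignment (RAA).

RAA normalizes the percentage of properly paired reads of a sample against a
reference so that samples can be compared across references despite sample-
level technical variation (library quality, PCR duplication, DNA integrity).
For a sample *s* in cluster *c* and references *r = 1..R*:

    Profile(c, r) = mean over members m of c of PP%(m, r)
    w_s           = mean over r of PP%(s, r) / Profile(c, r)
    RAA(s, r)     = PP%(s, r) / w_s

The weight factor ``w_s`` captures the sample's multiplicative quality offset
relative to its varietal cluster; dividing by it cancels that offset, leaving
the reference-affinity signal that reflects subgenome composition (a sample
with more A-subgenome copies aligns better to the A reference).  Because each
sample is included in its own cluster mean, the cluster mean of weight
factors is exactly 1, and if every sample equals the profile times a constant
whose cluster mean is 1, RAA recovers the profile to machine precision.

Per-chromosome RAA repeats the identical procedure on chromosome-scope
statistics rows; chromosome-specific weight factors absorb chromosome-level
technical effects.  RAA is deliberately not normalized by chromosome length.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd

from .alignment_stats import GENOME_SCOPE, validate_stats

#: sentinel cluster label for samples that belong to no cluster
UNCLUSTERED = "unclustered"

#: weight factors outside this interval are unusual enough to warn about
TYPICAL_WEIGHT_RANGE = (0.95, 1.05)

CLUSTER_COLUMNS = ["sample_id", "cluster_label"]
RAA_COLUMNS = [
    "sample_id",
    "reference_id",
    "scope",
    "pp_percent",
    "weight_factor",
    "raa",
]


def validate_clusters(clusters: pd.DataFrame, stats: pd.DataFrame) -> pd.DataFrame:
    """Every sample in the stats table must have a cluster entry."""
    missing = [c for c in CLUSTER_COLUMNS if c not in clusters.columns]
    if missing:
        raise ValueError(f"cluster table missing columns: {missing}")
    if clusters["sample_id"].duplicated().any():
        raise ValueError("duplicate sample_id in cluster assignment")
    absent = set(stats["sample_id"]) - set(clusters["sample_id"])
    if absent:
        raise ValueError(f"samples without cluster assignment: {sorted(absent)}")
    return clusters


def cluster_profile(
    stats: pd.DataFrame,
    clusters: pd.DataFrame,
    scope: str = GENOME_SCOPE,
    min_cluster_size: int = 3,
) -> pd.DataFrame:
    """Per-(cluster, reference) arithmetic mean of pp_percent at one scope.

    Clusters with fewer than ``min_cluster_size`` members (and the
    :data:`UNCLUSTERED` sentinel) are excluded with a warning; their samples
    later receive weight 1.0.
    """
    validate_stats(stats)
    validate_clusters(clusters, stats)
    sub = stats[stats["scope"] == scope].merge(clusters, on="sample_id")
    sub = sub[sub["cluster_label"] != UNCLUSTERED]
    sizes = sub.groupby("cluster_label")["sample_id"].nunique()
    small = sizes[sizes < min_cluster_size].index.tolist()
    if small:
        warnings.warn(
            f"clusters below minimum size {min_cluster_size} excluded from "
            f"profiles: {small}",
            stacklevel=2,
        )
        sub = sub[~sub["cluster_label"].isin(small)]
    prof = (
        sub.groupby(["cluster_label", "reference_id"], as_index=False)["pp_percent"]
        .mean()
        .rename(columns={"pp_percent": "profile_pp"})
    )
    prof["scope"] = scope
    return prof


def weight_factors(
    stats: pd.DataFrame,
    profiles: pd.DataFrame,
    clusters: pd.DataFrame,
    scope: str = GENOME_SCOPE,
) -> pd.DataFrame:
    """Per-sample weight factor: mean over references of sample/profile ratios.

    Samples whose cluster has no profile (unclustered or below the size
    minimum) get weight 1.0 and are flagged in the ``normalized`` column.
    A reference missing from a sample's rows is dropped from that sample's
    mean with a warning; a zero profile value is an error.
    """
    if (profiles["profile_pp"] == 0).any():
        bad = profiles[profiles["profile_pp"] == 0].iloc[0]
        raise ValueError(
            f"zero cluster profile for {bad['cluster_label']}/{bad['reference_id']}"
        )
    sub = stats[stats["scope"] == scope].merge(clusters, on="sample_id")
    profiled = set(profiles["cluster_label"])
    rows = []
    for sample_id, grp in sub.groupby("sample_id"):
        label = grp["cluster_label"].iloc[0]
        if label not in profiled:
            rows.append(
                {"sample_id": sample_id, "scope": scope, "weight_factor": 1.0,
                 "cluster_label": label, "normalized": False}
            )
            continue
        prof = profiles[profiles["cluster_label"] == label].set_index("reference_id")
        refs = [r for r in prof.index if r in set(grp["reference_id"])]
        dropped = set(prof.index) - set(refs)
        if dropped:
            warnings.warn(
                f"sample {sample_id} missing references {sorted(dropped)}; "
                "dropped from its weight-factor mean",
                stacklevel=2,
            )
        if not refs:
            raise ValueError(f"sample {sample_id} shares no reference with its profile")
        pp = grp.set_index("reference_id")["pp_percent"]
        ratios = [pp[r] / prof.loc[r, "profile_pp"] for r in refs]
        w = float(np.mean(ratios))
        if w <= 0:
            raise ValueError(f"non-positive weight factor for sample {sample_id}")
        rows.append(
            {"sample_id": sample_id, "scope": scope, "weight_factor": w,
             "cluster_label": label, "normalized": True}
        )
    out = pd.DataFrame(rows)
    lo, hi = TYPICAL_WEIGHT_RANGE
    atypical = out[(out["normalized"]) & ((out["weight_factor"] < lo) | (out["weight_factor"] > hi))]
    if len(atypical):
        warnings.warn(
            f"{len(atypical)} weight factor(s) outside the typical "
            f"{lo}-{hi} range (max deviation at "
            f"{atypical.iloc[0]['sample_id']})",
            stacklevel=2,
        )
    unnorm = out[~out["normalized"]]
    if len(unnorm):
        warnings.warn(
            f"{len(unnorm)} sample(s) without a usable cluster profile got "
            "weight 1.0 (unnormalized)",
            stacklevel=2,
        )
    return out


def compute_raa(
    stats: pd.DataFrame,
    weights: pd.DataFrame,
    scope: str = GENOME_SCOPE,
) -> pd.DataFrame:
    """RAA table: pp_percent divided by the sample's weight factor."""
    sub = stats[stats["scope"] == scope]
    missing = set(sub["sample_id"]) - set(weights["sample_id"])
    if missing:
        raise ValueError(f"missing weight factor for samples: {sorted(missing)}")
    merged = sub.merge(
        weights[weights["scope"] == scope][["sample_id", "weight_factor"]],
        on="sample_id",
    )
    merged["raa"] = merged["pp_percent"] / merged["weight_factor"]
    return merged[RAA_COLUMNS]


def raa_pipeline(
    stats: pd.DataFrame,
    clusters: pd.DataFrame,
    per_chromosome: bool = False,
    min_cluster_size: int = 3,
) -> pd.DataFrame:
    """Profile -> weights -> RAA, at genome scope or per chromosome.

    In per-chromosome mode the whole procedure is repeated independently on
    each chromosome's statistics (chromosome-specific weight factors), and
    the genome scope is included as well.
    """
    scopes = [GENOME_SCOPE]
    if per_chromosome:
        scopes += sorted(s for s in stats["scope"].unique() if s != GENOME_SCOPE)
    tables = []
    for scope in scopes:
        prof = cluster_profile(stats, clusters, scope, min_cluster_size)
        w = weight_factors(stats, prof, clusters, scope)
        tables.append(compute_raa(stats, w, scope))
    return pd.concat(tables, ignore_index=True)


def rank_references(
    raa: pd.DataFrame,
    by: str = "sample",
    clusters: pd.DataFrame | None = None,
    tie_margin: float = 0.005,
    scope: str = GENOME_SCOPE,
) -> pd.DataFrame:
    """Order references by descending RAA per sample (or per cluster mean).

    Returns one row per (key, rank) with a ``tied_with_next`` flag set when
    the relative gap to the next reference is below ``tie_margin``.
    """
    sub = raa[raa["scope"] == scope].copy()
    if by == "cluster":
        if clusters is None:
            raise ValueError("cluster ranking requires a cluster assignment")
        sub = sub.merge(clusters, on="sample_id")
        sub = (
            sub.groupby(["cluster_label", "reference_id"], as_index=False)["raa"]
            .mean()
            .rename(columns={"cluster_label": "key"})
        )
    elif by == "sample":
        sub = sub.rename(columns={"sample_id": "key"})[["key", "reference_id", "raa"]]
    else:
        raise ValueError(f"unknown ranking mode {by!r}")
    rows = []
    for key, grp in sub.groupby("key"):
        ordered = grp.sort_values(
            ["raa", "reference_id"], ascending=[False, True]
        ).reset_index(drop=True)
        for i, rec in ordered.iterrows():
            tied = False
            if i + 1 < len(ordered):
                nxt = ordered.loc[i + 1, "raa"]
                denom = max(abs(rec["raa"]), 1e-12)
                tied = abs(rec["raa"] - nxt) / denom < tie_margin
            rows.append(
                {"key": key, "rank": i + 1, "reference_id": rec["reference_id"],
                 "raa": rec["raa"], "tied_with_next": tied}
            )
    return pd.DataFrame(rows)


def write_raa(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_raa(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
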