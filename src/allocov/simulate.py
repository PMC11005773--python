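"""Synthetic hybrid-genome inputs: depth tracks, stats panels, sequences.

Everything downstream modules consume can be generated here with full
statistical control and mandatory seeding:

* :func:`simulate_depths` — paired window-depth tracks for a hybrid accession
  with a per-chromosome dosage mosaic (segment overrides planting
  introgressions or whole-chromosome exchanges), cross-mapping background,
  and sampling noise, plus the identity-like window map and truth tables.
* :func:`simulate_stats_panel` — a clustered panel of alignment-percentage
  statistics with per-sample multiplicative quality effects, for the RAA
  weight-factor machinery.
* :func:`simulate_sequences` — an optional sequence-level route: two
  subgenome FASTAs diverged from a common ancestor, plus read pairs drawn
  according to the dosage mosaic, for end-to-end runs through an external
  aligner.

Depth model.  A window with *a* copies on subgenome A out of total ploidy
*p*, at per-copy depth *u* and cross-mapping rate *beta*, has expected depths

    E[d_A] = u (a (1 - beta) + (p - a) beta)        E[d_B] symmetric

so E[d_A + d_B] = u p regardless of the split.  Sampling noise is applied at
fragment resolution: the window depth is n * L_f / W with
n ~ Poisson(E[d] W / L_f) for fragment length L_f (default 300 bp, a 2x150
paired-end insert).  This reproduces the sampling error of a median over a
100-kb window — relative noise ~ 1/sqrt(E[d] W / L_f) — rather than the far
larger error a per-window Poisson draw on the depth value itself would
imply.  Optional overdispersion switches the count draw to negative
binomial.  What this generator does *not* emulate: repeat-driven depth
spikes (the very thing the median absorbs on real data), GC bias,
mappability variation, or inhomogeneous conservation along chromosomes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .depth_windows import DEFAULT_WINDOW_SIZE, DEPTH_COLUMNS, WindowGrid
from .homology_map import MAP_COLUMNS
from .alignment_stats import STATS_COLUMNS, make_stats_row

#: genome-wide average depth the study design aims for, in x coverage
DEFAULT_TARGET_DEPTH = 7.0

#: default fragment length for the fragment-resolution noise model, bp
DEFAULT_FRAGMENT_LENGTH = 300

#: genome-wide mean properly-paired percentages per reference, a realistic
#: panel-average affinity profile for an A/B/S reference trio
DEFAULT_PANEL_PROFILE = {"A": 81.8, "B": 70.9, "S": 76.0}


@dataclass(frozen=True)
class SegmentOverride:
    """Replace the composition of windows [start_window, end_window) of one
    chromosome (window indices, 0-based half-open)."""

    chrom: str
    start_window: int
    end_window: int
    composition: str


@dataclass(frozen=True)
class SimScenario:
    """A hybrid accession's genome design and sequencing conditions."""

    n_chromosomes: int = 10
    chromosome_length: int = 10_000_000
    window_size: int = DEFAULT_WINDOW_SIZE
    ploidy: int = 3
    composition: str = "AAB"
    overrides: tuple[SegmentOverride, ...] = ()
    per_copy_depth: float | None = None  # default: DEFAULT_TARGET_DEPTH / ploidy
    beta: float = 0.0
    noise: str = "poisson"  # "poisson" | "none"
    overdispersion: float | None = None  # NB dispersion; None = pure Poisson
    fragment_length: int = DEFAULT_FRAGMENT_LENGTH
    conserved_fraction: float = 1.0
    seed: int = 0

    def __post_init__(self):
        letters = sorted(set(self.composition))
        if not (letters == ["A", "B"] or letters == ["A", "S"] or len(letters) == 1):
            raise ValueError(
                f"composition letters must be within {{A,B}} or {{A,S}}, got "
                f"{self.composition!r}"
            )
        if len(self.composition) != self.ploidy:
            raise ValueError("composition length must equal ploidy")
        if not 0 <= self.beta < 0.5:
            raise ValueError("beta must be in [0, 0.5)")
        if self.noise not in ("poisson", "none"):
            raise ValueError(f"unknown noise model {self.noise!r}")
        if not 0 < self.conserved_fraction <= 1:
            raise ValueError("conserved_fraction must be in (0, 1]")
        for ov in self.overrides:
            if len(ov.composition) != self.ploidy:
                raise ValueError(
                    f"override composition {ov.composition!r} has wrong ploidy"
                )
            if sorted(set(ov.composition + self.composition)) not in (
                ["A", "B"], ["A", "S"], [self.anchor_letter],
            ):
                raise ValueError(
                    f"override letters {ov.composition!r} incompatible with "
                    f"genome composition {self.composition!r}"
                )

    @property
    def anchor_letter(self) -> str:
        return "A"

    @property
    def partner_letter(self) -> str:
        others = set(self.composition) - {"A"}
        for ov in self.overrides:
            others |= set(ov.composition) - {"A"}
        return sorted(others)[0] if others else "B"

    @property
    def depth_per_copy(self) -> float:
        if self.per_copy_depth is not None:
            return self.per_copy_depth
        return DEFAULT_TARGET_DEPTH / self.ploidy

    @property
    def chromosomes(self) -> list[str]:
        return [f"chr{i}" for i in range(1, self.n_chromosomes + 1)]

    @property
    def n_windows(self) -> int:
        return -(-self.chromosome_length // self.window_size)

    def grid(self, reference_id: str) -> WindowGrid:
        return WindowGrid(
            reference_id,
            {c: self.chromosome_length for c in self.chromosomes},
            self.window_size,
        )


@dataclass
class SimResult:
    depth_anchor: pd.DataFrame
    depth_partner: pd.DataFrame
    window_map: pd.DataFrame
    truth_windows: pd.DataFrame
    truth_segments: pd.DataFrame
    scenario: SimScenario


def _dosage_per_window(scenario: SimScenario) -> pd.DataFrame:
    """Truth table: anchor copy number per window, overrides applied."""
    anchor = scenario.anchor_letter
    base_a = scenario.composition.count(anchor)
    rows = []
    for chrom in scenario.chromosomes:
        a = np.full(scenario.n_windows, base_a, dtype=int)
        for ov in scenario.overrides:
            if ov.chrom != chrom:
                continue
            if not 0 <= ov.start_window < ov.end_window <= scenario.n_windows:
                raise ValueError(
                    f"override {ov} outside chromosome ({scenario.n_windows} windows)"
                )
            a[ov.start_window : ov.end_window] = ov.composition.count(anchor)
        for w in range(scenario.n_windows):
            start = w * scenario.window_size
            rows.append(
                {
                    "chrom": chrom,
                    "start": start,
                    "end": min(start + scenario.window_size, scenario.chromosome_length),
                    "a": int(a[w]),
                    "b": scenario.ploidy - int(a[w]),
                }
            )
    truth = pd.DataFrame(rows)
    truth["composition"] = [
        anchor * r.a + scenario.partner_letter * r.b
        for r in truth.itertuples(index=False)
    ]
    return truth


def _truth_segments(truth: pd.DataFrame, scenario: SimScenario) -> pd.DataFrame:
    """Run-length encode windows deviating from the genome-wide composition."""
    segments = []
    for chrom, grp in truth.groupby("chrom", sort=False):
        grp = grp.sort_values("start").reset_index(drop=True)
        comps = list(grp["composition"])
        i = 0
        while i < len(comps):
            j = i
            while j < len(comps) and comps[j] == comps[i]:
                j += 1
            if comps[i] != scenario.composition:
                segments.append(
                    {
                        "chrom": chrom,
                        "start": int(grp["start"].iloc[i]),
                        "end": int(grp["end"].iloc[j - 1]),
                        "start_window": i,
                        "end_window": j,
                        "composition": comps[i],
                        "whole_chromosome": (j - i) == len(comps),
                    }
                )
            i = j
    return pd.DataFrame(
        segments,
        columns=["chrom", "start", "end", "start_window", "end_window",
                 "composition", "whole_chromosome"],
    )


def _noisy_depth(expected: np.ndarray, scenario: SimScenario,
                 rng: np.random.Generator) -> np.ndarray:
    if scenario.noise == "none":
        return expected.astype(float)
    scale = scenario.window_size / scenario.fragment_length
    lam = expected * scale
    if scenario.overdispersion is None:
        counts = rng.poisson(lam)
    else:
        r = scenario.overdispersion
        counts = rng.negative_binomial(r, r / (r + np.maximum(lam, 1e-12)))
    return counts / scale


def simulate_depths(scenario: SimScenario) -> SimResult:
    """Generate the paired depth tracks, window map, and truth tables."""
    rng = np.random.default_rng(scenario.seed)
    truth = _dosage_per_window(scenario)
    u, beta, p = scenario.depth_per_copy, scenario.beta, scenario.ploidy
    a = truth["a"].to_numpy()
    e_anchor = u * (a * (1 - beta) + (p - a) * beta)
    e_partner = u * ((p - a) * (1 - beta) + a * beta)
    d_anchor = _noisy_depth(e_anchor, scenario, rng)
    d_partner = _noisy_depth(e_partner, scenario, rng)

    anchor_ref = scenario.anchor_letter
    partner_ref = scenario.partner_letter

    def track(depth: np.ndarray, ref: str) -> pd.DataFrame:
        t = truth[["chrom", "start", "end"]].copy()
        t.insert(0, "track_id", f"sim_{scenario.composition}")
        t.insert(1, "reference_id", ref)
        t["median_depth"] = depth
        return t[DEPTH_COLUMNS]

    conserved = rng.random(len(truth)) < scenario.conserved_fraction
    wmap_rows = []
    for direction in (f"{anchor_ref}->{partner_ref}", f"{partner_ref}->{anchor_ref}"):
        for (rec, keep) in zip(truth.itertuples(index=False), conserved):
            wmap_rows.append(
                {
                    "direction": direction,
                    "ref1_chrom": rec.chrom, "ref1_start": rec.start,
                    "ref1_end": rec.end,
                    "ref2_chrom": rec.chrom if keep else None,
                    "ref2_start": rec.start if keep else np.nan,
                    "ref2_end": rec.end if keep else np.nan,
                    "aligned_bases": (rec.end - rec.start) if keep else 0,
                }
            )
    return SimResult(
        depth_anchor=track(d_anchor, anchor_ref),
        depth_partner=track(d_partner, partner_ref),
        window_map=pd.DataFrame(wmap_rows, columns=MAP_COLUMNS),
        truth_windows=truth,
        truth_segments=_truth_segments(truth, scenario),
        scenario=scenario,
    )


# ---------------------------------------------------------------------------
# panel of alignment statistics

@dataclass(frozen=True)
class ClusterSpec:
    """One varietal cluster: its reference-affinity profile and members."""

    label: str
    n_samples: int
    profile: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_PANEL_PROFILE))
    multipliers: tuple[float, ...] | None = None  # explicit per-sample quality

    def __post_init__(self):
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        for ref, pp in self.profile.items():
            if not 0 < pp <= 100:
                raise ValueError(f"profile for {ref} outside (0, 100]: {pp}")
        if self.multipliers is not None and len(self.multipliers) != self.n_samples:
            raise ValueError("multipliers length must equal n_samples")


@dataclass(frozen=True)
class PanelScenario:
    """A clustered sample panel with per-sample multiplicative quality."""

    clusters: tuple[ClusterSpec, ...]
    multiplier_range: tuple[float, float] = (0.95, 1.05)
    noise_sd: float = 0.0  # additive percentage-point noise on each pp value
    total_reads: int = 1_000_000
    seed: int = 0


def evenly_spaced_multipliers(n: int, half_width: float = 0.05) -> tuple[float, ...]:
    """n multipliers symmetric about 1 spanning [1 - hw, 1 + hw]; mean is 1."""
    return tuple(np.linspace(1.0 - half_width, 1.0 + half_width, n))


def simulate_stats_panel(
    panel: PanelScenario,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate (stats table, cluster assignment, truth multipliers).

    Each sample's pp_percent per reference is its cluster profile times the
    sample's quality multiplier, plus optional additive noise, clipped into
    (0, 100] with a warning when clipping occurs.  Counts are back-filled at
    ``total_reads`` so the percentages survive the count round trip.
    """
    import warnings as _warnings

    rng = np.random.default_rng(panel.seed)
    stats_rows, cluster_rows, truth_rows = [], [], []
    sample_no = 0
    for spec in panel.clusters:
        if spec.multipliers is not None:
            q = np.asarray(spec.multipliers, dtype=float)
        else:
            lo, hi = panel.multiplier_range
            q = rng.uniform(lo, hi, size=spec.n_samples)
        for i in range(spec.n_samples):
            sample_no += 1
            sample_id = f"s{sample_no:03d}"
            cluster_rows.append({"sample_id": sample_id, "cluster_label": spec.label})
            truth_rows.append(
                {"sample_id": sample_id, "cluster_label": spec.label,
                 "multiplier": float(q[i])}
            )
            for ref, profile_pp in spec.profile.items():
                pp = q[i] * profile_pp
                if panel.noise_sd > 0:
                    pp += rng.normal(0.0, panel.noise_sd)
                if pp > 100 or pp <= 0:
                    _warnings.warn(
                        f"pp_percent for {sample_id}/{ref} clipped into (0, 100]",
                        stacklevel=2,
                    )
                    pp = min(max(pp, 1e-4), 100.0)
                properly = round(pp / 100.0 * panel.total_reads)
                stats_rows.append(
                    make_stats_row(sample_id, ref, "genome", panel.total_reads, properly)
                )
    stats = pd.DataFrame(stats_rows, columns=STATS_COLUMNS)
    clusters = pd.DataFrame(cluster_rows)
    truth = pd.DataFrame(truth_rows)
    return stats, clusters, truth


# ---------------------------------------------------------------------------
# sequence-level output

def simulate_sequences(
    scenario: SimScenario,
    divergence: float,
    out_dir: str | Path | None = None,
    emit_reads: bool = False,
    read_length: int = 150,
    error_rate: float = 0.0,
):
    """Two subgenome FASTAs diverged from a common ancestor, optional reads.

    Each subgenome copy of the ancestor is mutated independently at
    ``divergence`` substitutions/bp (each hit site replaced by one of the
    three other bases).  Reads, when requested, are single-end fragments
    drawn window by window in proportion to the window's dosage, with origin
    ("A"/"B") recorded in the read name.  Returns (records_anchor,
    records_partner, reads) where reads is a list of (name, sequence) or
    None.
    """
    if not 0 <= divergence <= 0.3:
        raise ValueError("divergence must be in [0, 0.3]")
    rng = np.random.default_rng(scenario.seed)
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)

    def mutate(seq: np.ndarray) -> np.ndarray:
        out = seq.copy()
        hits = np.nonzero(rng.random(len(seq)) < divergence)[0]
        if len(hits):
            shift = rng.integers(1, 4, size=len(hits))
            idx = (np.searchsorted(bases, out[hits]) + shift) % 4
            out[hits] = bases[idx]
        return out

    anchor_records, partner_records = [], []
    genomes: dict[str, dict[str, np.ndarray]] = {scenario.anchor_letter: {},
                                                 scenario.partner_letter: {}}
    for chrom in scenario.chromosomes:
        ancestor = rng.choice(bases, size=scenario.chromosome_length)
        seq_a, seq_b = mutate(ancestor), mutate(ancestor)
        genomes[scenario.anchor_letter][chrom] = seq_a
        genomes[scenario.partner_letter][chrom] = seq_b
        anchor_records.append(
            SeqRecord(Seq(seq_a.tobytes().decode()), id=chrom, description="")
        )
        partner_records.append(
            SeqRecord(Seq(seq_b.tobytes().decode()), id=chrom, description="")
        )

    reads = None
    if emit_reads:
        reads = []
        truth = _dosage_per_window(scenario)
        u = scenario.depth_per_copy
        for rec in truth.itertuples(index=False):
            span = rec.end - rec.start
            for letter, copies in ((scenario.anchor_letter, rec.a),
                                   (scenario.partner_letter, rec.b)):
                if copies == 0:
                    continue
                n_reads = rng.poisson(u * copies * span / read_length)
                starts = rng.integers(
                    rec.start, max(rec.start + 1, rec.end - read_length),
                    size=n_reads,
                )
                for k, s in enumerate(starts):
                    seq = genomes[letter][rec.chrom][s : s + read_length].copy()
                    if error_rate > 0:
                        errs = np.nonzero(rng.random(len(seq)) < error_rate)[0]
                        if len(errs):
                            shift = rng.integers(1, 4, size=len(errs))
                            idx = (np.searchsorted(bases, seq[errs]) + shift) % 4
                            seq[errs] = bases[idx]
                    reads.append(
                        (f"{letter}_{rec.chrom}_{s}_{k}", seq.tobytes().decode())
                    )

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        SeqIO.write(anchor_records, out_dir / f"subgenome_{scenario.anchor_letter}.fasta", "fasta")
        SeqIO.write(partner_records, out_dir / f"subgenome_{scenario.partner_letter}.fasta", "fasta")
        if reads is not None:
            with open(out_dir / "reads.fastq", "w") as fh:
                for name, seq in reads:
                    fh.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")
    return anchor_records, partner_records, reads


# ---------------------------------------------------------------------------
# named presets mirroring the published varietal-lineage mosaics

def _plantain_aab(seed: int) -> SimScenario:
    # AAB genome; chr7 fully B-replaced (ABB); five telomeric A-donor (AAA)
    # introgressions: starts of chr4/6/8/9, end of chr10
    return SimScenario(
        n_chromosomes=10,
        ploidy=3,
        composition="AAB",
        per_copy_depth=2.5,
        beta=0.03,
        overrides=(
            SegmentOverride("chr7", 0, 100, "ABB"),
            SegmentOverride("chr4", 0, 30, "AAA"),
            SegmentOverride("chr6", 0, 15, "AAA"),
            SegmentOverride("chr8", 0, 15, "AAA"),
            SegmentOverride("chr9", 0, 15, "AAA"),
            SegmentOverride("chr10", 85, 100, "AAA"),
        ),
        seed=seed,
    )


def _popoulu_aab(seed: int) -> SimScenario:
    # AAB with a B-donor (ABB) introgression at the start of chr7 and an
    # A-donor (AAA) introgression at the end of chr10
    return SimScenario(
        n_chromosomes=11,
        ploidy=3,
        composition="AAB",
        beta=0.03,
        overrides=(
            SegmentOverride("chr7", 0, 40, "ABB"),
            SegmentOverride("chr10", 85, 100, "AAA"),
        ),
        seed=seed,
    )


def _popoulu_aab_maoli(seed: int) -> SimScenario:
    # the shorter chr7 variant: starts ~1/8 into the chromosome
    base = _popoulu_aab(seed)
    return replace(
        base,
        overrides=(
            SegmentOverride("chr7", 12, 40, "ABB"),
            SegmentOverride("chr10", 85, 100, "AAA"),
        ),
    )


def _bluggoe_abb(seed: int) -> SimScenario:
    # ABB with B-donor (BBB) introgressions on chr4 and chr11 (x2) and
    # A-donor (AAB) introgressions on chr4 and chr9
    return SimScenario(
        n_chromosomes=11,
        ploidy=3,
        composition="ABB",
        beta=0.03,
        overrides=(
            SegmentOverride("chr4", 0, 20, "BBB"),
            SegmentOverride("chr4", 70, 90, "AAB"),
            SegmentOverride("chr9", 40, 60, "AAB"),
            SegmentOverride("chr11", 10, 30, "BBB"),
            SegmentOverride("chr11", 60, 80, "BBB"),
        ),
        seed=seed,
    )


def _pelipita_abb(seed: int) -> SimScenario:
    # ABB with whole-chromosome B-exchanges (BBB) on chr2, chr7 and chr11
    return SimScenario(
        n_chromosomes=11,
        ploidy=3,
        composition="ABB",
        beta=0.05,
        overrides=(
            SegmentOverride("chr2", 0, 100, "BBB"),
            SegmentOverride("chr7", 0, 100, "BBB"),
            SegmentOverride("chr11", 0, 100, "BBB"),
        ),
        seed=seed,
    )


def _aaab_africa(seed: int) -> SimScenario:
    # synthetic tetraploid AAAB inheriting the plantain chr7 exchange (AABB)
    return SimScenario(
        n_chromosomes=11,
        ploidy=4,
        composition="AAAB",
        beta=0.03,
        overrides=(SegmentOverride("chr7", 0, 100, "AABB"),),
        seed=seed,
    )


PRESETS: dict[str, Callable[[int], SimScenario]] = {
    "plantain_aab": _plantain_aab,
    "popoulu_aab": _popoulu_aab,
    "popoulu_aab_maoli": _popoulu_aab_maoli,
    "bluggoe_abb": _bluggoe_abb,
    "pelipita_abb": _pelipita_abb,
    "aaab_africa": _aaab_africa,
}


def preset_scenario(name: str, seed: int) -> SimScenario:
    """A named lineage preset with the given seed."""
    try:
        factory = PRESETS[name]
    except KeyError:
        raise ValueError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}"
        ) from None
    return factory(seed)
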