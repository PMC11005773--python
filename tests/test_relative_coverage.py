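"""Relative Coverage normalization, background estimation, dosage calls,
segmentation, and chromosome ratio summaries."""

import numpy as np
import pandas as pd
import pytest

from allocov.relative_coverage import (
    BackgroundModel,
    chromosome_ratio_table,
    classify_dosage,
    estimate_background,
    expected_levels,
    normalize,
    segment,
)
from allocov.simulate import SegmentOverride, SimScenario, simulate_depths

from conftest import depth_track, identity_window_map


def make_rc(chrom_lengths, ws, depth_a_fn, depth_b_fn, baseline="chromosome"):
    a = depth_track(chrom_lengths, ws, depth_a_fn, ref="A")
    b = depth_track(chrom_lengths, ws, depth_b_fn, ref="B")
    wmap = identity_window_map(chrom_lengths, ws)
    return normalize(a, b, wmap, baseline=baseline)


class TestNormalize:
    def test_balanced_diploid_is_flat_one(self, two_chrom_lengths):
        rc = make_rc(two_chrom_lengths, 50_000, lambda c, s: 5, lambda c, s: 5)
        assert np.allclose(rc["r_anchor"], 1.0)
        assert np.allclose(rc["r_partner"], 1.0)

    def test_two_to_one_closed_form(self, two_chrom_lengths):
        # d_A = 2u, d_B = u -> M_c = 1.5u -> r_A = 4/3, r_B = 2/3
        rc = make_rc(two_chrom_lengths, 50_000, lambda c, s: 10, lambda c, s: 5)
        assert np.allclose(rc["r_anchor"], 4 / 3)
        assert np.allclose(rc["r_partner"], 2 / 3)

    def test_pure_partner_chromosome_hits_range_extremes(self):
        # a 0:3 chromosome: r_anchor ~ 0, r_partner ~ 2, never above 2
        scenario = SimScenario(
            n_chromosomes=1, chromosome_length=5_000_000, composition="ABB",
            overrides=(SegmentOverride("chr1", 0, 50, "BBB"),),
            beta=0.0, noise="none", seed=0,
        )
        res = simulate_depths(scenario)
        rc = normalize(res.depth_anchor, res.depth_partner, res.window_map)
        assert np.allclose(rc["r_anchor"], 0.0)
        assert np.allclose(rc["r_partner"], 2.0)
        assert rc["r_partner"].max() <= 2.0 + 1e-9

    def test_chromosome_mean_of_combined_is_one_exactly(self, two_chrom_lengths):
        rng = np.random.default_rng(4)
        rc = make_rc(
            two_chrom_lengths, 50_000,
            lambda c, s: rng.uniform(1, 10), lambda c, s: rng.uniform(1, 10),
        )
        means = rc.groupby("chrom").apply(
            lambda g: ((g["r_anchor"] + g["r_partner"]) / 2).mean(),
            include_groups=False,
        )
        assert np.allclose(means, 1.0, atol=1e-12)

    def test_unmapped_windows_excluded(self, two_chrom_lengths):
        a = depth_track(two_chrom_lengths, 50_000, lambda c, s: 5, ref="A")
        b = depth_track(two_chrom_lengths, 50_000, lambda c, s: 5, ref="B")
        wmap = identity_window_map(two_chrom_lengths, 50_000,
                                   unmapped={("chr1", 0)})
        rc = normalize(a, b, wmap)
        assert ("chr1", 0) not in set(zip(rc["chrom"], rc["start"]))
        assert len(rc) == len(a) - 1

    def test_zero_depth_chromosome_errors(self, two_chrom_lengths):
        with pytest.raises(ValueError, match="zero combined depth"):
            make_rc(two_chrom_lengths, 50_000,
                    lambda c, s: 0 if c == "chr1" else 5,
                    lambda c, s: 0 if c == "chr1" else 5)

    def test_genome_baseline_exposes_whole_chromosome_aneuploidy(self):
        lengths = {"chr1": 200_000, "chr2": 200_000}
        # chr2 carries twice the total copies; per-chromosome baseline hides it
        rc_chrom = make_rc(lengths, 50_000,
                           lambda c, s: 10 if c == "chr2" else 5,
                           lambda c, s: 10 if c == "chr2" else 5)
        rc_genome = make_rc(lengths, 50_000,
                            lambda c, s: 10 if c == "chr2" else 5,
                            lambda c, s: 10 if c == "chr2" else 5,
                            baseline="genome")
        assert np.allclose(rc_chrom["r_anchor"], 1.0)
        chr2 = rc_genome[rc_genome["chrom"] == "chr2"]
        chr1 = rc_genome[rc_genome["chrom"] == "chr1"]
        assert chr2["r_anchor"].mean() > 1.2 > chr1["r_anchor"].mean()


class TestExpectedLevels:
    def test_levels_span_zero_to_two_and_shrink_with_beta(self):
        clean = expected_levels(3, 0.0)
        assert np.allclose(clean, [0, 2 / 3, 4 / 3, 2])
        shrunk = expected_levels(3, 0.05)
        assert shrunk[0] > 0 and shrunk[-1] < 2
        assert np.allclose(clean.sum(), shrunk.sum())  # symmetric shrinkage


class TestClassifyDosage:
    @pytest.mark.parametrize(
        "r_anchor, a_hat, label",
        [(1.33, 2, "AAB"), (0.67, 1, "ABB"), (0.0, 0, "BBB"), (2.0, 3, "AAA")],
    )
    def test_triploid_ratio_levels(self, r_anchor, a_hat, label):
        rc = pd.DataFrame(
            {"track_id": "t", "anchor": "A", "partner": "B", "chrom": "chr1",
             "start": [0], "end": [100_000], "r_anchor": [r_anchor],
             "r_partner": [2 - r_anchor]}
        )
        calls = classify_dosage(rc, ploidy=3, background=0.0)
        assert calls["a_hat"].iloc[0] == a_hat
        assert calls["composition"].iloc[0] == label

    def test_equidistant_tie_goes_to_smaller_copy_number(self):
        rc = pd.DataFrame(
            {"track_id": "t", "anchor": "A", "partner": "B", "chrom": "chr1",
             "start": [0], "end": [100_000], "r_anchor": [1.0],
             "r_partner": [1.0]}
        )
        calls = classify_dosage(rc, ploidy=3, background=0.0)
        assert calls["a_hat"].iloc[0] == 1  # midway between 2/3 and 4/3

    def test_anomalous_window_flagged_but_classified(self):
        rc = pd.DataFrame(
            {"track_id": "t", "anchor": "A", "partner": "B", "chrom": "chr1",
             "start": [0], "end": [100_000], "r_anchor": [2.5],
             "r_partner": [0.0]}
        )
        calls = classify_dosage(rc, ploidy=3, background=0.0)
        assert calls["anomalous"].iloc[0]
        assert calls["a_hat"].iloc[0] == 3

    def test_accuracy_on_noisy_simulation(self):
        """>= 99 % of windows called correctly at beta = 0.1, 2x per copy."""
        scenario = SimScenario(
            n_chromosomes=5, chromosome_length=10_000_000, composition="AAB",
            per_copy_depth=2.0, beta=0.1,
            overrides=(
                SegmentOverride("chr2", 0, 100, "ABB"),
                SegmentOverride("chr3", 0, 40, "AAA"),
                SegmentOverride("chr4", 50, 100, "BBB"),
            ),
            seed=12,
        )
        res = simulate_depths(scenario)
        rc = normalize(res.depth_anchor, res.depth_partner, res.window_map)
        calls = classify_dosage(rc, 3, 0.1)
        merged = calls.merge(res.truth_windows, on=["chrom", "start"])
        accuracy = (merged["a_hat"] == merged["a"]).mean()
        assert accuracy >= 0.99


class TestEstimateBackground:
    def _rc(self, beta, noise, seed=3, per_copy_depth=30.0):
        scenario = SimScenario(
            n_chromosomes=4, chromosome_length=10_000_000, composition="AAB",
            per_copy_depth=per_copy_depth, beta=beta, noise=noise,
            overrides=(
                SegmentOverride("chr2", 0, 100, "AAA"),
                SegmentOverride("chr3", 30, 70, "AAA"),
            ),
            seed=seed,
        )
        res = simulate_depths(scenario)
        return normalize(res.depth_anchor, res.depth_partner, res.window_map)

    def test_null_background_recovered(self):
        model = estimate_background(self._rc(0.0, "poisson"), 3)
        assert model.beta < 0.01
        assert model.n_pure_windows > 0

    def test_injected_background_recovered(self):
        model = estimate_background(self._rc(0.05, "poisson"), 3)
        assert model.beta == pytest.approx(0.05, abs=0.01)
        assert model.converged

    def test_noise_free_recovery_is_exact(self):
        model = estimate_background(self._rc(0.04, "none"), 3)
        assert model.beta == pytest.approx(0.04, abs=1e-6)

    def test_no_pure_windows_falls_back_with_warning(self):
        scenario = SimScenario(
            n_chromosomes=2, chromosome_length=5_000_000, composition="AAB",
            beta=0.02, noise="none", seed=1,
        )
        res = simulate_depths(scenario)
        rc = normalize(res.depth_anchor, res.depth_partner, res.window_map)
        with pytest.warns(UserWarning, match="fallback"):
            model = estimate_background(rc, 3, fallback_beta=0.07)
        assert model.beta == 0.07
        assert model.from_fallback


class TestSegment:
    def _calls(self, scenario):
        res = simulate_depths(scenario)
        rc = normalize(res.depth_anchor, res.depth_partner, res.window_map)
        return classify_dosage(rc, scenario.ploidy, scenario.beta), res

    def test_uniform_composition_yields_no_segments(self):
        scenario = SimScenario(n_chromosomes=3, composition="AAB",
                               per_copy_depth=2.5, seed=2)
        calls, _ = self._calls(scenario)
        assert len(segment(calls)) == 0

    def test_planted_segment_recovered_despite_flipped_windows(self):
        scenario = SimScenario(
            n_chromosomes=2, composition="AAB", per_copy_depth=2.5, beta=0.02,
            overrides=(SegmentOverride("chr1", 30, 70, "AAA"),), seed=6,
        )
        calls, res = self._calls(scenario)
        # corrupt two isolated windows inside and outside the segment
        calls.loc[calls.index[10], "composition"] = "AAA"
        calls.loc[calls.index[50], "composition"] = "AAB"
        segs = segment(calls, min_windows=5, smooth_k=5)
        assert len(segs) == 1
        seg, truth = segs.iloc[0], res.truth_segments.iloc[0]
        ws = scenario.window_size
        assert seg["composition"] == "AAA"
        assert abs(seg["start"] - truth["start"]) <= 5 * ws
        assert abs(seg["end"] - truth["end"]) <= 5 * ws
        assert not seg["whole_chromosome"]

    def test_whole_chromosome_exchange_flagged(self):
        scenario = SimScenario(
            n_chromosomes=3, composition="ABB", per_copy_depth=2.5, beta=0.02,
            overrides=(SegmentOverride("chr2", 0, 100, "BBB"),), seed=8,
        )
        calls, _ = self._calls(scenario)
        segs = segment(calls)
        assert len(segs) == 1
        assert segs.iloc[0]["composition"] == "BBB"
        assert segs.iloc[0]["whole_chromosome"]

    def test_short_runs_never_reported(self):
        scenario = SimScenario(
            n_chromosomes=1, composition="AAB", per_copy_depth=2.5, noise="none",
            overrides=(SegmentOverride("chr1", 10, 13, "AAA"),), seed=1,
        )
        calls, _ = self._calls(scenario)
        segs = segment(calls, min_windows=5, smooth_k=1)
        assert len(segs) == 0


class TestChromosomeRatioTable:
    def test_balanced_track_ratio_one(self, two_chrom_lengths):
        rc = make_rc(two_chrom_lengths, 50_000, lambda c, s: 5, lambda c, s: 5)
        table = chromosome_ratio_table(rc)
        assert np.allclose(table["ratio"], 1.0)

    def test_aab_ratio_two_and_introgression_is_minimum(self):
        scenario = SimScenario(
            n_chromosomes=4, composition="AAB", per_copy_depth=2.5, noise="none",
            overrides=(SegmentOverride("chr3", 0, 50, "ABB"),), seed=1,
        )
        res = simulate_depths(scenario)
        rc = normalize(res.depth_anchor, res.depth_partner, res.window_map)
        table = chromosome_ratio_table(rc).set_index("chrom")
        unmodified = table.drop("chr3")
        assert np.allclose(unmodified["ratio"], 2.0)
        assert table["ratio"].idxmin() == "chr3"

    def test_zero_partner_reports_infinite_sentinel(self, two_chrom_lengths):
        rc = make_rc(two_chrom_lengths, 50_000, lambda c, s: 5, lambda c, s: 0)
        table = chromosome_ratio_table(rc)
        assert np.isinf(table["ratio"]).all()


def test_background_model_rejects_out_of_range_beta():
    with pytest.raises(ValueError):
        BackgroundModel(beta=0.6)
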