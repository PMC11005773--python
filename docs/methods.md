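# Methods

This note records the models, parameter choices and numerical conventions
behind the package, and what the simulation-based tests do and do not
establish about real data.

## RAA: model and conventions

RAA treats a sample's properly-paired alignment percentage PP%(s, r) as a
product of two effects: a sample-level technical quality factor q_s
(library quality, PCR duplication, DNA integrity) and a biological affinity
of the sample's genome for reference r. Averaging the sample-to-cluster
ratios over all references estimates q_s as the weight factor w_s, because
the biological affinity is shared by the cluster and cancels in the ratio;
dividing by w_s leaves the affinity signal.

Conventions, and why:

* **The sample is included in its own cluster mean.** Then the cluster mean
  of weight factors is exactly 1 (an algebraic identity, enforced by a
  property test), and RAA is exactly the profile whenever samples are the
  profile times constants averaging to 1.
* **Cluster size minimum** defaults to 3 members: with fewer members the
  cluster mean is dominated by the sample itself and the weight factor
  degenerates toward 1 regardless of quality. Samples without a usable
  cluster get weight 1.0 and are flagged `normalized = False` rather than
  dropped — an unnormalized percentage is still interpretable, a silently
  missing sample is not.
* **Weights outside 0.95–1.05 warn but never error.** The interval is an
  empirical observation about well-behaved short-read panels, not a
  constraint of the model.
* **Per-chromosome RAA recomputes profiles and weights from
  chromosome-scope statistics** instead of reusing genome-scope weights:
  technical effects (e.g. coverage dropouts) can be chromosome-specific.
  RAA is not normalized by chromosome length; values across chromosomes are
  plotted and compared directly.
* pp_percent is carried at 4 decimal places internally and rounded to the
  presentation precision (1 dp) only in plots/reports. Counts follow
  flagstat "primary" semantics: secondary/supplementary records are excluded
  from numerator and denominator; reads on unlisted contigs and unmapped
  reads count in genome scope only. This is stated in the TSV header of
  every stats file the package writes.

## Relative Coverage: model and conventions

Window depths d_anchor, d_partner on the two references of a concatenated
pair are compared only over homologous window pairs (see window map below)
and normalized per chromosome by M_c = mean((d_anchor + d_partner)/2).

* **Why the combined mean:** the combined depth is, in expectation,
  independent of how the p copies split between subgenomes — reads from all
  copies land somewhere in the pair — so M_c ≈ u·p/2 regardless of dosage,
  and a fully exchanged chromosome still reads r ≈ 0 vs r ≈ 2 instead of
  being renormalized to look balanced. Normalizing each track by its own
  mean would erase exactly the signal being sought. A genome-wide baseline
  option exists for the one thing the per-chromosome baseline masks:
  whole-chromosome *total* aneuploidy.
* **Background model:** β is a single cross-mapping rate applied uniformly
  over mapped (conserved) windows. In reality cross-mapping scales with
  local conservation density; the uniform-β model is the simplest one that
  separates background from dosage, and mapped windows are by construction
  the conserved ones. The estimator iterates: classify windows at the
  current β, re-estimate β as the median of (minor-side r)/2 over windows
  called dosage-pure, stop when the change is < 1e-4 (at most 10
  iterations, typically 2). With no pure windows it falls back to a
  configured β with a warning. The median needs the minor-side expected
  window depth to be resolvable (u·p·β per window well above the depth
  quantization); at very low coverage the estimate biases low, which only
  makes dosage calls more conservative.
* **Dosage calling** assigns each window the copy number whose expected
  level 2(a(1−β) + (p−a)β)/p is nearest to the observed r_anchor, ties
  broken toward the smaller copy number (within a 1e-9 floating-point
  tolerance, so exact midpoints behave deterministically). Values are not
  clipped at 2: the 0–2 range is a statistical property, and windows above
  2(1 + 0.1) are flagged anomalous but still classified.
* **Segmentation** smooths composition labels with a centred rolling
  majority over `smooth_k` windows (default 5), run-length encodes, and
  reports runs differing from the accession's modal composition with at
  least `min_windows` windows (default 5, i.e. 500 kb at the default window
  size — segments shorter than that are indistinguishable from noise runs
  at ~7× coverage). A run covering ≥ 95 % of a chromosome's mapped windows
  is flagged whole-chromosome; the 5 % slack absorbs unmapped and
  misclassified edge windows. All of these are artifact decisions — the
  underlying ratio plots are traditionally read by eye — and all are
  config-exposed.
* Composition labels put the anchor reference's letter first: anchor A,
  p = 3, a = 1 → "ABB".

## Depth windows and filtering

Depth is computed from primary, properly paired, non-duplicate records
without XA/SA tags (the bwa uniqueness convention), over each read's
aligned reference span; CIGAR deletions inside reads are not subtracted,
a per-base error that is negligible against a 100-kb window median. Zero
depth positions are included in the median so absent regions score 0 rather
than being skipped. Window size defaults to 100 kb: large enough that the
median is stable at ~7× total coverage, small enough to resolve telomeric
introgressions of a few hundred kb. Pooling sums member tracks window-wise,
the depth-scale equivalent of merging the BAMs of a clonal cluster before
computing depth.

## Window map

Each source window is assigned the partner window with the largest
accumulated aligned-base overlap across all PAF blocks, assuming collinear
base correspondence within a block (block-internal indels shift assignments
by far less than a window). Ties break toward the smaller partner start
coordinate (deterministic); assignments below 20 % of the window size are
marked unmapped and excluded downstream — conserved-fraction thresholds
only remove windows, never reassign them, so lowering the threshold is
monotone. Strand is ignored: depth is strand-symmetric. Consuming a
whole-genome PAF is equivalent to aligning the windows themselves as
queries; the per-base majority-vote oracle in the test suite checks the
equivalence on synthetic cases.

## Simulator

The simulator generates window-level depth directly rather than reads:
expected depths follow the dosage/background model above, and noise is
applied at fragment resolution — fragment counts n ~ Poisson(E[d]·W/L_f)
with L_f = 300 bp (a 2×150 paired-end insert), giving window depth
n·L_f/W. This reproduces the actual sampling error of a 100-kb windowed
median (relative sd ≈ 1/sqrt(E[d]·W/L_f), about 3 % at 4×); drawing the
window depth itself from a Poisson would overstate that error by a factor
of ~sqrt(W/L_f) ≈ 18. Optional negative-binomial overdispersion is
available; a sequence-level route (diverged FASTA pair plus reads drawn per
the dosage mosaic) exists for cross-validation through an external aligner
and is never required by tests.

Defaults mirror the study design the package targets: ~7× total depth per
accession (per-copy depth 7/p), 100-kb windows, triploid AAB/ABB genomes
over 10–11 chromosomes of 100 windows each, per-sample quality multipliers
uniform in 0.95–1.05, and panel affinity profiles {A: 81.8, B: 70.9,
S: 76.0} percent properly paired. Named presets plant the published lineage
mosaics: `plantain_aab` (whole-chr7 ABB plus five telomeric AAA
introgressions on chr4/6/8/9/10, β = 0.03, per-copy depth 2.5×),
`popoulu_aab` and its shorter-chr7 `popoulu_aab_maoli` variant,
`bluggoe_abb`, `pelipita_abb` (whole-chromosome BBB on chr2/7/11,
β = 0.05), and `aaab_africa` (tetraploid, AABB chr7). The stats panel
back-fills read counts at 10⁶ total reads so percentages with ≤ 4 decimals
survive the count round trip exactly.

**What passing tests show, and do not show.** Recovery on these simulations
demonstrates the estimators are correct under their own model: dosage-level
separation at realistic depth, background cancellation, exact weight-factor
algebra. They do not demonstrate robustness to what the generator omits —
repeat-driven spikes (mitigated on real data by the median and the
uniqueness filters), GC and mappability bias, conservation gradients, or
reference assembly errors. Real-data runs should inspect the relative
coverage plots alongside the segment calls.

## Problem sizes and determinism

Simulated analyses use 10–11 chromosomes × 100 windows (1000–1100 windows
per accession) and panels of up to 30 samples; each full pipeline run
completes in seconds. All randomness flows through a single integer seed
per scenario (numpy default_rng); identical seeds give byte-identical
outputs, which the test suite asserts. `scripts/acceptance.py` derives one
sub-seed per scenario from its `--seed` argument and recomputes every
reported value from scratch at run time.

## Known limitations

* β is uniform per reference pair; strongly heterogeneous conservation
  yields locally biased dosage levels (flagged only through residuals).
* The background estimator needs dosage-pure windows; accessions without
  any pure segment fall back to a configured β.
* Segmentation's rolling-majority smoothing can shift true breakpoints by
  up to `smooth_k` windows and cannot resolve events shorter than
  `min_windows`.
* Window-map assignment is winner-take-all per window; windows split evenly
  across rearrangement breakpoints carry partner depth from only the
  majority side.
* RAA is a relative metric: it ranks references within a sample but does
  not by itself yield copy numbers; quantitative dosage comes from
  Relative Coverage.
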