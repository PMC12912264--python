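# Methods

This note documents the models, numerical choices and synthetic-data
assumptions behind desmokit, in the spirit of a package methods appendix.
It states no empirical result beyond what the test suite and
`scripts/acceptance.py` compute themselves.

## FRAP model and fitting

Recovery is modeled as two saturating exponentials sharing a plateau:
`F(t) = M[p_f(1 − e^(−k_f t)) + (1 − p_f)(1 − e^(−k_s t))]` with the
y-intercept pinned to zero (the bleach point defines zero recovery) and
bounds `M ∈ [0,1]`, `p_f ∈ [0,1]`, `k_f ≥ k_s > 0`.  The fast/slow
labeling is enforced after fitting by swapping `(k_f, k_s)` and
`p_f ↔ 1 − p_f` when needed, so the labels are identifiable.

*Normalization.* `normalize_trace` maps the post-bleach value to 0 and the
pre-bleach mean to 1 (full-scale normalization).  No reference-region
photobleaching correction is applied; traces are assumed already
background-corrected.

*Optimization.* Biexponential least squares is multimodal, so each fit
launches from 8 deterministic starts: slow halftimes log-spaced over
(window, window/3, window/10, window/30) crossed with fast/slow rate
ratios (10, 30), with the plateau initialized from the mean of the last
four points and the fast share at 0.15.  The lowest-SSE solution wins;
ties break toward the smaller `k_fast`.  Tolerances are set to 1e-14 so
noiseless traces recover generating parameters to ≤1e-6 relative error.

*Rate lower bound.* Both rates are bounded below by `ln2 / window`
(no halftime longer than the observation window).  Components slower than
the window are not identifiable from the data, and without the bound the
single-trace objective has a flat ridge (`M → 1`, `k_s → 0`) that noise
realizations pull the global optimum onto; those runaway fits would then
be excluded by the plateau-deviation rule, one-sidedly truncating the
cohort.  The bound is inactive for pooled cohort fits at realistic
parameters.

*Quality control.* A trace is excluded when the fit `r² < 0.85`
(`r² = 1 − SSE/SST`, SST about the trace mean) or when
`|plateau − mean(last four observed values)| > 0.25`.  Both rules are
strict inequalities, so values exactly at the boundary are kept.  Even
with the rate bound, a few upward-tilted noisy traces of large-plateau
constructs still trigger the plateau rule; because that exclusion is
one-sided, cohort estimates carry a small negative bias (fractions of a
percentage point at the default noise), which is inherent to the
procedure rather than to this implementation.

*Cohort summary.* The headline parameters come from one fit to all kept
traces' points pooled (invariant to duplicating every trace).  Whether to
pool or to average per-trace fits was an open choice; pooling matches the
convention of fitting the plotted cohort data and is markedly more stable
at realistic noise.  Per-trace fitting remains available via
`fit_two_phase`.  Confidence intervals are nonparametric bootstrap over
traces (2000 resamples by default, seeded), each resample refit from the
full-data estimate; per-timepoint recovery is summarized as mean with a
t-based normal-theory CI.  The packaged construct presets carry the
published cohort mobile fractions and slow halftimes; the fast pool is
set to 10% of the mobile pool (inside the reported 3–15% range) with a
20 s halftime, fixed for reproducibility because no fast-pool halftime is
published.

*Estimation limits.* A Cramér–Rao analysis of the default simulation
design (50 traces, noise sd 0.02, 10 s sampling over 600 s) gives a best
attainable sd of roughly 0.4–0.6 percentage points for the mobile
fraction and 6–13 s for the slow halftime, depending on construct.
Single-seed cohort estimates therefore scatter at that scale around the
generating values; the test suite checks recovery at 5% relative
tolerance, which the pooled estimator meets comfortably.

## Enrichment statistics

Zeros and missing intensities are treated as absent observations
(distinct from a measured 0 in the stored tables); a protein needs at
least two observed values per condition to be tested and is otherwise
reported untested, never enriched.  No imputation is performed — the
t-test stays exact on observed values.  The test is unpaired, equal
variance, two-tailed, on log2 intensities; fold change is the geometric
ratio `2^(mean log2 bait − mean log2 control)`, consistent with testing
in log2 space.  The hit gate is `FC ≥ 10` (inclusive) and `p < 0.001`
(strict); the fold-change operator is configurable because both inclusive
and strict conventions appear in practice.  No multiple-testing
correction enters the gate; a Benjamini–Hochberg q-value column is
emitted for information only.

iBAQ-style abundance subtracts the control average from the bait average
on the **linear** scale and reports log2 of the difference.  Published
iBAQ(log2) columns hold values around 18–22 — log2 of absolute
abundances — which log2-space subtraction (a fold change, typically 1–7)
cannot produce; the linear reading is therefore the default, with
`subtract_scale="log2"` exposed for the geometric-ratio variant.
Proteins with no observed control signal fall back to the bait average
alone.  Percent-of-bait is `100 · 2^(ibaq − ibaq_bait)`, exactly 100 for
the bait; `infer_bait_log2` recovers the bait reference from published
(iBAQ, %) row pairs by averaging `ibaq + log2(100/pct)`.

Over-representation analysis is a generic one-sided hypergeometric tail
with BH adjustment and fold enrichment `(k/n)/(K/N)` — deliberately plain
plumbing, standing in for proprietary pathway software whose curated
content is out of scope.

## Network tiering

The published tier definitions (primary binds the bait; secondary binds
primary but not the bait; and so on) are formalized as unit-weight
shortest-path layering from the root, computed by breadth-first search on
the undirected edge set restricted to the interactome plus root.  A gene
adjacent both to the root and to a primary gene is primary — shortest
distance wins.  The quaternary tier is distance 4; genes farther than
`max_tier` are reported unconnected with reason `beyond_max_tier`,
distinct from `unreachable` (has edges, no path) and `isolated` (no
edges).  Edge direction and evidence tags are ignored: binding is
symmetric.  The partition property (tiers plus unconnected plus root
exactly cover the input, pairwise disjoint) is asserted on every run.

## Synthetic data

Generators are pure functions of (parameters, seed) via
`numpy.random.default_rng`.

* **FRAP traces** sample the model every 10 s for 10 min by default and
  add i.i.d. Gaussian read noise.  Real traces additionally carry
  contraction motion artifacts, acquisition bleaching and reference-drift
  — none are simulated, so passing recovery tests demonstrates correctness
  of the estimator, not robustness to those artifacts.
* **Intensity tables** draw per-protein baselines uniform on log2
  [20, 27] with multiplicative log-normal replicate noise
  (`sd_log2 = sqrt(ln(1+CV²))/ln2`); enriched proteins get their bait
  mean multiplied by the design fold change.  The default CV of 0.2 is a
  package choice of a realistic label-free replicate CV; it is not a
  published value.  Real tables additionally show missing-not-at-random
  dropout and correlated batch structure, which are not emulated.
* **Networks** plant each tier-k gene with at least one edge into tier
  k−1 and add optional extra edges only within a layer or between
  adjacent layers, so no shortcut can shorten a root distance and the
  planted layering is exactly recoverable by construction.
* **Images** place curved random-walk "contact" segments (dilated to
  ~3 px width) on a uniform dim cytoplasm.  Contact intensities vary with
  CV 0.05 around the contact mean, and the channel-2 variates are built
  by exact Gram–Schmidt so the masked Pearson equals the requested level
  exactly before read noise, and contact means are exact (making the
  planted contact/cytoplasm ratio exact).  Images are float64 single
  plane; 16-bit quantization is deliberately avoided because it would
  destroy these exactness guarantees, and multi-plane stacks are reduced
  by maximum projection at read time instead of being simulated.

## Colocalization

The threshold is the classic iterative intermeans fixed point
`T = (mean(pixels ≤ T) + mean(pixels > T))/2`, iterated from the global
mean to convergence (tolerance 1e-9); dark-background polarity takes
pixels above T as foreground.  The exact thresholding variant used by any
given acquisition pipeline is rarely verifiable, so the mask function is
pluggable — any boolean mask can be passed to the downstream statistics.
Pearson is computed on the raw (unthresholded) channel values inside the
mask; constant channels are flagged undefined rather than returning a
number.  The cytoplasm region for enrichment ratios is the cell area
minus the contact mask; with no cell mask supplied the whole frame counts
as cell, which suits synthetic images with uniform background, and an
Otsu-derived cell mask is available for real images.  Letter displays
come from all-pairs Tukey HSD at α = 0.05, with letters assigned per
maximal clique of the non-significance graph.  For two-condition designs
the paired t-test runs on biological-replicate means, not pooled
cell-level points.

## In-silico PCR

Matching is exact (no mismatch or melting-temperature model): products
pair plus-strand forward-primer sites with downstream sites whose
plus-strand sequence is the reverse complement of the reverse primer.
Coordinates are 0-based half-open so length always equals `end − start`.
Isoform templates are assembled by concatenating included exon fragments;
validation uses synthetic exon constructs, since real-gene amplicon sizes
depend on transcript sequence not bundled with the package.

## Known limitations

* Cohort FRAP estimates inherit a small negative bias from the one-sided
  plateau-deviation exclusion (see above); at the default noise this is
  within the seed-to-seed scatter.
* The enrichment t-test assumes equal variances and log-normal noise;
  heavy-tailed real data may need the permutation route the tests use as
  an oracle.
* Tier assignment treats all curated edges as equally reliable and
  undirected; no evidence weighting is attempted.
* The isodata mask is global; images with strong illumination gradients
  need flat-fielding upstream, which the package does not provide.
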