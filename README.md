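# desmokit

A Python toolkit for the desk-scale analyses behind bait-proximity
interactome studies of cardiomyocyte cell–cell junctions: FRAP recovery
kinetics of junctional proteins, BioID-style enrichment selection and
iBAQ quantification, interactome set and abundance comparisons,
hierarchical interaction-network tiering, mask-based colocalization
statistics, and in-silico PCR for splice-isoform discrimination.  Every
input class can be generated in-package with known ground truth, so the
whole pipeline is testable without any external download.

It is written for cell biologists and proteomics analysts who have a
MaxQuant-style protein intensity table, FRAP trace exports, curated
interaction edge lists or two-channel junction images, and want the
statistical machinery those figures are built from as composable,
importable functions.

## The models at the core

**FRAP kinetics.** Recovery of a bleached junctional pool is modeled as a
two-phase association with a common plateau,

```
F(t) = M [ p_f (1 − e^(−k_f t)) + (1 − p_f)(1 − e^(−k_s t)) ],
M ∈ [0,1],  p_f ∈ [0,1],  k_f ≥ k_s > 0,  F(0) = 0,
```

where `M` is the mobile fraction, `p_f` the fast-pool share and
`t½ = ln2/k` the recovery halftimes.  Fits are bounded nonlinear least
squares with deterministic multi-start; traces are excluded when the fit
`r² < 0.85` or when the fitted plateau deviates from the mean of the last
four observed points by more than 0.25.  Cohorts are summarized by a
pooled fit with bootstrap confidence intervals.

**Enrichment.** Per protein, an unpaired equal-variance two-tailed
Student's t-test on log2 intensities (bait vs control, zeros treated as
missing) with geometric fold change `FC = 2^(Δ mean log2)`; a hit
requires `FC ≥ 10` and `p < 0.001`.  Abundance is control-subtracted iBAQ
reported as log2 and as percent of the bait.

**Network tiers.** An interactome is layered around its bait by
unit-weight shortest-path distance in a curated interaction graph:
primary interactors bind the bait directly, secondary interactors reach
it only through a primary gene, and so on to quaternary; everything
farther or unreachable is reported unconnected with a reason code.

**Colocalization.** The analysis channel is masked by iterative-intermeans
(isodata) thresholding with dark-background polarity, Pearson correlation
is computed over the masked pixels only, and contact enrichment is the
contact/cytoplasm mean-intensity ratio.  Groups are compared by one-way
ANOVA with Tukey letter displays, or a paired t-test on replicate means.

## Worked example

`examples/frap_cohort.py` simulates 50 noisy DSG2-preset traces and runs
the full fit → QC → cohort pipeline:

```
construct            : DSG2
traces kept/excluded : 50/0
mobile fraction      : 27.6% (95% CI 26.5-30.0)
slow-pool halftime   : 251.3 s (95% CI 219.5-323.3)
fast pool            : 11.7% of mobile, t1/2 23.5 s
```

The mobile fraction is the share of the junctional pool that exchanges
within the 10-minute window; the slow-pool halftime sets the exchange
timescale of the stable desmosome core.  The generating truth (26.9%,
231.0 s) sits inside both confidence intervals.  The other scripts in
`examples/` walk through enrichment selection, interactome comparison,
network tiering, colocalization and isoform PCR the same way.

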