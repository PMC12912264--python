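"""Fit a synthetic FRAP cohort and summarize junction-protein kinetics.

Simulates 50 noisy recovery traces from the packaged DSG2 preset, fits each
with the constrained two-phase association model, applies the r-squared and
plateau-deviation quality filters, and pools the kept traces into cohort
estimates with bootstrap confidence intervals.
"""

from desmokit.frap import analyze_cohort
from desmokit.synthetic import FRAP_PRESETS, gen_frap_traces

preset = FRAP_PRESETS["DSG2"]
traces = gen_frap_traces(preset, n_traces=50, noise_sd=0.02, seed=1)
summary = analyze_cohort(traces, n_boot=200, seed=1)

print(f"construct            : {preset.name}")
print(f"traces kept/excluded : {summary.n_traces_kept}/{summary.n_excluded}")
print(f"mobile fraction      : {summary.mobile_fraction_pct:.1f}% "
      f"(95% CI {summary.ci95_mobile[0]:.1f}-{summary.ci95_mobile[1]:.1f})")
print(f"slow-pool halftime   : {summary.halftime_slow_s:.1f} s "
      f"(95% CI {summary.ci95_slow[0]:.1f}-{summary.ci95_slow[1]:.1f})")
print(f"fast pool            : {summary.fast_pct_of_mobile:.1f}% of mobile, "
      f"t1/2 {summary.halftime_fast_s:.1f} s")
print()
print("The mobile fraction is the share of the junctional pool that "
      "exchanges within the 10-min window; the slow-pool halftime sets the "
      "exchange timescale of the stable desmosome core (truth: "
      f"{100 * preset.mobile_fraction:.1f}%, {preset.slow_halftime:.1f} s).")
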