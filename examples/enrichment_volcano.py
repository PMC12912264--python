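"""Select proximity-labeling hits from a spiked bait-vs-control table.

Generates a 6-vs-6 replicate log-normal intensity table with 50 proteins
spiked at 20-fold enrichment, removes single-peptide identifications, runs
the log2 t-test volcano statistics, applies the fold-change/p-value gate and
quantifies the hits relative to the bait.
"""

from desmokit.enrichment import (compute_abundance, compute_protein_stats,
                                 filter_min_peptides, select_enriched)
from desmokit.synthetic import SpikeDesign, gen_intensity_table

design = SpikeDesign(n_proteins=1000, n_enriched=50, enriched_fold_change=20.0,
                     replicate_cv=0.2, n_replicates=6,
                     singleton_fraction=0.10, seed=7)
table, truth = gen_intensity_table(design)

filtered, n_removed = filter_min_peptides(table, min_unique=2)
stats = select_enriched(compute_protein_stats(filtered),
                        fc_min=10.0, p_max=0.001)
hits = set(stats.loc[stats["enriched"], "protein_id"])

print(f"proteins in table        : {len(table)}")
print(f"single-peptide removals  : {n_removed}")
print(f"hits passing FC>=10,p<1e-3: {len(hits)}")
print(f"true spikes recovered    : {len(hits & truth)}/{len(truth)}")
print(f"false positives          : {len(hits - truth)}")

bait_id = stats.sort_values("fold_change", ascending=False)["gene"].iloc[0]
abund = compute_abundance(filtered, hits, bait_gene=bait_id)
print("\ntop 5 hits by abundance (percent of bait):")
for _, row in abund.head(5).iterrows():
    print(f"  {row['gene']:>10}  iBAQ(log2)={row['ibaq_log2']:.2f}  "
          f"{row['pct_of_bait']:.1f}%")
print("\nThe gate keeps proteins both strongly and reproducibly enriched "
      "over control; percent-of-bait ranks hits on the absolute scale.")
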