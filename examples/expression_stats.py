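"""Test a gene set's coordinated expression response with Welch + Stouffer.

Generates a log2 expression table for three genes across the four-condition
scratch/treatment design (3 replicates, 2 timepoints) with a planted 2.5-log2
upregulation under scratch + treatment, then runs per-gene Welch t-tests and
combines the p-values into one gene-set-level p with the Stouffer Z-transform.
"""

import woundnet as wn

genes = ["Tnf", "Wnt5a", "Col3a1"]
table = wn.make_expression_table(
    genes,
    effects={(g, "yesScratch-yesTreat"): 2.5 for g in genes},
    noise_sd=0.3,
    seed=0,
)
frame, combined = wn.gene_tests(
    table, "noScratch-noTreat", "yesScratch-yesTreat", timepoint="5h"
)
print("gene     t         df     p")
for row in frame.itertuples(index=False):
    print(f"{row.gene:8s} {row.t:8.3f}  {row.df:5.2f}  {row.p:.4g}")
print(f"Stouffer combined: Z = {combined.z_combined:.3f}, "
      f"p = {combined.p_combined:.3g} over n = {combined.n} genes")
# Individually modest p-values reinforce each other: the combined p asks
# whether the genes respond to the treatment as a coordinated set.
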