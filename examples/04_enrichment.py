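"""Gene-set overlap enrichment for a bound-gene list.

Fisher exact tests against an explicit gene universe with Benjamini-
Hochberg adjustment across sets, plus the chi-square test for unequal
proportions on a single 2x2 table.
"""

from rg4coloc import (
    ContingencyTable2x2,
    chi_square_proportions,
    fisher_exact,
    set_overlap_report,
)

universe = {f"g{i}" for i in range(2000)}
bound = {f"g{i}" for i in range(793)}  # genes bound by the RBP
annotation_sets = {
    "mitochondrial": {f"g{i}" for i in range(700, 793)}
    | {f"g{i}" for i in range(1500, 1600)},
    "glycolysis": {f"g{i}" for i in range(0, 120)},
    "random_set": {f"g{i}" for i in range(1000, 1180)},
}

report = set_overlap_report(bound, annotation_sets, universe)
print(report.to_string(index=False, float_format=lambda x: f"{x:.3g}"))
print(
    "\n'fraction' is overlap / bound genes (mitochondrial: "
    f"{report.set_index('name').loc['mitochondrial', 'fraction']:.1%} of bound)."
)

odds, p_f = fisher_exact(ContingencyTable2x2(8, 2, 2, 8))
stat, p_c = chi_square_proportions(ContingencyTable2x2(20, 10, 10, 20))
print(f"\nFisher [[8,2],[2,8]]: OR={odds:.1f}, two-sided p={p_f:.4f}")
print(f"chi-square [[20,10],[10,20]]: statistic={stat:.3f}, p={p_c:.4f}")
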