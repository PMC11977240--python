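"""Bootstrap colocalization test of binding sites around RG4 anchors.

Half the simulated binding sites sit at Gaussian offsets (mean -25 nt,
sd 10 nt) from planted RG4 midpoints; the test counts (site, RG4) pairs
with offsets in the asymmetric window [-80, +30] nt per anchor and compares
against B random matched-count site sets.
"""

from rg4coloc import SimConfig, classify_pattern, coloc_test, simulate_dataset
from rg4coloc.transcript_model import REGION_ORDER

cfg = SimConfig(n_tx=50, n_sites=400, rho=0.5, seed=42)
_, tms, truth, sites = simulate_dataset(cfg)

results = {}
for lab in [None, *REGION_ORDER]:
    name = "ALL" if lab is None else lab.value
    res = coloc_test(
        sites, truth.rg4_sites, tms, region_filter=lab, B=500, seed=1
    )
    if lab is not None:
        results[lab] = res
    print(
        f"{name:6s} T_obs={res.observed_stat:7.4f}  empirical P={res.empirical_p:.4g}"
        f"  ({res.n_anchors} anchors, {res.n_sites} sites)"
    )

print(
    "\nT_obs is the pair count per anchor inside the [-80,+30] nt window; the"
    "\nempirical P is the fraction of B=500 bootstrap null statistics >= T_obs"
    "\n(no pseudocount, so P can be exactly 0)."
)
print(
    "pattern vs (5'UTR n.s., CDS sig., 3'UTR sig.) reference:",
    classify_pattern(results, alpha=0.05),
)
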