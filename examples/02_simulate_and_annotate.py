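"""Simulate a transcriptome with planted RG4s, then annotate binding sites.

Prints the region proportions of the binding sites (the 5'UTR/CDS/3'UTR
split) and feature densities per kilobase of each region.
"""

from rg4coloc import (
    SimConfig,
    density_per_kb,
    region_proportions,
    simulate_dataset,
)
from rg4coloc.transcript_model import REGION_ORDER

cfg = SimConfig(n_tx=40, n_sites=300, rho=0.5, seed=7)
seqs, tms, truth, sites = simulate_dataset(cfg)
print(f"{len(tms)} transcripts, {len(truth.rg4_sites)} planted RG4s, {len(sites)} sites")

props = region_proportions(sites)
dens_sites = density_per_kb(sites, tms)
dens_rg4 = density_per_kb(truth.rg4_sites, tms)
print(f"{'region':8s} {'site frac':>10s} {'sites/kb':>10s} {'RG4s/kb':>10s}")
for lab in REGION_ORDER:
    print(
        f"{lab.value:8s} {props[lab]:10.3f} {dens_sites[lab]:10.3f} {dens_rg4[lab]:10.3f}"
    )
print(
    "\nPlanted RG4s follow a 3'UTR-predominant distribution (10/35/55%), so the"
    "\nRG4 per-kb density is highest outside the 5'UTR; half the binding sites"
    "\nwere planted near RG4s, which pulls site density toward RG4-rich regions."
)
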