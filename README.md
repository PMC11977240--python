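# rg4coloc

Analysis of RNA G-quadruplex (RG4) / RNA-binding-protein (RBP)
colocalization on mRNAs.

RG4s are four-stranded structures formed by stacked guanine tetrads in
G-rich RNA; several RBPs bind at or near them and modulate their folding.
Given CLIP-derived binding-site peaks, an RG4 catalog (experimental, or
predicted from sequence) and a transcript annotation, this package answers
the questions a transcriptome-scale colocalization study asks:

- **Where does the RBP bind?** Peaks are mapped onto coding transcripts and
  labelled 5'UTR / CDS / 3'UTR; the package reports region proportions and
  densities per kilobase of region.
- **Does the RBP bind near RG4s?** For every same-transcript (RG4, site)
  pair, the signed midpoint offset d = mid(site) − mid(RG4) is profiled; the
  test statistic is the pair count per RG4 anchor inside an asymmetric
  window (default −80..+30 nt). Significance comes from a matched-count
  bootstrap: B random site sets (default B = 1000), each with as many sites
  as the true set and the same widths, placed uniformly over the analyzed
  transcript regions, giving an empirical P-value
  P = #{T_null ≥ T_obs} / B with no pseudocount (P may be exactly 0 or 1).
- **Which RG4s?** A QGRS-style predictor enumerates motifs of four G-runs
  of t ≥ 2 tetrads with loops of 1–36 nt within ≤ 30 nt and scores them with
  a documented surrogate G-score,
  `score = 12·(t−2) + 21 − ceil(mean(loops)) − (max(loop) − min(loop))`,
  so the conventional high-confidence thresholds (19, 21) remain meaningful.
- **What do the targets do?** Flat gene-set overlap enrichment with Fisher
  exact tests against an explicit universe, Benjamini–Hochberg adjustment,
  plus the chi-square test for unequal proportions.

A seeded synthetic-transcriptome generator plants RG4s and binding-site
mixtures with known ground truth, so the whole pipeline runs and is testable
at desk scale without any external downloads.

## Worked example

```python
from rg4coloc import SimConfig, coloc_test, predict_qgrs, simulate_dataset

print(predict_qgrs("GGGAGGGAGGGAGGG")[0])
# RG4Site(tx_id='seq', start=0, end=15, score=32, tetrads=3, source='predicted')

cfg = SimConfig(n_tx=50, n_sites=400, rho=0.5, seed=42)  # 50% colocalized sites
_, tms, truth, sites = simulate_dataset(cfg)
res = coloc_test(sites, truth.rg4_sites, tms, B=500, seed=1)
print(res.observed_stat, res.empirical_p)
# 2.7976190476190474 0.0
```

The three-tetrad motif with loops (1,1,1) scores 12·1 + 21 − 1 − 0 = 32.
In the simulation, 2.80 (site, RG4) pairs per anchor fall in the −80..+30 nt
window; none of the 500 bootstrap null sets reaches that, so the empirical
P is exactly 0 — the planted colocalization is recovered.

The same stages are scriptable from a shell:

```sh
rg4coloc simulate --n-tx 20 --n-sites 200 --seed 3 --out sim/
rg4coloc run-all --annotation sim/annotation.bed --peaks sim/peaks.bed \
    --rg4s sim/truth_rg4.bed --min-score 0 --boot 200 --seed 5 --out out/
```

`out/summary.json` then holds, per region (5'UTR, CDS, 3'UTR and pooled),
the observed windowed statistic and its empirical P, alongside profile
tables, region proportions and the annotated site list. Short narrative
scripts for each capability live in `examples/`.

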