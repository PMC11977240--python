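# Methods

## Coordinate model

All coordinates are 0-based half-open. GFF3 (1-based closed) is converted
on read; BED is native. Transcript coordinate 0 is the 5' end, so on the
minus strand it maps to the genomically rightmost exonic base and a
positive offset always means "toward the 3' end" — distances never need
per-strand sign fixes downstream. A coding transcript is partitioned into
5'UTR `[0, cds_start)`, CDS `[cds_start, cds_end)` and 3'UTR
`[cds_end, length)`; every position carries exactly one label.

Multi-isoform genes are collapsed to one canonical transcript per gene by
default (longest CDS; ties broken by transcript length, then transcript
id), because counting a peak once per isoform would inflate region
proportions. `canonical_policy="all"` disables the collapse. Non-coding
transcripts are excluded from region analyses.

## Peak mapping

A peak is assigned by an anchor base — its midpoint `floor((start+end)/2)`,
or the narrowPeak summit when `summit_policy="summit"`. The anchor must be
exonic in a coding transcript; peaks whose anchor is intronic or intergenic
are counted as unmapped rather than projected, which avoids inventing
spliced peak extents. When several transcripts contain the anchor the one
with the longest CDS wins (then longest transcript, then id). The peak's
transcript-frame interval is the exonic extent of the peak on that
transcript; its region label comes from the anchor. Each peak maps to at
most one transcript.

## QGRS surrogate scorer

A QGRS candidate is four runs of t consecutive Gs (t ≥ `g_min` = 2)
separated by loops of length `loop_min`..`loop_max` (1..36) within a window
of at most `max_qgrs_length` (30) nt. The four runs must come from four
distinct maximal G-runs — equivalently, every loop contains at least one
non-G — so an uninterrupted G stretch is not a QGRS and site boundaries are
unambiguous. N breaks a G-run; loops may contain any base.

The score is

    score = 12·(t − 2) + 21 − ceil(mean(l1, l2, l3)) − (max(l) − min(l)),

floored at 0. It rewards tetrads and short, even loops, and is calibrated
so a minimal G2 motif with loops (1,1,1) scores 20, keeping the
conventional 19/21 thresholds discriminative: only motifs with three or
more tetrads can reach 21. The coefficients are configurable
(`QgrsParams`); the scorer is deliberately documented as *not* numerically
identical to the original QGRS Mapper G-score, whose exact formula is
proprietary to the published tool. Note one consequence of the spread term:
lengthening the shortest loop can raise the score slightly by evening the
loops; monotone decrease is guaranteed only when a longest loop grows.

Overlapping candidates are resolved greedily by (score desc, length asc,
start asc, tetrads desc) — deterministic, and the retained set is maximal:
every candidate either survives or overlaps a kept site.

## Colocalization test

For each same-transcript (RG4, site) pair the signed midpoint offset
d = mid(site) − mid(RG4) is recorded; all pairs with |d| ≤ W (default 200)
enter the profile, not just nearest neighbours, so the profile is
order-independent and matches a window-style density plot. Profiles are
normalized to pairs per anchor per nucleotide; the conservation identity
Σ density · binwidth · n_anchors = n_pairs holds exactly.

The test statistic is T = (# pairs with d in [−80, +30]) / n_anchors — a
pooled windowed count, with per-bin empirical P-values also emitted
(uncorrected) in the profile table. The asymmetric default window reflects
binding that concentrates just upstream of the structured element.

The null is a matched-count bootstrap: B site sets (default 1000), each
with the true set's size and widths, placed uniformly at random over the
analyzed transcript region space. A transcript region is chosen with
probability proportional to its number of admissible start positions
(length − width + 1), then the start is uniform; placements never cross a
region boundary, and overlaps among random sites are allowed. The default
null is stratified by region — each random site stays in its original
region class — because placing sites over the whole transcriptome would
conflate regional site abundance with positional colocalization; a
`transcriptome` mode provides the whole-transcript null. The empirical
P-value is #{T_null ≥ T_obs}/B with no pseudocount; ties count against the
observed statistic, so P can be exactly 0 or exactly 1.

Reproducibility: replicate b uses an RNG substream derived from the master
seed by counter (`SeedSequence(seed, spawn_key=(b,))`), so null statistics
are independent of iteration order and identical seeds give identical
results bit for bit.

A per-region significance pattern (p ≤ α for 5'UTR, CDS, 3'UTR) can be
compared against a reference pattern; the default reference is
(not-significant, significant, significant).

## Enrichment

Gene-set overlap uses Fisher's exact test (two-sided by the
minimum-likelihood rule, via scipy) against an explicit, caller-supplied
universe — the choice of universe (expressed genes vs all genes) changes
the answer, so it is a required input rather than a default. The odds ratio
is the sample odds ratio ad/bc, reported as ∞ when bc = 0.
Benjamini–Hochberg adjustment is applied across sets by default. The
chi-square test for unequal proportions is the Pearson statistic
N(ad − bc)² / ((a+b)(c+d)(a+c)(b+d)), 1 df, no continuity correction.

## Synthetic data generator

The generator emulates what the analysis assumes about real data:

- **Transcripts.** `n_tx` coding transcripts with region lengths drawn
  uniformly from 5'UTR 100–300, CDS 300–1500 (rounded to a codon
  multiple), 3'UTR 300–2000 nt — plausible mRNA scale; conventions, not
  measurements. Each transcript is a single-exon contig: the analysis runs
  in transcript coordinates, and multi-exon conversion is exercised by the
  annotation readers and their property tests instead.
- **Background sequence.** i.i.d. bases with G fraction `g_background`
  (default 0.25); G-runs are truncated at `max_bg_grun` (3). Truncation
  alone cannot rule out four G3-runs with short loops arising by chance, so
  a scrub pass mutates one G in any residual background candidate scoring
  ≥ 21 (never touching planted motifs). The planted catalog is therefore
  exactly the set of high-scoring RG4s, which is what makes ground-truth
  recovery tests meaningful.
- **Planted RG4s.** Poisson(λ = 2) motifs per transcript; the region is
  drawn from (0.10, 0.35, 0.55) over (5'UTR, CDS, 3'UTR) — a
  3'UTR-predominant distribution — and the motif (t ∈ {2,3}, loops 1–7 nt,
  non-G loops, one-base non-G guards) is placed uniformly inside it. Every
  planted motif is detectable by the predictor (the greedy retained set is
  maximal, so a predicted site always overlaps it); its surrogate score is
  recorded in the truth. Two-tetrad motifs score ≤ 20, so analyses of
  planted truth should use `min_score=0`, while the ≥ 21 predicted set
  recovers the three-tetrad subset.
- **Binding sites.** A mixture: round(ρ·n_sites) sites at offset
  round(N(μ, σ)) from a uniformly chosen planted RG4 midpoint (defaults
  μ = −25, σ = 10 nt, chosen so default simulations exercise the asymmetric
  −80..+30 statistic), the remainder uniform over transcript space; widths
  uniform in 20–50 nt (eCLIP-peak scale). Ground truth records the
  colocalized flag and generating anchor per site.

What the generator does **not** emulate: expression-weighted peak
abundance, crosslinking sequence biases, peak-caller artifacts, isoform
mixtures, or genomic (spliced) coordinates. Passing tests therefore show
the statistics behave correctly under the stated model, not that any
particular biological dataset will reproduce a given pattern.

## Problem sizes and numerical choices

The test suite and the acceptance script run the bootstrap at reduced but
statistically meaningful scale: null calibration uses 200 datasets of 30
transcripts / 200 sites with B = 200 and checks the α = 0.05 rejection
rate against the exact binomial 99% envelope; power uses the default
50-transcript / 400-site configuration with B = 500 over 50 replicates.
These sizes give stable pass/fail behaviour in minutes on one CPU.

Degenerate inputs are errors, not silent results: empty site or anchor
sets, empty stat windows, zero-length regions with nonzero counts, B < 1,
non-coding transcripts in region sums, ρ > 0 with no planted anchors.
Midpoints of even-length intervals use floor((s+e)/2). BED score columns
are capped at 1000 for format validity with the true surrogate score in
column 7.

## Known limitations

- The surrogate G-score ranks motifs like the published tool but is not
  numerically identical to it; thresholds transfer by construction, scores
  do not.
- Peaks whose anchor is intronic are dropped rather than spliced onto the
  transcript; studies with predominantly intronic binding need a different
  mapping rule.
- The bootstrap null randomizes site positions only; it preserves site
  counts and widths but not any sequence composition preference of the
  RBP, so sequence-driven confounding (e.g. G-rich binding away from
  G4-forming structure) is outside the model.
- The stratified null conditions on the observed per-region site counts;
  region-level abundance shifts are a question for the density/proportion
  outputs, not the positional test.
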