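"""End-to-end orchestration of the colocalization analysis.

Stages: read annotation -> build/read the RG4 catalog -> map peaks ->
region proportions and densities -> per-region bootstrap colocalization
tests -> optional gene-set enrichment. All outputs are deterministic for a
fixed config (seed included), so identical configs produce byte-identical
bundles.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

from . import __version__
from .binding_sites import (
    density_per_kb,
    fraction_bound_mrnas_with_rg4,
    map_peaks,
    region_proportions,
    write_annotated_sites,
)
from .coloc import (
    DEFAULT_STAT_WINDOW,
    classify_pattern,
    coloc_profile_table,
    coloc_test,
)
from .enrichment import read_gene_sets, set_overlap_report
from .rg4 import (
    QgrsParams,
    filter_by_score,
    predict_catalog,
    read_rg4_bed,
    write_rg4_bed,
)
from .transcript_model import (
    REGION_ORDER,
    read_annotation,
    read_fasta,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Paths and parameters of one pipeline run."""

    annotation: str
    peaks: str
    out_dir: str
    sequences: str | None = None  # FASTA; required unless rg4s is given
    rg4s: str | None = None  # BED6 catalog; else predicted from sequences
    gene_sets: str | None = None
    universe: str | None = None  # one gene id per line; default: annotated genes
    frame: str = "transcript"  # coordinate frame of peaks/rg4s files
    rbp: str = "RBP"
    min_score: int = 21
    qgrs: QgrsParams = field(default_factory=QgrsParams)
    W: int = 200
    binwidth: int = 10
    stat_window: tuple[int, int] = DEFAULT_STAT_WINDOW
    B: int = 1000
    alpha: float = 0.05
    seed: int = 0
    canonical_policy: str = "longest_cds"
    null_mode: str = "stratified"
    profile: bool = True
    plot: bool = False  # additionally write profile_<region>.png

    def validate(self) -> None:
        for fld in ("annotation", "peaks"):
            p = getattr(self, fld)
            if p is None or not Path(p).exists():
                raise FileNotFoundError(f"config field {fld!r}: missing file {p!r}")
        if self.rg4s is None and self.sequences is None:
            raise ValueError("config needs either 'rg4s' or 'sequences'")
        for fld in ("sequences", "rg4s", "gene_sets", "universe"):
            p = getattr(self, fld)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"config field {fld!r}: missing file {p!r}")


def run_pipeline(cfg: RunConfig) -> dict:
    """Run every stage and write the report bundle; returns the summary."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    tms = read_annotation(cfg.annotation, canonical_policy=cfg.canonical_policy)
    coding = [tm for tm in tms if tm.is_coding]
    logger.info("annotation: %d transcripts (%d coding)", len(tms), len(coding))

    if cfg.rg4s is not None:
        rg4s = read_rg4_bed(cfg.rg4s, frame=cfg.frame, tms=coding)
    else:
        seqs = read_fasta(cfg.sequences)
        rg4s = predict_catalog(
            {tm.tx_id: seqs[tm.tx_id] for tm in coding if tm.tx_id in seqs},
            cfg.qgrs,
        )
    rg4s = filter_by_score(rg4s, cfg.min_score)
    write_rg4_bed(rg4s, out / "rg4_catalog.bed")

    sites = map_peaks(cfg.peaks, coding, frame=cfg.frame, rbp=cfg.rbp)
    if not sites:
        raise ValueError("stage map_peaks: no peaks mapped to coding transcripts")
    write_annotated_sites(sites, out / "annotated_sites.tsv")

    props = region_proportions(sites)
    dens_sites = density_per_kb(sites, coding)
    dens_rg4 = density_per_kb(rg4s, coding)
    with open(out / "proportions.tsv", "w") as fh:
        fh.write("#region\tsite_fraction\tsite_density_per_kb\trg4_density_per_kb\n")
        for lab in REGION_ORDER:
            fh.write(
                f"{lab.value}\t{props[lab]:.6f}\t{dens_sites[lab]:.6f}"
                f"\t{dens_rg4[lab]:.6f}\n"
            )

    results = {}
    summary: dict = {
        "schema_version": 1,
        "package_version": __version__,
        "seed": cfg.seed,
        "B": cfg.B,
        "stat_window": list(cfg.stat_window),
        "alpha": cfg.alpha,
        "n_transcripts": len(coding),
        "n_rg4": len(rg4s),
        "n_sites": len(sites),
        "regions": {},
    }
    region_filters = [None, *REGION_ORDER]
    for lab in region_filters:
        name = "ALL" if lab is None else lab.value
        try:
            res = coloc_test(
                sites,
                rg4s,
                coding,
                region_filter=lab,
                B=cfg.B,
                stat_window=cfg.stat_window,
                W=cfg.W,
                seed=cfg.seed,
                null_mode=cfg.null_mode,
            )
        except ValueError as e:
            logger.warning("coloc %s skipped: %s", name, e)
            continue
        if lab is not None:
            results[lab] = res
        summary["regions"][name] = {
            "observed_stat": res.observed_stat,
            "empirical_p": res.empirical_p,
            "n_anchors": res.n_anchors,
            "n_sites": res.n_sites,
        }
        if cfg.profile:
            _, table = coloc_profile_table(
                sites,
                rg4s,
                coding,
                region_filter=lab,
                B=cfg.B,
                W=cfg.W,
                binwidth=cfg.binwidth,
                seed=cfg.seed,
                null_mode=cfg.null_mode,
            )
            table.to_csv(out / f"profile_{name}.tsv", sep="\t", index=False)
            if cfg.plot:
                from .coloc import plot_profile

                plot_profile(table, out / f"profile_{name}.png", title=name)
    if len(results) == 3:
        summary["pattern_vs_reference"] = classify_pattern(results, alpha=cfg.alpha)

    frac = fraction_bound_mrnas_with_rg4(sites, rg4s) if rg4s else 0.0
    summary["fraction_bound_mrnas_with_rg4"] = frac

    if cfg.gene_sets is not None:
        gene_by_tx = {tm.tx_id: tm.gene_id for tm in coding}
        bound = {gene_by_tx[s.tx_id] for s in sites}
        if cfg.universe is not None:
            universe = {
                g.strip()
                for g in Path(cfg.universe).read_text().splitlines()
                if g.strip()
            }
        else:
            universe = set(gene_by_tx.values())
        sets = read_gene_sets(cfg.gene_sets)
        sets = {k: v & universe for k, v in sets.items()}
        report = set_overlap_report(bound & universe, sets, universe)
        report.to_csv(out / "enrichment.tsv", sep="\t", index=False)
        summary["n_gene_sets"] = len(sets)

    (out / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n"
    )
    prov = {
        "config": asdict(cfg),
        "package_version": __version__,
        "schema_version": 1,
    }
    (out / "provenance.json").write_text(
        json.dumps(prov, indent=2, sort_keys=True, default=str) + "\n"
    )
    return summary
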