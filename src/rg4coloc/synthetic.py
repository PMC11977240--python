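"""Seeded synthetic transcriptomes with planted RG4s and binding sites.

The generator emulates the structure the colocalization analysis assumes:
coding transcripts with 5'UTR/CDS/3'UTR partitions, RG4 motifs planted with
a 3'UTR-predominant regional distribution, and binding sites drawn from a
two-component mixture — a colocalized component placed at a Gaussian offset
from a planted RG4 midpoint and a uniform background — with ground truth
recorded for recovery tests.

Background sequence is i.i.d. with a configurable G fraction; background
G-runs are truncated, and any residual background QGRS reaching the
high-score threshold is disrupted by a single G mutation, so the planted
catalog is exactly the set of high-scoring RG4s by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .binding_sites import BindingSite
from .coloc import _build_spaces, _draw_placements
from .rg4 import DEFAULT_PARAMS, QgrsParams, RG4Site, _candidates, score_qgrs
from .transcript_model import (
    GenomicInterval,
    RegionLabel,
    TranscriptModel,
    assign_region,
    region_bounds,
)

_ALPHABET = np.array(list("ACTG"))  # index 3 = G


@dataclass
class SimConfig:
    """Generator parameters; defaults define the standard study conditions."""

    n_tx: int = 50
    len_5utr: tuple[int, int] = (100, 300)
    len_cds: tuple[int, int] = (300, 1500)
    len_3utr: tuple[int, int] = (300, 2000)
    g_background: float = 0.25
    max_bg_grun: int = 3
    rg4_rate: float = 2.0  # expected planted RG4s per transcript
    rg4_region_probs: tuple[float, float, float] = (0.10, 0.35, 0.55)
    n_sites: int = 400
    rho: float = 0.5  # colocalized fraction of binding sites
    offset_mu: float = -25.0  # nucleotides, negative = upstream of the RG4
    offset_sd: float = 10.0
    site_width: tuple[int, int] = (20, 50)
    seed: int = 0
    scrub_background: bool = True
    scrub_min_score: int = 21

    def __post_init__(self) -> None:
        if abs(sum(self.rg4_region_probs) - 1.0) > 1e-9:
            raise ValueError("rg4_region_probs must sum to 1")
        if not (0.0 <= self.rho <= 1.0):
            raise ValueError("rho must be in [0, 1]")
        if not (0.0 <= self.g_background <= 1.0):
            raise ValueError("g_background must be in [0, 1]")
        for lo, hi in (self.len_5utr, self.len_cds, self.len_3utr, self.site_width):
            if not (0 < lo <= hi):
                raise ValueError("length ranges must be nonempty and positive")


@dataclass
class SyntheticTruth:
    """Ground truth of one simulated dataset."""

    rg4_sites: list[RG4Site] = field(default_factory=list)
    rg4_regions: list[RegionLabel] = field(default_factory=list)
    sites: list[BindingSite] = field(default_factory=list)
    colocalized: list[bool] = field(default_factory=list)
    anchor_index: list[int | None] = field(default_factory=list)


def _background_array(
    L: int, g: float, max_run: int, rng: np.random.Generator
) -> np.ndarray:
    p = [(1 - g) / 3] * 3 + [g]
    arr = rng.choice(4, size=L, p=p)
    isg = (arr == 3).astype(np.int8)
    d = np.diff(np.concatenate(([0], isg, [0])))
    starts = np.nonzero(d == 1)[0]
    ends = np.nonzero(d == -1)[0]
    for s, e in zip(starts, ends):
        if e - s > max_run:
            pos = np.arange(s + max_run, e, max_run + 1)
            arr[pos] = rng.integers(0, 3, size=len(pos))
    return arr


def _plant_motif(
    arr: np.ndarray,
    occupied: np.ndarray,
    lo: int,
    hi: int,
    rng: np.random.Generator,
) -> tuple[int, int, int, tuple[int, int, int]] | None:
    """Try to place one four-G-run motif inside [lo, hi); returns
    (start, length, tetrads, loops) or None if it did not fit."""
    t = int(rng.integers(2, 4))  # tetrad count in {2, 3}
    loops = tuple(int(x) for x in rng.integers(1, 8, size=3))
    mlen = 4 * t + sum(loops)
    if hi - lo < mlen:
        return None
    pos = lo + int(rng.integers(0, hi - lo - mlen + 1))
    # guard one base on each side so planted G-runs stay isolated
    glo, ghi = max(0, pos - 1), min(len(arr), pos + mlen + 1)
    if occupied[glo:ghi].any():
        return None
    motif = []
    for k in range(4):
        motif.extend([3] * t)
        if k < 3:
            motif.extend(rng.integers(0, 3, size=loops[k]))
    arr[pos : pos + mlen] = motif
    for gpos in (pos - 1, pos + mlen):
        if 0 <= gpos < len(arr) and arr[gpos] == 3:
            arr[gpos] = int(rng.integers(0, 3))
    occupied[glo:ghi] = True
    return pos, mlen, t, loops


def _scrub_background(
    arr: np.ndarray,
    footprint: np.ndarray,
    min_score: int,
    params: QgrsParams,
    max_iter: int = 50,
) -> None:
    """Mutate one G per residual background QGRS scoring >= min_score.

    Candidates overlapping a planted footprint are left untouched."""
    for _ in range(max_iter):
        seq = "".join(_ALPHABET[arr])
        mutated: set[int] = set()
        for a, e, _t, _loops, sc in _candidates(seq, params):
            if sc < min_score or footprint[a:e].any():
                continue
            for i in range(a, e):
                if arr[i] == 3 and i not in mutated:
                    arr[i] = 0  # G -> A breaks the run
                    mutated.add(i)
                    break
        if not mutated:
            return


def simulate_transcriptome(
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
    params: QgrsParams = DEFAULT_PARAMS,
) -> tuple[dict[str, str], list[TranscriptModel], SyntheticTruth]:
    """Generate sequences, transcript models and planted-RG4 ground truth.

    Each transcript is modeled as its own single-exon contig (analysis runs
    in transcript coordinates; multi-exon coordinate conversion is exercised
    by real annotations, not by the generator). Reproducible under
    cfg.seed."""
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=(0,)))
    seqs: dict[str, str] = {}
    tms: list[TranscriptModel] = []
    truth = SyntheticTruth()
    region_probs = np.asarray(cfg.rg4_region_probs)
    for i in range(cfg.n_tx):
        tx_id = f"TX{i:04d}"
        l5 = int(rng.integers(cfg.len_5utr[0], cfg.len_5utr[1] + 1))
        lc = int(rng.integers(cfg.len_cds[0], cfg.len_cds[1] + 1))
        lc = max(3, lc - lc % 3)  # coding frame
        l3 = int(rng.integers(cfg.len_3utr[0], cfg.len_3utr[1] + 1))
        L = l5 + lc + l3
        tm = TranscriptModel(
            tx_id,
            f"GENE{i:04d}",
            tx_id,
            "+",
            (GenomicInterval(tx_id, 0, L, "+"),),
            l5,
            l5 + lc,
        )
        arr = _background_array(L, cfg.g_background, cfg.max_bg_grun, rng)
        occupied = np.zeros(L, dtype=bool)
        n_rg4 = int(rng.poisson(cfg.rg4_rate))
        for _ in range(n_rg4):
            placed = None
            for _attempt in range(100):
                label = (RegionLabel.FIVE_UTR, RegionLabel.CDS, RegionLabel.THREE_UTR)[
                    int(rng.choice(3, p=region_probs))
                ]
                lo, hi = region_bounds(tm, label)
                placed = _plant_motif(arr, occupied, lo, hi, rng)
                if placed is not None:
                    break
            if placed is None:
                raise RuntimeError(
                    f"{tx_id}: could not place an RG4 motif after 100 attempts"
                )
            pos, mlen, t, loops = placed
            truth.rg4_sites.append(
                RG4Site(
                    tx_id,
                    pos,
                    pos + mlen,
                    score_qgrs(t, loops, params),
                    tetrads=t,
                    source="experimental",
                )
            )
            truth.rg4_regions.append(assign_region(tm, (2 * pos + mlen) // 2))
        if cfg.scrub_background:
            _scrub_background(arr, occupied, cfg.scrub_min_score, params)
        seqs[tx_id] = "".join(_ALPHABET[arr])
        tms.append(tm)
    return seqs, tms, truth


def simulate_binding_sites(
    cfg: SimConfig,
    truth: SyntheticTruth,
    tms: Sequence[TranscriptModel],
    rng: np.random.Generator | None = None,
    rbp: str = "SIM",
) -> tuple[list[BindingSite], SyntheticTruth]:
    """Place binding sites: a colocalized fraction rho at Gaussian offsets
    from planted RG4 midpoints, the rest uniform over transcript space."""
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=(1,)))
    n_coloc = int(np.rint(cfg.rho * cfg.n_sites))
    n_bg = cfg.n_sites - n_coloc
    if n_coloc > 0 and not truth.rg4_sites:
        raise ValueError("rho > 0 requires at least one planted RG4 anchor")
    by_tx = {tm.tx_id: tm for tm in tms}
    sites: list[BindingSite] = []
    truth.sites = sites
    truth.colocalized = []
    truth.anchor_index = []
    w_lo, w_hi = cfg.site_width
    for _ in range(n_coloc):
        k = int(rng.integers(0, len(truth.rg4_sites)))
        anchor = truth.rg4_sites[k]
        tm = by_tx[anchor.tx_id]
        off = int(np.rint(rng.normal(cfg.offset_mu, cfg.offset_sd)))
        w = int(rng.integers(w_lo, w_hi + 1))
        start = anchor.mid + off - w // 2
        start = min(max(start, 0), tm.length - w)
        sites.append(
            BindingSite(
                rbp, tm.tx_id, start, start + w, assign_region(tm, start + w // 2)
            )
        )
        truth.colocalized.append(True)
        truth.anchor_index.append(k)
    if n_bg:
        space = _build_spaces(tms, None, "transcriptome", W=0)
        widths = rng.integers(w_lo, w_hi + 1, size=n_bg).astype(np.int64)
        idx, start = _draw_placements(space, widths, [None] * n_bg, rng)
        for i in range(n_bg):
            tx = space.tx_ids[space.tx_index[idx[i]]]
            s, w = int(start[i]), int(widths[i])
            sites.append(
                BindingSite(
                    rbp, tx, s, s + w, assign_region(by_tx[tx], s + w // 2)
                )
            )
            truth.colocalized.append(False)
            truth.anchor_index.append(None)
    return sites, truth


def simulate_dataset(
    cfg: SimConfig,
) -> tuple[dict[str, str], list[TranscriptModel], SyntheticTruth, list[BindingSite]]:
    """Convenience: transcriptome + binding sites in one call."""
    seqs, tms, truth = simulate_transcriptome(cfg)
    sites, truth = simulate_binding_sites(cfg, truth, tms)
    return seqs, tms, truth, sites


def write_truth(
    truth: SyntheticTruth, out_dir: str | Path, prefix: str = "truth"
) -> None:
    """Write ground truth: RG4 BED6+, sites BED6 with colocalized flag in
    column 7, and a JSON summary."""
    import json

    from .rg4 import write_rg4_bed

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_rg4_bed(truth.rg4_sites, out / f"{prefix}_rg4.bed")
    rows = []
    for s, flag in zip(truth.sites, truth.colocalized):
        rows.append(
            f"{s.tx_id}\t{s.start}\t{s.end}\t{s.rbp}\t0\t+\t{int(flag)}"
        )
    (out / f"{prefix}_sites.bed").write_text("\n".join(rows) + ("\n" if rows else ""))
    summary = {
        "n_rg4": len(truth.rg4_sites),
        "n_sites": len(truth.sites),
        "n_colocalized": int(sum(truth.colocalized)),
        "rg4_regions": {
            lab.value: sum(1 for r in truth.rg4_regions if r is lab)
            for lab in RegionLabel
        },
    }
    (out / f"{prefix}.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
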