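"""Colocalization of RBP binding sites with RG4 anchors.

The observed signal is a signed-offset profile: for every same-transcript
(RG4, binding site) pair the offset d = mid(site) - mid(RG4) is recorded
(positive = site downstream, toward the 3' end). The test statistic T is the
number of pairs with offset inside an asymmetric window around the anchor
(default -80..+30 nt) divided by the number of anchors. Significance is
assessed against a matched-count bootstrap null: B random site sets, each
with as many sites as the true set and the same site widths, placed
uniformly over the analyzed transcript region space. The empirical P-value
is #{T_null >= T_obs} / B with no pseudocount, so P may be exactly 0 or 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .binding_sites import BindingSite
from .rg4 import RG4Site
from .transcript_model import (
    REGION_ORDER,
    RegionLabel,
    TranscriptModel,
    assign_region,
    region_bounds,
)

DEFAULT_STAT_WINDOW = (-80, 30)


@dataclass
class DensityProfile:
    """Binned pair density around anchors: pairs per anchor per nucleotide."""

    offsets: np.ndarray  # bin centers, nucleotides
    binwidth: int
    density: np.ndarray
    n_anchors: int
    n_pairs: int


@dataclass
class ColocResult:
    """Observed windowed statistic, bootstrap null and empirical P."""

    region: str  # region label value or "ALL"
    observed_stat: float
    null_stats: list[float]
    empirical_p: float
    stat_window: tuple[int, int]
    B: int
    seed: int
    n_anchors: int
    n_sites: int


# ---------------------------------------------------------------------------
# offsets and profiles


def _anchor_mids_by_tx(
    rg4s: Sequence[RG4Site],
    tms: Sequence[TranscriptModel],
    region_filter: RegionLabel | None,
) -> dict[str, np.ndarray]:
    by_tx_tm = {tm.tx_id: tm for tm in tms}
    mids: dict[str, list[int]] = {}
    for r in rg4s:
        tm = by_tx_tm.get(r.tx_id)
        if tm is None or not tm.is_coding:
            continue
        if region_filter is not None and assign_region(tm, r.mid) is not region_filter:
            continue
        mids.setdefault(r.tx_id, []).append(r.mid)
    return {tx: np.sort(np.asarray(v, dtype=np.int64)) for tx, v in mids.items()}


def _filter_sites(
    sites: Sequence[BindingSite], region_filter: RegionLabel | None
) -> list[BindingSite]:
    if region_filter is None:
        return list(sites)
    return [s for s in sites if s.region is region_filter]


def site_rg4_offsets(
    sites: Sequence[BindingSite],
    rg4s: Sequence[RG4Site],
    tms: Sequence[TranscriptModel],
    region_filter: RegionLabel | None = None,
    W: int = 200,
) -> list[int]:
    """Signed midpoint offsets for all same-transcript (RG4, site) pairs.

    Every pair with |d| <= W is reported (all pairs, not nearest-only);
    both features must pass the region filter.
    """
    anchors = _anchor_mids_by_tx(rg4s, tms, region_filter)
    offsets: list[int] = []
    for s in _filter_sites(sites, region_filter):
        a = anchors.get(s.tx_id)
        if a is None:
            continue
        d = s.mid - a
        offsets.extend(int(x) for x in d[(d >= -W) & (d <= W)])
    return offsets


def density_profile(
    offsets: Sequence[int], W: int, binwidth: int, n_anchors: int
) -> DensityProfile:
    """Histogram offsets over [-W, +W] normalized per anchor per nucleotide."""
    if n_anchors <= 0:
        raise ValueError("n_anchors must be positive")
    if (2 * W) % binwidth != 0:
        raise ValueError("binwidth must divide 2W")
    edges = np.arange(-W, W + binwidth, binwidth)
    counts, _ = np.histogram(np.asarray(list(offsets)), bins=edges)
    centers = (edges[:-1] + edges[1:]) / 2.0
    return DensityProfile(
        offsets=centers,
        binwidth=binwidth,
        density=counts / (n_anchors * binwidth),
        n_anchors=n_anchors,
        n_pairs=int(counts.sum()),
    )


def windowed_stat(
    offsets: Sequence[int],
    n_anchors: int,
    stat_window: tuple[int, int] = DEFAULT_STAT_WINDOW,
) -> float:
    """Pairs per anchor with offset in [d_lo, d_hi] (inclusive bounds)."""
    d_lo, d_hi = stat_window
    if d_lo > d_hi:
        raise ValueError("empty stat window")
    if n_anchors <= 0:
        raise ValueError("n_anchors must be positive")
    arr = np.asarray(list(offsets))
    if arr.size == 0:
        return 0.0
    return float(np.count_nonzero((arr >= d_lo) & (arr <= d_hi))) / n_anchors


# ---------------------------------------------------------------------------
# matched-count bootstrap null


@dataclass
class _PlacementSpace:
    """Flattened placement regions with a shared global coordinate frame.

    Each space is one (transcript, region) stretch sites can land in. Global
    coordinates separate transcripts by more than the profile window so a
    single sorted array supports same-transcript pair counting."""

    tx_ids: list[str]
    tx_index: np.ndarray  # per space
    r_start: np.ndarray  # region start in transcript coords
    r_len: np.ndarray
    labels: list[RegionLabel | None]
    stride: int  # global coordinate stride between transcripts


def _build_spaces(
    tms: Sequence[TranscriptModel],
    region_filter: RegionLabel | None,
    mode: str,
    W: int,
) -> _PlacementSpace:
    coding = sorted(
        (tm for tm in tms if tm.is_coding), key=lambda t: t.tx_id
    )
    if not coding:
        raise ValueError("no coding transcripts")
    stride = max(tm.length for tm in coding) + 2 * W + 2
    tx_ids, tx_index, r_start, r_len, labels = [], [], [], [], []
    for i, tm in enumerate(coding):
        tx_ids.append(tm.tx_id)
        if mode == "transcriptome" and region_filter is None:
            regions: list[tuple[RegionLabel | None, int, int]] = [
                (None, 0, tm.length)
            ]
        else:
            wanted = REGION_ORDER if region_filter is None else (region_filter,)
            regions = []
            for lab in wanted:
                lo, hi = region_bounds(tm, lab)
                regions.append((lab, lo, hi - lo))
        for lab, lo, ln in regions:
            if ln <= 0:
                continue
            tx_index.append(i)
            r_start.append(lo)
            r_len.append(ln)
            labels.append(lab)
    return _PlacementSpace(
        tx_ids=tx_ids,
        tx_index=np.asarray(tx_index, dtype=np.int64),
        r_start=np.asarray(r_start, dtype=np.int64),
        r_len=np.asarray(r_len, dtype=np.int64),
        labels=labels,
        stride=stride,
    )


def _draw_placements(
    space: _PlacementSpace,
    widths: np.ndarray,
    labels: Sequence[RegionLabel | None],
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Place one random site per input width; returns (space_idx, start).

    ``labels[i]`` restricts site i to spaces with that label (stratified
    null); None means any space. Transcript regions are chosen with
    probability proportional to the number of admissible start positions
    (region length - width + 1), then the start is uniform. Draw order is
    fixed (label group in region order, widths ascending) so results are
    reproducible."""
    n = len(widths)
    space_idx = np.empty(n, dtype=np.int64)
    start = np.empty(n, dtype=np.int64)
    lab_keys = [lab.value if lab is not None else "" for lab in labels]
    order_groups: list[tuple[str, RegionLabel | None]] = []
    seen = set()
    for lab in [None, *REGION_ORDER]:
        key = lab.value if lab is not None else ""
        if key in lab_keys and key not in seen:
            order_groups.append((key, lab))
            seen.add(key)
    for key, lab in order_groups:
        grp = np.asarray([i for i, k in enumerate(lab_keys) if k == key])
        cand = (
            np.arange(len(space.labels))
            if lab is None
            else np.asarray(
                [j for j, sl in enumerate(space.labels) if sl is lab or sl is None]
            )
        )
        if cand.size == 0:
            raise ValueError(f"empty placement space for {lab}")
        lens = space.r_len[cand]
        for w in np.unique(widths[grp]):
            sub = grp[widths[grp] == w]
            avail = np.maximum(lens - w + 1, 0)
            total = avail.sum()
            if total == 0:
                raise ValueError(
                    f"no region of the placement space fits width {int(w)}"
                )
            picks = rng.choice(cand.size, size=sub.size, p=avail / total)
            space_idx[sub] = cand[picks]
            start[sub] = space.r_start[cand[picks]] + rng.integers(
                0, avail[picks]
            )
    return space_idx, start


def bootstrap_random_sites(
    sites: Sequence[BindingSite],
    tms: Sequence[TranscriptModel],
    region_filter: RegionLabel | None = None,
    seed: int = 0,
    mode: str = "stratified",
    rng: np.random.Generator | None = None,
) -> list[BindingSite]:
    """One bootstrap replicate: as many random sites as the true set.

    Each output site keeps one input site's width and is placed uniformly
    over the analyzed region space. mode="stratified" (default) keeps each
    site inside its original region class; mode="transcriptome" places sites
    anywhere on the transcripts. Overlaps among random sites are permitted.
    """
    filt = _filter_sites(sites, region_filter)
    if not filt:
        return []
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(seed))
    space = _build_spaces(tms, region_filter, mode, W=0)
    widths = np.asarray([s.end - s.start for s in filt], dtype=np.int64)
    labels = (
        [s.region for s in filt]
        if (mode == "stratified" and region_filter is None)
        else [region_filter] * len(filt)
    )
    space_idx, start = _draw_placements(space, widths, labels, rng)
    by_tx = {tm.tx_id: tm for tm in tms}
    out = []
    for i in range(len(filt)):
        j = space_idx[i]
        tx = space.tx_ids[space.tx_index[j]]
        s, e = int(start[i]), int(start[i] + widths[i])
        out.append(
            BindingSite(
                rbp=filt[i].rbp,
                tx_id=tx,
                start=s,
                end=e,
                region=assign_region(by_tx[tx], (s + e) // 2),
            )
        )
    return out


def _global_anchor_array(
    anchors: Mapping[str, np.ndarray], space: _PlacementSpace
) -> np.ndarray:
    tx_pos = {tx: i for i, tx in enumerate(space.tx_ids)}
    parts = [
        anchors[tx] + tx_pos[tx] * space.stride
        for tx in anchors
        if tx in tx_pos
    ]
    if not parts:
        return np.empty(0, dtype=np.int64)
    return np.sort(np.concatenate(parts))


def _count_pairs(
    anchor_global: np.ndarray, mids_global: np.ndarray, d_lo: int, d_hi: int
) -> int:
    # d = mid - anchor in [d_lo, d_hi]  <=>  anchor in [mid - d_hi, mid - d_lo]
    hi = np.searchsorted(anchor_global, mids_global - d_lo, side="right")
    lo = np.searchsorted(anchor_global, mids_global - d_hi, side="left")
    return int((hi - lo).sum())


def empirical_pvalue(observed: float, null_stats: Sequence[float]) -> float:
    """#{null >= observed} / B, no pseudocount; ties count as >=, so the
    result may be exactly 0 or exactly 1."""
    null_arr = np.asarray(list(null_stats), dtype=float)
    if null_arr.size == 0:
        raise ValueError("need at least one null statistic")
    return float(np.count_nonzero(null_arr >= observed)) / null_arr.size


def coloc_test(
    sites: Sequence[BindingSite],
    rg4s: Sequence[RG4Site],
    tms: Sequence[TranscriptModel],
    region_filter: RegionLabel | None = None,
    B: int = 1000,
    stat_window: tuple[int, int] = DEFAULT_STAT_WINDOW,
    W: int = 200,
    seed: int = 0,
    null_mode: str = "stratified",
) -> ColocResult:
    """Matched-count bootstrap colocalization test.

    Observed statistic: pairs per anchor with offset in ``stat_window``.
    Null: B independent random site sets (seed-derived substreams, one per
    replicate, so results do not depend on iteration order); empirical
    P = #{T_null >= T_obs} / B without pseudocount.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    d_lo, d_hi = stat_window
    if d_lo > d_hi:
        raise ValueError("empty stat window")
    if not (-W <= d_lo and d_hi <= W):
        raise ValueError("stat_window must lie within [-W, W]")
    anchors = _anchor_mids_by_tx(rg4s, tms, region_filter)
    n_anchors = sum(len(v) for v in anchors.values())
    filt = _filter_sites(sites, region_filter)
    if n_anchors == 0 or not filt:
        raise ValueError("need >= 1 RG4 anchor and >= 1 site after filtering")

    space = _build_spaces(tms, region_filter, null_mode, W)
    anchor_global = _global_anchor_array(anchors, space)
    tx_pos = {tx: i for i, tx in enumerate(space.tx_ids)}

    obs_mids = np.asarray(
        [s.mid + tx_pos[s.tx_id] * space.stride for s in filt if s.tx_id in tx_pos],
        dtype=np.int64,
    )
    t_obs = _count_pairs(anchor_global, obs_mids, d_lo, d_hi) / n_anchors

    widths = np.asarray([s.end - s.start for s in filt], dtype=np.int64)
    labels = (
        [s.region for s in filt]
        if (null_mode == "stratified" and region_filter is None)
        else [region_filter] * len(filt)
    )
    null_stats = []
    for b in range(B):
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(b,)))
        space_idx, start = _draw_placements(space, widths, labels, rng)
        mids = (
            space.tx_index[space_idx] * space.stride + start + widths // 2
        )
        null_stats.append(
            _count_pairs(anchor_global, np.sort(mids), d_lo, d_hi) / n_anchors
        )
    p = empirical_pvalue(t_obs, null_stats)
    return ColocResult(
        region=region_filter.value if region_filter is not None else "ALL",
        observed_stat=float(t_obs),
        null_stats=[float(x) for x in null_stats],
        empirical_p=p,
        stat_window=stat_window,
        B=B,
        seed=seed,
        n_anchors=n_anchors,
        n_sites=len(filt),
    )


def coloc_profile_table(
    sites: Sequence[BindingSite],
    rg4s: Sequence[RG4Site],
    tms: Sequence[TranscriptModel],
    region_filter: RegionLabel | None = None,
    B: int = 1000,
    W: int = 200,
    binwidth: int = 10,
    seed: int = 0,
    null_mode: str = "stratified",
):
    """Observed profile plus per-bin bootstrap envelope.

    Returns (DensityProfile, pandas.DataFrame) with columns bin_center,
    observed_density, null_mean, null_q025, null_q975, empirical_p_bin.
    Per-bin empirical P-values are raw (uncorrected) bootstrap tail
    fractions, one per bin."""
    import pandas as pd

    anchors = _anchor_mids_by_tx(rg4s, tms, region_filter)
    n_anchors = sum(len(v) for v in anchors.values())
    filt = _filter_sites(sites, region_filter)
    if n_anchors == 0 or not filt:
        raise ValueError("need >= 1 RG4 anchor and >= 1 site after filtering")
    obs_offsets = site_rg4_offsets(sites, rg4s, tms, region_filter, W)
    prof = density_profile(obs_offsets, W, binwidth, n_anchors)

    space = _build_spaces(tms, region_filter, null_mode, W)
    anchor_global = _global_anchor_array(anchors, space)
    widths = np.asarray([s.end - s.start for s in filt], dtype=np.int64)
    labels = (
        [s.region for s in filt]
        if (null_mode == "stratified" and region_filter is None)
        else [region_filter] * len(filt)
    )
    edges = np.arange(-W, W + binwidth, binwidth)
    null_dens = np.empty((B, len(edges) - 1))
    for b in range(B):
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(b,)))
        space_idx, start = _draw_placements(space, widths, labels, rng)
        mids = space.tx_index[space_idx] * space.stride + start + widths // 2
        lo = np.searchsorted(anchor_global, mids - W, side="left")
        hi = np.searchsorted(anchor_global, mids + W, side="right")
        offs = []
        for i in np.nonzero(hi > lo)[0]:
            offs.append(mids[i] - anchor_global[lo[i] : hi[i]])
        arr = np.concatenate(offs) if offs else np.empty(0, dtype=np.int64)
        counts, _ = np.histogram(arr, bins=edges)
        null_dens[b] = counts / (n_anchors * binwidth)
    table = pd.DataFrame(
        {
            "bin_center": prof.offsets,
            "observed_density": prof.density,
            "null_mean": null_dens.mean(axis=0),
            "null_q025": np.quantile(null_dens, 0.025, axis=0),
            "null_q975": np.quantile(null_dens, 0.975, axis=0),
            "empirical_p_bin": (null_dens >= prof.density).mean(axis=0),
        }
    )
    return prof, table


def plot_profile(table, path, title: str = "") -> None:
    """Plot an observed density profile with its bootstrap null envelope.

    ``table`` is the DataFrame from :func:`coloc_profile_table`."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 3.5))
    ax.fill_between(
        table["bin_center"],
        table["null_q025"],
        table["null_q975"],
        color="0.8",
        label="null 95% envelope",
    )
    ax.plot(table["bin_center"], table["null_mean"], color="0.5", lw=1, label="null mean")
    ax.plot(
        table["bin_center"], table["observed_density"], color="C3", lw=1.5, label="observed"
    )
    ax.axvline(0, color="k", lw=0.5, ls=":")
    ax.set_xlabel("offset from RG4 midpoint (nt)")
    ax.set_ylabel("pairs / anchor / nt")
    if title:
        ax.set_title(title)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


REFERENCE_PATTERN = (False, True, True)  # (5'UTR, CDS, 3'UTR) significance


def classify_pattern(
    results: Mapping[RegionLabel, ColocResult],
    alpha: float = 0.05,
    reference: tuple[bool, bool, bool] = REFERENCE_PATTERN,
) -> str:
    """Compare a per-region significance pattern with a reference pattern.

    The default reference encodes significant colocalization in CDS and
    3'UTR but not 5'UTR. Returns "same" or "different"."""
    missing = [lab.name for lab in REGION_ORDER if lab not in results]
    if missing:
        raise ValueError(f"missing region result(s): {', '.join(missing)}")
    pattern = tuple(results[lab].empirical_p <= alpha for lab in REGION_ORDER)
    return "same" if pattern == reference else "different"
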