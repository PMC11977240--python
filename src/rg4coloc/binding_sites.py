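"""RBP binding-site ingestion, transcript mapping and region statistics.

Peaks (BED6 or ENCODE narrowPeak) are mapped onto coding transcripts by an
anchor base — the peak midpoint by default, or the narrowPeak summit — and
labelled 5'UTR/CDS/3'UTR by that anchor. One peak maps to at most one
transcript (the canonical set is expected; ties go to the longest CDS).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .rg4 import RG4Site
from .transcript_model import (
    REGION_ORDER,
    GenomicInterval,
    RegionLabel,
    TranscriptModel,
    assign_region,
    genomic_to_transcript,
    region_lengths,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BindingSite:
    """An RBP peak in transcript coordinates with its region label."""

    rbp: str
    tx_id: str
    start: int
    end: int
    region: RegionLabel
    source_interval: GenomicInterval | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty binding site [{self.start}, {self.end})")

    @property
    def mid(self) -> int:
        return (self.start + self.end) // 2


def _parse_peak_line(f: list[str], lineno: int) -> tuple[str, int, int, int | None]:
    """Return (chrom, start, end, summit_offset or None)."""
    try:
        chrom, start, end = f[0], int(f[1]), int(f[2])
        summit = int(f[9]) if len(f) >= 10 else None
        if summit is not None and summit < 0:
            summit = None  # narrowPeak convention: -1 = no summit called
    except (ValueError, IndexError) as e:
        raise ValueError(f"line {lineno}: malformed peak line ({e})") from e
    return chrom, start, end, summit


def read_peaks(path: str | Path) -> list[tuple[str, int, int, int | None]]:
    """Read BED6 or narrowPeak rows as (chrom, start, end, summit)."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 3:
                raise ValueError(f"line {lineno}: need >= 3 columns")
            rows.append(_parse_peak_line(f, lineno))
    return rows


def map_peaks(
    peaks: str | Path | Sequence[tuple[str, int, int, int | None]],
    tms: Sequence[TranscriptModel],
    frame: str = "genomic",
    rbp: str = "RBP",
    summit_policy: str = "midpoint",
) -> list[BindingSite]:
    """Map peaks to transcripts and label their region.

    frame="transcript": column 1 is a transcript id and coordinates are
    transcript coordinates already. frame="genomic": the anchor base
    (midpoint, or summit with summit_policy="summit") must fall in an exon of
    a coding transcript; the peak's exonic extent around the anchor becomes
    the transcript interval. Unmapped peaks are counted and logged.
    """
    if isinstance(peaks, (str, Path)):
        peaks = read_peaks(peaks)
    coding = [tm for tm in tms if tm.is_coding]
    by_tx = {tm.tx_id: tm for tm in coding}
    by_chrom: dict[str, list[TranscriptModel]] = {}
    # deterministic candidate order encoding the tie-break: longest CDS,
    # then longest transcript, then tx_id
    for tm in sorted(coding, key=lambda t: (-t.cds_length, -t.length, t.tx_id)):
        by_chrom.setdefault(tm.chrom, []).append(tm)

    sites: list[BindingSite] = []
    unmapped = 0
    for chrom, start, end, summit in peaks:
        if frame == "transcript":
            tm = by_tx.get(chrom)
            if tm is None or end > tm.length:
                unmapped += 1
                continue
            anchor = (
                start + summit
                if (summit_policy == "summit" and summit is not None)
                else (start + end) // 2
            )
            sites.append(
                BindingSite(rbp, tm.tx_id, start, end, assign_region(tm, anchor))
            )
            continue
        g_anchor = (
            start + summit
            if (summit_policy == "summit" and summit is not None)
            else (start + end) // 2
        )
        hit = None
        for tm in by_chrom.get(chrom, []):
            t_anchor = genomic_to_transcript(tm, g_anchor)
            if t_anchor is not None:
                hit = (tm, t_anchor)
                break
        if hit is None:
            unmapped += 1
            continue
        tm, t_anchor = hit
        tpos = sorted(
            t
            for g in range(start, end)
            if (t := genomic_to_transcript(tm, g)) is not None
        )
        sites.append(
            BindingSite(
                rbp,
                tm.tx_id,
                tpos[0],
                tpos[-1] + 1,
                assign_region(tm, t_anchor),
                source_interval=GenomicInterval(chrom, start, end, tm.strand),
            )
        )
    if unmapped:
        logger.info("map_peaks: %d peak(s) unmapped", unmapped)
    return sites


def region_proportions(sites: Sequence[BindingSite]) -> dict[RegionLabel, float]:
    """Fraction of binding sites per region; fractions sum to 1."""
    if not sites:
        raise ValueError("no binding sites")
    n = len(sites)
    counts = {label: 0 for label in REGION_ORDER}
    for s in sites:
        counts[s.region] += 1
    return {label: counts[label] / n for label in REGION_ORDER}


def _feature_region(
    feat: BindingSite | RG4Site, by_tx: Mapping[str, TranscriptModel]
) -> RegionLabel:
    if isinstance(feat, BindingSite):
        return feat.region
    return assign_region(by_tx[feat.tx_id], feat.mid)


def density_per_kb(
    features: Sequence[BindingSite | RG4Site],
    tms: Sequence[TranscriptModel],
) -> dict[RegionLabel, float]:
    """Features per kilobase of each region (count / region length in kb)."""
    lengths = region_lengths(tms)
    by_tx = {tm.tx_id: tm for tm in tms}
    counts = {label: 0 for label in REGION_ORDER}
    for feat in features:
        counts[_feature_region(feat, by_tx)] += 1
    out = {}
    for label in REGION_ORDER:
        if lengths[label] == 0:
            if counts[label]:
                raise ValueError(f"{label.name}: nonzero count in zero-length region")
            out[label] = 0.0
        else:
            out[label] = counts[label] / (lengths[label] / 1000.0)
    return out


def fraction_bound_mrnas_with_rg4(
    sites: Sequence[BindingSite],
    rg4s: Sequence[RG4Site],
    per_region: bool = False,
    tms: Sequence[TranscriptModel] | None = None,
) -> float | dict[RegionLabel, float]:
    """Fraction of bound mRNAs that contain at least one RG4.

    With per_region=True, for each region the denominator is the set of
    transcripts with a binding site in that region and the numerator those
    that also carry an RG4 (midpoint) in the same region; requires ``tms``
    to place RG4s.
    """
    bound = {s.tx_id for s in sites}
    if not bound:
        raise ValueError("no bound transcripts")
    if not per_region:
        with_rg4 = {r.tx_id for r in rg4s}
        return len(bound & with_rg4) / len(bound)
    if tms is None:
        raise ValueError("per_region requires transcript models")
    by_tx = {tm.tx_id: tm for tm in tms}
    out = {}
    for label in REGION_ORDER:
        bound_r = {s.tx_id for s in sites if s.region is label}
        rg4_r = {
            r.tx_id
            for r in rg4s
            if r.tx_id in by_tx and assign_region(by_tx[r.tx_id], r.mid) is label
        }
        out[label] = len(bound_r & rg4_r) / len(bound_r) if bound_r else 0.0
    return out


def write_annotated_sites(sites: Sequence[BindingSite], path: str | Path) -> None:
    """Annotated-site table: BED6-style columns plus region and tx_id.

    Tab-separated with a documented header; deterministic order."""
    header = "#tx_id\tstart\tend\trbp\tscore\tstrand\tregion"
    rows = [header]
    for s in sorted(sites, key=lambda x: (x.tx_id, x.start, x.end, x.rbp)):
        rows.append(
            f"{s.tx_id}\t{s.start}\t{s.end}\t{s.rbp}\t0\t+\t{s.region.value}"
        )
    Path(path).write_text("\n".join(rows) + "\n")
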