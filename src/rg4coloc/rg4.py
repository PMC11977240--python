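"""RG4 (RNA G-quadruplex) site catalogs and QGRS-style motif prediction.

A QGRS (quadruplex-forming G-rich sequence) candidate is four runs of t
consecutive guanines (the tetrad count, t >= 2) separated by three loops.
The scorer here is a documented surrogate of the commonly used G-score:

    score = beta_t * (t - 2) + S0 - ceil(mean(l1, l2, l3)) - (max(l) - min(l))

floored at 0, with beta_t = 12 and S0 = 21 by default. It rewards extra
tetrads and short, even loops, and is calibrated so that a minimal two-tetrad
motif with loops (1, 1, 1) scores 20 — keeping the conventional 19 and 21
score thresholds discriminative. It is NOT numerically identical to the
original QGRS Mapper G-score.
"""

from __future__ import annotations

import bisect
import logging
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .transcript_model import TranscriptModel, genomic_to_transcript

logger = logging.getLogger(__name__)

_VALID = set("ACGTUN")


@dataclass(frozen=True)
class QgrsParams:
    """Tunable constants of the surrogate QGRS scorer."""

    g_min: int = 2
    loop_min: int = 1
    loop_max: int = 36
    max_qgrs_length: int = 30
    score_tetrad_weight: int = 12  # beta_t
    score_base: int = 21  # S0

    def __post_init__(self) -> None:
        if self.g_min < 2:
            raise ValueError("g_min must be >= 2")
        if self.loop_min < 0 or self.loop_max < self.loop_min:
            raise ValueError("need 0 <= loop_min <= loop_max")
        if 4 * self.g_min + 3 * self.loop_min > self.max_qgrs_length:
            raise ValueError("minimal QGRS does not fit in max_qgrs_length")


DEFAULT_PARAMS = QgrsParams()


@dataclass(frozen=True)
class RG4Site:
    """An RG4 interval in transcript coordinates (0-based half-open)."""

    tx_id: str
    start: int
    end: int
    score: int
    tetrads: int = 2
    source: str = "predicted"  # "predicted" | "experimental"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty RG4 interval [{self.start}, {self.end})")
        if self.score < 0:
            raise ValueError("score must be >= 0")

    @property
    def mid(self) -> int:
        return (self.start + self.end) // 2


def score_qgrs(tetrads: int, loops: Sequence[int], params: QgrsParams = DEFAULT_PARAMS) -> int:
    """Surrogate G-score of a single QGRS placement."""
    l1, l2, l3 = loops
    raw = (
        params.score_tetrad_weight * (tetrads - 2)
        + params.score_base
        - math.ceil((l1 + l2 + l3) / 3)
        - (max(loops) - min(loops))
    )
    return max(0, raw)


def _g_run_starts(seq: str, t: int) -> tuple[list[int], list[int]]:
    """Start positions of every t-long G-run, with the id of the maximal
    G-run each one belongs to."""
    starts: list[int] = []
    run_ids: list[int] = []
    n = len(seq)
    i = 0
    run_id = 0
    while i < n:
        if seq[i] == "G":
            j = i
            while j < n and seq[j] == "G":
                j += 1
            if j - i >= t:
                starts.extend(range(i, j - t + 1))
                run_ids.extend([run_id] * (j - t + 1 - i))
            run_id += 1
            i = j
        else:
            i += 1
    return starts, run_ids


def _candidates(seq: str, params: QgrsParams):
    """Yield (start, end, t, loops, score) for every QGRS placement."""
    max_run = 0
    run = 0
    for c in seq:
        run = run + 1 if c == "G" else 0
        max_run = max(max_run, run)
    for t in range(params.g_min, max_run + 1):
        starts, run_ids = _g_run_starts(seq, t)
        rid = dict(zip(starts, run_ids))
        span = params.max_qgrs_length
        for ia, a in enumerate(starts):
            limit = a + span - t  # last admissible run start
            # chain three more runs with loop constraints; runs must come
            # from distinct maximal G-runs so every loop holds a non-G base
            lo1 = bisect.bisect_left(starts, a + t + params.loop_min)
            hi1 = bisect.bisect_right(starts, min(a + t + params.loop_max, limit))
            for b in starts[lo1:hi1]:
                if rid[b] == rid[a]:
                    continue
                lo2 = bisect.bisect_left(starts, b + t + params.loop_min)
                hi2 = bisect.bisect_right(starts, min(b + t + params.loop_max, limit))
                for c_ in starts[lo2:hi2]:
                    if rid[c_] == rid[b]:
                        continue
                    lo3 = bisect.bisect_left(starts, c_ + t + params.loop_min)
                    hi3 = bisect.bisect_right(
                        starts, min(c_ + t + params.loop_max, limit)
                    )
                    for d in starts[lo3:hi3]:
                        if rid[d] == rid[c_]:
                            continue
                        loops = (b - a - t, c_ - b - t, d - c_ - t)
                        yield (
                            a,
                            d + t,
                            t,
                            loops,
                            score_qgrs(t, loops, params),
                        )


def predict_qgrs(
    seq: str,
    params: QgrsParams = DEFAULT_PARAMS,
    tx_id: str = "seq",
) -> list[RG4Site]:
    """Predict non-overlapping QGRS sites in a nucleotide sequence.

    Every window of at most ``max_qgrs_length`` containing four G-runs of
    t >= g_min tetrads with loops in [loop_min, loop_max] is a candidate;
    overlapping candidates are resolved greedily by (score desc, length asc,
    start asc). Ns break G-runs; loops may contain any base but each loop
    must contain at least one non-G (the four runs come from four distinct
    maximal G-runs, so an uninterrupted G stretch is not a QGRS).
    """
    s = seq.upper().replace("U", "T")
    for i, c in enumerate(s):
        if c not in "ACGTN":
            raise ValueError(f"invalid character {seq[i]!r} at position {i}")
    cands = sorted(
        _candidates(s, params),
        key=lambda c: (-c[4], c[1] - c[0], c[0], -c[2]),
    )
    occupied = bytearray(len(s))
    kept = []
    for start, end, t, _loops, score in cands:
        if any(occupied[start:end]):
            continue
        for i in range(start, end):
            occupied[i] = 1
        kept.append(RG4Site(tx_id, start, end, score, tetrads=t, source="predicted"))
    kept.sort(key=lambda r: r.start)
    return kept


def predict_catalog(
    seqs: Mapping[str, str], params: QgrsParams = DEFAULT_PARAMS
) -> list[RG4Site]:
    """Predict QGRS sites across a whole transcript sequence set."""
    sites: list[RG4Site] = []
    for tx_id in sorted(seqs):
        sites.extend(predict_qgrs(seqs[tx_id], params, tx_id=tx_id))
    return sites


def filter_by_score(sites: Iterable[RG4Site], min_score: int) -> list[RG4Site]:
    """Retain sites with score >= min_score, order preserved."""
    return [s for s in sites if s.score >= min_score]


def read_rg4_bed(
    path: str | Path,
    frame: str = "transcript",
    tms: Sequence[TranscriptModel] | None = None,
    source: str = "experimental",
) -> list[RG4Site]:
    """Read an RG4 catalog from BED6 (optional column 7 = uncapped score).

    frame="transcript": column 1 is the transcript id, coordinates are
    transcript coordinates. frame="genomic": coordinates are genomic and are
    lifted onto the transcripts in ``tms``; intervals split across introns
    (or not fully exonic) are dropped with a logged count.
    """
    sites: list[RG4Site] = []
    dropped = 0
    skipped_ids = 0
    if frame == "genomic":
        if tms is None:
            raise ValueError("genomic frame requires transcript models")
        by_chrom: dict[str, list[TranscriptModel]] = {}
        for tm in sorted(tms, key=lambda t: t.tx_id):
            by_chrom.setdefault(tm.chrom, []).append(tm)
    tx_ids = {tm.tx_id for tm in tms} if tms is not None else None
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 6:
                raise ValueError(f"line {lineno}: BED6 needs >= 6 columns")
            try:
                chrom, start, end = f[0], int(f[1]), int(f[2])
                score = int(f[6]) if len(f) > 6 else int(float(f[4]))
            except ValueError as e:
                raise ValueError(f"line {lineno}: malformed BED field ({e})") from e
            if frame == "transcript":
                if tx_ids is not None and chrom not in tx_ids:
                    skipped_ids += 1
                    continue
                sites.append(RG4Site(chrom, start, end, score, source=source))
                continue
            mapped = None
            for tm in by_chrom.get(chrom, []):
                t1 = genomic_to_transcript(tm, start)
                t2 = genomic_to_transcript(tm, end - 1)
                if t1 is None or t2 is None:
                    continue
                lo, hi = min(t1, t2), max(t1, t2)
                if hi - lo != end - 1 - start:  # spans an intron
                    continue
                mapped = RG4Site(tm.tx_id, lo, hi + 1, score, source=source)
                break
            if mapped is None:
                dropped += 1
            else:
                sites.append(mapped)
    if dropped:
        logger.info("read_rg4_bed: dropped %d interval(s) not fully exonic", dropped)
    if skipped_ids:
        logger.info("read_rg4_bed: skipped %d line(s) with unknown tx_id", skipped_ids)
    return sites


def write_rg4_bed(sites: Sequence[RG4Site], path: str | Path) -> None:
    """Write sites as extended BED6: score column capped at 1000 for BED
    validity, true score in column 7. Deterministic (tx_id, start) order."""
    rows = []
    for s in sorted(sites, key=lambda r: (r.tx_id, r.start, r.end)):
        rows.append(
            "\t".join(
                map(
                    str,
                    [
                        s.tx_id,
                        s.start,
                        s.end,
                        f"rg4_{s.source}",
                        min(s.score, 1000),
                        "+",
                        s.score,
                        s.tetrads,
                    ],
                )
            )
        )
    Path(path).write_text("\n".join(rows) + ("\n" if rows else ""))
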