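"""Transcript models, coordinate conversion and 5'UTR/CDS/3'UTR region logic.

All coordinates inside the package are 0-based half-open. GFF3 input
(1-based closed) is converted on read; BED input is native. Transcript
coordinate 0 is the 5' end of the transcript, i.e. on the minus strand it
corresponds to the genomically rightmost exonic base.
"""

from __future__ import annotations

import bisect
import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

logger = logging.getLogger(__name__)


class RegionLabel(Enum):
    """The three functional regions partitioning a coding transcript."""

    FIVE_UTR = "5UTR"
    CDS = "CDS"
    THREE_UTR = "3UTR"

    def __repr__(self) -> str:  # compact in test output
        return self.name


REGION_ORDER: tuple[RegionLabel, ...] = (
    RegionLabel.FIVE_UTR,
    RegionLabel.CDS,
    RegionLabel.THREE_UTR,
)


@dataclass(frozen=True)
class GenomicInterval:
    """A stranded genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class TranscriptModel:
    """Exon/CDS structure of one transcript.

    ``exons`` are non-overlapping and sorted genomically (by start).
    ``cds_start_tx``/``cds_end_tx`` are half-open transcript coordinates;
    both are ``None`` for non-coding transcripts.
    """

    tx_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[GenomicInterval, ...]
    cds_start_tx: int | None = None
    cds_end_tx: int | None = None
    _cum: tuple[int, ...] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        exons = tuple(sorted(self.exons, key=lambda e: e.start))
        for a, b in zip(exons, exons[1:]):
            if a.end > b.start:
                raise ValueError(f"{self.tx_id}: overlapping exons {a} / {b}")
        object.__setattr__(self, "exons", exons)
        cum = [0]
        for e in exons:
            cum.append(cum[-1] + len(e))
        self._cum = tuple(cum)
        if (self.cds_start_tx is None) != (self.cds_end_tx is None):
            raise ValueError(f"{self.tx_id}: partial CDS annotation")
        if self.cds_start_tx is not None:
            if not (0 <= self.cds_start_tx < self.cds_end_tx <= self.length):
                raise ValueError(
                    f"{self.tx_id}: CDS [{self.cds_start_tx}, {self.cds_end_tx}) "
                    f"outside [0, {self.length})"
                )

    @property
    def length(self) -> int:
        return self._cum[-1]

    @property
    def is_coding(self) -> bool:
        return self.cds_start_tx is not None

    @property
    def cds_length(self) -> int:
        return (self.cds_end_tx - self.cds_start_tx) if self.is_coding else 0


def genomic_to_transcript(tm: TranscriptModel, gpos: int) -> int | None:
    """Map a genomic position to a transcript coordinate, or None if intronic
    or outside the transcript."""
    starts = [e.start for e in tm.exons]
    i = bisect.bisect_right(starts, gpos) - 1
    if i < 0:
        return None
    e = tm.exons[i]
    if not (e.start <= gpos < e.end):
        return None
    plus = tm._cum[i] + (gpos - e.start)
    return plus if tm.strand == "+" else tm.length - 1 - plus


def transcript_to_genomic(tm: TranscriptModel, tpos: int) -> int:
    """Inverse of :func:`genomic_to_transcript` on exonic bases."""
    if not (0 <= tpos < tm.length):
        raise ValueError(f"{tm.tx_id}: transcript position {tpos} out of range")
    plus = tpos if tm.strand == "+" else tm.length - 1 - tpos
    i = bisect.bisect_right(tm._cum, plus) - 1
    e = tm.exons[i]
    return e.start + (plus - tm._cum[i])


def assign_region(tm: TranscriptModel, tpos: int) -> RegionLabel:
    """Label a transcript position as 5'UTR, CDS or 3'UTR (half-open bounds)."""
    if not tm.is_coding:
        raise ValueError(f"{tm.tx_id} is non-coding; region labels undefined")
    if not (0 <= tpos < tm.length):
        raise ValueError(f"{tm.tx_id}: position {tpos} out of range")
    if tpos < tm.cds_start_tx:
        return RegionLabel.FIVE_UTR
    if tpos < tm.cds_end_tx:
        return RegionLabel.CDS
    return RegionLabel.THREE_UTR


def region_bounds(tm: TranscriptModel, label: RegionLabel) -> tuple[int, int]:
    """Half-open transcript-coordinate bounds of one region."""
    if not tm.is_coding:
        raise ValueError(f"{tm.tx_id} is non-coding")
    if label is RegionLabel.FIVE_UTR:
        return 0, tm.cds_start_tx
    if label is RegionLabel.CDS:
        return tm.cds_start_tx, tm.cds_end_tx
    return tm.cds_end_tx, tm.length


def region_lengths(tms: Iterable[TranscriptModel]) -> dict[RegionLabel, int]:
    """Total nucleotides per region over a set of coding transcripts."""
    totals = {label: 0 for label in REGION_ORDER}
    for tm in tms:
        if not tm.is_coding:
            raise ValueError(f"{tm.tx_id} is non-coding; exclude before summing")
        for label in REGION_ORDER:
            lo, hi = region_bounds(tm, label)
            totals[label] += hi - lo
    return totals


# ---------------------------------------------------------------------------
# annotation I/O


def _select_canonical(tms: list[TranscriptModel]) -> list[TranscriptModel]:
    """One transcript per gene: longest CDS, tie -> longest transcript,
    tie -> lexicographically smallest tx_id."""
    by_gene: dict[str, list[TranscriptModel]] = {}
    for tm in tms:
        by_gene.setdefault(tm.gene_id, []).append(tm)
    kept = []
    for gene in sorted(by_gene):
        cands = by_gene[gene]
        cands.sort(key=lambda t: (-t.cds_length, -t.length, t.tx_id))
        kept.append(cands[0])
    return kept


def read_annotation(
    path: str | Path,
    canonical_policy: str = "longest_cds",
    coding_only: bool = False,
) -> list[TranscriptModel]:
    """Read transcript models from GFF3 or BED12.

    canonical_policy: "longest_cds" keeps one transcript per gene
    (longest CDS, ties broken by transcript length then tx_id); "all"
    keeps every transcript.
    """
    path = Path(path)
    if path.suffix.lower() in (".gff", ".gff3"):
        tms = _read_gff3(path)
    else:
        tms = _read_bed12(path)
    if coding_only:
        tms = [tm for tm in tms if tm.is_coding]
    if canonical_policy == "longest_cds":
        tms = _select_canonical(tms)
    elif canonical_policy != "all":
        raise ValueError(f"unknown canonical_policy {canonical_policy!r}")
    return sorted(tms, key=lambda t: (t.chrom, t.exons[0].start, t.tx_id))


def _read_gff3(path: Path) -> list[TranscriptModel]:
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    tms: list[TranscriptModel] = []
    feats = list(db.features_of_type(("transcript", "mRNA")))
    for tx in feats:
        tx_id = tx.attributes.get("transcript_id", [tx.id])[0]
        gene_id = tx.attributes.get(
            "gene_id", tx.attributes.get("Parent", [tx_id])
        )[0]
        exons = tuple(
            GenomicInterval(tx.seqid, f.start - 1, f.end, tx.strand)
            for f in db.children(tx, featuretype="exon")
        )
        if not exons:
            logger.warning("%s: no exons; skipped", tx_id)
            continue
        cds_feats = list(db.children(tx, featuretype="CDS"))
        cds_start_tx = cds_end_tx = None
        tm = TranscriptModel(tx_id, gene_id, tx.seqid, tx.strand, exons)
        if cds_feats:
            g_lo = min(f.start - 1 for f in cds_feats)
            g_hi = max(f.end - 1 for f in cds_feats)
            t1 = genomic_to_transcript(tm, g_lo)
            t2 = genomic_to_transcript(tm, g_hi)
            if t1 is None or t2 is None:
                logger.warning("%s: CDS outside exons; transcript skipped", tx_id)
                continue
            cds_start_tx, cds_end_tx = min(t1, t2), max(t1, t2) + 1
        tms.append(
            TranscriptModel(
                tx_id, gene_id, tx.seqid, tx.strand, exons, cds_start_tx, cds_end_tx
            )
        )
    return tms


def _parse_bed12_line(line: str, lineno: int) -> TranscriptModel:
    f = line.rstrip("\n").split("\t")
    if len(f) < 12:
        raise ValueError(f"line {lineno}: BED12 needs 12 columns, got {len(f)}")
    try:
        chrom, start, end = f[0], int(f[1]), int(f[2])
        name, strand = f[3], f[5]
        thick_start, thick_end = int(f[6]), int(f[7])
        n_blocks = int(f[9])
        sizes = [int(x) for x in f[10].rstrip(",").split(",")]
        offsets = [int(x) for x in f[11].rstrip(",").split(",")]
    except ValueError as e:
        raise ValueError(f"line {lineno}: malformed BED12 field ({e})") from e
    if len(sizes) != n_blocks or len(offsets) != n_blocks:
        raise ValueError(f"line {lineno}: blockCount inconsistent with block lists")
    if "|" in name:
        gene_id, tx_id = name.split("|", 1)
    else:
        gene_id = tx_id = name
    exons = tuple(
        GenomicInterval(chrom, start + o, start + o + s, strand)
        for s, o in zip(sizes, offsets)
    )
    tm = TranscriptModel(tx_id, gene_id, chrom, strand, exons)
    if thick_start < thick_end:
        t1 = genomic_to_transcript(tm, thick_start)
        t2 = genomic_to_transcript(tm, thick_end - 1)
        if t1 is None or t2 is None:
            raise ValueError(f"line {lineno}: thickStart/thickEnd outside exon blocks")
        tm = TranscriptModel(
            tx_id, gene_id, chrom, strand, exons, min(t1, t2), max(t1, t2) + 1
        )
    return tm


def _read_bed12(path: Path) -> list[TranscriptModel]:
    tms = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            tms.append(_parse_bed12_line(line, lineno))
    return tms


def write_bed12(tms: Sequence[TranscriptModel], path: str | Path) -> None:
    """Write transcript models as BED12 (CDS encoded in thickStart/thickEnd).

    Output is deterministic: sorted by (chrom, start, tx_id)."""
    rows = []
    for tm in sorted(tms, key=lambda t: (t.chrom, t.exons[0].start, t.tx_id)):
        start = tm.exons[0].start
        end = tm.exons[-1].end
        if tm.is_coding:
            g1 = transcript_to_genomic(tm, tm.cds_start_tx)
            g2 = transcript_to_genomic(tm, tm.cds_end_tx - 1)
            thick = (min(g1, g2), max(g1, g2) + 1)
        else:
            thick = (start, start)
        sizes = ",".join(str(len(e)) for e in tm.exons)
        offsets = ",".join(str(e.start - start) for e in tm.exons)
        rows.append(
            "\t".join(
                map(
                    str,
                    [
                        tm.chrom,
                        start,
                        end,
                        f"{tm.gene_id}|{tm.tx_id}",
                        0,
                        tm.strand,
                        thick[0],
                        thick[1],
                        "0,0,0",
                        len(tm.exons),
                        sizes,
                        offsets,
                    ],
                )
            )
        )
    Path(path).write_text("\n".join(rows) + ("\n" if rows else ""))


def read_fasta(path: str | Path) -> dict[str, str]:
    """Transcript sequences keyed by record id (must match tx_id)."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name in seqs:  # preserve insertion order (generator order)
            fh.write(f">{name}\n")
            s = seqs[name]
            for i in range(0, len(s), width):
                fh.write(s[i : i + width] + "\n")
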