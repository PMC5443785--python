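"""Genomic-region classification of SSR loci.

Transcripts are decomposed into CDS, 5'/3' UTR, non-coding exon, intron and
a 2 kb strand-aware promoter upstream of the transcription start site.  A
locus is classified per transcript with priority CDS > UTR5/UTR3 >
non-coding exon > intron, with promoter reported only when no exonic or
intronic feature of that transcript is touched; the summary label across
transcripts uses CDS > UTR5 > UTR3 > non-coding exon > promoter > intron >
intergenic.  A locus overlapping several transcripts with conflicting labels
is additionally flagged multi-transcript, mirroring the separate tally such
loci receive in region counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .errors import CoordinateError, MalformedAnnotationError
from .motifs import MAX_PERIOD, MIN_PERIOD
from .scan import SSRLocus

PROMOTER_LEN = 2000

#: summary-label priority, highest first ("intergenic" is the absence of all)
PRIORITY = ("CDS", "UTR5", "UTR3", "exon_noncoding", "promoter", "intron")

Interval = tuple[int, int]


def _merge(intervals: Sequence[Interval]) -> list[Interval]:
    out: list[Interval] = []
    for s, e in sorted(intervals):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def _subtract(a: Sequence[Interval], b: Sequence[Interval]) -> list[Interval]:
    """Interval-set difference a \\ b (both sorted, non-overlapping)."""
    out: list[Interval] = []
    bi = iter(b)
    cur = next(bi, None)
    for s, e in a:
        pos = s
        while cur is not None and cur[0] < e:
            if cur[1] <= pos:
                cur = next(bi, None)
                continue
            if cur[0] > pos:
                out.append((pos, min(cur[0], e)))
            pos = max(pos, cur[1])
            if cur[1] >= e:
                break
            cur = next(bi, None)
        if pos < e:
            out.append((pos, e))
    return out


@dataclass
class Transcript:
    """One transcript with derived region intervals (0-based half-open)."""

    tid: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[Interval]
    cds: list[Interval]
    utr5: list[Interval] = field(default_factory=list)
    utr3: list[Interval] = field(default_factory=list)
    introns: list[Interval] = field(default_factory=list)
    exon_noncoding: list[Interval] = field(default_factory=list)
    promoter: Optional[Interval] = None

    @property
    def span(self) -> Interval:
        return (self.exons[0][0], self.exons[-1][1])

    def derive(self, chrom_length: Optional[int] = None) -> "Transcript":
        if self.strand not in "+-":
            raise MalformedAnnotationError(f"transcript {self.tid}: bad strand {self.strand!r}")
        self.exons = _merge(self.exons)
        self.cds = _merge(self.cds)
        if not self.exons:
            raise MalformedAnnotationError(f"transcript {self.tid} has no exons")
        # every CDS base must be exonic
        if self.cds and _subtract(self.cds, self.exons):
            raise MalformedAnnotationError(f"transcript {self.tid}: CDS not contained in exons")
        self.introns = [(e1, s2) for (_, e1), (s2, _) in zip(self.exons, self.exons[1:])]
        if self.cds:
            utr = _subtract(self.exons, self.cds)
            cds_start, cds_end = self.cds[0][0], self.cds[-1][1]
            left = [iv for iv in utr if iv[1] <= cds_start]
            right = [iv for iv in utr if iv[0] >= cds_end]
            self.utr5, self.utr3 = (left, right) if self.strand == "+" else (right, left)
            self.exon_noncoding = []
        else:
            self.utr5, self.utr3 = [], []
            self.exon_noncoding = list(self.exons)
        if self.strand == "+":
            tss = self.exons[0][0]
            self.promoter = (max(0, tss - PROMOTER_LEN), tss) if tss > 0 else None
        else:
            tss = self.exons[-1][1]
            end = tss + PROMOTER_LEN
            if chrom_length is not None:
                end = min(end, chrom_length)
            self.promoter = (tss, end) if end > tss else None
        return self


class RegionModel:
    """Collection of transcripts with an interval index for classification."""

    def __init__(self, transcripts: Iterable[Transcript],
                 chrom_lengths: Optional[Mapping[str, int]] = None):
        self.chrom_lengths = dict(chrom_lengths) if chrom_lengths else None
        self.transcripts: dict[str, Transcript] = {}
        for tx in transcripts:
            clen = self.chrom_lengths.get(tx.chrom) if self.chrom_lengths else None
            self.transcripts[tx.tid] = tx.derive(clen)
        self._trees: dict[str, IntervalTree] = {}
        for tx in self.transcripts.values():
            tree = self._trees.setdefault(tx.chrom, IntervalTree())
            lo, hi = tx.span
            if tx.promoter:
                lo, hi = min(lo, tx.promoter[0]), max(hi, tx.promoter[1])
            tree.addi(lo, hi, tx.tid)

    def genes(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for tx in self.transcripts.values():
            out.setdefault(tx.gene_id, []).append(tx.tid)
        return out

    def overlapping(self, chrom: str, start: int, end: int) -> list[Transcript]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return sorted((self.transcripts[iv.data] for iv in tree.overlap(start, end)),
                      key=lambda t: t.tid)


@dataclass(frozen=True)
class RegionCall:
    locus_id: str
    per_transcript: tuple[tuple[str, str], ...]  # (tid, label), sorted by tid
    summary: str
    n_transcripts_hit: int
    multi_transcript: bool


def _hits(intervals: Sequence[Interval], start: int, end: int) -> bool:
    return any(s < end and e > start for s, e in intervals)


def _transcript_label(tx: Transcript, start: int, end: int) -> Optional[str]:
    if _hits(tx.cds, start, end):
        return "CDS"
    if _hits(tx.utr5, start, end):
        return "UTR5"
    if _hits(tx.utr3, start, end):
        return "UTR3"
    if _hits(tx.exon_noncoding, start, end):
        return "exon_noncoding"
    if _hits(tx.introns, start, end):
        return "intron"
    if tx.promoter and tx.promoter[0] < end and tx.promoter[1] > start:
        return "promoter"
    return None


def classify_region(locus: SSRLocus, model: RegionModel) -> RegionCall:
    """Label one locus against every transcript it touches."""
    labels: list[tuple[str, str]] = []
    for tx in model.overlapping(locus.chrom, locus.start, locus.end):
        label = _transcript_label(tx, locus.start, locus.end)
        if label is not None:
            labels.append((tx.tid, label))
    if not labels:
        return RegionCall(locus.locus_id, (), "intergenic", 0, False)
    summary = min((lab for _, lab in labels), key=PRIORITY.index)
    n_hit = sum(1 for _, lab in labels if lab != "promoter")
    distinct = {lab for _, lab in labels}
    return RegionCall(locus.locus_id, tuple(sorted(labels)), summary,
                      n_hit, len(distinct) > 1 and len(labels) > 1)


def classify_catalogue(loci: Sequence[SSRLocus], model: RegionModel) -> pd.DataFrame:
    calls = [classify_region(l, model) for l in loci]
    return pd.DataFrame({
        "locus_id": [c.locus_id for c in calls],
        "summary": [c.summary for c in calls],
        "n_transcripts_hit": [c.n_transcripts_hit for c in calls],
        "multi_transcript": [c.multi_transcript for c in calls],
    })


_CODES = {"intergenic": 0, "intron": 1, "promoter": 2, "exon_noncoding": 3,
          "UTR3": 4, "UTR5": 5, "CDS": 6}
_CODE_NAMES = {v: k for k, v in _CODES.items()}


def _paint_chrom(model: RegionModel, chrom: str, length: int) -> np.ndarray:
    """Per-base region class for one chromosome; higher-priority classes
    painted last so they win at shared bases."""
    paint = np.zeros(length, dtype=np.int8)
    layers: dict[str, list[Interval]] = {k: [] for k in _CODES if k != "intergenic"}
    for tx in model.transcripts.values():
        if tx.chrom != chrom:
            continue
        layers["intron"].extend(tx.introns)
        if tx.promoter:
            layers["promoter"].append(tx.promoter)
        layers["exon_noncoding"].extend(tx.exon_noncoding)
        layers["UTR3"].extend(tx.utr3)
        layers["UTR5"].extend(tx.utr5)
        layers["CDS"].extend(tx.cds)
    for name in ("intron", "promoter", "exon_noncoding", "UTR3", "UTR5", "CDS"):
        code = _CODES[name]
        for s, e in layers[name]:
            paint[max(0, s):min(length, e)] = code
    return paint


def region_densities(loci: Sequence[SSRLocus], model: RegionModel,
                     chrom_lengths: Mapping[str, int]) -> pd.DataFrame:
    """SSR bp per Mb of each region class, split by period.

    Each genomic base belongs to exactly one class (priority CDS > UTR5 >
    UTR3 > non-coding exon > promoter > intron > intergenic); a locus
    contributes its overlapping bp to each class it spans.  Classes with
    zero total length get NaN densities.
    """
    paints = {c: _paint_chrom(model, c, n) for c, n in chrom_lengths.items()}
    region_bp = {name: 0 for name in _CODES}
    for paint in paints.values():
        counts = np.bincount(paint, minlength=7)
        for code, name in _CODE_NAMES.items():
            region_bp[name] += int(counts[code])
    ssr_bp = {(name, p): 0 for name in _CODES for p in range(MIN_PERIOD, MAX_PERIOD + 1)}
    for locus in loci:
        if locus.chrom not in paints:
            raise CoordinateError(f"locus on unknown chromosome {locus.chrom!r}")
        counts = np.bincount(paints[locus.chrom][locus.start:locus.end], minlength=7)
        for code, name in _CODE_NAMES.items():
            ssr_bp[(name, locus.motif.period)] += int(counts[code])
    rows = []
    for name in _CODES:
        total = region_bp[name]
        row = {"region": name, "region_bp": total}
        for p in range(MIN_PERIOD, MAX_PERIOD + 1):
            bp = ssr_bp[(name, p)]
            row[f"ssr_bp_p{p}"] = bp
            row[f"density_p{p}"] = bp / (total / 1e6) if total else float("nan")
        row["ssr_bp"] = sum(ssr_bp[(name, p)] for p in range(MIN_PERIOD, MAX_PERIOD + 1))
        row["density"] = row["ssr_bp"] / (total / 1e6) if total else float("nan")
        rows.append(row)
    return pd.DataFrame(rows).set_index("region")


def overlap_variants(loci: Sequence[SSRLocus],
                     intervals: Iterable[tuple[str, int, int]]) -> dict:
    """Flag loci sharing >= 1 bp with any interval (half-open semantics).

    Returns ``{"flags": Series locus_id -> bool, "n_overlap": int,
    "fraction": float}``.
    """
    trees: dict[str, IntervalTree] = {}
    for chrom, start, end in intervals:
        if end <= start:
            raise CoordinateError(f"malformed interval {chrom}:{start}-{end}")
        trees.setdefault(chrom, IntervalTree()).addi(start, end)
    flags = {}
    for locus in loci:
        tree = trees.get(locus.chrom)
        flags[locus.locus_id] = bool(tree and tree.overlap(locus.start, locus.end))
    n = sum(flags.values())
    total = len(flags)
    return {"flags": pd.Series(flags, dtype=bool),
            "n_overlap": n,
            "fraction": n / total if total else float("nan")}
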