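"""Perfect-repeat microsatellite scanner.

Detects maximal perfect tandem repeats with 2-6 bp primitive units.  A run
qualifies when its repeat count reaches the period-specific minimum implied
by a 10 bp tract floor and a 3-repeat floor (5 repeats for dinucleotides, 4
for trinucleotides, 3 for tetra/penta/hexanucleotides) and is trimmed to
whole units anchored at the leftmost full unit.  Overlapping loci -- of any
period -- are removed entirely rather than arbitrated, so a catalogue only
contains repeats with an unambiguous description.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import CoordinateError, InvalidAlphabetError
from .motifs import MAX_PERIOD, MIN_PERIOD, MotifClass, canonical_motif, is_primitive

DEFAULT_MIN_LEN = 10
DEFAULT_MIN_REPEAT = 3


def min_repeats_for_period(period: int, min_len: int = DEFAULT_MIN_LEN,
                           min_repeat: int = DEFAULT_MIN_REPEAT) -> int:
    """Minimum qualifying repeat count for a unit length.

    Combines the tract-length floor (``min_len`` bp) with the repeat-count
    floor: ``max(min_repeat, ceil(min_len / period))``.  With the defaults
    this yields 5, 4, 3, 3, 3 for periods 2..6.
    """
    return max(min_repeat, math.ceil(min_len / period))


@dataclass(frozen=True)
class SSRLocus:
    """One perfect tandem repeat on a reference sequence.

    Coordinates are 0-based half-open; ``end - start`` always equals
    ``repeat_count * motif.period``.
    """

    chrom: str
    start: int
    end: int
    motif: MotifClass
    repeat_count: int

    @property
    def ref_len(self) -> int:
        return self.end - self.start

    @property
    def locus_id(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"

    def sort_key(self):
        return (self.chrom, self.start, self.end, self.motif.period)


# ASCII codes for the DNA alphabet
_A, _C, _G, _T, _N = 65, 67, 71, 84, 78


def scan_sequence(seq: str, chrom: str, min_len: int = DEFAULT_MIN_LEN,
                  min_repeat: int = DEFAULT_MIN_REPEAT) -> list[SSRLocus]:
    """Report every maximal perfect repeat run meeting the thresholds.

    ``N`` terminates runs and never participates in a repeat.  Runs are
    trimmed to whole units; only primitive units are emitted, so a tract is
    reported once, at its smallest period.  The returned list is sorted by
    (start, end, period) and may contain overlapping loci of different
    periods; apply :func:`resolve_overlaps` to obtain a catalogue.
    """
    s = seq.upper()
    if not s:
        return []
    a = np.frombuffer(s.encode("ascii"), dtype=np.uint8)
    acgt = (a == _A) | (a == _C) | (a == _G) | (a == _T)
    if not bool(np.all(acgt | (a == _N))):
        bad = s[int(np.argmax(~(acgt | (a == _N))))]
        raise InvalidAlphabetError(f"sequence {chrom!r} contains invalid character {bad!r}")
    n = a.size
    loci: list[SSRLocus] = []
    for period in range(MIN_PERIOD, MAX_PERIOD + 1):
        if n < 2 * period:
            continue
        min_reps = min_repeats_for_period(period, min_len, min_repeat)
        match = (a[:-period] == a[period:]) & acgt[:-period]
        edges = np.flatnonzero(np.diff(np.concatenate(([0], match.view(np.int8), [0]))))
        for run_start, run_end in zip(edges[::2], edges[1::2]):
            tract = int(run_end - run_start) + period
            reps = tract // period
            if reps < min_reps or reps * period < min_len:
                continue
            unit = s[run_start:run_start + period]
            if not is_primitive(unit):
                continue
            start = int(run_start)
            loci.append(SSRLocus(chrom, start, start + reps * period,
                                 canonical_motif(unit), reps))
    loci.sort(key=SSRLocus.sort_key)
    return loci


def resolve_overlaps(loci: list[SSRLocus]) -> list[SSRLocus]:
    """Drop *every* locus that shares at least one base with another.

    Both members of an overlapping pair are removed (nested loci included);
    loci that merely touch (half-open adjacency) are kept.  Input must be
    sorted by (chrom, start).
    """
    for prev, cur in zip(loci, loci[1:]):
        if (cur.chrom, cur.start) < (prev.chrom, prev.start):
            raise CoordinateError("loci must be sorted by (chrom, start)")
    drop = [False] * len(loci)
    for i, locus in enumerate(loci):
        j = i + 1
        while j < len(loci) and loci[j].chrom == locus.chrom and loci[j].start < locus.end:
            drop[i] = drop[j] = True
            j += 1
    return [locus for locus, d in zip(loci, drop) if not d]


def catalogue_genome(sequences: Mapping[str, str], min_len: int = DEFAULT_MIN_LEN,
                     min_repeat: int = DEFAULT_MIN_REPEAT) -> list[SSRLocus]:
    """Scan every sequence and resolve overlaps into a non-overlapping,
    (chrom, start)-sorted catalogue."""
    loci: list[SSRLocus] = []
    for chrom in sequences:
        loci.extend(scan_sequence(sequences[chrom], chrom, min_len, min_repeat))
    loci.sort(key=SSRLocus.sort_key)
    return resolve_overlaps(loci)


def catalogue_to_frame(loci: Iterable[SSRLocus]) -> pd.DataFrame:
    rows = [(l.chrom, l.start, l.end, l.motif.canonical, l.motif.period,
             l.repeat_count, l.ref_len, l.locus_id) for l in loci]
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "motif", "period",
                                       "repeat_count", "ref_len", "locus_id"])


def summarize_counts(loci: Iterable[SSRLocus]) -> pd.DataFrame:
    """Locus counts per motif class (one row per class, with period)."""
    counts = Counter((l.motif.canonical, l.motif.period) for l in loci)
    rows = sorted((p, m, c) for (m, p), c in counts.items())
    return pd.DataFrame(rows, columns=["period", "motif", "count"])


def density_stats(loci: Iterable[SSRLocus],
                  chrom_lengths: Mapping[str, int]) -> dict:
    """Per-chromosome and genome-wide SSR densities.

    Returns a dict with:

    ``per_chrom``
        DataFrame indexed by chromosome with per-period SSR bp, density in
        bp/Mb and occupied fraction.
    ``genome_fraction``
        total SSR bp / genome bp.
    ``genome_density_bp_per_mb``
        total SSR bp per Mb of genome.
    ``per_motif_fraction``
        Series: genome fraction occupied by each motif class.
    """
    per = {c: Counter() for c in chrom_lengths}
    motif_bp: Counter = Counter()
    for locus in loci:
        if locus.chrom not in chrom_lengths:
            raise CoordinateError(f"locus on unknown chromosome {locus.chrom!r}")
        if locus.end > chrom_lengths[locus.chrom] or locus.start < 0:
            raise CoordinateError(f"locus {locus.locus_id} exceeds chromosome bounds")
        per[locus.chrom][locus.motif.period] += locus.ref_len
        motif_bp[locus.motif.canonical] += locus.ref_len
    rows = []
    for chrom, length in chrom_lengths.items():
        mb = length / 1e6
        total = sum(per[chrom].values())
        row = {"chrom": chrom, "length": length, "ssr_bp": total,
               "density_bp_per_mb": total / mb if mb else float("nan"),
               "fraction": total / length if length else float("nan")}
        for period in range(MIN_PERIOD, MAX_PERIOD + 1):
            row[f"bp_p{period}"] = per[chrom][period]
            row[f"density_p{period}"] = per[chrom][period] / mb if mb else float("nan")
        rows.append(row)
    frame = pd.DataFrame(rows).set_index("chrom")
    genome_bp = sum(chrom_lengths.values())
    ssr_bp = int(frame["ssr_bp"].sum())
    motif_fraction = pd.Series(
        {m: bp / genome_bp for m, bp in sorted(motif_bp.items())}, dtype=float)
    return {
        "per_chrom": frame,
        "genome_fraction": ssr_bp / genome_bp if genome_bp else float("nan"),
        "genome_density_bp_per_mb": ssr_bp / (genome_bp / 1e6) if genome_bp else float("nan"),
        "per_motif_fraction": motif_fraction,
    }
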