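"""Cross-species conservation of SSR flanking sequence.

Each locus carries two 200 bp flanks.  For every other species, tabulated
alignment hits of the left and right flank are paired: the species counts
as conserving the locus when some left hit and some right hit land on the
same target chromosome, in the same orientation, in the correct relative
order, with a target-side gap strictly below 300 bp.  The number of
conserving species (0-14) is the locus's conservation category; category 0
loci are species-specific.  Independently, a per-base conservation score
track (e.g. PhyloP) is averaged over the two flanks.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import CoordinateError
from .scan import SSRLocus

FLANK_LEN = 200
MAX_INTERVAL = 300

HIT_COLUMNS = ["locus", "side", "species", "tchrom", "tstart", "tend", "orient"]


@dataclass(frozen=True)
class ConservationCall:
    locus_id: str
    species_hit: frozenset[str]
    mean_score: float  # NaN when no scored base exists

    @property
    def category(self) -> int:
        return len(self.species_hit)


def _pairs_qualify(left: pd.DataFrame, right: pd.DataFrame,
                   max_interval: int) -> bool:
    for _, lh in left.iterrows():
        for _, rh in right.iterrows():
            if lh["tchrom"] != rh["tchrom"] or lh["orient"] != rh["orient"]:
                continue
            if lh["orient"] == "+":
                gap = rh["tstart"] - lh["tend"]
            else:
                # flanks map in reversed order on the minus strand
                gap = lh["tstart"] - rh["tend"]
            if 0 <= gap < max_interval:
                return True
    return False


def pair_flank_hits(hits: pd.DataFrame, locus_ids: Sequence[str],
                    max_interval: int = MAX_INTERVAL) -> dict[str, frozenset[str]]:
    """Species conserving each locus, by the left/right pairing rule.

    ``hits`` columns: locus, side ("left"/"right"), species, tchrom,
    tstart, tend, orient ("+"/"-").  A species counts once per locus no
    matter how many qualifying pairs exist.  Loci absent from the table get
    an empty species set (category 0).
    """
    if len(hits):
        if ((hits["tend"] <= hits["tstart"]).any()
                or (hits["tstart"] < 0).any()):
            raise CoordinateError("malformed hit coordinates (tend <= tstart or negative)")
        bad_side = set(hits["side"]) - {"left", "right"}
        if bad_side:
            raise ValueError(f"unknown flank side(s): {sorted(bad_side)}")
    out: dict[str, set[str]] = {str(l): set() for l in locus_ids}
    if len(hits):
        for (locus, species), group in hits.groupby(["locus", "species"], sort=False):
            if locus not in out:
                continue
            left = group[group["side"] == "left"]
            right = group[group["side"] == "right"]
            if len(left) and len(right) and _pairs_qualify(left, right, max_interval):
                out[str(locus)].add(str(species))
    return {l: frozenset(s) for l, s in out.items()}


class ScoreTrack:
    """Per-base score lookups over sorted, non-overlapping bedGraph intervals."""

    def __init__(self, frame: pd.DataFrame):
        # columns: chrom, start, end, value
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, g in frame.groupby("chrom"):
            g = g.sort_values("start")
            starts = g["start"].to_numpy(int)
            ends = g["end"].to_numpy(int)
            if np.any(ends[:-1] > starts[1:]) or np.any(ends <= starts):
                raise CoordinateError(f"score track intervals overlap or are empty on {chrom}")
            self._by_chrom[str(chrom)] = (starts, ends, g["value"].to_numpy(float))

    def sum_count(self, chrom: str, lo: int, hi: int) -> tuple[float, int]:
        """(sum of per-base scores, number of scored bases) in [lo, hi)."""
        if chrom not in self._by_chrom or hi <= lo:
            return 0.0, 0
        starts, ends, values = self._by_chrom[chrom]
        i = int(bisect_right(ends, lo))
        j = int(bisect_left(starts, hi))
        total, count = 0.0, 0
        for k in range(i, j):
            ov = min(int(ends[k]), hi) - max(int(starts[k]), lo)
            if ov > 0:
                total += values[k] * ov
                count += ov
        return total, count


def mean_flank_score(locus: SSRLocus, track: ScoreTrack,
                     flank: int = FLANK_LEN) -> float:
    """Mean per-base score over the two flanks; NaN when nothing is scored.

    Bases without a score are simply skipped; the left flank is clipped at
    position 0.
    """
    total, count = 0.0, 0
    for lo, hi in ((max(0, locus.start - flank), locus.start),
                   (locus.end, locus.end + flank)):
        s, c = track.sum_count(locus.chrom, lo, hi)
        total += s
        count += c
    return total / count if count else float("nan")


def conservation_calls(hits: pd.DataFrame, loci: Sequence[SSRLocus],
                       track: Optional[ScoreTrack] = None,
                       max_interval: int = MAX_INTERVAL,
                       flank: int = FLANK_LEN) -> list[ConservationCall]:
    species = pair_flank_hits(hits, [l.locus_id for l in loci], max_interval)
    calls = []
    for locus in loci:
        score = mean_flank_score(locus, track, flank) if track is not None else float("nan")
        calls.append(ConservationCall(locus.locus_id, species[locus.locus_id], score))
    return calls


def category_summary(calls: Sequence[ConservationCall],
                     n_species: int = 14) -> pd.DataFrame:
    """Counts and score quartiles per conservation category 0..n_species."""
    frame = pd.DataFrame({
        "category": [c.category for c in calls],
        "score": [c.mean_score for c in calls],
    })
    rows = []
    for cat in range(n_species + 1):
        sub = frame.loc[frame["category"] == cat, "score"].dropna()
        rows.append({
            "category": cat,
            "n_loci": int((frame["category"] == cat).sum()),
            "score_q1": sub.quantile(0.25) if len(sub) else float("nan"),
            "score_median": sub.median() if len(sub) else float("nan"),
            "score_q3": sub.quantile(0.75) if len(sub) else float("nan"),
        })
    return pd.DataFrame(rows).set_index("category")
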