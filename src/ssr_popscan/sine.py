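"""SSR enrichment in the vicinity of SINE retrotransposon boundaries.

For every SINE copy, the 200 bp outside each element end is split into ten
non-overlapping 20 bp windows indexed by distance to the boundary (bin 1 is
the nearest).  Windows accumulate SSR bp by overlap; the per-bin density is
pooled SSR bp over pooled window bp across all copies, with window bp clipped
at chromosome ends excluded from the denominator.  The genome-wide SSR
fraction serves as the flat control against which enrichment is judged.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import pandas as pd

from .errors import CoordinateError
from .scan import SSRLocus, density_stats


class _Coverage:
    """Overlap-length queries against a set of non-overlapping sorted loci."""

    def __init__(self, loci: Sequence[SSRLocus]):
        self._by_chrom: dict[str, tuple[list[int], list[int]]] = {}
        for locus in loci:
            starts, ends = self._by_chrom.setdefault(locus.chrom, ([], []))
            starts.append(locus.start)
            ends.append(locus.end)

    def bp_in(self, chrom: str, lo: int, hi: int) -> int:
        if chrom not in self._by_chrom or hi <= lo:
            return 0
        starts, ends = self._by_chrom[chrom]
        i = bisect_right(ends, lo)
        j = bisect_left(starts, hi)
        return sum(min(ends[k], hi) - max(starts[k], lo) for k in range(i, j))


@dataclass
class EnrichmentProfile:
    """Windowed SSR length density around SINE boundaries."""

    windows: pd.DataFrame  # columns: bin, ssr_bp, window_bp, density
    control: float  # genome-wide SSR fraction
    motif: Optional[str] = None


def _window_bounds(sine: tuple[str, int, int], side: str, b: int, window: int,
                   chrom_len: int) -> tuple[int, int]:
    chrom, start, end = sine
    if side == "left":  # upstream of the 5' boundary; bin b nearest the element
        lo, hi = start - b * window, start - (b - 1) * window
    else:
        lo, hi = end + (b - 1) * window, end + b * window
    return max(0, lo), min(chrom_len, hi)


def enrichment_profile(loci: Sequence[SSRLocus],
                       sine_intervals: Sequence[tuple[str, int, int]],
                       chrom_lengths: Mapping[str, int],
                       flank: int = 200, window: int = 20,
                       motif: Optional[str] = None) -> EnrichmentProfile:
    """Pooled per-bin SSR density over all SINE copies.

    ``motif`` restricts both the windowed bp and the control density to one
    canonical motif class.
    """
    if flank % window:
        raise ValueError(f"flank {flank} is not a multiple of window {window}")
    for chrom, start, end in sine_intervals:
        if end <= start:
            raise CoordinateError(f"degenerate SINE interval {chrom}:{start}-{end}")
        if chrom not in chrom_lengths:
            raise CoordinateError(f"SINE on unknown chromosome {chrom!r}")
    stats = density_stats(loci, chrom_lengths)
    if motif is None:
        selected = list(loci)
        control = stats["genome_fraction"]
    else:
        selected = [l for l in loci if l.motif.canonical == motif]
        control = float(stats["per_motif_fraction"].get(motif, 0.0))
    cov = _Coverage(selected)
    n_bins = flank // window
    ssr_bp = [0] * n_bins
    window_bp = [0] * n_bins
    for sine in sorted(sine_intervals):
        chrom_len = chrom_lengths[sine[0]]
        for side in ("left", "right"):
            for b in range(1, n_bins + 1):
                lo, hi = _window_bounds(sine, side, b, window, chrom_len)
                if hi <= lo:
                    continue
                window_bp[b - 1] += hi - lo
                ssr_bp[b - 1] += cov.bp_in(sine[0], lo, hi)
    frame = pd.DataFrame({
        "bin": range(1, n_bins + 1),
        "ssr_bp": ssr_bp,
        "window_bp": window_bp,
        "density": [s / w if w else float("nan") for s, w in zip(ssr_bp, window_bp)],
    })
    return EnrichmentProfile(windows=frame, control=control, motif=motif)


def profile_by_motif(loci: Sequence[SSRLocus],
                     sine_intervals: Sequence[tuple[str, int, int]],
                     chrom_lengths: Mapping[str, int],
                     flank: int = 200, window: int = 20) -> dict[str, EnrichmentProfile]:
    motifs = sorted({l.motif.canonical for l in loci})
    return {m: enrichment_profile(loci, sine_intervals, chrom_lengths, flank, window, m)
            for m in motifs}


def top_enriched_motifs(profiles: Mapping[str, EnrichmentProfile], k: int = 6) -> list[str]:
    """Motifs ranked by peak window density relative to their genome-wide
    density; ties broken lexicographically.  Returns all motifs if ``k``
    exceeds the motif count."""
    scored = []
    for name in sorted(profiles):
        prof = profiles[name]
        peak = prof.windows["density"].max()
        ratio = peak / prof.control if prof.control else float("inf")
        scored.append((-ratio, name))
    scored.sort()
    return [name for _, name in scored[:k]]
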