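"""Loss-of-function candidate classification for polymorphic SSR alleles.

A non-reference allele of a repeat inside coding sequence shifts the reading
frame when its length change is not a multiple of 3; a repeat overlapping
the first or last 2 bp of an intron can disturb the donor or acceptor splice
site regardless of frame.  Splice-site sides are strand-aware: on the minus
strand the donor dinucleotide sits at the genomic right end of the intron.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .annotate import RegionModel, Transcript, _hits
from .errors import InvalidAlleleError
from .scan import SSRLocus

SPLICE_CORE = 2  # bp of intron end treated as the donor/acceptor site


@dataclass(frozen=True)
class LofCall:
    locus_id: str
    allele: int  # bp length of the non-reference allele
    transcript: Optional[str]
    consequence: str  # frameshift | splice_donor | splice_acceptor | inframe | none
    detail: str = ""


def _splice_sites(tx: Transcript) -> list[tuple[int, int, str, int]]:
    """(start, end, kind, intron_index) for each intron's 2 bp core sites."""
    sites = []
    introns = tx.introns if tx.strand == "+" else list(reversed(tx.introns))
    for idx, (s, e) in enumerate(introns, start=1):
        if tx.strand == "+":
            donor, acceptor = (s, min(s + SPLICE_CORE, e)), (max(e - SPLICE_CORE, s), e)
        else:
            donor, acceptor = (max(e - SPLICE_CORE, s), e), (s, min(s + SPLICE_CORE, e))
        sites.append((donor[0], donor[1], "splice_donor", idx))
        sites.append((acceptor[0], acceptor[1], "splice_acceptor", idx))
    return sites


def classify_lof(locus: SSRLocus, alleles: Sequence[int],
                 model: RegionModel) -> list[LofCall]:
    """One call per (non-reference allele, overlapping transcript).

    The reference allele is the locus tract length and must be present in
    ``alleles``.  Frameshift requires the tract to overlap CDS and a length
    delta with ``delta % 3 != 0``; an in-frame CDS change is reported as
    ``inframe``; splice-site overlap is reported when the frame is intact
    (or the locus is outside CDS).  Loci outside any transcript yield
    ``none`` calls with no transcript.
    """
    period = locus.motif.period
    for allele in alleles:
        if allele < period:
            raise InvalidAlleleError(
                f"allele {allele} bp shorter than one {period} bp unit at {locus.locus_id}")
    if locus.ref_len not in alleles:
        raise InvalidAlleleError(f"reference allele missing for {locus.locus_id}")
    alts = sorted({int(a) for a in alleles if a != locus.ref_len})
    transcripts = model.overlapping(locus.chrom, locus.start, locus.end)
    calls: list[LofCall] = []
    for allele in alts:
        delta = allele - locus.ref_len
        emitted = False
        for tx in transcripts:
            in_cds = _hits(tx.cds, locus.start, locus.end)
            splice = next(((kind, idx) for s, e, kind, idx in _splice_sites(tx)
                           if s < locus.end and e > locus.start), None)
            if in_cds and delta % 3 != 0:
                calls.append(LofCall(locus.locus_id, allele, tx.tid, "frameshift",
                                     f"delta={delta:+d}"))
            elif splice is not None:
                kind, idx = splice
                calls.append(LofCall(locus.locus_id, allele, tx.tid, kind,
                                     f"intron={idx};delta={delta:+d}"))
            elif in_cds:
                calls.append(LofCall(locus.locus_id, allele, tx.tid, "inframe",
                                     f"delta={delta:+d}"))
            else:
                calls.append(LofCall(locus.locus_id, allele, tx.tid, "none"))
            emitted = True
        if not emitted:
            calls.append(LofCall(locus.locus_id, allele, None, "none"))
    return calls


def lof_table(loci: Sequence[SSRLocus], alleles_by_locus: dict[str, Sequence[int]],
              model: RegionModel) -> pd.DataFrame:
    rows = []
    for locus in loci:
        alleles = alleles_by_locus.get(locus.locus_id)
        if alleles is None:
            continue
        for call in classify_lof(locus, alleles, model):
            rows.append({"locus_id": call.locus_id, "allele": call.allele,
                         "transcript": call.transcript,
                         "consequence": call.consequence, "detail": call.detail})
    return pd.DataFrame(rows, columns=["locus_id", "allele", "transcript",
                                       "consequence", "detail"])
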