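"""Reference summary counts from the genome-wide porcine SSR survey.

These are the published headline tallies for Sus scrofa assembly 10.2 and
its population resequencing panel.  They are inputs for internal-consistency
checks (per-class sums and percentages recomputed by the package's own
routines); desk-scale runs cannot regenerate them, since they require the
full pig assembly and the SRA resequencing panel.
"""

from __future__ import annotations

#: reference-genome SSR counts per period (di..hexa)
GENOME_SSR_COUNTS = {2: 395_943, 3: 209_971, 4: 507_867, 5: 281_380, 6: 225_308}
#: reported genome-wide SSR total
GENOME_SSR_TOTAL = 1_620_469

#: high-quality polymorphic SSR counts per period
HQ_PSSR_COUNTS = {2: 7_032, 3: 2_379, 4: 5_026, 5: 1_579, 6: 511}
#: reported high-quality pSSR total
HQ_PSSR_TOTAL = 16_527

#: genotyped loci across the 102-individual panel
N_GENOTYPED_LOCI = 1_343_193
#: loci with at least two observed alleles (polymorphic SSRs)
N_PSSR = 630_906
#: pSSRs overlapping at least one dbSNP indel
N_PSSR_INDEL_OVERLAP = 280_375
#: high-quality pSSRs overlapping at least one dbSNP indel
N_HQ_INDEL_OVERLAP = 13_542
#: linkage-map microsatellite markers with coordinates / overlapping a pSSR
N_LINKAGE_MARKERS = 887
N_LINKAGE_MARKERS_OVERLAP = 736
#: genotyped loci with call rate >= 0.6 / mean coverage >= 3
N_CALL_RATE_GE_06 = 820_354
N_COVERAGE_GE_3 = 463_793


def percentage(part: float, whole: float, digits: int = 2) -> float:
    """Percentage of ``part`` in ``whole``, rounded to ``digits`` places."""
    if whole == 0:
        raise ZeroDivisionError("percentage of an empty total is undefined")
    return round(100.0 * part / whole, digits)
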