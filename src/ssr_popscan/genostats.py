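"""Per-locus population statistics from diploid STR genotype calls.

Genotype tables hold one row per called sample x locus with two allele
lengths (total repeat-tract bp), the allelotype likelihood-ratio score Q and
the supporting read count; missing calls are absent rows.  A locus is
polymorphic (a pSSR) when at least two distinct alleles are observed over
the called chromosomes.  High-quality pSSRs must additionally clear, with
the stated boundary semantics: mean coverage strictly > 3x, mean
-log10(1-Q) strictly > 0.6, call rate >= 0.6, reference tract <= 80 bp and
minor allele frequency strictly > 0.1.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConsistencyError
from .scan import SSRLocus

GENOTYPE_COLUMNS = ["sample", "locus", "allele_a", "allele_b", "q", "reads"]


@dataclass(frozen=True)
class LocusStats:
    locus_id: str
    n_called: int
    call_rate: float
    mean_coverage: float
    mean_neglog1mq: float
    allele_freqs: Mapping[int, float]
    n_alleles: int
    maf: float
    het_obs: float
    pic: float


def locus_stats(calls: pd.DataFrame, n_samples_total: int) -> LocusStats:
    """Summarise one locus from its called rows.

    Allele frequencies are counted over ``2 * n_called`` chromosomes; PIC is
    the expected-heterozygosity form ``1 - sum(p_i^2)``; MAF is the
    frequency of the second-most-frequent allele (0 for monomorphic loci).
    """
    n_called = len(calls)
    if n_called == 0:
        raise ValueError("locus has no calls; report as uncalled instead")
    if n_samples_total < n_called:
        raise ValueError("n_samples_total smaller than number of calls")
    locus_id = str(calls["locus"].iloc[0])
    alleles = Counter(calls["allele_a"].astype(int)) + Counter(calls["allele_b"].astype(int))
    n_chrom = 2 * n_called
    freqs = {int(a): c / n_chrom for a, c in sorted(alleles.items())}
    by_freq = sorted(freqs.values(), reverse=True)
    maf = by_freq[1] if len(by_freq) > 1 else 0.0
    het_obs = float((calls["allele_a"] != calls["allele_b"]).mean())
    pic = 1.0 - sum(p * p for p in freqs.values())
    q = np.asarray(calls["q"], dtype=float)
    return LocusStats(
        locus_id=locus_id,
        n_called=n_called,
        call_rate=n_called / n_samples_total,
        mean_coverage=float(calls["reads"].sum()) / n_called,
        mean_neglog1mq=float(np.mean(-np.log10(1.0 - q))),
        allele_freqs=freqs,
        n_alleles=len(freqs),
        maf=maf,
        het_obs=het_obs,
        pic=pic,
    )


def locus_stats_table(calls: pd.DataFrame, n_samples_total: int) -> pd.DataFrame:
    """Per-locus statistics for a whole genotype table (indexed by locus)."""
    rows = []
    for _, group in calls.groupby("locus", sort=True):
        s = locus_stats(group, n_samples_total)
        rows.append({
            "locus_id": s.locus_id, "n_called": s.n_called, "call_rate": s.call_rate,
            "mean_coverage": s.mean_coverage, "mean_neglog1mq": s.mean_neglog1mq,
            "n_alleles": s.n_alleles, "maf": s.maf, "het_obs": s.het_obs, "pic": s.pic,
        })
    return pd.DataFrame(rows).set_index("locus_id")


def is_polymorphic(stats) -> bool:
    """True iff the locus shows at least two alleles."""
    n = stats.n_alleles if isinstance(stats, LocusStats) else stats["n_alleles"]
    return int(n) >= 2


def filter_high_quality(stats: pd.DataFrame, loci: Sequence[SSRLocus],
                        min_cov: float = 3.0, min_neglog1mq: float = 0.6,
                        min_call_rate: float = 0.6, max_ref_len: int = 80,
                        min_maf: float = 0.1) -> set[str]:
    """Locus ids passing every quality criterion and polymorphism.

    Boundary semantics follow the stated criteria wording: coverage and
    mean -log10(1-Q) and MAF are strict inequalities; call rate and
    reference length are inclusive.
    """
    ref_len = {l.locus_id: l.ref_len for l in loci}
    missing = set(stats.index) - set(ref_len)
    if missing:
        raise ConsistencyError(f"loci in stats but not in catalogue: {sorted(missing)[:5]}")
    passing = set()
    for locus_id, row in stats.iterrows():
        if (row["mean_coverage"] > min_cov
                and row["mean_neglog1mq"] > min_neglog1mq
                and row["call_rate"] >= min_call_rate
                and ref_len[locus_id] <= max_ref_len
                and row["maf"] > min_maf
                and row["n_alleles"] >= 2):
            passing.add(str(locus_id))
    return passing


def summarize_catalogue(stats: pd.DataFrame, loci: Sequence[SSRLocus],
                        calls: pd.DataFrame) -> dict:
    """Population-level summaries over a genotyped catalogue.

    Returns per-sample called-locus counts, per-locus called-sample counts,
    mean allele number binned by reference repeat count within each period,
    per-motif-class distributions of allele number / MAF / PIC, and the
    polymorphic proportion per motif class.
    """
    meta = pd.DataFrame({
        "locus_id": [l.locus_id for l in loci],
        "motif": [l.motif.canonical for l in loci],
        "period": [l.motif.period for l in loci],
        "repeat_count": [l.repeat_count for l in loci],
    }).set_index("locus_id")
    joined = stats.join(meta, how="inner")
    per_sample = calls.groupby("sample").size().rename("n_loci_called").sort_index()
    per_locus = calls.groupby("locus").size().rename("n_samples_called").sort_index()
    by_repeat = (joined.groupby(["period", "repeat_count"])["n_alleles"]
                 .mean().rename("mean_allele_number").reset_index())
    per_motif = (joined.groupby(["period", "motif"])
                 .agg(n_loci=("n_alleles", "size"),
                      mean_allele_number=("n_alleles", "mean"),
                      mean_maf=("maf", "mean"),
                      mean_pic=("pic", "mean"),
                      pssr_proportion=("n_alleles", lambda s: float((s >= 2).mean())))
                 .reset_index())
    return {"per_sample": per_sample, "per_locus": per_locus,
            "allele_number_by_repeat": by_repeat, "per_motif": per_motif}


def reference_repeat_bins(loci: Sequence[SSRLocus]) -> pd.Series:
    """Reference repeat count keyed by locus id (helper for plots/joins)."""
    return pd.Series({l.locus_id: l.repeat_count for l in loci}, dtype=int)
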