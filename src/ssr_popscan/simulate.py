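"""Synthetic-data generator with planted ground truth.

Produces every input the pipeline consumes -- a genome with planted perfect
SSRs, gene models, SINE copies with repeat-enriched boundaries,
breed-structured diploid genotype tables with per-call quality and
coverage, cross-species flank-hit tables and a conservation score track --
together with exact truth tables.  Background sequence is re-sampled
wherever an unplanned repeat would meet the scanner thresholds, so scanner
recovery of the planted catalogue is an exact test, not a statistical one.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

import math
from bisect import bisect_left, insort
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .annotate import RegionModel, Transcript
from .errors import SimulationError
from .genostats import locus_stats
from .motifs import canonical_motif, orbit
from .scan import SSRLocus, min_repeats_for_period, scan_sequence

# ---------------------------------------------------------------------------
# configuration


@dataclass
class GenomePlan:
    n_chroms: int = 2
    chrom_length: int = 1_000_000
    gc: float = 0.42  # genome-wide GC fraction of the background


@dataclass
class SSRPlan:
    #: planted locus count per period
    counts: dict = field(default_factory=lambda: {2: 150, 3: 120, 4: 110, 5: 70, 6: 50})
    #: repeat-count range (inclusive) per period
    repeat_range: dict = field(default_factory=lambda: {
        2: (5, 20), 3: (4, 12), 4: (3, 10), 5: (3, 8), 6: (3, 6)})
    #: motif-class weights per period; A/T-rich classes dominate, CG-containing
    #: classes are rare, mirroring mammalian genome composition
    motif_weights: dict = field(default_factory=lambda: {
        2: {"AC": 0.46, "AT": 0.30, "AG": 0.21, "CG": 0.03},
        3: {"AAC": 0.30, "AAT": 0.27, "AAG": 0.12, "AGG": 0.10, "AGC": 0.09,
            "ACC": 0.07, "CCG": 0.03, "ACG": 0.02, "AGT": 0.05, "ACT": 0.05},
        4: {"AAAT": 0.28, "AAAC": 0.18, "AAAG": 0.15, "AATG": 0.13,
            "ACAT": 0.13, "AAGG": 0.13},
        5: {"AAAAT": 0.32, "AAAAC": 0.22, "AAAAG": 0.18, "AATAG": 0.28},
        6: {"ACAGCC": 0.33, "AAAAAT": 0.25, "AAAAAC": 0.22, "AATAAG": 0.20}})
    #: number of dinucleotide loci planted with reference tracts > 80 bp
    n_long: int = 4
    long_repeat_range: tuple = (45, 55)


@dataclass
class GenePlan:
    n_genes: int = 30
    #: fraction of the trinucleotide quota planted inside 5' UTRs
    utr5_tri_fraction: float = 0.10
    minus_strand_fraction: float = 0.4


@dataclass
class SINEPlan:
    n_sines: int = 40
    sine_length: int = 300
    #: extra loci planted within 40 bp of SINE boundaries
    n_boundary_ssrs: int = 40
    boundary_motifs: tuple = ("AAAT", "AAAC", "AAAG", "AAAAT", "AAC")
    boundary_zone: int = 40


@dataclass
class PopPlan:
    #: breed -> (group, n_samples, planted per-genotype heterozygosity)
    breeds: dict = field(default_factory=lambda: {
        "Meishan": ("CH", 2, 0.25), "Jinhua": ("CH", 2, 0.25),
        "Tongcheng": ("CH", 2, 0.25), "Xiang": ("CH", 2, 0.25),
        "Duroc": ("EU", 2, 0.10), "Landrace": ("EU", 2, 0.10),
        "LargeWhite": ("EU", 2, 0.10), "Pietrain": ("EU", 2, 0.10)})
    missing_rate: float = 0.10
    coverage_lambda: float = 6.0  # passing loci: reads ~ 1 + Poisson(lambda)
    q_pass: tuple = (0.80, 0.99)
    q_fail: tuple = (0.30, 0.60)
    #: fraction of genotyped loci engineered to pass the high-quality filter
    hq_fraction: float = 0.6
    #: lognormal sigma of group- and breed-level allele-frequency divergence;
    #: strong breed-level drift keeps each breed's two samples more similar
    #: to each other than to any other breed, as in real closed breeds
    group_sigma: float = 1.5
    breed_sigma: float = 1.5
    #: fraction of loci given one non-unit-length allele (frameshift fodder)
    indel_noise: float = 0.0


@dataclass
class ScorePlan:
    base: float = 0.0
    step: float = 0.15  # score increase per conservation category
    jitter: float = 0.01


@dataclass
class SimConfig:
    seed: int = 0
    genome: GenomePlan = field(default_factory=GenomePlan)
    ssr: SSRPlan = field(default_factory=SSRPlan)
    genes: GenePlan = field(default_factory=GenePlan)
    sines: SINEPlan = field(default_factory=SINEPlan)
    pop: PopPlan = field(default_factory=PopPlan)
    score: ScorePlan = field(default_factory=ScorePlan)


SPECIES = ("cattle", "dog", "horse", "cat", "gorilla", "elephant", "wallaby",
           "platypus", "rabbit", "sheep", "chimpanzee", "rat", "mouse", "human")

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


# ---------------------------------------------------------------------------
# placement bookkeeping


class _Reserver:
    """Non-overlapping placement of padded intervals on one chromosome."""

    def __init__(self, length: int):
        self.length = length
        self._starts: list[int] = []
        self._ends: list[int] = []

    def is_free(self, start: int, end: int) -> bool:
        if start < 0 or end > self.length:
            return False
        i = bisect_left(self._starts, end)
        return not (i > 0 and self._ends[i - 1] > start)

    def reserve(self, start: int, end: int) -> None:
        # merge with any overlapping neighbours so is_free stays correct
        i = bisect_left(self._starts, start)
        while i > 0 and self._ends[i - 1] >= start:
            i -= 1
            start = min(start, self._starts[i])
            end = max(end, self._ends[i])
            del self._starts[i], self._ends[i]
        while i < len(self._starts) and self._starts[i] <= end:
            end = max(end, self._ends[i])
            del self._starts[i], self._ends[i]
        self._starts.insert(i, start)
        self._ends.insert(i, end)

    def place(self, rng: np.random.Generator, length: int, pad: int,
              lo: int = 0, hi: Optional[int] = None, tries: int = 2000) -> int:
        hi = self.length if hi is None else hi
        for _ in range(tries):
            pos = int(rng.integers(lo, max(lo + 1, hi - length)))
            if self.is_free(pos - pad, pos + length + pad):
                self.reserve(pos - pad, pos + length + pad)
                return pos
        raise SimulationError("could not place an interval; plan too dense for genome size")


# ---------------------------------------------------------------------------
# genome simulation


@dataclass
class SimGenome:
    sequences: dict  # chrom -> str
    chrom_lengths: dict
    truth_loci: list  # list[SSRLocus], sorted, non-overlapping
    transcripts: list  # list[Transcript] (underived copies are fine)
    model: RegionModel
    sine_intervals: list  # (chrom, start, end)
    #: locus ids planted inside 5' UTRs / within SINE boundary zones
    utr5_locus_ids: list
    sine_locus_ids: list


def _gene_transcript(gene_idx: int, chrom: str, start: int, strand: str) -> Transcript:
    """Three-exon coding gene laid out from ``start`` (1.7 kb span)."""
    e1, i1, e2, i2, e3 = (start, start + 300), (start + 300, start + 700), \
        (start + 700, start + 900), (start + 900, start + 1300), (start + 1300, start + 1700)
    cds = [(start + 120, start + 300), e2, (start + 1300, start + 1450)]
    return Transcript(tid=f"tx{gene_idx:03d}", gene_id=f"gene{gene_idx:03d}",
                      chrom=chrom, strand=strand, exons=[e1, e2, e3], cds=cds)

GENE_SPAN = 1700


def _weighted_choice(rng: np.random.Generator, weights: dict) -> str:
    keys = sorted(weights)
    p = np.array([weights[k] for k in keys], dtype=float)
    return keys[int(rng.choice(len(keys), p=p / p.sum()))]


def _random_unit(rng: np.random.Generator, canonical: str) -> str:
    members = sorted(orbit(canonical))
    return members[int(rng.integers(len(members)))]


def simulate_genome(config: SimConfig) -> SimGenome:
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    gp, sp, gep, sip = config.genome, config.ssr, config.genes, config.sines
    chroms = [f"chr{i + 1}" for i in range(gp.n_chroms)]
    chrom_lengths = {c: gp.chrom_length for c in chroms}
    p_bases = np.array([(1 - gp.gc) / 2, gp.gc / 2, gp.gc / 2, (1 - gp.gc) / 2])
    seqs = {c: _BASES[rng.choice(4, size=gp.chrom_length, p=p_bases)].copy()
            for c in chroms}
    reservers = {c: _Reserver(gp.chrom_length) for c in chroms}

    # --- genes, evenly spread, promoter space reserved
    transcripts: list[Transcript] = []
    per_chrom = max(1, gep.n_genes // gp.n_chroms)
    margin = 25_000
    gidx = 0
    for c in chroms:
        spacing = (gp.chrom_length - 2 * margin) // per_chrom
        for k in range(per_chrom):
            if gidx >= gep.n_genes:
                break
            start = margin + k * spacing + int(rng.integers(0, 2000))
            strand = "-" if rng.random() < gep.minus_strand_fraction else "+"
            tx = _gene_transcript(gidx, c, start, strand)
            lo = start - 2000 if strand == "+" else start
            hi = start + GENE_SPAN if strand == "+" else start + GENE_SPAN + 2000
            if reservers[c].is_free(lo - 50, hi + 50):
                reservers[c].reserve(lo - 50, hi + 50)
                transcripts.append(tx)
                gidx += 1
    model = RegionModel([_gene_transcript(int(t.tid[2:]), t.chrom,
                                          t.exons[0][0], t.strand)
                         for t in transcripts], chrom_lengths)

    # --- SINE copies in remaining space; reserve the element plus its
    # 200 bp analysis flanks so nothing else lands there
    sine_intervals: list[tuple[str, int, int]] = []
    for i in range(sip.n_sines):
        c = chroms[i % len(chroms)]
        pos = reservers[c].place(rng, sip.sine_length, pad=260)
        sine_intervals.append((c, pos, pos + sip.sine_length))
    sine_intervals.sort()

    # --- plant SSRs
    truth: list[SSRLocus] = []
    utr5_ids: list[str] = []
    sine_ids: list[str] = []

    def plant(chrom: str, pos: int, unit: str, reps: int) -> SSRLocus:
        tract = (unit * reps).encode("ascii")
        seqs[chrom][pos:pos + len(tract)] = np.frombuffer(tract, dtype=np.uint8)
        locus = SSRLocus(chrom, pos, pos + len(tract), canonical_motif(unit), reps)
        truth.append(locus)
        return locus

    def draw(period: int) -> tuple[str, int]:
        canonical = _weighted_choice(rng, sp.motif_weights[period])
        lo, hi = sp.repeat_range[period]
        lo = max(lo, min_repeats_for_period(period))
        reps = int(rng.integers(lo, hi + 1))
        return _random_unit(rng, canonical), reps

    # SINE-boundary loci: inside the reserved flank zones, within 40 bp;
    # each (copy, side) slot is used at most once
    n_boundary = min(sip.n_boundary_ssrs, 2 * len(sine_intervals))
    for i in range(n_boundary):
        chrom, s, e = sine_intervals[(i // 2) % len(sine_intervals)]
        canonical = sip.boundary_motifs[i % len(sip.boundary_motifs)]
        period = len(canonical)
        reps = min_repeats_for_period(period) + int(rng.integers(0, 3))
        unit = _random_unit(rng, canonical)
        length = period * reps
        offset = int(rng.integers(0, max(1, sip.boundary_zone - length)))
        if i % 2 == 0:
            pos = s - offset - length  # left flank, end within 40 bp of start
        else:
            pos = e + offset  # right flank
        locus = plant(chrom, pos, unit, reps)
        sine_ids.append(locus.locus_id)

    # trinucleotide loci inside 5' UTRs
    n_utr5 = int(round(sp.counts.get(3, 0) * gep.utr5_tri_fraction))
    utr5_zones = [(tx.chrom, iv) for tx in model.transcripts.values()
                  for iv in tx.utr5]
    for i in range(min(n_utr5, len(utr5_zones))):
        chrom, (zs, ze) = utr5_zones[i]
        unit, reps = draw(3)
        reps = min(reps, (ze - zs - 8) // 3)
        if reps < min_repeats_for_period(3):
            reps = min_repeats_for_period(3)
        pos = zs + 4
        locus = plant(chrom, pos, unit, reps)
        reservers[chrom].reserve(pos - 12, pos + reps * 3 + 12)
        utr5_ids.append(locus.locus_id)

    # remaining quota, uniformly placed
    remaining = dict(sp.counts)
    remaining[3] = remaining.get(3, 0) - len(utr5_ids)
    n_long_left = sp.n_long
    for period in sorted(remaining):
        for _ in range(remaining[period]):
            unit, reps = draw(period)
            if period == 2 and n_long_left > 0:
                reps = int(rng.integers(*sp.long_repeat_range))
                n_long_left -= 1
            chrom = chroms[int(rng.integers(len(chroms)))]
            length = period * reps
            pos = reservers[chrom].place(rng, length, pad=12)
            plant(chrom, pos, unit, reps)

    truth.sort(key=SSRLocus.sort_key)

    # --- background cleanup: re-sample any base giving rise to an
    # unplanned (or extended) repeat, keeping planted tracts untouched
    protected = {c: np.zeros(gp.chrom_length, dtype=bool) for c in chroms}
    for locus in truth:
        protected[locus.chrom][locus.start:locus.end] = True
    truth_set = {(l.chrom, l.start, l.end, l.motif.canonical, l.repeat_count)
                 for l in truth}
    for _ in range(100):
        found = []
        for c in chroms:
            found.extend(scan_sequence(seqs[c].tobytes().decode("ascii"), c))
        found_set = {(l.chrom, l.start, l.end, l.motif.canonical, l.repeat_count)
                     for l in found}
        extras = found_set - truth_set
        missing = truth_set - found_set
        if not extras and not missing:
            break
        for chrom, start, end, _, _ in extras:
            mask = ~protected[chrom][start:end]
            idx = np.flatnonzero(mask) + start
            seqs[chrom][idx] = _BASES[rng.integers(0, 4, size=idx.size)]
        for chrom, start, end, _motif, _reps in missing:
            period = len(_motif)
            for lo, hi in ((max(0, start - period), start),
                           (end, min(gp.chrom_length, end + period))):
                mask = ~protected[chrom][lo:hi]
                idx = np.flatnonzero(mask) + lo
                seqs[chrom][idx] = _BASES[rng.integers(0, 4, size=idx.size)]
    else:
        raise SimulationError("background cleanup did not converge")

    sequences = {c: seqs[c].tobytes().decode("ascii") for c in chroms}
    return SimGenome(sequences=sequences, chrom_lengths=chrom_lengths,
                     truth_loci=truth, transcripts=transcripts, model=model,
                     sine_intervals=sine_intervals,
                     utr5_locus_ids=utr5_ids, sine_locus_ids=sine_ids)


# ---------------------------------------------------------------------------
# genotype simulation


_FAIL_CYCLE = ("coverage", "quality", "call_rate", "maf", "monomorphic")


def _target_allele_count(repeat_count: int, period: int,
                         rng: np.random.Generator) -> int:
    """Allele number grows stochastically with the reference repeat count."""
    base = 2 + (repeat_count >= 8) + (repeat_count >= 14)
    return int(min(6, base + rng.integers(0, 2)))


def _one_locus(locus: SSRLocus, intent: str, samples: list, pop: PopPlan,
               groups: dict, rng: np.random.Generator) -> Optional[list]:
    period = locus.motif.period
    ref = locus.ref_len
    n = len(samples)
    if intent == "monomorphic":
        alleles = [ref]
        f_global = np.array([1.0])
    else:
        n_all = _target_allele_count(locus.repeat_count, period, rng)
        deltas = rng.choice(np.array([-3, -2, -1, 1, 2, 3]), size=n_all - 1,
                            replace=False)
        alleles = [ref] + [ref + int(d) * period for d in deltas]
        if min(alleles) < period:
            alleles = [a for a in alleles if a >= period] or [ref]
        if pop.indel_noise and rng.random() < pop.indel_noise:
            alleles.append(ref + period + 1)  # non-unit length change
        n_all = len(alleles)
        f_global = rng.dirichlet(np.full(n_all, 2.0))
        if intent != "maf":
            f_global = 0.55 * f_global + 0.45 / n_all  # keep a real minor allele
    n_all = len(alleles)
    group_factor = {g: np.exp(rng.normal(0.0, pop.group_sigma, n_all))
                    for g in groups}
    breed_freqs = {}
    for breed, (group, _ns, _het) in pop.breeds.items():
        f = f_global * group_factor[group] * np.exp(rng.normal(0.0, pop.breed_sigma, n_all))
        breed_freqs[breed] = f / f.sum()

    if intent == "call_rate":
        n_called = int(math.floor(0.55 * n))
        called_idx = rng.choice(n, size=n_called, replace=False)
    else:
        drop = np.flatnonzero(rng.random(n) < pop.missing_rate)
        max_drop = int(math.floor(0.4 * n))
        drop = drop[:max_drop]
        called_idx = np.array([i for i in range(n) if i not in set(drop.tolist())])
    rows = []
    for i in sorted(called_idx.tolist()):
        sample, breed = samples[i]
        het_p = pop.breeds[breed][2]
        f = breed_freqs[breed]
        if n_all >= 2 and rng.random() < het_p:
            pick = rng.choice(n_all, size=2, replace=False, p=f)
            a, b = alleles[int(pick[0])], alleles[int(pick[1])]
        else:
            a = b = alleles[int(rng.choice(n_all, p=f))]
        rows.append([sample, locus.locus_id, min(a, b), max(a, b), 0.0, 0])
    if intent == "maf":
        for r in rows:
            r[2] = r[3] = alleles[0]
        if len(alleles) > 1:
            rows[0][2], rows[0][3] = min(alleles[0], alleles[1]), max(alleles[0], alleles[1])
    n_called = len(rows)
    if intent == "coverage":
        reads = rng.integers(1, 4, size=n_called)
    else:
        reads = 1 + rng.poisson(pop.coverage_lambda, size=n_called)
    q_lo, q_hi = pop.q_fail if intent == "quality" else pop.q_pass
    qs = rng.uniform(q_lo, q_hi, size=n_called)
    for r, rd, q in zip(rows, reads, qs):
        r[4] = float(q)
        r[5] = int(rd)

    frame = pd.DataFrame(rows, columns=["sample", "locus", "allele_a", "allele_b",
                                        "q", "reads"])
    # call-level criteria only; the reference-length criterion is fixed by
    # the planted tract and handled by the caller's intent assignment
    stats = locus_stats(frame, n)
    passes = (stats.mean_coverage > 3.0 and stats.mean_neglog1mq > 0.6
              and stats.call_rate >= 0.6
              and stats.maf > 0.1 and stats.n_alleles >= 2)
    if passes != (intent == "pass"):
        return None
    return rows


def simulate_genotypes(config: SimConfig, loci: Sequence[SSRLocus]) -> dict:
    """Breed-structured diploid genotype calls with an engineered
    high-quality pass-set.

    Returns ``{"calls": DataFrame, "breed_map": DataFrame, "truth":
    DataFrame}``.  ``truth.intent`` is "pass" for loci engineered to clear
    every high-quality criterion, otherwise the single criterion the locus
    was engineered to fail ("ref_len" for loci whose reference tract
    exceeds 80 bp).
    """
    pop = config.pop
    samples = [(f"{breed}_{i + 1}", breed)
               for breed, (_g, ns, _h) in pop.breeds.items() for i in range(ns)]
    groups = {g for g, _, _ in pop.breeds.values()}
    master = np.random.SeedSequence([config.seed, 2])
    children = master.spawn(len(loci))
    all_rows: list = []
    truth_rows = []
    fail_i = 0
    for idx, locus in enumerate(loci):
        rng = np.random.default_rng(children[idx])
        if locus.ref_len > 80:
            intent = "ref_len"
        elif rng.random() < pop.hq_fraction:
            intent = "pass"
        else:
            intent = _FAIL_CYCLE[fail_i % len(_FAIL_CYCLE)]
            fail_i += 1
        attempt_intent = "pass" if intent == "ref_len" else intent
        for _ in range(200):
            rows = _one_locus(locus, attempt_intent, samples, pop, groups, rng)
            if rows is not None:
                break
        else:
            raise SimulationError(f"could not realise intent {intent!r} at {locus.locus_id}")
        all_rows.extend(rows)
        truth_rows.append({"locus_id": locus.locus_id, "intent": intent})
    calls = pd.DataFrame(all_rows, columns=["sample", "locus", "allele_a",
                                            "allele_b", "q", "reads"])
    breed_map = pd.DataFrame(
        [(s, b, pop.breeds[b][0]) for s, b in samples],
        columns=["sample", "breed", "group"])
    truth = pd.DataFrame(truth_rows).set_index("locus_id")
    return {"calls": calls, "breed_map": breed_map, "truth": truth}


# ---------------------------------------------------------------------------
# conservation simulation


_DECOYS = ("gap_300", "wrong_chrom", "wrong_order", "left_only", "wrong_orient")


def simulate_conservation(config: SimConfig, loci: Sequence[SSRLocus],
                          chrom_lengths: dict) -> dict:
    """Flank-hit tables, a score track and true conservation categories.

    Category cycles 0..14 over loci; hit files contain qualifying
    left/right pairs for exactly the assigned species plus decoy hits that
    violate one pairing rule each (gap of exactly 300 bp, different target
    chromosome, wrong order, unpaired side, mismatched orientation).  The
    score track level increases with the category.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    sc = config.score
    hit_rows = []
    truth_rows = []
    score_rows = []
    covered: dict[str, list] = {c: [] for c in chrom_lengths}
    for idx, locus in enumerate(loci):
        category = idx % (len(SPECIES) + 1)
        conserved = SPECIES[:category]
        for s_i, species in enumerate(SPECIES):
            tchrom = f"{species}_chr1"
            base = 10_000 + idx * 2_000
            gap = int(rng.integers(0, 300))
            minus = (idx + s_i) % 3 == 0
            if species in conserved:
                if minus:
                    hit_rows.append([locus.locus_id, "right", species, tchrom,
                                     base, base + 200, "-"])
                    hit_rows.append([locus.locus_id, "left", species, tchrom,
                                     base + 200 + gap, base + 400 + gap, "-"])
                else:
                    hit_rows.append([locus.locus_id, "left", species, tchrom,
                                     base, base + 200, "+"])
                    hit_rows.append([locus.locus_id, "right", species, tchrom,
                                     base + 200 + gap, base + 400 + gap, "+"])
            elif (idx + s_i) % 4 == 0:  # decoy for a non-conserved species
                kind = _DECOYS[(idx + s_i) % len(_DECOYS)]
                if kind == "gap_300":
                    hit_rows.append([locus.locus_id, "left", species, tchrom,
                                     base, base + 200, "+"])
                    hit_rows.append([locus.locus_id, "right", species, tchrom,
                                     base + 500, base + 700, "+"])
                elif kind == "wrong_chrom":
                    hit_rows.append([locus.locus_id, "left", species, tchrom,
                                     base, base + 200, "+"])
                    hit_rows.append([locus.locus_id, "right", species,
                                     f"{species}_chr2", base + 250, base + 450, "+"])
                elif kind == "wrong_order":
                    hit_rows.append([locus.locus_id, "right", species, tchrom,
                                     base, base + 200, "+"])
                    hit_rows.append([locus.locus_id, "left", species, tchrom,
                                     base + 250, base + 450, "+"])
                elif kind == "left_only":
                    hit_rows.append([locus.locus_id, "left", species, tchrom,
                                     base, base + 200, "+"])
                else:  # wrong_orient
                    hit_rows.append([locus.locus_id, "left", species, tchrom,
                                     base, base + 200, "+"])
                    hit_rows.append([locus.locus_id, "right", species, tchrom,
                                     base + 250, base + 450, "-"])
        level = sc.base + sc.step * category + float(rng.normal(0.0, sc.jitter))
        truth_rows.append({"locus_id": locus.locus_id, "category": category,
                           "score_level": level})
        for lo, hi in ((max(0, locus.start - 200), locus.start),
                       (locus.end, min(chrom_lengths[locus.chrom], locus.end + 200))):
            for s, e in _uncovered(covered[locus.chrom], lo, hi):
                score_rows.append([locus.chrom, s, e, level])
                insort(covered[locus.chrom], (s, e))
    hits = pd.DataFrame(hit_rows, columns=["locus", "side", "species", "tchrom",
                                           "tstart", "tend", "orient"])
    scores = pd.DataFrame(score_rows, columns=["chrom", "start", "end", "value"])
    scores = scores.sort_values(["chrom", "start"]).reset_index(drop=True)
    truth = pd.DataFrame(truth_rows).set_index("locus_id")
    return {"hits": hits, "scores": scores, "truth": truth}


def _uncovered(existing: list, lo: int, hi: int) -> list:
    """Sub-intervals of [lo, hi) not yet covered by ``existing`` (sorted)."""
    out = []
    pos = lo
    for s, e in existing:
        if e <= pos:
            continue
        if s >= hi:
            break
        if s > pos:
            out.append((pos, s))
        pos = max(pos, e)
        if pos >= hi:
            break
    if pos < hi:
        out.append((pos, hi))
    return out
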