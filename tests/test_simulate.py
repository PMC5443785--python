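"""Synthetic-data generator: determinism, planted-truth closure, structure."""

import numpy as np
import pandas as pd
import pytest

from ssr_popscan.conserve import pair_flank_hits
from ssr_popscan.genostats import filter_high_quality, locus_stats_table
from ssr_popscan.popgen import (breed_median_het_ratio, distance_matrix, nj_tree,
                                windowed_het_ratio)
from ssr_popscan.scan import catalogue_genome
from ssr_popscan.simulate import (SimConfig, simulate_genome, simulate_genotypes)


def small_config(seed=3, **ssr_counts):
    cfg = SimConfig(seed=seed)
    cfg.genome.n_chroms = 1
    cfg.genome.chrom_length = 150_000
    cfg.ssr.counts = ssr_counts or {2: 10, 3: 8, 4: 6, 5: 3, 6: 3}
    cfg.ssr.n_long = 1
    cfg.genes.n_genes = 4
    cfg.sines.n_sines = 6
    cfg.sines.n_boundary_ssrs = 6
    return cfg


def as_tuples(loci):
    return [(l.chrom, l.start, l.end, l.motif.canonical, l.repeat_count) for l in loci]


class TestGenomeSimulation:
    def test_deterministic_under_fixed_seed(self):
        a = simulate_genome(small_config())
        b = simulate_genome(small_config())
        assert a.sequences == b.sequences
        assert as_tuples(a.truth_loci) == as_tuples(b.truth_loci)
        c = simulate_genome(small_config(seed=4))
        assert c.sequences != a.sequences

    def test_scanner_recovers_exactly_the_planted_loci(self, sim_genome):
        catalogue = catalogue_genome(sim_genome.sequences)
        assert as_tuples(catalogue) == as_tuples(sim_genome.truth_loci)

    def test_requested_counts_are_planted(self, sim_config, sim_genome):
        per_period = pd.Series([l.motif.period for l in sim_genome.truth_loci]
                               ).value_counts().to_dict()
        expected = dict(sim_config.ssr.counts)
        expected[4] = expected.get(4, 0)
        # boundary loci add tetra/penta/tri motifs on top of the base quota
        total_requested = sum(sim_config.ssr.counts.values()) + \
            min(sim_config.sines.n_boundary_ssrs, 2 * sim_config.sines.n_sines)
        assert sum(per_period.values()) == total_requested

    def test_zero_ssrs_requested_yields_clean_genome(self):
        cfg = small_config()
        cfg.ssr.counts = {}
        cfg.ssr.n_long = 0
        cfg.sines.n_boundary_ssrs = 0
        genome = simulate_genome(cfg)
        assert genome.truth_loci == []
        assert catalogue_genome(genome.sequences) == []

    def test_long_loci_exceed_reference_length_cap(self, sim_config, sim_genome):
        n_long = sum(1 for l in sim_genome.truth_loci if l.ref_len > 80)
        assert n_long == sim_config.ssr.n_long

    def test_truth_loci_non_overlapping_and_sorted(self, sim_genome):
        loci = sim_genome.truth_loci
        for prev, cur in zip(loci, loci[1:]):
            assert (prev.chrom, prev.start) <= (cur.chrom, cur.start)
            if prev.chrom == cur.chrom:
                assert cur.start >= prev.end

    def test_utr5_planted_loci_sit_in_utr5(self, sim_genome):
        from ssr_popscan.annotate import classify_region

        by_id = {l.locus_id: l for l in sim_genome.truth_loci}
        assert sim_genome.utr5_locus_ids
        for locus_id in sim_genome.utr5_locus_ids:
            call = classify_region(by_id[locus_id], sim_genome.model)
            assert call.summary == "UTR5"

    def test_sine_boundary_loci_lie_within_40_bp(self, sim_genome):
        by_id = {l.locus_id: l for l in sim_genome.truth_loci}
        assert sim_genome.sine_locus_ids
        for locus_id in sim_genome.sine_locus_ids:
            locus = by_id[locus_id]
            near = any(locus.chrom == chrom
                       and (0 <= s - locus.end <= 40 or 0 <= locus.start - e <= 40)
                       for chrom, s, e in sim_genome.sine_intervals)
            assert near


class TestGenotypeSimulation:
    def test_deterministic_under_fixed_seed(self):
        cfg = small_config()
        genome = simulate_genome(cfg)
        a = simulate_genotypes(cfg, genome.truth_loci)
        b = simulate_genotypes(cfg, genome.truth_loci)
        assert a["calls"].equals(b["calls"])

    def test_engineered_pass_set_is_exactly_recovered(self, sim_genome, sim_genotypes,
                                                      n_samples):
        stats = locus_stats_table(sim_genotypes["calls"], n_samples)
        passing = filter_high_quality(stats, sim_genome.truth_loci)
        truth = sim_genotypes["truth"]
        assert passing == set(truth.index[truth["intent"] == "pass"])

    def test_zero_missing_rate_gives_full_call_rate(self):
        cfg = small_config()
        cfg.pop.missing_rate = 0.0
        cfg.pop.hq_fraction = 1.0
        genome = simulate_genome(cfg)
        geno = simulate_genotypes(cfg, genome.truth_loci)
        hq = geno["truth"].index[geno["truth"]["intent"] == "pass"]
        counts = geno["calls"].groupby("locus").size()
        n = sum(ns for _g, ns, _h in cfg.pop.breeds.values())
        assert (counts.loc[hq] == n).all()

    def test_monomorphic_intent_yields_single_allele(self, sim_genotypes):
        truth = sim_genotypes["truth"]
        calls = sim_genotypes["calls"]
        mono = truth.index[truth["intent"] == "monomorphic"]
        for locus_id in mono[:10]:
            sub = calls[calls["locus"] == locus_id]
            assert len(set(sub["allele_a"]) | set(sub["allele_b"])) == 1

    def test_nj_tree_clusters_breed_pairs_and_groups(self, sim_genome, sim_genotypes,
                                                     n_samples):
        """End to end: high-quality genotypes separate the two planted
        population groups and pair up breed mates."""
        stats = locus_stats_table(sim_genotypes["calls"], n_samples)
        hq = filter_high_quality(stats, sim_genome.truth_loci)
        calls = sim_genotypes["calls"][sim_genotypes["calls"]["locus"].isin(hq)]
        tree = nj_tree(distance_matrix(calls))
        splits = tree.splits()
        breed_map = sim_genotypes["breed_map"]
        all_samples = set(breed_map["sample"])
        for breed, sub in breed_map.groupby("breed"):
            pair = frozenset(sub["sample"])
            assert pair in splits or frozenset(all_samples - pair) in splits
        for group, sub in breed_map.groupby("group"):
            side = frozenset(sub["sample"])
            assert side in splits or frozenset(all_samples - side) in splits

    def test_windowed_het_ratio_separates_planted_heterozygosity(
            self, sim_genome, sim_genotypes, n_samples):
        stats = locus_stats_table(sim_genotypes["calls"], n_samples)
        hq = filter_high_quality(stats, sim_genome.truth_loci)
        calls = sim_genotypes["calls"][sim_genotypes["calls"]["locus"].isin(hq)]
        breed_map = dict(zip(sim_genotypes["breed_map"]["sample"],
                             sim_genotypes["breed_map"]["group"]))
        windowed = windowed_het_ratio(calls, sim_genome.truth_loci, breed_map,
                                      sim_genome.chrom_lengths)
        medians = breed_median_het_ratio(windowed)
        assert medians["CH"] > medians["EU"]


class TestConservationSimulation:
    def test_categories_recovered_exactly(self, sim_genome, sim_conservation):
        species = pair_flank_hits(sim_conservation["hits"],
                                  [l.locus_id for l in sim_genome.truth_loci])
        recovered = {locus_id: len(s) for locus_id, s in species.items()}
        assert recovered == sim_conservation["truth"]["category"].to_dict()

    def test_decoy_hits_present_but_never_counted(self, sim_conservation):
        """The hit table contains pairs violating the gap/chrom/order rules;
        exact category recovery (above) shows none of them pair."""
        hits = sim_conservation["hits"]
        # at least one decoy with a gap of exactly 300 exists in the table
        gaps = []
        for (locus, species), g in hits.groupby(["locus", "species"]):
            left = g[g["side"] == "left"]
            right = g[g["side"] == "right"]
            for _, lh in left.iterrows():
                for _, rh in right.iterrows():
                    if lh["orient"] == rh["orient"] == "+" and lh["tchrom"] == rh["tchrom"]:
                        gaps.append(rh["tstart"] - lh["tend"])
        assert 300 in gaps

    def test_score_levels_increase_with_category(self, sim_genome, sim_conservation):
        from ssr_popscan.conserve import ScoreTrack, mean_flank_score

        track = ScoreTrack(sim_conservation["scores"])
        truth = sim_conservation["truth"]
        frame = pd.DataFrame({
            "category": truth["category"],
            "score": [mean_flank_score(l, track) for l in sim_genome.truth_loci],
        })
        medians = frame.groupby("category")["score"].median()
        assert (np.diff(medians.to_numpy()) > 0).all()
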